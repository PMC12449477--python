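"""Shared data model for the zonation pipeline.

All spatial coordinates are micrometres (µm) in image convention: x grows
rightward, y grows downward.  Areas are µm².  Gene counts are raw transcript
counts per cell unless a table is explicitly marked as normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


class SchemaError(ValidationError):
    """Raised when a table is missing a required column."""


class DimensionError(ValidationError):
    """Raised when matrix dimensions disagree with feature/cell lists."""


class ConfigError(ValueError):
    """Raised when a marker/panel configuration is inconsistent."""


@dataclass(frozen=True)
class PanelGenes:
    """Ordered gene panel; the background universe for every analysis."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise ValidationError(f"panel gene names not unique: {dupes[:5]}")

    @property
    def size(self) -> int:
        return len(self.names)

    def index_of(self, gene: str) -> int:
        try:
            return self.names.index(gene)
        except ValueError:
            raise ConfigError(f"gene {gene!r} not in panel") from None

    def __contains__(self, gene: object) -> bool:
        return gene in self.names

    def __len__(self) -> int:
        return len(self.names)


class CellTable:
    """Per-cell centroids, areas and a sparse cell × gene count matrix.

    Parameters
    ----------
    cell_ids
        Unique opaque identifiers, one per cell.
    x, y
        Centroid coordinates in µm.
    area
        Cell areas in µm², strictly positive.
    counts
        Sparse (n_cells × n_genes) matrix.  Nonnegative integers unless
        ``normalized=True`` (after total-count normalization counts are
        nonnegative floats).
    genes
        The bound :class:`PanelGenes`.
    """

    def __init__(
        self,
        cell_ids: Sequence[str],
        x: np.ndarray,
        y: np.ndarray,
        area: np.ndarray,
        counts: sp.spmatrix,
        genes: PanelGenes,
        normalized: bool = False,
    ) -> None:
        self.cell_ids = np.asarray(cell_ids, dtype=object)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.area = np.asarray(area, dtype=float)
        self.counts = sp.csr_matrix(counts)
        self.genes = genes
        self.normalized = normalized
        self._validate()

    def _validate(self) -> None:
        n = len(self.cell_ids)
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_id values are not unique")
        for name, arr in (("x", self.x), ("y", self.y), ("area", self.area)):
            if arr.shape != (n,):
                raise DimensionError(f"{name} has shape {arr.shape}, expected ({n},)")
        if n and not np.all(self.area > 0):
            bad = int(np.sum(self.area <= 0))
            raise ValidationError(f"{bad} cells with non-positive area")
        if self.counts.shape != (n, self.genes.size):
            raise DimensionError(
                f"counts shape {self.counts.shape} != (n_cells={n}, "
                f"n_genes={self.genes.size})"
            )
        data = self.counts.data
        if data.size and data.min() < 0:
            raise ValidationError("negative values in count matrix")
        if not self.normalized and data.size:
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integral values in raw count matrix")
            self.counts.data = np.round(data).astype(np.int64)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense per-cell vector for one gene."""
        j = self.genes.index_of(gene)
        return np.asarray(self.counts[:, j].todense()).ravel()

    def subset(self, mask: np.ndarray) -> "CellTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellTable(
            self.cell_ids[idx], self.x[idx], self.y[idx], self.area[idx],
            self.counts[idx], self.genes, normalized=self.normalized,
        )

    def to_anndata(self):
        """Adapter to an :class:`anndata.AnnData` (obs carries x/y/area)."""
        import anndata as ad
        import pandas as pd

        obs = pd.DataFrame(
            {"x": self.x, "y": self.y, "area": self.area},
            index=pd.Index(self.cell_ids.astype(str), name="cell_id"),
        )
        var = pd.DataFrame(index=pd.Index(self.genes.names, name="gene"))
        return ad.AnnData(X=self.counts.copy(), obs=obs, var=var)


@dataclass
class TypeRule:
    """One ordered marker rule: label plus positive/negative marker sets.

    ``mode`` controls the positive-marker combinator: ``"any"`` (one
    positive marker suffices, the common disjunctive panel reading) or
    ``"all"`` (conjunction, used for compound labels such as CXCL13+CD8+).
    Negative markers always require a count of exactly zero.
    """

    label: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()
    mode: str = "any"

    def __post_init__(self) -> None:
        if not self.positive:
            raise ConfigError(f"rule {self.label!r} has no positive markers")
        if self.mode not in ("any", "all"):
            raise ConfigError(f"rule {self.label!r}: mode must be 'any' or 'all'")


UNCLASSIFIED = "U.C."


@dataclass
class MarkerConfig:
    """Ordered cell-typing rules plus the special grid/hot-cold rules."""

    rules: list[TypeRule]
    tumour_positive: tuple[str, ...] = ("CDH1", "SFTPB", "SFTPC")
    tumour_negative: tuple[str, ...] = ("SFTPD",)
    hotcold_gene: str = "CD274"

    def validate_against(self, genes: PanelGenes) -> None:
        for rule in self.rules:
            for g in rule.positive + rule.negative:
                if g not in genes:
                    raise ConfigError(
                        f"rule {rule.label!r} references unknown gene {g!r}"
                    )
        for g in self.tumour_positive + self.tumour_negative + (self.hotcold_gene,):
            if g not in genes:
                raise ConfigError(f"special rule references unknown gene {g!r}")

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "MarkerConfig":
        rules = [
            TypeRule(
                label=entry["label"],
                positive=tuple(entry.get("positive", ())),
                negative=tuple(entry.get("negative", ())),
                mode=entry.get("mode", "any"),
            )
            for entry in cfg.get("cell_types", [])
        ]
        tumour = cfg.get("tumour_rule", {})
        return cls(
            rules=rules,
            tumour_positive=tuple(tumour.get("positive", ("CDH1", "SFTPB", "SFTPC"))),
            tumour_negative=tuple(tumour.get("negative", ("SFTPD",))),
            hotcold_gene=cfg.get("hotcold_gene", "CD274"),
        )


@dataclass
class RegionPolygon:
    """A labelled closed ring in µm, counter-clockwise winding."""

    label: str
    vertices: np.ndarray = field(repr=False)  # (n, 2) without repeated closing vertex

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("polygon vertices must be (n, 2)")
        # drop a repeated closing vertex
        if len(self.vertices) >= 2 and np.allclose(self.vertices[0], self.vertices[-1]):
            self.vertices = self.vertices[:-1]
        if len(self.vertices) < 3:
            raise ValidationError(f"polygon {self.label!r} has <3 distinct vertices")
        from shapely.geometry import Polygon
        from shapely.geometry.polygon import orient

        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValidationError(f"polygon {self.label!r} is self-intersecting")
        # normalize winding to counter-clockwise (positive signed area in the
        # mathematical sense; note y grows downward in image convention)
        oriented = orient(poly, sign=1.0)
        self.vertices = np.asarray(oriented.exterior.coords)[:-1]

    def to_shapely(self):
        from shapely.geometry import Polygon

        return Polygon(self.vertices)
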