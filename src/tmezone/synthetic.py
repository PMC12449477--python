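"""Seeded synthetic-tissue generator.

Emulates the statistical structure the zonation analysis assumes for a
post-treatment tumour section profiled on a targeted in situ panel:

* tumour nests — dense discs of epithelial tumour cells inside a sparser
  stroma of fibroblasts and immune cells;
* a chemokine gradient — immune cells within ``d_peri`` µm of a nest
  boundary express designated chemokine genes (CXCL9/CXCL13 analogues) at a
  fold-change ``peri_fold`` over the baseline rate;
* a hot/cold mosaic — tumour cells carry patch-wise immune-hot
  (CD274-high) or immune-cold (CD274-low, proliferation-high) states;
* optional latent coupling — a designated gene pair shares a per-cell
  latent Poisson intensity, thinned so the count correlation equals a
  target ρ (closed form: thinning a shared Poisson N ~ Poisson(λ/ρ) with
  keep-probability ρ gives two Poisson(λ) marginals with corr exactly ρ).

The generator's geometric truth (distance to the nearest nest boundary) is
computed analytically from the nest circles, independently of the grid
pipeline, so it can serve as ground truth for the code under test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .model import CellTable, MarkerConfig, PanelGenes, RegionPolygon, TypeRule
from . import io as tio


class SpecError(ValueError):
    """Raised when a TissueSpec is internally inconsistent."""


# ---------------------------------------------------------------------------
# default panel: the named markers every analysis touches, padded with
# anonymous filler genes to the 302-gene panel size used as the enrichment
# background.

_NAMED_GENES = [
    # epithelial / tumour
    "CDH1", "KRT5", "KRT8", "KRT14", "KRT17", "EPCAM", "SFTPB", "SFTPC", "SFTPD",
    "FOXA1", "SOX2", "TP63", "EGFR", "ERBB2", "SLC2A1", "TSTD1", "PTP4A1",
    # stromal / structural
    "COL1A1", "PDPN", "LMOD1", "PECAM1", "FSCN1",
    # lymphoid
    "CD3E", "CD4", "CD8A", "CD19", "POU2AF1", "IL2RG", "CXCR6", "GZMB", "IFNG",
    # myeloid / dendritic
    "CD68", "CD163", "MSR1", "MS4A4A", "ITGAX", "HLA-DQB2", "CYTIP", "CCL18",
    # chemokines and receptors
    "CXCL9", "CXCL10", "CXCL13", "CXCL16", "CXCL5", "CXCL14", "CXCR2", "CXCR3",
    "CXCR4", "CCR7", "IL10RB", "IL7R", "IFNGR1", "IFNGR2", "TLR4",
    # checkpoint / immune state
    "CD274", "CTLA4", "IDO1", "LAG3", "TIGIT", "ICOS",
    # proliferation / DNA damage / cold program
    "MKI67", "MYC", "RAD21", "RAD23B", "HMGB1", "VEGFA", "VEGFB", "CTNNB1",
    "OAS2", "IRF1", "IFIH1", "STAT1", "NFKB1", "CIITA", "DDX58", "CGAS",
    "TMEM173", "IRF9", "TLR2", "IL18", "IL33", "CCL2", "CCL3",
]

PANEL_SIZE = 302


def default_panel(size: int = PANEL_SIZE) -> PanelGenes:
    """The default targeted panel: named markers + anonymous filler genes."""
    if size < len(_NAMED_GENES):
        raise SpecError(f"panel size {size} < {len(_NAMED_GENES)} named markers")
    filler = [f"SYN{i:03d}" for i in range(size - len(_NAMED_GENES))]
    return PanelGenes(tuple(_NAMED_GENES + filler))


#: baseline Poisson rate for every (cell, gene) pair not set by a type rule —
#: models low-level off-target / ambient signal.
BACKGROUND_RATE = 0.01

#: per-type marker rates (transcripts per cell); strong markers sit at 3–6
#: counts per cell, the scale at which a count>=2 positivity call is reliable.
DEFAULT_RATES: dict[str, dict[str, float]] = {
    "tumour": {
        "CDH1": 5.0, "KRT8": 3.0, "EPCAM": 3.0, "SFTPB": 3.0, "SFTPC": 3.0,
        "KRT17": 1.0, "MKI67": 0.3, "MYC": 0.5,
    },
    "CAF": {"COL1A1": 6.0, "FSCN1": 1.0},
    "myeloid": {"CD68": 5.0, "CD163": 3.0, "MSR1": 2.0, "ITGAX": 1.5,
                "CXCL9": 2.0, "CXCL10": 1.5, "CXCL16": 1.0},
    "LYM": {"CD3E": 5.0, "CD8A": 3.0, "CD4": 1.5, "IL2RG": 1.5,
            "CXCL13": 2.0, "GZMB": 1.5, "IFNG": 0.8, "CXCR6": 1.0},
    "plasma": {"POU2AF1": 5.0, "CD19": 2.0},
}

DEFAULT_MIXTURE: dict[str, float] = {
    "tumour": 0.30, "LYM": 0.25, "CAF": 0.15, "myeloid": 0.15, "plasma": 0.15,
}

IMMUNE_TYPES = ("LYM", "myeloid", "plasma")
DEFAULT_CHEMOKINES = ("CXCL9", "CXCL13")


def default_marker_config() -> MarkerConfig:
    """Ordered typing rules matching the generator's expression model."""
    return MarkerConfig(
        rules=[
            TypeRule("plasma", ("POU2AF1",)),
            TypeRule("myeloid", ("CD68", "CD163")),
            TypeRule("LYM", ("CD3E", "CD4", "CD8A")),
            TypeRule("CAF", ("COL1A1",)),
            TypeRule("tumour", ("CDH1", "KRT8")),
        ],
    )


@dataclass(frozen=True)
class Nest:
    """A circular tumour nest (centre in µm, radius in µm)."""

    x: float
    y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise SpecError("nest radius must be positive")


@dataclass(frozen=True)
class HotColdSpec:
    """Mosaic hot/cold state of tumour cells, assigned patch-wise."""

    patch_size: float = 100.0       # µm; mosaic granularity
    hot_fraction: float = 0.5
    gene: str = "CD274"
    lam_hot: float = 3.0            # >= 2 so a count>=2 call is recoverable
    lam_cold: float = 0.1           # <= 0.2
    proliferation_gene: str = "MKI67"
    lam_prolif_hot: float = 0.5
    lam_prolif_cold: float = 2.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.hot_fraction <= 1.0:
            raise SpecError("hot fraction must lie in [0, 1]")
        if self.patch_size <= 0:
            raise SpecError("patch size must be positive")


@dataclass(frozen=True)
class CouplingSpec:
    """Latent coupling of a gene pair via shared-Poisson thinning.

    Both genes are redrawn from a shared latent N ~ Poisson(λ/ρ) with
    keep-probability ρ, where λ is ``gene_a``'s per-cell rate after all
    other modifiers; their per-cell count correlation is then exactly ρ.
    """

    gene_a: str = "CXCL9"
    gene_b: str = "CXCL10"
    rho: float = 0.74

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise SpecError("coupling rho must lie in [0, 1]")


@dataclass
class TissueSpec:
    """Full description of one synthetic tissue."""

    field_size: tuple[float, float] = (1200.0, 1200.0)
    n_cells: int = 20_000
    nests: tuple[Nest, ...] = (Nest(600.0, 600.0, 250.0),)
    mixture: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {t: dict(r) for t, r in DEFAULT_RATES.items()}
    )
    background_rate: float = BACKGROUND_RATE
    chemokine_genes: tuple[str, ...] = DEFAULT_CHEMOKINES
    peri_fold: float = 3.0          # fold-change f near the nest boundary
    d_peri: float = 20.0            # µm; reach of the peri enrichment
    hotcold: HotColdSpec | None = field(default_factory=HotColdSpec)
    coupling: CouplingSpec | None = None
    area_log_mean: float = float(np.log(80.0))   # lognormal cell areas, µm²
    area_log_sd: float = 0.4
    area_min: float = 10.0
    panel_size: int = PANEL_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.mixture.values()))
        if not np.isclose(total, 1.0):
            raise SpecError(f"mixture proportions sum to {total}, not 1")
        if self.n_cells <= 0:
            raise SpecError("n_cells must be positive")
        if self.peri_fold <= 0:
            raise SpecError("peri_fold must be positive")
        w, h = self.field_size
        for nest in self.nests:
            if not (0 <= nest.x - nest.radius and nest.x + nest.radius <= w
                    and 0 <= nest.y - nest.radius and nest.y + nest.radius <= h):
                raise SpecError(f"nest {nest} exceeds field bounds {self.field_size}")
        for t, lams in self.rates.items():
            if any(l < 0 for l in lams.values()):
                raise SpecError(f"negative rate in type {t!r}")


@dataclass
class SyntheticTissue:
    """Generator output: the cell table, nest polygons and the truth record."""

    table: CellTable
    regions: list[RegionPolygon]
    truth: dict


def boundary_distance(x: np.ndarray, y: np.ndarray, nests: Sequence[Nest]) -> np.ndarray:
    """Analytic signed distance (µm) to the nearest nest boundary.

    Negative inside a nest, positive outside; computed from the circle
    geometry, independent of any grid.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d = np.full(x.shape, np.inf)
    for nest in nests:
        d = np.minimum(d, np.hypot(x - nest.x, y - nest.y) - nest.radius)
    return d


def generate_hotcold_labels(
    x: np.ndarray, y: np.ndarray, spec: HotColdSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Patch-wise hot/cold labels for tumour-cell positions.

    The field is tiled with ``patch_size`` squares; each patch is hot with
    probability ``hot_fraction``; a cell inherits its patch's state.
    Returns (labels array of 'hot'/'cold', patch ids).
    """
    px = np.floor(np.asarray(x) / spec.patch_size).astype(np.int64)
    py = np.floor(np.asarray(y) / spec.patch_size).astype(np.int64)
    # dense patch lattice keyed by (px, py); draw states for the occupied range
    if len(px) == 0:
        return np.array([], dtype=object), np.array([], dtype=np.int64)
    nx = int(px.max()) + 1
    ny = int(py.max()) + 1
    states = rng.random((ny, nx)) < spec.hot_fraction
    hot = states[py, px]
    labels = np.where(hot, "hot", "cold").astype(object)
    return labels, py * nx + px


def _sample_in_nests(
    n: int, nests: Sequence[Nest], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    areas = np.array([np.pi * nest.radius**2 for nest in nests])
    which = rng.choice(len(nests), size=n, p=areas / areas.sum())
    r = np.array([nests[i].radius for i in which])
    cx = np.array([nests[i].x for i in which])
    cy = np.array([nests[i].y for i in which])
    rad = r * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return cx + rad * np.cos(theta), cy + rad * np.sin(theta)


def _nest_polygon(nest: Nest, n_vertices: int = 64) -> RegionPolygon:
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    verts = np.column_stack(
        [nest.x + nest.radius * np.cos(theta), nest.y + nest.radius * np.sin(theta)]
    )
    return RegionPolygon(label="tumour", vertices=verts)


def generate_tissue(spec: TissueSpec) -> SyntheticTissue:
    """Generate one tissue realization; identical spec (incl. seed) is
    byte-identical on repeated runs."""
    rng = np.random.default_rng(spec.seed)
    genes = default_panel(spec.panel_size)
    w, h = spec.field_size
    type_names = list(spec.mixture.keys())
    counts_per_type = rng.multinomial(spec.n_cells, [spec.mixture[t] for t in type_names])

    # placement: tumour cells uniform inside nests, everything else CSR over
    # the whole field (simplest null compatible with the downstream tests)
    xs, ys, types = [], [], []
    for t, n_t in zip(type_names, counts_per_type):
        if n_t == 0:
            continue
        if t == "tumour":
            tx, ty = _sample_in_nests(n_t, spec.nests, rng)
        else:
            tx = rng.random(n_t) * w
            ty = rng.random(n_t) * h
        xs.append(tx)
        ys.append(ty)
        types.extend([t] * n_t)
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    cell_type = np.array(types, dtype=object)
    n = len(x)

    dist = boundary_distance(x, y, spec.nests)
    is_immune = np.isin(cell_type, IMMUNE_TYPES)
    peri_enriched = is_immune & (np.abs(dist) < spec.d_peri)

    # per-cell, per-gene Poisson rates
    lam = np.full((n, genes.size), spec.background_rate)
    gene_idx = {g: j for j, g in enumerate(genes.names)}
    for t, gene_rates in spec.rates.items():
        sel = cell_type == t
        for g, l in gene_rates.items():
            lam[sel, gene_idx[g]] = l
    for g in spec.chemokine_genes:
        lam[peri_enriched, gene_idx[g]] *= spec.peri_fold

    tumour_sel = cell_type == "tumour"
    hotcold_labels = np.full(n, "", dtype=object)
    if spec.hotcold is not None:
        hl, _patches = generate_hotcold_labels(
            x[tumour_sel], y[tumour_sel], spec.hotcold, rng
        )
        hotcold_labels[tumour_sel] = hl
        hot = tumour_sel.copy()
        hot[tumour_sel] = hl == "hot"
        cold = tumour_sel & ~hot
        hc = spec.hotcold
        lam[hot, gene_idx[hc.gene]] = hc.lam_hot
        lam[cold, gene_idx[hc.gene]] = hc.lam_cold
        lam[hot, gene_idx[hc.proliferation_gene]] = hc.lam_prolif_hot
        lam[cold, gene_idx[hc.proliferation_gene]] = hc.lam_prolif_cold

    counts = rng.poisson(lam)

    coupling_record: dict | None = None
    if spec.coupling is not None and spec.coupling.rho > 0:
        c = spec.coupling
        ja, jb = gene_idx[c.gene_a], gene_idx[c.gene_b]
        shared = rng.poisson(lam[:, ja] / c.rho)
        counts[:, ja] = rng.binomial(shared, c.rho)
        counts[:, jb] = rng.binomial(shared, c.rho)
        coupling_record = {
            "gene_a": c.gene_a, "gene_b": c.gene_b, "rho": c.rho,
            "construction": "shared-Poisson thinning; count corr == rho exactly",
        }

    areas = np.exp(rng.normal(spec.area_log_mean, spec.area_log_sd, n))
    areas = np.maximum(areas, spec.area_min)

    cell_ids = [f"cell_{i:06d}" for i in range(n)]
    table = CellTable(
        cell_ids=cell_ids, x=x, y=y, area=areas,
        counts=sp.csr_matrix(counts), genes=genes,
    )
    regions = [_nest_polygon(nest) for nest in spec.nests]

    band_edges = [0.0, 20.0, 70.0, 120.0]
    band_names = ["peri", "mid", "distal"]
    true_band = np.full(n, "beyond", dtype=object)
    true_band[dist < 0] = "inside"
    for name, lo, hi in zip(band_names, band_edges[:-1], band_edges[1:]):
        true_band[(dist >= lo) & (dist < hi)] = name

    truth = {
        "spec": _spec_to_jsonable(spec),
        "cell_id": cell_ids,
        "cell_type": cell_type.tolist(),
        "boundary_distance_um": dist.tolist(),
        "true_band": true_band.tolist(),
        "peri_enriched": peri_enriched.tolist(),
        "hotcold": hotcold_labels.tolist(),
        "coupling": coupling_record,
    }
    return SyntheticTissue(table=table, regions=regions, truth=truth)


def _spec_to_jsonable(spec: TissueSpec) -> dict:
    d = asdict(spec)
    d["field_size"] = list(spec.field_size)
    d["nests"] = [asdict(nest) for nest in spec.nests]
    d["mixture"] = dict(spec.mixture)
    d["rates"] = {t: dict(r) for t, r in spec.rates.items()}
    return d


def spec_from_dict(cfg: Mapping) -> TissueSpec:
    """Build a TissueSpec from a plain (YAML-loaded) mapping."""
    kwargs = dict(cfg)
    if "field_size" in kwargs:
        kwargs["field_size"] = tuple(kwargs["field_size"])
    if "nests" in kwargs:
        kwargs["nests"] = tuple(Nest(**nd) for nd in kwargs["nests"])
    if "hotcold" in kwargs and kwargs["hotcold"] is not None:
        kwargs["hotcold"] = HotColdSpec(**kwargs["hotcold"])
    if "coupling" in kwargs and kwargs["coupling"] is not None:
        kwargs["coupling"] = CouplingSpec(**kwargs["coupling"])
    if "chemokine_genes" in kwargs:
        kwargs["chemokine_genes"] = tuple(kwargs["chemokine_genes"])
    return TissueSpec(**kwargs)


def emit_bundle(tissue: SyntheticTissue, out_dir: str | Path) -> dict[str, Path]:
    """Write the standard input bundle plus truth.json."""
    out = Path(out_dir)
    paths = tio.write_cell_bundle(tissue.table, out)
    regions_path = out / "regions.geojson"
    tio.write_polygons(tissue.regions, regions_path)
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(tissue.truth, fh)
    paths["regions"] = regions_path
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# spot-level coupled fields (used to test correlation recovery)

def coupled_spot_maps(
    rho: float, n_spots: int, mean: float = 50.0, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two spot-level count maps whose latent correlation is exactly ``rho``.

    Shared-Poisson thinning: N ~ Poisson(mean/ρ) per spot, each map a
    Binomial(N, ρ) thinning; marginals are Poisson(mean) and the pairwise
    correlation is ρ in closed form (Cov = ρ²·Var(N) = ρ·mean).
    """
    if not 0.0 <= rho <= 1.0:
        raise SpecError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if rho == 0.0:
        return (rng.poisson(mean, n_spots).astype(float),
                rng.poisson(mean, n_spots).astype(float))
    shared = rng.poisson(mean / rho, n_spots)
    a = rng.binomial(shared, rho).astype(float)
    b = rng.binomial(shared, rho).astype(float)
    return a, b
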