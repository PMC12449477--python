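"""End-to-end pipeline orchestration.

One :class:`PipelineConfig` drives the stage chain
simulate (optional) → typecells → density → zonate → cluster → enrich →
hotcold; every stage writes its declared TSV outputs into the run
directory, and a manifest records the effective config, its hash, and the
package version so any output can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import celltyping, density, enrichment, io as tio, synthetic, zonation
from .model import ConfigError

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Fully serializable run configuration (every decision flag included)."""

    out_dir: str = "run"
    # inputs: either a bundle directory, or simulate=True to generate one
    input_dir: str | None = None
    simulate: bool = True
    tissue_spec: dict = field(default_factory=dict)   # overrides for TissueSpec
    seed: int = 0
    # stage parameters
    tau: int = 2                     # per-cell positivity threshold
    spacing: float = 10.0            # zonation grid, µm
    band_edges: tuple[float, ...] = (0.0, 20.0, 70.0, 120.0)
    band_names: tuple[str, ...] = ("peri", "mid", "distal")
    connectivity: int = 8
    contour: str = "first"           # or "largest"
    grid_min_count: int = 1
    k: int = 125                     # spot grid
    quantile: float = 0.95
    alpha: float = 0.05
    hotcold_gene: str = "CD274"
    gmt_path: str | None = None
    compound_classes: tuple[tuple[str, ...], ...] = (("CXCL13", "CD8A"), ("CD8A",))

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_edges"] = list(self.band_edges)
        d["band_names"] = list(self.band_names)
        d["compound_classes"] = [list(c) for c in self.compound_classes]
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "band_edges" in cfg:
            cfg["band_edges"] = tuple(cfg["band_edges"])
        if "band_names" in cfg:
            cfg["band_names"] = tuple(cfg["band_names"])
        if "compound_classes" in cfg:
            cfg["compound_classes"] = tuple(tuple(c) for c in cfg["compound_classes"])
        return cls(**cfg)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _band_partition(config: PipelineConfig) -> zonation.BandPartition:
    edges = config.band_edges
    if len(config.band_names) != len(edges) - 1:
        raise ConfigError("band_names must have one entry fewer than band_edges")
    return zonation.BandPartition(
        tuple(
            zonation.Band(n, float(a), float(b))
            for n, a, b in zip(config.band_names, edges[:-1], edges[1:])
        )
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the stage chain; returns the output directory.

    Identical config (including seed) reproduces every output byte for
    byte.  A stage failure raises :class:`PipelineError` naming the stage;
    the manifest then records the failed stage and marks the run
    incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_jsonable(),
        "config_hash": config_hash(config),
        "version": __version__,
        "stages": [],
        "complete": False,
    }
    stage_name = "setup"

    def _manifest_write() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    try:
        # ---- input ------------------------------------------------------
        if config.simulate:
            stage_name = "simulate"
            t0 = time.monotonic()
            spec_kwargs = dict(config.tissue_spec)
            spec_kwargs.setdefault("seed", config.seed)
            spec = synthetic.spec_from_dict(spec_kwargs)
            tissue = synthetic.generate_tissue(spec)
            synthetic.emit_bundle(tissue, out / "input")
            input_dir = out / "input"
            manifest["stages"].append({"name": "simulate", "n_cells": tissue.table.n_cells,
                                       "seconds": round(time.monotonic() - t0, 3)})
        elif config.input_dir:
            input_dir = Path(config.input_dir)
        else:
            raise ConfigError("config needs input_dir or simulate: true")

        stage_name = "read"
        table = tio.read_cell_bundle(
            input_dir / "cells.csv.gz", input_dir / "matrix.mtx.gz",
            input_dir / "features.tsv", input_dir / "cells.tsv",
        )
        regions = tio.read_polygons(input_dir / "regions.geojson")
        log.info("read %d cells, %d genes, %d regions",
                 table.n_cells, table.genes.size, len(regions))

        # ---- typecells --------------------------------------------------
        stage_name = "typecells"
        t0 = time.monotonic()
        pos = celltyping.call_positivity(table, tau=config.tau)
        calls = celltyping.assign_cell_types(pos, synthetic.default_marker_config())
        calls_out = calls.copy()
        calls_out.insert(0, "cell_id", table.cell_ids.astype(str))
        tio.write_table(calls_out, out / "celltypes.tsv", "celltypes")
        manifest["stages"].append({"name": "typecells",
                                   "seconds": round(time.monotonic() - t0, 3)})

        # ---- density ----------------------------------------------------
        stage_name = "density"
        t0 = time.monotonic()
        region_label = _assign_regions(table, regions)
        if any(region_label != ""):
            prof = density.density(table, "region", regions=region_label)
            rows = [
                {"band": rname, "gene": g, "density": float(v)}
                for rname, row in zip(prof.unit_ids, prof.dense())
                for g, v in zip(table.genes.names, row)
            ]
            tio.write_table(pd.DataFrame(rows), out / "region_density.tsv",
                            "band_profile")
        manifest["stages"].append({"name": "density",
                                   "seconds": round(time.monotonic() - t0, 3)})

        # ---- zonate -----------------------------------------------------
        stage_name = "zonate"
        t0 = time.monotonic()
        grid = zonation.build_grid(table, s=config.spacing)
        rule = synthetic.default_marker_config()
        mask = zonation.smooth_mask(
            zonation.tumour_mask(grid, rule, min_count=config.grid_min_count)
        )
        contour = zonation.extract_contour(mask, which=config.contour)
        dfield = zonation.distance_field(
            mask, contour, spacing=config.spacing,
            connectivity=config.connectivity, origin=grid.origin,
        )
        bands = _band_partition(config)
        classes = _compound_classes(pos, config)
        cell_band, profile = zonation.assign_bands(
            table, grid, dfield, bands, cell_classes=classes
        )
        _write_distance_field(out, grid, dfield, bands)
        tio.write_table(
            pd.DataFrame(
                {"order": np.arange(len(contour.walk)),
                 "iy": [c[0] for c in contour.walk],
                 "ix": [c[1] for c in contour.walk]}
            ),
            out / "contour.tsv", "contour",
        )
        tio.write_table(profile.densities, out / "band_profile.tsv", "band_profile")
        if profile.proportions is not None:
            tio.write_table(profile.proportions, out / "band_proportions.tsv",
                            "band_proportions")
        manifest["stages"].append({"name": "zonate", "grid": [grid.ny, grid.nx],
                                   "contour_cells": int(len(contour.cells)),
                                   "seconds": round(time.monotonic() - t0, 3)})

        # ---- cluster ----------------------------------------------------
        stage_name = "cluster"
        t0 = time.monotonic()
        mat = zonation.band_profile_matrix(profile)
        if len(mat) >= 2:
            dend = zonation.upgmc_cluster(mat, labels=list(mat.index))
            (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        manifest["stages"].append({"name": "cluster",
                                   "seconds": round(time.monotonic() - t0, 3)})

        # ---- enrich -----------------------------------------------------
        stage_name = "enrich"
        t0 = time.monotonic()
        if config.gmt_path:
            norm = enrichment.filter_and_normalize(table)
            sgrid = enrichment.spot_grid(norm, k=config.k)
            degs = enrichment.call_spot_degs(sgrid, q=config.quantile)
            sets = enrichment.read_gmt(config.gmt_path, norm.genes, drop_missing=True)
            emap = enrichment.enrich_spots(degs, sets)
            tio.write_table(emap.to_frame(), out / "enrichment_map.tsv",
                            "enrichment_map")
            corr_rows = []
            for term in emap.terms:
                for gene in ("CXCL13", "CXCL9", "CXCL10"):
                    if gene in norm.genes:
                        r, n = enrichment.correlate_map(
                            emap.term_map(term), sgrid.gene_map(gene)
                        )
                        corr_rows.append({"map_a": term, "map_b": gene,
                                          "r": r, "n_spots": n})
            if corr_rows:
                tio.write_table(pd.DataFrame(corr_rows), out / "correlations.tsv",
                                "correlations")
        manifest["stages"].append({"name": "enrich",
                                   "seconds": round(time.monotonic() - t0, 3)})

        # ---- hotcold ----------------------------------------------------
        stage_name = "hotcold"
        t0 = time.monotonic()
        labels = density.classify_hotcold(table, basis_gene=config.hotcold_gene)
        tio.write_table(labels, out / "hotcold_labels.tsv", "labels")
        tumour_cells = (calls["label"] == "tumour").to_numpy()
        lab = labels["label"].to_numpy(object).copy()
        if tumour_cells.sum() >= 4 and len(set(lab[tumour_cells])) == 2:
            sub = table.subset(tumour_cells)
            contrast = density.hotcold_contrast(sub, lab[tumour_cells], level="cell")
            tio.write_table(contrast, out / "hotcold_comparison.tsv", "comparison")
        manifest["stages"].append({"name": "hotcold",
                                   "seconds": round(time.monotonic() - t0, 3)})

        manifest["complete"] = True
        _manifest_write()
        return out
    except PipelineError:
        _manifest_write()
        raise
    except Exception as exc:
        manifest["failed_stage"] = stage_name
        manifest["error"] = str(exc)
        _manifest_write()
        raise PipelineError(stage_name, exc) from exc


def _assign_regions(table, regions) -> np.ndarray:
    from shapely.geometry import Point
    from shapely.strtree import STRtree

    label = np.full(table.n_cells, "", dtype=object)
    if not regions:
        return label
    polys = [r.to_shapely() for r in regions]
    tree = STRtree(polys)
    pts = [Point(x, y) for x, y in zip(table.x, table.y)]
    for i, pt in enumerate(pts):
        for j in tree.query(pt, predicate="intersects"):
            label[i] = regions[int(j)].label
            break
    return label


def _compound_classes(pos, config: PipelineConfig) -> np.ndarray | None:
    """Class labels such as CXCL13+CD8+ vs CXCL13−CD8+ from positivity calls."""
    try:
        specs = config.compound_classes
        if not specs:
            return None
        classes = np.full(pos.positive.shape[0], "", dtype=object)
        base = specs[-1]           # the broadest class, e.g. ("CD8A",)
        marker = specs[0]          # the refined class, e.g. ("CXCL13","CD8A")
        broad = celltyping.compound_positive(pos, tuple(base))
        fine = celltyping.compound_positive(pos, tuple(marker))
        distinguishing = [g for g in marker if g not in base]
        neg = np.ones_like(broad)
        for g in distinguishing:
            neg &= pos.gene_zero(g)
        classes[broad & neg] = "+".join(base) + "+/" + "-".join(distinguishing) + "-"
        classes[fine] = "+".join(marker) + "+"
        return classes
    except ConfigError:
        return None


def _write_distance_field(out: Path, grid, dfield, bands) -> None:
    xs, ys = grid.centres()
    iy, ix = np.meshgrid(np.arange(grid.ny), np.arange(grid.nx), indexing="ij")
    flat_d = dfield.flat()
    tio.write_table(
        pd.DataFrame(
            {"ix": ix.ravel(), "iy": iy.ravel(),
             "x_centre": xs[ix.ravel()], "y_centre": ys[iy.ravel()],
             "signed_distance": flat_d,
             "band": bands.assign(flat_d)}
        ),
        out / "distance_field.tsv", "distance_field",
    )
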