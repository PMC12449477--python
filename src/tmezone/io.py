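"""Readers and writers for the instrument-style export dialects.

The input bundle mirrors what imaging-based in situ platforms export:

* ``cells.csv[.gz]`` — columns ``cell_id,x_centroid,y_centroid,cell_area``
* ``matrix.mtx[.gz]`` + ``features.tsv`` + ``cells.tsv`` — MatrixMarket
  coordinate-integer triplets with the feature and cell identifier lists
* ``regions.geojson`` — FeatureCollection of labelled polygons (µm)
* ``panel.yaml`` — marker configuration (see :func:`read_marker_config`)

All readers transparently accept gzip-compressed files.
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .model import (
    CellTable,
    ConfigError,
    DimensionError,
    MarkerConfig,
    PanelGenes,
    RegionPolygon,
    SchemaError,
    ValidationError,
)

log = logging.getLogger(__name__)

REQUIRED_CELL_COLUMNS = ("cell_id", "x_centroid", "y_centroid", "cell_area")


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_id_list(path: str | Path) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def read_cell_bundle(
    cells_path: str | Path,
    matrix_path: str | Path,
    features_path: str | Path,
    cell_list_path: str | Path | None = None,
) -> CellTable:
    """Read a cells table plus sparse matrix bundle into a :class:`CellTable`.

    Matrix orientation (genes × cells vs cells × genes) is resolved by
    matching the declared dimensions against the feature list length;
    when both dimensions match (square), genes × cells is preferred, since
    feature-major is the instrument dialect.  The choice is logged.
    """
    cells = pd.read_csv(cells_path)
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cells table missing column(s): {', '.join(missing)}")

    features = _read_id_list(features_path)
    genes = PanelGenes(tuple(features))

    with _open_maybe_gzip(matrix_path, "rb") as fh:
        mat = sp.coo_matrix(scipy.io.mmread(fh))

    n_cells = len(cells)
    n_genes = len(features)
    if mat.shape == (n_genes, n_cells):
        orientation = "genes x cells"
        mat = mat.T
    elif mat.shape == (n_cells, n_genes):
        orientation = "cells x genes"
    else:
        raise DimensionError(
            f"matrix shape {mat.shape} matches neither (genes={n_genes}, "
            f"cells={n_cells}) nor its transpose"
        )
    log.info("matrix read as %s (shape %s)", orientation, mat.shape)

    cell_ids = cells["cell_id"].astype(str).tolist()
    if cell_list_path is not None:
        listed = [str(c) for c in _read_id_list(cell_list_path)]
        if len(listed) != n_cells:
            raise DimensionError(
                f"cell list has {len(listed)} entries, cells table has {n_cells}"
            )
        if listed != cell_ids:
            # matrix columns follow the cell list; reorder to the cells table
            order = {cid: i for i, cid in enumerate(listed)}
            try:
                perm = [order[c] for c in cell_ids]
            except KeyError as exc:
                raise ValidationError(f"cell id {exc} absent from cell list") from None
            mat = sp.csr_matrix(mat)[perm]

    return CellTable(
        cell_ids=cell_ids,
        x=cells["x_centroid"].to_numpy(float),
        y=cells["y_centroid"].to_numpy(float),
        area=cells["cell_area"].to_numpy(float),
        counts=sp.csr_matrix(mat),
        genes=genes,
    )


def read_transcripts(path: str | Path, min_qv: float | None = None) -> pd.DataFrame:
    """Optional transcript-level table (x, y, feature_name, qv).

    ``min_qv`` applies a quality threshold; default off, since whether the
    source analyses filtered on decoding quality is not established.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y", "feature_name", "qv") if c not in df.columns]
    if missing:
        raise SchemaError(f"transcripts table missing column(s): {', '.join(missing)}")
    if min_qv is not None:
        df = df[df["qv"] >= min_qv].reset_index(drop=True)
    return df


def read_polygons(path: str | Path) -> list[RegionPolygon]:
    """Read labelled region polygons from a GeoJSON FeatureCollection."""
    with _open_maybe_gzip(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [doc] if doc.get("type") == "Feature" else [])
    out: list[RegionPolygon] = []
    for feat in feats:
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise TypeError(f"non-polygon geometry: {geom.get('type')!r}")
        ring = geom["coordinates"][0]
        label = str(feat.get("properties", {}).get("label", f"region_{len(out)}"))
        out.append(RegionPolygon(label=label, vertices=np.asarray(ring, float)))
    return out


def write_polygons(polygons: Iterable[RegionPolygon], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"label": p.label},
            "geometry": {
                "type": "Polygon",
                "coordinates": [
                    [[float(x), float(y)] for x, y in p.vertices]
                    + [[float(p.vertices[0, 0]), float(p.vertices[0, 1])]]
                ],
            },
        }
        for p in polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_marker_config(path: str | Path, genes: PanelGenes | None = None) -> MarkerConfig:
    """Read a panel/marker YAML configuration.

    Schema::

        cell_types:            # ordered; first matching rule wins
          - label: epithelial
            positive: [KRT5, CDH1]
            negative: []
            mode: any          # or "all" for compound labels
        tumour_rule:
          positive: [CDH1, SFTPB, SFTPC]
          negative: [SFTPD]
        hotcold_gene: CD274
    """
    with _open_maybe_gzip(path) as fh:
        cfg = yaml.safe_load(fh)
    mc = MarkerConfig.from_dict(cfg)
    if genes is not None:
        mc.validate_against(genes)
    return mc


# ---------------------------------------------------------------------------
# tabular output schemas

#: declared output schemas: name -> (required columns, p/q pairing enforced)
TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "comparison": ("gene", "n_a", "n_b", "mean_a", "mean_b", "t", "p", "q", "d", "flag"),
    "celltypes": ("cell_id", "label", "supporting_markers"),
    "marker_summary": ("group", "marker", "mean", "z", "pct_positive"),
    "labels": ("cell_id", "label"),
    "distance_field": ("ix", "iy", "x_centre", "y_centre", "signed_distance", "band"),
    "contour": ("order", "ix", "iy"),
    "band_profile": ("band", "gene", "density"),
    "band_proportions": ("band", "cell_class", "n_cells", "proportion"),
    "enrichment_map": ("ix", "iy", "term", "minus_log10_q", "minus_log10_p"),
    "correlations": ("map_a", "map_b", "r", "n_spots"),
}

FLOAT_FORMAT = "%.10g"


def write_table(rows: pd.DataFrame, path: str | Path, format: str) -> None:
    """Write a declared output table as TSV with a header.

    Floats are written at %.10g, which round-trips the pipeline's numeric
    range losslessly at that precision.  Any schema containing a ``p``
    column must also carry the BH-adjusted ``q`` column.
    """
    if format not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table schema {format!r}")
    cols = TABLE_SCHEMAS[format]
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise SchemaError(f"{format} table missing column(s): {', '.join(missing)}")
    if "p" in cols and "q" not in rows.columns:
        raise SchemaError(f"{format} table has p-values but no q column")
    rows.loc[:, list(cols)].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_table(path: str | Path, format: str) -> pd.DataFrame:
    if format not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table schema {format!r}")
    return pd.read_csv(path, sep="\t")


def write_cell_bundle(table: CellTable, out_dir: str | Path) -> dict[str, Path]:
    """Write a CellTable as the standard bundle (genes × cells matrix)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells_csv": out / "cells.csv.gz",
        "matrix": out / "matrix.mtx.gz",
        "features": out / "features.tsv",
        "cell_list": out / "cells.tsv",
    }
    pd.DataFrame(
        {
            "cell_id": table.cell_ids.astype(str),
            "x_centroid": table.x,
            "y_centroid": table.y,
            "cell_area": table.area,
        }
    ).to_csv(paths["cells_csv"], index=False, float_format=FLOAT_FORMAT)
    with gzip.open(paths["matrix"], "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(table.counts.T), field="integer")
    paths["features"].write_text("".join(f"{g}\n" for g in table.genes.names))
    paths["cell_list"].write_text(
        "".join(f"{c}\n" for c in table.cell_ids.astype(str))
    )
    return paths
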