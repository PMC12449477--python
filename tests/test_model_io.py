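"""Data-model invariants and bundle/table round-trips."""

import gzip

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tmezone import io as tio
from tmezone.model import (
    CellTable,
    DimensionError,
    PanelGenes,
    RegionPolygon,
    SchemaError,
    ValidationError,
)


def _write_bundle(tmp_path, cells_df, mtx_lines, features):
    cells = tmp_path / "cells.csv"
    cells_df.to_csv(cells, index=False)
    mtx = tmp_path / "matrix.mtx"
    mtx.write_text("\n".join(mtx_lines) + "\n")
    feats = tmp_path / "features.tsv"
    feats.write_text("".join(f"{g}\n" for g in features))
    return cells, mtx, feats


class TestCellTable:
    def test_area_must_be_positive(self):
        with pytest.raises(ValidationError, match="area"):
            CellTable(["a"], [0.0], [0.0], [0.0], sp.csr_matrix((1, 1)),
                      PanelGenes(("g1",)))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="unique"):
            CellTable(["a", "a"], [0, 1], [0, 1], [1, 1],
                      sp.csr_matrix((2, 1)), PanelGenes(("g1",)))

    def test_negative_and_fractional_counts_rejected(self):
        genes = PanelGenes(("g1",))
        with pytest.raises(ValidationError, match="negative"):
            CellTable(["a"], [0.0], [0.0], [1.0],
                      sp.csr_matrix(np.array([[-1.0]])), genes)
        with pytest.raises(ValidationError, match="non-integral"):
            CellTable(["a"], [0.0], [0.0], [1.0],
                      sp.csr_matrix(np.array([[0.5]])), genes)


class TestReadCellBundle:
    def test_triplet_identity_ingest(self, tmp_path):
        # 3 cells x 2 genes, entries (g1,c1)=2 and (g2,c3)=1, genes-major
        cells_df = pd.DataFrame(
            {"cell_id": ["c1", "c2", "c3"], "x_centroid": [0.0, 1.0, 2.0],
             "y_centroid": [0.0, 0.0, 0.0], "cell_area": [1.0, 1.0, 1.0]}
        )
        mtx = ["%%MatrixMarket matrix coordinate integer general",
               "2 3 2", "1 1 2", "2 3 1"]
        paths = _write_bundle(tmp_path, cells_df, mtx, ["g1", "g2"])
        table = tio.read_cell_bundle(*paths)
        dense = np.asarray(table.counts.todense())
        expected = np.array([[2, 0], [0, 0], [0, 1]])
        np.testing.assert_array_equal(dense, expected)
        assert table.genes.size == 2

    def test_orientation_inference_is_deterministic(self, tmp_path):
        cells_df = pd.DataFrame(
            {"cell_id": ["c1", "c2"], "x_centroid": [0.0, 1.0],
             "y_centroid": [0.0, 0.0], "cell_area": [1.0, 1.0]}
        )
        # square 2x2 matrix: ambiguous; genes-major preferred
        mtx = ["%%MatrixMarket matrix coordinate integer general",
               "2 2 1", "1 2 7"]
        paths = _write_bundle(tmp_path, cells_df, mtx, ["g1", "g2"])
        t1 = tio.read_cell_bundle(*paths)
        t2 = tio.read_cell_bundle(*paths)
        np.testing.assert_array_equal(
            np.asarray(t1.counts.todense()), np.asarray(t2.counts.todense())
        )
        # genes-major: entry (gene 1, cell 2) lands on cell c2, gene g1
        assert t1.counts[1, 0] == 7

    def test_missing_column_named_in_error(self, tmp_path):
        cells_df = pd.DataFrame({"cell_id": ["c1"], "x_centroid": [0.0],
                                 "y_centroid": [0.0]})
        mtx = ["%%MatrixMarket matrix coordinate integer general", "1 1 0"]
        paths = _write_bundle(tmp_path, cells_df, mtx, ["g1"])
        with pytest.raises(SchemaError, match="cell_area"):
            tio.read_cell_bundle(*paths)

    def test_dimension_mismatch(self, tmp_path):
        cells_df = pd.DataFrame(
            {"cell_id": ["c1", "c2"], "x_centroid": [0.0, 1.0],
             "y_centroid": [0.0, 0.0], "cell_area": [1.0, 1.0]}
        )
        mtx = ["%%MatrixMarket matrix coordinate integer general", "3 3 0"]
        paths = _write_bundle(tmp_path, cells_df, mtx, ["g1"])
        with pytest.raises(DimensionError):
            tio.read_cell_bundle(*paths)

    def test_roundtrip_preserves_every_entry(self, tmp_path, small_tissue):
        table = small_tissue.table.subset(np.arange(200))
        paths = tio.write_cell_bundle(table, tmp_path / "bundle")
        back = tio.read_cell_bundle(
            paths["cells_csv"], paths["matrix"], paths["features"],
            paths["cell_list"],
        )
        assert back.n_cells == table.n_cells
        assert back.genes.size == table.genes.size
        assert (back.counts != table.counts).nnz == 0


class TestPolygons:
    def test_unit_square_roundtrip(self, tmp_path):
        square = RegionPolygon("roi", np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        path = tmp_path / "regions.geojson"
        tio.write_polygons([square], path)
        polys = tio.read_polygons(path)
        assert len(polys) == 1
        assert polys[0].label == "roi"
        assert len(polys[0].vertices) == 4

    def test_labels_preserved_for_multiple_polygons(self, tmp_path):
        polys = [
            RegionPolygon("a", np.array([[0, 0], [1, 0], [0, 1]], float)),
            RegionPolygon("b", np.array([[5, 5], [6, 5], [5, 6]], float)),
        ]
        path = tmp_path / "two.geojson"
        tio.write_polygons(polys, path)
        back = tio.read_polygons(path)
        assert [p.label for p in back] == ["a", "b"]

    def test_repeated_closing_vertex_deduplicated(self):
        ring = np.array([[0, 0], [2, 0], [2, 2], [0, 2], [0, 0]], float)
        poly = RegionPolygon("r", ring)
        assert len(poly.vertices) == 4

    def test_winding_normalized_ccw(self):
        clockwise = np.array([[0, 0], [0, 2], [2, 2], [2, 0]], float)
        poly = RegionPolygon("r", clockwise)
        v = poly.vertices
        signed_area = 0.5 * np.sum(
            v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1]
        )
        assert signed_area > 0

    def test_degenerate_ring_rejected(self):
        with pytest.raises(ValidationError):
            RegionPolygon("r", np.array([[0, 0], [1, 1]], float))

    def test_non_polygon_geometry_rejected(self, tmp_path):
        path = tmp_path / "pt.geojson"
        path.write_text(
            '{"type":"FeatureCollection","features":[{"type":"Feature",'
            '"properties":{"label":"x"},"geometry":{"type":"Point",'
            '"coordinates":[0,0]}}]}'
        )
        with pytest.raises(TypeError):
            tio.read_polygons(path)


class TestWriteTable:
    def test_unknown_schema(self, tmp_path):
        with pytest.raises(SchemaError, match="unknown"):
            tio.write_table(pd.DataFrame(), tmp_path / "x.tsv", "nope")

    def test_empty_comparison_is_header_only(self, tmp_path):
        cols = tio.TABLE_SCHEMAS["comparison"]
        df = pd.DataFrame(columns=list(cols))
        out = tmp_path / "cmp.tsv"
        tio.write_table(df, out, "comparison")
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 1
        assert lines[0].split("\t") == list(cols)

    def test_roundtrip_at_declared_precision(self, tmp_path):
        df = pd.DataFrame(
            {"gene": ["a", "b"], "n_a": [3, 3], "n_b": [4, 4],
             "mean_a": [0.123456789, 1.0], "mean_b": [2.0, 3.0],
             "t": [1.5, -2.25], "p": [0.04, 0.5], "q": [0.08, 0.5],
             "d": [0.7, -0.1], "flag": ["ok", "ok"]}
        )
        out = tmp_path / "cmp.tsv"
        tio.write_table(df, out, "comparison")
        back = tio.read_table(out, "comparison")
        for col in ("mean_a", "t", "p", "q", "d"):
            np.testing.assert_allclose(back[col], df[col], rtol=1e-9)

    def test_p_requires_q_column(self, tmp_path):
        df = pd.DataFrame({c: [] for c in tio.TABLE_SCHEMAS["comparison"]})
        df = df.drop(columns=["q"])
        with pytest.raises(SchemaError, match="q"):
            tio.write_table(df, tmp_path / "x.tsv", "comparison")

    def test_gzip_inputs_accepted(self, tmp_path, small_tissue):
        # the bundle writer emits .gz files; reading them back covers the path
        table = small_tissue.table.subset(np.arange(50))
        paths = tio.write_cell_bundle(table, tmp_path)
        assert paths["cells_csv"].suffix == ".gz"
        back = tio.read_cell_bundle(
            paths["cells_csv"], paths["matrix"], paths["features"],
            paths["cell_list"],
        )
        assert back.n_cells == 50


class TestOptionalInputs:
    def test_transcripts_with_optional_qv_filter(self, tmp_path):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0], "y": [0.0, 0.0, 0.0],
             "feature_name": ["g1", "g1", "g2"], "qv": [40.0, 10.0, 30.0]}
        )
        path = tmp_path / "transcripts.csv"
        df.to_csv(path, index=False)
        assert len(tio.read_transcripts(path)) == 3          # default: no filter
        assert len(tio.read_transcripts(path, min_qv=20.0)) == 2
        bad = tmp_path / "bad.csv"
        df.drop(columns=["qv"]).to_csv(bad, index=False)
        with pytest.raises(SchemaError, match="qv"):
            tio.read_transcripts(bad)

    def test_marker_config_yaml(self, tmp_path):
        path = tmp_path / "panel.yaml"
        path.write_text(
            "cell_types:\n"
            "  - label: CAF\n"
            "    positive: [COL1A1]\n"
            "  - label: CXCL13+CD8+\n"
            "    positive: [CXCL13, CD8A]\n"
            "    mode: all\n"
            "tumour_rule:\n"
            "  positive: [CDH1]\n"
            "  negative: [SFTPD]\n"
            "hotcold_gene: CD274\n"
        )
        genes = PanelGenes(("COL1A1", "CXCL13", "CD8A", "CDH1", "SFTPD", "CD274"))
        cfg = tio.read_marker_config(path, genes)
        assert [r.label for r in cfg.rules] == ["CAF", "CXCL13+CD8+"]
        assert cfg.rules[1].mode == "all"
        assert cfg.tumour_negative == ("SFTPD",)
        from tmezone.model import ConfigError

        with pytest.raises(ConfigError):
            tio.read_marker_config(path, PanelGenes(("COL1A1",)))
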