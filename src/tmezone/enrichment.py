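"""Spot-level DEG calling and gene-set over-representation mapping.

The field of view is divided into a k × k spot lattice (default 125 × 125 =
15,625 spots).  After total-count normalization, a gene is a spot-DEG in the
spots where its normalized expression reaches its own top-5% level across
all spots (per-gene nearest-rank 95th percentile, zeros never qualify).
Each spot's DEG set is tested for over-representation against every
supplied gene set with the one-sided hypergeometric upper tail on the panel
background (302 genes by default), BH-adjusted across terms within the
spot; maps carry −log10 of the adjusted (and raw) p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .density import bh_adjust
from .model import CellTable, ConfigError, PanelGenes

P_FLOOR = 1e-300


def filter_and_normalize(
    table: CellTable, min_gene_counts: int = 10, min_cell_counts: int = 10
) -> CellTable:
    """Drop low-count genes and cells, then total-count normalize.

    Genes with fewer than ``min_gene_counts`` total transcripts and cells
    with fewer than ``min_cell_counts`` transcripts are removed (boundary
    values are retained).  Remaining cells are scaled so each cell's total
    equals the median per-cell total measured *before* filtering.
    """
    import scanpy as sc

    adata = table.to_anndata()
    pre_totals = np.asarray(adata.X.sum(axis=1)).ravel()
    target = float(np.median(pre_totals))
    sc.pp.filter_genes(adata, min_counts=min_gene_counts)
    sc.pp.filter_cells(adata, min_counts=min_cell_counts)
    if adata.n_obs == 0:
        raise ValueError("all cells removed by the count filter")
    sc.pp.normalize_total(adata, target_sum=target)
    return CellTable(
        cell_ids=adata.obs.index.to_numpy(object),
        x=adata.obs["x"].to_numpy(float),
        y=adata.obs["y"].to_numpy(float),
        area=adata.obs["area"].to_numpy(float),
        counts=sp.csr_matrix(adata.X),
        genes=PanelGenes(tuple(adata.var.index)),
        normalized=True,
    )


@dataclass
class SpotGrid:
    """k × k spot lattice with per-spot summed (normalized) expression."""

    k: int
    origin: tuple[float, float]
    spot_size: tuple[float, float]     # µm per spot along x and y
    matrix: sp.csr_matrix              # k² × n_genes; row = iy * k + ix
    genes: PanelGenes

    @property
    def n_spots(self) -> int:
        return self.k * self.k

    def gene_map(self, gene: str) -> np.ndarray:
        j = self.genes.index_of(gene)
        return np.asarray(self.matrix[:, j].todense()).ravel()


def spot_grid(table: CellTable, k: int = 125) -> SpotGrid:
    """Divide the cell bounding box into k × k equal spots and sum each
    spot's member-cell expression."""
    if k < 2:
        raise ValueError("spot grid needs k >= 2")
    if table.n_cells == 0:
        raise ValueError("cannot grid an empty cell table")
    x0, y0 = float(table.x.min()), float(table.y.min())
    wx = (float(table.x.max()) - x0) / k or 1.0
    wy = (float(table.y.max()) - y0) / k or 1.0
    ix = np.minimum(np.floor((table.x - x0) / wx).astype(np.int64), k - 1)
    iy = np.minimum(np.floor((table.y - y0) / wy).astype(np.int64), k - 1)
    flat = iy * k + ix
    pool = sp.csr_matrix(
        (np.ones(table.n_cells), (flat, np.arange(table.n_cells))),
        shape=(k * k, table.n_cells),
    )
    return SpotGrid(
        k=k, origin=(x0, y0), spot_size=(wx, wy),
        matrix=sp.csr_matrix(pool @ table.counts), genes=table.genes,
    )


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank (ceiling) quantile: the ⌈q·n⌉-th smallest value."""
    v = np.sort(np.asarray(values))
    n = len(v)
    rank = int(np.ceil(q * n))
    return float(v[min(max(rank, 1), n) - 1])


@dataclass
class SpotDEGSet:
    """Boolean spot × gene DEG calls plus the per-gene cutoffs."""

    calls: np.ndarray                  # bool (n_spots, n_genes)
    cutoffs: np.ndarray                # per-gene quantile cutoff
    genes: PanelGenes
    saturated: np.ndarray              # genes constant>0 across spots (flagged)

    def spot_genes(self, spot: int) -> list[str]:
        return [self.genes.names[j] for j in np.flatnonzero(self.calls[spot])]


def call_spot_degs(grid: SpotGrid, q: float = 0.95) -> SpotDEGSet:
    """Per-gene top-(1−q) DEG calls across spots.

    A gene is a DEG in a spot when its expression there is >= its own
    nearest-rank q-quantile over all spots and strictly positive.  Genes
    constant and positive across all spots saturate the rule (DEG
    everywhere); they are flagged, not suppressed.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("quantile must lie strictly between 0 and 1")
    X = np.asarray(grid.matrix.todense())
    n = X.shape[0]
    rank = min(max(int(np.ceil(q * n)), 1), n)
    cutoffs = np.sort(X, axis=0)[rank - 1]
    calls = (X >= cutoffs) & (X > 0)
    saturated = (X.max(axis=0) == X.min(axis=0)) & (X.max(axis=0) > 0)
    return SpotDEGSet(calls=calls, cutoffs=cutoffs, genes=grid.genes,
                      saturated=saturated)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background panel."""

    sets: dict[str, tuple[str, ...]]
    background: PanelGenes

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            missing = [g for g in genes if g not in self.background]
            if missing:
                raise ConfigError(
                    f"term {term!r} has genes outside the background: {missing[:5]}"
                )


def read_gmt(path, background: PanelGenes, drop_missing: bool = False
             ) -> GeneSetCollection:
    """Read GMT gene sets (term <tab> description <tab> genes...).

    With ``drop_missing`` genes absent from the background are dropped
    instead of raising.
    """
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genes = tuple(g for g in parts[2:] if g)
            if drop_missing:
                genes = tuple(g for g in genes if g in background)
            sets[parts[0]] = genes
    return GeneSetCollection(sets=sets, background=background)


def write_gmt(sets: dict[str, tuple[str, ...]], path) -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, "na", *genes]) + "\n")


def hypergeom_tail(overlap: int, background: int, term_size: int, n_deg: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(background, term_size, n_deg)."""
    return float(scipy.stats.hypergeom.sf(overlap - 1, background, term_size, n_deg))


@dataclass
class EnrichmentMap:
    """spot × term −log10 p maps (adjusted and raw)."""

    terms: list[str]
    minus_log10_q: np.ndarray          # (n_spots, n_terms)
    minus_log10_p: np.ndarray
    k: int

    def term_map(self, term: str, adjusted: bool = True) -> np.ndarray:
        j = self.terms.index(term)
        src = self.minus_log10_q if adjusted else self.minus_log10_p
        return src[:, j]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for spot in range(self.minus_log10_q.shape[0]):
            iy, ix = divmod(spot, self.k)
            for j, term in enumerate(self.terms):
                rows.append(
                    {"ix": ix, "iy": iy, "term": term,
                     "minus_log10_q": self.minus_log10_q[spot, j],
                     "minus_log10_p": self.minus_log10_p[spot, j]}
                )
        return pd.DataFrame(rows)


def enrich_spots(degs: SpotDEGSet, sets: GeneSetCollection) -> EnrichmentMap:
    """Hypergeometric over-representation of every term in every spot's DEG
    set, BH-adjusted across terms within each spot."""
    if degs.genes.names != sets.background.names:
        raise ConfigError("DEG panel and enrichment background differ")
    N = sets.background.size
    terms = list(sets.sets)
    gene_idx = {g: j for j, g in enumerate(degs.genes.names)}
    term_ind = np.zeros((len(terms), N), dtype=np.int8)
    for i, term in enumerate(terms):
        for g in sets.sets[term]:
            term_ind[i, gene_idx[g]] = 1
    calls = degs.calls.astype(np.int64)
    n_deg = calls.sum(axis=1)                       # per spot
    overlap = calls @ term_ind.T                    # spots × terms
    term_sizes = term_ind.sum(axis=1)

    p = np.empty(overlap.shape, float)
    for j, m in enumerate(term_sizes):
        p[:, j] = scipy.stats.hypergeom.sf(overlap[:, j] - 1, N, int(m), n_deg)
    q = np.vstack([bh_adjust(row) for row in p])
    p = np.clip(p, P_FLOOR, 1.0)
    q = np.clip(q, P_FLOOR, 1.0)
    return EnrichmentMap(
        terms=terms,
        minus_log10_q=np.maximum(-np.log10(q), 0.0),
        minus_log10_p=np.maximum(-np.log10(p), 0.0),
        k=int(np.sqrt(degs.calls.shape[0])),
    )


def correlate_map(map_a: np.ndarray, map_b: np.ndarray) -> tuple[float, int]:
    """Pearson product-moment correlation over spots; (r, n_spots).

    Returns (nan, n) with a zero-variance input (undefined correlation).
    """
    a = np.asarray(map_a, float).ravel()
    b = np.asarray(map_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must cover the same spots")
    n = len(a)
    if n < 3 or a.std() == 0.0 or b.std() == 0.0:
        return float("nan"), n
    r = float(np.corrcoef(a, b)[0, 1])
    return r, n
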