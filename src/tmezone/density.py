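"""Gene-density profiles and two-group contrasts.

Gene density is transcript counts per µm² of cell (or pooled region) area.
Contrasts use Welch's unequal-variance t test (two-sided), Benjamini–
Hochberg step-up correction over the genes tested in one call, and the
classic pooled-sd Cohen's d for effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .model import CellTable, ConfigError, PanelGenes


@dataclass
class DensityProfile:
    """unit × gene densities (counts per µm²)."""

    unit_ids: np.ndarray
    matrix: sp.csr_matrix          # units × genes, float
    genes: PanelGenes
    level: str                     # "cell" or "region"

    def gene_density(self, gene: str) -> np.ndarray:
        j = self.genes.index_of(gene)
        return np.asarray(self.matrix[:, j].todense()).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


def density(
    table: CellTable,
    grouping: str = "cell",
    regions: np.ndarray | pd.Series | None = None,
) -> DensityProfile:
    """Per-cell density (count/area) or per-region pooled density
    (Σcounts / Σarea over member cells).

    For ``grouping="region"`` pass a per-cell region label array; cells
    labelled with the empty string are outside every region.
    """
    if grouping == "cell":
        inv_area = sp.diags(1.0 / table.area)
        return DensityProfile(
            unit_ids=table.cell_ids.copy(),
            matrix=sp.csr_matrix(inv_area @ table.counts),
            genes=table.genes,
            level="cell",
        )
    if grouping != "region":
        raise ValueError("grouping must be 'cell' or 'region'")
    if regions is None:
        raise ValueError("region grouping requires per-cell region labels")
    regions = np.asarray(regions, dtype=object)
    names = [r for r in pd.unique(regions) if r != ""]
    rows = []
    for name in names:
        sel = regions == name
        if not sel.any():
            raise ValueError(f"region {name!r} has no member cells")
        pooled = np.asarray(table.counts[sel].sum(axis=0)).ravel()
        rows.append(pooled / table.area[sel].sum())
    return DensityProfile(
        unit_ids=np.asarray(names, dtype=object),
        matrix=sp.csr_matrix(np.vstack(rows)) if rows else sp.csr_matrix((0, table.genes.size)),
        genes=table.genes,
        level="region",
    )


def cohens_d(a: np.ndarray, b: np.ndarray, axis: int = 0) -> np.ndarray:
    """Classic Cohen's d with the pooled Bessel-corrected standard deviation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.shape[axis], b.shape[axis]
    va = a.var(axis=axis, ddof=1)
    vb = b.var(axis=axis, ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a.mean(axis=axis) - b.mean(axis=axis)) / pooled


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN p-values propagate as NaN."""
    p = np.asarray(p, float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def welch_bh_cohen(
    a: np.ndarray,
    b: np.ndarray,
    gene_names: list[str] | tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-gene Welch t, two-sided p, BH q (one family per call), Cohen's d.

    ``a`` and ``b`` are (n_units × n_genes) density matrices.  Zero-variance
    genes are handled explicitly: if both groups are constant and equal the
    difference carries no evidence (t=0, p=1, d=0, flag ``zero_var_equal``);
    if constant but unequal, t/p/d are undefined and flagged, and the gene
    is excluded from the BH family.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.ndim == 2 and a.shape[1] != b.shape[1]:
        raise ValueError("group matrices must share the gene axis")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("Welch's t requires >= 2 units per group")
    n_genes = a.shape[1]
    if gene_names is None:
        gene_names = [f"g{j}" for j in range(n_genes)]

    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    var_a, var_b = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    zero_var = (var_a == 0) & (var_b == 0)
    equal_const = zero_var & (mean_a == mean_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        res = scipy.stats.ttest_ind(a, b, axis=0, equal_var=False)
        t = np.asarray(res.statistic, float)
        p = np.asarray(res.pvalue, float)
        d = cohens_d(a, b)

    flag = np.full(n_genes, "ok", dtype=object)
    flag[zero_var & ~equal_const] = "zero_var_unequal"
    flag[equal_const] = "zero_var_equal"
    t[equal_const] = 0.0
    p[equal_const] = 1.0
    d[equal_const] = 0.0
    t[zero_var & ~equal_const] = np.nan
    p[zero_var & ~equal_const] = np.nan
    d[zero_var & ~equal_const] = np.nan

    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": list(gene_names),
            "n_a": na, "n_b": nb,
            "mean_a": mean_a, "mean_b": mean_b,
            "t": t, "p": p, "q": q, "d": d, "flag": flag,
        }
    )


def classify_hotcold(table: CellTable, basis_gene: str = "CD274") -> pd.DataFrame:
    """Immune-hot vs immune-cold cell labels by the basis-gene count rule:
    hot when count >= 2, cold when count <= 1."""
    if basis_gene not in table.genes:
        raise ConfigError(f"basis gene {basis_gene!r} not in panel")
    counts = table.gene_counts(basis_gene)
    labels = np.where(counts >= 2, "hot", "cold").astype(object)
    return pd.DataFrame(
        {"cell_id": table.cell_ids.astype(str), "label": labels,
         "basis_count": counts}
    )


def hotcold_contrast(
    table: CellTable,
    labels: pd.DataFrame | np.ndarray,
    level: str = "cell",
    exclude: np.ndarray | None = None,
    region_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene hot-vs-cold density contrast (hot is group A).

    ``exclude`` is a boolean per-cell mask of cells to drop before the
    contrast (e.g. poorly segmented cells).  For ``level="region"`` pass
    per-cell ``region_labels``; each region is labelled hot/cold by the
    majority label of its member cells, and the contrast runs over region
    densities.
    """
    lab = labels["label"].to_numpy() if isinstance(labels, pd.DataFrame) else np.asarray(labels, dtype=object)
    if lab.shape[0] != table.n_cells:
        raise ValueError("labels length must equal number of cells")
    keep = np.ones(table.n_cells, dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, bool)

    if level == "cell":
        prof = density(table.subset(keep), "cell")
        lab_k = lab[keep]
        dense = prof.dense()
        a = dense[lab_k == "hot"]
        b = dense[lab_k == "cold"]
    elif level == "region":
        if region_labels is None:
            raise ValueError("region-level contrast requires region_labels")
        reg = np.asarray(region_labels, dtype=object)[keep]
        sub = table.subset(keep)
        prof = density(sub, "region", regions=reg)
        lab_k = lab[keep]
        region_state = {}
        for name in prof.unit_ids:
            members = lab_k[reg == name]
            region_state[name] = "hot" if (members == "hot").mean() >= 0.5 else "cold"
        dense = prof.dense()
        states = np.array([region_state[r] for r in prof.unit_ids], dtype=object)
        a = dense[states == "hot"]
        b = dense[states == "cold"]
    else:
        raise ValueError("level must be 'cell' or 'region'")

    if len(a) == 0 or len(b) == 0:
        raise ValueError("one of the hot/cold classes is empty")
    return welch_bh_cohen(a, b, gene_names=list(table.genes.names))
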