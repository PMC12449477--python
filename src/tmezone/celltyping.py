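"""Per-cell marker positivity, rule-based cell typing, and marker summaries.

Positivity follows the asymmetric count rule used for targeted in situ
panels: a cell is *positive* for a gene when its count is >= τ (default 2)
and *negative* when the count is exactly 0.  A count of 1 under τ=2 is
neither — it fails positive-marker tests and fails negative-marker tests,
so it is excluded from both sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CellTable, ConfigError, MarkerConfig, PanelGenes, UNCLASSIFIED


@dataclass
class PositivityMatrix:
    """Boolean positivity (count >= τ) and exact-zero masks, cells × genes."""

    positive: np.ndarray        # bool (n_cells, n_genes)
    zero: np.ndarray            # bool (n_cells, n_genes): count == 0
    tau: int
    genes: PanelGenes

    def gene_positive(self, gene: str) -> np.ndarray:
        return self.positive[:, self.genes.index_of(gene)]

    def gene_zero(self, gene: str) -> np.ndarray:
        return self.zero[:, self.genes.index_of(gene)]


def call_positivity(table: CellTable, tau: int = 2) -> PositivityMatrix:
    """Threshold raw counts into the positive / negative / indeterminate calls."""
    if tau < 1:
        raise ValueError("positivity threshold tau must be >= 1")
    counts = np.asarray(table.counts.todense())
    return PositivityMatrix(
        positive=counts >= tau,
        zero=counts == 0,
        tau=tau,
        genes=table.genes,
    )


def assign_cell_types(pos: PositivityMatrix, cfg: MarkerConfig) -> pd.DataFrame:
    """First-match assignment over the ordered rule list.

    A rule matches when its positive markers fire (any/all per the rule's
    mode) and every negative marker has a count of exactly zero.  Cells
    matching no rule are labelled ``U.C.``.  Returns a DataFrame with
    columns (cell_id is positional index): label, supporting_markers.
    """
    cfg.validate_against(pos.genes)
    n = pos.positive.shape[0]
    labels = np.full(n, UNCLASSIFIED, dtype=object)
    support = np.full(n, "", dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in cfg.rules:
        pos_cols = np.column_stack([pos.gene_positive(g) for g in rule.positive])
        hits = pos_cols.all(axis=1) if rule.mode == "all" else pos_cols.any(axis=1)
        for g in rule.negative:
            hits &= pos.gene_zero(g)
        sel = unassigned & hits
        labels[sel] = rule.label
        if sel.any():
            idx = np.flatnonzero(sel)
            marker_names = np.array(rule.positive, dtype=object)
            support[idx] = [
                ",".join(marker_names[pos_cols[i]]) for i in idx
            ]
        unassigned &= ~sel
    return pd.DataFrame({"label": labels, "supporting_markers": support})


def compound_positive(pos: PositivityMatrix, genes: tuple[str, ...],
                      negative: tuple[str, ...] = ()) -> np.ndarray:
    """Conjunction call, e.g. CXCL13+CD8+ cells via ('CXCL13', 'CD8A')."""
    mask = np.ones(pos.positive.shape[0], dtype=bool)
    for g in genes:
        mask &= pos.gene_positive(g)
    for g in negative:
        mask &= pos.gene_zero(g)
    return mask


def marker_summary(
    table: CellTable,
    groups: np.ndarray | pd.Series,
    markers: list[str],
    tau: int = 2,
) -> pd.DataFrame:
    """Group × marker means, cross-group z scores, and percent positive.

    For each marker the z score standardizes the *group means* across the
    set of groups using the population standard deviation — the descriptive
    convention for bubble-chart summaries over a small fixed group set.
    With a single group (or zero variance) z is reported as 0 and flagged.
    """
    groups = np.asarray(groups, dtype=object)
    if groups.shape[0] != table.n_cells:
        raise ValueError("groups length must equal number of cells")
    group_names = [g for g in pd.unique(groups) if g != ""]
    counts = np.asarray(table.counts.todense())
    rows = []
    for marker in markers:
        j = table.genes.index_of(marker)
        means, pcts = [], []
        for g in group_names:
            sel = groups == g
            vec = counts[sel, j]
            means.append(float(vec.mean()) if vec.size else np.nan)
            pcts.append(100.0 * float((vec >= tau).mean()) if vec.size else np.nan)
        means_arr = np.asarray(means)
        sd = float(np.std(means_arr))  # population sd across group means
        flag = "ok"
        if len(group_names) < 2 or sd == 0.0:
            z = np.zeros(len(group_names))
            flag = "zero_variance" if len(group_names) >= 2 else "single_group"
        else:
            z = (means_arr - means_arr.mean()) / sd
        for g, m, zz, p in zip(group_names, means_arr, z, pcts):
            rows.append({"group": g, "marker": marker, "mean": m,
                         "z": float(zz), "pct_positive": p, "flag": flag})
    return pd.DataFrame(rows)
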