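"""Genotype contrasts: differential expression at any scope, subtype
proportion shifts, and cross-condition cluster-similarity AUROC.

Differential expression reuses the Wilcoxon rank-sum machinery of the
taxonomy module with a detection floor (a gene must be detected in at
least ``min_detection`` of cells in one of the two conditions) and no fold
change floor. Per-cell DE treats cells as independent samples, which
overstates significance when cells share a library; results carry a
pseudoreplication warning flag for that reason.

Cluster similarity follows the neighbor-voting idea: pooled cells are
correlated (Spearman, on a chosen gene set) and each cluster's mean
correlation to another dataset's cells is scored by how well it ranks that
dataset's matching cluster members (AUROC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix
from .taxonomy import rank_markers

__all__ = [
    "DEResult",
    "condition_de",
    "shared_de",
    "proportion_shift",
    "select_similarity_genes",
    "cluster_similarity",
]


@dataclass
class DEResult:
    scope: str
    table: pd.DataFrame
    background: list[str]
    n_significant: int
    n_up_large: int  # FDR-significant with log2fc > +0.5
    n_down_large: int  # FDR-significant with log2fc < -0.5
    pseudoreplication_warning: str = (
        "per-cell DE treats cells as independent; p-values are optimistic "
        "when cells share a library"
    )

    def significant_genes(self, alpha: float = 0.05) -> set[str]:
        t = self.table
        return set(t.loc[t["p_adj"] < alpha, "gene"])


def condition_de(
    norm: NormalizedMatrix,
    condition: np.ndarray,
    scope_cells: np.ndarray | None = None,
    scope: str = "all",
    min_detection: float = 0.10,
    alpha: float = 0.05,
    large_fc: float = 0.5,
) -> DEResult:
    """Condition-A vs condition-B Wilcoxon DE within a cell scope.

    ``condition`` must take exactly two values over the scope; the first
    in sorted order is group A (log2fc > 0 means higher in A). The
    background is the tested gene universe (detection >= ``min_detection``
    in either condition) — the set over-representation analyses must use.
    """
    condition = np.asarray(condition, dtype=object)
    if scope_cells is None:
        scope_cells = np.arange(norm.n_cells)
    scope_cells = np.asarray(scope_cells, dtype=int)
    vals = sorted(set(condition[scope_cells]), key=str)
    if len(vals) != 2:
        raise ValueError(f"scope must contain exactly 2 conditions, got {vals}")
    a = scope_cells[condition[scope_cells] == vals[0]]
    b = scope_cells[condition[scope_cells] == vals[1]]
    table = rank_markers(
        norm, a, b, min_pct=min_detection, min_diff_pct=0.0, logfc_threshold=0.0
    )
    sig = table[table["p_adj"] < alpha]
    return DEResult(
        scope=scope,
        table=table,
        background=list(table["gene"]),
        n_significant=len(sig),
        n_up_large=int((sig["log2fc"] > large_fc).sum()),
        n_down_large=int((sig["log2fc"] < -large_fc).sum()),
    )


def shared_de(result_a: DEResult, result_b: DEResult, alpha: float = 0.05) -> dict:
    """Venn counts of FDR-significant genes between two DE results."""
    sa = result_a.significant_genes(alpha)
    sb = result_b.significant_genes(alpha)
    return {
        "scope_a": result_a.scope,
        "scope_b": result_b.scope,
        "n_a": len(sa),
        "n_b": len(sb),
        "n_shared": len(sa & sb),
        "n_a_only": len(sa - sb),
        "n_b_only": len(sb - sa),
        "shared": sorted(sa & sb),
    }


def proportion_shift(
    labels: np.ndarray,
    condition: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test of per-cluster proportion differences.

    The statistic per cluster is |proportion in A - proportion in B|; the
    null permutes condition labels over cells. P-values use +1 smoothing
    and are BH-adjusted across clusters.
    """
    labels = np.asarray(labels, dtype=object)
    condition = np.asarray(condition, dtype=object)
    vals = sorted(set(condition), key=str)
    if len(vals) != 2:
        raise ValueError("exactly two conditions required")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse")
    rng = np.random.default_rng(seed)
    in_a = condition == vals[0]
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both conditions must be non-empty")
    uniq = sorted(set(labels), key=str)
    onehot = np.stack([(labels == u).astype(float) for u in uniq])  # clusters x cells

    def props(mask: np.ndarray) -> np.ndarray:
        return onehot[:, mask].sum(axis=1) / mask.sum()

    observed = np.abs(props(in_a) - props(~in_a))
    exceed = np.zeros(len(uniq))
    for _ in range(n_perm):
        perm = rng.permutation(in_a)
        stat = np.abs(props(perm) - props(~perm))
        exceed += stat >= observed - 1e-15
    p = (1.0 + exceed) / (n_perm + 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "cluster": uniq,
            "prop_a": props(in_a),
            "prop_b": props(~in_a),
            "abs_diff": observed,
            "p": p,
            "p_adj": p_adj,
        }
    )


def select_similarity_genes(
    matrices: list[NormalizedMatrix],
    n_bins: int = 10,
) -> list[str]:
    """Intersection of variable genes across datasets, skipping the top
    expression bin.

    Per dataset, genes are binned into ``n_bins`` equal-frequency bins by
    mean normalized expression; within each bin except the top, genes with
    variance-to-mean dispersion above the bin median are "variable". The
    returned list is the intersection across datasets, in the first
    dataset's gene order.
    """
    if not matrices:
        raise ValueError("need at least one dataset")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    selected = None
    for m in matrices:
        genes = [g for g in m.gene_ids if g in common]
        idx = m.gene_index(genes)
        X = m.lognorm[idx]
        mu = np.asarray(X.mean(axis=1)).ravel()
        ex2 = np.asarray(X.multiply(X).mean(axis=1)).ravel()
        var = np.maximum(ex2 - mu**2, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(mu > 0, var / mu, 0.0)
        order = rankdata(mu, method="ordinal") - 1
        bins = np.minimum((order * n_bins) // len(genes), n_bins - 1)
        variable = set()
        for b in range(n_bins - 1):  # top bin excluded
            mask = bins == b
            if not mask.any():
                continue
            med = np.median(disp[mask])
            for g, d, in_bin in zip(genes, disp, mask):
                if in_bin and d > med:
                    variable.add(g)
        selected = variable if selected is None else selected & variable
    out = [g for g in matrices[0].gene_ids if g in selected]
    if len(out) < 50:
        import warnings

        warnings.warn(f"only {len(out)} similarity genes selected")
    return out


def cluster_similarity(
    norm_a: NormalizedMatrix,
    labels_a: np.ndarray,
    norm_b: NormalizedMatrix,
    labels_b: np.ndarray,
    genes: list[str],
) -> pd.DataFrame:
    """Neighbor-voting AUROC between every cluster pair across datasets.

    Cells are pooled; votes for dataset-B cells from cluster a are the
    mean Spearman correlation (over ``genes``) to a's cells; the AUROC of
    those votes discriminating cluster b's cells from the rest of B fills
    entry (a, b). Size-1 clusters yield NA.
    """
    ia = norm_a.gene_index(genes)
    ib = norm_b.gene_index(genes)
    A = np.asarray(norm_a.lognorm[ia].todense())  # genes x cellsA
    B = np.asarray(norm_b.lognorm[ib].todense())
    # Spearman: rank within each cell, then Pearson between cells
    ra = np.apply_along_axis(rankdata, 0, A)
    rb = np.apply_along_axis(rankdata, 0, B)

    def standardize(M: np.ndarray) -> np.ndarray:
        mu = M.mean(axis=0)
        sd = M.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (M - mu) / sd

    za = standardize(ra)
    zb = standardize(rb)
    corr = za.T @ zb / za.shape[0]  # cellsA x cellsB

    labels_a = np.asarray(labels_a, dtype=object)
    labels_b = np.asarray(labels_b, dtype=object)
    ua = sorted(set(labels_a), key=str)
    ub = sorted(set(labels_b), key=str)
    out = pd.DataFrame(index=pd.Index(ua, name="cluster_a"), columns=pd.Index(ub, name="cluster_b"), dtype=float)
    for a_lab in ua:
        a_mask = labels_a == a_lab
        if a_mask.sum() < 2:
            out.loc[a_lab] = np.nan
            continue
        votes = corr[a_mask].mean(axis=0)  # over B cells
        vote_ranks = rankdata(votes)
        for b_lab in ub:
            b_mask = labels_b == b_lab
            n_pos, n_neg = int(b_mask.sum()), int((~b_mask).sum())
            if n_pos < 2 or n_neg == 0:
                out.loc[a_lab, b_lab] = np.nan
                continue
            auroc = (vote_ranks[b_mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
            out.loc[a_lab, b_lab] = auroc
    return out
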