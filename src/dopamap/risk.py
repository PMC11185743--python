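"""Cell-level polygenic disease-relevance scoring with matched controls.

Each cell receives a weighted average of normalized expression over
GWAS-implicated genes, with per-gene weights ``z / (sigma + eps)``
(inverse-variance, eps = 0.05). The raw score is normalized against
``n_ctrl`` control gene sets in which every risk gene is replaced by a
random gene from the same (mean, variance) expression bin, inheriting its
z-weight: ``(raw - mean_ctrl) / sd_ctrl`` per cell. Population-level
inference resamples cells with replacement within each group and reports
the percentile bootstrap confidence interval of the group mean normalized
score; a group is significant when its CI excludes 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix

__all__ = [
    "RiskGeneSet",
    "load_risk_genes",
    "bin_genes",
    "score_cells",
    "group_bootstrap",
]

EPS_VS = 0.05  # variance floor in the inverse-variance weighting


@dataclass
class RiskGeneSet:
    """Gene -> z-weight mapping restricted to the expression matrix."""

    weights: pd.Series  # index gene, values z
    provenance: str = ""
    ortholog_mapped: bool = False
    unmapped: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights.to_numpy(float))):
            raise ValueError("z-weights must be finite")
        if self.unmapped is None:
            self.unmapped = []


def load_risk_genes(
    z_table: pd.DataFrame,
    matrix_genes,
    ortholog_map: pd.DataFrame | None = None,
    min_overlap: int = 25,
    provenance: str = "",
) -> RiskGeneSet:
    """Map a (gene, z) table through an ortholog map and intersect with the
    expression matrix's genes.

    ``ortholog_map`` has columns (human, mouse); a human gene mapping to
    several mouse genes passes its z to each of them. Raises when fewer
    than ``min_overlap`` genes survive.
    """
    if not {"gene", "z"} <= set(z_table.columns):
        raise ValueError("z_table needs columns gene, z")
    mapped: dict[str, float] = {}
    unmapped: list[str] = []
    if ortholog_map is not None:
        if not {"human", "mouse"} <= set(ortholog_map.columns):
            raise ValueError("ortholog_map needs columns human, mouse")
        lut: dict[str, list[str]] = {}
        for _, row in ortholog_map.iterrows():
            lut.setdefault(str(row["human"]).upper(), []).append(str(row["mouse"]))
        for _, row in z_table.iterrows():
            targets = lut.get(str(row["gene"]).upper())
            if not targets:
                unmapped.append(str(row["gene"]))
                continue
            for t in targets:
                mapped[t] = float(row["z"])
    else:
        mapped = {str(r["gene"]): float(r["z"]) for _, r in z_table.iterrows()}
    present = set(map(str, matrix_genes))
    kept = {g: z for g, z in mapped.items() if g in present}
    dropped = [g for g in mapped if g not in present]
    if len(kept) < min_overlap:
        raise ValueError(
            f"only {len(kept)} risk genes overlap the matrix (need >= {min_overlap})"
        )
    return RiskGeneSet(
        weights=pd.Series(kept, dtype=float),
        provenance=provenance,
        ortholog_mapped=ortholog_map is not None,
        unmapped=unmapped + dropped,
    )


def _equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per value (stable under ties by rank)."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(values))
    return np.minimum((ranks * n_bins) // len(values), n_bins - 1)


def bin_genes(
    norm: NormalizedMatrix, n_mean_bin: int = 20, n_var_bin: int = 20
) -> pd.DataFrame:
    """(mean_bin, var_bin) per gene on the normalized matrix.

    Genes are cut into ``n_mean_bin`` equal-frequency bins by mean log
    expression; within each mean bin, into ``n_var_bin`` equal-frequency
    bins by variance. Bins collapse gracefully when genes are scarce.
    """
    X = norm.lognorm
    mu = np.asarray(X.mean(axis=1)).ravel()
    ex2 = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(ex2 - mu**2, 0.0)
    n_genes = len(mu)
    if n_genes < n_mean_bin * n_var_bin:
        import warnings

        warnings.warn(
            f"{n_genes} genes for {n_mean_bin}x{n_var_bin} bins; bins will collapse"
        )
    mean_bin = _equal_frequency_bins(mu, min(n_mean_bin, n_genes))
    var_bin = np.zeros(n_genes, dtype=int)
    for b in np.unique(mean_bin):
        mask = mean_bin == b
        var_bin[mask] = _equal_frequency_bins(var[mask], min(n_var_bin, int(mask.sum())))
    return pd.DataFrame(
        {"mean_bin": mean_bin, "var_bin": var_bin, "mean": mu, "var": var},
        index=pd.Index(norm.gene_ids, name="gene"),
    )


def score_cells(
    norm: NormalizedMatrix,
    risk: RiskGeneSet,
    bins: pd.DataFrame,
    n_ctrl: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw and control-normalized disease-relevance score per cell.

    Weights are ``z / (sigma + 0.05)`` on the normalized expression;
    the raw score is ``sum_g w_g x_gc / sum_g |w_g|``. Each control set
    replaces every risk gene by a uniform draw from its (mean, var) bin
    (nearest non-empty bin if needed), inheriting the gene's z. The
    normalized score is the per-cell z-score of raw against controls; a
    Monte-Carlo p ``(1 + #{ctrl >= raw}) / (n_ctrl + 1)`` is included.
    """
    genes = [g for g in risk.weights.index if g in set(norm.gene_ids)]
    if not genes:
        raise ValueError("no risk genes present in the matrix")
    rng = np.random.default_rng(seed)
    gidx = {g: i for i, g in enumerate(norm.gene_ids)}
    X = np.asarray(norm.lognorm.todense())  # genes x cells
    sigma = X.std(axis=1)

    def weighted_score(gene_pos: np.ndarray, z: np.ndarray) -> np.ndarray:
        w = z / (sigma[gene_pos] + EPS_VS)
        denom = np.abs(w).sum()
        if denom == 0:
            return np.zeros(X.shape[1])
        return w @ X[gene_pos] / denom

    risk_pos = np.array([gidx[g] for g in genes])
    z = risk.weights.loc[genes].to_numpy(float)
    raw = weighted_score(risk_pos, z)

    if np.all(z == 0):
        return pd.DataFrame(
            {"raw": raw, "normalized": 0.0, "mc_p": 1.0, "degenerate": True},
            index=pd.Index(norm.cell_ids, name="cell_id"),
        )

    # control pools per (mean_bin, var_bin)
    key = bins["mean_bin"].astype(str) + ":" + bins["var_bin"].astype(str)
    pools: dict[str, np.ndarray] = {
        k: np.array([gidx[g] for g in idx]) for k, idx in key.groupby(key).groups.items()
    }
    bin_centers = {
        k: (bins.loc[list(key[key == k].index), "mean"].mean(),) for k in pools
    }
    gene_pool = []
    for g in genes:
        k = key.loc[g]
        pool = pools[k]
        if len(pool) == 0:  # pragma: no cover - pools are never empty by construction
            k = min(pools, key=lambda kk: abs(bin_centers[kk][0] - bins.loc[g, "mean"]))
            pool = pools[k]
        gene_pool.append(pool)

    ctrl_scores = np.empty((n_ctrl, X.shape[1]))
    for c in range(n_ctrl):
        draw = np.array([pool[rng.integers(len(pool))] for pool in gene_pool])
        ctrl_scores[c] = weighted_score(draw, z)
    mu_c = ctrl_scores.mean(axis=0)
    sd_c = ctrl_scores.std(axis=0)
    sd_c = np.where(sd_c > 0, sd_c, 1.0)
    normalized = (raw - mu_c) / sd_c
    mc_p = (1.0 + (ctrl_scores >= raw[None, :]).sum(axis=0)) / (n_ctrl + 1.0)
    return pd.DataFrame(
        {"raw": raw, "normalized": normalized, "mc_p": mc_p, "degenerate": False},
        index=pd.Index(norm.cell_ids, name="cell_id"),
    )


def group_bootstrap(
    scores: pd.Series | np.ndarray,
    groups,
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile-bootstrap CI of the mean normalized score per group.

    Cells are resampled with replacement within each group ``n_boot``
    times; the CI spans the (alpha/2, 1-alpha/2) percentiles of the
    resampled means, and a group is significant iff its CI excludes 0.
    Groups of one cell report NA.
    """
    s = np.asarray(pd.Series(scores), dtype=float)
    g = np.asarray(pd.Series(groups), dtype=object)
    if len(s) != len(g):
        raise ValueError("scores and groups must align")
    rng = np.random.default_rng(seed)
    rows = []
    for u in sorted(set(g), key=str):
        vals = s[g == u]
        n = len(vals)
        if n < 2:
            import warnings

            warnings.warn(f"group {u!r} has {n} cell(s); CI is NA")
            rows.append(
                {"group": u, "n": n, "mean": float(vals.mean()) if n else np.nan,
                 "ci_lo": np.nan, "ci_hi": np.nan, "significant": False}
            )
            continue
        draws = rng.integers(0, n, size=(n_boot, n))
        means = vals[draws].mean(axis=1)
        lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        rows.append(
            {"group": u, "n": n, "mean": float(vals.mean()), "ci_lo": float(lo),
             "ci_hi": float(hi), "significant": bool(lo > 0 or hi < 0)}
        )
    return pd.DataFrame(rows)
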