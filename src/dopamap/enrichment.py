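"""Gene-set enrichment: preranked GSEA, hypergeometric over-representation
against a custom expression background, and synaptic-annotation fractions.

The preranked statistic is the weighted Kolmogorov-Smirnov running sum:
walking genes in decreasing score order, hits increment proportionally to
|score| (weight exponent 1) and misses decrement uniformly; the
enrichment score (ES) is the extremum of the running sum. Significance
comes from random same-size gene sets drawn from the ranked universe;
p-values are two-sided on |ES| with +1 smoothing, and NES divides ES by
the mean |null ES| of matching sign.

Over-representation uses the upper-tail hypergeometric with a
caller-supplied background — typically the >=10%-detection gene universe
of the contrast that produced the hit list, so that results are not
trivially enriched for cell-type-specific pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "SynapticAnnotation",
    "read_gmt",
    "write_gmt",
    "preranked_gsea",
    "overrepresentation",
    "synaptic_fractions",
]


@dataclass
class GeneSetCollection:
    """Named gene sets; symbols are upper-cased for matching."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            up = [g.upper() for g in genes]
            if not up:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = list(dict.fromkeys(up))
        self.sets = clean


def read_gmt(path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *genes]) + "\n")


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> np.ndarray:
    """Enrichment scores for one or many hit-position sets.

    ``positions``: (n_sets x k) 0-based positions of hits in the ranking,
    sorted ascending per row; ``weights``: matching |score| weights. The
    running sum is evaluated just before and just after every hit (its
    extrema can only occur there).
    """
    positions = np.atleast_2d(positions)
    weights = np.atleast_2d(weights)
    n_sets, k = positions.shape
    n_miss = n_total - k
    wsum = weights.sum(axis=1, keepdims=True)
    wsum = np.where(wsum > 0, wsum, 1.0)
    cum_hit = np.cumsum(weights, axis=1) / wsum
    j = np.arange(k)
    miss_after = (positions + 1 - (j + 1)) / max(n_miss, 1)
    miss_before = (positions - j) / max(n_miss, 1)
    after = cum_hit - miss_after
    before = np.concatenate([np.zeros((n_sets, 1)), cum_hit[:, :-1]], axis=1) - miss_before
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_sets), idx]


def preranked_gsea(
    ranked: pd.Series | dict,
    sets: GeneSetCollection,
    min_size: int = 25,
    max_size: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a gene -> score ranking.

    Returns one row per gene set that matched [min_size, max_size] genes:
    ES, NES, permutation p (two-sided on |ES|, +1 smoothing), BH-adjusted
    p, and the matched size. Sets outside the size window are recorded in
    the ``skipped`` attribute of the result frame.
    """
    s = pd.Series(ranked, dtype=float)
    if s.index.duplicated().any():
        raise ValueError("ranked list contains duplicate genes")
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("scores must be finite")
    s.index = s.index.str.upper()
    order = np.argsort(-s.to_numpy(), kind="mergesort")
    genes = s.index.to_numpy()[order]
    scores = s.to_numpy()[order]
    absw = np.abs(scores)
    pos_of = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)

    rows, skipped = [], []
    for name, members in sets.sets.items():
        hit_pos = np.sort([pos_of[g] for g in members if g in pos_of])
        k = len(hit_pos)
        if not (min_size <= k <= max_size):
            skipped.append({"set": name, "size": k})
            continue
        es = float(_es_from_positions(hit_pos, absw[hit_pos], n)[0])
        null_pos = np.sort(
            np.stack([rng.choice(n, size=k, replace=False) for _ in range(n_perm)]), axis=1
        )
        null_es = _es_from_positions(null_pos, absw[null_pos], n)
        p = (1.0 + np.sum(np.abs(null_es) >= abs(es))) / (n_perm + 1.0)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        denom = np.mean(np.abs(same_sign)) if len(same_sign) else np.mean(np.abs(null_es))
        nes = es / denom if denom > 0 else 0.0
        rows.append({"set": name, "ES": es, "NES": nes, "p": p, "size": k})
    out = pd.DataFrame(rows, columns=["set", "ES", "NES", "p", "size"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    out.attrs["skipped"] = skipped
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def overrepresentation(
    hits: list[str],
    background: list[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    ``background`` must contain every hit (use the detection-filtered gene
    universe of the comparison that produced the hits); set membership is
    intersected with the background before testing.
    """
    bg = {g.upper() for g in background}
    hit = {g.upper() for g in hits}
    stray = hit - bg
    if stray:
        raise ValueError(f"hits not in background: {sorted(stray)[:10]}")
    M, N = len(bg), len(hit)
    rows = []
    for name, members in sets.sets.items():
        in_bg = set(members) & bg
        K = len(in_bg)
        k = len(in_bg & hit)
        p = float(hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size_bg": K, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


PRESYNAPTIC_LIKE = ("presynaptic", "postsynaptic", "active zone")


@dataclass
class SynapticAnnotation:
    """Gene -> compartment labels and function labels.

    Compartment labels finer than "synaptic" (presynaptic, postsynaptic,
    active zone) imply the synaptic label, which is added if missing.
    """

    compartments: dict[str, set[str]]
    functions: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.compartments = {g.upper(): set(v) for g, v in self.compartments.items()}
        self.functions = {g.upper(): set(v) for g, v in self.functions.items()}
        for labels in self.compartments.values():
            if labels & set(PRESYNAPTIC_LIKE):
                labels.add("synaptic")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "SynapticAnnotation":
        """Build from a tidy TSV-style table: gene, compartment, function."""
        comp: dict[str, set[str]] = {}
        func: dict[str, set[str]] = {}
        for _, row in table.iterrows():
            g = str(row["gene"]).upper()
            if pd.notna(row.get("compartment")) and row.get("compartment"):
                comp.setdefault(g, set()).add(str(row["compartment"]))
            if pd.notna(row.get("function")) and row.get("function"):
                func.setdefault(g, set()).add(str(row["function"]))
        return cls(compartments=comp, functions=func)


def synaptic_fractions(degs: list[str], annotation: SynapticAnnotation) -> dict:
    """Compartment and function fractions of a DEG list.

    Reports the fraction of DEGs with any synaptic localization, and —
    among those synaptic DEGs — per-compartment and per-function fractions,
    with counts alongside (the "20/77"-style numbers).
    """
    degs_u = list(dict.fromkeys(g.upper() for g in degs))
    if not degs_u:
        return {"n_degs": 0, "n_synaptic": 0, "frac_synaptic": 0.0, "compartments": {}, "functions": {}}
    synaptic = [g for g in degs_u if "synaptic" in annotation.compartments.get(g, set())]
    n_syn = len(synaptic)
    comp_report = {}
    for label in PRESYNAPTIC_LIKE:
        hits = [g for g in synaptic if label in annotation.compartments.get(g, set())]
        comp_report[label] = {
            "count": len(hits),
            "of_synaptic": len(hits) / n_syn if n_syn else 0.0,
            "of_total": len(hits) / len(degs_u),
        }
    func_labels = sorted({f for g in synaptic for f in annotation.functions.get(g, set())})
    func_report = {}
    for label in func_labels:
        hits = [g for g in degs_u if label in annotation.functions.get(g, set())]
        func_report[label] = {"count": len(hits), "of_total": len(hits) / len(degs_u)}
    return {
        "n_degs": len(degs_u),
        "n_synaptic": n_syn,
        "frac_synaptic": n_syn / len(degs_u),
        "compartments": comp_report,
        "functions": func_report,
    }
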