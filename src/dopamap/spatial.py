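"""Mapping spatial-panel cells onto a dissociated reference taxonomy.

The transfer path is: select panel genes with comparable average counts in
both datasets, embed both in the reference PCA space fit on those shared
genes (each dataset z-scored with its own statistics), find
mutual-nearest-neighbor anchor pairs scored by neighborhood overlap, then
transfer labels and impute whole-transcriptome expression per query cell
as an anchor-weighted average. A per-query-cell similarity score in [0,1]
gates high-confidence assignments (default threshold 0.5). Anatomical
context comes from named region polygons: each cell is assigned the first
polygon (priority order) covering its coordinates, or "elsewhere".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix, NormalizedMatrix
from .taxonomy import Embedding, normalize, reduce

__all__ = [
    "AnchorSet",
    "TransferResult",
    "RegionMap",
    "select_shared_features",
    "find_anchors",
    "transfer_labels",
    "impute_expression",
    "imputation_fidelity",
    "correspondence_flows",
    "assign_regions",
    "regional_composition",
]


def select_shared_features(
    reference: CountMatrix,
    query: CountMatrix,
    max_ratio: float = 4.0,
    min_detection: float = 0.01,
) -> list[str]:
    """Panel genes with comparable average counts per cell in both datasets.

    A gene is kept iff detected in at least ``min_detection`` of cells in
    both datasets and the query/reference ratio of mean counts per cell is
    within [1/max_ratio, max_ratio]. Failed probes (zero detection in the
    query) are always excluded.
    """
    shared = [g for g in query.gene_ids if g in set(reference.gene_ids)]
    if not shared:
        raise ValueError("gene universes do not overlap")
    ri = reference.gene_index(shared)
    qi = query.gene_index(shared)
    R = reference.counts[ri]
    Q = query.counts[qi]
    det_r = np.asarray((R > 0).sum(axis=1)).ravel() / reference.n_cells
    det_q = np.asarray((Q > 0).sum(axis=1)).ravel() / query.n_cells
    mean_r = np.asarray(R.mean(axis=1)).ravel()
    mean_q = np.asarray(Q.mean(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_r > 0, mean_q / np.maximum(mean_r, 1e-300), np.inf)
    keep = (
        (det_r >= min_detection)
        & (det_q >= min_detection)
        & (det_q > 0)
        & (ratio >= 1.0 / max_ratio)
        & (ratio <= max_ratio)
    )
    out = [g for g, k in zip(shared, keep) if k]
    if not out:
        raise ValueError(
            "no shared features pass the filters; relax max_ratio or min_detection"
        )
    return out


@dataclass
class AnchorSet:
    """Mutual-nearest-neighbor pairs between reference and query cells.

    ``pairs`` has columns (ref_idx, query_idx, score); scores in [0,1] are
    the fraction of joint-space neighbors the two cells share. The joint
    embedding (reference scores and projected query scores) is retained
    for kernel weighting downstream.
    """

    pairs: pd.DataFrame
    ref_scores: np.ndarray
    query_scores: np.ndarray
    ref_cell_ids: np.ndarray
    query_cell_ids: np.ndarray


def _scale_within(X: sp.csr_matrix) -> np.ndarray:
    """Dense per-gene z-score (cells x genes) using this dataset's stats."""
    dense = np.asarray(X.todense()).T
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (dense - mu) / sd


def find_anchors(
    reference: CountMatrix,
    query: CountMatrix,
    shared_genes: list[str],
    k_anchor: int = 5,
    n_components: int = 30,
    k_score: int = 30,
    seed: int = 0,
    target_sum: float = 1e4,
) -> AnchorSet:
    """Anchor pairs from MNN matching in a projected joint space.

    Both datasets are depth-normalized on the shared genes and z-scored
    per dataset; the reference defines a PCA basis and the query is
    projected onto it. MNN pairs at ``k_anchor`` cross-dataset neighbors
    become anchors, scored by the Jaccard-style overlap of their
    ``k_score`` joint-space neighborhoods.
    """
    if len(shared_genes) < 30:
        raise ValueError(f"need >= 30 shared genes, got {len(shared_genes)}")
    ref_sub = reference.subset_genes(shared_genes)
    qry_sub = query.subset_genes(shared_genes)
    ref_norm = normalize(ref_sub, target_sum=target_sum)
    qry_norm = normalize(qry_sub, target_sum=target_sum)
    ref_scaled = ref_norm.scaled
    qry_scaled = qry_norm.scaled

    n_comp = min(n_components, len(shared_genes) - 1, ref_scaled.shape[0] - 1)
    emb = reduce(ref_norm, n_components=n_comp, seed=seed)
    center = ref_scaled.mean(axis=0)  # PCA centers the clipped matrix
    ref_pc = (ref_scaled - center) @ emb.loadings
    qry_pc = (qry_scaled - center) @ emb.loadings

    nn_r = NearestNeighbors(n_neighbors=min(k_anchor, len(ref_pc))).fit(ref_pc)
    nn_q = NearestNeighbors(n_neighbors=min(k_anchor, len(qry_pc))).fit(qry_pc)
    q_to_r = nn_r.kneighbors(qry_pc, return_distance=False)
    r_to_q = nn_q.kneighbors(ref_pc, return_distance=False)
    r_sets = [set(row) for row in r_to_q]
    pairs = [
        (int(r), int(q))
        for q in range(len(qry_pc))
        for r in q_to_r[q]
        if q in r_sets[int(r)]
    ]
    if not pairs:
        raise ValueError("no mutual nearest neighbor pairs found")

    joint = np.vstack([ref_pc, qry_pc])
    k_eff = min(k_score, len(joint) - 1)
    nn_joint = NearestNeighbors(n_neighbors=k_eff).fit(joint)
    # neighborhoods include the point itself so that coincident cells
    # (identical profiles) share their full neighborhood and score 1
    neigh = nn_joint.kneighbors(joint, return_distance=False)
    neigh_sets = [set(row) | {i} for i, row in enumerate(neigh)]
    n_ref = len(ref_pc)
    scores = [
        np.clip(len(neigh_sets[r] & neigh_sets[n_ref + q]) / k_eff, 0.0, 1.0)
        for r, q in pairs
    ]
    table = pd.DataFrame(pairs, columns=["ref_idx", "query_idx"])
    table["score"] = scores
    return AnchorSet(
        pairs=table,
        ref_scores=ref_pc,
        query_scores=qry_pc,
        ref_cell_ids=ref_norm.cell_ids,
        query_cell_ids=qry_norm.cell_ids,
    )


@dataclass
class TransferResult:
    """Per-query-cell predicted label with similarity score and gate flag."""

    table: pd.DataFrame  # index query cell id: predicted_label, score, high_confidence
    label_scores: pd.DataFrame  # query cells x labels, rows sum to 1
    score_threshold: float


def _anchor_weights(anchors: AnchorSet, k_weight: int) -> tuple[np.ndarray, np.ndarray]:
    """(query_cells x anchors) dense weight matrix, rows sum to 1.

    Each query cell takes its ``k_weight`` nearest anchors (by distance to
    the anchor's query cell in the joint space), weighted by a Gaussian
    kernel with bandwidth the k-th distance, times the anchor score. An
    anchor coincident with the query cell on both of its sides is an
    exact profile match and takes the entire weight (this makes mapping a
    dataset onto itself reproduce it instead of smoothing it).
    Returns (weights, reachable mask).
    """
    anchor_q = anchors.pairs["query_idx"].to_numpy()
    anchor_r = anchors.pairs["ref_idx"].to_numpy()
    anchor_pos = anchors.query_scores[anchor_q]
    k_eff = min(k_weight, len(anchor_pos))
    nn = NearestNeighbors(n_neighbors=k_eff).fit(anchor_pos)
    dist, ind = nn.kneighbors(anchors.query_scores)
    bw = np.maximum(dist[:, -1], 1e-12)
    kern = np.exp(-0.5 * (dist / bw[:, None]) ** 2)
    kern *= anchors.pairs["score"].to_numpy()[ind]
    tol = 1e-6 * np.maximum(bw, 1.0)
    near_q = dist < tol[:, None]
    if near_q.any():
        ref_pos = anchors.ref_scores[anchor_r[ind]]  # cells x k x K
        dr = np.linalg.norm(ref_pos - anchors.query_scores[:, None, :], axis=2)
        exact = near_q & (dr < tol[:, None])
        has_exact = exact.any(axis=1)
        kern[has_exact] = np.where(exact[has_exact], kern[has_exact], 0.0)
    W = np.zeros((len(anchors.query_scores), len(anchors.pairs)))
    rows = np.repeat(np.arange(len(anchors.query_scores)), k_eff)
    W[rows, ind.ravel()] = kern.ravel()
    totals = W.sum(axis=1)
    reachable = totals > 0
    W[reachable] /= totals[reachable, None]
    return W, reachable


def transfer_labels(
    anchors: AnchorSet,
    reference_labels,
    k_weight: int = 50,
    score_threshold: float = 0.5,
) -> TransferResult:
    """Kernel-weighted anchor voting for reference labels.

    Per query cell, label scores are the summed normalized weights of its
    anchors carrying each reference label; the prediction is the argmax
    and the similarity score its value. Cells with no reachable anchor get
    score 0 and label "unassigned".
    """
    if len(anchors.pairs) == 0:
        raise ValueError("anchor set is empty")
    ref_labels = np.asarray(pd.Series(reference_labels, dtype=object))
    W, reachable = _anchor_weights(anchors, k_weight)
    anchor_lab = ref_labels[anchors.pairs["ref_idx"].to_numpy()]
    uniq = sorted(set(anchor_lab), key=str)
    score_mat = np.zeros((W.shape[0], len(uniq)))
    for j, u in enumerate(uniq):
        score_mat[:, j] = W[:, anchor_lab == u].sum(axis=1)
    best = np.argmax(score_mat, axis=1)
    best_score = score_mat[np.arange(len(best)), best]
    predicted = np.array([uniq[b] for b in best], dtype=object)
    predicted[~reachable] = "unassigned"
    best_score[~reachable] = 0.0
    table = pd.DataFrame(
        {
            "predicted_label": predicted,
            "score": best_score,
            "high_confidence": best_score > score_threshold,
        },
        index=pd.Index(anchors.query_cell_ids, name="cell_id"),
    )
    label_scores = pd.DataFrame(score_mat, index=table.index, columns=[str(u) for u in uniq])
    return TransferResult(table=table, label_scores=label_scores, score_threshold=score_threshold)


def impute_expression(
    anchors: AnchorSet,
    reference_norm: NormalizedMatrix,
    k_weight: int = 50,
) -> pd.DataFrame:
    """Anchor-weighted average of reference normalized expression.

    Returns a query-cells x reference-genes table covering genes absent
    from the spatial panel; each imputed value is a convex combination of
    the contributing reference cells' normalized expression.
    """
    if len(anchors.pairs) == 0:
        raise ValueError("anchor set is empty")
    W, _ = _anchor_weights(anchors, k_weight)
    ref_expr = np.asarray(reference_norm.lognorm.todense()).T  # ref cells x genes
    anchor_expr = ref_expr[anchors.pairs["ref_idx"].to_numpy()]
    imputed = W @ anchor_expr
    return pd.DataFrame(
        imputed,
        index=pd.Index(anchors.query_cell_ids, name="cell_id"),
        columns=reference_norm.gene_ids,
    )


def imputation_fidelity(
    imputed: pd.DataFrame,
    measured: CountMatrix,
    genes: list[str] | None = None,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-gene Pearson r between measured and imputed expression.

    Computed over cells with non-zero values in both matrices; genes with
    fewer than ``min_cells`` such cells (e.g. failed probes) report NA.
    """
    if genes is None:
        genes = [g for g in measured.gene_ids if g in set(imputed.columns)]
    cells = [c for c in imputed.index if c in set(measured.cell_ids)]
    meas = np.asarray(measured.subset_cells(cells).counts.todense())
    meas_genes = {g: i for i, g in enumerate(measured.gene_ids)}
    imp = imputed.loc[cells]
    rows = []
    for g in genes:
        x = meas[meas_genes[g]]
        y = imp[g].to_numpy(float)
        mask = (x > 0) & (y > 0)
        if mask.sum() < min_cells:
            rows.append({"gene": g, "r": np.nan, "n_cells": int(mask.sum())})
            continue
        xv, yv = x[mask], y[mask]
        if xv.std() == 0 or yv.std() == 0:
            rows.append({"gene": g, "r": np.nan, "n_cells": int(mask.sum())})
            continue
        rows.append({"gene": g, "r": float(np.corrcoef(xv, yv)[0, 1]), "n_cells": int(mask.sum())})
    return pd.DataFrame(rows)


def correspondence_flows(labels_a, labels_b, min_flow: float = 0.10) -> pd.DataFrame:
    """Cluster-correspondence flow table between two labelings.

    Rows are (source, target, n_cells, fraction of source); fractions per
    source sum to 1 before rows below ``min_flow`` are dropped.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b):
        raise ValueError("labelings must cover the same cells")
    if len(a) == 0:
        raise ValueError("empty labelings")
    tab = pd.crosstab(a.to_numpy(), b.to_numpy())
    rows = []
    for src in tab.index:
        total = tab.loc[src].sum()
        for dst in tab.columns:
            n = int(tab.loc[src, dst])
            frac = n / total
            if n and frac >= min_flow:
                rows.append({"source": src, "target": dst, "n_cells": n, "fraction": frac})
    return pd.DataFrame(rows, columns=["source", "target", "n_cells", "fraction"])


@dataclass
class RegionMap:
    """Named 2-D polygons (micrometers) in priority order."""

    polygons: list[tuple[str, Polygon]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.polygons]
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique")
        for n, p in self.polygons:
            if not p.is_valid or p.area == 0:
                raise ValueError(f"malformed region polygon {n!r}")

    @classmethod
    def from_geojson(cls, obj: dict) -> "RegionMap":
        polys = []
        for feat in obj.get("features", []):
            name = feat.get("properties", {}).get("name")
            if name is None:
                raise ValueError("region feature lacks a 'name' property")
            coords = feat["geometry"]["coordinates"][0]
            polys.append((name, Polygon(coords)))
        return cls(polys)

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"name": n},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[list(pt) for pt in p.exterior.coords]],
                    },
                }
                for n, p in self.polygons
            ],
        }


def assign_regions(cell_meta: pd.DataFrame, regions: RegionMap) -> pd.Series:
    """Region label per cell: first polygon (priority order) covering the
    point wins, boundary points count as inside, otherwise "elsewhere"."""
    if "x_um" not in cell_meta.columns or "y_um" not in cell_meta.columns:
        raise ValueError("cell metadata lacks x_um / y_um coordinates")
    prepared = [(name, prep(poly), poly) for name, poly in regions.polygons]
    out = []
    for x, y in zip(cell_meta["x_um"], cell_meta["y_um"]):
        pt = Point(float(x), float(y))
        label = "elsewhere"
        for name, prepped, poly in prepared:
            # prepared covers() excludes some boundary cases; fall back to exact
            if prepped.contains(pt) or poly.covers(pt):
                label = name
                break
        out.append(label)
    return pd.Series(out, index=cell_meta.index, name="region")


def regional_composition(region_labels, group_labels) -> dict[str, pd.DataFrame]:
    """Counts plus both normalizations of the region x group table.

    ``within_region`` rows sum to 1 (what each region is composed of);
    ``within_group`` columns sum to 1 (how each group distributes over
    regions).
    """
    r = pd.Series(region_labels)
    g = pd.Series(group_labels)
    if len(r) != len(g):
        raise ValueError("labelings must cover the same cells")
    counts = pd.crosstab(r.to_numpy(), g.to_numpy())
    counts.index.name = "region"
    counts.columns.name = "group"
    within_region = counts.div(counts.sum(axis=1), axis=0)
    within_group = counts.div(counts.sum(axis=0), axis=1)
    return {"counts": counts, "within_region": within_region, "within_group": within_group}
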