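"""Clustering taxonomy: normalization, embedding, community detection,
cluster dendrogram, node-wise differential expression, stepwise marker
codes, shorthand names, and resampling-based cluster stability.

The analysis path mirrors the standard droplet single-cell workflow:
depth normalization to a fixed target sum with log1p, per-gene z-scoring
clipped at a cap, PCA, an exact k-nearest-neighbor graph converted to
shared-nearest-neighbor (Jaccard) weights, and seeded modularity community
detection. The dendrogram is average-linkage agglomeration of cluster
centroids in PC space. Differential expression at each dendrogram node —
restricted to cells descending from that node — yields branch markers,
from which each leaf inherits a stepwise code: the ordered list of
branch-defining genes from root to leaf that uniquely identifies it as an
intersectional gate recipe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "Embedding",
    "Clustering",
    "TaxonomyTree",
    "normalize",
    "reduce",
    "cluster",
    "cluster_pipeline",
    "build_tree",
    "rank_markers",
    "annotate_nodes",
    "derive_codes",
    "name_clusters",
    "stability",
    "summarize_stability",
    "resolution_sweep",
]


# ---------------------------------------------------------------------------
# normalization and embedding
# ---------------------------------------------------------------------------

def normalize(matrix: CountMatrix, target_sum: float = 1e4, scale_cap: float = 10.0) -> NormalizedMatrix:
    """Depth-normalize to ``target_sum`` counts, log1p, then z-score genes.

    Zero-depth cells are excluded with a warning (they carry no
    information). Constant genes get all-zero z-scores. The z-scored form
    is clipped at ``+-scale_cap`` and densified (cells x genes) for PCA.
    """
    X = matrix.counts.tocsc().astype(np.float64)
    depth = np.asarray(X.sum(axis=0)).ravel()
    keep = depth > 0
    if not keep.all():
        import warnings

        warnings.warn(f"excluding {np.sum(~keep)} zero-depth cells from normalization")
        X = X[:, keep]
        depth = depth[keep]
    X = X.multiply(target_sum / depth[np.newaxis, :]).tocsr()
    X.data = np.log1p(X.data)

    dense = np.asarray(X.todense()).T  # cells x genes
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    scaled = (dense - mu) / sd_safe
    scaled[:, sd == 0] = 0.0
    np.clip(scaled, -scale_cap, scale_cap, out=scaled)
    return NormalizedMatrix(
        lognorm=X.tocsr(),
        scaled=scaled,
        gene_ids=matrix.gene_ids,
        cell_ids=matrix.cell_ids[keep],
        target_sum=target_sum,
        scale_cap=scale_cap,
        gene_means=mu,
        gene_stds=sd,
    )


@dataclass
class Embedding:
    """PCA scores (cells x K) and loadings (genes x K) with provenance."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    n_components: int
    seed: int


def reduce(norm: NormalizedMatrix, n_components: int = 32, seed: int = 0) -> Embedding:
    """PCA of the scaled matrix with a fixed sign convention.

    Each component's sign is chosen so its largest-magnitude loading is
    positive, making runs reproducible across BLAS builds.
    """
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    rank = min(norm.scaled.shape)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank bound {rank}")
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(norm.scaled)
    loadings = pca.components_.T  # genes x K
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return Embedding(
        scores=scores * flip,
        loadings=loadings * flip,
        explained_variance_ratio=pca.explained_variance_ratio_,
        cell_ids=norm.cell_ids,
        gene_ids=norm.gene_ids,
        n_components=n_components,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# graph clustering
# ---------------------------------------------------------------------------

@dataclass
class Clustering:
    labels: np.ndarray  # contiguous ints from 0
    k_neighbors: int
    resolution: float
    seed: int
    modularity: float
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def _snn_graph(scores: np.ndarray, k_neighbors: int, prune: float = 1 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor Jaccard weights over the exact kNN graph.

    Neighborhoods include the cell itself (the usual convention for
    ``k.param``); edges with Jaccard overlap below ``prune`` are dropped.
    """
    n = scores.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k_neighbors, n)).fit(scores)
    ind = nn.kneighbors(return_distance=False)
    rows = np.repeat(np.arange(n), ind.shape[1])
    A = sp.csr_matrix(
        (np.ones(rows.size), (rows, ind.ravel())), shape=(n, n), dtype=np.float64
    )
    A = A.maximum(sp.identity(n, format="csr"))
    k = np.asarray(A.sum(axis=1)).ravel()
    inter = (A @ A.T).tocoo()
    union = k[inter.row] + k[inter.col] - inter.data
    jac = inter.data / union
    keep = (jac >= prune) & (inter.row != inter.col)
    return sp.csr_matrix((jac[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))


def cluster(
    embedding: Embedding,
    k_neighbors: int = 40,
    resolution: float = 0.8,
    seed: int = 0,
) -> Clustering:
    """Seeded modularity community detection on the SNN graph.

    Singleton communities are merged into the cluster with the nearest
    centroid; labels are relabeled 0..k-1 by decreasing size (ties broken
    by smallest member index).
    """
    n = embedding.scores.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < n_cells")
    W = _snn_graph(embedding.scores, k_neighbors)
    W = ((W + W.T) / 2).tocoo()
    mask = W.row < W.col
    g = ig.Graph(
        n=n,
        edges=list(zip(W.row[mask].tolist(), W.col[mask].tolist())),
        edge_attrs={"weight": W.data[mask].tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)

    # merge singletons into the nearest cluster by centroid distance
    sizes = np.bincount(labels)
    if (sizes == 1).any() and (sizes > 1).any():
        big = np.flatnonzero(sizes > 1)
        centroids = np.vstack([embedding.scores[labels == b].mean(axis=0) for b in big])
        for lone in np.flatnonzero(sizes == 1):
            i = int(np.flatnonzero(labels == lone)[0])
            d = np.linalg.norm(centroids - embedding.scores[i], axis=1)
            labels[i] = big[int(np.argmin(d))]

    # contiguous relabel by decreasing size, then first-member order
    uniq = np.unique(labels)
    order = sorted(uniq, key=lambda u: (-(labels == u).sum(), int(np.flatnonzero(labels == u)[0])))
    remap = {u: i for i, u in enumerate(order)}
    labels = np.array([remap[u] for u in labels])
    return Clustering(
        labels=labels,
        k_neighbors=k_neighbors,
        resolution=resolution,
        seed=seed,
        modularity=float(part.modularity),
        cell_ids=embedding.cell_ids,
    )


def cluster_pipeline(
    matrix: CountMatrix,
    target_sum: float = 1e4,
    scale_cap: float = 10.0,
    n_components: int = 32,
    k_neighbors: int = 40,
    resolution: float = 0.8,
    seed: int = 0,
) -> tuple[NormalizedMatrix, Embedding, Clustering]:
    """normalize -> reduce -> cluster with one parameter set."""
    norm = normalize(matrix, target_sum=target_sum, scale_cap=scale_cap)
    n_comp = min(n_components, min(norm.scaled.shape) - 1)
    emb = reduce(norm, n_components=max(2, n_comp), seed=seed)
    clu = cluster(emb, k_neighbors=min(k_neighbors, norm.n_cells - 1), resolution=resolution, seed=seed)
    return norm, emb, clu


# ---------------------------------------------------------------------------
# dendrogram
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyTree:
    """Binary dendrogram over cluster ids with per-node marker tables.

    ``children`` maps internal node name -> (left, right); leaves are the
    string forms of cluster ids. ``node_markers[node][side]`` holds the
    MarkerRow table for that side vs the other, computed from descendant
    cells only. ``codes[leaf]`` is the stepwise (gene, "+") list;
    ``names[leaf]`` the Family^TopGene shorthand.
    """

    children: dict[str, tuple[str, str]]
    root: str
    leaves: list[str]
    node_markers: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)
    flagged_nodes: list[str] = field(default_factory=list)
    codes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    recipes: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    top_genes: dict[str, list[str]] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)

    def descendant_leaves(self, node: str) -> list[str]:
        if node not in self.children:
            return [node]
        l, r = self.children[node]
        return self.descendant_leaves(l) + self.descendant_leaves(r)

    def path_to(self, leaf: str) -> list[tuple[str, str]]:
        path: list[tuple[str, str]] = []
        node = self.root
        while node in self.children:
            l, r = self.children[node]
            if leaf in self.descendant_leaves(l):
                path.append((node, "left"))
                node = l
            else:
                path.append((node, "right"))
                node = r
        if node != leaf:
            raise KeyError(f"leaf {leaf!r} not in tree")
        return path

    def internal_nodes(self) -> list[str]:
        return list(self.children)

    def to_newick(self) -> str:
        def fmt(node: str) -> str:
            if node not in self.children:
                return self.names.get(node, node).replace(" ", "_")
            l, r = self.children[node]
            return f"({fmt(l)},{fmt(r)})"

        return fmt(self.root) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions (as the smaller-side frozenset isn't
        canonical, both sides' sets are reduced to the one not containing
        the first leaf)."""
        anchor = self.leaves[0]
        parts = set()
        for node in self.children:
            below = set(self.descendant_leaves(node))
            if 1 < len(below) < len(self.leaves):
                side = below if anchor not in below else set(self.leaves) - below
                parts.add(frozenset(side))
        return parts


def build_tree(embedding: Embedding, clustering: Clustering) -> TaxonomyTree:
    """Average-linkage agglomeration of cluster centroids in PC space."""
    labels = clustering.labels
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters to build a tree")
    centroids = np.vstack([embedding.scores[labels == u].mean(axis=0) for u in uniq])
    Z = linkage(centroids, method="average", metric="euclidean")
    children: dict[str, tuple[str, str]] = {}
    node_name = {i: str(uniq[i]) for i in range(len(uniq))}
    for j, (a, b, _, _) in enumerate(Z):
        name = f"n{j}"
        children[name] = (node_name[int(a)], node_name[int(b)])
        node_name[len(uniq) + j] = name
    root = node_name[len(uniq) + len(Z) - 1]
    tree = TaxonomyTree(children=children, root=root, leaves=[str(u) for u in uniq])
    tree.families = _assign_families(tree)
    return tree


def _assign_families(tree: TaxonomyTree, n_splits: int = 2) -> dict[str, str]:
    """Leaf -> family from the top-level divisions of the tree.

    The root split and the next split of the largest internal part give
    (up to) three families, mirroring major-branch-point families.
    """
    groups: list[str] = [tree.root]
    for _ in range(n_splits):
        splittable = [g for g in groups if g in tree.children]
        if not splittable:
            break
        largest = max(splittable, key=lambda g: len(tree.descendant_leaves(g)))
        groups.remove(largest)
        groups.extend(tree.children[largest])
    fam = {}
    for i, g in enumerate(sorted(groups, key=lambda g: -len(tree.descendant_leaves(g)))):
        for leaf in tree.descendant_leaves(g):
            fam[leaf] = f"Fam{i + 1}"
    return fam


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def rank_markers(
    norm: NormalizedMatrix,
    cells_a,
    cells_b,
    min_pct: float = 0.2,
    min_diff_pct: float = 0.25,
    logfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Wilcoxon rank-sum markers of group A vs group B.

    Per gene: detection fractions pct1/pct2; fold change
    ``log2((mean(expm1 x_A) + 1) / (mean(expm1 x_B) + 1))``. A gene is
    tested only if ``max(pct1, pct2) >= min_pct`` and
    ``|pct1 - pct2| >= min_diff_pct`` and ``|log2fc| >= logfc_threshold``.
    P-values use the normal approximation with tie correction; BH
    adjustment is across tested genes. Rows are sorted by decreasing
    |log2fc|, then p, then gene id.
    """
    ia = np.asarray(cells_a, dtype=int)
    ib = np.asarray(cells_b, dtype=int)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both groups must be non-empty")
    X = norm.lognorm.tocsc()
    A = X[:, ia]
    B = X[:, ib]
    pct1 = np.asarray((A > 0).sum(axis=1)).ravel() / len(ia)
    pct2 = np.asarray((B > 0).sum(axis=1)).ravel() / len(ib)
    Aa = A.copy()
    Aa.data = np.expm1(Aa.data)
    Bb = B.copy()
    Bb.data = np.expm1(Bb.data)
    mean_a = np.asarray(Aa.mean(axis=1)).ravel()
    mean_b = np.asarray(Bb.mean(axis=1)).ravel()
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    tested = (
        (np.maximum(pct1, pct2) >= min_pct)
        & (np.abs(pct1 - pct2) >= min_diff_pct)
        & (np.abs(log2fc) >= logfc_threshold)
    )
    idx = np.flatnonzero(tested)
    if len(idx) == 0:
        return pd.DataFrame(columns=["gene", "log2fc", "pct1", "pct2", "p", "p_adj"])
    dense_a = np.asarray(A[idx].todense())
    dense_b = np.asarray(B[idx].todense())
    res = mannwhitneyu(dense_a, dense_b, axis=1, alternative="two-sided", method="asymptotic")
    p = np.atleast_1d(res.pvalue)
    p = np.where(np.isnan(p), 1.0, p)  # all-tied gene: no evidence either way
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": norm.gene_ids[idx],
            "log2fc": log2fc[idx],
            "pct1": pct1[idx],
            "pct2": pct2[idx],
            "p": p,
            "p_adj": p_adj,
        }
    )
    out = out.sort_values(
        by=["log2fc", "p", "gene"],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def annotate_nodes(
    tree: TaxonomyTree,
    norm: NormalizedMatrix,
    clustering: Clustering,
    min_pct: float = 0.2,
    min_diff_pct: float = 0.25,
    logfc_threshold: float = 1.0,
) -> TaxonomyTree:
    """Node-wise DE between the two arms, using descendant cells only.

    For each internal node, ``node_markers[node]["left"]`` is the marker
    table of the left arm vs the right arm (and symmetrically); arms with
    fewer than 3 cells leave the node un-annotated and flagged.
    """
    labels = clustering.labels.astype(str)
    tree.node_markers = {}
    tree.flagged_nodes = []
    for node in tree.internal_nodes():
        l, r = tree.children[node]
        left_cells = np.flatnonzero(np.isin(labels, tree.descendant_leaves(l)))
        right_cells = np.flatnonzero(np.isin(labels, tree.descendant_leaves(r)))
        if len(left_cells) < 3 or len(right_cells) < 3:
            tree.flagged_nodes.append(node)
            continue
        left_tab = rank_markers(norm, left_cells, right_cells, min_pct, min_diff_pct, logfc_threshold)
        right_tab = left_tab.copy()
        right_tab["log2fc"] = -right_tab["log2fc"]
        right_tab[["pct1", "pct2"]] = right_tab[["pct2", "pct1"]].to_numpy()
        right_tab = right_tab.sort_values(
            by=["log2fc", "p", "gene"],
            key=lambda s: -s.abs() if s.name == "log2fc" else s,
            kind="mergesort",
        ).reset_index(drop=True)
        tree.node_markers[node] = {"left": left_tab, "right": right_tab}
    return tree


def _top_side_marker(table: pd.DataFrame, rank: int = 0) -> str | None:
    """rank-th gene upregulated on this side (positive log2fc)."""
    up = table[table["log2fc"] > 0]
    if len(up) <= rank:
        return None
    return str(up.iloc[rank]["gene"])


def derive_codes(tree: TaxonomyTree, markers_per_node: int = 3) -> TaxonomyTree:
    """Stepwise code per leaf: top up-markers of each side taken, root->leaf.

    Codes are distinct by construction (distinct root-to-leaf paths); an
    un-annotated node on a path raises. The intersectional recipe string
    renders each step as positive detection gates; ``markers_per_node``
    genes per branch (default 3) keep the gates stringent, since a single
    moderately enriched gene is a leaky detection gate.
    """
    tree.codes = {}
    tree.recipes = {}
    for leaf in tree.leaves:
        code: list[tuple[str, str]] = []
        for node, side in tree.path_to(leaf):
            if node not in tree.node_markers:
                raise ValueError(f"node {node!r} on path to leaf {leaf!r} is not annotated")
            for k in range(markers_per_node):
                g = _top_side_marker(tree.node_markers[node][side], k)
                if g is not None:
                    code.append((g, "+"))
        tree.codes[leaf] = code
        tree.recipes[leaf] = " & ".join(f"{g}{s}" for g, s in code)
    rendered = list(tree.recipes.values())
    if len(set(rendered)) != len(rendered):
        raise ValueError("stepwise codes are not unique across leaves")
    return tree


def name_clusters(
    tree: TaxonomyTree,
    norm: NormalizedMatrix,
    clustering: Clustering,
    min_pct: float = 0.2,
    min_diff_pct: float = 0.0,
    logfc_threshold: float = 0.25,
) -> TaxonomyTree:
    """Shorthand Family^TopGene names from one-vs-rest-of-family DE.

    Within each family, each cluster is contrasted against the family's
    other cells; the top upregulated gene names the cluster, collisions
    fall through to the next-ranked gene, and clusters without passing
    markers (or single-cluster families) get a ``Family^cN`` fallback.
    The top 3 genes per cluster are retained for reporting.
    """
    labels = clustering.labels.astype(str)
    tree.names = {}
    tree.top_genes = {}
    used: set[str] = set()
    for leaf in sorted(tree.leaves, key=lambda x: (len(x), x)):
        fam = tree.families.get(leaf, "Fam?")
        fam_leaves = [l for l, f in tree.families.items() if f == fam]
        own = np.flatnonzero(labels == leaf)
        rest = np.flatnonzero(np.isin(labels, [l for l in fam_leaves if l != leaf]))
        table = (
            rank_markers(norm, own, rest, min_pct, min_diff_pct, logfc_threshold)
            if len(rest) >= 3 and len(own) >= 3
            else pd.DataFrame(columns=["gene", "log2fc", "pct1", "pct2", "p", "p_adj"])
        )
        up = table[table["log2fc"] > 0]
        tree.top_genes[leaf] = [str(g) for g in up["gene"].head(3)]
        name = None
        for g in up["gene"]:
            cand = f"{fam}^{g}"
            if cand not in used:
                name = cand
                break
        if name is None:
            name = f"{fam}^c{leaf}"
        used.add(name)
        tree.names[leaf] = name
    return tree


# ---------------------------------------------------------------------------
# stability and resolution sweep
# ---------------------------------------------------------------------------

def _coclustering_score(orig_members: np.ndarray, new_labels: np.ndarray) -> float:
    """Pair-Jaccard co-clustering score of one original cluster.

    Let O be the retained cell pairs inside the original cluster and N the
    retained pairs sharing a replicate cluster with at least one endpoint
    in the original cluster; the score is |O & N| / |O | N|. A cluster
    whose members are split apart loses pairs from O; a cluster merged
    with outsiders gains spurious pairs in N — both depress the score,
    which is 1 exactly when the cluster reappears unchanged.
    ``orig_members`` indexes into ``new_labels`` (retained cells only).
    """
    n = len(orig_members)
    o_pairs = n * (n - 1) / 2
    member_labels = new_labels[orig_members]
    inter = 0.0
    spurious = 0.0
    rep_sizes = np.bincount(new_labels)
    for lab in np.unique(member_labels):
        k = int((member_labels == lab).sum())
        inter += k * (k - 1) / 2
        spurious += k * (rep_sizes[lab] - k)
    union = o_pairs + spurious
    return inter / union if union else 1.0


def stability(
    matrix: CountMatrix,
    clustering: Clustering,
    downsample_frac: float = 0.8,
    n_reps: int = 10,
    seed: int = 0,
    **pipeline_params,
) -> pd.DataFrame:
    """Downsample-recluster stability per original cluster.

    Each replicate samples ``downsample_frac`` of cells without
    replacement, re-runs the full normalize/reduce/cluster pipeline with
    the original parameters, and scores each original cluster by the
    pair-Jaccard co-clustering score (see ``_coclustering_score``): 1 when
    the cluster reappears intact, depressed when its cells scatter or the
    cluster absorbs outsiders. Returns long-format rows
    (cluster, rep, score); clusters with fewer than 2 retained cells skip
    that replicate.
    """
    if not 0 < downsample_frac < 1:
        raise ValueError("downsample_frac must be in (0, 1)")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    pipeline_params.setdefault("k_neighbors", clustering.k_neighbors)
    pipeline_params.setdefault("resolution", clustering.resolution)
    rng = np.random.default_rng(seed)
    n = matrix.n_cells
    rows = []
    for rep in range(n_reps):
        keep = np.sort(rng.choice(n, size=int(round(downsample_frac * n)), replace=False))
        sub = matrix.subset_cells(keep)
        _, _, sub_clu = cluster_pipeline(sub, seed=int(rng.integers(2**31)), **pipeline_params)
        pos_in_keep = {c: i for i, c in enumerate(keep)}
        for u in np.unique(clustering.labels):
            members = np.flatnonzero(clustering.labels == u)
            retained = np.array([pos_in_keep[m] for m in members if m in pos_in_keep], dtype=int)
            if len(retained) < 2:
                continue
            rows.append(
                {"cluster": int(u), "rep": rep, "score": _coclustering_score(retained, sub_clu.labels)}
            )
    return pd.DataFrame(rows)


def summarize_stability(report: pd.DataFrame) -> pd.DataFrame:
    """Box-plot statistics per cluster: median, quartiles, whiskers at
    1.5x IQR, and outlier scores beyond them."""
    out = []
    for u, grp in report.groupby("cluster"):
        s = grp["score"].to_numpy()
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        out.append(
            {
                "cluster": u,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_lo": s[s >= lo].min(),
                "whisker_hi": s[s <= hi].max(),
                "outliers": list(s[(s < lo) | (s > hi)]),
                "n_reps": len(s),
            }
        )
    return pd.DataFrame(out)


def resolution_sweep(
    embedding: Embedding,
    resolutions: list[float],
    k_neighbors: int = 40,
    seed: int = 0,
) -> tuple[dict[float, Clustering], pd.DataFrame]:
    """Clusterings at each resolution plus the cross-resolution flow table.

    The edge table links each cluster at resolution i to the clusters its
    cells fall into at resolution i+1, weighted by cell count — the input
    for cluster-tree plots.
    """
    if sorted(resolutions) != list(resolutions):
        raise ValueError("resolutions must be sorted ascending")
    clusterings = {
        r: cluster(embedding, k_neighbors=k_neighbors, resolution=r, seed=seed) for r in resolutions
    }
    rows = []
    for r_lo, r_hi in zip(resolutions[:-1], resolutions[1:]):
        a = clusterings[r_lo].labels
        b = clusterings[r_hi].labels
        tab = pd.crosstab(a, b)
        for src in tab.index:
            for dst in tab.columns:
                w = int(tab.loc[src, dst])
                if w:
                    rows.append(
                        {"res_from": r_lo, "cluster_from": int(src), "res_to": r_hi,
                         "cluster_to": int(dst), "n_cells": w}
                    )
    return clusterings, pd.DataFrame(rows)
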