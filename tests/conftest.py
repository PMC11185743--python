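"""Shared fixtures: the default synthetic study, computed once per session.

The default study conditions — 3 families, 6 leaves, 4-fold branch
markers, 3000 cells at 5000 mean UMI — are expensive enough that the
clustered reference and its taxonomy are session-scoped and shared by the
recovery, spatial, contrast, and risk tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import dopamap.qc as qc
import dopamap.synthio as synthio
import dopamap.taxonomy as taxonomy


@pytest.fixture(scope="session")
def truth6():
    return synthio.make_truth(n_genes=600, leaves_per_family=(2, 2, 2), seed=1, effect_size=4.0)


@pytest.fixture(scope="session")
def reference(truth6):
    return synthio.simulate_counts(truth6, n_cells=3000, depth_mean=5000.0, seed=1)


@pytest.fixture(scope="session")
def clustered(truth6, reference):
    """Doublet-cleaned reference with normalization, embedding, clustering,
    annotated tree, and the cluster <-> planted-leaf correspondence."""
    _, _, clu0 = taxonomy.cluster_pipeline(reference)
    flagged = qc.flag_doublet_clusters(reference, clu0.labels, truth6.glial_genes, 0.5)
    clean = reference.subset_cells(np.flatnonzero(~np.isin(clu0.labels, flagged)))
    norm, emb, clu = taxonomy.cluster_pipeline(clean)
    tree = taxonomy.build_tree(emb, clu)
    tree = taxonomy.annotate_nodes(tree, norm, clu)
    tree = taxonomy.derive_codes(tree)
    tree = taxonomy.name_clusters(tree, norm, clu)
    truth_leaf = clean.cell_meta["truth_leaf"].to_numpy()
    cross = pd.crosstab(truth_leaf, clu.labels)
    cluster_to_leaf = {str(c): cross[c].idxmax() for c in cross.columns}
    return {
        "matrix": clean,
        "norm": norm,
        "embedding": emb,
        "clustering": clu,
        "tree": tree,
        "truth_leaf": truth_leaf,
        "cluster_to_leaf": cluster_to_leaf,
        "leaf_to_cluster": {v: k for k, v in cluster_to_leaf.items()},
    }


@pytest.fixture(scope="session")
def spatial_query(truth6, clustered):
    return synthio.simulate_spatial(truth6, clustered["matrix"], n_cells=1500, seed=2)


def two_blob_counts(n_per: int = 120, n_genes: int = 60, seed: int = 0, separation: float = 8.0):
    """Two Poisson populations with disjoint high-expression gene blocks."""
    rng = np.random.default_rng(seed)
    base = np.full(n_genes, 2.0)
    mu_a = base.copy()
    mu_a[: n_genes // 4] *= separation
    mu_b = base.copy()
    mu_b[n_genes // 4 : n_genes // 2] *= separation
    counts = np.concatenate(
        [
            rng.poisson(mu_a, size=(n_per, n_genes)),
            rng.poisson(mu_b, size=(n_per, n_genes)),
        ]
    ).T
    from dopamap.containers import CountMatrix

    genes = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    cells = np.array([f"c{i}" for i in range(2 * n_per)], dtype=object)
    gene_meta = pd.DataFrame({"is_mito": False, "is_ribo": False}, index=pd.Index(genes))
    labels = np.array([0] * n_per + [1] * n_per)
    return CountMatrix(counts, genes, cells, None, gene_meta), labels
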