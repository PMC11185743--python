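"""Graph clustering, dendrogram topology, node annotation, stepwise codes,
cluster naming, and the resolution sweep."""

import numpy as np
import pandas as pd
import pytest

import dopamap.taxonomy as taxonomy
from dopamap.taxonomy import Clustering, Embedding, TaxonomyTree

from conftest import two_blob_counts


def blob_embedding(seed=0, n_per=100, sep=10.0):
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [rng.normal(0, 1, size=(n_per, 4)), rng.normal(sep, 1, size=(n_per, 4))]
    )
    return Embedding(
        scores=pts,
        loadings=np.zeros((4, 4)),
        explained_variance_ratio=np.ones(4) / 4,
        cell_ids=np.array([f"c{i}" for i in range(2 * n_per)], dtype=object),
        gene_ids=np.array(list("abcd"), dtype=object),
        n_components=4,
        seed=0,
    ), np.array([0] * n_per + [1] * n_per)


class TestCluster:
    def test_two_blobs_exact_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        emb, truth = blob_embedding()
        clu = taxonomy.cluster(emb, k_neighbors=10, resolution=0.2, seed=0)
        assert clu.n_clusters == 2
        assert adjusted_rand_score(truth, clu.labels) == 1.0

    def test_resolution_zero_single_cluster(self):
        # connected graph (one blob): the zero-resolution limit merges all
        emb, _ = blob_embedding(sep=0.0)
        clu = taxonomy.cluster(emb, k_neighbors=10, resolution=1e-6, seed=0)
        assert clu.n_clusters == 1

    def test_labels_contiguous_and_seeded(self):
        emb, _ = blob_embedding(seed=3, sep=3.0)
        c1 = taxonomy.cluster(emb, k_neighbors=10, resolution=0.8, seed=7)
        c2 = taxonomy.cluster(emb, k_neighbors=10, resolution=0.8, seed=7)
        np.testing.assert_array_equal(c1.labels, c2.labels)
        assert sorted(set(c1.labels)) == list(range(c1.n_clusters))

    def test_k_neighbors_bound(self):
        emb, _ = blob_embedding(n_per=5)
        with pytest.raises(ValueError, match="k_neighbors"):
            taxonomy.cluster(emb, k_neighbors=10)

    def test_planted_six_leaves_recovered(self, clustered):
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(clustered["truth_leaf"], clustered["clustering"].labels)
        assert ari >= 0.9


class TestBuildTree:
    def test_first_merge_is_nearest_pair(self):
        scores = np.array([[0.0, 0], [1.0, 0], [10.0, 0]])
        scores = np.repeat(scores, 5, axis=0)
        labels = np.repeat([0, 1, 2], 5)
        emb = Embedding(scores, np.zeros((2, 2)), np.ones(2),
                        np.array([f"c{i}" for i in range(15)], dtype=object),
                        np.array(["a", "b"], dtype=object), 2, 0)
        clu = Clustering(labels, 3, 0.8, 0, 0.0)
        tree = taxonomy.build_tree(emb, clu)
        first = tree.children["n0"]
        assert set(first) == {"0", "1"}

    def test_leaf_set_equals_cluster_set(self, clustered):
        tree = clustered["tree"]
        clu = clustered["clustering"]
        assert sorted(tree.leaves) == sorted(str(u) for u in np.unique(clu.labels))

    def test_single_cluster_rejected(self):
        emb, _ = blob_embedding(n_per=10)
        clu = Clustering(np.zeros(20, dtype=int), 5, 0.8, 0, 0.0)
        with pytest.raises(ValueError, match="2 clusters"):
            taxonomy.build_tree(emb, clu)

    def test_planted_family_bipartitions_recovered(self, truth6, clustered):
        # the inferred tree contains every planted family bipartition
        tree = clustered["tree"]
        c2l = clustered["cluster_to_leaf"]
        inferred = {
            frozenset(truth6.families[c2l[l]] for l in part)
            for part in ({frozenset(tree.descendant_leaves(n)) for n in tree.internal_nodes()})
        }
        fams = set(truth6.families.values())
        for fam in fams:
            # some tree node's descendant leaves map exactly onto each family
            parts = [
                {truth6.families[c2l[l]] for l in tree.descendant_leaves(n)}
                for n in tree.internal_nodes()
            ]
            assert {fam} in parts


class TestAnnotateAndCodes:
    def test_planted_branch_markers_recovered(self, truth6, clustered):
        tree = clustered["tree"]
        c2l = clustered["cluster_to_leaf"]

        def truth_node_for(leafset):
            for tn in truth6.internal_nodes():
                a, b = truth6.children[tn]
                fa = frozenset(truth6.descendant_leaves(a))
                fb = frozenset(truth6.descendant_leaves(b))
                if leafset == fa:
                    return tn, "left"
                if leafset == fb:
                    return tn, "right"
            return None, None

        recalls = []
        for node in tree.internal_nodes():
            for i, side in enumerate(["left", "right"]):
                child = tree.children[node][i]
                leafset = frozenset(c2l[x] for x in tree.descendant_leaves(child))
                tn, ts = truth_node_for(leafset)
                assert tn is not None, f"inferred node {node} matches no planted branch"
                planted = {g for g, _ in truth6.node_markers[tn][ts]}
                up = set(tree.node_markers[node][side].query("log2fc > 0")["gene"])
                recalls.append(len(planted & up) / len(planted))
        assert np.mean(recalls) >= 0.8

    def test_node_markers_use_descendants_only(self, clustered):
        # recomputing a deep node's markers from its descendant cells alone
        # reproduces the stored tables (locality)
        tree = clustered["tree"]
        norm = clustered["norm"]
        clu = clustered["clustering"]
        deep = [n for n in tree.internal_nodes() if len(tree.descendant_leaves(n)) == 2][0]
        labels = clu.labels.astype(str)
        l, r = tree.children[deep]
        li = np.flatnonzero(np.isin(labels, tree.descendant_leaves(l)))
        ri = np.flatnonzero(np.isin(labels, tree.descendant_leaves(r)))
        direct = taxonomy.rank_markers(norm, li, ri)
        pd.testing.assert_frame_equal(direct, tree.node_markers[deep]["left"])

    def test_identical_arms_empty_markers(self):
        # arms drawn from one distribution: nothing passes the pct filter
        from test_taxonomy_core import counts_matrix

        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(60, 80)) + 1
        norm = taxonomy.normalize(counts_matrix(counts))
        tree = TaxonomyTree(children={"root": ("0", "1")}, root="root", leaves=["0", "1"])
        clu = Clustering(np.repeat([0, 1], 40), 5, 0.8, 0, 0.0)
        tree = taxonomy.annotate_nodes(tree, norm, clu)
        assert len(tree.node_markers["root"]["left"]) == 0

    def test_small_arm_flagged_not_annotated(self):
        from test_taxonomy_core import counts_matrix

        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, size=(30, 12)) + 1
        norm = taxonomy.normalize(counts_matrix(counts))
        tree = TaxonomyTree(children={"root": ("0", "1")}, root="root", leaves=["0", "1"])
        clu = Clustering(np.array([0] * 10 + [1] * 2), 3, 0.8, 0, 0.0)
        tree = taxonomy.annotate_nodes(tree, norm, clu)
        assert tree.flagged_nodes == ["root"]
        assert "root" not in tree.node_markers

    def test_two_leaf_base_case(self):
        # manual 2-leaf tree: codes are the single top marker per side
        tree = TaxonomyTree(children={"root": ("0", "1")}, root="root", leaves=["0", "1"])
        mk = lambda genes, fcs: pd.DataFrame(
            {"gene": genes, "log2fc": fcs, "pct1": 1.0, "pct2": 0.0, "p": 0.01, "p_adj": 0.02}
        )
        tree.node_markers = {
            "root": {"left": mk(["gX", "gY"], [3.0, -2.0]), "right": mk(["gY", "gX"], [2.0, -3.0])}
        }
        tree = taxonomy.derive_codes(tree, markers_per_node=1)
        assert tree.codes["0"] == [("gX", "+")]
        assert tree.codes["1"] == [("gY", "+")]
        assert tree.recipes["0"] == "gX+"

    def test_codes_pairwise_distinct(self, clustered):
        recipes = list(clustered["tree"].recipes.values())
        assert len(set(recipes)) == len(recipes)

    def test_unannotated_node_raises(self):
        tree = TaxonomyTree(children={"root": ("0", "1")}, root="root", leaves=["0", "1"])
        with pytest.raises(ValueError, match="root"):
            taxonomy.derive_codes(tree)

    def test_codes_gate_precision(self, truth6, clustered):
        # literal detection gates isolate each target leaf
        tree = clustered["tree"]
        m = clustered["matrix"]
        tl = clustered["truth_leaf"]
        c2l = clustered["cluster_to_leaf"]
        detected = m.counts > 0
        gidx = {g: i for i, g in enumerate(m.gene_ids)}
        precisions = []
        for leaf in tree.leaves:
            mask = np.ones(m.n_cells, dtype=bool)
            for g, _ in tree.codes[leaf]:
                mask &= np.asarray(detected[gidx[g]].todense()).ravel()
            assert mask.sum() > 0
            precisions.append((tl[mask] == c2l[leaf]).mean())
        assert np.median(precisions) >= 0.8


class TestNameClusters:
    def test_names_follow_family_and_top_gene(self, clustered):
        tree = clustered["tree"]
        for leaf in tree.leaves:
            fam = tree.families[leaf]
            assert tree.names[leaf].startswith(f"{fam}^")
        assert len(set(tree.names.values())) == len(tree.leaves)

    def test_leaf_names_match_planted_leaf_markers(self, truth6, clustered):
        # for most leaves the naming gene is one of the leaf's planted markers
        tree = clustered["tree"]
        c2l = clustered["cluster_to_leaf"]
        hits = 0
        for leaf in tree.leaves:
            gene = tree.names[leaf].split("^")[1]
            planted = set(truth6.markers_for_leaf(c2l[leaf]))
            hits += gene in planted
        assert hits >= 5

    def test_single_cluster_family_fallback(self):
        tree = TaxonomyTree(children={"root": ("0", "1")}, root="root", leaves=["0", "1"])
        tree.families = {"0": "FamA", "1": "FamB"}
        rng = np.random.default_rng(1)
        from test_taxonomy_core import counts_matrix

        counts = rng.poisson(3.0, size=(30, 20)) + 1
        norm = taxonomy.normalize(counts_matrix(counts))
        clu = Clustering(np.repeat([0, 1], 10), 5, 0.8, 0, 0.0)
        tree = taxonomy.name_clusters(tree, norm, clu)
        assert tree.names == {"0": "FamA^c0", "1": "FamB^c1"}


class TestResolutionSweep:
    def test_single_blob_chain(self):
        rng = np.random.default_rng(5)
        emb = Embedding(rng.normal(size=(80, 3)), np.zeros((3, 3)), np.ones(3),
                        np.array([f"c{i}" for i in range(80)], dtype=object),
                        np.array(list("abc"), dtype=object), 3, 0)
        clusterings, edges = taxonomy.resolution_sweep(emb, [0.0001, 0.001], k_neighbors=10, seed=0)
        assert all(c.n_clusters == 1 for c in clusterings.values())
        assert len(edges) == 1 and edges.iloc[0]["n_cells"] == 80

    def test_edge_weights_conserve_cells(self, clustered):
        emb = clustered["embedding"]
        res = [0.2, 0.5, 0.8]
        clusterings, edges = taxonomy.resolution_sweep(emb, res, k_neighbors=40, seed=0)
        for r_lo, r_hi in zip(res[:-1], res[1:]):
            sub = edges[(edges["res_from"] == r_lo) & (edges["res_to"] == r_hi)]
            for src in sub["cluster_from"].unique():
                out = sub[sub["cluster_from"] == src]["n_cells"].sum()
                assert out == (clusterings[r_lo].labels == src).sum()

    def test_cluster_count_mostly_non_decreasing(self, clustered):
        emb = clustered["embedding"]
        res = [round(0.1 * k, 1) for k in range(1, 12)]
        clusterings, _ = taxonomy.resolution_sweep(emb, res, k_neighbors=40, seed=0)
        ks = [clusterings[r].n_clusters for r in res]
        steps = sum(b >= a for a, b in zip(ks[:-1], ks[1:]))
        assert steps >= 9

    def test_unsorted_resolutions_rejected(self, clustered):
        with pytest.raises(ValueError, match="ascending"):
            taxonomy.resolution_sweep(clustered["embedding"], [0.8, 0.1])
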