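"""End-to-end orchestration of the analysis stages.

A run is driven by a plain config mapping (YAML/JSON-compatible) with a
single global seed. Per-stage seeds are derived by stable hashing of
(global seed, stage name), so inserting or removing a stage never shifts
another stage's random stream. Stages execute in dependency order:

    simulate -> qc -> taxonomy -> spatial -> contrast -> enrichment -> risk

Each stage writes deterministic CSV/JSON artifacts into the output
directory and records them, with SHA-256 hashes, in a run manifest.
On the default config the pipeline runs entirely on synthetic data: the
gene sets fed to enrichment and the risk gene table are derived from the
planted truth so that every stage has a meaningful input.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import contrast, enrichment, qc, risk, spatial, synthio, taxonomy
from .containers import CountMatrix
from .io import write_count_matrix, write_regions, write_truth
from .spatial import RegionMap
from shapely.geometry import Polygon

__all__ = ["default_config", "derive_seed", "run_pipeline"]

_FLOAT_FMT = "%.17g"


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def default_config(seed: int = 0) -> dict:
    """Desk-scale synthetic study: 3 families, 6 leaves, planted effects."""
    return {
        "seed": seed,
        "simulate": {
            "n_genes": 600,
            "leaves_per_family": [2, 2, 2],
            "effect_size": 4.0,
            "n_cells": 3000,
            "depth_mean": 5000.0,
            "dispersion": 10.0,
            "n_spatial_cells": 1500,
        },
        "qc": {"min_features": 10, "max_pct_mito": 0.5},
        "taxonomy": {
            "target_sum": 10000.0,
            "scale_cap": 10.0,
            "n_components": 32,
            "k_neighbors": 40,
            "resolution": 0.8,
            "min_pct": 0.2,
            "min_diff_pct": 0.25,
            "logfc_threshold": 1.0,
        },
        "spatial": {
            "max_ratio": 4.0,
            "min_detection": 0.01,
            "k_anchor": 5,
            "k_weight": 50,
            "score_threshold": 0.5,
            "min_flow": 0.10,
        },
        "contrast": {"min_detection": 0.10, "n_perm": 500},
        "enrichment": {"min_size": 3, "max_size": 500, "n_perm": 1000},
        "risk": {"n_ctrl": 200, "n_boot": 2000, "alpha": 0.05},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _save_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: dict, outdir, stages: list[str] | None = None) -> dict:
    """Execute the configured stages and return the run manifest.

    ``stages`` defaults to all stages; any contiguous-from-the-start
    subset is runnable (later stages need earlier in-memory artifacts and
    will raise naming the missing stage otherwise).
    """
    all_stages = ["simulate", "qc", "taxonomy", "spatial", "contrast", "enrichment", "risk"]
    stages = stages or all_stages
    unknown = set(stages) - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"seed": seed, "stages": {}, "config": config}
    state: dict = {}

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in paths},
            "seed": derive_seed(seed, stage),
        }

    def need(key: str, stage: str):
        if key not in state:
            raise RuntimeError(f"stage {stage!r} requires an earlier stage; run it first")
        return state[key]

    if "simulate" in stages:
        p = config["simulate"]
        truth = synthio.make_truth(
            n_genes=p["n_genes"],
            leaves_per_family=tuple(p["leaves_per_family"]),
            effect_size=p["effect_size"],
            seed=derive_seed(seed, "simulate"),
        )
        ref = synthio.simulate_counts(
            truth,
            n_cells=p["n_cells"],
            depth_mean=p["depth_mean"],
            dispersion=p["dispersion"],
            seed=derive_seed(seed, "simulate.counts"),
        )
        spa = synthio.simulate_spatial(
            truth, ref, n_cells=p["n_spatial_cells"], seed=derive_seed(seed, "simulate.spatial")
        )
        write_truth(truth, out / "truth.json")
        write_count_matrix(ref, out / "reference")
        write_count_matrix(spa, out / "spatial")
        regions = RegionMap([(n, Polygon(c)) for n, c in truth.regions.items()])
        write_regions(regions, out / "regions.geojson")
        state.update(truth=truth, reference=ref, spatial=spa, regions=regions)
        record("simulate", [out / "truth.json", out / "regions.geojson",
                            out / "reference" / "matrix.mtx", out / "spatial" / "matrix.mtx"])

    if "qc" in stages:
        ref: CountMatrix = need("reference", "qc")
        qc_table = qc.compute_qc(ref)
        kept = qc.filter_cells(
            qc_table,
            [qc.QCWindow(applies_to="all",
                         min_features=config["qc"]["min_features"],
                         max_pct_mito=config["qc"]["max_pct_mito"])],
        )
        ref_f = ref.subset_cells(kept)
        _save_csv(qc_table, out / "qc_cells.csv", index=True)
        state["reference_filtered"] = ref_f
        record("qc", [out / "qc_cells.csv"])

    if "taxonomy" in stages:
        ref_f = need("reference_filtered", "taxonomy")
        t = config["taxonomy"]
        norm, emb, clu = taxonomy.cluster_pipeline(
            ref_f,
            target_sum=t["target_sum"],
            scale_cap=t["scale_cap"],
            n_components=t["n_components"],
            k_neighbors=t["k_neighbors"],
            resolution=t["resolution"],
            seed=derive_seed(seed, "taxonomy"),
        )
        truth = state.get("truth")
        glial = truth.glial_genes if truth is not None else []
        doublet_clusters = qc.flag_doublet_clusters(ref_f, clu.labels, glial) if glial else []
        keep_mask = ~np.isin(clu.labels, doublet_clusters)
        if doublet_clusters and keep_mask.sum() < len(keep_mask):
            ref_clean = ref_f.subset_cells(np.flatnonzero(keep_mask))
            norm, emb, clu = taxonomy.cluster_pipeline(
                ref_clean,
                target_sum=t["target_sum"],
                scale_cap=t["scale_cap"],
                n_components=t["n_components"],
                k_neighbors=t["k_neighbors"],
                resolution=t["resolution"],
                seed=derive_seed(seed, "taxonomy"),
            )
        else:
            ref_clean = ref_f
        tree = taxonomy.build_tree(emb, clu)
        tree = taxonomy.annotate_nodes(
            tree, norm, clu,
            min_pct=t["min_pct"], min_diff_pct=t["min_diff_pct"],
            logfc_threshold=t["logfc_threshold"],
        )
        tree = taxonomy.derive_codes(tree)
        tree = taxonomy.name_clusters(tree, norm, clu)
        labels_df = pd.DataFrame(
            {"cell_id": norm.cell_ids, "cluster": clu.labels,
             "name": [tree.names[str(l)] for l in clu.labels],
             "family": [tree.families[str(l)] for l in clu.labels]}
        )
        _save_csv(labels_df, out / "clusters.csv")
        codes_df = pd.DataFrame(
            [{"cluster": leaf, "name": tree.names[leaf], "recipe": tree.recipes[leaf]}
             for leaf in tree.leaves]
        )
        _save_csv(codes_df, out / "stepwise_codes.csv")
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        state.update(norm=norm, embedding=emb, clustering=clu, tree=tree,
                     reference_clean=ref_clean)
        record("taxonomy", [out / "clusters.csv", out / "stepwise_codes.csv", out / "tree.nwk"])

    if "spatial" in stages:
        ref_clean = need("reference_clean", "spatial")
        spa = need("spatial", "spatial")
        clu = need("clustering", "spatial")
        spar = config["spatial"]
        shared = spatial.select_shared_features(
            ref_clean, spa, max_ratio=spar["max_ratio"], min_detection=spar["min_detection"]
        )
        anchors = spatial.find_anchors(
            ref_clean, spa, shared, k_anchor=spar["k_anchor"],
            seed=derive_seed(seed, "spatial"),
        )
        transfer = spatial.transfer_labels(
            anchors, clu.labels, k_weight=spar["k_weight"],
            score_threshold=spar["score_threshold"],
        )
        regions = need("regions", "spatial")
        region_labels = spatial.assign_regions(spa.cell_meta, regions)
        comp = spatial.regional_composition(region_labels, transfer.table["predicted_label"])
        flows = spatial.correspondence_flows(
            spa.cell_meta["truth_leaf"], transfer.table["predicted_label"],
            min_flow=spar["min_flow"],
        )
        _save_csv(transfer.table, out / "transfer.csv", index=True)
        _save_csv(comp["within_region"], out / "region_composition.csv", index=True)
        _save_csv(flows, out / "flows.csv")
        state.update(transfer=transfer, region_labels=region_labels, shared_genes=shared)
        record("spatial", [out / "transfer.csv", out / "region_composition.csv", out / "flows.csv"])

    if "contrast" in stages:
        norm = need("norm", "contrast")
        ref_clean = need("reference_clean", "contrast")
        c = config["contrast"]
        genotype = ref_clean.cell_meta["genotype"].to_numpy()
        de = contrast.condition_de(norm, genotype, min_detection=c["min_detection"])
        shift = contrast.proportion_shift(
            state["clustering"].labels, genotype, n_perm=c["n_perm"],
            seed=derive_seed(seed, "contrast"),
        )
        _save_csv(de.table, out / "de_global.csv")
        _save_csv(shift, out / "proportion_shift.csv")
        state["de_global"] = de
        record("contrast", [out / "de_global.csv", out / "proportion_shift.csv"])

    if "enrichment" in stages:
        de = need("de_global", "enrichment")
        truth = need("truth", "enrichment")
        e = config["enrichment"]
        sets = {
            f"family_{fam}_markers": sorted(
                {g for lf, f in truth.families.items() if f == fam
                 for g in truth.markers_for_leaf(lf)}
            )
            for fam in sorted(set(truth.families.values()))
        }
        sets["genotype_effect_genes"] = sorted({ef["gene"] for ef in truth.genotype_effects})
        collection = enrichment.GeneSetCollection(sets=sets, source="synthetic-truth")
        ranked = pd.Series(
            (np.where(de.table["log2fc"] >= 0, 1.0, -1.0)
             * -np.log10(de.table["p"].to_numpy() + 1e-300)),
            index=de.table["gene"].to_numpy(),
        )
        gsea = enrichment.preranked_gsea(
            ranked, collection, min_size=e["min_size"], max_size=e["max_size"],
            n_perm=e["n_perm"], seed=derive_seed(seed, "enrichment"),
        )
        hits = sorted(de.significant_genes())
        ora = (
            enrichment.overrepresentation(hits, de.background, collection)
            if hits else pd.DataFrame(columns=["set", "overlap", "set_size_bg", "p", "p_adj"])
        )
        _save_csv(gsea, out / "gsea.csv")
        _save_csv(ora, out / "ora.csv")
        record("enrichment", [out / "gsea.csv", out / "ora.csv"])

    if "risk" in stages:
        norm = need("norm", "risk")
        truth = need("truth", "risk")
        clu = need("clustering", "risk")
        r = config["risk"]
        target_leaf = truth.leaves[0]
        z_table = pd.DataFrame(
            {"gene": truth.markers_for_leaf(target_leaf), "z": 4.0}
        )
        rset = risk.load_risk_genes(z_table, norm.gene_ids, min_overlap=5,
                                    provenance="synthetic-truth")
        bins = risk.bin_genes(norm)
        scores = risk.score_cells(norm, rset, bins, n_ctrl=r["n_ctrl"],
                                  seed=derive_seed(seed, "risk"))
        groups = clu.labels.astype(str)
        boot = risk.group_bootstrap(scores["normalized"], groups, n_boot=r["n_boot"],
                                    alpha=r["alpha"], seed=derive_seed(seed, "risk.boot"))
        _save_csv(scores, out / "risk_scores.csv", index=True)
        _save_csv(boot, out / "risk_groups.csv")
        record("risk", [out / "risk_scores.csv", out / "risk_groups.csv"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
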