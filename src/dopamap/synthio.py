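"""Synthetic dissociated and spatial-panel datasets with planted truth.

The generator emulates the structure of a midbrain dopamine-neuron survey:
a three-family hierarchy of transcriptomic subtypes whose branch points
carry upregulated marker genes, negative-binomial UMI counts with per-cell
depth variation, sex-specific gene expression with a technical-dropout
class, glial/neuron doublet clusters, and a reduced spatial gene panel with
probe-failure genes and region-structured coordinates. Every planted
property is recorded in a :class:`TruthSpec` so that recovery by the
analysis stages can be measured exactly.

The count model is negative binomial with a shared dispersion ``r``
(variance ``mu + mu**2 / r``) and lognormal per-cell depth factors
(sigma = 0.35). A mutant genotype multiplies the mean of its effect genes
without changing subtype proportions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = ["TruthSpec", "make_truth", "simulate_counts", "simulate_spatial", "DEFAULT_REGIONS"]

FAMILIES = ("F1", "F2", "F3")

#: Default pseudo-section region rectangles, micrometers, origin bottom-left.
#: Deliberately non-contiguous so that an "elsewhere" class exists.
DEFAULT_REGIONS: dict[str, list[tuple[float, float]]] = {
    "SNc": [(0, 0), (800, 0), (800, 400), (0, 400)],
    "VTA": [(900, 0), (1700, 0), (1700, 400), (900, 400)],
    "RR": [(0, 500), (800, 500), (800, 900), (0, 900)],
    "CLi": [(900, 500), (1700, 500), (1700, 900), (900, 900)],
}


@dataclass
class TruthSpec:
    """Complete ground truth for one synthetic study.

    ``children`` maps internal node name -> (left, right) child names; leaf
    names are absent from it. ``node_markers`` maps node -> side
    ("left"/"right") -> list of (gene, fold-change multiplier) upregulated
    in that side's descendants.
    """

    children: dict[str, tuple[str, str]]
    leaves: list[str]
    families: dict[str, str]  # leaf -> family
    node_markers: dict[str, dict[str, list[tuple[str, float]]]]
    leaf_proportions: dict[str, float]
    genotype_effects: list[dict]  # {gene, scope: leaf|family|global, target, effect}
    sex_genes: tuple[list[str], list[str]]  # (male-specific, female-specific)
    glial_genes: list[str]
    doublet_fraction: float
    panel: list[str]
    probe_failures: list[str]
    region_layout: dict[str, dict[str, float]]  # leaf -> region -> prob
    regions: dict[str, list[tuple[float, float]]]
    gene_ids: list[str]
    baseline: np.ndarray  # relative per-gene baseline expression
    seed: int

    def __post_init__(self) -> None:
        total = sum(self.leaf_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"leaf proportions sum to {total}, not 1")
        universe = set(self.gene_ids)
        for node, sides in self.node_markers.items():
            for side, marks in sides.items():
                for g, _ in marks:
                    if g not in universe:
                        raise ValueError(f"marker {g} at {node}/{side} not in gene universe")
        if not set(self.probe_failures) <= set(self.panel):
            raise ValueError("probe_failures must be a subset of the panel")
        for leaf in self.leaves:
            if leaf not in self._paths():
                raise ValueError(f"leaf {leaf} unreachable from root")

    # -- tree helpers ---------------------------------------------------
    def _paths(self) -> dict[str, list[tuple[str, str]]]:
        """leaf -> list of (node, side taken) from root down."""
        paths: dict[str, list[tuple[str, str]]] = {}

        def walk(node: str, acc: list[tuple[str, str]]) -> None:
            if node not in self.children:
                paths[node] = acc
                return
            left, right = self.children[node]
            walk(left, acc + [(node, "left")])
            walk(right, acc + [(node, "right")])

        walk("root", [])
        return paths

    def path_to(self, leaf: str) -> list[tuple[str, str]]:
        return self._paths()[leaf]

    def descendant_leaves(self, node: str) -> list[str]:
        if node not in self.children:
            return [node]
        left, right = self.children[node]
        return self.descendant_leaves(left) + self.descendant_leaves(right)

    def internal_nodes(self) -> list[str]:
        return list(self.children)

    def markers_for_leaf(self, leaf: str) -> list[str]:
        """All marker genes upregulated along the leaf's root-to-leaf path."""
        out: list[str] = []
        for node, side in self.path_to(leaf):
            out.extend(g for g, _ in self.node_markers[node][side])
        return out

    # -- expression profiles -------------------------------------------
    def leaf_profile(self, leaf: str) -> np.ndarray:
        """Relative expression (sums to 1) of a pure cell of ``leaf``."""
        p = self.baseline.copy()
        gidx = {g: i for i, g in enumerate(self.gene_ids)}
        for node, side in self.path_to(leaf):
            for g, mult in self.node_markers[node][side]:
                p[gidx[g]] *= mult
        return p / p.sum()

    def glial_profile(self) -> np.ndarray:
        p = self.baseline.copy()
        gidx = {g: i for i, g in enumerate(self.gene_ids)}
        for g in self.glial_genes:
            p[gidx[g]] = 0.012  # strongly expressed in glia
        return p / p.sum()

    # -- (de)serialization ----------------------------------------------
    def to_json(self) -> str:
        d = {
            "children": {k: list(v) for k, v in self.children.items()},
            "leaves": self.leaves,
            "families": self.families,
            "node_markers": {
                n: {s: [[g, m] for g, m in marks] for s, marks in sides.items()}
                for n, sides in self.node_markers.items()
            },
            "leaf_proportions": self.leaf_proportions,
            "genotype_effects": self.genotype_effects,
            "sex_genes": [self.sex_genes[0], self.sex_genes[1]],
            "glial_genes": self.glial_genes,
            "doublet_fraction": self.doublet_fraction,
            "panel": self.panel,
            "probe_failures": self.probe_failures,
            "region_layout": self.region_layout,
            "regions": {k: [list(p) for p in v] for k, v in self.regions.items()},
            "gene_ids": self.gene_ids,
            "baseline": self.baseline.tolist(),
            "seed": self.seed,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthSpec":
        d = json.loads(text)
        return cls(
            children={k: tuple(v) for k, v in d["children"].items()},
            leaves=d["leaves"],
            families=d["families"],
            node_markers={
                n: {s: [(g, float(m)) for g, m in marks] for s, marks in sides.items()}
                for n, sides in d["node_markers"].items()
            },
            leaf_proportions=d["leaf_proportions"],
            genotype_effects=d["genotype_effects"],
            sex_genes=(d["sex_genes"][0], d["sex_genes"][1]),
            glial_genes=d["glial_genes"],
            doublet_fraction=d["doublet_fraction"],
            panel=d["panel"],
            probe_failures=d["probe_failures"],
            region_layout=d["region_layout"],
            regions={k: [tuple(p) for p in v] for k, v in d["regions"].items()},
            gene_ids=d["gene_ids"],
            baseline=np.asarray(d["baseline"], dtype=float),
            seed=d["seed"],
        )


def _balanced_subtree(prefix: str, leaves: list[str], children: dict) -> str:
    """Build a balanced binary subtree over ``leaves``; returns root name."""
    if len(leaves) == 1:
        return leaves[0]
    mid = (len(leaves) + 1) // 2
    left = _balanced_subtree(prefix + "l", leaves[:mid], children)
    right = _balanced_subtree(prefix + "r", leaves[mid:], children)
    children[prefix] = (left, right)
    return prefix


def make_truth(
    n_genes: int = 600,
    leaves_per_family: tuple[int, int, int] = (2, 2, 2),
    seed: int = 0,
    effect_size: float = 4.0,
    markers_per_node: int = 10,
    n_panel: int = 120,
    n_probe_failures: int = 2,
    doublet_fraction: float = 0.03,
    leaf_proportions: dict[str, float] | None = None,
    genotype_effect: float = 2.0,
    n_global_effect_genes: int = 8,
    n_family_effect_genes: int = 4,
) -> TruthSpec:
    """Plant a three-family taxonomy and every auxiliary structure.

    Each internal node of the binary tree receives ``markers_per_node``
    unique marker genes per side, upregulated ``effect_size``-fold in all
    cells descending through that side. The spatial panel contains every
    marker gene plus random filler genes up to ``n_panel``;
    ``n_probe_failures`` filler genes are designated failed probes.
    Raises ``ValueError`` when ``n_genes`` cannot supply unique markers,
    sex, glial and effect genes.
    """
    if len(leaves_per_family) != 3:
        raise ValueError("exactly 3 families are modeled")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]

    children: dict[str, tuple[str, str]] = {}
    fam_roots = []
    leaves: list[str] = []
    families: dict[str, str] = {}
    for fam, k in zip(FAMILIES, leaves_per_family):
        fam_leaves = [f"{fam}.{j}" for j in range(k)]
        leaves.extend(fam_leaves)
        families.update({lf: fam for lf in fam_leaves})
        fam_roots.append(_balanced_subtree(f"n{fam}", fam_leaves, children))
    children["n12"] = (fam_roots[0], fam_roots[1])
    children["root"] = ("n12", fam_roots[2])

    internal = list(children)
    n_markers = 2 * markers_per_node * len(internal)
    n_sex, n_glial = 4, 5
    n_effects = n_global_effect_genes + n_family_effect_genes
    budget = n_markers + n_sex + n_glial + n_effects
    if budget > n_genes:
        raise ValueError(f"gene budget exhausted: need {budget} special genes, have {n_genes}")

    pool = list(rng.permutation(n_genes))
    take = lambda k: [genes[pool.pop()] for _ in range(k)]

    node_markers: dict[str, dict[str, list[tuple[str, float]]]] = {}
    for node in internal:
        node_markers[node] = {
            "left": [(g, effect_size) for g in take(markers_per_node)],
            "right": [(g, effect_size) for g in take(markers_per_node)],
        }

    male_genes, female_genes = take(2), take(2)
    glial_genes = take(n_glial)
    global_eff = take(n_global_effect_genes)
    family_eff = take(n_family_effect_genes)
    genotype_effects = [
        {"gene": g, "scope": "global", "target": None, "effect": genotype_effect}
        for g in global_eff
    ] + [
        {"gene": g, "scope": "family", "target": "F1", "effect": genotype_effect}
        for g in family_eff
    ]

    marker_genes = [g for sides in node_markers.values() for s in sides.values() for g, _ in s]
    panel = list(dict.fromkeys(marker_genes))
    filler = [genes[i] for i in pool if genes[i] not in set(panel)]
    panel += filler[: max(0, n_panel - len(panel))]
    probe_failures = filler[: n_probe_failures] if n_probe_failures else []

    if leaf_proportions is None:
        leaf_proportions = {lf: 1.0 / len(leaves) for lf in leaves}

    region_names = list(DEFAULT_REGIONS)
    region_layout = {}
    for i, lf in enumerate(leaves):
        primary = region_names[i % len(region_names)]
        layout = {r: 0.04 / (len(region_names) - 1) for r in region_names if r != primary}
        layout[primary] = 0.90
        layout["elsewhere"] = 0.06
        region_layout[lf] = layout

    # lognormal baseline: a few high expressors, a long tail of low ones;
    # glial markers are essentially silent in dopaminergic cells
    baseline = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    baseline /= baseline.sum()
    gidx = {g: i for i, g in enumerate(genes)}
    for g in glial_genes:
        baseline[gidx[g]] *= 1e-4
    # branch markers sit at moderate expression (~0.3-0.65 expected counts at
    # 5000 UMI depth) where an effect_size-fold shift produces the near-binary
    # detection difference characteristic of subtype markers
    for g in marker_genes:
        baseline[gidx[g]] = rng.uniform(5e-5, 9e-5)
    # genotype-effect genes must be robustly detected in both conditions
    for g in global_eff + family_eff:
        baseline[gidx[g]] = rng.uniform(4e-4, 2e-3)
    baseline /= baseline.sum()

    return TruthSpec(
        children=children,
        leaves=leaves,
        families=families,
        node_markers=node_markers,
        leaf_proportions=leaf_proportions,
        genotype_effects=genotype_effects,
        sex_genes=(male_genes, female_genes),
        glial_genes=glial_genes,
        doublet_fraction=doublet_fraction,
        panel=panel,
        probe_failures=probe_failures,
        region_layout=region_layout,
        regions={k: list(v) for k, v in DEFAULT_REGIONS.items()},
        gene_ids=genes,
        baseline=baseline,
        seed=seed,
    )


_SEX_WEIGHT = 0.004  # relative expression per expressed sex gene
_SEX_DROPOUT = 0.05  # fraction of cells with both sex gene sets dropped out


def _apply_sex(profile: np.ndarray, truth: TruthSpec, sex: str, gidx: dict[str, int]) -> np.ndarray:
    p = profile.copy()
    male, female = truth.sex_genes
    on = male if sex == "male" else female if sex == "female" else []
    for g in male + female:
        p[gidx[g]] = 0.0
    for g in on:
        p[gidx[g]] = _SEX_WEIGHT
    return p / p.sum()


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance ``mean + mean**2/r``."""
    mean = np.maximum(mean, 1e-12)
    return rng.negative_binomial(dispersion, dispersion / (dispersion + mean))


def simulate_counts(
    truth: TruthSpec,
    n_cells: int = 3000,
    depth_mean: float = 5000.0,
    dispersion: float = 10.0,
    doublet_fraction: float | None = None,
    seed: int = 0,
    depth_sigma: float = 0.35,
) -> CountMatrix:
    """Simulate a dissociated-profile dataset from planted truth.

    Cells are drawn from ``truth.leaf_proportions``; a cell's per-gene mean
    is its leaf profile (branch markers multiplied along the root-to-leaf
    path) times genotype effects times a lognormal depth factor. Doublet
    cells mix one leaf profile 50/50 with the glial profile and carry
    ``truth_leaf="doublet"``. Two control and two mutant pseudo-samples are
    assigned round-robin.
    """
    if n_cells < len(truth.leaves):
        import warnings

        warnings.warn("n_cells below leaf count; some leaves will be empty")
    rng = np.random.default_rng(seed)
    if doublet_fraction is None:
        doublet_fraction = truth.doublet_fraction

    leaves = truth.leaves
    props = np.array([truth.leaf_proportions[lf] for lf in leaves])
    leaf_of = rng.choice(len(leaves), size=n_cells, p=props / props.sum())
    is_doublet = rng.random(n_cells) < doublet_fraction
    sex_draw = rng.random(n_cells)
    sexes = np.where(sex_draw < 0.5, "male", "female").astype(object)
    sexes[rng.random(n_cells) < _SEX_DROPOUT] = "indeterminate"
    samples = np.array(["control_1", "control_2", "mutant_1", "mutant_2"], dtype=object)[
        np.arange(n_cells) % 4
    ]
    genotype = np.where(pd.Series(samples).str.startswith("control"), "control", "mutant")

    gidx = {g: i for i, g in enumerate(truth.gene_ids)}
    profiles = {lf: truth.leaf_profile(lf) for lf in leaves}
    glial = truth.glial_profile()

    depth = rng.lognormal(np.log(depth_mean) - depth_sigma**2 / 2, depth_sigma, size=n_cells)

    counts = np.empty((len(truth.gene_ids), n_cells), dtype=np.int64)
    truth_leaf = np.empty(n_cells, dtype=object)
    for c in range(n_cells):
        lf = leaves[leaf_of[c]]
        p = profiles[lf]
        if is_doublet[c]:
            p = 0.5 * p + 0.5 * glial
            truth_leaf[c] = "doublet"
        else:
            truth_leaf[c] = lf
        p = _apply_sex(p, truth, sexes[c], gidx)
        if genotype[c] == "mutant":
            p = p.copy()
            for eff in truth.genotype_effects:
                hit = (
                    eff["scope"] == "global"
                    or (eff["scope"] == "family" and truth.families.get(lf) == eff["target"])
                    or (eff["scope"] == "leaf" and lf == eff["target"])
                )
                if hit:
                    p[gidx[eff["gene"]]] *= eff["effect"]
            p = p / p.sum()
        counts[:, c] = _nb_draw(rng, depth[c] * p, dispersion)

    cell_ids = np.array([f"cell{c:05d}" for c in range(n_cells)], dtype=object)
    cell_meta = pd.DataFrame(
        {
            "sample": samples,
            "genotype": genotype,
            "sex_true": sexes,
            "truth_leaf": truth_leaf,
            "truth_family": [
                truth.families.get(lf, "doublet") for lf in truth_leaf
            ],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    gene_meta = pd.DataFrame(
        {"is_mito": False, "is_ribo": False},
        index=pd.Index(truth.gene_ids, name="gene_id"),
    )
    return CountMatrix(sp.csr_matrix(counts), np.array(truth.gene_ids, dtype=object), cell_ids, cell_meta, gene_meta)


def _point_in_rect(rect: list[tuple[float, float]], rng: np.random.Generator) -> tuple[float, float]:
    xs = [p[0] for p in rect]
    ys = [p[1] for p in rect]
    return rng.uniform(min(xs), max(xs)), rng.uniform(min(ys), max(ys))


def _point_elsewhere(regions: dict, rng: np.random.Generator) -> tuple[float, float]:
    """Uniform point in the bounding frame outside all region rectangles."""
    xs = [p[0] for rect in regions.values() for p in rect]
    ys = [p[1] for rect in regions.values() for p in rect]
    lo_x, hi_x = min(xs) - 100, max(xs) + 100
    lo_y, hi_y = min(ys) - 100, max(ys) + 100
    for _ in range(1000):
        x, y = rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)
        inside = any(
            min(p[0] for p in rect) <= x <= max(p[0] for p in rect)
            and min(p[1] for p in rect) <= y <= max(p[1] for p in rect)
            for rect in regions.values()
        )
        if not inside:
            return x, y
    raise RuntimeError("could not place a point outside all regions")


def simulate_spatial(
    truth: TruthSpec,
    reference: CountMatrix | None = None,
    n_cells: int = 1500,
    seed: int = 0,
    depth_mean: float = 250.0,
    dispersion: float = 10.0,
    depth_sigma: float = 0.35,
    volume_median: float = 1500.0,
    volume_sigma: float = 0.3,
) -> CountMatrix:
    """Simulate a spatial-panel dataset: panel genes only, with coordinates.

    Expression follows the same leaf profiles restricted and renormalized to
    ``truth.panel``; probe-failure genes are forced to zero detection.
    Coordinates are drawn per cell from the leaf's placement distribution
    over named region rectangles (or the gaps between them for
    "elsewhere"); cell volume is lognormal around ``volume_median`` um^3.
    """
    if not truth.panel:
        raise ValueError("truth.panel is empty")
    for name, rect in truth.regions.items():
        xs = {p[0] for p in rect}
        ys = {p[1] for p in rect}
        if len(xs) < 2 or len(ys) < 2:
            raise ValueError(f"region polygon {name!r} is degenerate (zero area)")
    if reference is not None and not set(truth.panel) <= set(reference.gene_ids):
        raise ValueError("panel genes missing from the reference gene axis")
    rng = np.random.default_rng(seed)

    panel_idx = np.array([truth.gene_ids.index(g) for g in truth.panel])
    fail_mask = np.array([g in set(truth.probe_failures) for g in truth.panel])

    leaves = truth.leaves
    props = np.array([truth.leaf_proportions[lf] for lf in leaves])
    leaf_of = rng.choice(len(leaves), size=n_cells, p=props / props.sum())

    profiles = {}
    for lf in leaves:
        p = truth.leaf_profile(lf)[panel_idx]
        p[fail_mask] = 0.0
        profiles[lf] = p / p.sum()

    depth = rng.lognormal(np.log(depth_mean) - depth_sigma**2 / 2, depth_sigma, size=n_cells)
    counts = np.empty((len(truth.panel), n_cells), dtype=np.int64)
    xs = np.empty(n_cells)
    ys = np.empty(n_cells)
    region_lab = np.empty(n_cells, dtype=object)
    truth_leaf = np.empty(n_cells, dtype=object)
    for c in range(n_cells):
        lf = leaves[leaf_of[c]]
        truth_leaf[c] = lf
        counts[:, c] = _nb_draw(rng, depth[c] * profiles[lf], dispersion)
        layout = truth.region_layout[lf]
        names = list(layout)
        reg = names[rng.choice(len(names), p=np.array([layout[n] for n in names]))]
        region_lab[c] = reg
        if reg == "elsewhere":
            xs[c], ys[c] = _point_elsewhere(truth.regions, rng)
        else:
            xs[c], ys[c] = _point_in_rect(truth.regions[reg], rng)
    counts[fail_mask, :] = 0

    volume = rng.lognormal(np.log(volume_median), volume_sigma, size=n_cells)
    cell_ids = np.array([f"sp{c:05d}" for c in range(n_cells)], dtype=object)
    cell_meta = pd.DataFrame(
        {
            "sample": "merfish_1",
            "x_um": xs,
            "y_um": ys,
            "volume_um3": volume,
            "truth_leaf": truth_leaf,
            "truth_family": [truth.families[lf] for lf in truth_leaf],
            "truth_region": region_lab,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    gene_meta = pd.DataFrame(
        {"is_mito": False, "is_ribo": False},
        index=pd.Index(truth.panel, name="gene_id"),
    )
    return CountMatrix(
        sp.csr_matrix(counts),
        np.array(truth.panel, dtype=object),
        cell_ids,
        cell_meta,
        gene_meta,
    )
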