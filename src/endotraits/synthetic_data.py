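"""Synthetic culture-collection inputs with the structure the analysis assumes.

Generates everything the pipeline consumes — a phylogeny, a taxonomy table,
a Biolog plate, and isolate metadata — plus ground-truth labels, so every
stage is testable without any external data.

The generator emulates a field study design: ``n_leaves`` leaves, two
isolation methods (leaf sectioning and maceration), and a fixed number of
isolates per leaf x method cell. Isolates sit on a simulated pure-birth
(Yule) phylogeny; nested "classes" and "orders" are defined by cutting the
tree at fixed depths. Each class is predominantly slow- or fast-growing
(clade fidelity is configurable), slow and fast isolates draw their mean
growth and niche width from separate Gaussians, and the isolation method
is biased toward fast growers for maceration — mirroring the empirical
pattern that sectioning recovers slow growers and maceration fast growers.

Per-well optical densities realize the drawn traits: an isolate's used
wells carry its growth signal scaled so that its mean standardized growth
across the whole plate matches the drawn value, unused wells carry only
sub-threshold noise around the water-control level.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .biolog import BiologPlate
from .trees import Phylogeny

__all__ = ["CommunitySpec", "SyntheticCommunity", "simulate_tree",
           "simulate_community", "cut_tree_groups"]


@dataclass
class CommunitySpec:
    """Parameters of the simulated study.

    Growth means/sds are in OD590 units; niche widths in resource counts.
    The defaults reproduce the study conditions the analysis is built for:
    12 leaves x 2 methods x 10 isolates = 240 isolates, slow growers at
    0.04 +/- 0.03 OD590 with niche width 46 +/- 25, fast growers at
    0.29 +/- 0.14 with width 82 +/- 12, and maceration recovering fast
    growers with probability 0.85.
    """

    n_leaves: int = 12
    isolates_per_leaf_method: int = 10
    methods: tuple[str, str] = ("sectioning", "maceration")
    slow_mean: float = 0.04
    slow_sd: float = 0.03
    fast_mean: float = 0.29
    fast_sd: float = 0.14
    slow_width_mean: float = 46.0
    slow_width_sd: float = 25.0
    fast_width_mean: float = 82.0
    fast_width_sd: float = 12.0
    p_fast_given_maceration: float = 0.85
    n_resources: int = 95
    clade_assemblage_fidelity: float = 0.9
    # depth fractions (of tree height) at which taxonomy levels are cut
    class_depth_frac: float = 0.25
    order_depth_frac: float = 0.40
    otu_depth_frac: float = 0.75
    # plate noise model
    water_mean: float = 0.05
    water_sd: float = 0.01
    used_noise_sd: float = 0.02
    unused_noise_sd: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        for name in ("slow_sd", "fast_sd", "slow_width_sd", "fast_width_sd",
                     "water_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("p_fast_given_maceration", "clade_assemblage_fidelity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for mean, sd in ((self.slow_width_mean, self.slow_width_sd),
                         (self.fast_width_mean, self.fast_width_sd)):
            if mean - self.n_resources > 3 * sd:
                raise ValueError(
                    "infeasible niche-width distribution: mean exceeds the "
                    "number of resources by more than 3 sd"
                )

    @property
    def n_isolates(self) -> int:
        return self.n_leaves * len(self.methods) * self.isolates_per_leaf_method


@dataclass
class SyntheticCommunity:
    """Bundle of generated inputs plus ground truth for recovery tests."""

    tree: Phylogeny
    taxonomy: pd.DataFrame  # indexed by isolate_id: otu_id, class, order
    plate: BiologPlate
    metadata: pd.DataFrame  # isolate_id, leaf_id, plot, treatment, method, ...
    truth: dict

    def write(self, outdir) -> dict[str, str]:
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "plate": os.path.join(outdir, "plate.csv"),
            "metadata": os.path.join(outdir, "metadata.csv"),
            "taxonomy": os.path.join(outdir, "taxonomy.csv"),
            "tree": os.path.join(outdir, "tree.nwk"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        self.plate.to_csv(paths["plate"])
        self.metadata.to_csv(paths["metadata"], index=False)
        self.taxonomy.to_csv(paths["taxonomy"], index_label="isolate_id")
        self.tree.write_newick(paths["tree"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2)
        return paths


def simulate_tree(
    n_tips: int,
    seed: int | None = None,
    birth_rate: float = 1.0,
    prefix: str = "t",
) -> Phylogeny:
    """Pure-birth (Yule) tree conditioned on ``n_tips`` extant tips.

    Forward simulation from the root split: with k extant lineages the
    waiting time to the next split is Exponential(k * birth_rate) and a
    uniformly chosen lineage splits; after the (n-1)-th split all tips are
    extended by one further Exponential(n * birth_rate) waiting time, so
    the tree is ultrametric with strictly positive terminal branches.
    Expected height is sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.edge.length = 0.0
    first = [dendropy.Node(), dendropy.Node()]
    for c in first:
        root.add_child(c)
    pending = {id(c): 0.0 for c in first}
    active = list(first)
    while len(active) < n_tips:
        k = len(active)
        dt = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            pending[id(node)] += dt
        i = int(rng.integers(k))
        parent = active.pop(i)
        parent.edge.length = pending.pop(id(parent))
        kids = [dendropy.Node(), dendropy.Node()]
        for c in kids:
            parent.add_child(c)
            pending[id(c)] = 0.0
        active.extend(kids)
    dt = rng.exponential(1.0 / (n_tips * birth_rate))
    width = len(str(n_tips))
    for j, node in enumerate(active, start=1):
        node.edge.length = pending.pop(id(node)) + dt
        node.taxon = taxa.new_taxon(label=f"{prefix}{j:0{width}d}")
    return Phylogeny(tree)


def cut_tree_groups(
    tree: Phylogeny, depth_frac: float, prefix: str
) -> dict[str, list[str]]:
    """Partition tips into clades by cutting the tree at a fixed depth.

    The cut depth is ``depth_frac`` times the maximum root-to-tip distance;
    every edge crossing that depth founds one group. Group names are
    ``prefix`` plus a 1-based index in tree traversal order.
    """
    dtree = tree._tree
    depth: dict[int, float] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (
                node.edge.length or 0.0
            )
    height = max(depth[id(l)] for l in dtree.leaf_node_iter())
    d = depth_frac * height
    groups: dict[str, list[str]] = {}
    idx = 0

    def tips_below(node):
        return [l.taxon.label for l in node.leaf_iter()]

    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if depth[id(node)] >= d and depth[id(node.parent_node)] < d:
            idx += 1
            groups[f"{prefix}{idx:02d}"] = tips_below(node)
    return groups


def _balanced_class_labels(
    classes: dict[str, list[str]], rng: np.random.Generator, n_total: int
) -> dict[str, str]:
    """Assign each class a majority assemblage, keeping both represented.

    Classes draw slow/fast fairly; if either assemblage would cover less
    than 20% of isolates, whole classes are flipped (choosing the flip
    that best rebalances) until both are adequately represented.
    """
    names = list(classes)
    labels = {c: ("fast" if rng.random() < 0.5 else "slow") for c in names}
    sizes = {c: len(t) for c, t in classes.items()}

    def share(lab):
        return sum(sizes[c] for c in names if labels[c] == lab) / n_total

    for _ in range(len(names)):
        low = min(("slow", "fast"), key=share)
        if share(low) >= 0.2:
            break
        majority = "fast" if low == "slow" else "slow"
        candidates = [c for c in names if labels[c] == majority]
        # flip the class that brings the minority share closest to 0.5
        best = min(candidates,
                   key=lambda c: abs(share(low) + sizes[c] / n_total - 0.5))
        labels[best] = low
    return labels


def simulate_community(spec: CommunitySpec | None = None) -> SyntheticCommunity:
    """Generate one synthetic culture collection under ``spec``.

    Fully deterministic given ``spec.seed``. See the module docstring for
    the generative model; ground truth (per-isolate assemblage, drawn mean
    growth and niche width, clade labels) is returned in ``truth``.
    """
    spec = spec or CommunitySpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_isolates

    tree = simulate_tree(n, seed=int(rng.integers(2**31)), prefix="iso")
    tips = list(tree.tips)
    classes = cut_tree_groups(tree, spec.class_depth_frac, "Class")
    orders = cut_tree_groups(tree, spec.order_depth_frac, "Order")
    otus = cut_tree_groups(tree, spec.otu_depth_frac, "OTU")

    tip_class = {t: c for c, ts in classes.items() for t in ts}
    tip_order = {t: o for o, ts in orders.items() for t in ts}
    tip_otu = {t: o for o, ts in otus.items() for t in ts}

    class_assemblage = _balanced_class_labels(classes, rng, n)
    assemblage: dict[str, str] = {}
    for t in tips:
        major = class_assemblage[tip_class[t]]
        if rng.random() < spec.clade_assemblage_fidelity:
            assemblage[t] = major
        else:
            assemblage[t] = "slow" if major == "fast" else "fast"

    # isolation method biased by assemblage, filling fixed-size halves.
    # Maceration draws its half by weighted sampling without replacement
    # with weight p_fast_given_maceration for fast isolates and its
    # complement for slow ones (Efraimidis-Spirakis keys); at p = 0.5 this
    # is exactly a uniform split, so method and assemblage are independent.
    half = spec.n_leaves * spec.isolates_per_leaf_method
    p = spec.p_fast_given_maceration
    weights = np.array([
        max(p if assemblage[t] == "fast" else 1.0 - p, 1e-12) for t in tips
    ])
    keys = -np.log(rng.uniform(size=n)) / weights
    mac_idx = set(np.argsort(keys)[:half])
    method_name = {True: "maceration", False: "sectioning"}
    if "maceration" not in spec.methods:  # custom method names: keep order
        method_name = {True: spec.methods[1], False: spec.methods[0]}
    method_of = {t: method_name[i in mac_idx] for i, t in enumerate(tips)}

    # leaves: shuffle within method, chunk into cells of fixed size
    leaf_ids = [f"L{j:02d}" for j in range(1, spec.n_leaves + 1)]
    plots = {leaf: f"P{(j // 3) + 1}" for j, leaf in enumerate(leaf_ids)}
    treatments = {leaf: ("Control" if (j // 3) % 2 == 0 else "NPK")
                  for j, leaf in enumerate(leaf_ids)}
    leaf_of: dict[str, str] = {}
    for method in spec.methods:
        members = [t for t in tips if method_of[t] == method]
        rng.shuffle(members)
        for j, t in enumerate(members):
            leaf_of[t] = leaf_ids[j // spec.isolates_per_leaf_method]

    # growth traits
    growth: dict[str, float] = {}
    width: dict[str, int] = {}
    for t in tips:
        if assemblage[t] == "slow":
            g = rng.normal(spec.slow_mean, spec.slow_sd)
            w = rng.normal(spec.slow_width_mean, spec.slow_width_sd)
        else:
            g = rng.normal(spec.fast_mean, spec.fast_sd)
            w = rng.normal(spec.fast_width_mean, spec.fast_width_sd)
        growth[t] = float(g)
        width[t] = int(np.clip(round(w), 0, spec.n_resources))

    # plate: used wells carry the growth signal scaled so the isolate's
    # mean standardized growth over the whole plate equals the drawn value
    resources = [f"R{j:02d}" for j in range(1, spec.n_resources + 1)]
    water = np.maximum(rng.normal(spec.water_mean, spec.water_sd, size=n), 0.0)
    od = np.empty((n, spec.n_resources))
    used_sets: dict[str, list[int]] = {}
    for i, t in enumerate(tips):
        w = width[t]
        used = rng.choice(spec.n_resources, size=w, replace=False)
        used_sets[t] = sorted(int(u) for u in used)
        row = water[i] + rng.normal(0.0, spec.unused_noise_sd,
                                    size=spec.n_resources)
        if w > 0:
            per_well = growth[t] * spec.n_resources / w
            row[used] = water[i] + per_well + rng.normal(
                0.0, spec.used_noise_sd, size=w)
        od[i] = row
    plate = BiologPlate(
        od=pd.DataFrame(od, index=tips, columns=resources),
        water=pd.Series(water, index=tips, name="water"),
    )

    taxonomy = pd.DataFrame(
        {
            "otu_id": [tip_otu[t] for t in tips],
            "class": [tip_class[t] for t in tips],
            "order": [tip_order[t] for t in tips],
        },
        index=pd.Index(tips, name="isolate_id"),
    )
    metadata = pd.DataFrame(
        {
            "isolate_id": tips,
            "leaf_id": [leaf_of[t] for t in tips],
            "plot": [plots[leaf_of[t]] for t in tips],
            "treatment": [treatments[leaf_of[t]] for t in tips],
            "method": [method_of[t] for t in tips],
            "otu_id": [tip_otu[t] for t in tips],
            "class": [tip_class[t] for t in tips],
            "order": [tip_order[t] for t in tips],
            "species": [f"sp_{tip_otu[t]}" for t in tips],
        }
    )
    tree.annotate_tips(taxonomy)

    richness_truth = (
        metadata.groupby(["leaf_id", "method"])["otu_id"].nunique()
    )
    truth = {
        "params": asdict(spec),
        "assemblage": assemblage,
        "mean_growth": growth,
        "niche_width": width,
        "used_resources": used_sets,
        "class_assemblage": class_assemblage,
        "richness_per_leaf_method": {
            f"{leaf}|{method}": int(v)
            for (leaf, method), v in richness_truth.items()
        },
    }
    return SyntheticCommunity(
        tree=tree, taxonomy=taxonomy, plate=plate, metadata=metadata,
        truth=truth,
    )
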