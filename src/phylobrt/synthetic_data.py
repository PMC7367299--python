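"""Simulated phylogenies and trait/response data with known structure.

The generator emulates the structure of the comparative dataset the
pipeline targets: ~89 species on a phylogeny, 17 mixed-type life-history
traits carrying phylogenetic signal, and a sensitivity response that takes
at most 13 distinct values (one per receptor subtype), driven partly by
traits and partly by relatedness. Every stage of the analysis — consensus,
distances, eigenvectors, model frame, boosting, partition — can therefore
be exercised end-to-end with a known generative truth.

Components:

* **Yule (pure-birth) trees** with exponential waiting times; simple, and
  with an analytic expected height useful for validation.
* **Brownian-motion traits**: a root value of 0 and independent Gaussian
  increments with variance sigma^2 * branch length along each branch —
  the canonical model of gradual continuous-trait evolution, and the
  source of phylogenetic signal in the continuous traits.
* **Mk-style categorical traits**: a symmetric Markov jump process along
  branches from a uniform root state (jump events Poisson with the given
  rate; each jump picks uniformly among the other states).
* **Response pathway**: latent = trait component + Brownian component +
  noise, where ``phylo_weight`` sets the fraction of systematic variance
  carried by the Brownian (purely phylogenetic) component. The latent
  value is discretised by quantiles into subtypes, and each subtype is
  assigned an EC50 on a log-spaced grid spanning three orders of magnitude
  (mirroring the up-to-1,000-fold sensitivity range among the real
  subtypes).

Ordered categorical traits are quantile-discretised Brownian traits (so
they stay ordinal); nominal traits evolve under the jump process. Missing
cells are introduced completely at random at ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import dendropy
import numpy as np
import pandas as pd

from .trait_table import (
    CONTINUOUS,
    DEFAULT_TRAIT_SCHEMA,
    NOMINAL,
    ORDERED,
    TraitTable,
)

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_yule_tree",
    "simulate_bm_trait",
    "simulate_mk_trait",
    "random_nni",
    "perturbed_tree_set",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """Conditions of a simulated comparative study.

    Defaults match the target structure: 89 tips, the canonical 17-trait
    schema, 13 subtypes, one dominant continuous driver trait
    (incubation period), a 0.2 share of systematic variance carried by
    phylogeny, and 5% missing cells.
    """

    n_tips: int = 89
    birth_rate: float = 1.0
    n_trees: int = 25
    nni_moves: int = 2
    branch_length_jitter_sd: float = 0.1
    bm_sigma2: float = 1.0
    mk_rate: float = 0.5
    trait_effects: dict = field(
        default_factory=lambda: {"incubation_period": 1.0}
    )
    phylo_weight: float = 0.2
    noise_sd: float = 0.3
    n_subtypes: int = 13
    ec50_log10_min: float = -1.0
    ec50_log10_span: float = 3.0
    missing_rate: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if not 0 <= self.phylo_weight <= 1:
            raise ValueError("phylo_weight must be in [0, 1]")
        if not 2 <= self.n_subtypes <= 13:
            raise ValueError("n_subtypes must be in [2, 13]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        unknown = set(self.trait_effects) - set(DEFAULT_TRAIT_SCHEMA)
        if unknown:
            raise ValueError(f"trait_effects name unknown traits: {sorted(unknown)}")


@dataclass
class SimulatedDataset:
    """Output bundle of :func:`simulate_dataset`.

    ``truth`` carries the generative components (latent response, its
    trait and phylogenetic parts) for recovery testing.
    """

    trees: dendropy.TreeList
    traits: TraitTable
    subtype_by_species: dict
    ec50_by_subtype: dict
    truth: dict


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed=0
) -> dendropy.Tree:
    """Simulate a pure-birth tree with ``n_tips`` extant tips.

    Starting from a root with two lineages, each period with k lineages
    lasts an exponential time with rate k * birth_rate and ends with a
    uniformly chosen lineage splitting; a final exponential period with n
    lineages precedes the present, so the expected height is
    sum_{k=2..n} 1 / (k * birth_rate). Tips are labelled sp001, sp002, ...
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = _as_rng(seed)
    labels = [f"sp{i + 1:03d}" for i in range(n_tips)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    birth_time = {root: 0.0}
    active = [root.new_child(), root.new_child()]
    t = 0.0
    for node in active:
        birth_time[node] = 0.0
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node = active[i]
        node.edge.length = t - birth_time[node]
        c1, c2 = node.new_child(), node.new_child()
        birth_time[c1] = birth_time[c2] = t
        active[i : i + 1] = [c1, c2]
        k += 1
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for i, node in enumerate(active):
        node.edge.length = t - birth_time[node]
        node.taxon = tns.get_taxon(labels[i])
    return tree


def simulate_bm_trait(tree: dendropy.Tree, sigma2: float, seed=0) -> pd.Series:
    """Brownian-motion tip values: root 0, increment variance sigma2 * length."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = _as_rng(seed)
    value = {tree.seed_node: 0.0}
    out = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            bl = node.edge.length or 0.0
            value[node] = value[node.parent_node] + rng.normal(
                0.0, np.sqrt(sigma2 * bl)
            )
        if node.is_leaf():
            out[node.taxon.label] = value[node]
    return pd.Series(out).sort_index()


def simulate_mk_trait(
    tree: dendropy.Tree, n_states: int, rate: float, seed=0
) -> pd.Series:
    """Symmetric Markov-jump categorical tip states from a uniform root.

    Jump events along a branch of length t are Poisson(rate * t); each
    jump moves to a uniformly chosen different state. Returns integer
    state indices in [0, n_states).
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = _as_rng(seed)
    state = {tree.seed_node: int(rng.integers(n_states))}
    out = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            s = state[node.parent_node]
            bl = node.edge.length or 0.0
            for _ in range(rng.poisson(rate * bl)):
                step = int(rng.integers(n_states - 1))
                s = step if step < s else step + 1
            state[node] = s
        if node.is_leaf():
            out[node.taxon.label] = state[node]
    return pd.Series(out).sort_index()


def random_nni(tree: dendropy.Tree, rng, n_moves: int = 1) -> dendropy.Tree:
    """Apply random nearest-neighbour-interchange moves in place.

    Each move picks an internal node with a sibling and swaps one of its
    children with that sibling, preserving branch lengths on the moved
    subtrees.
    """
    rng = _as_rng(rng)
    for _ in range(n_moves):
        candidates = [
            nd
            for nd in tree.preorder_internal_node_iter()
            if nd.parent_node is not None
            and len(nd.parent_node.child_nodes()) >= 2
            and len(nd.child_nodes()) >= 2
        ]
        if not candidates:
            break
        node = candidates[int(rng.integers(len(candidates)))]
        siblings = [c for c in node.parent_node.child_nodes() if c is not node]
        sib = siblings[int(rng.integers(len(siblings)))]
        child = node.child_nodes()[int(rng.integers(len(node.child_nodes())))]
        parent = node.parent_node
        parent.remove_child(sib)
        node.remove_child(child)
        parent.add_child(child)
        node.add_child(sib)
    return tree


def perturbed_tree_set(
    true_tree: dendropy.Tree,
    n_trees: int,
    nni_moves: int,
    jitter_sd: float,
    rng,
) -> dendropy.TreeList:
    """The true tree plus NNI-perturbed, length-jittered replicates.

    Emulates a posterior sample of trees around the true topology, so that
    consensus building has realistic disagreement to resolve. Branch
    lengths are multiplied by lognormal(0, jitter_sd) factors.
    """
    rng = _as_rng(rng)
    trees = dendropy.TreeList(taxon_namespace=true_tree.taxon_namespace)
    trees.append(true_tree.clone(depth=1))
    for _ in range(max(0, n_trees - 1)):
        rep = true_tree.clone(depth=1)
        random_nni(rep, rng, n_moves=nni_moves)
        if jitter_sd > 0:
            for edge in rep.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = float(
                        edge.length * np.exp(rng.normal(0.0, jitter_sd))
                    )
        trees.append(rep)
    return trees


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _quantile_codes(values: pd.Series, levels: list) -> pd.Series:
    """Discretise a continuous series into ordered codes by quantile."""
    ranks = values.rank(method="first")
    bins = np.ceil(ranks / len(values) * len(levels)).astype(int) - 1
    return pd.Series(
        [levels[b] for b in bins.clip(0, len(levels) - 1)],
        index=values.index,
    )


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Simulate trees, a 17-trait table, and a subtype/EC50 response map.

    The latent response is
    ``sqrt(1 - w) * z(trait part) + sqrt(w) * z(BM part) + noise`` with
    w = ``phylo_weight``, the trait part a linear combination of the
    standardised driver traits named in ``trait_effects``, and the BM part
    an independent Brownian trait on the true tree. The latent value is
    quantile-discretised into ``n_subtypes`` subtypes (S01, S02, ...) whose
    EC50s sit on a log-spaced grid, so the species-level response built
    from the maps is monotone in the latent ordering.
    """
    config = SimConfig() if config is None else config
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    (
        tree_seed, set_seed, trait_seed, bm_seed, noise_seed, miss_seed
    ) = ss.spawn(6)

    true_tree = simulate_yule_tree(
        config.n_tips, config.birth_rate, np.random.default_rng(tree_seed)
    )
    trees = perturbed_tree_set(
        true_tree,
        config.n_trees,
        config.nni_moves,
        config.branch_length_jitter_sd,
        np.random.default_rng(set_seed),
    )

    trait_rng = np.random.default_rng(trait_seed)
    columns = {}
    for name, spec in DEFAULT_TRAIT_SCHEMA.items():
        if spec["kind"] == CONTINUOUS:
            columns[name] = simulate_bm_trait(
                true_tree, config.bm_sigma2, trait_rng
            )
        elif spec["kind"] == ORDERED:
            base = simulate_bm_trait(true_tree, config.bm_sigma2, trait_rng)
            columns[name] = _quantile_codes(base, spec["levels"])
        else:
            states = simulate_mk_trait(
                true_tree, len(spec["levels"]), config.mk_rate, trait_rng
            )
            columns[name] = pd.Series(
                [spec["levels"][s] for s in states], index=states.index
            )
    full = pd.DataFrame(columns)
    species = list(full.index)
    n = len(species)

    trait_part = np.zeros(n)
    for name, beta in config.trait_effects.items():
        kind = DEFAULT_TRAIT_SCHEMA[name]["kind"]
        if kind == NOMINAL:
            raise ValueError(
                f"trait_effects must name continuous/ordered traits, "
                f"got nominal {name!r}"
            )
        trait_part += beta * _standardize(full[name].to_numpy(dtype=float))
    bm_part = _standardize(
        simulate_bm_trait(
            true_tree, 1.0, np.random.default_rng(bm_seed)
        ).to_numpy()
    )
    w = config.phylo_weight
    latent = np.sqrt(1.0 - w) * _standardize(trait_part) + np.sqrt(w) * bm_part
    latent = latent + np.random.default_rng(noise_seed).normal(
        0.0, config.noise_sd, n
    )

    order = pd.Series(latent, index=species).rank(method="first")
    bins = (
        np.ceil(order / n * config.n_subtypes).astype(int).clip(1, config.n_subtypes)
    )
    subtype_by_species = {
        sp: f"S{int(b):02d}" for sp, b in bins.items()
    }
    grid = np.logspace(
        config.ec50_log10_min,
        config.ec50_log10_min + config.ec50_log10_span,
        config.n_subtypes,
    )
    ec50_by_subtype = {
        f"S{i + 1:02d}": float(grid[i]) for i in range(config.n_subtypes)
    }

    observed = full.copy()
    if config.missing_rate > 0:
        miss_rng = np.random.default_rng(miss_seed)
        mask = miss_rng.random(observed.shape) < config.missing_rate
        observed = observed.mask(pd.DataFrame(
            mask, index=observed.index, columns=observed.columns
        ))
    traits = TraitTable(data=observed, schema=dict(DEFAULT_TRAIT_SCHEMA))
    truth = {
        "latent": pd.Series(latent, index=species),
        "trait_component": pd.Series(_standardize(trait_part), index=species),
        "phylo_component": pd.Series(bm_part, index=species),
        "true_tree": true_tree,
    }
    return SimulatedDataset(
        trees=trees,
        traits=traits,
        subtype_by_species=subtype_by_species,
        ec50_by_subtype=ec50_by_subtype,
        truth=truth,
    )
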