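"""Multispecies-coalescent data generator with known truth.

Genealogies follow the Kingman coalescent within each species (pairwise
coalescence rate 1/Ne per generation, so the expected coalescence time of a
pair is Ne generations and the expected within-species diversity is
theta = 2*Ne*mu — the haploid convention appropriate for an asexual,
mitochondrial-like locus).  At each divergence time of the (ultrametric)
species tree the surviving lineages enter the ancestral population.  No
recombination, migration or selection.  Sequences then evolve along the
genealogy under a GTR-family model with invariant sites and discrete-gamma
rate variation; one unit of branch length is one generation and the expected
divergence of two sequences whose lineages split t generations ago is
2*mu*t plus the ancestral coalescent contribution (~theta_ancestral).

Two fixture presets emulate the shape of a darwinulid ostracod study:
``coi_like`` (5 morphospecies containing 16 species in total, 58 specimens
carrying 29 distinct haplotypes of a 385 bp COI-like fragment) and
``its2_like`` (5 species, 22 specimens, 14 distinct haplotypes of a slower
nuclear marker).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy
import msprime
import numpy as np
import pandas as pd

from .io_formats import Alignment
from .phylo_trees import node_ages, parse_newick
from .subst_models import BASES, SubstitutionModel, get_preset

__all__ = [
    "SpeciesSpec",
    "SimulationConfig",
    "Fixture",
    "simulate_genealogy",
    "simulate_genealogies",
    "simulate_sequences",
    "generate_fixture",
    "coi_like_config",
    "its2_like_config",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesSpec:
    """One species: sample size and effective population size."""

    name: str
    n_tips: int
    Ne: float

    def __post_init__(self) -> None:
        if self.n_tips < 1:
            raise ValueError("n_tips must be >= 1")
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")


@dataclass
class SimulationConfig:
    """Ground truth of a multispecies-coalescent simulation.

    ``species_tree`` is a Newick string over the species names with branch
    lengths in generations (ultrametric); ``None`` for a single species.
    Ancestral populations take the mean Ne of the populations they merge
    unless overridden via ``ancestral_Ne``.
    """

    species: tuple[SpeciesSpec, ...]
    species_tree: str | None
    mu: float
    L: int
    model: SubstitutionModel
    seed: int
    ancestral_Ne: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if len(self.species) > 1 and self.species_tree is None:
            raise ValueError("several species require a species_tree")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")

    @property
    def theta_true(self) -> dict[str, float]:
        """Per-species theta = 2 * Ne * mu."""
        return {s.name: 2.0 * s.Ne * self.mu for s in self.species}

    def divergence_times(self) -> dict[frozenset, float]:
        """Pairwise species divergence times (generations before present)."""
        if self.species_tree is None:
            return {}
        tree = parse_newick(self.species_tree)
        ages = node_ages(tree, require_ultrametric=True, rtol=1e-4)
        out: dict[frozenset, float] = {}
        for node in tree.preorder_internal_node_iter():
            children = node.child_nodes()
            for i, a in enumerate(children):
                for b in children[i + 1 :]:
                    for la in (l.taxon.label for l in a.leaf_iter()):
                        for lb in (l.taxon.label for l in b.leaf_iter()):
                            out[frozenset((la, lb))] = ages[node]
        return out

    def expected_K(self, a: str, b: str) -> float:
        """2*mu*t plus the ancestral-coalescent term theta_anc."""
        t = self.divergence_times()[frozenset((a, b))]
        by_name = {s.name: s.Ne for s in self.species}
        ne_anc = self.ancestral_Ne.get("root", (by_name[a] + by_name[b]) / 2.0)
        return 2.0 * self.mu * t + 2.0 * self.mu * ne_anc


def _demography(config: SimulationConfig) -> msprime.Demography:
    demography = msprime.Demography()
    by_name = {s.name: s for s in config.species}
    for spec in config.species:
        demography.add_population(name=spec.name, initial_size=spec.Ne)
    if config.species_tree is not None:
        tree = parse_newick(config.species_tree)
        ages = node_ages(tree, require_ultrametric=True, rtol=1e-4)
        pop_of: dict[dendropy.Node, str] = {}
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label not in by_name:
                raise ValueError(f"species tree tip {leaf.taxon.label!r} not in species list")
            pop_of[leaf] = leaf.taxon.label
        internal = sorted(
            tree.preorder_internal_node_iter(), key=lambda nd: ages[nd]
        )
        counter = 0
        sizes = {s.name: s.Ne for s in config.species}
        for node in internal:
            derived = [pop_of[c] for c in node.child_nodes()]
            name = f"anc{counter}" if node.parent_node is not None else "root"
            counter += 1
            size = config.ancestral_Ne.get(name, float(np.mean([sizes[d] for d in derived])))
            sizes[name] = size
            demography.add_population(name=name, initial_size=size)
            demography.add_population_split(time=ages[node], derived=derived, ancestral=name)
            pop_of[node] = name
    return demography


def _tskit_to_dendropy(ts, labels: dict[int, str]) -> dendropy.Tree:
    """Convert the (single) tskit tree to a dendropy tree in generations."""
    tsk_tree = ts.first()
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(u: int) -> dendropy.Node:
        node = dendropy.Node()
        node.support = None
        children = tsk_tree.children(u)
        if not children:
            node.taxon = tns.require_taxon(label=labels[u])
        for c in children:
            child = build(c)
            node.add_child(child)
            child.edge.length = tsk_tree.time(u) - tsk_tree.time(c)
        return node

    tree.seed_node = build(tsk_tree.root)
    tree.is_rooted = True
    return tree


def _tip_labels(config: SimulationConfig) -> dict[int, str]:
    labels = {}
    counter = 0
    for spec in config.species:
        for i in range(spec.n_tips):
            labels[counter] = f"{spec.name}_{i + 1}"
            counter += 1
    return labels


def simulate_genealogy(config: SimulationConfig) -> dendropy.Tree:
    """One multispecies-coalescent genealogy (ultrametric, in generations)."""
    return next(simulate_genealogies(config, 1))


def simulate_genealogies(config: SimulationConfig, n: int) -> Iterator[dendropy.Tree]:
    """Stream of independent genealogies under *config* (seeded)."""
    demography = _demography(config)
    samples = [
        msprime.SampleSet(spec.n_tips, population=spec.name, ploidy=1)
        for spec in config.species
    ]
    labels = _tip_labels(config)
    replicates = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        ploidy=1,
        random_seed=max(int(config.seed) % (2**31), 1),
        num_replicates=n,
    )
    for ts in replicates:
        yield _tskit_to_dendropy(ts, labels)


def simulate_sequences(
    tree: dendropy.Tree, config: SimulationConfig, seed_offset: int = 1
) -> Alignment:
    """Evolve sequences along *tree* (branch lengths in generations).

    The root sequence is drawn from the stationary frequencies; each site is
    invariant with probability p_inv, otherwise assigned one discrete-gamma
    category; transition matrices are P(mu * branch * rate).  With mu = 0 all
    sequences equal the root sequence.
    """
    model, L, mu = config.model, config.L, config.mu
    rng = np.random.default_rng((int(config.seed) + seed_offset) % (2**31))
    k = len(model.category_rates)
    site_cat = np.full(L, -1, dtype=np.int64)  # -1: invariant
    variable = rng.random(L) >= model.p_inv
    site_cat[variable] = rng.integers(0, k, int(variable.sum()))
    states: dict[dendropy.Node, np.ndarray] = {}
    root_state = rng.choice(4, size=L, p=model.freqs)
    states[tree.seed_node] = root_state
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = states[node.parent_node]
        t = mu * (node.edge.length or 0.0)
        state = parent_state.copy()
        if t > 0:
            for c in range(k):
                sites = np.flatnonzero(site_cat == c)
                if not len(sites):
                    continue
                P = model.transition_matrix(t * model.category_rates[c])
                cum = np.cumsum(P, axis=1)
                u = rng.random(len(sites))
                state[sites] = (
                    u[:, None] > cum[parent_state[sites]]
                ).sum(axis=1)
        states[node] = state
    base_arr = np.frombuffer("".join(BASES).encode(), dtype=np.uint8)
    records = []
    for leaf in tree.leaf_node_iter():
        seq = base_arr[states[leaf]].tobytes().decode()
        records.append((leaf.taxon.label, seq))
    return Alignment.from_records(records)


# ---------------------------------------------------------------------------
# fixtures

@dataclass
class Fixture:
    """A simulated dataset plus its ground truth."""

    alignment: Alignment
    truth: pd.DataFrame
    tree: dendropy.Tree
    config: SimulationConfig


def _graft_duplicates(
    tree: dendropy.Tree, duplicates: dict[str, list[str]]
) -> dendropy.Tree:
    """Attach zero-length sibling tips for repeatedly-sampled haplotypes."""
    for leaf in list(tree.leaf_node_iter()):
        extra = duplicates.get(leaf.taxon.label, [])
        if not extra:
            continue
        carrier_taxon = leaf.taxon
        length = leaf.edge.length
        leaf.taxon = None
        original = dendropy.Node()
        original.taxon = carrier_taxon
        original.support = None
        original.edge.length = 0.0
        leaf.add_child(original)
        for label in extra:
            node = dendropy.Node()
            node.taxon = tree.taxon_namespace.require_taxon(label=label)
            node.support = None
            node.edge.length = 0.0
            leaf.add_child(node)
        leaf.edge.length = length
    return tree


def _pick_carriers(aln: Alignment, need: dict[str, int]) -> dict[str, list[str]] | None:
    """Per species, the first tips of the *h* most frequent distinct haplotypes."""
    by_species: dict[str, list[tuple[str, str]]] = {}
    for label, seq in aln.records:
        by_species.setdefault(label.rsplit("_", 1)[0], []).append((label, seq))
    out: dict[str, list[str]] = {}
    for name, h in need.items():
        classes: dict[str, list[str]] = {}
        for label, seq in by_species[name]:
            classes.setdefault(seq, []).append(label)
        if len(classes) < h:
            return None
        ranked = sorted(classes.values(), key=lambda labs: (-len(labs), labs[0]))
        out[name] = [labs[0] for labs in ranked[:h]]
    return out


# (morphospecies, species, specimens, distinct haplotypes, theta)
_COI_DESIGN = [
    ("MspA", "A1", 6, 3, 0.003), ("MspA", "A2", 4, 2, 0.003),
    ("MspA", "A3", 4, 2, 0.004), ("MspA", "A4", 3, 2, 0.005),
    ("MspA", "A5", 3, 1, 0.004), ("MspA", "A6", 3, 1, 0.004),
    ("MspA", "A7", 2, 1, 0.008),
    ("MspB", "B1", 6, 3, 0.003), ("MspB", "B2", 4, 2, 0.003),
    ("MspB", "B3", 3, 2, 0.003), ("MspB", "B4", 2, 1, 0.004),
    ("MspB", "B5", 2, 1, 0.010),
    ("MspC", "C1", 4, 3, 0.007), ("MspC", "C2", 3, 2, 0.005),
    ("MspD", "D1", 5, 2, 0.008),
    ("MspE", "E1", 4, 1, 0.010),
]

# species-tree times in generations (ultrametric; deepest split 3.5e6)
_COI_SPECIES_TREE = (
    "(((((((A1:450000,A2:450000):150000,A3:600000):150000,A4:750000):450000,"
    "((A5:700000,A6:700000):300000,A7:1000000):200000):800000,D1:2000000):800000,"
    "E1:2800000):700000,"
    "((((B1:550000,B2:550000):300000,(B3:650000,B4:650000):200000):150000,"
    "B5:1000000):2000000,(C1:1100000,C2:1100000):1900000):500000);"
)

_ITS2_DESIGN = [
    ("MspA", "S1", 8, 5, 0.003), ("MspA", "S2", 5, 3, 0.002),
    ("MspB", "S3", 4, 3, 0.004),
    ("MspC", "S4", 3, 2, 0.003), ("MspC", "S5", 2, 1, 0.002),
]

_ITS2_SPECIES_TREE = (
    "(((S1:1200000,S2:1200000):3800000,S3:5000000):1000000,"
    "(S4:1500000,S5:1500000):4500000);"
)


def _design_config(design, species_tree: str, mu: float, L: int, model, seed: int) -> SimulationConfig:
    species = tuple(
        SpeciesSpec(name, h, theta / (2.0 * mu)) for _, name, _, h, theta in design
    )
    return SimulationConfig(
        species=species, species_tree=species_tree, mu=mu, L=L, model=model, seed=seed
    )


def coi_like_config(seed: int = 1) -> SimulationConfig:
    """Mitochondrial-like preset: 16 species in 5 morphospecies, 385 bp."""
    return _design_config(_COI_DESIGN, _COI_SPECIES_TREE, 2e-8, 385, get_preset("coi_paper"), seed)


def its2_like_config(seed: int = 1) -> SimulationConfig:
    """Nuclear-like preset: 5 species, slower substitution, shallower splits."""
    return _design_config(_ITS2_DESIGN, _ITS2_SPECIES_TREE, 5e-9, 300, get_preset("its2_paper"), seed)


def generate_fixture(preset="coi_like", seed: int = 1) -> Fixture:
    """Simulate a preset (or custom config) dataset with duplicated haplotypes.

    For the shipped presets the specimen counts exceed the distinct-haplotype
    counts: distinct haplotype carriers are simulated on the genealogy and
    repeatedly-sampled haplotypes are emitted as exact duplicates (grafted
    onto the genealogy as zero-length sibling tips), so the complete/pruned
    dataset sizes are fixed by design.  Simulation is retried with a derived
    seed in the rare event that two carrier haplotypes collide.
    """
    if isinstance(preset, SimulationConfig):
        config = preset
        design = None
    elif preset == "coi_like":
        config = coi_like_config(seed)
        design = _COI_DESIGN
    elif preset == "its2_like":
        config = its2_like_config(seed)
        design = _ITS2_DESIGN
    else:
        raise ValueError(f"unknown preset {preset!r}")
    if design is None:
        attempt_config = config
        tree = simulate_genealogy(config)
        aln = simulate_sequences(tree, config)
    else:
        # identical haplotypes are common at theta*L of order 1, exactly as in
        # real samples; to pin the distinct-haplotype count we oversample each
        # species and keep its most frequent distinct haplotypes as carriers
        need = {name: h for _, name, _, h, _ in design}
        oversampled = tuple(
            SpeciesSpec(s.name, s.n_tips if need[s.name] == 1 else need[s.name] + 9, s.Ne)
            for s in config.species
        )
        for attempt in range(50):
            attempt_config = SimulationConfig(
                species=oversampled,
                species_tree=config.species_tree,
                mu=config.mu,
                L=config.L,
                model=config.model,
                seed=(config.seed + 7919 * attempt) % (2**31),
                ancestral_Ne=config.ancestral_Ne,
            )
            big_tree = simulate_genealogy(attempt_config)
            big_aln = simulate_sequences(big_tree, attempt_config)
            carriers = _pick_carriers(big_aln, need)
            if carriers is not None and len({big_aln.sequence(c) for cs in carriers.values() for c in cs}) == sum(
                need.values()
            ):
                break
            logger.info("haplotype shortfall/collision at attempt %d; resimulating", attempt)
        else:
            raise RuntimeError("could not simulate the designed number of distinct haplotypes")
        keep = [c for cs in carriers.values() for c in cs]
        big_tree.retain_taxa_with_labels(keep)
        tree = big_tree
        aln = big_aln.subset(keep)
        # rename carriers to the canonical <species>_<h> labels
        rename_carrier = {}
        for name, labels in carriers.items():
            for h, lab in enumerate(labels):
                rename_carrier[lab] = f"{name}_{h + 1}"
        aln = Alignment.from_records(
            [(rename_carrier[lab], aln.sequence(lab)) for lab in keep]
        )
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = rename_carrier[leaf.taxon.label]
    theta = config.theta_true
    if design is None:
        truth = pd.DataFrame(
            [
                {
                    "label": lab,
                    "species": lab.rsplit("_", 1)[0],
                    "morphospecies": lab.rsplit("_", 1)[0],
                    "theta_true": theta[lab.rsplit("_", 1)[0]],
                    "haplotype": lab,
                }
                for lab in aln.labels
            ]
        )
        return Fixture(aln, truth, tree, attempt_config)
    # emit duplicate specimens per design (first haplotype is the most-sampled)
    records = []
    rows = []
    first_label: dict[str, str] = {}
    grafts: dict[str, list[str]] = {}
    hap_seq = dict(aln.records)
    for morpho, name, n_specimens, n_haps, _ in design:
        copies = [n_specimens - n_haps + 1] + [1] * (n_haps - 1)
        specimen = 0
        for h in range(n_haps):
            carrier = f"{name}_{h + 1}"
            for c in range(copies[h]):
                specimen += 1
                label = f"{name}_s{specimen}"
                records.append((label, hap_seq[carrier]))
                if c == 0:
                    first_label[carrier] = label
                else:
                    grafts.setdefault(carrier, []).append(label)
                rows.append(
                    {
                        "label": label,
                        "species": name,
                        "morphospecies": morpho,
                        "theta_true": theta[name],
                        "haplotype": first_label[carrier],
                    }
                )
    full = Alignment.from_records(records)
    # carry specimen labels onto the genealogy: the first copy replaces the
    # carrier tip, further copies become zero-length sibling tips
    tree = _graft_duplicates(tree, grafts)
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in first_label:
            leaf.taxon.label = first_label[leaf.taxon.label]
    truth = pd.DataFrame(rows)
    return Fixture(full, truth, tree, attempt_config)
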