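"""The K/theta (4x) rule for evolutionary-genetic species delimitation.

Two clades on a single-locus tree are called separate species when the
model-corrected mean divergence between them, K, is at least four times the
within-clade diversity theta, and the probability that samples of the two
clades come from populations isolated long enough to be reciprocally
monophyletic is at least 0.95.  The rationale: under drift alone the gap
between clusters within one species averages 2*Ne generations (95% within
4*Ne), at which point K = 8*Ne*mu while theta ~ 2*Ne*mu, so K/theta = 4
marks the depth that drift can no longer explain.

The four-step procedure:

1. build an NJ tree and keep clades with >= 90% bootstrap support;
2. for each clade compute the mean pairwise uncorrected difference d, the
   nucleotide diversity pi = d*n/(n-1) and theta = pi/(1 - 4*pi/3) (when all
   n sequences are identical, d is computed as if one sequence differed at a
   single site: d = 2/(L*n));
3. compute K as the mean model-corrected distance between the clade and its
   sister (or, when the sister is unsupported, the closest supported clade);
4. compare K/theta with 4 and look up the reciprocal-monophyly probability
   for the two sample sizes at divergence tau = K/theta (in units of Ne
   generations; see docs/methods.md for this time convention).
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import Alignment
from .phylo_trees import (
    Clade,
    bootstrap_support,
    leaf_labels,
    midpoint_root,
    neighbor_joining,
    well_supported_clades,
)
from .subst_models import (
    SubstitutionModel,
    _ml_distance_from_counts,
    _pair_counts,
    distance_matrix,
    encode_alignment,
    p_distance_matrix,
)

__all__ = [
    "CladeDiversity",
    "KThetaConfig",
    "KThetaResult",
    "KThetaReport",
    "clade_diversity",
    "between_clade_K",
    "select_comparison_pairs",
    "reciprocal_monophyly_prob",
    "ktheta_test",
    "run_ktheta",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CladeDiversity:
    """Within-clade diversity summary (step 2 of the procedure)."""

    clade: Clade
    n: int
    d: float | None
    pi: float | None
    theta: float | None
    all_identical: bool


def _theta_from_pi(pi: float) -> float:
    return pi / (1.0 - 4.0 * pi / 3.0)


def clade_diversity(aln: Alignment, clade: Clade | Iterable[str]) -> CladeDiversity:
    """d, pi and theta for one clade.

    ``d`` is the mean pairwise uncorrected difference over all within-clade
    pairs (pairwise gap deletion).  For a singleton clade d/pi/theta are
    undefined (None).  When all sequences are identical, d = 2/(L*n), i.e.
    as if one sequence differed from each of the others at one site.
    """
    if not isinstance(clade, Clade):
        clade = Clade(frozenset(clade), 1.0)
    labels = sorted(clade.labels)
    missing = set(labels) - set(aln.labels)
    if missing:
        raise KeyError(f"clade tips not in alignment: {sorted(missing)}")
    n = len(labels)
    if n == 1:
        return CladeDiversity(clade, 1, None, None, None, False)
    sub = aln.subset(labels)
    dmat = p_distance_matrix(encode_alignment(sub))
    iu = np.triu_indices(n, k=1)
    d = float(dmat[iu].mean())
    all_identical = d == 0.0
    if all_identical:
        d = 2.0 / (aln.length * n)
    pi = d * n / (n - 1)
    return CladeDiversity(clade, n, d, pi, _theta_from_pi(pi), all_identical)


def between_clade_K(
    aln: Alignment, a: Clade | Iterable[str], b: Clade | Iterable[str], model: SubstitutionModel
) -> float:
    """Mean model-corrected distance over all cross-clade sequence pairs."""
    labels_a = a.labels if isinstance(a, Clade) else frozenset(a)
    labels_b = b.labels if isinstance(b, Clade) else frozenset(b)
    if labels_a & labels_b:
        raise ValueError(f"clades overlap: {sorted(labels_a & labels_b)}")
    sub = aln.subset(labels_a | labels_b)
    enc = encode_alignment(sub)
    index = {lab: k for k, lab in enumerate(sub.labels)}
    dists = []
    for la, lb in itertools.product(sorted(labels_a), sorted(labels_b)):
        counts = _pair_counts(enc[index[la]], enc[index[lb]])
        dists.append(_ml_distance_from_counts(model, counts).distance)
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# reciprocal monophyly

@functools.lru_cache(maxsize=None)
def _ancestral_rm_prob(a: int, b: int) -> float:
    """P(reciprocal monophyly) for a pure-ancestry lineages of one sample and
    b of the other entering a single panmictic population.

    First-join recursion: any cross join before both samples have fully
    coalesced breaks monophyly, except the final root join.
    """
    if a < 1 or b < 1:
        raise ValueError("lineage counts must be >= 1")
    if a == 1 and b == 1:
        return 1.0
    pairs = (a + b) * (a + b - 1) / 2.0
    p = 0.0
    if a >= 2:
        p += (a * (a - 1) / 2.0) * _ancestral_rm_prob(a - 1, b)
    if b >= 2:
        p += (b * (b - 1) / 2.0) * _ancestral_rm_prob(a, b - 1)
    return p / pairs


def _surviving_lineages(n: int, tau: float, rng: np.random.Generator, reps: int) -> np.ndarray:
    """Number of ancestral lineages of an n-sample after tau (units of Ne)."""
    survivors = np.full(reps, n, dtype=np.int64)
    if n < 2 or tau <= 0:
        return survivors
    elapsed = np.zeros(reps)
    for k in range(n, 1, -1):
        rate = k * (k - 1) / 2.0
        elapsed += rng.exponential(1.0 / rate, size=reps)
        survivors[elapsed <= tau] = k - 1
    return survivors


def reciprocal_monophyly_prob(
    n1: int,
    n2: int,
    tau: float,
    mode: str = "mc",
    mc_reps: int = 100_000,
    seed: int | None = None,
    with_se: bool = False,
):
    """Probability that samples of n1 and n2 sequences from two populations
    separated tau*Ne generations ago are reciprocally monophyletic.

    ``mode="mc"`` simulates the two-population coalescent (pairwise
    coalescence rate 1/Ne within each population, standard Kingman in the
    ancestor): the isolation phase is simulated, the ancestral phase is
    integrated exactly given the surviving lineage counts.  ``mode="closed"``
    is the closed form, available for n1 <= 2 and n2 <= 2.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if mode == "closed":
        if n1 > 2 or n2 > 2:
            raise ValueError("closed form available only for n1 <= 2 and n2 <= 2; use mode='mc'")
        p1 = 1.0 - math.exp(-tau) if n1 == 2 else 1.0
        p2 = 1.0 - math.exp(-tau) if n2 == 2 else 1.0
        # condition on whether each pair has coalesced before the split
        p = (
            p1 * p2
            + p1 * (1 - p2) * _ancestral_rm_prob(1, 2)
            + (1 - p1) * p2 * _ancestral_rm_prob(2, 1)
            + (1 - p1) * (1 - p2) * _ancestral_rm_prob(2, 2)
        )
        return (p, 0.0) if with_se else p
    if mode != "mc":
        raise ValueError(f"unknown mode {mode!r}")
    if mc_reps < 1:
        raise ValueError("mc_reps must be >= 1")
    rng = np.random.default_rng(seed)
    s1 = _surviving_lineages(n1, tau, rng, mc_reps)
    s2 = _surviving_lineages(n2, tau, rng, mc_reps)
    table = np.array([[_ancestral_rm_prob(a, b) for b in range(1, n2 + 1)] for a in range(1, n1 + 1)])
    values = table[s1 - 1, s2 - 1]
    p = float(values.mean())
    if with_se:
        se = float(values.std(ddof=1) / math.sqrt(mc_reps)) if mc_reps > 1 else float("nan")
        return p, se
    return p


# ---------------------------------------------------------------------------
# pair selection and the test itself

def _sister_leafset(node: dendropy.Node, tree: dendropy.Tree) -> frozenset | None:
    parent = node.parent_node
    if parent is None:
        return None
    sibs = [c for c in parent.child_nodes() if c is not node]
    if not sibs:
        return None
    out: set[str] = set()
    for sib in sibs:
        out |= {leaf.taxon.label for leaf in sib.leaf_iter()}
    return frozenset(out)


def select_comparison_pairs(
    tree: dendropy.Tree,
    clades: Sequence[Clade],
    aln: Alignment,
    model: SubstitutionModel,
) -> list[tuple[Clade, Clade, bool]]:
    """Pair each well-supported clade with its sister, or with the closest
    (lowest-K) supported non-nested clade when the sister is unsupported.

    Selection descends the tree hierarchically: within each scope (first the
    whole tree, then each maximal clade in turn) only the *maximal*
    well-supported clades are paired, so nested clades are compared at their
    own level exactly once, never against clades that contain them.
    Singleton tips count as trivially supported candidate partners, so pairs
    with n2 = 1 arise naturally.  Each unordered pair is reported once.
    """
    all_labels = frozenset(leaf_labels(tree))
    supported: dict[frozenset, Clade] = {}
    for clade in clades:
        if clade.labels != all_labels:
            supported.setdefault(clade.labels, clade)
    singles: dict[frozenset, Clade] = {
        frozenset([leaf.taxon.label]): Clade(frozenset([leaf.taxon.label]), 1.0, leaf)
        for leaf in tree.leaf_node_iter()
    }
    pairs: dict[frozenset, tuple[Clade, Clade, bool]] = {}
    k_cache: dict[frozenset, float] = {}

    def k_between(a: Clade, b: Clade) -> float:
        key = frozenset([a.labels, b.labels])
        if key not in k_cache:
            k_cache[key] = between_clade_K(aln, a, b, model)
        return k_cache[key]

    def emit(a: Clade, b: Clade, is_sister: bool) -> None:
        pair_key = frozenset([a.labels, b.labels])
        if len(pair_key) == 2:
            pairs.setdefault(pair_key, (a, b, is_sister))

    def recurse(scope: frozenset) -> None:
        inside = [c for key, c in supported.items() if key < scope]
        maximal = [
            c
            for c in inside
            if not any(c.labels < other.labels for other in inside)
        ]
        covered = frozenset().union(*(c.labels for c in maximal)) if maximal else frozenset()
        loose_tips = [singles[frozenset([lab])] for lab in sorted(scope - covered)]
        for clade in maximal:
            sister = _sister_leafset(clade.node, tree) if clade.node is not None else None
            partner = None
            is_sister = False
            if sister is not None and (sister in supported or sister in singles):
                partner = supported.get(sister) or singles.get(sister)
                is_sister = True
            else:
                # lowest-K maximal (hence non-nested) partner within the scope
                others = [c for c in maximal if c is not clade] + loose_tips
                if others:
                    partner = min(
                        others, key=lambda c: (k_between(clade, c), sorted(c.labels))
                    )
            if partner is not None:
                emit(clade, partner, is_sister)
        for clade in maximal:
            recurse(clade.labels)

    recurse(all_labels)
    return list(pairs.values())


@dataclass
class KThetaConfig:
    """Tunables of the four-step procedure."""

    support_threshold: float = 0.90
    ratio_threshold: float = 4.0
    p_threshold: float = 0.95
    theta_rule: str = "larger"  # "larger" | "smaller_on_n2"
    flag_margin: float = 0.05
    mc_reps: int = 100_000
    bootstrap_replicates: int = 1000
    bootstrap_method: str = "p"
    distance_method: str = "model"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.support_threshold <= 1.0:
            raise ValueError("support_threshold must be in [0, 1]")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.theta_rule not in ("larger", "smaller_on_n2"):
            raise ValueError(f"unknown theta_rule {self.theta_rule!r}")


@dataclass
class KThetaResult:
    """Outcome of one K/theta test (one row of the report)."""

    clade_a: CladeDiversity
    clade_b: CladeDiversity
    K: float
    theta_used: float
    theta_source: str
    ratio: float
    n1: int
    n2: int
    p_2clades: float | None
    is_sister: bool
    decision: str
    flags: tuple[str, ...] = ()


def _select_theta(
    div_a: CladeDiversity, div_b: CladeDiversity, rule: str
) -> tuple[float, str, CladeDiversity, CladeDiversity]:
    """theta to divide K by; returns (theta, provenance, larger-n-first order)."""
    # report the larger sample first, matching the n1, n2 convention
    first, second = (div_a, div_b) if div_a.n >= div_b.n else (div_b, div_a)
    if first.theta is None and second.theta is None:
        raise ValueError("theta undefined on both sides (both clades have n = 1)")
    if second.theta is None:
        return first.theta, f"only defined theta (other clade has n=1)", first, second
    if first.theta is None:
        return second.theta, f"only defined theta (other clade has n=1)", first, second
    larger, smaller = (first, second) if first.theta >= second.theta else (second, first)
    if rule == "smaller_on_n2" and larger.n == 2:
        # theta = 2d at n=2 is likely an over-correction: use the other clade
        return smaller.theta, "smaller theta (larger-theta clade has n=2)", first, second
    return larger.theta, "larger theta (conservative)", first, second


def ktheta_test(
    aln: Alignment,
    tree: dendropy.Tree,
    pair: tuple[Clade, Clade, bool],
    model: SubstitutionModel,
    config: KThetaConfig | None = None,
) -> KThetaResult:
    """Steps 2-4 for one clade pair: diversities, K, ratio, monophyly, call."""
    config = config or KThetaConfig()
    clade_a, clade_b, is_sister = pair
    div_a = clade_diversity(aln, clade_a)
    div_b = clade_diversity(aln, clade_b)
    K = between_clade_K(aln, clade_a, clade_b, model)
    theta_used, theta_source, first, second = _select_theta(div_a, div_b, config.theta_rule)
    ratio = K / theta_used
    # time convention: K = 2*mu*t and theta = 2*Ne*mu give t/Ne = K/theta,
    # so the rate-1/Ne monophyly model is entered at tau = ratio; published
    # lookup-table p values may differ (see docs/methods.md).
    tau = ratio
    if first.n <= 2 and second.n <= 2:
        p = reciprocal_monophyly_prob(first.n, second.n, tau, mode="closed")
    else:
        p = reciprocal_monophyly_prob(
            first.n, second.n, tau, mode="mc", mc_reps=config.mc_reps, seed=config.seed
        )
    ratio_ok = ratio >= config.ratio_threshold
    p_ok = p >= config.p_threshold
    flags = []
    if ratio_ok and p_ok:
        decision = "species"
    elif ratio_ok and p >= config.p_threshold * (1.0 - config.flag_margin):
        # the ratio criterion is hard; a narrow miss on the monophyly
        # probability is flagged rather than silently rejected
        decision = "flagged"
        flags.append(f"monophyly probability {p:.3f} narrowly below {config.p_threshold}")
    else:
        decision = "not-species"
    logger.debug(
        "ktheta pair %s | %s: K=%g theta=%g (%s) ratio=%g n=(%d,%d) p=%g -> %s",
        sorted(first.clade.labels), sorted(second.clade.labels),
        K, theta_used, theta_source, ratio, first.n, second.n, p, decision,
    )
    return KThetaResult(
        clade_a=first,
        clade_b=second,
        K=K,
        theta_used=theta_used,
        theta_source=theta_source,
        ratio=ratio,
        n1=first.n,
        n2=second.n,
        p_2clades=p,
        is_sister=is_sister,
        decision=decision,
        flags=tuple(flags),
    )


@dataclass
class KThetaReport:
    """Full K/theta run: tree, supported clades and per-pair results."""

    results: list[KThetaResult]
    tree: dendropy.Tree
    clades: list[Clade]
    config: KThetaConfig = field(default_factory=KThetaConfig)

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "clade_a": "+".join(sorted(r.clade_a.clade.labels)),
                    "clade_b": "+".join(sorted(r.clade_b.clade.labels)),
                    "K": r.K,
                    "theta": r.theta_used,
                    "K/theta": round(r.ratio, 2),
                    "n1": r.n1,
                    "n2": r.n2,
                    "p_2clades": r.p_2clades,
                    "is_sister": r.is_sister,
                    "decision": r.decision,
                    "flags": ";".join(r.flags),
                }
            )
        return pd.DataFrame(rows)

    @property
    def n_species_pairs(self) -> int:
        return sum(1 for r in self.results if r.decision == "species")


def run_ktheta(
    aln: Alignment,
    model: SubstitutionModel,
    config: KThetaConfig | None = None,
) -> KThetaReport:
    """The full four-step K/theta procedure on an alignment.

    Deterministic under a fixed config seed (bootstrap and Monte Carlo seeds
    derive from it).
    """
    config = config or KThetaConfig()
    if aln.n < 4:
        raise ValueError("need at least 4 sequences for the K/theta procedure")
    dm = distance_matrix(aln, config.distance_method, model)
    nj = neighbor_joining(dm)
    rooted = midpoint_root(nj)
    bootstrap_support(
        aln,
        config.bootstrap_method,
        model,
        config.bootstrap_replicates,
        config.seed,
        rooted,
    )
    clades = [
        c
        for c in well_supported_clades(rooted, threshold=config.support_threshold)
    ]
    if not clades:
        warnings.warn("no clades reach the bootstrap support threshold; empty K/theta report")
        return KThetaReport([], rooted, [], config)
    pairs = select_comparison_pairs(rooted, clades, aln, model)
    results = []
    for pair in pairs:
        try:
            results.append(ktheta_test(aln, rooted, pair, model, config))
        except ValueError as exc:  # e.g. both clades singletons
            logger.info("skipping pair %s: %s", pair, exc)
    return KThetaReport(results, rooted, clades, config)
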