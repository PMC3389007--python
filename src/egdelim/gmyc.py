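"""Generalized mixed Yule-coalescent (GMYC) species delimitation.

On an ultrametric tree, branching events older than a threshold age T are
modelled as inter-species diversification and events younger than T as
intra-species coalescence.  Reading waiting intervals from the root towards
the tips, interval i of duration ``x_i`` carries the combined hazard

    b_i = lambda_spec * k_i**p_spec
        + lambda_coal * sum_j (m_ij * (m_ij - 1))**p_coal

where ``k_i`` counts species-level lineages (lineages whose subtending edge
descends from a diversification node) and ``m_ij`` counts the lineages inside
within-species cluster j.  The log-likelihood is
``sum_i [ln b_i - b_i * x_i]``; the null model treats the whole tree as a
single process with hazard ``lambda * (n_i * (n_i - 1))**p``.  The scaling
exponents make both the Yule and coalescent processes special cases and
absorb departures from either.

The single-threshold fit profiles the likelihood over candidate thresholds
(one per inter-node age gap, plus an "everything coalescent" boundary
candidate that yields the one-species solution); the multiple-threshold fit
greedily moves per-lineage transitions node by node from the single-threshold
optimum.  Species = within-species clusters plus singleton lineages crossing
the threshold; the confidence set collects the species counts of all
candidate solutions within 2 log-likelihood units of the maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .io_formats import Alignment, collapse_haplotypes
from .phylo_trees import leaf_labels, node_ages, upgma
from .subst_models import SubstitutionModel, distance_matrix

__all__ = [
    "GMYCFit",
    "GMYCConfig",
    "GMYCReport",
    "LRTestResult",
    "gmyc_loglik",
    "null_loglik",
    "fit_null",
    "fit_gmyc_single",
    "fit_gmyc_multiple",
    "lr_test",
    "lr_test_from_statistic",
    "compare_thresholds",
    "run_gmyc",
]

logger = logging.getLogger(__name__)

_P_BOUNDS = (0.01, 10.0)
_LOG_LAMBDA_BOUNDS = (-15.0, 10.0)
_OPT_TOL = 1e-8


# ---------------------------------------------------------------------------
# interval bookkeeping

class _IntervalData:
    """Waiting intervals of an ultrametric tree, root-to-present.

    Interval i spans the time slice ending (at its older edge) with internal
    node ``events[i]``; ``active[i]`` lists the lineages (identified by the
    node below each crossing edge) present during the interval.
    """

    def __init__(self, tree: dendropy.Tree):
        if len(tree.leaf_nodes()) < 2:
            raise ValueError("need at least 2 tips")
        if not tree.is_rooted:
            raise ValueError("GMYC requires a rooted ultrametric tree")
        self.tree = tree
        self.ages = node_ages(tree, require_ultrametric=True)
        post_index = {nd: i for i, nd in enumerate(tree.postorder_node_iter())}
        internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        # ascending age; postorder breaks ties so children precede parents
        internal.sort(key=lambda nd: (self.ages[nd], post_index[nd]))
        self.events: list[dendropy.Node] = []
        self.active: list[tuple[dendropy.Node, ...]] = []
        x = []
        n = []
        current = set(tree.leaf_node_iter())
        prev_age = 0.0
        for u in internal:
            self.events.append(u)
            self.active.append(tuple(current))
            x.append(self.ages[u] - prev_age)
            n.append(len(current))
            for child in u.child_nodes():
                current.discard(child)
            current.add(u)
            prev_age = self.ages[u]
        self.x = np.maximum(np.array(x), 0.0)
        self.n = np.array(n, dtype=float)
        self.height = self.ages[tree.seed_node]
        self.internal = internal
        self.n_tips = len(tree.leaf_nodes())

    def classification_from_threshold(self, threshold: float) -> frozenset:
        """Coalescent nodes for a single global threshold age."""
        return frozenset(u for u in self.internal if self.ages[u] < threshold)

    def classification_stats(self, coal: frozenset):
        """Per-interval species-lineage counts and cluster m(m-1) terms."""
        top: dict[dendropy.Node, dendropy.Node] = {}
        for u in self.tree.preorder_node_iter():
            if u.is_leaf() or u not in coal:
                continue
            parent = u.parent_node
            top[u] = top[parent] if (parent is not None and parent in coal) else u
        M = len(self.events)
        k = np.zeros(M)
        mm: list[float] = []
        idx: list[int] = []
        for i, lineages in enumerate(self.active):
            counts: dict[dendropy.Node, int] = {}
            species = 0
            for v in lineages:
                parent = v.parent_node
                if parent in coal:
                    root = top[parent]
                    counts[root] = counts.get(root, 0) + 1
                else:
                    species += 1
            k[i] = species
            for m in counts.values():
                if m >= 2:
                    mm.append(m * (m - 1))
                    idx.append(i)
        return k, np.array(mm, dtype=float), np.array(idx, dtype=int)

    def species_partition(self, coal: frozenset) -> list[frozenset]:
        """Tip-label sets of the species implied by a classification."""
        out = []
        for u in self.internal:
            if u in coal and (u.parent_node is None or u.parent_node not in coal):
                out.append(frozenset(leaf.taxon.label for leaf in u.leaf_iter()))
        for leaf in self.tree.leaf_node_iter():
            if leaf.parent_node not in coal:
                out.append(frozenset([leaf.taxon.label]))
        return out


def _classification_loglik(
    idata: _IntervalData,
    stats,
    lambda_spec: float,
    p_spec: float,
    lambda_coal: float,
    p_coal: float,
) -> float:
    k, mm, idx = stats
    M = len(idata.x)
    b = lambda_spec * np.power(k, p_spec, where=k > 0, out=np.zeros_like(k))
    if len(mm):
        b = b + lambda_coal * np.bincount(idx, weights=mm**p_coal, minlength=M)
    if np.any(b <= 0.0):
        return -np.inf
    return float(np.sum(np.log(b)) - np.sum(b * idata.x))


def gmyc_loglik(
    tree: dendropy.Tree,
    thresholds: Sequence[float] | float,
    lambda_spec: float,
    p_spec: float,
    lambda_coal: float,
    p_coal: float,
    classification: Iterable[dendropy.Node] | None = None,
) -> float:
    """GMYC log-likelihood at fixed parameters.

    ``thresholds`` is a single global threshold age (a scalar or length-1
    list); a value at or above the root age classifies every node as
    coalescent (the one-species solution).  Lineage-specific multi-threshold
    classifications are passed as an explicit node set via
    ``classification``.  An interval whose hazard is zero yields ``-inf``.
    """
    if lambda_spec <= 0 or lambda_coal <= 0 or p_spec <= 0 or p_coal <= 0:
        raise ValueError("rates and exponents must be positive")
    idata = _IntervalData(tree)
    if classification is not None:
        coal = frozenset(classification)
    else:
        if np.ndim(thresholds) == 0:
            thresholds = [float(thresholds)]
        if len(thresholds) != 1:
            raise ValueError(
                "a bare list of several threshold ages does not identify which "
                "lineage each applies to; pass classification= instead"
            )
        T = float(thresholds[0])
        if T <= 0:
            raise ValueError("threshold must be positive")
        coal = idata.classification_from_threshold(
            T if T < idata.height else np.nextafter(idata.height, np.inf)
        )
        if T >= idata.height:
            coal = frozenset(idata.internal)
    stats = idata.classification_stats(coal)
    return _classification_loglik(idata, stats, lambda_spec, p_spec, lambda_coal, p_coal)


def null_loglik(tree: dendropy.Tree, lam: float, p: float) -> float:
    """Single-process null: hazard lambda * (n_i (n_i - 1))**p on every interval."""
    if lam <= 0 or p <= 0:
        raise ValueError("rate and exponent must be positive")
    idata = _IntervalData(tree)
    b = lam * (idata.n * (idata.n - 1.0)) ** p
    if np.any(b <= 0.0):
        return -np.inf
    return float(np.sum(np.log(b)) - np.sum(b * idata.x))


# ---------------------------------------------------------------------------
# fitting

def _fit_null_from_idata(idata: _IntervalData) -> tuple[float, float, float]:
    nn = idata.n * (idata.n - 1.0)

    def neg(params):
        loglam, p = params
        b = 10.0**loglam * nn**p
        return -(np.sum(np.log(b)) - np.sum(b * idata.x))

    total = float(np.sum(nn * idata.x))
    lam0 = len(idata.x) / max(total, 1e-300)
    best = None
    for p0 in (1.0, 0.5, 2.0):
        res = minimize(
            neg,
            x0=[np.log10(lam0), p0],
            method="Nelder-Mead",
            bounds=[_LOG_LAMBDA_BOUNDS, _P_BOUNDS],
            options={"xatol": _OPT_TOL, "fatol": _OPT_TOL, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return -float(best.fun), 10.0 ** best.x[0], float(best.x[1])


def fit_null(tree: dendropy.Tree) -> tuple[float, float, float]:
    """Maximise the null likelihood; returns (loglik, lambda, p)."""
    return _fit_null_from_idata(_IntervalData(tree))


def _optimize_classification(idata, stats, starts) -> tuple[float, np.ndarray]:
    """Maximise over (lambda_spec, p_spec, lambda_coal, p_coal)."""

    def neg(params):
        loglam1, p1, loglam2, p2 = params
        ll = _classification_loglik(idata, stats, 10.0**loglam1, p1, 10.0**loglam2, p2)
        return np.inf if not np.isfinite(ll) else -ll

    bounds = [_LOG_LAMBDA_BOUNDS, _P_BOUNDS, _LOG_LAMBDA_BOUNDS, _P_BOUNDS]
    best = None
    for x0 in starts:
        res = minimize(
            neg,
            x0=np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": _OPT_TOL, "fatol": _OPT_TOL, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return -float(best.fun), best.x


def _default_starts(idata: _IntervalData, stats) -> list[np.ndarray]:
    k, mm, idx = stats
    spec_time = float(np.sum(k * idata.x))
    coal_time = float(np.sum(np.bincount(idx, weights=mm, minlength=len(idata.x)) * idata.x))
    n_events = len(idata.x)
    l1 = np.log10(max(n_events / max(spec_time, 1e-12), 1e-12))
    l2 = np.log10(max(n_events / max(coal_time, 1e-12), 1e-12))
    return [
        np.array([l1, 1.0, l2, 1.0]),
        np.array([l1, 0.5, l2, 0.5]),
        np.array([l1, 2.0, l2, 2.0]),
    ]


@dataclass
class GMYCFit:
    """A fitted GMYC model (single or multiple threshold)."""

    tree: dendropy.Tree
    method: str
    ll_null: float
    ll_gmyc: float
    lambda_spec: float
    p_spec: float
    lambda_coal: float
    p_coal: float
    thresholds: tuple[float, ...]
    n_species: int
    ci_species: tuple[int, int]
    intervals: np.ndarray
    classification: frozenset
    species: list[frozenset]
    profile: list[tuple[float, int]] = field(default_factory=list, repr=False)

    @property
    def lr_statistic(self) -> float:
        return max(2.0 * (self.ll_gmyc - self.ll_null), 0.0)


def _candidate_thresholds(idata: _IntervalData) -> list[float]:
    ages = sorted({idata.ages[u] for u in idata.internal}, reverse=True)
    cands = [ages[0] * (1.0 + 1e-9)]  # everything coalescent: one species
    for hi, lo in zip(ages, ages[1:]):
        cands.append((hi + lo) / 2.0)
    if ages[-1] > 0:
        cands.append(ages[-1] / 2.0)  # everything diversification: n species
    return cands


def fit_gmyc_single(tree: dendropy.Tree, ll_null: float | None = None) -> GMYCFit:
    """Profile the GMYC likelihood over all single-threshold candidates.

    Candidates sit at midpoints between consecutive distinct node ages (the
    likelihood is piecewise constant in T between node ages), plus the
    just-above-tips and at-root boundary solutions.  Ties prefer fewer
    species.  The confidence set spans the species counts of all candidates
    within 2 log-likelihood units of the optimum.
    """
    idata = _IntervalData(tree)
    if idata.n_tips < 3:
        raise ValueError("need at least 3 tips to fit the GMYC model")
    if ll_null is None:
        ll_null, _, _ = _fit_null_from_idata(idata)
    best = None
    profile: list[tuple[float, int, float]] = []  # (ll, n_species, T)
    for T in _candidate_thresholds(idata):
        coal = idata.classification_from_threshold(T)
        stats = idata.classification_stats(coal)
        ll, params = _optimize_classification(idata, stats, _default_starts(idata, stats))
        n_species = len(idata.species_partition(coal))
        profile.append((ll, n_species, T))
        if best is None or ll > best[0] + 1e-12:
            best = (ll, params, T, coal, n_species)
    ll, params, T, coal, n_species = best
    if not np.isfinite(ll):
        raise RuntimeError("GMYC single-threshold optimisation failed to converge")
    within = [ns for l, ns, _ in profile if l >= ll - 2.0]
    return GMYCFit(
        tree=tree,
        method="single",
        ll_null=ll_null,
        ll_gmyc=ll,
        lambda_spec=10.0 ** params[0],
        p_spec=float(params[1]),
        lambda_coal=10.0 ** params[2],
        p_coal=float(params[3]),
        thresholds=(T,),
        n_species=n_species,
        ci_species=(min(within), max(within)),
        intervals=idata.x,
        classification=coal,
        species=idata.species_partition(coal),
        profile=[(l, ns) for l, ns, _ in profile],
    )


def _feasible_moves(idata: _IntervalData, coal: frozenset):
    """Monotone single-node toggles: grow or shrink coalescent subtrees."""
    for u in idata.internal:
        if u in coal:
            parent = u.parent_node
            if parent is None or parent not in coal:
                yield u  # cluster root -> diversification (transition tipward)
        else:
            if all(c.is_leaf() or c in coal for c in u.child_nodes()):
                yield u  # boundary node -> coalescent (transition rootward)


def _multiple_thresholds(idata: _IntervalData, coal: frozenset) -> tuple[float, ...]:
    """One transition age per cluster stem (midpoint of the stem edge)."""
    ages = []
    for u in idata.internal:
        if u in coal and (u.parent_node is None or u.parent_node not in coal):
            top = idata.ages[u.parent_node] if u.parent_node is not None else idata.ages[u]
            ages.append((idata.ages[u] + top) / 2.0)
    return tuple(sorted(ages, reverse=True))


def fit_gmyc_multiple(tree: dendropy.Tree, single: GMYCFit | None = None) -> GMYCFit:
    """Greedy multiple-threshold refinement from the single-threshold optimum.

    Repeatedly proposes moving one local transition a node rootward or
    tipward, re-optimising the four parameters for each proposal, and accepts
    the best move while it improves the log-likelihood by more than 1e-6.
    Ties are broken toward fewer thresholds (fewer clusters).
    """
    if single is None:
        single = fit_gmyc_single(tree)
    idata = _IntervalData(tree)
    coal = single.classification
    stats = idata.classification_stats(coal)
    warm = np.array(
        [np.log10(single.lambda_spec), single.p_spec, np.log10(single.lambda_coal), single.p_coal]
    )
    ll, params = _optimize_classification(idata, stats, [warm] + _default_starts(idata, stats))
    evaluated: list[tuple[float, int]] = list(single.profile)
    evaluated.append((ll, len(idata.species_partition(coal))))
    for _ in range(2 * len(idata.internal)):
        best_move = None
        for u in _feasible_moves(idata, coal):
            coal_new = coal ^ {u}
            stats_new = idata.classification_stats(coal_new)
            ll_new, params_new = _optimize_classification(idata, stats_new, [params])
            n_clusters = sum(
                1
                for v in idata.internal
                if v in coal_new and (v.parent_node is None or v.parent_node not in coal_new)
            )
            evaluated.append((ll_new, len(idata.species_partition(coal_new))))
            cand = (ll_new, -n_clusters, coal_new, params_new)
            if best_move is None or cand[:2] > best_move[:2]:
                best_move = cand
        if best_move is None or best_move[0] <= ll + 1e-6:
            break
        ll, _, coal, params = best_move
    # final polish with standard restarts
    stats = idata.classification_stats(coal)
    ll, params = _optimize_classification(idata, stats, [params] + _default_starts(idata, stats))
    if ll < single.ll_gmyc:  # greedy must not end below its start
        ll, params, coal = single.ll_gmyc, warm, single.classification
    n_species = len(idata.species_partition(coal))
    within = [ns for l, ns in evaluated if l >= ll - 2.0]
    return GMYCFit(
        tree=tree,
        method="multiple",
        ll_null=single.ll_null,
        ll_gmyc=ll,
        lambda_spec=10.0 ** params[0],
        p_spec=float(params[1]),
        lambda_coal=10.0 ** params[2],
        p_coal=float(params[3]),
        thresholds=_multiple_thresholds(idata, coal),
        n_species=n_species,
        ci_species=(min(within), max(within)),
        intervals=idata.x,
        classification=coal,
        species=idata.species_partition(coal),
        profile=evaluated,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio tests

@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    p_value: float


def lr_test_from_statistic(statistic: float, df: int) -> LRTestResult:
    """Chi-square upper tail for an already-computed (-)2*dLL statistic."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    statistic = max(float(statistic), 0.0)
    return LRTestResult(statistic, df, float(chi2.sf(statistic, df)))


def lr_test(ll_constrained: float, ll_general: float, df: int) -> LRTestResult:
    """Likelihood-ratio test of a nested pair of fits."""
    if ll_general < ll_constrained - 1e-6:
        raise ValueError(
            f"general model log-likelihood {ll_general} below constrained {ll_constrained}"
        )
    return lr_test_from_statistic(2.0 * (ll_general - ll_constrained), df)


#: degrees of freedom of GMYC vs null (extra rate, exponent and threshold)
GMYC_NULL_DF = 3


def compare_thresholds(single: GMYCFit, multiple: GMYCFit) -> LRTestResult:
    """Single- vs multiple-threshold fit; df = (number of thresholds) - 1."""
    if set(leaf_labels(single.tree)) != set(leaf_labels(multiple.tree)):
        raise ValueError("fits are not on the same tree")
    df = max(1, len(multiple.thresholds) - 1)
    statistic = max(2.0 * (multiple.ll_gmyc - single.ll_gmyc), 0.0)
    return lr_test_from_statistic(statistic, df)


# ---------------------------------------------------------------------------
# the 2x2 analysis grid

@dataclass
class GMYCConfig:
    model: SubstitutionModel | None = None
    outgroup: tuple[str, ...] = ()
    threshold_mode: str = "both"  # "single" | "multiple" | "both"
    include_pruned: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("single", "multiple", "both"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


@dataclass
class GMYCReport:
    fits: dict[tuple[str, str], GMYCFit]
    tests: dict[tuple[str, str], LRTestResult]
    comparisons: dict[str, LRTestResult]
    config: GMYCConfig

    def table(self) -> pd.DataFrame:
        datasets: dict[str, dict] = {}
        for (dataset, mode), fit in self.fits.items():
            row = datasets.setdefault(
                dataset, {"dataset": dataset, "n": len(leaf_labels(fit.tree)), "ll_null": fit.ll_null}
            )
            test = self.tests[(dataset, mode)]
            row[f"ll_gmyc_{mode}"] = fit.ll_gmyc
            row[f"n_species_{mode}"] = fit.n_species
            row[f"ci_{mode}"] = f"{fit.ci_species[0]}-{fit.ci_species[1]}"
            row[f"p_{mode}"] = test.p_value
        for dataset, cmp in self.comparisons.items():
            datasets[dataset]["p_single_vs_multiple"] = cmp.p_value
        return pd.DataFrame(list(datasets.values()))


def _tree_from_alignment(aln: Alignment, model: SubstitutionModel) -> dendropy.Tree:
    dm = distance_matrix(aln, "model", model)
    return upgma(dm)


def run_gmyc(
    data: Alignment | dendropy.Tree,
    config: GMYCConfig | None = None,
) -> GMYCReport:
    """Complete/pruned x single/multiple GMYC analysis grid.

    From an alignment: outgroup taxa are dropped, an ultrametric tree is
    built by UPGMA on model-corrected distances, and the analysis is repeated
    on the haplotype-pruned alignment (unique sequences only).  From a user
    ultrametric tree: tree building is skipped and only the complete dataset
    is analysed.
    """
    config = config or GMYCConfig()
    datasets: dict[str, dendropy.Tree] = {}
    if isinstance(data, dendropy.Tree):
        tree = data
        if config.outgroup:
            tree = tree.clone(depth=1)
            taxa = [t for t in tree.taxon_namespace if t.label in set(config.outgroup)]
            tree.prune_taxa(taxa)
        datasets["complete"] = tree
    else:
        aln = data.drop(config.outgroup) if config.outgroup else data
        if config.model is None:
            raise ValueError("a SubstitutionModel is required to build trees from sequences")
        datasets["complete"] = _tree_from_alignment(aln, config.model)
        if config.include_pruned:
            pruned_aln, _ = collapse_haplotypes(aln)
            if pruned_aln.n >= 3:
                datasets["pruned"] = _tree_from_alignment(pruned_aln, config.model)
    modes = ("single", "multiple") if config.threshold_mode == "both" else (config.threshold_mode,)
    fits: dict[tuple[str, str], GMYCFit] = {}
    tests: dict[tuple[str, str], LRTestResult] = {}
    comparisons: dict[str, LRTestResult] = {}
    for name, tree in datasets.items():
        single = fit_gmyc_single(tree)
        if "single" in modes:
            fits[(name, "single")] = single
            tests[(name, "single")] = lr_test(single.ll_null, single.ll_gmyc, GMYC_NULL_DF)
        if "multiple" in modes:
            multiple = fit_gmyc_multiple(tree, single)
            fits[(name, "multiple")] = multiple
            tests[(name, "multiple")] = lr_test(multiple.ll_null, multiple.ll_gmyc, GMYC_NULL_DF)
            if "single" in modes:
                comparisons[name] = compare_thresholds(single, multiple)
    return GMYCReport(fits, tests, comparisons, config)
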