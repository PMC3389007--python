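"""GTR-family substitution models and pairwise distances.

The K/theta procedure needs two kinds of pairwise distance: the uncorrected
proportion of differing sites ("d", computed with pairwise deletion of gaps
and N) and a model-corrected distance ("K") that accounts for multiple hits
under a general time-reversible model with optional invariant sites (+I) and
discrete-gamma rate variation (+G).

The rate matrix Q is normalised so that one unit of branch length equals one
expected substitution per site at stationarity, averaged over the variable
fraction of sites: ``(1 - p_inv) * sum_i pi_i * (-Q_ii) = 1`` with the mean
discrete-gamma rate equal to 1.  Corrected distances are therefore directly
comparable with uncorrected proportions at low divergence.

Two presets ship with the package: ``coi_paper`` (TrN+I+G parameters fitted
to a darwinulid ostracod COI fragment, expressed in the GTR parameterisation)
and ``its2_paper`` (TPM2uf+G parameters for the corresponding ITS2 data).
"""

from __future__ import annotations

import functools
import importlib.resources
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .io_formats import Alignment

__all__ = [
    "SubstitutionModel",
    "DistanceMatrix",
    "discrete_gamma_rates",
    "p_distance",
    "ml_pairwise_distance",
    "ml_pairwise_distance_detail",
    "distance_matrix",
    "load_model_config",
    "get_preset",
    "encode_alignment",
    "p_distance_matrix",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: order of the six exchangeability parameters
EXCHANGE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean-of-quantile-slice discretisation of Gamma(shape, scale=1/shape).

    Returns ``k`` equal-weight category rates averaging exactly 1.  This is
    the usual "+G" discretisation with k categories.
    """
    if shape <= 0:
        raise ValueError(f"gamma shape must be positive, got {shape}")
    if k < 1:
        raise ValueError(f"need at least one category, got {k}")
    if k == 1:
        return np.ones(1)
    # slice boundaries at quantiles i/k; slice mean via the incomplete-gamma
    # identity E[X; X in slice] = F_{shape+1}(b) - F_{shape+1}(a) for mean-1 X
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=shape, scale=1.0 / shape)
    cdf_up = gamma_dist.cdf(bounds, a=shape + 1, scale=1.0 / shape)
    cdf = np.concatenate([[0.0], cdf_up, [1.0]])
    rates = k * np.diff(cdf)
    return rates / rates.mean()


class SubstitutionModel:
    """A GTR-family model: base frequencies, exchangeabilities, +I, +G."""

    def __init__(
        self,
        freqs,
        exchangeabilities,
        p_inv: float = 0.0,
        gamma_shape: float | None = None,
        n_categories: int = 4,
    ):
        freqs = np.asarray(freqs, dtype=float)
        exch = np.asarray(exchangeabilities, dtype=float)
        if freqs.shape != (4,):
            raise ValueError("freqs must be 4 values (A, C, G, T)")
        if exch.shape != (6,):
            raise ValueError("exchangeabilities must be 6 values (AC, AG, AT, CG, CT, GT)")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"freqs must sum to 1, got {freqs.sum()!r}")
        if np.any(freqs <= 0):
            raise ValueError("all base frequencies must be positive")
        if np.any(exch <= 0):
            raise ValueError("all exchangeabilities must be positive")
        if not 0.0 <= p_inv < 1.0:
            raise ValueError(f"p_inv must be in [0, 1), got {p_inv}")
        if gamma_shape is not None and gamma_shape <= 0:
            raise ValueError(f"gamma_shape must be positive, got {gamma_shape}")
        if n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        self.freqs = freqs
        self.exchangeabilities = exch
        self.p_inv = float(p_inv)
        self.gamma_shape = None if gamma_shape is None else float(gamma_shape)
        self.n_categories = 1 if gamma_shape is None else int(n_categories)
        self._build()

    def _build(self) -> None:
        pi = self.freqs
        S = np.zeros((4, 4))
        for rate, (i, j) in zip(self.exchangeabilities, _PAIRS):
            S[i, j] = S[j, i] = rate
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        norm = (1.0 - self.p_inv) * float(-(pi * np.diag(Q)).sum())
        Q /= norm
        self.Q = Q
        # reversible Q: symmetrise with pi^{1/2}, eigendecompose once
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec / sq[:, None]          # D^{-1/2} U
        self._right = eigvec.T * sq[None, :]       # U^T D^{1/2}
        if self.gamma_shape is None:
            self.category_rates = np.ones(1)
        else:
            self.category_rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for a single rate-1 category."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def category_matrices(self, t: float) -> np.ndarray:
        """Stacked P(t * r_c) over the discrete-gamma categories."""
        return np.stack([self.transition_matrix(t * r) for r in self.category_rates])

    def __repr__(self) -> str:  # pragma: no cover
        g = "none" if self.gamma_shape is None else f"{self.gamma_shape:g}x{self.n_categories}"
        return (
            f"SubstitutionModel(freqs={np.round(self.freqs, 4).tolist()}, "
            f"exch={np.round(self.exchangeabilities, 4).tolist()}, "
            f"p_inv={self.p_inv:g}, gamma={g})"
        )


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances in substitutions/site."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("\t".join(("",) + self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        """Read a labelled TSV matrix; PHYLIP square format is also accepted."""
        lines = [ln.rstrip("\n") for ln in Path(path).open() if ln.strip()]
        first = lines[0].split()
        if len(first) == 1 and first[0].isdigit():
            # PHYLIP square dialect: count line, then label + n values per row
            n = int(first[0])
            labels, rows = [], []
            for ln in lines[1 : n + 1]:
                parts = ln.split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
            return cls(tuple(labels), np.array(rows))
        header = lines[0].split("\t")[1:]
        labels, rows = [], []
        for ln in lines[1:]:
            parts = ln.split("\t")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if header != labels:
            raise ValueError("row and column labels disagree")
        return cls(tuple(labels), np.array(rows))


# ---------------------------------------------------------------------------
# distances

def encode_alignment(aln: Alignment) -> np.ndarray:
    """Encode as an (n, L) int8 matrix; A,C,G,T -> 0..3, gap/N -> -1."""
    lookup = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        lookup[ord(base)] = idx
    out = np.empty((aln.n, aln.length), dtype=np.int8)
    for row, (_, seq) in zip(out, aln.records):
        row[:] = lookup[np.frombuffer(seq.encode(), dtype=np.uint8)]
    return out


def _pair_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """4x4 site-pattern count matrix over comparable (both ungapped) sites."""
    ok = (x >= 0) & (y >= 0)
    counts = np.zeros((4, 4))
    np.add.at(counts, (x[ok], y[ok]), 1.0)
    return counts


def p_distance(aln: Alignment, i: str, j: str) -> float:
    """Uncorrected proportion of differing sites, pairwise deletion of gaps/N."""
    enc = encode_alignment(aln.subset([i, j]))
    order = [lab for lab in aln.labels if lab in (i, j)]
    x, y = enc[order.index(i)], enc[order.index(j)]
    ok = (x >= 0) & (y >= 0)
    total = int(ok.sum())
    if total == 0:
        raise ValueError(f"no comparable ungapped sites between {i!r} and {j!r}")
    return float((x[ok] != y[ok]).sum() / total)


def p_distance_matrix(encoded: np.ndarray) -> np.ndarray:
    """All-pairs p-distance from an encoded matrix (one-hot matmul trick)."""
    valid = encoded >= 0
    comparable = valid.astype(np.float64) @ valid.T.astype(np.float64)
    matches = np.zeros_like(comparable)
    for b in range(4):
        m = (encoded == b).astype(np.float64)
        matches += m @ m.T
    if np.any(comparable == 0):
        bad = np.argwhere((comparable == 0) & ~np.eye(len(encoded), dtype=bool))
        if len(bad):
            raise ValueError(f"no comparable sites for record pair {tuple(bad[0])}")
        comparable[comparable == 0] = 1.0  # single-record degenerate case
    d = (comparable - matches) / comparable
    np.fill_diagonal(d, 0.0)
    return d


class MLDistance(NamedTuple):
    distance: float
    saturated: bool
    loglik: float


def _ml_distance_from_counts(
    model: SubstitutionModel, counts: np.ndarray, t_max: float = 10.0, xatol: float = 1e-8
) -> MLDistance:
    total = counts.sum()
    if total == 0:
        raise ValueError("no comparable ungapped sites")
    if counts.sum() == np.trace(counts):
        return MLDistance(0.0, False, 0.0)
    pi = model.freqs
    w = (1.0 - model.p_inv) / len(model.category_rates)
    inv = model.p_inv * np.diag(pi)

    def neg_loglik(t: float) -> float:
        F = inv.copy()
        for r in model.category_rates:
            F += w * (pi[:, None] * model.transition_matrix(t * r))
        with np.errstate(divide="ignore"):
            logF = np.log(F)
        ll = float((counts * logF)[counts > 0].sum())
        return -ll

    res = minimize_scalar(
        neg_loglik, bounds=(1e-12, t_max), method="bounded", options={"xatol": xatol}
    )
    t_hat = float(res.x)
    saturated = t_hat > t_max - 1e-3 and neg_loglik(t_max) <= res.fun + 1e-9
    if saturated:
        t_hat = t_max
    return MLDistance(t_hat, saturated, -float(res.fun))


def ml_pairwise_distance_detail(
    model: SubstitutionModel, aln: Alignment, i: str, j: str, t_max: float = 10.0
) -> MLDistance:
    """ML distance plus saturation flag and attained log-likelihood."""
    sub = aln.subset([i, j])
    enc = encode_alignment(sub)
    order = list(sub.labels)
    counts = _pair_counts(enc[order.index(i)], enc[order.index(j)])
    return _ml_distance_from_counts(model, counts, t_max=t_max)


def ml_pairwise_distance(
    model: SubstitutionModel, aln: Alignment, i: str, j: str, t_max: float = 10.0
) -> float:
    """Maximum-likelihood pairwise distance under *model*.

    Maximises the two-sequence likelihood over t in [0, t_max] (tolerance
    1e-8).  Identical sequences give 0; a maximum at the upper bound returns
    the bound and emits a saturation warning.
    """
    res = ml_pairwise_distance_detail(model, aln, i, j, t_max=t_max)
    if res.saturated:
        warnings.warn(f"distance between {i!r} and {j!r} saturated at bound {t_max}")
    return res.distance


def distance_matrix(
    aln: Alignment, method: str = "p", model: SubstitutionModel | None = None
) -> DistanceMatrix:
    """All pairwise distances by the chosen method ("p" or "model")."""
    if aln.n < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    if method == "p":
        values = p_distance_matrix(encode_alignment(aln))
        return DistanceMatrix(aln.labels, values)
    if method == "model":
        if model is None:
            raise ValueError("method 'model' requires a SubstitutionModel")
        enc = encode_alignment(aln)
        n = aln.n
        values = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                counts = _pair_counts(enc[a], enc[b])
                values[a, b] = values[b, a] = _ml_distance_from_counts(model, counts).distance
        return DistanceMatrix(aln.labels, values)
    raise ValueError(f"unknown distance method {method!r}")


# ---------------------------------------------------------------------------
# presets

def _model_from_dict(cfg: dict) -> SubstitutionModel:
    shape = cfg.get("gamma_shape")
    if isinstance(shape, str) and shape.lower() == "none":
        shape = None
    freqs = np.asarray(cfg["freqs"], dtype=float)
    total = freqs.sum()
    if abs(total - 1.0) > 0.02:
        raise ValueError(f"base frequencies sum to {total:g}, expected ~1")
    # published frequency sets are rounded to 2 d.p. and may not sum to 1
    freqs = freqs / total
    return SubstitutionModel(
        freqs=freqs,
        exchangeabilities=cfg["rates"],
        p_inv=float(cfg.get("p_inv", 0.0)),
        gamma_shape=shape,
        n_categories=int(cfg.get("categories", 4)),
    )


def load_model_config(path: str | Path) -> SubstitutionModel:
    """Load a model from a YAML file with keys freqs, rates, p_inv, gamma_shape, categories."""
    with Path(path).open() as fh:
        return _model_from_dict(yaml.safe_load(fh))


@functools.lru_cache(maxsize=None)
def get_preset(name: str) -> SubstitutionModel:
    """Shipped presets: ``coi_paper`` (GTR+I+G) and ``its2_paper`` (GTR+G)."""
    resource = importlib.resources.files("egdelim").joinpath(f"presets/{name}.yaml")
    if not resource.is_file():
        raise KeyError(f"unknown model preset {name!r}")
    return _model_from_dict(yaml.safe_load(resource.read_text()))
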