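"""The Generative Tree Model and exact criterion values within it.

The model M(k, gamma) consists of a binary class label Y ~ Bern(1/2), k+1
"active" predictors X_i | Y ~ N(gamma^(i-1) Y, 1) (conditionally
independent given Y, with geometrically decaying class separation), and one
"child" predictor X1^(1) | X_1 ~ N(X_1, 1) that depends on Y only through
X_1.  The active predictors form the Markov blanket of Y; the child is
redundant once X_1 is known.

Every class-conditional law of a subset is Gaussian with mean y * mu and a
fixed covariance, so subsets are two-component Gaussian mixtures and all
criterion values (CMI, JMI, CIFE, mRMR) evaluate exactly through the
mixture-entropy function ``h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np

from .mixtures import (
    HALF_LOG_2PI_E,
    DomainError,
    MixtureSpec,
    QuadratureConfig,
    h,
    mi_with_label,
    subset_entropy_mi,
)

__all__ = [
    "GTMSpec",
    "VariableId",
    "SubsetDistribution",
    "CriterionValue",
    "CRITERIA",
    "subset_distribution",
    "mi_label_subset",
    "cmi",
    "jmi",
    "cife",
    "mrmr",
    "cmi_cife_gap",
    "score",
    "pair_mi",
    "pair_mi_given_label",
    "cmi_last_active_closed",
    "jmi_scores_closed",
    "cife_scores_closed",
]

_HALF_LOG_2 = 0.5 * math.log(2.0)


@dataclass(frozen=True)
class GTMSpec:
    """Parameters of the Generative Tree Model M(k, gamma).

    ``k`` sets the number of active predictors (k+1 of them); ``gamma`` in
    (0, 1] is the geometric decay of the class separations: smaller gamma
    means later actives carry less information about Y.
    """

    k: int
    gamma: float

    def __post_init__(self) -> None:
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise DomainError("k must be an integer >= 1")
        if not (0.0 < self.gamma <= 1.0):
            raise DomainError("gamma must lie in (0, 1]")

    @property
    def n_variables(self) -> int:
        return self.k + 2


@dataclass(frozen=True, order=True)
class VariableId:
    """A predictor in the tree model: active X_i or the child X1^(1).

    Ordering is actives by index then the child last; this is also the
    tie-breaking order of greedy selection.
    """

    _order: int
    kind: Literal["active", "child"]
    index: int

    @staticmethod
    def active(index: int) -> "VariableId":
        if index < 1:
            raise DomainError("active index must be >= 1")
        return VariableId(index, "active", index)

    @staticmethod
    def child() -> "VariableId":
        # the model has a single child variable, attached to X_1
        return VariableId(10**9, "child", 1)

    def __str__(self) -> str:
        return f"X{self.index}" if self.kind == "active" else "X1^(1)"


CHILD = VariableId.child()


def variables(spec: GTMSpec) -> list[VariableId]:
    """All k+2 predictors of the model, in canonical order."""
    return [VariableId.active(i) for i in range(1, spec.k + 2)] + [CHILD]


def _validate_subset(spec: GTMSpec, S: Sequence[VariableId]) -> tuple[VariableId, ...]:
    out = tuple(S)
    if len(set(out)) != len(out):
        raise DomainError("duplicate variables in subset")
    for v in out:
        if v.kind == "active" and not (1 <= v.index <= spec.k + 1):
            raise DomainError(f"active index {v.index} outside 1..{spec.k + 1}")
    return out


@dataclass(frozen=True)
class SubsetDistribution:
    """Class-conditional law of a subset: X_S | Y = y ~ N(y * mu, sigma)."""

    variables: tuple[VariableId, ...]
    mu: np.ndarray
    sigma: np.ndarray

    def to_mixture_spec(self) -> MixtureSpec:
        return MixtureSpec(self.mu, self.sigma)


def subset_distribution(spec: GTMSpec, S: Sequence[VariableId]) -> SubsetDistribution:
    """Mean-difference vector and covariance of a subset of predictors.

    Actives contribute mean gamma^(i-1) and unit variance; the child has
    mean 1 (it inherits X_1's full separation) and variance 2, with unit
    covariance with X_1.  All other pairs are conditionally independent
    given Y, hence uncorrelated within a class.
    """
    S = _validate_subset(spec, S)
    if not S:
        raise DomainError("subset must be nonempty")
    d = len(S)
    mu = np.empty(d)
    sigma = np.eye(d)
    for a, va in enumerate(S):
        if va.kind == "active":
            mu[a] = spec.gamma ** (va.index - 1)
        else:
            mu[a] = 1.0
            sigma[a, a] = 2.0
    for a, va in enumerate(S):
        for b in range(a + 1, d):
            vb = S[b]
            pair = {va.kind, vb.kind}
            if pair == {"active", "child"}:
                active = va if va.kind == "active" else vb
                if active.index == 1:
                    sigma[a, b] = sigma[b, a] = 1.0
    return SubsetDistribution(S, mu, sigma)


@dataclass(frozen=True)
class CriterionValue:
    """One evaluated criterion score, in nats."""

    criterion: str
    candidate: VariableId
    conditioning: tuple[VariableId, ...]
    value: float


@lru_cache(maxsize=None)
def _mi_label_cached(
    gamma: float, k: int, S: tuple[VariableId, ...], cfg: QuadratureConfig
) -> float:
    dist = subset_distribution(GTMSpec(k, gamma), S)
    return mi_with_label(dist.to_mixture_spec(), cfg)


def mi_label_subset(
    spec: GTMSpec, S: Sequence[VariableId], cfg: QuadratureConfig | None = None
) -> float:
    """I(X_S, Y): mutual information between a subset of predictors and the label.

    Cached per (gamma, subset) since greedy selection revisits shared
    subsets and the underlying quadrature dominates cost.
    """
    cfg = cfg or QuadratureConfig()
    key = tuple(sorted(_validate_subset(spec, S)))
    if not key:
        return 0.0
    return _mi_label_cached(spec.gamma, spec.k, key, cfg)


def _check_candidate(spec, j: VariableId, S: Sequence[VariableId]):
    S = _validate_subset(spec, S)
    if j in S:
        raise DomainError(f"candidate {j} already in the conditioning set")
    _validate_subset(spec, (j,))
    return S


def _clamp_zero(value: float, tol: float = 1e-9) -> float:
    return 0.0 if -tol < value < tol else value


def cmi(
    spec: GTMSpec,
    j: VariableId,
    S: Sequence[VariableId],
    cfg: QuadratureConfig | None = None,
) -> float:
    """Conditional mutual information I(X_j, Y | X_S).

    Computed as the chain-rule increment I(X_{S+j}, Y) - I(X_S, Y); for an
    empty conditioning set this is the marginal MI.  Values within 1e-9 of
    zero are clamped to exactly zero (the child given X_1 is conditionally
    independent of Y, and quadrature noise should not mask that).
    """
    S = _check_candidate(spec, j, S)
    value = mi_label_subset(spec, S + (j,), cfg) - mi_label_subset(spec, S, cfg)
    return _clamp_zero(value)


def pair_mi(
    spec: GTMSpec,
    i: VariableId,
    j: VariableId,
    cfg: QuadratureConfig | None = None,
) -> float:
    """Unconditional mutual information I(X_i, X_j) between two predictors."""
    if i == j:
        raise DomainError("pair_mi requires two distinct variables")
    _validate_subset(spec, (i, j))
    specA = subset_distribution(spec, (i,)).to_mixture_spec()
    specB = subset_distribution(spec, (j,)).to_mixture_spec()
    specAB = subset_distribution(spec, (i, j)).to_mixture_spec()
    return subset_entropy_mi(specA, specB, specAB, cfg)


def pair_mi_given_label(spec: GTMSpec, i: VariableId, j: VariableId) -> float:
    """Class-conditional mutual information I(X_i, X_j | Y).

    Within a class every pair is independent except (X_1, X1^(1)), which is
    bivariate normal with correlation 1/sqrt(2), giving
    -1/2 log(1 - rho^2) = (1/2) log 2.
    """
    if i == j:
        raise DomainError("pair requires two distinct variables")
    _validate_subset(spec, (i, j))
    kinds = {i.kind, j.kind}
    if kinds == {"active", "child"}:
        active = i if i.kind == "active" else j
        if active.index == 1:
            return _HALF_LOG_2
    return 0.0


def jmi(
    spec: GTMSpec,
    j: VariableId,
    S: Sequence[VariableId],
    cfg: QuadratureConfig | None = None,
) -> float:
    """Joint Mutual Information criterion: average pairwise CMI.

    ``(1/|S|) sum_{i in S} I(X_j, Y | X_i)``; for an empty conditioning set
    the score is the marginal MI I(X_j, Y) (the average is undefined at
    |S| = 0 and the first greedy step ranks candidates by relevance alone).
    """
    S = _check_candidate(spec, j, S)
    if not S:
        return mi_label_subset(spec, (j,), cfg)
    return sum(cmi(spec, j, (i,), cfg) for i in S) / len(S)


def cife(
    spec: GTMSpec,
    j: VariableId,
    S: Sequence[VariableId],
    cfg: QuadratureConfig | None = None,
) -> float:
    """Conditional Infomax Feature Extraction score.

    ``I(X_j, Y) + sum_{i in S} [I(X_i, X_j | Y) - I(X_i, X_j)]`` — marginal
    relevance plus the full (unweighted) sum of three-way interaction
    informations.  May be negative when redundancy dominates.
    """
    S = _check_candidate(spec, j, S)
    value = mi_label_subset(spec, (j,), cfg)
    for i in S:
        value += pair_mi_given_label(spec, i, j) - pair_mi(spec, i, j, cfg)
    return _clamp_zero(value)


def mrmr(
    spec: GTMSpec,
    j: VariableId,
    S: Sequence[VariableId],
    cfg: QuadratureConfig | None = None,
) -> float:
    """Minimal-redundancy maximal-relevance score.

    ``I(X_j, Y) - (1/|S|) sum_{i in S} I(X_j, X_i)``: JMI with the
    class-conditional redundancy terms omitted.
    """
    S = _check_candidate(spec, j, S)
    value = mi_label_subset(spec, (j,), cfg)
    if S:
        value -= sum(pair_mi(spec, i, j, cfg) for i in S) / len(S)
    return _clamp_zero(value)


def cmi_cife_gap(
    spec: GTMSpec,
    j: VariableId,
    S: Sequence[VariableId],
    cfg: QuadratureConfig | None = None,
) -> float:
    """CMI minus CIFE for the same candidate and conditioning set.

    Quantifies the error of the second-order truncation; for the child
    candidate against S = {X_1, X_2} it equals I(X1^(1), X_2) exactly.
    """
    return cmi(spec, j, S, cfg) - cife(spec, j, S, cfg)


CRITERIA = {"cmi": cmi, "jmi": jmi, "cife": cife, "mrmr": mrmr}


def score(
    spec: GTMSpec,
    criterion: str,
    j: VariableId,
    S: Sequence[VariableId],
    cfg: QuadratureConfig | None = None,
) -> CriterionValue:
    """Evaluate a named criterion, returning a CriterionValue record."""
    if criterion not in CRITERIA:
        raise DomainError(f"unknown criterion {criterion!r}; choose from {sorted(CRITERIA)}")
    value = CRITERIA[criterion](spec, j, S, cfg)
    return CriterionValue(criterion, j, tuple(S), value)


# ---------------------------------------------------------------------------
# Closed forms for the two candidates of interest with S = {X_1, ..., X_k}.
# These re-derive, through the pairwise mixture MIs, the per-candidate
# expressions used in the model analysis; tests check them against the
# generic subset computations above.
# ---------------------------------------------------------------------------


def cmi_last_active_closed(spec: GTMSpec, cfg: QuadratureConfig | None = None) -> float:
    """I(X_{k+1}, Y | X_1..X_k) = h(sqrt(sum_{i=0}^k g^{2i})) - h(sqrt(sum_{i=0}^{k-1} g^{2i}))."""
    g2 = spec.gamma**2
    s_k = sum(g2**i for i in range(spec.k + 1))
    s_km1 = s_k - g2**spec.k
    return h(math.sqrt(s_k), cfg) - h(math.sqrt(s_km1), cfg)


def jmi_scores_closed(
    k: int, gamma: float, cfg: QuadratureConfig | None = None
) -> tuple[float, float]:
    """JMI of (X_{k+1}, X1^(1)) given S = {X_1..X_k}, by the pairwise-CMI sums.

    active: (1/k) sum_{i=1}^k [h(sqrt(g^{2k} + g^{2(i-1)})) - h(g^{i-1})]
    child:  0 for k = 1, else
            (1/k) sum_{i=2}^k [h(sqrt(g^{2(i-1)} + 1/2)) - h(g^{i-1})]
    """
    g = gamma
    active = (
        sum(
            h(math.sqrt(g ** (2 * k) + g ** (2 * (i - 1))), cfg) - h(g ** (i - 1), cfg)
            for i in range(1, k + 1)
        )
        / k
    )
    if k == 1:
        child = 0.0
    else:
        child = (
            sum(
                h(math.sqrt(g ** (2 * (i - 1)) + 0.5), cfg) - h(g ** (i - 1), cfg)
                for i in range(2, k + 1)
            )
            / k
        )
    return active, child


def cife_scores_closed(
    k: int, gamma: float, cfg: QuadratureConfig | None = None
) -> tuple[float, float]:
    """CIFE of (X_{k+1}, X1^(1)) given S = {X_1..X_k}.

    active: (1-k) [h(g^k) - 1/2 log(2 pi e)]
            + sum_{i=1}^k [h(sqrt(g^{2k} + g^{2(i-1)})) - h(g^{i-1})]
    child:  0 for k = 1, else
            (1-k) [h(1/sqrt(2)) - 1/2 log(2 pi e)]
            + sum_{i=2}^k [h(sqrt(g^{2(i-1)} + 1/2)) - h(g^{i-1})]

    At gamma = 1 both are affine in k with slopes
    -(2h(1) - h(sqrt 2) - 1/2 log(2 pi e)) and
    -(h(1) + h(1/sqrt 2) - h(sqrt(3/2)) - 1/2 log(2 pi e)); both tend to
    -infinity, the active faster, so the child eventually outscores it.
    """
    g = gamma
    active = (1 - k) * (h(g**k, cfg) - HALF_LOG_2PI_E) + sum(
        h(math.sqrt(g ** (2 * k) + g ** (2 * (i - 1))), cfg) - h(g ** (i - 1), cfg)
        for i in range(1, k + 1)
    )
    if k == 1:
        child = 0.0
    else:
        child = (1 - k) * (h(1.0 / math.sqrt(2.0), cfg) - HALF_LOG_2PI_E) + sum(
            h(math.sqrt(g ** (2 * (i - 1)) + 0.5), cfg) - h(g ** (i - 1), cfg)
            for i in range(2, k + 1)
        )
    return active, child
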