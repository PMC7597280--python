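"""Exact information measures for two-component Gaussian mixtures.

This module implements the differential entropy of an equal-weight mixture
of two Gaussians sharing a covariance matrix, its mutual information with
the binary mixing label, and derived quantities (sub-vector mutual
information, interaction information, total correlation).

The central object is the one-dimensional mixture-entropy function

    h(a) = entropy of (1/2) N(0, 1) + (1/2) N(a, 1)   (nats),

evaluated by adaptive quadrature.  Every multivariate quantity reduces to
``h`` through the Mahalanobis separation ``||Sigma^{-1/2} mu||`` of the two
component centers: for a d-variate mixture with mean difference ``mu`` and
shared covariance ``Sigma``,

    H(X)   = h(||Sigma^{-1/2} mu||) + (d-1)/2 log(2*pi*e) + 1/2 log det Sigma
    I(X,Y) = h(||Sigma^{-1/2} mu||) - 1/2 log(2*pi*e),

where Y ~ Bern(1/2) is the mixing label.  ``h`` is strictly increasing and
bounded between the standard-normal entropy and that entropy plus log 2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
from scipy.integrate import quad

__all__ = [
    "HALF_LOG_2PI_E",
    "DomainError",
    "QuadratureError",
    "QuadratureConfig",
    "MixtureSpec",
    "h",
    "mixture_entropy",
    "mi_with_label",
    "subset_entropy_mi",
    "interaction_information",
    "total_correlation",
]

#: One-dimensional standard normal entropy, (1/2) log(2*pi*e), in nats.
HALF_LOG_2PI_E: float = 0.5 * math.log(2.0 * math.pi * math.e)

_LOG_SQRT_8PI = math.log(2.0 * math.sqrt(2.0 * math.pi))


class DomainError(ValueError):
    """Raised when inputs are outside the mathematical domain of an operation."""


class QuadratureError(RuntimeError):
    """Raised when the adaptive quadrature cannot certify the requested accuracy."""


@dataclass(frozen=True)
class QuadratureConfig:
    """Accuracy controls for the one-dimensional entropy quadrature.

    abs_tol / rel_tol
        Absolute and relative tolerances passed to the adaptive rule.
    truncation_halfwidth
        The integrand is integrated on ``[min(0,a)-T, max(0,a)+T]`` with
        ``T`` this many standard deviations; the Gaussian tail beyond
        T = 12 contributes less than 1e-30.
    """

    abs_tol: float = 1e-10
    rel_tol: float = 1e-10
    truncation_halfwidth: float = 12.0

    def __post_init__(self) -> None:
        for name in ("abs_tol", "rel_tol", "truncation_halfwidth"):
            if not (getattr(self, name) > 0):
                raise DomainError(f"{name} must be strictly positive")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "QuadratureConfig":
        allowed = {"abs_tol", "rel_tol", "truncation_halfwidth"}
        unknown = set(mapping) - allowed
        if unknown:
            raise DomainError(f"unknown quadrature config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str) -> "QuadratureConfig":
        """Load from a JSON or YAML file with keys abs_tol/rel_tol/truncation_halfwidth."""
        with open(path) as fh:
            text = fh.read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise DomainError(f"config file {path!r} must contain a mapping")
        return cls.from_mapping(data)


_DEFAULT_CFG = QuadratureConfig()


class MixtureSpec:
    """A d-variate equal-weight two-component Gaussian mixture.

    The components are centered at ``0`` and ``mu`` and share the covariance
    ``sigma``; the mixing label is Bern(1/2).  Unequal weights are rejected:
    the closed-form entropy/MI results below hold for the symmetric mixture
    only.
    """

    #: relative eigenvalue floor below which sigma is treated as singular
    _EIG_FLOOR = 1e-12

    def __init__(self, mu, sigma) -> None:
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        if mu.ndim != 1 or mu.size < 1:
            raise DomainError("mu must be a one-dimensional vector of length >= 1")
        if not np.all(np.isfinite(mu)):
            raise DomainError("mu must be finite")
        sigma = np.asarray(sigma, dtype=float)
        if sigma.ndim == 0:
            sigma = sigma.reshape(1, 1)
        if sigma.shape != (mu.size, mu.size):
            raise DomainError(
                f"sigma must be {mu.size}x{mu.size}, got shape {sigma.shape}"
            )
        if not np.all(np.isfinite(sigma)):
            raise DomainError("sigma must be finite")
        if not np.allclose(sigma, sigma.T, atol=1e-10, rtol=0.0):
            raise DomainError("sigma must be symmetric (tolerance 1e-10)")
        sym = 0.5 * (sigma + sigma.T)
        eigval, eigvec = np.linalg.eigh(sym)
        if eigval[0] <= 0 or eigval[0] < self._EIG_FLOOR * eigval[-1]:
            raise DomainError(
                f"sigma is singular or not positive definite (eigenvalues {eigval})"
            )
        self.mu = mu
        self.sigma = sym
        self._eigval = eigval
        self._eigvec = eigvec

    @property
    def d(self) -> int:
        return self.mu.size

    @property
    def log_det_sigma(self) -> float:
        return float(np.sum(np.log(self._eigval)))

    @property
    def separation(self) -> float:
        """Mahalanobis distance ``||Sigma^{-1/2} mu||`` between the component centers.

        Computed through the symmetric eigendecomposition of sigma; the
        entropy and MI of the mixture depend on mu and sigma only through
        this scalar.
        """
        z = self._eigvec.T @ self.mu
        return float(np.sqrt(np.sum(z * z / self._eigval)))

    def whitened(self) -> "MixtureSpec":
        """The standardized mixture ``Sigma^{-1/2} X`` (identity covariance)."""
        inv_root = self._eigvec @ np.diag(self._eigval**-0.5) @ self._eigvec.T
        return MixtureSpec(inv_root @ self.mu, np.eye(self.d))

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Log of the mixture density at rows of ``x`` (shape (n, d))."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = x @ self._eigvec
        m = self.mu @ self._eigvec
        inv = 1.0 / self._eigval
        q0 = np.einsum("ij,j,ij->i", z, inv, z)
        zc = z - m
        q1 = np.einsum("ij,j,ij->i", zc, inv, zc)
        log_norm = -0.5 * (self.d * math.log(2.0 * math.pi) + self.log_det_sigma)
        return log_norm - math.log(2.0) + np.logaddexp(-0.5 * q0, -0.5 * q1)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MixtureSpec(d={self.d}, mu={self.mu!r})"


_H_CACHE: dict[tuple, float] = {}


def h(a: float, cfg: QuadratureConfig | None = None) -> float:
    """Entropy (nats) of the mixture (1/2)N(0,1) + (1/2)N(a,1), a >= 0.

    Strictly increasing in ``a``, with h(0) = (1/2) log(2*pi*e) and
    h(a) -> (1/2) log(2*pi*e) + log 2 as the components separate.  Callers
    pass the magnitude of the separation; negative ``a`` is rejected since
    the entropy is reflection-invariant.
    """
    cfg = cfg or _DEFAULT_CFG
    a = float(a)
    if not math.isfinite(a):
        raise DomainError("a must be finite")
    if a < 0:
        raise DomainError("a must be nonnegative (pass the separation magnitude)")
    key = (a, cfg.abs_tol, cfg.rel_tol, cfg.truncation_halfwidth)
    cached = _H_CACHE.get(key)
    if cached is not None:
        return cached

    def neg_f_log_f(x: float) -> float:
        # f(x) = (exp(-x^2/2) + exp(-(x-a)^2/2)) / (2 sqrt(2 pi))
        q0 = -0.5 * x * x
        q1 = -0.5 * (x - a) * (x - a)
        log_f = np.logaddexp(q0, q1) - _LOG_SQRT_8PI
        f = math.exp(log_f)
        if f < 1e-300:  # x log x -> 0 tail; avoids log of exactly zero
            return 0.0
        return -f * log_f

    lo = min(0.0, a) - cfg.truncation_halfwidth
    hi = max(0.0, a) + cfg.truncation_halfwidth
    value, err = quad(
        neg_f_log_f, lo, hi, epsabs=cfg.abs_tol, epsrel=cfg.rel_tol, limit=500
    )
    if err > max(cfg.abs_tol, cfg.rel_tol * abs(value)) * 100:
        raise QuadratureError(
            f"entropy quadrature did not converge for a={a}: "
            f"value={value}, estimated error={err}, interval=[{lo}, {hi}]"
        )
    _H_CACHE[key] = value
    return value


def mixture_entropy(spec: MixtureSpec, cfg: QuadratureConfig | None = None) -> float:
    """Entropy (nats) of a d-variate equal-weight two-component mixture.

    Equals ``h(||Sigma^{-1/2} mu||) + (d-1)/2 log(2 pi e) + (1/2) log det Sigma``;
    a rotation sends the separation onto one coordinate, leaving d-1
    independent standard normal coordinates, and whitening contributes the
    log-determinant through the scaling property of differential entropy.
    """
    cfg = cfg or _DEFAULT_CFG
    return (
        h(spec.separation, cfg)
        + (spec.d - 1) * HALF_LOG_2PI_E
        + 0.5 * spec.log_det_sigma
    )


def mi_with_label(spec: MixtureSpec, cfg: QuadratureConfig | None = None) -> float:
    """Mutual information I(X, Y) between the mixture and its mixing label.

    Equals ``h(||Sigma^{-1/2} mu||) - (1/2) log(2 pi e)``: the conditional
    entropy given the label is Gaussian and independent of the mean, so MI
    reduces to the excess of the mixture entropy over it.  Nonnegative and
    at most log 2 (the label is binary).
    """
    cfg = cfg or _DEFAULT_CFG
    value = h(spec.separation, cfg) - HALF_LOG_2PI_E
    if value < 0.0:
        if value < -1e-9:
            raise QuadratureError(f"negative mutual information {value}")
        value = 0.0
    return value


def _check_marginal(sub: MixtureSpec, joint: MixtureSpec, idx: np.ndarray, name: str):
    if not np.allclose(sub.mu, joint.mu[idx], atol=1e-10, rtol=0.0):
        raise DomainError(f"spec{name}.mu is not the corresponding sub-vector of specAB.mu")
    if not np.allclose(
        sub.sigma, joint.sigma[np.ix_(idx, idx)], atol=1e-10, rtol=0.0
    ):
        raise DomainError(f"spec{name}.sigma is not the corresponding block of specAB.sigma")


def subset_entropy_mi(
    specA: MixtureSpec,
    specB: MixtureSpec,
    specAB: MixtureSpec,
    cfg: QuadratureConfig | None = None,
) -> float:
    """Mutual information I(A, B) between two sub-vectors of one mixture.

    ``specAB`` is the joint mixture whose leading block is ``specA`` and
    trailing block is ``specB`` (consistency is checked); the value is
    H(A) + H(B) - H(A, B), each term an exact mixture entropy.
    """
    cfg = cfg or _DEFAULT_CFG
    if specA.d + specB.d != specAB.d:
        raise DomainError("dimensions of specA and specB must sum to specAB")
    ia = np.arange(specA.d)
    ib = np.arange(specA.d, specAB.d)
    _check_marginal(specA, specAB, ia, "A")
    _check_marginal(specB, specAB, ib, "B")
    value = (
        mixture_entropy(specA, cfg)
        + mixture_entropy(specB, cfg)
        - mixture_entropy(specAB, cfg)
    )
    if value < 0.0:
        if value < -1e-8:
            raise QuadratureError(f"negative subset mutual information {value}")
        value = 0.0
    return value


def interaction_information(entropies: Mapping[frozenset, float]) -> float:
    """p-way interaction information from a table of subset entropies.

    ``entropies`` maps every nonempty subset (as a frozenset of the p
    variable indices) to its joint entropy.  The value is the alternating
    Moebius sum ``-sum_T (-1)^(p-|T|) H(X_T)``; for p = 2 this is the
    mutual information, for p = 3 the familiar three-way synergy/redundancy
    measure (negative values indicate redundancy).  Supported for p <= 4.
    """
    if not entropies:
        raise DomainError("entropies mapping is empty")
    universe = frozenset().union(*entropies.keys())
    p = len(universe)
    if p < 2:
        raise DomainError("interaction information needs at least 2 variables")
    if p > 4:
        raise DomainError("interaction information supported for p <= 4 only")
    total = 0.0
    for size in range(1, p + 1):
        for subset in combinations(sorted(universe), size):
            key = frozenset(subset)
            if key not in entropies:
                raise DomainError(f"missing entropy for subset {sorted(subset)}")
            total -= (-1) ** (p - size) * entropies[key]
    return total


def total_correlation(spec: MixtureSpec, cfg: QuadratureConfig | None = None) -> float:
    """Total correlation (sum of marginal entropies minus joint entropy).

    For the standardized mixture (identity covariance) this reduces to
    ``sum_i h(|mu_i|) - h(||mu||) + (1-d)/2 log(2 pi e)``.  Non-identity
    covariances are rejected; use the subset machinery for those.
    """
    cfg = cfg or _DEFAULT_CFG
    if not np.allclose(spec.sigma, np.eye(spec.d), atol=1e-10, rtol=0.0):
        raise DomainError("total_correlation requires identity covariance")
    value = (
        sum(h(abs(m), cfg) for m in spec.mu)
        - h(float(np.linalg.norm(spec.mu)), cfg)
        + (1 - spec.d) * HALF_LOG_2PI_E
    )
    if value < 0.0:
        if value < -1e-8:
            raise QuadratureError(f"negative total correlation {value}")
        value = 0.0
    return value
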