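"""Sampling from the tree model and Monte-Carlo validation oracles.

The sampler draws labeled data from M(k, gamma) through its noise
representation X_i = gamma^(i-1) Y + eps_i, X1^(1) = X_1 + eps_{k+2} with
i.i.d. standard normal noise.  The Monte-Carlo entropy estimator
-(1/n) sum log p(x_i), with p the exact mixture density, provides an
independent check of the quadrature-based entropies and mutual
informations: it shares no code path with the one-dimensional entropy
integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gtm import GTMSpec
from .mixtures import HALF_LOG_2PI_E, DomainError, MixtureSpec

__all__ = ["SampleBatch", "sample_gtm", "mc_entropy", "mc_mi_with_label"]


@dataclass(frozen=True)
class SampleBatch:
    """Labeled draws from M(k, gamma): columns X_1..X_{k+1}, X1^(1)."""

    n: int
    labels: np.ndarray
    data: np.ndarray
    seed: int

    @property
    def column_names(self) -> list[str]:
        k_plus_1 = self.data.shape[1] - 1
        return [f"x{i}" for i in range(1, k_plus_1 + 1)] + ["x1_child"]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=self.column_names)
        df.insert(0, "y", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sample_gtm(spec: GTMSpec, n: int, seed: int) -> SampleBatch:
    """Draw ``n`` labeled samples from M(k, gamma), reproducibly per seed."""
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    eps = rng.standard_normal((n, spec.k + 2))
    gammas = spec.gamma ** np.arange(spec.k + 1)
    data = np.empty((n, spec.k + 2))
    data[:, : spec.k + 1] = y[:, None] * gammas[None, :] + eps[:, : spec.k + 1]
    data[:, spec.k + 1] = data[:, 0] + eps[:, spec.k + 1]
    return SampleBatch(n, y, data, seed)


def _draw_mixture(spec: MixtureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    y = rng.integers(0, 2, size=n)
    chol = np.linalg.cholesky(spec.sigma)
    z = rng.standard_normal((n, spec.d))
    return y[:, None] * spec.mu[None, :] + z @ chol.T


def mc_entropy(spec: MixtureSpec, n: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo mixture entropy: mean of -log p over ``n`` draws, with SE."""
    if n < 1000:
        raise DomainError("n must be >= 1000 for a meaningful standard error")
    rng = np.random.default_rng(seed)
    x = _draw_mixture(spec, n, rng)
    neg_log_p = -spec.log_density(x)
    return float(neg_log_p.mean()), float(neg_log_p.std(ddof=1) / math.sqrt(n))


def mc_mi_with_label(spec: MixtureSpec, n: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo I(X, Y): MC entropy minus the exact conditional entropy.

    Given the label the law is Gaussian with covariance sigma, so
    H(X | Y) = d/2 log(2 pi e) + 1/2 log det sigma exactly; only the
    marginal entropy is estimated and the SE propagates unchanged.
    """
    est, se = mc_entropy(spec, n, seed)
    cond = spec.d * HALF_LOG_2PI_E + 0.5 * spec.log_det_sigma
    return est - cond, se
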