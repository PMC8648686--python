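"""Exchangeable random paintboxes W_i = Y_i / (Y_1 + ... + Y_N).

One fresh, independent paintbox is drawn per generation; offspring numbers
are Multinomial(N, W).  Besides the two samplers this module provides
empirical diagnostics for the variance identity
``Var(nu_1) = N(N-1) E[W_1^2]`` and for the concentration behaviour of the
weights (moment decay, partial-sum tails, normalization deviations).  The
diagnostics check qualitative decay and limiting constants only — they are
Monte-Carlo estimates, not proofs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .offspring_laws import YLaw, rho_squared

__all__ = [
    "WeightVector",
    "sample_weights",
    "multinomial_offspring",
    "variance_nu1",
    "VarianceIdentity",
    "weight_moment_decay",
    "weight_sum_tail",
    "normalization_deviation",
    "sample_iid_sum",
    "diagnostic_row",
]

_SUM_TOL = 1e-12
# cap on elements drawn at once in chunked fallbacks
_CHUNK_ELEMS = 10_000_000


@dataclass
class WeightVector:
    """One generation's paintbox: nonnegative weights summing to one."""

    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1 or len(self.w) < 2:
            raise ValueError("weight vector must be 1-d with at least 2 entries")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > _SUM_TOL:
            raise ValueError("weights must sum to 1 within 1e-12")

    @property
    def n(self) -> int:
        return len(self.w)


def sample_weights(law: YLaw, n: int, rng: np.random.Generator) -> WeightVector:
    """Draw a fresh Dirichlet-type paintbox of size n >= 2."""
    if n < 2:
        raise ValueError("population size must be >= 2")
    y = law.sample(n, rng)
    return WeightVector(y / y.sum())


def multinomial_offspring(w: WeightVector, rng: np.random.Generator) -> np.ndarray:
    """Offspring counts nu ~ Multinomial(n, w); they sum to n exactly."""
    p = w.w / w.w.sum()  # exact renormalization for the multinomial sampler
    return rng.multinomial(w.n, p)


def sample_iid_sum(law: YLaw, count, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` independent copies of Y_1 + ... + Y_count.

    ``count`` may be a scalar or an integer array of length ``size``.
    Closed under convolution for gamma and deterministic laws, which gives
    an O(1)-per-draw fast path; other families fall back to summing
    explicit samples in chunks.
    """
    count = np.asarray(count)
    if np.any(count < 0):
        raise ValueError("count must be >= 0")
    if law.family == "deterministic":
        return np.broadcast_to(count * law.params[0], (size,)).astype(float).copy()
    if law.family == "gamma":
        shape, scale = law.params
        total_shape = np.broadcast_to(count * shape, (size,))
        out = np.zeros(size)
        pos = total_shape > 0
        out[pos] = rng.gamma(total_shape[pos], scale)
        return out
    # generic fallback
    if count.ndim == 0:
        c = int(count)
        if c == 0:
            return np.zeros(size)
        out = np.empty(size)
        rows_per_chunk = max(1, _CHUNK_ELEMS // max(c, 1))
        for start in range(0, size, rows_per_chunk):
            stop = min(start + rows_per_chunk, size)
            draws = law.sample((stop - start) * c, rng).reshape(stop - start, c)
            out[start:stop] = draws.sum(axis=1)
        return out
    return np.array(
        [law.sample(int(c), rng).sum() if c > 0 else 0.0 for c in count]
    )


@dataclass
class VarianceIdentity:
    """Shared-draw estimates of Var(nu_1) and N(N-1) E[W_1^2]."""

    empirical: float
    identity_value: float
    se_empirical: float
    se_identity: float
    n: int
    reps: int

    def __iter__(self):  # unpack as (empirical, identity_value)
        return iter((self.empirical, self.identity_value))


def variance_nu1(
    law: YLaw, n: int, reps: int, rng: np.random.Generator
) -> VarianceIdentity:
    """Estimate Var(nu_1) and the identity value N(N-1) E[W_1^2].

    Both statistics are computed from the same ``reps`` paintbox draws; by
    exchangeability nu_1 given W is Binomial(n, W_1), which is what is
    sampled here.  ``identity_value`` converges to rho^2 as n grows.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable variance estimate")
    w1 = np.empty(reps)
    rows_per_chunk = max(1, _CHUNK_ELEMS // n)
    for start in range(0, reps, rows_per_chunk):
        stop = min(start + rows_per_chunk, reps)
        y = law.sample((stop - start) * n, rng).reshape(stop - start, n)
        w1[start:stop] = y[:, 0] / y.sum(axis=1)
    nu1 = rng.binomial(n, w1)

    empirical = float(np.var(nu1, ddof=1))
    # SE of the sample variance from fourth central moments
    dev = nu1 - nu1.mean()
    m4 = np.mean(dev**4)
    var_of_var = (m4 - (reps - 3) / (reps - 1) * empirical**2) / reps
    se_emp = float(np.sqrt(max(var_of_var, 0.0)))

    w1sq = w1**2
    identity = float(n * (n - 1) * w1sq.mean())
    se_id = float(n * (n - 1) * w1sq.std(ddof=1) / np.sqrt(reps))
    return VarianceIdentity(empirical, identity, se_emp, se_id, n, reps)


def weight_moment_decay(
    law: YLaw, n: int, order: int, reps: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo estimate of E[(Y/(Y + H_n))^order], H_n = sum of n copies.

    Scaled by n^order the estimate stays bounded as n grows, and for
    order 2 it approaches rho^2 / n^2.
    """
    law.moment(order)  # raises if the needed moment is infinite
    y = law.sample(reps, rng)
    h = sample_iid_sum(law, n, reps, rng)
    return float(np.mean((y / (y + h)) ** order))


def weight_sum_tail(
    law: YLaw, n: int, k: int, eps: float, reps: int, rng: np.random.Generator
) -> float:
    """Empirical frequency of { sum_{i<=k} W_i >= (1+eps) k/n }."""
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    s_top = sample_iid_sum(law, k, reps, rng)
    s_rest = sample_iid_sum(law, n - k, reps, rng)
    frac = s_top / (s_top + s_rest)
    return float(np.mean(frac >= (1.0 + eps) * k / n))


def normalization_deviation(
    law: YLaw, n: int, alpha: float, reps: int, rng: np.random.Generator
) -> float:
    """Empirical frequency of { |n / sum(Y) - 1| >= n^(-alpha) }."""
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 1/2)")
    h = sample_iid_sum(law, n, reps, rng)
    return float(np.mean(np.abs(n / h - 1.0) >= n ** (-alpha)))


def diagnostic_row(law: YLaw, n: int, statistic: str, value: float, reps: int, seed) -> dict:
    """One CSV-ready record of a paintbox diagnostic."""
    return {
        "law": law.describe(),
        "n": n,
        "statistic": statistic,
        "value": value,
        "reps": reps,
        "seed": seed,
    }
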