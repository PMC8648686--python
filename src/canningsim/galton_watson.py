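"""Slightly supercritical Galton-Watson machinery.

Offspring laws used to sandwich the early Cannings frequency process:
mixed Poisson ``Pois(Y * m)``, mixed binomial ``Bin(T, Y * c)``, the
two-point law ``(1-beta*s) delta_1 + beta*s delta_2`` and explicit pmf
tables.  On top of the laws:

- survival probabilities as the smallest pgf fixed point (bisection),
- Haldane's ``2s / sigma^2`` first-order approximation,
- the size-biased "immortal line" offspring law,
- an exact finite-state DP for the two-point process with lumped overflow,
- generation-n moments, the threshold-generation rule ``choose_n0``, and
  extinction-time tails by pgf iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .offspring_laws import YLaw

__all__ = [
    "GWLaw",
    "GWTrajectory",
    "PMFVector",
    "PgfUnavailableError",
    "mixed_poisson",
    "mixed_binomial",
    "two_point",
    "explicit",
    "gw_simulate",
    "survival_probability",
    "haldane_survival",
    "immortal_line_law",
    "two_point_dp",
    "gw_moments",
    "choose_n0",
    "absorption_time_tail",
    "growth_factor_upper",
    "growth_factor_lower",
]

_MASS_TOL = 1e-12
_DEFAULT_POP_CAP = 10_000_000


class PgfUnavailableError(ValueError):
    """pgf unavailable for this kind -- simulate instead."""


@dataclass(frozen=True)
class GWLaw:
    """An offspring distribution with exact mean and variance.

    Exactly one parameter set is populated, depending on ``kind``:
    ``mixed_poisson`` (ylaw, factor), ``mixed_binomial`` (trials, ylaw,
    p_scale), ``two_point`` (beta, s) or ``explicit`` (pmf).
    """

    kind: str
    ylaw: YLaw | None = None
    factor: float = 1.0
    trials: int = 0
    p_scale: float = 0.0
    beta: float = 0.0
    s: float = 0.0
    pmf: tuple[float, ...] = ()

    @property
    def mean(self) -> float:
        if self.kind == "mixed_poisson":
            return self.factor * self.ylaw.mean
        if self.kind == "mixed_binomial":
            return self.trials * self.p_scale * self.ylaw.mean
        if self.kind == "two_point":
            return 1.0 + self.beta * self.s
        return float(np.dot(np.arange(len(self.pmf)), self.pmf))

    @property
    def variance(self) -> float:
        if self.kind == "mixed_poisson":
            # Var = m^2 Var(Y) + m E[Y] by conditioning on Y
            return self.factor**2 * self.ylaw.variance + self.factor * self.ylaw.mean
        if self.kind == "mixed_binomial":
            t, c, y = self.trials, self.p_scale, self.ylaw
            return (
                t * c * y.mean
                - t * c**2 * y.moment(2)
                + t**2 * c**2 * y.variance
            )
        if self.kind == "two_point":
            bs = self.beta * self.s
            return bs * (1.0 - bs)
        k = np.arange(len(self.pmf))
        m = self.mean
        return float(np.dot(k * k, self.pmf) - m * m)

    # -- pgf -------------------------------------------------------------

    @property
    def has_pgf(self) -> bool:
        if self.kind in ("two_point", "explicit"):
            return True
        if self.kind == "mixed_poisson":
            return self.ylaw.has_closed_laplace
        if self.kind == "mixed_binomial":
            return self.ylaw.family in ("deterministic", "two_point", "table")
        return False

    def pgf(self, q: float) -> float:
        """f(q) = E[q^Z] for q in [0, 1]."""
        if self.kind == "two_point":
            bs = self.beta * self.s
            return (1.0 - bs) * q + bs * q * q
        if self.kind == "explicit":
            return float(np.polynomial.polynomial.polyval(q, np.asarray(self.pmf)))
        if self.kind == "mixed_poisson":
            return float(self.ylaw.laplace(self.factor * (1.0 - q)))
        if self.kind == "mixed_binomial":
            if self.ylaw.family == "deterministic":
                p = self.p_scale * self.ylaw.params[0]
                return float((1.0 - p * (1.0 - q)) ** self.trials)
            if self.ylaw.family in ("two_point", "table"):
                vals, probs = self.ylaw._atoms()
                return float(
                    np.dot(probs, (1.0 - self.p_scale * vals * (1.0 - q)) ** self.trials)
                )
        raise PgfUnavailableError(
            f"pgf unavailable for {self.kind} with Y family "
            f"{self.ylaw.family if self.ylaw else None!r} -- simulate instead"
        )

    # -- explicit pmf (possibly truncated with tracked tail) -------------

    def pmf_array(self, tol: float = 1e-14, max_len: int = 1 << 20) -> np.ndarray:
        """Pmf on 0..K with total mass >= 1 - tol (exact for finite kinds)."""
        if self.kind == "explicit":
            return np.asarray(self.pmf, dtype=float)
        if self.kind == "two_point":
            bs = self.beta * self.s
            return np.array([0.0, 1.0 - bs, bs])
        if self.kind == "mixed_poisson":
            fam = self.ylaw.family
            if fam == "deterministic":
                lam = self.factor * self.ylaw.params[0]
                dist = stats.poisson(lam)
            elif fam == "gamma":
                shape, scale = self.ylaw.params
                dist = stats.nbinom(shape, 1.0 / (1.0 + self.factor * scale))
            elif fam in ("two_point", "table"):
                vals, probs = self.ylaw._atoms()
                kmax = 64
                while kmax < max_len:
                    k = np.arange(kmax + 1)
                    pm = stats.poisson.pmf(k[:, None], self.factor * vals[None, :]) @ probs
                    if 1.0 - pm.sum() < tol:
                        return pm
                    kmax *= 2
                raise ValueError("pmf truncation did not converge")
            else:
                raise PgfUnavailableError(
                    f"no explicit pmf for mixed_poisson with Y family {fam!r}"
                )
            kmax = int(dist.isf(tol / 10.0)) + 10
            return dist.pmf(np.arange(kmax + 1))
        raise PgfUnavailableError(f"no explicit pmf for kind {self.kind!r}")


def mixed_poisson(ylaw: YLaw, factor: float) -> GWLaw:
    """Offspring ~ Pois(Y * factor); mean = factor E[Y]."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return GWLaw("mixed_poisson", ylaw=ylaw, factor=factor)


def mixed_binomial(trials: int, ylaw: YLaw, p_scale: float) -> GWLaw:
    """Offspring ~ Bin(trials, Y * p_scale) (success prob clipped to 1 in sampling)."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if p_scale <= 0:
        raise ValueError("p_scale must be > 0")
    return GWLaw("mixed_binomial", ylaw=ylaw, trials=trials, p_scale=p_scale)


def two_point(beta: float, s: float) -> GWLaw:
    """Offspring 1 w.p. 1 - beta*s, 2 w.p. beta*s; never hits zero."""
    if not 0.0 < beta * s < 1.0:
        raise ValueError("beta * s must lie in (0, 1)")
    return GWLaw("two_point", beta=beta, s=s)


def explicit(pmf) -> GWLaw:
    pmf = np.asarray(pmf, dtype=float)
    if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > _MASS_TOL:
        raise ValueError("pmf must be nonnegative and sum to 1")
    return GWLaw("explicit", pmf=tuple(pmf))


# -- growth-factor presets from the bounding constructions ------------------


def growth_factor_upper(n: int, b: float, delta: float, alpha: float, s: float) -> float:
    """Literal upper-bound per-capita factor (1+N^(b+2d-1))(1+N^(-a))/(1-s)."""
    return (1.0 + n ** (b + 2 * delta - 1)) * (1.0 + n ** (-alpha)) / (1.0 - s)


def growth_factor_lower(
    n: int, delta: float, alpha: float, s: float, eps: float
) -> float:
    """Literal lower-bound per-capita factor (1+N^(-a))/(1-s+(1+e)N^(d-1))."""
    return (1.0 + n ** (-alpha)) / (1.0 - s + (1.0 + eps) * n ** (delta - 1))


# -- simulation -------------------------------------------------------------


@dataclass
class GWTrajectory:
    z: np.ndarray
    exploded: bool = False


def gw_simulate(
    law: GWLaw,
    z0: int,
    generations: int,
    rng: np.random.Generator,
    pop_cap: int = _DEFAULT_POP_CAP,
) -> GWTrajectory:
    """Exact branching simulation; Y is drawn fresh per individual per generation.

    Stops early (flagged ``exploded``) if the population exceeds ``pop_cap``.
    """
    if z0 < 0:
        raise ValueError("z0 must be >= 0")
    z = [int(z0)]
    for _ in range(generations):
        cur = z[-1]
        if cur == 0:
            z.append(0)
            continue
        if cur > pop_cap:
            return GWTrajectory(np.asarray(z), exploded=True)
        if law.kind == "two_point":
            nxt = cur + rng.binomial(cur, law.beta * law.s)
        elif law.kind == "mixed_poisson":
            y = law.ylaw.sample(cur, rng)
            nxt = int(rng.poisson(law.factor * y).sum())
        elif law.kind == "mixed_binomial":
            y = law.ylaw.sample(cur, rng)
            p = np.clip(law.p_scale * y, 0.0, 1.0)
            nxt = int(rng.binomial(law.trials, p).sum())
        else:  # explicit
            pmf = np.asarray(law.pmf)
            nxt = int(rng.choice(len(pmf), size=cur, p=pmf / pmf.sum()).sum())
        z.append(int(nxt))
    return GWTrajectory(np.asarray(z), exploded=False)


# -- survival / extinction --------------------------------------------------


def survival_probability(law: GWLaw, tol: float = 1e-12) -> float:
    """phi = 1 - q*, q* the smallest fixed point of the pgf in [0, 1].

    Returns 0 for (sub)critical laws.  Bisection to ``tol`` on the bracket
    [0, 1 - 1e-15]; supercriticality decided by mean > 1 + 1e-12.
    """
    if law.mean <= 1.0 + 1e-12:
        return 0.0
    if not law.has_pgf:
        raise PgfUnavailableError(
            f"pgf unavailable for kind {law.kind!r} -- simulate instead"
        )
    if law.pgf(0.0) == 0.0:
        return 1.0
    lo, hi = 0.0, 1.0 - 1e-15
    # invariant: f(lo) > lo (below the fixed point), f(hi) < hi (above it)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if law.pgf(mid) > mid:
            lo = mid
        else:
            hi = mid
    return 1.0 - 0.5 * (lo + hi)


def haldane_survival(s: float, sigma2: float) -> float:
    """First-order survival approximation 2s / sigma^2."""
    if s <= 0 or sigma2 <= 0:
        raise ValueError("s and sigma2 must be > 0")
    return 2.0 * s / sigma2


def absorption_time_tail(
    law: GWLaw,
    z0: int,
    horizon: int,
    rng: np.random.Generator | None = None,
    reps: int = 10_000,
) -> float:
    """P(extinction time > horizon), exact via pgf iteration q <- f(q) from 0.

    Falls back to Monte Carlo (requires ``rng``) when no pgf is available.
    """
    if z0 < 0 or horizon < 0:
        raise ValueError("z0 and horizon must be >= 0")
    if law.has_pgf:
        q = 0.0
        for _ in range(horizon):
            q = law.pgf(q)
        return 1.0 - q**z0
    if rng is None:
        raise PgfUnavailableError(
            "pgf unavailable -- pass rng for a Monte-Carlo estimate"
        )
    alive = 0
    for _ in range(reps):
        traj = gw_simulate(law, z0, horizon, rng)
        alive += traj.exploded or traj.z[-1] > 0
    return alive / reps


# -- immortal lines ---------------------------------------------------------


@dataclass
class PMFVector:
    """Probabilities on states 0..cap plus lumped mass beyond the cap."""

    probs: np.ndarray
    overflow: float = 0.0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        total = self.probs.sum() + self.overflow
        if np.any(self.probs < -1e-15) or abs(total - 1.0) > _MASS_TOL:
            raise ValueError("pmf mass must be nonnegative and total 1 within 1e-12")

    @property
    def cap(self) -> int:
        return len(self.probs) - 1

    def mean(self) -> float:
        """Mean over the retained states (a lower bound if overflow > 0)."""
        return float(np.dot(np.arange(len(self.probs)), self.probs))

    def prob_leq(self, x: float) -> float:
        hi = min(int(math.floor(x)), self.cap)
        return float(self.probs[: hi + 1].sum()) if hi >= 0 else 0.0

    def prob_geq(self, x: float) -> float:
        """Overflow counts as state >= cap + 1."""
        lo = max(int(math.ceil(x)), 0)
        if lo > self.cap:
            return self.overflow
        return float(self.probs[lo:].sum()) + self.overflow


def immortal_line_law(law: GWLaw, phi: float, kmax: int) -> PMFVector:
    """Offspring law of the skeleton of immortal lines.

    P(Z* = k) = (1/phi) E[ C(Z,k) phi^k (1-phi)^(Z-k) ] for k >= 1; the
    mean equals the mean of the original law.  Mass beyond ``kmax`` is
    tracked as overflow and must stay below 1e-6.
    """
    if not 0.0 < phi <= 1.0:
        raise ValueError("phi must lie in (0, 1]")
    pz = law.pmf_array()
    z = np.arange(len(pz))
    out = np.zeros(kmax + 1)
    for k in range(1, kmax + 1):
        out[k] = np.dot(pz, stats.binom.pmf(k, z, phi)) / phi
    # k = 0 is excluded by construction (immortal lines have >= 1 child)
    overflow = max(1.0 - out.sum(), 0.0)
    if overflow > 1e-6:
        raise ValueError(f"overflow mass {overflow:.2e} > 1e-6: kmax too small")
    return PMFVector(out, overflow)


# -- exact two-point DP -----------------------------------------------------


def two_point_dp(beta: float, s: float, n_gens: int, cap: int) -> PMFVector:
    """Exact distribution of the two-point process after ``n_gens`` generations.

    Transition from k adds Bin(k, beta*s); states above ``cap`` are lumped
    into absorbing overflow (valid for monotone events: the path is
    nondecreasing, so mass above the cap never returns).
    """
    bs = beta * s
    if not 0.0 < bs < 1.0:
        raise ValueError("beta * s must lie in (0, 1)")
    if cap < 2:
        raise ValueError("cap must be >= 2")
    k = np.arange(1, cap + 1)
    j = k[None, :] - k[:, None]  # added individuals; pmf is 0 outside 0..k
    trans = stats.binom.pmf(j, k[:, None], bs)
    leak = stats.binom.sf(cap - k, k, bs)  # mass jumping beyond the cap

    probs = np.zeros(cap)
    probs[0] = 1.0  # state 1
    overflow = 0.0
    for _ in range(n_gens):
        overflow += float(np.dot(probs, leak))
        probs = probs @ trans
        total = probs.sum() + overflow
        if abs(total - 1.0) > _MASS_TOL:
            raise AssertionError(f"mass leak in two-point DP: {total - 1.0:.3e}")
    full = np.zeros(cap + 1)
    full[1:] = probs
    return PMFVector(full, overflow)


def gw_moments(m: float, sigma2: float, n: int) -> tuple[float, float]:
    """Generation-n mean and variance: (m^n, sigma^2 m^n (m^n - 1)/(m^2 - m))."""
    if m <= 0:
        raise ValueError("m must be > 0")
    if n < 0:
        raise ValueError("n must be >= 0")
    if m == 1.0:
        return 1.0, n * sigma2
    mn = m**n
    return mn, sigma2 * mn * (mn - 1.0) / (m * m - m)


def choose_n0(beta: float, s: float, delta: float) -> int:
    """Smallest n with (1 + beta*s)^n >= 2 (1/s)^(1+delta).

    Exact integer search by repeated multiplication (no logarithm
    rounding at the threshold boundary).
    """
    bs = beta * s
    if not 0.0 < bs < 1.0:
        raise ValueError("beta * s must lie in (0, 1)")
    if not 0.0 < s < 1.0:
        raise ValueError("s must lie in (0, 1)")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    threshold = 2.0 * (1.0 / s) ** (1.0 + delta)
    growth = 1.0 + bs
    value, n = growth, 1
    while value < threshold:
        value *= growth
        n += 1
    return n
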