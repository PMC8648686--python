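"""The Cannings frequency process with selection.

Each generation a fresh paintbox W is drawn; with k beneficial individuals
present, the next count is Binomial(N, p) with

    p = sum_{i<=k} W_i / (sum_{i<=k} W_i + (1-s) sum_{i>k} W_i),

i.e. wildtype reproductive weights are damped by the factor 1-s.  The two
absorbing states are 0 and N.

Sampling is two-stage (weights, then the binomial given the weights); the
mixed binomial is never marginalized.  For gamma and deterministic Y the
partial sums of i.i.d. Y's are drawn directly from their exact convolution
laws, which is distributionally identical to materializing all N weights
and far cheaper.  A vectorized batch engine drives the Monte-Carlo
fixation estimates; the scalar `step`/`run_to_absorption` API serves single
trajectories and tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from statsmodels.stats.proportion import proportion_confint

from .offspring_laws import YLaw, make_ylaw
from .paintbox import WeightVector, sample_iid_sum

__all__ = [
    "SCHEMES",
    "CanningsConfig",
    "TrajectoryRecord",
    "Estimate",
    "BatchResult",
    "success_probability",
    "step",
    "run_to_absorption",
    "simulate_batch",
    "estimate_fixation",
    "estimate_fixation_crn",
    "exact_fixation_wf",
    "counterexample_weights",
    "default_max_gen",
    "wilson_interval",
]

SCHEMES = ("dirichlet_type", "wright_fisher", "counterexample")

_EXACT_WF_MAX_N = 2000


@dataclass(frozen=True)
class CanningsConfig:
    """Complete specification of one Cannings-with-selection model.

    Selection is given either directly as ``s`` in [0,1) or through the
    power law ``s = c * n**(-b)`` via :meth:`from_power_law`.  The derived
    exponent ``b_n = -ln(s)/ln(n)`` is reported for traceability.
    """

    n: int
    s: float
    ylaw: YLaw = field(default_factory=lambda: make_ylaw("deterministic", (1.0,)))
    scheme: str = "dirichlet_type"
    gamma: float | None = None  # counterexample big-weight exponent

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("population size must be >= 2")
        if not 0.0 <= self.s < 1.0:
            raise ValueError("selection strength must lie in [0, 1)")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if self.scheme == "counterexample":
            if self.gamma is None or not 0.0 < self.gamma < 0.5:
                raise ValueError("counterexample scheme needs gamma in (0, 1/2)")

    @classmethod
    def from_power_law(cls, n: int, c: float, b: float, **kwargs) -> "CanningsConfig":
        """Build a config with s = c * n**(-b)."""
        return cls(n=n, s=c * n ** (-b), **kwargs)

    @property
    def b_n(self) -> float | None:
        """Exponent -ln(s)/ln(n); None in the neutral case."""
        if self.s == 0.0:
            return None
        return -math.log(self.s) / math.log(self.n)

    def selection_in_moderate_regime(self, eta: float) -> bool:
        """Whether n^(-1/2+eta) <= s <= n^(-eta) for the supplied eta."""
        if not 0.0 < eta < 0.25:
            raise ValueError("eta must lie in (0, 1/4)")
        return self.n ** (-0.5 + eta) <= self.s <= self.n ** (-eta)


@dataclass
class TrajectoryRecord:
    """One forward trajectory with absorption and first-passage bookkeeping."""

    x: np.ndarray
    absorbed_at: int | None
    final: int | None
    hits: dict
    censored: bool = False


@dataclass
class Estimate:
    """Monte-Carlo probability estimate with a Wilson confidence interval."""

    point: float
    successes: int
    reps: int
    ci_low: float
    ci_high: float
    seed: int | None = None
    censored: int = 0

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def wilson_interval(successes: int, reps: int, alpha: float = 0.05):
    """Wilson score interval; collapses to a point for degenerate outcomes."""
    if reps <= 0:
        raise ValueError("reps must be positive")
    lo, hi = proportion_confint(successes, reps, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def default_max_gen(config: CanningsConfig) -> int:
    """Generous multiple of the fixation timescale: ~20 ln(N)/s, or 50N neutrally."""
    if config.s > 0:
        return math.ceil(20.0 * math.log(config.n) / config.s)
    return 50 * config.n


# -- single-step dynamics ---------------------------------------------------


def success_probability(k: int, w: WeightVector, s: float) -> float:
    """Per-child probability of picking a beneficial parent.

    Equals the beneficial weight mass when s = 0, is 1 at k = N, and is
    strictly increasing in s for 0 < k < N.
    """
    if not 0 <= k <= w.n:
        raise ValueError(f"k must lie in [0, {w.n}], got {k}")
    a = float(np.sum(w.w[:k]))
    total = float(np.sum(w.w))
    return a / (a + (1.0 - s) * (total - a))


def _split_sums(law: YLaw, k, n: int, rng: np.random.Generator, size: int):
    """(sum of k i.i.d. Y, sum of n-k i.i.d. Y), vectorized over replicates."""
    a = sample_iid_sum(law, k, size, rng)
    b = sample_iid_sum(law, np.asarray(n) - np.asarray(k), size, rng)
    return a, b


def _batch_success_prob(
    config: CanningsConfig, k: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Success probabilities for a vector of current counts (all in 1..N-1)."""
    n, s = config.n, config.s
    if config.scheme == "wright_fisher":
        return k / (k + (1.0 - s) * (n - k))
    if config.scheme == "counterexample":
        big_w = n ** (-config.gamma)
        small_w = (1.0 - big_w) / (n - 1)
        has_big = rng.random(len(k)) < k / n
        a = np.where(has_big, big_w + (k - 1) * small_w, k * small_w)
        return a / (a + (1.0 - s) * (1.0 - a))
    a, b = _split_sums(config.ylaw, k, n, rng, len(k))
    return a / (a + (1.0 - s) * b)


def step(config: CanningsConfig, k: int, rng: np.random.Generator) -> int:
    """One generation: fresh weights, then Binomial(N, p).  Absorbing at 0, N."""
    if not 0 <= k <= config.n:
        raise ValueError(f"k must lie in [0, {config.n}], got {k}")
    if k in (0, config.n):
        return k
    p = _batch_success_prob(config, np.array([k]), rng)[0]
    return int(rng.binomial(config.n, p))


def counterexample_weights(n: int, gamma: float, rng: np.random.Generator) -> WeightVector:
    """One uniformly chosen index gets weight n^(-gamma), the rest split evenly."""
    if not 0.0 < gamma < 0.5:
        raise ValueError("gamma must lie in (0, 1/2)")
    big = n ** (-gamma)
    w = np.full(n, (1.0 - big) / (n - 1))
    w[rng.integers(n)] = big
    return WeightVector(w)


# -- trajectories -----------------------------------------------------------


def run_to_absorption(
    config: CanningsConfig,
    x0: int,
    max_gen: int | None = None,
    rng: np.random.Generator | None = None,
    record_levels=(),
) -> TrajectoryRecord:
    """Iterate until hitting {0, N} or max_gen (censored, not an error).

    ``hits`` maps each requested level to the first generation g with
    X_g >= level (levels never reached are absent).
    """
    if rng is None:
        raise ValueError("an explicitly seeded generator is required")
    if not 0 <= x0 <= config.n:
        raise ValueError(f"x0 must lie in [0, {config.n}]")
    if max_gen is None:
        max_gen = default_max_gen(config)
    if max_gen < 1:
        raise ValueError("max_gen must be >= 1")

    x = [x0]
    hits = {lvl: 0 for lvl in record_levels if x0 >= lvl}
    k = x0
    for g in range(1, max_gen + 1):
        if k in (0, config.n):
            break
        k = step(config, k, rng)
        x.append(k)
        for lvl in record_levels:
            if lvl not in hits and k >= lvl:
                hits[lvl] = g
    absorbed = k in (0, config.n)
    return TrajectoryRecord(
        x=np.asarray(x),
        absorbed_at=(len(x) - 1) if absorbed else None,
        final=k if absorbed else None,
        hits=hits,
        censored=not absorbed,
    )


@dataclass
class BatchResult:
    """Vectorized ensemble of trajectories (final states and level hits)."""

    n: int                     # population size (fixation state)
    final: np.ndarray          # state at stop time (absorbed or censored)
    censored: np.ndarray       # bool mask of unabsorbed replicates
    hit: dict                  # level -> bool mask "ever reached >= level"
    generations: int

    @property
    def fixed(self) -> np.ndarray:
        return (self.final == self.n) & ~self.censored


def simulate_batch(
    config: CanningsConfig,
    x0: int,
    reps: int,
    rng: np.random.Generator,
    max_gen: int | None = None,
    levels=(),
) -> BatchResult:
    """Run ``reps`` independent trajectories in lockstep (vectorized)."""
    if not 0 <= x0 <= config.n:
        raise ValueError(f"x0 must lie in [0, {config.n}]")
    if max_gen is None:
        max_gen = default_max_gen(config)
    n = config.n
    k = np.full(reps, x0, dtype=np.int64)
    hit = {lvl: k >= lvl for lvl in levels}
    active = (k > 0) & (k < n)
    g = 0
    while active.any() and g < max_gen:
        ka = k[active]
        p = _batch_success_prob(config, ka, rng)
        k[active] = rng.binomial(n, p)
        for lvl in levels:
            hit[lvl] |= k >= lvl
        active = (k > 0) & (k < n)
        g += 1
    return BatchResult(n=n, final=k, censored=active, hit=hit, generations=g)


def estimate_fixation(
    config: CanningsConfig,
    x0: int,
    reps: int,
    rng: np.random.Generator,
    max_gen: int | None = None,
    seed: int | None = None,
) -> Estimate:
    """Monte-Carlo fixation probability with a 95% Wilson interval."""
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if x0 in (0, config.n):
        point = float(x0 == config.n)
        return Estimate(point, int(point) * reps, reps, point, point, seed=seed)
    res = simulate_batch(config, x0, reps, rng, max_gen=max_gen)
    n_censored = int(res.censored.sum())
    if n_censored:
        warnings.warn(
            f"{n_censored}/{reps} replicates unabsorbed after max_gen; "
            "counted as non-fixed",
            stacklevel=2,
        )
    successes = int(((res.final == config.n) & ~res.censored).sum())
    lo, hi = wilson_interval(successes, reps)
    return Estimate(successes / reps, successes, reps, lo, hi, seed=seed, censored=n_censored)


def estimate_fixation_crn(
    n: int,
    s_values,
    x0: int,
    reps: int,
    base_seed: int,
    scheme: str = "wright_fisher",
    ylaw: YLaw | None = None,
    gamma: float | None = None,
):
    """Fixation estimates across an s-grid with common random numbers.

    Replicate r uses seed base_seed + r for every s, so the estimated
    fixation probability is a nondecreasing-in-s comparison on shared
    randomness (up to the residual coupling noise of fresh weights).
    """
    out = []
    for s in s_values:
        kwargs = {} if ylaw is None else {"ylaw": ylaw}
        config = CanningsConfig(n=n, s=float(s), scheme=scheme, gamma=gamma, **kwargs)
        max_gen = default_max_gen(config)
        successes = 0
        for r in range(reps):
            rng = np.random.default_rng(base_seed + r)
            rec = run_to_absorption(config, x0, max_gen=max_gen, rng=rng)
            successes += rec.final == n
        lo, hi = wilson_interval(successes, reps)
        out.append(Estimate(successes / reps, successes, reps, lo, hi, seed=base_seed))
    return out


# -- exact oracle for deterministic weights ---------------------------------


def exact_fixation_wf(n: int, s: float, x0: int) -> float:
    """Exact fixation probability for the deterministic-weight chain.

    With W_i = 1/N the transition from k is Binomial(N, k/(k+(1-s)(N-k))).
    Solves the absorbing-chain system u = P u with u(0)=0, u(N)=1 by a
    dense linear solve; limited to n <= 2000.
    """
    if n > _EXACT_WF_MAX_N:
        raise ValueError(f"dense solve limited to n <= {_EXACT_WF_MAX_N}")
    if not 0 <= x0 <= n:
        raise ValueError(f"x0 must lie in [0, {n}]")
    if x0 == 0:
        return 0.0
    if x0 == n:
        return 1.0
    k = np.arange(1, n)
    p = k / (k + (1.0 - s) * (n - k))
    # rows: transition pmf over 0..n from each interior state
    pmf = stats.binom.pmf(np.arange(n + 1)[None, :], n, p[:, None])
    q = pmf[:, 1:n]                      # interior -> interior
    r = pmf[:, n]                        # interior -> fixation
    u = linalg.solve(np.eye(n - 1) - q, r)
    return float(u[x0 - 1])
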