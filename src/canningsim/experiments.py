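"""Headline experiments: Haldane ratio sweeps, three-phase decomposition,
and the skewed-weight counterexample, plus tabular output helpers.

The fixation probability of a single beneficial mutant is compared against
the first-order prediction 2s/rho^2 and its finite-N refinement
1/N + 2s/rho^2.  The phase decomposition factorizes fixation through the
levels ceil(N^(b+delta)) and ceil(eps N) using the strong Markov property;
conditional estimates reuse surviving trajectories rather than restarting
from deterministic states.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cannings import (
    CanningsConfig,
    Estimate,
    estimate_fixation,
    simulate_batch,
    wilson_interval,
)
from .offspring_laws import YLaw, rho_squared

__all__ = [
    "PhaseConfig",
    "SweepRow",
    "PhaseResult",
    "CounterexampleResult",
    "haldane_prediction",
    "lessard_ladret_prediction",
    "ratio_sweep",
    "phase_decomposition",
    "counterexample_experiment",
    "counterexample_w2_moment",
    "write_results",
]


def haldane_prediction(s: float, rho2: float) -> float:
    """First-order fixation prediction 2 s / rho^2."""
    if s < 0 or rho2 < 1.0 - 1e-12:
        raise ValueError("need s >= 0 and rho2 >= 1")
    return 2.0 * s / rho2

def lessard_ladret_prediction(n: int, s: float, rho2: float) -> float:
    """Finite-N refinement 1/N + 2 s / rho^2 (always >= the first-order value)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return 1.0 / n + haldane_prediction(s, rho2)


@dataclass(frozen=True)
class PhaseConfig:
    """Level thresholds for the three growth phases.

    level1 = ceil(N^(b+delta)) is the end of the branching-dominated phase,
    level2 = ceil(eps*N) the macroscopic level; fixation at N is phase 3.
    """

    delta: float
    eps: float
    level1: int
    level2: int

    @classmethod
    def for_model(cls, n: int, b: float, delta: float = 0.1, eps: float = 0.02):
        if delta <= 0:
            raise ValueError("delta must be > 0")
        if not 0.0 < eps < 0.5:
            raise ValueError("eps must lie in (0, 1/2)")
        if b + delta >= 0.5:
            warnings.warn(
                f"b + delta = {b + delta:.3f} >= 1/2: outside the regime where "
                "the branching approximation of the first phase is controlled",
                stacklevel=2,
            )
        level1 = math.ceil(n ** (b + delta))
        level2 = math.ceil(eps * n)
        if not level1 < level2 < n:
            raise ValueError(
                f"need level1 < level2 < n, got {level1}, {level2}, {n}"
            )
        return cls(delta=delta, eps=eps, level1=level1, level2=level2)


@dataclass
class SweepRow:
    n: int
    s: float
    b_n: float | None
    ylaw: str
    scheme: str
    x0: int
    reps: int
    successes: int
    p_hat: float
    ci_low: float
    ci_high: float
    censored: int
    haldane: float
    lessard_ladret: float
    ratio: float | None
    seed: int | None


def ratio_sweep(
    grid,
    x0: int,
    reps: int,
    rng: np.random.Generator,
    seed: int | None = None,
    out: str | None = None,
) -> list[SweepRow]:
    """One fixation estimate per grid point (n, selection, ylaw, scheme).

    ``selection`` is either a raw s or a pair (c, b) meaning s = c n^(-b).
    Per-point failures are logged and skipped; rows are appended to ``out``
    (CSV) as they are produced so long sweeps are resumable.
    """
    rows: list[SweepRow] = []
    for n, selection, ylaw, scheme in grid:
        try:
            if isinstance(selection, tuple):
                c, b = selection
                config = CanningsConfig.from_power_law(
                    n, c, b, ylaw=ylaw, scheme=scheme
                )
            else:
                config = CanningsConfig(n=n, s=float(selection), ylaw=ylaw, scheme=scheme)
            est = estimate_fixation(config, x0, reps, rng, seed=seed)
            rho2 = rho_squared(ylaw)
            hal = haldane_prediction(config.s, rho2)
            row = SweepRow(
                n=n,
                s=config.s,
                b_n=config.b_n,
                ylaw=ylaw.describe(),
                scheme=scheme,
                x0=x0,
                reps=reps,
                successes=est.successes,
                p_hat=est.point,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                censored=est.censored,
                haldane=hal,
                lessard_ladret=lessard_ladret_prediction(n, config.s, rho2),
                ratio=(est.point / hal) if hal > 0 else None,
                seed=seed,
            )
        except Exception as exc:  # keep the sweep alive on per-point failure
            warnings.warn(f"sweep point {(n, selection, scheme)} failed: {exc}")
            continue
        rows.append(row)
        if out is not None:
            frame = pd.DataFrame([asdict(row)])
            frame.to_csv(
                out, mode="a", index=False, header=not _file_has_content(out)
            )
    return rows


def _file_has_content(path: str) -> bool:
    try:
        with open(path) as fh:
            return bool(fh.readline())
    except OSError:
        return False


@dataclass
class PhaseResult:
    p1: Estimate
    p2_given_1: Estimate
    p3_given_2: Estimate
    overall: Estimate
    phase: PhaseConfig
    low_confidence: bool = False

    @property
    def product(self) -> float:
        return self.p1.point * self.p2_given_1.point * self.p3_given_2.point


def phase_decomposition(
    config: CanningsConfig,
    phase: PhaseConfig,
    reps: int,
    rng: np.random.Generator,
    x0: int = 1,
    seed: int | None = None,
) -> PhaseResult:
    """Factorize fixation through level1 and level2 on shared trajectories.

    p1 = P(reach level1 from x0), p2 = P(reach level2 | reached level1),
    p3 = P(fix | reached level2); the product estimates the overall
    fixation probability (chain rule / strong Markov property).
    """
    res = simulate_batch(
        config, x0, reps, rng, levels=(phase.level1, phase.level2)
    )
    hit1 = res.hit[phase.level1]
    hit2 = res.hit[phase.level2]
    fixed = res.fixed

    def _make(successes: int, total: int) -> Estimate:
        if total == 0:
            return Estimate(math.nan, 0, 0, math.nan, math.nan, seed=seed)
        lo, hi = wilson_interval(successes, total)
        return Estimate(successes / total, successes, total, lo, hi, seed=seed)

    n1 = int(hit1.sum())
    p1 = _make(n1, reps)
    p2 = _make(int((hit2 & hit1).sum()), n1)
    p3 = _make(int((fixed & hit2).sum()), int(hit2.sum()))
    overall = _make(int(fixed.sum()), reps)
    return PhaseResult(
        p1=p1,
        p2_given_1=p2,
        p3_given_2=p3,
        overall=overall,
        phase=phase,
        low_confidence=n1 < 50,
    )


def counterexample_w2_moment(n: int, gamma: float) -> float:
    """Exact E[W_1^2] for the skewed scheme: one index gets n^(-gamma).

    W_1 = n^(-gamma) w.p. 1/n, else (1 - n^(-gamma))/(n-1).
    """
    big = n ** (-gamma)
    return big**2 / n + (1.0 - big) ** 2 / (n * (n - 1))


@dataclass
class CounterexampleResult:
    p_hat: Estimate
    haldane_naive: float
    w2_moment: float

    @property
    def ratio(self) -> float:
        return self.p_hat.point / self.haldane_naive


def counterexample_experiment(
    n: int,
    gamma: float,
    selection: float,
    x0: int,
    reps: int,
    rng: np.random.Generator,
    seed: int | None = None,
) -> CounterexampleResult:
    """Fixation under the skewed-weight scheme vs the naive prediction.

    The naive first-order value s / (N^2 E[W_1^2]) undershoots the neutral
    floor 1/N when gamma < b/2; the estimated probability cannot.
    """
    config = CanningsConfig(
        n=n, s=selection, scheme="counterexample", gamma=gamma
    )
    est = estimate_fixation(config, x0, reps, rng, seed=seed)
    w2 = counterexample_w2_moment(n, gamma)
    naive = selection / (n**2 * w2) if selection > 0 else 0.0
    return CounterexampleResult(p_hat=est, haldane_naive=naive, w2_moment=w2)


# -- output -----------------------------------------------------------------


def _row_dicts(rows) -> list[dict]:
    out = []
    for r in rows:
        out.append(asdict(r) if not isinstance(r, dict) else dict(r))
    return out


def write_results(rows, path: str, format: str = "csv", meta: dict | None = None):
    """Write rows deterministically (12 significant digits, stable columns).

    A metadata header (version, seed, config hash) is emitted as comment
    lines for CSV and as a top-level "meta" object for JSON.
    """
    if not rows:
        raise ValueError("rows must be nonempty")
    if format not in ("csv", "json"):
        raise ValueError("format must be 'csv' or 'json'")
    records = _row_dicts(rows)
    meta = dict(meta or {})
    meta.setdefault("writer", "canningsim-0.1.0")
    digest = hashlib.sha256(
        json.dumps(records, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    meta["config_hash"] = digest

    if format == "json":
        with open(path, "w") as fh:
            json.dump({"meta": meta, "rows": records}, fh, indent=1, default=str)
        return
    frame = pd.DataFrame(records)
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}={meta[key]}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")
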