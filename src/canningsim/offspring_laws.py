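"""Laws of the positive per-capita fitness variable Y.

A paintbox of Dirichlet type is built from i.i.d. positive random variables
``Y_1, ..., Y_N`` via ``W_i = Y_i / sum(Y)``.  This module represents the
law of ``Y``: exact raw moments, samplers, the asymptotic neutral offspring
variance ``rho^2 = E[Y^2] / E[Y]^2``, and a flag for the existence of an
exponential moment ``E[exp(hY)] < infinity`` (which some of the theoretical
predictions require).

All laws have strictly positive support; an atom at zero or negative mass
is rejected at construction.  By default laws are rescaled so that
``E[Y] = 1``, which leaves ``rho^2`` unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "YLaw",
    "MomentUndefinedError",
    "LaplaceUnavailableError",
    "make_ylaw",
    "parse_ylaw",
    "moment",
    "rho_squared",
    "sample_y",
    "FAMILIES",
]

FAMILIES = ("deterministic", "gamma", "lognormal", "pareto", "two_point", "table")

#: families for which E[exp(hY)] < infinity for some h > 0
_EXP_MOMENT_OK = frozenset({"deterministic", "gamma", "two_point", "table"})


class MomentUndefinedError(ValueError):
    """Requested raw moment is infinite for this law."""


class LaplaceUnavailableError(ValueError):
    """No closed form for E[exp(-tY)] is implemented for this family."""


@dataclass(frozen=True)
class YLaw:
    """Distribution of the positive variable Y, with exact moments.

    Parameters are stored in canonical (possibly rescaled) form:

    - ``deterministic``: ``(value,)``
    - ``gamma``:         ``(shape, scale)``
    - ``lognormal``:     ``(mu, sigma)`` of the underlying normal
    - ``pareto``:        ``(index, scale)`` — density ``a x_m^a / x^{a+1}``
    - ``two_point``:     ``(v1, v2, p1)`` — value ``v1`` w.p. ``p1``
    - ``table``:         explicit finite support in ``support``/``probs``
    """

    family: str
    params: tuple[float, ...] = ()
    normalized: bool = False
    support: tuple[float, ...] = field(default=())
    probs: tuple[float, ...] = field(default=())

    # -- moments ---------------------------------------------------------

    def moment(self, n: int) -> float:
        """Exact n-th raw moment E[Y^n]; raises if infinite."""
        if n < 0 or n != int(n):
            raise ValueError(f"moment order must be a nonnegative integer, got {n}")
        n = int(n)
        if self.family == "deterministic":
            return self.params[0] ** n
        if self.family == "gamma":
            shape, scale = self.params
            out = 1.0
            for i in range(n):
                out *= (shape + i) * scale
            return out
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(n * mu + 0.5 * n * n * sigma * sigma)
        if self.family == "pareto":
            index, scale = self.params
            if n >= index:
                raise MomentUndefinedError(
                    f"moment of order {n} undefined for pareto(index={index})"
                )
            return index * scale**n / (index - n)
        # two_point / table
        vals, probs = self._atoms()
        return float(np.dot(probs, vals**n))

    @property
    def mean(self) -> float:
        return self.moment(1)

    @property
    def variance(self) -> float:
        m1 = self.moment(1)
        return self.moment(2) - m1 * m1

    @property
    def has_exponential_moment(self) -> bool:
        """Whether E[exp(hY)] is finite for some h > 0."""
        return self.family in _EXP_MOMENT_OK

    # -- transforms ------------------------------------------------------

    @property
    def has_closed_laplace(self) -> bool:
        return self.family in ("deterministic", "gamma", "two_point", "table")

    def laplace(self, t):
        """E[exp(-t Y)] for t >= 0 (scalar or array)."""
        t = np.asarray(t, dtype=float)
        if self.family == "deterministic":
            return np.exp(-t * self.params[0])
        if self.family == "gamma":
            shape, scale = self.params
            return (1.0 + scale * t) ** (-shape)
        if self.family in ("two_point", "table"):
            vals, probs = self._atoms()
            return np.exp(-np.multiply.outer(t, vals)) @ probs
        raise LaplaceUnavailableError(
            f"no closed-form Laplace transform for family {self.family!r}"
        )

    # -- sampling --------------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n i.i.d. draws using the supplied generator."""
        if n < 1:
            raise ValueError(f"sample size must be >= 1, got {n}")
        if self.family == "deterministic":
            return np.full(n, self.params[0])
        if self.family == "gamma":
            shape, scale = self.params
            return rng.gamma(shape, scale, size=n)
        if self.family == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size=n)
        if self.family == "pareto":
            index, scale = self.params
            return scale * (1.0 + rng.pareto(index, size=n))
        vals, probs = self._atoms()
        return rng.choice(vals, size=n, p=probs)

    # -- helpers ---------------------------------------------------------

    def _atoms(self) -> tuple[np.ndarray, np.ndarray]:
        if self.family == "two_point":
            v1, v2, p1 = self.params
            return np.array([v1, v2]), np.array([p1, 1.0 - p1])
        if self.family == "table":
            return np.asarray(self.support), np.asarray(self.probs)
        raise ValueError(f"{self.family} has no finite support")

    def describe(self) -> str:
        if self.family == "table":
            pairs = ",".join(f"{v:g}@{p:g}" for v, p in zip(self.support, self.probs))
            return f"table:{pairs}"
        return f"{self.family}:" + ",".join(f"{p:g}" for p in self.params)


def make_ylaw(
    family: str,
    params=(),
    *,
    normalize: bool = True,
    support=None,
    probs=None,
) -> YLaw:
    """Build a YLaw, optionally rescaled so that E[Y] = 1.

    ``params`` follows the user-facing convention:

    - ``deterministic``: ``(value,)``
    - ``gamma``:         ``(shape,)`` or ``(shape, scale)``
    - ``lognormal``:     ``(sigma2,)`` or ``(sigma2, mu)``
    - ``pareto``:        ``(index,)`` or ``(index, scale)``
    - ``two_point``:     ``(v1, v2)`` or ``(v1, v2, p1)``
    - ``table``:         pass ``support=`` and ``probs=`` instead
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    params = tuple(float(p) for p in np.atleast_1d(params))

    if family == "deterministic":
        (value,) = params or (1.0,)
        if value <= 0:
            raise ValueError("deterministic value must be > 0")
        canonical = (1.0 if normalize else value,)
        return YLaw("deterministic", canonical, normalized=normalize or value == 1.0)

    if family == "gamma":
        if len(params) == 1:
            shape, scale = params[0], 1.0
        else:
            shape, scale = params
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        if normalize:
            scale = 1.0 / shape
        return YLaw("gamma", (shape, scale), normalized=normalize or shape * scale == 1.0)

    if family == "lognormal":
        if len(params) == 1:
            sigma2, mu = params[0], 0.0
        else:
            sigma2, mu = params
        if sigma2 <= 0:
            raise ValueError("lognormal sigma^2 must be > 0")
        if normalize:
            mu = -0.5 * sigma2
        sigma = math.sqrt(sigma2)
        normd = abs(mu + 0.5 * sigma2) < 1e-15
        return YLaw("lognormal", (mu, sigma), normalized=normd)

    if family == "pareto":
        if len(params) == 1:
            index, scale = params[0], 1.0
        else:
            index, scale = params
        if index <= 0 or scale <= 0:
            raise ValueError("pareto index and scale must be > 0")
        if normalize:
            if index <= 1:
                raise MomentUndefinedError(
                    "cannot normalize pareto with index <= 1 (infinite mean)"
                )
            scale = (index - 1.0) / index
        normd = index > 1 and abs(index * scale / (index - 1.0) - 1.0) < 1e-12
        return YLaw("pareto", (index, scale), normalized=normd)

    if family == "two_point":
        if len(params) == 2:
            v1, v2, p1 = *params, 0.5
        else:
            v1, v2, p1 = params
        if v1 <= 0 or v2 <= 0:
            raise ValueError("two_point values must be > 0")
        if not 0.0 < p1 < 1.0:
            raise ValueError("two_point probability must lie in (0,1)")
        mean = p1 * v1 + (1.0 - p1) * v2
        if normalize:
            v1, v2 = v1 / mean, v2 / mean
        return YLaw("two_point", (v1, v2, p1), normalized=normalize or mean == 1.0)

    # table
    if support is None or probs is None:
        raise ValueError("table family requires support= and probs=")
    vals = np.asarray(support, dtype=float)
    pr = np.asarray(probs, dtype=float)
    if vals.shape != pr.shape or vals.ndim != 1 or len(vals) == 0:
        raise ValueError("support and probs must be 1-d of equal length")
    if np.any(vals <= 0):
        raise ValueError("table support must be strictly positive")
    if np.any(pr < 0) or abs(pr.sum() - 1.0) > 1e-12:
        raise ValueError("table probs must be nonnegative and sum to 1")
    mean = float(np.dot(pr, vals))
    if normalize:
        vals = vals / mean
    return YLaw(
        "table",
        (),
        normalized=normalize or mean == 1.0,
        support=tuple(vals),
        probs=tuple(pr),
    )


def parse_ylaw(text: str, *, normalize: bool = True) -> YLaw:
    """Parse a "family:param[,param]" description, e.g. "gamma:2".

    The table family uses "table:v1@p1,v2@p2,...".
    """
    family, _, rest = text.partition(":")
    family = family.strip()
    if family == "table":
        support, probs = [], []
        for pair in rest.split(","):
            v, _, p = pair.partition("@")
            support.append(float(v))
            probs.append(float(p))
        return make_ylaw("table", support=support, probs=probs, normalize=normalize)
    params = [float(x) for x in rest.split(",")] if rest else []
    return make_ylaw(family, params, normalize=normalize)


# Functional aliases matching the operation-style interface. ---------------


def moment(law: YLaw, n: int) -> float:
    return law.moment(n)


def rho_squared(law: YLaw) -> float:
    """Asymptotic neutral offspring variance E[Y^2] / E[Y]^2 (>= 1)."""
    m1 = law.moment(1)
    return law.moment(2) / (m1 * m1)


def sample_y(law: YLaw, n: int, rng: np.random.Generator) -> np.ndarray:
    return law.sample(n, rng)
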