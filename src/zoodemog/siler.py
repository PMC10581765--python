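"""Siler bathtub mortality model: hazard, survival, density and sampling.

The hazard combines a declining juvenile term, a constant background term
and an exponentially increasing senescent (Gompertz) term:

    mu(x) = exp(a0 - a1*x) + c + exp(b0 + b1*x)

All ages are continuous, in years, measured from birth.  The cumulative
hazard has a closed form, which is used everywhere (numerical quadrature is
reserved for test oracles).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "SilerParams",
    "hazard",
    "cumulative_hazard",
    "survival",
    "density",
    "first_year_mortality",
    "sample_ages_at_death",
    "age_at_min_hazard",
    "upper_support",
]


@dataclass(frozen=True)
class SilerParams:
    """The five Siler mortality parameters.

    ``a0`` and ``b0`` are unconstrained log-scale levels; ``a1`` and ``b1``
    are strictly positive rates (yr^-1); ``c`` is a non-negative constant
    hazard (yr^-1).  ``c == 0`` is admitted as a degenerate boundary.
    """

    a0: float
    a1: float
    c: float
    b0: float
    b1: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.a0, self.a1, self.c, self.b0, self.b1]).all():
            raise ValueError("Siler parameters must be finite")
        if self.a1 <= 0:
            raise ValueError(f"a1 must be > 0, got {self.a1}")
        if self.b1 <= 0:
            raise ValueError(f"b1 must be > 0, got {self.b1}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.c, self.b0, self.b1])

    @classmethod
    def from_array(cls, theta) -> "SilerParams":
        a0, a1, c, b0, b1 = (float(v) for v in theta)
        return cls(a0, a1, c, b0, b1)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SilerParams":
        return cls(**json.loads(text))


def _check_age(x):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be non-negative")
    return x


def hazard(p: SilerParams, x):
    """Mortality rate mu(x); vectorized over ``x``."""
    x = _check_age(x)
    return np.exp(p.a0 - p.a1 * x) + p.c + np.exp(p.b0 + p.b1 * x)


def cumulative_hazard(p: SilerParams, x):
    """Integral of the hazard from 0 to ``x`` (closed form)."""
    x = _check_age(x)
    juv = np.exp(p.a0) / p.a1 * (1.0 - np.exp(-p.a1 * x))
    sen = np.exp(p.b0) / p.b1 * np.expm1(p.b1 * x)
    return juv + p.c * x + sen


def survival(p: SilerParams, x):
    """S(x) = exp(-U(x)); the complement of the CDF of ages at death."""
    return np.exp(-cumulative_hazard(p, x))


def density(p: SilerParams, x):
    """Probability density of ages at death, mu(x) * S(x)."""
    return hazard(p, x) * survival(p, x)


def first_year_mortality(p: SilerParams) -> float:
    """Probability of dying before age 1: q1 = 1 - S(1)."""
    return float(1.0 - survival(p, 1.0))


def age_at_min_hazard(p: SilerParams) -> float:
    """Age at which the hazard reaches its minimum (maturity proxy).

    Closed form ``(a0 - b0 + ln(a1/b1)) / (a1 + b1)`` from setting the
    derivative of the hazard to zero, clipped at 0.
    """
    x_star = (p.a0 - p.b0 + np.log(p.a1 / p.b1)) / (p.a1 + p.b1)
    return float(max(x_star, 0.0))


def upper_support(p: SilerParams, tail: float = 1e-12, hazard_scale: float = 1.0) -> float:
    """Smallest power-of-two age with ``S(x)**hazard_scale < tail``.

    Siler survival has no finite support; this doubling search provides the
    effective upper integration/sampling limit.
    """
    x = 1.0
    target = -np.log(tail) / hazard_scale
    with np.errstate(over="ignore"):  # overshooting to inf ends the search
        while cumulative_hazard(p, x) < target:
            x *= 2.0
            if x > 1e7:
                raise RuntimeError(
                    "failed to bracket the survival tail; pathological parameters"
                )
    return x


def invert_cumulative_hazard(p: SilerParams, targets: np.ndarray) -> np.ndarray:
    """Solve U(x) = t for each target t >= 0 (vectorized, monotone Newton)."""
    targets = np.asarray(targets, dtype=float)
    if np.any(targets < 0):
        raise ValueError("cumulative-hazard targets must be non-negative")
    hi = 1.0
    tmax = targets.max(initial=0.0)
    while cumulative_hazard(p, hi) < tmax:
        hi *= 2.0
        if hi > 1e7:
            raise RuntimeError(
                "failed to bracket inverse cumulative hazard; pathological parameters"
            )
    grid = np.linspace(0.0, hi, 4097)
    u_grid = cumulative_hazard(p, grid)
    x = np.interp(targets, u_grid, grid)
    for _ in range(60):
        f = cumulative_hazard(p, x) - targets
        if np.max(np.abs(f)) < 1e-12:
            break
        x = np.clip(x - f / hazard(p, x), 0.0, hi)
    return x


def sample_ages_at_death(
    p: SilerParams,
    n: int,
    seed,
    min_age: float = 0.0,
    hazard_scale: float = 1.0,
) -> np.ndarray:
    """Draw i.i.d. ages at death by inverting the survival function.

    ``min_age > 0`` draws from the distribution conditional on surviving to
    ``min_age`` (left truncation); ``hazard_scale`` multiplies the hazard
    (proportional-hazards sampling, S(x)**hazard_scale).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    u0 = cumulative_hazard(p, float(min_age))
    targets = u0 - np.log(u) / hazard_scale
    return invert_cumulative_hazard(p, targets)
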