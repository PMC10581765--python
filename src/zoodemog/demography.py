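"""Demographic functionals of a hazard and nonparametric life tables.

Continuous quantities (remaining life expectancy, lifespan inequality and
equality) are computed by adaptive quadrature of the Siler survival curve.
Discrete life tables come from the Kaplan-Meier product-limit estimator on a
1-year age grid with left-closed intervals [x, x+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .siler import SilerParams, cumulative_hazard, survival, upper_support

__all__ = [
    "LifeTable",
    "life_expectancy",
    "lifespan_inequality",
    "lifespan_equality",
    "build_life_table",
    "discrete_life_expectancy",
]

_QUAD_OPTS = dict(epsabs=1e-10, epsrel=1e-10, limit=500)


def life_expectancy(p: SilerParams, x: float = 0.0) -> float:
    """Remaining life expectancy e_x = int_x^inf S(t) dt / S(x)."""
    if x < 0:
        raise ValueError("age must be non-negative")
    sx = float(survival(p, x))
    if sx <= 1e-300:
        raise ValueError(f"survival at age {x} is numerically zero")
    xmax = max(upper_support(p), x + 1.0)
    integral, _ = quad(lambda t: survival(p, t), x, xmax, **_QUAD_OPTS)
    return integral / sx


def lifespan_inequality(p: SilerParams, x: float = 0.0) -> float:
    """H_x: survival-weighted mean accumulation of hazard after age x.

    H_x = [int_x^inf S(t)/S(x) * (U(t) - U(x)) dt] / e_x.  Equals exactly 1
    for a constant hazard; small when deaths concentrate at old ages.
    """
    if x < 0:
        raise ValueError("age must be non-negative")
    sx = float(survival(p, x))
    if sx <= 1e-300:
        raise ValueError(f"survival at age {x} is numerically zero")
    ux = float(cumulative_hazard(p, x))
    xmax = max(upper_support(p), x + 1.0)
    ex_num, _ = quad(lambda t: survival(p, t), x, xmax, **_QUAD_OPTS)
    num, _ = quad(
        lambda t: survival(p, t) * (cumulative_hazard(p, t) - ux), x, xmax, **_QUAD_OPTS
    )
    return num / ex_num


def lifespan_equality(p: SilerParams, x: float = 0.0) -> float:
    """eps_x = -ln H_x; larger when deaths concentrate at older ages."""
    h = lifespan_inequality(p, x)
    if h <= 0:
        raise ValueError(f"lifespan inequality must be positive, got {h}")
    return -float(np.log(h))


@dataclass
class LifeTable:
    """Discrete-age life table from the product-limit estimator.

    ``lx`` is cumulative survival at integer ages (l0 = 1 unless deaths occur
    at exactly age 0), ``dx`` raw death counts in [x, x+1), ``nx`` the number
    at risk at age x, and ``qx`` the 1-year death probability implied by lx.
    """

    ages: np.ndarray
    nx: np.ndarray
    dx: np.ndarray
    lx: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.nx = np.asarray(self.nx, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        self.lx = np.asarray(self.lx, dtype=float)
        self.qx = np.asarray(self.qx, dtype=float)
        if np.any(np.diff(self.lx) > 1e-12):
            raise ValueError("lx must be non-increasing")
        if np.any((self.qx < -1e-12) | (self.qx > 1 + 1e-12)):
            raise ValueError("qx must lie in [0, 1]")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "nx": self.nx, "dx": self.dx, "lx": self.lx, "qx": self.qx}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(
            ages=df["age"].to_numpy(),
            nx=df["nx"].to_numpy(),
            dx=df["dx"].to_numpy(),
            lx=df["lx"].to_numpy(),
            qx=df["qx"].to_numpy(),
        )


def build_life_table(event_ages, max_age: int | None = None) -> LifeTable:
    """Kaplan-Meier product-limit life table on an integer-age grid.

    ``event_ages`` is an iterable of ``(age, is_death)``; censored records
    leave the risk set at their censoring age.  At tied ages, deaths are
    processed before censorings (standard convention).
    """
    events = list(event_ages)
    if not events:
        raise ValueError("no events supplied")
    ages = np.array([a for a, _ in events], dtype=float)
    deaths = np.array([bool(d) for _, d in events])
    if np.any(ages < 0):
        raise ValueError("event ages must be non-negative")
    if not deaths.any():
        warnings.warn("no deaths in input; survival is 1 throughout", UserWarning)

    # product-limit over distinct death times, deaths before censorings at ties
    death_times = np.unique(ages[deaths])
    km_s, km_t = [], []
    s = 1.0
    for t in death_times:
        at_risk = np.sum(ages >= t)
        d = np.sum(deaths & (ages == t))
        s *= 1.0 - d / at_risk
        km_t.append(t)
        km_s.append(s)
    km_t = np.asarray(km_t)
    km_s = np.asarray(km_s)

    if max_age is None:
        max_age = int(np.ceil(ages.max()))
    grid = np.arange(max_age + 1)
    # right-continuous step function: lx includes deaths at exactly age x
    if km_t.size == 0:
        lx = np.ones(grid.size)
    else:
        idx = np.searchsorted(km_t, grid, side="right")
        lx = np.where(idx == 0, 1.0, km_s[np.clip(idx - 1, 0, None)])
    nx = np.array([np.sum(ages >= a) for a in grid], dtype=float)
    dx = np.array(
        [np.sum(deaths & (ages >= a) & (ages < a + 1)) for a in grid], dtype=float
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        lx_next = np.append(lx[1:], lx[-1])
        qx = np.where(lx > 0, 1.0 - lx_next / np.where(lx > 0, lx, 1.0), 0.0)
    return LifeTable(ages=grid, nx=nx, dx=dx, lx=lx, qx=qx)


def discrete_life_expectancy(lt: LifeTable, x: int = 0) -> float:
    """Discrete approximation sum_{i=x}^{omega} l_i / l_x."""
    if x < 0 or x > lt.max_age:
        raise ValueError(f"age {x} outside table range")
    i = int(np.searchsorted(lt.ages, x))
    if lt.ages[i] != x:
        raise ValueError(f"age {x} not on the table grid")
    lx = lt.lx[i]
    if lx <= 0:
        raise ValueError(f"cumulative survival at age {x} is zero")
    return float(np.sum(lt.lx[i:]) / lx)
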