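"""Reconstruct Siler mortality for wild populations from published data.

Wild survival is typically reported as stage-specific survival probabilities
over multi-year age intervals, as discrete life tables, or as digitized
cumulative-survival points.  Fitting a Siler model to these makes life
expectancy and lifespan equality comparable with posterior estimates from
census data.  Wild fits are point estimates: the published inputs carry no
uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .demography import LifeTable, discrete_life_expectancy, life_expectancy
from .siler import SilerParams, age_at_min_hazard, survival

__all__ = [
    "StageSurvivalData",
    "stage_survival_from_siler",
    "fit_stage_data",
    "fit_cumulative_survival",
    "verify_against_lifetable",
    "WildFitResult",
]


@dataclass(frozen=True)
class StageSurvivalData:
    """Stage-specific survival: (start_age, end_age, probability) triples,
    ordered and non-overlapping, plus an optional age at maturity."""

    stages: tuple
    maturity_age: float | None = None
    source: str = ""

    def __post_init__(self):
        stages = tuple((int(a), int(b), float(p)) for a, b, p in self.stages)
        object.__setattr__(self, "stages", stages)
        prev_end = -1
        for a, b, p in stages:
            if b <= a:
                raise ValueError(f"stage [{a}, {b}) is empty")
            if a < prev_end:
                raise ValueError("stages must be ordered and non-overlapping")
            if not (0 < p <= 1):
                raise ValueError(f"stage survival {p} outside (0, 1]")
            prev_end = b

    @classmethod
    def from_csv(cls, path, maturity_age=None, source="") -> "StageSurvivalData":
        df = pd.read_csv(path)
        stages = tuple(
            (int(r.start_age), int(r.end_age), float(r.survival))
            for r in df.itertuples()
        )
        if maturity_age is None and "maturity_age" in df.columns:
            maturity_age = float(df["maturity_age"].iloc[0])
        return cls(stages=stages, maturity_age=maturity_age, source=source)


def _stage_survival_from_lx(lx: np.ndarray, start: int, end: int) -> float:
    # weighted mean of age-specific survivals p_i = l_i / l_{i-1} over the
    # stage's integer ages i = start .. end-1, weighted by cumulative
    # survival l_i.  The i = 0 term has no l_{-1}; it is taken as the
    # first-year survival l_1 / l_0, which also keeps the constant-hazard
    # case exact (every term e^{-c}).
    idx = np.arange(start, end)
    li = lx[idx]
    ratio_num = np.where(idx == 0, lx[np.minimum(idx + 1, lx.size - 1)], li)
    ratio_den = np.where(idx == 0, lx[idx], lx[np.maximum(idx - 1, 0)])
    if np.any(li <= 0) or np.any(ratio_den <= 0):
        raise ValueError(f"cumulative survival underflows in stage [{start}, {end})")
    pi = ratio_num / ratio_den
    return float(np.sum(pi * li) / np.sum(li))


def stage_survival_from_siler(p: SilerParams, stage) -> float:
    """Stage survival over [x, x+n) implied by a Siler model.

    Weighted average of the one-year survival probabilities p_i = l_i/l_{i-1}
    with l_i = S(i), weighted by l_i, over the stage's integer ages.
    """
    start, end = int(stage[0]), int(stage[1])
    if start < 0 or end - start < 1:
        raise ValueError("stage must cover at least one year, ages >= 0")
    lx = survival(p, np.arange(0, end + 1, dtype=float))
    return _stage_survival_from_lx(lx, start, end)


@dataclass
class WildFitResult:
    params: SilerParams
    residuals: np.ndarray
    cost: float
    n_restarts_used: int = 0
    extras: dict = field(default_factory=dict)


_BOUNDS_LO = np.array([-8.0, np.log(1e-3), np.log(1e-6), -12.0, np.log(1e-3)])
_BOUNDS_HI = np.array([4.0, np.log(10.0), np.log(2.0), 2.0, np.log(2.0)])


def _unpack(z: np.ndarray) -> SilerParams:
    return SilerParams(z[0], np.exp(z[1]), np.exp(z[2]), z[3], np.exp(z[4]))


def _multistart_least_squares(residual_fn, rng, n_restarts=5):
    starts = [np.array([-1.0, 0.0, np.log(0.05), -5.0, np.log(0.1)])]
    for _ in range(n_restarts - 1):
        starts.append(_BOUNDS_LO + rng.uniform(size=5) * (_BOUNDS_HI - _BOUNDS_LO))
    best = None
    for z0 in starts:
        try:
            res = least_squares(
                residual_fn, z0, bounds=(_BOUNDS_LO, _BOUNDS_HI),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("wild-fit optimizer failed to converge from any start")
    return best


def fit_stage_data(
    data: StageSurvivalData,
    weight_maturity: float = 1.0,
    n_restarts: int = 5,
    seed: int = 0,
) -> WildFitResult:
    """Least-squares Siler fit to stage-specific survival probabilities.

    Minimizes the squared differences between observed and model stage
    survivals plus ``weight_maturity`` times the squared difference between
    the observed age at maturity and the model's age at minimum hazard.
    """
    n_constraints = len(data.stages) + (1 if data.maturity_age is not None else 0)
    if n_constraints < 3:
        warnings.warn(
            f"only {n_constraints} constraints for 5 parameters; fit is "
            "under-determined",
            UserWarning,
        )
    observed = np.array([p for _, _, p in data.stages])
    max_end = max(b for _, b, _ in data.stages)
    sqrt_w = np.sqrt(weight_maturity)

    def residual_fn(z):
        p = _unpack(z)
        lx = survival(p, np.arange(0, max_end + 1, dtype=float))
        lx = np.maximum(lx, 1e-300)
        model = np.array(
            [_stage_survival_from_lx(lx, a, b) for a, b, _ in data.stages]
        )
        res = model - observed
        if data.maturity_age is not None:
            res = np.append(res, sqrt_w * (age_at_min_hazard(p) - data.maturity_age))
        return res

    rng = np.random.default_rng(seed)
    best = _multistart_least_squares(residual_fn, rng, n_restarts)
    return WildFitResult(
        params=_unpack(best.x), residuals=best.fun, cost=float(best.cost),
        n_restarts_used=n_restarts,
    )


def fit_cumulative_survival(
    points, n_restarts: int = 5, seed: int = 0
) -> WildFitResult:
    """Least-squares Siler fit of S(x) to (age, cumulative survival) points."""
    pts = sorted((float(a), float(l)) for a, l in points)
    ages = np.array([a for a, _ in pts])
    lx = np.array([l for _, l in pts])
    if ages.size < 5:
        raise ValueError("need at least 5 cumulative-survival points")
    dup = pd.Series(lx).groupby(ages).nunique()
    if (dup > 1).any():
        raise ValueError("duplicated ages with inconsistent survival values")
    uniq_ages, idx = np.unique(ages, return_index=True)
    uniq_lx = lx[idx]
    if np.any(np.diff(uniq_lx) > 1e-12):
        raise ValueError("cumulative survival must be non-increasing in age")
    if np.any((lx <= 0) | (lx > 1)):
        raise ValueError("cumulative survival must lie in (0, 1]")

    def residual_fn(z):
        return survival(_unpack(z), ages) - lx

    rng = np.random.default_rng(seed)
    best = _multistart_least_squares(residual_fn, rng, n_restarts)
    return WildFitResult(
        params=_unpack(best.x), residuals=best.fun, cost=float(best.cost),
        n_restarts_used=n_restarts,
    )


def verify_against_lifetable(p: SilerParams, lt: LifeTable) -> dict:
    """Compare continuous e0/e1 of a fitted model against the discrete
    approximations from a raw life table; returns both and their differences."""
    if lt.max_age < 1 or lt.lx[0] <= 0:
        raise ValueError("life table does not overlap the model's age range")
    if lt.lx[1] <= 0:
        raise ValueError("life table has no survival beyond age 1")
    report = {}
    for age in (0, 1):
        cont = life_expectancy(p, age)
        disc = discrete_life_expectancy(lt, age)
        report[f"e{age}_continuous"] = cont
        report[f"e{age}_discrete"] = disc
        report[f"e{age}_difference"] = cont - disc
    return report
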