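"""Bayesian Siler estimation from left-truncated, right-censored census data.

Metropolis-Hastings MCMC over the five Siler parameters, optional
proportional-hazards coefficients for provenance, and latent birth times for
individuals whose birth date is only known up to an interval.  Chains are
run sequentially with per-chain seeds spawned from a master seed, so runs
are bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dates import to_decimal_year
from .siler import SilerParams, upper_support

__all__ = [
    "CensusRecord",
    "MCMCConfig",
    "PriorSpec",
    "PosteriorChains",
    "record_loglik",
    "cohort_loglik",
    "run_mcmc",
    "psrf",
    "posterior_functionals",
    "FunctionalDraws",
    "records_to_frame",
    "load_census",
]

# half-day offset for same-day entry/exit so no interval has zero length
_HALF_DAY = 0.5 / 365.25

PROVENANCE_LEVELS = ("captive_born", "wild_born", "not_reported")
REFERENCE_PROVENANCE = "captive_born"


@dataclass(frozen=True)
class CensusRecord:
    """One individual's observation window, event type and covariates.

    ``birth_date`` may be None, in which case ``birth_min``/``birth_max``
    bound the (latent) birth time.  Dates are anything pandas parses.
    """

    id: str
    sex: str
    provenance: str
    entry_date: object
    depart_date: object
    depart_type: str
    birth_date: object = None
    birth_min: object = None
    birth_max: object = None

    def __post_init__(self):
        if self.depart_type not in ("death", "censored"):
            raise ValueError(f"{self.id}: depart_type must be death|censored")
        if self.birth_date is None and (self.birth_min is None or self.birth_max is None):
            raise ValueError(f"{self.id}: need birth_date or birth_min/birth_max")
        entry = to_decimal_year(self.entry_date)
        depart = to_decimal_year(self.depart_date)
        if depart < entry:
            raise ValueError(f"{self.id}: depart_date before entry_date")
        b_hi = to_decimal_year(
            self.birth_date if self.birth_date is not None else self.birth_min
        )
        if b_hi > entry + 1e-9:
            raise ValueError(f"{self.id}: birth after entry_date")


def records_to_frame(records) -> pd.DataFrame:
    """Census records (dataclasses or a DataFrame) -> canonical DataFrame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "id": [r.id for r in records],
                "sex": [r.sex for r in records],
                "provenance": [r.provenance for r in records],
                "birth_date": [r.birth_date for r in records],
                "birth_min": [r.birth_min for r in records],
                "birth_max": [r.birth_max for r in records],
                "entry_date": [r.entry_date for r in records],
                "depart_date": [r.depart_date for r in records],
                "depart_type": [r.depart_type for r in records],
            }
        )
    for col in ("birth_date", "birth_min", "birth_max"):
        if col not in df.columns:
            df[col] = pd.NA
        else:
            # empty strings in CSV round-trips mean "missing"
            df[col] = df[col].replace("", pd.NA)
    return df


def load_census(path) -> pd.DataFrame:
    """Read the census CSV schema (ISO-8601 dates, empty birth_date means
    the interval columns are required)."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "sex", "provenance", "entry_date", "depart_date", "depart_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"census file missing columns: {sorted(missing)}")
    return records_to_frame(df)


@dataclass
class _Cohort:
    """Numeric arrays extracted from census records for likelihood work."""

    ids: np.ndarray
    birth: np.ndarray        # current decimal-year birth (latent for unknown)
    birth_lo: np.ndarray
    birth_hi: np.ndarray
    unknown: np.ndarray      # bool mask of interval births
    entry: np.ndarray
    depart: np.ndarray
    death: np.ndarray        # bool
    prov_code: np.ndarray    # 0 = reference level
    prov_levels: tuple

    @property
    def n(self) -> int:
        return self.ids.size

    def ages(self):
        """(x, x_t) given current birth times, with half-day floor."""
        x = self.depart - self.birth
        xt = np.maximum(self.entry - self.birth, 0.0)
        x = np.maximum(x, xt + _HALF_DAY)
        return x, xt


def _build_cohort(records) -> _Cohort:
    df = records_to_frame(records)
    n = len(df)
    if n == 0:
        raise ValueError("empty cohort")
    entry = to_decimal_year(df["entry_date"])
    depart = to_decimal_year(df["depart_date"])
    has_birth = df["birth_date"].notna().to_numpy()
    birth = np.full(n, np.nan)
    birth_lo = np.full(n, np.nan)
    birth_hi = np.full(n, np.nan)
    if has_birth.any():
        birth[has_birth] = to_decimal_year(df.loc[has_birth, "birth_date"])
        birth_lo[has_birth] = birth[has_birth]
        birth_hi[has_birth] = birth[has_birth]
    unknown = ~has_birth
    if unknown.any():
        if df.loc[unknown, ["birth_min", "birth_max"]].isna().to_numpy().any():
            bad = df.loc[unknown & df["birth_min"].isna(), "id"]
            raise ValueError(f"records with neither birth_date nor interval: {list(bad)[:5]}")
        lo = to_decimal_year(df.loc[unknown, "birth_min"])
        hi = to_decimal_year(df.loc[unknown, "birth_max"])
        hi = np.minimum(hi, np.asarray(entry)[unknown])  # birth cannot follow entry
        if np.any(lo > hi + 1e-9):
            raise ValueError("birth_min after min(birth_max, entry_date)")
        birth_lo[unknown] = lo
        birth_hi[unknown] = hi
        birth[unknown] = 0.5 * (lo + hi)
    if np.any(birth[has_birth] > np.asarray(entry)[has_birth] + 1e-9):
        raise ValueError("birth_date after entry_date")
    if np.any(np.asarray(depart) < np.asarray(entry)):
        raise ValueError("depart_date before entry_date")
    levels = tuple(
        [REFERENCE_PROVENANCE]
        + sorted(set(df["provenance"].astype(str)) - {REFERENCE_PROVENANCE})
    )
    code = {lev: i for i, lev in enumerate(levels)}
    prov = df["provenance"].astype(str).map(code).to_numpy()
    return _Cohort(
        ids=df["id"].to_numpy(),
        birth=birth,
        birth_lo=birth_lo,
        birth_hi=birth_hi,
        unknown=unknown,
        entry=np.asarray(entry, dtype=float),
        depart=np.asarray(depart, dtype=float),
        death=(df["depart_type"].astype(str) == "death").to_numpy(),
        prov_code=prov,
        prov_levels=levels,
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _loglik_terms_np(theta, x, xt, death, log_eg, eg):
    a0, a1, c, b0, b1 = theta
    if a1 <= 0 or b1 <= 0 or c < 0:
        return np.full_like(x, -np.inf)
    ea0, eb0 = math.exp(a0), math.exp(b0)
    u_x = ea0 / a1 * (1.0 - np.exp(-a1 * x)) + c * x + eb0 / b1 * np.expm1(b1 * x)
    u_t = ea0 / a1 * (1.0 - np.exp(-a1 * xt)) + c * xt + eb0 / b1 * np.expm1(b1 * xt)
    ll = -eg * (u_x - u_t)
    mu = np.exp(a0 - a1 * x) + c + np.exp(b0 + b1 * x)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ll = np.where(death, ll + log_eg + np.log(mu), ll)
    return np.where(np.isfinite(ll), ll, -np.inf)


try:  # numba speeds the MCMC inner loop ~10x; numpy fallback is equivalent
    from numba import njit

    @njit(cache=True)
    def _loglik_sum_nb(a0, a1, c, b0, b1, x, xt, death, log_eg, eg):  # pragma: no cover
        if a1 <= 0 or b1 <= 0 or c < 0:
            return -np.inf
        ea0 = math.exp(a0)
        eb0 = math.exp(b0)
        total = 0.0
        for i in range(x.size):
            ux = ea0 / a1 * (1.0 - math.exp(-a1 * x[i])) + c * x[i] + eb0 / b1 * (
                math.exp(b1 * x[i]) - 1.0
            )
            ut = ea0 / a1 * (1.0 - math.exp(-a1 * xt[i])) + c * xt[i] + eb0 / b1 * (
                math.exp(b1 * xt[i]) - 1.0
            )
            ll = -eg[i] * (ux - ut)
            if death[i]:
                mu = math.exp(a0 - a1 * x[i]) + c + math.exp(b0 + b1 * x[i])
                ll += log_eg[i] + math.log(mu)
            if not math.isfinite(ll):
                return -np.inf
            total += ll
        if not math.isfinite(total):
            return -np.inf
        return total

    def _loglik_sum(theta, x, xt, death, log_eg, eg):
        a0, a1, c, b0, b1 = theta
        return _loglik_sum_nb(a0, a1, c, b0, b1, x, xt, death, log_eg, eg)

except ImportError:  # pragma: no cover

    def _loglik_sum(theta, x, xt, death, log_eg, eg):
        return float(np.sum(_loglik_terms_np(theta, x, xt, death, log_eg, eg)))


def record_loglik(x: float, xt: float, is_death: bool, p: SilerParams) -> float:
    """Log-likelihood of one record: log f(x) - log S(xt) for deaths,
    log S(x) - log S(xt) for censored observations."""
    if xt < 0 or x < xt:
        raise ValueError("require 0 <= x_t <= x")
    arr = _loglik_terms_np(
        p.as_array(),
        np.array([float(x)]),
        np.array([float(xt)]),
        np.array([bool(is_death)]),
        np.zeros(1),
        np.ones(1),
    )
    return float(arr[0])


def cohort_loglik(records, p: SilerParams, gamma: dict | None = None) -> float:
    """Summed log-likelihood over a cohort, optionally with proportional
    hazards by provenance: level z multiplies the hazard by exp(gamma_z)
    (reference level captive_born has coefficient 0)."""
    cohort = records if isinstance(records, _Cohort) else _build_cohort(records)
    x, xt = cohort.ages()
    log_eg, eg = _gamma_arrays(cohort, gamma)
    terms = _loglik_terms_np(p.as_array(), x, xt, cohort.death, log_eg, eg)
    if not np.isfinite(terms).all():
        bad = cohort.ids[~np.isfinite(terms)]
        raise ValueError(f"non-finite likelihood for records: {list(bad)[:5]}")
    return float(terms.sum())


def _gamma_arrays(cohort: _Cohort, gamma: dict | None):
    if not gamma:
        z = np.zeros(cohort.n)
        return z, np.ones(cohort.n)
    g = np.zeros(len(cohort.prov_levels))
    for lev, val in gamma.items():
        if lev == REFERENCE_PROVENANCE:
            if val != 0:
                raise ValueError("reference provenance must have coefficient 0")
            continue
        if lev not in cohort.prov_levels:
            raise ValueError(f"unknown provenance level {lev!r}")
        g[cohort.prov_levels.index(lev)] = val
    log_eg = g[cohort.prov_code]
    return log_eg, np.exp(log_eg)


# ---------------------------------------------------------------------------
# priors and MCMC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative defaults: Normal(0, sd) on a0, b0 and gamma;
    half-Normal(sd) on the positive parameters a1, c, b1.  The birth-time
    prior for interval births is Uniform over the interval."""

    a0_sd: float = 10.0
    b0_sd: float = 10.0
    rate_sd: float = 1.0
    gamma_sd: float = 10.0

    def log_prior(self, theta: np.ndarray, gammas: np.ndarray | None = None) -> float:
        a0, a1, c, b0, b1 = theta
        if a1 <= 0 or b1 <= 0 or c < 0:
            return -np.inf
        lp = -0.5 * (a0 / self.a0_sd) ** 2 - 0.5 * (b0 / self.b0_sd) ** 2
        lp -= 0.5 * (a1**2 + c**2 + b1**2) / self.rate_sd**2
        if gammas is not None and gammas.size:
            lp -= 0.5 * float(np.sum((gammas / self.gamma_sd) ** 2))
        return lp


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults mirror the reference protocol of eight
    chains of 50 000 iterations, 10 000 burn-in, thinning every 20."""

    n_chains: int = 8
    n_iter: int = 50_000
    burn_in: int = 10_000
    thinning: int = 20
    seed: int = 0
    proposal_scales: tuple = (0.2, 0.1, 0.02, 0.2, 0.02)
    gamma_scale: float = 0.1
    adapt_window: int = 50
    target_acceptance: float = 0.25
    fit_provenance: bool = False

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")


@dataclass
class PosteriorChains:
    """Post-burn-in thinned draws, one block per chain."""

    param_names: list
    draws: np.ndarray                 # (n_chains, n_kept, n_params)
    birth_draws: np.ndarray | None    # (n_chains, n_kept, n_unknown) or None
    unknown_ids: np.ndarray | None
    acceptance: pd.DataFrame          # per chain x parameter acceptance rate
    prov_levels: tuple = ()
    config: MCMCConfig | None = None

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def flat(self, name: str) -> np.ndarray:
        j = self.param_names.index(name)
        return self.draws[:, :, j].reshape(-1)

    def flat_params(self) -> np.ndarray:
        """All retained draws of the five Siler parameters, stacked."""
        cols = [self.param_names.index(k) for k in ("a0", "a1", "c", "b0", "b1")]
        return self.draws[:, :, cols].reshape(-1, 5)

    def by_param(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.param_names.index(name)]

    def psrf_all(self) -> dict:
        return {name: psrf(self.by_param(name)) for name in self.param_names}

    def posterior_mean_births(self) -> pd.Series:
        if self.birth_draws is None:
            raise ValueError("no latent birth times were sampled")
        means = self.birth_draws.reshape(-1, self.birth_draws.shape[-1]).mean(axis=0)
        return pd.Series(means, index=self.unknown_ids, name="posterior_mean_birth")

    def to_frame(self) -> pd.DataFrame:
        n_chains, n_kept, _ = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(-1, len(self.param_names)),
                          columns=self.param_names)
        df.insert(0, "chain", np.repeat(np.arange(n_chains), n_kept))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.param_names:
            flat = self.flat(name)
            lo, med, hi = np.quantile(flat, [0.025, 0.5, 0.975])
            rows.append(
                dict(parameter=name, median=med, lower95=lo, upper95=hi,
                     rhat=psrf(self.by_param(name)))
            )
        return pd.DataFrame(rows)


def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one scalar.

    ``chains`` has shape (n_chains, n_draws).  R-hat compares the
    between-chain and within-chain variances; values near 1 indicate the
    chains have mixed.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    var_plus = (n - 1) / n * w + b_over_n
    # identical chains give (n-1)/n < 1; clip, as the diagnostic floor is 1
    return float(max(np.sqrt(var_plus / w), 1.0))


def run_mcmc(
    records,
    config: MCMCConfig | None = None,
    prior: PriorSpec | None = None,
) -> PosteriorChains:
    """Metropolis-Hastings over Siler parameters (+ optional provenance
    coefficients) with latent birth-time imputation for interval births.

    Per-parameter Gaussian random-walk proposals with scale adaptation
    during burn-in toward ~25% acceptance; latent births use independence
    proposals uniform over each record's interval.  Two runs with the same
    config (seed included) produce bit-identical chains.
    """
    config = config or MCMCConfig()
    prior = prior or PriorSpec()
    cohort = records if isinstance(records, _Cohort) else _build_cohort(records)
    if cohort.n < 100:
        warnings.warn(
            f"only {cohort.n} individuals; at least 100 recommended for "
            "unbiased mortality estimates",
            UserWarning,
        )

    n_gamma = len(cohort.prov_levels) - 1 if config.fit_provenance else 0
    param_names = ["a0", "a1", "c", "b0", "b1"] + [
        f"gamma_{lev}" for lev in cohort.prov_levels[1 : 1 + n_gamma]
    ]
    scales0 = np.array(list(config.proposal_scales) + [config.gamma_scale] * n_gamma)
    n_par = 5 + n_gamma

    unknown_idx = np.flatnonzero(cohort.unknown)
    n_unknown = unknown_idx.size
    kept_iters = range(config.burn_in, config.n_iter, config.thinning)
    n_kept = len(kept_iters)

    theta_init = _mle_theta(cohort, prior)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws = np.empty((config.n_chains, n_kept, n_par))
    all_births = (
        np.empty((config.n_chains, n_kept, n_unknown)) if n_unknown else None
    )
    acc_rows = []

    for ci in range(config.n_chains):
        rng = np.random.default_rng(seeds[ci])
        draws, births, acc = _run_chain(
            cohort, config, prior, rng, scales0, n_gamma, unknown_idx, n_kept,
            theta_init,
        )
        all_draws[ci] = draws
        if all_births is not None:
            all_births[ci] = births
        acc_rows.append(acc)

    acceptance = pd.DataFrame(acc_rows, columns=param_names + (["birth"] if n_unknown else []))
    acceptance.index.name = "chain"
    return PosteriorChains(
        param_names=param_names,
        draws=all_draws,
        birth_draws=all_births,
        unknown_ids=cohort.ids[unknown_idx] if n_unknown else None,
        acceptance=acceptance,
        prov_levels=cohort.prov_levels,
        config=config,
    )


def _mle_theta(cohort: _Cohort, prior: PriorSpec) -> np.ndarray:
    """Posterior-mode starting point (latent births at interval midpoints).

    Chains are initialized here with per-chain jitter; the mode search runs
    on a log scale for the positive parameters and is deterministic.
    """
    from scipy.optimize import minimize

    x, xt = cohort.ages()
    log_eg, eg = np.zeros(cohort.n), np.ones(cohort.n)

    def negative_log_posterior(z):
        theta = np.array([z[0], np.exp(z[1]), np.exp(z[2]), z[3], np.exp(z[4])])
        lp = _loglik_sum(theta, x, xt, cohort.death, log_eg, eg)
        lp += prior.log_prior(theta)
        return -lp if np.isfinite(lp) else 1e12

    z0 = np.array([-1.0, 0.0, np.log(0.05), -5.0, np.log(0.1)])
    res = minimize(
        negative_log_posterior, z0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-6},
    )
    z = res.x if np.isfinite(res.fun) else z0
    return np.array([z[0], np.exp(z[1]), np.exp(z[2]), z[3], np.exp(z[4])])


def _run_chain(cohort, config, prior, rng, scales0, n_gamma, unknown_idx, n_kept,
               theta_init):
    n_par = 5 + n_gamma
    scales = scales0.copy()
    # jittered start around the posterior mode; positive parameters jittered
    # multiplicatively to respect their constraints
    jitter = rng.normal(0.0, 0.15, size=5)
    theta = np.array([
        theta_init[0] + jitter[0],
        theta_init[1] * math.exp(jitter[1]),
        max(theta_init[2], 1e-4) * math.exp(jitter[2]),
        theta_init[3] + jitter[3],
        theta_init[4] * math.exp(jitter[4]),
    ])
    gammas = rng.normal(0.0, 0.1, size=n_gamma)
    birth = cohort.birth.copy()
    if unknown_idx.size:
        lo, hi = cohort.birth_lo[unknown_idx], cohort.birth_hi[unknown_idx]
        birth[unknown_idx] = lo + rng.uniform(size=unknown_idx.size) * (hi - lo)

    x = np.maximum(cohort.depart - birth, np.maximum(cohort.entry - birth, 0.0) + _HALF_DAY)
    xt = np.maximum(cohort.entry - birth, 0.0)
    death = cohort.death

    def gamma_arrays(g):
        if n_gamma == 0:
            return np.zeros(cohort.n), np.ones(cohort.n)
        full = np.concatenate([[0.0], g, np.zeros(len(cohort.prov_levels) - 1 - n_gamma)])
        log_eg = full[cohort.prov_code]
        return log_eg, np.exp(log_eg)

    log_eg, eg = gamma_arrays(gammas)

    # per-parameter random walk runs in a centered parameterization that
    # decorrelates the level/rate pairs: the juvenile term is anchored at
    # age 1 and the senescent (Gompertz) term at the mean observed age,
    # i.e. zc = (a0 - a1*xa, a1, c, b0 + b1*xc, b1)
    x_anchor_juv = 1.0
    x_anchor_sen = float(np.mean(x))

    def to_natural(zc):
        return np.array([
            zc[0] + zc[1] * x_anchor_juv,
            zc[1],
            zc[2],
            zc[3] - zc[4] * x_anchor_sen,
            zc[4],
        ])

    def to_centered(th):
        return np.array([
            th[0] - th[1] * x_anchor_juv,
            th[1],
            th[2],
            th[3] + th[4] * x_anchor_sen,
            th[4],
        ])

    zc = to_centered(theta)
    cur_ll = _loglik_sum(theta, x, xt, death, log_eg, eg)
    cur_lp = cur_ll + prior.log_prior(theta, gammas)

    draws = np.empty((n_kept, n_par))
    births_out = np.empty((n_kept, unknown_idx.size)) if unknown_idx.size else None
    acc_count = np.zeros(n_par)
    win_count = np.zeros(n_par)
    birth_acc = 0
    birth_tries = 0
    kept = 0

    for it in range(config.n_iter):
        for j in range(n_par):
            step = rng.normal() * scales[j]
            if j < 5:
                prop_zc = zc.copy()
                prop_zc[j] += step
                prop_theta = to_natural(prop_zc)
                prop_gammas = gammas
            else:
                prop_zc = zc
                prop_theta = theta
                prop_gammas = gammas.copy()
                prop_gammas[j - 5] += step
            lprior = prior.log_prior(prop_theta, prop_gammas)
            if np.isfinite(lprior):
                if j >= 5:
                    plog_eg, peg = gamma_arrays(prop_gammas)
                else:
                    plog_eg, peg = log_eg, eg
                ll = _loglik_sum(prop_theta, x, xt, death, plog_eg, peg)
                lp = ll + lprior
                if np.log(rng.uniform()) < lp - cur_lp:
                    theta, gammas, zc = prop_theta, prop_gammas, prop_zc
                    if j >= 5:
                        log_eg, eg = plog_eg, peg
                    cur_ll, cur_lp = ll, lp
                    acc_count[j] += 1
                    win_count[j] += 1
            else:
                rng.uniform()  # keep the random stream aligned

        if unknown_idx.size:
            lo, hi = cohort.birth_lo[unknown_idx], cohort.birth_hi[unknown_idx]
            prop_b = lo + rng.uniform(size=unknown_idx.size) * (hi - lo)
            xu, xtu = x[unknown_idx], xt[unknown_idx]
            cur_terms = _loglik_terms_np(
                theta, xu, xtu, death[unknown_idx], log_eg[unknown_idx], eg[unknown_idx]
            )
            pxt = np.maximum(cohort.entry[unknown_idx] - prop_b, 0.0)
            px = np.maximum(cohort.depart[unknown_idx] - prop_b, pxt + _HALF_DAY)
            prop_terms = _loglik_terms_np(
                theta, px, pxt, death[unknown_idx], log_eg[unknown_idx], eg[unknown_idx]
            )
            accept = np.log(rng.uniform(size=unknown_idx.size)) < prop_terms - cur_terms
            if accept.any():
                sel = unknown_idx[accept]
                birth[sel] = prop_b[accept]
                x[sel] = px[accept]
                xt[sel] = pxt[accept]
                delta = float(np.sum(prop_terms[accept] - cur_terms[accept]))
                cur_ll += delta
                cur_lp += delta
            birth_acc += int(accept.sum())
            birth_tries += unknown_idx.size

        if it < config.burn_in and (it + 1) % config.adapt_window == 0:
            rate = win_count / config.adapt_window
            scales *= np.exp(rate - config.target_acceptance)
            win_count[:] = 0.0

        if it == config.burn_in - 1 and np.any(acc_count == 0):
            dead = [i for i, a in enumerate(acc_count) if a == 0]
            raise RuntimeError(
                f"no accepted proposals for parameter index(es) {dead} during "
                "burn-in; rescale proposal_scales"
            )

        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            draws[kept, :5] = theta
            if n_gamma:
                draws[kept, 5:] = gammas
            if births_out is not None:
                births_out[kept] = birth[unknown_idx]
            kept += 1

    rates = list(acc_count / config.n_iter)
    if birth_tries:
        rates.append(birth_acc / birth_tries)
    return draws, births_out, rates


# ---------------------------------------------------------------------------
# posterior functionals
# ---------------------------------------------------------------------------

@dataclass
class FunctionalDraws:
    """Posterior draws of life expectancy, lifespan equality and first-year
    mortality, mapped draw-by-draw through the demographic functionals."""

    ages: list
    life_expectancy: dict = field(default_factory=dict)   # age -> draws
    lifespan_equality: dict = field(default_factory=dict)  # age -> draws
    first_year_mortality: np.ndarray | None = None
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric, per_age in (
            ("life_expectancy", self.life_expectancy),
            ("lifespan_equality", self.lifespan_equality),
        ):
            for age, d in per_age.items():
                lo, med, hi = np.quantile(d, [0.025, 0.5, 0.975])
                rows.append(dict(metric=metric, age=age, median=med, lower95=lo, upper95=hi))
        lo, med, hi = np.quantile(self.first_year_mortality, [0.025, 0.5, 0.975])
        rows.append(dict(metric="first_year_mortality", age=1, median=med,
                         lower95=lo, upper95=hi))
        return pd.DataFrame(rows)


def posterior_functionals(
    chains: PosteriorChains | np.ndarray,
    ages=(0.0, 1.0),
    rhat_threshold: float = 1.05,
    grid_step: float = 0.05,
) -> FunctionalDraws:
    """Map every retained parameter draw to e_x, eps_x at the requested ages
    and q1, using a shared trapezoid grid (step ``grid_step`` years, upper
    limit where every draw's survival < 1e-12).  Draws yielding non-finite
    functionals are dropped and counted."""
    if isinstance(chains, PosteriorChains):
        rhats = {k: chains.psrf_all()[k] for k in ("a0", "a1", "c", "b0", "b1")}
        worst = max(rhats.values())
        if worst > rhat_threshold:
            warnings.warn(
                f"max R-hat {worst:.3f} exceeds {rhat_threshold}; chains may "
                "not have converged",
                UserWarning,
            )
        params = chains.flat_params()
    else:
        params = np.asarray(chains, dtype=float).reshape(-1, 5)

    ages = [float(a) for a in ages]
    m = params.shape[0]
    a0 = params[:, 0:1]
    a1 = params[:, 1:2]
    c = params[:, 2:3]
    b0 = params[:, 3:4]
    b1 = params[:, 4:5]

    xmax = max(
        upper_support(SilerParams.from_array(params[i]))
        for i in range(0, m, max(1, m // 64))
    )
    xmax = max(xmax, max(ages) + 1.0, 2.0)
    grid = np.arange(0.0, xmax + grid_step, grid_step)

    with np.errstate(over="ignore", invalid="ignore"):
        u = (
            np.exp(a0) / a1 * (1.0 - np.exp(-a1 * grid))
            + c * grid
            + np.exp(b0) / b1 * np.expm1(b1 * grid)
        )
        s = np.exp(-u)

    ok = np.isfinite(s).all(axis=1)
    n_failed = int(m - ok.sum())
    s, u = s[ok], u[ok]

    out = FunctionalDraws(ages=ages)
    errstate = np.errstate(over="ignore", invalid="ignore", divide="ignore")
    errstate.__enter__()
    for age in ages:
        i = int(round(age / grid_step))
        if abs(grid[i] - age) > 1e-9:
            i = int(np.argmin(np.abs(grid - age)))
        sx = s[:, i]
        ex = np.trapezoid(s[:, i:], grid[i:], axis=1) / sx
        # where survival has underflowed to 0, u may be inf; the integrand
        # s * (u - u_x) is 0 there, not nan
        integrand = np.where(
            s[:, i:] > 0.0, s[:, i:] * (u[:, i:] - u[:, i : i + 1]), 0.0
        )
        hx = np.trapezoid(integrand, grid[i:], axis=1) / sx / ex
        good = np.isfinite(ex) & np.isfinite(hx) & (hx > 0)
        n_failed += int((~good).sum())
        out.life_expectancy[age] = ex[good]
        out.lifespan_equality[age] = -np.log(hx[good])
    errstate.__exit__(None, None, None)
    i1 = int(round(1.0 / grid_step))
    out.first_year_mortality = 1.0 - s[:, i1]
    out.n_failed = n_failed
    return out
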