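"""End-to-end orchestration: data preparation, per-stratum inference,
posterior functionals, period/sex comparisons and wild-vs-census placement.

Data preparation follows the analysis rules: unknown-sex records are
excluded, then the 1% longest-lived individuals are trimmed (jointly across
periods, before stratification), and each remaining individual is assigned
to the single period containing its entry date.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._dates import to_decimal_year
from .demography import lifespan_equality, life_expectancy
from .inference import (
    MCMCConfig,
    PriorSpec,
    load_census,
    posterior_functionals,
    records_to_frame,
    run_mcmc,
)
from .kl import compare_groups
from .siler import first_year_mortality
from .wildfit import StageSurvivalData, fit_cumulative_survival, fit_stage_data

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "prepare_data",
    "quantile_of_point",
    "run_full_analysis",
]

log = logging.getLogger("zoodemog")

VALID_SEXES = ("F", "M")
MIN_STRATUM_SIZE = 100


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for a full run."""

    period_breaks: tuple
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    ages: tuple = (0.0, 1.0)
    maturity_age: float | None = None
    trim_fraction: float = 0.01
    split_at_boundaries: bool = False  # config switch; default keeps whole careers
    rhat_threshold: float = 1.05

    def report_ages(self) -> tuple:
        ages = list(self.ages)
        if self.maturity_age is not None and self.maturity_age not in ages:
            ages.append(float(self.maturity_age))
        return tuple(ages)


def prepare_data(records, period_breaks, trim_fraction: float = 0.01):
    """Apply the exclusion rules and stratify by sex and period.

    Returns ``(strata, audit)``: a dict mapping (sex, period label) to a
    census DataFrame, and an audit of exclusions whose counts sum back to
    the input count.  Ties in the 1% longest-lived trim are broken by the
    earliest departure date.
    """
    df = records_to_frame(records).reset_index(drop=True)
    n_input = len(df)
    sex_ok = df["sex"].isin(VALID_SEXES)
    n_unknown_sex = int((~sex_ok).sum())
    df = df[sex_ok].copy()

    # observed lifespan: departure minus (midpoint) birth; used only to rank
    # for the trim rule
    birth_mid = np.where(
        df["birth_date"].notna() & (df["birth_date"].astype(str) != ""),
        to_decimal_year(df["birth_date"].where(df["birth_date"].astype(str) != "", None)),
        0.5
        * (
            to_decimal_year(df["birth_min"].where(df["birth_min"].astype(str) != "", None))
            + to_decimal_year(df["birth_max"].where(df["birth_max"].astype(str) != "", None))
        ),
    )
    depart = to_decimal_year(df["depart_date"])
    lifespan = depart - birth_mid
    n_trim = int(round(trim_fraction * len(df)))
    if n_trim > 0:
        order = np.lexsort((np.asarray(depart), -lifespan))
        trim_idx = df.index.to_numpy()[order[:n_trim]]
        df = df.drop(index=trim_idx)
    audit = {
        "input": n_input,
        "excluded_unknown_sex": n_unknown_sex,
        "excluded_longest_lived": n_trim,
        "retained": len(df),
        "warnings": [],
    }

    edges = np.asarray(period_breaks, dtype=float)
    entry = np.asarray(to_decimal_year(df["entry_date"]))
    lo = min(entry.min(), edges.min()) - 1 if len(df) else 0
    hi = max(entry.max(), edges.max()) + 1 if len(df) else 1
    full_edges = np.array([lo, *edges, hi])
    labels = [
        f"{'pre' if i == 0 else int(full_edges[i])}-{int(full_edges[i + 1])}"
        for i in range(len(full_edges) - 1)
    ]
    idx = np.clip(np.searchsorted(full_edges, entry, side="right") - 1, 0,
                  len(labels) - 1)
    df = df.assign(period=[labels[i] for i in idx])

    strata = {}
    for (sex, period), grp in df.groupby(["sex", "period"], sort=True):
        strata[(sex, period)] = grp.drop(columns="period").reset_index(drop=True)
        if len(grp) < MIN_STRATUM_SIZE:
            audit["warnings"].append(
                f"stratum (sex={sex}, period={period}) has {len(grp)} "
                f"individuals (< {MIN_STRATUM_SIZE})"
            )
    audit["strata_counts"] = {f"{s}|{p}": len(g) for (s, p), g in strata.items()}
    audit["period_labels"] = labels
    return strata, audit


def quantile_of_point(posterior_draws, point_value: float) -> float:
    """Empirical CDF of the posterior draws evaluated at a point estimate."""
    draws = np.asarray(posterior_draws, dtype=float).ravel()
    if draws.size < 200:
        raise ValueError("need at least 200 draws")
    return float(np.mean(draws <= point_value))


@dataclass
class AnalysisReport:
    """Full-run output: per-stratum posterior summaries, convergence
    diagnostics, comparison tables, wild placements and the data-prep audit."""

    audit: dict
    stratum_summaries: dict          # (sex, period) -> DataFrame
    rhat: dict                       # (sex, period) -> {param: rhat}
    acceptance: dict                 # (sex, period) -> mean acceptance per param
    kl_tables: dict                  # name -> DataFrame
    wild: list = field(default_factory=list)
    functional_draws: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def key(k):
            return "|".join(k) if isinstance(k, tuple) else k

        return {
            "audit": self.audit,
            "stratum_summaries": {
                key(k): v.to_dict(orient="records")
                for k, v in self.stratum_summaries.items()
            },
            "rhat": {key(k): v for k, v in self.rhat.items()},
            "acceptance": {key(k): v for k, v in self.acceptance.items()},
            "kl_tables": {k: v.to_dict(orient="records") for k, v in self.kl_tables.items()},
            "wild": self.wild,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_full_analysis(census, config: AnalysisConfig, wild_inputs=None) -> AnalysisReport:
    """Prepare -> per-stratum MCMC -> functionals -> comparisons -> report.

    ``census`` is a DataFrame or a path to the census CSV.  ``wild_inputs``
    is an optional list of dicts with keys ``label``, ``sex`` and either
    ``stage_data`` (StageSurvivalData) or ``cumulative`` (age, lx points).
    Strata that fail the convergence threshold are flagged in the report,
    never dropped silently.
    """
    if not isinstance(census, pd.DataFrame):
        census = load_census(census)
    strata, audit = prepare_data(census, config.period_breaks, config.trim_fraction)
    ages = config.report_ages()

    summaries, rhats, acc, draws_by_stratum = {}, {}, {}, {}
    for i, ((sex, period), grp) in enumerate(sorted(strata.items())):
        log.info("fitting stratum sex=%s period=%s (n=%d)", sex, period, len(grp))
        cfg = MCMCConfig(**{**asdict(config.mcmc), "seed": config.mcmc.seed + 1000 * i})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            chains = run_mcmc(grp, cfg, config.prior)
            fd = posterior_functionals(chains, ages=ages,
                                       rhat_threshold=config.rhat_threshold)
        rhats[(sex, period)] = chains.psrf_all()
        acc[(sex, period)] = chains.acceptance.mean(axis=0).to_dict()
        log.info(
            "stratum sex=%s period=%s: mean acceptance %s",
            sex, period,
            {k: round(v, 3) for k, v in acc[(sex, period)].items()},
        )
        summaries[(sex, period)] = fd.summary()
        draws_by_stratum[(sex, period)] = fd

    audit["converged"] = {
        f"{s}|{p}": bool(max(r[k] for k in ("a0", "a1", "c", "b0", "b1"))
                         <= config.rhat_threshold)
        for (s, p), r in rhats.items()
    }

    # chronological period order comes from prepare_data, not label sort
    periods = [p for p in audit["period_labels"] if any(q == p for _, q in strata)]
    latest = periods[-1]
    kl_tables = {}
    for sex in sorted({s for s, _ in strata}):
        groups = {
            p: _functional_map(draws_by_stratum[(sex, p)], ages)
            for (s, p) in strata
            if s == sex
        }
        if len(groups) >= 2 and latest in groups:
            kl_tables[f"periods_{sex}"] = compare_groups(groups, reference=latest)
    sex_groups = {
        s: _functional_map(draws_by_stratum[(s, latest)], ages)
        for (s, p) in strata
        if p == latest
    }
    if len(sex_groups) >= 2:
        kl_tables["sexes_latest_period"] = compare_groups(sex_groups, reference="F")

    wild_rows = []
    for item in wild_inputs or []:
        if "stage_data" in item:
            fit = fit_stage_data(item["stage_data"])
        elif "cumulative" in item:
            fit = fit_cumulative_survival(item["cumulative"])
        else:
            raise ValueError("wild input needs 'stage_data' or 'cumulative'")
        p = fit.params
        row = {
            "label": item.get("label", "wild"),
            "sex": item.get("sex", "F"),
            "params": asdict(p),
            "e1": life_expectancy(p, 1.0),
            "eps1": lifespan_equality(p, 1.0),
            "q1": first_year_mortality(p),
        }
        key = (row["sex"], latest)
        if key in draws_by_stratum:
            fd = draws_by_stratum[key]
            row["quantile_e1"] = quantile_of_point(fd.life_expectancy[1.0], row["e1"])
            row["quantile_eps1"] = quantile_of_point(
                fd.lifespan_equality[1.0], row["eps1"]
            )
        wild_rows.append(row)

    return AnalysisReport(
        audit=audit,
        stratum_summaries=summaries,
        rhat=rhats,
        acceptance=acc,
        kl_tables=kl_tables,
        wild=wild_rows,
        functional_draws=draws_by_stratum,
    )


def _functional_map(fd, ages) -> dict:
    out = {}
    for age in ages:
        out[f"e{_fmt_age(age)}"] = fd.life_expectancy[age]
        out[f"eps{_fmt_age(age)}"] = fd.lifespan_equality[age]
    out["q1"] = fd.first_year_mortality
    return out


def _fmt_age(age: float) -> str:
    return str(int(age)) if float(age).is_integer() else str(age)
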