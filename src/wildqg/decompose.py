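"""Geber decomposition of the phenotypic trend into covariate contributions.

Each fixed-effect covariate's contribution to the change in the mean
working-scale trait is the product of the trait's sensitivity to the
covariate (the fixed-effect coefficient, per posterior sample) and the
covariate's temporal trend (the OLS slope of its yearly population mean on
year), accumulated over the study span. Categorical covariates contribute
through every non-reference level's coefficient times the trend in that
level's yearly proportion; because proportions sum to one each year, the
result is invariant to the choice of reference level. Contributions are
additive on the working scale and are back-transformed to days at the
reference baseline for reporting.

Only fixed effects are decomposed this way: random effects other than the
additive genetic one are independent of year by construction, so
persistent environmental trends appear either in the year covariate's
contribution or in the unexplained remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PosteriorChain
from .posterior import PosteriorSummary, posterior_summary
from .selection import Reference

__all__ = [
    "CovariateTrajectory",
    "ChangeComponent",
    "covariate_trajectories",
    "trajectory_slope",
    "geber_contribution",
    "component_table",
    "temperature_sensitivity",
    "GEBER_COVARIATES",
]

GEBER_COVARIATES = ("age", "status", "offspring_sex", "temperature",
                    "inbreeding", "genetic_group")


@dataclass
class CovariateTrajectory:
    """Yearly population mean of one covariate term (or level proportion)."""

    name: str
    yearly: pd.Series     # index year, value mean/proportion
    counts: pd.Series

    @property
    def slope(self) -> float:
        return trajectory_slope(self.yearly)


def trajectory_slope(yearly: pd.Series) -> float:
    """OLS slope of yearly means on year (gap years ignored)."""
    y = yearly.dropna()
    x = y.index.to_numpy(float)
    v = y.to_numpy(float)
    xc = x - x.mean()
    return float((xc @ v) / (xc @ xc))


def covariate_trajectories(records: pd.DataFrame) -> dict:
    """Yearly means (continuous terms) and level proportions (categorical
    terms) for every decomposable covariate. Years with no records are
    flagged and carried as gaps."""
    years = np.arange(records["year"].min(), records["year"].max() + 1)
    counts = records.groupby("year").size().reindex(years, fill_value=0)
    gaps = counts[counts == 0].index.tolist()
    if gaps:
        warnings.warn(f"years without records: {gaps}", stacklevel=2)
    out: dict[str, CovariateTrajectory] = {}

    def add(name, series):
        out[name] = CovariateTrajectory(name, series.reindex(years), counts)

    g = records.groupby("year")
    add("age", g["age"].mean())
    add("age2", g["age"].apply(lambda a: np.mean(np.asarray(a, float) ** 2)))
    for term in ("temperature", "inbreeding", "genetic_group"):
        add(term, g[term].mean())
    add("offspring_sex[M]", g["offspring_sex"].apply(lambda s: np.mean(s == "M")))
    for lev in sorted(records["status"].unique()):
        add(f"status[{lev}]", g["status"].apply(lambda s, lev=lev: np.mean(s == lev)))
    add("year_covariate", pd.Series(years.astype(float), index=years))
    return out


# coefficient-name -> trajectory-name pairs per decomposable covariate
def _terms_for(covariate: str, chain: PosteriorChain, trait: str):
    names = chain.fixed[trait].columns
    if covariate == "age":
        return [("age", "age"), ("age2", "age2")]
    if covariate == "status":
        return [(c, c) for c in names if c.startswith("status[")]
    if covariate == "offspring_sex":
        return [("offspring_sex[M]", "offspring_sex[M]")]
    if covariate == "year_covariate":
        return [("year_covariate", "year_covariate")]
    if covariate in ("temperature", "inbreeding", "genetic_group"):
        return [(covariate, covariate)]
    raise ValueError(f"unknown covariate {covariate!r}")


@dataclass
class ChangeComponent:
    """One named contribution to the phenotypic change over the span."""

    name: str
    working_samples: np.ndarray          # total working-scale change over the span
    days_samples: np.ndarray
    summary: PosteriorSummary
    yearly_effect: pd.DataFrame = field(default=None, repr=False)  # year x posterior-mean effect

    @classmethod
    def from_working(cls, name, working, ref: Reference, yearly=None):
        days = ref.baseline_days * (np.exp(np.asarray(working) / 100.0) - 1.0)
        return cls(name, np.asarray(working), days, posterior_summary(days), yearly)


def geber_contribution(
    chain: PosteriorChain,
    covariate: str,
    trajectories: dict,
    ref: Reference,
    trait: str = "z",
) -> ChangeComponent:
    """Contribution of one covariate's temporal change to the trait trend.

    Per posterior sample: ``sum over terms of coefficient x trajectory
    slope x span`` on the working scale, then converted to days. The
    per-year effect series (at posterior-mean coefficients) is attached for
    plotting the dynamics.
    """
    terms = _terms_for(covariate, chain, trait)
    fx = chain.fixed[trait]
    missing = [c for c, _ in terms if c not in fx.columns]
    if missing:
        raise ValueError(f"chain lacks coefficients {missing} for covariate {covariate!r}")
    total = np.zeros(chain.n_samples)
    yearly = None
    for coef, traj_name in terms:
        traj = trajectories[traj_name]
        beta = fx[coef].to_numpy()
        total = total + beta * traj.slope * ref.span_years
        contrib_t = beta.mean() * traj.yearly
        yearly = contrib_t if yearly is None else yearly + contrib_t
    yearly = (yearly - yearly.dropna().iloc[0]).rename("effect").to_frame()
    return ChangeComponent.from_working(covariate, total, ref, yearly)


def component_table(
    components: list,
    observed_days: float,
    evolution: dict | None = None,
    ref: Reference | None = None,
) -> pd.DataFrame:
    """Assemble the components-of-change table.

    ``evolution`` maps estimator names to per-sample days-over-span arrays
    (e.g. conservative/non-conservative BLUP trends, STS). Two roll-ups are
    reported: the summed fixed-effect components alone, and fixed effects
    plus the first evolution estimate; the unexplained remainder is the
    observed change minus the latter, per sample.
    """
    rows = []

    def add_row(name, days_samples, kind):
        s = posterior_summary(np.asarray(days_samples))
        rows.append(dict(component=name, kind=kind, mode=s.mode,
                         hpd_low=s.hpd_low, hpd_high=s.hpd_high, mean=s.mean))

    n = min(len(c.working_samples) for c in components)
    work_sum = np.sum([c.working_samples[:n] for c in components], axis=0)
    for c in components:
        add_row(c.name, c.days_samples, "fixed-effect")
    base = ref.baseline_days if ref is not None else None
    if base is None:
        raise ValueError("component_table needs the Reference for roll-ups")
    explained_fixed = base * (np.exp(work_sum / 100.0) - 1.0)
    add_row("explained (fixed effects)", explained_fixed, "roll-up")
    if evolution:
        for name, days in evolution.items():
            add_row(name, days, "evolution")
        first = next(iter(evolution.values()))
        m = min(n, len(first))
        explained_all = explained_fixed[:m] + np.asarray(first)[:m]
        add_row("explained (fixed effects + evolution)", explained_all, "roll-up")
        add_row("unexplained", observed_days - explained_all, "roll-up")
    rows.append(dict(component="observed", kind="observed", mode=observed_days,
                     hpd_low=np.nan, hpd_high=np.nan, mean=observed_days))
    return pd.DataFrame(rows)


def temperature_sensitivity(
    chain_with_year: PosteriorChain,
    chain_without_year: PosteriorChain,
    trajectories: dict,
    ref: Reference,
) -> dict:
    """Temperature contribution under the with-year and without-year model
    variants, side by side (the year covariate absorbs part of any trend
    collinear with temperature)."""
    return {
        "with_year": geber_contribution(chain_with_year, "temperature", trajectories, ref),
        "without_year": geber_contribution(chain_without_year, "temperature", trajectories, ref),
    }
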