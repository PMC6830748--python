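"""Estimators of realised genetic change and the drift null.

Three estimators of the genetic trend are provided:

* conservative BLUP regression — per posterior sample, an OLS slope of
  female breeding values on the mean birth year of their offspring, from
  the animal model that *includes* year as a fixed covariate (some genetic
  change is absorbed by the year effect, hence "conservative");
* non-conservative BLUP regression — the same slope from the model without
  the year covariate;
* the secondary theorem of selection (Robertson-Price identity) — the
  additive genetic covariance between the trait and latent relative
  fitness, halved for female-limited expression, as the expected
  per-generation genetic change.

Because a trend in predicted breeding values can also arise from drift,
the observed slope is compared against a null distribution generated by
gene-dropping breeding values down the fixed pedigree (at the posterior
additive variance) and re-applying the identical regression recipe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, gene_drop_breeding_values
from .posterior import PosteriorSummary, posterior_summary
from .selection import Reference, ResponsePrediction
from .model import PosteriorChain

__all__ = [
    "BlupTrend",
    "DriftNull",
    "mean_offspring_year",
    "blup_trend",
    "blup_trend_spline",
    "sts_estimate",
    "drift_null",
]


def mean_offspring_year(records: pd.DataFrame) -> pd.Series:
    """Mean calving year per female (the regression abscissa)."""
    return records.groupby("female")["year"].mean()


def _slope_weights(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    ssx = xc @ xc
    if ssx == 0:
        raise ValueError("no variation in mean offspring birth year")
    return xc / ssx


@dataclass
class BlupTrend:
    """Posterior of the breeding-value trend (working units per year)."""

    slope_samples: np.ndarray
    summary: PosteriorSummary
    prob_nonnegative: float            # P(slope >= 0); NaN if degenerate
    days_span: ResponsePrediction | None = None
    degenerate: bool = False


def blup_trend(chain: PosteriorChain, records: pd.DataFrame,
               ref: Reference | None = None, trait: str = "z") -> BlupTrend:
    """Regress each posterior sample's breeding values on mean offspring
    birth year (one point per breeding female); summarise the slope.

    With a ``ref``, the slope is also expressed as days over the study
    span via the standard back-transformation.
    """
    moy = mean_offspring_year(records)
    if len(moy) < 3:
        raise ValueError(f"only {len(moy)} females with records; need at least 3")
    pos = {v: i for i, v in enumerate(chain.ped_ids)}
    cols = np.array([pos[f] for f in moy.index])
    bv = chain.breeding_values(trait)[:, cols]           # (S, n_females)
    w = _slope_weights(moy.to_numpy(float))
    slopes = bv @ w
    degenerate = bool(np.all(slopes == 0.0))  # e.g. all BVs exactly zero
    prob = float(np.mean(slopes >= 0.0)) if not degenerate else float("nan")
    days = None
    if ref is not None:
        days = ResponsePrediction.from_per_generation(
            "blup_trend", slopes * ref.generation_time, ref
        )
    return BlupTrend(slopes, posterior_summary(slopes), prob, days, degenerate)


def blup_trend_spline(
    chain: PosteriorChain,
    membership: dict,
    trait: str = "z",
    max_samples: int = 200,
    lam: float | None = None,
) -> pd.DataFrame:
    """Smooth per-year mean breeding values, one curve per posterior sample.

    ``membership`` maps year -> iterable of individual ids alive in that
    year. Each sample's yearly means are smoothed with a cubic smoothing
    spline (penalty chosen by generalised cross-validation unless ``lam``
    is given); heavy penalisation collapses the curve to a straight line,
    so near-linear curves indicate a linear genetic trend.

    Returns a tidy frame with columns ``year, sample, value``.
    """
    from scipy.interpolate import make_smoothing_spline

    years = np.array(sorted(membership))
    pos = {v: i for i, v in enumerate(chain.ped_ids)}
    cols = [np.array([pos[i] for i in membership[y] if i in pos], dtype=int) for y in years]
    bv = chain.breeding_values(trait)
    S = min(len(bv), max_samples)
    out = []
    for s in range(S):
        means = np.array([bv[s, c].mean() if len(c) else np.nan for c in cols])
        ok = ~np.isnan(means)
        if ok.sum() < 4:
            continue
        if np.allclose(means[ok], means[ok][0]):
            fitted = np.full(ok.sum(), means[ok][0])
        else:
            spl = make_smoothing_spline(years[ok].astype(float), means[ok], lam=lam)
            fitted = spl(years[ok].astype(float))
        out.append(pd.DataFrame({"year": years[ok], "sample": s, "value": fitted}))
    return pd.concat(out, ignore_index=True)


def sts_estimate(chain: PosteriorChain, ref: Reference,
                 trait: str = "z", fitness: str = "lbs") -> ResponsePrediction:
    """Secondary-theorem estimate: additive trait-fitness covariance / 2,
    interpreted as working-scale change per generation and converted."""
    if "additive" not in chain.block_traits or fitness not in chain.block_traits["additive"]:
        raise ValueError("chain lacks an additive trait-fitness covariance")
    per_gen = chain.vc("additive", trait, fitness) / 2.0
    return ResponsePrediction.from_per_generation("sts", per_gen, ref)


@dataclass
class DriftNull:
    """Null distribution of the BV trend under pure drift."""

    null_slopes: np.ndarray
    observed_slope: float
    exceedance: float       # share of null slopes <= observed (as large or larger an advance)
    n_sims: int


def drift_null(
    ped: Pedigree,
    sigma_a_samples: np.ndarray,
    records: pd.DataFrame,
    observed_slope: float,
    n_sims: int = 1000,
    seed: int | None = None,
    resample_sigma: bool = True,
) -> DriftNull:
    """Gene-drop breeding values down the pedigree and re-run the identical
    female-BV-on-mean-offspring-year regression for each simulation.

    Each simulation uses an additive variance drawn from its posterior
    (``resample_sigma=False`` fixes it at the posterior mean instead). The
    exceedance fraction is the share of null slopes at least as negative
    as the observed slope (an advance "as large or larger").
    """
    if n_sims < 2:
        raise ValueError("need at least 2 simulations")
    rng = np.random.default_rng(seed)
    moy = mean_offspring_year(records)
    cols = ped.positions(moy.index)
    w = _slope_weights(moy.to_numpy(float))
    unit = gene_drop_breeding_values(ped, 1.0, n_reps=n_sims, rng=rng)  # (n_sims, n)
    sig = np.asarray(sigma_a_samples, dtype=float)
    if resample_sigma:
        scale = np.sqrt(rng.choice(sig, size=n_sims))
    else:
        scale = np.full(n_sims, np.sqrt(sig.mean()))
    slopes = (unit[:, cols] @ w) * scale
    exceed = float(np.mean(slopes <= observed_slope))
    return DriftNull(slopes, float(observed_slope), exceed, n_sims)


def membership_from_lifespans(individuals: pd.DataFrame, years) -> dict:
    """Year -> ids alive in that year, from ``id, cohort, death_year``
    columns (NaN death = alive through the last year)."""
    out = {}
    coh = individuals["cohort"].to_numpy()
    death = individuals["death_year"].to_numpy(float)
    ids = individuals["id"].to_numpy()
    for y in years:
        alive = (coh <= y) & (np.isnan(death) | (death >= y))
        out[int(y)] = list(ids[alive])
    return out
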