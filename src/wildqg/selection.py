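"""Selection differentials, gradients and breeder's-equation predictions.

The fitness trait is female lifetime breeding success (LBS), modelled on a
latent log scale; under log-normality of expected fitness, covariances with
the latent scale equal covariances with relative fitness on the data scale,
so the latent-scale (co)variances are used directly as selection parameters.

The selection differential on the working-scale trait is the sum of the
individual-level and maternal-level trait-fitness covariances, halved
because selection acts through females only (males carry the genes but do
not express the trait). Gradients scale the differential by the matching
phenotypic variance (univariate) or solve ``beta = P^-1 s`` (multivariate).
Predicted responses are ``R = h^2 s`` (univariate) and ``dz = beta_z *
sigma2_A(z) + beta_bw * sigma_A(z, bw)`` (bivariate focal-trait form), all
computed per posterior sample so that uncertainty propagates to every
derived quantity.

Unit conventions: per-generation changes on the working scale ``z = 100
ln(days)``; conversions report days per generation, days per year, days
over the study span, and Haldanes (working-scale phenotypic SDs per
generation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ChainSettings, ModelSpec, PosteriorChain, fit_model
from .posterior import PosteriorSummary, posterior_summary

__all__ = [
    "Reference",
    "SelectionEstimate",
    "ResponsePrediction",
    "selection_differential",
    "selection_gradient",
    "multivariate_gradients",
    "breeders_equation_univariate",
    "breeders_equation_multivariate",
    "convert_units",
    "subset_selection_analysis",
    "SUBSETS",
]

GENERATION_TIME = 8.0   # years
STUDY_SPAN = 45.0       # years


@dataclass
class Reference:
    """Quantities needed to express working-scale changes in days.

    ``baseline_days`` is the predicted mean parturition date (days after
    May 1) at which the back-transformation ``days = B * (exp(dz/100) - 1)``
    is evaluated; by convention the observed mean over the first years of
    the study. ``phenotypic_sd`` is the per-sample working-scale phenotypic
    SD (the Haldane denominator).
    """

    baseline_days: float
    phenotypic_sd: np.ndarray | float = 1.0
    generation_time: float = GENERATION_TIME
    span_years: float = STUDY_SPAN

    @classmethod
    def from_data(cls, records: pd.DataFrame, chain: PosteriorChain | None = None,
                  first_years: int = 3, **kw) -> "Reference":
        years = np.sort(records["year"].unique())[:first_years]
        base = float(np.exp(records.loc[records["year"].isin(years), "z"].mean() / 100.0))
        sd = np.sqrt(chain.total_variance("z")) if chain is not None else 1.0
        return cls(baseline_days=base, phenotypic_sd=sd, **kw)


def convert_units(per_generation: np.ndarray, ref: Reference) -> dict:
    """Express a per-generation working-scale change in every reporting unit.

    The change is scaled linearly on the working (log) scale to the span of
    interest and back-transformed to days at the baseline mean, separately
    per posterior sample:

    ``days_span = B * (exp(dz_gen * span / T / 100) - 1)``.
    """
    dz = np.asarray(per_generation, dtype=float)
    B, T, span = ref.baseline_days, ref.generation_time, ref.span_years
    days_gen = B * (np.exp(dz / 100.0) - 1.0)
    days_span = B * (np.exp(dz * span / T / 100.0) - 1.0)
    sd = np.asarray(ref.phenotypic_sd, dtype=float)
    if sd.ndim and dz.ndim and len(sd) != len(dz):
        # samples from independently fitted chains: pair by index
        n = min(len(sd), len(dz))
        haldanes = dz[:n] / sd[:n]
    else:
        haldanes = dz / sd
    return {
        "working_per_generation": dz,
        "days_per_generation": days_gen,
        "days_per_year": days_span / span,
        "days_span": days_span,
        "haldanes": haldanes,
    }


@dataclass
class ResponsePrediction:
    """Per-sample predicted (or estimated) evolutionary change, with every
    unit variant and its posterior summary."""

    name: str
    units: dict
    summaries: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.summaries:
            self.summaries = {k: posterior_summary(v) for k, v in self.units.items()}

    @property
    def days_span(self) -> PosteriorSummary:
        return self.summaries["days_span"]

    def table(self) -> pd.DataFrame:
        rows = [
            dict(quantity=self.name, unit=k, mode=s.mode, hpd_low=s.hpd_low,
                 hpd_high=s.hpd_high, mean=s.mean)
            for k, s in self.summaries.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_per_generation(cls, name, per_generation, ref: Reference) -> "ResponsePrediction":
        return cls(name, convert_units(per_generation, ref))


@dataclass
class SelectionEstimate:
    """Posterior of selection parameters from a trait-fitness model."""

    differential: np.ndarray          # halved, working units per generation
    gradient: np.ndarray
    phenotypic_variance: np.ndarray   # individual + maternal variance of the trait
    summary: PosteriorSummary = None
    n_dropped: int = 0

    def __post_init__(self):
        if self.summary is None:
            self.summary = posterior_summary(self.differential)


def selection_differential(chain: PosteriorChain, trait: str = "z",
                           fitness: str = "lbs") -> SelectionEstimate:
    """Selection differential: (individual + maternal trait-fitness
    covariance) / 2, per posterior sample.

    The halving accounts for the trait being expressed in females only;
    it is applied exactly once, here.
    """
    for block in ("individual", "maternal"):
        if block not in chain.block_traits or fitness not in chain.block_traits[block]:
            raise ValueError(f"chain lacks a {block}-level covariance with {fitness!r}")
    cov_i = chain.vc("individual", trait, fitness)
    cov_m = chain.vc("maternal", trait, fitness)
    s = (cov_i + cov_m) / 2.0
    var = chain.vc("individual", trait) + chain.vc("maternal", trait)
    return SelectionEstimate(differential=s, gradient=s / var, phenotypic_variance=var)


def selection_gradient(est: SelectionEstimate) -> np.ndarray:
    """Univariate gradient: differential / (individual + maternal variance)."""
    return est.differential / est.phenotypic_variance


def multivariate_gradients(chain: PosteriorChain, traits=("z", "birth_weight"),
                           fitness: str = "lbs"):
    """Per-sample ``beta = P^-1 s`` from a trivariate trait-fitness chain.

    ``P`` sums the individual- and maternal-level (co)variances of the
    phenotypic traits; ``s`` sums the matching trait-fitness covariances,
    halved. Singular ``P`` samples are dropped (with a count).

    Returns ``(beta, s, P, n_dropped)``: arrays of shape (S, k), (S, k),
    (S, k, k).
    """
    k = len(traits)
    S = chain.n_samples
    P = np.empty((S, k, k))
    s = np.empty((S, k))
    for a, ta in enumerate(traits):
        s[:, a] = (chain.vc("individual", ta, fitness) + chain.vc("maternal", ta, fitness)) / 2.0
        for b, tb in enumerate(traits):
            P[:, a, b] = chain.vc("individual", ta, tb) + chain.vc("maternal", ta, tb)
    beta = np.full((S, k), np.nan)
    dropped = 0
    for i in range(S):
        try:
            beta[i] = np.linalg.solve(P[i], s[i])
        except np.linalg.LinAlgError:
            dropped += 1
    ok = ~np.isnan(beta[:, 0])
    return beta[ok], s[ok], P[ok], dropped


def breeders_equation_univariate(h2: np.ndarray, s: np.ndarray,
                                 ref: Reference) -> ResponsePrediction:
    """Univariate breeder's equation ``R = h^2 s``, per aligned sample."""
    n = min(len(h2), len(s))
    return ResponsePrediction.from_per_generation(
        "breeders_equation_univariate", np.asarray(h2)[:n] * np.asarray(s)[:n], ref
    )


def breeders_equation_multivariate(
    g_chain: PosteriorChain, beta: np.ndarray, ref: Reference,
    traits=("z", "birth_weight"), focal: str = "z",
):
    """Focal-trait multivariate response ``dz = beta_z sigma2_A(z) +
    beta_bw sigma_A(z, bw)`` with G from a bivariate animal-model chain.

    ``beta`` samples (from the trivariate selection model) and G samples
    are drawn from independently fitted models; they are paired by index
    after truncation to the shorter chain. Also returns the per-sample
    difference from the direct (univariate-form) term ``beta_z sigma2_A(z)``.
    """
    ga = {t: g_chain.vc("additive", focal, t) for t in traits}
    n = min(len(beta), len(ga[focal]))
    dz = np.zeros(n)
    for j, t in enumerate(traits):
        dz += beta[:n, j] * ga[t][:n]
    direct = beta[:n, list(traits).index(focal)] * ga[focal][:n]
    pred = ResponsePrediction.from_per_generation("breeders_equation_multivariate", dz, ref)
    diff = ResponsePrediction.from_per_generation("multivariate_minus_direct", dz - direct, ref)
    return pred, diff


SUBSETS = ("all", "natural", "culled", "dead-only")


def _subset_females(fitness: pd.DataFrame, subset: str) -> pd.Series:
    culled = fitness["culled"].astype(bool)
    alive = fitness["alive"].astype(bool)
    if subset == "all":
        keep = pd.Series(True, index=fitness.index)
    elif subset == "natural":
        keep = ~alive & ~culled
    elif subset == "culled":
        keep = culled
    elif subset == "dead-only":
        keep = ~alive
    else:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")
    return keep


def subset_selection_analysis(
    records: pd.DataFrame,
    ped,
    fitness: pd.DataFrame,
    subset: str,
    h2: np.ndarray,
    ref: Reference,
    chain: ChainSettings | None = None,
    female_covariates: pd.DataFrame | None = None,
    min_females: int = 50,
    prior: str = "parameter_expanded",
    inbreeding: bool = True,
):
    """Re-estimate selection on a subset of females (culled vs natural
    death vs excluding living) and redo the univariate prediction.

    Both the fitness table and the calving records are restricted to the
    subset, so the analysis is self-contained for those females.
    """
    keep = _subset_females(fitness, subset)
    fit_sub = fitness.loc[keep].reset_index(drop=True)
    females = set(fit_sub["female"])
    rec_sub = records[records["female"].isin(females)].reset_index(drop=True)
    if len(fit_sub) < min_females or rec_sub["female"].nunique() < 3:
        raise ValueError(
            f"subset {subset!r} too small to fit: {len(fit_sub)} females, "
            f"{rec_sub['female'].nunique()} with records"
        )
    spec = ModelSpec.selection(chain=chain or ChainSettings.default_multivariate(),
                               prior=prior, inbreeding=inbreeding)
    post = fit_model(spec, rec_sub, ped, fitness=fit_sub,
                     female_covariates=female_covariates)
    est = selection_differential(post)
    pred = breeders_equation_univariate(h2, est.differential, ref)
    pred.name = f"breeders_equation_univariate[{subset}]"
    return est, pred
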