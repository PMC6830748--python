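"""End-to-end orchestration: data I/O, model fits, and the summary bundle.

``run_pipeline`` chains every stage of the analysis — phenotypic trend,
animal-model fits, selection and response predictions, the three genetic
trend estimators, the drift null and the Geber decomposition — on either a
simulated dataset or CSV inputs, writing tidy CSV outputs (each row tagged
with the run seed, package version and config hash) and returning the
in-memory results for programmatic use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .model import (ChainSettings, ModelSpec, fit_model, heritability,
                    repeatability)
from .pedigree import read_pedigree_csv
from .posterior import posterior_summary
from .selection import (Reference,
                        breeders_equation_multivariate,
                        breeders_equation_univariate, multivariate_gradients,
                        selection_differential, subset_selection_analysis)
from .simulate import SimulationConfig, SyntheticDataset, simulate_population
from .trends import (blup_trend, blup_trend_spline, drift_null,
                     membership_from_lifespans, sts_estimate)
from .decompose import (GEBER_COVARIATES, component_table,
                        covariate_trajectories, geber_contribution,
                        temperature_sensitivity)

__all__ = ["PipelineConfig", "PipelineResult", "phenotypic_trend", "run_pipeline", "load_dataset"]


@dataclass
class PipelineConfig:
    """What to run and where to put it."""

    outdir: str = "wildqg_out"
    seed: int = 1
    simulate: SimulationConfig | None = None
    data_dir: str | None = None          # directory with pedigree/records/fitness CSVs
    fast: bool = True                    # desk-scale chain lengths
    prior: str = "parameter_expanded"    # multivariate models
    univariate_prior: str = "parameter_expanded"  # 'inverse_gamma' is the classical
                                         # default but mixes slowly at desk chains
    n_drift_sims: int = 1000
    subsets: tuple = ("natural", "culled")
    multivariate: bool = True            # fit G-matrix + trivariate models
    resume: bool = False                 # reuse cached chains in outdir
    plots: bool = False
    inbreeding_effect: bool = True       # fit the inbreeding fixed effect
    # optional explicit chain settings (override fast/full defaults)
    univariate_chain: ChainSettings | None = None
    multivariate_chain: ChainSettings | None = None

    def chain(self, offset: int, multivariate: bool = False) -> ChainSettings:
        seed = (self.seed * 1000 + offset) % (2**31 - 1)
        override = self.multivariate_chain if multivariate else self.univariate_chain
        if override is not None:
            return dataclasses.replace(override, seed=seed)
        if self.fast:
            return ChainSettings.fast(seed=seed, multivariate=multivariate)
        if multivariate:
            return ChainSettings.default_multivariate(seed=seed)
        return ChainSettings(seed=seed)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, keyed for reporting."""

    summary: pd.DataFrame
    tables: dict = field(default_factory=dict)
    chains: dict = field(default_factory=dict)
    objects: dict = field(default_factory=dict)


def phenotypic_trend(records: pd.DataFrame, span_years: float | None = None) -> dict:
    """OLS trend of parturition date (days) on year, with the standard
    frequentist 95% CI, totalled over the study span; plus the variant on
    per-female means (mean date against mean year)."""
    years = records["year"].to_numpy(float)
    if len(np.unique(years)) < 2:
        raise ValueError("need at least 2 distinct years")
    span = span_years if span_years is not None else years.max() - years.min() + 1
    days = records["pdate"].to_numpy(float)
    fit = stats.linregress(years, days)
    n = len(years)
    tcrit = stats.t.ppf(0.975, n - 2) if n > 2 else np.nan
    agg = records.groupby("female").agg(my=("year", "mean"), md=("pdate", "mean"))
    fit_f = stats.linregress(agg["my"], agg["md"])
    return {
        "slope_per_year": fit.slope,
        "total_days": fit.slope * span,
        "ci_low": (fit.slope - tcrit * fit.stderr) * span,
        "ci_high": (fit.slope + tcrit * fit.stderr) * span,
        "aggregated_slope_per_year": fit_f.slope,
        "aggregated_total_days": fit_f.slope * span,
        "span_years": span,
        "n_records": n,
    }


def load_dataset(data_dir) -> SyntheticDataset:
    """Load the three CSVs (plus truth tables if present) from a directory."""
    d = Path(data_dir)
    ped = read_pedigree_csv(d / "pedigree.csv")
    records = pd.read_csv(d / "records.csv")
    fitness = pd.read_csv(d / "fitness.csv")
    temp = (pd.read_csv(d / "temperature.csv")
            if (d / "temperature.csv").exists() else pd.DataFrame())
    ti_path = d / "truth_individuals.csv"
    truth_ind = pd.read_csv(ti_path) if ti_path.exists() else pd.DataFrame()
    tr_path = d / "truth_records.csv"
    truth_rec = pd.read_csv(tr_path) if tr_path.exists() else pd.DataFrame()
    cfg_path = d / "config.json"
    cfg = SimulationConfig.from_file(cfg_path) if cfg_path.exists() else SimulationConfig()
    return SyntheticDataset(ped, records, fitness, temp, truth_ind, truth_rec, cfg)


def _female_covariates(ds: SyntheticDataset) -> pd.DataFrame:
    if len(ds.truth_individuals):
        return ds.truth_individuals[["id", "inbreeding", "genetic_group"]]
    cov = ds.records.groupby("female")[["inbreeding", "genetic_group"]].first().reset_index()
    return cov.rename(columns={"female": "id"})


class _ChainCache:
    def __init__(self, outdir: Path, enabled: bool, tag: str):
        self.dir = outdir / "cache"
        self.enabled = enabled
        self.tag = tag

    def fit(self, name, spec, *args, **kw):
        path = self.dir / f"{name}-{self.tag}-{spec.chain.seed}.pkl"
        if self.enabled and path.exists():
            with open(path, "rb") as fh:
                return pickle.load(fh)
        chain = fit_model(spec, *args, **kw)
        self.dir.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(chain, fh)
        return chain


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle under ``cfg.outdir``."""
    t_start = time.time()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.data_dir is not None:
        ds = load_dataset(cfg.data_dir)
    else:
        sim = cfg.simulate or SimulationConfig(seed=cfg.seed)
        ds = simulate_population(sim)
        ds.write(out / "data")
    records, ped, fitness = ds.records, ds.pedigree, ds.fitness
    fem_cov = _female_covariates(ds)
    cfg_hash = hashlib.md5(
        json.dumps(dataclasses.asdict(cfg.simulate or SimulationConfig()),
                   sort_keys=True, default=str).encode()
    ).hexdigest()[:10]
    cache = _ChainCache(out, cfg.resume, cfg_hash)

    results: dict[str, float | str] = {}
    tables: dict[str, pd.DataFrame] = {}
    chains: dict = {}
    objects: dict = {}

    # 1. phenotypic trend
    trend = phenotypic_trend(records)
    results.update({f"phenotypic_trend.{k}": v for k, v in trend.items()})

    # 2. univariate animal models (with and without the year covariate)
    inb = cfg.inbreeding_effect
    uni = cache.fit("univariate_year",
                    ModelSpec.univariate(chain=cfg.chain(1), inbreeding=inb,
                                         prior=cfg.univariate_prior),
                    records, ped, female_covariates=fem_cov)
    uni_ny = cache.fit("univariate_noyear",
                       ModelSpec.univariate(year_covariate=False, chain=cfg.chain(2),
                                            inbreeding=inb, prior=cfg.univariate_prior),
                       records, ped, female_covariates=fem_cov)
    chains.update(univariate=uni, univariate_noyear=uni_ny)
    ref = Reference.from_data(records, uni)

    h2, h2_sum = heritability(uni)
    rep, rep_sum = repeatability(uni, fem_cov[fem_cov["id"].isin(records["female"])])
    results["heritability.mode"] = h2_sum.mode
    results["heritability.hpd_low"], results["heritability.hpd_high"] = h2_sum.hpd_low, h2_sum.hpd_high
    results["repeatability.mode"] = rep_sum.mode

    # 3. selection and univariate prediction
    sel = cache.fit("selection",
                    ModelSpec.selection(chain=cfg.chain(3, True), prior=cfg.prior,
                                        inbreeding=inb),
                    records, ped, fitness=fitness, female_covariates=fem_cov)
    chains["selection"] = sel
    est = selection_differential(sel)
    pred_uni = breeders_equation_univariate(h2, est.differential, ref)
    objects["selection"] = est
    objects["prediction_univariate"] = pred_uni
    s_days = ref.baseline_days * (np.exp(est.differential / 100.0) - 1.0)
    ssum = posterior_summary(s_days)
    results["selection_differential.days_per_generation"] = ssum.mode
    results["selection_differential.hpd_low"] = ssum.hpd_low
    results["selection_differential.hpd_high"] = ssum.hpd_high
    results["selection_gradient.mode"] = posterior_summary(est.gradient).mode
    results["prediction_univariate.days_span"] = pred_uni.days_span.mode
    results["prediction_univariate.haldanes"] = pred_uni.summaries["haldanes"].mode

    # 4. STS
    sts_chain = cache.fit("sts",
                          ModelSpec.selection(additive=True, chain=cfg.chain(4, True),
                                              prior=cfg.prior, inbreeding=inb),
                          records, ped, fitness=fitness, female_covariates=fem_cov)
    chains["sts"] = sts_chain
    sts = sts_estimate(sts_chain, ref)
    objects["sts"] = sts
    results["sts.days_span"] = sts.days_span.mode

    # 5. multivariate models
    if cfg.multivariate:
        pair = cache.fit("trait_pair",
                         ModelSpec.trait_pair(chain=cfg.chain(5, True), prior=cfg.prior,
                                              inbreeding=inb),
                         records, ped)
        # the phenotypic P matrix is informed only by females who expressed
        # the traits; never-recorded females' (p_z, p_bw) pairs are pure
        # imputation noise and destabilise the covariance block, so the
        # trivariate model conditions on recorded females
        fit_tri = fitness[fitness["female"].isin(set(records["female"]))].reset_index(drop=True)
        tri = cache.fit("trivariate",
                        ModelSpec.trivariate(chain=cfg.chain(6, True), prior=cfg.prior,
                                             inbreeding=inb),
                        records, ped, fitness=fit_tri, female_covariates=fem_cov)
        chains.update(trait_pair=pair, trivariate=tri)
        beta, svec, P, dropped = multivariate_gradients(tri)
        pred_multi, pred_diff = breeders_equation_multivariate(pair, beta, ref)
        objects["prediction_multivariate"] = pred_multi
        results["prediction_multivariate.days_span"] = pred_multi.days_span.mode
        results["gradient_z.mode"] = posterior_summary(beta[:, 0]).mode
        results["gradient_bw.mode"] = posterior_summary(beta[:, 1]).mode
        ga = pair.blocks["additive"]
        results["genetic_covariance_z_bw.mean"] = float(ga[:, 0, 1].mean())
        results["heritability_bw.mode"] = posterior_summary(
            pair.vc("additive", "birth_weight") / pair.total_variance("birth_weight")).mode

    # 6. genetic trends and drift null
    bt = blup_trend(uni, records, ref)
    bt_ny = blup_trend(uni_ny, records, ref)
    objects.update(blup_trend=bt, blup_trend_noyear=bt_ny)
    results["blup_trend.slope"] = bt.summary.mode
    results["blup_trend.prob_nonnegative"] = bt.prob_nonnegative
    results["blup_trend.days_span"] = bt.days_span.days_span.mode
    results["blup_trend_noyear.days_span"] = bt_ny.days_span.days_span.mode
    dn = drift_null(ped, uni.vc("additive", "z"), records,
                    observed_slope=bt.summary.mode, n_sims=cfg.n_drift_sims,
                    seed=(cfg.seed * 1000 + 7) % (2**31 - 1))
    objects["drift_null"] = dn
    results["drift.exceedance"] = dn.exceedance

    if len(ds.truth_individuals):
        years = sorted(records["year"].unique())
        membership = membership_from_lifespans(ds.truth_individuals, years)
        membership = {y: [i for i in m if i in set(uni.ped_ids)]
                      for y, m in membership.items()}
        tables["spline_curves"] = blup_trend_spline(uni, membership)

    # 7. decomposition
    traj = covariate_trajectories(records)
    covs = [c for c in GEBER_COVARIATES if inb or c != "inbreeding"]
    comps = [geber_contribution(uni, c, traj, ref) for c in covs]
    comps.append(geber_contribution(uni, "year_covariate", traj, ref))
    evolution = {
        "evolution (BLUPs, year)": bt.days_span.units["days_span"],
        "evolution (BLUPs, no year)": bt_ny.days_span.units["days_span"],
        "evolution (STS)": sts.units["days_span"],
    }
    ctab = component_table(comps, trend["total_days"], evolution, ref)
    tables["components"] = ctab
    for c in comps:
        results[f"component.{c.name}.days_span"] = c.summary.mode
    ts = temperature_sensitivity(uni, uni_ny, traj, ref)
    results["temperature.with_year"] = ts["with_year"].summary.mode
    results["temperature.without_year"] = ts["without_year"].summary.mode
    unexp = ctab.loc[ctab["component"] == "unexplained", "mode"]
    if len(unexp):
        results["unexplained.days_span"] = float(unexp.iloc[0])

    # 8. subset selection analyses
    for i, sub in enumerate(cfg.subsets):
        try:
            est_s, pred_s = subset_selection_analysis(
                records, ped, fitness, sub, h2, ref,
                chain=cfg.chain(10 + i, True), female_covariates=fem_cov,
                prior=cfg.prior, inbreeding=inb,
            )
            results[f"subset.{sub}.differential"] = est_s.summary.mode
            results[f"subset.{sub}.prediction_days_span"] = pred_s.days_span.mode
        except ValueError as e:
            warnings.warn(f"subset {sub!r} skipped: {e}", stacklevel=2)

    # 9. write bundle
    summary = pd.DataFrame(
        [dict(quantity=k, value=v) for k, v in results.items()]
    )
    summary["seed"] = cfg.seed
    summary["version"] = __version__
    summary["config_hash"] = cfg_hash
    summary.to_csv(out / "summary.csv", index=False)
    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.csv", index=False)
    if cfg.plots:
        try:
            from . import plots
            plots.report_figures(out, records, objects, tables)
        except ImportError:
            warnings.warn("matplotlib unavailable; skipping figures", stacklevel=2)
    results["runtime_seconds"] = time.time() - t_start
    return PipelineResult(summary=summary, tables=tables, chains=chains, objects=objects)
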