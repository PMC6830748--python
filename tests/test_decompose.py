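import numpy as np
import pandas as pd
import pytest

from wildqg import (Reference, component_table, covariate_trajectories,
                    geber_contribution, trajectory_slope)
from wildqg.model import PosteriorChain

REF = Reference(baseline_days=30.0, phenotypic_sd=30.0)


def coef_chain(coefs: dict, n=8):
    """Chain with given fixed-effect coefficient values (constant samples)."""
    fx = pd.DataFrame({k: np.full(n, v) for k, v in coefs.items()})
    fx.insert(0, "intercept", np.zeros(n))
    return PosteriorChain(
        spec=None, seed=0, fixed={"z": fx},
        blocks={"year": np.full((n, 1, 1), 1.0)}, block_traits={"year": ("z",)},
        resid={"z": np.ones(n)}, additive_effects=None, ped_ids=None,
    )


def synthetic_records(n_years=20, temp_slope=0.03, seed=0):
    rng = np.random.default_rng(seed)
    years = np.repeat(np.arange(2000, 2000 + n_years), 30)
    df = pd.DataFrame({
        "female": [f"f{i%60}" for i in range(len(years))],
        "year": years,
        "age": rng.integers(3, 15, len(years)).astype(float),
        "status": rng.choice(["milk", "naive", "true.yeld"], len(years)),
        "offspring_sex": rng.choice(["F", "M"], len(years)),
        "temperature": 13.0 + temp_slope * (years - 2000) + rng.normal(0, 0.1, len(years)),
        "inbreeding": 0.01,
        "genetic_group": rng.uniform(0, 0.2, len(years)),
    })
    return df


class TestTrajectories:
    def test_constant_covariate_flat(self):
        rec = synthetic_records()
        rec["temperature"] = 12.5
        traj = covariate_trajectories(rec)
        assert traj["temperature"].slope == pytest.approx(0.0, abs=1e-12)

    def test_temperature_slope_recovered(self):
        traj = covariate_trajectories(synthetic_records(temp_slope=0.03))
        assert traj["temperature"].slope == pytest.approx(0.03, abs=0.01)

    def test_sex_ratio_near_half(self):
        traj = covariate_trajectories(synthetic_records())
        assert traj["offspring_sex[M]"].yearly.mean() == pytest.approx(0.5, abs=0.05)

    def test_status_proportions_sum_to_one(self):
        traj = covariate_trajectories(synthetic_records())
        tot = sum(traj[k].yearly for k in traj if k.startswith("status["))
        assert np.allclose(tot, 1.0)

    def test_gap_year_flagged(self):
        rec = synthetic_records()
        rec = rec[rec["year"] != 2005]
        with pytest.warns(UserWarning, match="without records"):
            traj = covariate_trajectories(rec)
        assert np.isnan(traj["temperature"].yearly.loc[2005])


class TestGeber:
    def test_zero_coefficient_zero_contribution(self):
        traj = covariate_trajectories(synthetic_records())
        ch = coef_chain({"temperature": 0.0})
        comp = geber_contribution(ch, "temperature", traj, REF)
        assert np.all(comp.days_samples == 0.0)

    def test_arithmetic(self):
        # coefficient 2 x slope 0.5/yr x span 45 = +45 working units
        years = np.arange(2000, 2010)
        traj = {"temperature": type("T", (), {
            "slope": 0.5, "yearly": pd.Series(0.5 * (years - 2000.0), index=years)})()}
        ch = coef_chain({"temperature": 2.0})
        comp = geber_contribution(ch, "temperature", traj, REF)
        assert np.allclose(comp.working_samples, 45.0)
        assert np.allclose(comp.days_samples, 30.0 * (np.exp(0.45) - 1.0))

    def test_constant_covariate_gives_zero(self):
        rec = synthetic_records()
        rec["genetic_group"] = 0.1
        traj = covariate_trajectories(rec)
        ch = coef_chain({"genetic_group": 5.0})
        comp = geber_contribution(ch, "genetic_group", traj, REF)
        assert np.allclose(comp.working_samples, 0.0, atol=1e-9)

    def test_additivity_on_working_scale(self):
        traj = covariate_trajectories(synthetic_records())
        ch = coef_chain({"temperature": -2.0, "age": -3.0, "age2": 0.15})
        joint = (geber_contribution(ch, "temperature", traj, REF).working_samples
                 + geber_contribution(ch, "age", traj, REF).working_samples)
        # recompute from scratch: sum of coefficient x slope x span
        expect = (-2.0 * traj["temperature"].slope
                  - 3.0 * traj["age"].slope + 0.15 * traj["age2"].slope) * 45.0
        assert np.allclose(joint, expect, atol=1e-9)

    def test_reference_level_invariance(self):
        """Adding a constant to every status level's effect (a change of
        reference level) leaves the component unchanged because the level
        proportions sum to one in every year."""
        rec = synthetic_records(seed=3)
        traj = covariate_trajectories(rec)
        levels = [k for k in traj if k.startswith("status[")]
        base = {lev: b for lev, b in zip(levels, [0.0, 1.5, -2.0])}
        shifted = {lev: b + 7.0 for lev, b in base.items()}
        c1 = geber_contribution(coef_chain(base), "status", traj, REF)
        c2 = geber_contribution(coef_chain(shifted), "status", traj, REF)
        assert np.allclose(c1.working_samples, c2.working_samples, atol=1e-8)

    def test_missing_coefficient_fatal(self):
        traj = covariate_trajectories(synthetic_records())
        ch = coef_chain({"temperature": 1.0})
        with pytest.raises(ValueError, match="lacks coefficients"):
            geber_contribution(ch, "age", traj, REF)


class TestComponentTable:
    def test_all_zero_coefficients(self):
        traj = covariate_trajectories(synthetic_records())
        ch = coef_chain({"temperature": 0.0, "age": 0.0, "age2": 0.0})
        comps = [geber_contribution(ch, c, traj, REF) for c in ("temperature", "age")]
        tab = component_table(comps, observed_days=-12.3,
                              evolution={"evolution": np.zeros(8)}, ref=REF)
        expl = tab.loc[tab["component"] == "explained (fixed effects)", "mode"].iloc[0]
        unexp = tab.loc[tab["component"] == "unexplained", "mode"].iloc[0]
        assert expl == pytest.approx(0.0, abs=1e-12)
        assert unexp == pytest.approx(-12.3, abs=1e-12)

    def test_rollup_rows_present(self):
        traj = covariate_trajectories(synthetic_records())
        ch = coef_chain({"temperature": -1.0})
        comps = [geber_contribution(ch, "temperature", traj, REF)]
        tab = component_table(comps, observed_days=-10.0,
                              evolution={"evo": np.full(8, -2.0)}, ref=REF)
        kinds = set(tab["kind"])
        assert {"fixed-effect", "evolution", "roll-up", "observed"} <= kinds


def test_trajectory_slope_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(5)
    years = np.arange(1990, 2020)
    y = pd.Series(0.2 * years + rng.normal(0, 1, len(years)), index=years)
    fit = sm.OLS(y.to_numpy(), sm.add_constant(years.astype(float))).fit()
    assert trajectory_slope(y) == pytest.approx(fit.params[1], rel=1e-10)


class TestTruthRecovery:
    def test_temperature_only_change_attributed_to_temperature(self):
        """When warming is the only systematic driver (all other fixed
        effects zero, no selection, no environmental year trend), the
        temperature component accounts for the bulk of the observed change
        and every other component sits near zero."""
        import warnings

        from conftest import small_config
        from wildqg import (ChainSettings, ModelSpec, component_table,
                            fit_model, phenotypic_trend, simulate_population)

        warnings.filterwarnings("ignore", category=RuntimeWarning)
        cfg = small_config(
            beta_age=0.0, beta_age2=0.0, beta_offspring_male=0.0,
            beta_inbreeding=0.0, beta_genetic_group=0.0,
            status_effects={s: 0.0 for s in
                            ("milk", "naive", "summer.yeld", "true.yeld", "winter.yeld")},
            env_trend=0.0, selection_strength=0.0, genetic_cov_fitness=0.0,
            temp_slope=0.12, temp_sd=0.5, sigma_year=20.0, seed=71,
        )
        ds = simulate_population(cfg)
        # without the year covariate so the temperature trend is not shared
        chain = fit_model(
            ModelSpec.univariate(year_covariate=False, inbreeding=False,
                                 chain=ChainSettings(1200, 400, 2, seed=3)),
            ds.records, ds.pedigree, female_covariates=ds.truth_individuals)
        ref = Reference.from_data(ds.records, chain, span_years=cfg.n_years)
        traj = covariate_trajectories(ds.records)
        comps = {c: geber_contribution(chain, c, traj, ref)
                 for c in ("age", "status", "offspring_sex", "temperature",
                           "genetic_group")}
        observed = phenotypic_trend(ds.records)["total_days"]
        # truth: beta_T * slope * span on the working scale, in days
        truth_working = cfg.beta_temperature * cfg.temp_slope * cfg.n_years
        truth_days = ref.baseline_days * (np.exp(truth_working / 100.0) - 1.0)
        temp = comps["temperature"].summary
        assert temp.hpd_low <= truth_days <= temp.hpd_high
        assert temp.mode < 0
        for name, c in comps.items():
            if name != "temperature":
                assert abs(c.summary.mode) < 0.35, name
        tab = component_table(list(comps.values()), observed,
                              evolution={"evolution": np.zeros(chain.n_samples)},
                              ref=ref)
        unexp = tab.loc[tab["component"] == "unexplained", ["hpd_low", "hpd_high"]].iloc[0]
        assert unexp["hpd_low"] <= 0.0 <= unexp["hpd_high"] or abs(
            tab.loc[tab["component"] == "unexplained", "mode"].iloc[0]) < 2.0
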