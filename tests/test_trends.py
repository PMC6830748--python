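import numpy as np
import pandas as pd
import pytest

from wildqg import (Reference, blup_trend, blup_trend_spline, drift_null,
                    mean_offspring_year, sts_estimate)
from wildqg.model import PosteriorChain

from test_model import make_chain

REF = Reference(baseline_days=30.0, phenotypic_sd=30.0)


def bv_chain(bv_matrix, ids):
    """Chain whose additive-effect samples are given directly."""
    bv = np.asarray(bv_matrix, float)
    S = bv.shape[0]
    return PosteriorChain(
        spec=None, seed=0,
        fixed={"z": pd.DataFrame({"intercept": np.zeros(S)})},
        blocks={"additive": np.full((S, 1, 1), 1.0)},
        block_traits={"additive": ("z",)},
        resid={"z": np.ones(S)},
        additive_effects=bv[:, :, None],
        ped_ids=np.asarray(ids),
    )


def records_for(females, years):
    return pd.DataFrame({"female": females, "year": years,
                         "pdate": 30.0, "z": 340.0})


class TestBlupTrend:
    def test_degenerate_all_zero(self):
        ids = [f"f{i}" for i in range(6)]
        rec = records_for(ids, [2000, 2001, 2002, 2003, 2004, 2005])
        ch = bv_chain(np.zeros((20, 6)), ids)
        bt = blup_trend(ch, rec, REF)
        assert bt.degenerate
        assert np.isnan(bt.prob_nonnegative)
        assert np.all(bt.slope_samples == 0.0)

    def test_recovers_linear_trend_in_bvs(self):
        # regression-recipe oracle: BVs exactly linear in mean offspring year
        ids = [f"f{i}" for i in range(10)]
        years = np.arange(2000, 2010)
        rec = records_for(ids, years)
        bv = np.tile(-0.3 * (years - years.mean()), (15, 1))
        bt = blup_trend(bv_chain(bv, ids), rec)
        assert bt.summary.mode == pytest.approx(-0.3, abs=1e-9)
        assert bt.prob_nonnegative == 0.0
        # matches an independent least-squares fit
        ref_slope = np.polyfit(years, bv[0], 1)[0]
        assert bt.slope_samples[0] == pytest.approx(ref_slope, abs=1e-9)

    def test_mean_offspring_year_aggregation(self):
        rec = pd.DataFrame({"female": ["a", "a", "b"], "year": [2000, 2004, 2002]})
        moy = mean_offspring_year(rec)
        assert moy["a"] == 2002.0 and moy["b"] == 2002.0

    def test_few_females_fatal(self):
        ids = ["a", "b"]
        rec = records_for(ids, [2000, 2001])
        with pytest.raises(ValueError, match="at least 3"):
            blup_trend(bv_chain(np.zeros((5, 2)), ids), rec)


class TestSpline:
    def test_constant_bvs_give_flat_curves(self):
        ids = [f"f{i}" for i in range(8)]
        membership = {y: ids for y in range(2000, 2012)}
        ch = bv_chain(np.full((10, 8), 2.5), ids)
        curves = blup_trend_spline(ch, membership)
        assert np.allclose(curves["value"], 2.5, atol=1e-9)

    def test_linear_bvs_give_linear_curves(self):
        years = np.arange(2000, 2015)
        ids = [f"f{y}" for y in years]
        membership = {int(y): [f"f{y}"] for y in years}
        bv = np.tile(0.4 * (years - 2000.0), (5, 1))
        curves = blup_trend_spline(bv_chain(bv, ids), membership)
        for _, g in curves.groupby("sample"):
            fitted = np.polyval(np.polyfit(g["year"], g["value"], 1), g["year"])
            assert np.allclose(g["value"], fitted, atol=1e-6)


class TestSts:
    def test_zero_additive_cross_covariance(self):
        S = np.array([[100.0, 0.0], [0.0, 1.0]])
        ch = make_chain({"additive": [S] * 8}, {"additive": ("z", "lbs")},
                        {"z": [1.0] * 8})
        est = sts_estimate(ch, REF)
        assert np.all(est.units["days_span"] == 0.0)

    def test_halving(self):
        S = np.array([[100.0, -2.0], [-2.0, 1.0]])
        ch = make_chain({"additive": [S] * 8}, {"additive": ("z", "lbs")},
                        {"z": [1.0] * 8})
        est = sts_estimate(ch, REF)
        assert np.allclose(est.units["working_per_generation"], -1.0)

    def test_missing_cross_covariance_fatal(self):
        ch = make_chain({"additive": [1.0] * 5}, {"additive": ("z",)},
                        {"z": [1.0] * 5})
        with pytest.raises(ValueError):
            sts_estimate(ch, REF)


class TestDriftNull:
    def test_symmetric_null_exceedance_near_half(self, small_dataset):
        ds = small_dataset
        dn = drift_null(ds.pedigree, np.full(50, 100.0), ds.records,
                        observed_slope=0.0, n_sims=400, seed=1)
        assert dn.exceedance == pytest.approx(0.5, abs=0.08)
        # null slopes are mean-zero within Monte-Carlo error
        se = dn.null_slopes.std() / np.sqrt(dn.n_sims)
        assert abs(dn.null_slopes.mean()) < 4 * se

    def test_extreme_observed_slope(self, small_dataset):
        ds = small_dataset
        dn = drift_null(ds.pedigree, np.full(20, 100.0), ds.records,
                        observed_slope=-1e9, n_sims=100, seed=2)
        assert dn.exceedance == 0.0

    def test_sign_symmetric_distribution(self, small_dataset):
        ds = small_dataset
        a = drift_null(ds.pedigree, np.full(20, 100.0), ds.records,
                       observed_slope=-0.5, n_sims=2000, seed=3)
        b = drift_null(ds.pedigree, np.full(20, 100.0), ds.records,
                       observed_slope=0.5, n_sims=2000, seed=3)
        # P(slope <= -c) should mirror P(slope >= c)
        assert a.exceedance == pytest.approx(1.0 - b.exceedance, abs=0.04)


class TestDriftStability:
    def test_exceedance_stable_in_n_sims(self, small_dataset):
        """Going from 1,000 to 10,000 drift simulations moves the
        exceedance fraction by less than 0.02."""
        ds = small_dataset
        a = drift_null(ds.pedigree, np.full(30, 100.0), ds.records,
                       observed_slope=-0.05, n_sims=1000, seed=11)
        b = drift_null(ds.pedigree, np.full(30, 100.0), ds.records,
                       observed_slope=-0.05, n_sims=10000, seed=12)
        assert 0.02 < a.exceedance < 0.98  # informative comparison point
        assert abs(a.exceedance - b.exceedance) < 0.02


class TestRegressionRecipeOracle:
    def test_truth_bv_trend_recovered(self, small_dataset):
        """Applying the regression recipe to the simulator's true BVs
        recovers the realised genetic trend."""
        ds = small_dataset
        moy = mean_offspring_year(ds.records)
        truth = ds.truth_individuals.set_index("id").loc[moy.index, "a"]
        expect = np.polyfit(moy.to_numpy(float), truth.to_numpy(), 1)[0]
        ch = bv_chain(np.tile(truth.to_numpy(), (7, 1)), list(moy.index))
        bt = blup_trend(ch, ds.records)
        assert bt.summary.mode == pytest.approx(expect, rel=1e-6)
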