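import warnings

import numpy as np
import pandas as pd
import pytest

from wildqg import (ChainSettings, ModelSpec, PosteriorChain, TraitSpec,
                    effective_sample_size, extract_blups, fit_model,
                    heritability, repeatability, validate_pedigree)

from conftest import tiny_config
from wildqg.simulate import simulate_population

warnings.filterwarnings("ignore", category=RuntimeWarning)


def make_chain(blocks, block_traits, resid, fixed=None):
    """Hand-build a PosteriorChain for arithmetic tests."""
    S = len(next(iter(resid.values())))
    fixed = fixed or {"z": pd.DataFrame({"intercept": np.zeros(S)})}
    return PosteriorChain(
        spec=None, seed=0, fixed=fixed,
        blocks={b: np.asarray(v, float).reshape(S, *np.shape(v[0])) if np.ndim(v[0]) else
                np.asarray(v, float)[:, None, None] for b, v in blocks.items()},
        block_traits=block_traits,
        resid={k: np.asarray(v, float) for k, v in resid.items()},
        additive_effects=None, ped_ids=None,
    )


class TestSummariesArithmetic:
    def test_heritability_single_sample(self):
        ch = make_chain(
            {"additive": [2.0], "individual": [3.0], "maternal": [1.0],
             "cohort": [1.0], "year": [1.0]},
            {b: ("z",) for b in ("additive", "individual", "maternal", "cohort", "year")},
            {"z": [2.0]},
        )
        h2, s = heritability(ch)
        assert h2[0] == pytest.approx(0.2)

    def test_heritability_constant_half(self):
        ch = make_chain(
            {"additive": [5.0] * 50, "year": [3.0] * 50},
            {"additive": ("z",), "year": ("z",)},
            {"z": [2.0] * 50},
        )
        h2, s = heritability(ch)
        assert s.mode == pytest.approx(0.5)
        assert (s.hpd_low, s.hpd_high) == (0.5, 0.5)

    def test_repeatability_additive_year_resid_only(self):
        ch = make_chain(
            {"additive": [4.0] * 20, "year": [2.0] * 20},
            {"additive": ("z",), "year": ("z",)},
            {"z": [2.0] * 20},
            fixed={"z": pd.DataFrame({"intercept": np.zeros(20)})},
        )
        cov = pd.DataFrame({"inbreeding": [0.0, 0.1], "genetic_group": [0.0, 0.0]})
        rep, s = repeatability(ch, cov)
        assert rep[0] == pytest.approx(4.0 / 8.0)

    def test_repeatability_zero_when_nothing_constant(self):
        ch = make_chain(
            {"year": [2.0] * 20},
            {"year": ("z",)},
            {"z": [2.0] * 20},
        )
        cov = pd.DataFrame({"inbreeding": [0.0, 0.0], "genetic_group": [0.0, 0.0]})
        rep, s = repeatability(ch, cov)
        assert np.all(rep == 0.0)


@pytest.fixture(scope="module")
def tiny_ds():
    return simulate_population(tiny_config())


def quick_chain(seed, iters=800, burn=300, thin=2):
    return ChainSettings(iterations=iters, burn_in=burn, thinning=thin, seed=seed)


class TestFitting:
    def test_same_seed_identical_chains(self, tiny_ds):
        spec = ModelSpec.univariate(inbreeding=False, chain=quick_chain(5, 300, 100))
        a = fit_model(spec, tiny_ds.records, tiny_ds.pedigree)
        b = fit_model(spec, tiny_ds.records, tiny_ds.pedigree)
        assert np.array_equal(a.vc("additive", "z"), b.vc("additive", "z"))
        assert a.fixed["z"].equals(b.fixed["z"])

    def test_chain_invariants(self, tiny_ds):
        spec = ModelSpec.univariate(inbreeding=False, chain=quick_chain(6, 400, 100, 3))
        ch = fit_model(spec, tiny_ds.records, tiny_ds.pedigree)
        assert ch.n_samples == spec.chain.n_samples
        for b in ch.blocks:
            for t in ch.block_traits[b]:
                assert np.all(ch.vc(b, t) > 0)
        assert np.all(ch.resid["z"] > 0)

    def test_zero_additive_variance_detected(self):
        cfg = tiny_config(sigma_a=0.0, gencov_z_bw=0.0, genetic_cov_fitness=0.0,
                          selection_strength=0.0, seed=33)
        ds = simulate_population(cfg)
        spec = ModelSpec.univariate(inbreeding=False, chain=quick_chain(7, 1000, 300))
        ch = fit_model(spec, ds.records, ds.pedigree)
        h2, s = heritability(ch)
        assert s.mode < 0.05

    def test_unphenotyped_offspring_blup_is_half_of_parents(self):
        # conditional-normal oracle: with an unknown sire, an unphenotyped
        # daughter's BV posterior mean is half her dam's
        rng = np.random.default_rng(8)
        n_dam = 40
        rows = []
        for i in range(n_dam):
            rows.append((f"d{i}", "", "", "F", 0))
            rows.append((f"o{i}", "", f"d{i}", "F", 1))
        ped = validate_pedigree(pd.DataFrame(
            rows, columns=["id", "sire", "dam", "sex", "cohort"]))
        a = rng.normal(0, 2.0, n_dam)
        rec = pd.DataFrame({
            "female": np.repeat([f"d{i}" for i in range(n_dam)], 8),
            "year": 2000,
            "z": np.repeat(a, 8) + rng.normal(0, 1.0, n_dam * 8),
        })
        spec = ModelSpec((TraitSpec("z", "gaussian", (), ("additive",)),),
                         chain=quick_chain(8, 2000, 500, 3))
        ch = fit_model(spec, rec, ped, prune=False)
        dams = extract_blups(ch, [f"d{i}" for i in range(n_dam)]).mean(axis=0).to_numpy()
        offs = extract_blups(ch, [f"o{i}" for i in range(n_dam)]).mean(axis=0).to_numpy()
        slope = (dams @ offs) / (dams @ dams)
        assert slope == pytest.approx(0.5, abs=0.06)

    def test_blup_accuracy_increases_with_h2(self):
        corr = {}
        for h2, (sa, sr) in {"low": (90.0, 810.0), "high": (540.0, 360.0)}.items():
            cfg = tiny_config(sigma_a=sa, sigma_resid=sr, seed=34,
                              gencov_z_bw=0.0, selection_strength=0.0)
            ds = simulate_population(cfg)
            spec = ModelSpec.univariate(inbreeding=False, chain=quick_chain(9, 1500, 500))
            ch = fit_model(spec, ds.records, ds.pedigree)
            females = sorted(set(ds.records["female"]))
            est = extract_blups(ch, females).mean(axis=0)
            truth = ds.truth_individuals.set_index("id").loc[females, "a"]
            corr[h2] = np.corrcoef(est, truth)[0, 1]
        assert corr["high"] > corr["low"] > 0

    def test_variance_proportions_invariant_to_scaling(self, tiny_ds):
        spec = ModelSpec.univariate(inbreeding=False, chain=quick_chain(10, 500, 200))
        a = fit_model(spec, tiny_ds.records, tiny_ds.pedigree)
        rec2 = tiny_ds.records.copy()
        rec2["z"] = rec2["z"] * 3.0
        b = fit_model(spec, rec2, tiny_ds.pedigree)
        h2a, sa = heritability(a)
        h2b, sb = heritability(b)
        # the chains share an RNG stream but tiny float differences grow
        # chaotically, so compare the posteriors, not individual draws
        assert abs(h2a.mean() - h2b.mean()) < 0.02
        assert abs(sa.mode - sb.mode) < 0.02
        ra = (a.resid["z"] / a.total_variance("z")).mean()
        rb = (b.resid["z"] / b.total_variance("z")).mean()
        assert abs(ra - rb) < 0.02

    def test_singular_design_fatal(self, tiny_ds):
        rec = tiny_ds.records.copy()
        rec["temperature"] = 5.0  # collinear with the intercept
        with pytest.raises(ValueError, match="singular"):
            fit_model(ModelSpec.univariate(inbreeding=False, chain=quick_chain(11, 200, 50)),
                      rec, tiny_ds.pedigree)

    def test_extract_blups_missing_individual_fatal(self, tiny_ds):
        spec = ModelSpec.univariate(inbreeding=False, chain=quick_chain(12, 300, 100))
        ch = fit_model(spec, tiny_ds.records, tiny_ds.pedigree)
        with pytest.raises(KeyError):
            extract_blups(ch, ["nobody-here"])


class TestPriorFamilies:
    def test_prior_swap_leaves_differential_indistinguishable(self, tiny_ds):
        from wildqg import selection_differential

        modes = {}
        hpd_width = None
        for prior in ("inverse_gamma", "parameter_expanded"):
            spec = ModelSpec.selection(chain=quick_chain(13, 1200, 400), prior=prior, inbreeding=False)
            ch = fit_model(spec, tiny_ds.records, tiny_ds.pedigree,
                           fitness=tiny_ds.fitness,
                           female_covariates=tiny_ds.truth_individuals)
            est = selection_differential(ch)
            modes[prior] = est.summary.mode
            hpd_width = est.summary.hpd_high - est.summary.hpd_low
        assert abs(modes["inverse_gamma"] - modes["parameter_expanded"]) < 0.10 * hpd_width


def test_effective_sample_size_behaviour():
    rng = np.random.default_rng(0)
    iid = rng.standard_normal(2000)
    ar = np.empty(2000)
    ar[0] = 0.0
    for i in range(1, 2000):
        ar[i] = 0.95 * ar[i - 1] + rng.standard_normal()
    assert effective_sample_size(iid) > 1200
    assert effective_sample_size(ar) < 400
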