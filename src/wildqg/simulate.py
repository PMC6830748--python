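"""Synthetic pedigreed populations with known ground truth.

The generator emulates the statistical structure of a long-term study of
parturition date in a wild ungulate population: an overlapping-generation
pedigree built by yearly demography, a heritable log-scale trait with
additive, permanent-environment, maternal, year, cohort and residual
variance components, an offspring birth-weight trait genetically correlated
with it, lifetime breeding success (LBS) as an overdispersed, zero-inflated
Poisson fitness measure genetically correlated with the trait, a warming
temperature covariate, immigrant founders, and random culling.

The working phenotype is ``z = 100 * ln(B)`` where ``B`` is parturition
date in days after May 1; fixed-effect sizes and variance components below
are all on that working scale. Every stochastic component of each record is
stored in truth tables, so the decomposition ``z = mu + fixed + a + p + m +
c + y + r`` is exact and every downstream estimator can be checked against
its simulated truth.

Fecundity selection is implemented mechanistically: a female's annual
probability of breeding declines on the logit scale with her genetic +
permanent-environment propensity for late parturition, which produces a
genuine trend in breeding values down the pedigree. The LBS table is, by
default, drawn from the configured latent-scale model (a known additive
trait-fitness covariance), which gives every fitness-based estimator an
exactly known truth; set ``fitness_mode='pedigree'`` to use realised
offspring counts instead.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree, genetic_group_proportions, validate_pedigree

__all__ = ["SimulationConfig", "SyntheticDataset", "SimulationError", "simulate_population", "simulate_fitness"]


class SimulationError(RuntimeError):
    """Raised when the simulated population goes extinct or config is invalid."""


STATUSES = ("milk", "naive", "summer.yeld", "true.yeld", "winter.yeld")


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic study system.

    Defaults are tuned to the scale of the motivating study system: about
    3,300 calving records from ~750 breeding females over a 45-year period,
    a working-scale phenotypic variance near 900 (h2 ~ 0.17, repeatability
    ~ 0.2), a warming rut-period temperature, and fecundity selection for
    earlier parturition.
    """

    seed: int = 20160501

    # demography
    n_founder_females: int = 80
    n_founder_males: int = 60
    n_years: int = 45
    start_year: int = 1972
    carrying_capacity: int = 75          # breeding females per year
    breeding_prob: float = 0.55          # baseline annual breeding probability
    female_breeding_ages: tuple = (3, 16)
    male_breeding_ages: tuple = (4, 14)
    max_age: int = 18
    calf_survival: float = 0.75          # survival through first year
    juvenile_survival: float = 0.90      # ages 1-2
    adult_survival: float = 0.95         # ages 3-9; declines linearly after
    senescence_rate: float = 0.05        # survival drop per year past age 9
    n_immigrants: int = 20               # immigrant founders over the study
    immigrant_bv_shift: float = 0.0      # mean BV of immigrant founders (working scale)
    male_skew: float = 0.8               # lognormal SD of per-male yearly mating weight

    # trait: working scale z = 100*ln(days after May 1)
    mu: float = 380.0
    sigma_a: float = 150.0
    sigma_pe: float = 10.0
    sigma_m: float = 8.0
    sigma_year: float = 70.0
    sigma_cohort: float = 15.0
    sigma_resid: float = 650.0
    beta_age: float = -3.0
    beta_age2: float = 0.15
    status_effects: dict = field(
        default_factory=lambda: {
            "milk": 0.0,
            "naive": 5.0,
            "summer.yeld": -2.0,
            "true.yeld": -5.0,
            "winter.yeld": -4.0,
        }
    )
    beta_offspring_male: float = 0.5
    beta_temperature: float = -2.5
    beta_inbreeding: float = 20.0
    beta_genetic_group: float = 2.0
    env_trend: float = -0.35             # linear year trend folded into year effects

    # temperature trajectory (degrees C)
    temp_intercept: float = 13.0
    temp_slope: float = 0.04
    temp_sd: float = 0.4

    # offspring birth weight (kg), treated as a maternal trait
    mu_bw: float = 6.5
    sigma_a_bw: float = 0.68
    gencov_z_bw: float = -1.78
    sigma_pe_bw: float = 0.15
    sigma_m_bw: float = 0.05
    sigma_year_bw: float = 0.10
    sigma_cohort_bw: float = 0.05
    sigma_resid_bw: float = 0.60
    beta_offspring_male_bw: float = 0.3

    # selection & fitness
    selection_strength: float = 0.05     # logit decline of breeding prob per working unit
    genetic_cov_fitness: float = -5.5    # sigma_A(z, latent log fitness)
    fitness_intercept: float = 0.55      # latent log mean of LBS
    fitness_overdispersion_sd: float = 0.5
    zero_inflation: float = 0.20
    fitness_mode: str = "drawn"          # 'drawn' (configured model) or 'pedigree'
    standardize_founder_bv: bool = False # rescale initial founders' BVs so their
                                         # sample covariance equals the configured
                                         # additive covariance exactly (used by
                                         # parameter-recovery experiments)
    culling_prob: float = 0.15
    culling_mode: str = "random"         # 'random' or 'truncate'

    def validate(self) -> None:
        for name in (
            "sigma_a", "sigma_pe", "sigma_m", "sigma_year", "sigma_cohort",
            "sigma_resid", "sigma_a_bw", "sigma_pe_bw", "sigma_m_bw",
            "sigma_year_bw", "sigma_cohort_bw", "sigma_resid_bw",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"variance {name} must be >= 0")
        for name in ("breeding_prob", "zero_inflation", "culling_prob",
                     "calf_survival", "juvenile_survival", "adult_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"probability {name}={v} outside [0, 1]")
        ga = np.array([[self.sigma_a, self.gencov_z_bw], [self.gencov_z_bw, self.sigma_a_bw]])
        if np.linalg.eigvalsh(ga).min() < -1e-9:
            raise SimulationError("additive (z, bw) covariance matrix not positive semi-definite")
        if self.fitness_mode not in ("drawn", "pedigree"):
            raise SimulationError(f"unknown fitness_mode {self.fitness_mode!r}")
        if self.culling_mode not in ("random", "truncate"):
            raise SimulationError(f"unknown culling_mode {self.culling_mode!r}")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_file(self, path) -> None:
        d = dataclasses.asdict(self)
        d["female_breeding_ages"] = list(d["female_breeding_ages"])
        d["male_breeding_ages"] = list(d["male_breeding_ages"])
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        for k in ("female_breeding_ages", "male_breeding_ages"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SyntheticDataset:
    """A simulated population: pedigree, phenotype and fitness tables, truth."""

    pedigree: Pedigree
    records: pd.DataFrame        # one row per calving
    fitness: pd.DataFrame        # one row per female: lbs, culled, alive
    temperature: pd.DataFrame    # year, temperature
    truth_individuals: pd.DataFrame
    truth_records: pd.DataFrame  # per-record variance components
    config: SimulationConfig

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.table.to_csv(out / "pedigree.csv", index=False)
        self.records.to_csv(out / "records.csv", index=False)
        self.fitness.to_csv(out / "fitness.csv", index=False)
        self.temperature.to_csv(out / "temperature.csv", index=False)
        self.truth_individuals.to_csv(out / "truth_individuals.csv", index=False)
        self.truth_records.to_csv(out / "truth_records.csv", index=False)
        self.config.to_file(out / "config.json")


def _survival(cfg: SimulationConfig, age: int) -> float:
    if age < 1:
        return cfg.calf_survival
    if age < 3:
        return cfg.juvenile_survival
    if age <= 9:
        return cfg.adult_survival
    return max(cfg.adult_survival - cfg.senescence_rate * (age - 9), 0.0)


def simulate_population(cfg: SimulationConfig) -> SyntheticDataset:
    """Run the full demographic + phenotypic simulation.

    Phase 1 runs the yearly demography (who lives, who breeds with whom),
    propagating true breeding values down the pedigree as it grows so that
    fecundity selection can act on them. Phase 2 validates the pedigree,
    computes inbreeding and immigrant-ancestry covariates, and assembles
    phenotypes component by component.

    Raises
    ------
    SimulationError
        If the population runs out of breeding females or sires.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    logit_p0 = np.log(cfg.breeding_prob / (1 - cfg.breeding_prob))
    G = np.array([[cfg.sigma_a, cfg.gencov_z_bw], [cfg.gencov_z_bw, cfg.sigma_a_bw]])
    Lg = _chol_psd(G)

    # --- phase 1: demography --------------------------------------------
    ind: dict[str, dict] = {}
    counter = [0]

    founder_pool: list = []
    if cfg.standardize_founder_bv:
        n_f0 = cfg.n_founder_females + cfg.n_founder_males
        raw = rng.standard_normal((n_f0, 2)) @ Lg.T
        X = raw - raw.mean(axis=0)
        S_emp = X.T @ X / n_f0
        if np.linalg.eigvalsh(G).min() > 1e-9 and np.linalg.eigvalsh(S_emp).min() > 0:
            X = X @ np.linalg.inv(np.linalg.cholesky(S_emp)).T @ Lg.T
        founder_pool = list(X)

    def new_individual(sex, cohort, sire="", dam="", immigrant=0.0):
        counter[0] += 1
        iid = f"D{counter[0]:05d}"
        if sire == "" and dam == "":
            if founder_pool and not immigrant:
                a = founder_pool.pop()
            else:
                a = Lg @ rng.standard_normal(2)
            if immigrant:
                a = a + np.array([cfg.immigrant_bv_shift, 0.0])
        else:
            mid = 0.5 * (ind[sire]["a"] + ind[dam]["a"])
            a = mid + np.sqrt(0.5) * (Lg @ rng.standard_normal(2))
        ind[iid] = dict(
            sex=sex, cohort=cohort, sire=sire, dam=dam, a=a,
            pe=rng.normal(0.0, np.sqrt(cfg.sigma_pe)),
            pe_bw=rng.normal(0.0, np.sqrt(cfg.sigma_pe_bw)),
            mat=rng.normal(0.0, np.sqrt(cfg.sigma_m)),
            mat_bw=rng.normal(0.0, np.sqrt(cfg.sigma_m_bw)),
            alive=True, death_year=None, ever_bred=False, last_bred=None,
            immigrant=immigrant,
        )
        return iid

    for _ in range(cfg.n_founder_females):
        age = int(rng.integers(1, 10))
        new_individual("F", cfg.start_year - age)
    for _ in range(cfg.n_founder_males):
        age = int(rng.integers(1, 10))
        new_individual("M", cfg.start_year - age)
    immigrant_years = np.sort(rng.integers(1, cfg.n_years, size=cfg.n_immigrants))

    years = np.arange(cfg.start_year, cfg.start_year + cfg.n_years)
    temperature = cfg.temp_intercept + cfg.temp_slope * np.arange(cfg.n_years) + rng.normal(
        0.0, cfg.temp_sd, size=cfg.n_years
    )
    events = []  # (dam, sire, offspring, year, age, status)

    for t, year in enumerate(years):
        # immigrants arrive as young adults with unknown parents
        for _ in range(int(np.sum(immigrant_years == t))):
            sex = "F" if rng.random() < 0.5 else "M"
            new_individual(sex, year - int(rng.integers(2, 5)), immigrant=1.0)

        alive = [i for i, v in ind.items() if v["alive"]]
        fem = [i for i in alive if ind[i]["sex"] == "F"
               and cfg.female_breeding_ages[0] <= year - ind[i]["cohort"] <= cfg.female_breeding_ages[1]]
        males = [i for i in alive if ind[i]["sex"] == "M"
                 and cfg.male_breeding_ages[0] <= year - ind[i]["cohort"] <= cfg.male_breeding_ages[1]]
        if not fem or not males:
            raise SimulationError(
                f"population lost in {year}: {len(fem)} breeding females, {len(males)} sires alive"
            )
        # fecundity selection on the female's constant trait propensity
        prop = np.array([ind[i]["a"][0] + ind[i]["pe"] for i in fem])
        p = 1.0 / (1.0 + np.exp(-(logit_p0 - cfg.selection_strength * prop)))
        chosen = [i for i, u, pi in zip(fem, rng.random(len(fem)), p) if u < pi]
        if len(chosen) > cfg.carrying_capacity:
            keep = rng.choice(len(chosen), size=cfg.carrying_capacity, replace=False)
            chosen = [chosen[j] for j in sorted(keep)]
        weights = rng.lognormal(0.0, cfg.male_skew, size=len(males))
        weights /= weights.sum()
        for dam in chosen:
            sire = males[int(rng.choice(len(males), p=weights))]
            sex = "F" if rng.random() < 0.5 else "M"
            off = new_individual(sex, year, sire=sire, dam=dam)
            age = year - ind[dam]["cohort"]
            events.append((dam, sire, off, year, age, _status(ind[dam], year, rng)))
            ind[dam]["ever_bred"] = True
            ind[dam]["last_bred"] = year

        # survival
        for i in alive + [j for j in ind if ind[j]["cohort"] == year]:
            v = ind[i]
            if not v["alive"]:
                continue
            age = year - v["cohort"]
            if age >= cfg.max_age or rng.random() > _survival(cfg, age):
                v["alive"] = False
                v["death_year"] = year

    # --- phase 2: pedigree-derived covariates and phenotypes -------------
    ped_df = pd.DataFrame(
        {
            "id": list(ind.keys()),
            "sire": [v["sire"] for v in ind.values()],
            "dam": [v["dam"] for v in ind.values()],
            "sex": [v["sex"] for v in ind.values()],
            "cohort": [v["cohort"] for v in ind.values()],
        }
    )
    ped = validate_pedigree(ped_df)
    F = dict(zip(ped.ids, ped.inbreeding))
    q = dict(
        zip(
            ped.ids,
            genetic_group_proportions(
                ped, {i: v["immigrant"] for i, v in ind.items() if v["sire"] == ""}
            ),
        )
    )

    year_eff = cfg.env_trend * (np.arange(cfg.n_years) - (cfg.n_years - 1) / 2) + rng.normal(
        0.0, np.sqrt(cfg.sigma_year), size=cfg.n_years
    )
    year_eff_bw = rng.normal(0.0, np.sqrt(cfg.sigma_year_bw), size=cfg.n_years)
    cohorts = sorted({v["cohort"] for v in ind.values()})
    coh_eff = dict(zip(cohorts, rng.normal(0.0, np.sqrt(cfg.sigma_cohort), size=len(cohorts))))
    coh_eff_bw = dict(zip(cohorts, rng.normal(0.0, np.sqrt(cfg.sigma_cohort_bw), size=len(cohorts))))
    # maternal effect exerted on a female's records is her dam's; founders'
    # unknown dams each get a unique phantom effect
    phantom_m: dict[str, float] = {}
    phantom_m_bw: dict[str, float] = {}

    rec_rows, truth_rows = [], []
    for dam, sire, off, year, age, status in events:
        v = ind[dam]
        t = year - cfg.start_year
        if v["dam"] != "":
            m_eff, m_eff_bw = ind[v["dam"]]["mat"], ind[v["dam"]]["mat_bw"]
        else:
            if dam not in phantom_m:
                phantom_m[dam] = rng.normal(0.0, np.sqrt(cfg.sigma_m))
                phantom_m_bw[dam] = rng.normal(0.0, np.sqrt(cfg.sigma_m_bw))
            m_eff, m_eff_bw = phantom_m[dam], phantom_m_bw[dam]
        male = ind[off]["sex"] == "M"
        fixed = (
            cfg.beta_age * age
            + cfg.beta_age2 * age**2
            + cfg.status_effects[status]
            + cfg.beta_offspring_male * male
            + cfg.beta_temperature * temperature[t]
            + cfg.beta_inbreeding * F[dam]
            + cfg.beta_genetic_group * q[dam]
        )
        r = rng.normal(0.0, np.sqrt(cfg.sigma_resid))
        z = cfg.mu + fixed + v["a"][0] + v["pe"] + m_eff + coh_eff[v["cohort"]] + year_eff[t] + r
        r_bw = rng.normal(0.0, np.sqrt(cfg.sigma_resid_bw))
        bw = (
            cfg.mu_bw
            + cfg.beta_offspring_male_bw * male
            + v["a"][1]
            + v["pe_bw"]
            + m_eff_bw
            + coh_eff_bw[v["cohort"]]
            + year_eff_bw[t]
            + r_bw
        )
        rec_rows.append(
            dict(
                female=dam, year=year, age=age, status=status,
                offspring_id=off, offspring_sex=ind[off]["sex"],
                temperature=temperature[t], pdate=float(np.exp(z / 100.0)),
                z=z, birth_weight=bw, inbreeding=F[dam], genetic_group=q[dam],
            )
        )
        truth_rows.append(
            dict(
                female=dam, year=year, mu=cfg.mu, fixed=fixed, a=v["a"][0],
                pe=v["pe"], m=m_eff, c=coh_eff[v["cohort"]], y=year_eff[t], r=r, z=z,
            )
        )

    records = pd.DataFrame(rec_rows)
    truth_records = pd.DataFrame(truth_rows)
    truth_ind = pd.DataFrame(
        {
            "id": list(ind.keys()),
            "sex": [v["sex"] for v in ind.values()],
            "cohort": [v["cohort"] for v in ind.values()],
            "a": [v["a"][0] for v in ind.values()],
            "a_bw": [v["a"][1] for v in ind.values()],
            "pe": [v["pe"] for v in ind.values()],
            "maternal": [v["mat"] for v in ind.values()],
            "alive": [v["alive"] for v in ind.values()],
            "death_year": [v["death_year"] for v in ind.values()],
            "inbreeding": [F[i] for i in ind.keys()],
            "genetic_group": [q[i] for i in ind.keys()],
        }
    )
    ds = SyntheticDataset(
        pedigree=ped,
        records=records,
        fitness=pd.DataFrame(),
        temperature=pd.DataFrame({"year": years, "temperature": temperature}),
        truth_individuals=truth_ind,
        truth_records=truth_records,
        config=cfg,
    )
    ds.fitness = simulate_fitness(ds, cfg, rng=rng)
    return ds


def _status(v: dict, year: int, rng) -> str:
    """Reproductive status from recent breeding history (simple Markov rule)."""
    if not v["ever_bred"]:
        return "naive"
    if v["last_bred"] == year - 1:
        u = rng.random()
        if u < 0.60:
            return "milk"
        return "summer.yeld" if u < 0.80 else "winter.yeld"
    return "true.yeld"


def simulate_fitness(
    ds: SyntheticDataset, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Lifetime breeding success, culled and alive flags for every female.

    In 'drawn' mode LBS is Poisson with latent log-mean
    ``intercept + (cov/sigma_A) * a_i + overdispersion``, so the additive
    genetic covariance between the trait and latent log fitness equals
    ``genetic_cov_fitness`` by construction, then zero-inflated by an
    independent Bernoulli mask. In 'pedigree' mode LBS is the realised
    offspring count. Culling is an independent flag among dead females
    ('random'), or additionally truncates LBS at a random count
    ('truncate'), which dilutes the trait-fitness covariance among culled
    females.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    ti = ds.truth_individuals
    females = ti[ti["sex"] == "F"].reset_index(drop=True)
    n = len(females)
    slope = cfg.genetic_cov_fitness / cfg.sigma_a if cfg.sigma_a > 0 else 0.0
    latent = (
        cfg.fitness_intercept
        + slope * females["a"].to_numpy()
        + rng.normal(0.0, cfg.fitness_overdispersion_sd, size=n)
    )
    if cfg.fitness_mode == "drawn":
        lbs = rng.poisson(np.exp(latent))
        lbs[rng.random(n) < cfg.zero_inflation] = 0
    else:
        counts = ds.records["female"].value_counts()
        lbs = females["id"].map(counts).fillna(0).astype(int).to_numpy()
    dead = ~females["alive"].to_numpy()
    culled = dead & (rng.random(n) < cfg.culling_prob)
    if cfg.culling_mode == "truncate":
        cap = rng.poisson(1.5, size=n)
        lbs = np.where(culled, np.minimum(lbs, cap), lbs)
    return pd.DataFrame(
        {
            "female": females["id"],
            "lbs": lbs,
            "latent_log_fitness": latent,
            "culled": culled,
            "alive": females["alive"].to_numpy(),
        }
    )


def _chol_psd(m: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(m)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
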