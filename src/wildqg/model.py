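"""Bayesian animal models: a hand-rolled Gibbs sampler.

Fits Gaussian and overdispersed-Poisson (log-link) traits in a single
mixed-model framework with pedigree-structured additive genetic effects and
iid permanent-environment, maternal, cohort and year effects, any of which
may covary across traits. This covers the model family the package needs:

* univariate animal model of the working-scale trait (with or without a
  year covariate);
* bivariate trait-fitness models for selection differentials and, with an
  additive cross-covariance, the Robertson-Price / secondary-theorem
  estimate of genetic change;
* bivariate trait-birth-weight animal model (the G matrix);
* trivariate trait-birth-weight-fitness model (multivariate gradients).

Sampler design
--------------
All location effects (fixed effects and every random-effect level) are
updated **jointly** each iteration by the perturbation ("conditioning by
kriging") device: draw a prior realisation ``theta*`` (gene-dropping the
additive effects down the pedigree), a data-noise realisation ``e*``, and
solve ``C delta = W' R^-1 (y - W theta* - e*)`` where ``C`` is the
mixed-model coefficient matrix; ``theta* + delta`` is an exact draw from
the Gaussian full conditional. The sparse system is solved by conjugate
gradients preconditioned with an occasionally refreshed LU factorisation:
``C`` changes only through the variance components, which move slowly, so
a stale factorisation is an excellent preconditioner, and whenever it is
rebuilt the solve is exact and CG is skipped. Joint updates avoid the
notoriously slow single-site mixing of additive genetic effects.

(Co)variance components have conjugate inverse-Wishart full conditionals
(inverse-gamma in one dimension, shape = rate = 0.001, i.e. degree of
belief 0.002 on a unit working variance). A parameter-expanded prior
(working mean 0, working variance 1000) is available for non-residual
blocks via the standard multiplicative redundant parameterisation, which
improves mixing for variances near zero.

A Poisson trait is handled through a latent log-mean per observation whose
residual is the trait's overdispersion. Because fitness is measured once
per individual, that latent residual is allowed to covary with the repeated
traits' permanent-environment effects in a joint individual-level
covariance block — the individual-level trait-fitness covariance that the
selection analysis consumes. Within the Gaussian sweep the latent residual
is marginalised into a regression on the permanent effects (its conditional
mean enters the design, its conditional variance the residual line), which
keeps every conditional exactly Gaussian; the latent values themselves get
vectorised random-walk Metropolis updates against the Poisson likelihood.

For variance components near zero the centred Gibbs chain is known to move
slowly; the parameter-expanded prior is the remedy and is the default for
the multivariate models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg, splu
from scipy.stats import invwishart

from .pedigree import Pedigree, gene_drop_breeding_values

__all__ = [
    "TraitSpec",
    "ChainSettings",
    "ModelSpec",
    "PosteriorChain",
    "fit_model",
    "heritability",
    "repeatability",
    "extract_blups",
    "effective_sample_size",
]

GAUSSIAN = "gaussian"
POISSON = "poisson"
BLOCK_ORDER = ("additive", "individual", "maternal", "cohort", "year")
Z_FIXED = ("offspring_sex", "status", "age", "genetic_group", "year_covariate",
           "inbreeding", "temperature")
Z_RANDOM = ("additive", "permanent", "maternal", "cohort", "year")


@dataclass(frozen=True)
class TraitSpec:
    """One response in a (possibly multi-trait) animal model."""

    name: str
    distribution: str = GAUSSIAN
    fixed: tuple = ()
    random: tuple = ()

    def __post_init__(self):
        if self.distribution not in (GAUSSIAN, POISSON):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.distribution == POISSON and "permanent" in self.random:
            raise ValueError("a once-measured Poisson trait has no separate permanent effect")
        if self.distribution == POISSON and "year" in self.random:
            raise ValueError("a once-measured Poisson trait has no year variance")


@dataclass(frozen=True)
class ChainSettings:
    """MCMC chain lengths; ``fast()`` supplies desk-scale settings."""

    iterations: int = 130_000
    burn_in: int = 30_000
    thinning: int = 100
    seed: int = 1

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in + self.thinning - 1) // self.thinning

    @classmethod
    def default_multivariate(cls, seed: int = 1) -> "ChainSettings":
        return cls(iterations=260_000, burn_in=60_000, thinning=200, seed=seed)

    @classmethod
    def fast(cls, seed: int = 1, multivariate: bool = False) -> "ChainSettings":
        if multivariate:
            return cls(iterations=3_200, burn_in=800, thinning=4, seed=seed)
        return cls(iterations=1_900, burn_in=500, thinning=2, seed=seed)


@dataclass(frozen=True)
class ModelSpec:
    """Trait list + prior family + chain settings."""

    traits: tuple
    prior: str = "inverse_gamma"  # or "parameter_expanded"
    chain: ChainSettings = field(default_factory=ChainSettings)

    def __post_init__(self):
        if self.prior not in ("inverse_gamma", "parameter_expanded"):
            raise ValueError(f"unknown prior family {self.prior!r}")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names")

    def with_chain(self, chain: ChainSettings) -> "ModelSpec":
        return replace(self, chain=chain)

    # -- canonical model constructors ------------------------------------

    @staticmethod
    def univariate(year_covariate: bool = True, inbreeding: bool = True,
                   chain: ChainSettings | None = None,
                   prior: str = "inverse_gamma") -> "ModelSpec":
        """The univariate animal model of the working-scale trait."""
        fx = ["offspring_sex", "status", "age", "genetic_group"]
        if year_covariate:
            fx.append("year_covariate")
        if inbreeding:
            fx.append("inbreeding")
        fx.append("temperature")
        z = TraitSpec("z", GAUSSIAN, tuple(fx), Z_RANDOM)
        return ModelSpec((z,), prior=prior, chain=chain or ChainSettings())

    @staticmethod
    def selection(additive: bool = False, chain: ChainSettings | None = None,
                  prior: str = "parameter_expanded",
                  inbreeding: bool = True) -> "ModelSpec":
        """Bivariate trait-fitness model: the selection-differential model,
        or (``additive=True``) the model carrying the additive trait-fitness
        covariance for the secondary-theorem estimate. Fitness keeps only an
        intercept and the genetic-group covariate; the trait keeps every
        fixed effect except temperature."""
        z_rand = ("permanent", "maternal", "cohort", "year") + (("additive",) if additive else ())
        w_rand = ("maternal", "cohort") + (("additive",) if additive else ())
        fx = ["offspring_sex", "status", "age", "genetic_group", "year_covariate"]
        if inbreeding:
            fx.append("inbreeding")
        z = TraitSpec("z", GAUSSIAN, tuple(fx), z_rand)
        w = TraitSpec("lbs", POISSON, ("genetic_group",), w_rand)
        return ModelSpec((z, w), prior=prior,
                         chain=chain or ChainSettings.default_multivariate())

    @staticmethod
    def trait_pair(chain: ChainSettings | None = None,
                   prior: str = "parameter_expanded",
                   inbreeding: bool = True) -> "ModelSpec":
        """Bivariate animal model of the trait and offspring birth weight."""
        fx = ("offspring_sex", "status", "age", "genetic_group",
              "year_covariate", "temperature") + (("inbreeding",) if inbreeding else ())
        z = TraitSpec("z", GAUSSIAN, fx, Z_RANDOM)
        bw = TraitSpec("birth_weight", GAUSSIAN, fx, Z_RANDOM)
        return ModelSpec((z, bw), prior=prior,
                         chain=chain or ChainSettings.default_multivariate())

    @staticmethod
    def trivariate(chain: ChainSettings | None = None,
                   prior: str = "parameter_expanded",
                   inbreeding: bool = True) -> "ModelSpec":
        """Trait, birth weight and fitness: the multivariate *phenotypic*
        selection model. Like the bivariate selection model it carries no
        additive effects — the individual-level (permanent) blocks absorb
        the genetic variance, and the resulting P and s feed ``beta =
        P^-1 s``; the G matrix comes from the separate trait-pair animal
        model."""
        fx = ("offspring_sex", "status", "age", "genetic_group",
              "year_covariate") + (("inbreeding",) if inbreeding else ())
        rand = ("permanent", "maternal", "cohort", "year")
        z = TraitSpec("z", GAUSSIAN, fx, rand)
        bw = TraitSpec("birth_weight", GAUSSIAN, fx, rand)
        w = TraitSpec("lbs", POISSON, ("genetic_group",), ("maternal", "cohort"))
        return ModelSpec((z, bw, w), prior=prior,
                         chain=chain or ChainSettings.default_multivariate())


# ---------------------------------------------------------------------------


@dataclass
class PosteriorChain:
    """Thinned MCMC samples of one fitted model."""

    spec: ModelSpec
    seed: int
    fixed: dict                  # trait -> DataFrame (samples x coefficient)
    blocks: dict                 # block name -> (S, k, k) covariance samples
    block_traits: dict           # block name -> tuple of component trait names
    resid: dict                  # gaussian trait -> (S,) residual variance
    additive_effects: np.ndarray | None  # (S, n_ped, k_additive)
    ped_ids: np.ndarray | None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        src = self.resid if self.resid else self.blocks
        return len(next(iter(src.values())))

    def vc(self, block: str, t1: str, t2: str | None = None) -> np.ndarray:
        """Samples of a (co)variance component, e.g. ``vc('additive', 'z')``
        or the individual-level cross-covariance ``vc('individual', 'z',
        'lbs')``."""
        t2 = t2 or t1
        comps = self.block_traits[block]
        return self.blocks[block][:, comps.index(t1), comps.index(t2)].copy()

    def variance_components(self, trait: str) -> dict:
        """All variance components touching ``trait``, plus its residual."""
        out = {}
        for b, comps in self.block_traits.items():
            if trait in comps:
                out[b] = self.vc(b, trait)
        if trait in self.resid:
            out["residual"] = self.resid[trait].copy()
        return out

    def total_variance(self, trait: str) -> np.ndarray:
        return np.sum(list(self.variance_components(trait).values()), axis=0)

    def breeding_values(self, trait: str) -> np.ndarray:
        """(S, n_pedigree) additive-effect samples for ``trait``."""
        if self.additive_effects is None:
            raise ValueError("model stores no additive effects")
        comps = [t for t in self.block_traits["additive"]]
        return self.additive_effects[:, :, comps.index(trait)]

    def fixed_effect(self, trait: str, name: str) -> np.ndarray:
        return self.fixed[trait][name].to_numpy().copy()


# -- design building -------------------------------------------------------


def _fixed_design(terms, df: pd.DataFrame, year0: float):
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in terms:
        if term == "offspring_sex":
            cols.append((df["offspring_sex"].to_numpy() == "M").astype(float))
            names.append("offspring_sex[M]")
        elif term == "status":
            levels = sorted(df["status"].unique())
            for lev in levels[1:]:  # first level (alphabetical) is the reference
                cols.append((df["status"].to_numpy() == lev).astype(float))
                names.append(f"status[{lev}]")
        elif term == "age":
            a = df["age"].to_numpy(float)
            cols += [a, a**2]
            names += ["age", "age2"]
        elif term == "year_covariate":
            cols.append(df["year"].to_numpy(float) - year0)
            names.append("year_covariate")
        elif term in ("genetic_group", "inbreeding", "temperature"):
            cols.append(df[term].to_numpy(float))
            names.append(term)
        else:
            raise ValueError(f"unknown fixed term {term!r}")
    X = np.column_stack(cols)
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ValueError("singular fixed-effect design")
    return X, names


class _Component:
    """One (block, trait) column group of the design."""

    __slots__ = ("block", "trait", "pattern", "kappa_pattern", "n_levels")

    def __init__(self, block, trait, pattern, n_levels, kappa_pattern=None):
        self.block = block
        self.trait = trait
        self.pattern = pattern               # this trait's rows -> level columns
        self.kappa_pattern = kappa_pattern   # Poisson rows -> level columns
        self.n_levels = n_levels


def _incidence(row_idx, level_idx, n_rows, n_levels):
    return sparse.csr_matrix(
        (np.ones(len(row_idx)), (row_idx, level_idx)), shape=(n_rows, n_levels)
    )


def _poisson_frame(fitness, records, female_covariates):
    df = fitness.copy()
    if "genetic_group" not in df.columns or "inbreeding" not in df.columns:
        if female_covariates is not None:
            cov = female_covariates.rename(columns={"id": "female"})
            df = df.merge(cov[["female", "inbreeding", "genetic_group"]],
                          on="female", how="left")
        else:
            cov = records.groupby("female")[["inbreeding", "genetic_group"]].first().reset_index()
            df = df.merge(cov, on="female", how="left")
        df[["inbreeding", "genetic_group"]] = df[["inbreeding", "genetic_group"]].fillna(0.0)
    return df


def fit_model(
    spec: ModelSpec,
    records: pd.DataFrame,
    ped: Pedigree,
    fitness: pd.DataFrame | None = None,
    female_covariates: pd.DataFrame | None = None,
    store_additive: bool = True,
    prune: bool = True,
) -> PosteriorChain:
    """Run the Gibbs sampler for ``spec`` and return the thinned chain.

    Parameters
    ----------
    records:
        One row per calving: ``female, year, age, status, offspring_sex,
        temperature, inbreeding, genetic_group`` plus the Gaussian response
        columns named in the spec (``z``, ``birth_weight``).
    ped:
        Validated pedigree covering every female in the data.
    fitness:
        One row per female (``female, lbs``); required when the spec
        contains a Poisson trait.
    female_covariates:
        ``id, inbreeding, genetic_group`` for fitness females (used for the
        fitness model's fixed effects); defaults to values carried in
        ``records`` and zeros for never-recorded females.
    prune:
        Restrict the fitted pedigree to the ancestor closure of the data
        individuals (exact for inference and much faster); set False to
        keep breeding-value samples for every pedigree member.
    """
    gtraits = [t for t in spec.traits if t.distribution == GAUSSIAN]
    ptraits = [t for t in spec.traits if t.distribution == POISSON]
    if len(ptraits) > 1:
        raise ValueError("at most one Poisson trait is supported")
    ptrait = ptraits[0] if ptraits else None
    if ptrait is not None and fitness is None:
        raise ValueError("spec contains a Poisson trait but no fitness table was given")
    if not gtraits:
        raise ValueError("at least one Gaussian trait is required")

    year0 = float(records["year"].min())
    row_frames, responses = [], []
    for t in spec.traits:
        if t.distribution == GAUSSIAN:
            row_frames.append(records)
            responses.append(records[t.name].to_numpy(float))
        else:
            df = _poisson_frame(fitness, records, female_covariates)
            row_frames.append(df)
            responses.append(df["lbs"].to_numpy(float))
    n_rows = np.array([len(f) for f in row_frames])
    offsets = np.concatenate([[0], np.cumsum(n_rows)]).astype(int)
    N = int(offsets[-1])

    Xs, xnames = [], []
    for t, df in zip(spec.traits, row_frames):
        X, nm = _fixed_design(t.fixed, df, year0)
        Xs.append(X)
        xnames.append(nm)

    data_females = sorted(set().union(*[set(f["female"]) for f in row_frames]))
    if prune:
        ped = ped.ancestor_closure(data_females)

    # --- random-effect levels -------------------------------------------
    dam_of = dict(zip(ped.ids, ped.table["dam"]))
    coh_of = dict(zip(ped.ids, ped.cohort))

    def mat_key(f):
        d = dam_of[f]
        return d if d != "" else f"ph:{f}"

    females_all = data_females
    level_sets = {
        "additive": list(ped.ids),
        "individual": females_all,
        "maternal": sorted({mat_key(f) for f in females_all}),
        "cohort": sorted({coh_of[f] for f in females_all}),
        "year": sorted(set(records["year"])),
    }
    level_pos = {b: {v: i for i, v in enumerate(lv)} for b, lv in level_sets.items()}

    def level_of(block, df):
        f = df["female"]
        if block == "additive":
            return ped.positions(f)
        if block == "individual":
            return np.array([level_pos["individual"][x] for x in f], dtype=int)
        if block == "maternal":
            return np.array([level_pos["maternal"][mat_key(x)] for x in f], dtype=int)
        if block == "cohort":
            return np.array([level_pos["cohort"][coh_of[x]] for x in f], dtype=int)
        if block == "year":
            return np.array([level_pos["year"][y] for y in df["year"]], dtype=int)
        raise KeyError(block)

    # block -> ordered trait components (the Poisson latent residual sits
    # last in the individual block and has no theta columns of its own)
    block_traits: dict[str, list] = {}
    for b in BLOCK_ORDER:
        comp = []
        for t in spec.traits:
            key = "permanent" if b == "individual" else b
            if key in t.random:
                comp.append(t.name)
        if b == "individual" and ptrait is not None and comp:
            comp.append(ptrait.name)
        if comp:
            block_traits[b] = comp

    tr_index = {t.name: i for i, t in enumerate(spec.traits)}
    components: list[_Component] = []
    for b in BLOCK_ORDER:
        if b not in block_traits:
            continue
        L = len(level_sets[b])
        for tname in block_traits[b]:
            if b == "individual" and ptrait is not None and tname == ptrait.name:
                continue
            ti = tr_index[tname]
            rows = np.arange(offsets[ti], offsets[ti + 1])
            patt = _incidence(rows, level_of(b, row_frames[ti]), N, L)
            kap = None
            if b == "individual" and ptrait is not None:
                pi = tr_index[ptrait.name]
                prow = np.arange(offsets[pi], offsets[pi + 1])
                kap = _incidence(prow, level_of("individual", row_frames[pi]), N, L)
            components.append(_Component(b, tname, patt, L, kap))

    frame = _SamplerFrame(
        spec, spec.traits, row_frames, responses, offsets, Xs, xnames,
        components, block_traits, level_sets, ped, store_additive,
    )
    return frame.run()


# -- the sampler ------------------------------------------------------------


class _SamplerFrame:
    """Indexing state + the Gibbs sweep."""

    PRIOR_FIXED_VAR = 1.0e6
    CG_REFRESH = 30          # rebuild the LU preconditioner past this many CG iters

    def __init__(self, spec, traits, row_frames, responses, offsets, Xs,
                 xnames, components, block_traits, level_sets, ped, store_additive):
        self.spec = spec
        self.rng = np.random.default_rng(spec.chain.seed)
        self.traits = traits
        self.row_frames, self.responses = row_frames, responses
        self.offsets = offsets
        self.Xs, self.xnames = Xs, xnames
        self.components = components
        self.block_traits = block_traits
        self.level_sets = level_sets
        self.ped = ped
        self.Ainv = ped.a_inverse().tocsc()
        self.store_additive = store_additive
        self.N = int(offsets[-1])
        self.trait_rows = [np.arange(offsets[i], offsets[i + 1]) for i in range(len(traits))]

        self.pois_idx = [i for i, t in enumerate(traits) if t.distribution == POISSON]
        self.ptrait = traits[self.pois_idx[0]] if self.pois_idx else None
        self.has_pois_ind = self.ptrait is not None and "individual" in block_traits

        # theta layout
        self.fix_slices = []
        off = 0
        for X in Xs:
            self.fix_slices.append(slice(off, off + X.shape[1]))
            off += X.shape[1]
        self.comp_slices = []
        for c in components:
            self.comp_slices.append(slice(off, off + c.n_levels))
            off += c.n_levels
        self.dim = off

        if self.ptrait is not None:
            pi = self.pois_idx[0]
            self.counts = self.responses[pi].astype(float)
            self.eta = np.log(self.counts + 0.5)
            pos = {v: j for j, v in enumerate(level_sets["individual"])}
            self.pois_level = np.array(
                [pos[f] for f in row_frames[pi]["female"]], dtype=int
            ) if self.has_pois_ind else None

        # padded fixed designs (global row space)
        pads = []
        for i, X in enumerate(Xs):
            M = sparse.lil_matrix((self.N, X.shape[1]))
            M[self.trait_rows[i], :] = X
            pads.append(M.tocsr())
        self.X_padded = pads

        self._init_state()

    def _init_state(self):
        var0 = {}
        for i, t in enumerate(self.traits):
            var0[t.name] = (max(float(np.var(self.responses[i])), 1e-6)
                            if t.distribution == GAUSSIAN else 1.0)
        self.Sigma = {
            b: np.diag([var0[c] / 6.0 for c in comps])
            for b, comps in self.block_traits.items()
        }
        self.resid_var = {
            t.name: var0[t.name] / 2.0 for t in self.traits if t.distribution == GAUSSIAN
        }
        self.px = self.spec.prior == "parameter_expanded"
        # the block holding the Poisson residual behaves like a residual
        # covariance and is never parameter-expanded
        self.px_blocks = [
            b for b in self.block_traits
            if self.px and not (b == "individual" and self.has_pois_ind)
        ]
        self.alpha = {b: np.ones(len(self._theta_comps(b))) for b in self.px_blocks}
        self.Psi = {b: self.Sigma[b][: len(self.alpha[b]), : len(self.alpha[b])].copy()
                    for b in self.px_blocks}
        self.theta = np.zeros(self.dim)
        self._lu = None
        self._cg_iters = np.inf
        self.mh_accept = []
        self.cg_trace = []

    def _theta_comps(self, b):
        """Component trait names of block b that own theta columns."""
        comps = self.block_traits[b]
        if b == "individual" and self.has_pois_ind:
            return comps[:-1]
        return comps

    def _comp_indices(self, b):
        return [j for j, c in enumerate(self.components) if c.block == b]

    # -- per-iteration assembly -------------------------------------------

    def _kappa(self):
        S = self.Sigma["individual"]
        kp = S.shape[0] - 1
        Spp, spw, sww = S[:kp, :kp], S[:kp, -1], S[-1, -1]
        kap = np.linalg.solve(Spp, spw)
        v = float(sww - spw @ kap)
        return kap, max(v, 1e-8 * sww + 1e-12)

    def _scale_of(self, j):
        c = self.components[j]
        if c.block in self.px_blocks:
            return self.alpha[c.block][self._theta_comps(c.block).index(c.trait)]
        return 1.0

    def _assemble(self):
        kap, vcond = (self._kappa() if self.has_pois_ind else (None, None))
        self.vcond = vcond
        pieces = list(self.X_padded)
        for j, c in enumerate(self.components):
            s = self._scale_of(j)
            P = c.pattern if s == 1.0 else c.pattern * s
            if c.kappa_pattern is not None:
                names = self._theta_comps("individual")
                P = P + c.kappa_pattern * (kap[names.index(c.trait)] * s)
            pieces.append(P)
        W = sparse.hstack(pieces, format="csr")
        r = np.empty(self.N)
        for i, t in enumerate(self.traits):
            r[self.trait_rows[i]] = (
                self.resid_var[t.name] if t.distribution == GAUSSIAN else vcond
            )
        self._W, self._r = W, r

    def _prior_cov(self, b):
        if b in self.px_blocks:
            return self.Psi[b]
        S = self.Sigma[b]
        if b == "individual" and self.has_pois_ind:
            return S[:-1, :-1]
        return S

    def _prior_precision(self):
        blocks = [sparse.identity(s.stop - s.start) * (1.0 / self.PRIOR_FIXED_VAR)
                  for s in self.fix_slices]
        for b in BLOCK_ORDER:
            if b not in self.block_traits:
                continue
            idx = self._comp_indices(b)
            if not idx:
                continue
            Si = np.linalg.inv(self._prior_cov(b))
            K = self.Ainv if b == "additive" else sparse.identity(self.components[idx[0]].n_levels)
            blocks.append(sparse.kron(Si, K) if Si.shape[0] > 1 else K * Si[0, 0])
        return sparse.block_diag(blocks, format="csc")

    def _prior_draw(self):
        th = np.empty(self.dim)
        rng = self.rng
        for s in self.fix_slices:
            th[s] = rng.normal(0.0, np.sqrt(self.PRIOR_FIXED_VAR), s.stop - s.start)
        for b in BLOCK_ORDER:
            if b not in self.block_traits:
                continue
            idx = self._comp_indices(b)
            if not idx:
                continue
            Sig = self._prior_cov(b)
            k = Sig.shape[0]
            L = self.components[idx[0]].n_levels
            if b == "additive":
                U = gene_drop_breeding_values(
                    self.ped, Sig if k > 1 else float(Sig[0, 0]), rng=rng
                ).reshape(L, k)
            else:
                U = rng.standard_normal((L, k)) @ _chol(Sig).T
            for jj, j in enumerate(idx):
                th[self.comp_slices[j]] = U[:, jj]
        return th

    def _sample_location(self, y):
        W, r = self._W, self._r
        Rinv = sparse.diags(1.0 / r)
        C = (W.T @ Rinv @ W + self._prior_precision()).tocsc()
        th_star = self._prior_draw()
        e_star = self.rng.normal(0.0, np.sqrt(r))
        rhs = W.T @ (Rinv @ (y - W @ th_star - e_star))
        if self._lu is None or self._cg_iters > self.CG_REFRESH:
            self._lu = _splu_spd(C)
            delta = self._lu.solve(rhs)
            self._cg_iters = 0
        else:
            it = [0]
            delta, info = cg(
                C, rhs, M=LinearOperator(C.shape, self._lu.solve, dtype=np.float64),
                rtol=1e-8, atol=0.0, maxiter=200,
                callback=lambda _: it.__setitem__(0, it[0] + 1),
            )
            self._cg_iters = it[0]
            if info != 0:
                self._lu = _splu_spd(C)
                delta = self._lu.solve(rhs)
                self._cg_iters = 0
        self.cg_trace.append(self._cg_iters)
        self.theta = th_star + delta

    # -- variance updates --------------------------------------------------

    def _theta_values(self, b, scaled=True):
        """(L, k) current effect values of block b's theta components."""
        idx = self._comp_indices(b)
        cols = [
            self.theta[self.comp_slices[j]] * (self._scale_of(j) if scaled else 1.0)
            for j in idx
        ]
        return np.column_stack(cols)

    def _eta_pred_other(self):
        """Poisson linear predictor excluding the individual-level residual."""
        pi = self.pois_idx[0]
        rows = self.trait_rows[pi]
        pred = (self._W @ self.theta)[rows]
        if self.has_pois_ind:
            kap, _ = self._kappa()
            P = self._theta_values("individual")
            pred = pred - P[self.pois_level] @ kap
        return pred

    def _update_variances(self):
        rng = self.rng
        pred = self._W @ self.theta
        for i, t in enumerate(self.traits):
            if t.distribution != GAUSSIAN:
                continue
            rows = self.trait_rows[i]
            res = self._y[rows] - pred[rows]
            self.resid_var[t.name] = _inv_gamma(
                rng, 0.001 + len(rows) / 2.0, 0.001 + res @ res / 2.0
            )
        for b in self.block_traits:
            px = b in self.px_blocks
            U = self._theta_values(b, scaled=not px)
            if b == "individual" and self.has_pois_ind:
                kap, vcond = self._kappa()
                e = U @ kap + rng.normal(0.0, np.sqrt(vcond), U.shape[0])
                e[self.pois_level] = self.eta - self._eta_pred_other()
                U = np.column_stack([U, e])
            L, k = U.shape
            S = U.T @ (self.Ainv @ U) if b == "additive" else U.T @ U
            nu0 = 0.002 if k == 1 else float(k)
            post = np.atleast_2d(
                invwishart.rvs(df=nu0 + L, scale=_pd_guard(nu0 * np.eye(k) + S),
                               random_state=rng)
            )
            if px:
                self.Psi[b] = post
                a = self.alpha[b]
                self.Sigma[b] = np.diag(a) @ post @ np.diag(a)
            else:
                self.Sigma[b] = post

    def _update_alpha(self):
        """Parameter-expansion scales: a Gaussian regression draw each,
        followed by a group (Liu-Sabatti) rebalancing move.

        The redundant pair (alpha_j, v_j) is identified only through its
        product; left alone the factors can drift to numerical extremes
        (alpha -> 0, v -> huge) and destabilise the Psi update. The group
        move slice-samples a scale c along the likelihood-invariant ray
        (alpha c, v / c) from its exact conditional (working prior x
        effect prior x Jacobian x Haar measure), which re-centres the
        factors without touching the effects the data see.
        """
        resid = self._y - self._W @ self.theta
        for b in self.px_blocks:
            names = self._theta_comps(b)
            for jj, j in enumerate(self._comp_indices(b)):
                c = self.components[j]
                v = self.theta[self.comp_slices[j]]
                x = c.pattern @ v
                if c.kappa_pattern is not None:
                    kap, _ = self._kappa()
                    x = x + (c.kappa_pattern @ v) * kap[names.index(c.trait)]
                rsc = x / self._r
                a_old = self.alpha[b][jj]
                part = resid + a_old * x
                prec = x @ rsc + 1.0 / 1000.0
                mean = (part @ rsc) / prec
                a_new = self.rng.normal(mean, 1.0 / np.sqrt(prec))
                self.alpha[b][jj] = a_new
                resid = part - a_new * x
            self._rebalance_px(b)
            a = self.alpha[b]
            self.Sigma[b] = np.diag(a) @ self.Psi[b] @ np.diag(a)

    def _rebalance_px(self, b):
        idx = self._comp_indices(b)
        V = np.column_stack([self.theta[self.comp_slices[j]] for j in idx])
        L = V.shape[0]
        try:
            Psi_inv = np.linalg.inv(self.Psi[b])
        except np.linalg.LinAlgError:
            return
        # the effect prior is N(0, Psi x K) with K = A for the additive
        # block, identity otherwise: inner products must be K^-1-weighted
        KV = self.Ainv @ V if b == "additive" else V.copy()
        for jj, j in enumerate(idx):
            vj = V[:, jj].copy()
            kvj = KV[:, jj].copy()
            ssq = float(vj @ kvj)
            if ssq == 0.0:
                continue
            a_q = Psi_inv[jj, jj] * ssq
            w = KV @ Psi_inv[:, jj]
            b_q = 2.0 * (float(vj @ w) - a_q)
            alpha_j = self.alpha[b][jj]

            def logpi(t):
                return (-(alpha_j ** 2) * np.exp(2 * t) / 2000.0
                        - 0.5 * (a_q * np.exp(-2 * t) + b_q * np.exp(-t))
                        + (1.0 - L) * t)

            t = _slice_1d(logpi, 0.0, self.rng)
            cscale = np.exp(t)
            self.alpha[b][jj] = alpha_j * cscale
            V[:, jj] = vj / cscale
            KV[:, jj] = kvj / cscale
            self.theta[self.comp_slices[j]] = V[:, jj]

    # -- Poisson latent updates -------------------------------------------

    def _update_eta(self, n_sweeps: int = 4):
        pi = self.pois_idx[0]
        rows = self.trait_rows[pi]
        mu = (self._W @ self.theta)[rows]  # includes the kappa*p loading
        v = self.vcond
        w = self.counts
        step = 2.0 / np.sqrt(w + 1.0 / v + 0.5)
        eta = self.eta
        acc = 0.0
        for _ in range(n_sweeps):
            prop = eta + self.rng.normal(0.0, step)
            logr = (
                w * (prop - eta)
                - (np.exp(prop) - np.exp(eta))
                - ((prop - mu) ** 2 - (eta - mu) ** 2) / (2.0 * v)
            )
            keep = np.log(self.rng.random(len(eta))) < logr
            eta = np.where(keep, prop, eta)
            acc += keep.mean()
        self.eta = eta
        self.mh_accept.append(acc / n_sweeps)
        self._y[rows] = eta

    # -- main loop ---------------------------------------------------------

    def run(self) -> PosteriorChain:
        ch = self.spec.chain
        self._y = np.concatenate(
            [self.eta if t.distribution == POISSON else self.responses[i]
             for i, t in enumerate(self.traits)]
        )
        fixed_keep = {t.name: [] for t in self.traits}
        block_keep = {b: [] for b in self.block_traits}
        resid_keep = {t: [] for t in self.resid_var}
        add_keep = []
        add_idx = self._comp_indices("additive")

        for it in range(ch.iterations):
            self._assemble()
            self._sample_location(self._y)
            if self.px:
                self._update_alpha()
            self._update_variances()
            if self.ptrait is not None:
                self._assemble()  # kappa / vcond changed with Sigma
                self._update_eta()
            if it >= ch.burn_in and (it - ch.burn_in) % ch.thinning == 0:
                for i, t in enumerate(self.traits):
                    fixed_keep[t.name].append(self.theta[self.fix_slices[i]].copy())
                for b in self.block_traits:
                    block_keep[b].append(self.Sigma[b].copy())
                for t in self.resid_var:
                    resid_keep[t].append(self.resid_var[t])
                if add_idx and self.store_additive:
                    add_keep.append(self._theta_values("additive"))

        fixed = {
            t.name: pd.DataFrame(np.array(fixed_keep[t.name]), columns=self.xnames[i])
            for i, t in enumerate(self.traits)
        }
        chain = PosteriorChain(
            spec=self.spec,
            seed=ch.seed,
            fixed=fixed,
            blocks={b: np.array(v) for b, v in block_keep.items()},
            block_traits={b: tuple(c) for b, c in self.block_traits.items()},
            resid={t: np.array(v) for t, v in resid_keep.items()},
            additive_effects=np.array(add_keep) if add_keep else None,
            ped_ids=self.ped.ids.copy(),
            diagnostics={
                "cg_iterations": np.array(self.cg_trace),
                "mh_acceptance": float(np.mean(self.mh_accept)) if self.mh_accept else None,
            },
        )
        _warn_if_short(chain)
        return chain


def heritability(chain: PosteriorChain, trait: str = "z"):
    """Per-sample narrow-sense heritability: additive variance over the sum
    of every variance component (including residual).

    Returns ``(samples, summary)`` where ``summary`` is a
    :class:`~wildqg.posterior.PosteriorSummary`.
    """
    from .posterior import posterior_summary

    h2 = chain.vc("additive", trait) / chain.total_variance(trait)
    return h2, posterior_summary(h2)


def repeatability(chain: PosteriorChain, female_covariates: pd.DataFrame,
                  trait: str = "z"):
    """Individual-level repeatability: the share of phenotypic variance from
    everything constant for a female — additive, permanent-environment,
    maternal and cohort variance plus the variance (across females) of the
    linear predictor from the inbreeding and genetic-group fixed effects.
    Year and residual variance (and that same fixed-effect variance) complete
    the denominator.

    ``female_covariates`` must carry ``inbreeding`` and ``genetic_group``
    columns, one row per female entering the variance calculation.
    """
    from .posterior import posterior_summary

    vcs = chain.variance_components(trait)
    constant = sum(vcs.get(b, 0.0) for b in ("additive", "individual", "maternal", "cohort"))
    varying = vcs.get("year", 0.0) + vcs["residual"]
    F = female_covariates["inbreeding"].to_numpy(float)
    q = female_covariates["genetic_group"].to_numpy(float)
    bF = (chain.fixed[trait]["inbreeding"].to_numpy()
          if "inbreeding" in chain.fixed[trait] else np.zeros(chain.n_samples))
    bq = (chain.fixed[trait]["genetic_group"].to_numpy()
          if "genetic_group" in chain.fixed[trait] else np.zeros(chain.n_samples))
    lp = bF[:, None] * F[None, :] + bq[:, None] * q[None, :]
    fixed_var = lp.var(axis=1)
    rep = (constant + fixed_var) / (constant + fixed_var + varying)
    return rep, posterior_summary(rep)


def extract_blups(chain: PosteriorChain, ids, trait: str = "z") -> pd.DataFrame:
    """Posterior samples of additive effects (columns = individuals).

    Raises ``KeyError`` if an individual is absent from the fitted pedigree
    (e.g. pruned away; refit with ``prune=False`` to keep everyone).
    """
    bv = chain.breeding_values(trait)
    pos = {v: i for i, v in enumerate(chain.ped_ids)}
    missing = [i for i in ids if i not in pos]
    if missing:
        raise KeyError(f"individuals not in the fitted pedigree: {missing[:5]}")
    cols = [pos[i] for i in ids]
    return pd.DataFrame(bv[:, cols], columns=list(ids))


def _splu_spd(C):
    """Sparse LU tuned for SPD systems: symmetric MMD ordering and diagonal
    pivoting keep the factor close to a Cholesky (far less fill than the
    default partial-pivoting choices on these badly scaled systems)."""
    return splu(C, permc_spec="MMD_AT_PLUS_A",
                options=dict(DiagPivotThresh=0.0, SymmetricMode=True))


def _chol(S):
    S = np.atleast_2d(S)
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(S)
        return v @ np.diag(np.sqrt(np.clip(w, 0, None)))


def _inv_gamma(rng, shape, rate):
    return rate / rng.gamma(shape, 1.0)


def _pd_guard(S):
    """Symmetrise and, if needed, eigenvalue-clip a scale matrix so the
    inverse-Wishart draw cannot fail on rounding-level indefiniteness."""
    S = 0.5 * (S + S.T)
    try:
        np.linalg.cholesky(S)
        return S
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(S)
        floor = max(w.max(), 1.0) * 1e-10
        return v @ np.diag(np.clip(w, floor, None)) @ v.T


def _slice_1d(logf, x0, rng, w=1.0, max_steps=20):
    """Univariate slice sampler (stepping out + shrinkage)."""
    y = logf(x0) + np.log(rng.random())
    lo, hi = x0 - w * rng.random(), 0.0
    hi = lo + w
    steps = max_steps
    while steps > 0 and logf(lo) > y:
        lo -= w
        steps -= 1
    steps = max_steps
    while steps > 0 and logf(hi) > y:
        hi += w
        steps -= 1
    for _ in range(100):
        x = rng.uniform(lo, hi)
        if logf(x) >= y:
            return x
        if x < x0:
            lo = x
        else:
            hi = x
    return x0


def effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS estimate."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 4 or np.ptp(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * xc.var())
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] < 0.0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def _warn_if_short(chain: PosteriorChain):
    for t, v in chain.resid.items():
        ess = effective_sample_size(v)
        if ess < 50:
            warnings.warn(
                f"effective sample size for residual variance of {t!r} is {ess:.0f}; "
                "consider longer chains", RuntimeWarning, stacklevel=3,
            )
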