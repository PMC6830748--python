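# Methods

`wildqg` decomposes a multi-decade trend in a seasonal life-history trait of
a wild, pedigreed population into evolutionary and non-genetic components.
The motivating system is a red-deer-like population in which mean parturition
date advances over a 45-year study period; the package asks how much of that
advance is genetic change (and whether drift could produce it), how much is
plasticity in response to warming rut-season temperatures, how much is
shifting age/reproductive-status structure, and how much remains unexplained.
This note records the models, the defaults and the reasoning behind every
genuinely open design choice.

## Working scale

Parturition date is measured in days after May 1 (`B`, strictly positive) and
analysed as `z = 100 ln(B)`: the natural log makes residuals close to
Gaussian, and the factor 100 keeps variance components at convenient
magnitudes. All model parameters live on this working scale. Changes are
reported back in days via `Δdays = B_ref (exp(Δz/100) − 1)`, evaluated at a
baseline `B_ref` equal to the observed mean parturition date over the first
three study years. A working-scale change per generation is first scaled
linearly (on the log scale) to the reporting horizon — per year via the
8-year generation time, over the span via the 45-year study period — and only
then back-transformed; the two operations do not commute exactly, and this
order keeps day-scale quantities mutually consistent
(`days/year × span = days over span` holds to machine precision). Haldanes
divide the per-generation working-scale change by the per-posterior-sample
working-scale phenotypic SD, the only SD defined sample-by-sample.

## Pedigree machinery

The numerator relationship matrix `A` is built with the tabular recursion in
topological order and held dense; study-scale pedigrees (a few thousand
members) cost a few MB. Inbreeding is `F_i = A(sire, dam)/2`. The sparse
`A⁻¹` consumed by the sampler comes directly from pedigree structure
(Henderson's rules with the inbreeding correction). Unknown parents are
treated as unique, unrelated, non-inbred founders throughout — in `A`, in
`F`, and in gene dropping, where an individual with one unknown parent
receives that parent's contribution as a fresh founder draw. Immigrant
ancestry (`q`) propagates the founder labels {0 = resident, 1 = immigrant}
down the pedigree as the parental mean; unassigned founders default to
resident, since immigrants are the labelled exception in this system.

Model fits prune the pedigree to the ancestor closure of the data
individuals. The closure is closed under parenthood, so every relationship
among retained individuals is intact and the likelihood is exactly unchanged;
it typically halves the system size. Breeding values for pruned individuals
are simply not sampled; pass `prune=False` where they are wanted.

## The Gibbs sampler

All models are fitted by a purpose-built Gibbs sampler (module `model`).
Location effects — fixed effects and every random-effect level, additive
effects included — are updated jointly each iteration by the perturbation
device: a prior draw (additive effects by gene-dropping), a noise draw, and
one solve against the mixed-model coefficient matrix yield an exact draw
from the joint Gaussian full conditional. The sparse solve uses conjugate
gradients (relative tolerance 1e-8) preconditioned by an occasionally
refreshed LU factorisation computed in symmetric mode with diagonal
pivoting; the factorisation is rebuilt whenever CG needs more than 30
iterations, and on rebuild iterations the solve is exact. Joint updates
sidestep the very slow single-site mixing of additive effects.

Variance components get conjugate updates: inverse-gamma with shape = rate
= 0.001 for scalar components (equivalently one degree of belief 0.002 on a
unit variance), inverse-Wishart with degrees of freedom equal to the block
dimension for covariance blocks. The alternative `parameter_expanded` prior
(working mean 0, working variance 1000; degree of belief 0.002 for
single-trait blocks, the block dimension for shared blocks) uses the
multiplicative redundant parameterisation — per-component scale factors with
N(0, 1000) priors updated as regression coefficients — and is the default
for multivariate models, where some components sit near zero and the centred
chain would otherwise crawl. Because the redundant pair is identified only
through its product, each scale draw is followed by a group
(generalised-Gibbs) move that slice-samples a rescaling along the
likelihood-invariant ray from its exact conditional, keeping the two
factors numerically balanced. Residual (co)variances are never
parameter-expanded; the individual-level block of a fitness model contains
the fitness residual and is treated as residual-like. Swapping the two prior
families moves selection estimates by much less than posterior uncertainty
(this is tested).

Lifetime breeding success (LBS) is an overdispersed Poisson trait: each
female carries a latent log-mean whose residual is the overdispersion.
Because LBS is measured once, that latent residual plays the role of the
individual-level effect and is allowed to covary with the repeated traits'
permanent-environment effects in one joint covariance block — precisely the
individual-level trait–fitness covariance that selection analysis needs.
Inside the Gaussian sweep the latent residual is folded in by regression
(its conditional mean on the permanent effects enters the design, its
conditional variance the residual line), keeping every conditional exactly
Gaussian; the latent values themselves get vectorised random-walk Metropolis
updates (four sweeps per iteration, step scaled per observation, acceptance
typically ~0.5). Latent-scale covariances with LBS are used directly as
selection parameters: under log-normality of expected fitness they equal
covariances with relative fitness on the data scale.

Chain-length defaults are long (univariate 130,000 iterations, burn-in
30,000, thinning 100; multivariate 260,000 / 60,000 / 200), matching common
practice for these models; `ChainSettings.fast()` provides the desk-scale
settings used by the pipeline's fast mode (univariate 1,900/500/2,
multivariate 3,200/800/4), and every test chooses chains explicitly. Point
estimates are posterior modes located by maximising a Gaussian KDE with
Silverman's bandwidth (modes of ratios are bandwidth-sensitive, so one rule
is fixed package-wide and recorded on the summary object); intervals are
shortest-interval 95% HPDs. Fixed-effect reference categories are the
alphabetically first levels; only contrast-invariant quantities (variance
shares, covariances, Geber contributions) are interpreted. Convergence is
the user's responsibility as in any MCMC workflow; the fitter warns when
the residual-variance effective sample size falls below 50.

## Selection and predicted responses

The selection differential is the individual-level plus maternal-level
trait–fitness covariance, halved exactly once because only females express
the trait. The univariate gradient divides the (halved) differential by the
matching phenotypic variance (individual + maternal); the multivariate
gradients solve `β = P⁻¹s` per posterior sample with `P` and `s` assembled
from the same two levels symmetrically, dropping (and counting) singular
samples. Predicted responses are `R = h²s` and, for the focal trait,
`Δz = β_z σ²_A(z) + β_bw σ_A(z,bw)` with `G` taken from the separate
bivariate trait–birth-weight animal model; `β` and `G` come from
independently fitted chains and are paired by index, which propagates both
posteriors as independent uncertainties. The selection models used for
differentials and gradients are phenotypic (no additive blocks — only the
secondary-theorem variant adds one): their individual-level effects absorb
the genetic variance, so `P` is the repeatable (individual + maternal)
phenotypic matrix. The trivariate model conditions on females with calving
records: a phenotypic `P` is only informed by expressed phenotypes, and
imputing both permanent components for never-recorded females would add an
unanchored random walk to that covariance block. The bivariate differential
keeps every female with a fitness record, which is what protects it from
the invisible-fraction problem.

The two predictions are different estimands. `h²s` scales the
trait–fitness covariance by the *total* phenotypic variance, as if
selection acted on single measurements; `β_z σ²_A` scales the same
covariance by the *repeatable* variance, treating selection as acting on
the individual-constant component (the only part lifetime fitness can
covary with). When the repeatable share of variance is small — as in the
synthetic defaults, where within-female year and residual noise dominate —
the multivariate prediction is correspondingly larger in magnitude than
the univariate one. The exact identity the package guarantees (and tests)
is between the multivariate response and its gradient-form direct term
when the cross-trait covariances vanish.

Subset analyses (natural-death
females, culled females, excluding the living) restrict both the fitness
table and the calving records to the subset and refit the selection model;
the h² entering the subset prediction is the full-data one.

## Genetic-trend estimators and the drift null

The BLUP trend regresses, within each posterior sample, every breeding
female's additive effect on the mean birth year of her offspring; the slope
posterior is summarised along with `P(slope ≥ 0)`. The conservative variant
takes breeding values from the model that includes year as a fixed
covariate (some genetic trend is ceded to the year effect); the
non-conservative variant omits it and will absorb environmental trends into
breeding values — the simulation tests exhibit both failure directions. The
secondary-theorem (Robertson–Price) estimate is the additive genetic
covariance between the trait and latent fitness, halved, read from the
trait–fitness model extended with an additive covariance block.

The drift null gene-drops breeding values down the *full* fixed pedigree —
founders from N(0, σ²_A), descendants from mid-parent values plus
inbreeding-corrected Mendelian noise — and applies the identical regression
recipe. Each of the (default 1,000) simulations draws σ²_A from its
posterior; a flag fixes it at the posterior mean instead, since the
stricter reading of "conditional on the estimated variance" is ambiguous.
The comparison point is the posterior mode of the conservative BLUP slope,
and the exceedance fraction counts null slopes at least as negative
(an advance "as large or larger"). For qualitative inspection of
nonlinearity, per-sample yearly mean breeding values over the individuals
alive each year are smoothed with cubic smoothing splines (penalty by
generalised cross-validation), the 1-D analogue of thin-plate smoothing;
the curves are plot output only.

## Geber decomposition

A covariate's contribution to the working-scale trend is (coefficient ×
covariate trend × span), per posterior sample; the covariate trend is the
OLS slope of its yearly population mean (or level proportion) on year.
Categorical covariates sum every non-reference level's term; because
proportions sum to one each year, the result is invariant to the reference
level (tested). Age contributes through both polynomial terms. Only fixed
effects are decomposed: random effects other than the additive one are
independent of year by construction, so persistent environmental trends
surface either in the year covariate's own component (reported as the
"remaining linear trend") or in the unexplained remainder. Two roll-ups are
reported, because "explained" is genuinely ambiguous: the summed
fixed-effect components alone, and fixed-effect components plus the
(conservative BLUP) evolution estimate; the unexplained remainder is the
observed phenotypic change minus the latter, per sample, with the observed
change treated as a constant. Inbreeding and immigrant-ancestry components
are computed exactly like the plasticity terms; note that pedigree-depth
artefacts can inflate estimated inbreeding over time, so the inbreeding
component of real data should be read with that caveat (the package reports
raw pedigree F only). Temperature is reported under both the with-year and
without-year models side by side, since the year covariate absorbs any
trend collinear with warming.

## The synthetic-data generator

The generator (module `simulate`) emulates the statistical structure the
analysis assumes, not deer demography in detail. Yearly demography builds an
overlapping-generation pedigree: founder cohorts with spread ages, female
breeding between ages 3 and 16 at a baseline annual probability of 0.55
capped at 75 breeders/year, polygynous siring with lognormal male skew,
age-structured survival (calf 0.75, juvenile 0.90, adult 0.95 with linear
senescence past age 9), ~20 immigrant founders arriving through the study,
and random culling flags on 15% of deaths. Defaults produce roughly 3,300
calving records from ~850 females over 45 years with ~1,600–1,900 females
carrying an LBS record — the scale of the motivating study.

The trait follows the full variance structure on the working scale:
additive 150, permanent environment 10, maternal 8, year 70, cohort 15,
residual 650 (total ≈ 900, h² ≈ 0.17, repeatability ≈ 0.20), with fixed
effects for age (−3.0, +0.15 quadratic), reproductive status (five levels
generated by a simple Markov rule on recent breeding history), offspring
sex (+0.5), rut temperature (−2.5 per °C on a trajectory warming at
0.04 °C/year), inbreeding (+20 per unit F) and immigrant ancestry (+2 per
unit q), plus an environmental year trend of −0.35 working units/year
folded into the year effects. Birth weight is a second, genetically
correlated maternal trait (additive 0.68, covariance −1.78 with the date
trait). True breeding values are propagated down the pedigree as mid-parent
values plus Mendelian noise while the population is being built, so that
fecundity selection — the annual breeding probability declines on the logit
scale by 0.05 per working unit of a female's genetic + permanent propensity
for late calving — produces a genuine breeding-value trend (about −2 days
over the span at the defaults). The Mendelian variance in this forward pass
ignores parental inbreeding (F is unknown until the pedigree is complete);
realised F is small, so the approximation is a ≲1% variance error, and the
standalone gene-dropping routine does apply the correction.

Fitness comes in two modes. The default draws LBS from the latent model
`log μ = 0.55 + (σ_A(z,w)/σ²_A) a_i + N(0, 0.5²)` with an *exactly known*
additive trait–fitness covariance (−5.5 at the defaults, chosen so the
secondary-theorem estimate lands in the few-days-over-span range), then
zero-inflates with an independent Bernoulli(0.2) mask — deliberately
violating the log-normality the secondary theorem assumes, so tests can
reproduce that bias qualitatively. `fitness_mode="pedigree"` uses realised
offspring counts instead. A `culling_mode="truncate"` option caps culled
females' LBS at an independent random count, genuinely diluting the
trait–fitness covariance among culled females for the subset analyses. The
drawn-LBS covariance and the demographic selection knob are set
independently; their defaults mirror the motivating system, where the
secondary-theorem estimate exceeded the breeding-value trend, and tests
that need exact truth switch one of them off.

For parameter-recovery experiments the generator can standardise the
initial founders' breeding values so their sample covariance equals the
configured additive covariance exactly — with ~140 founders the realised
base-population variance otherwise jitters by ~10%, which blurs what
"true heritability" means for a single replicate. The option is off by
default.

Everything stochastic flows from one `numpy` Generator seeded from the
config, so a dataset is bit-identical across runs and platforms. Truth
tables store every component of every record (the decomposition
`z − (μ + fixed + a + p + m + c + y + r)` is zero to 1e-10) and every
individual's true breeding values, which is what downstream recovery tests
regress against.

What the generator does *not* emulate: density dependence, spatial
structure, observation error in covariates, pedigree reconstruction error,
temperature effects on survival, or time-varying selection. Passing tests
therefore demonstrate that the estimators recover the truth under the
model's own assumptions at study scale — not that those assumptions hold in
any particular field system.

## Problem sizes used by the shipped runs

The reproduction script (`scripts/acceptance.py`) simulates the default
study conditions at a reduced demographic scale — 45 years with a cap of 45
breeding females/year (~1,900 records) — and runs the full pipeline with the
desk-scale chains; the test suite uses smaller populations still, with each
test choosing its chain lengths explicitly. These sizes are the package's
shipped defaults for a complete desk run; the full-scale, full-chain
configuration is one flag away (`--full`, default simulation config) and was
used to sanity-check that estimates do not shift structurally with scale.

## Known limitations

* Single-chain MCMC; between-chain diagnostics are left to the user.
* The once-measured-trait machinery supports exactly one Poisson fitness
  trait; other non-Gaussian responses are out of scope.
* KDE posterior modes carry O(bandwidth) noise; with a few hundred thinned
  samples, modes of ratios can wobble by a few percent of the HPD width.
* Effective sample sizes for variance components are far below the thinned
  sample count at desk-scale chains; interval endpoints are correspondingly
  noisy.
* The unexplained remainder treats the observed phenotypic change as a
  constant rather than propagating its (frequentist) CI.
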