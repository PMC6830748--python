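# wildqg

**Quantitative-genetic decomposition of phenotypic trends in wild pedigreed
populations.**

Long-term studies of wild vertebrates routinely document multi-decade shifts
in phenology — in the motivating system, the mean parturition date of red
deer hinds advanced by roughly two weeks over a 45-year study. The hard
question is *why*: how much of the shift is adaptive evolution (a trend in
breeding values driven by selection), how much is phenotypic plasticity in
response to warming, how much reflects changing population structure (age
and reproductive-status composition, offspring sex ratio, inbreeding, gene
flow), and how much could be genetic drift? `wildqg` implements the complete
analysis chain for that question, for quantitative geneticists and
evolutionary ecologists working with pedigreed long-term data, together with
a synthetic-data generator with known ground truth so every estimator can be
validated end to end.

## The models

The working phenotype is `z = 100 ln(B)`, with `B` the parturition date in
days after May 1. The core is the **animal model**

```
z_ij = mu + X'b + a_i + p_i + m_i + c_i + y_j + r_ij,
(a_1..a_n)' ~ N(0, sigma2_A * A)
```

with fixed effects (offspring sex, reproductive status, age + age²,
immigrant-ancestry proportion, offspring birth year, inbreeding F, rut
temperature) and random additive-genetic (`A` = pedigree relationship
matrix), permanent-environment, maternal, cohort and year effects. It is
fitted by a purpose-built Gibbs sampler (joint location updates via sparse
solves; conjugate inverse-gamma/inverse-Wishart variance updates; optional
parameter-expanded priors; latent-variable Metropolis updates for
overdispersed-Poisson fitness). On top of it the package computes:

* **heritability** `h² = sigma2_A / sigma2_P` and repeatability;
* **selection differentials** `s` = (individual + maternal trait–fitness
  covariance)/2 from a bivariate model of the trait and lifetime breeding
  success (log-link, latent scale = relative-fitness scale), gradients
  `beta = s / sigma2` and `beta = P⁻¹s`;
* **predicted responses** `R = h²s` and `Δz = beta_z sigma2_A(z) +
  beta_bw sigma_A(z, bw)` (with `G` from a bivariate trait–birth-weight
  animal model), in days/generation, days/year, days over the span and
  Haldanes;
* **realised genetic change** three ways: conservative and non-conservative
  BLUP trend regressions (breeding values on mean offspring birth year, per
  posterior sample) and the secondary theorem of selection / Robertson–Price
  identity `ΔG = sigma_A(z, w)/2`;
* a **gene-dropping drift null** for the breeding-value trend;
* a **Geber decomposition** of the phenotypic trend into per-covariate
  contributions (coefficient × covariate trend × span) with explained and
  unexplained roll-ups.

## A worked example

```
$ python examples/04_selection_and_response.py
selection differential (working units/generation): -2.47 (95% HPD -3.505 to -1.348)
heritability: 0.1163 (95% HPD 0.01138 to 0.1578)
predicted response, days_per_generation: -0.08128 (95% HPD -0.1487 to -0.01278)
predicted response, days_span: -0.2535 (95% HPD -0.4625 to -0.03993)
predicted response, haldanes: -0.008113 (95% HPD -0.01457 to -0.0009236)

A negative differential means earlier-calving females leave more
offspring; the response scales it by heritability and is reported per
generation (8 y), over the 25-year span, and in Haldanes.
```

The differential says females with earlier latent calving dates leave
measurably more offspring (−2.5 working units of trait per generation of
selection); multiplied by a heritability of ~0.12 the breeder's equation
predicts roughly a quarter-day advance over this (reduced, 25-year)
simulated study — the same arithmetic the full pipeline applies at study
scale. Other examples cover the pedigree machinery
(`01`), the generator and its truth tables (`02`), the univariate animal
model (`03`), BLUP trends, the secondary-theorem estimate and the drift
null (`05`), and the components-of-change table (`06`).

The full pipeline is one call (or `wildqg run` from a shell):

```python
from wildqg import PipelineConfig, run_pipeline
res = run_pipeline(PipelineConfig(outdir="out", seed=1))
print(res.summary)
```

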