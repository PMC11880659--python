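# Methods

## The model

`covary` fits a Gaussian multivariate mixed-effects ("character-state")
model to an 8-trait phenotype panel measured on male guppies from a
replicated mesocosm exposure experiment: two behaviours (activity,
refuge use) assayed on three trials each, and six once-measured traits
(body condition, coloration, gonopodium length, sperm vitality, sperm
velocity, sperm count). For individual *i* in treatment *t(i)* and
mesocosm *m(i)*, trait *k*, occasion *o*:

```
y_iko = mu_k + beta_{t(i),k} + gamma_k * trial_o + a_{m(i),k} + u_{i,k} + eps_iko

u_i      ~ MVN(0, Sigma_B^{t(i)})    8-dim individual intercept, per treatment
a_{m,k}  ~ N(0, sigma_meso_k^2)      mesocosm intercept, per trait
eps_iko  ~ N(0, sigma_W_{t,k}^2)     behaviours: free, per treatment
eps_iko  ~ N(0, 0.01)                once-measured traits: pinned
```

All responses are z-standardized per trait (pooled over treatments and
trials) before fitting; the trial covariate is left-centred (trial 1 =
0) and enters for the behaviours only, with one slope per behaviour
shared across treatments. Treatment uses reference coding with the
unexposed (control) group as reference.

Key structural choices:

- **Treatment-stratified (co)variances.** Each treatment gets its own
  8x8 between-individual covariance matrix `Sigma_B` and its own
  within-individual variance per behaviour. These are the scientific
  targets: posterior contrasts of variance components (dV) quantify how
  exposure reshapes "individuality" (between) and "plasticity" (within),
  and the off-diagonals of `Sigma_B` carry the pace-of-life-syndrome
  correlations.
- **Pinned residual for once-measured traits.** A trait observed once
  per individual cannot separate within- from between-individual
  variance; its residual variance is fixed at the small reference value
  0.01 so virtually all variance loads on `u`. This is the standard
  device for mixing single- and repeated-measure responses in one
  multivariate model.
- **No residual correlations across traits.** A residual correlation
  matrix would be ill-posed for the six pinned-variance traits, so
  residuals are independent across traits within an occasion and all
  between-trait association is carried by `Sigma_B`.
- **Mesocosm effects independent across traits** with one SD per trait
  shared across treatments: with only 12 mesocosms (4 per treatment)
  there is no information for a richer structure.
- **Missing cells are skipped** in the likelihood, not imputed (e.g.
  males that yielded no ejaculate).

## Priors

The prior family is conjugate so that every full conditional is exact:

| block | weakly-informative default | flat flavour |
|---|---|---|
| fixed effects | Normal(0, 1) | Normal(0, 100^2) |
| scalar variances (mesocosm, within) | InvGamma(0.35, 0.02) | InvGamma(0.001, 0.001) |
| `Sigma_B` per treatment | InvWishart(df = 10, I) | InvWishart(df = 9, 0.001 I) |

The variance default was chosen so that the implied prior on an SD is
genuinely diffuse across the scales this design produces — central 90%
mass roughly (0.1, 12) on standardized data — and in particular does
not push small components upward: the mesocosm variance has only 12
levels to inform it and a true value near 0.02 on the standardized
scale, and heavier inverse-gamma defaults (e.g. IG(1, 0.3)) inflate it
severalfold, which leaks into the treatment effects. With the default
above, weakly-informative and flat flavours give fixed-effect posterior
means agreeing to well under 0.1 SD on full-design synthetic data, the
robustness property the analysis relies on.

The inverse-Wishart df of `dim + 2` is the smallest proper choice with a
finite mean; its marginal correlation densities are near-uniform, in the
spirit of a concentration-1 (LKJ-type) correlation prior. Draws of
`Sigma_B` are reported as SD vectors plus correlation matrices.

## Sampler

Block Gibbs with closed-form conditionals, in the **hierarchical
(centered) parameterization**: the latent state per individual is the
trait-vector mean `eta_i = mu + beta_t + a_m + u_i`, sampled jointly
from its 8-dim Gaussian conditional, with fixed effects and mesocosm
intercepts then updated at the `eta` level where the relevant noise is
`Sigma_B`. This matters: with the once-measured traits' residual
variance pinned at 0.01, the naive observation-level parameterization
alternates nearly-degenerate conditionals and the chain barely moves
(split-Rhat > 3 in practice); the centered form mixes freely (split-Rhat
about 1.005 at the full-length settings).

Update order per sweep: `eta` (batched: individuals sharing a treatment
and missingness pattern share a conditional precision, so each group is
one Cholesky plus a matrix solve) -> (mu, beta) jointly (24-dim Gaussian)
-> mesocosm vectors and their variances -> `Sigma_B` per treatment
(inverse-Wishart via Bartlett decomposition) -> trial slopes -> within
variances (inverse-gamma). Toy models without individual effects fall
back to observation-level updates, which makes the single-trait
known-variance configuration an exact iid sampler — the conjugate oracle
used in the tests.

Determinism: each chain draws from an independent child of
`SeedSequence(seed)`; parameters update in a fixed order; input tables
are canonically sorted (individual, trait, occasion) before compilation,
so posterior results are invariant to input row order.

Full-length settings are 4 chains x 8000 iterations with 3000 warmup and
thinning 2 (10000 retained draws). Diagnostics: in-repo split-Rhat
(cross-checked against arviz) and arviz bulk ESS; a fit is flagged, and
a warning emitted, when any split-Rhat exceeds 1.01 or any bulk ESS
falls below 400. A `prior_only` mode zeroes the data weights so the same
kernel samples the joint prior, which the tests compare to the stated
densities by Kolmogorov-Smirnov.

## Derived traits

- **Body condition** is the scaled mass index `SMI = M (L0/L)^b`, with
  `b` the standardized-major-axis slope of ln(mass) on ln(length),
  computed as OLS slope divided by the Pearson correlation (the Peig &
  Green estimator), and `L0` a reference length. On the study's
  morphometric scale these are b = 3.203 and L0 = 17.43 mm.
- **Coloration** is (orange + black patch area) / body area, in [0, 1].
- **Sperm velocity** is the tracked-count-weighted mean of per-sample
  curvilinear velocity (VCL, um/s). "Accounting for the number of sperm
  tracked" is read as count-weighting rather than a tracking-count
  filter; the weights are explicit in the record type so a filtering
  variant is a one-line change upstream.
- **Sperm count** is the mean subsample total (live + dead) scaled by
  the dilution factor and a chamber-volume factor. Both scalings are
  explicit parameters because extender volumes varied between males and
  the chamber geometry is not part of the data contract.
- **Vitality** is sum(live)/(sum(live)+sum(dead)) over subsamples.

Standardization returns the per-trait means/SDs so reports can be mapped
back to measurement units exactly.

## Synthetic data and what the tests show

The generator is the exact generative mirror of the fitted model —
same design, same independence assumptions — so parameter-recovery
results are well-posed: they validate the inference machinery, not the
model's fit to real fish. Features of real data it deliberately does not
emulate: non-Gaussian trait distributions (counts, proportions before
transformation), residual correlations between behaviours scored in the
same trial, missingness that correlates with phenotype, and any
correlation of mesocosm effects across traits.

Scenario truths (standardized scale):

- **null** — all treatment/trial effects zero, diagonal `Sigma_B`
  (behaviours 0.35, others 0.9), within variance 0.65 everywhere,
  mesocosm SD 0.15. Used for type-I-like calibration.
- **paper-like** — the study conditions in qualitative form: an
  activity-refuge between-individual correlation of -0.4 in every
  treatment; within-individual behavioural variances ordered control >
  exposed (activity 0.65/0.34/0.46, refuge 0.65/0.39/0.53, so the
  control-minus-low contrasts sit near the reported ~0.3); non-monotonic
  body-condition effects (-0.52 low, +0.48 high); longer gonopodia and
  slower sperm under exposure; trial slopes -0.22 (activity) and +0.19
  (refuge); elevated sperm-count individuality in the low treatment.
- **strong-syndrome** — a single fast-slow factor loading most traits
  (guaranteed positive-definite by construction), for power checks.

Validation studies run at the full design size (144 males) with
shortened replicate chains (2 x 800 iterations, 300 warmup; 20
replicates), which keeps a full study under two minutes while leaving
Monte-Carlo error well inside the tolerances checked: 95% CI coverage of
generating parameters is ~95%, the syndrome correlation's sign is
recovered in 19/20 replicates, and the null 89%-CI exclusion rate is
~0.08 against the nominal 0.11.

## Numerical choices and degenerate inputs

- Covariance inputs are validated as symmetric PSD (eigenvalue tolerance
  1e-8 relative); singular PSD matrices are handled in the generator via
  an eigendecomposition factor, so zero-variance scenarios are exact.
- `log_density` returns -inf (not an exception) for non-positive-definite
  covariance values so samplers can reject them.
- Credible intervals are equal-tailed quantile intervals (89% and 95%);
  the support rule is the 89% interval excluding zero. Intervals from
  fewer than 100 draws emit a precision warning.
- dV contrasts always label minuend and subtrahend (`group_a - group_b`);
  reported sign conventions are never implicit.
- Zero-variance traits, all-equal lengths, zero total sperm counts and
  similar degenerate inputs raise typed errors naming the offending
  trait or field.
- Chains are initialized at zero effects with variances at 0.5/0.25;
  with conjugate updates the warmup of the full-length settings is far
  beyond what burn-in requires.

## Limitations

- Gaussian responses only; no model comparison, pedigree/phylogenetic
  effects, or residual correlation structure.
- The conjugate prior family differs from the half-t/LKJ-style priors
  common in gradient-based fits of such models; the flavour-robustness
  check above is the evidence that this choice does not drive the
  reported quantities at this design size.
- With 4 mesocosms per treatment, treatment fixed effects are weakly
  identified relative to mesocosm noise; their posteriors are honest
  about this (wide), but single-replicate point estimates can sit 1-2
  posterior SDs from the truth.
- The between-individual correlation posteriors shrink toward zero at
  n = 48 individuals per treatment (inverse-Wishart pooling); sign and
  support are recovered reliably, magnitudes are conservative.
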