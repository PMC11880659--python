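# covary

Bayesian multivariate mixed models for **between- and within-individual
(co)variance** of repeatedly measured phenotypes, built around a guppy
mesocosm pollutant-exposure experiment: 144 males in 3 exposure
treatments (control / low / high) x 4 mesocosms x 12 fish, with two
behaviours (activity, refuge use) assayed on 3 trials each and six
life-history and sperm traits measured once.

It is aimed at behavioural and evolutionary ecologists asking questions
that live in variance components rather than means: does exposure change
*individuality* (between-individual variance V_B), *plasticity*
(within-individual variance V_W), behavioural *repeatability*
R = V_B/(V_B + V_W), or the *pace-of-life syndrome* — the
between-individual correlations linking behaviour, life history and
reproductive traits?

## The model

For individual *i* (treatment *t(i)*, mesocosm *m(i)*), trait *k*,
occasion *o*, on z-standardized traits:

    y_iko = mu_k + beta_{t(i),k} + gamma_k trial_o + a_{m(i),k} + u_ik + eps_iko

    u_i     ~ MVN(0, Sigma_B^{t(i)})        per-treatment 8x8 covariance
    a_{m,k} ~ N(0, sigma^2_{meso,k})        mesocosm random intercept
    eps     ~ N(0, sigma^2_{W,t,k})         behaviours (per treatment)
    eps     ~ N(0, 0.01)                    once-measured traits (pinned)

The quantities of interest are posterior **variance contrasts**
dV = V(group_a) - V(group_b) at the between (dVA) and within (dVW)
levels, the per-treatment between-individual **correlation matrices**,
and **repeatability** — all summarized with 89% and 95% equal-tailed
credible intervals, with support declared when the 89% interval excludes
zero. Inference is by an in-repo block-Gibbs sampler in the hierarchical
parameterization (see `docs/methods.md`); upstream, the package derives
the traits themselves (scaled mass index via the standardized-major-axis
exponent, coloration proportion, count-weighted sperm velocity,
haemocytometer counts, live/dead vitality). A synthetic-data module
generates the full design with known ground truth, so every stage is
testable by parameter recovery without any data download.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (each is a thin wrapper over the library; `covary
simulate|derive|fit|summarize|report` exposes the same stages as a CLI):

```
$ python analysis/01_simulate.py --seed 1
scenario          : paper-like (seed 1)
individuals       : 144
rows              : 1728 (864 behavioural observations)

$ python analysis/03_fit_model.py --seed 3 --quick
observations      : 1728 from 144 individuals
retained draws    : 1000 (2 chains x 500)
max split-Rhat    : 1.0558

$ python analysis/04_summarize.py
within-individual activity variance, control - low:
  dVW = +0.390 [89% 0.200, 0.610] (generating truth +0.310)  supported=True
between-individual activity-refuge correlation, control:
  r = -0.587 [89% -0.796, -0.311] (generating truth -0.400)  supported=True
activity repeatability (control): 0.265 [89% 0.156, 0.390]
```

Read: control fish are more behaviourally variable within-individual
than low-exposure fish (the dVW contrast is positive and its 89% CI
excludes zero), and more-active individuals consistently use the refuge
less (negative between-individual correlation) — both recovering the
generating truth within posterior uncertainty. Dropping `--quick` runs
the full-length sampler settings (4 chains x 8000 iterations, 3000
warmup, thinning 2; 10000 retained draws). `analysis/02_derive_traits.py`
exercises the raw-measurement stage (the fitted allometric exponent
prints next to its generating value), and `analysis/05_validate.py` runs
the replicated recovery/calibration studies.

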