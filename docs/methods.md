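# Methods

This package implements an inference pipeline for assigning pregnancy
status to beluga (*Delphinapterus leucas*) from blubber progesterone (BP)
concentrations, and for estimating the pregnancy rate of a blindly
sampled population. This note records the models, the parameter choices
that matter, and the design decisions taken where the design was open.

## The measurement chain

Progesterone, a lipophilic steroid, accumulates in blubber during
gestation. A competitive ELISA returns pg mL⁻¹ in assay buffer; the
back-calculation to tissue concentration is

    bp_tissue = (raw × buffer_volume × dilution / 1000) / (recovery × mass)   [ng g⁻¹]

with buffer volume defaulting to 0.5 mL (the extract is resuspended in
500 µL), dilution factors of 1–5000, and the recovery fraction
(extraction efficiency: 0.883 for carcass batches, 0.710 for biopsy
batches) dividing out extraction losses. Dilution and recovery
corrections are multiplicative and commute, so their order is
irrelevant. The per-lipid metric divides by the lipid mass fraction of
the sample; because biopsy samples carry far less lipid than carcass
samples (≈ 24% vs ≈ 60–66%), the two metrics can classify a low-lipid
sample differently, and samples with lipid ≤ 5% (boundary inclusive) are
excluded from per-lipid analyses. Carcass samples without a measured
lipid content are imputed with the measured-carcass mean, 66.4%.

All analyses run on natural-log concentrations. Non-positive values are
rejected rather than silently floored; a preprocessing helper can floor
at a configurable detection limit (default 0.1 ng g⁻¹, the smallest
concentration the known-status series contains).

## Three classifiers

**Fixed threshold.** A cutoff of 100 ng g⁻¹ tissue (≈ 150 ng g⁻¹ lipid),
placed in a visible break of the BP frequency distribution. A value
exactly at the threshold classifies pregnant; no observed value sits on
the boundary, so either convention would fit — inclusive-above is fixed
here and documented. `find_gap` locates the widest empty interval
between consecutive order statistics inside a search window (default
1–1000 ng g⁻¹; without the window the unbounded gap above the sample
maximum would always win).

**Bayesian Gaussian mixture.** Log BP is modelled as a K-component
normal mixture (K ∈ {1, 2, 3}, chosen by WAIC), with priors
μ_k ~ Normal(0, 10), σ_k ~ Half-Normal(5), w ~ Dirichlet(1) — on the log
scale the data range spans roughly −2.3 to 7.1, so these are weakly
informative. Sampling is Gibbs: Gumbel-max categorical draws for the
latent allocations, conjugate normal updates for the means, Dirichlet
updates for the weights, and a random-walk Metropolis step (step 0.25 on
log σ) for the scales, whose Half-Normal prior is not conjugate. Label
switching is removed exactly by relabelling components into ascending
mean order after every sweep — a measure-preserving permutation of the
label-symmetric posterior that makes the ascending-means constraint hold
in every retained draw; it replaces an ordered-means reparameterization
because it is the natural mechanism inside a Gibbs sweep and yields the
identical invariant. The highest-mean component is read as the pregnant
cluster; with K = 3 the middle component is "intermediate", and where a
dichotomy is required intermediates score as non-pregnant (they stay in
the mature denominator of the pregnancy rate but not in the pregnant
numerator). Each individual of unknown status receives the posterior
mean of its component responsibilities; hard assignment is the most
probable cluster.

**Bayesian logistic regression.** Pregnancy (1 = confirmed pregnant;
0 = males, lactating, immature, resting females) on log BP, priors
Normal(0, 10) on intercept and slope. Females that gave birth shortly
before sampling are withheld from training — their BP can sit anywhere
between pregnant and non-pregnant levels — and predicted as missing
responses: each posterior draw implies a probability for every unknown,
and the posterior mean is reported. A mean probability ≥ 0.5 indicates
pregnancy (boundary inclusive). Derived per draw: the odds ratio
exp(β₁) per unit of log BP (the printed phrasing "per ng g⁻¹" is read as
shorthand for per-unit-log, consistent with the log-transformed
predictor; the ambiguity is documented, not resolved), and the
equal-odds concentration exp(−β₀/β₁), which errors out when slope draws
straddle zero. Sampling is random-walk Metropolis started at the
posterior mode with a Laplace-approximation proposal covariance
(scaled 2.4²/d), which mixes well for this two-parameter posterior.

### MCMC geometry and diagnostics

The full protocol runs 50 000 iterations of three independent chains,
burn-in 10 000, thinning 40 — 1000 retained draws per chain. A scaled
geometry (5000 / 1000 / 4, same retained-draw count) is provided for
tests and quick runs; the analysis scripts default to it and expose
`--full-mcmc`. Convergence is monitored with the classic Gelman–Rubin
potential scale reduction factor per parameter; any R-hat ≥ 1.1 raises a
warning with the offending values attached rather than failing silently.
R-hat is floored at 1 (values below 1 come only from the (n−1)/n
shrinkage and carry no information, so exact-copy chains report 1.0).
WAIC uses the variance form of the effective-parameter penalty,
WAIC = −2(lppd − p_waic2), computed over the retained draws; lower is
better. All randomness descends from one run seed through counter-based
stream splitting (numpy `SeedSequence` spawn keys hashed from stage
names), so fixed seeds give bit-identical draws and tables.

## Pregnancy rate with maturity correction

Skin colour (grey → off-white → white with age) is an imperfect maturity
proxy. Necropsy series give maturity probabilities of 1.0 (white), 1.0
(off-white) and 0.1 (grey) for females aged 3+; with a three-year
reproductive cycle, one third of mature females are expected to enter
gestation each year. "Virtual biopsies" — females repeatedly flanked by
a newborn calf that would have been darted — enter as lactating (mature,
non-pregnant) records without a BP value, flagged so classifiers skip
them; they exist to keep hard-to-dart lactating females in the sample.
The minimum mature denominator counts presumed-pregnant females,
intermediate-cluster females and the virtual lactating females; the
remaining non-pregnant females of unknown maturity contribute
`round(Σ count_c × p_c)` additional matures. Rounding is to the nearest
integer with halves away from zero (so 10.5 → 11 and 49.2 → 49, matching
both intermediate roundings the arithmetic requires). On the study's
published sample composition (30+3 white, 9+3 off-white, 12+3 grey; 20
pregnant over 45 minimum mature; 15 unknown-maturity non-pregnant split
7/3/5) this yields 49 expected mature, 16 expected pregnancies, and a
rate moving from 20/45 = 44.4% to 20/56 = 35.7%.

## The synthetic-data generator

Published group statistics are raw-scale means and SDs; the generator
draws each group from the lognormal matching those moments
(σ² = ln(1 + s²/m²), μ = ln m − σ²/2), the minimal distribution
consistent with positive support and log-scale analysis. The
distributional form within groups is a modelling choice of this package,
not an empirical claim. Known-status tables use the seven carcass groups
(n = 62 total). Unknown-population presets encode the study conditions:
a harvest-carcass-like population mixing the resting and pregnant
moments with weights 0.54/0.46 and lipid Beta(mean 0.609), and a
biopsy-like population mixing three clusters at the reported biopsy
cluster moments (0.9 ± 0.5, 33.6 ± 21.3, 253 ± 99 ng g⁻¹, weights
20/23/22 over 65) with lipid Beta(mean 0.243). The lipid SDs (0.10
carcass, 0.15 biopsy) are not published; they were fixed once at values
giving realistic spreads (carcasses nearly all above 30% lipid, biopsies
with a visible low-lipid tail). Lipid fractions are moment-matched Beta
draws truncated at 10⁻³ so per-lipid concentrations stay finite. The
latent generating component is stored in a dedicated `latent_truth`
column outside the classifier-visible schema.

What the generator does **not** emulate: assay noise beyond the group
SDs (no plate effects, no inter-/intra-assay CV structure), carcass
decomposition effects on hormone or lipid content, age structure,
senescence, or any spatial/herd segregation. Passing recovery tests on
synthetic data therefore demonstrates that the estimators recover the
parameters of the assumed data-generating process at realistic sample
sizes — not that the assumed process is the true biology.

## Validation studies and problem sizes

Because real blind samples carry no ground truth, the estimators are
validated by simulation at the study's group moments. The mixture study
runs 20 seeded replicates of n = 200 (100 per component, resting vs
pregnant moments), fits K = 1 and K = 2 at the scaled geometry, and
scores 95% credible-interval coverage of both generating log-means and
the fraction of replicates where WAIC prefers K = 2. The logistic check
generates n = 500 from (β₀, β₁) = (−8, 2) on log BP over (0, 7) and
scores interval coverage of both coefficients. These sizes keep the full
validation suite at a few minutes on one core while leaving the
Monte-Carlo error of the coverage counts small.

## Known limitations

- The mixture assumes normal components on the log scale; heavy-tailed
  or skewed within-group laws would distort membership probabilities.
- WAIC at n ≈ 60–200 is itself noisy; the K chosen for a borderline
  dataset can flip between neighbouring seeds.
- The equal-odds concentration is reported only when the slope posterior
  is bounded away from zero; weak-signal data must be summarized on the
  log-odds scale instead.
- The maturity schedule is a point estimate from necropsy counts; its
  sampling uncertainty (e.g. 1/10 grey) is not propagated into the
  adjusted rate.
- Adjudicating recently parturient females as expected-pregnant is an
  assumption about hormone clearance time, not ground truth; error
  counts inherit it.
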