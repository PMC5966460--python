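# Methods

`mucopair` reimplements, as a tested library, the statistical layer of a
paired crossover safety study of topical gels on the rectal mucosa: a
label-free proteomics differential-expression pipeline and two Bayesian
paired models for 16S microbiome data, driven by a synthetic-study generator
so every stage is runnable and testable without external data.

## Study design encoded by the comparison registry

Six subjects each receive four gels — {placebo, drug} x {HEC, carbopol}
formulation — in a crossover with washout, after a longitudinal baseline
period. The registry (`workflow.proteome_comparisons`,
`workflow.microbiome_comparisons`) derives every paired contrast from sample
metadata alone: each post-gel time point versus the subject's baseline, and
drug versus matched placebo within formulation. Proteome time points are
T0/2 h/24 h (four baseline samples per subject); microbiome time points are
T0/24 h/7 d (two baselines per subject). Because the same registry feeds both
platforms, the pairing definitions cannot drift apart.

For baseline-referenced microbiome contrasts, each subject's baseline
samples are pooled by summing counts and depths. Pooling keeps the binomial
likelihood exact (reads from replicate baselines are exchangeable draws from
the same subject-level composition); averaging proportions would not.

## Proteomics pipeline

Stages run in a fixed, logged order:

1. **Total-signal normalisation.** Each sample is scaled so column totals
   equal the cross-sample mean total; within-sample proportions are
   untouched.
2. **Technical-replicate CV filter.** Proteins with coefficient of variation
   (sd/mean, ddof = 1) >= 25% across replicates of the pooled reference are
   removed.
3. **Median normalisation.** For each sample, the no-intercept least-squares
   slope `b` of its log2 abundances on a reference log2 profile `M` (the
   across-sample median) is computed and the sample multiplied by
   `2**((1-b)*sum(M^2)/sum(M))` — the unique rescaling making the refitted
   slope exactly 1. The pipeline freezes `M` once, from the total-normalised
   matrix. This matters: if the profile is recomputed on every call, the
   total-signal and median corrections impose two incompatible one-scalar
   constraints per sample and the alternation 2-cycles instead of converging
   (we measured a stable ~0.15 log2 oscillation). With a frozen reference
   the stage is a projection: re-applying both steps reproduces its output
   to machine precision, which is what the test suite asserts.
4. **Outlier report.** Samples whose total abundance falls outside
   median +/- 1.5 IQR are flagged and *kept* (the longitudinal design would
   be broken by dropping subjects' samples). A Tukey-fence variant
   (quartile +/- 1.5 IQR) is available via `center="quartile"`.
5. **Baseline averaging.** Arithmetic mean per protein per subject over all
   baseline samples.
6. **Paired testing.** Per protein, per-subject `log2(treatment/reference)`
   (reference = baseline average, or the matched placebo sample), a
   two-tailed paired t-test across subjects, and Benjamini–Hochberg
   adjustment across all proteins within a comparison; significant at
   q < 0.05. Proteins with a zero or missing intensity in any needed ratio
   are excluded and reported rather than imputed — with six subjects,
   imputation would fabricate a third of a test's information.

The BH step-up is implemented directly (reverse cumulative minimum of
`m*p_(j)/j`) so it agrees bit-for-bit with the definition; statsmodels'
`fdr_bh` is kept as an independent cross-check in the tests.

`detectable_log2fc` inverts the noncentral-t power function (via
statsmodels) to give the smallest detectable paired effect; at n = 6,
alpha = 0.05, power = 0.80 the standardised bound is dz ≈ 1.43, so a
within-pair sd of ~1.6 log2 units makes |2.3 log2 FC| the detectable
threshold. That sd is the generator's default `within_pair_sd_log2`.

Hierarchical clustering uses distance 1 − Pearson correlation with complete
linkage; when baseline samples are included, clustering operates on
abundances that were **not** baseline-normalised (normalising first would
force baselines toward zero and distort the correlation structure).
Dendrograms export to Newick.

## Shannon-diversity model

Per sample, `H = -sum p ln p`. Because H is bounded by `ln K` for K retained
taxa, the evenness ratio `H / ln K` (Pielou scaling — our choice; the
transform itself needs a (0,1) argument and the scaling constant is the only
natural one) is clamped to [1e-6, 1-1e-6] and logit-transformed. The paired
model for n transformed pairs is

    yT_i ~ Normal(muT_i, sigmaT)      yC_i ~ Normal(muC_i, sigmaC)
    Delta.mu_i = muT_i - muC_i ~ Laplace(mu, sigma)

taken literally: one observation per pair and arm, per-pair free means,
shared arm-level sds, and a heavy-tailed Laplace pooling the per-pair
differences. The reported effect is the posterior of `mu`. Priors are
weakly informative — Normal(0, 5) on locations, half-Normal(0, 2.5) on
all three scales — chosen proper and diffuse relative to the transformed
scale (values lie roughly in (-3, 3)).

## Per-taxon abundance model with measurement error

For one taxon and n subject pairs:

    yT_i ~ Binomial(nReadsT_i, pT_i)          (and likewise control)
    log10(pT_i) ~ Normal(log10(tpT_i), sigmaT_i)
    Delta_i = log10(tpT_i / tpC_i) ~ Normal(mu, tau)

The effect size is the posterior mean of `mu`, the population mean of
log10 ratios of *true* relative abundances; `10**mu` reads directly as a
fold change. The p-value is the two-sided posterior tail probability
`2*min{P(mu>0), P(mu<0)}`, floored at 1/n_draws (the posterior construction
is our documented choice), BH-adjusted across taxa within a comparison and
called significant at q < 0.01.

**Measurement-error calibration.** Replicate positive controls (~14
aliquots of one mixed specimen) give, per taxon detected in every
replicate, the median and variance of log10 relative abundance.
`log10(variance)` is regressed linearly on the median (the functional form
is our choice; it is the simplest monotone law the replicate data support),
the slope clipped to <= 0 so rarer taxa are never predicted more precise,
and predicted sds floored at 1e-3. By default sigma is evaluated once per
arm at the taxon's median log10 abundance in that arm's samples;
per-observation evaluation is a flag.

**Priors and support.** Normal(0, 1) on `mu`, half-Normal(0, 1) on `tau`,
logit-scale Normal(logit(pooled observed proportion), 2) on each `tpC_i`;
latent log10 proportions are hard-clamped below 0 (valid because modelled
taxa are far below 100% abundance). A taxon with zero counts in every
sample of one arm is skipped with a warning.

## Taxa filtering

A taxon enters a comparison iff its study-wide mean relative abundance
exceeds 1e-5, it is detected in >= 25% of study samples, and it is detected
in >= 4 subjects of the comparison (either member of the pair). "Detected
per subject" means a nonzero count in the treatment or control sample; the
pooled-baseline columns do not count toward the study-wide rules. The filter
is idempotent (the frequency rule only relaxes when taxa are removed).

## MCMC

Both models run on a vectorised affine-invariant ensemble sampler
(Goodman–Weare stretch move, a = 2): gradient-free and invariant to linear
reparameterisation, which matters because these posteriors mix latent
proportions pinned by 10^4–10^6 reads with weakly identified hierarchical
scales. The prescribed plan — 3 chains, 10,000 iterations, thinning 10 —
runs the three chains as independent ensembles (2*ndim walkers each) inside
one vectorised log-density call; the first half of iterations is warm-up and
each stored chain pools its walkers after thinning. Convergence is gated by
the potential scale reduction factor

    R-hat = sqrt(((n-1)/n * W + B/n) / W)

computed from between/within-chain variances only (so pooled walkers form a
valid chain for the diagnostic); results with R-hat > 1.1 on the headline
parameter carry a non-convergence warning, and the CLI's strict mode turns
that into exit code 3. A fast profile (3 chains x 2,000 iterations, thin 2)
is used throughout the test suite and acceptance script. Initial points come
from the observed data (e.g. `log10((y+0.5)/(n+1))`), with walker spread
matched to the per-coordinate posterior scale.

## Synthetic-data generator

The generator emulates the study at the count/intensity-table level — no
reads, spectra or chromatograms.

* **Proteome.** Protein base intensities span ~4 orders of magnitude
  (log-rank coverage of label-free data); per-subject offsets
  (sd 0.5 log2) and per-sample noise with sd `within_pair_sd_log2/sqrt(2)`
  (default total paired sd ~1.6 log2, the value implied by the
  80%-power-at-|2.3 log2FC| design) sit on top. Nine technical replicates
  of the pooled reference are lognormal with CV 5% (configurable decoys get
  CV 60% and should fail the 25% filter).
* **Microbiome.** Per-subject baseline compositions are additive
  logistic-normal (diagonal covariance) around a shared rank-abundance
  pattern, subject sd 0.5 log10; samples add diagonal log10 noise
  (sd 0.08); depths are lognormal around 58,671 reads (dispersion 0.3) and
  counts multinomial. Planted effects multiply chosen taxa by
  `10**log10_ratio` before renormalisation and, by default, apply to *both*
  arms at the effect formulation/time point — a formulation/application
  effect, which keeps drug-vs-placebo contrasts truly null and matches the
  study finding that the vehicle, not the drug, drove changes. Compositional
  closure means an injected ratio on an abundant taxon is attenuated in the
  observed ratios; tests therefore plant effects on taxa in the ~0.5–2%
  abundance range, where the attenuation is negligible (and where the real
  study's significant taxa sat).
* **Positive controls.** Replicates of one fixed composition whose log10
  abundances are jittered with sd `0.05 + 0.1*max(0, -2 - m)` — constant
  above 1% abundance, growing linearly below — then counted multinomially,
  so the measurement-error fit has a recoverable target.

What the generator does *not* emulate: taxonomic mis-assignment, batch and
run effects, chimeras, carryover between crossover periods (the study's
effects resolved within the washout), correlated (non-diagonal)
compositional noise, and proteome missingness mechanisms. Passing tests
therefore demonstrate correctness of the statistical machinery under the
models' own assumptions, not robustness to those real-data pathologies.

## Problem sizes used in tests and the acceptance script

Simulation-backed checks run at study scale (n = 6 pairs) with the fast
MCMC profile; replicate counts are 20 seeded runs for the two recovery
checks, 200 null proteome studies (382 proteins each), 500 power
replicates, 50 null microbiome studies of 5 taxa each, and 60 repetitions
for credible-interval calibration. End-to-end workflow tests use 20 taxa at
depth 20,000 with two planted effects of 0.6 log10 on ~1%-abundance taxa.
These sizes are the package's own choice of a thorough-but-quick default;
all are parameters, not constants.

## Numerical choices and degenerate inputs

* Paired t-tests refuse zero-variance differences (no p = 0 convention);
  the vectorised matrix version returns NaN for such rows and BH propagates
  NaN without counting it toward m.
* `bh_adjust` computes each term as `m*p/j` exactly as the definition
  writes it, so equality with a brute-force implementation is exact, not
  approximate.
* Shannon uses natural logs with `0*log(0) := 0`; compositions must sum to
  1 within 1e-9.
* The logit clamp (1e-6) bounds transformed diversities to ±13.82.
* Observed-proportion medians for sigma assignment use `(y+0.5)/(n+1)` to
  stay finite at zero counts; the model itself uses raw counts.
* PSRF returns 1 for identical constant chains and +inf when chains are
  constant but unequal.
* Classic (non-split) R-hat can fall slightly below 1 on short chains; the
  convergence gate is one-sided (R-hat <= 1.1).

## Known limitations

* The diversity model has one observation per pair and arm, so sigmaT and
  sigmaC are only weakly identified; the Laplace hierarchy regularises the
  fit, but per-pair interval widths should not be over-interpreted.
* Posterior tail p-values are bounded below by 1/n_draws (~1.3e-5 with the
  fast profile); reproducing q-values of 1e-13 requires the full chain plan
  and many more kept draws.
* The measurement-error law extrapolates linearly outside the abundance
  range spanned by the positive controls (monotonicity and the floor bound
  the damage).
* Total-signal normalisation redistributes large one-sided proteome shifts
  onto null proteins (a closure artifact); the differential test is
  calibrated under the global null but not under gross one-sided
  perturbations of a large fraction of the proteome.
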