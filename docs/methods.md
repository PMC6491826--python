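# Methods

This note records the statistical model, the defaults and why they were
chosen, the numerical decisions, and what the synthetic benchmark does and
does not establish.

## Ratio normalisation and the ε floor

Microbiome abundance tables are compositional: only relative information
survives sequencing. Instead of scaling each sample to a fixed sum, every
feature is divided by a per-sample *divisor* value — a single feature, or
the geometric mean of a set, required to be strictly positive in all
samples entering the analysis. Ratios to a common divisor are invariant to
any per-sample rescaling, so sequencing depth cancels exactly (this is
asserted as a test property).

Divisor strategies:

* **min_variance** (default): among all-positive features, pick the one
  whose log relative abundance has the smallest across-sample variance — a
  "stable reference taxon" heuristic. With the synthetic generator this
  recovers the planted reference feature.
* **iterative**: start from min_variance, run the full differential test,
  rebuild the divisor as the geometric mean of the all-positive features
  *not* called significant, and repeat until the significant set is stable
  (capped at 5 rounds). This hardens the divisor against accidentally
  choosing a differential feature.
* **manual**: caller-supplied, validated for positivity.

ε is the minimum positive ratio over the **whole** table — both groups
jointly — so the two groups share one dropout support. The divisor and ε
are recorded in every output header.

## The zero-inflated lognormal mixture and its EM fit

Each feature × group ratio vector is modelled as

    R ~ Unif(0, ε)     with probability p     (dropout)
    R ~ LN(μ, σ²)      with probability 1 − p

Zeros are treated as censored dropout candidates and imputed at the
deterministic midpoint δ = ε/2 of the uniform support (a seeded random-draw
alternative would change results run to run for no inferential gain; the
deterministic midpoint keeps runs bit-reproducible). Positive observations
belong to the lognormal component with certainty: ε is the smallest
positive ratio, so the uniform support contains no observed positive value
and their responsibility τ is exactly 0.

EM on the complete-data log-likelihood

    ℓ = Σ z·log[p·u(y)] + Σ (1 − z)·log[(1 − p)·φ(y; μ, σ²)]

with u the uniform density and φ the normal density of log R:

* E-step: for zeros, τ = p·(1/ε) / [p·(1/ε) + (1 − p)·f_LN(δ)]; τ = 0 for
  positives.
* M-step: p = mean(τ); μ = Σ(1 − τ)·y / Σ(1 − τ); σ² analogously.
* Initialisation: p⁰ = zero fraction, μ⁰/σ⁰ = moments of the positive logs.
* Convergence: |Δ loglik| < 1e−8, at most 500 iterations; σ floored at
  1e−6 so degenerate inputs (identical positive values) terminate cleanly.

Because all zeros share one imputed value, each iteration reduces to scalar
updates on sufficient statistics of the positive entries, making thousands
of per-feature fits cheap. The observed-data log-likelihood is recorded at
every iteration; monotonicity of the trace (tolerance 1e−10) is asserted in
tests, and on small instances the EM optimum is checked against an
exhaustive 0.01-resolution grid maximisation of the same likelihood.

One subtlety the grid check exposed: if ε is estimated from a *single short
vector's* own minimum positive value, δ = ε/2 can land inside the lognormal
bulk and the likelihood becomes multimodal. In the pipeline ε is the
table-wide minimum over hundreds of features, which sits far below any one
feature's positives, so the dropout and abundance components are well
separated. Single-vector fits (as in the calibration benchmarks) should
therefore pass the known generative floor as ε rather than the vector's own
minimum.

## The two-group test

The group difference in μ is tested with a responsibility-weighted Welch
*t*: effective sizes n_g = Σ(1 − τ), weighted variances with an
(n_g − 1) denominator, Welch–Satterthwaite degrees of freedom, two-sided
*t* p-value. When a feature has no zeros this is *exactly* the classical
Welch t-test on log ratios (asserted to 1e−10). Features with effective
size < 2 in either group are reported untestable with p = 1 rather than
dropped, so the output row set is predictable.

Before testing, features positive in fewer than 20% of samples in *both*
groups, or with fewer than 3 positive samples in either group (below which
the lognormal component is unidentifiable), are excluded. Multiple testing
uses Benjamini–Hochberg at FDR 0.05 by default — the field-standard choice
for feature-wise abundance screens. Natural logarithms throughout.

Under the synthetic null (no planted effects, no evenness gradient,
300 features × 40 + 40 samples) the raw p < 0.05 fraction sits at the
nominal rate and BH at 0.05 makes essentially no discoveries; with 10% of
features shifted by 2.0 on the log scale, median sensitivity exceeds 0.9 at
empirical FDR below 0.10. Both are recomputed by the test suite and
`scripts/acceptance.py` at exactly these problem sizes — chosen so that the
whole calibration runs in seconds while leaving each feature ~8–30
effective observations per group, a realistic regime for cohort subgroups.

## Diversity and the diversity–disease logit

Shannon entropy (nats) and inverse-Simpson are computed on per-sample
relative abundances; zero entries contribute zero (the x·ln x → 0 limit).
The three-state comparison pools small and large adenoma into one adenoma
state (progression stages of the same lesion type) and uses Kruskal–Wallis
followed by Dunn's pairwise z with mid-rank ties and tie-corrected
variance. Pairwise p-values are reported **unadjusted** by default, with
Bonferroni and BH available by flag — unadjusted pairwise reporting is the
convention the package mirrors, and the adjustment choice is recorded in
the output.

The logistic model logit(P) = β₁·d + β₀ (d = Shannon index, P = probability
of CRC) is fitted by maximum likelihood on healthy + CRC samples by default;
adenoma samples can be admitted by flag, in which case CRC remains the
positive class. Complete separation is flagged (`converged = False`, with a
warning) rather than penalised or raised — the estimator stays a plain
logit. A zero-variance predictor degenerates to the intercept-only model
(slope 0, intercept = logit(prevalence)); with the predictor collinear with
the intercept only the class mean is estimable, and this degenerate answer
is the informative one.

## Co-occurrence networks

Within each disease state (≥ 3 samples), features passing a 10% prevalence
filter are correlated across samples; pairs with |r| > 0.5 become edges and
node weight is the feature's mean relative abundance in that state. Pearson
correlation is the default; Spearman is available by flag — both appear in
practice and the package treats the choice as a config field, defaulting to
Pearson, which is appropriate when the effective species number is high
(tens) rather than low. Negative correlations are kept as signed edges by
default (`use_absolute = True`); switching it off yields a strictly
positive co-occurrence network. Constant features are dropped with a
warning naming them. No permutation p-values are attached to edges: the
coefficient threshold is the criterion, and statistical edge testing is a
deliberate non-feature. Edge sets are compared across states as shared /
state-unique partitions.

## Classifier

The differential features (significant, ordered by q-value, ties broken by
|Δμ| then id, truncated to 9 — a compact biomarker-panel size) feed a
random forest (500 trees, default tree settings) evaluated with stratified
5-fold cross-validation on relative abundances. The headline number is the
**pooled out-of-fold AUC**: one ROC over all samples, each scored by the
fold that held it out — the least-variance single-number convention.
Per-fold AUCs are also reported. The seed drives both the fold shuffle and
the forest, so results are bit-reproducible.

## The synthetic-study generator

`simulate_study` emulates the structure the analyses assume:

* **Group sizes** default to a cohort-like 61 / 27 / 15 / 53
  (healthy / small adenoma / large adenoma / CRC); tests use smaller,
  documented sizes for speed.
* **Per-feature parameters**: log-mean μ_i ~ U(0, 3), log-sd
  σ_i ~ U(0.3, 1.2), dropout p_i ~ U(0.3, 0.8). With multinomial sampling
  zeros on top, the emitted table is > 50% zeros — the sparsity regime of
  real stool metagenomes. Dropout is applied to the latent abundance
  *before* compositional renormalisation (structural zeros); finite
  sequencing depth adds sampling zeros — two zero sources, matching the
  undersampling interpretation of dropouts.
* **Depth**: lognormal with log-mean ln 50 000 and log-sd 0.3, a plausible
  genus-table read-count scale.
* **Evenness gradient**: each state's compositions are raised to the power
  1 + g·s (s = 0 … 3 along progression, g = 0.1 by default) and
  renormalised. Any g > 0 makes expected Shannon strictly decreasing along
  progression; g = 0.1 yields a healthy-to-CRC decline of a few tenths of a
  nat, the order seen in CRC cohorts. Resolving the *ordering* of adjacent
  states from realised tables needs a few dozen samples per state because
  the per-step expected drop (~0.13 nat) is comparable to the per-sample sd.
* **Planted effects**: a configurable fraction of features (10% by default)
  has Δ = 2.0 added to μ in CRC samples only.
* **Reference feature**: one all-positive, non-differential, low-variance
  feature is always planted so divisor selection is well-posed.
* **Stages** are assigned to CRC samples at cohort-like proportions
  (15:7:10:21 for I:II:III:IV).

All draws flow from one integer seed; identical configs are bit-identical.

What the generator does **not** emulate: taxonomic correlation structure
(features are independent given the composition constraint), batch or
cohort effects, overdispersion beyond lognormal, read-level errors, and
compositionally induced spurious correlations beyond the shared-sum
constraint. Passing tests therefore demonstrate the statistical machinery
is correct and calibrated under the stated generative law, not that real
tables satisfy that law; on real data the prevalence filter, divisor
diagnostics, and the choice between Pearson and Spearman deserve scrutiny.

## Numerical choices and degenerate inputs

* Zero imputation at δ = ε/2, deterministic.
* σ floor 1e−6 (fits on identical values converge with σ at the floor).
* E-step computed in log space with an overflow guard; p = 0 and p = 1 are
  handled as exact limits.
* A zero-variance test statistic is resolved by sign: t = 0, p = 1 when the
  means agree, |t| = ∞, p = 0 otherwise.
* Dunn variance ≤ 0 (all values tied) is guarded to z = 0, p = 1.
* Correlation matrices are symmetrised, clipped to [−1, 1], unit diagonal.
* Writers use `%.17g` for count tables (exact float round-trip) and
  `%.10g` for derived result tables; no timestamps, so outputs are
  byte-stable under a fixed seed.

## Known limitations

* The weighted Welch test treats the EM point estimates as data; it does
  not propagate uncertainty in τ. Calibration is verified empirically
  rather than derived.
* Differences in dropout probability between groups are not tested — only
  the log-mean shift. A feature present in one group and absent in the
  other will surface through the prevalence filter and effective-size
  flags, not through a dedicated test.
* The divisor must exist: a table where every feature has at least one zero
  needs manual intervention (prevalence-filter first, or a pseudo-divisor).
* The network stage thresholds raw correlations on relative abundances and
  inherits their compositional biases; it is a descriptive screen, not
  inference.
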