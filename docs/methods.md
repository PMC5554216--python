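# Methods

This note records the statistical model implemented by `siteocc`, the
choices made where the design was genuinely open, and what the simulation
framework does and does not establish.

## Data model and ingest

The unit of observation is a quantified peptide feature in one LC-MS/MS
run: (peptide sequence, modification form, charge state, isotope index)
with an integrated chromatographic peak area.  Charge states and isotope
indices 0–4 are the quantified ions of typical high-resolution peptide
mapping; column names are mapped from the exported report via a YAML
schema, since such reports have user-defined headers.

Two contracts matter downstream:

* **Zero/blank areas are unobserved, not zero.**  A peak that was not
  integrated is assumed censored below the detection limit; ingest drops
  the row and the absence reappears as a censored cell in the feature
  matrix.  Treating these as literal zeros is exactly the naive baseline's
  bias mechanism.
* **Attribution requires single-site forms.**  A peptide modified at two
  sites cannot have its intensity attributed to either site, so multi-site
  forms are removed before site-level analysis.  Carboxymethylated cysteine
  (+58 Da) is introduced on every free cysteine during sample preparation
  and therefore does not count as a modification for this rule.  Features
  with isotopic dot product < 0.7 (strict) are removed as mis-assigned
  peaks; the threshold is configurable and absent idotp values are kept.

## Sub-plot summarization

Per (site, form), the runs × features matrix of log2 intensities is reduced
to one summary per run in three steps.

**Feature selection.**  A feature is retained when observed in at least
`ceil(min_coverage × R)` of the R runs (default `min_coverage = 0.5`; no
numeric rule is published for this search, so the coverage threshold is
this package's concrete rule).  If nothing qualifies, the single
best-covered feature is kept (ties: larger total raw intensity, then
lexicographic label), making selection deterministic under input
permutation.  With `harmonize=True` (default) charge states qualifying in
any form of a site are retained for all its forms, keeping forms comparable
when one charge state drops out of a single run — the situation profile
plots typically reveal.

**Censored imputation.**  Remaining missing cells are left-censored.  A
censored normal linear model (the Gaussian accelerated-failure-time form)
with additive run and feature effects is fitted by maximum likelihood:
observed cells contribute density terms, censored cells contribute
`Φ((L_f − pred)/σ)` with a per-feature limit `L_f = 0.99 × min` observed
log2 intensity of that feature.  Imputed value = `min(prediction, L_f)`,
so imputed values never exceed the limit; observed values are never
touched.  A feature never observed at all is dropped (nothing to anchor
it); a run with no observed feature yields no summary rather than an
error.  The optimizer is BFGS on the explicit negative log-likelihood;
σ is parameterized on the log scale and clipped to `exp([-10, 5])`.

**Tukey median polish.**  The completed matrix is decomposed as
`overall + run + feature + residual` by alternating median sweeps (rows =
runs first), stopping when no effect changes by more than 1e-6 or after
100 sweeps; even-length medians are midpoints.  The run-level summary is
`overall + run effect` — resistant to a single outlying feature in a run,
which mean-based summaries are not.  A LogOfSum alternative (log2 of the
summed raw areas of the retained features per run) is available for
comparison; it skips imputation and simply omits runs with no observation.

## Whole-plot inference

Run summaries are independent whole-plot units.  Per form, condition means
are estimated with the residual variance pooled across that form's
conditions: `s² = Σ_k Σ_r (s_kr − μ̂_k)²/df`, `df = Σ_k (n_k − 1)`,
`se_k = s/√n_k`.  Pooling is within form only — forms differ in feature
sets and noise.  A singleton condition borrows the pooled `s`; if every
condition is singleton the SE is unavailable and downstream intervals and
tests refuse the form rather than fabricate uncertainty.

## Occupancy and the delta method

Occupancy is the softmax of the μ's in base 2; its variance is the
first-order delta-method form

    Var(p_j) ≈ (ln 2)² Σ_l [p_j (δ_jl − p_l)]² Var(μ̂_l),

treating forms as independent.  Computation shifts all μ's by their
maximum before exponentiating, which changes nothing (occupancy is
invariant to common shifts) but keeps 2^25-scale intensities in safe
floating-point range.  Because the contributing variances carry different
dfs, the effective df is Satterthwaite's
`(Σ v_l)² / Σ v_l²/df_l` over the per-form variance terms; intervals are
`p ± t_{df_eff} · se`, clipped to [0, 1] with no logit transform.
Combined occupancy pools raw abundance over a site set — each site enters
with its summed 2^μ weight, i.e. an equal-ionization-efficiency
approximation across sites; the same delta-method and df machinery applies
to the pooled gradient.

**Degrees of freedom in the H1 contrast.**  Each form's `s²` is pooled
across both conditions, so the two conditions' occupancy variances draw on
the *same* chi-squares.  Combining `se_A` and `se_B` by Satterthwaite as
if independent double-counts those chi-squares (df ≈ 16 instead of ≈ 8 in
the three-form simulation scenario) and measurably inflates the type I
error of the occupancy test at three replicates.  `OccupancyEstimate`
therefore carries its per-form variance components, and `test_h1`
recombines them per form — one chi-square per form, terms summed across
conditions — which matches standard split-plot df accounting.  When
estimates come from elsewhere without a component breakdown, the test
falls back to the plain two-component Satterthwaite combination.

## Differential testing

H2 is the ordinary relative label-free contrast of one form's log2
abundance; H3 subtracts an unmodified reference peptide's abundance in the
same runs first (here the fixture and CLI default to the convention of a
stable, well-covered unmodified peptide), cancelling global run-level
intensity shifts; H1 contrasts occupancies and is the test that addresses
the stated quantity directly.  All tests are two-sided t tests of
`difference / SE`; direction is the sign of the difference (condition A
minus B).  BH step-up adjustment is applied per comparison family — the
family is the list handed to `adjust_bh`, and the CLI uses one family per
volcano panel (one comparison × one hypothesis).  Whether positive-control
comparisons at two stress doses form one family or two is exposed to the
caller rather than fixed.  Confusion metrics against control labels use
`p_adj < cutoff` as the positive call and the standard
sensitivity/specificity/PPV ratios.

The naive route is implemented as practiced: per-run ratio of summed raw
areas (an absent feature contributes zero), run-averaged, with a Welch
t-test across runs.  Welch rather than pooled-variance is this package's
choice — replicate counts of 3 vs 6 are the realistic design and the
baseline's variance homogeneity is exactly what is in doubt.

## Simulation framework

Simulation operates at the summarized level: the sub-plot stage is
bypassed and run summaries for form *j* are drawn i.i.d.
`Normal(μ_j, sd_log2)` with

    μ_j = mean_log2 + log2 p_j − (1/K) Σ_l log2 p_l,

so the μ's imply exactly the target occupancies and average to
`mean_log2`.  Defaults encode the reference scenario: three forms at
5/20/75 % occupancy, `mean_log2 = 25`, `sd_log2 = 0.2`, 3 replicates per
condition, 1000 datasets, α = 0.05.

* **Missingness** removes one named form's summary from one replicate.
  The proposed route treats the empty cell as censored and imputes it with
  the same censored-regression machinery, applied to the condition's
  runs × forms summary matrix (within condition, so a between-condition
  effect cannot leak into imputed values); the naive route scores the form
  zero in that run.
* **Power settings** shift the tested form's occupancy in condition B by
  an absolute 5/10/15 percentage points (interpreted as absolute, not
  relative), rescaling the other forms proportionally to re-sum to 1; the
  default tested form is the 20 % form.
* **Metrics:** mean relative error `(p̂ − p)/p` and mean 95 % CI width per
  form (estimation), and per-form rejection rates at raw α (testing; no
  multiplicity adjustment inside the calibration experiment).

Observed behaviour at the defaults: the proposed H1 test's type I error
sits near nominal, while the naive t-test is conservative on complete data
and becomes both biased and inefficient once a summary is missing (the
zero-scored run inflates the between-run variance of the affected form).
These simulations share the generator with the estimators' assumptions —
normal, independent, homoscedastic summaries and a single site — so
passing them shows internal consistency and correct calibration under the
stated model, not robustness to correlated features, heteroscedastic
noise, retention-time artifacts or interference, which real peptide maps
contain.

Run resampling draws (or exhaustively enumerates) run subsets of size 2–3
per condition and re-runs the full differential pipeline per subset,
reporting max/median/min adjusted significance per form — the
small-sample-stability view of the analysis.

## Numerical and interface choices

* Log base 2 throughout; the `(ln 2)²` delta-method factor is part of the
  contract.
* Seeded `numpy.random.Generator` everywhere; identical seeds give
  byte-identical outputs, and every CLI run writes a manifest (inputs'
  SHA-256, parameters, seed, version).
* Plain-text interfaces only: CSV reports/designs/outputs, YAML configs,
  JSON summaries.
* The synthetic fixture generator emulates report structure (feature
  envelopes over charges/isotopes, per-run log-normal variation,
  configurable missingness and low-idotp rows), not chromatography;
  envelope weights are fixed, so fixture "features" are more mutually
  consistent than real ones.
* Problem sizes in the shipped tests (500–1000 simulated datasets,
  10⁶-draw Monte-Carlo oracles, 2000-replicate coverage checks) were
  chosen so the binomial/Monte-Carlo error of each checked quantity is
  several times smaller than the asserted band.

## Known limitations

* Forms entirely absent from one condition (e.g. a stress-induced form
  never seen at reference) are estimated only where observed; occupancy in
  the absent condition is computed over the observed forms, which
  overstates their shares there.
* The equal-ionization-efficiency assumption of combined occupancy is
  uncorrected (no labeled reference peptides).
* Feature selection's coverage rule is a stand-in for a richer
  representativeness search; `min_coverage` and harmonization are exposed
  precisely because they are judgment calls.
* The censored-regression imputation assumes additive run/feature effects
  and normal errors; gross interferences violate it and should be caught
  upstream at curation.
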