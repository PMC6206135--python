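# Methods

This note documents the models and numerical choices behind `irdm`, what
the synthetic-data generator does and does not emulate, and the package's
known limitations.

## Signature scores

A signature score is the arithmetic mean of a gene list's log2 expression
values in one sample.  A score is only reported when at least 70% of the
signature's genes are present and non-missing (mirroring the assay's
30%-missing QC philosophy); the threshold is configurable everywhere it
applies.  The published affine maps — 38·(u + 1.35) for proliferation,
30·(u + 1.40) for immunity — are unbounded, while the scores are defined on
0–100; we clip to [0, 100].  Group boundaries are inclusive on the upper
side (proliferation-high iff score ≥ 50; istrong iff score ≥ 42, mirroring
the explicit "larger or equal" proliferation convention).  Note the
immunity map sends u = 0 exactly to the istrong cutoff 42: on
median-centered data, a sample is istrong when its mean immunity expression
exceeds the cohort-typical level.

## Subtyping

The classifier is a single-sample predictor: Spearman rank correlation
(average ranks for ties) between the sample profile and each of six
centroids, assignment to the argmax.  Taken literally, "highest
one-minus-correlation" would pick the *most dissimilar* centroid; we
maximize the correlation itself, consistent with the nearest-centroid
single-sample-predictor literature.  Exact ties are broken by the fixed
label order (Basal, HER2E, Immuno, LumA, LumB, Normal) and flagged.

Confidence is 1 − p with p the two-sided p-value of the winning correlation
from the t approximation (df = n − 2); with ~66 genes the approximation is
accurate, and an exact permutation test is available for short vectors
(n ≤ 8).  Calls with confidence < 0.95 become Mixed.  Because the winner is
the best of six correlated centroids and no multiplicity correction is
applied, a pure-noise profile is *not* Mixed 95% of the time — Monte Carlo
puts the Mixed rate near 86%.  This selection effect is a property of the
confidence rule itself, not of this implementation.

Missing genes are handled by pairwise-complete correlation, subject to a
70% coverage minimum (below it the call is Mixed with confidence 0).  The
subtyping gene set defaults to the 66 non-housekeeper panel genes —
housekeepers exist for normalization, not discrimination — and is
configurable.  Because the classifier is rank-based, calls are invariant to
any strictly monotone per-sample transform; we therefore accept any
log-scale matrix state (raw counts are rejected).

Centroid training is the per-gene mean over each subtype's labelled
samples, requiring at least two samples per class.

## Risk score

The published equations mix correlation-scale covariates with 0–100 scores;
applied verbatim, a proliferation score of 60 would contribute 0.24·60 =
14.4 to a quantity whose 0–100 display scaling is 90·u + 50 — dimensionally
impossible.  We divide both scaled scores by 100 (range [0, 1], the same
order of magnitude as correlations) before applying the coefficients; the
divisor is a field of `RiskCoefficients` for users who prefer another
convention.  Risk groups: low < 33 ≤ med < 50 ≤ high, upper boundaries
inclusive for consistency with the score conventions.  The Normal
correlation participates in subtype assignment but carries no risk weight.
Unknown ER status falls to branch B and is flagged; an optional fallback
(`infer_er_status`) calls ER from a two-component Gaussian mixture over the
ER-category signature score and should always be treated as inferred, not
clinical.

Refitting (`refit_coefficients`) reproduces the published training design:
samples whose winning-centroid correlation is ≥ 0.7 form the training
subset, follow-up is truncated at 10 years, and a Cox proportional-hazards
model (lifelines) of time-to-event on the five correlations plus the two
[0, 1] scores is fitted per branch.  **Identifiability caveat:** the
correlation covariates of a nearest-centroid cohort are strongly collinear
(each sample's correlation vector sits near its subtype's prototype; the
0.7 cutoff tightens this further).  At a few thousand samples the partial
standard deviations of the correlation covariates are ~0.05–0.1, so Cox
standard errors for those coefficients are of order 0.5–1.5.  Coefficients
of magnitude ≤ 0.1 (Immuno and immunity in branch B) are therefore not
sign-identifiable at cohort sizes like 2000 — detecting the sign of −0.06
would need roughly 25× more events.  The package reports standard errors
alongside estimates so users can see this directly; point estimates of the
small coefficients should not be over-interpreted, at any cohort size
comparable to the original 404-sample training subset.

## Preprocessing

Fixed stage order, enforced via a matrix state flag (`raw_counts` →
`cpm_log2` → `centered_standardized`):

1. **QC** — keep samples with total reads strictly greater than 10 000 and
   fewer than 30% of the 72 panel genes at zero count ("missing" is
   operationalized as a zero count; the assay defines no other detection
   threshold).  Decisions use only the sample's own column.
2. **Normalization** — counts divided by transcript length, scaled to
   counts-per-million within sample, then log2(CPM + 1).  The +1 offset is
   the standard zero-safe choice.  Zero counts become missing values.
3. **Imputation** — KNN over samples (Euclidean distance on shared observed
   genes, uniform mean of k = 10 neighbors; scikit-learn's `KNNImputer`).
   Observed entries are never modified, and imputed values are convex
   combinations of observed values, hence inside each gene's observed
   range.  Genes missing in ≥ 30% of samples are refused.
4. **Centering/standardization** — gene rows median-centered, sample
   columns scaled to unit SD (ddof = 1).  A single row-then-column pass
   cannot satisfy both constraints simultaneously, so the two steps are
   iterated, in that order, to joint convergence (tolerance 1e-10;
   converges in a handful of sweeps).  Constant input columns are rejected
   up front.

## Synthetic cohorts

The generator emulates a processed cohort over the 72-gene panel with the
structural assumptions the method relies on, built in explicitly:

- **Centroids** (`make_centroids`): block-structured marker means per
  subtype (basal keratins high in Basal, ER axis high in luminal tumors,
  HER2 amplicon in HER2E, proliferation per the spec'd subtype means), plus
  per-gene jitter (SD 0.25).  The immunity-gene jitter is shared across
  subtypes so the five non-Immuno centroids have *identical* immunity
  profiles; Immuno sits a constant +1.5 log2 above them.  Proliferation
  jitter is likewise shared so each centroid's mean proliferation equals
  the specified value up to a common constant.
- **Samples** (`generate_cohort`): subtype centroid + i.i.d. Gaussian noise
  (default SD 0.3 log2 units) + a per-sample immunity-axis displacement
  δ ~ N(0, 0.5²) applied to the 17 immunity genes only — so immune
  infiltration is independent of subtype by construction.  Gene rows are
  median-centered, the state real processed datasets arrive in.  ER status
  is drawn per subtype (e.g. Basal 95% ER-negative; the probabilities are
  documented configuration defaults, not literature estimates).
- **Survival**: each sample's event time is exponential with hazard
  h₀·exp(β·u), where u is the *measured* unscaled iRDM score of the
  sample's own profile under the published coefficients, with independent
  exponential censoring (defaults h₀ = 0.05/yr, censoring 0.05/yr, β = 1 —
  roughly 35–45% events within 10 years).  Using the measured covariates
  makes the Cox refit a well-specified model.  β = 0 yields flat-hazard
  null cohorts for calibration tests.
- **TIL**: pathologist TIL percentage is modelled as 30 + 40·(immune
  signal) + N(0, 10²), clipped to [0, 100], where the immune signal is the
  displacement δ plus the Immuno group's +1.5 baseline — TIL measures the
  same infiltrate that drives immunity-gene expression.
- **Counts** (`generate_counts`): per-sample multinomial reads with
  probabilities ∝ 2^expression × transcript length (lengths uniform
  500–3000 bases), optional dropout zeros and deliberately under-sequenced
  samples to exercise the QC gates.
- **Single cells** (`generate_single_cells`): 12–78 cells per tumor, 2–3
  carcinoma subtypes per tumor plus ~30% immune cells (globally low
  expression, immunity genes high, a dividing sub-fraction also
  proliferation-high), with heavy dropout recorded as missing.

Everything is reproducible from the spec's seed (independent substreams for
centroids, cohort, counts and cells).

What the generator does **not** emulate: batch effects and platform
differences, probe-level noise, realistic RNA-seq error profiles or UMIs,
correlated gene-gene noise within signatures, non-proportional hazards, and
informative censoring.  Tests passing on these cohorts demonstrate the
pipeline's correctness and calibration under its own assumptions, not
clinical performance on real data.

### Default study sizes

Tests and the acceptance script use: 600 samples (balanced subtypes, noise
0.3) for label recovery; 300 per noise level for Mixed-fraction
monotonicity; 2000 samples with near-zero censoring and baseline hazard
0.2/yr ("events-rich") for coefficient refitting; 200 replicates of 120
samples for null calibration; 40 samples at depth 10⁶ for the counts round
trip; 2000 samples for the immunity-independence contingency test; 6 tumors
for heterogeneity.  These sizes give the Monte-Carlo checks stable margins
while keeping a full run fast.

## Numerical choices

- Spearman p-values: two-sided t approximation everywhere by default;
  exact permutation available for n ≤ 8.
- Degenerate correlations (constant vector, < 3 complete pairs) propagate
  as NaN with confidence 0, never as a silent 0 correlation.
- Matrix I/O writes 17 significant digits, making the text round trip
  lossless for float64.
- Gene matching is case-insensitive with a small alias table (e.g.
  HER2 → ERBB2); missing values stay missing (never zero-filled) until the
  imputation stage.
- KM curves use lifelines' product-limit estimator (Greenwood variance);
  the k-group log-rank p-value comes from the χ² approximation with k − 1
  df.  Follow-up is truncated at 10 years by default, matching the risk
  model's training horizon.

## Known limitations

- The basal/ER/HER2/invasion/housekeeper panel categories are placeholder
  gene lists from the PAM50 literature, not the assay's actual supplementary
  lists; results on real data require configuring the true panel.
- The Mixed confidence rule is uncorrected for six-way selection (see
  above); its false-assignment rate under pure noise is ~14%, not 5%.
- Small risk coefficients are not sign-identifiable from realistic cohort
  sizes (see the refitting caveat); the published point values are used as
  fixed constants, not re-derived.
- Batch correction across cohorts is out of scope; the pipeline accepts
  externally harmonized matrices.
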