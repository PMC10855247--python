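# Methods

## Data model

Raw input is a long-format table of quantification cycles: one row per
(sample, assay, plate, replicate) well, with undetermined wells encoded
by a configurable sentinel set (default `Undetermined`, `NA`, empty).
Cq must be finite and positive; the key quadruple must be unique.
Sample metadata carries group (control / endometriosis), age, BMI,
menstrual phase, ASRM stage (stage is `not_applicable` exactly for
controls) and optional 414 nm absorbance. Assay metadata assigns roles:
`target`, extraction/RT spike-ins, `interplate_calibrator`,
`hemolysis_stable` / `hemolysis_erythrocyte`, `reference_candidate`,
`reference`; an assay may carry several.

### Replicate collapsing

Technical duplicates are averaged over their determined members. A
group is flagged discordant when the Cq spread exceeds the discordance
limit (default 0.5 cycles — duplicate Cq agreement well within one
cycle is the usual bench expectation) or when any member is
undetermined. Flags never drop data: a pair with one undetermined
member contributes its determined value, flagged, and an all-missing
group stays undetermined. The decision to flag-and-keep rather than
discard is ours; instrument exports rarely state a concordance rule.

### Detection limit

Cq values strictly greater than 35 cycles are treated as below the
assay's detection level. The boundary is inclusive: Cq = 35.0 is
detected. Undetected values remain in the collapsed table for audit
but are masked (NaN) in every matrix handed to normalization or
statistics.

## Synthetic cohorts

The generator exists so that each pipeline stage can be tested against
known ground truth. For target assay *i*, sample *j* on plate *b*,
replicate *r*:

    Cq_ijr = baseline_i − effect_i·[j is case] + u_j + a_ij
             − k_i·log2(1 + h_j) + p_b + ε_ijr

with per-sample RNA-content shift `u_j ~ N(0, σ_sample)` (default SD
1 cycle) shared by every endogenous assay, per-(sample, assay)
biological noise `a_ij ~ N(0, σ_assay_i)`, latent hemolysis
`h_j ~ LogNormal(0, 1)`, erythrocyte sensitivity `k_i` (cycles per
log2(1+h); 2.0 for the miR-451a analogue, 0 elsewhere by default),
plate offsets `p_b` (drawn with SD 0.5 cycles over 2 plates, or fixed
per config) and duplicate noise `ε ~ N(0, 0.2)`. Spike-ins and the
calibrator receive only `p_b + ε`: they are added in fixed amounts, so
they carry no sample shift, disease effect or hemolysis term — this
asymmetry is precisely what makes global-mean and reference
normalization meaningful and what the spike-in QC verifies. Cq is
capped at 40 (no-amplification ceiling), and values drift past the
35-cycle detection limit for the high-baseline assays, exercising the
censoring path.

Cohort defaults mirror the validation-arm design the package targets:
72 controls vs 67 cases; ages N(31.7, 5.2²) vs N(37.5, 7.0²) years, so
age is a genuine confounder and the age-adjusted ROC is exercised;
stage and menstrual-phase frequencies follow the same cohort's mix
(stages I/II rare, III/IV dominant; controls mostly proliferative).
Absorbance at 414 nm is an affine noisy readout of the same latent
hemolysis, `a0 + a1·h` floored at zero, so the two hemolysis metrics
correlate by construction. The default panel holds 25 assays — a
designed biomarker with a +0.41 log2 case effect (true fold change
1.33), two designed-stable reference candidates (SD 0.05), the
hemolysis pair, fifteen generic targets with assorted baselines and a
few non-null effects, three extraction spike-ins, one RT spike-in and
the interplate calibrator. A `full_panel()` preset extends to 185
assays with ~20 % partially-undetectable baselines for profiling-scale
tests.

Hemolysis subtracts `k·log2(1+h)` cycles, i.e. acts multiplicatively
on abundance; the delta Cq score (stable − erythrocyte) is then
monotone increasing in `h`, matching its use as a hemolysis proxy.
The hemolysis magnitude distribution is synthetic — chosen so that
roughly 5–15 % of samples exceed the delta Cq ≤ 9 bound — because
quantitative serum hemolysis distributions are rarely reported.

What the generator does **not** emulate: amplification-efficiency
differences between assays, PCR inhibitors, extraction-batch
chemistry, non-Gaussian heavy-tailed technical error, and any
covariate structure beyond the group difference in age. Tests passing
on these cohorts therefore demonstrate correctness of the pipeline's
arithmetic and its statistical calibration under the stated model, not
robustness to every failure mode of real serum panels.

## Interplate calibration

Factor of plate *b* = mean calibrator Cq on *b* − global mean
calibrator Cq (over all calibrator wells); every Cq on plate *b* is
reduced by that factor. Consequences used as exactness checks: after
calibration all per-plate calibrator means equal the global mean, and
the well-count-weighted factors sum to zero. A plate without a
detected calibrator is a hard error. Note the identifiability limit: a
common offset shared by all plates is invisible to calibration, so
factors recover injected offsets only up to an additive constant; this
cancels in every downstream dCq.

## Normalization schemes and sign conventions

Two schemes, with deliberately opposite signs, each tagged on the
output matrix:

- **profiling / global mean**: common set = target assays detected in
  every sample; `dCq = (per-sample mean over the common set) − Cq`;
  higher dCq = more abundant. Assays outside the common set still get
  dCq where detected; technical controls are excluded throughout.
- **validation / reference**: `dCq = Cq − mean(reference Cq)`; lower
  dCq = more abundant; relative expression `2^−dCq`. Samples with any
  undetected reference are excluded with an explicit reason.

Both schemes subtract a per-sample quantity, so the RNA-content shift
`u_j` cancels exactly — group-effect estimates are unbiased even at
σ_sample = 1 cycle. One attenuation is worth knowing: under the
global-mean scheme an assay with a true effect that is itself in the
common set has its estimated effect shrunk by a factor (1 − 1/m) for a
common set of size m, because the effect leaks into the per-sample
mean. At panel scale (m ≈ 40+) this is below 0.01 log2 units for the
effects of interest; the attenuation is absent from the reference
scheme provided the references are effect-free.

Fold changes are signed: abundance log2 difference Δ (case − control)
maps to `2^Δ` when Δ ≥ 0 and `−2^−Δ` otherwise, so magnitudes are
always ≥ 1 and a ratio of 0.58 prints as −1.73; exact ties map to +1.
The DE code branches on the matrix's scheme tag to get Δ's sign right.

## Reference stability

Candidates (restricted to assays detected in all samples) are ranked
by a model-based variance-decomposition stability value. With genes
*i*, groups *g* of size *n_g* (G groups):

1. center each sample across candidates: `z_igj = x_igj − mean_i x_igj`;
2. per gene/group mean `m_ig` and unbiased variance `s²_ig` of z;
3. weighted grand mean `m_i`; raw difference `d_ig = m_ig − m_i`;
4. between-group variance estimate
   `γ̂²_i = max(0, Σ_g d_ig²/(G−1) − Σ_g (s²_ig/n_g)/G)` and shrunken
   difference `d̃_ig = d_ig · γ̂²/(γ̂² + s²_ig/n_g)` (zero when γ̂² = 0);
5. stability `ρ_i = (1/G) Σ_g (|d̃_ig| + √(s²_ig/n_g))`, lower = better.

Ties break lexicographically on assay id. The original NormFinder
software applies additional finite-gene-count corrections whose exact
form is not reproducible without its source data conventions; this
estimator is the documented variant above, and its guarantees are
behavioral (correct ranking, exact invariance to per-sample constants,
group relabeling and sample order) rather than numeric agreement with
any published stability table.

Two practical caveats, both visible in the test suite: (i) the
centering step spreads a strongly regulated candidate's group effect
across all candidates (at gene count I, a Δ-shifted gene adds Δ/I of
apparent intergroup difference to everyone), so candidate sets should
not knowingly include strongly disease-regulated assays — with few
candidates this materially degrades discrimination; (ii) at n ≈ 10 per
group the variance estimates of noisy candidates fluctuate enough that
a genuinely stable gene's rank-1 probability is ~95–97 %, not 1.

`select_references` takes the top-k (default 2, the usual two-reference
recommendation), optionally gated by a stability cutoff, and — when
raw Cq and groups are supplied — reports a t-test on the chosen
assays' mean Cq between groups, which should be non-significant for a
sound reference pair.

## Biomarker statistics

- **t-tests**: Welch by default (robust to unequal variances); a
  pooled-variance flag exists for strict textbook fidelity. Zero-spread
  degenerate inputs give p = 1 at equal means, p = 0 otherwise.
- **multiple testing**: BH q-values are always reported; significance
  gates on raw p < 0.05, the convention for small candidate panels
  (both columns are emitted so the reader can apply either).
- **ROC**: logistic `group ~ expression + age` fitted by ML
  (statsmodels); the score is the fitted probability; AUC is the
  rank-based Mann–Whitney area (tie-corrected); sensitivity/specificity
  are reported at the Youden-optimal threshold, and the operating rule
  is tagged on the result since other rules (fixed specificity, closest
  to (0,1)) give different pairs. Perfect separation is flagged: the
  MLE diverges, a weakly-penalized fit supplies a rank-preserving
  score, and AUC is reported as 1.0 with coefficients marked
  non-identified. Only age is adjusted for; BMI is deliberately left
  out of the default model.
- **stratified comparisons**: control vs each ASRM stage and stage III
  vs IV (t-tests), one-way ANOVA across menstrual phases within
  controls and proliferative vs secretory. Strata below 5 samples are
  skipped with the reason recorded — tiny-stage comparisons are noise.
- **hemolysis sweep**: for each threshold (descending, ∞ = unfiltered)
  re-run the group test, the dCq-vs-delta-Cq correlation and the
  age-adjusted AUC on the retained samples. The ∞ row reproduces the
  unfiltered analysis bit-identically; retained counts are monotone in
  the threshold. Note that filtering restricts the range of the latent
  hemolysis level, so a contamination-driven correlation shrinks toward
  its contamination-free value after filtering — the signature the
  sweep is designed to reveal.

## Numerical conventions

- All Cq arithmetic is float64; exactness tests assert toy examples to
  1e−12.
- CSV output uses a fixed `%.10g` float format, making repeated runs
  with the same seed byte-identical.
- Simulation uses `numpy.random.default_rng(seed)` with a fixed draw
  order; a fixed seed fully determines every output including metadata.
- Undefined statistics (correlation of a constant vector, tests with
  < 2 samples per group) are reported as NaN with a reason, never
  raised mid-pipeline.

## Problem sizes used in the test suite

Statistical calibration checks run at sizes chosen to make their
tolerances meaningful on a laptop: type-I error over 10,000 null
assays at n = 10/10 (rate asserted at 0.05 ± 0.01); normalization
unbiasedness over 50 cohorts of 500/500 samples (bias bound 0.02 log2
units); stability rank recovery over 1,000 cohorts of 8 candidates at
n = 10/10 (≥ 95 % rank-1); binormal AUC agreement at n = 2000/2000
(± 0.02); end-to-end AUC recovery over 100 cohorts of 72/67 with a
200-resample percentile bootstrap (≥ 90 % interval coverage of the
designed AUC 0.84, obtained by solving the binormal formula
AUC = Φ(√(d_expr² + d_age²)/√2) for the expression effect given the
cohort's age separation).

## Known limitations

- Efficiency-corrected quantification (Pfaffl) and standard-curve
  absolute quantification are out of scope; the comparative-Cq method
  assumes near-100 % amplification efficiency.
- Amplification-curve processing and Cq calling are instrument-side;
  the pipeline starts at exported Cq values.
- The stability estimator is grouped (uses case/control labels); a
  group-blind single-cohort mode is not provided.
- Absorbance-based hemolysis filtering is available but off by
  default; delta Cq is the operative filter, absorbance is used
  correlatively.
- The simulator's defaults describe one study design; they are inputs
  to the tests, not estimates fitted to any dataset.
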