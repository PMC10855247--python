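# cqmark

Analysis pipeline for serum microRNA RT-qPCR biomarker studies: raw
quantification-cycle (Cq) handling, technical quality control,
interplate calibration, normalization, reference-miRNA selection and
age-adjusted diagnostic statistics — together with a synthetic cohort
generator so every stage is testable without patient data.

## The problem

Circulating miRNAs are attractive minimally invasive disease markers
(the motivating use case is distinguishing women with endometriosis
from healthy controls using serum miR-30c-5p), but serum RT-qPCR data
are fragile in specific, well-understood ways:

- **no fixed RNA input** — serum miRNA content varies per sample, so
  raw Cq values are only interpretable after normalization;
- **hemolysis** — erythrocyte lysis during blood draw floods the serum
  with red-cell miRNAs (miR-451a above all) and can fabricate or mask
  group differences;
- **plate effects** — multi-plate studies need interplate calibration
  before values are comparable;
- **confounding** — when cases and controls differ in age, diagnostic
  performance must be assessed with age in the model.

`cqmark` implements the full workflow around those hazards.

## Methods at a glance

- **Replicate collapsing and censoring.** Technical duplicates are
  averaged; pairs that disagree by more than 0.5 cycles (or with an
  undetermined member) are flagged, never silently dropped. Cq > 35 is
  treated as below the detection level and masked downstream.
- **Interplate calibration.** Per plate *b*, the calibration factor is
  mean(calibrator Cq on *b*) − mean(global calibrator Cq); every well
  on the plate is shifted by −factor.
- **Two normalization schemes.** Profiling: dCq = (per-sample global
  mean over assays detected in all samples) − assay Cq, higher = more
  abundant. Validation: dCq = assay Cq − mean(reference miRNA Cq),
  lower = more abundant, relative expression 2^−dCq (comparative-Cq
  method). The scheme tag travels with the matrix so fold-change signs
  cannot silently flip.
- **Reference selection.** Candidates detected in all samples are
  ranked by a model-based stability value ρ that combines intragroup
  variance with a shrunken intergroup difference (NormFinder-style
  variance decomposition); lower ρ = more stable.
- **Hemolysis QC.** delta Cq = Cq(miR-23a-3p) − Cq(miR-451a); larger =
  more hemolysis; samples pass at delta Cq ≤ 9. Oxy-hemoglobin
  absorbance at 414 nm is tracked as the orthogonal readout.
- **Biomarker statistics.** Welch t-tests on dCq with signed fold
  changes (ratio 0.58 prints as −1.73), Benjamini–Hochberg q-values
  reported alongside raw p, logistic `group ~ expression + age` ROC
  with Mann–Whitney AUC and Youden-point sensitivity/specificity, and
  a hemolysis-threshold sweep that re-runs the analysis under
  successively stricter filters.

## Worked example

Simulate the default cohort (72 controls vs 67 cases, compact
25-assay panel, plate offsets, duplicate noise, hemolysis) and run the
full pipeline on it:

```bash
cqmark simulate --seed 1 --out demo
cqmark qc     --cq demo/cq.csv --samples demo/samples.csv --assays demo/assays.csv --out demo/qc
cqmark report --cq demo/cq.csv --samples demo/samples.csv --assays demo/assays.csv \
              --assay miR-30c-5p --out demo/report
```

which prints:

```
samples: 139
retained at delta Cq <= 9.0: 127
hemolysis method agreement: r=0.8441 p=6.58e-39 (n=139)
spike-ins passing: 5/5

references: miR-30e-5p, miR-15b-5p
miR-30c-5p: p=8.15e-06 fold_change=1.313
age-adjusted AUC=0.7929 sens=0.5821 spec=0.9306
spike-ins passing: 5/5
```

Reading the output: both hemolysis metrics agree (r = 0.84) and 127 of
139 samples fall within the delta Cq ≤ 9 hemolysis bound; all five
spike-ins are group-constant, so extraction/RT/qPCR behaved; the two
designed-stable candidates are picked as references; and the simulated
biomarker — generated with a +0.41 log2 disease effect, i.e. a true
fold change of 1.33 — is recovered at fold change 1.31 with p ≈ 1e−5
and an age-adjusted AUC of 0.79.

Library use mirrors the CLI:

```python
from cqmark import (SimulationConfig, simulate_cohort, collapse_replicates,
                    interplate_calibrate, apply_detection_limit,
                    normalize_reference, differential_expression)

cohort = simulate_cohort(SimulationConfig(seed=1))
collapsed, factors = interplate_calibrate(collapse_replicates(cohort.cq), "UniSp3")
collapsed = apply_detection_limit(collapsed)
matrix = normalize_reference(collapsed, ["miR-30e-5p", "miR-15b-5p"],
                             assays=cohort.assays)
de = differential_expression(matrix, cohort.samples.set_index("sample_id")["group"])
```

## Documentation

See `docs/methods.md` for the generative model behind the simulator,
the stability estimator, numerical conventions, and known limitations.
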