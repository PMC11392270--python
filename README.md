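# ehgpreterm

Non-invasive prediction of premature birth (delivery before 37 completed
weeks of gestation) from the electrohysterogram (EHG) — the uterine EMG
recorded on the maternal abdomen.  The package implements, end to end, a
fully automated analysis of whole 30-minute, 3-channel, 20 Hz EHG records:

1. **Band-limited feature extraction.**  Four features per signal
   (S2, S3) and frequency band: peak frequency *PF*, median frequency
   *MF*, normalized peak amplitude *PA*, and sample entropy *SE*
   (m = 3, r = 0.15·SD, Chebyshev distance).  Ten bands between 0.08 and
   5.0 Hz cover the Fast Wave Low band of uterine activity
   (notably B0L′ = 0.125–0.575 Hz) and the maternal-heart harmonics
   (B1–B3, 1.0–5.0 Hz).  *PA* is the in-band spectral peak of the
   band-filtered signal divided by the peak of the reference band
   B0 (0.08–1.0 Hz):

   ```
   PA = max_{k ∈ band} P(k)  /  max_{k ∈ B0} P_R(k)
   ```

2. **Stabilized sequential forward selection (SFS).**  Over N repeated
   stratified 80/20 holdout partitions, a greedy wrapper ranks all
   features by stratified 5-fold cross-validated misclassification error
   (MCE); each repetition's error-minimizing prefix updates an occurrence
   histogram, and the average-MCE minimizer fixes the final subset size.
   Running this per classifier × feature set and tallying the two highest
   histogram peaks identifies the top-two candidate biomarkers.

3. **Leak-free imbalanced evaluation (Partition-Synthesis).**  SMOTE
   over-sampling balances the premature minority *strictly after* every
   train/test and train/validation split; full parent provenance is kept
   and audited, so a synthetic sample can never leak held-out information.
   Five classifiers (pseudo-LDA, pseudo-QDA, Gaussian naive Bayes,
   SVM poly-3, SVM RBF) are scored by Se, Sp, PPV, NPV, CA and AUC over
   the repetitions, with vertically averaged ROC curves and averaged
   decision boundaries (1-D threshold, 2-D 50 %-likelihood isoline).

4. **Composite biomarker.**  A linear discriminant on the two headline
   features, x = (PA S3 B0L′, MF S2 B3):

   ```
   y = sign(xᵀw − b),   w = [5.98, −4.02]ᵀ,   b = −12.78
   ```

   Positive scores indicate elevated premature-birth risk.

Because the study datasets (TPEHG DB, TPEHGT DS, ICEHG DS on PhysioNet)
cannot be bundled, the package ships a first-class **synthetic EHG
generator** that reproduces the record layout (group PL of premature
records vs term groups TL/IL/CL/ICL by delivery mode, 20 Hz, 3 channels)
and plants the two class effects the features measure: an elevated FWL
spectral peak and a lowered maternal-heart rate (third harmonic inside
B3).  Every pipeline stage is exercisable — and tested — without
downloads.

## Worked example

```python
from ehgpreterm import (
    ClassEffectParams, ClassifierSpec, GroupLabel, SyntheticConfig,
    composite_biomarker, generate_dataset, repeated_evaluation,
    stratified_holdout,
)
from ehgpreterm.pipeline import extract_table
from ehgpreterm.spectral_features import ExtractionConfig, FeatureSpec

score, label = composite_biomarker(pa=0.82, mf=3.90)
print(f"composite score = {score:+.3f} -> {'premature risk' if label > 0 else 'term'}")

config = SyntheticConfig(
    group_sizes={GroupLabel.PL: 12, GroupLabel.TL: 40, GroupLabel.IL: 8},
    duration_s=300.0, seed=42,
    effects=ClassEffectParams(fwl_peak_gain=1.6, mhr_shift=0.05),
)
records = generate_dataset(config)
specs = [FeatureSpec("PA", "S3", "B0Lp"), FeatureSpec("MF", "S2", "B3")]
table = extract_table(records, specs, ExtractionConfig(estimator="welch", welch_nperseg=512))
plans = [stratified_holdout(table, seed=i, repetition_index=i) for i in range(1, 11)]
summary = repeated_evaluation(table, ["PA_S3_B0Lp", "MF_S2_B3"],
                              ClassifierSpec("lda_pseudo"), plans)
ca, ca_sd = summary.test_summary["CA"]
auc, auc_sd = summary.test_summary["AUC"]
print(f"LDA, PA+MF, 10 repetitions: CA {100*ca:.1f}% +/- {100*ca_sd:.1f}%, "
      f"AUC {auc:.2f} +/- {auc_sd:.2f}")
```

prints

```
composite score = +2.006 -> premature risk
LDA, PA+MF, 10 repetitions: CA 92.5% +/- 6.1%, AUC 0.93 +/- 0.09
```

The composite score is positive, so this hypothetical record (a high FWL
peak amplitude of 0.82 with a slow maternal heart rate) falls on the
premature side of the linear boundary.  The 60-record synthetic study
plants mild spectral effects and still reaches a mean test-set
classification accuracy near 92 % — real EHG cohorts are far noisier.

A command-line interface mirrors the library
(`ehgpreterm synth / extract / select / evaluate`, each with `--seed` and
`--out`); every stage writes a JSON manifest that reproduces its outputs
bit-exactly.

## Layout

| module | contents |
| --- | --- |
| `records_io` | WFDB-style record reader/writer, record groups, feature-table CSV persistence |
| `bands` | the ten-band table |
| `spectral_features` | filtering, spectra, PF/MF/PA/SE, per-record extraction |
| `resampling` | stratified holdout & k-fold, SMOTE with provenance, leak audit |
| `feature_selection` | feature sets (76/60/30/24), p-value pre-sort, SFS, stabilized aggregation, top-two tally |
| `classify_eval` | the five classifiers, metrics, ROC averaging, decision boundaries, composite biomarker |
| `synthetic_data` | the synthetic EHG generator |
| `experiments` | scaled end-to-end recovery / null / leak-audit experiments |
| `pipeline`, `cli` | orchestration and the `ehgpreterm` command |
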