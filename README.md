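# emrisk

Early disease risk assessment from longitudinal outpatient diagnosis
records.

`emrisk` is for epidemiologists and clinical-informatics researchers who
want to ask: *given only the diagnoses a patient accumulated before a
disease was ever formally diagnosed, how well can that future diagnosis be
predicted?* The package was built around the rheumatoid-arthritis use case
(ICD-9-CM 714.0, normalized `71400`) on an administrative-claims-style
cohort, but every stage is generic in the target code.

## The method

1. **Preprocessing.** Raw rows `(patient_id, visit_date, icd9_code)` are
   read from CSV, codes are normalized to the canonical five-character
   ICD-9-CM form (`714.0 → 71400`), and three classes of noise are removed:
   malformed identifiers/codes, missing or out-of-window dates, and garbled
   content.
2. **Cohort selection.** Cases are patients with ≥ 2 target-code diagnoses
   who also appear in a catastrophic-illness registry; their histories are
   censored strictly before the first target diagnosis (the index date), so
   the model only ever sees pre-diagnosis data. Controls have records in
   the window and no target-code evidence at all.
3. **Patient–disease matrix.** Histories are binarized into
   `PD ∈ {0,1}^{N×M}`: entry `(n, m)` is 1 iff patient *n* was ever
   diagnosed with code *m*.
4. **Latent risk factors.** `PD` is factorized as `PD ≈ PR·DRᵀ` with
   nonnegative `PR` (N×R patient loadings) and `DR` (M×R disease loadings)
   by minimizing the squared Frobenius error `‖PD − PR·DRᵀ‖²_F` with the
   classic multiplicative updates

   ```
   PR ← PR ∘ (PD·DR) ⊘ (PR·(DRᵀDR) + ε)
   DR ← DR ∘ (PDᵀ·PR) ⊘ (DR·(PRᵀPR) + ε)
   ```

   which keep the factors nonnegative and never increase the objective.
5. **Risk classification.** An RBF-kernel SVM (`C = 2`, `γ = 2⁻⁵`) is
   trained on the rows of `PR`. Unseen patients are *folded in*: their
   binary history row is projected onto the learned `DR` basis by the same
   multiplicative update, so evaluation can be fully inductive.
6. **Evaluation.** Stratified 10-fold cross-validation reporting
   sensitivity `TP/CP`, specificity `TN/CN`, accuracy `(TP+TN)/(CP+CN)`,
   macro-averaged over folds with the population standard deviation as the
   stability measure. The number of factors `R` is chosen by sweeping
   candidates and keeping the most accurate rank whose
   sensitivity–specificity gap stays below 5%.

Because national claims databases are access-restricted, the package ships
a synthetic EMR generator with planted latent-theme structure (case-enriched
risk themes, dated visit streams, injected noise records, a registry file)
so the entire pipeline is testable end to end with known ground truth.

## Worked example

```python
import tempfile
from emrisk import SyntheticConfig, generate_synthetic_emr, DiseaseRiskModel

cfg = SyntheticConfig(n_cases=100, n_controls=100, vocab_size=150, seed=42)
paths = generate_synthetic_emr(cfg, tempfile.mkdtemp())

model = DiseaseRiskModel.from_files(
    paths["records"], paths["registry"], target_code="71400", rank=5
)
results = model.fit(seed=7)
print(results.summary())
```

```
Early Disease Risk Assessment
==============================================
patients                     200   (cases 100, controls 100)
diagnosis codes (M)          149
latent factors (R)             5
NMF iterations               126   final objective 1531.6576
SVM (RBF)             C=2, gamma=0.03125
seed                           7
----------------------------------------------
10-fold stratified CV (inductive):
  sensitivity    0.8400 (SD 0.1497)
  specificity    0.7700 (SD 0.0781)
  accuracy       0.8050 (SD 0.0850)
```

`from_files` runs the full chain (noise filtering → cohort selection with
censoring → binary matrix). The summary reports the cohort and matrix
dimensions and the out-of-sample CV estimates: at this small scale the
model recovers ~80% of future cases from pre-diagnosis records alone.
`results.top_codes(0)` lists the diagnosis codes loading highest on a
latent factor, `results.predict(new_histories)` scores unseen patients, and
`model.sweep_rank([...])` applies the rank-selection rule.

The same pipeline is available as a CLI:

```bash
emrisk simulate --config cfg.yaml --out sim/
emrisk preprocess --in sim/records.csv --out clean.csv --report noise.yaml
emrisk cohort --records clean.csv --registry sim/registry.txt --out cohort/
emrisk matrix --cohort cohort/ --out pd
emrisk sweep-r --matrix pd --r 100:900:100 --folds 10 --out sweep.csv
emrisk evaluate --matrix pd --rank 200 --folds 10 --out result.yaml
```

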