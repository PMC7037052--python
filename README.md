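# bbbperm

Blood–brain-barrier (BBB) permeability modelling from chromatographic
lipophilicity and molecular descriptors.

Whether a drug-like molecule reaches the central nervous system is
summarised by log BB, the decadic log of its steady-state brain/plasma
concentration ratio. Measuring log BB in vivo is slow, costly and
ethically fraught, so medicinal chemists estimate it from surrogates.
`bbbperm` implements one complete, reproducible surrogate workflow for
congeneric series of small, neutral drug-like compounds:

1. **Chromatographic lipophilicity.** Isocratic reversed-phase HPLC
   retention, log k = log10((t_R − t_0)/t_0), falls linearly with the
   organic-modifier volume fraction φ (Soczewiński–Wachtmeister):
   log k = log k_w − s·φ. Extrapolating to φ = 0 gives log k_w, a
   lipophilicity index measurable on plain ODS columns or on biomimetic
   phases (immobilized artificial membrane, immobilized cholesterol).
   The package fits these lines, the calibrations between columns, and
   the within-column log k_w vs s relation.
2. **Abraham LFER calibration.** On a training set with experimental
   log BB, the solvation-parameter linear free-energy relationship
   log BB = c + eE + sS + aA + bB + vV
   is fitted by OLS with full diagnostics (coefficient SEs, R², residual
   SD, F, VIF, descriptor pairwise R², leverage with the warning limit
   h\* = 3m/n defining the applicability domain).
3. **Per-column QSARs.** For compounds without experimental log BB, the
   LFER predictions are regressed on three cheap predictors — log k_w on
   one stationary phase, topological polar surface area (TPSA) and
   molecular polarizability α — giving column-specific models
   log BB = c + k·log k_w + t·TPSA + a·α that need only one HPLC series
   and two computed descriptors per new compound.
4. **Validation.** Leave-one-out (exact hat-value shortcut) and seeded
   leave-50%-out cross-validation (PRESS, Q², MSEcv) for every model.

The package ships the complete study tables it was validated against
(65 test compounds × 3 stationary phases, 23 training compounds) as CSV
fixtures, plus seeded synthetic-data generators so every stage is testable
against known ground truth.

## Worked example

```bash
$ bbbperm calibrate-lfer
log_bb = 0.934(± 0.165) + 0.191(± 0.107) E - 0.605(± 0.134) S - 0.743(± 0.137) A - 0.768(± 0.177) B + 0.545(± 0.104) V
N = 23; SD = 0.134; R2 = 0.9039; F = 32
h* = 0.6522; max VIF = 10.69
```

The equation says BBB permeation falls with polarity (S), hydrogen-bond
acidity (A) and basicity (B), and rises with molecular volume (V) and,
weakly, excess molar refraction (E). R² = 0.9039 with residual SD 0.134
log units over 23 compounds; h\* = 3·5/23 = 0.6522 is the leverage above
which a prediction falls outside the model's applicability domain.

The same from Python, through to predictions and cross-validation:

```python
from bbbperm import PipelineConfig, run_pipeline
results = run_pipeline(PipelineConfig())
print(results["predictions"].head(3).to_string(index=False))
```

```
compound_id  log_bb_lfer  leverage_lfer  inside_domain_lfer  log_bb_qsar_ODS  log_bb_qsar_IAM  log_bb_qsar_Cholester
          1         0.21       0.168820                True             0.19             0.20                   0.22
          2         0.32       0.198477                True             0.21             0.22                   0.24
          3         0.26       0.169120                True             0.21             0.22                   0.24
```

Compound 1 is predicted at log BB = 0.21 by the LFER (leverage 0.17,
inside the domain) and at 0.19/0.20/0.22 by the three column QSARs —
mildly brain-penetrant. The cross-validation table for the ODS QSAR
(`results["cv"]`):

```
model_id scheme    press       q2   mse_cv
qsar_ODS    LOO 0.327173 0.829702 0.005033
qsar_ODS   L50O 0.346539 0.819621 0.005331
```

`bbbperm run-all --out results/` writes the full report bundle
(predictions.csv, cv.csv, models.json, summary.txt); `fit-retention`,
`fit-qsar`, `cross-validate` and `predict` expose the individual stages.

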