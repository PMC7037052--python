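# Methods

## Model and assumptions

The package treats BBB permeation prediction as three chained linear
models.

**Retention extrapolation.** For a neutral solute on a reversed-phase
column, isocratic retention follows log k = log k_w − s·φ over the
organic-modifier range used in practice (φ roughly 0.2–0.6 acetonitrile).
`RetentionExtrapolator` fits this by OLS per compound/column; log k_w is
the intercept and s is stored as the positive slope magnitude (reversed
phase retention decreases with φ). Logarithms are decadic throughout.
At least 3 points and 2 distinct φ values are required (one residual
degree of freedom); a response with zero variance yields s = 0 and, by
convention, r² = 0 with a flag, avoiding a 0/0. The dead-time marker
identity is metadata; no correction is applied. The model assumes the
solutes are neutral at the working pH and that linearity holds over the
measured φ range — ionisable compounds, gradient elution and peak-shape
effects are out of scope.

**Abraham LFER.** log BB is regressed on the five Abraham solute
descriptors (E, S, A, B, V) with intercept. The model assumes the
training compounds are congeneric with the prediction set and neutral,
and that log BB is governed by the same bulk interactions that drive
partitioning. A minimum of 7 training compounds is enforced (5
descriptors + intercept + 1 residual df).

**Column QSARs.** log BB (from the LFER) is regressed on
(log k_w, TPSA, α) per stationary phase. These models exist so that new
congeners need only an HPLC measurement and two computed descriptors.

## Reproduction conventions

Two deliberately explicit conventions make published report tables
reproducible to their printed 2 decimals; both are parameters, not
hard-wired behaviour:

* **Equation precision** (`equation_precision=3`, `coef_precision` on
  `predict`): prediction tables are generated by applying equations with
  coefficients rounded to 3 decimals — the precision at which such
  equations are published. Full-precision prediction
  (`coef_precision=None`) is the default on the estimators themselves.
* **Response rounding** (`response_rounding=2`): the QSAR response is the
  LFER prediction rounded to 2 decimals, i.e. exactly the numbers that
  appear in a published prediction table, since that is demonstrably what
  the downstream regression consumed. Unrounded responses
  (`response_rounding=None`) shift the QSAR R² by ≤ 0.0005 on the
  packaged data.

Report tables round half away from zero (`round_half_away`), matching
printed tables; numpy's half-to-even would differ on exact .005 cases.

## Regression diagnostics

* "SD" is the residual standard error sqrt(SSE/(n−p−1)).
* F and p are the global regression F test with (p, n−p−1) df.
* VIF_j = 1/(1−R²_j) from auxiliary regressions with intercept.
* Standardized coefficients are the OLS coefficients after z-scoring
  predictors and response (ddof=1). With all components retained, PLS
  standardized coefficients coincide with these, so they stand in for
  PLS-software plots.
* Leverage is the hat-matrix diagonal; the warning limit is h\* = 3m/n
  with m the number of descriptors (intercept excluded). Many Williams
  plots use 3(p+1)/n instead; the convention here follows the workflow
  the package reproduces and is documented precisely because the two
  differ. New-point leverage is x(XᵀX)⁻¹xᵀ in the training design space,
  and `inside_domain` is leverage ≤ h\*.

## Cross-validation

* **LOO**: PRESS by the exact shortcut Σ(e_i/(1−h_ii))²; the test suite
  asserts equality with an explicit n-refit loop to 1e−10. Q² =
  1 − PRESS/SS_tot with SS_tot about the full-sample mean, so Q² ≤ R²
  always. MSEcv = PRESS/n. Requires n > p+2 so every fold is estimable.
* **Leave-50%-out**: each repeat draws ⌈n/2⌉ training rows uniformly
  without replacement (seeded `numpy.random.default_rng`), fits, predicts
  the rest, and the held-out SSE is rescaled by n/n_test; PRESS is the
  average over repeats (default 200, stable to ~1–2% at these sample
  sizes). Rank-deficient repeats are skipped; >10% skipped is an error.

A caution for readers comparing against published validation tables of
this workflow: a printed "Q²" column there can equal the *adjusted R²* of
the full fit, 1−(1−R²)(n−1)/(n−p−1) — on the packaged study data the
printed values match adjusted R² to all four digits for every model while
the printed PRESS values match the standard LOO PRESS computed here to
every printed digit. Published MSEcv entries are likewise internally
inconsistent with PRESS/n. `bbbperm` therefore reports the standard
PRESS-based Q² in `CrossValidationResult` and exposes adjusted R² as
`r2_adj` on the model summary; the two are never conflated.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not the chemistry that produces it:

* retention series: the exact line plus iid Gaussian noise on log k
  (default sd 0.02 log units, the replicate-scale scatter of averaged
  retention measurements) over a default grid φ ∈ {0.3, 0.4, 0.5, 0.6};
* descriptor tables: descriptors drawn independently and uniformly over
  the ranges observed for the drug-like azole solutes the package was
  built around (E 0.87–2.90, S 0.92–3.18, A 0–0.75, B 0.80–2.05,
  V 1.1–3.0), response linear in the descriptors plus Gaussian noise
  (default sd 0.13, matching the calibration model's residual SD).

Real descriptor sets are correlated (pairwise R² up to ~0.7 here) and
bounded by chemistry, not by a box; independent uniform sampling is a
stand-in. Passing recovery tests therefore demonstrates correctness of
the estimators under the assumed linear-Gaussian structure — not that
the LFER itself is the right model for any particular compound class.
All generators are bit-reproducible under a fixed seed; zero noise
composed with the matching fitter recovers parameters to 1e−10.

Monte-Carlo problem sizes used in the test suite (e.g. 500 replicates at
n = 100, 1000 replicate retention fits, 200-repeat half-sample CV) were
chosen so sampling error sits well below the tolerances being asserted.

## Numerical choices and degenerate inputs

* Rank deficiency is detected before fitting and reported with the names
  of the dependent columns; a zero-variance predictor aliases the
  intercept and is reported the same way.
* OLS is delegated to statsmodels; the normal-equations solution is kept
  in the tests as an independent oracle, not in the library path.
* An observation with leverage ≈ 1 makes its LOO fold singular and
  raises a fold-failure error rather than returning an inflated PRESS.
* Leave-50%-out with n < 10 is refused (half-samples too small to be
  meaningful for p ≥ 1).

## Known limitations

* The LFER and QSAR layers are plain OLS; no robust or Bayesian
  variants, and no true PLS with component selection.
* Applicability-domain flags use the leverage rule only; structural or
  response-space domain checks are not implemented. Extending the
  leverage rule from the LFER to the QSAR layer is this package's
  choice.
* Descriptor computation (E, S, A, B, V, TPSA, α) from structures is out
  of scope; descriptors are inputs.
* The QSAR built on a computed log P (`lipophilicity_source="alogps"`)
  is implemented but ships without a packaged reference, as per-compound
  computed log P values are not part of the fixture tables.
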