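# leafwater

Estimation of leaf water status — equivalent water thickness (EWT) and fuel
moisture content (FMC) — from hyperspectral leaf reflectance, using adaptive
spectral absorption indices alongside ten classical fixed-band water indices,
with 10-fold cross-validated regression.

## Who this is for

Vegetation spectroscopists and remote-sensing ecologists who measure leaf
reflectance (350–2500 nm, e.g. with an ASD FieldSpec) together with leaf
fresh weight, dry weight and area, and want per-leaf water status estimated
from spectral indices — particularly across mixed species, where the
wavelengths of the water absorption features shift from leaf to leaf and
fixed-band indices lose accuracy.

## The method

Gravimetric targets, from fresh weight FW (g), dry weight DW (g) and
one-sided area A (cm²):

    EWT = (FW − DW) / A      [g cm⁻²]
    FMC = (FW − DW) / FW     [fraction; reported as %]

A leaf water absorption feature consists of an absorption peak m (the
reflectance minimum, at λ_m) flanked by two shoulders S₁, S₂ (local maxima
at λ₁ < λ_m < λ₂). The line S₁→S₂ is the nonabsorption baseline. With the
symmetry parameter

    d = (λ₂ − λ_m) / (λ₂ − λ₁)

the baseline reflectance at the peak is ρ_M = d·ρ₁ + (1−d)·ρ₂, and the
spectral absorption index is the relative absorption depth

    SAI = ρ_M / ρ_m = (d·ρ₁ + (1−d)·ρ₂) / ρ_m .

Three SAIs are computed, with peak and shoulders located **per leaf** by
extremum search: SAI_970 (915–1085 nm), SAI_1200 (1085–1265 nm) and
SAI_1660 (1630–1690 nm). Because the bands adapt to each leaf, the SAIs are
robust to the few-nanometre feature shifts between species that degrade
fixed-band indices. Ten classical indices (WI, SRWI, NDWI_1240, RDI,
RATIO_975, RATIO_1200, DWI, MSI, NDII, GVMI) are computed for comparison.

Each index–target pair is fitted with linear, quadratic and exponential
forms and scored by 10-fold cross-validation: R²cv is the squared Pearson
correlation between pooled out-of-fold predictions and observations, and
rRMSEcv is the out-of-fold RMSE divided by the mean observed target.

A synthetic-data module generates leaf-like spectra (Gaussian water dips at
970/1200/1450/1950 nm whose depths scale with EWT, a dry-matter dip at
1660 nm strengthening as FMC falls, per-leaf peak-position jitter and
measurement noise) with exact ground truth, so the whole pipeline is
testable without any field data.

## Worked example

```sh
leafwater simulate --seed 2 --out data/
leafwater indices --spectra data/spectra.csv --meta data/metadata.csv --out table.csv
leafwater fit --table table.csv --target ewt --out reports/
```

The `fit` step prints the per-index ranking; on the default simulated study
(n=292, three species, 5 nm feature jitter) the head of the table reads:

```
     index        P          regression_equation     r2cv  rrmse_cv_pct      form  n_used
  SAI_1200  <0.0001 y = -0.041*x^2+0.157*x-0.115 0.974732      3.825772 quadratic     292
RATIO_1200  <0.0001           y = -0.131*x+0.131 0.962013      4.690879    linear     292
 RATIO_975  <0.0001           y = -0.207*x+0.209 0.879416      8.357560    linear     292
...
prediction similarity SAI_1200 vs RATIO_1200: R^2 = 0.941
per-species SAI_1200 slopes: 0.061 to 0.063
```

Reading this: the adaptive SAI_1200 is the best EWT predictor (R²cv 0.975,
out-of-fold error 3.8 % of the mean EWT), ahead of the fixed-band
RATIO_1200 — the adaptive band location pays off under per-leaf feature
shifts. The two indices' predictions are nevertheless highly similar
(R² = 0.94): both track the same 1200 nm absorption depth. The per-species
slopes of the SAI_1200–EWT line agree within ~4 %, i.e. one pooled
calibration transfers across the three species. The same commands with
`--target fmc` rank SAI_1660 first.

Equivalent library use:

```python
import leafwater as lw

spectra, metadata, truth = lw.generate_dataset(lw.GeneratorConfig(seed=2))
table = lw.build_index_table(spectra, metadata)
result = lw.IndexRegression(table, "SAI_1200", "ewt", form="linear").fit(k=10, seed=1)
print(result.summary())
```

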