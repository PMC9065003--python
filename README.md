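# ramansalt

Quantifying salt (NaCl) stress in wheat leaves from Raman microspectroscopy,
for plant scientists and chemometricians who want a tested, scriptable
version of the full analysis chain: spectral preprocessing, Amide I band
deconvolution, and machine-learning regression of the growth-medium salt
concentration.

Elevated NaCl in the growth medium changes a leaf's biochemistry — cell-wall
carbohydrates (cellulose 522 cm⁻¹, pectin 747 cm⁻¹), amino acids (serine
855 cm⁻¹), pigments (carotenoid 1515 cm⁻¹, chlorophyll b 1563 cm⁻¹) and the
protein Amide I envelope (1600–1700 cm⁻¹) all respond. Those changes are
visible in Raman maps, so a regression model trained on preprocessed spectra
can read the stress level (in mM NaCl) straight off a leaf.

## What the package does

* **`spectio`** — plain-text (TSV/CSV) spectral tables in wide or long
  layout, with a sidecar metadata table (week, concentration in mM,
  replicate, scan coordinates); strict axis-alignment invariants.
* **`preprocess`** — the study's conditioning chain: boxcar denoising
  (window 3), fluorescence-baseline removal by concatenating straight lines
  between consecutive local minima, L2 (vector) normalization, and outlier
  elimination keeping spectra between the 0.5% and 99.5% quantiles of a
  per-spectrum score.
* **`bandfit`** — band component analysis: sub-peak counting from the
  negative lobes of a Savitzky–Golay second derivative, multi-Gaussian
  least-squares deconvolution (height / center / FWHM / area), and band
  trends across (week, concentration) groups.
* **`saltreg`** — an exact Gaussian process regressor with constant basis
  β·**1** and the rational quadratic kernel

  k(r) = σ_f² (1 + r²/(2αl²))^(−α),  r = ‖x − x′‖₂,

  hyperparameters (l, α, σ_f, σ_n) fit by maximizing the log marginal
  likelihood (multi-restart L-BFGS, analytic gradients, β profiled by GLS);
  squared-exponential / Matérn-5/2 / exponential kernels, ridge-linear and
  regression-tree baselines; stratified 80/20 evaluation, 5-fold CV,
  leave-one-concentration-out, and growth-week inference by minimum median
  residual.
* **`synthgen`** — a seeded synthetic generator producing study-shaped
  datasets (4 concentrations × weeks, band trends, broad fluorescence,
  per-spectrum heterogeneity, additive noise) and 61 × 61 raster scans.
* **`cli`** — `ramansalt simulate | preprocess | bands | train | predict |
  loco | predict-week | run`, with a YAML config and a digest-carrying run
  manifest for byte-reproducible pipelines.

## Worked example

```python
import numpy as np
from ramansalt.synthgen import SynthConfig, generate_dataset
from ramansalt.preprocess import preprocess_pipeline, PreprocessConfig
from ramansalt.saltreg import GPRFactory, SplitSpec, stratified_split, evaluate

cfg = SynthConfig(weeks=(2, 3, 4), n_per_group=150, seed=7)
dataset, truth = generate_dataset(cfg)
clean, report = preprocess_pipeline(dataset, PreprocessConfig())
print(f"{dataset.n_spectra} spectra generated, "
      f"{clean.n_spectra} kept after 0.5%/99.5% elimination")

week3 = clean.subset(np.nonzero(clean.meta["week"].to_numpy() == 3)[0])
X = week3.intensities
y = week3.meta["concentration_mM"].to_numpy(dtype=float)
X_tr, X_te, y_tr, y_te = stratified_split(X, y, SplitSpec(seed=0))
model = GPRFactory(kernel_tag="rq", seed=0).fit(X_tr, y_tr)
rep = evaluate(model, X_te, y_te, week=3)
p = model.model.params
print(f"week 3 GPR-RQ: test RMSE {rep.rmse:.2f} mM, R^2 {rep.r2:.3f}")
print(f"kernel: l={p.length_scale:.3f}, alpha={p.alpha:.3f}, "
      f"sigma_f={p.signal_sd:.1f} mM, sigma_n={p.noise_sd:.2f} mM, "
      f"beta={model.model.beta:.1f} mM")
for conc, med in sorted(rep.per_concentration_medians.items()):
    print(f"  true {conc:5.0f} mM -> median prediction {med:7.2f} mM")
```

Output:

```
1800 spectra generated, 1782 kept after 0.5%/99.5% elimination
week 3 GPR-RQ: test RMSE 11.70 mM, R^2 0.956
kernel: l=1.199, alpha=0.239, sigma_f=116.8 mM, sigma_n=0.00 mM, beta=15.9 mM
  true     0 mM -> median prediction    5.62 mM
  true    50 mM -> median prediction   47.67 mM
  true   100 mM -> median prediction   99.37 mM
  true   150 mM -> median prediction  150.96 mM
```

Reading it: 18 of 1800 synthetic spectra fell outside the 0.5%/99.5% score
quantiles and were eliminated. On the week-3 data the rational-quadratic GP
predicts the held-out 20% test set with an 11.7 mM root-mean-square error and
explains 95.6% of the concentration variance; the median prediction within
each true concentration group sits within a few mM of the truth, which is
the signature of a well-calibrated model. The small fitted length scale
(l ≈ 1.2 against unit-norm spectra) and near-zero σ_n reflect the smooth,
low-noise structure of spectra after normalization.

The same pipeline from the shell:

```sh
ramansalt simulate --out spectra.tsv --meta meta.csv --seed 7
ramansalt preprocess --in spectra.tsv --meta meta.csv --out corrected.tsv
ramansalt train --in corrected.tsv --meta corrected.meta.csv \
    --model gpr-rq --week 3 --seed 0 --out model.bin --report eval.json
```

## Layout

```
src/ramansalt/      library (spectio, preprocess, bandfit, saltreg, synthgen, cli)
tests/              pytest suite (unit, property and end-to-end tests)
scripts/            acceptance.py
docs/methods.md     model details, parameter choices, generator assumptions
```
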