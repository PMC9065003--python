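# Methods

`ramansalt` implements a chemometric pipeline for quantifying salt (NaCl)
stress in wheat leaves from Raman microspectroscopy maps: bespoke spectral
preprocessing, band-component analysis of the Amide I envelope, and
regression of medium salt concentration (mM) from whole spectra with an
exact Gaussian process. A synthetic-spectrum generator with the same
statistical structure makes every stage testable without instrument data.

## Preprocessing

Each spectrum is processed in this order:

1. **Boxcar denoising** — moving mean, window 3 spectral points by default
   (odd, configurable). Edge points average over the truncated window, so no
   intensity is fabricated beyond the measured axis.
2. **Fluorescence baseline** — interior local minima of the (smoothed)
   spectrum are taken as anchors; the baseline is the concatenation of
   straight lines between consecutive anchors, evaluated in shift (cm⁻¹)
   coordinates, with the first and last points always included so the profile
   covers the full axis. A local minimum is defined as a strict decrease from
   the left and a non-strict increase to the right, which resolves plateaus
   deterministically. The baseline is subtracted; corrected + baseline
   reconstructs the input exactly, the corrected value is exactly zero at
   every anchor, and negative corrected intensities (noise below the
   baseline) are kept, not clipped.
3. **L2 (vector) normalization** — each corrected spectrum is divided by its
   Euclidean norm, giving unit-norm vectors. This also cancels the
   multiplicative spectrum-to-spectrum intensity heterogeneity that scan maps
   of living tissue show.
4. **Quantile elimination** — a scalar score per spectrum (default: total
   corrected intensity; alternatively the raw L2 norm) is computed, and
   spectra whose score falls outside the closed interval between the 0.5%
   and 99.5% sample quantiles are removed. Quantiles use the
   linear-interpolation convention between order statistics, recorded in the
   filter report for reproducibility. Scoring is global by default and can be
   computed within (week, concentration) groups instead.

The scored quantity and the position of elimination in the chain are
under-determined in the source protocol; both are configurable, and the
defaults above are recorded in every `QuantileFilterReport`.

## Band component analysis

Broad features such as the Amide I envelope (default window 1590–1720 cm⁻¹,
covering the 1619/1646/1657/1669/1686 cm⁻¹ components) are decomposed as a
sum of Gaussian lines parameterized by height h, center c and full width at
half maximum w:

    g(ν) = h · exp(−4 ln2 (ν − c)² / w²),   area = h · w · √(π / (4 ln 2)).

FWHM is used rather than σ because band widths are conventionally reported
that way. The number of components is chosen from the second derivative: a
Savitzky–Golay second derivative (order 3, window 21 points by default —
about one band FWHM at 1 cm⁻¹ sampling, the matched-width rule; window 11
under-smooths realistic noise) is computed, and each negative lobe whose
depth reaches a configurable fraction (default 10%) of the deepest lobe
counts as one sub-peak, its minimum position seeding the fit. The
least-squares fit (trust-region reflective, bounds keeping heights
non-negative, centers inside the window and widths above half a grid step)
iterates until the relative cost change falls below 1e-10 or 500 residual
evaluations; non-convergence is reported through a flag, and center
collapses within one grid step raise a warning.

Band trends across the (week, concentration) design are extracted either as
the groupwise mean and interquartile range of the per-spectrum maximum
intensity near each band, or — for center shifts — by fitting the group mean
spectrum, because single-spectrum fits at realistic noise are too unstable
to chart. Fitted components are matched to the requested band positions by
nearest center; the requested positions act as a common reference across
groups, which stays stable when the fitted component count varies.

## Concentration regression

The regressor is an exact Gaussian process over preprocessed (unit-norm)
spectra with a constant basis and, by default, the rational quadratic
kernel

    k_RQ(r) = σ_f² (1 + r² / (2αl²))^(−α),   r = ‖x − x′‖₂,

a scale mixture of squared-exponential kernels that converges to the
squared exponential as α → ∞. Squared-exponential, Matérn-5/2 and
exponential kernels are available under the same interface. σ_f (signal
amplitude) and σ_n (noise level), not part of the kernel's textbook form,
are required for a usable GP and are optimized jointly with l and α.

The constant mean is β·H with H an n-vector of ones; β is profiled out by
generalized least squares at every hyperparameter evaluation, and by the
envelope theorem the profiled likelihood gradient needs no β term. The
remaining hyperparameters maximize the exact log marginal likelihood by
L-BFGS on log parameters with analytic gradients, from the initialization
l = median pairwise training distance, α = 1, σ_f = sd(y), σ_n = σ_f/10,
plus three restarts with jittered (σ = 0.5 in log space) seeded starting
points. Because every kernel depends on the inputs only through pairwise
distances, the squared-distance matrix is computed once per fit. A 1e-10
jitter stabilizes the Cholesky factorization, and σ_n has a 1e-8 floor.
Exact GP only: fits beyond a configurable budget (default 3,000 training
spectra) raise an error suggesting stratified subsampling rather than
silently degrading.

Comparator models are ridge-regularized linear regression (plain least
squares is ill-posed with ~1500 wavenumber features and a few hundred
spectra; the ridge path is selected by internal cross-validation over a
small alpha grid) and a depth-limited CART regression tree.

### Evaluation protocols

* **80/20 split** stratified by concentration level, seeded, so every level
  appears in both halves; **5-fold** seeded cross-validation.
* Reports carry RMSE (mM), R², per-sample residuals (true − predicted) and
  the median prediction per true concentration. Predictions are not clamped
  to the design range, since residual analysis needs raw values.
* **Leave-one-concentration-out**: a whole concentration group is withheld
  from training and the median prediction deviation on it measures
  interpolation to unseen stress levels.
* **Week inference**: with one model per growth week, an unknown sample set
  of known concentration is assigned the week whose model has the smallest
  absolute median residual; ties break toward the earlier week. Models are
  trained per week; the first two growth weeks are excluded from regression
  by default because young leaves scan too heterogeneously.

## Synthetic data generator

Each synthetic spectrum is

    I(ν) = F(ν) + h · Σ_b A_b(week, c) · g(ν; μ_b(c), w_b) + ε(ν)

with `F` a broad fluorescence Gaussian (amplitude 600, center 1200 cm⁻¹,
FWHM 1500 cm⁻¹) over a linear offset (60 + 0.02·ν) — smooth enough that the
piecewise-linear baseline estimator approximates it, as the method assumes;
`h` a lognormal per-spectrum heterogeneity factor (σ = 0.3 for weeks 0–1,
0.08 for later weeks, encoding the poor scan-to-scan reproducibility of
young leaves); and `ε` i.i.d. Gaussian noise (sd 3 raw counts). Band
amplitudes respond linearly to the concentration fraction c/c_max and to
week, clipped at zero:

    A_b = base_b · max(0, 1 + week_slope_b · week + conc_slope_b · c/c_max),
    μ_b = center0_b + center_shift_b · c/c_max.

The default band set sits at the canonical leaf positions (cellulose 522,
pectin 747, serine 855, carotenoid 1515, chlorophyll b 1563, and the
1619/1646/1657/1669/1686 cm⁻¹ amide-region components; the shipped
`band_assignments.csv` lists the tentative assignments). Signs follow the
reported biology: the carbohydrate/amino-acid and pigment bands lose
intensity as medium salt rises; the amide-region bands gain intensity with
salt within a week; all bands share a decreasing trend across weeks
(7–11% of base per week); and the 1619/1669/1686 cm⁻¹ centers red-shift
with salt. Magnitudes are plausible placeholders, not biological
measurements: the amplitude scale is arbitrary units, so the meaningful
quantity is the peak signal-to-noise ratio, anchored at ~20–50 for the
mid-study weeks — typical of 2-s integration leaf spectra — such that the
per-week concentration information content of the default design matches
the performance regime reported for real leaf maps (R² low-0.9s at a few
hundred spectra per week). Raster scans place one spectrum per grid node
inclusive of both edges (a 300 × 300 μm region at 5 μm steps gives
61 × 61 = 3721 spectra). Everything is reproducible from one integer seed.

What the generator does **not** emulate: cosmic-ray spikes, detector
binning and wavelength-calibration error, non-Gaussian (shot-noise) count
statistics, spatial correlation within a scan, Lorentzian/Voigt line
shapes (a Lorentzian switch exists for misspecification tests), and any
real biochemical dose–response magnitudes. Passing tests therefore show
that the pipeline recovers the structure it assumes at realistic SNR — not
that real leaves behave like the generator.

## Problem sizes and numerical choices

The packaged study analog uses weeks 2–4, concentrations 0/50/100/150 mM
and 150 spectra per group (600 per week, ~1,800 total) — the same factorial
design as the source study at desk scale, chosen so a full run (generation,
preprocessing, three GP fits, leave-one-group-out and week inference)
completes in well under a minute on one CPU. Degenerate inputs are handled
explicitly: empty spectrum sets, zero-norm spectra, all-equal filter
scores (everything kept), zero-variance evaluation targets (R² reported as
missing with a warning), and non-finite likelihoods (restart discarded;
an error only if every restart fails).

## Known limitations

* The piecewise-linear baseline tracks the lower noise envelope; with heavy
  noise it biases corrected intensities slightly upward. This is inherent
  to the local-minima method, not corrected post hoc.
* Exact GP cost grows as O(n³); the training budget guards it, and no
  sparse approximation is provided.
* The week-inference statistic compares medians only; with weakly separated
  week signatures and small sample sets it is sensitive to sampling noise,
  so a fresh sample set of ≥ ~100 spectra is recommended.
* Reported R²/RMSE on synthetic data characterize the pipeline under the
  generator's assumptions; they are analogs of, not estimates of, any
  real-data figure.
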