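# Methods

## The measurement model

A SERDS acquisition series measures one particle consecutively at three
excitation wavelengths, 784, 785 and 786 nm, at laser powers 130, 180 and
200 mW, in that order. All spectra are expressed on a common Raman-shift
axis referenced to 785 nm excitation. On that axis two kinds of signal
behave differently:

* **Raman bands** are fixed in shift coordinates relative to *their own*
  excitation. A band at shift *c* therefore appears at
  *c + 10⁷(1/785 − 1/λ_ex)* on the common axis: −16.25 cm⁻¹ for 784 nm,
  +16.21 cm⁻¹ for 786 nm, about 32.5 cm⁻¹ apart for the 2 nm pair. The
  local rate is 10⁷/λ² ≈ 16.2 cm⁻¹ per nm near 785 nm.
* **Everything tied to the detector** — fluorescence background, ambient
  light lines, etaloning ripple — is fixed in absolute wavelength, hence at
  identical positions on the common axis for every excitation.

Subtracting the pair therefore cancels wavelength-fixed terms and turns
each band into a derivative-like S-shape. Because the fluorescence
photobleaches between the consecutive exposures and the powers differ, the
two backgrounds differ in *amplitude* (not shape); the subtrahend is scaled
by an optimization factor *k* before subtraction to re-match them.

## The difference optimization

`optimize_factor` minimizes, over *k* in [0.2, 5.0],

    Σᵢ | movmedian( m − k·s , 2·h+1 )ᵢ |

with a moving-median half-width *h* = 50 pixels (≈ 275 cm⁻¹ on the default
grid). The median over a window much wider than any band annihilates the
narrow S-shaped difference features while passing the broadband background
residual, so the objective measures how much background survives; the L1
norm resists leakage from the few pixels where bands do survive the
smoother. The scalar search is bounded Brent to 1e-6 in *k*; a brute-force
grid search (step 1e-3) is provided as an independent oracle and the two
agree to the grid step in tests. Hitting a search bound raises a warning
rather than an error — it usually means the pair's backgrounds differ more
than fivefold.

On noise-free synthetic pairs the recovered *k* matches the true background
amplitude ratio to ~0.1 % (tests require < 2 %), and the band-free residual
of the difference is below 10⁻³ of the background amplitude. In the
bleaching regime (second acquisition weaker) *k* > 1, which also makes the
negative difference lobes systematically stronger than the positive ones.

## Quality control and normalization

For each class the mean optimized (pre-normalization) difference is
computed once over all members; members with Pearson *r* < 0.52 to that
mean are discarded. The mean is deliberately non-iterative — a single pass
with no recomputation after discards — since with coherent majorities the
incoherent spectra barely move the mean, and a one-pass rule is
reproducible without a convergence criterion. Classes with a single member
are kept with *r* undefined and a warning.

Surviving differences are divided by their Euclidean norm. "Area"-style
normalization by the signed integral is ill-posed here: the signed area of
a difference spectrum is (1 − k) times the band area and crosses zero near
k = 1, so the unit-L2 interpretation is used instead. Normalization makes
the classification input invariant under any common positive rescaling of
the raw pair (verified as a property test).

## Reconstruction and the raw-spectrum branch

For comparison with conventional processing, a difference can be
re-integrated: S(n) = Σ_{x≤n} s(x) over pixels in axis order, shifted to be
non-negative, followed by SNIP baseline subtraction to remove the
integration ramp. Summation is a low-pass operation, so reconstruction
trades resolution for familiarity; no deconvolution is attempted. On a
single synthetic band the reconstructed maximum lands within ~1 cm⁻¹ of the
true center (the acceptance bound is the ~16 cm⁻¹ excitation displacement)
and correlates > 0.9 with the band-only truth.

The raw branch applies SNIP directly to the preprocessed 784 nm or 786 nm
spectra. SNIP here is the decreasing-window variant: in log-log-sqrt (LLS)
compressed space, y_i ← min(y_i, (y_{i−w} + y_{i+w})/2) for w = m, m−1, …,
1. The default m = 24 pixels (~66 cm⁻¹) comfortably exceeds the half-width
of the widest default band so bands are clipped away; on a broad synthetic
background under five narrow Lorentzians the band-free baseline RMSE is
~1.2 % of the background amplitude (bound 2 %). Negative inputs are clipped
to zero for the LLS transform with a warning — difference-derived and
noisy spectra legitimately go below zero. An optional `split_at_cm1` runs
the estimate separately on two axis regions; the default estimates jointly.

## Spike removal and calibrations

Cosmic spikes are detected by the modified z-score of D_i = 2y_i − y_{i−1}
− y_{i+1} (one-sided, z > 8 by default): a single-pixel spike makes D large
and positive at the spike and negative at its neighbours, so one-sided
flagging repairs the spike without dragging in its neighbours; adjacent
double spikes still produce D = +A at both pixels and are both caught.
Flagged pixels are replaced by the median of a 5-pixel neighbourhood
excluding other flagged pixels (widened if necessary). The MAD scale falls
back to the mean absolute deviation when the median deviation is zero
(noiseless fixtures), and a constant spectrum yields no flags. The repair
is idempotent on the tested fixtures.

Wavelength calibration fits a degree-1..3 polynomial from observed peak
pixels to reference shifts by least squares, refusing non-monotone
mappings; the ASTM E1840 4-acetaminophen shift table ships as the default
reference, and any user table is accepted. Intensity calibration divides
by the smoothed measured white-light spectrum times the known lamp
emission, normalized to unit mean gain so only the spectral *shape* of the
detector response is corrected. Synthetic spectra are born calibrated;
the calibration fits are exercised on synthetic miscalibrations.

## Classification

The preprocessed, optimized, normalized differences (or either comparison
branch) are split into an equal-per-class training set —
floor(0.6 × smallest class) per class by default, the balanced-training
recipe — with the remainder as test set. PCA (mean-centered SVD, sign
convention: largest-magnitude loading positive) separates structured
variation in the low components from noise in the high ones; LDA with
equal priors (training is balanced by construction) classifies the
truncated scores. Two-class problems reduce to the sign of LD1; LD axes
are oriented so the lexicographically first class has negative mean score,
making score plots reproducible.

The number of PCs per stage is chosen by stratified tenfold
cross-validation with the PCA refit inside each fold (no leakage of
held-out spectra into the basis). The selection rule is configurable:
maximum mean accuracy, or the default one-standard-error rule (smallest
candidate within one SE of the best), which favours parsimonious models
when the accuracy curve plateaus. The replication recipe for the pollen
study pins 10 PCs (habit), 13 (tree genera) and 11 (non-tree genera)
instead of re-selecting.

The hierarchy runs habit (tree vs non-tree) over all spectra, then
independent genus models inside each habit group, each with its own split
and CV, and can execute all input variants (difference, reconstructed,
raw-784, raw-786) on the same particles for a side-by-side table of
averaged metrics.

Confusion matrices are stored as counts[predicted, real] — rows are
predicted classes — and per-class metrics are one-vs-rest: TP = the
diagonal cell, FN = rest of the column, FP = rest of the row, TN = the
remainder; sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, precision TP/(TP+FP), reported in percent and rounded
half-up to one decimal for report output (unrounded values are kept
internally; tests compare unrounded values at 0.05 tolerance). The
implementation is fuzz-tested against per-instance counting on 1,000
random matrices and against the three published reference tables shipped
in `serdskit.tables`.

## The synthetic-data generator

The simulator emulates the features of real SERDS acquisitions that the
pipeline's correctness depends on, with defaults chosen as the study
conditions:

| parameter | default | meaning |
|---|---|---|
| excitations / powers | 784/785/786 nm at 130/180/200 mW | acquisition order 784 → 785 → 786 |
| axis | 300–3100 cm⁻¹, 1024 points | fingerprint + CH-stretch regions |
| band shape | Lorentzian (Gaussian optional) | typical Raman lineshape |
| background | Gaussian in absolute wavelength, center 830 nm, width 70 nm, amplitude 1200 counts | autofluorescence profile |
| bleach_factor | 0.6 per acquisition | geometric decay per 0.5 s exposure+dwell cycle |
| noise | σ = sqrt(max(signal, 10)) | Poisson-like but reproducible Gaussian |
| amplitude jitter | 10 % per band, 20 % global | biological + focus variability per particle |
| spikes / ambient / etalon | off by default | enabled for the robustness demonstrations |

Only three time points exist per particle, so bleaching is modelled as a
geometric per-acquisition multiplier rather than continuous-time kinetics;
no quantitative bleaching rate is published, so it is a free parameter.
The default 0.6 places the simulator in the regime where total intensity
*decreases* across the triplet despite rising laser power — the background
decay outpaces the power-driven growth of the bands — which is the regime
the optimization step exists for. (With power-scaled backgrounds this
strict decrease requires bleach < 130/180 ≈ 0.72.)

Eight default class profiles (alder, birch, hazel, larch; cyclamen, rumex,
mugwort, moor grass) share the sporopollenin bands at 1007, 1454 and
1614 cm⁻¹ and amide features at 1310 and 1650 cm⁻¹, carry a habit marker
band (CH₂ stretch at 2850 cm⁻¹ for trees, a carbonyl at 1735 cm⁻¹ for
non-trees), one genus-specific fingerprint band each, and genus-dependent
1614 cm⁻¹ amplitudes (weak for moor grass). Larch gets extra CH₂ signal
for its conifer lipids.

**What passing tests do and do not show.** The generator's classes are
separated by clean, disjoint marker bands; real pollen genera overlap far
more subtly, and real backgrounds vary in shape as well as amplitude
between acquisitions. End-to-end accuracies near 100 % on synthetic data
therefore validate the *pipeline plumbing and its statistical hygiene*
(no leakage, correct metrics, chance-level under label permutation), not
the discriminability of real pollen. Conversely, the physics-level checks
(k recovery, background cancellation, perturbation suppression, noise
variance (1 + k²)·σ²) are quantitative statements about the algorithms
that transfer directly.

## Numerical choices and degenerate inputs

* Subtraction requires a bitwise-identical axis; `resample` (linear
  interpolation, no extrapolation) is the explicit escape hatch.
* The ambient/etalon suppression demonstration runs in the
  matched-background regime (no bleaching, equal powers, k ≈ 1):
  wavelength-fixed terms enter both acquisitions identically and subtract
  with weight (1 − k), so near-total cancellation is a k ≈ 1 property; with
  strong bleaching a (1 − k)-weighted residual survives by construction.
* Zero-variance spectra: no spike flags, QC r defined as 0 for
  zero-variance members, L2 normalization refuses zero vectors, the
  optimization refuses an identically-zero subtrahend.
* LDA within-class scatter is regularized by sklearn's SVD solver;
  PCA truncation keeps it well-conditioned in practice.
* Seeds: every stochastic stage derives a named child seed from the global
  seed via `numpy.random.SeedSequence` with a CRC-32 of the stage name, so
  stages are independently reproducible.
* Problem sizes: the shipped tests and the acceptance script simulate 30–40
  particles per class (720–960 triplet spectra) on the 1024-point grid;
  these sizes give stable accuracy estimates for eight well-separated
  synthetic classes while keeping a full run in seconds.

## Known limitations

* The optimization assumes the two backgrounds differ by a scalar; shape
  changes between acquisitions (e.g. spectrally non-uniform bleaching) are
  outside the model and will leave a structured residual.
* Reconstruction is the plain cumulative-sum variant; deconvolution-,
  kernel- and least-squares reconstructions are out of scope.
* The QC mean is single-pass; with a majority of incoherent spectra in a
  class the class mean itself is corrupted and the filter degrades.
* Wide-CSV headers require unique sample_ids; triplets use the
  `<particle>#<excitation>` naming convention to stay unique.
* Vendor binary formats (SPC/SPA, JCAMP-DX) and hyperspectral cubes are
  not read.
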