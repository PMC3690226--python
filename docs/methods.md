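# Methods

## Classification model

The classifier operates on one feature vector per case: the normalized
256-bin luminance histogram of the whole segmented tumor, its derived
luminance-range scalar, and optionally one scalar ADC value
(units 10⁻³ mm²/s, measured externally).

**Quantization.** 12-bit luminance (0–4095) is mapped to 8 bits by
`floor(v / 16)`, so each of the 256 bins aggregates exactly 16 consecutive
source levels. Quantizing an already-8-bit volume is an error, not a no-op.

**Luminance range.** A bin participates when its normalized frequency is
*strictly* greater than the frequency threshold `th` (default 0.002). The
range is the span in bins between the outermost participating bins; gaps
inside the span are allowed. The alternative reading — the longest
contiguous supra-threshold run — is available via
`luminance_range(..., contiguous=True)` but is not the default: the span
interpretation is the natural reading of "the luminance range whose
normalized frequency is larger than a threshold", and for a bimodal
glioblastoma histogram it is the quantity that actually captures the
rim-to-core dynamic range. Range units are 8-bit bins (0–255) throughout,
including the learned thresholds.

**Gate.** From a labeled training set the gate learns four numbers: the
maximum range and ADC over lymphomas, and the minimum range and ADC over
glioblastomas. Two geometries:

* *Case 1* — the class extrema overlap on at least one enabled criterion.
  Typical lymphoma: `ADC < TH_ADC_gli_min` **or** `range < TH_range_gli_min`.
  Typical glioblastoma: `ADC > TH_ADC_lym_max` **or** `range > TH_range_lym_max`.
* *Case 2* — every enabled criterion has a gap between the extrema. The
  inequalities swap to the same-class extrema: typical lymphoma below the
  lymphoma maxima, typical glioblastoma above the glioblastoma minima.

All inequalities are strict, so a value exactly at a threshold never fires.
When a case has no ADC value, or ADC was not enabled at training, the ADC
clauses are skipped. Design choices where the rule's prose is silent:

* **Conflict policy.** A case flagged typical-lymphoma by one criterion and
  typical-glioblastoma by the other is routed to the SVM as nontypical.
  Deferring contradictory evidence to the learned classifier is the
  conservative reading of "nontypical"; the alternative (priority of one
  criterion) would silently encode a feature preference.
* **Tie rule for baselines.** Single-value thresholding labels a value
  strictly below the cut lymphoma, otherwise glioblastoma.

By construction of the extrema the gate can never mislabel a *training*
case (it outputs the true label or nontypical); held-out cases can be
mislabeled, which is intrinsic to the method — notably the Case-2 ADC
clause, which fires whenever a test case's ADC falls below the training
lymphomas' maximum even if its luminance range is uninformative there.

**SVM.** Nontypical cases go to a binary SVM over the full histogram,
trained on *all* training cases (typical included). Kernels: linear
(`Σxᵢyᵢ`), Gaussian (`exp(−γ‖x−y‖²)`), histogram intersection
(`Σ min(xᵢ, yᵢ)`), and exponential chi-square
(`exp(−γ Σ (xᵢ−yᵢ)²/(xᵢ+yᵢ))`, 0/0 terms dropped). Defaults `C = 1` and
`γ = 1/256` (one over the histogram dimension); the method's source
material reports kernel choice but no hyperparameters, and on normalized
histograms these are the standard neutral settings. All kernels are fed to
the solver as precomputed Gram matrices, which makes training deterministic
for fixed inputs.

**Baselines.** The single-value baselines cut at the midpoint between the
learned extrema, `(TH_gli_min + TH_lym_max) / 2`, for ADC and range
respectively; the subset methods (`svm_only`, `range_gate_plus_svm`,
`adc_gate_plus_svm`) disable parts of the hybrid.

## Segmentation

Seed-based region growing stands in for a fast interactive 3D segmenter;
the mask only feeds histogram generation, so moderate accuracy is enough.
Each seed's 3×3×3 neighborhood mean is one intensity *mode*; the tumor
model is the set of tumor-seed modes (a glioblastoma needs seeds in both
rim and core), the background model likewise. A voxel is acceptable when it
is strictly closer to the nearest tumor mode than to the nearest background
mode **and** within `tolerance·σ` of the nearest tumor mode, where σ is the
pooled within-neighborhood standard deviation of the tumor seeds, floored
at 1 luminance unit so zero-noise images remain well defined. The mask is
the set of acceptable voxels 26-connected to the tumor seeds, computed by
iterative binary dilation (equivalent to FIFO flood fill, but
order-independent); `max_iters` caps the number of dilation sweeps and
defaults to the voxel count (full convergence). Tumor seeds are always
included, background seeds never. Identical tumor and background modes
raise an error asking for better seeds. A static multi-mode model is used
instead of a single evolving regional mean because bimodal tumors would
otherwise reject whichever compartment the mean drifts away from.

Properties: deterministic; monotone in `tolerance` (the acceptable set can
only grow); output is one 26-connected component when the seeds sit inside
one tumor.

## Synthetic phantom generator

The generator emulates exactly the class-conditional statistics the
classifier exploits; it is not an anatomical brain simulator.

* **Geometry** — one axis-aligned ellipsoid per case, semi-axes drawn
  uniformly from `tumor_radius_range_vox` (default 8–13 voxels,
  independently per axis: mild anisotropy), placed uniformly with a
  2-voxel border margin. The glioblastoma rim is the outer 30 % of the
  normalized radius.
* **Intensities** (12-bit): background 600 ± 60; lymphoma 1400 ± 80
  (single compartment); glioblastoma rim 2800 ± 150 over core 1000 ± 150.
  Per-tissue sd models biological texture; independent scanner noise
  (Gaussian, default σ = 40; Rician behind `noise_model="rician"`) is added
  on top, then values are clipped to [0, 4095] and rounded. "Noiseless"
  phantoms in tests set both the texture sds and σ to zero, which yields
  exact two/three-intensity images and makes exact segmentation recovery a
  meaningful contract.
* **ADC** — one scalar per case: lymphoma N(0.7, 0.3²), glioblastoma
  N(1.0, 0.3²) ×10⁻³ mm²/s, truncated at 0.05. The means put the midpoint
  (0.85) inside the 0.8–1.0 band where naive ADC cuts work best; the sd is
  calibrated so the theoretical best single ADC cut is ≈ 69 % — "modestly
  above chance", matching the clinical finding that class ADC distributions
  overlap substantially.
* **Volume shape** — default 64×64×40 voxels at 1 mm spacing. Real
  structural acquisitions are larger (e.g. 256×256×160), but histogram and
  gate statistics depend on tumor voxel counts, not field of view; the
  smaller grid keeps cohort generation fast without changing the feature
  distributions materially.
* **Determinism** — per-case seeds are a SHA-256 mix of (cohort seed, case
  index); the class label is folded into the RNG stream. Identical
  (label, params, seed) reproduce bit-identical volumes.

What the phantoms do **not** model: partial-volume effects, anatomy,
multi-focal or infiltrative growth, bias fields, or ADC maps as images
(ADC is a scalar per case). Consequently, on phantoms the range feature
separates the classes essentially perfectly — range-based methods saturate
near accuracy 1.0 — whereas on real cohorts the range distributions overlap
and the hybrid's margin over its baselines is larger. Passing tests
demonstrate the pipeline's contracts and the method's internal logic, not
clinical performance.

## Evaluation protocol

For each k, k cases per class are drawn uniformly without replacement for
training; thresholds and SVM are re-learned each repetition; the held-out
remainder is scored (default 1,000 repetitions; tests and the acceptance
script use 200 to stay desk-scale, stated here as the package's own choice
of problem size). Sensitivity counts lymphoma as positive. Splits are a
pure function of (cohort order, seed, k, repetition) — never of the method
or kernel — so method comparisons are paired. Metrics whose class is absent
from a test split are excluded from averages with a reported count (cannot
happen at k ≤ 19 with 20 per class). The threshold sweep recomputes range
features per `th`; a `th` under which some histogram has no
supra-threshold bin is flagged in the output rather than skipped.

## Known limitations

* The gate's Case-2 ADC clause can mislabel held-out cases whose ADC falls
  below the training lymphomas' maximum while their range lies inside the
  training range gap; with overlapping ADC distributions this happens with
  small but nonzero probability at small k (it vanishes for k ≳ 11, where
  disjoint ADC training samples become vanishingly rare).
* Segmentation assumes roughly piecewise-constant tumor compartments; it is
  not suitable for infiltrative lesions with smooth intensity gradients.
* The SVM offers no probabilistic output or calibration; the package is
  two-class only.
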