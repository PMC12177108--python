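# Methods

## Signal model and phantom

The analysis assumes the proton-density mechanism of phase-resolved lung
MRI: parenchymal signal intensity falls as the lung inflates and rises on
expiration, so over tidal breathing every ventilated voxel oscillates at
the respiratory frequency with an amplitude proportional to its regional
ventilation. The phantom generator realizes this directly:

    S(x,y,t) = S0(x,y) · [1 − a(x,y)·(1 − cos(φ(t) − lag(x,y)))/2]
                       · [1 + p(x,y)·sin(2π f_card t)] + ε

with `a` the fractional ventilation-amplitude map, `φ(t)` the respiratory
phase (0 at end-expiration, π at end-inspiration), `lag` a per-voxel phase
lag modelling delayed regional emptying, `p` a faster perfusion
oscillation at the cardiac frequency, and `ε` additive Gaussian (optionally
Rician) noise. Defaults mirror a typical single-slice protocol: 128×128
matrix, 250 frames at 135 ms (≈34 s), 4 s respiratory period, 1.1 Hz
cardiac frequency, baseline lung signal 100 a.u. inside a brighter torso
(300 a.u.).

Ventilation heterogeneity has two programmable sources. Binary defect and
lag regions are blob-shaped patches with an exact voxel count (the lowest-k
values of a Gaussian-smoothed random field), since a defect *fraction* is
the primary ground truth the defect-percentage metrics must recover. On top
of that, a smooth multiplicative lognormal amplitude field with coefficient
of variation `amplitude_cv` (default 0.10) provides the continuous spread
of regional ventilation present even in healthy lungs; without it the RVent
histogram would be two-valued and the quartile-based indices degenerate.
The cohort generator scales `amplitude_cv` with the defect fraction
(0.10 + 0.8·defect), so diseased phantoms show both more defects and wider
dispersion — the two features that drive the defect percentages and the
histogram indices respectively.

What the phantom does **not** emulate: MRI physics (k-space, coils,
T1/T2*), deformable respiratory motion (only rigid drift is available),
through-plane motion, structural pathology, and realistic scanner noise
spectra. Tests passing on phantoms therefore establish the correctness of
the computation chain — phase sorting, map algebra, thresholds, statistics
— not robustness to every artifact of real acquisitions, where registration
quality and segmentation accuracy dominate.

## Preprocessing

* **Registration** is translation-only: each frame is aligned by phase
  cross-correlation (subpixel, upsample factor 10) to the frame whose
  spatial-mean signal is closest to the temporal median — an intermediate
  respiratory position. Group-oriented deformable registration is treated
  as an external concern behind this pluggable stage; phantoms default to
  motion-free, and the registration mode is off by default.
* **Segmentation** is a classical fallback (the lungs are the dark interior
  regions enclosed by the Otsu-thresholded body, cleaned by morphology,
  largest two components kept), with a truth-mask bypass because masks are
  inputs in real use. On phantoms it exceeds 0.9 Dice against truth.
* **Vessel removal** applies an Otsu threshold over a 256-bin histogram of
  the temporal-mean in-mask intensities and removes the bright class. Two
  guards handle degenerate histograms: a constant sample is returned
  unchanged, and a split that would remove ≥50% of the mask (near-unimodal
  input, where Otsu's small-class bias cuts into the parenchyma) is
  skipped with a warning. Vessel removal is off by default since phantom
  truth masks are vessel-free.
* **Low-pass filtering** is a zero-phase Butterworth (order 5, forward–
  backward) along each voxel's time course. The default 0.7 Hz cutoff sits
  between typical respiratory (0.2–0.4 Hz) and cardiac (~1 Hz) peaks:
  respiratory gain ≥ 0.99, cardiac gain ≈ 0.01 after the double pass. The
  filter family and cutoff are declared defaults, configurable; an optional
  check warns when the estimated spectral peaks do not bracket the cutoff.

## Phase estimation and sorting

The respiratory frequency is the dominant FFT peak of the spatial-mean
in-lung signal below the filter cutoff, refined by minimizing the residual
of a least-squares cosine fit within one FFT bin of the coarse peak (the
raw FFT resolution of a ~34 s series, ~0.03 Hz, is too coarse for
percent-level frequency accuracy). Per-frame phases come from a sliding-
window cosine fit (window ≈ 2 periods) so slow drift of the breathing
period is tracked; the fit quality (variance explained) is reported and
values below 0.2 raise an error. The phase convention puts end-expiration
(signal maximum) at φ = 0 and end-inspiration (signal minimum) at φ = π.

Frames are sorted into 15 equal-width phase bins by default (≈250 frames
over ≈8 cycles fill 15 bins comfortably; the count is configurable with a
floor of 10). Empty bins inherit the circularly nearest occupied bin;
more than 30% empty bins aborts with an insufficient-sampling error.
End-inspiration/expiration are the bins with extreme mean lung signal
(lowest index wins ties), and the mid state is the bin nearest the phase
midway along the inspiratory limb from end-expiration to end-inspiration —
one consistent, documented choice where "midway" is otherwise ambiguous.

## Maps and thresholds

RVent is evaluated voxelwise from the three key states; non-positive
denominators are repaired to 0 and counted. The defect threshold is
deterministic: 0.4 × the 90th percentile of in-mask RVent, with strictly-
below counting as defective (a voxel exactly at threshold is normal). All
percentiles in the package — VDP threshold, FVL reference band, outlier
trim, quartiles — use linear interpolation between closest ranks.

For the FVL map the loop is serialized as volume-then-flow, each segment
standardized to zero mean and unit variance, and the Pearson correlation
of the concatenation with the reference's is reported in percent, clipped
below at zero. The comparison is evaluated **at zero phase shift** by
default: a region that empties with a phase lag produces a loop that is a
rotated copy of the reference, and maximizing over circular shifts would
score it as normal, defeating the purpose of the map (a quarter-cycle lag
correlates at ≈99% under shift search versus ≈0% at zero shift). Shift
search remains available (`shift_search=True`) for studies where pure
timing differences should be forgiven. Zero-variance loops score 0 and are
counted.

## Heterogeneity metrics

Trimming (values strictly above the 99th percentile removed) precedes all
histogram metrics. IQD = IQR/mean and IHI = Σ|v − median|/Σv are both
ratios of degree-1 quantities and hence invariant to rescaling the series.
Kurtosis is reported non-excess (3 for a normal distribution). The pooled
cohort histogram rescales each subject's sample by its own median, bins on
a shared grid, converts to unit-area densities and averages with equal
subject weights — a declared convention for "normalized".

## Cohort statistics

The normality gate is Shapiro–Wilk at α = 0.05, applied per group
(unpaired) or to the paired differences. The parametric route uses the
Welch t-test by default — group variances in heterogeneity metrics
routinely differ by an order of magnitude between healthy and diseased
groups, where the pooled-variance form is anticonservative; the pooled
form is available by flag. Rank tests are exact for n ≤ 25 without ties,
otherwise tie-corrected asymptotic. Zero-variance groups and constant
differences route to the rank tests; all-zero paired differences return
p = 1 with a warning. Spearman correlations use midranks with asymptotic
p-values, adjusted per covariate across the supplied metric family by the
Hochberg step-up procedure (via statsmodels, cross-checked in the tests
against a brute-force enumeration).

## Numerical and design choices

* Raster convention (row, column), 0-based, time/phase as the last axis;
  masks and maps share the series raster. NIfTI 2D+t files carry a JSON
  sidecar with the frame interval.
* Determinism: every stochastic component is driven by an explicit seed;
  identical seeds give bit-identical phantoms and pipeline outputs, and
  every run writes its fully resolved configuration next to its outputs.
* Outputs are written atomically (temp file + rename), so interrupted runs
  never leave truncated CSV/NIfTI files that look valid.
* Problem sizes: single-subject validation runs use the full 128×128,
  250-frame geometry; cohort-scale simulations (30 subjects × 2 conditions,
  with replicates) use 64×64 phantoms, which preserve every property being
  tested while keeping multi-replicate runs fast.
* The post-bronchodilator member of a simulated pair reuses the subject's
  seed, so the same anatomy persists and defect regions shrink in place; a
  shrink factor of 1.0 reproduces the pre acquisition exactly.

## Known limitations

* Registration is rigid/translational only; real free-breathing series
  need deformable registration upstream.
* The segmentation fallback assumes the dark-lungs/bright-body contrast of
  the phantom and of proton lung MRI; it is not a general lung segmenter.
* Perfusion is modelled only as a nuisance oscillation to be filtered out;
  the package computes no perfusion maps.
* Single slice only: multi-slice/3D series are rejected at load time.
* The FVL reference requires ≥100 lung voxels and a non-degenerate RVent
  distribution; pathological inputs raise explicit errors rather than
  producing silent maps.
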