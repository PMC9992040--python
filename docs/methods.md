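# Methods

This note documents the models, estimators and numerical choices behind
`perfopulse`, and what the synthetic test bench does and does not show
about real scans.

## Signal model

A 2D cine phase-contrast (PC) acquisition measures, per cardiac phase, a
complex image whose phase encodes through-plane velocity:

    v = venc · φ / π,            φ ∈ [−π, π)

with venc the velocity-encoding limit (20 cm/s by default; faster flow
aliases). The acquisition geometry mirrors a 3T basal-ganglia protocol:
250 × 250 mm² field of view, 0.3 × 0.3 mm² acquired in-plane resolution
zero-filled in k-space to 0.2 × 0.2 mm², 8–15 reconstructed cardiac phases
depending on heart rate. No background-phase correction is modelled; the
scanner's phase-to-velocity scaling is taken as the ideal relation above.

Pixel (r, c) sits at physical position ((r+0.5)·Δrow, (c+0.5)·Δcol) mm,
row-major and 0-based. Zero-filling evaluates the acquired frame's
band-limited (trigonometric) interpolant on the finer grid; a linear phase
ramp in k-space accounts for the half-pixel offset between the two
pixel-center conventions, so positions are comparable across grids. When
the field of view is not an integer multiple of the requested spacing the
matrix size is rounded up and the actual spacing recorded in
`meta["zero_fill"]`. Zero-filling preserves each frame's spatial mean to
numerical precision and reproduces the original samples exactly wherever
old and new pixel centers coincide; per-pixel noise variance is unchanged
(though noise becomes spatially correlated).

## Synthetic cine generator

The generator exists so that every downstream stage can be validated
against exact ground truth.

**Waveforms.** Each vessel's velocity over the cycle is a raised-cosine
pulse sampled at the cardiac phases and affinely rescaled so that the
sampled temporal mean equals `v_mean` and the sampled (max−min)/mean equals
`vpi_true` *exactly* — applying the pulsatility-index definition to a
generated curve recovers the input to machine precision, which anchors the
recovery tests. The pulse peak position is a free parameter (default 0.15
of the cycle, an early-systolic peak). Only the mean and pulsatility are
constrained by the application; the raised-cosine family itself is a
modelling choice (smooth, unimodal, physiologically plausible).

**Rendering.** Per cardiac phase the complex image is static tissue plus,
for each vessel, a Gaussian blood blob that locally displaces tissue:

    pixel = T·(1 − f·w) + f·g·T·w·e^{iπv(t)/venc}

with `T` tissue magnitude, `w` the (anisotropic) Gaussian profile with
minor-axis FWHM = `diameter_mm`, `g` the blood/tissue signal gain and
`f` an amplitude fraction (1 for vessels, <1 for ghost decoys). Oblique
vessels are modelled by stretching the major axis (`axis_ratio`). The
scene is rendered at the acquired grid, i.i.d. complex Gaussian noise of
per-channel SD `noise_sigma` is added, and the stack passes through the
same zero-filling as real data — partial-volume attenuation, interpolation
ringing and spatially correlated noise therefore arise naturally instead of
being modelled separately.

**Decoys and repositioning.** Ghost decoys are displaced copies of a
parent vessel at a fraction of its amplitude (half the field of view by
default, as in pulsatile ghosting; the benchmark scene places them 1.0 mm
from the parent to exercise the proximity rule). Repositioning between
scans is a rigid jitter — uniform sub-voxel translation within ±1 acquired
pixel and rotation within ±2° about the FOV center — plus an
independently re-drawn ROI, emulating replanning.

**Benchmark scene.** 50 circular perforators (vPI 0.45, v_mean 5–8 cm/s),
10 oblique decoys (axis ratio 3) and 10 ghost decoys (30% amplitude) on a
jittered 4 mm grid, tissue SNR 10, on a 76.8 mm field of view (the full
250 mm FOV would be empty air for a scene this size; resolutions, venc and
cardiac sampling keep their protocol values). The blood/tissue gain is
2.25: bright enough that every vessel center tests at z ≈ 20, low enough
that the truncation-ringing sidelobes of a vessel stay below the velocity
significance threshold beyond the 1.2 mm deduplication radius — the role
k-space apodization plays on scanners. Scene SNR is a free parameter; no
noise magnitude is implied by the application.

**What the generator does not emulate.** Relaxation-weighted contrast
(T1/T2, flip angle), inflow enhancement dynamics, SENSE noise
amplification, velocity aliasing, non-rigid motion, background phase
drift, and anatomically realistic vessel layouts. Passing tests therefore
demonstrate the *algorithmic* correctness and statistical calibration of
the pipeline under a controlled signal model — not clinical performance on
scanner data.

## Detection chain

Inside a supplied ROI:

1. **Noise map** — per pixel, the SD of the complex signal over the
   cardiac cycle: σ_complex = √(var Re + var Im) (sample variances);
   per-channel σ = σ_complex/√2. At vessel pixels the pulsatile signal
   inflates the estimate, making the subsequent test conservative there.
2. **Magnitude SNR mask** — pixels whose cycle-averaged magnitude SNR is 2
   or less are removed (strictly-greater keep). Zero-noise pixels count as
   infinite SNR and are kept (logged).
3. **Velocity significance** — the velocity noise SD is propagated from
   the magnitude noise, σ_v = (venc/π)·σ/mean-magnitude (small-angle phase
   noise), and |mean velocity|·√n/σ_v is tested two-sided. Because σ is
   estimated from the same n cardiac phases, the null reference is Student
   t with 2(n−1) degrees of freedom (a normal reference is available but
   mis-calibrates the false-positive rate at n ≈ 12: ~7.5% instead of 5%).
   Multiple testing across ROI pixels is Bonferroni-controlled by default.
   Benjamini–Hochberg FDR is available, but FDR admits false-positive
   *pixels* in proportion to the amount of true signal found (≈ α·m₁
   isolated pixels for m₁ discovered vessel pixels), each of which
   surfaces as a spurious one-voxel artery; family-wise control keeps the
   expected count of spurious clusters near α per scan regardless of scene
   content. Pixels with zero estimated noise are significant iff their
   |mean velocity| exceeds a 10⁻⁵ cm/s floor (guards against FFT round-off
   in noise-free simulations).
4. **Clustering** — 8-connected components (configurable 4); the
   representative voxel is the cluster's maximum-|mean velocity| pixel,
   ties broken to the smallest row then column.
5. **Circularity filter** — principal-axis lengths 2·√(eigenvalues) of the
   population covariance of the cluster's pixel coordinates, floored at
   half a pixel (a single pixel is circular, ratio 1); clusters with
   major/minor > 2 are removed as oblique vessels.
6. **Proximity deduplication** — candidates are visited in descending
   |mean velocity| (ties by raster order of the representative) and
   accepted iff their representative lies ≥ 1.2 mm from every accepted
   one; near-duplicates are mostly ghosting or ringing artefacts of a
   detected vessel. Greedy order makes chains deterministic (in a 9-8-7
   chain at 1.0 mm steps, the 9 and the 7 survive).

Detection is deterministic for fixed input and configuration, monotone in
each of its thresholds, and every candidate cluster is kept in a
provenance table with the filter that removed it. Signed velocities enter
the ranking as magnitudes (flow direction is not informative for
detection); reported per-vessel velocities keep their sign, while waveform
analysis uses magnitudes.

## Outcomes

Waveforms are |velocity| at each representative voxel over the cycle.
V_mean is the temporal mean of the vessel-averaged waveform. For the vPI,
each curve is divided by its own temporal mean (so the averaged normalized
curve has mean exactly 1 — the identity the property tests pin), curves
with nonpositive temporal mean are excluded with a warning rather than
failing the scan, and vPI = (max − min)/mean of the averaged curve on the
cardiac-phase grid — no temporal interpolation, so coarser cardiac
sampling can only flatten the curve and lower the vPI. The vPI is
invariant to per-vessel velocity scale and to vessel duplication.

## Reliability statistics

Bland–Altman quantities use differences d = x − y with the sample SD
(n−1): LoA = mean(d) ± 1.96·SD(d), CoR = 1.96·SD(d), CoR% =
100·CoR/mean((x+y)/2), CV = CoR/1.96. CoR% is displayed rounded to integer
percent. `agreement_from_summary` recomputes these from published summary
values (mean difference, SD, mean measurement) — useful for checking
reported tables, some of whose printed limits are internally inconsistent
with their printed inputs; the implementation always follows the formula,
not any particular table.

The ICC is the single-measurement two-way form computed from ANOVA mean
squares; the default is absolute agreement, ICC(2,1) — the standard
test–retest choice, sensitive to systematic offsets between scans — with
the consistency form ICC(3,1) available. The model label is always
recorded in the report.

The sample-size calculation uses the classic normal approximation
n/group = ⌈2·((z₁₋α/₂ + z_power)·sd/δ)²⌉ with δ = baseline·relative
increase. For vPI 0.43 ± 0.16 and a 50% increase at power 0.8, α 0.05
this gives 9 per group (18 total). The normal approximation slightly
undershoots the exact two-sample-t power (0.76 at n = 9); a `method="t"`
variant solves the exact power equation and is the one validated by
simulation against its nominal power.

## Simulated test–retest experiment

`run_retest_experiment` draws a cohort (defaults: per-subject N ≈ round
𝒩(8, 3) vessels floored at 1, V_mean ~ 𝒩(6.5, 1.0) cm/s with ±15%
per-vessel scatter, vPI ~ 𝒩(0.45, 0.14) truncated below at 0.05, heart
rate ~ 𝒩(67, 10) bpm mapped to 8–15 cardiac phases) and gives each
subject three scans: scan 1, scan 2 after repositioning, scan 3
immediately after scan 2 without repositioning. Each scan runs through
detection and waveform analysis; Bland–Altman/ICC/t reports are produced
for scan 1 vs 2 (with repositioning) and scan 2 vs 3 (without). Runs are
deterministic under a fixed seed, the seed and a configuration hash are
embedded in every output file, and a failing subject is flagged and
skipped rather than aborting the cohort.

The cohort simulates on a 38.4 mm field of view (protocol resolutions
retained), which keeps a 35-subject × 3-scan experiment around ten
seconds on one CPU; the outcome statistics are driven by the vessel
neighbourhood, not by the empty periphery. Because the repositioning
jitter is sub-voxel, it adds little variance on top of receiver noise —
the coefficients of repeatability with and without repositioning are
similar, and a realized cohort can show either ordering. Tests therefore
compare them with a one-sided sampling tolerance: the SD-ratio bound
√F₀.₀₅(34, 34) ≈ 0.75 at n = 35.

## Known limitations

- The detector tests the *temporal-mean* velocity; vessels with near-zero
  mean but strong pulsatile excursions would be missed (rare for arterial
  inflow).
- Velocity significance relies on small-angle phase-noise propagation,
  which degrades below magnitude SNR ≈ 3; such pixels are usually removed
  by the SNR mask first.
- The circularity filter's covariance axes are computed in pixel units and
  assume square pixels (true for both protocol grids).
- Ghost decoys inherit their parent's waveform exactly; real ghosts are
  modulated by the acquisition order.
- The power calculation assumes equal group variances and a normal
  outcome.
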