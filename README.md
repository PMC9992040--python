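# perfopulse

Velocity and pulsatility analysis of cerebral **perforating arteries** on
2D cine phase-contrast (2D-PC) MRI, with a fully synthetic test bench and
the test–retest reliability statistics needed to plan studies with these
markers.

## The problem

Small-vessel disease damages the sub-millimetre perforating arteries that
supply the basal ganglia, but conventional MRI only shows the end-stage
tissue lesions. Velocity-encoded 2D-PC MRI can probe the vessels
themselves: in a cine acquisition the phase of every pixel is proportional
to through-plane blood velocity (`v = venc·φ/π`, with venc the encoding
limit), so sub-voxel arteries appear as isolated pixels whose mean velocity
stands significantly above the noise. From each scan three outcomes are
derived:

- **N_detected** — the number of perforating arteries surviving all
  detection filters;
- **V_mean** — the temporal mean of the average velocity waveform over all
  detected vessels (cm/s);
- **vPI** — the velocity pulsatility index of the mean normalized waveform,

  vPI = (V_max − V_min) / V_mean,

  where each vessel's curve is first divided by its own temporal mean
  (making the mean of the averaged curve exactly 1) and V_max/V_min are the
  extrema of that averaged curve over the cardiac cycle.

Because single-scan precision is limited at 3T, the package also implements
the agreement statistics used to quantify test–retest reliability:
Bland–Altman limits of agreement (LoA = mean difference ± 1.96·SD of
differences), the coefficient of repeatability (CoR = 1.96·SD, also as a
percentage of the mean), the coefficient of variation (CV = CoR/1.96),
two-way ICCs, Dice overlap of rater ROIs, paired t-tests, and a two-group
sample-size calculation.

## What is in the package

| module | role |
|---|---|
| `perfopulse.pc_io` | cine PC data model, `v = venc·φ/π` conversion, k-space zero-filling, NIfTI + YAML sidecar I/O |
| `perfopulse.synthetic_cine` | scene generator with planted sub-voxel vessels, oblique and ghost decoys, complex Gaussian noise, repositioning jitter |
| `perfopulse.vessel_detection` | SNR mask → velocity significance test → clustering → circularity filter → 1.2 mm deduplication |
| `perfopulse.hemodynamics` | waveform extraction, V_mean, vPI |
| `perfopulse.reliability` | Bland–Altman, CoR/CV, ICC, Dice, paired t, power |
| `perfopulse.cli_pipeline` | `perfopulse` CLI and the three-scan retest experiment |

No scanner data is required: the synthetic module renders cine series with
known ground truth (velocity waveforms with exact mean and vPI), which is
how every stage of the pipeline is validated.

## Worked example

```python
import numpy as np
from perfopulse import detect_perforators, analyze_scan
from perfopulse.synthetic_cine import AcquisitionSpec, PerforatorSpec, render_cine
from perfopulse.reliability import compare_scans

# four sub-voxel perforators at typical velocities, tissue SNR 10
acq = AcquisitionSpec(fov_mm=38.4, noise_sigma=10.0, seed=4)
perfs = [
    PerforatorSpec(center_mm=(x, y), v_mean_cm_s=v, vpi_true=0.45, signal_gain=2.25)
    for (x, y), v in zip([(14, 14), (18, 22), (24, 16), (22, 26)], [5.8, 6.5, 7.1, 6.2])
]
series, roi, truth = render_cine(perfs, acq)
vessels = detect_perforators(series, roi)
stats = analyze_scan(series, vessels)
print(f"N_detected = {vessels.n_detected}")
print(f"V_mean     = {stats.v_mean:.2f} cm/s")
print(f"vPI        = {stats.vpi:.3f}")

# agreement between two repeated measurements of V_mean over 8 subjects
scan1 = np.array([6.1, 7.0, 5.9, 6.6, 7.4, 5.2, 6.8, 6.0])
scan2 = np.array([6.4, 6.6, 6.2, 6.9, 7.1, 5.6, 6.5, 6.3])
rep = compare_scans(scan1, scan2)
print(f"LoA        = ({rep.loa_low:.2f}, {rep.loa_high:.2f})")
print(f"CoR        = {rep.cor:.2f} cm/s ({rep.cor_pct:.0f}% of the mean)")
print(f"ICC(2,1)   = {rep.icc:.2f}")
```

prints

```
N_detected = 4
V_mean     = 5.58 cm/s
vPI        = 0.439
LoA        = (-0.74, 0.59)
CoR        = 0.67 cm/s (10% of the mean)
ICC(2,1)   = 0.85
```

All four planted vessels are recovered; the measured V_mean sits below the
planted 5.8–7.1 cm/s because a sub-voxel vessel shares its voxel with
static tissue (partial volume), while the vPI — a pure shape measure — is
recovered almost unbiased. The agreement block shows a repeatable
measurement: 95% of test–retest differences are expected within ±0.67 cm/s.

The same pipeline is scriptable from the shell:

```bash
perfopulse simulate --out scan/ --seed 4
perfopulse detect --series scan/series --roi scan/roi.nii.gz --out vessels.csv
perfopulse analyze --series scan/series --vessels vessels.csv --out stats.csv
perfopulse run --out experiment/ --seed 1 --n-subjects 35   # full retest study
```

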