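# cardimu

Simulation and analysis of combined accelerometer + gyro measurements of
cardiac motion, for studying how gravity compensation affects the detection
of myocardial ischemia.

## The problem

A miniature inertial sensor sutured to the heart wall measures epicardial
motion continuously — attractive for monitoring after cardiac surgery,
where regional ischemia shows up as reduced end-systolic motion (ESM).
But an accelerometer on the beating heart does not measure motion alone:
the heart *rotates* roughly 10° about its long axis every beat, so the
projection of gravity onto the sensor axes varies within each cycle.

Two compensation strategies exist:

- **Static compensation (STAc)** subtracts the per-cycle mean acceleration.
  The cycle-varying gravity component (up to `g·sin(θ) ≈ 1.6 m/s²` for a
  10° rotation) survives, and double integration turns it into a phantom
  displacement several times larger than the true one.
- **Dynamic compensation (DYNc)** integrates the gyro to a per-sample
  orientation track and removes the gravity vector at every sample, leaving
  (ideally) pure motion acceleration.

The subtlety this package lets you explore: the gravity *artifact tracks
the rotation*, and rotation itself is a sensitive ischemia marker. Removing
the artifact makes the displacement estimate accurate — but not necessarily
a better ischemia detector, because the "contamination" carried real
diagnostic signal.

## What's in the box

| module | contents |
| --- | --- |
| `cardimu.simulate` | forward model: rigid-rotation + translation kinematics with exact ground truth, body-frame accelerometer/gyro signals with gravity, synthetic ECG, LV pressure and segment-length traces, multi-subject cohorts with controllable biological variability |
| `cardimu.segmentation` | R-peak detection, heart-cycle slicing, time normalisation, median-beat ensembles |
| `cardimu.kinematics` | static/dynamic gravity compensation, gyro → orientation integration, drift-corrected double integration, rotation traces |
| `cardimu.metrics` | end-systole timing from heart rate, end-systolic motion, main-contraction-direction 3D→1D reduction |
| `cardimu.work` | regional myocardial work (pressure–strain loop area) |
| `cardimu.detection` | random-intercept logistic scoring, Mann–Whitney AUC, ROC operating points, DeLong's paired test, sensitivity at fixed specificity |
| `cardimu.spectral` | Welch periodogram with the analysis window settings (600-sample Hann windows, 595 overlap, zero-padded) |
| `cardimu.io`, `cardimu.pipeline`, `cardimu.cli` | CSV/npz recording format, validated YAML run configs, end-to-end pipeline, `cardimu` command-line tool |

## Worked example

Why static compensation overestimates (`examples/01_static_vs_dynamic_compensation.py`):

```python
from cardimu.simulate import REFERENCE_PARAMS, Geometry, NoiseConfig, simulate_subject

rec = simulate_subject(
    REFERENCE_PARAMS["baseline"],               # rotation 9.6°, circ. ESM 6.0 mm, HR 108
    geometry=Geometry(inclination_deg=90.0), # supine: maximal gravity artifact
    noise=NoiseConfig.NOISELESS,
    n_cycles=10, seed=1,
)
```

Running the script prints:

```
true circumferential ESM : 6.00 mm
static  compensation ESM : 18.71 mm (3.12x the truth)
dynamic compensation ESM : 5.97 mm (0.99x the truth)
```

The statically compensated estimate is **3.1× the true displacement**; the
dynamically compensated one recovers the truth within 1%. The spectral
footprint of the mechanism (`examples/02_rotation_spectrum.py`): at
120 bpm the rotation signal's PSD peaks at **1.965 Hz** (fundamental
2.00 Hz, bin width 0.085 Hz).

Cohort-level detection (`examples/04_cohort_detection.py`), with
between-subject variability doubled to keep the task off the AUC ceiling:

```
method   AUC    sens@spec0.8
ROT     1.000   1.000
STAc    0.933   0.933
DYNc    0.781   0.548
```

Rotation detects ischemia best, and the *uncorrected* displacement beats
the corrected one — the gravity artifact carried diagnostic signal.
Regional work on the same cohort drops from a median 689 mmHg·% at
baseline to 98 mmHg·% under ischemia.

The same pipeline is scriptable from the shell:

```sh
cardimu simulate --seed 5 --out recordings/
cardimu analyze --in recordings/ --out analysis/
cardimu psd --recording recordings/S00_baseline.csv --channel rotation --out psd.csv
```

## Documentation

- [`docs/methods.md`](docs/methods.md) — forward model, estimation
  choices, numerical conventions and known limitations.
- [`examples/`](examples/) — four narrative scripts covering the
  compensation mechanism, the rotation spectrum, pressure–strain work
  loops and cohort-level detection statistics.
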