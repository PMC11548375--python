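# nirsleep

Single-sensor NIRS sleep staging for preterm infants. The package converts
raw dual-wavelength 100 Hz light intensities to hemodynamic signals via the
modified Beer–Lambert law, rates signal quality on a 1–5 scale and selects
the best channel, extracts heart rate and respiratory rate by windowed
spectral peak-picking (30-s windows, 7.5-s stride, adaptive bands), builds
eight 1 Hz feature modalities per one-minute epoch, and classifies active
sleep (AS) vs quiet sleep (QS) with a 1-D CNN and six benchmark classifiers
under pooled 10-fold and leave-measurement-out 5-fold cross-validation.

A bundled synthetic neonatal-NIRS simulator (cardiac + respiratory
oscillations, drift, motion artifacts, state-dependent HR/RR dynamics,
0.4 Hz reference vitals, 1-minute AS/QS/Wake labels) makes every stage
testable without clinical data.

## Layout

| module | role |
| --- | --- |
| `nirsleep.synthetic` | seeded simulator: timeline → vitals → raw intensities |
| `nirsleep.optics` | OD conversion and modified Beer–Lambert inversion |
| `nirsleep.quality` | 1–5 signal-quality rating, channel selection |
| `nirsleep.vitals` | spectral HR/RR extraction + 1 Hz spline interpolation |
| `nirsleep.features` | eight 1 Hz modalities, 8×60 epoch assembly |
| `nirsleep.models` / `nirsleep._cnn` | NumPy 1-D CNN + six sklearn benchmarks |
| `nirsleep.evaluation` | CV fold planning, metrics, agreement stats, PMA analysis |
| `nirsleep.io` / `nirsleep.cli` | SNIRF/CSV readers and writers, CLI |
| `nirsleep.cohort` | published cohort manifest and fixture fold plan |

The CNN is implemented in pure NumPy (Adam, class-weighted binary
cross-entropy, learning rate 0.001, batch size 2) so no deep-learning
framework is required; the XGBoost benchmark is backed by sklearn gradient
boosting with the same published hyperparameters (see
`nirsleep.models.COMPAT_TABLE` for the full hyperparameter mapping).

## CLI

```sh
nirsleep simulate --seed 1 --duration 30 --out out/sim          # synthetic recording
nirsleep extract-vitals --in out/sim/recording.snirf --out out/vitals
nirsleep report --vitals-dir out/vitals \
    --reference out/sim/reference_vitals.csv --out out/agreement.csv
nirsleep features --in out/sim/recording.snirf \
    --annotations out/sim/annotations.csv --out out/features
nirsleep cross-validate --scheme lmo --models cnn,rf,xgb --out out/cv
```

Every command accepts `--seed`; all randomness flows from it. YAML configs
(`--config`) are validated strictly (unknown keys rejected) and the fully
resolved configuration plus its hash are written to `run_meta.json`.

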