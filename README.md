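# imusa

Respiratory-event detection and sleep-apnea screening from body-worn IMU
(tri-axial accelerometer + gyroscope) recordings, with a synthetic overnight
recording generator for testing without clinical data.

## What it does

1. **Respiratory extraction** — per-axis zero-phase FIR band-pass
   (0.13–0.7 Hz), scalar respiratory amplitude `RA_t = ‖(X,Y,Z)‖`, a
   dominant-axis respiratory waveform stitched per 30-s epoch with polarity
   continuity, and a piecewise-constant respiratory frequency `RF_t` from
   negative-to-positive zero crossings.
2. **Event detection** — amplitude events where the fast (3-s) 95th-percentile
   envelope of `RA_t` drops >30% below the slow (30-s) envelope for 10–90 s;
   frequency events where `RF_t` drops >30% below its 30-s upper envelope,
   suppressed wherever the amplitude criterion already holds. Hourly counts
   give RAEI / RFEI per sensor channel.
3. **AHI estimation** — device-specific linear models (Amue Link, Xperia,
   iPhone defaults included; refit with `fit_device_model`) map the four
   indices to a respiratory event index (REI), classified into
   no-SA / mild / moderate / severe with device-specific cutoffs.
4. **Concordance** — breath-by-breath matching of detected events against
   reference annotations on a nadir-segmented time axis with a one-breath
   gap tolerance, plus 2×2 metrics, macro-F1, Bland-Altman and ROC/AUC.
5. **Simulation** — quasi-sinusoidal breathing with cycle jitter, amplitude
   drift, scheduled apnea/hypopnea/frequency-only events, posture rotations
   and out-of-band contaminants, fully deterministic per seed.

## CLI

```bash
# generate a synthetic night with ground truth
imusa simulate --preset moderate_sa --duration 3600 --seed 7 \
    --out rec.csv --truth truth.csv --nadirs nadirs.csv

# detect respiratory events and compute RAEI/RFEI
imusa detect --recording rec.csv --out events.csv --indices indices.yaml

# estimate AHI (REI) and severity from the indices
imusa estimate-ahi --indices indices.yaml --device xperia

# breath-by-breath concordance vs the reference annotations
imusa evaluate --events events.csv --reference truth.csv \
    --breaths nadirs.csv --gap 1 --report report.yaml
```

Recordings are plain CSV (`t,ax,ay,az,gx,gy,gz`) with a `#`-prefixed YAML
header (device, sampling rate, units, start offset); annotations are CSV
(`onset_s,duration_s,type`); device models are YAML.

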