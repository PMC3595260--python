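# speecherp

Dual-locked ERP analysis of speech-production EEG.

When someone names a picture aloud, the interesting brain events are not
only those that follow the stimulus — they are the ones that *precede the
act of speaking*. `speecherp` implements the complete analysis chain for
studying word production time-locked both to stimulus presentation and to
vocal onset:

* **EMG-robust preprocessing** — zero-phase 0.16 Hz high-pass,
  regression-based ocular correction (EOG propagation factors estimated
  after removing the event-locked average), and blind source separation by
  canonical correlation (**BSS-CCA**) between the signal and its one-sample
  delay, applied on non-overlapping 1.5 s windows. Components whose average
  spectral power in the EMG band (15–30 Hz) reaches **1/5** of the power in
  the EEG band (0–15 Hz) are removed, targeting the articulation bursts
  that otherwise bury everything near vocal onset.
* **Surface Laplacian (CSD)** — spherical-spline interpolation (spline
  degree m = 3, 15 Legendre terms, 10 cm head sphere) with analytic
  evaluation of the negative surface Laplacian, in µV/cm²; reference-free
  and spatially sharpening.
* **Component statistics** — global field power (spatial SD across
  channels), data-driven analysis windows at the fastest GFP increases,
  per-subject regression slopes t-tested against zero, per-subject peak
  latencies inside a 100 ms grand-average-defined window on 40 ms-smoothed
  data, baseline-independent peak-to-peak *surface* amplitudes, and
  latency–RT correlation plus grouped regression.
* **Distributed source estimation** — depth-weighted minimum norm on an
  800-dipole envelope lattice with signal-subspace-correlation (subcorr)
  weighting, baseline noise covariance, and an empirical null: source
  amplitudes pooled over all dipoles and baseline samples define a
  quantile threshold (α = 0.001) for flagging post-event activity.
* **A synthetic speech-EEG generator** — 64-channel Biosemi-style montage
  at 512 Hz, three-shell spherical forward model, stimulus- and
  response-locked dipolar sources, truncated-normal reaction times
  (mean 651 ms, SD 72 ms, 1500 ms deadline), articulation EMG bursts
  straddling vocal onset, blinks, and 1/f background — with full ground
  truth, so every stage of the chain is testable end to end without any
  recordings.

The core minimum-norm solution is `J = W Gᵀ (G W Gᵀ + λC)⁻¹ d`, with
per-source weights `W` combining depth weighting `‖g_s‖^(−γ)` (γ = 0.5)
and the subcorr of each source's whitened forward field with the data's
principal subspace.

## Worked example

```python
import numpy as np
from speecherp import (HeadModel, build_montage, simulate_recording,
                       highpass, ocular_correct, remove_emg, select_trials,
                       epoch, reject_artifacts, average, csd_transform)
from speecherp.synth import ArtifactSpec, TrialSchedule, default_sources

montage = build_montage("biosemi64", r_head_cm=10.0)
head = HeadModel()
schedule = TrialSchedule(n_trials=100, seed=42)
rec, events, truth = simulate_recording(
    montage, head, default_sources(montage, head), ArtifactSpec(), schedule)
print(f"simulated {rec.duration_s:.0f} s of 68-channel EEG, "
      f"mean RT {np.nanmean(truth.rts_ms):.0f} ms")

rec = highpass(rec, 0.16)
rec, factors = ocular_correct(rec, events=events)
rec, report = remove_emg(rec, window_s=1.5, ratio_threshold=0.2)
print(f"BSS-CCA processed {len(report)} windows, "
      f"removed {report.n_components_removed.mean():.1f} components/window")

good = select_trials(events)
ep = reject_artifacts(epoch(rec, good, "response"))
csd = csd_transform(average(ep), montage)
fcz = csd.channel("FCz")
print(f"retained {ep.n_retained}/{ep.n_trials} trials; response-locked "
      f"FCz CSD peaks {abs(csd.times_ms[np.argmin(fcz)]):.0f} ms before "
      f"vocal onset ({fcz.min():.2f} µV/cm²)")
```

prints

```
simulated 252 s of 68-channel EEG, mean RT 644 ms
BSS-CCA processed 169 windows, removed 56.8 components/window
retained 66/99 trials; response-locked FCz CSD peaks 256 ms before vocal onset (-0.81 µV/cm²)
```

The generator places a fronto-medial source peaking 250 ms
before vocal onset; after filtering, ocular correction, window-wise EMG
removal, rejection, averaging and the Laplacian transform, the measured
peak lands at −256 ms — the response-locked pipeline recovers what the
stimulus-locked average would smear out by the ~72 ms reaction-time
jitter.

The same chain is available from the shell:

```bash
speecherp simulate --seed 42 --n-trials 100 --out subj01
speecherp clean-emg subj01/recording.edf --out subj01_clean.edf
speecherp preprocess subj01_clean.edf subj01/events.tsv --out subj01_pre
speecherp run-all --seed 7 --out results/ --set n_subjects=12
```

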