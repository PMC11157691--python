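# opmloop

Real-time, model-based magnetic field correction for wearable OPM-MEG,
as a desk-scale simulation and analysis package.

## The problem

Zero-field optically pumped magnetometers (OPMs) only work in a narrow
field range: their output clips ("saturates") at a residual field of
roughly ±1.5 nT, and their gain degrades well before that.  Inside a
magnetically shielded room the background field is a few nT and varies
with position, so a participant wearing an OPM array who walks around
drives the sensors out of range — large head movements and MEG have been
mutually exclusive.

A fix is to null the field *at each sensor* in real time using the
electromagnetic coils already on board each OPM.  Instead of one control
loop per channel, the array-wide interference is modelled with low-order
regular solid harmonics — in the simplest form a spatially **homogeneous
field** `B = [Bx, By, Bz]` — and the model prediction is fed back to
every coil.  This is homogeneous field correction (HFC) run in a closed
loop.

## The model

For a rigid array whose channel *i* has unit orientation `ρ_i`, a
homogeneous background couples as `y_i = B·ρ_i`.  Stacking orientations
into `N` (channels × 3) gives `Y = N B`, so the field estimate is
`B = N⁺ Y` (Moore–Penrose pseudo-inverse).  Two projectors follow:

* **feedback**: `M N⁺` predicts the interference at the feedback-coil
  orientations `M` (a row subset of `N` here) — the field to cancel;
* **denoising**: `I − N N⁺` removes the modelled interference from
  recorded data offline (and must also be applied to forward-model lead
  fields).

Because the array is rigid, both matrices are constant in the array
frame no matter how the head moves.  An optional order-2 basis appends
the five traceless-symmetric linear-gradient terms.

The closed loop mirrors the real acquisition chain: 6 kHz sampling in
60-sample (10 ms) chunks, chunk averaging (a moving-average filter with
its −3 dB point at 44 Hz), `u = y + previous feedback` to estimate the
uncorrected field, projection through `M N⁺`, an optional 1 Hz low-pass
(4th-order Butterworth as two streaming transposed-direct-form-II
biquads), per-axis DAC quantization (LSB 1.8/3.1 pT for Y/Z), and
command timing with ~41 ms loop lag, ≤3 ms jitter, occasional 15 ms
serial overruns, and a 5 ms Y→Z stagger.  Sensors are simulated with
`y = G(e·ρ + B_neural) + noise`, hard clipping, and 3% nearest-neighbour
coil cross-talk.

Performance is judged by the median shielding factor

```
mSF(f) = 20 log10( median_ch ASD_feedback-off / median_ch ASD_feedback-on )
```

with Welch amplitude spectral densities over 20 s segments, and by the
evoked-response pipeline (saturation rejection, 2–40 Hz band,
−200..+500 ms epochs, one-sample t over trials, SNR = squared peak t in
95–105 ms).

## Worked example

```python
import numpy as np
import opmloop as o
from opmloop.scenario_generator import default_room_field, make_field, make_walk
from opmloop.artifact_detection import detect_saturation, reject_trials, trial_windows

array = o.make_helmet_array(17, feedback="all")       # 34 channels
field = make_field(default_room_field(drift_seed=11)) # <2 nT centre, ~3.5 nT front
traj  = make_walk(100.0, seed=2)                      # 0.5 m/s loop, 120 Hz

for fb in (False, True):
    res = o.simulate_closed_loop(array, field, trajectory=traj,
                                 seed=4, feedback_on=fb, store_truth=False)
    rep = detect_saturation(res.recorded)
    wins = trial_windows(np.arange(1.0, 98.0, 0.5), 6000.0,
                         n_samples=res.recorded.n_samples)
    kept = reject_trials(wins, rep)
    print(f"feedback {'on ' if fb else 'off'}: "
          f"{kept.sum()}/{len(kept)} trials unsaturated")
```

prints

```
feedback off: 72/194 trials unsaturated
feedback on : 194/194 trials unsaturated
```

i.e. without feedback roughly two thirds of the 0.7 s trials contain at
least one saturated channel sample (almost all of them while the walker
is more than 0.5 m from the room centre), while with the closed-loop
correction every trial survives.  The same simulations show the
characteristic spectral trade-off: the correction attenuates slow drifts
(positive mSF below 0.2 Hz) but raises the noise floor above ~1 Hz,
because the quantized, delayed feedback injects noise there.

There is also a CLI (`opmloop simulate|hfc|detect-saturation|
classify-trials|evaluate|make-scenario`); see `opmloop --help`.

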