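# Methods

This note documents the models, numerical choices and limitations of
`opmloop`: what is simulated, with which defaults and why, and what the
passing tests do and do not demonstrate about real recordings.

## Interference model and projectors

The background interference across a rigid OPM array is expanded in
gradients of regular solid harmonics.  Order 1 is a spatially
homogeneous field, three parameters `[Bx, By, Bz]`; channel *i* with
unit orientation `ρ_i` sees `y_i = B·ρ_i`, independent of position.
Order 2 appends five linear-gradient terms.  The gradient basis is the
five Cartesian traceless-symmetric tensors

```
G1 = diag(1,−1,0)   G2 = diag(0,1,−1)
G3 = e_x e_y + e_y e_x   G4 = e_x e_z + e_z e_x   G5 = e_y e_z + e_z e_y
```

with basis fields `B_k(r) = G_k r`; symmetry gives zero curl, zero trace
gives zero divergence, so each term is a valid source-free magnetostatic
field.  Any five independent traceless-symmetric tensors span the same
space; this set is chosen for readability and is asserted source-free by
finite differences in the tests.

All pseudo-inverses use SVD with a relative singular-value cutoff of
`1e-10·σmax`; directions below the cutoff are dropped with a warning
naming the count, since a degenerate geometry (e.g. coplanar
orientations) should be loud, not silently regularised.  Matrices are
always built in `SensorArray` channel order; the feedback matrix `M` is
the row subset of `N` with `feedback=True`, in the same order.

Saturated samples are not imputed; the model fit can optionally exclude
mostly-saturated channels per tick
(`LoopConfig.exclude_saturated_from_fit`), but the default includes all
channels — the simplest reading of how a real-time system would behave,
since the controller has no saturation oracle.

## Streaming DSP

The controller's 1 Hz low-pass is a 4th-order Butterworth factored into
two biquads in transposed direct form II, stepped one sample per call
with persistent per-channel state; streaming output is bit-identical to
batch `sosfilt`.  Section pairing/ordering follows scipy's nearest-pole
pairing (the lower-Q section first); the choice affects internal state
trajectories, not outputs.  The filter runs at the 100 Hz chunk rate: the
commanded signal only exists once per chunk, so filtering the 6 kHz
stream would be vacuous for the output path.  By default only the model
*output* is filtered (`filter_stage="output"`); input or both are
configurable, since both arrangements were plausible in the original
hardware and the data cannot distinguish them here.

Chunk averaging of 60 samples at 6 kHz acts as a moving-average filter
with magnitude `|sin(πfn/fs)/(n sin(πf/fs))|`; its −3 dB point, found by
bisection to 0.01 Hz, rounds to 44 Hz.

## Closed-loop plant

Per 10 ms chunk: the sensor chunk mean `y` is added to the per-channel
intended feedback currently in effect (`u = y + prev_feedback` — the
controller's estimate of the uncorrected field; it deliberately uses the
*intended* quantized value, not the cross-talk-corrupted actual field,
which it cannot observe), projected through `M N⁺`, filtered, quantized
per axis, and scheduled.  Commands are zero-order holds (DAC behaviour).
Timing defaults: total loop lag 41 ms measured from the *start* of the
chunk (i.e. including the 10 ms accumulation — the decomposition is not
observable, so the config exposes the total and the chunk length
separately); uniform jitter in [0, 3] ms; with probability 0.19 an extra
15 ms serial-link overrun; Y-axis commands precede Z-axis commands by
5 ms; per-axis command order is never allowed to invert.

Sensor model: `y = G(e·ρ + B_neural) + noise`, hard-clipped at the
saturation limit (default 1.5 nT, per-channel jitter optional).  Gain is
linear by default with a `gain_fn` hook for field-dependent gain (the
hardware gain is nonlinear near saturation but no standard formula
exists).  White noise defaults to 15 fT/√Hz, a typical OPM floor.
Quantization rounds half away from zero and clips to the 16-bit DAC
range; LSBs default to 1.8 pT (Y) and 3.1 pT (Z).  Cross-talk: 3% of a
coil's field is added to the nearest other OPM's same-axis channel.
Initial on-sensor nulling is modelled as perfect zeroing of the t=0
field; all feedback rides on top of it.  The unmeasured laser (X) axis
carries no channels and receives no feedback.

With noise, quantization and clipping disabled the plant is linear
(superposition holds to rounding), and
`recorded + G·applied_feedback = G·(true_background + neural)` wherever
unsaturated — both are asserted in tests.

## Synthetic scenarios

The emulated room has a 3 m × 4 m footprint (x = width, y = depth with
+y the "front", z = up).  The static field is a homogeneous offset
(~0.5 nT) plus the symmetric-traceless gradient
`diag(−0.75, 1.5, −0.75) nT/m`, giving <2 nT within 0.5 m of the centre
and ~3.5 nT at the front wall — the regime in which an uncorrected
walker saturates away from the centre.  The slow drift is a per-component
band-limited random walk: white noise low-passed at 0.2 Hz and scaled to
150 pT per component.  The real room's drift spectrum is only known
qualitatively (slow, hundreds of pT, power below ~0.5 Hz), so these are
free choices fixed once and documented, not calibrated to any recording.

Walking is a rounded-rectangle loop through the front half of the room
traversed at 0.5 m/s on a periodic arc-length-parameterised cubic
spline, heading aligned with travel, sampled at 120 Hz; optional
tracking dropouts are injected where the path strays >1.2 m from the
centre, emulating marker loss near walls.  Gap filling uses linear
interpolation for gaps <0.2 s and shape-preserving piecewise-cubic
(PCHIP) for longer ones; quaternions are nlerp-ed and renormalised;
boundary gaps stay unfilled.

The auditory stream is a roving oddball: sets of identical tones with
lengths drawn from weights 2.5/2.5/2.75/2.75 (%) for 1–4 and 12.5% each
for 5–11 (printed weights total 98% and are renormalised), frequencies
uniform on {500..800} Hz in 50 Hz steps with consecutive sets forced
distinct, inter-stimulus interval exactly 0.5 s.  Expected set length is
≈7.4, so 80 deviants yield ≈590 tones per block.

The evoked stand-in is a Gaussian-envelope deflection (σ = 18 ms)
peaking 100 ms after onset, 100 fT at the best channel, with a bilateral
signed topography generated by two opposite-polarity point dipoles near
the ears.  `make_brain_noise` adds per-channel band-limited (<40 Hz)
background activity, default 150 fT/√Hz, emulating the ongoing brain and
residual environmental noise that dominates trial variance in real
recordings; without it the synthetic trial variance would be
unrealistically dominated by sensor noise alone.

What the generator does *not* emulate: cross-axis projection error,
calibration drift, gain nonlinearity (unless supplied), mechanical
vibration, cable artifacts, and any realistic drift spectrum.  Passing
tests therefore demonstrate the correctness and qualitative behaviour of
the control loop and analysis chain under the stated assumptions, not
quantitative performance in any particular room.

## Saturation detection

Each channel's block is histogrammed by amplitude in 1 pT bins anchored
at the data min/max (empty interior bins count as zero).  If the
outermost 5 bins at either end hold strictly more than double the count
of the adjacent 5 bins, those amplitudes are marked saturated; samples
in marked ranges are flagged.  Two guards: (i) amplitudes below 1 nT can
never be marked — applied to the marking decision itself, since the
sparse extreme bins of a perfectly Gaussian channel (counts of 0–2)
would otherwise trip the count rule; (ii) channels with fewer than 50
occupied bins (including constant channels) are skipped with a warning,
because the tail comparison is undefined there.  "Exactly double" does
not mark.  The detector is by construction invariant to time
permutation, and adding clipped mass never un-marks a range.

Trial rejection removes any epoch in which any channel has a flagged
sample.  Position classification labels a trial "outside" if any
trajectory sample in its window exceeds the 0.5 m radius horizontally,
with short-gap (<0.2 s) interpolated positions trusted and longer-gap
positions forced to "outside".

## Evaluation

Welch ASDs use Hann windows, 50% overlap, mean averaging, 20 s segments
(0.05 Hz grid) — segment length is stated by the procedure, the rest are
conventional defaults.  The shielding factor applies `20·log10` to the
ratio of channel-median *amplitude* spectral densities, consistent with
the fT/√Hz convention of OPM noise plots; a `power=True` switch gives
`10·log10` on power densities.  The uncertainty band propagates the
standard error of each median (≈1.2533 σ/√n) to the dB ratio.  The
median is taken over channels of each condition first, then the ratio.

The evoked pipeline decimates to 1 kHz, applies band-stops at 50, 120
and 83 Hz (half-width 2 Hz — the notch width is a package choice), a
2 Hz high-pass and 40 Hz low-pass, all 5th-order Butterworth run
forward-backward (zero phase); epochs span −200..+500 ms; no baseline
correction by default (the 2 Hz high-pass serves that role; pre-stimulus
mean subtraction is available).  The one-sample t uses a relative
zero-variance guard (`sd ≤ 1e-10·|mean|` → NaN, flagged) because
bit-identical trials leave rounding-level variance.  SNR change is
`100(max t_b² − max t_a²)/max t_a²` with the max over channels and time
in 95–105 ms.  Source time courses are `X = L⁺Y` from user-supplied lead
fields, which must be HFC-projected first via `correct_lead_fields`.

## Problem sizes used in the tests

The session-scoped end-to-end simulations are a 160 s stationary drift
run on a 42-channel array (feedback to 22 channels) and a pair of 100 s
walking runs (feedback off/on) on a 34-channel array; these sizes give
~15 Welch segments at 0.05 Hz resolution and ~190 auditory trials while
keeping the full suite to a couple of minutes.  The drift run reproduces
the spectral trade-off (mSF > 0 below 0.2 Hz, < 0 above 1 Hz); the
walking pair reproduces the order-of-magnitude reduction in saturated
trials outside the central 0.5 m and the trial-count-driven evoked SNR
gain.

## Known limitations

* The real-time correction is not exactly a projector on the recorded
  data (per-axis staggered, quantized, delayed commands), so offline
  HFC plus lead-field correction is only an approximation to undoing it.
* Order-2 feedback requires coil geometry able to realise gradient
  fields per sensor, which on-board coils approximate only locally; the
  simulator applies commanded fields per channel and does not model coil
  field inhomogeneity beyond the cross-talk coefficient.
* Cross-talk uses a single nearest-neighbour coefficient, not a measured
  matrix.
* The walking field scenario is static-plus-drift; moving ferromagnetic
  sources or vibration-induced field modulation are not modelled.
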