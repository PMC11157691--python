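"""Closed-loop plant simulation of the real-time field-correction system.

The simulated control loop mirrors the acquisition hardware: sensors are
sampled at 6 kHz and consumed in 60-sample (10 ms) chunks; each chunk is
averaged to one reading vector ``y``; the controller forms
``u = y + previous feedback`` (its estimate of the field had no feedback
been applied), projects it through ``M pinv(N)`` to get the desired
per-coil nulling field, optionally low-pass filters it at 1 Hz, quantizes
it to the coil DAC resolution, and schedules the commands: the radial (Y)
axes are updated first and the tangential (Z) axes 5 ms later, each after
a transport latency with jitter and occasional serial-link overruns.
Commands act as a zero-order hold until the next update.

The sensor model is a simplified signal equation
``y = G (e . rho + B_neural) + e_OPM`` with hard clipping at the
saturation limit (~1.5 nT), per-channel white noise, 16-bit DAC
quantization, and nearest-neighbour coil cross-talk.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .harmonic_model import Projector, SensorArray, _pinv_reporting
from .realtime_dsp import BiquadCascade, design_lowpass
from .recording import Recording

__all__ = [
    "OPMChannelModel",
    "TimingModel",
    "LoopConfig",
    "ControllerState",
    "SimResult",
    "quantize",
    "opm_forward",
    "controller_tick",
    "simulate_closed_loop",
]

DAC_HALF_RANGE = 2 ** 15  # 16-bit DAC: commands clip at +/- 2^15 LSB


@dataclass
class OPMChannelModel:
    """Sensor/coil model of one OPM channel population.

    Parameters
    ----------
    gain : float
        Unitless OPM gain (default 1.0).  ``gain_fn`` may supply a
        field-dependent gain instead; it receives the residual field (T)
        and returns the gain (the hardware gain is nonlinear at large
        fields, but no standard formula exists, so the default is linear).
    saturation_limit : float
        Hard clipping level in tesla (default 1.5 nT).
    saturation_jitter_sd : float
        Per-channel spread of the clipping level (the real limit varies
        between sensors); 0 disables.
    white_noise_asd : float
        Sensor white-noise amplitude spectral density in T/sqrt(Hz)
        (default 15 fT/sqrt(Hz)); per-sample sd is
        ``asd * sqrt(sample_rate / 2)``.
    lsb_y, lsb_z : float
        Coil DAC least-significant-bit field step per axis (tesla).
    crosstalk_coeff : float
        Fraction of a coil's field seen by the nearest neighbouring OPM's
        same-axis channel (default 3%).
    """

    gain: float = 1.0
    gain_fn: object = None
    saturation_limit: float = 1.5e-9
    saturation_jitter_sd: float = 0.0
    white_noise_asd: float = 15e-15
    lsb_y: float = 1.8e-12
    lsb_z: float = 3.1e-12
    crosstalk_coeff: float = 0.03

    def __post_init__(self) -> None:
        if self.saturation_limit <= 0:
            raise ValueError("saturation_limit must be positive")
        if not 0 <= self.crosstalk_coeff < 1:
            raise ValueError("crosstalk_coeff must be in [0, 1)")
        if self.lsb_y <= 0 or self.lsb_z <= 0:
            raise ValueError("lsb must be positive")

    def sample_noise_sd(self, sample_rate: float) -> float:
        """Per-sample white-noise standard deviation (T) at a given rate."""
        return self.white_noise_asd * np.sqrt(sample_rate / 2.0)


@dataclass
class TimingModel:
    """Timing of the command path.

    ``base_latency_ms`` is the total loop lag from the *start* of a chunk
    to its commands taking effect, and therefore includes the 10 ms chunk
    accumulation itself (total ~41 ms for the defaults).  Per tick a
    uniform jitter in ``[0, jitter_max_ms]`` is added, plus an extra
    ``overrun_extra_ms`` with probability ``overrun_prob`` (the serial
    link occasionally receives a command before the previous one has been
    processed).  Y-axis commands go out first; Z-axis commands follow
    after ``axis_stagger_ms``.
    """

    update_interval_ms: float = 10.0
    axis_stagger_ms: float = 5.0
    base_latency_ms: float = 41.0
    jitter_max_ms: float = 3.0
    overrun_extra_ms: float = 15.0
    overrun_prob: float = 0.19

    def __post_init__(self) -> None:
        for name in ("update_interval_ms", "axis_stagger_ms", "base_latency_ms",
                     "jitter_max_ms", "overrun_extra_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.overrun_prob <= 1:
            raise ValueError("overrun_prob must be in [0, 1]")

    @classmethod
    def ideal(cls) -> "TimingModel":
        """Zero-latency, jitter-free timing (commands act at chunk end)."""
        return cls(base_latency_ms=10.0, axis_stagger_ms=0.0,
                   jitter_max_ms=0.0, overrun_prob=0.0)


@dataclass
class LoopConfig:
    """Full configuration of the closed-loop plant."""

    sample_rate: float = 6000.0
    chunk_size: int = 60
    filter_cutoff_hz: float | None = 1.0
    filter_order: int = 4
    filter_stage: str = "output"      # "output", "input", "both", "none"
    model_order: int = 1
    opm: OPMChannelModel = field(default_factory=OPMChannelModel)
    timing: TimingModel = field(default_factory=TimingModel)
    enable_noise: bool = True
    enable_quantization: bool = True
    enable_clipping: bool = True
    exclude_saturated_from_fit: bool = False

    def __post_init__(self) -> None:
        if self.filter_stage not in ("output", "input", "both", "none"):
            raise ValueError("filter_stage must be output/input/both/none")

    @property
    def chunk_rate(self) -> float:
        """Controller update rate in Hz (100 Hz for the defaults)."""
        return self.sample_rate / self.chunk_size


def quantize(value, lsb: float):
    """Quantize field values to integer DAC steps.

    Rounds to the nearest multiple of ``lsb`` (ties rounded half away
    from zero) and clips to the 16-bit command range ``+/- 2^15 lsb``.
    The quantization error is bounded by ``lsb/2`` and for well-exercised
    inputs has RMS ``lsb / sqrt(12)``.
    """
    if lsb <= 0:
        raise ValueError("lsb must be positive")
    v = np.asarray(value, dtype=float)
    steps = np.sign(v) * np.floor(np.abs(v) / lsb + 0.5)
    steps = np.clip(steps, -DAC_HALF_RANGE, DAC_HALF_RANGE)
    out = steps * lsb
    return float(out) if np.isscalar(value) else out


def opm_forward(model: OPMChannelModel, residual_field, orientation,
                neural: float = 0.0, rng: np.random.Generator | None = None,
                sample_rate: float = 6000.0):
    """Simplified OPM signal equation for one channel and one sample.

    ``y = G (e . rho + B_neural) + e_OPM`` followed by hard clipping at
    the saturation limit.

    Returns
    -------
    (y, saturated) : (float, bool)
    """
    orientation = np.asarray(orientation, dtype=float)
    if abs(np.linalg.norm(orientation) - 1.0) > 1e-9:
        raise ValueError("orientation must be a unit vector")
    proj = float(np.dot(np.asarray(residual_field, dtype=float), orientation))
    gain = model.gain if model.gain_fn is None else float(model.gain_fn(proj))
    y = gain * (proj + neural)
    if rng is not None:
        y += rng.normal(0.0, model.sample_noise_sd(sample_rate))
    limit = model.saturation_limit
    saturated = abs(y) > limit
    if saturated:
        y = np.sign(y) * limit
    return float(y), bool(saturated)


@dataclass
class ControllerState:
    """Mutable state of the feedback controller between ticks.

    ``prev_feedback`` holds the per-channel *intended* feedback currently
    in effect (the quantized, filtered value the controller commanded —
    the controller cannot observe cross-talk), so that
    ``u = chunk mean + prev_feedback`` estimates the uncorrected field.
    """

    n_channels: int
    prev_feedback: np.ndarray = field(init=False)
    u: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.prev_feedback = np.zeros(self.n_channels)
        self.u = np.zeros(self.n_channels)


@dataclass
class Command:
    """One scheduled per-axis coil update."""

    effect_sample: int
    fb_slots: np.ndarray     # indices into the feedback-channel list
    values: np.ndarray       # intended coil fields (T)


def controller_tick(state: ControllerState, proj: Projector,
                    filt: BiquadCascade | None, timing: TimingModel,
                    chunk_mean: np.ndarray, *, opm: OPMChannelModel,
                    chunk_end_time: float, sample_rate: float,
                    rng: np.random.Generator,
                    enable_quantization: bool = True,
                    fit_mask: np.ndarray | None = None) -> list[Command]:
    """One controller update: estimate, project, filter, quantize, schedule.

    Parameters
    ----------
    chunk_mean : ndarray (n_channels,)
        Mean sensor reading of the most recent complete chunk.
    fit_mask : ndarray of bool, optional
        Channels to include in the model fit (True = keep).  When given
        and not all-True, the projector is re-derived from the masked
        basis for this tick (used to exclude saturated channels).

    Returns
    -------
    list of Command
        Y-axis and Z-axis command batches with their effect samples.
    """
    array = proj.array
    state.u = chunk_mean + state.prev_feedback
    if fit_mask is not None and not fit_mask.all():
        coeff = _pinv_reporting(proj.N[fit_mask]) @ state.u[fit_mask]
        desired = proj.M @ coeff
    else:
        desired = proj.feedback_matrix @ state.u
    if filt is not None:
        desired = filt.step(desired)

    fb_idx = array.feedback_indices
    if enable_quantization:
        vals = desired.copy()
        for axis, lsb in (("Y", opm.lsb_y), ("Z", opm.lsb_z)):
            sel = np.array([array.axes[g] == axis for g in fb_idx])
            if sel.any():
                vals[sel] = quantize(desired[sel], lsb)
    else:
        vals = desired

    jitter = rng.uniform(0.0, timing.jitter_max_ms) if timing.jitter_max_ms else 0.0
    overrun = timing.overrun_extra_ms if (
        timing.overrun_prob and rng.uniform() < timing.overrun_prob) else 0.0
    delay = (timing.base_latency_ms - timing.update_interval_ms
             + jitter + overrun) / 1000.0
    delay = max(delay, 0.0)

    commands = []
    for axis, extra in (("Y", 0.0), ("Z", timing.axis_stagger_ms / 1000.0)):
        sel = np.flatnonzero([array.axes[g] == axis for g in fb_idx])
        if sel.size == 0:
            continue
        t_eff = chunk_end_time + delay + extra
        commands.append(Command(
            effect_sample=int(np.ceil(t_eff * sample_rate - 1e-9)),
            fb_slots=sel, values=vals[sel]))
    return commands


@dataclass
class SimResult:
    """Output of a closed-loop simulation, with ground truth.

    ``recorded`` is what the OPMs output (noise, quantized feedback and
    clipping included; its saturation mask is the *true* clip mask).
    ``true_background`` is the projected background each channel would
    have seen with no feedback, after the initial on-sensor nulling.
    Wherever no channel is saturated and noise is off,
    ``recorded + gain * applied_feedback == gain * (true_background + neural)``.
    """

    recorded: Recording
    applied_feedback: np.ndarray
    true_background: np.ndarray | None
    saturation_truth: np.ndarray
    commands: np.ndarray          # (n_ticks, n_feedback) intended commands
    tick_times: np.ndarray
    config: LoopConfig
    seed: int


def _interp_trajectory(traj, times: np.ndarray):
    """Rigid-motion resampling: positions (linear) and rotation matrices
    (slerp) of the array frame at the requested times."""
    from scipy.spatial.transform import Rotation, Slerp

    if not traj.tracked.all():
        raise ValueError(
            "trajectory has untracked gaps; fill them first (fill_gaps)")
    pos = np.column_stack([
        np.interp(times, traj.times, traj.positions[:, k]) for k in range(3)])
    # scipy uses scalar-last quaternions
    q = traj.quaternions[:, [1, 2, 3, 0]]
    rot = Rotation.from_quat(q)
    slerp = Slerp(traj.times, rot)
    t = np.clip(times, traj.times[0], traj.times[-1])
    return pos, slerp(t).as_matrix()


def simulate_closed_loop(array: SensorArray, field_fn, duration: float | None = None,
                         trajectory=None, neural: np.ndarray | None = None,
                         config: LoopConfig | None = None, seed: int = 0,
                         feedback_on: bool = True,
                         store_truth: bool = True) -> SimResult:
    """Run the full-rate closed-loop simulation.

    Parameters
    ----------
    array : SensorArray
        Rigid channel geometry (positions/orientations in the array frame).
    field_fn : callable
        Background field ``(positions (n,3), times (n,)) -> (n,3)`` in
        tesla, in room coordinates (see :mod:`opmloop.scenario_generator`).
    duration : float, optional
        Simulation length in seconds; defaults to the trajectory span.
    trajectory : Trajectory, optional
        Rigid-body motion of the array through the room; stationary at
        the room centre if omitted.  Must be gap-free.
    neural : ndarray (n_channels, n_samples), optional
        Additive per-channel neural signal in tesla.
    feedback_on : bool
        If False the controller never issues commands (reference run).
    store_truth : bool
        If False, ``true_background`` is not kept (saves memory on long
        runs).

    Notes
    -----
    The initial on-sensor nulling is modelled as perfect zeroing of the
    t=0 per-channel field; the feedback is applied on top of it.  The
    unmeasured X axis carries no channels here by construction of
    ``SensorArray`` (only Y/Z channels exist), matching hardware that
    leaves the X coil in its initialised state.
    """
    config = config or LoopConfig()
    fs, chunk = config.sample_rate, config.chunk_size
    if duration is None:
        if trajectory is None:
            raise ValueError("need duration or trajectory")
        duration = float(trajectory.times[-1]) + 1.0 / trajectory.sample_rate
    n_samples = int(round(duration * fs))
    n_chunks = n_samples // chunk
    n_samples = n_chunks * chunk
    if n_chunks < 1:
        raise ValueError("duration shorter than one chunk")
    times = np.arange(n_samples) / fs
    nch = array.n_channels

    rng = np.random.default_rng(seed)
    noise_rng, timing_rng, sat_rng = rng.spawn(3)

    # --- true projected background per channel, full rate ---------------
    if trajectory is None:
        B_true = np.empty((nch, n_samples))
        for i in range(nch):
            B = field_fn(array.positions[i][None, :], times)
            B_true[i] = B @ array.orientations[i]
    else:
        head_pos, R = _interp_trajectory(trajectory, times)
        B_true = np.empty((nch, n_samples))
        for i in range(nch):
            p = head_pos + np.einsum("tij,j->ti", R, array.positions[i])
            o = np.einsum("tij,j->ti", R, array.orientations[i])
            B = field_fn(p, times)
            B_true[i] = np.einsum("tj,tj->t", B, o)

    null = B_true[:, 0].copy()          # perfect on-sensor zeroing at t=0
    B_true -= null[:, None]

    # --- sensor population ----------------------------------------------
    opm = config.opm
    limits = np.full(nch, opm.saturation_limit)
    if opm.saturation_jitter_sd > 0:
        limits = np.abs(limits + opm.saturation_jitter_sd * sat_rng.standard_normal(nch))
    noise_sd = opm.sample_noise_sd(fs) if config.enable_noise else 0.0

    # --- feedback plumbing ----------------------------------------------
    proj = Projector(array, order=config.model_order)
    fb_idx = array.feedback_indices
    n_fb = fb_idx.size
    crosstalk = _crosstalk_matrix(array, opm.crosstalk_coeff)

    out_filt = in_filt = None
    if config.filter_cutoff_hz is not None and config.filter_stage != "none":
        if config.filter_stage in ("output", "both"):
            out_filt = design_lowpass(config.filter_cutoff_hz, config.chunk_rate,
                                      config.filter_order, n_channels=n_fb)
        if config.filter_stage in ("input", "both"):
            in_filt = design_lowpass(config.filter_cutoff_hz, config.chunk_rate,
                                     config.filter_order, n_channels=nch)

    state = ControllerState(nch)
    coil_levels = np.zeros(n_fb)          # intended coil fields in effect
    actual_levels = np.zeros(nch)         # incl. cross-talk
    pending: list[tuple[int, int, Command]] = []
    tiebreak = 0
    last_effect = {"Y": -1, "Z": -1}

    recorded = np.empty((nch, n_samples))
    applied = np.empty((nch, n_samples))
    sat_mask = np.zeros((nch, n_samples), dtype=bool)
    cmd_log = np.zeros((n_chunks, n_fb))
    gain = opm.gain

    for k in range(n_chunks):
        sl = slice(k * chunk, (k + 1) * chunk)
        chunk_end = (k + 1) * chunk

        # apply scheduled commands falling inside this chunk, in order
        fb_chunk = np.tile(actual_levels[:, None], (1, chunk))
        while pending and pending[0][0] < chunk_end:
            eff, _, cmd = heapq.heappop(pending)
            coil_levels[cmd.fb_slots] = cmd.values
            actual_levels = crosstalk @ coil_levels
            state.prev_feedback[:] = 0.0
            state.prev_feedback[fb_idx] = coil_levels
            local = max(eff - k * chunk, 0)
            fb_chunk[:, local:] = actual_levels[:, None]

        residual = B_true[:, sl] - fb_chunk
        y = residual + (neural[:, sl] if neural is not None else 0.0)
        if opm.gain_fn is not None:
            y = np.asarray(opm.gain_fn(residual)) * y
        else:
            y = gain * y
        if noise_sd > 0:
            y = y + noise_rng.normal(0.0, noise_sd, size=y.shape)
        if config.enable_clipping:
            clipped = np.abs(y) > limits[:, None]
            y = np.clip(y, -limits[:, None], limits[:, None])
            sat_mask[:, sl] = clipped
        recorded[:, sl] = y
        applied[:, sl] = fb_chunk

        if not feedback_on or n_fb == 0:
            continue

        chunk_mean = y.mean(axis=1)
        if in_filt is not None:
            chunk_mean = in_filt.step(chunk_mean)
        fit_mask = None
        if config.exclude_saturated_from_fit and config.enable_clipping:
            frac = sat_mask[:, sl].mean(axis=1)
            if (frac > 0.5).any() and (frac <= 0.5).sum() >= proj.N.shape[1]:
                fit_mask = frac <= 0.5
        cmds = controller_tick(
            state, proj, out_filt, config.timing, chunk_mean, opm=opm,
            chunk_end_time=chunk_end / fs, sample_rate=fs, rng=timing_rng,
            enable_quantization=config.enable_quantization, fit_mask=fit_mask)
        for cmd in cmds:
            axis = array.axes[fb_idx[cmd.fb_slots[0]]]
            # serial link processes commands in order: never reorder an axis
            cmd.effect_sample = max(cmd.effect_sample, last_effect[axis] + 1)
            last_effect[axis] = cmd.effect_sample
            heapq.heappush(pending, (cmd.effect_sample, tiebreak, cmd))
            tiebreak += 1
        full = np.zeros(n_fb)
        full[:] = coil_levels
        for cmd in cmds:
            full[cmd.fb_slots] = cmd.values
        cmd_log[k] = full

    rec = Recording(recorded, fs, list(array.labels), saturation_mask=sat_mask)
    return SimResult(
        recorded=rec,
        applied_feedback=applied,
        true_background=B_true if store_truth else None,
        saturation_truth=sat_mask,
        commands=cmd_log,
        tick_times=(np.arange(n_chunks) + 1) * chunk / fs,
        config=config,
        seed=seed,
    )


def _crosstalk_matrix(array: SensorArray, coeff: float) -> np.ndarray:
    """Map intended coil fields (feedback channels) to actual per-channel
    fields: unity on the coil's own channel plus ``coeff`` on the nearest
    other OPM's same-axis channel."""
    fb_idx = array.feedback_indices
    C = np.zeros((array.n_channels, fb_idx.size))
    for j, g in enumerate(fb_idx):
        C[g, j] = 1.0
        if coeff <= 0:
            continue
        best, best_d = None, np.inf
        for i in range(array.n_channels):
            if array.axes[i] != array.axes[g]:
                continue
            d = np.linalg.norm(array.positions[i] - array.positions[g])
            if 1e-9 < d < best_d:
                best, best_d = i, d
        if best is not None:
            C[best, j] += coeff
    return C
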