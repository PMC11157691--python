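"""Synthetic scenarios: room field, walking participant, stimuli, neural signal.

This module stands in for the magnetically shielded room (MSR), the
walking participant with optical motion capture, and the auditory
roving-oddball paradigm, so that the closed-loop correction can be
exercised end to end on a desk.  Everything is reproducible from
(config, seed).

The emulated MSR has a 3 m x 4 m footprint.  Coordinates: x spans the
3 m width, y the 4 m depth with +y the "front" of the room where the
background field is highest, z is up.  The static background field is a
homogeneous offset plus a linear gradient, chosen so the magnitude stays
under ~2 nT within 0.5 m of the centre and reaches ~3.5 nT at the front,
on top of which rides a slow, spatially homogeneous drift (band-limited
below ~0.5 Hz, hundreds of pT RMS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .harmonic_model import SensorArray

__all__ = [
    "ROOM_HALF_X",
    "ROOM_HALF_Y",
    "DriftSpec",
    "RoomFieldSpec",
    "Trajectory",
    "StimulusSchedule",
    "EvokedTemplate",
    "make_field",
    "make_walk",
    "fill_gaps",
    "make_stimuli",
    "make_neural",
    "make_brain_noise",
    "make_helmet_array",
    "default_room_field",
    "default_waypoints",
]

ROOM_HALF_X = 1.5   # m, half of the 3 m room width
ROOM_HALF_Y = 2.0   # m, half of the 4 m room depth (front at +y)


# --------------------------------------------------------------------------
# Background field
# --------------------------------------------------------------------------
@dataclass
class DriftSpec:
    """Slow, spatially homogeneous environmental drift.

    A band-limited random walk: per-component Gaussian noise generated on
    a coarse grid, low-pass filtered so essentially all power lies below
    ``cutoff_hz``, rescaled to ``sd`` per component, and evaluated at
    arbitrary times by cubic interpolation.

    Parameters
    ----------
    sd : float
        Standard deviation per field component in tesla (default 150 pT,
        a typical slow drift scale inside a shielded room).
    cutoff_hz : float
        Low-pass corner of the drift spectrum (default 0.2 Hz).
    duration : float
        Time span (s) the drift process is defined over.
    seed : int
        Seed for the drift realisation.
    """

    sd: float = 150e-12
    cutoff_hz: float = 0.2
    duration: float = 600.0
    seed: int = 0

    def realise(self):
        """Return a callable ``times -> (n, 3)`` drift field in tesla."""
        from scipy import signal as sps

        grid_rate = max(20.0, 40.0 * self.cutoff_hz)
        n = int(np.ceil(self.duration * grid_rate)) + 2
        rng = np.random.default_rng(self.seed)
        raw = rng.standard_normal((n, 3))
        sos = sps.butter(4, self.cutoff_hz, fs=grid_rate, output="sos")
        filt = sps.sosfilt(sos, raw, axis=0)
        # drop the filter transient before normalising
        settle = min(n // 4, int(5 * grid_rate / self.cutoff_hz))
        body = filt[settle:] if n - settle > 10 else filt
        scale = self.sd / body.std(axis=0)
        filt = (filt - body.mean(axis=0)) * scale
        t_grid = np.arange(n) / grid_rate
        spline = CubicSpline(t_grid, filt, axis=0)

        def drift(times):
            t = np.clip(np.asarray(times, dtype=float), 0.0, t_grid[-1])
            return spline(t)

        return drift


@dataclass
class RoomFieldSpec:
    """Static + drifting background field over the room volume.

    ``B(r, t) = offset + gradient @ r + drift(t)``.

    The gradient tensor should be symmetric and traceless for a
    physically realisable (source-free) static field; a warning is issued
    otherwise.  Units: ``offset`` in T, ``gradient`` in T/m.
    """

    homogeneous_offset: np.ndarray = field(
        default_factory=lambda: np.array([0.3e-9, 0.4e-9, 0.2e-9]))
    gradient: np.ndarray = field(
        default_factory=lambda: np.diag([-0.75e-9, 1.5e-9, -0.75e-9]))
    drift: DriftSpec | None = None

    def __post_init__(self) -> None:
        self.homogeneous_offset = np.asarray(self.homogeneous_offset, dtype=float)
        self.gradient = np.asarray(self.gradient, dtype=float)
        if self.homogeneous_offset.shape != (3,) or self.gradient.shape != (3, 3):
            raise ValueError("offset must be (3,), gradient (3, 3)")
        G = self.gradient
        if not np.allclose(G, G.T, atol=1e-15) or abs(np.trace(G)) > 1e-15 * (
            1 + np.abs(G).max()
        ):
            warnings.warn("gradient tensor is not symmetric-traceless; the "
                          "static field is not source-free", stacklevel=2)


def default_room_field(drift_seed: int = 0, drift_sd: float = 150e-12,
                       with_gradient: bool = True) -> RoomFieldSpec:
    """Default emulated-MSR field: <2 nT near the centre, ~3.5 nT at the front."""
    return RoomFieldSpec(
        gradient=np.diag([-0.75e-9, 1.5e-9, -0.75e-9]) if with_gradient
        else np.zeros((3, 3)),
        drift=DriftSpec(sd=drift_sd, seed=drift_seed),
    )


def make_field(spec: RoomFieldSpec):
    """Build the background field function from a room spec.

    Returns
    -------
    field_fn : callable
        ``field_fn(positions, times) -> (n, 3)`` field in tesla, where
        ``positions`` is ``(n, 3)`` or ``(3,)`` and ``times`` is ``(n,)``
        or scalar.  Deterministic given the drift seed.
    """
    drift = spec.drift.realise() if spec.drift is not None else None
    offset = spec.homogeneous_offset
    G = spec.gradient

    def field_fn(positions, times):
        r = np.atleast_2d(np.asarray(positions, dtype=float))
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if r.shape[0] == 1 and t.shape[0] > 1:
            r = np.broadcast_to(r, (t.shape[0], 3))
        out = offset + r @ G.T
        if drift is not None:
            out = out + drift(t)
        return out

    return field_fn


# --------------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------------
@dataclass
class Trajectory:
    """Rigid-body trajectory of the sensor array (head) through the room.

    Quaternions are stored scalar-first ``(qw, qx, qy, qz)`` and unit-norm
    wherever the sample is valid.  ``tracked`` is False where the motion
    system lost the markers; ``interpolated`` marks samples later filled
    by :func:`fill_gaps`, with ``gap_length_s`` recording the duration of
    the gap each filled sample belonged to.
    """

    times: np.ndarray
    positions: np.ndarray
    quaternions: np.ndarray
    tracked: np.ndarray
    interpolated: np.ndarray | None = None
    gap_length_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        self.tracked = np.asarray(self.tracked, dtype=bool)
        n = self.times.shape[0]
        if self.positions.shape != (n, 3) or self.quaternions.shape != (n, 4):
            raise ValueError("positions must be (n, 3), quaternions (n, 4)")
        if self.interpolated is None:
            self.interpolated = np.zeros(n, dtype=bool)
        if self.gap_length_s is None:
            self.gap_length_s = np.zeros(n)
        ok = self.tracked
        norms = np.linalg.norm(self.quaternions[ok], axis=1)
        if ok.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("quaternions must be unit norm where tracked")

    @property
    def sample_rate(self) -> float:
        dt = np.diff(self.times)
        return 1.0 / float(np.median(dt)) if dt.size else 0.0

    def observed(self) -> "Trajectory":
        """Copy with untracked samples blanked (NaN), as the motion-capture
        system would deliver it."""
        pos = self.positions.copy()
        quat = self.quaternions.copy()
        pos[~self.tracked] = np.nan
        quat[~self.tracked] = np.nan
        return replace(self, positions=pos, quaternions=quat)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "time_s": self.times,
            "x_m": self.positions[:, 0],
            "y_m": self.positions[:, 1],
            "z_m": self.positions[:, 2],
            "qw": self.quaternions[:, 0],
            "qx": self.quaternions[:, 1],
            "qy": self.quaternions[:, 2],
            "qz": self.quaternions[:, 3],
            "tracked": self.tracked.astype(int),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            times=df["time_s"].to_numpy(float),
            positions=df[["x_m", "y_m", "z_m"]].to_numpy(float),
            quaternions=df[["qw", "qx", "qy", "qz"]].to_numpy(float),
            tracked=df["tracked"].to_numpy(bool),
        )


def default_waypoints() -> np.ndarray:
    """Rounded-rectangle walking loop through the front half of the room."""
    return np.array([
        [0.0, 0.0],
        [0.9, 0.35],
        [1.0, 0.95],
        [0.6, 1.5],
        [-0.6, 1.5],
        [-1.0, 0.95],
        [-0.9, 0.35],
    ])


def make_walk(duration: float, waypoints: np.ndarray | None = None,
              speed: float = 0.5, sample_rate: float = 120.0,
              height: float = 1.3, seed: int | None = None,
              dropout: str | None = None, dropout_radius: float = 1.2,
              dropout_prob: float = 0.6) -> Trajectory:
    """Smooth looping walk through the room, sampled at motion-capture rate.

    The waypoints (x, y) are closed into a loop with a periodic cubic
    spline parameterised by arc length and traversed at constant speed.
    The heading (rotation about z) is aligned with the direction of
    travel.  With ``dropout="edges"``, tracking-loss segments are
    injected where the path strays beyond ``dropout_radius`` from the
    room centre, emulating marker loss near the walls.

    Parameters
    ----------
    duration : float
        Walk length in seconds.
    speed : float
        Walking speed in m/s; 0 gives a stationary trajectory at the
        first waypoint.
    height : float
        Constant head height in metres.

    Returns
    -------
    Trajectory
        The *true* trajectory (positions present everywhere) with the
        dropout mask set; use :meth:`Trajectory.observed` for what the
        motion system would record.
    """
    times = np.arange(int(round(duration * sample_rate))) / sample_rate
    n = times.size
    if waypoints is None:
        waypoints = default_waypoints()
    waypoints = np.asarray(waypoints, dtype=float)
    if np.any(np.abs(waypoints[:, 0]) > ROOM_HALF_X) or np.any(
            np.abs(waypoints[:, 1]) > ROOM_HALF_Y):
        raise ValueError("waypoints outside the 3 x 4 m room footprint")

    if speed <= 0:
        pos = np.tile(np.r_[waypoints[0], height], (n, 1))
        quat = np.tile([1.0, 0, 0, 0], (n, 1))
        return Trajectory(times, pos, quat, np.ones(n, dtype=bool))

    closed = np.vstack([waypoints, waypoints[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s_knots = np.r_[0.0, np.cumsum(seg)]
    spline = CubicSpline(s_knots, closed, axis=0, bc_type="periodic")
    lap = s_knots[-1]

    s = (speed * times) % lap
    xy = spline(s)
    vel = spline(s, 1) * speed
    yaw = np.arctan2(vel[:, 1], vel[:, 0])
    pos = np.column_stack([xy, np.full(n, height)])
    # rotation about z by yaw, scalar-first quaternion
    quat = np.column_stack([
        np.cos(yaw / 2), np.zeros(n), np.zeros(n), np.sin(yaw / 2)])

    tracked = np.ones(n, dtype=bool)
    if dropout == "edges":
        rng = np.random.default_rng(seed)
        r = np.linalg.norm(pos[:, :2], axis=1)
        far = r > dropout_radius
        # drop a random sub-segment of each excursion beyond the radius
        for i0, i1 in _bool_runs(far):
            if rng.uniform() < dropout_prob and i1 - i0 > 3:
                a = rng.integers(i0, max(i0 + 1, i1 - 2))
                b = rng.integers(a + 1, i1)
                tracked[a:b + 1] = False
    return Trajectory(times, pos, quat, tracked)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs (stop exclusive -> returned as
    inclusive end index)."""
    out = []
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    for a, b in zip(idx[::2], idx[1::2]):
        out.append((int(a), int(b - 1)))
    return out


def fill_gaps(traj: Trajectory, linear_max_s: float = 0.2) -> Trajectory:
    """Fill motion-capture dropouts.

    Gaps shorter than ``linear_max_s`` are filled by linear interpolation
    between the bracketing valid samples; longer gaps by shape-preserving
    piecewise-cubic (PCHIP) interpolation fitted over all valid samples.
    Quaternions are filled by normalised linear interpolation between the
    bracketing valid samples and renormalised.  Filled samples are
    flagged ``interpolated`` with the originating gap duration recorded;
    gaps touching the sequence boundary are left unfilled (still
    untracked) with a warning.
    """
    tracked = traj.tracked
    if tracked.all():
        return replace(traj)
    if not tracked.any():
        raise ValueError("no valid samples to interpolate from")
    times = traj.times
    pos = traj.positions.copy()
    quat = traj.quaternions.copy()
    new_tracked = tracked.copy()
    interp = np.zeros(times.size, dtype=bool)
    gap_len = np.zeros(times.size)
    dt = float(np.median(np.diff(times)))

    valid_idx = np.flatnonzero(tracked)
    pchip = PchipInterpolator(times[valid_idx], traj.positions[valid_idx], axis=0)

    for i0, i1 in _bool_runs(~tracked):
        if i0 == 0 or i1 == times.size - 1:
            warnings.warn("gap at sequence boundary left unfilled", stacklevel=2)
            continue
        length = (i1 - i0 + 1) * dt
        tt = times[i0:i1 + 1]
        ta, tb = times[i0 - 1], times[i1 + 1]
        if length < linear_max_s:
            w = (tt - ta) / (tb - ta)
            pos[i0:i1 + 1] = (1 - w)[:, None] * traj.positions[i0 - 1] \
                + w[:, None] * traj.positions[i1 + 1]
        else:
            pos[i0:i1 + 1] = pchip(tt)
        qa, qb = traj.quaternions[i0 - 1], traj.quaternions[i1 + 1]
        if np.dot(qa, qb) < 0:          # shortest arc
            qb = -qb
        w = ((tt - ta) / (tb - ta))[:, None]
        q = (1 - w) * qa + w * qb
        quat[i0:i1 + 1] = q / np.linalg.norm(q, axis=1, keepdims=True)
        new_tracked[i0:i1 + 1] = True
        interp[i0:i1 + 1] = True
        gap_len[i0:i1 + 1] = length

    return Trajectory(times, pos, quat, new_tracked,
                      interpolated=interp, gap_length_s=gap_len)


# --------------------------------------------------------------------------
# Auditory paradigm
# --------------------------------------------------------------------------
#: Tone frequencies of the roving-oddball stream (Hz).
TONE_FREQS = np.array([500.0, 550, 600, 650, 700, 750, 800])

#: Set-length distribution: lengths 1..11 with printed weights
#: 2.5/2.5/2.75/2.75 then 12.5 each for 5..11 (percent; they total 98 and
#: are renormalised to 1).
SET_LENGTHS = np.arange(1, 12)
SET_WEIGHTS = np.array([2.5, 2.5, 2.75, 2.75] + [12.5] * 7)
SET_WEIGHTS = SET_WEIGHTS / SET_WEIGHTS.sum()


@dataclass
class StimulusSchedule:
    """Tone onset list of a roving-oddball block.

    The stream is a sequence of sets of identical tones; the first tone
    of each set (a frequency change) is the deviant.  Inter-stimulus
    interval is exactly 0.5 s with no jitter.
    """

    onsets: np.ndarray
    tone_freq: np.ndarray
    is_deviant: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.tone_freq = np.asarray(self.tone_freq, dtype=float)
        self.is_deviant = np.asarray(self.is_deviant, dtype=bool)

    @property
    def n_tones(self) -> int:
        return self.onsets.size

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "onset_s": self.onsets,
            "freq_hz": self.tone_freq,
            "deviant": self.is_deviant.astype(int),
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StimulusSchedule":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["onset_s"].to_numpy(float), df["freq_hz"].to_numpy(float),
                   df["deviant"].to_numpy(bool))


def make_stimuli(n_deviants: int = 80, seed: int | None = None,
                 isi: float = 0.5, t_start: float = 1.0) -> StimulusSchedule:
    """Generate a roving-oddball stimulus block.

    ``n_deviants`` sets are generated; each set's length is drawn from
    the weighted distribution over 1..11 (expected length ~7.4, so 80
    deviants give roughly 570-600 tones) and its frequency is drawn
    uniformly from the seven tone frequencies, forced to differ from the
    preceding set.  Onsets are spaced exactly ``isi`` seconds apart.
    """
    if n_deviants < 1:
        raise ValueError("n_deviants must be >= 1")
    rng = np.random.default_rng(seed)
    freqs, deviants = [], []
    prev = None
    for _ in range(n_deviants):
        choices = TONE_FREQS[TONE_FREQS != prev] if prev is not None else TONE_FREQS
        f = float(rng.choice(choices))
        length = int(rng.choice(SET_LENGTHS, p=SET_WEIGHTS))
        freqs.extend([f] * length)
        deviants.extend([True] + [False] * (length - 1))
        prev = f
    n = len(freqs)
    onsets = t_start + isi * np.arange(n)
    return StimulusSchedule(onsets, np.array(freqs), np.array(deviants))


# --------------------------------------------------------------------------
# Neural signal
# --------------------------------------------------------------------------
@dataclass
class EvokedTemplate:
    """Stand-in auditory evoked response (M100-like).

    A Gaussian-envelope deflection peaking ``peak_latency`` seconds after
    tone onset, with a bilateral dipolar field topography generated by
    two equivalent current-dipole-like point sources near the ears (of
    opposite polarity across the midline).  Amplitude is the peak field
    at the best channel.
    """

    peak_latency: float = 0.100   # s
    width: float = 0.018          # s, Gaussian sigma
    amplitude: float = 100e-15    # T at the best channel
    source_offset: float = 0.07   # m, lateral offset of the two sources

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak time course evaluated at times ``t`` (s after onset)."""
        return np.exp(-0.5 * ((t - self.peak_latency) / self.width) ** 2)


def _dipole_field(r: np.ndarray, r0: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Magnetic dipole field (unnormalised) at points r from a dipole at r0."""
    d = r - r0
    dist = np.linalg.norm(d, axis=-1, keepdims=True)
    dist = np.maximum(dist, 1e-3)
    dhat = d / dist
    return (3 * (dhat @ m)[..., None] * dhat - m) / dist ** 3


def spatial_pattern(array: SensorArray, template: EvokedTemplate | None = None
                    ) -> np.ndarray:
    """Signed per-channel weights of the bilateral evoked topography,
    normalised to unit maximum magnitude."""
    template = template or EvokedTemplate()
    off = template.source_offset
    m = np.array([0.0, 1.0, 0.0])
    w = (_dipole_field(array.positions, np.array([+off, 0, -0.02]), m)
         - _dipole_field(array.positions, np.array([-off, 0, -0.02]), m))
    w = np.einsum("ij,ij->i", w, array.orientations)
    return w / np.abs(w).max()


def make_neural(schedule: StimulusSchedule, array: SensorArray,
                template: EvokedTemplate | None = None,
                sample_rate: float = 6000.0,
                duration: float | None = None) -> np.ndarray:
    """Per-channel additive neural signal for a stimulus schedule.

    Each tone adds one instance of the template time course, scaled by
    the fixed per-channel spatial weights.  Returns a
    ``(n_channels, n_samples)`` array in tesla.
    """
    if duration is None:
        duration = (schedule.onsets[-1] if schedule.n_tones else 0.0) + 1.0
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    course = np.zeros(n)
    template = template or EvokedTemplate()
    span = int(round((template.peak_latency + 5 * template.width) * sample_rate))
    for onset in schedule.onsets:
        i0 = int(round(onset * sample_rate))
        if i0 >= n:
            break
        i1 = min(n, i0 + span)
        course[i0:i1] += template.waveform(t[i0:i1] - onset)
    w = spatial_pattern(array, template) * template.amplitude
    return np.outer(w, course)


def make_brain_noise(n_channels: int, n_samples: int, sample_rate: float,
                     asd: float = 150e-15, cutoff_hz: float = 40.0,
                     seed: int | None = None) -> np.ndarray:
    """Ongoing background activity: per-channel band-limited noise.

    Emulates the combined ongoing brain activity and residual
    environmental noise that dominates evoked-response trial variance in
    real recordings.  White Gaussian noise is low-passed at ``cutoff_hz``
    (2nd-order Butterworth) and scaled so its amplitude spectral density
    in the passband is approximately ``asd`` (T/sqrt(Hz), default
    150 fT/sqrt(Hz)).
    """
    from scipy import signal as sps

    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n_samples))
    sos = sps.butter(2, cutoff_hz, fs=sample_rate, output="sos")
    out = sps.sosfilt(sos, white, axis=1)
    return out * asd * np.sqrt(sample_rate / 2.0)


# --------------------------------------------------------------------------
# Synthetic sensor layout
# --------------------------------------------------------------------------
def make_helmet_array(n_opms: int = 17, head_radius: float = 0.10,
                      feedback: int | str = "all",
                      frame: str = "scanner-cast") -> SensorArray:
    """Synthetic dual-axis helmet layout on the upper hemisphere of a head.

    OPMs are placed quasi-uniformly (Fibonacci lattice) on the upper
    half of a sphere of ``head_radius`` metres centred at the origin of
    the array frame.  Each OPM contributes a radial channel (axis tag
    ``"Y"``, oriented along the outward surface normal) and a tangential
    channel (``"Z"``) at the same position.

    Parameters
    ----------
    feedback : int or "all" or "none"
        Number of OPMs with feedback enabled (both channels); an integer
        k enables every other OPM until k are selected, mixing feedback
        and reference sensors over the head as in a split-array noise
        recording.
    """
    if n_opms < 2:
        raise ValueError("need at least 2 OPMs")
    i = np.arange(n_opms)
    golden = (1 + 5 ** 0.5) / 2
    # Fibonacci lattice on the upper hemisphere (z in [0.15, 1])
    z = 0.15 + (1.0 - 0.15) * (i + 0.5) / n_opms
    phi = 2 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1 - z ** 2))
    normals = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    positions = head_radius * normals

    if feedback == "all":
        fb_opms = np.ones(n_opms, dtype=bool)
    elif feedback == "none":
        fb_opms = np.zeros(n_opms, dtype=bool)
    else:
        k = int(feedback)
        if not 0 <= k <= n_opms:
            raise ValueError("feedback count out of range")
        fb_opms = np.zeros(n_opms, dtype=bool)
        order = np.r_[np.arange(0, n_opms, 2), np.arange(1, n_opms, 2)]
        fb_opms[order[:k]] = True

    labels, pos, ori, axes, fb = [], [], [], [], []
    up = np.array([0.0, 0.0, 1.0])
    for j in range(n_opms):
        nrm = normals[j]
        tang = np.cross(up, nrm)
        if np.linalg.norm(tang) < 1e-6:
            tang = np.array([1.0, 0.0, 0.0])
        tang = tang / np.linalg.norm(tang)
        for axis, o in (("Y", nrm), ("Z", tang)):
            labels.append(f"S{j + 1:02d}-{axis}")
            pos.append(positions[j])
            ori.append(o)
            axes.append(axis)
            fb.append(fb_opms[j])
    return SensorArray(labels, np.array(pos), np.array(ori), axes,
                       np.array(fb), frame=frame)
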