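"""Spectral and evoked-response evaluation.

Two families of metrics quantify what the feedback does to the data:

* spectral — Welch amplitude spectral densities (ASD, field/sqrt(Hz))
  over 20 s segments, and the median shielding factor

  ``mSF(f) = 20 log10( median_ch ASD_off(f) / median_ch ASD_on(f) )``

  in dB, positive where the correction reduces noise;

* evoked — the standard sensor-level pipeline: downsample to 1 kHz,
  band-stop / band-pass filtering (zero-phase 5th-order Butterworth),
  epoching around tone onsets (-200..+500 ms), trial averaging with a
  one-sample t-statistic per channel and time point, and an SNR change
  defined as the ratio of squared peak t-statistics in the 95-105 ms
  window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .artifact_detection import trial_windows
from .recording import Recording

__all__ = [
    "PsdResult",
    "EvokedResult",
    "welch_psd",
    "median_shielding_factor",
    "preprocess_evoked",
    "epoch_and_average",
    "snr_ratio",
    "source_timeseries",
]

#: sd of the sample median of n Gaussian-ish draws is ~1.2533 sd/sqrt(n)
MEDIAN_EFFICIENCY = np.sqrt(np.pi / 2.0)


@dataclass
class PsdResult:
    """Welch amplitude spectral density per channel.

    ``psd`` is in field/sqrt(Hz) (amplitude, not power), channels x
    frequencies; the lowest resolvable frequency is 1/segment_length.
    """

    frequencies: np.ndarray
    psd: np.ndarray
    segment_length: float
    labels: list[str] = field(default_factory=list)
    estimator: str = "welch"


def welch_psd(rec: Recording, segment_s: float = 20.0,
              window: str = "hann", overlap: float = 0.5,
              tmin: float | None = None, tmax: float | None = None) -> PsdResult:
    """Welch ASD of a recording over fixed-length segments.

    Parameters
    ----------
    segment_s : float
        Segment length in seconds (default 20, giving a 0.05 Hz grid).
    tmin, tmax : float, optional
        Restrict the estimate to an analysis window (e.g. the period
        with feedback on).
    """
    if tmin is not None or tmax is not None:
        rec = rec.crop(tmin if tmin is not None else rec.t0,
                       tmax if tmax is not None else rec.t0 + rec.duration)
    nper = int(round(segment_s * rec.sample_rate))
    if rec.n_samples < 2 * nper:
        raise ValueError(
            f"recording too short: need >= 2 segments of {segment_s} s")
    f, pxx = signal.welch(rec.data, fs=rec.sample_rate, window=window,
                          nperseg=nper, noverlap=int(round(overlap * nper)),
                          average="mean", detrend="constant", axis=-1)
    keep = f > 0
    return PsdResult(f[keep], np.sqrt(pxx[:, keep]), segment_s, list(rec.labels))


def median_shielding_factor(psd_off: PsdResult, psd_on: PsdResult,
                            power: bool = False):
    """Median shielding factor in dB, with a standard-error band.

    The median over channels is taken of each ASD, then

    ``mSF(f) = 20 log10(median_off / median_on)``

    (or ``10 log10`` of the ratio when ``power=True`` and the inputs are
    interpreted as power rather than amplitude densities).  The band
    propagates the standard error of each median
    (``~1.2533 sd/sqrt(n)``) to the dB ratio.

    Returns
    -------
    frequencies, msf_db, se_db : ndarray
    """
    if psd_off.psd.shape[1] != psd_on.psd.shape[1] or not np.allclose(
            psd_off.frequencies, psd_on.frequencies):
        raise ValueError("frequency grids must match")
    fac = 10.0 if power else 20.0
    med_off = np.median(psd_off.psd, axis=0)
    med_on = np.median(psd_on.psd, axis=0)
    if np.any(med_off <= 0) or np.any(med_on <= 0):
        raise ValueError("zero median spectral density")
    msf = fac * np.log10(med_off / med_on)
    se_off = MEDIAN_EFFICIENCY * psd_off.psd.std(axis=0, ddof=1) / np.sqrt(
        psd_off.psd.shape[0])
    se_on = MEDIAN_EFFICIENCY * psd_on.psd.std(axis=0, ddof=1) / np.sqrt(
        psd_on.psd.shape[0])
    se = fac / np.log(10) * np.sqrt((se_off / med_off) ** 2 + (se_on / med_on) ** 2)
    return psd_off.frequencies, msf, se


@dataclass
class PreprocessConfig:
    """Evoked-pipeline filtering parameters (zero-phase Butterworth)."""

    target_rate: float = 1000.0
    band_stop_hz: tuple = (50.0, 120.0, 83.0)
    band_stop_half_width: float = 2.0
    high_pass_hz: float = 2.0
    low_pass_hz: float = 40.0
    order: int = 5


def preprocess_evoked(rec: Recording, config: PreprocessConfig | None = None
                      ) -> Recording:
    """Downsample and filter a recording for evoked analysis.

    Downsamples to 1 kHz, applies band-stop filters (line noise and
    camera/modulation mixing frequencies), then a 2 Hz high-pass and a
    40 Hz low-pass.  All filters are 5th-order Butterworth applied
    forward-backward (zero phase).  The saturation mask is decimated by
    logical-OR over each decimation window so flagged samples stay
    flagged.
    """
    config = config or PreprocessConfig()
    data, fs, mask = rec.data, rec.sample_rate, rec.saturation_mask
    if fs > config.target_rate:
        q = fs / config.target_rate
        if abs(q - round(q)) > 1e-9:
            raise ValueError("sample rate must be an integer multiple of target")
        q = int(round(q))
        data = signal.decimate(data, q, axis=1, zero_phase=True)
        n = data.shape[1]
        mask = mask[:, :n * q].reshape(mask.shape[0], n, q).any(axis=2)
        fs = config.target_rate
    for f0 in config.band_stop_hz:
        if f0 >= fs / 2:
            continue
        sos = signal.butter(config.order,
                            [f0 - config.band_stop_half_width,
                             f0 + config.band_stop_half_width],
                            btype="bandstop", fs=fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
    sos_hp = signal.butter(config.order, config.high_pass_hz, btype="high",
                           fs=fs, output="sos")
    data = signal.sosfiltfilt(sos_hp, data, axis=1)
    sos_lp = signal.butter(config.order, config.low_pass_hz, btype="low",
                           fs=fs, output="sos")
    data = signal.sosfiltfilt(sos_lp, data, axis=1)
    return Recording(data, fs, list(rec.labels), saturation_mask=mask, t0=rec.t0)


@dataclass
class EvokedResult:
    """Trial-averaged evoked response with per-point t-statistics.

    ``mean`` and ``t_stat`` are channels x time over the epoch window;
    ``t_stat`` is the one-sample t over trials.  Where trial variance is
    zero the t-statistic is undefined and set to NaN (``degenerate`` is
    flagged).
    """

    times: np.ndarray
    mean: np.ndarray
    t_stat: np.ndarray
    n_trials: int
    window: tuple[float, float]
    labels: list[str] = field(default_factory=list)
    degenerate: bool = False


def epoch_and_average(rec: Recording, onsets: np.ndarray,
                      keep: np.ndarray | None = None,
                      window: tuple[float, float] = (-0.2, 0.5),
                      subsample: int | None = None,
                      seed: int | None = None,
                      baseline: bool = False) -> EvokedResult:
    """Epoch a recording around tone onsets and average over trials.

    Parameters
    ----------
    onsets : ndarray
        Tone onset times in seconds.
    keep : ndarray of bool, optional
        Post-rejection trial subset (aligned with ``onsets`` after
        out-of-bounds trials are dropped).
    subsample : int, optional
        Randomly select this many trials (seeded) to equalise counts
        between conditions.
    baseline : bool
        Subtract the pre-stimulus mean per trial and channel (off by
        default — the 2 Hz high-pass serves that role).
    """
    wins = trial_windows(onsets, rec.sample_rate, window, rec.n_samples, rec.t0)
    if keep is not None:
        keep = np.asarray(keep, dtype=bool)
        if keep.size != wins.shape[0]:
            raise ValueError("keep length must match usable trial count")
        wins = wins[keep]
    if wins.shape[0] == 0:
        raise ValueError("no trials to average")
    if subsample is not None and subsample < wins.shape[0]:
        rng = np.random.default_rng(seed)
        wins = wins[np.sort(rng.choice(wins.shape[0], subsample, replace=False))]

    nt = wins[0, 1] - wins[0, 0]
    trials = np.stack([rec.data[:, a:b] for a, b in wins])  # (n_tr, ch, t)
    times = window[0] + np.arange(nt) / rec.sample_rate
    if baseline:
        pre = times < 0
        trials = trials - trials[:, :, pre].mean(axis=2, keepdims=True)
    n = trials.shape[0]
    mean = trials.mean(axis=0)
    degenerate = False
    if n < 2:
        t = np.full(mean.shape, np.nan)
        degenerate = True
    else:
        sd = trials.std(axis=0, ddof=1)
        # identical trials give sd at rounding level, not exactly zero
        zero = sd <= 1e-10 * np.abs(mean)
        if zero.any():
            degenerate = True
            warnings.warn("zero trial variance at some points; t set to NaN",
                          stacklevel=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(zero, np.nan, mean / (sd / np.sqrt(n)))
    return EvokedResult(times, mean, t, n, window, list(rec.labels), degenerate)


def snr_ratio(a: EvokedResult, b: EvokedResult,
              window: tuple[float, float] = (0.095, 0.105)) -> float:
    """Percent SNR change from ``a`` to ``b``.

    SNR is the square of the maximum |t| over channels and time within
    the window (a power ratio); the change is
    ``100 (max t_b^2 - max t_a^2) / max t_a^2``.
    """
    if a.window != b.window:
        raise ValueError("evoked windows must match")

    def peak(e: EvokedResult) -> float:
        sel = (e.times >= window[0]) & (e.times <= window[1])
        return float(np.nanmax(np.abs(e.t_stat[:, sel])))

    ta, tb = peak(a), peak(b)
    return 100.0 * (tb ** 2 - ta ** 2) / ta ** 2


def source_timeseries(L: np.ndarray, evoked: EvokedResult) -> np.ndarray:
    """Least-squares source time courses: ``X = pinv(L) Y``.

    ``L`` is a user-supplied lead-field matrix (channels x sources);
    apply the denoising projector to it first
    (:func:`opmloop.harmonic_model.correct_lead_fields`) if the data were
    HFC-projected.
    """
    L = np.asarray(L, dtype=float)
    if L.shape[0] != evoked.mean.shape[0]:
        raise ValueError("lead-field rows must match evoked channels")
    return np.linalg.pinv(L) @ evoked.mean
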