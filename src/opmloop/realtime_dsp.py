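"""Streaming filters for the feedback loop.

Two pieces of signal processing run inside the real-time loop:

* chunk averaging — the 6 kHz input stream is consumed in 60-sample
  (10 ms) chunks and each chunk is reduced to one mean vector, which both
  sets the 100 Hz controller update rate and acts as a moving-average
  anti-alias filter (first null at 100 Hz, -3 dB near 44 Hz);
* a point-by-point 4th-order Butterworth low-pass on the model output,
  factored into two biquads implemented in transposed direct form II so
  that one sample can be processed per call with persistent state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

__all__ = [
    "BiquadCascade",
    "ChunkBuffer",
    "design_lowpass",
    "chunk_average",
    "moving_average_response",
]


@dataclass
class BiquadCascade:
    """Cascade of second-order sections with per-channel streaming state.

    Coefficients are stored in scipy ``sos`` layout
    ``[b0, b1, b2, a0, a1, a2]`` with ``a0 = 1``.  The delay registers
    (``state``, shape ``(n_sections, 2, n_channels)``) implement the
    transposed direct form II recurrence

    .. code-block:: text

        y  = b0*x + z1
        z1 = b1*x - a1*y + z2
        z2 = b2*x - a2*y

    applied section by section.  Processing is bit-identical to batch
    filtering the same sequence (``scipy.signal.sosfilt`` from zero
    state) one sample at a time.
    """

    sos: np.ndarray
    n_channels: int
    state: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sos = np.atleast_2d(np.asarray(self.sos, dtype=float))
        if self.sos.shape[1] != 6:
            raise ValueError("sos must have 6 columns")
        # stability: poles of every section strictly inside the unit circle
        for sec in self.sos:
            poles = np.roots(sec[3:])
            if np.any(np.abs(poles) >= 1.0):
                raise ValueError("unstable section: pole on/outside unit circle")
        self.state = np.zeros((self.sos.shape[0], 2, self.n_channels))

    @property
    def n_sections(self) -> int:
        return self.sos.shape[0]

    def reset(self) -> None:
        """Zero all delay registers."""
        self.state[:] = 0.0

    def step(self, x: np.ndarray) -> np.ndarray:
        """Process one multichannel sample; updates internal state.

        Parameters
        ----------
        x : ndarray, shape (n_channels,)

        Returns
        -------
        ndarray, shape (n_channels,)
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_channels,):
            raise ValueError(f"expected shape ({self.n_channels},), got {x.shape}")
        if np.isnan(x).any():
            raise ValueError("NaN input would poison the filter state")
        for k in range(self.n_sections):
            b0, b1, b2, _, a1, a2 = self.sos[k]
            z = self.state[k]
            y = b0 * x + z[0]
            z[0] = b1 * x - a1 * y + z[1]
            z[1] = b2 * x - a2 * y
            x = y
        return x

    def response(self, freqs: np.ndarray, sample_rate: float) -> np.ndarray:
        """Complex frequency response at the given frequencies (Hz)."""
        _, h = signal.sosfreqz(self.sos, worN=2 * np.pi * np.asarray(freqs) / sample_rate)
        return h

    def group_delay(self, freq: float, sample_rate: float) -> float:
        """Group delay in seconds at one frequency, by finite phase difference."""
        df = freq * 1e-4 if freq > 0 else 1e-6
        f = np.array([freq - df, freq + df]) if freq > df else np.array([df, 2 * df])
        h = self.response(f, sample_rate)
        dphi = np.angle(h[1] / h[0])
        return float(-dphi / (2 * np.pi * (f[1] - f[0])))


def design_lowpass(cutoff: float, sample_rate: float, order: int = 4,
                   n_channels: int = 1) -> BiquadCascade:
    """Design a Butterworth low-pass as a streaming biquad cascade.

    A 4th-order design factors into two second-order sections; scipy's
    nearest-pole pairing is used, which places the lower-Q section first.
    Magnitude at the cutoff is -3 dB by construction.

    Parameters
    ----------
    cutoff : float
        -3 dB corner frequency in Hz; must be below Nyquist.
    sample_rate : float
        Rate at which :meth:`BiquadCascade.step` will be called (for the
        feedback loop this is the 100 Hz chunk rate).
    order : int
        Filter order (default 4 = two biquads).
    n_channels : int
        Number of independent channels sharing the coefficients.
    """
    if not 0 < cutoff < sample_rate / 2:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={sample_rate / 2} Hz), got {cutoff}"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    return BiquadCascade(sos=sos, n_channels=n_channels)


@dataclass
class ChunkBuffer:
    """Fixed-size accumulation buffer for the controller input.

    Defaults match the acquisition: 60 samples at 6 kHz = 10 ms chunks.
    """

    n_channels: int
    chunk_size: int = 60
    sample_rate: float = 6000.0
    buffer: np.ndarray = field(init=False)
    _filled: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        self.buffer = np.zeros((self.n_channels, self.chunk_size))

    @property
    def chunk_duration(self) -> float:
        """Chunk span in seconds (10 ms for the defaults)."""
        return self.chunk_size / self.sample_rate

    @property
    def full(self) -> bool:
        return self._filled == self.chunk_size

    def push(self, sample: np.ndarray) -> bool:
        """Append one multichannel sample; returns True when full."""
        if self.full:
            raise RuntimeError("buffer full; call chunk_average / reset first")
        self.buffer[:, self._filled] = sample
        self._filled += 1
        return self.full

    def reset(self) -> None:
        self._filled = 0


def chunk_average(buffer: ChunkBuffer | np.ndarray) -> np.ndarray:
    """Arithmetic mean over time of one full chunk, per channel.

    Accepts a full :class:`ChunkBuffer` (which is reset) or a raw
    ``(n_channels, chunk_size)`` array.
    """
    if isinstance(buffer, ChunkBuffer):
        if not buffer.full:
            raise ValueError("chunk buffer not full")
        out = buffer.buffer.mean(axis=1)
        buffer.reset()
        return out
    arr = np.asarray(buffer, dtype=float)
    return arr.mean(axis=-1)


def moving_average_response(n: int, sample_rate: float):
    """Magnitude response and -3 dB corner of an n-sample moving average.

    The chunk-averaging stage behaves as a moving-average filter with

    ``|H(f)| = |sin(pi f n / fs) / (n sin(pi f / fs))|``.

    Parameters
    ----------
    n : int
        Averaging length in samples (>= 1).
    sample_rate : float
        Input sampling rate in Hz.

    Returns
    -------
    gain : callable
        Vectorised ``f -> |H(f)|``.
    minus3db : float or None
        Lowest frequency where the magnitude crosses 1/sqrt(2), solved by
        bisection to 0.01 Hz; None if no crossing exists below Nyquist
        (e.g. ``n = 1``, an all-pass).
    """
    if n < 1:
        raise ValueError("n must be >= 1")

    def gain(f):
        f = np.asarray(f, dtype=float)
        x = np.pi * f / sample_rate
        num = np.sin(n * x)
        den = n * np.sin(x)
        out = np.where(np.abs(den) < 1e-300, 1.0, np.abs(np.divide(
            num, np.where(np.abs(den) < 1e-300, 1.0, den))))
        return np.where(f == 0.0, 1.0, out)

    target = 1.0 / np.sqrt(2.0)
    nyq = sample_rate / 2.0
    if n == 1:
        return gain, None
    # bracket the first downward crossing on a fine grid, then bisect
    grid = np.linspace(0.0, nyq, 20001)
    g = gain(grid)
    below = np.flatnonzero(g < target)
    if below.size == 0:
        return gain, None
    i = below[0]
    lo, hi = grid[i - 1], grid[i]
    f3 = optimize.bisect(lambda f: gain(f) - target, lo, hi, xtol=0.01)
    return gain, float(f3)
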