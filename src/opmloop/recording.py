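"""Multichannel magnetometer recordings.

The :class:`Recording` container holds a uniformly sampled multichannel
time series in tesla, together with the sampling rate, channel labels and
an optional per-sample saturation mask.  All processing modules operate on
this container; file I/O lives in :mod:`opmloop.cli_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording"]


@dataclass
class Recording:
    """A uniformly sampled multichannel magnetic-field time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Field values in tesla.
    sample_rate : float
        Sampling rate in Hz.
    labels : list of str
        Channel labels, one per row of ``data``.
    saturation_mask : ndarray of bool, optional
        True where a sample is flagged as saturated (clipped).  Same shape
        as ``data``.  Defaults to all-False.
    t0 : float
        Time of the first sample in seconds (default 0).
    """

    data: np.ndarray
    sample_rate: float
    labels: list[str] = field(default_factory=list)
    saturation_mask: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.labels:
            self.labels = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.saturation_mask is None:
            self.saturation_mask = np.zeros(self.data.shape, dtype=bool)
        else:
            self.saturation_mask = np.asarray(self.saturation_mask, dtype=bool)
            if self.saturation_mask.shape != self.data.shape:
                raise ValueError("saturation_mask shape must match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with selected fields replaced."""
        return replace(self, **changes)

    def crop(self, tmin: float, tmax: float) -> "Recording":
        """Return the sub-recording with ``tmin <= t < tmax`` (seconds)."""
        t = self.times
        sel = (t >= tmin) & (t < tmax)
        return Recording(
            self.data[:, sel],
            self.sample_rate,
            list(self.labels),
            self.saturation_mask[:, sel],
            t0=float(t[sel][0]) if sel.any() else tmin,
        )
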