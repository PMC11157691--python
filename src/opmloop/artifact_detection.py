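"""Amplitude-histogram saturation detection and trial rejection.

OPM output clips near +/-1.5 nT, but the exact level varies between
sensors, so saturation is detected from the data themselves.  Each
channel's block of samples is histogrammed by amplitude in 1 pT bins
(time order is irrelevant).  Unsaturated data are approximately Gaussian
with monotonically decaying tails; clipping piles probability mass onto
the extreme bins.  If the outermost ``tail_bins`` bins at either end hold
more than ``ratio`` times the count of the adjacent ``tail_bins`` bins,
those extreme bins are marked saturated.  As a guard, no sample with
magnitude below 1 nT can ever be flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .recording import Recording
from .scenario_generator import Trajectory

__all__ = [
    "SaturationReport",
    "detect_saturation",
    "reject_trials",
    "classify_trials_by_radius",
    "trial_windows",
]


@dataclass
class SaturationReport:
    """Result of amplitude-histogram saturation detection.

    ``saturated_ranges`` maps channel label to a list of (low, high)
    amplitude intervals (tesla) marked as saturated; ``mask`` is the
    per-sample flag array, derivable solely from the block's own
    histogram.
    """

    labels: list[str]
    mask: np.ndarray
    saturated_ranges: dict[str, list[tuple[float, float]]]
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "channels": {
                lab: [[lo, hi] for lo, hi in rngs]
                for lab, rngs in self.saturated_ranges.items() if rngs
            },
            "skipped_channels": list(self.skipped),
            "n_flagged_samples": int(self.mask.sum()),
        }


def detect_saturation(block: Recording, bin_width: float = 1e-12,
                      tail_bins: int = 5, ratio: float = 2.0,
                      floor: float = 1e-9) -> SaturationReport:
    """Detect saturated samples from the amplitude histogram of a block.

    Per channel: a histogram over [min, max] in ``bin_width`` bins
    (anchored at the data extremes, empty interior bins counted as zero)
    is compared at its tails.  If the outermost ``tail_bins`` bins hold
    strictly more than ``ratio`` times the count of the adjacent
    ``tail_bins`` bins, the amplitude range of the outer bins is marked
    saturated.  Samples falling in marked ranges with ``|value| >= floor``
    get ``mask = True``.  Channels with fewer than ``10 * tail_bins``
    occupied bins (including constant channels) are skipped with a
    warning — the tail comparison is undefined for them.
    """
    mask = np.zeros(block.data.shape, dtype=bool)
    ranges: dict[str, list[tuple[float, float]]] = {}
    skipped: list[str] = []

    for i, lab in enumerate(block.labels):
        x = block.data[i]
        ranges[lab] = []
        lo, hi = float(x.min()), float(x.max())
        if hi - lo < bin_width:
            warnings.warn(f"channel {lab} is (near-)constant; saturation "
                          "detection skipped", stacklevel=2)
            skipped.append(lab)
            continue
        n_bins = int(np.ceil((hi - lo) / bin_width))
        edges = lo + bin_width * np.arange(n_bins + 1)
        edges[-1] = max(edges[-1], hi)
        counts, _ = np.histogram(x, bins=edges)
        occupied = int((counts > 0).sum())
        if occupied < 10 * tail_bins:
            warnings.warn(
                f"channel {lab}: only {occupied} occupied amplitude bins "
                f"(<{10 * tail_bins}); saturation detection skipped",
                stacklevel=2)
            skipped.append(lab)
            continue

        ch_mask = np.zeros(x.shape, dtype=bool)
        # top tail: outermost tail_bins vs the previous tail_bins; the
        # floor applies to marking itself — amplitudes below 1 nT can
        # never be saturated, so tails not reaching the floor are ignored
        # (a pure Gaussian's sparse extreme bins would otherwise trip the
        # count rule)
        if edges[-1] >= floor and counts[-tail_bins:].sum() \
                > ratio * counts[-2 * tail_bins:-tail_bins].sum():
            lo_edge = edges[-tail_bins - 1]
            ranges[lab].append((float(lo_edge), float(edges[-1])))
            ch_mask |= x >= lo_edge
        if edges[0] <= -floor and counts[:tail_bins].sum() \
                > ratio * counts[tail_bins:2 * tail_bins].sum():
            hi_edge = edges[tail_bins]
            ranges[lab].append((float(edges[0]), float(hi_edge)))
            ch_mask |= x < hi_edge
        ch_mask &= np.abs(x) >= floor      # sub-1 nT data can never be flagged
        mask[i] = ch_mask

    return SaturationReport(list(block.labels), mask, ranges, skipped)


def trial_windows(onsets: np.ndarray, sample_rate: float,
                  window: tuple[float, float] = (-0.2, 0.5),
                  n_samples: int | None = None, t0: float = 0.0) -> np.ndarray:
    """Per-trial (start, stop) sample indices for an epoch window.

    Trials whose window falls outside the recording are dropped.
    """
    onsets = np.asarray(onsets, dtype=float)
    start = np.round((onsets + window[0] - t0) * sample_rate).astype(int)
    stop = start + int(round((window[1] - window[0]) * sample_rate))
    keep = start >= 0
    if n_samples is not None:
        keep &= stop <= n_samples
    return np.column_stack([start[keep], stop[keep]])


def reject_trials(windows: np.ndarray, report_or_mask) -> np.ndarray:
    """Keep/reject partition of trials by saturation.

    A trial is rejected iff any sample of any channel inside its window
    is flagged in the saturation mask.

    Parameters
    ----------
    windows : ndarray (n_trials, 2)
        Per-trial (start, stop) sample indices (stop exclusive).
    report_or_mask : SaturationReport or ndarray of bool

    Returns
    -------
    kept : ndarray of bool, shape (n_trials,)
    """
    mask = report_or_mask.mask if isinstance(report_or_mask, SaturationReport) \
        else np.asarray(report_or_mask, dtype=bool)
    any_sat = mask.any(axis=0)
    # cumulative count lets each trial query its window in O(1)
    csum = np.r_[0, np.cumsum(any_sat)]
    kept = np.empty(windows.shape[0], dtype=bool)
    for k, (a, b) in enumerate(windows):
        kept[k] = (csum[b] - csum[a]) == 0
    return kept


def classify_trials_by_radius(onsets: np.ndarray, traj: Trajectory,
                              radius: float = 0.5,
                              window: tuple[float, float] = (-0.2, 0.5),
                              gap_trust_s: float = 0.2) -> np.ndarray:
    """Label each trial inside/outside a central cylinder of given radius.

    A trial is *outside* iff, at any trajectory sample within its window,
    the horizontal (x, y) distance from the room centre exceeds
    ``radius``.  Interpolated positions from gaps shorter than
    ``gap_trust_s`` are trusted; samples filled across longer gaps (and
    unfilled dropouts) are assumed to be outside.

    Returns
    -------
    outside : ndarray of bool, shape (n_trials,)
    """
    onsets = np.asarray(onsets, dtype=float)
    r = np.linalg.norm(traj.positions[:, :2], axis=1)
    gap = traj.gap_length_s if traj.gap_length_s is not None else np.zeros(r.size)
    untrusted = (~traj.tracked) | (traj.interpolated & (gap >= gap_trust_s))
    beyond = (r > radius) | untrusted
    outside = np.zeros(onsets.size, dtype=bool)
    for k, onset in enumerate(onsets):
        sel = (traj.times >= onset + window[0]) & (traj.times <= onset + window[1])
        outside[k] = bool(beyond[sel].any())
    return outside
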