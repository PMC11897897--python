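"""Fractional-window moving average and smoothed intrinsic-cyclizability estimators.

The smoother is a centered moving average whose window size ``k`` may be
fractional:

* odd integer ``k``   — plain mean of the k centered values;
* even integer ``k``  — the two endpoints at offsets +-k/2 get weight
  ``1/(2k)``, the k-1 interior offsets weight ``1/k`` (weights sum to 1);
* non-integer ``k``   — the two bracketing-integer smooths are combined as
  ``(w1*S_k1 + w2*S_k2) / (w1 + w2)`` with ``w1 = 1/(k-k1)``,
  ``w2 = 1/(k2-k)``, i.e. inverse-distance weights.

At ``k`` equal to the helical repeat (10.4 bp) the window cancels the
sinusoidal tether bias almost exactly while preserving the slowly varying
intrinsic signal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tracks import PositionTrack, pearson

__all__ = [
    "SmoothingWindow",
    "moving_average",
    "mean_tracks",
    "c0s_estimate",
    "window_consistency_scan",
    "local_amplitude",
    "amplitude_ratio_track",
]


@dataclass(frozen=True)
class SmoothingWindow:
    """A (possibly fractional) moving-average window of size ``k`` bp."""

    k: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k) and self.k > 1):
            raise ValueError("window size k must be > 1")

    @property
    def is_integer(self) -> bool:
        return float(self.k).is_integer()

    @property
    def k1(self) -> int:
        """Lower bracketing integer (undefined concept for integer k)."""
        return int(math.floor(self.k))

    @property
    def k2(self) -> int:
        return self.k1 + 1

    @property
    def w1(self) -> float:
        return 1.0 / (self.k - self.k1)

    @property
    def w2(self) -> float:
        return 1.0 / (self.k2 - self.k)

    @property
    def halfspan(self) -> int:
        """Largest offset from the center any constituent window reaches."""
        if self.is_integer:
            k = int(self.k)
            return k // 2 if k % 2 == 0 else (k - 1) // 2
        return max(_int_halfspan(self.k1), _int_halfspan(self.k2))


def _int_halfspan(k: int) -> int:
    return k // 2 if k % 2 == 0 else (k - 1) // 2


def _int_kernel(k: int) -> np.ndarray:
    if k % 2 == 1:
        return np.full(k, 1.0 / k)
    kernel = np.full(k + 1, 1.0 / k)
    kernel[0] = kernel[-1] = 1.0 / (2.0 * k)
    return kernel


def _smooth_int(values: np.ndarray, k: int) -> np.ndarray:
    kernel = _int_kernel(k)
    half = kernel.size // 2
    # NaN inside a window propagates to the output (no imputation);
    # positions whose window runs off the track are emitted as NaN.
    out = np.convolve(values, kernel[::-1], mode="same")
    if half > 0:
        out[:half] = np.nan
        out[-half:] = np.nan
    return out


def moving_average(track: PositionTrack, k: float) -> PositionTrack:
    """Centered moving average with (possibly fractional) window size *k*.

    Output shares the input grid; positions whose widest required window is
    incomplete, or whose window contains a missing value, come out missing.
    """
    window = SmoothingWindow(k)
    if not np.any(track.mask):
        raise ValueError("cannot smooth an all-missing track")
    if len(track) < 2 * window.halfspan + 1:
        raise ValueError(
            f"track of length {len(track)} too short for window k={k}"
        )
    if window.is_integer:
        smoothed = _smooth_int(track.values, int(window.k))
    else:
        s1 = _smooth_int(track.values, window.k1)
        s2 = _smooth_int(track.values, window.k2)
        smoothed = (window.w1 * s1 + window.w2 * s2) / (window.w1 + window.w2)
    return track.with_values(smoothed)


def mean_tracks(tracks: Sequence[PositionTrack]) -> PositionTrack:
    """Per-position arithmetic mean of co-registered tracks.

    A position is missing in the output if it is missing in any input.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to average")
    first = tracks[0]
    for other in tracks[1:]:
        first.require_same_grid(other)
    stacked = np.vstack([t.values for t in tracks])
    return first.with_values(stacked.mean(axis=0))


def c0s_estimate(smoothed_tracks: Sequence[PositionTrack]) -> PositionTrack:
    """Six-track intrinsic-cyclizability estimate.

    *smoothed_tracks* must be the six k=10.4-smoothed tracks, n = 26/29/31 on
    the forward and reverse-complement strands, co-registered on forward
    window-center coordinates; the estimate is their per-position mean.
    """
    if len(smoothed_tracks) != 6:
        raise ValueError(
            f"c0s_estimate expects exactly six smoothed tracks, got {len(smoothed_tracks)}"
        )
    return mean_tracks(smoothed_tracks)


def window_consistency_scan(
    tracks_by_n: Sequence[PositionTrack], k_values: Iterable[float]
) -> pd.DataFrame:
    """Mean pairwise correlation among smoothed tracks per window size.

    For each ``k`` every track is smoothed and the average of all pairwise
    Pearson correlations (over jointly non-missing positions) is reported.
    A good bias-cancelling window makes the per-n estimates agree, so the
    scan peaks near the helical repeat.
    """
    tracks = list(tracks_by_n)
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to scan")
    for other in tracks[1:]:
        tracks[0].require_same_grid(other)
    rows = []
    for k in k_values:
        # k = 1 means no smoothing; the smoother itself requires k > 1
        smoothed = tracks if k == 1 else [moving_average(t, k) for t in tracks]
        corrs = [
            pearson(a, b) for a, b in itertools.combinations(smoothed, 2)
        ]
        rows.append({"k": float(k), "mean_pairwise_correlation": float(np.mean(corrs))})
    return pd.DataFrame(rows)


def local_amplitude(track: PositionTrack, halfwidth: int = 5) -> PositionTrack:
    """Local sinusoid amplitude approximated by half the range in l +- halfwidth.

    Assumes the baseline and amplitude are roughly constant across the 2*halfwidth+1
    window, so the half-range of the oscillating signal estimates its amplitude.
    Edges (and windows touching missing values) are missing.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    span = 2 * halfwidth + 1
    out = np.full(len(track), np.nan)
    if len(track) >= span:
        windows = np.lib.stride_tricks.sliding_window_view(track.values, span)
        # plain max/min propagate NaN, which is the desired missing policy
        out[halfwidth : len(track) - halfwidth] = (
            windows.max(axis=1) - windows.min(axis=1)
        ) / 2.0
    return track.with_values(out)


def amplitude_ratio_track(
    amp_a: PositionTrack, amp_b: PositionTrack, tol: float = 1e-9
) -> PositionTrack:
    """Per-position ratio ``amp_a / amp_b``; missing where the denominator is tiny."""
    amp_a.require_same_grid(amp_b)
    denom = amp_b.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.abs(denom) < tol, np.nan, amp_a.values / denom)
    return amp_a.with_values(ratio)
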