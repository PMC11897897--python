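"""Per-base position tracks along a single chromosome.

A :class:`PositionTrack` stores one real value per base-pair position.  The
coordinate of a value is the *center* of the 50-bp window it scores: position
``l`` refers to the window covering bases ``l-24 .. l+25`` (1-based,
inclusive), so ``l`` is the 25th base of the window.  Missing values are
represented as ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PositionTrack", "normalize_track", "pearson"]


@dataclass
class PositionTrack:
    """A contiguous real-valued signal along one chromosome.

    Parameters
    ----------
    chrom:
        Chromosome / contig identifier.
    origin:
        1-based coordinate of ``values[0]`` (window-center convention).
    values:
        One value per base; ``NaN`` marks missing positions.
    """

    chrom: str
    origin: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")
        if self.values.size < 1:
            raise ValueError("track must contain at least one value")
        self.origin = int(self.origin)

    def __len__(self) -> int:
        return self.values.size

    @property
    def positions(self) -> np.ndarray:
        """1-based coordinate of every value."""
        return self.origin + np.arange(self.values.size)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a value is present (finite)."""
        return np.isfinite(self.values)

    def same_grid(self, other: "PositionTrack") -> bool:
        """True if *other* shares chromosome, origin and length."""
        return (
            self.chrom == other.chrom
            and self.origin == other.origin
            and len(self) == len(other)
        )

    def require_same_grid(self, other: "PositionTrack") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"coordinate mismatch: ({self.chrom}, {self.origin}, {len(self)}) "
                f"vs ({other.chrom}, {other.origin}, {len(other)})"
            )

    def with_values(self, values: np.ndarray) -> "PositionTrack":
        """A new track on the same grid with different values."""
        values = np.asarray(values, dtype=float)
        if values.size != self.values.size:
            raise ValueError("replacement values must keep the track length")
        return PositionTrack(self.chrom, self.origin, values)

    def value_at(self, position: int) -> float:
        """Value at a 1-based chromosome coordinate."""
        idx = int(position) - self.origin
        if idx < 0 or idx >= self.values.size:
            raise IndexError(f"position {position} outside track {self.chrom}")
        return float(self.values[idx])


def normalize_track(track: PositionTrack) -> PositionTrack:
    """Standardize a track to mean 0 / sd 1 over its non-missing positions."""
    finite = track.values[track.mask]
    if finite.size < 2:
        raise ValueError("need at least two non-missing values to normalize")
    sd = float(np.std(finite))
    if sd == 0.0:
        raise ValueError("cannot normalize a track with zero spread")
    return track.with_values((track.values - float(np.mean(finite))) / sd)


def pearson(a: PositionTrack | np.ndarray, b: PositionTrack | np.ndarray) -> float:
    """Pearson correlation over jointly non-missing positions."""
    x = a.values if isinstance(a, PositionTrack) else np.asarray(a, dtype=float)
    y = b.values if isinstance(b, PositionTrack) else np.asarray(b, dtype=float)
    if x.size != y.size:
        raise ValueError("tracks must have equal length")
    m = np.isfinite(x) & np.isfinite(y)
    if m.sum() < 2:
        raise ValueError("need at least two jointly non-missing positions")
    xs, ys = x[m], y[m]
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("correlation undefined for a constant track")
    return float(np.corrcoef(xs, ys)[0, 1])
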