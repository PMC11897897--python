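"""Sequence- and track-level diagnostics for residual tether bias.

Residual sinusoidal bias in a cyclizability estimate shows up as ~10-bp
periodic, antiphase AA/AT/TA/TT oscillations in the top vs bottom score
quartiles, as rotational-phase-locked oscillation around nucleosome dyads,
and as a strong ~10-bp peak in the Fourier spectrum.  A clean estimate shows
none of these, but retains genuine signals such as depleted poly(dA:dT)
tracts among bendable sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import periodogram

from .biotin import q_score
from .tracks import PositionTrack

__all__ = [
    "SequenceSet",
    "DinucProfile",
    "CoverageProfile",
    "SpectrumResult",
    "DyadProfile",
    "RatioTuneResult",
    "quartile_split",
    "dinuc_ww_frequency",
    "polyat_coverage",
    "autocorrelation",
    "cross_correlation",
    "power_spectrum",
    "peak_period",
    "dyad_profile",
    "tune_amplitude_ratio",
    "at_frequency",
    "band_power",
]

_ALPHABET = frozenset("ACGTN")
WW = frozenset({"AA", "AT", "TA", "TT"})


@dataclass
class SequenceSet:
    """Fixed-length scored sequences (the 50-bp loop-seq library shape)."""

    ids: list[str]
    sequences: list[str]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sequences = [s.upper() for s in self.sequences]
        self.scores = np.asarray(self.scores, dtype=float)
        if not (len(self.ids) == len(self.sequences) == self.scores.size):
            raise ValueError("ids, sequences and scores must align")
        if self.sequences:
            length = len(self.sequences[0])
            for seq in self.sequences:
                if len(seq) != length:
                    raise ValueError("all sequences must have the same length")
                if not set(seq) <= _ALPHABET:
                    raise ValueError(
                        f"sequence contains characters outside ACGTN: {seq!r}"
                    )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def seq_length(self) -> int:
        if not self.sequences:
            raise ValueError("empty sequence set")
        return len(self.sequences[0])

    def subset(self, indices: Sequence[int]) -> "SequenceSet":
        idx = list(indices)
        return SequenceSet(
            [self.ids[i] for i in idx],
            [self.sequences[i] for i in idx],
            self.scores[idx],
        )


@dataclass(frozen=True)
class DinucProfile:
    """Per-position WW (AA/AT/TA/TT) dinucleotide frequency, positions 1..L-1."""

    values: np.ndarray
    label: str = ""


@dataclass(frozen=True)
class CoverageProfile:
    """Per-position fraction of sequences covered by a qualifying tract."""

    values: np.ndarray
    label: str = ""


@dataclass(frozen=True)
class SpectrumResult:
    frequencies: np.ndarray  # cycles per bp
    power: np.ndarray

    def total_power(self) -> float:
        """Integrated spectrum; equals the input variance (Parseval)."""
        if self.frequencies.size < 2:
            return 0.0
        df = float(self.frequencies[1] - self.frequencies[0])
        return float(np.sum(self.power) * df)


@dataclass(frozen=True)
class DyadProfile:
    offsets: np.ndarray
    mean: np.ndarray
    n_dyads: int
    n_skipped: int


@dataclass(frozen=True)
class RatioTuneResult:
    best_f: float
    f_grid: np.ndarray
    band_power: np.ndarray
    #: False when the band power is flat across the grid, i.e. there is no
    #: periodic signal to tune against and the argmin is not meaningful
    stable: bool


def quartile_split(sset: SequenceSet) -> tuple[SequenceSet, SequenceSet]:
    """Top and bottom score quartiles (floor(N/4) records each).

    Ties are broken by stable input order: among equal scores, earlier
    records enter the top quartile first (and likewise the bottom).
    """
    n = len(sset)
    if n < 4:
        raise ValueError("need at least four records to split into quartiles")
    q = n // 4
    top = np.argsort(-sset.scores, kind="stable")[:q]
    bottom = np.argsort(sset.scores, kind="stable")[:q]
    return sset.subset(top), sset.subset(bottom)


def dinuc_ww_frequency(sset: SequenceSet, label: str = "") -> DinucProfile:
    """Fraction of sequences whose bases (p, p+1) form AA, AT, TA or TT.

    N-containing dinucleotides never match.  Positions are 1..L-1.
    """
    if len(sset) == 0:
        raise ValueError("empty sequence set")
    length = sset.seq_length
    counts = np.zeros(length - 1)
    for seq in sset.sequences:
        for p in range(length - 1):
            if seq[p : p + 2] in WW:
                counts[p] += 1
    return DinucProfile(counts / len(sset), label)


def _homopolymer_runs(seq: str, min_len: int) -> np.ndarray:
    """Boolean mask of positions inside a run of a single base A or T of
    length >= min_len.  Mixed A/T stretches do not qualify."""
    mask = np.zeros(len(seq), dtype=bool)
    i = 0
    while i < len(seq):
        base = seq[i]
        j = i
        while j < len(seq) and seq[j] == base:
            j += 1
        if base in "AT" and j - i >= min_len:
            mask[i:j] = True
        i = j
    return mask


def polyat_coverage(
    sset: SequenceSet, min_len: int = 4, label: str = ""
) -> CoverageProfile:
    """Per-position fraction of sequences inside a poly(dA:dT) tract.

    A tract is a maximal homopolymeric run of A's, or of T's, of length at
    least *min_len*.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if len(sset) == 0:
        raise ValueError("empty sequence set")
    covered = np.zeros(sset.seq_length)
    for seq in sset.sequences:
        covered += _homopolymer_runs(seq, min_len)
    return CoverageProfile(covered / len(sset), label)


_MIN_OVERLAP = 30


def cross_correlation(
    a: PositionTrack, b: PositionTrack, max_lag: int
) -> np.ndarray:
    """Lagged Pearson correlation corr(a(i+k), b(i)) for k = 0..max_lag."""
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    x, y = a.values, b.values
    if x.size != y.size:
        raise ValueError("tracks must have equal length")
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        xs, ys = x[k:], y[: y.size - k]
        m = np.isfinite(xs) & np.isfinite(ys)
        if m.sum() < _MIN_OVERLAP:
            raise ValueError(
                f"only {int(m.sum())} overlapping positions at lag {k}; "
                f"need at least {_MIN_OVERLAP}"
            )
        out[k] = np.corrcoef(xs[m], ys[m])[0, 1]
    return out


def autocorrelation(track: PositionTrack, max_lag: int) -> np.ndarray:
    return cross_correlation(track, track, max_lag)


def power_spectrum(track: PositionTrack) -> SpectrumResult:
    """Raw periodogram (no taper) of the mean-subtracted track."""
    values = track.values
    if not np.all(np.isfinite(values)):
        raise ValueError("power_spectrum requires a gap-free segment; trim first")
    if values.size < 64:
        raise ValueError("need at least 64 positions for a spectrum")
    freqs, power = periodogram(values - values.mean(), fs=1.0, window="boxcar")
    return SpectrumResult(freqs, power)


def peak_period(spec: SpectrumResult, band: tuple[float, float]) -> float:
    """Period (bp) of the maximal power whose period lies within *band*."""
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must be a (low, high) period interval")
    with np.errstate(divide="ignore"):
        periods = 1.0 / spec.frequencies
    in_band = (periods >= lo) & (periods <= hi) & (spec.frequencies > 0)
    if not np.any(in_band):
        raise ValueError(f"no spectral estimate inside period band {band}")
    idx = np.flatnonzero(in_band)[np.argmax(spec.power[in_band])]
    return float(periods[idx])


def band_power(values: np.ndarray, band: tuple[float, float] = (9.0, 12.0)) -> float:
    """Summed periodogram power of a short profile within a period band.

    Used to quantify ~10-bp periodicity in quartile WW / A/T profiles.
    """
    return _band_split(values, band)[0]


def _band_split(
    values: np.ndarray, band: tuple[float, float]
) -> tuple[float, float]:
    """(summed in-band power, mean per-bin out-of-band power)."""
    x = np.asarray(values, dtype=float)
    freqs, power = periodogram(x - x.mean(), fs=1.0, window="boxcar")
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / freqs, np.inf)
    in_band = (periods >= band[0]) & (periods <= band[1])
    out_band = ~in_band & (freqs > 0)
    floor = float(np.mean(power[out_band])) if np.any(out_band) else 0.0
    return float(np.sum(power[in_band])), floor


def dyad_profile(
    track: PositionTrack, dyads: Sequence[int], flank: int = 73
) -> DyadProfile:
    """Mean track value at each offset in [-flank, +flank] from the dyads.

    Dyads whose flanked window leaves the track (or touches missing values
    only partially — missing values are averaged out per offset) are skipped
    and counted.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    offsets = np.arange(-flank, flank + 1)
    rows = []
    skipped = 0
    for dyad in dyads:
        start = int(dyad) - flank - track.origin
        stop = start + offsets.size
        if start < 0 or stop > len(track):
            skipped += 1
            continue
        rows.append(track.values[start:stop])
    if not rows:
        raise ValueError("no dyad has a complete flanked window inside the track")
    stacked = np.vstack(rows)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    return DyadProfile(offsets, mean, n_dyads=len(rows), n_skipped=skipped)


def at_frequency(sequences: Sequence[str]) -> np.ndarray:
    """Per-position fraction of sequences with an A or T (N never counts)."""
    if not sequences:
        raise ValueError("empty sequence list")
    length = len(sequences[0])
    counts = np.zeros(length)
    for seq in sequences:
        s = seq.upper()
        if len(s) != length:
            raise ValueError("all sequences must have the same length")
        for p, base in enumerate(s):
            if base in "AT":
                counts[p] += 1
    return counts / len(sequences)


def tune_amplitude_ratio(
    sequences: Sequence[str],
    c26: np.ndarray,
    c31: np.ndarray,
    f_grid: Sequence[float],
    top_n: int = 1000,
    band: tuple[float, float] = (9.0, 12.0),
    signal_floor: float = 3.0,
) -> RatioTuneResult:
    """Choose the weight f minimizing ~10-bp A/T periodicity of top sequences.

    For each f the sequences are ranked by ``c26 + f*c31``, the *top_n*
    highest are taken, and the Fourier power of their per-position A/T
    frequency in the 9-12-bp period band is measured; the f with minimal
    band power wins (smallest f on ties).  When no grid point shows band
    power above *signal_floor* times the off-band noise floor, there is no
    periodic signal to tune against and the result is flagged unstable.
    """
    f_values = np.asarray(list(f_grid), dtype=float)
    if f_values.size == 0:
        raise ValueError("f_grid must be nonempty")
    c26 = np.asarray(c26, dtype=float)
    c31 = np.asarray(c31, dtype=float)
    if not (len(sequences) == c26.size == c31.size):
        raise ValueError("sequences, c26 and c31 must align")
    if len(sequences) < top_n:
        raise ValueError(f"need at least top_n={top_n} sequences")
    powers = np.empty(f_values.size)
    ratios = np.empty(f_values.size)
    n_band_bins = max(
        1, round((1.0 / band[0] - 1.0 / band[1]) * len(sequences[0]))
    )
    for i, f in enumerate(f_values):
        scores = np.array([q_score(a, b, f) for a, b in zip(c26, c31)])
        top = np.argsort(-scores, kind="stable")[:top_n]
        profile = at_frequency([sequences[j] for j in top])
        powers[i], floor = _band_split(profile, band)
        ratios[i] = powers[i] / (floor * n_band_bins) if floor > 0 else np.inf
    best = int(np.argmin(powers))  # argmin returns the first (smallest f) tie
    stable = bool(np.max(ratios) >= signal_floor)
    return RatioTuneResult(float(f_values[best]), f_values, powers, stable)
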