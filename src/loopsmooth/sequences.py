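"""Genome sequences, 50-bp window extraction, and the artificial-chromosome
workflow for reference-free libraries.

Coordinates are 1-based inclusive internally.  The window scored at center
``l`` is ``S_l = X_{l-24} .. X_{l+25}`` (50 bp, ``l`` is its 25th base).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import SequenceSet
from .tracks import PositionTrack

__all__ = [
    "WINDOW", "GenomeSource", "ConcatIndex",
    "read_fasta", "reverse_complement", "extract_windows",
    "concat_library", "map_back",
    "read_library", "write_library",
]

WINDOW = 50
_LEFT = 24   # bases left of the center within a window
_RIGHT = 25  # bases right of the center

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSource:
    """Uppercase chromosome sequences keyed by unique identifier."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome source must contain at least one sequence")
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


def read_fasta(path: str | Path) -> GenomeSource:
    """Read a FASTA file into a :class:`GenomeSource`.

    Lowercase input is accepted and uppercased; duplicate headers and
    malformed records are rejected with the offending line number.
    """
    sequences: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                if name in sequences:
                    raise ValueError(f"{path}:{lineno}: duplicate FASTA header {name!r}")
                sequences[name] = []
                current = name
            else:
                if current is None:
                    raise ValueError(
                        f"{path}:{lineno}: sequence data before any FASTA header"
                    )
                sequences[current].append(line.upper())
    if not sequences:
        raise ValueError(f"{path}: empty FASTA file")
    return GenomeSource({k: "".join(v) for k, v in sequences.items()})


def extract_windows(
    genome: GenomeSource, chrom: str, centers: Sequence[int]
) -> SequenceSet:
    """50-bp windows centered at the given 1-based coordinates."""
    seq = genome[chrom]
    length = len(seq)
    bad = [l for l in centers if not (_LEFT + 1 <= l <= length - _RIGHT)]
    if bad:
        raise ValueError(
            f"window centers out of range on {chrom} (valid {_LEFT + 1}.."
            f"{length - _RIGHT}): {bad}"
        )
    windows = [seq[l - _LEFT - 1 : l + _RIGHT] for l in centers]
    ids = [f"{chrom}:{l}" for l in centers]
    return SequenceSet(ids, windows, np.full(len(windows), np.nan))


@dataclass
class ConcatIndex:
    """Placement of shuffled library records in an artificial chromosome."""

    ids: list[str]      # record ids in concatenated order
    starts: np.ndarray  # 1-based start of each record's 50-mer
    centers: np.ndarray  # 1-based window-center coordinate (start + 24)

    def center_of(self, record_id: str) -> int:
        return int(self.centers[self.ids.index(record_id)])


def concat_library(
    sset: SequenceSet, ordering_seed: int
) -> tuple[str, ConcatIndex]:
    """Concatenate 50-bp records, shuffled by seed, into one chromosome."""
    for seq in sset.sequences:
        if len(seq) != WINDOW:
            raise ValueError("concat_library requires all records to be 50 bp")
    order = np.random.default_rng(ordering_seed).permutation(len(sset))
    ids = [sset.ids[i] for i in order]
    chromosome = "".join(sset.sequences[i] for i in order)
    starts = np.arange(len(sset)) * WINDOW + 1
    return chromosome, ConcatIndex(ids, starts, starts + _LEFT)


def map_back(track: PositionTrack, index: ConcatIndex) -> pd.Series:
    """Per-record score: the track value at each record's center coordinate.

    Centers outside the track's span are a coordinate mismatch; missing
    track values propagate as NaN scores.
    """
    first, last = track.origin, track.origin + len(track) - 1
    out_of_span = [
        rid
        for rid, center in zip(index.ids, index.centers)
        if center < first or center > last
    ]
    if out_of_span:
        raise ValueError(
            f"track [{first}, {last}] does not cover centers of: {out_of_span[:5]}"
        )
    values = track.values[index.centers - track.origin]
    return pd.Series(values, index=pd.Index(index.ids, name="id"), name="score")


_LIBRARY_REQUIRED = ("id", "sequence", "c26", "c29", "c31")


def _sniff_delimiter(path: str | Path) -> str:
    with open(path) as handle:
        header = handle.readline()
        while header.startswith("#"):  # reproducibility comment lines
            header = handle.readline()
    return "\t" if "\t" in header else ","


def read_library(path: str | Path) -> pd.DataFrame:
    """Read a delimited library table (id, sequence, c26, c29, c31[, ...]).

    The delimiter is auto-detected between tab and comma; a header row is
    required.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"id": str})
    missing = [c for c in _LIBRARY_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: library table missing column(s) {missing}")
    return df


def write_library(
    df: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    df.to_csv(buf, sep=sep, index=False)
    Path(path).write_text(buf.getvalue())


def library_to_sequence_set(
    df: pd.DataFrame, score_col: str
) -> SequenceSet:
    """View a library table as a scored :class:`SequenceSet`."""
    if score_col not in df.columns:
        raise ValueError(f"score column {score_col!r} not in table")
    return SequenceSet(
        [str(x) for x in df["id"]],
        list(df["sequence"]),
        df[score_col].to_numpy(dtype=float),
    )
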