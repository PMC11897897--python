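"""Reading and writing position tracks and dyad lists.

Supported track formats:

* ``tsv``      — columns ``chrom, pos, value`` with ``pos`` the 1-based
  window-center coordinate; missing values written as ``nan``.
* ``bedGraph`` — 0-based half-open, one base per record; missing positions
  are omitted and re-read as missing.
* ``wig``      — ``fixedStep`` with ``step=1``; missing values written as
  ``nan`` (a deliberate extension so round-trips are lossless).

Dyad lists are BED intervals (0-based half-open); each interval's midpoint
is taken as the 1-based dyad coordinate.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np

from .tracks import PositionTrack

__all__ = ["read_track", "write_track", "read_dyads_bed", "write_dyads_bed"]

_FORMATS = ("tsv", "bedgraph", "wig")


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in _FORMATS:
            raise ValueError(f"unknown track format {fmt!r}; choose from {_FORMATS}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("bedgraph", "bdg"):
        return "bedgraph"
    if suffix == "wig":
        return "wig"
    return "tsv"


def write_track(
    track: PositionTrack,
    path: str | Path,
    fmt: str | None = None,
    header_comment: str | None = None,
) -> None:
    fmt = _infer_format(path, fmt)
    lines: list[str] = []
    if header_comment:
        lines.append(f"# {header_comment}")
    if fmt == "tsv":
        lines.append("chrom\tpos\tvalue")
        for pos, value in zip(track.positions, track.values):
            lines.append(f"{track.chrom}\t{pos}\t{float(value)!r}")
    elif fmt == "bedgraph":
        for pos, value in zip(track.positions, track.values):
            if np.isfinite(value):
                lines.append(f"{track.chrom}\t{pos - 1}\t{pos}\t{float(value)!r}")
    else:  # wig fixedStep, 1-based
        lines.append(f"fixedStep chrom={track.chrom} start={track.origin} step=1")
        lines.extend(f"{float(value)!r}" for value in track.values)
    Path(path).write_text("\n".join(lines) + "\n")


def _noncomment_lines(path: str | Path) -> Iterable[str]:
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line and not line.startswith("#") and not line.startswith("track"):
                yield line


def read_track(path: str | Path, fmt: str | None = None) -> PositionTrack:
    """Read a single-chromosome track file; format inferred from extension."""
    fmt = _infer_format(path, fmt)
    if fmt == "wig":
        return _read_wig(path)
    records: list[tuple[str, int, float]] = []
    for line in _noncomment_lines(path):
        fields = line.split("\t")
        if fmt == "tsv":
            if fields[0] == "chrom":
                continue
            chrom, pos, value = fields[0], int(fields[1]), float(fields[2])
        else:
            chrom, start, end, value = (
                fields[0], int(fields[1]), int(fields[2]), float(fields[3]),
            )
            if end - start != 1:
                raise ValueError(
                    f"{path}: bedGraph record spans {end - start} bases; "
                    "expected one base per record"
                )
            pos = start + 1  # 0-based half-open -> 1-based center
        records.append((chrom, pos, value))
    if not records:
        raise ValueError(f"{path}: no track records found")
    chroms = {chrom for chrom, _, _ in records}
    if len(chroms) > 1:
        raise ValueError(
            f"{path}: multi-chromosome track files are not supported (found {sorted(chroms)})"
        )
    chrom = records[0][0]
    positions = np.array([pos for _, pos, _ in records])
    origin = int(positions.min())
    values = np.full(int(positions.max()) - origin + 1, np.nan)
    values[positions - origin] = [value for _, _, value in records]
    return PositionTrack(chrom, origin, values)


def _read_wig(path: str | Path) -> PositionTrack:
    chrom: str | None = None
    start: int | None = None
    values: list[float] = []
    for line in _noncomment_lines(path):
        if line.startswith("fixedStep"):
            if chrom is not None:
                raise ValueError(f"{path}: multiple fixedStep blocks not supported")
            params = dict(
                item.split("=", 1) for item in line.split()[1:] if "=" in item
            )
            chrom = params["chrom"]
            start = int(params["start"])
            if int(params.get("step", 1)) != 1:
                raise ValueError(f"{path}: only step=1 wiggle tracks are supported")
        else:
            if chrom is None:
                raise ValueError(f"{path}: data before fixedStep declaration")
            values.append(float(line))
    if chrom is None or not values:
        raise ValueError(f"{path}: no wiggle data found")
    assert start is not None
    return PositionTrack(chrom, start, np.array(values))


def read_dyads_bed(path: str | Path) -> tuple[str, list[int]]:
    """Read dyad positions from BED; returns (chrom, 1-based dyad centers).

    For a BED interval [start, end) the dyad is the 1-based midpoint
    ``start + (end - start + 1) // 2``; a single-base interval [d, d+1)
    yields d+1.
    """
    chroms: set[str] = set()
    dyads: list[int] = []
    for line in _noncomment_lines(path):
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if end <= start:
            raise ValueError(f"{path}: empty BED interval {start}-{end}")
        chroms.add(chrom)
        dyads.append(start + (end - start + 1) // 2)
    if not dyads:
        raise ValueError(f"{path}: no BED records found")
    if len(chroms) > 1:
        raise ValueError(f"{path}: dyads span multiple chromosomes {sorted(chroms)}")
    return chroms.pop(), dyads


def write_dyads_bed(chrom: str, dyads: Iterable[int], path: str | Path) -> None:
    """Write 1-based dyad centers as single-base BED intervals."""
    lines = [f"{chrom}\t{d - 1}\t{d}" for d in dyads]
    Path(path).write_text("\n".join(lines) + "\n")
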