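"""Deterministic synthetic data with known answers.

Stands in for trained-model C_n predictions: a synthetic genome is built
with two planted, mechanically meaningful sequence features —

* blocks of helically phased WW (AA/TT-type) dinucleotides, which raise the
  designed intrinsic cyclizability in proportion to the *amplitude* of their
  10.4-bp periodicity (phase-agnostic, so an unbiased estimate's score
  quartiles show no coherent phase);
* poly(dA:dT) homopolymer tracts, which lower it.

C_n tracks for n = 26/29/31 on both strands are then generated from the
sinusoidal tether-bias forward model, so every downstream diagnostic has a
known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .features import _homopolymer_runs, WW
from .sequences import GenomeSource, WINDOW, write_library
from .simulate import BoundedWalkSpec, bounded_random_walk
from .tracks import PositionTrack
from .trackio import write_dyads_bed, write_track

__all__ = ["FixtureConfig", "Fixture", "sequence_c0_profile", "generate_cn_tracks", "generate_fixture", "write_fixture"]


@dataclass(frozen=True)
class FixtureConfig:
    genome_length: int = 12_000
    seed: int = 0
    chrom: str = "fixchr"
    period: float = 10.4
    #: planted periodic-WW blocks
    n_periodic_blocks: int = 40
    block_length: int = 120
    #: planted poly(dA:dT) tracts
    n_polyat_tracts: int = 60
    tract_length_range: tuple[int, int] = (5, 9)
    #: designed C_0 = baseline walk + bonus*WW-periodicity - penalty*poly(dA:dT)
    bonus: float = 3.0
    penalty: float = 2.0
    baseline_walk: BoundedWalkSpec = field(
        default_factory=lambda: BoundedWalkSpec(1.0 / 24.0, -0.75, 0.75)
    )
    a26_walk: BoundedWalkSpec = field(
        default_factory=lambda: BoundedWalkSpec(1.0 / 5.0, 0.1, 3.0)
    )
    ratio_31: float = 0.7  # true amplitude-ratio anchor of the planted bias
    noise_sd: float = 0.1
    dyad_spacing: int = 52  # exactly five helical turns: dyads phase-locked


@dataclass
class Fixture:
    config: FixtureConfig
    genome: GenomeSource
    c0_true: PositionTrack
    tracks: Mapping[tuple[int, str], PositionTrack]  # (n, 'fwd'|'rev')
    dyads: list[int]
    library: pd.DataFrame


def _ww_indicator(seq: str) -> np.ndarray:
    return np.array(
        [1.0 if seq[x : x + 2] in WW else 0.0 for x in range(len(seq) - 1)]
    )


def sequence_c0_profile(
    seq: str,
    period: float = 10.4,
    bonus: float = 3.0,
    penalty: float = 2.0,
    center_halfwidth: int = 10,
    min_run: int = 4,
    profile_smooth: int = 9,
    chrom: str = "seq",
) -> PositionTrack:
    """Sequence-determined part of the designed intrinsic cyclizability.

    For every valid window center l (25 .. len-25, 1-based) the score is
    ``bonus * P(l) - penalty * O(l)`` where P is the helical-period Fourier
    amplitude of the WW dinucleotide indicator across the window (phase
    discarded) and O the poly(dA:dT) coverage of the 2*center_halfwidth+1
    bases around the center.
    """
    seq = seq.upper()
    g = len(seq)
    if g < WINDOW:
        raise ValueError(f"sequence shorter than one {WINDOW}-bp window")
    w = _ww_indicator(seq)
    x = np.arange(w.size)
    theta = 2.0 * np.pi * x / period
    n_dinuc = WINDOW - 1
    kernel = np.ones(n_dinuc)
    sc = np.convolve(w * np.cos(theta), kernel, mode="valid")
    ss = np.convolve(w * np.sin(theta), kernel, mode="valid")
    periodicity = 2.0 * np.hypot(sc, ss) / n_dinuc  # amplitude, phase-free

    runs = _homopolymer_runs(seq, min_run).astype(float)
    span = 2 * center_halfwidth + 1
    occ_all = np.convolve(runs, np.ones(span) / span, mode="valid")
    # occ_all[j] covers 0-based bases j .. j+span-1, centered at 1-based j+center_halfwidth+1
    first_center = 25
    occ = occ_all[first_center - center_halfwidth - 1 : first_center - center_halfwidth - 1 + periodicity.size]
    values = bonus * periodicity - penalty * occ
    if profile_smooth > 1:
        # intrinsic cyclizability is assumed to evolve smoothly base-to-base;
        # a light boxcar keeps the designed track consistent with that premise
        values = np.convolve(values, np.ones(profile_smooth) / profile_smooth, mode="same")
    return PositionTrack(chrom, first_center, values)


def generate_cn_tracks(
    c0: PositionTrack,
    seed: int,
    period: float = 10.4,
    a26_walk: BoundedWalkSpec | None = None,
    ratio_31: float = 0.7,
    noise_sd: float = 0.1,
    strands: tuple[str, ...] = ("fwd", "rev"),
) -> dict[tuple[int, str], PositionTrack]:
    """Forward-model C_n tracks over a given intrinsic track.

    The forward strand's tether phase decreases by one base of helical twist
    per position; the reverse-complement strand runs antiparallel, so its
    phase (mapped onto forward window-center coordinates) increases, with an
    independent random phase origin per strand.
    """
    a26_walk = a26_walk or BoundedWalkSpec(1.0 / 5.0, 0.1, 3.0)
    ratio_29 = 1.0 - 3.0 * (1.0 - ratio_31) / 5.0
    names = ("a26", "phi_fwd", "phi_rev", "noise")
    rngs = dict(zip(names, map(np.random.default_rng, np.random.SeedSequence(seed).spawn(len(names)))))
    length = len(c0)
    a26 = bounded_random_walk(a26_walk, length, rngs["a26"])
    amplitudes = {26: a26, 29: a26 / ratio_29, 31: a26 / ratio_31}
    step = 2.0 * math.pi / period * np.arange(length)
    phases = {
        "fwd": rngs["phi_fwd"].uniform(0.0, 2.0 * math.pi) - step,
        "rev": rngs["phi_rev"].uniform(0.0, 2.0 * math.pi) + step,
    }
    out = {}
    for strand in strands:
        for n in (26, 29, 31):
            bias = amplitudes[n] * np.sin(2.0 * math.pi * n / period + phases[strand])
            noise = rngs["noise"].normal(0.0, noise_sd, size=length)
            out[(n, strand)] = c0.with_values(c0.values + bias + noise)
    return out


def generate_fixture(config: FixtureConfig | None = None) -> Fixture:
    """Build the full synthetic dataset (deterministic in ``config.seed``)."""
    config = config or FixtureConfig()
    g = config.genome_length
    names = ("genome", "blocks", "tracts", "baseline", "tracks")
    rngs = dict(zip(names, map(np.random.default_rng, np.random.SeedSequence(config.seed).spawn(len(names)))))

    bases = np.array(list("ACGT"))
    seq = rngs["genome"].choice(bases, size=g)

    # helically phased WW blocks: A-runs at crests of cos(2*pi*x/period),
    # phase-locked to the absolute genome coordinate
    phase_ok = np.cos(2.0 * np.pi * np.arange(g) / config.period) > 0.55
    starts = rngs["blocks"].choice(
        np.arange(100, g - 100 - config.block_length),
        size=config.n_periodic_blocks,
        replace=False,
    )
    for start in starts:
        block = slice(start, start + config.block_length)
        seq[block] = np.where(phase_ok[block], "A", seq[block])

    lo, hi = config.tract_length_range
    for _ in range(config.n_polyat_tracts):
        tlen = int(rngs["tracts"].integers(lo, hi + 1))
        pos = int(rngs["tracts"].integers(100, g - 100 - tlen))
        seq[pos : pos + tlen] = rngs["tracts"].choice(["A", "T"])

    genome_seq = "".join(seq)
    genome = GenomeSource({config.chrom: genome_seq})

    designed = sequence_c0_profile(
        genome_seq,
        period=config.period,
        bonus=config.bonus,
        penalty=config.penalty,
        chrom=config.chrom,
    )
    baseline = bounded_random_walk(config.baseline_walk, len(designed), rngs["baseline"])
    c0_true = designed.with_values(designed.values + baseline)

    tracks = generate_cn_tracks(
        c0_true,
        seed=int(rngs["tracks"].integers(0, 2**31 - 1)),
        period=config.period,
        a26_walk=config.a26_walk,
        ratio_31=config.ratio_31,
        noise_sd=config.noise_sd,
    )

    first, last = c0_true.origin, c0_true.origin + len(c0_true) - 1
    dyads = list(range(first + config.dyad_spacing, last - config.dyad_spacing, config.dyad_spacing))

    centers = np.arange(first, last + 1)
    offsets = centers - first
    library = pd.DataFrame(
        {
            "id": [f"{config.chrom}:{l}" for l in centers],
            "sequence": [genome_seq[l - 25 : l + 25] for l in centers],
            "c26": tracks[(26, "fwd")].values[offsets],
            "c29": tracks[(29, "fwd")].values[offsets],
            "c31": tracks[(31, "fwd")].values[offsets],
            "c0_true": c0_true.values[offsets],
        }
    )
    return Fixture(config, genome, c0_true, tracks, dyads, library)


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write the fixture as plain-text files (FASTA, TSV tracks, BED, table)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = fixture.config.chrom
    seq = fixture.genome[chrom]
    wrapped = "\n".join(seq[i : i + 70] for i in range(0, len(seq), 70))
    (outdir / "genome.fa").write_text(f">{chrom}\n{wrapped}\n")
    write_track(fixture.c0_true, outdir / "c0_true.tsv")
    for (n, strand), track in fixture.tracks.items():
        write_track(track, outdir / f"c{n}_{strand}.tsv")
    write_dyads_bed(chrom, fixture.dyads, outdir / "dyads.bed")
    write_library(fixture.library, outdir / "library.tsv")
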