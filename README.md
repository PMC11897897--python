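# loopsmooth

Debiasing of loop-seq DNA cyclizability measurements.

Loop-seq measures the cyclizability of 50-bp DNA fragments with a biotin
tether attached at position n = 26, 29 or 31 of the construct. The tether
adds a sinusoidal bias `A_n * sin(2*pi*n/10.4 + phi0)` whose phase tracks the
DNA rotational angle at the tether. `loopsmooth` implements:

- **`loopsmooth.biotin`** — the sinusoidal bias model: forward generation,
  phase progression along a chromosome, and the exact closed-form solver for
  intrinsic cyclizability under an assumed amplitude-ratio scheme
  (`A26/A31 = 0.7` with linear interpolation by default), plus the
  two-observation antiphase approximation and the `Q(f) = C26 + f*C31`
  ranking score.
- **`loopsmooth.smoothing`** — the fractional-window moving average
  (odd/even/fractional window weights), the six-track smoothed
  intrinsic-cyclizability estimate (n = 26/29/31 on both strands, smoothed at
  k = 10.4 and averaged), local half-range amplitude estimation, and the
  window-size consistency scan.
- **`loopsmooth.simulate`** — the simulation benchmark: bounded-random-walk
  parameters, three amplitude-ratio regimes (true / inverted / stochastically
  evolving ratios), correlation summaries, the assumed-ratio heatmap and the
  noise-sensitivity analysis.
- **`loopsmooth.features`** — residual-bias diagnostics: score-quartile
  AA/AT/TA/TT profiles, poly(dA:dT) tract coverage, auto/cross-correlation,
  Fourier periodograms, nucleosome-dyad-aligned profiles and amplitude-ratio
  weight tuning.
- **`loopsmooth.sequences` / `trackio` / `tracks`** — FASTA, BED,
  bedGraph/wiggle/TSV track I/O, 50-bp window extraction, track
  normalization, and the artificial-chromosome (concatenate / map-back)
  workflow for reference-free libraries.
- **`loopsmooth.fixtures`** — a deterministic synthetic-data generator:
  genomes with planted helically phased WW dinucleotides and poly(dA:dT)
  tracts, a designed intrinsic-cyclizability track, forward-model C_n tracks
  on both strands, dyad lists and library tables.

Coordinates are 1-based internally; a track value at position `l` scores the
50-bp window `l-24 .. l+25` (so `l` is the window's 25th base).
Reverse-strand tracks are registered to the same forward center coordinate.
BED/bedGraph files follow their 0-based half-open standards.

## Command line

```sh
loopsmooth --help
loopsmooth --seed 1 simulate --setting i --length 100000 --out-dir sim_i/
loopsmooth debias --in library.tsv --out debiased.tsv --ratio31 0.7
loopsmooth smooth --in c26.tsv --out c26_smoothed.tsv --k 10.4
loopsmooth c0s sm26F.tsv sm29F.tsv sm31F.tsv sm26R.tsv sm29R.tsv sm31R.tsv --out c0s.tsv
loopsmooth scan c26.tsv c29.tsv c31.tsv --k-values 7,9,10.4,11,14 --out scan.tsv
loopsmooth features --library scored.tsv --score-col c0_true --out profiles
loopsmooth dyad-profile --track c0s.tsv --dyads dyads.bed --flank 73 --out dyad.tsv
loopsmooth --seed 3 concat --library library.tsv --out-fasta concat.fa --out-index index.tsv
loopsmooth --seed 0 make-fixtures --genome-length 12000 --out-dir fixtures/
```

Library tables are tab- or comma-separated with a header and columns
`id, sequence, c26, c29, c31` (extra columns pass through). Track files are
`chrom  pos  value` TSV, bedGraph, or fixedStep wiggle. A YAML file passed
via `--config` supplies per-subcommand defaults; explicit options win.

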