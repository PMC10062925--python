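# methylhet

Streaming computation of seven DNA methylation heterogeneity measures from
bisulfite read alignments, plus a tagging utility for alignments produced by
non-Bismark aligners and a ground-truthed read simulator.

Phased methylation states within a sequencing read (its *epiallele*) carry
information about cell-to-cell epigenetic diversity that per-CpG average
methylation discards. `methylhet` extracts these patterns from the
Bismark-style per-base methylation call string (`XM` tag) and computes, in a
single pass over a coordinate-sorted SAM/BAM:

| subcommand | measure | granularity |
|---|---|---|
| `pdr` | proportion of discordant reads | per CpG |
| `mhl` | methylation haplotype load | per CpG |
| `lpmd` | local pairwise methylation discordance | global, per CpG pair, per distance |
| `pm` | epipolymorphism | per CpG quartet |
| `me` | methylation entropy | per CpG quartet |
| `fdrp` | fraction of discordant read pairs | per CpG (reservoir-sampled) |
| `qfdrp` | quantitative FDRP | per CpG (reservoir-sampled) |

All subcommands are one-sweep: each alignment record is read exactly once
and per-locus accumulators are flushed as soon as the sweep passes them, so
memory stays proportional to local pile-up depth, not genome size.

## Usage

```sh
# alignments not produced by Bismark: attach the XM call string first
methylhet tag -i aligned.bam -r genome.fa -o tagged.bam

# per-CpG / per-quartet measures (BED-like TSV: chrom start end value depth)
methylhet pdr  -i tagged.bam -o out.pdr.bed
methylhet mhl  -i tagged.bam -o out.mhl.bed --min-depth 10
methylhet pm   -i tagged.bam -o out.pm.bed
methylhet me   -i tagged.bam -o out.me.bed
methylhet fdrp -i tagged.bam -o out.fdrp.bed --max-depth 40 --seed 1

# LPMD: per-pair BED to -o, per-distance table via --dist-output,
# pooled global value printed to stdout
methylhet lpmd -i tagged.bam -o out.lpmd.bed --dist-output out.lpmd.dist.tsv
```

Input must be coordinate-sorted; unsorted input is rejected with an error.
All intervals in output are 0-based half-open (standard BED convention);
per-CpG records span the CpG dinucleotide (`end = start + 2`). Reverse-strand
calls are collapsed onto the forward-strand C at parse time, so both strands
contribute to the same coordinate.

Simulation and the read-length experiment:

```sh
# RRBS-like tagged alignments with per-locus analytic ground truth
methylhet simulate -o sim.sam --ground-truth truth.tsv \
    --n-loci 200 --depth 50 --read-length 50 --seed 7

# 3'-trim reads to mimic shorter sequencing lengths
methylhet trim -i sim.sam --lengths 25,30,35,45,50 --output-prefix sim_trim_
```

The simulator draws each read's epiallele i.i.d. from a per-locus pattern
distribution and writes valid sorted SAM; analytic values of all seven
measures are computed from the distribution by exhaustive enumeration — an
independent code path useful as a test oracle.

## Testing

```sh
python -m pytest -q tests/
```

The suite includes a CpG-centric in-memory brute-force reimplementation of
every measure (`tests/oracle.py`); on randomized synthetic alignments the
streaming results must be bit-identical to it. `tests/test_acceptance.py`
additionally checks analytic fixed points, the qFDRP <= FDRP invariant,
reservoir-sampling correctness, parameter recovery from simulations, the
PDR read-length bias (and LPMD's stability against it), and output format
contracts.

The acceptance report (runs an end-to-end smoke and writes the JSON report):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Notes on definitions

* **PDR** classifies a read as discordant when it carries both a methylated
  and an unmethylated CpG call; reads with fewer than `--min-cpgs`
  (default 4) calls are not classified.
* **LPMD** pools same-read CpG pairs with separations in
  `[--min-distance, --max-distance]` (default 2–16 bp), which makes it
  insensitive to read length, unlike PDR.
* **MHL** weights the fraction of fully methylated contiguous CpG runs by
  run length; substring lengths with no observable windows are excluded
  from both sums.
* **FDRP/qFDRP** sample at most `--max-depth` (default 40) reads per CpG
  with a single seeded reservoir (Algorithm R); results are deterministic
  for fixed input, flags and `--seed`, and exact (all-pairs) whenever the
  capacity exceeds the local depth.
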