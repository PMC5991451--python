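# chromopaint

Design chromosome-specific oligo-FISH "painting" probe sets from a
repeat-masked genome assembly.

The pipeline tiles a target chromosome into fixed-length candidate oligos
(default 45 nt every 5 nt), then applies four screens before emitting a
BED6 probe set:

1. **Repeat mask** — any candidate touching a soft-masked (lowercase),
   hard-masked (`N`) or ambiguous base is discarded.
2. **Genome-wide uniqueness** — candidates matching two or more loci at
   ≥ 75% ungapped identity (both strands, all chromosomes, the source
   locus included in the tally) are discarded.  The default search is
   seed-and-extend with mismatch-tolerant 9-mer seeds and exact
   verification, which guarantees detection of any second locus at
   ≥ 80% identity and never reports a false positive; `--exact` switches
   to a full scan with identical semantics.
3. **Secondary structure** — duplex Tm and hairpin Tm (strongest ungapped
   Watson-Crick stem, unified nearest-neighbor parameters) are computed
   per oligo; only oligos with dTm = Tm − hairpin-Tm strictly above 10 °C
   are kept (oligos with no stem at all always pass).
4. **Density selection** — one probe per bin (bin width 1000/density bp,
   default 2 oligos/kb), choosing the highest-dTm non-overlapping
   candidate per bin, optionally thinned evenly to a target count
   (e.g. 25,000).

All coordinates are 0-based half-open (BED convention).  Runs are fully
deterministic; each run writes the probe BED, a per-oligo thermo TSV, a
stage survivor report and a JSON run record (config, input digests,
counts).

## CLI

```sh
# design probes for one chromosome
chromopaint design --genome genome.fa --chrom Chr9 \
    --oligo-length 45 --step 5 --min-identity 0.75 --min-dtm 10 \
    --density 2 --target-count 25000 --out outdir/

# generate a seeded synthetic test genome + ground-truth manifest
chromopaint fixtures make --seed 1 --length 8000 --duplications 2 --out fx/

# validate a probe BED (parse, widths, sorting, bounds, non-overlap)
chromopaint validate-bed --bed outdir/probes.bed --genome genome.fa --width 45
```

## Library layout

| module                     | contents                                              |
| -------------------------- | ----------------------------------------------------- |
| `chromopaint.genome_io`    | mask-aware FASTA, BED6 read/write, interval types     |
| `chromopaint.candidates`   | tiling, mask filter, pipeline configuration           |
| `chromopaint.specificity`  | k-mer index, homology search (heuristic/exact/oracle) |
| `chromopaint.thermo`       | nearest-neighbor Tm, hairpin Tm, dTm screen           |
| `chromopaint.selection`    | density binning, thinning, stage reports              |
| `chromopaint.fixtures`     | seeded synthetic genomes with ground-truth manifests  |
| `chromopaint.pipeline`     | end-to-end orchestration, run records                 |
| `chromopaint.cli`          | `chromopaint` command                                 |
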