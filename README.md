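# sinescope

A toolkit for dissecting a SINE (short interspersed nuclear element)
family end to end on synthetic genomes with known ground truth:

- **io_formats** — FASTA / Ensembl-GTF / BED6 / bedGraph-with-counts /
  expression-TSV readers and writers, with one internal coordinate
  convention (0-based half-open).
- **synthetic** — builds a 231-nt head–body consensus (Pol III promoter
  head, two tandem 46-bp direct repeats carrying dual-function AG|GT
  splice sites, conserved GGAGTTCCC motif), implants copies with target
  site duplications (TSDs), poly(A) tails, point mutations and
  tandem/nested/spliced variants into random backgrounds, and simulates
  gene annotations, paired-tissue beta-binomial methylomes and
  sign-coupled expression — all with exact truth tables.
- **calibration** — the step-wise TSD search (anchored 8-mers, exact
  match in the 3′ flank, bidirectional extension, longest-duplication
  rule), AAAA/motif head–body–tail splitting, class I/II assignment,
  tandem/nested detection, and strand-aware proximal/distal annotation
  relative to gene TSSs.
- **seqstats** — composition, Gardiner–Garden CpG observed/expected
  ratio, CpG-island predicate, p-distances, nucleotide diversity, and
  the molecular clock t = D/(2α) with α = 4.6×10⁻⁹.
- **aligndist** — Needleman–Wunsch global alignment (+1/−1/−2 linear
  gaps), identity-based distance matrices, and a deterministic PCA
  embedding.
- **splicing** — CDS-overlap selection, splice-signal marking (5/3/T),
  projection onto consensus coordinates through alignment, the
  10,000-replicate uniform sampling null for hot splice sites
  (93 positions × 188 signals ⇒ k = 6 at α = 0.01), and the GU-AG
  excision model that turns the class-I consensus into the 185-nt
  class-II product.
- **methylation** — CpG depth/missingness filters, element-level means,
  exact Wilcoxon signed-rank and Spearman tests (enumeration-equivalent
  for small n), Fisher enrichment, and global per-tissue summaries.
- **pipeline** / **cli** — a seeded, deterministic end-to-end runner
  with a JSON manifest.

## CLI

```bash
# full pipeline (simulate → calibrate → stats → distances → splice → methylation)
sinescope run --seed 7 --out rundir
# individual stages
sinescope simulate --seed 7 --out simdir
sinescope calibrate --genome simdir/genome.fa --consensus simdir/consensus.fa \
    --out elements.tsv --bed elements.bed
sinescope stats --elements elements.tsv --genome simdir/genome.fa --out stats.tsv
sinescope distances --fasta seqs.fa --out dm.tsv --pca pca.tsv
sinescope splice-null --reps 10000 --alpha 0.01 --seed 1
```

`sinescope run` accepts a YAML config (`--config cfg.yaml`) whose keys
mirror `sinescope.pipeline.DEFAULT_CONFIG`; unknown keys are rejected
and all thresholds are echoed into the run log and `manifest.json`.
Reruns with the same config and seed are byte-identical.

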