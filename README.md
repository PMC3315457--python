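# regkit

A regulatory-genomics toolkit for ChIP-peak and co-expression analysis:

- **Motif models** (`regkit.motifs`) — position weight matrices from IUPAC
  consensus strings or count matrices, exact score distributions under a
  Markov-0 background, p-value-calibrated match thresholds (Patser-style),
  and both-strand sequence scanning.
- **Genomic intervals** (`regkit.intervals`) — peak unions, length-matched
  random background sampling, 10 kb peak-to-gene assignment, per-peak
  differential binding (ANOVA + BH-FDR), and binding/expression
  correlations.
- **Motif statistics** (`regkit.motifstats`) — peak-vs-background motif
  presence enrichment (Fisher exact, BH across a compendium),
  class-differential motif association, signed inter-site spacing
  histograms, and a spacing-constraint test against a pooled
  within-sequence shuffle null (≤25 bp vs >25 bp, 50 shuffles).
- **Gene-list statistics** (`regkit.genelists`) — expression filtering
  (>5 reads rule), hypergeometric overlap and fold enrichment,
  fold-change concordance, direction (quadrant) classification, exact
  binomial attenuation tests, and Venn-region accounting.
- **Co-expression** (`regkit.coexpression`) — quantile normalization,
  weighted-correlation-network modules (|r|^β adjacency, topological
  overlap, average linkage, static cut), consensus tight clustering by
  resampled k-means, coherent-cluster extraction against a second tissue,
  and per-module gene-list enrichment with a module-level contingency
  summary.
- **Synthetic data** (`regkit.synthetic`) — generators with planted ground
  truth: Markov-0 genomes, peak sequences with planted motifs and
  fixed-spacing motif pairs, two-tissue latent-factor expression matrices
  with shared/tissue-specific modules, and DE tables with exact list sizes,
  overlaps, and fold-change correlation.
- **I/O and CLI** (`regkit.fileio`, `regkit.cli`) — FASTA/BED6/GFF3/TSV
  readers and writers and a `regkit` command with subcommands
  `simulate`, `scan`, `enrich`, `spacing`, `overlap`, `coexpr`, `report`.
  Every run writes a metadata JSON with parameters, seeds, and input
  digests; identical config + seed gives byte-identical outputs.

## CLI quick start

```sh
# simulate peaks carrying a planted USP/JHRE pair 3 bp apart
regkit simulate --n-peaks 200 --pair GGGGTCACS GRCACGCKVS 3 \
    --seed 1 --out runs/sim

# spacing-constraint test at the five standard match thresholds
regkit spacing --fasta runs/sim/peaks.fasta \
    --anchor GGGGTCACS --cofactor GRCACGCKVS --alpha-grid \
    --seed 1 --out runs/spacing

# motif enrichment against auto-sampled length-matched background
regkit enrich --peaks peaks.fasta --genome genome.fasta \
    --peak-bed peaks.bed --motifs manifest.tsv --out runs/enrich
```

Motif manifests are TSV files with `name<TAB>IUPAC-or-matrix-path` rows;
matrices are whitespace tables with one line per position (A C G T).

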