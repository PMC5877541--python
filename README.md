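# mitofeatures

Descriptive analysis of insect mitochondrial genomes: the set of
computations a mitogenome announcement paper reports, packaged as a
tested Python library with a thin CLI.

A typical insect mitogenome is a ~16 kb circular molecule carrying 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one A+T-rich control
region (CR), densely packed with small intergenic spacers and overlaps.
`mitofeatures` computes, from a genome sequence and its feature table:

* **Annotation arithmetic** — gene sizes, the junction ledger
  (gap = start(next) − end(prev) − 1; + spacer, − overlap), genome
  length, comparison of the gene order to the ancestral insect
  arrangement, and the ATGNTAA bicistron motif at 7-nt gene overlaps.
* **Composition and strand skews** — for any partition (whole genome,
  PCGs by strand, codon positions, tRNAs, rRNAs, CR), with
  AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C); minority-strand
  partitions are read in gene sense.
* **Codon usage** — start/stop classification including incomplete stops
  (`T-`, `TA-`), per-strand codon counts, and relative synonymous codon
  usage RSCU(c) = N(c)·k / Σ_family N under the invertebrate
  mitochondrial code (translation table 5: 8-fold serine, 6-fold
  leucine, UAA/UAG stop family).
* **tRNA cloverleaf structure** — deterministic constrained folding
  (7-bp acceptor stem, 5-bp anticodon stem anchored on the annotated
  anticodon, 3–5 bp DHU/TΨC stems, DHU-less Ser(AGN)-type folds), with a
  per-arm census of Watson–Crick, G–U wobble and mismatched pairs, plus
  pairwise identity for rRNA comparisons.
* **Control-region structure** — leading/repeat/remainder segmentation,
  a tandem-repeat finder (simplified Tandem Repeats Finder
  re-implementation), poly-N tracts, stem-loop hairpins with 5′ TATA and
  3′ G(A)nT flanking motifs, and conserved sequence blocks (CSBs) across
  aligned control regions at 100/75/50 % identity tiers.
* **Synthetic data** — seeded generators for whole mitogenomes, tRNAs,
  control regions and CR alignments with complete planted ground truth,
  so every stage is testable without downloads.

The packaged reference tables transcribe the published annotation of the
stonefly *Suwallia teleckojensis* mitogenome (GenBank MF198253), which
is also the default layout of the genome generator. See
`docs/methods.md` for the algorithms and design decisions.

## Worked example

```python
from mitofeatures import (
    genome_length, junction_ledger, summarize_junctions,
    skew_from_proportions, rscu_from_counts,
)
from mitofeatures.data import load_reference_feature_table, load_reference_codon_usage

table = load_reference_feature_table()
print(genome_length(table))
summary = summarize_junctions(junction_ledger(table))
print(summary.spacer_count, summary.spacer_total, summary.overlap_count, summary.overlap_total)

at, gc = skew_from_proportions(36.5, 30.2, 11.6, 21.7)  # whole-genome %A/%T/%G/%C
print(round(at, 2), round(gc, 3))

df = load_reference_codon_usage()
print(round(rscu_from_counts(dict(zip(df.codon, df.n)))["TTA"], 2))
```

prints

```
16146
14 76 11 41
0.09 -0.303
2.6
```

i.e. a 16,146 bp genome whose 38 features leave 76 intergenic
nucleotides in 14 spacers and overlap by 41 nucleotides at 11 junctions;
a whole-genome composition skewed toward A over T (+0.09) and C over G
(−0.303); and UUA(Leu) used 2.6× more often than expected under uniform
synonym usage — the classic A+T-biased codon preference.

The `examples/` directory holds one short script per capability
(annotation statistics, composition skews, RSCU, tRNA folding,
control-region scanning, CSB calling); each generates or loads a small
input, runs the method and prints what the numbers mean. The same
functionality is scriptable via the CLI:

```bash
mitofeatures synth genome --seed 1 --out demo/
mitofeatures annotate-stats --table demo/features.tsv --fasta demo/genome.fasta
mitofeatures codon-usage --fasta demo/genome.fasta --table demo/features.tsv
mitofeatures cr-scan --fasta cr.fa --offset 14897
```

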