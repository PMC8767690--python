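# tcgtscope

Toolkit for detecting and characterizing transposable-element-driven
regulatory activity, built for the analyses that surround LTR-driven gene
regulation in the human germline and early embryo:

- **Transpochimeric gene transcripts (TcGTs).** A TcGT is a transcript that
  initiates inside the long terminal repeat (LTR) of an endogenous
  retrovirus and splices into an annotated gene, co-opting the LTR as an
  alternative promoter. `tcgtscope` calls TcGTs from assembled transcript
  models, aggregates their TSSs (single linkage within 100 bp per gene),
  counts occurrences per sample group, and scores per-subfamily
  over-representation of driver loci with a hypergeometric test,
  BH-corrected within each group.
- **Curated repeat annotation.** RepeatMasker-style records are parsed,
  fragmented integrants reassembled, LTR–internal(–LTR) runs merged into
  full-length ERV features, remaining unpaired LTRs flagged as *solo LTRs*
  (the internal-recombination product devoid of coding sequence), and TEs
  overlapping gene exons discarded.
- **ChIP peak / TE-subfamily enrichment.** Peaks are assigned to the TE
  they overlap by strictly more than 50% of their length; per-subfamily
  counts are tested with an exact binomial against the subfamily's share of
  the genome (correcting for total genomic size, `p0 = total_bp /
  genome_bp`). Replicate peak sets are reduced to consensus peaks
  (regions supported by ≥ 2 replicates, merged to the union interval), and
  a Fisher exact test scores whether a gene set is enriched for TSSs within
  50 kb of a TE locus set.
- **Expression clustering.** Gene + TE-locus count matrices are filtered
  (row sum ≥ number of samples), TMM-normalized — trimmed mean of M-values
  computed on gene rows, with gene counts as library size — z-scored per
  locus and clustered by complete-linkage hierarchical clustering with
  1 − Pearson correlation as distance, cut into two groups to separate
  maternal-style from ZGA-style temporal patterns.
- **Germline methylation profiling.** RRBS-style CpG calls are averaged,
  unweighted, into per-locus methylation levels (loci without profiled
  CpGs are excluded), replicate-averaged, summarized per subfamily, and
  locus sets are compared with a two-sided Wilcoxon rank-sum test.
- **Alignment signal profiles.** Gapped multiple alignments are trimmed of
  columns with more than 85% gaps; per-locus ChIP signal is min-max scaled
  to [0, 1], projected onto alignment columns and averaged into a consensus
  binding profile.
- **Cross-species scoring.** TE locus conservation is the fraction of the
  human sequence covered by the cross-species alignment, normalized by the
  subfamily consensus length; KZFP relatedness is scored on the zinc
  fingerprint (the four DNA-contacting residues, positions −1, 2, 3, 6, per
  finger) by global alignment of finger sequences.

Because the analyses were designed against consortium-scale accessions, the
package ships a first-class synthetic-data generator (`tcgtscope.simulate`)
that emulates every input — toy genome, TE catalog with fragmentation and
solo-LTR structure, group-structured transcriptomes with planted chimeras
and decoys, enriched peak sets, temporal expression matrices, CpG calls
with planted set differences, synteny and fingerprint tables — together
with a machine-readable ground truth, so every stage can be validated end
to end.

## Worked example

Run the whole pipeline on a simulated study and score it against the
planted ground truth:

```bash
tcgtscope demo --seed 42
```

Selected output (abridged):

```json
{
  "curation":  {"n_curated": 195, "catalog_matches_truth": true, "solo_ltr_count": 138},
  "tcgt":      {"precision": 1.0, "recall": 1.0,
                "per_group": {"oocyte": {"padj": 0.000567, "rank": 1},
                              "fourcell": {"padj": 0.000567, "rank": 1},
                              "eightcell": {"padj": 0.000567, "rank": 1}}},
  "peaks":     {"n_consensus": 317, "enriched_subfamily": "LTR12C",
                "padj": 1.21e-97, "rank": 1},
  "expression":{"cluster_rand_index": 1.0},
  "methylation":{"p": 1.85e-16, "median_a": 0.702, "median_b": 0.391}
}
```

Reading this: repeat curation reconstructed all 195 true loci (solo-LTR
flags included); all 30 planted chimeras were recovered with no false call
among 60 decoys; the planted driver subfamily (LTR12C) ranks first in every
group at adjusted p ≈ 5.7 × 10⁻⁴; the subfamily carrying 40% of the ChIP
peaks ranks first at adjusted p ≈ 10⁻⁹⁷; the maternal/ZGA expression
partition is recovered exactly (Rand index 1.0); and the planted 0.30
methylation difference between locus sets is detected at p ≈ 2 × 10⁻¹⁶
(medians 0.70 vs 0.39).

The same stages are available as individual subcommands
(`tcgtscope simulate | curate-repeats | call-tcgt | consensus-peaks |
enrich-peaks | proximity | cluster-expr | methyl | msa-profile |
ortho-score | fingerprint`) operating on flat files (GTF, BED-style TSV,
chrom.sizes, TSV matrices); `tcgtscope show-defaults` prints the analysis
parameters.

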