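# Methods

This note records the models, rules and numerical choices behind each
stage, the design decisions taken where a convention had to be fixed, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Coordinates and conventions

All intervals inside the package are 0-based half-open; converters sit at
the I/O boundary (GTF and RepeatMasker `.out` are 1-based inclusive on
disk, BED-style files half-open). "Overlap" always means a shared base
under the half-open rule, so abutting intervals do not overlap. Strand-aware
5′ ends: on the plus strand the TSS is the first exon's start; on the minus
strand it is `end − 1` of the genomically last exon.

## Exact statistics

Enrichment tests are one-sided toward over-representation — the upper tail
of the hypergeometric (`P(X ≥ k)`) for TcGT drivers, the upper tail of the
exact binomial for peak counts — because the question asked of each is
whether a subfamily is *over*-represented. Fisher's exact test (proximity
contrasts) and the Wilcoxon rank-sum test (methylation contrasts) are
two-sided. Multiple testing uses Benjamini–Hochberg step-up within each
declared family: for TcGT enrichment the family is all subfamilies within
one sample group (one heatmap column); for peak enrichment, all subfamilies
in one peak set.

The rank-sum test is exact (full enumeration of the Mann–Whitney U null)
when the pooled sample has at most 12 observations and no ties; otherwise
it uses the normal approximation with midranks and the standard tie
correction of the variance, without a continuity correction (so identical
samples give p = 1 exactly). The result records which branch was used.

## Repeat curation

Curation applies three steps in order: (1) *fragment reassembly* — records
sharing a RepeatMasker linkage id, or same-chromosome/strand/subfamily
records separated by at most 100 bp, merge into one feature spanning
min(start)–max(end); (2) *full-length ERV assembly* — runs of a paired LTR
and internal segment (e.g. LTR12C with HERV9 internals) on one strand,
each gap at most 500 bp, merge into one feature labeled by the internal
segment; (3) *exon exclusion* — any TE overlapping a gene exon by ≥ 1 bp
is discarded. The two gap defaults are configurable; 100 bp reflects the
small interruptions annotators introduce within one integrant, 500 bp the
larger LTR–internal junction gaps, and both are comfortably below the
spacing of independent integrants. A solo LTR is operationally an LTR-class
record not merged with any internal segment; an internal segment standing
alone is a single feature but not a solo LTR. Merging is idempotent.
Nested insertions (a TE interrupting another) are not resolved.

## TcGT calling

A transcript model yields a TcGT iff (a) its strand-aware TSS base lies
inside an LTR-class catalog locus, (b) it has at least one splice junction,
and (c) at least one exon downstream of a junction overlaps an annotated
gene exon. The junction requirement re-expresses "minimum one read spanning
a junction" at the transcript-model level: assemblers emitting these models
already require junction-supporting reads, so a model-level junction is the
faithful proxy. The cognate gene is the gene with the largest total
downstream exonic overlap; ties break to the lexicographically smallest
gene id. A TSS inside two overlapping LTRs is assigned to the strand-aware
5′-most one (logged).

Aggregation chains TSSs per (gene, driver subfamily) by single linkage at
≤ 100 bp; the representative TSS is the 5′-most member, and the per-group
occurrence of an aggregate is the number of that group's samples
contributing at least one member. Enrichment per (group, subfamily) is
hypergeometric over *loci*: k = distinct driver loci of the subfamily
active in the group, K = catalog loci of the subfamily, n = distinct driver
loci of any subfamily active in the group, N = all catalog LTR loci.
Counting loci rather than aggregates keeps the universe well defined (every
locus either drives or not); the aggregate-level alternative would make N
depend on the observed transcripts.

## Peak enrichment, consensus and proximity

A peak is assigned to the TE locus it overlaps most, and the assignment
stands only when overlap/peak-length is strictly greater than 0.5
("above 50%"). The binomial model treats each peak as one trial with
success probability `total_bp(subfamily) / genome_bp`; peak width is not
modeled, which makes the test slightly conservative for wide peaks (a peak
must be mostly inside a locus to count, which is rarer than its midpoint
landing there) — the calibration study below confirms super-uniform null
p-values. `genome_bp` is the sum of the supplied chromosome sizes.

Consensus peaks are the regions where peaks from at least two distinct
replicates overlap, expanded to the union of all peaks touching the region;
scores are discarded and no affinity re-scoring is attempted. The sweep
processes interval ends before starts at equal coordinates, so abutting
peaks never count as overlapping.

The proximity test classifies every gene by membership in the query set and
by whether its TSS lies within 50 kb of the nearest edge of any query TE
locus (0 if inside), and applies Fisher's exact test to the resulting 2×2
table. The TSS anchor (rather than the gene body) makes the distance
well defined for genes of very different lengths.

## Expression normalization and clustering

Rows (genes and TE loci together) are filtered by `row sum ≥ number of
samples`. TMM factors are computed on gene rows only, with gene-count
column sums as library sizes: the reference sample is the one whose
75th count percentile (scaled by library size) is closest to the mean;
per-sample log2 ratios against the reference are trimmed 30% from each
tail, average intensities 5% from each tail, and the surviving M-values are
averaged with inverse-variance (delta-method) weights; factors are rescaled
to a unit geometric mean. Values are reported as counts per million of the
effective (factor-scaled) gene library. Computing factors on genes and
applying them to TE loci keeps TE-driven composition changes from biasing
the normalization. Note that with more than two samples TMM factors are
only approximately invariant to uniform depth scaling of one library
(the precision weights depend weakly on depth); the two-sample contracts
(identical or uniformly scaled libraries → factors exactly 1) hold exactly.

Z-scores use the n−1 standard deviation; constant rows map to all-zero and
are flagged. Clustering is agglomerative with complete linkage on
1 − Pearson correlation between rows, cut into k = 2 groups; rows are
processed in sorted index order so the partition is invariant to input row
order (labels are renumbered by first appearance). Zero-variance rows are
held out of the tree and attached to the nearest cluster centroid
(euclidean), flagged. Per-subfamily summaries sum member-locus counts
without any multi-mapping filter. Differential-expression thresholding
(fold change > 2 and adjusted p < 0.05) is a filter over an externally
computed statistics table; the moderated test itself is out of scope.

## Methylation

Per-locus methylation is the unweighted mean of the levels of CpGs whose C
position falls inside the locus (strand ignored); loci with no profiled
CpG are absent from the output, and no coverage or minimum-CpG filter is
applied beyond ≥ 1 (configurable). Replicate averaging is unweighted over
the replicates that profiled the locus; subfamily levels are unweighted
means over detected member loci — deliberately *not* CpG-weighted, so a
CpG-dense locus does not dominate its subfamily (the two coincide only when
all loci have equal CpG counts). Set comparisons require disjoint locus-id
sets and report medians plus the two-sided rank-sum p.

## Alignment profiles

Columns whose gap fraction strictly exceeds 0.85 are removed (a column
that is exactly 85% gaps is kept); trimming happens before signal
averaging, since the plotted alignment is the trimmed one. Signal tracks
are min-max scaled per locus (constant tracks to all-zero, flagged),
projected so the i-th non-gap column carries the i-th track value and gap
columns are missing, and averaged column-wise over non-missing values with
a per-column coverage count.

## Cross-species scoring

TE conservation is `aligned_bp / consensus_length`, capped at 1 — aligned
bases of the *human* sequence (substitutions ignored), normalized by the
subfamily consensus so that short integrants are not inflated. Statuses
(not detected / same subfamily / same family / unannotated) partition all
(locus, species) pairs; similarity is 0 exactly when not detected.

The zinc-fingerprint score is this package's own declared convention (the
field has no canonical one): global alignment of the two finger sequences
by dynamic programming, per-finger match score = fraction of identical
residues at positions −1, 2, 3, 6 (0…1 in steps of ¼), gap penalty 0.25
per skipped finger, optimum normalized by the longer fingerprint and
clamped to [0, 1]. It is symmetric and equals 1 iff the fingerprints are
identical; deleting one of n fingers from an otherwise identical
fingerprint scores (n − 1 − 0.25)/n. KRAB-domain similarity is not computed
internally; callers may supply it as an external metric and the outputs
keep the two components separate. Ortholog candidates are ranked by this
score; ties break lexicographically and are flagged.

## Synthetic data: what it emulates, and what it does not

The generator draws every section from its own substream spawned from one
seed, so outputs are deterministic and editing one plan leaves the others
unchanged. Defaults define the packaged study:

- **Genome**: 2 chromosomes × 5 Mb — large enough for 50-kb proximity
  windows, small enough for seconds-scale runs. 120 genes of 2–3 exons;
  features placed with ≥ 1.2 kb spacing so independent loci never fall
  within a merge window.
- **TE catalog**: six subfamilies (an LTR12C-like planted subfamily with
  paired HERV9-style internals and 20% full-length proviruses, plus
  LTR12B-, THE1D-, MLT1D-, lone-internal- and AluY-like backgrounds;
  ~200 loci). Standalone records fragment with probability 0.25 into two
  within-span fragments sharing a linkage id; five decoy TEs are planted
  over gene exons so curation has something to discard.
- **Transcriptomes**: 3 groups × 2 samples; 10 planted chimeras per group
  (9 on the planted subfamily, 1 off-target driver, each on a distinct solo
  locus with a distinct cognate gene, TSS jittered ± 30 bp across samples)
  and 20 decoys per group, each violating exactly one calling predicate
  (mono-exonic in an LTR; spliced but TSS outside any TE; TSS in an LTR but
  spliced into intergenic space).
- **Peaks**: 500 peaks of 200 bp per replicate set, 40% placed fully inside
  planted-subfamily loci (guaranteeing > 50% overlap), the rest uniform;
  3 replicates with ± 10 bp jitter and a 20% single-replicate dropout so
  the consensus step is exercised.
- **Expression**: 5 stages × 2 replicates; maternal template (1,0,0,0,0)
  and ZGA template (0,0,0,1,1) over stages, 30 TE loci per cluster,
  negative-binomial counts (dispersion 0.1) around template × locus size ×
  sample depth, plus 150 flat gene rows so TMM has a gene library.
- **Methylation**: two disjoint sets of 50 loci; per-locus levels from
  Beta distributions with means 0.70 vs 0.40 at concentration κ = 20
  (sd ≈ 0.10), ~1 CpG per 100 bp, two replicates with sd 0.05 observation
  noise, clipped to [0, 1].
- **Orthologs**: per-species synteny detection probabilities falling with
  divergence (0.95 → 0.45), aligned fractions from Beta(8, 2), foreign
  labels same-subfamily/same-family/unannotated at 0.8/0.1/0.1; fingerprint
  candidates are the query with 1–5 fingers mutated plus random decoys.

The generator emulates the *statistical structure* of the real inputs, not
their sequence content: no nucleotide composition, no read-level noise, no
mappability or coverage bias, no overlapping genes or nested TEs, and CpG
levels are locus-homogeneous rather than position-dependent. Passing tests
therefore demonstrate that the implementations are correct and calibrated
under the planted model — not that real-data confounders (assembly
artifacts, multi-mapping, bisulfite conversion failure) are handled.

## Problem sizes used in validation

The test suite and the acceptance script validate at these scales, chosen
to make every check decisive in seconds: ≥ 500 random parameterizations
(population ≤ 12) against enumeration oracles for the exact tests and
1,000 random vectors for BH; the packaged seed-42 study (30 planted
chimeras, 60 decoys) for calling; 200 simulation replicates each for peak
null calibration (empirical α at 0.05 ≤ 0.07) and power (padj < 10⁻⁶ in
≥ 195/200); 50 replicates per noise level for cluster recovery; 50 + 200
replicates for methylation power and null uniformity; and 100 simulated
annotations for the curation round trip.

## Known limitations

Read mapping, transcript assembly, peak calling, bisulfite processing,
liftOver, MSA computation and moderated differential-expression statistics
are all upstream of this package and consumed as files. The binomial peak
model ignores peak width (conservative). The fingerprint score is a
declared stand-in for an unpublished scoring scheme and outputs are labeled
accordingly. The hypergeometric TcGT universe counts loci, not aggregates;
an aggregate-level variant would require a different background model.
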