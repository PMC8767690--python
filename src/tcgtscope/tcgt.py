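"""Transpochimeric gene transcript (TcGT) detection and enrichment.

A TcGT is a transcript that initiates inside an LTR-class transposable
element and splices into an annotated gene: its strand-aware 5' end (TSS)
lies within an LTR locus, it carries at least one splice junction, and at
least one exon downstream of a junction overlaps an annotated exon.  The
cognate gene is the one with the largest downstream exonic overlap.

Per gene and driver subfamily, TcGT TSSs within 100 bp of each other are
chained into aggregates (single linkage); per sample group, occurrence is
the number of samples contributing at least one member.  Per-subfamily
over-representation among the group's driver loci is then scored with a
hypergeometric test against the LTR catalog and BH-corrected within the
group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .repeats import TEInstance
from .stats import PValueVector, bh_adjust, hypergeom_sf

log = logging.getLogger(__name__)


@dataclass
class TranscriptModel:
    """An assembled transcript from one sample.

    ``exons`` are 0-based half-open intervals in ascending genomic order;
    transcription order follows ``strand``.
    """

    transcript_id: str
    sample_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.transcript_id}: empty exon [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = end

    @property
    def n_junctions(self) -> int:
        return len(self.exons) - 1


@dataclass
class TcGT:
    """One chimeric-transcript call: LTR driver locus, cognate gene, TSS."""

    driver_locus_id: str
    driver_subfamily: str
    gene_id: str
    tss: int
    sample_id: str
    transcript_id: str = ""


@dataclass
class TcGTAggregate:
    """A 100-bp single-linkage cluster of TcGT TSSs for one gene."""

    gene_id: str
    driver_subfamily: str
    representative_tss: int
    member_tss: list[int]
    members: list[TcGT] = field(default_factory=list)
    group_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class EnrichmentRow:
    subfamily: str
    group: str
    tcgt_count: int
    p: float
    padj: float

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 and 0 <= self.padj <= 1):
            raise ValueError(f"p-values outside [0,1]: p={self.p} padj={self.padj}")


def transcript_tss(t: TranscriptModel) -> int:
    """Strand-aware 5'-most transcribed base of a transcript."""
    if t.strand == "+":
        return t.exons[0][0]
    return t.exons[-1][1] - 1


def _downstream_exons(t: TranscriptModel) -> list[tuple[int, int]]:
    """Exons lying downstream of at least one splice junction."""
    return t.exons[1:] if t.strand == "+" else t.exons[:-1]


def call_tcgts(
    transcripts: Sequence[TranscriptModel],
    catalog: Sequence[TEInstance],
    gene_exons,
    ltr_class: str = "LTR",
) -> list[TcGT]:
    """Call TcGTs from transcript models against an LTR catalog and gene exons.

    ``gene_exons`` is a DataFrame with columns gene_id, chrom, start, end
    (half-open).  A transcript is called iff its TSS base lies inside an
    LTR-class locus, it has at least one splice junction, and an exon
    downstream of a junction overlaps an annotated gene exon.  The cognate
    gene is the gene with the largest total downstream overlap (ties break
    to the lexicographically smallest gene_id).
    """
    ltr_trees: dict[str, IntervalTree] = {}
    for te in catalog:
        if ltr_class and te.te_class != ltr_class:
            continue
        ltr_trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end, te)
    gene_trees: dict[str, IntervalTree] = {}
    for row in gene_exons.itertuples(index=False):
        if row.end > row.start:
            gene_trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.gene_id)

    calls: list[TcGT] = []
    for t in transcripts:
        if t.chrom not in ltr_trees:
            log.warning("transcript %s on %s absent from catalog; skipped", t.transcript_id, t.chrom)
            continue
        if t.n_junctions < 1:
            continue
        tss = transcript_tss(t)
        hits = [iv.data for iv in ltr_trees[t.chrom].at(tss)]
        if not hits:
            continue
        if len(hits) > 1:
            # overlapping LTRs: take the strand-aware 5'-most one
            key = (lambda te: te.start) if t.strand == "+" else (lambda te: -te.end)
            hits.sort(key=key)
            log.info("TSS of %s inside %d overlapping LTRs; assigned to %s",
                     t.transcript_id, len(hits), hits[0].locus_id)
        driver = min(hits, key=(lambda te: te.start) if t.strand == "+" else (lambda te: -te.end))

        gtree = gene_trees.get(t.chrom)
        if gtree is None:
            continue
        overlap_by_gene: dict[str, int] = {}
        for start, end in _downstream_exons(t):
            for iv in gtree.overlap(start, end):
                bp = min(end, iv.end) - max(start, iv.begin)
                overlap_by_gene[iv.data] = overlap_by_gene.get(iv.data, 0) + bp
        if not overlap_by_gene:
            continue
        gene = min(overlap_by_gene, key=lambda g: (-overlap_by_gene[g], g))
        calls.append(
            TcGT(
                driver_locus_id=driver.locus_id, driver_subfamily=driver.subfamily,
                gene_id=gene, tss=tss, sample_id=t.sample_id, transcript_id=t.transcript_id,
            )
        )
    return calls


def aggregate_tcgts(
    tcgts: Sequence[TcGT],
    window: int = 100,
    groups: Mapping[str, str] | None = None,
) -> list[TcGTAggregate]:
    """Single-linkage chain TcGT TSSs within ``window`` bp per (gene, subfamily).

    The representative TSS is the 5'-most (numerically smallest) member.
    When ``groups`` maps sample_id to group, each aggregate's group count is
    the number of distinct samples of that group contributing a member.
    """
    by_key: dict[tuple[str, str], list[TcGT]] = {}
    for c in tcgts:
        by_key.setdefault((c.gene_id, c.driver_subfamily), []).append(c)

    aggregates: list[TcGTAggregate] = []
    for (gene, subfam), members in sorted(by_key.items()):
        members = sorted(members, key=lambda c: (c.tss, c.sample_id, c.transcript_id))
        chain: list[TcGT] = []
        for c in members + [None]:  # type: ignore[list-item]
            if chain and (c is None or c.tss - chain[-1].tss > window):
                agg = TcGTAggregate(
                    gene_id=gene, driver_subfamily=subfam,
                    representative_tss=chain[0].tss,
                    member_tss=[m.tss for m in chain], members=list(chain),
                )
                if groups is not None:
                    counts: dict[str, int] = {}
                    for grp in set(groups.values()):
                        counts[grp] = len(
                            {m.sample_id for m in chain if groups.get(m.sample_id) == grp}
                        )
                    agg.group_counts = counts
                aggregates.append(agg)
                chain = []
            if c is not None:
                chain.append(c)
    return aggregates


def tcgt_enrichment_table(
    aggregates: Sequence[TcGTAggregate],
    catalog: Sequence[TEInstance],
    groups: Mapping[str, str],
    ltr_class: str = "LTR",
) -> list[EnrichmentRow]:
    """Per-(group, subfamily) hypergeometric over-representation of drivers.

    For each group g and subfamily S: k = distinct driver loci of S active
    in g, K = catalog loci of S, n = distinct driver loci of any subfamily
    active in g, N = all catalog LTR loci.  BH correction is applied across
    subfamilies within each group.
    """
    ltr_loci = [te for te in catalog if not ltr_class or te.te_class == ltr_class]
    loci_by_subfam: dict[str, set[str]] = {}
    for te in ltr_loci:
        loci_by_subfam.setdefault(te.subfamily, set()).add(te.locus_id)
    N = sum(len(v) for v in loci_by_subfam.values())
    group_names = sorted(set(groups.values()))
    subfamilies = sorted(loci_by_subfam)

    rows: list[EnrichmentRow] = []
    for grp in group_names:
        active: dict[str, set[str]] = {sf: set() for sf in subfamilies}
        n_active: set[str] = set()
        counts: dict[str, int] = {sf: 0 for sf in subfamilies}
        for agg in aggregates:
            members = [m for m in agg.members if groups.get(m.sample_id) == grp]
            if not members:
                continue
            sf = agg.driver_subfamily
            if sf not in active:  # driver outside the LTR universe
                continue
            counts[sf] += 1
            for m in members:
                active[sf].add(m.driver_locus_id)
                n_active.add(m.driver_locus_id)
        n = len(n_active)
        pvals = []
        for sf in subfamilies:
            k = len(active[sf])
            K = len(loci_by_subfam[sf])
            pvals.append(1.0 if n == 0 else hypergeom_sf(min(k, min(K, n)), K, n, N))
        adj = bh_adjust(PValueVector(pvals, subfamilies))
        for sf, p, padj in zip(subfamilies, pvals, adj.values):
            rows.append(EnrichmentRow(subfamily=sf, group=grp, tcgt_count=counts[sf], p=p, padj=padj))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]):
    import pandas as pd

    return pd.DataFrame(
        [{"subfamily": r.subfamily, "group": r.group, "tcgt_count": r.tcgt_count,
          "p": r.p, "padj": r.padj} for r in rows]
    )
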