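"""ChIP peak / TE-subfamily enrichment and consensus peak construction.

A peak is assigned to the TE locus it overlaps most, provided the overlap
exceeds half the peak (strictly above 50%).  Per-subfamily enrichment is an
exact binomial test of the number of assigned peaks against the subfamily's
share of the genome (correcting for total genomic size), BH-corrected
across subfamilies.  Consensus peaks are regions supported by at least two
replicates, merged into the union of the supporting intervals.  A Fisher
exact test scores whether a gene set is enriched for TSSs within 50 kb of a
set of TE loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .repeats import SubfamilySize, TEInstance
from .stats import PValueVector, bh_adjust, binom_sf, fisher_exact_2x2
from .tcgt import EnrichmentRow

log = logging.getLogger(__name__)


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    score: float | None = None
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak with start >= end: {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakAssignment:
    peak: Peak
    locus_id: str | None
    subfamily: str | None
    overlap_bp: int


def assign_peaks(
    peaks: Sequence[Peak],
    catalog: Sequence[TEInstance],
    min_frac: float = 0.5,
) -> list[PeakAssignment]:
    """Assign each peak to its best-overlapping TE locus.

    The assignment stands only if overlap_bp / peak_length is strictly
    greater than ``min_frac``; otherwise the peak is reported unassigned.
    """
    trees: dict[str, IntervalTree] = {}
    for te in catalog:
        trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end, te)
    out: list[PeakAssignment] = []
    for p in peaks:
        best: TEInstance | None = None
        best_bp = 0
        tree = trees.get(p.chrom)
        if tree is not None:
            for iv in tree.overlap(p.start, p.end):
                bp = min(p.end, iv.end) - max(p.start, iv.begin)
                te = iv.data
                if bp > best_bp or (bp == best_bp and best is not None and te.locus_id < best.locus_id):
                    best, best_bp = te, bp
        if best is not None and best_bp / p.length > min_frac:
            out.append(PeakAssignment(p, best.locus_id, best.subfamily, best_bp))
        else:
            out.append(PeakAssignment(p, None, None, best_bp))
    return out


def subfamily_peak_enrichment(
    assignments: Sequence[PeakAssignment],
    n_peaks_total: int,
    sizes: Sequence[SubfamilySize],
    genome_bp: int,
) -> list[EnrichmentRow]:
    """Binomial enrichment of assigned peaks per subfamily.

    Each peak is one Bernoulli trial with success probability
    total_bp(subfamily) / genome_bp; p = P(X >= k assigned peaks).
    """
    if genome_bp < max((s.total_bp for s in sizes), default=0):
        raise ValueError("genome_bp smaller than a subfamily's total size")
    counts: dict[str, int] = {}
    for a in assignments:
        if a.subfamily is not None:
            counts[a.subfamily] = counts.get(a.subfamily, 0) + 1
    usable = [s for s in sizes if s.total_bp > 0]
    for s in sizes:
        if s.total_bp <= 0:
            log.warning("subfamily %s has zero genomic size; skipped", s.subfamily)
    labels = [s.subfamily for s in usable]
    pvals = [
        binom_sf(counts.get(s.subfamily, 0), n_peaks_total, s.total_bp / genome_bp)
        for s in usable
    ]
    adj = bh_adjust(PValueVector(pvals, labels))
    return [
        EnrichmentRow(subfamily=sf, group="peaks", tcgt_count=counts.get(sf, 0), p=p, padj=q)
        for sf, p, q in zip(labels, pvals, adj.values)
    ]


def consensus_peaks(
    replicate_sets: Sequence[Sequence[Peak]],
    min_support: int = 2,
) -> list[Peak]:
    """Regions covered by >= ``min_support`` distinct replicates, merged.

    Each consensus peak spans the union of all replicate peaks overlapping
    a region of sufficient replicate support.  Symmetric in replicate order.
    """
    if len(replicate_sets) < min_support:
        raise ValueError(
            f"need at least {min_support} replicate sets, got {len(replicate_sets)}"
        )
    # sweep per chromosome over distinct-replicate coverage depth
    events: dict[str, list[tuple[int, int, int]]] = {}
    peaks_by_chrom: dict[str, list[Peak]] = {}
    for rep_idx, peaks in enumerate(replicate_sets):
        merged_per_rep: dict[str, IntervalTree] = {}
        for p in peaks:
            merged_per_rep.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
            peaks_by_chrom.setdefault(p.chrom, []).append(p)
        for chrom, tree in merged_per_rep.items():
            tree.merge_overlaps()
            for iv in tree:
                events.setdefault(chrom, []).append((iv.begin, +1, rep_idx))
                events.setdefault(chrom, []).append((iv.end, -1, rep_idx))

    out: list[Peak] = []
    for chrom in sorted(events):
        # ends sort before starts at equal positions: abutting half-open
        # intervals do not overlap
        evs = sorted(events[chrom], key=lambda e: (e[0], e[1]))
        depth = 0
        core_start: int | None = None
        cores: list[tuple[int, int]] = []
        for pos, delta, _rep in evs:
            depth += delta
            if depth >= min_support and core_start is None:
                core_start = pos
            elif depth < min_support and core_start is not None:
                cores.append((core_start, pos))
                core_start = None
        tree = IntervalTree()
        for p in peaks_by_chrom.get(chrom, []):
            tree.addi(p.start, p.end)
        spans = IntervalTree()
        for cs, ce in cores:
            hits = tree.overlap(cs, ce)
            lo = min(iv.begin for iv in hits)
            hi = max(iv.end for iv in hits)
            spans.addi(lo, hi)
        spans.merge_overlaps()
        for iv in sorted(spans):
            out.append(Peak(chrom, iv.begin, iv.end, replicate_id="consensus"))
    return out


def proximity_enrichment(
    gene_set: Sequence[str],
    all_genes: pd.DataFrame,
    te_loci: Sequence[TEInstance],
    window: int = 50_000,
) -> tuple[list[list[int]], float]:
    """Fisher test: is ``gene_set`` enriched for TSSs within ``window`` of a TE locus?

    ``all_genes`` must carry gene_id, chrom and tss columns.  Distance is
    from the gene TSS to the nearest TE edge, zero when the TSS lies inside
    a locus.  Returns the 2x2 table
    [[in-set & near, in-set & far], [out-of-set & near, out-of-set & far]]
    and the two-sided Fisher p-value.
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    gene_ids = set(all_genes["gene_id"])
    missing = set(gene_set) - gene_ids
    if missing:
        raise ValueError(f"gene_set members absent from all_genes: {sorted(missing)[:5]}")
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {t.chrom for t in te_loci}:
        loci = sorted((t.start, t.end) for t in te_loci if t.chrom == chrom)
        starts[chrom] = np.array([s for s, _ in loci])
        ends[chrom] = np.array([e for _, e in loci])

    in_set = set(gene_set)
    table = [[0, 0], [0, 0]]
    for row in all_genes.itertuples(index=False):
        near = False
        if row.chrom in starts:
            s, e = starts[row.chrom], ends[row.chrom]
            dist = np.where(
                (s <= row.tss) & (row.tss < e), 0,
                np.minimum(np.abs(s - row.tss), np.abs(row.tss - (e - 1))),
            )
            near = bool((dist <= window).any())
        i = 0 if row.gene_id in in_set else 1
        j = 0 if near else 1
        table[i][j] += 1
    return table, fisher_exact_2x2(table)


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subfamily": r.subfamily, "n_peaks": r.tcgt_count, "p": r.p, "padj": r.padj}
         for r in rows]
    )
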