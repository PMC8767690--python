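"""Curated transposable-element annotation.

Builds the TE catalog most analyses run against: parse RepeatMasker-style
records, reassemble integrants that the annotator split into fragments,
merge LTRs with their adjacent internal (``-int``) segments into single
full-length ERV features, flag the remaining unpaired LTRs as solo LTRs,
drop TEs that overlap gene exons, and tabulate per-subfamily genomic size.

All coordinates inside the package are 0-based half-open; converters sit at
the I/O boundary (RepeatMasker ``.out`` is 1-based inclusive, BED is already
half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)


@dataclass
class TEInstance:
    """One curated TE locus, possibly merged from several source records."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str = "."
    te_class: str = "."
    locus_id: str = ""
    is_solo_ltr: bool = False
    merged_from: list[str] = field(default_factory=list)
    linkage_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.locus_id or self.subfamily}: start >= end ({self.start} >= {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.merged_from:
            self.merged_from = [self.locus_id] if self.locus_id else []

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SubfamilySize:
    subfamily: str
    n_loci: int
    total_bp: int


def _split_class_family(tag: str) -> tuple[str, str]:
    if "/" in tag:
        cls, fam = tag.split("/", 1)
        return cls, fam
    return tag, "."


def parse_te_annotation(source: str | Path, dialect: str = "rmsk_out") -> list[TEInstance]:
    """Parse a TE annotation file into TEInstances.

    ``dialect`` is ``"rmsk_out"`` for the 15-column RepeatMasker ``.out``
    layout (1-based inclusive coordinates, strand ``C`` meaning minus,
    column 15 linking fragments of one integrant) or ``"bed"`` for a BED6+
    table with subfamily/family/class in columns 7-9 and an optional
    linkage id in column 10.
    """
    if dialect not in {"rmsk_out", "bed"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(source)
    instances: list[TEInstance] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if dialect == "rmsk_out":
                # the .out format opens with two header lines and a blank line
                if stripped.startswith(("SW", "score", "bit")):
                    continue
                fields = stripped.split()
                if len(fields) < 14:
                    raise ValueError(f"{path}:{lineno}: malformed RepeatMasker line ({len(fields)} fields)")
                try:
                    chrom = fields[4]
                    start = int(fields[5]) - 1  # 1-based inclusive -> half-open
                    end = int(fields[6])
                    strand = "-" if fields[8] == "C" else "+"
                    subfamily = fields[9]
                    te_class, family = _split_class_family(fields[10])
                    linkage = fields[14] if len(fields) > 14 else None
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed RepeatMasker line: {exc}") from exc
            else:
                if stripped.startswith(("#", "track", "browser")) or stripped.split("\t")[0] == "chrom":
                    continue
                fields = stripped.split("\t")
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6+ line has only {len(fields)} fields")
                try:
                    chrom = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    strand = fields[5]
                    subfamily = fields[6] if len(fields) > 6 else fields[3]
                    family = fields[7] if len(fields) > 7 else "."
                    te_class = fields[8] if len(fields) > 8 else "."
                    linkage = fields[9] if len(fields) > 9 and fields[9] not in {".", ""} else None
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
            locus_id = fields[3] if dialect == "bed" else f"{subfamily}|{chrom}:{start}-{end}"
            instances.append(
                TEInstance(
                    chrom=chrom, start=start, end=end, strand=strand,
                    subfamily=subfamily, family=family, te_class=te_class,
                    locus_id=locus_id, linkage_id=linkage,
                )
            )
    return instances


def _sorted(instances: Iterable[TEInstance]) -> list[TEInstance]:
    return sorted(instances, key=lambda t: (t.chrom, t.start, t.end))


def merge_fragments(instances: Sequence[TEInstance], max_gap: int = 100) -> list[TEInstance]:
    """Reassemble fragmented integrants into single features.

    Consecutive records on one chromosome merge when they share a non-null
    ``linkage_id`` (the annotator split one integrant) or when they are the
    same subfamily on the same strand separated by at most ``max_gap`` bp.
    The merged feature spans min(start)..max(end) and lists every source id
    in ``merged_from``.  Idempotent.
    """
    out: list[TEInstance] = []
    for inst in _sorted(instances):
        if out:
            prev = out[-1]
            same_linkage = (
                prev.linkage_id is not None
                and inst.linkage_id is not None
                and prev.linkage_id == inst.linkage_id
                and prev.chrom == inst.chrom
            )
            adjacent = (
                prev.chrom == inst.chrom
                and prev.strand == inst.strand
                and prev.subfamily == inst.subfamily
                and inst.start - prev.end <= max_gap
            )
            if same_linkage or adjacent:
                out[-1] = replace(
                    prev,
                    end=max(prev.end, inst.end),
                    merged_from=prev.merged_from + inst.merged_from,
                )
                continue
        out.append(replace(inst, merged_from=list(inst.merged_from)))
    return out


def assemble_full_length_ervs(
    instances: Sequence[TEInstance],
    ltr_int_pairs: Mapping[str, str],
    max_gap: int = 500,
    ltr_class: str = "LTR",
) -> list[TEInstance]:
    """Merge LTR - internal (- LTR) runs into full-length ERV features.

    ``ltr_int_pairs`` maps an LTR subfamily to the internal subfamily it
    flanks (for instance LTR12C -> HERV9-int).  Runs of a paired LTR and
    internal segments on one strand, each gap at most ``max_gap`` bp, are
    merged into one feature labeled by the internal segment's subfamily and
    family.  LTR-class records not merged with any internal segment — i.e.
    not next to a paired internal — are flagged solo LTRs, the
    internal-recombination product devoid of coding sequence; internal
    segments standing alone are single features, not solo LTRs.
    """
    internal_of = dict(ltr_int_pairs)
    internal_names = set(internal_of.values())

    def compatible(a: TEInstance, b: TEInstance) -> bool:
        if a.chrom != b.chrom or a.strand != b.strand or b.start - a.end > max_gap:
            return False
        pair = {a.subfamily, b.subfamily}
        if a.subfamily in internal_names and b.subfamily in internal_names:
            return a.subfamily == b.subfamily
        for ltr, internal in internal_of.items():
            if pair == {ltr, internal} or (len(pair) == 1 and ltr in pair):
                return pair != {ltr}  # two adjacent LTRs without an internal do not merge
        if a.subfamily in internal_of and b.subfamily in internal_names:
            log.warning("LTR %s adjacent to unpaired internal %s left unmerged", a.locus_id, b.locus_id)
        return False

    runs: list[list[TEInstance]] = []
    for inst in _sorted(instances):
        if runs and compatible(runs[-1][-1], inst):
            runs[-1].append(inst)
        else:
            runs.append([inst])

    out: list[TEInstance] = []
    for run in runs:
        internals = [t for t in run if t.subfamily in internal_names]
        if len(run) > 1 and internals:
            proto = internals[0]
            merged_ids = [i for t in run for i in t.merged_from]
            out.append(
                TEInstance(
                    chrom=proto.chrom, start=run[0].start, end=run[-1].end,
                    strand=proto.strand, subfamily=proto.subfamily,
                    family=proto.family, te_class=proto.te_class,
                    locus_id=run[0].locus_id, is_solo_ltr=False,
                    merged_from=merged_ids, linkage_id=proto.linkage_id,
                )
            )
        else:
            for t in run:
                # an LTR-class record left unmerged is a solo LTR
                solo = (
                    t.subfamily not in internal_names
                    and (t.te_class == ltr_class or t.subfamily in internal_of)
                )
                out.append(replace(t, is_solo_ltr=solo, merged_from=list(t.merged_from)))
    return out


def exclude_exon_overlaps(
    instances: Sequence[TEInstance],
    exons: Sequence[tuple[str, int, int]],
) -> list[TEInstance]:
    """Drop every TE overlapping any exon by >= 1 bp (half-open intervals)."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in exons:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    kept = [
        t for t in instances
        if t.chrom not in trees or not trees[t.chrom].overlap(t.start, t.end)
    ]
    removed = len(instances) - len(kept)
    if removed:
        log.info("exclude_exon_overlaps: removed %d of %d TE loci", removed, len(instances))
    return kept


def subfamily_sizes(instances: Sequence[TEInstance]) -> list[SubfamilySize]:
    """Per-subfamily locus count and total genomic size in bp."""
    acc: dict[str, list[int]] = {}
    for t in instances:
        cnt_bp = acc.setdefault(t.subfamily, [0, 0])
        cnt_bp[0] += 1
        cnt_bp[1] += t.length
    return [SubfamilySize(sf, n, bp) for sf, (n, bp) in sorted(acc.items())]


# ---------------------------------------------------------------- I/O

_CATALOG_COLUMNS = [
    "chrom", "start", "end", "locus_id", "score", "strand", "subfamily",
    "family", "te_class", "linkage_id", "is_solo_ltr", "merged_from",
]


def write_catalog(instances: Sequence[TEInstance], path: str | Path) -> None:
    """Write the catalog as a headered BED6+ TSV (half-open coordinates).

    Columns 7-9 carry subfamily/family/class and column 10 the linkage id,
    so the file also re-parses through ``parse_te_annotation(dialect="bed")``.
    """
    rows = [
        {
            "chrom": t.chrom, "start": t.start, "end": t.end,
            "locus_id": t.locus_id, "score": ".", "strand": t.strand,
            "subfamily": t.subfamily, "family": t.family, "te_class": t.te_class,
            "linkage_id": t.linkage_id or ".",
            "is_solo_ltr": int(t.is_solo_ltr),
            "merged_from": ",".join(t.merged_from) or ".",
        }
        for t in _sorted(instances)
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> list[TEInstance]:
    df = pd.read_csv(path, sep="\t", dtype={"linkage_id": str, "merged_from": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TEInstance(
                chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                strand=row.strand, subfamily=row.subfamily, family=row.family,
                te_class=row.te_class, locus_id=row.locus_id,
                is_solo_ltr=bool(int(row.is_solo_ltr)),
                merged_from=[] if row.merged_from == "." else str(row.merged_from).split(","),
                linkage_id=None if row.linkage_id in (".", "nan") or pd.isna(row.linkage_id) else str(row.linkage_id),
            )
        )
    return out


def write_subfamily_sizes(sizes: Sequence[SubfamilySize], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in sizes]).to_csv(path, sep="\t", index=False)
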