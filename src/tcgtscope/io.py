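"""Readers and writers for the flat genomic formats the pipeline consumes.

GTF is 1-based inclusive on disk and converted to the package's 0-based
half-open convention on read; BED-like tables are already half-open.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .tcgt import TranscriptModel

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attrs(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_transcript_gtf(path: str | Path, sample_id: str | None = None) -> list[TranscriptModel]:
    """Read assembled transcript models (exon features) from a GTF file."""
    sample = sample_id if sample_id is not None else Path(path).stem
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            if fields[2] != "exon":
                continue
            attrs = _parse_attrs(fields[8])
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            rec = exons.setdefault(tid, {"chrom": fields[0], "strand": fields[6], "exons": []})
            rec["exons"].append((int(fields[3]) - 1, int(fields[4])))
    models = []
    for tid, rec in exons.items():
        models.append(
            TranscriptModel(
                transcript_id=tid, sample_id=sample, chrom=rec["chrom"],
                strand=rec["strand"], exons=sorted(rec["exons"]),
            )
        )
    return models


def write_transcript_gtf(models: Sequence[TranscriptModel], path: str | Path, source: str = "tcgtscope") -> None:
    with open(path, "w") as fh:
        for m in models:
            for start, end in m.exons:
                attrs = f'transcript_id "{m.transcript_id}"; sample_id "{m.sample_id}";'
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene exons from a GTF into a table (gene_id, chrom, strand, start, end)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            if fields[2] != "exon":
                continue
            attrs = _parse_attrs(fields[8])
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: exon without gene_id")
            rows.append((gid, fields[0], fields[6], int(fields[3]) - 1, int(fields[4])))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])


def write_gene_annotation(genes: pd.DataFrame, path: str | Path, source: str = "tcgtscope") -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(
                f"{row.chrom}\t{source}\texon\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def gene_tss_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware gene TSS (the 5'-most transcribed base) per gene."""
    recs = []
    for gid, grp in genes.groupby("gene_id", sort=True):
        strand = grp["strand"].iloc[0]
        chrom = grp["chrom"].iloc[0]
        tss = int(grp["start"].min()) if strand == "+" else int(grp["end"].max()) - 1
        recs.append((gid, chrom, strand, tss))
    return pd.DataFrame(recs, columns=["gene_id", "chrom", "strand", "tss"])


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_peaks(path: str | Path, replicate_id: str | None = None):
    """Read a BED3+/narrowPeak file into Peak records."""
    from .peaks import Peak

    rep = replicate_id if replicate_id is not None else Path(path).stem
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with {len(fields)} fields")
            score = None
            if len(fields) >= 5 and fields[4] not in {".", ""}:
                score = float(fields[4])
            out.append(Peak(fields[0], int(fields[1]), int(fields[2]), score=score, replicate_id=rep))
    return out


def write_peaks(peaks, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{score}\t.\n")


def read_cpg_calls(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read CpG methylation calls from a bedGraph-like TSV.

    Accepts either (chrom, pos, meth_level) with the level already a
    fraction, or (chrom, pos, meth_count, total_count) from which the
    fraction is computed.  Returns columns chrom, pos, meth_level, sample_id.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] == 3:
        df.columns = ["chrom", "pos", "meth_level"]
    elif df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["chrom", "pos", "meth_count", "total_count"]
        if (df["total_count"] <= 0).any():
            raise ValueError(f"{path}: non-positive total_count")
        df["meth_level"] = df["meth_count"] / df["total_count"]
        df = df[["chrom", "pos", "meth_level"]]
    else:
        raise ValueError(f"{path}: expected 3 or 4 columns, got {df.shape[1]}")
    if ((df["meth_level"] < 0) | (df["meth_level"] > 1)).any():
        raise ValueError(f"{path}: methylation level outside [0,1]")
    df["sample_id"] = sample_id if sample_id is not None else Path(path).stem
    return df


def write_cpg_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls[["chrom", "pos", "meth_level"]].to_csv(path, sep="\t", header=False, index=False)
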