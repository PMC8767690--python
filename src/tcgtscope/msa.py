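"""Post-processing of externally computed gapped multiple alignments.

Columns denser than 85% gaps are trimmed, per-locus ChIP signal tracks are
min-max scaled to [0,1], projected onto alignment columns (gaps become
missing values), and averaged column-wise into a consensus binding profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

GAP = "-"


@dataclass
class GappedAlignment:
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class SignalTrack:
    locus_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError(f"{self.locus_id}: empty signal track")


def read_alignment_fasta(path: str | Path) -> GappedAlignment:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return GappedAlignment(rows)


def write_alignment_fasta(a: GappedAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in a.rows.items():
            fh.write(f">{rid}\n{seq}\n")


def trim_gap_columns(
    a: GappedAlignment, max_gap_frac: float = 0.85
) -> tuple[GappedAlignment, list[int]]:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_frac``.

    Returns the trimmed alignment and the original indices of kept columns.
    """
    if not a.rows:
        return GappedAlignment({}), []
    mat = np.array([list(s) for s in a.rows.values()])
    gap_frac = (mat == GAP).mean(axis=0)
    kept = [i for i in range(mat.shape[1]) if gap_frac[i] <= max_gap_frac]
    trimmed = {rid: "".join(seq[i] for i in kept) for rid, seq in a.rows.items()}
    return GappedAlignment(trimmed), kept


def scale_track(t: SignalTrack) -> SignalTrack:
    """Min-max scale to [0,1]; constant tracks become all-zero (flagged)."""
    lo, hi = float(t.values.min()), float(t.values.max())
    if hi == lo:
        log.info("scale_track: constant track %s mapped to zeros", t.locus_id)
        return SignalTrack(t.locus_id, np.zeros_like(t.values))
    return SignalTrack(t.locus_id, (t.values - lo) / (hi - lo))


def project_track(row: str, t: SignalTrack) -> np.ndarray:
    """Spread a per-base track over a gapped row; gaps carry NaN."""
    ungapped = sum(1 for c in row if c != GAP)
    if ungapped != t.values.size:
        raise ValueError(
            f"{t.locus_id}: track length {t.values.size} != ungapped row length {ungapped}"
        )
    out = np.full(len(row), np.nan)
    j = 0
    for i, c in enumerate(row):
        if c != GAP:
            out[i] = t.values[j]
            j += 1
    return out


def mean_profile(projected: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise mean over non-missing values, plus per-column coverage.

    Columns where no track contributes report NaN.
    """
    if len(projected) == 0:
        raise ValueError("need at least one projected track")
    mat = np.vstack(projected)
    coverage = np.sum(~np.isnan(mat), axis=0)
    total = np.nansum(mat, axis=0)
    mean = np.divide(total, coverage, out=np.full(mat.shape[1], np.nan),
                     where=coverage > 0)
    return mean, coverage


def alignment_profile(
    a: GappedAlignment,
    tracks: Mapping[str, SignalTrack],
    max_gap_frac: float = 0.85,
) -> pd.DataFrame:
    """Trim, scale, project and average: the full consensus-profile recipe.

    Tracks are given per locus in ungapped coordinates of the *original*
    rows; trimming happens first, so projected values at trimmed columns
    are dropped.  Returns a table (column, mean, coverage) over the
    trimmed alignment columns.
    """
    trimmed, kept = trim_gap_columns(a, max_gap_frac)
    projected = []
    for rid, track in tracks.items():
        if rid not in a.rows:
            raise KeyError(f"track {rid} not in alignment")
        full = project_track(a.rows[rid], scale_track(track))
        projected.append(full[kept])
    mean, cov = mean_profile(projected)
    return pd.DataFrame({"column": np.arange(len(kept)), "mean": mean, "coverage": cov})
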