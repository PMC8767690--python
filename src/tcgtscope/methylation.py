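"""Per-locus and per-subfamily CpG methylation from RRBS-style calls.

CpGs falling inside a TE locus (position of the C, half-open locus
interval, strand ignored) are averaged without coverage weighting into a
per-locus methylation level; loci with no profiled CpG are absent from the
output.  Replicates are averaged where available, and subfamily levels are
the unweighted mean over detected member loci.  Locus sets (for instance
KZFP-bound versus unbound integrants) are compared with a two-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .repeats import TEInstance
from .stats import RankSumResult, ranksum_test


@dataclass
class LocusMethylation:
    locus_id: str
    sample_id: str
    mean_meth: float
    n_cpgs: int

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise ValueError(f"{self.locus_id}: n_cpgs must be >= 1")
        if not (0.0 <= self.mean_meth <= 1.0):
            raise ValueError(f"{self.locus_id}: mean_meth outside [0,1]: {self.mean_meth}")


def locus_methylation(calls: pd.DataFrame, catalog: Sequence[TEInstance]) -> pd.DataFrame:
    """Mean methylation per (locus, sample) over contained CpGs.

    ``calls`` carries chrom, pos, meth_level, sample_id.  Returns a table
    with locus_id, sample_id, mean_meth, n_cpgs; loci with zero profiled
    CpGs are excluded.
    """
    if ((calls["meth_level"] < 0) | (calls["meth_level"] > 1)).any():
        raise ValueError("meth_level outside [0,1]")
    trees: dict[str, IntervalTree] = {}
    for te in catalog:
        trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end, te.locus_id)
    rows = []
    for call in calls.itertuples(index=False):
        tree = trees.get(call.chrom)
        if tree is None:
            continue
        for iv in tree.at(call.pos):
            rows.append((iv.data, call.sample_id, call.meth_level))
    if not rows:
        return pd.DataFrame(columns=["locus_id", "sample_id", "mean_meth", "n_cpgs"])
    df = pd.DataFrame(rows, columns=["locus_id", "sample_id", "meth_level"])
    out = (
        df.groupby(["locus_id", "sample_id"], sort=True)["meth_level"]
        .agg(mean_meth="mean", n_cpgs="size")
        .reset_index()
    )
    out["n_cpgs"] = out["n_cpgs"].astype(int)
    return out


def average_replicates(locus_table: pd.DataFrame, replicate_groups: Mapping[str, str]) -> pd.DataFrame:
    """Average per-locus levels over the replicates that profiled the locus.

    ``replicate_groups`` maps sample_id to a replicate-group tag; the mean
    is unweighted over the replicates present for each locus, and n_cpgs is
    summed over them.
    """
    df = locus_table.copy()
    df["sample_id"] = df["sample_id"].map(replicate_groups.__getitem__)
    return (
        df.groupby(["locus_id", "sample_id"], sort=True)
        .agg(mean_meth=("mean_meth", "mean"), n_cpgs=("n_cpgs", "sum"))
        .reset_index()
    )


def subfamily_methylation(locus_table: pd.DataFrame, membership: Mapping[str, str]) -> pd.DataFrame:
    """Unweighted mean of member-locus levels per (subfamily, sample)."""
    df = locus_table.copy()
    unmapped = sorted(set(df["locus_id"]) - set(membership))
    if unmapped:
        raise ValueError(f"loci without subfamily membership: {unmapped[:10]}")
    df["subfamily"] = df["locus_id"].map(membership.__getitem__)
    return (
        df.groupby(["subfamily", "sample_id"], sort=True)
        .agg(mean_meth=("mean_meth", "mean"), n_loci=("locus_id", "nunique"))
        .reset_index()
    )


def compare_locus_sets(
    locus_table: pd.DataFrame,
    set_a: Sequence[str],
    set_b: Sequence[str],
) -> RankSumResult:
    """Two-sided rank-sum comparison of per-locus methylation between two sets.

    The sets must be disjoint locus-id collections; values are the
    mean_meth of loci present in ``locus_table`` (replicate-averaged tables
    are accepted as-is).
    """
    sa, sb = set(set_a), set(set_b)
    shared = sa & sb
    if shared:
        raise ValueError(f"locus sets overlap: {sorted(shared)[:5]}")
    va = locus_table.loc[locus_table["locus_id"].isin(sa), "mean_meth"].to_numpy()
    vb = locus_table.loc[locus_table["locus_id"].isin(sb), "mean_meth"].to_numpy()
    if va.size == 0 or vb.size == 0:
        raise ValueError("one of the locus sets has no profiled loci")
    return ranksum_test(va, vb)
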