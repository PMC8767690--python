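"""Count-matrix filtering, TMM normalization and temporal-pattern clustering.

Counts over genes and TE loci travel together in one matrix so that
normalization factors — trimmed mean of M-values (TMM) computed on the gene
rows, with gene-count column sums as library sizes — apply to both.  TE
loci are row-standardized (z-scores) and clustered by hierarchical
agglomeration with 1 - Pearson correlation as the distance, cut into two
groups to separate maternal-style (high in oocyte, silent after the 2-cell
stage) from ZGA-style (silent early, induced from the 8-cell stage)
temporal patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

GENE = "gene"
TE_LOCUS = "te_locus"


@dataclass
class CountMatrix:
    """Nonnegative integer counts, rows = features (genes or TE loci)."""

    counts: pd.DataFrame
    feature_kind: pd.Series  # index-aligned, values in {gene, te_locus}

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("row/column ids must be unique")
        self.feature_kind = self.feature_kind.reindex(self.counts.index)
        if self.feature_kind.isna().any():
            missing = self.counts.index[self.feature_kind.isna()][:5].tolist()
            raise ValueError(f"feature_kind missing for rows {missing}")

    @property
    def gene_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.feature_kind == GENE]

    @property
    def te_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.feature_kind == TE_LOCUS]


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame
    factors: pd.Series
    feature_kind: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")


@dataclass
class ClusterAssignment:
    labels: pd.Series  # locus_id -> cluster in {1..k}
    zscores: pd.DataFrame
    flagged_constant: list[str] = field(default_factory=list)


def filter_low_counts(m: CountMatrix) -> CountMatrix:
    """Keep rows whose total count is at least the number of samples."""
    n_samples = m.counts.shape[1]
    keep = m.counts.sum(axis=1) >= n_samples
    return CountMatrix(m.counts.loc[keep].copy(), m.feature_kind.loc[keep].copy())


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    logratio_trim: float = 0.3, sum_trim: float = 0.05,
) -> float:
    """TMM scaling factor of one library against the reference.

    The trimmed mean of M-values: genes with extreme log-ratios (30% from
    each tail) or extreme average intensity (5% from each tail) are trimmed,
    the remaining M-values averaged with inverse-variance (delta-method)
    weights, and the factor is 2 to that mean.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = pd.Series(log_r).rank().to_numpy()
    rank_e = pd.Series(abs_e).rank().to_numpy()
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_normalize(m: CountMatrix) -> NormalizedMatrix:
    """TMM-normalize all rows using the gene rows only.

    Library sizes are the gene-count column sums; the reference library is
    the one whose 75th count percentile (scaled by library size) is closest
    to the mean across samples; factors are rescaled to a unit geometric
    mean.  Values are returned as counts per million of the effective
    (factor-scaled) gene library.
    """
    genes = m.gene_counts
    if genes.empty:
        raise ValueError("no gene rows: TMM requires gene counts as library size")
    if m.counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = genes.sum(axis=0).astype(float)
    zero = lib[lib == 0]
    if not zero.empty:
        raise ValueError(f"sample(s) with all-zero gene counts: {zero.index.tolist()}")
    g = genes.to_numpy(dtype=float)
    q75 = np.array([np.quantile(g[:, j], 0.75) / lib.iloc[j] for j in range(g.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array([
        _tmm_pair_factor(g[:, j], g[:, ref_idx], lib.iloc[j], lib.iloc[ref_idx])
        for j in range(g.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff_lib = lib.to_numpy() * factors
    values = m.counts.to_numpy(dtype=float) / eff_lib * 1e6
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=m.counts.index, columns=m.counts.columns),
        factors=pd.Series(factors, index=m.counts.columns, name="tmm_factor"),
        feature_kind=m.feature_kind.copy(),
    )


def zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-standardize (mean 0, sd 1 with n-1 denominator); constant rows -> 0."""
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if constant:
        log.info("zscore_rows: %d constant rows set to zero", len(constant))
    safe_sd = sd.replace(0, np.nan)
    z = values.sub(mu, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return z, constant


def average_by_stage(values: pd.DataFrame, stages: Mapping[str, str]) -> pd.DataFrame:
    """Average replicate columns per stage, keeping first-appearance order."""
    order: list[str] = []
    for col in values.columns:
        st = stages[col]
        if st not in order:
            order.append(st)
    grouped = values.T.groupby(values.columns.map(stages.__getitem__)).mean().T
    return grouped[order]


def cluster_loci(z: pd.DataFrame, k: int = 2) -> ClusterAssignment:
    """Cut a complete-linkage correlation-distance dendrogram into ``k`` groups.

    Distance between rows is 1 - Pearson correlation.  Zero-variance rows
    (undefined correlation) are held out, then assigned to the cluster with
    the nearest (euclidean) mean profile, and flagged.  Cluster labels are
    renumbered 1..k by first appearance in row order, which makes the
    assignment deterministic and row-order invariant up to relabeling.
    """
    if z.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {z.shape[0]}")
    sd = z.std(axis=1, ddof=1)
    ok = z.index[(sd > 0) & sd.notna()]
    flagged = [i for i in z.index if i not in set(ok)]
    zz = z.loc[ok].sort_index()  # row-order invariance
    if zz.shape[0] < k:
        raise ValueError("too few non-constant rows to cluster")
    corr = np.corrcoef(zz.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="complete")
    raw = fcluster(tree, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=zz.index).reindex([i for i in z.index if i in set(ok)])

    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = labels.map(remap)

    if flagged:
        centroids = z.loc[labels.index].groupby(labels).mean()
        for rid in flagged:
            d = ((centroids - z.loc[rid]) ** 2).sum(axis=1)
            labels.loc[rid] = int(d.idxmin())
        log.info("cluster_loci: %d zero-variance rows assigned to nearest centroid", len(flagged))
    labels = labels.reindex(z.index).astype(int)
    return ClusterAssignment(labels=labels, zscores=z, flagged_constant=flagged)


def sum_by_subfamily(m: CountMatrix, membership: Mapping[str, str]) -> pd.DataFrame:
    """Sum TE-locus counts per subfamily per sample."""
    te = m.te_counts
    unmapped = [i for i in te.index if i not in membership]
    if unmapped:
        raise ValueError(f"loci without subfamily membership: {unmapped[:10]}")
    groups = te.index.map(membership.__getitem__)
    return te.groupby(groups).sum()


def significant_features(
    stats_table: pd.DataFrame,
    fc_col: str = "fold_change",
    padj_col: str = "padj",
    fc_thresh: float = 2.0,
    padj_thresh: float = 0.05,
) -> pd.DataFrame:
    """Differential-expression thresholding over an external statistics table.

    Keeps features with |fold change| above ``fc_thresh`` (fold changes are
    taken as ratios; values below 1 count as 1/value) and adjusted p below
    ``padj_thresh``.  The moderated test producing the table is external.
    """
    fc = stats_table[fc_col].astype(float)
    effective = np.where(fc >= 1, fc, 1.0 / fc.replace(0, np.nan))
    keep = (effective > fc_thresh) & (stats_table[padj_col] < padj_thresh)
    return stats_table.loc[keep.fillna(False) if hasattr(keep, "fillna") else keep]


# ---------------------------------------------------------------- I/O

def read_count_matrix(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "feature_kind" not in df.columns:
        raise ValueError(f"{path}: expected a feature_kind column")
    kind = df.pop("feature_kind")
    return CountMatrix(df.astype(int), kind)


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    out = m.counts.copy()
    out.insert(0, "feature_kind", m.feature_kind)
    out.to_csv(path, sep="\t")
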