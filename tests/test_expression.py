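"""Count filtering, TMM normalization, z-scoring and pattern clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from tcgtscope.expression import (
    GENE,
    TE_LOCUS,
    CountMatrix,
    average_by_stage,
    cluster_loci,
    filter_low_counts,
    significant_features,
    sum_by_subfamily,
    tmm_normalize,
    zscore_rows,
)
from tcgtscope.simulate import rand_index, simulate_cluster_profiles


def cm(rows: dict, kinds: dict | str = GENE, cols=None):
    df = pd.DataFrame(rows, index=cols).T if cols else pd.DataFrame(rows).T
    if isinstance(kinds, str):
        kind = pd.Series(kinds, index=df.index)
    else:
        kind = pd.Series(kinds)
    return CountMatrix(df, kind)


def tmm_oracle(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    """Independent straight-line evaluation of the trimmed-mean formula."""
    q75 = np.array([np.quantile(counts[:, j], 0.75) / lib[j] for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = []
    for j in range(counts.shape[1]):
        M, A, W = [], [], []
        for o, r in zip(counts[:, j], counts[:, ref]):
            if o > 0 and r > 0:
                m = np.log2((o / lib[j]) / (r / lib[ref]))
                a = 0.5 * (np.log2(o / lib[j]) + np.log2(r / lib[ref]))
                M.append(m)
                A.append(a)
                W.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        M, A, W = map(np.asarray, (M, A, W))
        if M.size == 0 or np.abs(M).max() < 1e-6:
            factors.append(1.0)
            continue
        n = M.size
        rm, ra = rankdata(M), rankdata(A)
        lo_m, lo_a = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
        keep = (
            (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        )
        factors.append(2 ** (np.sum(M[keep] / W[keep]) / np.sum(1.0 / W[keep])))
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestFilter:
    def test_row_sum_threshold_is_sample_count(self):
        m = cm({"a": [1, 1, 0], "b": [1, 1, 1], "c": [2, 1, 1]})
        kept = filter_low_counts(m)
        assert list(kept.counts.index) == ["b", "c"]

    def test_single_sample_boundary(self):
        m = cm({"a": [1], "b": [0]})
        assert list(filter_low_counts(m).counts.index) == ["a"]


class TestTMM:
    def test_identical_libraries_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 200, size=50)
        m = cm({f"g{i}": [int(col[i])] * 2 for i in range(50)})
        norm = tmm_normalize(m)
        assert norm.factors.to_numpy() == pytest.approx([1.0, 1.0])

    def test_uniform_depth_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 200, size=80)
        m = cm({f"g{i}": [int(col[i]), int(col[i]) * 2] for i in range(80)})
        norm = tmm_normalize(m)
        assert norm.factors.to_numpy() == pytest.approx([1.0, 1.0])
        # CPM values identical after normalization
        assert np.allclose(norm.values.iloc[:, 0], norm.values.iloc[:, 1])

    def test_matches_independent_formula_evaluation(self):
        rng = np.random.default_rng(7)
        counts = rng.negative_binomial(10, 10 / (10 + rng.lognormal(4, 1, size=(200, 4))))
        counts[:50, 1] *= 4  # composition shift
        m = cm({f"g{i}": counts[i] for i in range(200)},
               cols=["A", "B", "C", "D"])
        got = tmm_normalize(m).factors.to_numpy()
        lib = counts.sum(axis=0).astype(float)
        assert got == pytest.approx(tmm_oracle(counts.astype(float), lib), abs=1e-10)

    def test_scale_invariance_of_factors(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 500, size=(100, 3))
        m1 = cm({f"g{i}": counts[i] for i in range(100)})
        scaled = counts.copy()
        scaled[:, 2] *= 7
        m2 = cm({f"g{i}": scaled[i] for i in range(100)})
        f1 = tmm_normalize(m1).factors.to_numpy()
        f2 = tmm_normalize(m2).factors.to_numpy()
        # near-invariance: the inverse-variance weights depend weakly on
        # depth, so factors shift slightly with >2 samples
        assert f1 == pytest.approx(f2, rel=0.05)

    def test_te_rows_normalized_but_excluded_from_factors(self):
        rng = np.random.default_rng(4)
        rows = {f"g{i}": rng.integers(1, 200, size=2) for i in range(40)}
        kinds = {k: GENE for k in rows}
        rows["te1"] = np.array([1000, 1])  # wildly imbalanced TE row
        kinds["te1"] = TE_LOCUS
        base = {k: v for k, v in rows.items() if k != "te1"}
        f_with = tmm_normalize(CountMatrix(pd.DataFrame(rows).T, pd.Series(kinds))).factors
        f_without = tmm_normalize(cm(base)).factors
        assert f_with.to_numpy() == pytest.approx(f_without.to_numpy())

    def test_all_zero_sample_rejected(self):
        m = cm({"a": [0, 5], "b": [0, 3]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_normalize(m)


class TestZscore:
    def test_hand_computed_row(self):
        z, flagged = zscore_rows(pd.DataFrame({"r": [2.0, 4.0, 6.0]}).T)
        assert z.loc["r"].to_numpy() == pytest.approx([-1.0, 0.0, 1.0])
        assert flagged == []

    def test_constant_row_zeroed_and_flagged(self):
        z, flagged = zscore_rows(pd.DataFrame({"r": [5.0, 5.0, 5.0]}).T)
        assert (z.loc["r"] == 0).all() and flagged == ["r"]

    def test_idempotent_on_standardized_rows(self):
        df = pd.DataFrame({"r": [-1.0, 0.0, 1.0]}).T
        z, _ = zscore_rows(df)
        assert z.to_numpy() == pytest.approx(df.to_numpy())


class TestClustering:
    def test_planted_two_pattern_recovery(self):
        rng = np.random.default_rng(0)
        data, labels = simulate_cluster_profiles(rng, n_per_cluster=10, noise_sd=0.1)
        z, _ = zscore_rows(data)
        assign = cluster_loci(z, k=2)
        assert rand_index(assign.labels.to_numpy(), labels.to_numpy()) == 1.0

    def test_k_equals_rows_gives_singletons(self):
        rng = np.random.default_rng(1)
        data, _ = simulate_cluster_profiles(rng, n_per_cluster=3, noise_sd=0.2)
        assign = cluster_loci(data, k=len(data))
        assert assign.labels.nunique() == len(data)

    def test_duplicated_rows_co_cluster(self):
        rng = np.random.default_rng(2)
        data, _ = simulate_cluster_profiles(rng, n_per_cluster=5, noise_sd=0.1)
        dup = data.loc[["locus_000"]].rename(index={"locus_000": "copy"})
        assign = cluster_loci(pd.concat([data, dup]), k=2)
        assert assign.labels["copy"] == assign.labels["locus_000"]

    def test_row_order_invariant_partition(self):
        rng = np.random.default_rng(3)
        data, labels = simulate_cluster_profiles(rng, n_per_cluster=8, noise_sd=0.2)
        a = cluster_loci(data, k=2).labels
        b = cluster_loci(data.iloc[::-1], k=2).labels
        assert rand_index(a.loc[data.index].to_numpy(), b.loc[data.index].to_numpy()) == 1.0

    def test_constant_row_assigned_and_flagged(self):
        rng = np.random.default_rng(4)
        data, _ = simulate_cluster_profiles(rng, n_per_cluster=5, noise_sd=0.1)
        data.loc["flat"] = 0.5
        assign = cluster_loci(data, k=2)
        assert assign.flagged_constant == ["flat"]
        assert assign.labels["flat"] in {1, 2}


class TestSubfamilySumsAndDE:
    def test_sum_and_conservation(self):
        m = CountMatrix(
            pd.DataFrame({"l1": [3, 5], "l2": [2, 0], "l3": [1, 1]}).T,
            pd.Series({"l1": TE_LOCUS, "l2": TE_LOCUS, "l3": TE_LOCUS}),
        )
        got = sum_by_subfamily(m, {"l1": "S", "l2": "S", "l3": "T"})
        assert got.loc["S"].tolist() == [5, 5]
        assert got.sum(axis=0).tolist() == m.counts.sum(axis=0).tolist()

    def test_unmapped_locus_rejected(self):
        m = CountMatrix(pd.DataFrame({"l1": [1, 2]}).T, pd.Series({"l1": TE_LOCUS}))
        with pytest.raises(ValueError, match="l1"):
            sum_by_subfamily(m, {})

    def test_stage_averaging(self):
        df = pd.DataFrame({"a_r1": [2.0], "a_r2": [4.0], "b_r1": [6.0]}, index=["x"])
        got = average_by_stage(df, {"a_r1": "a", "a_r2": "a", "b_r1": "b"})
        assert got.loc["x"].tolist() == [3.0, 6.0]

    def test_fold_change_and_padj_thresholds(self):
        table = pd.DataFrame(
            {"fold_change": [3.0, 0.25, 1.5, 4.0], "padj": [0.01, 0.01, 0.01, 0.2]},
            index=["up", "down", "weak", "ns"],
        )
        got = significant_features(table)
        assert list(got.index) == ["up", "down"]
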