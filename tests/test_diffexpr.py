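import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centfinder.diffexpr import (
    bh_adjust,
    consensus_markers,
    merged_exon_length,
    nb_wald_de,
    sample_quality_gate,
    size_factors,
    tpm,
    wilcoxon_markers,
)
from centfinder.synthdata import simulate_counts


class TestMergedExonLength:
    @pytest.mark.parametrize(
        "exons, expected",
        [
            ([("1", 1, 10), ("1", 5, 20), ("1", 30, 40)], 31),
            ([("1", 100, 199)], 100),
            ([("1", 1, 10), ("1", 1, 10)], 10),
            ([("1", 1, 10), ("2", 1, 10)], 20),  # different chromosomes
            ([("1", 1, 10), ("1", 11, 20)], 20),  # adjacent intervals merge
        ],
    )
    def test_interval_union(self, exons, expected):
        assert merged_exon_length(exons) == expected

    def test_permutation_invariant(self):
        exons = [("1", 5, 20), ("1", 30, 40), ("1", 1, 10)]
        for perm in itertools.permutations(exons):
            assert merged_exon_length(list(perm)) == 31

    def test_malformed_interval_errors(self):
        with pytest.raises(ValueError):
            merged_exon_length([("1", 10, 5)])
        with pytest.raises(ValueError):
            merged_exon_length([])


class TestTpm:
    def test_equal_rates_split_evenly(self):
        counts = pd.DataFrame({"s": [10, 20]}, index=["a", "b"])
        out = tpm(counts, pd.Series({"a": 1000, "b": 2000}))
        np.testing.assert_allclose(out["s"], [5e5, 5e5])

    def test_single_gene_is_million(self):
        counts = pd.DataFrame({"s": [7]}, index=["a"])
        assert tpm(counts, pd.Series({"a": 500}))["s"].iloc[0] == pytest.approx(1e6)

    def test_count_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 100, (10, 2)),
                              index=[f"g{i}" for i in range(10)], columns=["s1", "s2"])
        lengths = pd.Series(rng.integers(200, 3000, 10), index=counts.index)
        doubled = counts.copy()
        doubled["s1"] *= 2
        pd.testing.assert_series_equal(tpm(counts, lengths)["s1"],
                                       tpm(doubled, lengths)["s1"])

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 500, (50, 4)),
                              index=[f"g{i}" for i in range(50)])
        lengths = pd.Series(rng.integers(200, 5000, 50), index=counts.index)
        sums = tpm(counts, lengths).sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-9)

    def test_zero_length_expressed_gene_errors(self):
        counts = pd.DataFrame({"s": [5]}, index=["a"])
        with pytest.raises(ValueError):
            tpm(counts, pd.Series({"a": 0}))

    def test_all_zero_column_warns(self):
        counts = pd.DataFrame({"s1": [5], "s2": [0]}, index=["a"])
        with pytest.warns(UserWarning, match="all-zero"):
            out = tpm(counts, pd.Series({"a": 100}))
        assert out["s2"].iloc[0] == 0.0


class TestSizeFactors:
    def test_scale_equivariance(self):
        """Scaling one column by c scales its factor by c relative to
        the others (the absolute scale shifts with the geometric-mean
        reference, which is the method's free normalisation)."""
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 200, (100, 6)),
                              index=[f"g{i}" for i in range(100)])
        sf = size_factors(counts)
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        sf2 = size_factors(scaled)
        ratio = sf2 / sf
        rel = ratio.iloc[0] / ratio.iloc[1:]
        np.testing.assert_allclose(rel, 3.0, rtol=1e-9)
        # normalised counts unchanged up to one global constant
        norm1 = counts / sf
        norm2 = scaled / sf2
        const = (norm2 / norm1).values
        np.testing.assert_allclose(const, const.flat[0], rtol=1e-9)

    def test_no_all_positive_gene_errors(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="size factors"):
            size_factors(counts)


class TestBhAdjust:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_all_ones_unchanged(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestNbWaldDe:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(3)
        block = rng.integers(10, 300, (50, 4))
        counts = pd.DataFrame(np.hstack([block, block]),
                              index=[f"g{i}" for i in range(50)],
                              columns=[f"s{j}" for j in range(8)])
        groups = ["a"] * 4 + ["b"] * 4
        de = nb_wald_de(counts, groups)
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-8)
        assert not de["significant"].any()

    def test_planted_fold_changes_recovered(self):
        planted = {f"G{i:05d}": 2.0 for i in range(100)}
        counts, groups, _ = simulate_counts(n_genes=2000, n_per_group=10,
                                            planted=planted, seed=5)
        de = nb_wald_de(counts, groups, reference="reference")
        pl = de.loc[list(planted)]
        assert pl["log2fc"].abs().median() == pytest.approx(2.0, abs=0.25)
        assert (pl["padj"] < 0.05).mean() >= 0.9

    def test_significance_requires_twofold(self):
        planted = {f"G{i:05d}": 0.5 for i in range(50)}  # real but < twofold
        counts, groups, _ = simulate_counts(n_genes=500, n_per_group=30,
                                            planted=planted, mean=500, seed=6)
        de = nb_wald_de(counts, groups, reference="reference")
        pl = de.loc[list(planted)]
        assert (pl["padj"] < 0.05).mean() > 0.5  # detected ...
        assert not pl["significant"].any()  # ... but not biologically relevant

    def test_group_size_validation(self):
        counts = pd.DataFrame(np.ones((5, 3), dtype=int))
        with pytest.raises(ValueError):
            nb_wald_de(counts, ["a", "a", "b"])

    def test_padj_at_least_p(self):
        counts, groups, _ = simulate_counts(n_genes=200, n_per_group=5, seed=7)
        de = nb_wald_de(counts, groups)
        assert np.all(de["padj"] >= de["p"] - 1e-12)


def wilcoxon_exact_oracle(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().values
    n_a = len(a)
    obs = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2
    stats = [ranks[list(idx)].sum()
             for idx in itertools.combinations(range(len(pooled)), n_a)]
    stats = np.asarray(stats)
    return np.mean(np.abs(stats - mu) >= abs(obs - mu) - 1e-12)


class TestWilcoxonMarkers:
    def _expr(self, rows, labels):
        df = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                          columns=[f"c{j}" for j in range(len(labels))])
        return df, labels

    def test_exact_p_for_separated_groups(self):
        expr, labels = self._expr([[1, 2, 3, 4, 5, 6]], ["t"] * 3 + ["o"] * 3)
        out = wilcoxon_markers(expr, labels, "t")
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=4)
            expr = pd.DataFrame([np.concatenate([a, b])],
                                index=["g"], columns=[f"c{j}" for j in range(9)])
            out = wilcoxon_markers(expr, ["t"] * 5 + ["o"] * 4, "t")
            assert out["p"].iloc[0] == pytest.approx(wilcoxon_exact_oracle(a, b))

    def test_identical_groups_p_one(self):
        expr, labels = self._expr([[2, 2, 2, 2, 2, 2]], ["t"] * 3 + ["o"] * 3)
        out = wilcoxon_markers(expr, labels, "t")
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_flips_log2fc_same_p(self):
        expr, labels = self._expr([[1, 2, 3, 7, 8, 9]], ["t"] * 3 + ["o"] * 3)
        out_t = wilcoxon_markers(expr, labels, "t")
        out_o = wilcoxon_markers(expr, labels, "o")
        assert out_t["p"].iloc[0] == pytest.approx(out_o["p"].iloc[0])
        assert out_t["log2fc"].iloc[0] == pytest.approx(-out_o["log2fc"].iloc[0])

    def test_single_label_errors(self):
        expr, labels = self._expr([[1, 2, 3]], ["t"] * 3)
        with pytest.raises(ValueError):
            wilcoxon_markers(expr, labels, "t")


class TestConsensusMarkers:
    def test_sevenfold_in_every_study(self):
        ds1 = pd.Series({"A": 10.0, "B": 8.0, "C": 3.0})
        ds2 = pd.Series({"A": 9.0, "B": 6.0, "C": 12.0})
        micro = pd.Series({"A": 20.0, "B": 15.0, "C": 30.0})
        out = consensus_markers([ds1, ds2], micro, threshold=7.0)
        assert list(out.index) == ["A"]

    def test_threshold_one_keeps_all_ranked_by_microarray(self):
        ds = pd.Series({"A": 2.0, "B": 3.0})
        micro = pd.Series({"A": 5.0, "B": 9.0})
        out = consensus_markers([ds], micro, threshold=1.0)
        assert list(out.index) == ["B", "A"]

    def test_empty_tables(self):
        out = consensus_markers([pd.Series(dtype=float)], pd.Series(dtype=float))
        assert len(out) == 0

    def test_infinite_fold_change_survives(self):
        ds = pd.Series({"A": np.inf})
        micro = pd.Series({"A": 50.0})
        assert list(consensus_markers([ds], micro).index) == ["A"]


def test_sample_quality_gate():
    mat = pd.DataFrame(
        {"good": [5.0, 8.0], "bad": [5.0, 0.5]},
        index=["FCGR2B", "CLEC4M"],
    )
    assert sample_quality_gate(mat, ["FCGR2B", "CLEC4M"]) == ["good"]
    with pytest.warns(UserWarning, match="absent"):
        kept = sample_quality_gate(mat, ["STAB2"])
    assert kept == ["good", "bad"]
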