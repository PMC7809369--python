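import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centfinder.containers import ExpressionMatrix, PlatformSummary, ProbeMatrix, SampleRecord
from centfinder.ingest import (
    InclusionRules,
    aggregate_probes,
    assemble_matrix,
    filter_samples,
    quantile_normalize,
    select_platforms,
)

RULES = InclusionRules(
    organisms=("Homo sapiens",),
    labels=("biotin",),
    platform_prefixes=("A-AFFY",),
    deny_substrings=("carcinoma", "tumor", "tumour", "cancer", "hcc"),
)


def _rec(i, **kw):
    defaults = dict(organism="Homo sapiens", label="biotin",
                    platform_id="A-AFFY-44", characteristics=["liver"])
    defaults.update(kw)
    return SampleRecord(sample_id=f"s{i}", **defaults)


class TestFilterSamples:
    @pytest.mark.parametrize(
        "kwargs, kept",
        [
            (dict(), True),
            (dict(organism="Mus musculus"), False),
            (dict(characteristics=["hepatocellular carcinoma"]), False),
            (dict(label="Cy3"), False),
            (dict(platform_id="A-GEOD-1"), False),
            (dict(characteristics=["Liver Cancer biopsy"]), False),  # case-insensitive
        ],
    )
    def test_rules(self, kwargs, kept):
        out = filter_samples([_rec(0, **kwargs)], RULES)
        assert (len(out) == 1) == kept

    def test_missing_organism_rejected_not_raised(self):
        assert filter_samples([_rec(0, organism="")], RULES) == []

    def test_idempotent_and_order_preserving(self):
        records = [_rec(i) for i in range(3)] + [_rec(3, organism="Mus musculus")]
        once = filter_samples(records, RULES)
        assert filter_samples(once, RULES) == once
        assert [r.sample_id for r in once] == ["s0", "s1", "s2"]


class TestAggregateProbes:
    def _pm(self, values, mapping):
        df = pd.DataFrame(values, index=list(mapping) or None, columns=["s1"])
        return ProbeMatrix(values=df, probe_to_gene={k: v for k, v in mapping.items() if v})

    @pytest.mark.parametrize(
        "intensities, expected",
        [([4.0, 16.0], 8.0), ([7.0], 7.0), ([2.0, 4.0, 8.0], 4.0)],
    )
    def test_geometric_mean(self, intensities, expected):
        mapping = {f"p{i}": "GENE" for i in range(len(intensities))}
        pm = self._pm([[v] for v in intensities], mapping)
        em = aggregate_probes(pm)
        assert em.values.loc["GENE", "s1"] == pytest.approx(expected)
        assert em.log2_scale is False

    def test_unmapped_probes_dropped(self):
        df = pd.DataFrame([[4.0], [16.0], [5.0]], index=["p1", "p2", "px"], columns=["s1"])
        em = aggregate_probes(ProbeMatrix(values=df, probe_to_gene={"p1": "G", "p2": "G"}))
        assert list(em.values.index) == ["G"]

    def test_row_permutation_commutes(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 100, size=(6, 4))
        idx = [f"p{i}" for i in range(6)]
        mapping = {p: f"G{i % 2}" for i, p in enumerate(idx)}
        df = pd.DataFrame(vals, index=idx, columns=list("abcd"))
        em1 = aggregate_probes(ProbeMatrix(values=df, probe_to_gene=mapping))
        perm = rng.permutation(6)
        em2 = aggregate_probes(ProbeMatrix(values=df.iloc[perm], probe_to_gene=mapping))
        pd.testing.assert_frame_equal(em1.values, em2.values)

    def test_zero_intensity_error_names_probe_and_sample(self):
        df = pd.DataFrame([[4.0, 0.0]], index=["p1"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="p1.*s2"):
            aggregate_probes(ProbeMatrix(values=df, probe_to_gene={"p1": "G"}))


class TestQuantileNormalize:
    def _em(self, cols):
        df = pd.DataFrame(np.array(cols).T, columns=[f"s{i}" for i in range(len(cols))])
        df.index = [f"g{i}" for i in range(df.shape[0])]
        return ExpressionMatrix(df, log2_scale=True)

    def test_two_column_example(self):
        out = quantile_normalize(self._em([[1, 2, 3], [4, 5, 6]]))
        expected = np.array([[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]]).T
        np.testing.assert_allclose(out.values.values, expected)

    def test_identical_columns_fixed_point(self):
        em = self._em([[3, 1, 2], [3, 1, 2]])
        out = quantile_normalize(em)
        np.testing.assert_allclose(out.values.values, em.values.values)

    def test_tie_block_receives_mean_of_reference(self):
        # ref = [2, 3, 3.5]; tie block in column 1 spans positions 2-3
        out = quantile_normalize(self._em([[1, 2, 2], [3, 4, 5]]))
        np.testing.assert_allclose(out.values["s0"].values, [2.0, 3.25, 3.25])

    def test_single_sample_error(self):
        with pytest.raises(ValueError):
            quantile_normalize(self._em([[1, 2, 3]]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 12), st.integers(2, 6))
    def test_columns_share_sorted_values(self, seed, n_genes, n_samples):
        rng = np.random.default_rng(seed)
        em = self._em(list(rng.normal(size=(n_samples, n_genes))))
        out = quantile_normalize(em).values.values
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)


class TestSelectPlatforms:
    def test_product_rule_two_platforms(self):
        shared = {f"g{i}" for i in range(15000)}
        p1 = PlatformSummary("P1", 150, frozenset(shared | {f"x{i}" for i in range(1000)}))
        p2 = PlatformSummary("P2", 100, frozenset(shared | {f"y{i}" for i in range(5000)}))
        chosen, common = select_platforms([p1, p2])
        assert chosen == {"P1", "P2"}
        assert len(common) == 15000

    def test_single_platform(self):
        p = PlatformSummary("P1", 10, frozenset({"a", "b"}))
        chosen, common = select_platforms([p])
        assert chosen == {"P1"} and common == {"a", "b"}

    def test_forced_disjoint_platform_stands_alone(self):
        p1 = PlatformSummary("P1", 100, frozenset({"a", "b"}))
        p2 = PlatformSummary("P2", 5, frozenset({"c", "d"}))
        chosen, common = select_platforms([p1, p2], forced={"P2"})
        assert chosen == {"P2"} and common == {"c", "d"}

    def test_missing_forced_errors(self):
        with pytest.raises(ValueError, match="PX"):
            select_platforms([PlatformSummary("P1", 5, frozenset({"a"}))], forced={"PX"})

    def test_single_sample_platform_warns(self):
        with pytest.warns(UserWarning, match="single sample"):
            select_platforms([PlatformSummary("P1", 1, frozenset({"a"}))])

    def test_exhaustive_objective_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(40)]
        platforms = [
            PlatformSummary(
                f"P{i}",
                int(rng.integers(2, 50)),
                frozenset(rng.choice(universe, size=rng.integers(5, 40), replace=False)),
            )
            for i in range(6)
        ]
        chosen, common = select_platforms(platforms)
        by_id = {p.platform_id: p for p in platforms}
        achieved = sum(by_id[p].n_samples for p in chosen) * len(common)
        best = 0
        for r in range(1, 7):
            for combo in itertools.combinations(platforms, r):
                inter = frozenset.intersection(*(p.gene_set for p in combo))
                best = max(best, sum(p.n_samples for p in combo) * len(inter))
        assert achieved == best


class TestAssembleMatrix:
    def test_merge_on_shared_genes(self):
        a = ExpressionMatrix(pd.DataFrame({"s1": [1.0, 2.0]}, index=["A", "B"]), True)
        b = ExpressionMatrix(pd.DataFrame({"s2": [3.0, 4.0]}, index=["A", "B"]), True)
        out = assemble_matrix({"P1": a, "P2": b}, {"P1", "P2"})
        assert out.values.shape == (2, 2)
        assert [s.platform_id for s in out.samples] == ["P1", "P2"]

    def test_linear_scale_transformed(self):
        a = ExpressionMatrix(pd.DataFrame({"s1": [3.0]}, index=["A"]), log2_scale=False)
        out = assemble_matrix({"P1": a}, {"P1"})
        assert out.values.loc["A", "s1"] == pytest.approx(2.0)  # log2(3+1)
        assert out.log2_scale

    def test_disjoint_gene_sets_error(self):
        a = ExpressionMatrix(pd.DataFrame({"s1": [1.0]}, index=["A"]), True)
        b = ExpressionMatrix(pd.DataFrame({"s2": [1.0]}, index=["B"]), True)
        with pytest.raises(ValueError, match="no genes"):
            assemble_matrix({"P1": a, "P2": b}, {"P1", "P2"})
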