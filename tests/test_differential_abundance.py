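import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phylosym import (
    GroupingMap,
    OtuTable,
    anova_oneway,
    benjamini_hochberg,
    differential_abundance,
    tukey_kramer,
)


def _values(groups_data):
    values, assignments = {}, {}
    for g, arr in groups_data.items():
        for i, v in enumerate(arr):
            sid = f"{g}_{i}"
            values[sid] = float(v)
            assignments[sid] = g
    return values, GroupingMap(assignments)


class TestAnova:
    def test_all_equal_is_degenerate(self):
        values, groups = _values({"A": [1, 1, 1], "B": [1, 1, 1]})
        with pytest.warns(UserWarning):
            f, p = anova_oneway(values, groups)
        assert (f, p) == (0.0, 1.0)

    def test_zero_within_variance_unequal_means(self):
        values, groups = _values({"A": [1, 1], "B": [2, 2]})
        with pytest.warns(UserWarning):
            f, p = anova_oneway(values, groups)
        assert p == 0.0

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        values, groups = _values({"A": a, "B": b})
        f, p = anova_oneway(values, groups)
        t, pt = stats.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_matches_permutation_p(self, rng):
        data = {"A": [4.1, 5.2, 6.0, 5.5], "B": [5.0, 6.1, 7.2, 6.6], "C": [6.9, 7.5, 8.1, 7.0]}
        values, groups = _values(data)
        f_obs, p = anova_oneway(values, groups)
        pooled = np.concatenate(list(data.values()))
        sizes = [len(v) for v in data.values()]
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            if stats.f_oneway(*parts)[0] >= f_obs:
                count += 1
        p_perm = count / n_perm
        # agreement within Monte-Carlo error (3 SE, floor for tiny p)
        se = np.sqrt(max(p_perm, 1e-4) * (1 - min(p_perm, 0.999)) / n_perm)
        assert abs(p - p_perm) <= max(3 * se, 0.01)

    def test_small_group_named(self):
        values, groups = _values({"A": [1.0], "B": [2, 3]})
        with pytest.raises(ValueError, match="A"):
            anova_oneway(values, groups)


class TestTukeyKramer:
    def test_null_pairwise_p_near_one(self, rng):
        data = {g: rng.normal(0, 1, 60) for g in "ABC"}
        values, groups = _values(data)
        # identically distributed large groups: typical pairwise p is large;
        # check none is spuriously tiny and the full pair set is covered
        pairs = tukey_kramer(values, groups)
        assert {frozenset(p) for p, _ in pairs} == {
            frozenset(x) for x in (("A", "B"), ("A", "C"), ("B", "C"))
        }
        assert all(p > 0.001 for _, p in pairs)

    def test_balanced_two_groups_matches_t_test(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        values, groups = _values({"A": a, "B": b})
        (_, p_tk), = tukey_kramer(values, groups)
        _, p_t = stats.ttest_ind(a, b)
        assert p_tk == pytest.approx(p_t, rel=1e-6)

    def test_strongly_shifted_group_detected(self, rng):
        data = {"A": rng.normal(0, 1, 8), "B": rng.normal(0, 1, 8),
                "C": rng.normal(10, 1, 8)}
        values, groups = _values(data)
        for (g1, g2), p in tukey_kramer(values, groups):
            if "C" in (g1, g2):
                assert p < 0.001
            else:
                assert p > 0.001

    def test_relabeling_invariance(self, rng):
        data = {"A": rng.normal(0, 1, 6), "B": rng.normal(1, 1, 7), "C": rng.normal(2, 1, 5)}
        values, groups = _values(data)
        ps = {frozenset(pair): p for pair, p in tukey_kramer(values, groups)}
        renamed_values = values
        renamed_groups = GroupingMap({s: "X" + g for s, g in groups.assignments.items()})
        ps2 = {frozenset(pair): p for pair, p in tukey_kramer(renamed_values, renamed_groups)}
        for pair, p in ps.items():
            assert ps2[frozenset("X" + g for g in pair)] == pytest.approx(p, rel=1e-12)


class TestBenjaminiHochberg:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_and_single(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(benjamini_hochberg([0.123]), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30))
    def test_order_invariant_and_dominates_p(self, pvals):
        p = np.asarray(pvals)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1 + 1e-12)
        order = np.argsort(p, kind="stable")
        q_sorted_input = benjamini_hochberg(p[order])
        np.testing.assert_allclose(q[order], q_sorted_input, atol=1e-12)


class TestDifferentialAbundance:
    def _synthetic(self, rng, shift_taxon=None, shift_group=None, log2fc=0.0,
                   n_groups=5, per_group=8, n_taxa=12):
        samples, assignments = [], {}
        rows = []
        base = rng.uniform(2, 6, size=n_taxa)
        for g in range(n_groups):
            lab = f"G{g}"
            for i in range(per_group):
                sid = f"{lab}_{i}"
                mu = base.copy()
                if shift_taxon is not None and lab == shift_group:
                    mu[shift_taxon] += log2fc
                counts = rng.poisson(2.0 ** mu)
                samples.append(sid)
                assignments[sid] = lab
                rows.append(counts.astype(float))
        t = OtuTable(samples, [f"t{j}" for j in range(n_taxa)], np.array(rows))
        return t, GroupingMap(assignments)

    def test_planted_signal_recovered_with_correct_pairs(self, rng):
        t, g = self._synthetic(rng, shift_taxon=3, shift_group="G2", log2fc=3.0)
        res = differential_abundance(t, g, rank=None, alpha=0.05)
        assert "t3" in res.significant.index
        hit_pairs = res.pairwise[(res.pairwise["taxon"] == "t3") & (res.pairwise["p"] < 0.05)]
        assert not hit_pairs.empty
        assert all("G2" in (r["group1"], r["group2"]) for _, r in hit_pairs.iterrows())

    def test_q_dominates_p_and_pair_coverage(self, rng):
        t, g = self._synthetic(rng)
        res = differential_abundance(t, g, rank=None)
        assert np.all(res.table["q"].to_numpy() >= res.table["p"].to_numpy() - 1e-12)
        n_pairs = 5 * 4 // 2
        assert (res.pairwise.groupby("taxon").size() == n_pairs).all()

    def test_zero_taxon_table_empty_result(self):
        t = OtuTable(["s1", "s2", "s3", "s4"], [], np.zeros((4, 0)))
        g = GroupingMap({s: ("A" if i < 2 else "B") for i, s in enumerate(t.sample_ids)})
        res = differential_abundance(t, g, rank=None)
        assert res.table.empty and res.significant.empty

    def test_sample_order_and_label_invariance(self, rng):
        t, g = self._synthetic(rng, n_groups=3, per_group=5)
        res1 = differential_abundance(t, g, rank=None)
        perm = rng.permutation(t.n_samples)
        t2 = OtuTable([t.sample_ids[i] for i in perm], t.otu_ids, t.counts[perm])
        g2 = GroupingMap({s: "Z" + g[s] for s in t2.sample_ids})
        res2 = differential_abundance(t2, g2, rank=None)
        np.testing.assert_allclose(res1.table["p"].to_numpy(),
                                   res2.table.loc[res1.table.index, "p"].to_numpy(),
                                   atol=1e-10)

    def test_batched_pipeline_matches_per_taxon_tests(self, rng):
        # the table-level fast path must agree with the exact per-taxon
        # ANOVA and Tukey-Kramer operations
        t, g = self._synthetic(rng, n_groups=4, per_group=7, n_taxa=15)
        res = differential_abundance(t, g, rank=None, scale="relative")
        rel = t.counts / t.counts.sum(axis=1, keepdims=True) * 100.0
        for j, taxon in enumerate(t.otu_ids):
            values = {s: rel[i, j] for i, s in enumerate(t.sample_ids)}
            f, p = anova_oneway(values, g)
            assert res.table.loc[taxon, "F"] == pytest.approx(f, rel=1e-9)
            assert res.table.loc[taxon, "p"] == pytest.approx(p, rel=1e-9)
            exact = {frozenset(pair): tp for pair, tp in tukey_kramer(values, g)}
            sub = res.pairwise[res.pairwise["taxon"] == taxon]
            for _, r in sub.iterrows():
                key = frozenset((r["group1"], r["group2"]))
                assert r["p"] == pytest.approx(exact[key], rel=5e-3, abs=1e-5)

    def test_null_anova_p_approximately_uniform(self, rng):
        # i.i.d. values across 3 groups of 8: the per-taxon ANOVA p-value
        # should be ~Uniform(0,1); KS distance < 0.1 at 1,000 taxa
        ps = []
        for _ in range(1000):
            data = {g: rng.normal(0, 1, 8) for g in "ABC"}
            values, groups = _values(data)
            ps.append(anova_oneway(values, groups)[1])
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.1
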