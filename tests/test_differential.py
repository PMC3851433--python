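"""ANOVA/Tukey/BH machinery, fold change, list building, Venn partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tests.conftest import build_matrix, noisy_pattern
from troutarray.differential import (anova_omnibus, bh_adjust, collapse_replicates,
                                     derive_lists, fold_change,
                                     significant_entities, tukey_pairwise,
                                     venn_counts, venn_partition)


class TestAnova:
    def test_hand_computed_f(self):
        # SSB = 6 over 2 df, SSW = 6 over 6 df -> F = 3.0
        f, p = anova_omnibus([np.array([1., 2., 3.]), np.array([2., 3., 4.]),
                              np.array([3., 4., 5.])])
        assert f == pytest.approx(3.0, abs=1e-12)
        assert p == pytest.approx(stats.f.sf(3.0, 2, 6), abs=1e-12)

    def test_identical_groups(self):
        f, p = anova_omnibus([np.array([2., 2., 2.])] * 3)
        assert (f, p) == (0.0, 1.0)

    def test_two_groups_equal_squared_t(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        f, p_f = anova_omnibus([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t.statistic ** 2, rel=1e-12)
        assert p_f == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(20):
            groups = [rng.normal(rng.normal(0, 1), 1, size=int(rng.integers(3, 9)))
                      for _ in range(int(rng.integers(2, 5)))]
            f, p = anova_omnibus(groups)
            ref = stats.f_oneway(*groups)
            assert f == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="2 observations"):
            anova_omnibus([np.array([1.0]), np.array([1.0, 2.0])])


class TestTukey:
    def test_identical_groups_p_one(self):
        pp = tukey_pairwise({"A": np.array([1., 1., 1.]),
                             "B": np.array([1., 1., 1.]),
                             "C": np.array([1., 1., 1.])})
        assert all(p == 1.0 for p in pp.values())

    def test_symmetric_in_pair_order(self, rng):
        groups = {g: rng.normal(i, 1, 6) for i, g in enumerate("ABC")}
        pp = tukey_pairwise(groups)
        for (g1, g2), p in pp.items():
            assert p == pp[(g2, g1)]

    def test_label_swap_invariance(self, rng):
        a, b, c = (rng.normal(i, 1, 6) for i in range(3))
        p1 = tukey_pairwise({"A": a, "B": b, "C": c})[("A", "B")]
        p2 = tukey_pairwise({"B": b, "A": a, "C": c})[("A", "B")]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_scipy_tukey_hsd(self, rng):
        for _ in range(5):
            groups = [rng.normal(rng.normal(0, 1), 1, size=6) for _ in range(4)]
            mine = tukey_pairwise({str(i): g for i, g in enumerate(groups)})
            ref = stats.tukey_hsd(*groups)
            for i in range(4):
                for j in range(i + 1, 4):
                    assert mine[(str(i), str(j))] == pytest.approx(
                        ref.pvalue[i, j], abs=1e-8)

    def test_strong_shift_detected(self, rng):
        groups = {"A": rng.normal(0, 1, 6), "B": rng.normal(0, 1, 6),
                  "C": rng.normal(10, 1, 6)}
        pp = tukey_pairwise(groups)
        assert pp[("A", "C")] < 1e-6 and pp[("B", "C")] < 1e-6
        assert pp[("A", "B")] > 0.05


class TestBH:
    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.03] * 5), [0.03] * 5)

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_against_manual_step_up(self, rng):
        p = rng.uniform(size=40)
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone_and_dominates_p(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFoldChange:
    def matrix(self):
        return build_matrix({
            "e1": {"Wa": [3, 3], "Ws": [3, 3], "D": [5, 5], "WD": [4, 4]},
            "e2": {"Wa": [2, 2], "Ws": [2, 2], "D": [2, 2], "WD": [2, 2]},
        })

    def test_two_log2_units_is_fourfold_up(self):
        fd = fold_change(self.matrix(), ("D", "Wa"))
        assert fd.loc["e1", "fc"] == pytest.approx(4.0)
        assert fd.loc["e1", "direction"] == "up"

    def test_equal_means_tie_counts_up(self):
        fd = fold_change(self.matrix(), ("D", "Wa"))
        assert fd.loc["e2", "fc"] == pytest.approx(1.0)
        assert fd.loc["e2", "direction"] == "up"

    def test_reversed_pairing_reciprocal(self):
        m = self.matrix()
        a = fold_change(m, ("D", "Wa"))["fc"]
        b = fold_change(m, ("Wa", "D"))["fc"]
        np.testing.assert_allclose(a * b, 1.0, atol=1e-9)


class TestSignificantEntities:
    def spiked_matrix(self, rng, n_null=30):
        entities = {f"null{i}": noisy_pattern(rng, {g: 0 for g in
                                                    ("Wa", "Ws", "D", "WD")})
                    for i in range(n_null)}
        entities["spike"] = noisy_pattern(
            rng, {"Wa": 0, "Ws": 0, "WD": 0, "D": 8 * 0.15})
        return build_matrix(entities)

    def test_spiked_gene_found_in_its_pairings(self, rng):
        de = significant_entities(self.spiked_matrix(rng), alpha=0.05,
                                  fc_threshold=1.0)
        for pr, el in de.lists.items():
            if "D" in pr:
                assert "spike" in el.ids, pr
            else:
                assert "spike" not in el.ids, pr

    def test_alpha_nesting(self, rng):
        de = significant_entities(self.spiked_matrix(rng), alpha=0.05,
                                  fc_threshold=1.0)
        strict = derive_lists(de, alpha=0.01, fc_threshold=1.0)
        for pr in de.lists:
            assert strict[pr].ids <= de.lists[pr].ids

    def test_members_satisfy_thresholds(self, rng):
        de = significant_entities(self.spiked_matrix(rng), alpha=0.05,
                                  fc_threshold=2.0)
        for el in de.lists.values():
            m = el.members
            assert (m["q"] <= 0.05).all()
            assert (m["tukey_p"] <= 0.05).all()
            assert (np.maximum(m["fc"], 1 / m["fc"]) >= 2.0).all()
            assert el.n_up + el.n_down == len(el)

    def test_label_permutation_destroys_detections(self, rng):
        m = self.spiked_matrix(rng)
        perm = rng.permutation(m.samples)
        m.data.columns = perm  # shuffle which fish belongs to which group
        m.data = m.data[m.design.samples]
        de = significant_entities(m, alpha=0.05, fc_threshold=1.0)
        n_hits = sum(len(el) for el in de.lists.values())
        assert n_hits <= 2  # chance level on 31 entities x 6 pairings


class TestCollapse:
    def _list(self, names):
        de = significant_entities(build_matrix(
            {f"p{i}": noisy_pattern(np.random.default_rng(i),
                                    {"Wa": 0, "Ws": 0, "WD": 1, "D": 2})
             for i in range(len(names))},
            gene_names={f"p{i}": n for i, n in enumerate(names)},
        ), alpha=0.05, fc_threshold=1.0)
        return de.lists[("D", "Wa")]

    def test_first_probe_kept(self):
        el = self._list(["geneX", "geneX", "geneY"])
        collapsed = collapse_replicates(el)
        assert list(collapsed.members["entity_id"]) == ["p0", "p2"]

    def test_no_duplicates_identity(self):
        el = self._list(["a", "b", "c"])
        assert collapse_replicates(el).members.equals(
            el.members.reset_index(drop=True))

    def test_counts(self):
        el = self._list(["g1", "g1", "g1", "g2", "g3"])
        assert len(collapse_replicates(el)) == 3


class TestVenn:
    def test_published_two_set_arithmetic(self):
        # |A|=233, |B|=207, |A&B|=119 -> uniques 114 and 88, union 321
        a = {f"x{i}" for i in range(233)}
        b = {f"x{i}" for i in range(114, 114 + 207)}
        counts = venn_counts({"A": a, "B": b})
        assert counts[("A", "B")] == 119
        assert counts[("A",)] == 114
        assert counts[("B",)] == 88
        assert sum(counts.values()) == 321

    def test_disjoint(self):
        counts = venn_counts({"A": {1, 2}, "B": {3}})
        assert counts[("A", "B")] == 0

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)),
           st.sets(st.integers(0, 30)))
    def test_three_set_partition_exact(self, a, b, c):
        regions = venn_partition({"A": a, "B": b, "C": c})
        assert len(regions) == 7
        all_members = [x for r in regions.values() for x in r]
        assert len(all_members) == len(set(all_members))  # disjoint
        assert set(all_members) == a | b | c              # covering

    def test_wrong_arity(self):
        with pytest.raises(ValueError):
            venn_partition({"A": {1}})
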