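"""Nonparametric tests against enumeration oracles and closed forms."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from girdlekin.stats import (
    TestResult as StatResult,
    boxplot_stats,
    fisher_lsd,
    friedman,
    mann_whitney,
    report,
)


def exact_mw_pvalue(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of rank splits."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = {v: r for r, v in enumerate(np.sort(pooled), start=1)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    all_ranks = list(range(1, n1 + n2 + 1))
    for comb in combinations(all_ranks, n1):
        us.append(sum(comb) - n1 * (n1 + 1) / 2)
    us = np.asarray(us, dtype=float)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestMannWhitney:
    def test_u_zero_exact_p(self):
        """Fully separated 3 vs 3: U = 0, exact two-sided p = 2/20 = 0.1."""
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)
        assert r.test.endswith("exact")

    def test_identical_groups_p_one(self):
        assert mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).p_value == pytest.approx(1.0)
        # tie-free groups with U one below its symmetric centre: maximal p
        assert mann_whitney([1.0, 4.0, 5.0], [2.0, 3.0, 6.0]).p_value == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        r0 = mann_whitney(a, b)
        r1 = mann_whitney(a + 17.3, b + 17.3)
        assert r0.statistic == r1.statistic and r0.p_value == r1.p_value

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (5, 5), (6, 4), (7, 7)])
    def test_matches_enumeration_for_small_samples(self, n1, n2, rng):
        """Exact p equals full enumeration of all rank arrangements, n <= 7."""
        for _ in range(10):
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            r = mann_whitney(a, b)
            assert r.p_value == pytest.approx(exact_mw_pvalue(a, b), abs=1e-12)

    def test_empty_or_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mann_whitney([1.0], [2.0, 3.0])


class TestFriedman:
    def test_closed_form_identical_rankings(self):
        """n=5 blocks, k=3, identical rankings: 12n/(k(k+1)) sum(...) = 10."""
        blocks = np.tile([1.0, 2.0, 3.0], (5, 1)) + 100 * np.arange(5)[:, None]
        assert friedman(blocks).statistic == pytest.approx(10.0)

    def test_all_equal_cells(self):
        r = friedman(np.ones((5, 3)))
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_label_permutation_invariance(self, rng):
        blocks = rng.normal(size=(6, 4))
        perm = rng.permutation(4)
        r0, r1 = friedman(blocks), friedman(blocks[:, perm])
        assert r0.statistic == pytest.approx(r1.statistic)
        assert r0.p_value == pytest.approx(r1.p_value)

    def test_statistic_matches_scipy(self, rng):
        from scipy.stats import friedmanchisquare

        for _ in range(10):
            m = rng.normal(size=(7, 5))
            assert friedman(m).statistic == pytest.approx(friedmanchisquare(*m.T)[0])

    def test_missing_cells_rejected(self):
        m = np.ones((5, 3))
        m[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            friedman(m)

    def test_null_type_one_error_within_band(self):
        """Empirical level at alpha=.05 over 1000 null replicates (n=5, k=7)."""
        rng = np.random.default_rng(0)
        rejections = sum(
            friedman(rng.normal(size=(5, 7))).p_value <= 0.05 for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


class TestFisherLSD:
    def blocks(self, effect):
        rng = np.random.default_rng(42)
        base = rng.normal(size=(8, 1)) + rng.normal(scale=0.2, size=(8, 4))
        base[:, 0] += effect  # first condition shifted
        return base

    def test_gating_suppresses_post_hoc_when_omnibus_ns(self):
        rng = np.random.default_rng(7)
        blocks = rng.normal(size=(5, 4))
        labels = ["rockwood5", "construct1", "construct2", "construct3"]
        res = fisher_lsd(blocks, labels, [("rockwood5", "construct1")])
        if res.p_value > 0.05:
            assert res.pairwise == {}

    def test_significant_effect_detected_pairwise(self):
        blocks = self.blocks(effect=5.0)
        labels = ["rockwood5", "construct1", "construct2", "construct3"]
        res = fisher_lsd(blocks, labels, [("rockwood5", "construct1")])
        assert res.p_value <= 0.05
        assert res.pairwise["rockwood5_vs_construct1"].p_value < 0.05

    def test_identical_conditions_pairwise_p_one(self):
        rng = np.random.default_rng(3)
        blocks = rng.normal(size=(6, 3))
        blocks = np.column_stack([blocks, blocks[:, 2]])  # duplicate a condition
        blocks[:, 0] += 10  # make the omnibus significant
        labels = ["rockwood5", "construct1", "construct2", "construct3"]
        res = fisher_lsd(blocks, labels, [("construct2", "construct3")])
        assert res.p_value <= 0.05
        assert res.pairwise["construct2_vs_construct3"].p_value == pytest.approx(1.0)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            fisher_lsd(np.random.default_rng(0).normal(size=(5, 3)),
                       ["a", "b", "c"], [("a", "zzz")])


class TestResultInvariants:
    def test_p_value_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            StatResult("t", 1.0, 1.5, (3, 3))
        with pytest.raises(ValueError, match="statistic"):
            StatResult("t", np.nan, 0.5, (3, 3))


class TestBoxplotAndReport:
    #: seven hand-ordered values; quartiles by linear interpolation:
    #: q1 at position 1.5 -> 2.5, median 4, q3 at 4.5 -> 5.5
    SEVEN = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 40.0])

    def test_quartile_convention_pinned(self):
        s = boxplot_stats(self.SEVEN)
        assert s["q1"] == pytest.approx(2.5)
        assert s["median"] == pytest.approx(4.0)
        assert s["q3"] == pytest.approx(5.5)

    def test_minmax_whiskers_have_no_outliers(self):
        s = boxplot_stats(self.SEVEN, whiskers="minmax")
        assert s["whisker_low"] == 1.0 and s["whisker_high"] == 40.0
        assert s["outliers"] == []

    def test_tukey_whiskers_flag_outliers(self):
        s = boxplot_stats(self.SEVEN, whiskers="tukey")
        assert 40.0 in s["outliers"]
        assert s["whisker_high"] == 6.0

    def test_report_deterministic_and_complete(self):
        rng = np.random.default_rng(9)
        rows = []
        for g, shoulders in (("AC_first", "LMNOP"), ("CC_first", "QRSTU")):
            for s in shoulders:
                for c in ("intact", "rockwood5", "cc_only", "construct1",
                          "construct2", "construct3", "construct4"):
                    row = {"shoulder": s, "group": g,
                           "side": "left" if g == "AC_first" else "right",
                           "condition": c}
                    for k, d in enumerate(
                        ("retraction_protraction", "lateral_medial_rotation",
                         "anterior_posterior_tilt", "superior_inferior",
                         "anterior_posterior", "lateral_medial")
                    ):
                        row[f"alignment_{d}"] = rng.normal()
                        row[f"stability_{d}"] = abs(rng.normal()) + (0.2 if c == "rockwood5" else 0)
                    rows.append(row)
        table = pd.DataFrame(rows)
        r1 = report(table)
        r2 = report(table)
        assert r1["alignment"].equals(r2["alignment"])
        assert len(r1["alignment"]) == 6
        assert len(r1["stability"]) == 6
        assert not r1["boxplot"].empty

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            report(pd.DataFrame())
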