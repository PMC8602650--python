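"""Well summaries, control normalization, and the statistical tests."""
from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from organoidq import (
    ComputationError,
    InputError,
    fisher_exact_one_tailed,
    formation_efficiency,
    mann_whitney,
    normalize_to_control,
    one_way_anova,
    summarize_well,
)
from organoidq.segmentation import OrganoidRecord


def _obj(oid, area, label, on_border=False):
    return OrganoidRecord(
        object_id=oid, center=(0, 0), area_px=area,
        contour=np.zeros((0, 2), dtype=np.intp), class_label=label,
        on_border=on_border,
    )


class TestSummarizeWell:
    def test_mean_area_with_pixel_size(self):
        objs = [_obj(i, 100, "spheroid") for i in range(3)]
        s = summarize_well(objs, pixel_size_um=2.0)
        assert s.mean_area_um2 == 400.0
        assert s.n_objects == 3

    def test_class_percentages(self):
        objs = [_obj(i, 500, "budding") for i in range(6)]
        objs += [_obj(10 + i, 500, "spheroid") for i in range(4)]
        s = summarize_well(objs)
        assert s.pct_budding == 60.0 and s.pct_spheroid == 40.0
        assert s.pct_budding + s.pct_spheroid == 100.0

    def test_junk_only_well_is_degenerate_not_an_error(self):
        objs = [_obj(i, 50, "junk") for i in range(5)]
        s = summarize_well(objs)
        assert s.n_objects == 0 and s.n_junk == 5
        assert not s.percentages_defined
        assert s.pct_budding is None and s.mean_area_px is None

    def test_junk_included_when_flag_off(self):
        objs = [_obj(1, 100, "junk"), _obj(2, 300, "spheroid")]
        s = summarize_well(objs, exclude_junk=False)
        assert s.n_objects == 2
        assert s.mean_area_px == 200.0

    def test_border_exclusion(self):
        objs = [_obj(1, 100, "spheroid", on_border=True), _obj(2, 300, "spheroid")]
        s = summarize_well(objs, exclude_border=True)
        assert s.n_objects == 1 and s.mean_area_px == 300.0


class TestNormalizeToControl:
    def _wells(self, cond, values):
        return [
            summarize_well([_obj(1, v, "spheroid")], field_id=f"{cond}{i}",
                           condition=cond)
            for i, v in enumerate(values)
        ]

    def test_treatment_ratio(self):
        wells = self._wells("ENR", [100, 100]) + self._wells("SN", [200, 200])
        out = normalize_to_control(wells, "ENR")
        by = {c.condition: c for c in out}
        assert by["ENR"].normalized_mean == 1.0
        assert by["SN"].normalized_mean == 2.0

    def test_control_only_identity(self):
        out = normalize_to_control(self._wells("ENR", [123.0]), "ENR")
        assert len(out) == 1 and out[0].normalized_mean == 1.0

    def test_unequal_well_counts_match_brute_force(self):
        wells = (self._wells("ENR", [80, 120, 100]) + self._wells("A", [150, 250])
                 + self._wells("B", [90]))
        out = normalize_to_control(wells, "ENR")
        control_mean = (80 + 120 + 100) / 3  # hand-coded oracle
        expect = {"ENR": 100 / control_mean, "A": 200 / control_mean,
                  "B": 90 / control_mean}
        for c in out:
            assert c.normalized_mean == pytest.approx(expect[c.condition])

    def test_scaling_invariance(self):
        wells = self._wells("ENR", [100, 140]) + self._wells("A", [210, 190])
        base = normalize_to_control(wells, "ENR")
        scaled = normalize_to_control(
            self._wells("ENR", [300, 420]) + self._wells("A", [630, 570]), "ENR")
        for a, b in zip(base, scaled):
            assert a.normalized_mean == pytest.approx(b.normalized_mean)

    def test_zero_control_mean_rejected(self):
        wells = self._wells("ENR", [0.0]) + self._wells("A", [10.0])
        with pytest.raises(ComputationError):
            normalize_to_control(wells, "ENR")

    def test_missing_control_rejected(self):
        with pytest.raises(InputError):
            normalize_to_control(self._wells("A", [1.0]), "ENR")


class TestFormationEfficiency:
    @pytest.mark.parametrize("formed,seeded,expected",
                             [(50, 200, 25.0), (0, 10, 0.0), (200, 200, 100.0)])
    def test_percentage(self, formed, seeded, expected):
        assert formation_efficiency(formed, seeded) == expected

    def test_zero_seeded_rejected(self):
        with pytest.raises(InputError):
            formation_efficiency(1, 0)


def brute_force_mw_p(x, y, sidedness="two-sided"):
    """Enumerate every assignment of the pooled ranks to sample x."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        r = sum(sorted(range(1, len(pooled) + 1))[i] for i in comb)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_ge = (us >= u_obs).mean()
    p_le = (us <= u_obs).mean()
    if sidedness == "greater":
        return p_ge
    if sidedness == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestMannWhitney:
    def test_complete_separation_n5_matches_printed_p(self):
        res = mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert res.exact
        assert res.p_value == pytest.approx(2 / 252)
        assert round(res.p_value, 4) == 0.0079

    def test_complete_separation_n4_matches_printed_p(self):
        res = mann_whitney([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.exact
        assert res.p_value == pytest.approx(2 / 70)
        assert round(res.p_value, 4) == 0.0286

    def test_identical_samples_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 2)])
    def test_exact_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.permutation(np.arange(1, n1 + n2 + 1))[:n1].astype(float)
        y = np.setdiff1d(np.arange(1, n1 + n2 + 1), x).astype(float)
        for side in ("two-sided", "greater", "less"):
            res = mann_whitney(x, y, side)
            assert res.exact
            assert res.p_value == pytest.approx(brute_force_mw_p(x, y, side))

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=7)
        y = rng.normal(size=6)
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_ties_fall_back_to_normal_approximation(self):
        x = [1, 2, 2, 3, 5, 5, 5, 8]
        y = [2, 4, 4, 5, 6, 6, 7, 9]
        res = mann_whitney(x, y)
        assert not res.exact
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.integers(0, 50), min_size=1, max_size=9),
           st.lists(st.integers(0, 50), min_size=1, max_size=9))
    def test_u_statistics_sum_to_product(self, x, y):
        ux = mann_whitney(x, y).statistic
        uy = mann_whitney(y, x).statistic
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mann_whitney([], [1.0])


class TestOneWayAnova:
    def test_identical_groups_give_f_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_separated_groups_give_infinite_f(self):
        res = one_way_anova([[20.0] * 5, [90.0] * 5])
        assert math.isinf(res.statistic)
        assert res.p_value == 0.0

    def test_perfect_separation_gives_large_f(self):
        res = one_way_anova([[0.0, 0.001, -0.001], [1.0, 1.001, 0.999]])
        assert res.statistic > 1e4
        assert res.p_value < 0.001

    def test_f_matches_hand_computed_ratio(self):
        groups = [[2.0, 4.0, 6.0], [5.0, 7.0, 9.0], [1.0, 2.0, 3.0]]
        res = one_way_anova(groups)
        # arithmetic oracle
        flat = [v for g in groups for v in g]
        grand = sum(flat) / len(flat)
        ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
        f = (ssb / 2) / (ssw / 6)
        assert res.statistic == pytest.approx(f)

    def test_bonferroni_at_least_raw_and_capped(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(i * 0.3, 1, 6) for i in range(4)]
        res = one_way_anova(groups, posthoc="bonferroni")
        assert len(res.posthoc) == 6
        for row in res.posthoc.itertuples():
            assert row.p_adjusted >= row.p_raw - 1e-15
            assert row.p_adjusted <= 1.0

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(12)
        groups = [rng.normal(0, 1, 8), rng.normal(1, 1, 8), rng.normal(0.5, 1, 8)]
        res = one_way_anova(groups, posthoc="tukey",
                            group_names=["a", "b", "c"])
        data = np.concatenate(groups)
        labels = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        ref = pairwise_tukeyhsd(data, labels)
        assert np.allclose(sorted(res.posthoc["p_adjusted"]),
                           sorted(ref.pvalues), atol=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            one_way_anova([[1.0], [1.0, 2.0]])


class TestFisherExactOneTailed:
    def test_diagonal_3_matches_enumeration(self):
        res = fisher_exact_one_tailed([[3, 0], [0, 3]])
        assert res.p_value == pytest.approx(1 / 20)

    def test_diagonal_2_matches_enumeration(self):
        res = fisher_exact_one_tailed([[2, 0], [0, 2]])
        assert res.p_value == pytest.approx(1 / 6)

    def test_null_table_large_p(self):
        res = fisher_exact_one_tailed([[5, 5], [5, 5]])
        assert res.p_value > 0.5

    @pytest.mark.parametrize("table", [
        [[3, 1], [2, 4]], [[1, 5], [4, 2]], [[6, 0], [3, 3]], [[2, 2], [2, 2]],
    ])
    def test_matches_scipy_directional_oracle(self, table):
        res = fisher_exact_one_tailed(table)
        a, b = table[0]
        c, d = table[1]
        direction = "greater" if a * d >= b * c else "less"
        ref = sps.fisher_exact(table, alternative=direction)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_one_tailed([[1, -1], [0, 2]])

    def test_zero_margin_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_one_tailed([[0, 0], [1, 2]])
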