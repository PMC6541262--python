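"""Two-sample battery, assumption routing, and multiple-testing corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cultshare.corrections import CORRECTION_METHODS, adjust_pvalues
from cultshare.group_tests import (
    brunner_munzel,
    exploratory_sweep,
    fligner_policello,
    relative_effect,
    route_and_test,
    split_by_practice,
    sweep_corrections,
    t_test,
    wilcoxon_mann_whitney,
)


class TestSplit:
    def test_mutualism_group_sizes(self, joined_fixture):
        g1, g2 = split_by_practice(joined_fixture, "MM", "elevation")
        assert (len(g1), len(g2)) == (3, 19)

    def test_sizes_always_sum_to_22(self, joined_fixture):
        from cultshare.data import PRACTICE_CODES

        for code in PRACTICE_CODES:
            g1, g2 = split_by_practice(joined_fixture, code, "slope")
            assert len(g1) + len(g2) == 22

    def test_unknown_practice_rejected(self, joined_fixture):
        with pytest.raises(ValueError, match="XX"):
            split_by_practice(joined_fixture, "XX", "slope")


class TestIndividualTests:
    def test_wmw_exact_small_sample(self):
        r = wilcoxon_mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.p_value == pytest.approx(0.1)
        assert r.note == "exact"

    def test_wmw_exact_matches_scipy(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(3, 7))
            n2 = int(rng.integers(3, 13 - n1))
            g1 = rng.standard_normal(n1)
            g2 = rng.standard_normal(n2) + rng.normal(0, 1)
            ours = wilcoxon_mann_whitney(g1, g2).p_value
            ref = stats.mannwhitneyu(g1, g2, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_wmw_normal_approximation_converges_to_exact(self, rng):
        # the continuity-corrected approximation is within 0.0155 of the
        # exact null tail everywhere at n1 = n2 = 6 (enumerated bound)
        for _ in range(20):
            g1 = rng.standard_normal(6)
            g2 = rng.standard_normal(6)
            exact = wilcoxon_mann_whitney(g1, g2, exact_if_small=True).p_value
            approx = wilcoxon_mann_whitney(g1, g2, exact_if_small=False).p_value
            assert abs(exact - approx) < 0.02

    @pytest.mark.parametrize(
        "test", [t_test, wilcoxon_mann_whitney, fligner_policello, brunner_munzel]
    )
    def test_identical_groups_give_null_result(self, test):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        r = test(g, g)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "test", [t_test, wilcoxon_mann_whitney, fligner_policello, brunner_munzel]
    )
    def test_constant_equal_groups_degenerate(self, test):
        r = test([2.0, 2.0, 2.0, 2.0], [2.0, 2.0, 2.0, 2.0])
        assert r.degenerate
        assert r.p_value == 1.0

    def test_brunner_munzel_relative_effect_on_identical(self):
        assert relative_effect([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(0.5)

    def test_fligner_policello_antisymmetric(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(10) * 2 + 0.5
        assert fligner_policello(x, y).statistic == pytest.approx(
            -fligner_policello(y, x).statistic
        )

    def test_fligner_policello_detects_large_shift(self, rng):
        x = rng.standard_normal(15)
        y = rng.standard_normal(15) + 10
        assert fligner_policello(x, y).p_value < 1e-6


class TestRouting:
    def test_gaussian_equal_variance_routes_to_t(self):
        rng = np.random.default_rng(123)
        g1 = rng.standard_normal(11)
        g2 = rng.standard_normal(11)
        assert stats.shapiro(g1).pvalue > 0.05 and stats.shapiro(g2).pvalue > 0.05
        assert stats.levene(g1, g2, center="median").pvalue > 0.05
        results = route_and_test(g1, g2)
        assert [r.test_name for r in results] == ["t"]

    def test_heavy_tailed_unequal_variance_routes_to_battery(self):
        rng = np.random.default_rng(2718)
        for _ in range(50):
            g1 = rng.standard_cauchy(12)
            g2 = rng.standard_cauchy(12) * 40.0
            normal = (
                stats.shapiro(g1).pvalue > 0.05 and stats.shapiro(g2).pvalue > 0.05
            )
            hom = stats.levene(g1, g2, center="median").pvalue > 0.05
            if not normal and not hom:
                results = route_and_test(g1, g2)
                assert sorted(r.test_name for r in results) == [
                    "brunner_munzel", "fligner_policello", "wmw",
                ]
                return
        pytest.fail("never drew a sample failing both assumption checks")

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            route_and_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_fixture_sweep_schedules_294_combinations(self, joined_fixture):
        sweep = exploratory_sweep(joined_fixture)
        assert sweep.attrs["n_scheduled"] == 294
        assert sweep.attrs["n_skipped"] == 0
        assert len(sweep) <= 294 * 3
        assert set(sweep["test_name"]) <= {
            "t", "wmw", "fligner_policello", "brunner_munzel",
        }

    def test_sweep_corrections_columns(self, joined_fixture):
        sweep = exploratory_sweep(joined_fixture)
        corr = sweep_corrections(sweep)
        for method in CORRECTION_METHODS:
            assert f"adj_{method}" in corr.columns
            assert (corr[f"adj_{method}"] >= corr["p_value"] - 1e-12).all()


class TestCorrections:
    def test_bonferroni_saturates(self):
        assert adjust_pvalues([0.01] * 294, "bonferroni").adjusted[0] == 1.0

    @pytest.mark.parametrize("method", CORRECTION_METHODS)
    def test_single_test_identity(self, method):
        assert adjust_pvalues([0.123], method).adjusted[0] == pytest.approx(0.123)

    def test_holm_hand_example(self):
        adj = adjust_pvalues([0.01, 0.02, 0.03], "holm").adjusted
        assert adj == pytest.approx((0.03, 0.04, 0.04))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5], "holm")
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "holm")

    @settings(deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(1e-9, 1.0, exclude_min=False), min_size=1, max_size=40)
    )
    def test_fwer_method_ordering(self, p):
        holm = np.array(adjust_pvalues(p, "holm").adjusted)
        hoch = np.array(adjust_pvalues(p, "hochberg").adjusted)
        bonf = np.array(adjust_pvalues(p, "bonferroni").adjusted)
        raw = np.array(p)
        assert (hoch <= holm + 1e-12).all()
        assert (holm <= bonf + 1e-12).all()
        assert (holm >= raw - 1e-12).all()
        assert (hoch >= raw - 1e-12).all()

    def test_matches_statsmodels_reference(self, rng):
        mapping = {
            "bonferroni": "bonferroni",
            "sidak": "sidak",
            "holm": "holm",
            "hochberg": "simes-hochberg",
            "hommel": "hommel",
            "bh": "fdr_bh",
            "by": "fdr_by",
        }
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            for ours, theirs in mapping.items():
                a = np.asarray(adjust_pvalues(p, ours).adjusted)
                b = multipletests(p, method=theirs)[1]
                assert np.allclose(a, b, atol=1e-12), ours
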