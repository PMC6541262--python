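"""MIC, distance correlation and HHG against independent oracles."""

import math

import numpy as np
import pytest

from cultshare.dependence import (
    dependence_screen,
    distance_correlation,
    hhg_pvalues,
    hhg_statistics,
    mic,
)
from cultshare.data import encode_practices
from cultshare.dissimilarity import build_pairwise_table
from cultshare.hhg import scalar_distance_matrix
from cultshare.synthetic import SyntheticConfig, generate_dataset


def dcor_bruteforce(x, y):
    """Literal double-centering computation, element by element."""
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def centre(d):
        row = [sum(r) / n for r in d]
        col = [sum(d[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[d[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)]

    A, B = centre(a), centre(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvx = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    dvy = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return math.sqrt(max(0.0, dcov2) / math.sqrt(dvx * dvy))


def hhg_bruteforce(dx, dy):
    """Quadruple-loop HHG statistics, straight from the 2x2-table definition."""
    n = dx.shape[0]
    sc = sl = mc = ml = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a = [[0, 0], [0, 0]]
            for k in range(n):
                if k in (i, j):
                    continue
                row = 0 if dx[i, k] <= dx[i, j] else 1
                col = 0 if dy[i, k] <= dy[i, j] else 1
                a[row][col] += 1
            r1, r2 = a[0][0] + a[0][1], a[1][0] + a[1][1]
            c1, c2 = a[0][0] + a[1][0], a[0][1] + a[1][1]
            if 0 in (r1, r2, c1, c2):
                continue
            nf = n - 2
            chi = nf * (a[0][0] * a[1][1] - a[0][1] * a[1][0]) ** 2 / (r1 * r2 * c1 * c2)
            g = 0.0
            for (u, v), margin in (
                ((0, 0), r1 * c1), ((0, 1), r1 * c2), ((1, 0), r2 * c1), ((1, 1), r2 * c2),
            ):
                if a[u][v] > 0:
                    g += a[u][v] * math.log(a[u][v] * nf / margin)
            g *= 2.0
            sc += chi
            sl += g
            mc = max(mc, chi)
            ml = max(ml, g)
    return sc, sl, mc, ml


class TestMic:
    def test_symmetric(self, rng):
        x = rng.standard_normal(80)
        y = rng.standard_normal(80) + 0.3 * x
        assert mic(x, y) == pytest.approx(mic(y, x), abs=1e-12)

    def test_perfect_tie_free_dependence_is_one(self, rng):
        x = rng.standard_normal(50)
        assert mic(x, x) == pytest.approx(1.0)

    def test_independent_uniforms_stay_low(self, rng):
        x = rng.random(500)
        y = rng.random(500)
        assert mic(x, y) < 0.25

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero-variation"):
            mic(np.ones(20), np.arange(20.0))

    def test_detects_nonmonotone_relationship(self, rng):
        x = rng.uniform(-1, 1, 200)
        y = x**2 + rng.normal(0, 0.05, 200)
        assert mic(x, y) > 0.6


class TestDistanceCorrelation:
    def test_self_comparison_is_one(self, fixture_hamming):
        assert distance_correlation(fixture_hamming, fixture_hamming) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(40)
        assert distance_correlation(x, 3.0 * x + 7.0) == pytest.approx(1.0, abs=1e-12)

    def test_fixed_small_case_matches_bruteforce(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        assert distance_correlation(x, y) == pytest.approx(
            dcor_bruteforce(x, y), abs=1e-12
        )

    def test_matches_bruteforce_on_random_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            assert distance_correlation(x, y) == pytest.approx(
                dcor_bruteforce(x, y), abs=1e-12
            )

    def test_constant_input_degenerates_to_zero(self):
        assert distance_correlation(np.ones(10), np.arange(10.0)) == 0.0


class TestHHGStatistics:
    def test_matches_quadruple_loop_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 13))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            dx = scalar_distance_matrix(x)
            dy = scalar_distance_matrix(y)
            ours = hhg_statistics(dx, dy)
            oracle = hhg_bruteforce(dx, dy)
            assert ours == pytest.approx(oracle, rel=1e-12)

    def test_constant_y_gives_zero_statistics(self, rng):
        dx = scalar_distance_matrix(rng.standard_normal(10))
        dy = scalar_distance_matrix(np.zeros(10))
        assert hhg_statistics(dx, dy) == (0.0, 0.0, 0.0, 0.0)

    def test_asymmetric_matrix_rejected(self, rng):
        d = rng.random((6, 6))
        with pytest.raises(ValueError, match="symmetric"):
            hhg_statistics(d, scalar_distance_matrix(rng.standard_normal(6)))

    def test_perfect_dependence_dominates_permutations(self, rng):
        x = rng.standard_normal(20)
        dx = scalar_distance_matrix(x)
        obs = hhg_statistics(dx, dx)[0]
        for _ in range(200):
            perm = rng.permutation(20)
            stat = hhg_statistics(dx, dx[np.ix_(perm, perm)])[0]
            assert stat <= obs + 1e-9


class TestHHGPValues:
    def test_floor_is_inverse_permutations_plus_one(self, rng):
        # sum statistics reach the add-one floor under perfect dependence;
        # max statistics can be tied by permutations that recreate one
        # perfectly concordant small table, so they are only bounded below
        x = rng.standard_normal(40)
        pvals = hhg_pvalues(x, x, n_perm=99, seed=1)
        assert pvals[0] == pytest.approx(1 / 100)
        assert pvals[1] == pytest.approx(1 / 100)
        assert all(p >= 1 / 100 for p in pvals)

    def test_seed_reproducibility(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        assert hhg_pvalues(x, y, n_perm=99, seed=5) == hhg_pvalues(
            x, y, n_perm=99, seed=5
        )

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            hhg_pvalues(rng.standard_normal(10), rng.standard_normal(10), n_perm=10)


class TestDependencePower:
    def test_all_measures_detect_oscillatory_signal(self, rng):
        rejections = {"mic": 0, "dcor": 0, "hhg": 0}
        n_reps = 20
        for _ in range(n_reps):
            x = rng.random(200)
            y = np.sin(4 * np.pi * x) + rng.normal(0, 0.2, 200)
            if mic(x, y) > 0.4:
                rejections["mic"] += 1
            if distance_correlation(x, y) > 0.2:
                rejections["dcor"] += 1
            if hhg_pvalues(x, y, n_perm=99, seed=int(rng.integers(2**31)))[0] < 0.05:
                rejections["hhg"] += 1
        assert rejections["hhg"] >= 0.8 * n_reps
        assert rejections["mic"] >= 0.8 * n_reps
        assert rejections["dcor"] >= 0.8 * n_reps


class TestScreen:
    def test_small_synthetic_screen_has_23_rows(self):
        ds = generate_dataset(SyntheticConfig(n_societies=10, seed=2))
        pairs = build_pairwise_table(ds, encode_practices(ds))
        screen, corrected = dependence_screen(pairs, n_perm=99, seed=0)
        assert len(screen) == 23
        assert screen.iloc[-1]["variable"] == "hamming"
        assert screen.iloc[-1]["dcor"] == pytest.approx(1.0, abs=1e-12)
        assert set(corrected) == {"pval_sc", "pval_sl", "pval_mc", "pval_ml"}
        for table in corrected.values():
            assert len(table) == 23
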