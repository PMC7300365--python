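import subprocess
import textwrap
from itertools import product

import numpy as np
import pytest

import phagehost as ph
from phagehost.network import (
    BipartiteMatrix,
    _temperature_of,
    barber_qb,
    lp_brim,
    nodf,
    ntc_temperature,
    null_test,
    pack_matrix,
)
from conftest import make_bm, random_bm


# --- independent oracles -----------------------------------------------------

def naive_nodf(A):
    """Literal pair enumeration of the overlap/decreasing-fill metric."""
    A = np.asarray(A)

    def axis_pairs(M):
        fills = [set(np.flatnonzero(row)) for row in M]
        total, pairs = 0.0, 0
        for u in range(len(fills)):
            for v in range(u + 1, len(fills)):
                pairs += 1
                hi, lo = fills[u], fills[v]
                if len(hi) < len(lo):
                    hi, lo = lo, hi
                if len(hi) > len(lo) > 0:
                    total += 100.0 * len(hi & lo) / len(lo)
        return total, pairs

    rt, rp = axis_pairs(A)
    ct, cp = axis_pairs(A.T)
    return (rt + ct) / (rp + cp) / 100.0


def naive_qb(A, g, h):
    """Term-by-term evaluation of Barber's modularity."""
    A = np.asarray(A, dtype=float)
    k, d, m = A.sum(axis=1), A.sum(axis=0), A.sum()
    q = 0.0
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            if g[i] == h[j]:
                q += A[i, j] - k[i] * d[j] / m
    return q / m


def exhaustive_qb_optimum(A, n_modules=3):
    """Best Barber Qb over every labelling with up to n_modules modules."""
    r, c = A.shape
    best = -1.0
    for g in product(range(n_modules), repeat=r):
        for h in product(range(n_modules), repeat=c):
            best = max(best, naive_qb(A, g, h))
    return best


# --- NODF --------------------------------------------------------------------

class TestNodf:
    def test_staircase_is_perfectly_nested(self, staircase):
        overall, rows, cols = nodf(staircase)
        assert overall == rows == cols == 1.0

    def test_identity_matrix_scores_zero(self):
        assert nodf(make_bm([[1, 0], [0, 1]]))[0] == 0.0

    def test_all_ones_scores_zero(self):
        assert nodf(make_bm(np.ones((3, 3), dtype=int)))[0] == 0.0

    def test_percent_scale_flag(self, staircase):
        assert nodf(staircase, percent=True)[0] == 100.0

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            nodf(make_bm([[1, 1]]))

    def test_agrees_with_naive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            M = random_bm(rng, max_side=8)
            assert nodf(M)[0] == pytest.approx(naive_nodf(M.A), abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            M = random_bm(rng)
            perm = M.permuted(
                rng.permutation(M.shape[0]), rng.permutation(M.shape[1])
            )
            assert nodf(perm)[0] == pytest.approx(nodf(M)[0])

    def test_agrees_with_vegan(self, tmp_path):
        """Cross-check against the vegan R package's NODF on random matrices."""
        rng = np.random.default_rng(9)
        mats = [random_bm(rng, max_side=10) for _ in range(5)]
        for i, M in enumerate(mats):
            np.savetxt(tmp_path / f"m{i}.csv", M.A, fmt="%d", delimiter=",")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            for (f in commandArgs(trailingOnly=TRUE)) {
              m <- as.matrix(read.csv(f, header=FALSE))
              s <- nestednodf(m, order=TRUE)$statistic
              cat(sprintf("%.10f %.10f %.10f\\n", s["N.rows"], s["N.columns"], s["NODF"]))
            }
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script]
            + [str(tmp_path / f"m{i}.csv") for i in range(5)],
            capture_output=True, text=True, check=True,
        )
        for M, line in zip(mats, out.stdout.strip().splitlines()):
            v_rows, v_cols, v_all = map(float, line.split())
            overall, rows, cols = nodf(M, percent=True)
            assert rows == pytest.approx(v_rows, abs=1e-6)
            assert cols == pytest.approx(v_cols, abs=1e-6)
            assert overall == pytest.approx(v_all, abs=1e-6)


# --- temperature -------------------------------------------------------------

class TestTemperature:
    def test_all_ones_has_zero_temperature(self):
        T, n_ntc = ntc_temperature(make_bm(np.ones((4, 5), dtype=int)))
        assert T == 0.0 and n_ntc == 1.0

    def test_noiseless_nested_matrix_is_cold(self):
        M, _ = ph.simulate_nested_matrix(10, 14, fill=0.4, seed=2)
        T, _ = ntc_temperature(M)
        assert T < 5

    def test_checkerboard_hotter_than_nested(self):
        checker = (np.indices((4, 4)).sum(axis=0) % 2).astype(np.int8)
        nested, _ = ph.simulate_nested_matrix(4, 4, fill=0.5, seed=1)
        T_checker, _ = ntc_temperature(make_bm(checker))
        T_nested, _ = ntc_temperature(nested)
        assert T_checker > T_nested

    def test_temperature_in_range_and_consistent(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            M = random_bm(rng)
            T, n_ntc = ntc_temperature(M)
            assert 0.0 <= T <= 100.0
            assert n_ntc == pytest.approx((100 - T) / 100)

    def test_permutation_invariance_via_packing(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            M = random_bm(rng, max_side=6)
            perm = M.permuted(
                rng.permutation(M.shape[0]), rng.permutation(M.shape[1])
            )
            assert ntc_temperature(perm)[0] == pytest.approx(
                ntc_temperature(M)[0], abs=1e-9
            )


class TestPackMatrix:
    def test_packed_staircase_is_fixed_point(self, staircase):
        packed, row_order, col_order = pack_matrix(staircase)
        assert row_order == [0, 1, 2] and col_order == [0, 1, 2]
        assert (packed.A == staircase.A).all()

    def test_reversed_staircase_restored(self, staircase):
        reversed_ = staircase.permuted([2, 1, 0], [2, 1, 0])
        packed, _, _ = pack_matrix(reversed_)
        assert (packed.A == staircase.A).all()

    def test_degrees_preserved(self):
        rng = np.random.default_rng(13)
        M = random_bm(rng)
        packed, _, _ = pack_matrix(M)
        assert sorted(packed.k) == sorted(M.k)
        assert sorted(packed.d) == sorted(M.d)
        assert packed.m == M.m


# --- modularity --------------------------------------------------------------

class TestBarberQb:
    def test_single_module_partition_is_zero(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            M = random_bm(rng)
            rows = {l: 0 for l in M.row_labels}
            cols = {l: 0 for l in M.col_labels}
            assert barber_qb(M, rows, cols) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_blocks_closed_form(self):
        M = make_bm([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]])
        rows = {f"g{i}": i // 2 for i in range(4)}
        cols = {f"v{j}": j // 2 for j in range(4)}
        assert barber_qb(M, rows, cols) == pytest.approx(0.5)

    def test_unlabeled_node_rejected(self):
        M = make_bm([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="unlabeled"):
            barber_qb(M, {"g0": 0}, {"v0": 0, "v1": 1})

    def test_agrees_with_naive_summation(self):
        rng = np.random.default_rng(15)
        for _ in range(200):
            M = random_bm(rng, max_side=8)
            g = rng.integers(0, 3, M.shape[0])
            h = rng.integers(0, 3, M.shape[1])
            rows = dict(zip(M.row_labels, g))
            cols = dict(zip(M.col_labels, h))
            assert barber_qb(M, rows, cols) == pytest.approx(
                naive_qb(M.A, g, h), abs=1e-12
            )

    def test_invariance_under_permutation_with_label_transport(self):
        rng = np.random.default_rng(16)
        M = random_bm(rng)
        g = rng.integers(0, 3, M.shape[0])
        h = rng.integers(0, 3, M.shape[1])
        rows = dict(zip(M.row_labels, g))
        cols = dict(zip(M.col_labels, h))
        q = barber_qb(M, rows, cols)
        perm = M.permuted(rng.permutation(M.shape[0]), rng.permutation(M.shape[1]))
        assert barber_qb(perm, rows, cols) == pytest.approx(q)


class TestLpBrim:
    def test_two_disjoint_blocks_recovered(self):
        M = make_bm([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]])
        res = lp_brim(M, seed=1, n_restarts=5)
        assert res.qb == pytest.approx(0.5)
        assert res.n_modules == 2
        assert res.row_modules["g0"] == res.row_modules["g1"] == res.col_modules["v0"]
        assert res.row_modules["g2"] == res.col_modules["v2"]

    def test_all_ones_single_module(self):
        res = lp_brim(make_bm(np.ones((3, 4), dtype=int)), seed=2)
        assert res.qb == pytest.approx(0.0, abs=1e-12)
        assert res.n_modules == 1

    def test_matches_exhaustive_optimum_on_tiny_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(12):
            M = random_bm(rng, max_side=4)
            res = lp_brim(M, seed=3, n_restarts=10)
            assert res.qb == pytest.approx(
                exhaustive_qb_optimum(M.A, n_modules=3), abs=1e-9
            )

    def test_dominates_planted_partition(self):
        for seed in range(5):
            M, truth = ph.simulate_modular_matrix(
                [(3, 5)] * 3, p_within=0.9, p_between=0.05, seed=seed
            )
            planted_q = barber_qb(
                M,
                {l: truth.planted_partition[l] for l in M.row_labels},
                {l: truth.planted_partition[l] for l in M.col_labels},
            )
            assert lp_brim(M, seed=seed, n_restarts=10).qb >= planted_q - 1e-9

    def test_seeded_determinism(self):
        rng = np.random.default_rng(18)
        M = random_bm(rng)
        a = lp_brim(M, seed=5, n_restarts=5)
        b = lp_brim(M, seed=5, n_restarts=5)
        assert a == b


# --- null model --------------------------------------------------------------

class TestNullTest:
    def test_add_one_smoothing_lower_bound(self):
        M, _ = ph.simulate_nested_matrix(8, 10, fill=0.4, seed=6)
        res = null_test(M, "nodf", n_iterations=100, seed=1)
        assert res.p_empirical >= 1 / 101

    def test_planted_nestedness_detected(self):
        M, _ = ph.simulate_nested_matrix(10, 12, fill=0.35, seed=7)
        res = null_test(M, "nodf", n_iterations=200, seed=2)
        assert res.z is not None and res.z > 3

    def test_null_draw_is_calibrated(self):
        # matrices that ARE equiprobable draws should rarely look structured
        hits = 0
        reps = 30
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            while True:
                A = (rng.random((20, 20)) < 0.3).astype(np.int8)
                if A.sum(axis=1).all() and A.sum(axis=0).all():
                    break
            M = make_bm(A)
            res = null_test(M, "nodf", n_iterations=150, seed=rep)
            if res.z is not None and abs(res.z) < 3:
                hits += 1
        assert hits >= 0.95 * reps

    def test_qb_statistic_path(self):
        M, _ = ph.simulate_modular_matrix(
            [(3, 3), (3, 3)], p_within=0.95, p_between=0.05, seed=8
        )
        res = null_test(M, "qb", n_iterations=100, seed=3)
        assert res.statistic_name == "qb"
        assert res.observed > res.null_mean

    def test_unknown_statistic_rejected(self):
        M, _ = ph.simulate_nested_matrix(4, 4, fill=0.5, seed=1)
        with pytest.raises(ValueError):
            null_test(M, "degree", n_iterations=100)

    def test_seeded_determinism(self):
        M, _ = ph.simulate_nested_matrix(6, 8, fill=0.4, seed=9)
        a = null_test(M, "nodf", n_iterations=100, seed=4)
        b = null_test(M, "nodf", n_iterations=100, seed=4)
        assert a == b


class TestBipartiteMatrixValidation:
    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            BipartiteMatrix(A=np.array([[2, 0], [0, 1]]),
                            row_labels=["a", "b"], col_labels=["x", "y"])

    def test_empty_margin_rejected_for_statistics(self):
        M = BipartiteMatrix(A=np.array([[1, 0], [0, 0]]),
                            row_labels=["a", "b"], col_labels=["x", "y"])
        with pytest.raises(ValueError, match="empty"):
            nodf(M)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            BipartiteMatrix(A=np.eye(2, dtype=int),
                            row_labels=["a", "a"], col_labels=["x", "y"])
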