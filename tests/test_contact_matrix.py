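"""Contact-matrix storage, I/O, balancing, scaling, and capping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tiledc import (
    BinGrid,
    ContactMatrix,
    GenomicInterval,
    ice_balance,
    merge,
    percentile_cap,
    read_triplets,
    scale_to_mean_total,
    subtract,
    total_interactions,
    write_triplets,
)
from conftest import random_raw_matrix


def ice_oracle(dense, low_cov_fraction=0.02, tol=1e-4, max_iter=300):
    """Plain-Python iterative correction used as an independent check."""
    n = len(dense)
    d = [[float(dense[i][j]) for j in range(n)] for i in range(n)]
    marg = [sum(row) for row in d]
    masked = [m <= 0 for m in marg]
    positive = sorted(
        (i for i in range(n) if not masked[i]), key=lambda i: marg[i]
    )
    for i in positive[: math.floor(low_cov_fraction * len(positive))]:
        masked[i] = True
    for i in range(n):
        if masked[i]:
            for j in range(n):
                d[i][j] = 0.0
                d[j][i] = 0.0
    unmasked = [i for i in range(n) if not masked[i]]
    original_total = sum(
        dense[i][j] for i in range(n) for j in range(i, n)
        if not masked[i] and not masked[j]
    )
    for _ in range(max_iter):
        marg = [sum(row) for row in d]
        mean = sum(marg[i] for i in unmasked) / len(unmasked)
        if max(abs(marg[i] / mean - 1.0) for i in unmasked) <= tol:
            break
        r = [marg[i] / mean if not masked[i] else 1.0 for i in range(n)]
        for i in range(n):
            for j in range(n):
                d[i][j] /= r[i] * r[j]
    total = sum(d[i][j] for i in range(n) for j in range(i, n))
    if total > 0:
        f = original_total / total
        d = [[v * f for v in row] for row in d]
    return d, masked


class TestTripletIO:
    def test_single_line(self, grid10, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("0\t1\t5\n")
        m = read_triplets(p, grid10)
        assert m.get(0, 1) == 5

    def test_transposed_duplicates_fold(self, grid10, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("1\t0\t5\n0\t1\t2\n")
        m = read_triplets(p, grid10)
        assert m.get(0, 1) == 7
        assert m.n_entries == 1

    def test_round_trip(self, grid10, rng, tmp_path):
        m = random_raw_matrix(grid10, rng)
        path = tmp_path / "m.tsv"
        write_triplets(m, path)
        back = read_triplets(path, grid10)
        assert back.equals(m)
        assert (tmp_path / "m.tsv.grid.json").exists()

    def test_float_round_trip_exact(self, grid10, tmp_path):
        m = ContactMatrix(grid10, [0, 1], [1, 2], [0.1, 1 / 3], stage="balanced")
        path = tmp_path / "b.tsv"
        write_triplets(m, path)
        back = read_triplets(path, grid10, stage="balanced")
        assert back.equals(m)

    @pytest.mark.parametrize(
        "content,match",
        [
            ("0\t99\t5\n", "out of range"),
            ("0\t1\t-3\n", "non-negative"),
            ("0\t1\t2.5\n", "integer"),
            ("zero\tone\tfive\n", "unparsable"),
            ("0\t1\n", "expected"),
        ],
    )
    def test_bad_lines_report_line_number(self, grid10, tmp_path, content, match):
        p = tmp_path / "bad.tsv"
        p.write_text("0\t1\t1\n" + content)
        with pytest.raises(ValueError, match=match) as err:
            read_triplets(p, grid10)
        assert ":2" in str(err.value)

    def test_symmetric_access(self, grid10):
        m = ContactMatrix(grid10, [0], [3], [2.0], stage="raw")
        assert m.get(3, 0) == m.get(0, 3) == 2.0


class TestTotalAndMerge:
    def test_total_counts_pairs_once(self, grid10):
        m = ContactMatrix(grid10, [0, 1], [1, 1], [5.0, 2.0], stage="raw")
        assert total_interactions(m) == 7

    def test_total_empty(self, grid10):
        m = ContactMatrix(grid10, [], [], [], stage="raw")
        assert total_interactions(m) == 0

    def test_total_linear_in_scale(self, grid10, rng):
        m = random_raw_matrix(grid10, rng)
        assert total_interactions(m.scaled_by(2.0)) == pytest.approx(
            2 * total_interactions(m)
        )

    def test_total_undefined_for_subtraction(self, grid10):
        m = ContactMatrix(grid10, [0], [1], [-1.0], stage="subtraction")
        with pytest.raises(ValueError):
            total_interactions(m)

    def test_merge_with_empty_is_identity(self, grid10, rng):
        m = random_raw_matrix(grid10, rng)
        empty = ContactMatrix(grid10, [], [], [], stage="raw")
        merged = merge([m, empty])
        assert np.allclose(merged.values, m.values)

    def test_merge_self_doubles(self, grid10, rng):
        m = random_raw_matrix(grid10, rng)
        merged = merge([m, m])
        assert merged.stage == "merged"
        assert np.allclose(merged.values, 2 * m.values)

    def test_merge_disjoint_supports_is_union(self, grid10):
        a = ContactMatrix(grid10, [0], [1], [3.0], stage="raw")
        b = ContactMatrix(grid10, [2], [3], [4.0], stage="raw")
        merged = merge([a, b])
        assert merged.n_entries == 2
        assert merged.get(0, 1) == 3 and merged.get(2, 3) == 4

    def test_merge_rejects_mixed_stages(self, grid10):
        a = ContactMatrix(grid10, [0], [1], [3.0], stage="raw")
        b = ContactMatrix(grid10, [0], [1], [3.0], stage="balanced")
        with pytest.raises(ValueError):
            merge([a, b])


class TestIceBalance:
    def test_rank_one_balances_to_constant(self):
        grid = BinGrid(GenomicInterval("chrT", 0, 6000), 2000)
        v = np.array([1.0, 2.0, 4.0])
        dense = np.outer(v, v)
        m = ContactMatrix.from_dense(grid, dense, stage="raw")
        b, res = ice_balance(m)
        assert res.converged
        off = [b.get(0, 1), b.get(0, 2), b.get(1, 2)]
        assert np.allclose(off, off[0], rtol=1e-3)
        marg = b.to_dense().sum(axis=1)
        assert np.abs(marg / marg.mean() - 1).max() <= 1e-4

    def test_all_ones_unchanged_and_fast(self, grid10):
        n = grid10.n_bins
        m = ContactMatrix.from_dense(grid10, np.ones((n, n)), stage="raw")
        b, res = ice_balance(m)
        assert res.converged and res.iterations <= 2
        assert np.allclose(b.values, m.values)

    def test_zero_row_masked(self, grid10, rng):
        m = random_raw_matrix(grid10, rng)
        dense = m.to_dense()
        dense[4, :] = 0
        dense[:, 4] = 0
        m2 = ContactMatrix.from_dense(grid10, dense, stage="raw")
        b, res = ice_balance(m2)
        assert 4 in res.masked_bins
        assert 4 in b.masked_bins
        assert np.isnan(res.bias[4])

    def test_total_preserved(self, grid10, rng):
        m = random_raw_matrix(grid10, rng)
        b, _ = ice_balance(m)
        assert total_interactions(b) == pytest.approx(
            total_interactions(m), rel=1e-9
        )

    def test_rebalancing_near_idempotent(self, grid10, rng):
        m = random_raw_matrix(grid10, rng)
        b, _ = ice_balance(m)
        b_as_input = ContactMatrix(
            grid10, b.bins1, b.bins2, b.values, stage="merged"
        )
        b2, res2 = ice_balance(b_as_input)
        dense1, dense2 = b.to_dense(), b2.to_dense()
        assert np.abs(dense1 - dense2).max() <= 1e-4 * dense1.max()

    def test_matches_brute_force_oracle(self, rng):
        grid = BinGrid(GenomicInterval("chrT", 0, 40_000), 2000)
        for _ in range(20):
            m = random_raw_matrix(grid, rng, mean=8.0)
            b, res = ice_balance(m)
            oracle, masked = ice_oracle(m.to_dense().tolist())
            got = b.to_dense()
            want = np.array(oracle)
            scale = want.max() or 1.0
            assert np.abs(got - want).max() <= 1e-6 * scale

    def test_requires_raw_or_merged(self, grid10):
        m = ContactMatrix(grid10, [0], [1], [1.0], stage="scaled")
        with pytest.raises(ValueError):
            ice_balance(m)

    def test_all_zero_matrix_errors(self, grid10):
        m = ContactMatrix(grid10, [], [], [], stage="raw")
        with pytest.raises(ValueError, match="masked"):
            ice_balance(m)


class TestScaleSubtractCap:
    def _balanced(self, grid, values_scale, rng):
        m = random_raw_matrix(grid, rng)
        b, _ = ice_balance(m)
        return b.scaled_by(values_scale, stage="balanced")

    def test_scale_pair_totals_equalized(self, grid10, rng):
        a = self._balanced(grid10, 1.0, rng)
        b = a.scaled_by(3.0, stage="balanced")  # totals ratio 1:3
        sa, sb = scale_to_mean_total([a, b])
        ta, tb = total_interactions(sa), total_interactions(sb)
        mean = (total_interactions(a) + total_interactions(b)) / 2
        assert ta == pytest.approx(mean, rel=1e-9)
        assert tb == pytest.approx(mean, rel=1e-9)

    def test_scale_single_unchanged(self, grid10, rng):
        a = self._balanced(grid10, 1.0, rng)
        (s,) = scale_to_mean_total([a])
        assert np.allclose(s.values, a.values)

    def test_scale_factors_for_three(self, grid10):
        base = ContactMatrix(grid10, [0], [1], [10.0], stage="balanced")
        ms = [base, base.scaled_by(2.0), base.scaled_by(3.0)]  # totals 10,20,30
        scaled = scale_to_mean_total(ms)
        factors = [s.values[0] / m.values[0] for s, m in zip(scaled, ms)]
        assert factors == pytest.approx([2.0, 1.0, 2 / 3])

    def test_scale_preserves_within_matrix_ratios(self, grid10, rng):
        a = self._balanced(grid10, 1.0, rng)
        b = a.scaled_by(5.0, stage="balanced")
        sa, _ = scale_to_mean_total([a, b])
        assert np.allclose(sa.values / a.values, sa.values[0] / a.values[0])

    def test_scale_rejects_zero_total(self, grid10):
        z = ContactMatrix(grid10, [], [], [], stage="balanced")
        with pytest.raises(ValueError):
            scale_to_mean_total([z])

    def test_subtract_self_is_empty(self, grid10):
        a = ContactMatrix(grid10, [0], [1], [5.0], stage="scaled")
        d = subtract(a, a)
        assert d.stage == "subtraction"
        assert d.n_entries == 0

    def test_subtract_antisymmetric(self, grid10, rng):
        a = random_raw_matrix(grid10, rng).scaled_by(1.0, stage="scaled")
        b = random_raw_matrix(grid10, np.random.default_rng(1)).scaled_by(
            1.0, stage="scaled"
        )
        ab, ba = subtract(a, b), subtract(b, a)
        assert np.allclose(ab.values, -ba.values)

    def test_subtract_union_support(self, grid10):
        a = ContactMatrix(grid10, [0], [1], [5.0], stage="scaled")
        b = ContactMatrix(grid10, [0, 2], [1, 3], [2.0, 1.0], stage="scaled")
        d = subtract(a, b)
        assert d.get(0, 1) == 3 and d.get(2, 3) == -1

    def test_subtract_requires_scaled(self, grid10):
        a = ContactMatrix(grid10, [0], [1], [5.0], stage="scaled")
        b = ContactMatrix(grid10, [0], [1], [5.0], stage="balanced")
        with pytest.raises(ValueError):
            subtract(a, b)

    def test_cap_at_100_is_identity(self, grid10, rng):
        m = random_raw_matrix(grid10, rng)
        assert np.allclose(percentile_cap(m, 100).values, m.values)

    def test_cap_interpolates_order_statistics(self):
        grid = BinGrid(GenomicInterval("chrT", 0, 30_000), 2000)
        vals = np.arange(1.0, 101.0)
        iu, ju = np.triu_indices(grid.n_bins)
        m = ContactMatrix(grid, iu[:100], ju[:100], vals, stage="raw")
        capped = percentile_cap(m, 94)
        assert capped.values.max() == pytest.approx(94.06)
        assert np.count_nonzero(np.isclose(capped.values, 94.06)) >= 6

    def test_cap_subtraction_sign_symmetric(self, grid10):
        m = ContactMatrix(
            grid10, [0, 0, 1, 1], [1, 2, 2, 3], [-10.0, -1.0, 1.0, 10.0],
            stage="subtraction",
        )
        capped = percentile_cap(m, 97)
        pos_cap = np.percentile([1.0, 10.0], 97)
        assert capped.values.max() == pytest.approx(pos_cap)
        assert capped.values.min() == pytest.approx(-pos_cap)

    def test_cap_rejects_empty(self, grid10):
        with pytest.raises(ValueError):
            percentile_cap(ContactMatrix(grid10, [], [], [], stage="raw"), 94)
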