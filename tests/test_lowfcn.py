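import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hofcnet.errors import DegenerateSignalError, WindowError
from hofcnet.lowfcn import (
    DEFAULT_REGULARIZER_GRID,
    DEFAULT_THRESHOLD_LEVELS,
    pearson_fcn,
    sliding_windows,
    sparse_representation_fcn,
    standardize_columns,
    threshold_sparsify,
    windowed_fcns,
)
from hofcnet.synthetic import ModularCovSpec, make_modular_cov, sample_bold
from hofcnet.types import WindowSpec

from conftest import rand_sym


class TestStandardizeColumns:
    def test_forced_by_definition(self):
        out = standardize_columns(np.array([[1.0], [2.0], [3.0]], ndmin=2))
        expected = np.array([[-1 / math.sqrt(2)], [0.0], [1 / math.sqrt(2)]])
        np.testing.assert_allclose(out, expected, atol=1e-15)

    def test_idempotent(self, rng):
        x = standardize_columns(rng.standard_normal((30, 5)))
        np.testing.assert_allclose(standardize_columns(x), x, atol=1e-12)

    def test_zero_mean_unit_norm(self, rng):
        out = standardize_columns(rng.standard_normal((50, 10)))
        assert np.all(np.abs(out.mean(axis=0)) < 1e-12)
        assert np.all(np.abs(np.linalg.norm(out, axis=0) - 1.0) < 1e-12)

    def test_constant_column_names_roi(self):
        x = np.ones((10, 3))
        x[:, 0] = np.arange(10)
        x[:, 2] = np.arange(10) ** 2
        with pytest.raises(DegenerateSignalError, match="Amygdala"):
            standardize_columns(x, labels=["A", "Amygdala", "C"])


class TestPearsonFcn:
    def test_identical_columns(self, rng):
        col = rng.standard_normal(20)
        w = pearson_fcn(np.column_stack([col, col]))
        assert w[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_example(self):
        # deviations (-1.5,-0.5,0.5,1.5) . (-1.5,0.5,-0.5,1.5) = 4, norms sqrt(5)
        x = np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0], [4.0, 4.0]])
        assert pearson_fcn(x)[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_anticorrelation(self, rng):
        col = rng.standard_normal(15)
        w = pearson_fcn(np.column_stack([col, -col]))
        assert w[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_bounds_diag_symmetry(self, rng):
        w = pearson_fcn(rng.standard_normal((40, 8)))
        assert np.all(np.abs(w) <= 1.0)
        np.testing.assert_allclose(np.diag(w), 1.0)
        np.testing.assert_allclose(w, w.T, atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5.0, 5.0),
    )
    def test_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((25, 4))
        y = x.copy()
        y[:, 1] = scale * y[:, 1] + shift
        np.testing.assert_allclose(pearson_fcn(x), pearson_fcn(y), atol=1e-10)


def _sr_objective(xs, w, lam):
    return float(np.linalg.norm(xs - xs @ w) ** 2 + lam * np.abs(w).sum())


class TestSparseRepresentation:
    def test_negative_lambda(self, rng):
        with pytest.raises(ValueError):
            sparse_representation_fcn(rng.standard_normal((10, 3)), -0.1)

    def test_lasso_dead_zone(self, rng):
        x = rng.standard_normal((25, 6))
        xs = standardize_columns(x)
        gram = np.abs(xs.T @ xs - np.eye(6))
        lam = 2.0 * gram.max() + 1e-9
        w = sparse_representation_fcn(x, lam)
        assert np.all(w == 0.0)

    def test_unregularized_two_rois(self, rng):
        x = rng.standard_normal((30, 2))
        xs = standardize_columns(x)
        raw = sparse_representation_fcn(x, 0.0, symmetrize=None)
        expected = float(xs[:, 0] @ xs[:, 1])
        assert raw[1, 0] == pytest.approx(expected, abs=1e-10)
        assert raw[0, 1] == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("lam", [0.05, 0.3, 1.0])
    def test_kkt_certified_optimum(self, rng, lam):
        # independent oracle: subgradient (KKT) conditions of the per-column lasso
        x = rng.standard_normal((30, 5))
        xs = standardize_columns(x)
        w = sparse_representation_fcn(x, lam, symmetrize=None, tol=1e-12)
        for i in range(5):
            r = xs[:, i] - xs @ w[:, i]
            grad = 2.0 * (xs.T @ r)  # = lam * sgn(w_ji) at nonzero coords
            for j in range(5):
                if j == i:
                    continue
                if w[j, i] != 0.0:
                    assert grad[j] == pytest.approx(lam * np.sign(w[j, i]), abs=1e-6)
                else:
                    assert abs(grad[j]) <= lam + 1e-6

    @pytest.mark.parametrize("lam", [0.05, 0.5])
    def test_objective_matches_sklearn(self, rng, lam):
        from sklearn.linear_model import Lasso

        x = rng.standard_normal((30, 5))
        xs = standardize_columns(x)
        ours = sparse_representation_fcn(x, lam, symmetrize=None, tol=1e-12)
        v = xs.shape[0]
        for i in range(5):
            others = [j for j in range(5) if j != i]
            ref = Lasso(alpha=lam / (2 * v), fit_intercept=False, tol=1e-12,
                        max_iter=100_000)
            ref.fit(xs[:, others], xs[:, i])
            w_ref = np.zeros(5)
            w_ref[others] = ref.coef_
            obj_ref = float(
                np.linalg.norm(xs[:, i] - xs @ w_ref) ** 2 + lam * np.abs(w_ref).sum()
            )
            obj_ours = float(
                np.linalg.norm(xs[:, i] - xs @ ours[:, i]) ** 2
                + lam * np.abs(ours[:, i]).sum()
            )
            assert obj_ours <= obj_ref + 1e-6

    def test_support_monotone_in_lambda(self, rng):
        x = rng.standard_normal((40, 6))
        counts = [
            int(np.count_nonzero(sparse_representation_fcn(x, lam)))
            for lam in DEFAULT_REGULARIZER_GRID
        ]
        assert counts == sorted(counts, reverse=True)

    def test_zero_diagonal_and_symmetry(self, rng):
        w = sparse_representation_fcn(rng.standard_normal((25, 5)), 0.1)
        assert np.all(np.diag(w) == 0.0)
        np.testing.assert_allclose(w, w.T, atol=1e-10)


class TestSlidingWindows:
    def test_count_formula(self):
        assert len(sliding_windows(137, WindowSpec(70, 1))) == 68

    def test_single_full_window(self):
        assert sliding_windows(50, WindowSpec(50, 7)) == [(0, 50)]

    def test_enumeration(self):
        assert sliding_windows(10, WindowSpec(4, 3)) == [(0, 4), (3, 7), (6, 10)]

    def test_width_exceeds_series(self):
        with pytest.raises(WindowError):
            sliding_windows(10, WindowSpec(11, 1))

    @settings(max_examples=50, deadline=None)
    @given(v=st.integers(2, 300), n=st.integers(2, 300), s=st.integers(1, 50))
    def test_count_matches_floor_formula(self, v, n, s):
        if n > v:
            with pytest.raises(WindowError):
                sliding_windows(v, WindowSpec(n, s))
        else:
            wins = sliding_windows(v, WindowSpec(n, s))
            assert len(wins) == (v - n) // s + 1
            assert all(hi - lo == n for lo, hi in wins)
            assert wins[-1][1] <= v


class TestWindowedFcns:
    def test_single_window_equals_global(self, rng):
        x = rng.standard_normal((30, 4))
        out = windowed_fcns(x, WindowSpec(30, 30))
        assert len(out) == 1
        np.testing.assert_allclose(out[0], pearson_fcn(x), atol=1e-12)

    def test_count_consistency(self, rng):
        x = rng.standard_normal((60, 4))
        spec = WindowSpec(20, 7)
        assert len(windowed_fcns(x, spec)) == len(sliding_windows(60, spec))

    def test_stationary_mean_close_to_global(self):
        cov = make_modular_cov(ModularCovSpec(8, 2, 0.5, 0.1))
        ts = sample_bold(cov, 2000, 42)
        mean_w = np.mean(windowed_fcns(ts.data, WindowSpec(100, 50)), axis=0)
        # tolerance calibrated by repeat runs (~0.01 observed max deviation)
        assert np.max(np.abs(mean_w - pearson_fcn(ts.data))) < 0.05

    def test_degenerate_window_names_window(self):
        x = np.random.default_rng(1).standard_normal((20, 3))
        x[:10, 1] = 5.0  # constant inside the first window only
        with pytest.raises(DegenerateSignalError, match="window 1"):
            windowed_fcns(x, WindowSpec(10, 10))


class TestThresholdSparsify:
    def test_identity_at_one(self, rng):
        w = rand_sym(rng, 7)
        np.testing.assert_array_equal(threshold_sparsify(w, 1.0), w)

    def test_keeps_three_largest(self):
        w = np.zeros((4, 4))
        vals = [0.9, -0.8, 0.7, 0.3, -0.2, 0.1]
        iu = np.triu_indices(4, 1)
        w[iu] = vals
        w = w + w.T
        out = threshold_sparsify(w, 0.5)
        kept = out[iu]
        assert np.count_nonzero(kept) == 3
        np.testing.assert_array_equal(kept, [0.9, -0.8, 0.7, 0.0, 0.0, 0.0])

    def test_brute_force_count_oracle(self, rng):
        w = rand_sym(rng, 9)
        iu = np.triu_indices(9, 1)
        for frac in DEFAULT_THRESHOLD_LEVELS:
            out = threshold_sparsify(w, frac)
            expected = math.ceil(frac * iu[0].size)
            # brute force: sort magnitudes, cut
            cut = sorted(np.abs(w[iu]), reverse=True)[:expected]
            assert np.count_nonzero(out[iu]) == expected
            assert np.sum(np.abs(out[iu])) == pytest.approx(np.sum(cut))

    def test_count_monotone_in_fraction(self, rng):
        w = rand_sym(rng, 8)
        counts = [
            np.count_nonzero(threshold_sparsify(w, f)) for f in DEFAULT_THRESHOLD_LEVELS
        ]
        assert counts == sorted(counts)

    def test_deterministic_tie_break(self):
        w = np.ones((4, 4)) - np.eye(4) * 0.0  # all off-diagonal ties
        np.fill_diagonal(w, 0.0)
        out = threshold_sparsify(w, 0.5)
        iu = np.triu_indices(4, 1)
        # lexicographically first 3 of the 6 edges survive
        np.testing.assert_array_equal(out[iu], [1, 1, 1, 0, 0, 0])

    @pytest.mark.parametrize("frac", [0.0, -0.2, 1.3])
    def test_range_error(self, rng, frac):
        with pytest.raises(ValueError):
            threshold_sparsify(rand_sym(rng, 4), frac)

    def test_diagonal_preserved(self, rng):
        w = rand_sym(rng, 6) + np.diag(np.arange(6.0))
        out = threshold_sparsify(w, 0.01)
        np.testing.assert_array_equal(np.diag(out), np.diag(w))
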