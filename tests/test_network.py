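"""Blocking-layer linear algebra: Phi, B, H, least squares, prediction."""

import numpy as np
import pytest

import msrbf as m
from msrbf.errors import ValidationError
from msrbf.network import ModelState


def _random_model(rng, n_nodes=4, d=1, active=None):
    afs = [
        m.GaussianAF(tuple(rng.uniform(-3, 3, size=d)),
                     float(rng.uniform(0.3, 2.0)), float(rng.uniform(0.5, 2.0)))
        for _ in range(n_nodes)
    ]
    if active is None:
        active = [bool(rng.random() < 0.5) for _ in range(n_nodes)]
    return ModelState(afs=afs, block_active=active,
                      weights=rng.normal(size=n_nodes))


class TestResponseMatrix:
    def test_single_af_at_center(self):
        af = m.GaussianAF((1.0,), 1.0, 2.5)
        Phi = m.response_matrix([af], [[1.0]])
        assert Phi.shape == (1, 1)
        assert Phi[0, 0] == pytest.approx(2.5)

    def test_matches_per_kernel_loop(self, rng):
        afs = [m.GaussianAF((float(c),), 1.0 + i * 0.3, 1.0)
               for i, c in enumerate(rng.normal(size=4))]
        X = rng.normal(size=(15, 1))
        Phi = m.response_matrix(afs, X)
        for j, af in enumerate(afs):
            np.testing.assert_array_equal(Phi[:, j], m.evaluate(af, X))

    def test_duplicate_af_duplicates_column(self):
        af = m.GaussianAF((0.0,), 1.0, 1.0)
        Phi = m.response_matrix([af, af], [[0.3], [0.9]])
        np.testing.assert_array_equal(Phi[:, 0], Phi[:, 1])


class TestBlockingMatrix:
    def test_no_active_blocks_all_ones(self, rng):
        model = _random_model(rng, active=[False] * 4)
        B = m.blocking_matrix(model, rng.normal(size=(10, 1)))
        assert np.all(B == 1.0)

    def test_block_hits_later_columns_only(self):
        af1 = m.GaussianAF((0.0,), 1.0, 1.0)
        af2 = m.GaussianAF((10.0,), 1.0, 1.0)
        af3 = m.GaussianAF((20.0,), 1.0, 1.0)
        model = ModelState(afs=[af1, af2, af3],
                           block_active=[True, False, False],
                           weights=np.ones(3))
        X = np.array([[0.5], [50.0]])  # first point inside af1's field
        B = m.blocking_matrix(model, X)
        np.testing.assert_array_equal(B[0], [1.0, 0.0, 0.0])
        np.testing.assert_array_equal(B[1], [1.0, 1.0, 1.0])

    def test_matches_product_of_indicators_oracle(self, rng):
        for _ in range(20):
            model = _random_model(rng, n_nodes=5)
            X = rng.uniform(-4, 4, size=(25, 1))
            B = m.blocking_matrix(model, X)
            # explicit cumulative product of per-node pass indicators
            oracle = np.ones_like(B)
            for j in range(5):
                for l in range(j):
                    if model.block_active[l]:
                        inside = m.receptive_field_mask(
                            model.afs[l], X, model.radius_factor
                        )
                        oracle[:, j] *= (~inside).astype(float)
            np.testing.assert_array_equal(B, oracle)
            assert np.all(B[:, 0] == 1.0)
            assert set(np.unique(B)) <= {0.0, 1.0}

    def test_rows_non_increasing_for_blocked_points(self, rng):
        for _ in range(10):
            model = _random_model(rng, n_nodes=6)
            B = m.blocking_matrix(model, rng.uniform(-4, 4, size=(30, 1)))
            assert np.all(np.diff(B, axis=1) <= 0)


class TestEffectiveMatrix:
    def test_identity_when_b_all_ones(self, rng):
        Phi = rng.normal(size=(6, 3))
        np.testing.assert_array_equal(
            m.effective_matrix(Phi, np.ones((6, 3))), Phi
        )

    def test_elementwise_product_oracle(self, rng):
        Phi = rng.normal(size=(5, 4))
        B = (rng.random((5, 4)) < 0.5).astype(float)
        np.testing.assert_array_equal(m.effective_matrix(Phi, B), Phi * B)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            m.effective_matrix(np.ones((2, 2)), np.ones((3, 2)))


class TestSolveWeights:
    def test_square_full_rank_interpolates(self, rng):
        H = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        y = rng.normal(size=4)
        W, b = m.solve_weights(H, y, fit_bias=False)
        np.testing.assert_allclose(H @ W, y, atol=1e-9)
        assert b == 0.0

    def test_recovers_planted_solution(self, rng):
        H = rng.normal(size=(40, 5))
        w_star = rng.normal(size=5)
        W, _ = m.solve_weights(H, H @ w_star)
        np.testing.assert_allclose(W, w_star, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n, k = int(rng.integers(10, 50)), int(rng.integers(1, 8))
            H = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            W, _ = m.solve_weights(H, y)
            oracle = np.linalg.solve(H.T @ H, H.T @ y)
            np.testing.assert_allclose(W, oracle, rtol=1e-8, atol=1e-8)

    def test_bias_column_fit(self, rng):
        H = rng.normal(size=(30, 3))
        y = H @ np.array([1.0, -2.0, 0.5]) + 7.0
        W, b = m.solve_weights(H, y, fit_bias=True)
        assert b == pytest.approx(7.0, abs=1e-8)

    def test_rank_deficient_minimum_norm(self):
        H = np.ones((5, 2))  # duplicate columns
        W, _ = m.solve_weights(H, np.full(5, 2.0))
        np.testing.assert_allclose(W, [1.0, 1.0], atol=1e-10)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            m.solve_weights(np.array([[np.nan]]), np.array([1.0]))

    def test_appending_column_never_increases_residual(self, rng):
        y = rng.normal(size=30)
        H = rng.normal(size=(30, 1))
        prev = np.inf
        for k in range(2, 8):
            W, _ = m.solve_weights(H, y)
            ssr = float(np.sum((y - H @ W) ** 2))
            assert ssr <= prev + 1e-10
            prev = ssr
            H = np.column_stack([H, rng.normal(size=30)])


class TestPredict:
    def test_zero_weight_model_is_constant_bias(self):
        model = ModelState(afs=[m.GaussianAF((0.0,), 1.0, 1.0)],
                           block_active=[False], weights=[0.0], bias=3.0)
        np.testing.assert_array_equal(
            m.predict(model, [[0.0], [5.0]], return_labels=False), [3.0, 3.0]
        )

    def test_blocked_point_gets_zero_contribution(self):
        af1 = m.GaussianAF((0.0,), 1.0, 1.0)
        af2 = m.GaussianAF((0.5,), 1.0, 1.0)
        model = ModelState(afs=[af1, af2], block_active=[True, False],
                           weights=[0.0, 5.0])
        # point at 0.2 is inside af1's field -> af2's huge weight is gated off
        out = m.predict(model, [[0.2]], return_labels=False)
        assert out[0] == pytest.approx(0.0)

    def test_all_blocks_off_equals_plain_rbf(self, rng):
        model = _random_model(rng, active=[False] * 4)
        X = rng.normal(size=(20, 1))
        plain = m.response_matrix(model.afs, X) @ model.weights
        np.testing.assert_allclose(
            m.predict(model, X, return_labels=False), plain, atol=1e-12
        )

    def test_dimension_mismatch_rejected(self, rng):
        model = _random_model(rng, d=2)
        with pytest.raises(ValidationError):
            m.predict(model, np.ones((3, 5)))


def test_model_json_round_trip(rng):
    model = _random_model(rng)
    model.task = "classify"
    model.bias = 0.7
    model.trace = [{"k": 1, "GE": 0.1}]
    back = ModelState.from_json(model.to_json())
    assert [a.to_dict() for a in back.afs] == [a.to_dict() for a in model.afs]
    assert back.block_active == model.block_active
    np.testing.assert_array_equal(back.weights, model.weights)
    assert back.bias == model.bias and back.task == model.task
    assert back.trace == model.trace
    # a second round trip is byte-identical
    assert back.to_json() == ModelState.from_json(back.to_json()).to_json()
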