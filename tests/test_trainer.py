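"""Training loop: candidate evaluation, modes, grids, and trace invariants."""

import numpy as np
import pytest

import msrbf as m
from msrbf.network import ModelState
from msrbf.trainer import W0_GRID, TrainConfig, evaluate_candidate


def _pool(ds, n_widths=20, floor=0.05):
    wf = m.Waveform(ds.X[:, 0], ds.y)
    return m.build_pool_regression(wf, n_widths, floor)


def _fresh_state(task="regress", fit_bias=False):
    return ModelState(task=task, fit_bias=fit_bias)


class TestEvaluateCandidate:
    def test_planted_kernel_zeroes_both_errors(self):
        spec = m.SignalSpec(components=((0.0, 1.5, 2.0),), n_points=101,
                            domain=(-8.0, 8.0))
        ds = m.gen_two_scale_signal(spec)
        err = evaluate_candidate(
            _fresh_state(), m.GaussianAF((0.0,), 1.5, 1.0), ds
        )
        assert err.global_error == pytest.approx(0.0, abs=1e-10)
        assert err.local_error == pytest.approx(0.0, abs=1e-10)

    def test_state_is_not_mutated(self, two_scale):
        _, ds = two_scale
        state = _fresh_state()
        evaluate_candidate(state, m.GaussianAF((0.0,), 1.0, 1.0), ds)
        assert state.n_nodes == 0

    def test_empty_support_gives_sentinel(self, two_scale):
        _, ds = two_scale
        err = evaluate_candidate(
            _fresh_state(), m.GaussianAF((1e6,), 0.1, 1.0), ds
        )
        assert not err.local_defined and err.local_support == 0

    def test_ge_matches_metrics_on_predict_output(self, two_scale):
        _, ds = two_scale
        cand = m.GaussianAF((0.0,), 2.0, 1.0)
        err = evaluate_candidate(_fresh_state(), cand, ds)
        trial = ModelState(afs=[cand], block_active=[False], weights=np.zeros(1))
        W, b = m.solve_weights(m.response_matrix([cand], ds.X), ds.y)
        trial.weights, trial.bias = W, b
        pred = m.predict(trial, ds.X, return_labels=False)
        assert err.global_error == pytest.approx(
            m.global_error(ds.y, pred, "regress")
        )


class TestTrain:
    def test_two_scale_msrbf_blocks_narrow_then_captures_wide(self, two_scale):
        spec, ds = two_scale
        cfg = TrainConfig(mode="msrbf", task="regress", K_max=2, w0=0.8,
                          target_error_local=0.05, min_support=5,
                          R_penalty_scale=1.0)
        model = m.train(ds, cfg, pool=_pool(ds, n_widths=50))
        narrow = min(spec.components, key=lambda c: c[1])
        wide = max(spec.components, key=lambda c: c[1])
        got = sorted(((af.center[0], af.width) for af in model.afs),
                     key=lambda t: t[1])
        assert len(got) == 2
        assert got[0][1] == pytest.approx(narrow[1], rel=0.3)
        assert abs(got[0][0] - narrow[0]) <= narrow[1]
        assert got[1][1] == pytest.approx(wide[1], rel=0.3)

    def test_msrbf_zero_weight_no_blocking_equals_mkrbf(self, noisy_two_scale):
        _, ds = noisy_two_scale
        pool = _pool(ds)
        a = m.train(ds, TrainConfig(mode="msrbf", task="regress", K_max=4,
                                    w0=0.0, blocking=False), pool=pool)
        b = m.train(ds, TrainConfig(mode="mkrbf", task="regress", K_max=4),
                    pool=pool)
        assert [af.to_dict() for af in a.afs] == [af.to_dict() for af in b.afs]
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.bias == b.bias

    def test_global_target_stops_training_early(self, two_scale):
        _, ds = two_scale
        cfg = TrainConfig(mode="mkrbf", task="regress", K_max=7,
                          target_error_global=0.05)
        model = m.train(ds, cfg, pool=_pool(ds))
        steps = [t for t in model.trace if "k" in t]
        assert steps[-1]["terminated"]
        assert model.n_nodes < 7

    def test_blocking_is_irreversible_on_trace(self, two_scale):
        _, ds = two_scale
        cfg = TrainConfig(mode="msrbf", task="regress", K_max=5, w0=0.8,
                          target_error_local=0.05)
        model = m.train(ds, cfg, pool=_pool(ds))
        blocked = [t["n_blocked_total"] for t in model.trace if "k" in t]
        assert all(a <= b for a, b in zip(blocked, blocked[1:]))

    def test_pool_exhaustion_stops_gracefully(self, two_scale):
        _, ds = two_scale
        tiny = m.CandidatePool([m.GaussianAF((0.0,), 3.0, 1.0),
                                m.GaussianAF((4.0,), 0.5, 1.0)])
        model = m.train(ds, TrainConfig(mode="mkrbf", task="regress", K_max=7),
                        pool=tiny)
        assert model.n_nodes == 2
        assert any(t.get("event") == "pool_exhausted" for t in model.trace)

    def test_final_solve_reproduces_training_residual(self, noisy_two_scale):
        _, ds = noisy_two_scale
        model = m.train(ds, TrainConfig(mode="mkrbf", task="regress", K_max=3),
                        pool=_pool(ds))
        final = [t for t in model.trace if t.get("event") == "final_solve"][0]
        pred = m.predict(model, ds.X, return_labels=False)
        assert float(np.sum((ds.y - pred) ** 2)) == pytest.approx(final["ssr"])
        assert m.global_error(ds.y, pred, "regress") == pytest.approx(final["GE"])

    def test_shortcut_scoring_also_trains(self, two_scale):
        _, ds = two_scale
        cfg = TrainConfig(mode="mkrbf", task="regress", K_max=3,
                          exact_refit=False)
        model = m.train(ds, cfg, pool=_pool(ds))
        assert model.n_nodes == 3


@pytest.fixture(scope="module")
def grid_run():
    spec = m.default_waveform_spec(0)
    wf = m.gen_waveform(spec, n_bins=400, noise_floor_sd=spec.noise_sd)
    cfg = TrainConfig(task="regress", K_max=4, n_widths=15)
    return m.train_regression_grid(wf, cfg), wf


class TestRegressionGrid:
    def test_grid_has_exactly_eleven_entries(self, grid_run):
        (_, trace), _ = grid_run
        assert len(trace) == 11
        assert [r["w0"] for r in trace] == [round(w, 1) for w in
                                            np.arange(10, -1, -1) / 10]

    def test_w0_grid_constant(self):
        assert W0_GRID == (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.0)

    def test_returned_model_is_trace_argmin(self, grid_run):
        (model, trace), wf = grid_run
        floor = m.estimate_noise_floor(wf)
        pred = m.predict(model, wf.positions[:, None], return_labels=False)
        relmae, _ = m.relative_mae_sde(pred, wf.amplitudes, floor)
        assert relmae == pytest.approx(min(r["relMAE"] for r in trace))

    def test_zero_w0_entry_reproduces_mkrbf(self, grid_run):
        _, wf = grid_run
        cfg = TrainConfig(task="regress", K_max=4, n_widths=15)
        floor = m.estimate_noise_floor(wf)
        pool = m.build_pool_regression(wf, 15, floor)
        mk = m.train(wf.as_dataset(),
                     TrainConfig(task="regress", mode="mkrbf", K_max=4),
                     pool=pool)
        pred = m.predict(mk, wf.positions[:, None], return_labels=False)
        relmae, _ = m.relative_mae_sde(pred, wf.amplitudes, floor)
        (_, trace), _ = grid_run
        zero = [r for r in trace if r["w0"] == 0.0][0]
        assert zero["relMAE"] == pytest.approx(relmae)


class TestSkrbf:
    def test_single_candidate_pool_selects_it(self):
        spec = m.SignalSpec(components=((0.0, 1.0, 1.0),), n_points=51,
                            domain=(-4.0, 4.0))
        ds = m.gen_two_scale_signal(spec)
        pool = m.CandidatePool([m.GaussianAF((0.0,), 1.0, 1.0)])
        model = m.train(ds, TrainConfig(mode="skrbf", task="regress", K_max=1),
                        pool=pool)
        assert model.n_nodes == 1 and model.afs[0].width == 1.0

    def test_all_widths_shared_on_returned_model(self, clusters):
        cfg = TrainConfig(mode="skrbf", task="classify", K_max=3,
                          skrbf_widths=(1.5,), skrbf_grid_points=9)
        model = m.train_skrbf(clusters, cfg)
        assert len({af.width for af in model.afs}) == 1

    def test_planted_gaussian_reaches_near_zero_error(self):
        spec = m.SignalSpec(components=((0.0, 1.0, 2.0),), n_points=81,
                            domain=(-5.0, 5.0))
        ds = m.gen_two_scale_signal(spec)
        cfg = TrainConfig(mode="skrbf", task="regress", K_max=1,
                          skrbf_widths=(1.0,), skrbf_grid_points=11)
        model = m.train_skrbf(ds, cfg)
        pred = m.predict(model, ds.X, return_labels=False)
        assert m.global_error(ds.y, pred, "regress") < 1e-8
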