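import numpy as np
import pytest

import ppgcond as pc
from ppgcond.lstm import (
    _forward,
    _backward,
    _lstm_forward,
    lstm_cell_step,
)


def _identity_corpus(n_records, seed, L=4, S=2):
    """Records whose target equals the (normalized) PPG channel itself."""
    corpus = pc.generate_corpus(
        n_records, seed=seed, artifact_gain=0.0, noise_sd=0.01
    )
    out = []
    for rec, _ in corpus:
        rec = pc.normalize_record(rec)
        out.append(pc.segment_record(rec.replace(target=rec.ppg), L, S, hop=2))
    return pc.merge_datasets(out[:-1]), out[-1]


class TestBuildModel:
    def test_parameter_count_closed_form(self):
        nh = 4
        model = pc.build_model(pc.ModelConfig(L=4, S=1, n_hidden=nh, n_layers=1))
        assert model.num_params() == 4 * (nh * 4 + nh**2 + nh) + nh + 1

    def test_second_layer_input_width(self):
        model = pc.build_model(pc.ModelConfig(L=4, S=1, n_hidden=8, n_layers=2))
        assert model.params[1]["W"].shape == (8, 32)

    def test_grid_mode_rejects_three_layers(self):
        with pytest.raises(ValueError, match="n_layers"):
            pc.ModelConfig(L=4, S=1, n_hidden=8, n_layers=3).validate_grid()

    def test_vectorized_forward_matches_scalar_cell(self):
        rng = np.random.default_rng(2)
        model = pc.build_model(pc.ModelConfig(L=5, S=1, n_hidden=6, seed=2))
        layer = model.params[0]
        X = rng.standard_normal((3, 5, 4))
        H, _ = _lstm_forward(X, layer)
        h = np.zeros(6)
        c = np.zeros(6)
        for t in range(5):
            h, c, gates = lstm_cell_step(
                X[1, t], h, c, layer["W"], layer["U"], layer["b"]
            )
            i, f, g, o = gates
            for gate in (i, f, o):
                assert np.all((gate > 0) & (gate < 1))
            assert np.all((g > -1) & (g < 1))
            assert np.allclose(H[1, t], h)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        for nl in (1, 2):
            model = pc.build_model(
                pc.ModelConfig(L=4, S=2, n_hidden=5, n_layers=nl, seed=3)
            )
            X = rng.standard_normal((6, 4, 4))
            target = rng.standard_normal(6)
            y, H, io = _forward(model.params, X, want_caches=True)
            dy = np.sign(y - target) / 6
            grads = _backward(model.params, X, y, dy, H, io)

            def loss():
                return np.mean(np.abs(_forward(model.params, X) - target))

            eps = 1e-6
            for li, layer in enumerate(model.params):
                for key in layer:
                    flat = layer[key].ravel()
                    for j in rng.choice(flat.size, min(4, flat.size), replace=False):
                        old = flat[j]
                        flat[j] = old + eps
                        up = loss()
                        flat[j] = old - eps
                        down = loss()
                        flat[j] = old
                        numeric = (up - down) / (2 * eps)
                        analytic = grads[li][key].ravel()[j]
                        assert numeric == pytest.approx(analytic, abs=1e-6)


class TestTrain:
    def test_identity_task_converges(self):
        train_ds, eval_ds = _identity_corpus(5, seed=21)
        cfg = pc.ModelConfig(L=4, S=2, n_hidden=8, epochs=40, seed=21)
        model = pc.train(pc.build_model(cfg), train_ds, eval_ds)
        assert model.eval_loss_best < 0.05
        assert model.eval_loss_best == min(model.history["eval_loss"])
        assert len(model.history["eval_loss"]) <= cfg.epochs

    def test_training_is_deterministic(self):
        train_ds, eval_ds = _identity_corpus(3, seed=5)
        cfg = pc.ModelConfig(L=4, S=2, n_hidden=4, epochs=3, seed=5)
        a = pc.train(pc.build_model(cfg), train_ds, eval_ds)
        b = pc.train(pc.build_model(cfg), train_ds, eval_ds)
        assert a.history == b.history

    def test_zero_epochs_returns_untrained(self):
        train_ds, eval_ds = _identity_corpus(3, seed=5)
        cfg = pc.ModelConfig(L=4, S=2, n_hidden=4, epochs=0)
        model = pc.train(pc.build_model(cfg), train_ds, eval_ds)
        assert model.history == {"train_loss": [], "eval_loss": []}

    def test_mismatched_L_rejected(self):
        train_ds, eval_ds = _identity_corpus(3, seed=5)
        cfg = pc.ModelConfig(L=8, S=2, n_hidden=4, epochs=1)
        with pytest.raises(ValueError, match="L"):
            pc.train(pc.build_model(cfg), train_ds, eval_ds)


class TestConditionSignal:
    def test_output_length_and_range_untrained(self, noisy_record):
        rec, _ = noisy_record
        rec = pc.normalize_record(rec)
        model = pc.build_model(pc.ModelConfig(L=8, S=4, n_hidden=4, seed=0))
        out = pc.condition_signal(model, rec)
        assert len(out) == len(rec)
        assert np.all(np.isfinite(out.ppg))
        assert np.all((out.ppg >= -1) & (out.ppg <= 1))

    def test_span_length_record_is_fully_covered(self):
        n = 7  # exactly one span for L=4, S=2
        x = np.linspace(-1, 1, n)
        rec = pc.SignalRecord(
            ppg=x, acc_x=x, acc_y=x, acc_z=x, target=x, sampling_rate=32.0
        )
        model = pc.build_model(pc.ModelConfig(L=4, S=2, n_hidden=4, seed=0))
        out = pc.condition_signal(model, rec)
        assert len(out) == n


class TestGrid:
    def test_full_grid_has_240_variants(self):
        assert len(pc.enumerate_grid()) == 240

    def test_restricted_grid(self):
        assert len(pc.enumerate_grid(grid_L=(4,), grid_S=(1,))) == 8

    def test_empty_grid(self):
        df = pc.run_grid(None, grid_L=(), grid_S=())
        assert len(df) == 0

    def test_enumeration_matches_nested_loops(self):
        from ppgcond.lstm import GRID_L, GRID_S, GRID_NL, GRID_NH

        explicit = [
            (L, S, nl, nh)
            for L in GRID_L
            for S in GRID_S
            for nl in GRID_NL
            for nh in GRID_NH
        ]
        got = [(c.L, c.S, c.n_layers, c.n_hidden) for c in pc.enumerate_grid()]
        assert got == explicit


class TestPersistence:
    def test_model_round_trip(self, tmp_path):
        model = pc.build_model(pc.ModelConfig(L=4, S=2, n_hidden=4, seed=1))
        path = tmp_path / "model.pkl"
        pc.save_model(model, path)
        back = pc.load_model(path)
        assert back.config == model.config
        for a, b in zip(model.params, back.params):
            for k in a:
                assert np.array_equal(a[k], b[k])
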