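"""Forecasting stream: rasterization, ConvLSTM gate equations (against a
per-pixel loop oracle), baselines and metrics."""

import numpy as np
import pytest

import reefblocks as rb
from reefblocks import forecast as fc
from reefblocks.nn import Tensor
from reefblocks.synthetic import HealthState


def conv_same(x, w, b=None):
    """Plain 3x3 same-padding cross-correlation (loop oracle)."""
    cout, cin, kh, kw = w.shape
    _, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    out = np.zeros((cout, h, wd))
    for o in range(cout):
        for i in range(h):
            for j in range(wd):
                out[o, i, j] = (xp[:, i:i + 3, j:j + 3] * w[o]).sum()
        if b is not None:
            out[o] += b[o]
    return out


def sigmoid(z):
    return 1 / (1 + np.exp(-z))


class TestRasterize:
    def test_no_boxes_gives_all_background(self):
        r = fc.rasterize([], grid=40)
        assert np.all(r == fc.BACKGROUND)

    def test_severity_priority_bleached_over_healthy(self):
        boxes = [(HealthState.HEALTHY, 0.5, 0.5, 0.6, 0.6),
                 (HealthState.BLEACHED, 0.5, 0.5, 0.3, 0.3)]
        r = fc.rasterize(boxes, grid=40)
        assert r[20, 20] == HealthState.BLEACHED  # overlap goes to worse state
        assert r[10, 10] == HealthState.HEALTHY   # outside the bleached core

    def test_cell_center_rule_covers_exactly_100_cells(self):
        """A box spanning cell centers (10..19, 10..19) labels exactly 100
        cells (cell-center enumeration)."""
        # centers at (i + 0.5)/40; cover i in [10, 19] in both axes
        lo, hi = 10.5 / 40 - 1e-6, 19.5 / 40 + 1e-6
        cx = (lo + hi) / 2
        w = hi - lo
        r = fc.rasterize([(HealthState.DEAD, cx, cx, w, w)], grid=40)
        assert int((r == HealthState.DEAD).sum()) == 100


class TestConvLSTM:
    def test_zero_everything_gives_zero_states(self, rng):
        cell = fc.ConvLSTMCell(2, 3, rng=rng)
        for p in cell.parameters():
            p.data[:] = 0
        x = Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32))
        h, c = cell.step(x, cell.init_state(1, 4, 4))
        # sigma(0)=0.5, tanh(0)=0 -> c = 0.5*0 + 0.5*0 = 0, h = 0.5*tanh(0) = 0
        np.testing.assert_allclose(h.data, 0.0, atol=1e-7)
        np.testing.assert_allclose(c.data, 0.0, atol=1e-7)

    def test_saturated_forget_gate_preserves_cell_state(self, rng):
        cell = fc.ConvLSTMCell(2, 3, rng=rng)
        for p in cell.parameters():
            p.data[:] = 0
        n = cell.hidden
        cell.wx.bias.data[1 * n:2 * n] = 50.0    # forget gate -> 1
        cell.wx.bias.data[0 * n:1 * n] = -50.0   # input gate -> 0
        c_prev = Tensor(np.random.default_rng(0).normal(
            size=(1, 3, 4, 4)).astype(np.float32))
        h0 = Tensor(np.zeros((1, 3, 4, 4), dtype=np.float32))
        x = Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32))
        _, c = cell.step(x, (h0, c_prev))
        np.testing.assert_allclose(c.data, c_prev.data, atol=1e-5)

    def test_step_matches_per_pixel_loop_oracle(self, rng):
        """Random small instance: gate equations recomputed with literal
        loops agree within 1e-6."""
        cell = fc.ConvLSTMCell(2, 2, rng=rng)
        x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        h_prev = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        c_prev = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        h, c = cell.step(Tensor(x), (Tensor(h_prev), Tensor(c_prev)))
        wx, bx = cell.wx.weight.data, cell.wx.bias.data
        wh = cell.wh.weight.data
        z = conv_same(x[0], wx, bx) + conv_same(h_prev[0], wh)
        n = cell.hidden
        i = sigmoid(z[0 * n:1 * n])
        f = sigmoid(z[1 * n:2 * n])
        o = sigmoid(z[2 * n:3 * n])
        g = np.tanh(z[3 * n:4 * n])
        c_ref = f * c_prev[0] + i * g
        h_ref = o * np.tanh(c_ref)
        np.testing.assert_allclose(c.data[0], c_ref, atol=1e-6)
        np.testing.assert_allclose(h.data[0], h_ref, atol=1e-6)

    def test_two_layer_stack_feeds_hidden_forward(self, rng):
        model = fc.ConvLSTM(3, hidden=4, layers=2, rng=rng)
        seq = [Tensor(rng.normal(size=(2, 3, 5, 5)).astype(np.float32))
               for _ in range(2)]
        out = model(seq)
        assert out.shape == (2, 4, 5, 5)


class TestForecastModel:
    def test_probabilities_sum_to_one_at_every_pixel(self, rng):
        model = fc.ForecastModel(3, hidden=4, rng=rng)
        seq = [Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32))
               for _ in range(2)]
        probs = fc.forecast(seq, model)
        assert probs.shape == (2, 4, 6, 6)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_frames_deterministic(self, rng):
        model = fc.ForecastModel(3, hidden=4, rng=rng)
        model.eval()
        f = Tensor(rng.normal(size=(1, 3, 6, 6)).astype(np.float32))
        a = fc.forecast([f, f], model).data
        b = fc.forecast([f, f], model).data
        assert np.array_equal(a, b)

    def test_uniform_init_cross_entropy_is_ln4(self, rng):
        model = fc.ForecastModel(3, hidden=4, rng=rng)
        model.head.weight.data[:] = 0
        model.head.bias.data[:] = 0
        seq = [Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32))
               for _ in range(2)]
        target = np.zeros((2, 6, 6), dtype=np.uint8)
        target[0, 0, 0] = fc.BACKGROUND
        loss = fc.masked_cross_entropy(model.logits(seq), target)
        assert float(loss.data) == pytest.approx(np.log(4), abs=1e-5)


class TestTrainingContract:
    def test_no_gradient_reaches_frozen_extractor(self, drift_matrix):
        cfg = rb.SceneConfig(image_size=64, colony_count_range=(2, 4))
        sites = [rb.generate_site_series(cfg, drift_matrix, seed=i)
                 for i in range(4)]
        base = rb.build_model(rb.ModelConfig(width=4, input_size=64), seed=0)
        ex = fc.FrozenFeatureExtractor(base)
        tc = fc.ForecastTrainConfig(epochs=2, hidden=4, seed=0, batch_size=2)
        fc.train_forecaster(sites, ex, tc)  # asserts frozen internally
        assert all(p.grad is None for p in base.parameters())

    def test_split_leakage_detected(self, drift_matrix):
        cfg = rb.SceneConfig(image_size=64, colony_count_range=(1, 2))
        site = rb.generate_site_series(cfg, drift_matrix, seed=0)
        from reefblocks.errors import DataError
        with pytest.raises(DataError):
            fc.check_split_integrity([site], [site])


class TestBaselines:
    def test_naive_identity_and_disjoint_pfa(self):
        r = np.array([[0, 1], [2, 3]], dtype=np.uint8)
        assert fc.forecast_metrics(fc.naive_baseline(r), r)["PFA"] == 100.0
        flipped = 3 - r
        assert fc.forecast_metrics(fc.naive_baseline(flipped), r)["PFA"] == 0.0

    def test_markov_deterministic_chain_estimated_exactly(self):
        a = np.full((4, 4), 0, dtype=np.uint8)   # all Healthy
        b = np.full((4, 4), 1, dtype=np.uint8)   # all Sub-healthy
        mb = fc.markov_baseline([(a, b)])
        assert mb.matrix[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(mb.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_markov_rows_sum_to_one_with_uniform_fallback(self):
        mb = fc.markov_baseline([])
        np.testing.assert_allclose(mb.matrix, 0.25)

    def test_markov_tie_breaks_toward_higher_severity(self):
        m = np.full((4, 4), 0.25)
        mb = fc.MarkovBaseline(m)
        assert list(mb.prediction_rule) == [3, 3, 3, 3]

    def test_markov_recovers_generator_matrix_from_rasters(self, drift_matrix):
        """Per-cell transition estimates from 500 synthetic sites agree with
        the generating matrix entrywise within 0.04."""
        cfg = rb.SceneConfig(image_size=64, colony_count_range=(3, 6),
                             small_object_fraction=0.3)
        pairs = []
        for seed in range(500):
            s = rb.generate_site_series(cfg, drift_matrix, seed=seed)
            r1 = fc.rasterize(s.frames[0].boxes, 40)
            r2 = fc.rasterize(s.frames[1].boxes, 40)
            r3 = fc.rasterize(s.frames[2].boxes, 40)
            pairs.extend([(r1, r2), (r2, r3)])
        mb = fc.markov_baseline(pairs)
        assert np.abs(mb.matrix - drift_matrix).max() < 0.04


class TestMetrics:
    def test_perfect_prediction_scores(self):
        t = np.array([[0, 1, fc.BACKGROUND], [2, 3, 0]], dtype=np.uint8)
        m = fc.forecast_metrics(t.copy(), t)
        assert m["PFA"] == 100.0
        assert m["Macro_F1"] == 100.0
        assert m["MAE"] == 0.0

    def test_all_dead_versus_all_healthy_mae_is_three(self):
        t = np.zeros((5, 5), dtype=np.uint8)
        p = np.full((5, 5), 3, dtype=np.uint8)
        assert fc.forecast_metrics(p, t)["MAE"] == pytest.approx(3.0)

    def test_counting_oracle_on_hand_built_raster(self):
        """12 labeled cells, 8 correct -> PFA 66.67%."""
        t = np.full((4, 4), fc.BACKGROUND, dtype=np.uint8)
        p = t.copy()
        cells = [(i, j) for i in range(4) for j in range(3)]  # 12 labeled
        for k, (i, j) in enumerate(cells):
            t[i, j] = k % 4
            p[i, j] = (k % 4) if k < 8 else (k + 1) % 4
        m = fc.forecast_metrics(p, t)
        assert m["PFA"] == pytest.approx(100 * 8 / 12, abs=1e-9)

    def test_transition_groups_report_restricted_accuracy(self):
        y1 = np.array([[0, 0], [2, 1]], dtype=np.uint8)
        y2 = np.array([[0, 1], [2, 2]], dtype=np.uint8)
        t = np.array([[0, 2], [2, 3]], dtype=np.uint8)
        p = np.array([[0, 2], [3, 3]], dtype=np.uint8)
        m = fc.forecast_metrics(p, t, y1, y2)
        tr = m["transitions"]
        assert tr["Healthy->Healthy"] == 100.0
        assert tr["Healthy->Sub-healthy"] == 100.0
        assert tr["Stable Bleached"] == 0.0
        assert tr["Sub-healthy->Bleached"] == 100.0

    def test_shape_mismatch_rejected(self):
        from reefblocks.errors import DataError
        with pytest.raises(DataError):
            fc.forecast_metrics(np.zeros((2, 2)), np.zeros((3, 3)))
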