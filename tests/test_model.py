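"""Network components: attention bounds, fusion algebra, backbone shapes,
loss arithmetic, sigma stationary point, checkpointing, capacity."""

import math

import numpy as np
import pytest

from enosemix.autodiff import Tensor
from enosemix.model import (Adam, ChannelAttention, CrossFusion,
                            DynamicLossState, ModelConfig, MRCANet,
                            cross_entropy, dynamic_weighted_loss,
                            load_checkpoint, mse, save_checkpoint, softmax,
                            sum_loss)

RNG = np.random.default_rng(7)


class TestChannelAttention:
    def test_zero_weights_halve_the_input(self):
        att = ChannelAttention(np.random.default_rng(0), 8, 4)
        for p in att.parameters():
            p.data[...] = 0.0
        x = Tensor(RNG.standard_normal((3, 8, 5, 5)))
        out = att(x)
        np.testing.assert_allclose(out.data, 0.5 * x.data)  # sigmoid(0) = 0.5

    def test_constant_channel_pools_to_constant(self):
        att = ChannelAttention(np.random.default_rng(0), 4, 2)
        x = Tensor(np.full((2, 4, 3, 3), 2.5))
        ca = x.mean(axis=(2, 3))
        cm = x.max(axis=(2, 3))
        np.testing.assert_allclose(ca.data, 2.5)
        np.testing.assert_allclose(cm.data, 2.5)

    def test_gate_shrinks_and_preserves_sign(self):
        att = ChannelAttention(np.random.default_rng(1), 8, 4)
        x = Tensor(RNG.standard_normal((4, 8, 6, 6)))
        out = att(x)
        s = att.weights(x).data
        assert np.all((s > 0) & (s < 1))
        assert np.all(np.abs(out.data) <= np.abs(x.data))
        nz = x.data != 0
        assert np.all(np.sign(out.data[nz]) == np.sign(x.data[nz]))
        # direct per-element recomputation
        np.testing.assert_allclose(out.data, x.data * s[:, :, None, None])

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError):
            ChannelAttention(np.random.default_rng(0), 6, 4)


class TestCrossFusion:
    def setup_method(self):
        self.ta = Tensor(RNG.standard_normal((2, 3, 4, 4)))
        self.tb = Tensor(RNG.standard_normal((2, 3, 4, 4)))

    def test_identity_is_exact_pass_through(self):
        fusion = CrossFusion()
        a, b = fusion(self.ta, self.tb)
        np.testing.assert_array_equal(a.data, self.ta.data)
        np.testing.assert_array_equal(b.data, self.tb.data)

    def test_antidiagonal_swaps(self):
        fusion = CrossFusion()
        fusion.alpha.data = np.array([[0.0, 1.0], [1.0, 0.0]])
        a, b = fusion(self.ta, self.tb)
        np.testing.assert_array_equal(a.data, self.tb.data)
        np.testing.assert_array_equal(b.data, self.ta.data)

    def test_uniform_half_gives_mean(self):
        fusion = CrossFusion()
        fusion.alpha.data = np.full((2, 2), 0.5)
        a, b = fusion(self.ta, self.tb)
        mean = 0.5 * (self.ta.data + self.tb.data)
        np.testing.assert_allclose(a.data, mean)
        np.testing.assert_allclose(b.data, mean)

    def test_linearity_in_inputs(self):
        fusion = CrossFusion()
        fusion.alpha.data = np.array([[0.7, 0.2], [-0.1, 1.3]])
        a1, b1 = fusion(self.ta, self.tb)
        a2, b2 = fusion(self.ta * 3.0, self.tb * 3.0)
        np.testing.assert_allclose(a2.data, 3 * a1.data, rtol=1e-6)
        np.testing.assert_allclose(b2.data, 3 * b1.data, rtol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CrossFusion()(self.ta, Tensor(np.zeros((2, 3, 5, 5))))


class TestForward:
    def test_output_shapes_batch5(self):
        net = MRCANet(ModelConfig(input_hw=16), seed=0)
        probs, conc = net.forward(RNG.random((5, 8, 16, 16)))
        assert probs.shape == (5, 3)
        assert conc.shape == (5, 2)

    def test_spatial_trace_and_fc_width(self):
        # 16 -> 18 -> 20 under out = H + 2*2 - 3 + 1; FC1 sees 32*20*20
        net = MRCANet(ModelConfig(input_hw=16), seed=0)
        assert net.flat_features == 32 * 20 * 20
        h = net._shared(Tensor(RNG.random((2, 8, 16, 16)).astype(np.float32)), False)
        assert h.shape == (2, 16, 18, 18)

    def test_class_rows_sum_to_one(self):
        net = MRCANet(ModelConfig(), seed=1)
        probs, _ = net.forward(RNG.random((7, 8, 16, 16)))
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, rtol=1e-5)

    def test_non_square_input_rejected(self):
        net = MRCANet(ModelConfig(), seed=0)
        with pytest.raises(ValueError):
            net.forward(RNG.random((2, 8, 16, 15)))

    def test_fresh_mrca_equals_no_cross_variant(self):
        """Identity-initialized fusion makes MRCA match the NO-Cross ablation."""
        x = RNG.random((4, 8, 16, 16))
        full = MRCANet(ModelConfig(use_cross_fusion=True), seed=3)
        bare = MRCANet(ModelConfig(use_cross_fusion=False), seed=3)
        bare.load_state_dict({k: v for k, v in full.state_dict().items()})
        pf, cf = full.forward(x)
        pb, cb = bare.forward(x)
        np.testing.assert_allclose(pf.data, pb.data, rtol=1e-6)
        np.testing.assert_allclose(cf.data, cb.data, rtol=1e-6)

    def test_single_task_variants(self):
        probs, conc = MRCANet(ModelConfig(task="class"), seed=0).forward(
            RNG.random((2, 8, 16, 16)))
        assert probs is not None and conc is None
        probs, conc = MRCANet(ModelConfig(task="conc"), seed=0).forward(
            RNG.random((2, 8, 16, 16)))
        assert probs is None and conc is not None


class TestLosses:
    def test_dynamic_loss_at_unit_sigma(self):
        state = DynamicLossState((1.0, 1.0, 1.0))
        total = dynamic_weighted_loss(2.0, 4.0, 1.0, state)
        assert total.item() == pytest.approx(4.0)  # 1 + 2 + 1 + 0

    def test_dynamic_loss_asymmetric_weights(self):
        state = DynamicLossState((1.0, 1.0, 10.0))
        total = dynamic_weighted_loss(1.0, 4.0, 1.0, state)
        assert total.item() == pytest.approx(0.5 + 2.0 + 0.01 + 1.0)

    def test_sum_loss(self):
        assert sum_loss(2.0, 4.0, 1.0).item() == 7.0
        assert sum_loss(0.0, 0.0, 0.0).item() == 0.0

    def test_dynamic_at_unit_sigma_vs_sum_identity(self):
        # dynamic(sigma=1) = sum - (Lp + Le)/2 because of the half factors
        lp, le, lci = 2.0, 4.0, 1.0
        state = DynamicLossState((1.0, 1.0, 1.0))
        assert dynamic_weighted_loss(lp, le, lci, state).item() == \
            pytest.approx(sum_loss(lp, le, lci).item() - (lp + le) / 2)

    def test_negative_loss_rejected(self):
        with pytest.raises(ValueError):
            dynamic_weighted_loss(-0.1, 0.0, 0.0, DynamicLossState())

    def test_strictly_increasing_in_each_component(self):
        state = DynamicLossState((0.7, 1.3, 2.0))
        base = dynamic_weighted_loss(1.0, 1.0, 1.0, state).item()
        assert dynamic_weighted_loss(1.5, 1.0, 1.0, state).item() > base
        assert dynamic_weighted_loss(1.0, 1.5, 1.0, state).item() > base
        assert dynamic_weighted_loss(1.0, 1.0, 1.5, state).item() > base

    def test_sigma_descent_reaches_stationary_point(self):
        """Minimizing Lp/(2 sigma^2) + log10(sigma) over sigma alone gives
        sigma^2 = Lp * ln 10."""
        state = DynamicLossState((1.0, 1.0, 1.0))
        opt = Adam(state.parameters(), lr=0.01)
        for _ in range(4000):
            sp = (state.log_sigma * Tensor(np.eye(3)[0])).sum()
            loss = Tensor(1.0) * (sp * (-2.0)).exp() * 0.5 + sp * (1.0 / math.log(10.0))
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert state.sigmas[0] ** 2 == pytest.approx(math.log(10.0), abs=1e-3)

    def test_coercivity_on_each_axis(self):
        # 1/sigma^2 terms blow up as sigma -> 0; log regularizer as sigma -> inf
        tiny = DynamicLossState((1e-4, 1.0, 1.0))
        huge = DynamicLossState((1e4, 1.0, 1.0))
        mid = DynamicLossState((1.0, 1.0, 1.0))
        assert dynamic_weighted_loss(1, 1, 1, tiny).item() > \
            dynamic_weighted_loss(1, 1, 1, mid).item()
        assert dynamic_weighted_loss(1, 1, 1, huge).item() > \
            dynamic_weighted_loss(1, 1, 1, mid).item()

    def test_cross_entropy_matches_closed_form(self):
        logits = Tensor(np.log(np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]])))
        ce = cross_entropy(logits, np.array([0, 1]))
        assert ce.item() == pytest.approx(-(math.log(0.7) + math.log(0.8)) / 2)

    def test_mse_matches_closed_form(self):
        pred = Tensor(np.array([1.0, 2.0, 3.0]))
        assert mse(pred, np.array([1.0, 1.0, 1.0])).item() == pytest.approx(5 / 3)


class TestCheckpoint:
    def test_round_trip_is_bit_faithful(self, tmp_path):
        net = MRCANet(ModelConfig(), seed=9)
        state = DynamicLossState((1.5, 0.7, 2.0))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, net, state)
        net2, state2 = load_checkpoint(path)
        assert net2.config == net.config
        for k, v in net.state_dict().items():
            np.testing.assert_array_equal(net2.state_dict()[k], v)
            assert net2.state_dict()[k].dtype == v.dtype
        np.testing.assert_array_equal(state2.log_sigma.data, state.log_sigma.data)
        x = RNG.random((3, 8, 16, 16))
        p1, c1 = net.forward(x)
        p2, c2 = net2.forward(x)
        np.testing.assert_array_equal(p1.data, p2.data)
        np.testing.assert_array_equal(c1.data, c2.data)


class TestCapacity:
    def test_overfits_five_samples(self):
        """The network drives the total loss near zero on a 5-sample batch."""
        rng = np.random.default_rng(11)
        x = rng.random((5, 8, 16, 16)).astype(np.float32)
        y_class = np.array([0, 1, 2, 1, 0])
        y_conc = rng.random((5, 2)).astype(np.float32)
        net = MRCANet(ModelConfig(), seed=0)
        state = DynamicLossState()
        opt = Adam(net.parameters() + state.parameters(), lr=2e-3)
        total = None
        from enosemix.training import _column
        for _ in range(300):
            logits, conc = net.forward_raw(Tensor(x), training=True)
            loss = dynamic_weighted_loss(
                mse(_column(conc, 0, 2), y_conc[:, 0]),
                mse(_column(conc, 1, 2), y_conc[:, 1]),
                cross_entropy(logits, y_class), state)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total = loss.item()
        # component losses (not the regularized total) all near zero
        logits, conc = net.forward_raw(Tensor(x), training=True)
        assert cross_entropy(logits, y_class).item() < 0.01
        assert mse(_column(conc, 0, 2), y_conc[:, 0]).item() < 1e-3
        assert np.argmax(softmax(logits).data, axis=1).tolist() == y_class.tolist()
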