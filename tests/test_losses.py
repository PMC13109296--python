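"""Temperature softmax, distillation and attention-transfer objectives."""

import math

import numpy as np
import pytest

from phenodistill.attention import AttentionMap, attention_from_activation
from phenodistill.losses import (LossConfig, attention_loss,
                                 attention_loss_grad_activations,
                                 attention_loss_per_layer, combined_loss,
                                 combined_loss_gradients, distillation_loss,
                                 distillation_loss_grad_z, one_hot,
                                 softened_probabilities)

# frozen oracle values (high-precision closed forms)
E = math.e
Q_3_0_T3 = (E / (1 + E), 1 / (1 + E))  # softmax((3,0)/3) = softmax((1,0))
LN8 = math.log(8.0)                     # 2.0794415416798357
SQRT2 = math.sqrt(2.0)


class TestSoftenedProbabilities:
    def test_uniform_logits_give_uniform(self):
        for T in (0.5, 1.0, 3.0):
            q = softened_probabilities(np.zeros(8), T)
            np.testing.assert_allclose(q, np.full(8, 1 / 8), atol=1e-12)

    def test_two_class_worked_example(self):
        q = softened_probabilities(np.array([3.0, 0.0]), 3.0)
        np.testing.assert_allclose(q, Q_3_0_T3, atol=1e-12)
        assert abs(q[0] - 0.73106) < 5e-6 and abs(q[1] - 0.26894) < 5e-6

    def test_T1_is_standard_softmax(self, rng):
        z = rng.normal(size=8)
        expected = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(softened_probabilities(z, 1.0), expected,
                                   atol=1e-12)

    def test_high_temperature_approaches_uniform_monotonically(self):
        z = np.array([5.0, 0.0])
        tops = [softened_probabilities(z, T)[0] for T in (10.0, 100.0, 1000.0)]
        assert tops[0] > tops[1] > tops[2] > 0.5

    def test_sums_to_one_over_random_logits_and_temperatures(self, rng):
        for _ in range(250):
            z = rng.normal(scale=rng.uniform(0.1, 50), size=rng.integers(2, 12))
            for T in (0.5, 1.0, 3.0, 10.0):
                q = softened_probabilities(z, T)
                assert abs(q.sum() - 1.0) < 1e-9
                assert (q >= 0).all()

    def test_overflow_safe(self):
        q = softened_probabilities(np.array([1e4, 0.0]), 1.0)
        assert np.isfinite(q).all() and abs(q.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize("T", [0.0, -1.0])
    def test_nonpositive_temperature_rejected(self, T):
        with pytest.raises(ValueError, match="T"):
            softened_probabilities(np.zeros(3), T)


class TestDistillationLoss:
    def test_soft_loss_is_entropy_at_equality_uniform(self):
        """Student matching the teacher exactly on uniform logits: the soft
        cross-entropy equals the entropy of the uniform 8-class distribution."""
        z = np.zeros(8)
        bd = distillation_loss(z, z, one_hot(1), LossConfig())
        assert abs(bd.soft - LN8) < 1e-12

    def test_hard_loss_zero_at_confident_correct_prediction(self):
        z = np.zeros(8)
        z[2] = 60.0  # q^1 puts essentially all mass on class 3
        bd = distillation_loss(np.zeros(8), z, one_hot(3), LossConfig())
        assert bd.hard < 1e-9

    @pytest.mark.parametrize("alpha", [0.0, 1.0])
    def test_alpha_endpoints(self, rng, alpha):
        v, z = rng.normal(size=8), rng.normal(size=8)
        cfg = LossConfig(alpha=alpha)
        bd = distillation_loss(v, z, one_hot(5), cfg)
        expected = bd.soft if alpha == 1.0 else bd.hard
        assert abs(bd.total - expected) < 1e-12

    def test_gibbs_inequality(self, rng):
        """L_soft >= H(p^T), equality iff the softened outputs agree."""
        cfg = LossConfig()
        for _ in range(100):
            v, z = rng.normal(size=6), rng.normal(size=6)
            p = softened_probabilities(v, cfg.T)
            entropy = float(-(p * np.log(p)).sum())
            bd = distillation_loss(v, z, one_hot(1, 6), cfg)
            assert bd.soft >= entropy - 1e-12
        bd_eq = distillation_loss(v, v, one_hot(1, 6), cfg)
        p = softened_probabilities(v, cfg.T)
        assert abs(bd_eq.soft - float(-(p * np.log(p)).sum())) < 1e-12

    def test_shift_invariance(self, rng):
        v, z = rng.normal(size=8), rng.normal(size=8)
        cfg = LossConfig()
        a = distillation_loss(v, z, one_hot(2), cfg)
        b = distillation_loss(v + 7.3, z - 2.1, one_hot(2), cfg)
        assert abs(a.total - b.total) < 1e-9

    def test_T2_rescaling_flag(self, rng):
        v, z = rng.normal(size=8), rng.normal(size=8)
        plain = distillation_loss(v, z, one_hot(1), LossConfig(T=3.0))
        scaled = distillation_loss(v, z, one_hot(1),
                                   LossConfig(T=3.0, scale_soft_by_T2=True))
        assert abs(scaled.soft - 9.0 * plain.soft) < 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            distillation_loss(np.zeros(8), np.zeros(7), one_hot(1), LossConfig())


def _unit_maps(vals, layer):
    return AttentionMap(layer_index=layer, map=np.asarray(vals, float),
                        normalized=True)


class TestAttentionLoss:
    def test_zero_at_equality(self, rng):
        maps = [attention_from_activation(rng.random((4, 5, 5)), i + 1)
                for i in range(5)]
        assert attention_loss(maps, maps, (1, 2, 3, 4, 5)) == 0.0

    def test_orthogonal_unit_maps_give_sqrt2(self):
        a = _unit_maps([[1.0, 0.0]], 1)
        b = _unit_maps([[0.0, 1.0]], 1)
        assert abs(attention_loss([a], [b], (1,)) - SQRT2) < 1e-12

    def test_additive_over_layers(self, rng):
        s = [attention_from_activation(rng.random((3, 4, 4)), i + 1) for i in range(5)]
        t = [attention_from_activation(rng.random((3, 4, 4)), i + 1) for i in range(5)]
        total = attention_loss(s, t, (1, 3, 4))
        singles = sum(attention_loss(s, t, (l,)) for l in (1, 3, 4))
        assert abs(total - singles) < 1e-12
        per_layer = attention_loss_per_layer(s, t, (1, 3, 4))
        assert abs(sum(per_layer.values()) - total) < 1e-12

    def test_shape_mismatch_names_layer(self, rng):
        s = [attention_from_activation(rng.random((2, 4, 4)), 1)]
        t = [attention_from_activation(rng.random((2, 5, 5)), 1)]
        with pytest.raises(ValueError, match="layer 1"):
            attention_loss(s, t, (1,))


class TestCombinedLoss:
    def test_beta_zero_reduces_to_distillation(self, rng):
        v, z = rng.normal(size=8), rng.normal(size=8)
        cfg = LossConfig(beta=0.0)
        assert combined_loss(v, z, one_hot(4), [], [], cfg).total == \
            distillation_loss(v, z, one_hot(4), cfg).total

    def test_known_constant_parts(self):
        """alpha=0.5, beta=0.1 on parts (1, 2, 3) must total 1.8."""
        assert abs(0.5 * 1 + 0.5 * 2 + 0.1 * 3 - 1.8) < 1e-15  # arithmetic anchor
        # construct inputs realising L_soft=..., simpler: check weighting law
        cfg = LossConfig(alpha=0.5, beta=0.1, transfer_layers=(1,))
        rng = np.random.default_rng(0)
        act = rng.random((2, 3, 3))
        s_map = attention_from_activation(act, 1)
        t_map = attention_from_activation(rng.random((2, 3, 3)), 1)
        v, z = rng.normal(size=8), rng.normal(size=8)
        bd = combined_loss(v, z, one_hot(1), [s_map], [t_map], cfg)
        assert abs(bd.total - (0.5 * bd.soft + 0.5 * bd.hard + 0.1 * bd.attention)) \
            < 1e-12

    def test_default_weighting(self, rng):
        cfg = LossConfig()  # T=3, alpha=0.7, beta=0.001, layers {1,3,4}
        assert (cfg.T, cfg.alpha, cfg.beta, cfg.transfer_layers) == \
            (3.0, 0.7, 0.001, (1, 3, 4))
        s = [attention_from_activation(rng.random((2, 4, 4)), i + 1) for i in range(5)]
        t = [attention_from_activation(rng.random((2, 4, 4)), i + 1) for i in range(5)]
        v, z = rng.normal(size=8), rng.normal(size=8)
        bd = combined_loss(v, z, one_hot(6), s, t, cfg)
        assert abs(bd.total - (0.7 * bd.soft + 0.3 * bd.hard + 0.001 * bd.attention)) \
            < 1e-12

    def test_all_terms_nonnegative(self, rng):
        for _ in range(50):
            v, z = rng.normal(size=5), rng.normal(size=5)
            bd = distillation_loss(v, z, one_hot(2, 5), LossConfig())
            assert bd.soft >= 0 and bd.hard >= 0 and bd.total >= 0


class TestGradients:
    def test_logit_gradient_matches_finite_differences(self, rng):
        cfg = LossConfig(alpha=0.6, T=3.0, beta=0.0)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            v, z = rng.normal(size=n), rng.normal(size=n)
            c = one_hot(int(rng.integers(1, n + 1)), n)
            g = distillation_loss_grad_z(v, z, c, cfg)
            eps = 1e-6
            for i in range(n):
                zp, zm = z.copy(), z.copy()
                zp[i] += eps
                zm[i] -= eps
                fd = (distillation_loss(v, zp, c, cfg).total
                      - distillation_loss(v, zm, c, cfg).total) / (2 * eps)
                assert abs(fd - g[i]) <= 1e-4 * max(1.0, abs(fd))

    def test_combined_gradient_matches_finite_differences(self, rng):
        """Full objective: analytic d/dz and d/d(activation) vs central FD."""
        cfg = LossConfig(alpha=0.7, beta=0.5, transfer_layers=(1, 2))
        n = 8
        acts = [rng.random((3, 4, 4)) + 0.1 for _ in range(2)]
        t_maps = [attention_from_activation(rng.random((3, 4, 4)), i + 1)
                  for i in range(2)]
        v, z = rng.normal(size=n), rng.normal(size=n)
        c = one_hot(3, n)

        def total(z_, acts_):
            s_maps = [attention_from_activation(a, i + 1)
                      for i, a in enumerate(acts_)]
            return combined_loss(v, z_, c, s_maps, t_maps, cfg).total

        bd, g_z, g_acts = combined_loss_gradients(v, z, c, acts, t_maps, cfg)
        assert abs(bd.total - total(z, acts)) < 1e-12
        eps = 1e-6
        for i in range(n):
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            fd = (total(zp, acts) - total(zm, acts)) / (2 * eps)
            assert abs(fd - g_z[i]) <= 1e-4 * max(1.0, abs(fd))
        for li in range(2):
            for idx in [(0, 1, 2), (2, 3, 0), (1, 0, 3)]:
                ap = [a.copy() for a in acts]
                am = [a.copy() for a in acts]
                ap[li][idx] += eps
                am[li][idx] -= eps
                fd = (total(z, ap) - total(z, am)) / (2 * eps)
                ga = g_acts[li][idx]
                assert abs(fd - ga) <= 1e-4 * max(1e-6, abs(fd), abs(ga))

    def test_attention_gradient_zero_cases(self):
        t_map = _unit_maps([[1.0, 0.0]], 1)
        loss, grads = attention_loss_grad_activations(
            [np.zeros((2, 1, 2))], [t_map], (1,))
        assert loss == 1.0  # ||0 - A_T|| with unit-norm teacher map
        np.testing.assert_array_equal(grads[0], 0.0)


class TestAttentionFromActivation:
    def test_zero_activation_passes_through(self):
        m = attention_from_activation(np.zeros((3, 4, 4)), 2)
        assert not m.normalized
        np.testing.assert_array_equal(m.map, 0.0)

    def test_single_channel_is_normalised_square(self, rng):
        a = rng.random((1, 3, 3))
        m = attention_from_activation(a, 1)
        expected = a[0] ** 2
        np.testing.assert_allclose(m.map, expected / np.linalg.norm(expected),
                                   atol=1e-12)
        assert abs(np.linalg.norm(m.map) - 1.0) < 1e-6

    def test_scale_invariance(self, rng):
        a = rng.random((4, 5, 5))
        m1 = attention_from_activation(a, 1)
        m2 = attention_from_activation(2.0 * a, 1)
        np.testing.assert_allclose(m1.map, m2.map, atol=1e-12)

    def test_positive_where_any_channel_nonzero(self):
        a = np.zeros((2, 2, 2))
        a[1, 0, 1] = 0.5
        m = attention_from_activation(a, 1)
        assert m.map[0, 1] > 0 and m.map[0, 0] == 0
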