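"""Loss oracles: closed forms, brute-force scalar checks, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdanpl.autodiff import Tensor
from cdanpl.losses import (
    LossReport,
    adversarial_loss,
    combined_objective,
    cross_entropy,
    mc_loss,
    multilinear_map,
)


class ConstantD:
    """Stub discriminator returning a fixed output for every input row."""

    def __init__(self, value):
        self.value = value

    def __call__(self, phi):
        return Tensor(np.full(phi.shape[0], self.value), requires_grad=False)


class TestMultilinearMap:
    def test_basis_vectors_give_single_hot_entry(self):
        f = np.zeros((1, 4))
        f[0, 2] = 1.0
        g = np.zeros((1, 2))
        g[0, 1] = 1.0
        phi = multilinear_map(f, g).data
        expected = np.zeros(8)
        expected[2 * 2 + 1] = 1.0  # flat index of (2, 1)
        assert np.array_equal(phi[0], expected)

    def test_norm_identity(self, rng):
        f = rng.normal(size=(10, 6))
        g = rng.dirichlet(np.ones(3), size=10)
        phi = multilinear_map(f, g).data
        assert np.allclose(np.linalg.norm(phi, axis=1),
                           np.linalg.norm(f, axis=1) * np.linalg.norm(g, axis=1))

    def test_uniform_probs_repeat_features_scaled(self, rng):
        f = rng.normal(size=(5, 4))
        g = np.full((5, 2), 0.5)
        phi = multilinear_map(f, g).data
        assert np.allclose(phi[:, 0::2], 0.5 * f) and np.allclose(phi[:, 1::2], 0.5 * f)


class TestAdversarialLoss:
    def test_chance_discriminator_gives_two_log_two(self, rng):
        f = rng.normal(size=(6, 4))
        g = rng.dirichlet(np.ones(2), size=6)
        loss = adversarial_loss(ConstantD(0.5), f, g, f, g)
        assert float(loss.data) == pytest.approx(2 * np.log(2), abs=1e-10)

    def test_fully_fooled_discriminator_drives_loss_to_zero(self, rng):
        f = rng.normal(size=(4, 3))
        g = rng.dirichlet(np.ones(2), size=4)
        prev = np.inf
        for eps in (1e-2, 1e-3, 1e-4):
            D = type("D", (), {"__call__": lambda self, phi, e=eps: Tensor(
                np.where(np.arange(phi.shape[0]) < 4, e, 1 - e), requires_grad=False)})()
            # first 4 rows are source (D -> eps), remaining are target (D -> 1-eps)
            val = float(adversarial_loss(D, f, g, f, g).data)
            assert val < prev
            prev = val
        assert prev < 1e-3

    def test_hand_computed_pair(self):
        # one source with D=0.2, one target with D=0.7
        f = np.ones((1, 2))
        g = np.array([[0.5, 0.5]])

        class D:
            calls = 0

            def __call__(self, phi):
                return Tensor(np.array([0.2, 0.7]), requires_grad=False)

        val = float(adversarial_loss(D(), f, g, f, g).data)
        assert val == pytest.approx(-np.log(0.8) - np.log(0.7), abs=1e-10)
        assert val == pytest.approx(0.5798, abs=1e-4)

    def test_finite_for_saturated_outputs(self, rng):
        f = rng.normal(size=(3, 2))
        g = rng.dirichlet(np.ones(2), size=3)
        for v in (0.0, 1.0):
            assert np.isfinite(float(adversarial_loss(ConstantD(v), f, g, f, g).data))


class TestCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        probs = np.eye(2)[[0, 1, 1]]
        assert float(cross_entropy(probs, [0, 1, 1]).data) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_binary_is_log_two(self):
        probs = np.full((5, 2), 0.5)
        assert float(cross_entropy(probs, [0, 1, 0, 1, 0]).data) == pytest.approx(
            np.log(2), abs=1e-10)

    def test_three_sample_scalar_oracle(self):
        probs = np.array([[0.9, 0.1], [0.3, 0.7], [0.6, 0.4]])
        labels = [0, 1, 1]
        expected = -(np.log(0.9) + np.log(0.7) + np.log(0.4)) / 3
        assert float(cross_entropy(probs, labels).data) == pytest.approx(expected, abs=1e-10)

    def test_invalid_label_code_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.full((2, 2), 0.5), [0, 2])


def brute_force_mc(f, y, pair_mean=False):
    """Double-loop scalar oracle for the metric-constraint loss."""
    B = len(f)
    t = 0.0
    for u in range(B):
        for v in range(B):
            t += ((f[u] - f[v]) ** 2).sum()
    T_m = t / (B * (B - 1) if pair_mean else B)
    num = den = 0.0
    for u in range(B):
        for v in range(B):
            if u == v:
                continue
            w = np.exp(-((f[u] - f[v]) ** 2).sum() / T_m)
            if y[u] != y[v]:
                num += w
            else:
                den += w
    return np.log(num / den), T_m


class TestMcLoss:
    def test_matches_double_loop_oracle(self, rng):
        f = rng.normal(size=(4, 2))
        y = np.array([0, 0, 1, 1])
        for pair_mean in (False, True):
            val, tm, skipped = mc_loss(f, y, pair_mean=pair_mean)
            exp_val, exp_tm = brute_force_mc(f, y, pair_mean)
            assert not skipped
            assert float(val.data) == pytest.approx(exp_val, abs=1e-10)
            assert float(tm.data) == pytest.approx(exp_tm, abs=1e-10)

    def test_equidistant_configuration_closed_form(self):
        # regular simplex in 3-D: 4 points, all pairwise distances equal
        f = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                      [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        n_diff, n_same = 8, 4  # ordered pairs
        val, _, _ = mc_loss(f, y)
        assert float(val.data) == pytest.approx(np.log(n_diff / n_same), abs=1e-10)

    def test_decreases_as_classes_separate(self, rng):
        base = rng.normal(size=(10, 3)) * 0.3
        y = np.array([0, 1] * 5)
        offset = np.where(y[:, None] == 1, 1.0, -1.0) * np.array([1.0, 0, 0])
        vals = []
        for scale in (1, 2, 4, 8):
            f = base + scale * offset
            val, _, skipped = mc_loss(f, y)
            assert not skipped
            vals.append(float(val.data))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_rigid_motion_and_scale_invariance(self, rng):
        f = rng.normal(size=(6, 3))
        y = np.array([0, 0, 0, 1, 1, 1])
        ref = float(mc_loss(f, y)[0].data)
        # translation
        assert float(mc_loss(f + 5.0, y)[0].data) == pytest.approx(ref, abs=1e-9)
        # rotation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert float(mc_loss(f @ q, y)[0].data) == pytest.approx(ref, abs=1e-9)
        # global scaling (T_m rescales with the distances)
        assert float(mc_loss(3.7 * f, y)[0].data) == pytest.approx(ref, abs=1e-9)

    def test_label_permutation_invariance(self, rng):
        f = rng.normal(size=(6, 2))
        y = np.array([0, 1, 0, 1, 1, 0])
        ref = float(mc_loss(f, y)[0].data)
        assert float(mc_loss(f, 1 - y)[0].data) == pytest.approx(ref, abs=1e-12)

    def test_single_class_batch_skipped(self, rng):
        val, _, skipped = mc_loss(rng.normal(size=(4, 2)), np.zeros(4, int))
        assert skipped and float(val.data) == 0.0

    def test_tm_positive_for_distinct_samples(self, rng):
        _, tm, _ = mc_loss(rng.normal(size=(5, 2)), np.array([0, 0, 1, 1, 1]))
        assert float(tm.data) > 0

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_agreement_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        f = rng.normal(size=(n, 3))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        if not np.any(np.bincount(y) >= 2):
            return
        val, tm, skipped = mc_loss(f, y)
        if skipped:
            return
        exp_val, exp_tm = brute_force_mc(f, y)
        assert float(val.data) == pytest.approx(exp_val, abs=1e-8)
        assert float(tm.data) == pytest.approx(exp_tm, abs=1e-8)


class TestCombinedObjective:
    def test_hand_arithmetic(self):
        report = LossReport(L_cls=0.3, L_CE=0.1, L_adv=1.0, L_MC=0.2, lam=0.5)
        assert combined_objective(report) == pytest.approx(0.5 * (1.0 - 0.2) - 0.3 - 0.1,
                                                           abs=1e-12)
        assert combined_objective(report) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_components_give_zero(self):
        assert combined_objective(LossReport()) == 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            combined_objective(LossReport(), lam=-0.1)
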