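"""Loss family vs independent brute-force oracles and closed forms.

The oracles below are literal double-loop transcriptions of the softmax
definitions, written against plain numpy and kept independent of the
package's vectorized implementations.
"""

import math

import numpy as np
import pytest

from segssl.losses import (
    LossConfig,
    MemoryBank,
    combined_loss,
    fis_loss,
    nt_xent_loss,
    sd_loss,
    sd_probability,
    update_bank,
)
from segssl.nn import Tensor, grad_check

# ----------------------------------------------------------------- oracles


def brute_sd_loss(bank, F, labels, sd_tau=1.0):
    total = 0.0
    for f, s in zip(F, labels):
        num = math.exp(float(bank[s] @ f) / sd_tau)
        den = sum(math.exp(float(bank[j] @ f) / sd_tau) for j in range(len(bank)))
        total += -math.log(num / den)
    return total / len(labels)


def brute_fis_loss(F):
    V = F.T  # columns v_i indexed by feature dimension
    d = V.shape[0]
    total = 0.0
    for i in range(d):
        num = math.exp(float(V[i] @ V[i]))
        den = sum(math.exp(float(V[j] @ V[i])) for j in range(d))
        total += -math.log(num / den)
    return total


def brute_nt_xent(z_a, z_b, tau=1.0):
    z = np.vstack([z_a, z_b])
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    n = len(z)
    b = len(z_a)
    total = 0.0
    for i in range(n):
        j = i + b if i < b else i - b
        num = math.exp(float(z[i] @ z[j]) / tau)
        den = sum(
            math.exp(float(z[i] @ z[k]) / tau) for k in range(n) if k != i
        )
        total += -math.log(num / den)
    return total / n


def _unit_rows(rng, n, d):
    f = rng.normal(size=(n, d))
    return f / np.linalg.norm(f, axis=1, keepdims=True)


# ------------------------------------------------------------- SD pieces


class TestSdProbability:
    def test_single_segment_probability_one(self, rng):
        bank = MemoryBank(rng.normal(size=(1, 4)))
        assert sd_probability(bank, _unit_rows(rng, 1, 4)[0], 0) == pytest.approx(1.0)

    def test_two_segment_hand_value(self):
        bank = MemoryBank(np.array([[1.0, 0.0], [0.0, 1.0]]))
        p = sd_probability(bank, np.array([1.0, 0.0]), 0)
        assert p == pytest.approx(math.e / (math.e + 1), abs=1e-9)

    def test_normalizes_over_segments(self, rng):
        bank = MemoryBank(rng.normal(size=(7, 5)))
        f = _unit_rows(rng, 1, 5)[0]
        total = sum(sd_probability(bank, f, s, sd_tau=0.7) for s in range(7))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_label_out_of_range(self, rng):
        bank = MemoryBank(rng.normal(size=(3, 4)))
        with pytest.raises(IndexError):
            sd_probability(bank, _unit_rows(rng, 1, 4)[0], 3)


class TestSdLoss:
    def test_single_segment_loss_zero(self, rng):
        bank = MemoryBank(rng.normal(size=(1, 4)))
        F = _unit_rows(rng, 5, 4)
        assert sd_loss(bank, F, np.zeros(5, dtype=int)).item() == 0.0

    def test_hand_value_batch_of_one(self):
        bank = MemoryBank(np.array([[1.0, 0.0], [0.0, 1.0]]))
        loss = sd_loss(bank, np.array([[1.0, 0.0]]), np.array([0]))
        assert loss.item() == pytest.approx(-math.log(math.e / (math.e + 1)), abs=1e-9)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        M, d, b = rng.integers(2, 7), rng.integers(2, 6), rng.integers(1, 8)
        bank = MemoryBank(rng.normal(size=(M, d)))
        F = _unit_rows(rng, b, d)
        labels = rng.integers(0, M, size=b)
        tau = float(rng.uniform(0.5, 2.0))
        assert sd_loss(bank, F, labels, sd_tau=tau).item() == pytest.approx(
            brute_sd_loss(bank.bank, F, labels, tau), abs=1e-6
        )

    def test_label_bank_mismatch(self, rng):
        bank = MemoryBank(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError, match="segment labels"):
            sd_loss(bank, _unit_rows(rng, 2, 4), np.array([0, 5]))

    def test_equals_instance_discrimination_when_m_equals_n(self, rng):
        """With every instance its own segment, SD is exactly the ID loss."""
        N, d = 6, 4
        bank = MemoryBank(rng.normal(size=(N, d)))
        F = _unit_rows(rng, N, d)
        instance_labels = np.arange(N)
        assert sd_loss(bank, F, instance_labels).item() == pytest.approx(
            brute_sd_loss(bank.bank, F, instance_labels), abs=1e-9
        )


class TestUpdateBank:
    def test_momentum_one_keeps_bank(self, rng):
        bank = MemoryBank(rng.normal(size=(4, 3)), momentum=1.0)
        before = bank.bank.copy()
        update_bank(bank, _unit_rows(rng, 5, 3), rng.integers(0, 4, 5))
        np.testing.assert_array_equal(bank.bank, before)

    def test_half_momentum_arithmetic(self):
        bank = MemoryBank(np.array([[1.0, 0.0]]), momentum=0.5)
        update_bank(bank, np.array([[0.0, 1.0]]), np.array([0]))
        np.testing.assert_allclose(bank.bank[0], [0.7071, 0.7071], atol=1e-4)

    def test_absent_rows_untouched(self, rng):
        bank = MemoryBank(rng.normal(size=(5, 3)), momentum=0.5)
        before = bank.bank.copy()
        update_bank(bank, _unit_rows(rng, 2, 3), np.array([1, 3]))
        np.testing.assert_array_equal(bank.bank[[0, 2, 4]], before[[0, 2, 4]])
        assert not np.allclose(bank.bank[[1, 3]], before[[1, 3]])

    def test_rows_stay_unit_norm(self, rng):
        bank = MemoryBank(rng.normal(size=(5, 3)), momentum=0.3)
        for _ in range(10):
            update_bank(bank, _unit_rows(rng, 4, 3), rng.integers(0, 5, 4))
        np.testing.assert_allclose(
            np.linalg.norm(bank.bank, axis=1), 1.0, atol=1e-6
        )


# ------------------------------------------------------------------- FIS


class TestFisLoss:
    def test_single_dimension_zero(self, rng):
        assert fis_loss(rng.normal(size=(4, 1))).item() == 0.0

    @pytest.mark.parametrize("d", [2, 3, 4])
    def test_orthonormal_closed_form(self, d):
        F = np.eye(4)[:, :d]  # orthonormal columns
        expected = d * math.log(1 + (d - 1) / math.e)
        assert fis_loss(F).item() == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(200 + trial)
        F = rng.normal(size=(rng.integers(2, 8), rng.integers(2, 6)))
        assert fis_loss(F).item() == pytest.approx(brute_fis_loss(F), abs=1e-6)

    def test_column_collinearity_increases_loss(self):
        """Pulling one orthogonal column toward another raises the penalty."""
        base = np.eye(4)[:, :3]
        losses = []
        for eps in [0.0, 0.2, 0.4]:
            F = base.copy()
            F[:, 1] = (1 - eps) * base[:, 1] + eps * base[:, 0]
            F[:, 1] /= np.linalg.norm(F[:, 1])
            losses.append(fis_loss(F).item())
        assert losses[0] < losses[1] < losses[2]


# ---------------------------------------------------------------- NT-Xent


class TestNtXent:
    def test_single_pair_zero(self, rng):
        assert nt_xent_loss(
            _unit_rows(rng, 1, 4), _unit_rows(rng, 1, 4)
        ).item() == pytest.approx(0.0, abs=1e-9)

    def test_hand_value_two_pairs(self):
        z_a = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss = nt_xent_loss(z_a, z_a.copy(), tau=1.0)
        assert loss.item() == pytest.approx(math.log(1 + 2 / math.e), abs=1e-9)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(300 + trial)
        b, d = rng.integers(2, 8), rng.integers(2, 6)
        z_a, z_b = rng.normal(size=(b, d)), rng.normal(size=(b, d))
        tau = float(rng.uniform(0.5, 2.0))
        assert nt_xent_loss(z_a, z_b, tau).item() == pytest.approx(
            brute_nt_xent(z_a, z_b, tau), abs=1e-6
        )

    def test_invariant_under_common_rotation(self, rng):
        from scipy.stats import ortho_group

        z_a, z_b = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        Q = ortho_group.rvs(5, random_state=7)
        assert nt_xent_loss(z_a @ Q, z_b @ Q).item() == pytest.approx(
            nt_xent_loss(z_a, z_b).item(), abs=1e-6
        )

    def test_permutation_equivariance(self, rng):
        z_a, z_b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        perm = rng.permutation(5)
        assert nt_xent_loss(z_a[perm], z_b[perm]).item() == pytest.approx(
            nt_xent_loss(z_a, z_b).item(), abs=1e-9
        )

    def test_size_mismatch(self, rng):
        with pytest.raises(ValueError, match="paired"):
            nt_xent_loss(rng.normal(size=(3, 2)), rng.normal(size=(4, 2)))


# --------------------------------------------------------------- combined


class TestCombinedLoss:
    def _inputs(self, rng, b=4, d=3, M=5):
        z_a, z_b = rng.normal(size=(b, d)), rng.normal(size=(b, d))
        f2 = _unit_rows(rng, 2 * b, d)
        labels = rng.integers(0, M, size=2 * b)
        bank = MemoryBank(rng.normal(size=(M, d)))
        return z_a, z_b, f2, labels, bank

    def test_all_zero_weights(self, rng):
        z_a, z_b, f2, labels, bank = self._inputs(rng)
        cfg = LossConfig(lambda1=0, lambda2=0, lambda3=0)
        total, parts = combined_loss(z_a, z_b, f2, labels, bank, cfg)
        assert total.item() == 0.0

    def test_reduces_to_nt_xent(self, rng):
        z_a, z_b, f2, labels, bank = self._inputs(rng)
        cfg = LossConfig(lambda1=1, lambda2=0, lambda3=0, tau=0.8)
        total, _ = combined_loss(z_a, z_b, f2, labels, bank, cfg)
        assert total.item() == pytest.approx(
            nt_xent_loss(z_a, z_b, 0.8).item(), abs=1e-12
        )

    def test_additivity_against_components(self, rng):
        z_a, z_b, f2, labels, bank = self._inputs(rng)
        cfg = LossConfig(lambda1=1.0, lambda2=1.0, lambda3=1.0)
        total, parts = combined_loss(z_a, z_b, f2, labels, bank, cfg)
        manual = (
            nt_xent_loss(z_a, z_b, cfg.tau).item()
            + sd_loss(bank, f2, labels, cfg.sd_tau).item()
            + fis_loss(f2).item()
        )
        assert total.item() == pytest.approx(manual, abs=1e-9)
        assert total.item() == pytest.approx(
            parts["ls"] + parts["lsd"] + parts["lfd"], abs=1e-9
        )

    def test_weighted_sum(self, rng):
        z_a, z_b, f2, labels, bank = self._inputs(rng)
        cfg = LossConfig(lambda1=0.3, lambda2=2.0, lambda3=0.5)
        total, parts = combined_loss(z_a, z_b, f2, labels, bank, cfg)
        assert total.item() == pytest.approx(
            0.3 * parts["ls"] + 2.0 * parts["lsd"] + 0.5 * parts["lfd"], abs=1e-9
        )


# ---------------------------------------------------------- differentiability


def test_losses_have_finite_gradients_matching_central_differences(rng):
    b, d, M = 3, 3, 4
    bank = MemoryBank(rng.normal(size=(M, d)))
    labels = rng.integers(0, M, size=b)
    F = Tensor(rng.normal(size=(b, d)), requires_grad=True)
    z_a = Tensor(rng.normal(size=(b, d)), requires_grad=True)
    z_b = Tensor(rng.normal(size=(b, d)), requires_grad=True)
    assert grad_check(lambda: sd_loss(bank, F.normalize(), labels), [F]) < 1e-4
    assert grad_check(lambda: fis_loss(F), [F]) < 1e-4
    assert grad_check(lambda: nt_xent_loss(z_a, z_b, tau=0.9), [z_a, z_b]) < 1e-4
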