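"""Contrastive-objective unit tests.

Closed-form expectations are evaluated independently with ``math``
expressions inside the tests; batch losses are additionally checked
against a per-anchor scalar loop oracle.
"""

import math

import numpy as np
import pytest

from priorcon import autograd as ag
from priorcon.objectives import (
    LossConfig,
    cosine_score,
    contrastive_loss_graph,
    infonce_term,
    pgcon_loss,
    wincon_loss,
)

TAU = 0.07


def _orthogonal_setup(k, d=256):
    """Anchor = positive = e0; negatives = distinct basis vectors."""
    anchor = np.zeros(d); anchor[0] = 1.0
    negatives = np.eye(d)[1 : k + 1]
    return anchor, anchor.copy(), negatives


class TestCosineScore:
    def test_identical_unit_vectors(self):
        v = np.array([0.6, 0.8])
        assert cosine_score(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_score(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == pytest.approx(0.0)

    def test_antipodal(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_score(v, -v) == pytest.approx(-1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_score(np.zeros(3), np.ones(3))


class TestInfoNCEClosedForms:
    def test_orthogonal_negatives_closed_form(self):
        anchor, pos, negs = _orthogonal_setup(200)
        expected = math.log1p(200 * math.exp(-1.0 / TAU))
        assert infonce_term(anchor, pos, negs, TAU) == pytest.approx(expected, abs=1e-8)

    def test_all_equal_scores_is_log_k_plus_one(self):
        v = np.zeros(16); v[0] = 1.0
        negs = np.tile(v, (200, 1))
        assert infonce_term(v, v, negs, TAU) == pytest.approx(math.log(201), abs=1e-9)

    def test_equal_scores_invariant_to_tau(self):
        v = np.zeros(16); v[0] = 1.0
        negs = np.tile(v, (50, 1))
        for tau in (0.05, 0.1, 1.0):
            assert infonce_term(v, v, negs, tau) == pytest.approx(math.log(51), abs=1e-9)

    def test_invalid_tau_rejected(self):
        v = np.ones(4)
        with pytest.raises(ValueError, match="tau"):
            infonce_term(v, v, np.eye(4), 0.0)

    def test_no_negatives_rejected(self):
        v = np.ones(4)
        with pytest.raises(ValueError, match="negative"):
            infonce_term(v, v, np.zeros((0, 4)) + 1.0, TAU)


class TestPGConLoss:
    def test_identical_terms_total_equals_either(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((4, 16)); z /= np.linalg.norm(z, axis=1, keepdims=True)
        negs = rng.standard_normal((4, 8, 16))
        cfg = LossConfig(tau=TAU, k_negatives=8)
        rep = pgcon_loss(z, z, z, negs, negs, cfg)
        assert rep.total == pytest.approx(rep.l_co_p)
        assert rep.l_co_p == pytest.approx(rep.l_co_d)

    def test_orthogonal_construction_closed_form(self):
        anchor, _, negs = _orthogonal_setup(200)
        cfg = LossConfig(tau=TAU, k_negatives=200)
        rep = pgcon_loss(anchor, anchor, anchor, negs, negs, cfg)
        assert rep.total == pytest.approx(math.log1p(200 * math.exp(-1 / TAU)), abs=1e-8)

    def test_alpha_one_beta_zero_selects_bank_term(self):
        rng = np.random.default_rng(1)
        z_p, z_d, r = (rng.standard_normal((2, 8)) for _ in range(3))
        negs = rng.standard_normal((2, 5, 8))
        cfg = LossConfig(tau=TAU, alpha=1.0, beta=0.0, k_negatives=5)
        rep = pgcon_loss(z_p, z_d, r, negs, negs, cfg)
        assert rep.total == pytest.approx(rep.l_co_p, abs=1e-12)

    def test_weighted_total_identity(self):
        rng = np.random.default_rng(2)
        z_p, z_d, r = (rng.standard_normal((3, 8)) for _ in range(3))
        negs_p = rng.standard_normal((3, 4, 8))
        negs_d = rng.standard_normal((3, 4, 8))
        cfg = LossConfig(tau=TAU, k_negatives=4)
        rep = pgcon_loss(z_p, z_d, r, negs_p, negs_d, cfg)
        assert rep.total == pytest.approx(0.5 * rep.l_co_p + 0.5 * rep.l_co_d, abs=1e-6)
        assert rep.l_co_p >= 0 and rep.l_co_d >= 0


class TestWINConLoss:
    def test_enlarged_negative_set_closed_form(self):
        anchor, _, negs = _orthogonal_setup(200, d=300)
        win = np.eye(300)[220:284]  # 64 orthogonal WIN codes
        cfg = LossConfig(tau=TAU, k_negatives=200, mode="wincon")
        rep = wincon_loss(anchor, anchor, anchor, negs, negs, win, cfg)
        expected = math.log1p(264 * math.exp(-1 / TAU))
        assert rep.total == pytest.approx(expected, abs=1e-8)
        assert rep.n_negatives_used == 264

    def test_empty_win_batch_rejected(self):
        anchor, _, negs = _orthogonal_setup(8)
        cfg = LossConfig(mode="wincon", k_negatives=8)
        with pytest.raises(ValueError, match="nonempty"):
            wincon_loss(anchor, anchor, anchor, negs, negs, np.zeros((0, 256)), cfg)

    def test_own_win_as_hard_negative_raises_loss(self):
        anchor, _, negs = _orthogonal_setup(20)
        cfg = LossConfig(tau=TAU, k_negatives=20, mode="wincon")
        win_orth = np.eye(256)[30:31]
        win_hard = anchor[None].copy()
        soft = wincon_loss(anchor, anchor, anchor, negs, negs, win_orth, cfg)
        hard = wincon_loss(anchor, anchor, anchor, negs, negs, win_hard, cfg)
        assert hard.total > soft.total

    def test_graph_without_win_reduces_to_pgcon(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((4, 16)).astype(np.float64)
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        negs = rng.standard_normal((4, 6, 16))
        negs /= np.linalg.norm(negs, axis=2, keepdims=True)
        cfg = LossConfig(tau=TAU, k_negatives=6)
        _, rep_graph = contrastive_loss_graph(
            ag.Tensor(z), ag.Tensor(z), z, negs, negs, cfg, z_win=None
        )
        rep_np = pgcon_loss(z, z, z, negs, negs, cfg)
        assert rep_graph.total == pytest.approx(rep_np.total, abs=1e-9)


class TestLossProperties:
    def test_monotone_decreasing_in_positive_similarity(self):
        """For fixed negatives the loss falls as s(anchor, positive) rises."""
        d = 32
        anchor = np.zeros(d); anchor[0] = 1.0
        negs = np.eye(d)[5:15]
        values = []
        for theta in np.linspace(0.0, np.pi / 2, 8):
            pos = np.zeros(d)
            pos[0], pos[1] = np.cos(theta), np.sin(theta)
            values.append(infonce_term(anchor, pos, negs, TAU))
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_harder_negative_never_decreases_loss(self):
        d = 32
        anchor = np.zeros(d); anchor[0] = 1.0
        base = np.eye(d)[5:10]
        loss0 = infonce_term(anchor, anchor, base, TAU)
        for sim in (0.3, 0.7, 0.95):
            harder = base.copy()
            harder[0] = np.zeros(d)
            harder[0][0], harder[0][2] = sim, np.sqrt(1 - sim**2)
            assert infonce_term(anchor, anchor, harder, TAU) >= loss0

    def test_vectorized_batch_matches_scalar_loop(self):
        rng = np.random.default_rng(4)
        b, k, d = 8, 12, 32
        z_p = rng.standard_normal((b, d)); z_p /= np.linalg.norm(z_p, axis=1, keepdims=True)
        z_d = rng.standard_normal((b, d)); z_d /= np.linalg.norm(z_d, axis=1, keepdims=True)
        r = rng.standard_normal((b, d)); r /= np.linalg.norm(r, axis=1, keepdims=True)
        negs_p = rng.standard_normal((b, k, d))
        negs_p /= np.linalg.norm(negs_p, axis=2, keepdims=True)
        negs_d = rng.standard_normal((b, k, d))
        negs_d /= np.linalg.norm(negs_d, axis=2, keepdims=True)
        cfg = LossConfig(tau=TAU, k_negatives=k)
        rep = pgcon_loss(z_p, z_d, r, negs_p, negs_d, cfg)

        def loop_term(pos_set):
            acc = 0.0
            for i in range(b):
                pos = pos_set[i]
                s_pos = float(z_p[i] @ pos) / TAU
                s_negs = [float(z_p[i] @ (negs_p if pos_set is r else negs_d)[i, j]) / TAU
                          for j in range(k)]
                denom = math.exp(s_pos) + sum(math.exp(s) for s in s_negs)
                acc += -math.log(math.exp(s_pos) / denom)
            return acc / b

        assert rep.l_co_p == pytest.approx(loop_term(r), abs=1e-6)
        assert rep.l_co_d == pytest.approx(loop_term(z_d), abs=1e-6)

    def test_small_tau_limits(self):
        d = 16
        anchor = np.zeros(d); anchor[0] = 1.0
        negs = np.eye(d)[2:7]
        # unique top score at the positive -> loss -> 0
        assert infonce_term(anchor, anchor, negs, 1e-3) == pytest.approx(0.0, abs=1e-12)
        # unique top score at a negative -> loss grows without bound as tau falls
        pos = np.zeros(d); pos[1] = 1.0  # s_pos = 0
        hard = negs.copy(); hard[0] = anchor  # s_neg = 1
        l1 = infonce_term(anchor, pos, hard, 0.05)
        l2 = infonce_term(anchor, pos, hard, 0.01)
        assert l2 > l1 > 10


def test_graph_loss_gradients_match_finite_differences():
    rng = np.random.default_rng(5)
    b, k, d = 3, 4, 8
    z_p = rng.standard_normal((b, d))
    z_d = rng.standard_normal((b, d))
    r = rng.standard_normal((b, d)); r /= np.linalg.norm(r, axis=1, keepdims=True)
    negs = rng.standard_normal((b, k, d))
    win = rng.standard_normal((b, d))
    cfg = LossConfig(tau=0.2, k_negatives=k, mode="wincon")

    params = {
        "z_p": ag.Parameter(z_p.astype(np.float64)),
        "z_d": ag.Parameter(z_d.astype(np.float64)),
        "win": ag.Parameter(win.astype(np.float64)),
    }

    def build():
        zp_n = ag.l2_normalize(params["z_p"])
        zd_n = ag.l2_normalize(params["z_d"])
        win_n = ag.l2_normalize(params["win"])
        total, _ = contrastive_loss_graph(zp_n, zd_n, r, negs, negs, cfg, z_win=win_n)
        return total

    loss = build()
    ag.zero_grads(params.values())
    ag.backward(loss)
    eps = 1e-6
    for name, p in params.items():
        flat = p.data.ravel()
        for idx in rng.choice(flat.size, size=5, replace=False):
            old = flat[idx]
            flat[idx] = old + eps
            up = float(build().data)
            flat[idx] = old - eps
            down = float(build().data)
            flat[idx] = old
            num = (up - down) / (2 * eps)
            assert p.grad.ravel()[idx] == pytest.approx(num, abs=1e-5), name
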