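"""PGCon and WINCon contrastive objectives.

Both objectives are weighted sums of two InfoNCE terms sharing the same
anchor z_p (the prior-view code of instance i):

* the *bank term* contrasts z_p against its stale memory-bank row R_i
  (positive) and k randomly retrieved bank rows of other instances
  (negatives);
* the *view term* contrasts z_p against the distorted-view code z_d
  (positive) with its own k bank negatives.

The total is ``alpha * L_bank + beta * L_view`` with alpha = beta = 0.5.
WINCon appends the batch's B within-instance-negative codes z_win to the
negative list of *both* terms (an instance's own z_win included), so each
term scores 1 positive against k + B negatives.

Scores are cosine similarities divided by a temperature tau (0.07 by
default); with unit-norm codes the exponents reach ~1/tau, so every
softmax is evaluated through a max-shifted log-sum-exp.

The public functions operate on plain numpy arrays in float64 (used by
tests and analyses); the ``*_graph`` variants build the same values on
autograd tensors for training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.special import logsumexp as _sp_logsumexp

from . import autograd as ag
from .autograd import Tensor


class LossConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tau: float = 0.07
    alpha: float = 0.5
    beta: float = 0.5
    k_negatives: int = 200
    mode: str = "pgcon"

    @model_validator(mode="after")
    def _check(self) -> "LossConfig":
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.k_negatives < 1:
            raise ValueError("k_negatives must be >= 1")
        if self.mode not in ("pgcon", "wincon"):
            raise ValueError("mode must be 'pgcon' or 'wincon'")
        return self


@dataclass(frozen=True)
class LossReport:
    """Per-batch loss decomposition."""

    l_co_p: float  # bank term (anchor vs stale R_i)
    l_co_d: float  # view term (anchor vs z_d)
    total: float
    n_negatives_used: int


def cosine_score(z1: np.ndarray, z2: np.ndarray) -> float:
    """Cosine similarity of two vectors; errors on zero vectors."""
    z1 = np.asarray(z1, dtype=np.float64)
    z2 = np.asarray(z2, dtype=np.float64)
    n1, n2 = np.linalg.norm(z1), np.linalg.norm(z2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine score undefined for a zero vector")
    return float(z1 @ z2 / (n1 * n2))


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def infonce_term(
    anchor: np.ndarray, positive: np.ndarray, negatives: np.ndarray, tau: float
) -> float:
    """InfoNCE cross-entropy of one positive against k negatives.

    Accepts a single anchor (d,) with negatives (k, d), or a batch (B, d)
    with per-anchor negatives (B, k, d); batch values are averaged (the
    empirical estimate of the expectation over positive pairs).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    anchor = _normalize_rows(anchor)
    positive = _normalize_rows(positive)
    negatives = _normalize_rows(negatives)
    single = anchor.ndim == 1
    a = anchor[None] if single else anchor
    p = positive[None] if single else positive
    if negatives.ndim == 2:
        negs = np.broadcast_to(negatives, (a.shape[0],) + negatives.shape)
    else:
        negs = negatives
    if negs.shape[1] < 1:
        raise ValueError("need at least one negative")
    s_pos = (a * p).sum(axis=1) / tau  # (B,)
    s_neg = np.einsum("bd,bkd->bk", a, negs) / tau  # (B, k)
    all_scores = np.concatenate([s_pos[:, None], s_neg], axis=1)
    losses = _sp_logsumexp(all_scores, axis=1) - s_pos
    return float(losses.mean())


def _loss_pair(
    z_p, pos_bank, pos_view, negs_p, negs_d, config: LossConfig, z_win=None
) -> LossReport:
    z_p = np.atleast_2d(np.asarray(z_p, dtype=np.float64))
    pos_bank = np.atleast_2d(np.asarray(pos_bank, dtype=np.float64))
    pos_view = np.atleast_2d(np.asarray(pos_view, dtype=np.float64))
    negs_p = np.asarray(negs_p, dtype=np.float64)
    negs_d = np.asarray(negs_d, dtype=np.float64)
    if negs_p.ndim == 2:
        negs_p = np.broadcast_to(negs_p, (z_p.shape[0],) + negs_p.shape)
    if negs_d.ndim == 2:
        negs_d = np.broadcast_to(negs_d, (z_p.shape[0],) + negs_d.shape)
    if not (z_p.shape == pos_bank.shape == pos_view.shape):
        raise ValueError("z_p, R_i and z_d must share shape (B, d)")
    if negs_p.shape[:1] != z_p.shape[:1] or negs_d.shape[:1] != z_p.shape[:1]:
        raise ValueError("negative stacks must have one set per anchor")
    n_used = negs_p.shape[1]
    if z_win is not None:
        z_win = np.atleast_2d(np.asarray(z_win, dtype=np.float64))
        if z_win.shape[0] == 0:
            raise ValueError("wincon requires a nonempty z_win batch")
        b = z_p.shape[0]
        win_stack = np.broadcast_to(z_win, (b,) + z_win.shape)
        negs_p = np.concatenate([negs_p, win_stack], axis=1)
        negs_d = np.concatenate([negs_d, win_stack], axis=1)
        n_used = negs_p.shape[1]
    l_p = infonce_term(z_p, pos_bank, negs_p, config.tau)
    l_d = infonce_term(z_p, pos_view, negs_d, config.tau)
    total = config.alpha * l_p + config.beta * l_d
    return LossReport(l_co_p=l_p, l_co_d=l_d, total=total, n_negatives_used=n_used)


def pgcon_loss(z_p, z_d, r_i, negatives_p, negatives_d, config: LossConfig) -> LossReport:
    """Prior-guided contrast: bank term + view term, equally weighted."""
    if config.mode != "pgcon":
        raise ValueError("config.mode must be 'pgcon'")
    return _loss_pair(z_p, r_i, z_d, negatives_p, negatives_d, config)


def wincon_loss(
    z_p, z_d, r_i, negatives_p, negatives_d, z_win_batch, config: LossConfig
) -> LossReport:
    """PGCon with the batch's WIN codes appended to both negative lists."""
    if config.mode != "wincon":
        raise ValueError("config.mode must be 'wincon'")
    if z_win_batch is None or np.size(z_win_batch) == 0:
        raise ValueError("wincon requires a nonempty z_win batch")
    return _loss_pair(z_p, r_i, z_d, negatives_p, negatives_d, config, z_win=z_win_batch)


# ---------------------------------------------------------------------------
# autograd graph variants used by the training loop
# ---------------------------------------------------------------------------

def _infonce_graph(s_pos: Tensor, s_neg: Tensor, tau: float) -> Tensor:
    all_scores = ag.concat(
        [ag.reshape(s_pos, (s_pos.shape[0], 1)), s_neg], axis=1
    )
    all_scores = ag.scale(all_scores, 1.0 / tau)
    lse = ag.logsumexp(all_scores, axis=1)
    return ag.mean_all(ag.sub(lse, ag.scale(s_pos, 1.0 / tau)))


def contrastive_loss_graph(
    z_p: Tensor,
    z_d: Tensor,
    r_i: np.ndarray,
    negatives_p: np.ndarray,
    negatives_d: np.ndarray,
    config: LossConfig,
    z_win: Tensor | None = None,
) -> tuple[Tensor, LossReport]:
    """Differentiable batch loss; bank rows and bank negatives are constants.

    Gradients flow through the anchors, the distorted codes and (for
    WINCon) the WIN codes, matching a training step in which the bank is
    updated separately by EMA.
    """
    r_const = ag.constant(r_i, dtype=z_p.data.dtype)
    s_pos_bank = ag.rowwise_dot(z_p, r_const)
    s_pos_view = ag.rowwise_dot(z_p, z_d)
    s_neg_bank = ag.pair_scores(z_p, negatives_p)
    s_neg_view = ag.pair_scores(z_p, negatives_d)
    n_used = negatives_p.shape[1]
    if z_win is not None:
        s_win = ag.cross_scores(z_p, z_win)  # (B, B), includes own z_win
        s_neg_bank = ag.concat([s_neg_bank, s_win], axis=1)
        s_neg_view = ag.concat([s_neg_view, s_win], axis=1)
        n_used += z_win.shape[0]
    l_p = _infonce_graph(s_pos_bank, s_neg_bank, config.tau)
    l_d = _infonce_graph(s_pos_view, s_neg_view, config.tau)
    total = ag.add(ag.scale(l_p, config.alpha), ag.scale(l_d, config.beta))
    report = LossReport(
        l_co_p=float(l_p.data), l_co_d=float(l_d.data),
        total=float(total.data), n_negatives_used=n_used,
    )
    return total, report
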