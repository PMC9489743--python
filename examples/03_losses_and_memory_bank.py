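"""Contrastive objectives and the EMA memory bank on toy embeddings.

Evaluates the InfoNCE term on configurations with known closed-form
values and walks through one memory-bank update.
"""

import math

import numpy as np

from priorcon import LossConfig, infonce_term, init_bank, wincon_loss

tau = 0.07
d = 300
anchor = np.zeros(d); anchor[0] = 1.0
negatives = np.eye(d)[1:201]  # 200 negatives orthogonal to the anchor

loss = infonce_term(anchor, anchor.copy(), negatives, tau)
closed = math.log1p(200 * math.exp(-1 / tau))
print(f"InfoNCE, perfect positive vs 200 orthogonal negatives: {loss:.6e}")
print(f"closed form log(1 + 200 e^(-1/tau))                 : {closed:.6e}")

win = np.eye(d)[210:274]  # a batch of 64 orthogonal WIN codes
cfg = LossConfig(tau=tau, k_negatives=200, mode="wincon")
rep = wincon_loss(anchor, anchor, anchor, negatives, negatives, win, cfg)
print(f"WINCon with 200 + 64 negatives: total={rep.total:.6e} "
      f"(n_negatives_used={rep.n_negatives_used})")
# appending the WIN codes enlarges every denominator, so the loss rises
# from 1.25e-4 to 1.65e-4 even though all extra negatives are orthogonal

bank = init_bank(n=5, dim=4, seed=0, momentum=0.5)
bank.R[0] = np.array([1.0, 0.0, 0.0, 0.0])
bank.update(np.array([0]), np.array([[0.0, 1.0, 0.0, 0.0]]))
print(f"bank row after EMA(0.5) update of e0 with e1: {np.round(bank.R[0], 4)}")
# the mixed vector is re-normalised, giving (1/sqrt(2), 1/sqrt(2), 0, 0)
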