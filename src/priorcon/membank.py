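"""Exponential-moving-average memory bank of prior-view codes.

One row per dataset instance. Rows start as i.i.d. random unit vectors
(in 128-d two random rows are nearly orthogonal, so early negatives are
uninformative but harmless) and converge, by EMA over the prior-view
codes seen at each visit, toward per-instance summaries. Because only
the rows of the current batch are updated per step, the row used as the
positive for an anchor is always a *stale* version of its code — updated
only after the loss for that step is formed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class MemoryBank:
    """n x d store of unit-norm EMA codes with uniform negative sampling."""

    def __init__(self, codes: np.ndarray, momentum: float = 0.5, seed: int = 0):
        codes = np.asarray(codes, dtype=np.float64)
        if codes.ndim != 2 or codes.shape[0] < 1:
            raise ValueError("bank codes must be a nonempty n x d array")
        if not (0.0 <= momentum <= 1.0):
            raise ValueError("momentum must lie in [0, 1]")
        self.R = codes
        self.momentum = float(momentum)
        self.seed = int(seed)
        self._rng = np.random.default_rng(seed)

    @property
    def n(self) -> int:
        return self.R.shape[0]

    @property
    def dim(self) -> int:
        return self.R.shape[1]

    def update(self, indices: np.ndarray, z_p_batch: np.ndarray) -> None:
        """EMA-update the given rows in place and re-normalise them.

        ``R_i <- normalize(momentum * R_i + (1 - momentum) * z_p_i)``.
        """
        indices = np.asarray(indices, dtype=int)
        z = np.asarray(z_p_batch, dtype=np.float64)
        if indices.ndim != 1 or z.shape != (indices.size, self.dim):
            raise ValueError("indices must be 1-d and match z_p_batch rows")
        if np.unique(indices).size != indices.size:
            raise ValueError("batch indices must be unique")
        if indices.size and (indices.min() < 0 or indices.max() >= self.n):
            raise ValueError("bank index out of range")
        mixed = self.momentum * self.R[indices] + (1.0 - self.momentum) * z
        norms = np.linalg.norm(mixed, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self.R[indices] = mixed / norms

    def sample_negatives(
        self, exclude_index: int, k: int, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """k rows drawn uniformly without replacement, excluding one index.

        Returns ``(codes, indices)``.
        """
        if not 0 <= exclude_index < self.n:
            raise ValueError("exclude_index out of range")
        if k > self.n - 1:
            raise ValueError(f"cannot draw {k} negatives from a bank of {self.n} rows")
        rng = self._rng if rng is None else rng
        eligible = np.delete(np.arange(self.n), exclude_index)
        chosen = rng.choice(eligible, size=k, replace=False)
        return self.R[chosen], chosen

    def sample_negatives_batch(
        self, exclude_indices: np.ndarray, k: int, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Stack of per-anchor negative draws, shape (B, k, d)."""
        rng = self._rng if rng is None else rng
        return np.stack([
            self.sample_negatives(int(i), k, rng)[0] for i in np.asarray(exclude_indices)
        ])

    def export_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.R, columns=[f"dim_{j:03d}" for j in range(self.dim)])
        df.insert(0, "id", np.arange(self.n))
        df.to_csv(Path(path), index=False)


def init_bank(n: int, dim: int = 128, seed: int = 0, momentum: float = 0.5) -> MemoryBank:
    """Bank of ``n`` i.i.d. random unit vectors; deterministic per seed."""
    if n < 1:
        raise ValueError("bank size n must be >= 1")
    rng = np.random.default_rng(seed)
    codes = rng.standard_normal((n, dim))
    codes /= np.linalg.norm(codes, axis=1, keepdims=True)
    return MemoryBank(codes, momentum=momentum, seed=seed)
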