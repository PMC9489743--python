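"""Convolutional encoders mapping views to unit-norm 128-d codes.

The prior/WIN path is ``trunk -> global average pool -> 128-d fc -> L2
normalise`` (the paper-style f). The distorted path encodes each of the
nine jigsaw tiles to a 128-d code through the (optionally shared) trunk
plus a tile head, concatenates the nine codes in their permuted order and
compresses them with one fully-connected layer back to 128-d (h).

Two trunks are available: ``tiny_cnn`` — four stride-2 conv blocks,
~97k parameters, fast enough for CPU-scale experiments — and
``resnet50_like``, a deeper residual-style stack for larger runs. All
weights live in the package's own autograd tensors, so gradients flow to
the trunk from both heads.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from . import autograd as ag
from .autograd import Parameter, Tensor

CHECKPOINT_VERSION = 1


class EncoderConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    trunk: str = "tiny_cnn"
    embed_dim: int = 128
    tile_input_size: int = 40
    prior_input_size: int = 120
    share_trunk: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "EncoderConfig":
        if self.trunk not in ("tiny_cnn", "resnet50_like"):
            raise ValueError("trunk must be 'tiny_cnn' or 'resnet50_like'")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        return self


def _he_conv(rng, f, c, k):
    std = np.sqrt(2.0 / (c * k * k))
    return Parameter(rng.normal(0.0, std, size=(f, c, k, k)).astype(np.float32))


def _he_linear(rng, n_in, n_out):
    std = np.sqrt(2.0 / n_in)
    return Parameter(rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32))


def _zeros(*shape):
    return Parameter(np.zeros(shape, dtype=np.float32))


class _BatchNorm:
    """Per-channel batch norm with EMA running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            out, mu, var = ag.batch_norm_train(x, self.gamma, self.beta)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        return ag.batch_norm_eval(x, self.gamma, self.beta,
                                  self.running_mean, self.running_var)


class _ConvTrunk:
    """Stride-2 conv/BN/ReLU stack ending in a global average pool.

    Without the per-channel normalisation, pooled ReLU features of
    unrelated images share a dominant channel profile, all unit-norm
    codes start out nearly parallel and the contrastive gradients vanish.
    """

    def __init__(self, rng: np.random.Generator, channels: tuple[int, ...]):
        self.weights = []
        self.biases = []
        self.norms = []
        c_in = 3
        for c_out in channels:
            self.weights.append(_he_conv(rng, c_out, c_in, 3))
            self.biases.append(_zeros(c_out))
            self.norms.append(_BatchNorm(c_out))
            c_in = c_out
        self.out_channels = c_in

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        h = x
        for w, b, bn in zip(self.weights, self.biases, self.norms):
            h = ag.relu(bn(ag.conv2d(h, w, b, stride=2, pad=1), training))
        return ag.global_avg_pool(h)

    def parameters(self):
        params = [*self.weights, *self.biases]
        for bn in self.norms:
            params += [bn.gamma, bn.beta]
        return params


_TRUNK_CHANNELS = {
    "tiny_cnn": (16, 32, 64, 128),
    "resnet50_like": (32, 64, 128, 256, 256),  # plain deep stack at desk scale
}


class Encoder:
    """Shared-trunk dual-head encoder for prior/WIN and distorted views."""

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        channels = _TRUNK_CHANNELS[config.trunk]
        self.trunk = _ConvTrunk(rng, channels)
        self.tile_trunk = self.trunk if config.share_trunk else _ConvTrunk(rng, channels)
        d = config.embed_dim
        c_out = self.trunk.out_channels
        self.prior_head_w = _he_linear(rng, c_out, d)
        self.prior_head_b = _zeros(d)
        self.tile_head_w = _he_linear(rng, c_out, d)
        self.tile_head_b = _zeros(d)
        self.concat_w = _he_linear(rng, 9 * d, d)
        self.concat_b = _zeros(d)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Parameter]:
        params = self.trunk.parameters()
        if self.tile_trunk is not self.trunk:
            params = params + self.tile_trunk.parameters()
        params = params + [
            self.prior_head_w, self.prior_head_b,
            self.tile_head_w, self.tile_head_b,
            self.concat_w, self.concat_b,
        ]
        return params

    # -- forward passes -----------------------------------------------------

    @staticmethod
    def _to_nchw(views: np.ndarray) -> np.ndarray:
        views = np.asarray(views, dtype=np.float32)
        if views.ndim == 3:
            views = views[None]
        return np.ascontiguousarray(views.transpose(0, 3, 1, 2))

    def forward_prior(self, views: np.ndarray, training: bool = True) -> Tensor:
        """Batch of HxWx3 float views -> (B, 128) unit-norm codes (graph-built)."""
        x = self._to_nchw(views)
        s = self.config.prior_input_size
        if x.shape[2] != s or x.shape[3] != s:
            raise ValueError(f"prior/WIN views must be {s}x{s}, got {x.shape[2]}x{x.shape[3]}")
        pooled = self.trunk.forward(ag.constant(x), training)
        code = ag.linear(pooled, self.prior_head_w, self.prior_head_b)
        return ag.l2_normalize(code, axis=1)

    def forward_distorted(self, tile_batches: np.ndarray, training: bool = True) -> Tensor:
        """Batch of (9, h, w, 3) tile stacks -> (B, 128) unit-norm codes."""
        tiles = np.asarray(tile_batches, dtype=np.float32)
        if tiles.ndim == 4:
            tiles = tiles[None]
        if tiles.shape[1] != 9:
            raise ValueError(f"expected 9 tiles per instance, got {tiles.shape[1]}")
        b, _, h, w, _ = tiles.shape
        ts = self.config.tile_input_size
        if h != ts or w != ts:
            raise ValueError(f"tiles must be {ts}x{ts}, got {h}x{w}")
        flat = tiles.reshape(b * 9, h, w, 3)
        pooled = self.tile_trunk.forward(ag.constant(self._to_nchw(flat)), training)
        codes = ag.linear(pooled, self.tile_head_w, self.tile_head_b)  # (9B, d)
        codes = ag.reshape(codes, (b, 9 * self.config.embed_dim))
        out = ag.linear(codes, self.concat_w, self.concat_b)
        return ag.l2_normalize(out, axis=1)

    def encode_prior(self, views: np.ndarray) -> np.ndarray:
        """Inference (eval-mode) prior/WIN encoding; returns a (B, 128) array."""
        return np.array(self.forward_prior(views, training=False).data)

    def encode_distorted(self, tile_batches: np.ndarray) -> np.ndarray:
        """Inference (eval-mode) distorted-view encoding; returns (B, 128)."""
        return np.array(self.forward_distorted(tile_batches, training=False).data)

    # -- checkpointing ------------------------------------------------------

    def _norm_layers(self) -> list[_BatchNorm]:
        norms = list(self.trunk.norms)
        if self.tile_trunk is not self.trunk:
            norms += self.tile_trunk.norms
        return norms

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i:03d}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._norm_layers()):
            state[f"bnmean_{i:03d}"] = bn.running_mean
            state[f"bnvar_{i:03d}"] = bn.running_var
        return state

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for i, p in enumerate(params):
            a = np.asarray(arrays[f"param_{i:03d}"], dtype=np.float32)
            if a.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch for param {i}")
            p.data = a
        for i, bn in enumerate(self._norm_layers()):
            bn.running_mean = np.asarray(arrays[f"bnmean_{i:03d}"], dtype=np.float64)
            bn.running_var = np.asarray(arrays[f"bnvar_{i:03d}"], dtype=np.float64)


def save_checkpoint(path: str | Path, encoder: Encoder,
                    bank_codes: np.ndarray | None = None,
                    metadata: dict | None = None) -> None:
    """Self-describing .npz checkpoint: weights, config, optional bank, metadata."""
    payload = dict(encoder.state_arrays())
    header = {
        "version": CHECKPOINT_VERSION,
        "encoder_config": encoder.config.model_dump(),
        "metadata": metadata or {},
    }
    payload["header_json"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    if bank_codes is not None:
        payload["bank_codes"] = np.asarray(bank_codes, dtype=np.float32)
    np.savez(Path(path), **payload)


def load_checkpoint(path: str | Path) -> tuple[Encoder, np.ndarray | None, dict]:
    """Load a checkpoint; returns (encoder, bank_codes or None, metadata)."""
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["header_json"]).decode())
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header.get('version')}")
        encoder = Encoder(EncoderConfig.model_validate(header["encoder_config"]))
        encoder.load_state_arrays(
            {k: data[k] for k in data.files if k.startswith(("param_", "bnmean_", "bnvar_"))}
        )
        bank = np.array(data["bank_codes"]) if "bank_codes" in data.files else None
    return encoder, bank, header["metadata"]
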