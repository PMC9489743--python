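"""Seeded contrastive pretraining loop.

Per step: build the three views for a mini-batch, encode them, retrieve
per-anchor bank negatives, form the PGCon or WINCon loss, take an SGD
step with a per-iteration cosine-annealed learning rate, and only then
EMA-update the bank rows of the batch — so the positive R_i used in the
loss is always the stale pre-update row.

The run is a pure function of its configs (one master seed fans out to
scene loading order, per-epoch view transforms, negative draws and
encoder initialisation), which the determinism contract in the tests
relies on.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from pydantic import BaseModel, ConfigDict, model_validator

from . import autograd as ag
from .encoding import Encoder, EncoderConfig, save_checkpoint
from .membank import MemoryBank, init_bank
from .objectives import LossConfig, contrastive_loss_graph
from .seeding import child_seed, rng_for
from .transforms import TransformSet, resize_image
from .views import build_view_bundle, locate_prior_center, prior_box_at

OBJECTIVES = ("pgcon", "wincon", "pirl-baseline")

TRAIN_LOG_COLUMNS = ["step", "epoch", "L_co_p", "L_co_d", "total", "lr", "n_negatives_used"]


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    batch_size: int = 64
    epochs: int = 20
    lr_init: float = 0.012
    lr_final: float = 1.2e-5
    momentum_sgd: float = 0.9
    weight_decay: float = 1e-4
    bank_momentum: float = 0.5
    k_negatives: int = 200
    objective: str = "pgcon"
    crop_side: int = 48
    seed: int = 0
    snapshot_epochs: list[int] = []

    @model_validator(mode="after")
    def _check(self) -> "TrainConfig":
        if self.lr_final >= self.lr_init:
            raise ValueError("lr_final must be < lr_init")
        if min(self.batch_size, self.epochs, self.k_negatives) < 1:
            raise ValueError("batch_size, epochs and k_negatives must be >= 1")
        if not 0.0 <= self.momentum_sgd < 1.0:
            raise ValueError("momentum_sgd must lie in [0, 1)")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        return self


def cosine_lr(step: int, total_steps: int, lr_init: float, lr_final: float) -> float:
    """Cosine annealing from lr_init (step 0) to lr_final (step total_steps)."""
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    return lr_final + 0.5 * (lr_init - lr_final) * (1.0 + math.cos(math.pi * step / total_steps))


def load_images(manifest: pd.DataFrame, image_dir: str | Path) -> list[np.ndarray]:
    """Load the manifest's PNGs as uint8 arrays; errors name missing files."""
    image_dir = Path(image_dir)
    missing = [f for f in manifest["filename"] if not (image_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing image files: {missing}")
    return [np.asarray(Image.open(image_dir / f).convert("RGB")) for f in manifest["filename"]]


def _eval_prior_view(image: np.ndarray, crop_side: int, out_size: int,
                     center: tuple[int, int] | None = None) -> np.ndarray:
    """Deterministic transform-free prior view used for snapshots and eval."""
    if center is None:
        center = locate_prior_center(image)
    box = prior_box_at(center, crop_side, image.shape[:2]).box
    t, l, b, r = box
    crop = np.asarray(image, dtype=np.float64)[t:b, l:r] / 255.0
    return resize_image(crop, out_size)


def _eval_win_view(image: np.ndarray, crop_side: int, out_size: int,
                   center: tuple[int, int]) -> np.ndarray:
    box = prior_box_at(center, crop_side, image.shape[:2]).box
    t, l, b, r = box
    img = np.asarray(image, dtype=np.float64) / 255.0
    masked = img.copy()
    masked[t:b, l:r] = 0.0
    return resize_image(masked, out_size)


def _snapshot(encoder: Encoder, images, centers, bank: MemoryBank,
              cfg: TrainConfig, enc_cfg: EncoderConfig, path: Path) -> None:
    """Dump deterministic z_p, z_d, z_win codes plus bank rows to CSV."""
    from .views import make_distorted_view  # local to avoid cycle at import time

    out, tile = enc_cfg.prior_input_size, enc_cfg.tile_input_size
    rows = []
    for idx, (img, center) in enumerate(zip(images, centers)):
        pv = _eval_prior_view(img, cfg.crop_side, out, center)
        wv = _eval_win_view(img, cfg.crop_side, out, center)
        pbox = prior_box_at(center, cfg.crop_side, img.shape[:2])
        from .transforms import identity_transform_set
        tiles, _, _ = make_distorted_view(
            img, pbox, seed=0, tile_size=tile,
            t_p=identity_transform_set("T_p"), t_d=identity_transform_set("T_d"),
            permute=False,
        )
        z_p = encoder.encode_prior(pv)[0]
        z_w = encoder.encode_prior(wv)[0]
        z_d = encoder.encode_distorted(np.stack(tiles)[None])[0]
        rows.append((idx, "z_p", z_p))
        rows.append((idx, "z_d", z_d))
        rows.append((idx, "WIN", z_w))
    for idx in range(bank.n):
        rows.append((idx, "GN", bank.R[idx]))
    dim = encoder.config.embed_dim
    header = ["id", "group"] + [f"dim_{j:03d}" for j in range(dim)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for idx, group, code in rows:
            w.writerow([idx, group] + [f"{v:.8e}" for v in code])


def pretrain(
    manifest: pd.DataFrame,
    image_dir: str | Path,
    train_cfg: TrainConfig,
    encoder_cfg: EncoderConfig,
    loss_cfg: LossConfig,
    out_dir: str | Path,
    transforms: dict[str, TransformSet] | None = None,
) -> Path:
    """Run contrastive pretraining; returns the checkpoint path.

    Writes ``checkpoint.npz``, ``train_log.csv`` and (if snapshot epochs
    are configured) ``snapshots/epoch_<e>.csv`` under ``out_dir``.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = load_images(manifest, image_dir)
    n = len(images)
    objective = train_cfg.objective
    mode = "wincon" if objective == "wincon" else "pgcon"
    loss_cfg = loss_cfg.model_copy(update={"mode": mode, "k_negatives": train_cfg.k_negatives})
    seed = train_cfg.seed
    encoder = Encoder(encoder_cfg.model_copy(update={"seed": child_seed(seed, "encoder")}))
    bank = init_bank(n, encoder_cfg.embed_dim, seed=child_seed(seed, "bank"),
                     momentum=train_cfg.bank_momentum)
    neg_rng = rng_for(seed, "negatives")
    batch_rng = rng_for(seed, "batching")
    opt = ag.SGD(encoder.parameters(), lr=train_cfg.lr_init,
                 momentum=train_cfg.momentum_sgd, weight_decay=train_cfg.weight_decay)

    # the a*-argmax of an image never changes; cache it
    centers = [locate_prior_center(img) for img in images]
    t_p = (transforms or {}).get("T_p")
    t_d = (transforms or {}).get("T_d")
    t_win = (transforms or {}).get("T_win")

    batches_per_epoch = math.ceil(n / train_cfg.batch_size)
    total_steps = train_cfg.epochs * batches_per_epoch
    snapshots = sorted(set(train_cfg.snapshot_epochs))
    snap_dir = out_dir / "snapshots"
    if snapshots:
        snap_dir.mkdir(exist_ok=True)
        if 0 in snapshots:
            _snapshot(encoder, images, centers, bank, train_cfg, encoder_cfg,
                      snap_dir / "epoch_0.csv")

    log_path = out_dir / "train_log.csv"
    step = 0
    with open(log_path, "w", newline="") as log_fh:
        log = csv.writer(log_fh)
        log.writerow(TRAIN_LOG_COLUMNS)
        for epoch in range(1, train_cfg.epochs + 1):
            order = batch_rng.permutation(n)
            for b0 in range(0, n, train_cfg.batch_size):
                idx = order[b0 : b0 + train_cfg.batch_size]
                bundles = []
                for i in idx:
                    view_seed = child_seed(seed, "views", epoch, int(i))
                    if objective == "pirl-baseline":
                        # random crop replaces the redness prior
                        crng = rng_for(seed, "pirl-center", epoch, int(i))
                        h, w = images[i].shape[:2]
                        half = train_cfg.crop_side // 2
                        center = (int(crng.integers(half, h - half)),
                                  int(crng.integers(half, w - half)))
                    else:
                        center = centers[i]
                    bundles.append(build_view_bundle(
                        images[i], train_cfg.crop_side, view_seed,
                        out_size=encoder_cfg.prior_input_size,
                        tile_size=encoder_cfg.tile_input_size,
                        t_p=t_p, t_d=t_d, t_win=t_win, prior_center=center,
                    ))
                prior_batch = np.stack([bu.prior_view for bu in bundles])
                tile_batch = np.stack([np.stack(bu.distorted_tiles) for bu in bundles])
                z_p = encoder.forward_prior(prior_batch)
                z_d = encoder.forward_distorted(tile_batch)
                z_win = None
                if objective == "wincon":
                    win_batch = np.stack([bu.win_view for bu in bundles])
                    z_win = encoder.forward_prior(win_batch)
                negs_p = bank.sample_negatives_batch(idx, train_cfg.k_negatives, neg_rng)
                negs_d = bank.sample_negatives_batch(idx, train_cfg.k_negatives, neg_rng)
                r_i = bank.R[idx]  # stale rows, read before the update below
                total, report = contrastive_loss_graph(
                    z_p, z_d, r_i, negs_p, negs_d, loss_cfg, z_win=z_win
                )
                lr = cosine_lr(step, total_steps, train_cfg.lr_init, train_cfg.lr_final)
                opt.lr = lr
                opt.zero_grad()
                ag.backward(total)
                opt.step()
                bank.update(idx, z_p.data)  # EMA after the step: stale-positive order
                log.writerow([
                    step, epoch, f"{report.l_co_p:.8f}", f"{report.l_co_d:.8f}",
                    f"{report.total:.8f}", f"{lr:.8e}", report.n_negatives_used,
                ])
                step += 1
            if epoch in snapshots:
                _snapshot(encoder, images, centers, bank, train_cfg, encoder_cfg,
                          snap_dir / f"epoch_{epoch}.csv")

    ckpt_path = out_dir / "checkpoint.npz"
    save_checkpoint(ckpt_path, encoder, bank_codes=bank.R, metadata={
        "train_config": train_cfg.model_dump(),
        "loss_config": loss_cfg.model_dump(),
        "n_images": n,
        "total_steps": total_steps,
    })
    return ckpt_path
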