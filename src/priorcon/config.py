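"""Run configuration and manifest input/output.

A :class:`RunConfig` nests all component configs plus paths and the
master seed, loads from YAML with unknown keys rejected (errors name the
offending key), fills every default from the training conventions
(tau = 0.07, k = 200 per term, alpha = beta = 0.5, lr 0.012 -> 1.2e-5,
batch 64), and round-trips through YAML losslessly.

Manifests are plain CSVs with header
``filename,class_label,center_row,center_col,seed``; the label column may
be empty (pretraining is unsupervised) but evaluation operations require
it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .encoding import EncoderConfig
from .evaluation import KNNConfig
from .objectives import LossConfig
from .synthetic import MANIFEST_COLUMNS, SceneSpec
from .training import TrainConfig
from .transforms import TransformSet, default_transform_set


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    data_dir: str = "data"
    out_dir: str = "runs/default"
    train: TrainConfig = TrainConfig()
    encoder: EncoderConfig = EncoderConfig()
    loss: LossConfig = LossConfig()
    knn: KNNConfig = KNNConfig()
    scene: SceneSpec = SceneSpec()
    transforms: dict[str, list] | None = None

    def transform_sets(self) -> dict[str, TransformSet]:
        """Materialise the configured (or default) T_p/T_d/T_win sets."""
        out = {}
        for set_id in ("T_p", "T_d", "T_win"):
            if self.transforms and set_id in self.transforms:
                out[set_id] = TransformSet.from_config(set_id, self.transforms[set_id])
            else:
                out[set_id] = default_transform_set(set_id)
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def load_config(path: str | Path, log=None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Every field (filled default or explicit) is echoed through ``log``
    (a callable taking one string) when provided.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as err:
        lines = []
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"]) or "<root>"
            lines.append(f"config key '{loc}': {e['msg']}")
        raise ValueError(f"invalid config {path}: " + "; ".join(lines)) from err
    if log is not None:
        for key, value in sorted(_flatten(cfg.model_dump()).items()):
            log(f"config {key}={value}")
    return cfg


def _flatten(d: dict, prefix: str = "") -> dict:
    flat = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            flat.update(_flatten(v, key + "."))
        else:
            flat[key] = v
    return flat


def read_manifest(path: str | Path, image_dir: str | Path | None = None,
                  require_images: bool = False) -> pd.DataFrame:
    """Read a manifest CSV; optionally verify the referenced images exist."""
    path = Path(path)
    df = pd.read_csv(path)
    if "filename" not in df.columns:
        raise ValueError(f"manifest {path} lacks the required 'filename' column")
    if require_images:
        base = Path(image_dir) if image_dir is not None else path.parent
        missing = [f for f in df["filename"] if not (base / f).exists()]
        if missing:
            raise FileNotFoundError(f"manifest references missing images: {missing}")
    return df


def write_manifest(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in MANIFEST_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    records[cols].to_csv(Path(path), index=False)


def split_manifest(manifest: pd.DataFrame, val_fraction: float, seed: int
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified-ish train/val split by shuffled order."""
    import numpy as np

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(manifest))
    n_val = int(round(val_fraction * len(manifest)))
    val_idx = np.sort(order[:n_val])
    train_idx = np.sort(order[n_val:])
    return manifest.iloc[train_idx].reset_index(drop=True), manifest.iloc[val_idx].reset_index(drop=True)
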