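"""Evaluation protocols for pretrained encoders.

Three protocols probe what the frozen representations encode:

* **zero-shot weighted kNN** — a held-out query is classified by its
  top-k cosine neighbours among labelled reference codes, each neighbour
  voting with weight ``exp(s / tau)`` (tau = 0.1, k capped at
  ``n_train - 1``); no parameters are updated anywhere;
* **linear probe** — a two-layer fully-connected head is trained with
  cross-entropy on frozen embeddings;
* **embedding geometry** — the alignment (mean squared distance of
  positive pairs) and uniformity (log mean Gaussian-kernel similarity of
  all pairs, t = 2) metrics, plus per-snapshot 2-component PCA of the
  z_p / z_d / GN / WIN groups to visualise how the space evolves.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from . import autograd as ag
from .autograd import Parameter
from .encoding import Encoder
from .training import _eval_prior_view


class KNNConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k_neighbors: int = 290
    tau_knn: float = 0.1

    @model_validator(mode="after")
    def _check(self) -> "KNNConfig":
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.tau_knn <= 0:
            raise ValueError("tau_knn must be > 0")
        return self


def knn_predict(
    query: np.ndarray,
    train_codes: np.ndarray,
    train_labels: np.ndarray,
    config: KNNConfig,
) -> tuple[object, dict]:
    """Similarity-weighted kNN vote for one query code.

    Neighbour weight is ``exp(s / tau)`` with s the cosine similarity;
    class score is the summed weight of that class's neighbours among the
    top-k; ties go to the lowest class (sorted order).
    """
    query = np.asarray(query, dtype=np.float64)
    train_codes = np.asarray(train_codes, dtype=np.float64)
    train_labels = np.asarray(train_labels)
    if train_codes.shape[0] != train_labels.shape[0]:
        raise ValueError("train_codes and train_labels lengths differ")
    k = min(config.k_neighbors, train_codes.shape[0])
    sims = train_codes @ query
    top = np.argsort(-sims, kind="stable")[:k]
    weights = np.exp(sims[top] / config.tau_knn)
    classes = sorted(set(train_labels.tolist()))
    scores = {c: 0.0 for c in classes}
    for t, w in zip(top, weights):
        scores[train_labels[t]] += float(w)
    best = max(classes, key=lambda c: scores[c])  # max keeps the first (lowest) class on ties
    return best, scores


def knn_predict_batch(
    queries: np.ndarray,
    train_codes: np.ndarray,
    train_labels: np.ndarray,
    config: KNNConfig,
) -> np.ndarray:
    """Vectorised weighted-kNN prediction for a (Q, d) query stack."""
    queries = np.asarray(queries, dtype=np.float64)
    train_codes = np.asarray(train_codes, dtype=np.float64)
    labels = np.asarray(train_labels)
    classes = np.array(sorted(set(labels.tolist())))
    label_idx = np.searchsorted(classes, labels)
    k = min(config.k_neighbors, train_codes.shape[0])
    sims = queries @ train_codes.T  # (Q, n)
    top = np.argsort(-sims, axis=1, kind="stable")[:, :k]
    w = np.exp(np.take_along_axis(sims, top, axis=1) / config.tau_knn)
    onehot = np.eye(len(classes))[label_idx[top]]  # (Q, k, C)
    class_scores = (w[:, :, None] * onehot).sum(axis=1)
    return classes[np.argmax(class_scores, axis=1)]


def embed_manifest(
    encoder: Encoder,
    manifest: pd.DataFrame,
    image_dir: str | Path,
    crop_side: int,
) -> np.ndarray:
    """Deterministic prior-view embeddings for every manifest row."""
    from .training import load_images

    images = load_images(manifest, image_dir)
    out = encoder.config.prior_input_size
    views = np.stack([_eval_prior_view(img, crop_side, out) for img in images])
    # encode in chunks to bound memory
    codes = [encoder.encode_prior(views[i : i + 32]) for i in range(0, len(views), 32)]
    return np.concatenate(codes, axis=0)


def _require_labels(manifest: pd.DataFrame, what: str) -> np.ndarray:
    if "class_label" not in manifest.columns or manifest["class_label"].isna().any():
        raise ValueError(f"{what} requires a class_label column with no missing values")
    return manifest["class_label"].to_numpy()


def zero_shot_eval(
    encoder: Encoder,
    train_manifest: pd.DataFrame,
    eval_manifest: pd.DataFrame,
    image_dir: str | Path,
    crop_side: int,
    config: KNNConfig | None = None,
    eval_image_dir: str | Path | None = None,
) -> dict:
    """Top-1 weighted-kNN accuracy of frozen embeddings on a held-out set.

    The reference set is the (labelled) pretraining split; queries come
    from the disjoint evaluation split. No parameters are updated.
    """
    config = config or KNNConfig()
    eval_image_dir = image_dir if eval_image_dir is None else eval_image_dir
    if Path(image_dir) == Path(eval_image_dir):
        overlap = set(train_manifest["filename"]) & set(eval_manifest["filename"])
        if overlap:
            raise ValueError(f"train and eval splits overlap: {sorted(overlap)[:5]}")
    y_train = _require_labels(train_manifest, "zero-shot evaluation")
    y_eval = _require_labels(eval_manifest, "zero-shot evaluation")
    ref = embed_manifest(encoder, train_manifest, image_dir, crop_side)
    q = embed_manifest(encoder, eval_manifest, eval_image_dir, crop_side)
    k = min(config.k_neighbors, ref.shape[0] - 1) if ref.shape[0] > 1 else 1
    cfg = config.model_copy(update={"k_neighbors": k})
    preds = knn_predict_batch(q, ref, y_train, cfg)
    top1 = float(np.mean(preds == y_eval))
    return {"top1": top1, "n": int(len(y_eval)), "config": cfg.model_dump()}


def linear_probe(
    encoder: Encoder,
    train_manifest: pd.DataFrame,
    eval_manifest: pd.DataFrame,
    image_dir: str | Path,
    crop_side: int,
    n_epochs: int = 200,
    hidden_dim: int = 128,
    lr: float = 0.5,
    seed: int = 0,
) -> dict:
    """Train a 2-fc-layer head on frozen embeddings; report val top-1.

    The trunk is never touched: features are extracted once and only the
    head's four parameter tensors are optimised (full-batch SGD with
    momentum on the softmax cross-entropy).
    """
    y_train_raw = _require_labels(train_manifest, "linear probe")
    y_eval_raw = _require_labels(eval_manifest, "linear probe")
    classes = sorted(set(y_train_raw.tolist()))
    missing = set(y_eval_raw.tolist()) - set(classes)
    if missing:
        raise ValueError(f"classes absent from train split: {sorted(missing)}")
    cls_idx = {c: i for i, c in enumerate(classes)}
    y_train = np.array([cls_idx[c] for c in y_train_raw])
    y_eval = np.array([cls_idx[c] for c in y_eval_raw])

    x_train = embed_manifest(encoder, train_manifest, image_dir, crop_side).astype(np.float32)
    x_eval = embed_manifest(encoder, eval_manifest, image_dir, crop_side).astype(np.float32)

    rng = np.random.default_rng(seed)
    d, c = x_train.shape[1], len(classes)
    w1 = Parameter(rng.normal(0, np.sqrt(2.0 / d), size=(d, hidden_dim)).astype(np.float32))
    b1 = Parameter(np.zeros(hidden_dim, dtype=np.float32))
    w2 = Parameter(rng.normal(0, np.sqrt(2.0 / hidden_dim), size=(hidden_dim, c)).astype(np.float32))
    b2 = Parameter(np.zeros(c, dtype=np.float32))
    opt = ag.SGD([w1, b1, w2, b2], lr=lr, momentum=0.9)
    x_t = ag.constant(x_train)
    onehot = np.eye(c, dtype=np.float32)[y_train]

    for _ in range(n_epochs):
        logits = ag.linear(ag.relu(ag.linear(x_t, w1, b1)), w2, b2)
        lse = ag.logsumexp(logits, axis=1)
        picked = ag.rowwise_dot(logits, ag.constant(onehot))
        loss = ag.mean_all(ag.sub(lse, picked))
        opt.zero_grad()
        ag.backward(loss)
        opt.step()

    def predict(x):
        h = np.maximum(x @ w1.data + b1.data, 0)
        return np.argmax(h @ w2.data + b2.data, axis=1)

    return {
        "top1": float(np.mean(predict(x_eval) == y_eval)),
        "train_top1": float(np.mean(predict(x_train) == y_train)),
        "n": int(len(y_eval)),
        "classes": classes,
    }


def alignment_uniformity(
    pos_pairs: list[tuple[np.ndarray, np.ndarray]],
    all_codes: np.ndarray,
    alpha: float = 2.0,
    t: float = 2.0,
) -> dict:
    """Alignment / uniformity of an embedding set on the unit hypersphere.

    ``L_align = mean ||z_a - z_b||^alpha`` over positive pairs (the
    (z_p, z_d) pairs of the same image); ``L_uniform = log mean
    exp(-t ||z_i - z_j||^2)`` over all distinct unordered code pairs.
    Lower alignment = tighter positives; lower (more negative)
    uniformity = better spread.
    """
    all_codes = np.asarray(all_codes, dtype=np.float64)
    if all_codes.shape[0] < 2:
        raise ValueError("uniformity needs at least 2 codes")
    if not pos_pairs:
        raise ValueError("alignment needs at least one positive pair")
    diffs = [np.linalg.norm(np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64))
             for a, b in pos_pairs]
    l_align = float(np.mean(np.power(diffs, alpha)))
    sq = pdist(all_codes, "sqeuclidean")
    l_uniform = float(np.log(np.mean(np.exp(-t * sq))))
    return {"L_align": l_align, "L_uniform": l_uniform, "n_pairs": len(pos_pairs)}


SNAPSHOT_GROUPS = ("z_p", "z_d", "GN", "WIN")


def read_snapshot(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "group" not in df.columns or "id" not in df.columns:
        raise ValueError(f"snapshot {path} missing id/group columns")
    return df


def snapshot_codes(df: pd.DataFrame, group: str) -> np.ndarray:
    dims = [c for c in df.columns if c.startswith("dim_")]
    sub = df[df["group"] == group].sort_values("id")
    return sub[dims].to_numpy(dtype=np.float64)


def pca_snapshot(snapshot_paths: list[str | Path]) -> dict[str, pd.DataFrame]:
    """2-component PCA per snapshot over the union of embedding groups.

    Returns ``{snapshot_name: DataFrame(id, group, pc1, pc2)}``; the PCA
    is fitted independently per snapshot, matching how the evolving space
    is inspected epoch by epoch.
    """
    if len(snapshot_paths) < 2:
        raise ValueError("need at least 2 snapshots to show evolution")
    out: dict[str, pd.DataFrame] = {}
    for path in snapshot_paths:
        df = read_snapshot(path)
        dims = [c for c in df.columns if c.startswith("dim_")]
        coords = PCA(n_components=2, random_state=0).fit_transform(df[dims].to_numpy())
        out[Path(path).stem] = pd.DataFrame({
            "id": df["id"], "group": df["group"],
            "pc1": coords[:, 0], "pc2": coords[:, 1],
        })
    return out


def win_prior_cosine(snapshot_path: str | Path) -> float:
    """Mean cosine between each image's z_p and its own WIN code."""
    df = read_snapshot(snapshot_path)
    zp = snapshot_codes(df, "z_p")
    zw = snapshot_codes(df, "WIN")
    if zp.shape != zw.shape or zp.shape[0] == 0:
        raise ValueError("snapshot lacks matched z_p/WIN groups")
    return float(np.mean(np.sum(zp * zw, axis=1)))


def plot_pca(projections: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """One scatter PNG per snapshot, colour-coded by embedding group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    colors = {"z_p": "tab:red", "z_d": "tab:blue", "GN": "tab:gray", "WIN": "tab:green"}
    paths = []
    for name, df in projections.items():
        fig, axis = plt.subplots(figsize=(5, 5))
        for group, sub in df.groupby("group"):
            axis.scatter(sub["pc1"], sub["pc2"], s=10, alpha=0.7,
                         label=group, color=colors.get(group, "k"))
        axis.set_title(name)
        axis.legend()
        p = out_dir / f"pca_{name}.png"
        fig.savefig(p, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
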