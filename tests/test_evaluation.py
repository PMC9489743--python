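import hashlib
import math

import numpy as np
import pandas as pd
import pytest

from priorcon.encoding import Encoder, EncoderConfig
from priorcon.evaluation import (
    KNNConfig,
    alignment_uniformity,
    knn_predict,
    knn_predict_batch,
    linear_probe,
    pca_snapshot,
    win_prior_cosine,
    zero_shot_eval,
)


def _unit(rng, n, d=32):
    z = rng.standard_normal((n, d))
    return z / np.linalg.norm(z, axis=1, keepdims=True)


class TestKNNPredict:
    def test_exact_match_with_k1(self, rng):
        codes = _unit(rng, 10)
        labels = np.array(list("abcdefghij"))
        pred, _ = knn_predict(codes[4], codes, labels, KNNConfig(k_neighbors=1))
        assert pred == "e"

    def test_single_class_score_is_weight_sum(self, rng):
        codes = _unit(rng, 6)
        labels = np.array(["A"] * 6)
        cfg = KNNConfig(k_neighbors=6, tau_knn=0.1)
        query = codes[0]
        pred, scores = knn_predict(query, codes, labels, cfg)
        sims = codes @ query
        assert pred == "A"
        assert scores["A"] == pytest.approx(np.exp(sims / 0.1).sum(), rel=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        codes = _unit(rng, 40)
        labels = rng.integers(0, 3, size=40)
        cfg = KNNConfig(k_neighbors=7, tau_knn=0.1)
        queries = _unit(rng, 25)

        def brute(query):
            sims = [(float(codes[i] @ query), i) for i in range(40)]
            sims.sort(key=lambda t: -t[0])
            scores = {}
            for s, i in sims[:7]:
                scores[int(labels[i])] = scores.get(int(labels[i]), 0.0) + math.exp(s / 0.1)
            best = min(c for c in scores if scores[c] == max(scores.values()))
            return best

        batch_preds = knn_predict_batch(queries, codes, labels, cfg)
        for q, bp in zip(queries, batch_preds):
            single, _ = knn_predict(q, codes, labels, cfg)
            assert single == brute(q) == bp

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            knn_predict(np.ones(4), _unit(rng, 5, 4), np.array(["a"]), KNNConfig())


@pytest.fixture(scope="module")
def trained_free_encoder():
    """Untrained (random-weight) encoder: enough for protocol contracts."""
    return Encoder(EncoderConfig(seed=5))


class TestZeroShot:
    def test_shuffled_labels_give_chance_accuracy(self, rng):
        # label-free sanity directly on the kNN layer: random labels, 3 classes
        codes = _unit(rng, 300)
        queries = _unit(rng, 300)
        labels = rng.integers(0, 3, size=300)
        preds = knn_predict_batch(queries, codes, labels, KNNConfig(k_neighbors=30))
        acc = float(np.mean(preds == rng.integers(0, 3, size=300)))
        sigma = math.sqrt((1 / 3) * (2 / 3) / 300)
        assert abs(acc - 1 / 3) < 3 * sigma

    def test_self_match_with_k1_is_perfect(self, trained_free_encoder, small_dataset,
                                           tmp_path):
        import shutil

        data_dir, manifest = small_dataset
        mirror = tmp_path / "mirror"
        shutil.copytree(data_dir, mirror)
        res = zero_shot_eval(
            trained_free_encoder, manifest, manifest, data_dir, 48,
            KNNConfig(k_neighbors=1), eval_image_dir=mirror,
        )
        assert res["top1"] == 1.0

    def test_overlapping_splits_rejected(self, trained_free_encoder, small_dataset):
        data_dir, manifest = small_dataset
        with pytest.raises(ValueError, match="overlap"):
            zero_shot_eval(trained_free_encoder, manifest, manifest, data_dir, 48)

    def test_no_parameter_updates(self, trained_free_encoder, small_dataset):
        data_dir, manifest = small_dataset
        digest_before = _params_digest(trained_free_encoder)
        zero_shot_eval(trained_free_encoder, manifest.iloc[:8], manifest.iloc[8:],
                       data_dir, 48, KNNConfig(k_neighbors=3))
        assert _params_digest(trained_free_encoder) == digest_before

    def test_missing_labels_rejected(self, trained_free_encoder, small_dataset):
        data_dir, manifest = small_dataset
        unlabeled = manifest.drop(columns=["class_label"])
        with pytest.raises(ValueError, match="class_label"):
            zero_shot_eval(trained_free_encoder, unlabeled.iloc[:8], manifest.iloc[8:],
                           data_dir, 48)


def _params_digest(encoder):
    h = hashlib.sha256()
    for key, arr in sorted(encoder.state_arrays().items()):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


class TestLinearProbe:
    def test_frozen_trunk_unchanged(self, trained_free_encoder, small_dataset):
        data_dir, manifest = small_dataset
        train = manifest.groupby("class_label").head(3).reset_index(drop=True)
        evalm = manifest[~manifest["filename"].isin(train["filename"])].reset_index(drop=True)
        digest_before = _params_digest(trained_free_encoder)
        linear_probe(trained_free_encoder, train, evalm, data_dir, 48, n_epochs=5)
        assert _params_digest(trained_free_encoder) == digest_before

    def test_class_missing_from_train_rejected(self, trained_free_encoder, small_dataset):
        data_dir, manifest = small_dataset
        by_class = manifest.sort_values("class_label").reset_index(drop=True)
        train = by_class.iloc[:4]  # single class
        evalm = by_class.iloc[4:]
        with pytest.raises(ValueError, match="absent"):
            linear_probe(trained_free_encoder, train, evalm, data_dir, 48, n_epochs=1)

    def test_separable_features_reach_perfect_accuracy(self, rng, monkeypatch,
                                                       trained_free_encoder, small_dataset):
        """With linearly separable frozen features the probe must hit 1.0."""
        import priorcon.evaluation as ev

        data_dir, manifest = small_dataset
        labels = manifest["class_label"]
        classes = sorted(set(labels))
        centers = np.eye(128)[:3] * 5

        def fake_embed(encoder, man, image_dir, crop_side):
            idx = [classes.index(c) for c in man["class_label"]]
            noise = np.random.default_rng(0).normal(0, 0.05, size=(len(idx), 128))
            return (centers[idx] + noise).astype(np.float32)

        monkeypatch.setattr(ev, "embed_manifest", fake_embed)
        res = linear_probe(trained_free_encoder, manifest.iloc[:9], manifest.iloc[9:],
                           data_dir, 48, n_epochs=100)
        assert res["top1"] == 1.0


class TestAlignmentUniformity:
    def test_identical_pairs_give_zero_alignment(self, rng):
        z = _unit(rng, 10)
        rep = alignment_uniformity([(v, v.copy()) for v in z], z)
        assert rep["L_align"] == 0.0

    def test_all_equal_codes_give_zero_uniformity(self):
        z = np.tile(np.eye(8)[0], (5, 1))
        rep = alignment_uniformity([(z[0], z[1])], z)
        assert rep["L_uniform"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_sphere_monte_carlo_value(self):
        # 2000 i.i.d. uniform unit vectors in 128-d concentrate pairwise
        # squared distances at 2; the t=2 kernel mean gives ~ -3.938
        # (-4 + log E[exp(4 cos)] with Var[cos] = 1/128)
        rng = np.random.default_rng(123)
        z = _unit(rng, 2000, d=128)
        rep = alignment_uniformity([(z[0], z[1])], z)
        assert rep["L_uniform"] == pytest.approx(-3.938, abs=0.05)

    def test_matches_double_loop_oracle(self, rng):
        z = _unit(rng, 50, d=16)
        pairs = [(z[i], z[i + 25]) for i in range(25)]
        rep = alignment_uniformity(pairs, z)
        align = sum(float(np.sum((a - b) ** 2)) for a, b in pairs) / 25
        acc, cnt = 0.0, 0
        for i in range(50):
            for j in range(i + 1, 50):
                acc += math.exp(-2 * float(np.sum((z[i] - z[j]) ** 2)))
                cnt += 1
        assert rep["L_align"] == pytest.approx(align, abs=1e-9)
        assert rep["L_uniform"] == pytest.approx(math.log(acc / cnt), abs=1e-9)

    def test_too_few_codes_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            alignment_uniformity([(np.ones(4), np.ones(4))], np.ones((1, 4)))


def _write_snapshot(path, codes_by_group):
    rows = []
    for group, codes in codes_by_group.items():
        for i, code in enumerate(codes):
            rows.append({"id": i, "group": group,
                         **{f"dim_{j:03d}": v for j, v in enumerate(code)}})
    pd.DataFrame(rows).to_csv(path, index=False)


class TestPCASnapshot:
    def test_planar_codes_reconstruct_exactly(self, tmp_path, rng):
        basis = np.linalg.qr(rng.standard_normal((16, 2)))[0].T  # 2 x 16
        coords = rng.standard_normal((20, 2))
        codes = coords @ basis
        for name in ("epoch_0.csv", "epoch_5.csv"):
            _write_snapshot(tmp_path / name, {"z_p": codes})
        proj = pca_snapshot([tmp_path / "epoch_0.csv", tmp_path / "epoch_5.csv"])
        pcs = proj["epoch_0"][["pc1", "pc2"]].to_numpy()
        # distances are preserved exactly when the data is truly planar
        d_orig = np.linalg.norm(codes[:1] - codes, axis=1)
        d_proj = np.linalg.norm(pcs[:1] - pcs, axis=1)
        np.testing.assert_allclose(d_proj, d_orig, atol=1e-8)

    def test_duplicated_dataset_projects_identically_up_to_sign(self, tmp_path, rng):
        codes = rng.standard_normal((15, 8))
        _write_snapshot(tmp_path / "epoch_0.csv", {"z_p": codes})
        _write_snapshot(tmp_path / "epoch_1.csv", {"z_p": codes})
        proj = pca_snapshot([tmp_path / "epoch_0.csv", tmp_path / "epoch_1.csv"])
        a = proj["epoch_0"][["pc1", "pc2"]].to_numpy()
        b = proj["epoch_1"][["pc1", "pc2"]].to_numpy()
        for col in range(2):
            assert np.allclose(a[:, col], b[:, col]) or np.allclose(a[:, col], -b[:, col])

    def test_missing_group_column_rejected(self, tmp_path):
        pd.DataFrame({"id": [0], "dim_000": [1.0]}).to_csv(tmp_path / "epoch_0.csv", index=False)
        pd.DataFrame({"id": [0], "dim_000": [1.0]}).to_csv(tmp_path / "epoch_1.csv", index=False)
        with pytest.raises(ValueError, match="group"):
            pca_snapshot([tmp_path / "epoch_0.csv", tmp_path / "epoch_1.csv"])

    def test_fewer_than_two_snapshots_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="2 snapshots"):
            pca_snapshot([tmp_path / "only.csv"])


def test_win_prior_cosine_reads_matched_groups(tmp_path, rng):
    zp = _unit(rng, 6, 16)
    _write_snapshot(tmp_path / "s.csv", {"z_p": zp, "WIN": zp})
    assert win_prior_cosine(tmp_path / "s.csv") == pytest.approx(1.0)
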