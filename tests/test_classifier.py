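import numpy as np
import pandas as pd
import pytest

from emci.classifier import (
    ClassifierConfig,
    accuracy,
    confusion_matrix,
    predict,
    split_train_test,
    train,
    TrainedClassifier,
)


def _balanced_labels(n_per_class=50, classes=("A", "B")):
    ids = []
    vals = []
    for c in classes:
        for i in range(n_per_class):
            ids.append(f"{c}{i}")
            vals.append(c)
    return pd.Series(vals, index=ids, name="cell_type")


class TestSplit:
    def test_stratified_70_30(self):
        labels = _balanced_labels(50)
        tr, te = split_train_test(labels, train_frac=0.7, seed=0)
        assert len(tr) == 70 and len(te) == 30
        tr_counts = labels.loc[tr].value_counts()
        assert tr_counts["A"] == 35 and tr_counts["B"] == 35
        assert set(tr).isdisjoint(te)
        assert set(tr) | set(te) == set(labels.index)

    def test_full_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(_balanced_labels(), train_frac=1.0)

    def test_singleton_class_names_class(self):
        labels = pd.Series(["A", "A", "B"], index=["a1", "a2", "b1"])
        with pytest.raises(ValueError, match="B"):
            split_train_test(labels)

    def test_seed_determinism(self):
        labels = _balanced_labels(20)
        tr1, te1 = split_train_test(labels, seed=3)
        tr2, te2 = split_train_test(labels, seed=3)
        assert tr1 == tr2 and te1 == te2
        tr3, _ = split_train_test(labels, seed=4)
        assert tr1 != tr3
        assert labels.loc[tr1].value_counts().equals(labels.loc[tr3].value_counts())


class TestAccuracy:
    def test_perfect(self):
        assert accuracy(pd.Series(["A", "B"]), pd.Series(["A", "B"])) == 1.0

    def test_exact_match_multilabel_hand_count(self):
        # stage all correct; cell type correct on 2 of 4 -> exact-match 0.5
        pred = pd.DataFrame(
            {"stage": ["s1", "s1", "s2", "s2"], "cell_type": ["A", "A", "B", "B"]}
        )
        truth = pd.DataFrame(
            {"stage": ["s1", "s1", "s2", "s2"], "cell_type": ["A", "B", "A", "B"]}
        )
        assert accuracy(pred, truth, mode="exact-match-multilabel") == 0.5
        assert accuracy(pred[["stage"]], truth[["stage"]]) == 1.0
        assert accuracy(pred[["cell_type"]], truth[["cell_type"]]) == 0.5

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        pred = pd.Series(rng.choice(["A", "B", "C"], 30))
        truth = pd.Series(rng.choice(["A", "B", "C"], 30))
        perm = rng.permutation(30)
        assert accuracy(pred, truth) == accuracy(
            pred.iloc[perm].reset_index(drop=True),
            truth.iloc[perm].reset_index(drop=True),
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(pd.Series(dtype=object), pd.Series(dtype=object))

    def test_confusion_matrix(self):
        cm = confusion_matrix(["A", "B", "A"], ["A", "B", "B"])
        assert cm.loc["A", "A"] == 1
        assert cm.loc["B", "A"] == 1


class TestConfig:
    def test_defaults_follow_reference_settings(self):
        cfg = ClassifierConfig()
        assert cfg.epochs == 100
        assert cfg.learning_rate == pytest.approx(0.00005)
        assert cfg.momentum == pytest.approx(0.8)
        assert cfg.weight_decay == pytest.approx(0.0125)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(architecture="vgg")
        with pytest.raises(ValueError):
            ClassifierConfig(epochs=0)
        with pytest.raises(ValueError):
            ClassifierConfig(learning_rate=0.0)


@pytest.fixture(scope="module")
def tiny_trained():
    """A fast 3-class training run on trivially separable images."""
    rng = np.random.default_rng(0)
    n_per = 20
    images, labels, ids = [], [], []
    for c, cls in enumerate("ABC"):
        for i in range(n_per):
            img = rng.random((8, 8, 3)) * 0.05
            img[c * 2 : c * 2 + 2, :, c] += 0.9  # class-specific stripe
            images.append(np.clip(img, 0, 1))
            labels.append(cls)
            ids.append(f"{cls}{i}")
    labels = pd.Series(labels, index=ids, name="cell_type")
    cfg = ClassifierConfig(architecture="small-cnn", epochs=15, learning_rate=0.02,
                           seed=0, batch_size=16)
    clf = train(np.stack(images), labels, cfg, cell_ids=ids)
    return clf, np.stack(images), labels


class TestTrainPredict:
    def test_separable_recovery(self, tiny_trained):
        clf, _, _ = tiny_trained
        assert clf.test_accuracy >= 0.9

    def test_scores_on_simplex(self, tiny_trained):
        clf, images, _ = tiny_trained
        scores = predict(clf, images[:5])
        np.testing.assert_allclose(scores[0].sum(axis=1), 1.0, atol=1e-6)
        assert np.all(scores[0] >= 0)

    def test_training_image_argmax_matches_label(self, tiny_trained):
        clf, images, labels = tiny_trained
        train_ids = clf.split["train"][:10]
        pos = {c: i for i, c in enumerate(labels.index)}
        idx = [pos[c] for c in train_ids]
        pred = clf.predict_labels(images[idx])
        assert (pred["cell_type"].to_numpy() == labels.loc[train_ids].to_numpy()).mean() >= 0.9

    def test_batch_equals_per_image(self, tiny_trained):
        clf, images, _ = tiny_trained
        batch = predict(clf, images[:4])[0]
        singles = np.vstack([predict(clf, images[i : i + 1])[0] for i in range(4)])
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_shape_mismatch_rejected(self, tiny_trained):
        clf, _, _ = tiny_trained
        with pytest.raises(ValueError):
            clf.predict_scores(np.zeros((1, 5, 5, 3)))

    def test_loss_history_finite(self, tiny_trained):
        clf, _, _ = tiny_trained
        assert np.all(np.isfinite(clf.history["loss"]))
        assert clf.history["train_accuracy"].between(0, 1).all()

    def test_single_class_rejected(self):
        labels = pd.Series(["A"] * 10, index=[f"c{i}" for i in range(10)])
        with pytest.raises(ValueError):
            train(np.zeros((10, 8, 8, 3)), labels,
                  ClassifierConfig(architecture="small-cnn", epochs=1))

    def test_seed_determinism_weights_hash(self):
        rng = np.random.default_rng(1)
        images = rng.random((24, 8, 8, 3))
        labels = pd.Series(["A"] * 12 + ["B"] * 12,
                           index=[f"c{i}" for i in range(24)])
        cfg = ClassifierConfig(architecture="small-cnn", epochs=3,
                               learning_rate=0.01, seed=7)
        h1 = train(images, labels, cfg, cell_ids=list(labels.index)).weights_hash()
        h2 = train(images, labels, cfg, cell_ids=list(labels.index)).weights_hash()
        assert h1 == h2

    def test_save_load_round_trip(self, tmp_path, tiny_trained):
        clf, images, _ = tiny_trained
        clf.save(tmp_path / "model.npz")
        loaded = TrainedClassifier.load(tmp_path / "model.npz")
        np.testing.assert_allclose(
            loaded.predict_scores(images[:3])[0], clf.predict_scores(images[:3])[0],
            atol=1e-12,
        )

    def test_two_head_training(self):
        rng = np.random.default_rng(2)
        n = 40
        images = rng.random((n, 8, 8, 3)) * 0.05
        stage = ["early"] * (n // 2) + ["late"] * (n // 2)
        ctype = (["A", "B"] * (n // 2))[:n]
        for i in range(n):
            if stage[i] == "late":
                images[i, :2, :, 0] += 0.9
            if ctype[i] == "B":
                images[i, 6:, :, 1] += 0.9
        images = np.clip(images, 0, 1)
        labels = pd.DataFrame(
            {"stage": stage, "cell_type": ctype}, index=[f"c{i}" for i in range(n)]
        )
        cfg = ClassifierConfig(architecture="small-cnn", epochs=12,
                               learning_rate=0.02, seed=0, heads=2, batch_size=8)
        clf = train(images, labels, cfg, cell_ids=list(labels.index))
        scores = clf.predict_scores(images[:3])
        assert len(scores) == 2
        for s in scores:
            np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-6)
        assert clf.test_accuracy >= 0.5
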