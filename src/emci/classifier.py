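"""CNN training on pseudo-images: stratified splitting, SGD training, accuracy.

Defaults mirror the reference configuration (SGD with momentum 0.8, initial
learning rate 5e-5, L2 weight decay 0.0125, 100 epochs max); the ``small-cnn``
architecture is a desk-scale profile with the same training loop and is the
profile exercised by the test suite. Labels may be a single class column or
two columns (e.g. stage + cell type), realized as two softmax heads on a
shared trunk; joint accuracy is exact-match.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from emci import nn

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "TrainedClassifier",
    "split_train_test",
    "train",
    "predict",
    "accuracy",
    "confusion_matrix",
]

ARCHITECTURES = ("resnet50-like", "small-cnn")


@dataclass
class ClassifierConfig:
    architecture: str = "resnet50-like"
    epochs: int = 100
    learning_rate: float = 0.00005
    momentum: float = 0.8
    weight_decay: float = 0.0125
    batch_size: int = 32
    seed: int = 0
    heads: int = 1
    resnet_width: int = 16

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.learning_rate, self.momentum, self.weight_decay) < 0 or self.learning_rate == 0:
            raise ValueError("rates must be positive")
        if self.heads not in (1, 2):
            raise ValueError("heads must be 1 or 2")


def _as_label_frame(labels) -> pd.DataFrame:
    if isinstance(labels, pd.Series):
        return labels.to_frame()
    if isinstance(labels, pd.DataFrame):
        return labels
    raise TypeError("labels must be a pandas Series or DataFrame indexed by cell id")


def split_train_test(
    labels, train_frac: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified train/test split of labeled cell ids.

    Stratification is on the joint label (all columns combined). Every class
    needs at least 2 cells so both sides are nonempty.
    """
    df = _as_label_frame(labels)
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie strictly in (0, 1)")
    joint = df.astype(str).agg("|".join, axis=1)
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in sorted(joint.unique()):
        ids = np.asarray(joint.index[joint == cls], dtype=object)
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has a single cell; cannot stratify")
        ids = ids[rng.permutation(len(ids))]
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    return train_ids, test_ids


@dataclass
class TrainedClassifier:
    net: nn.MultiHeadNet
    class_names: list[list[str]]  # per head
    label_columns: list[str]
    config: ClassifierConfig
    history: pd.DataFrame = field(default_factory=pd.DataFrame)
    split: dict[str, list[str]] = field(default_factory=dict)
    input_shape: tuple[int, int, int] = (0, 0, 3)  # (H, W, C)
    test_accuracy: float | None = None

    def predict_scores(self, images: np.ndarray) -> list[np.ndarray]:
        """Per-head softmax score matrices for a batch of H x W x 3 images."""
        x = _to_nchw(images, self.input_shape)
        return self.net.predict_proba(x)

    def predict_labels(self, images: np.ndarray) -> pd.DataFrame:
        scores = self.predict_scores(images)
        out = {}
        for col, names, s in zip(self.label_columns, self.class_names, scores):
            out[col] = [names[i] for i in s.argmax(axis=1)]
        return pd.DataFrame(out)

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for arr in self.net.state():
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, *self.net.state())
        meta = {
            "class_names": self.class_names,
            "label_columns": self.label_columns,
            "config": asdict(self.config),
            "input_shape": list(self.input_shape),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = ClassifierConfig(**meta["config"])
        n_classes = [len(names) for names in meta["class_names"]]
        net = _build_net(cfg, n_classes)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            net.set_state([z[k] for k in z.files])
        return cls(
            net,
            meta["class_names"],
            meta["label_columns"],
            cfg,
            input_shape=tuple(meta["input_shape"]),
        )


def _build_net(cfg: ClassifierConfig, n_classes: list[int]) -> nn.MultiHeadNet:
    rng = np.random.default_rng(cfg.seed)
    if cfg.architecture == "small-cnn":
        return nn.build_small_cnn(n_classes, rng=rng)
    return nn.build_resnet(n_classes, width=cfg.resnet_width, rng=rng)


def _to_nchw(images: np.ndarray, expect: tuple[int, int, int] | None = None) -> np.ndarray:
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[3] != 3:
        raise ValueError(f"expected (n, H, W, 3) images, got shape {x.shape}")
    if expect is not None and expect[0] and x.shape[1:] != tuple(expect):
        raise ValueError(f"image shape {x.shape[1:]} != training shape {tuple(expect)}")
    return np.transpose(x, (0, 3, 1, 2))


def train(
    images: np.ndarray,
    labels,
    cfg: ClassifierConfig,
    cell_ids: list[str] | None = None,
    train_frac: float = 0.7,
) -> TrainedClassifier:
    """Train a CNN on (n, H, W, 3) pseudo-images with per-cell labels.

    ``labels`` is a Series (single head) or a DataFrame whose column count
    matches ``cfg.heads``; rows are matched to images by ``cell_ids`` (or by
    position when omitted). An internal stratified split records train/test
    cell ids; reported test accuracy uses exact-match over heads.
    """
    df = _as_label_frame(labels)
    x_all = _to_nchw(images)
    n = x_all.shape[0]
    if cell_ids is None:
        cell_ids = [str(i) for i in df.index[:n]] if len(df) == n else [str(i) for i in range(n)]
        df = df.iloc[:n] if len(df) >= n else df
    df = df.loc[[str(c) for c in cell_ids]]
    if df.shape[1] != cfg.heads:
        raise ValueError(f"label columns ({df.shape[1]}) != cfg.heads ({cfg.heads})")
    class_names = [sorted(df[col].astype(str).unique()) for col in df.columns]
    for col, names in zip(df.columns, class_names):
        if len(names) < 2:
            raise ValueError(f"label column {col!r} has a single class")

    y = [
        df[col].astype(str).map({c: i for i, c in enumerate(names)}).to_numpy(int)
        for col, names in zip(df.columns, class_names)
    ]
    train_ids, test_ids = split_train_test(df, train_frac=train_frac, seed=cfg.seed)
    pos = {str(c): i for i, c in enumerate(cell_ids)}
    tr = np.array([pos[str(c)] for c in train_ids], dtype=int)
    te = np.array([pos[str(c)] for c in test_ids], dtype=int)

    net = _build_net(cfg, [len(c) for c in class_names])
    opt = nn.SGDMomentum(net, cfg.learning_rate, cfg.momentum, cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)

    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(tr))
        epoch_loss = 0.0
        n_correct = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = tr[order[start : start + cfg.batch_size]]
            xb = x_all[idx]
            logits = net.forward(xb, train=True)
            dlogits = []
            batch_loss = 0.0
            exact = np.ones(len(idx), dtype=bool)
            for h, lg in enumerate(logits):
                yb = y[h][idx]
                loss, grad = nn.softmax_xent(lg, yb)
                batch_loss += loss
                dlogits.append(grad)
                exact &= lg.argmax(axis=1) == yb
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lower the learning rate (lr={cfg.learning_rate})"
                )
            net.backward(dlogits)
            opt.step()
            epoch_loss += batch_loss * len(idx)
            n_correct += int(exact.sum())
        history.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / len(tr),
                "train_accuracy": n_correct / len(tr),
            }
        )
        logger.debug("epoch %d: loss=%.4f acc=%.3f", epoch, history[-1]["loss"],
                     history[-1]["train_accuracy"])

    clf = TrainedClassifier(
        net=net,
        class_names=class_names,
        label_columns=[str(c) for c in df.columns],
        config=cfg,
        history=pd.DataFrame(history),
        split={"train": [str(c) for c in train_ids], "test": [str(c) for c in test_ids]},
        input_shape=tuple(images.shape[1:]),
    )

    if len(te):
        pred = clf.predict_labels(x_to_hwc(x_all[te]))
        truth = df.iloc[te].astype(str).reset_index(drop=True)
        mode = "single" if cfg.heads == 1 else "exact-match-multilabel"
        clf.test_accuracy = accuracy(pred, truth, mode=mode)
    return clf


def x_to_hwc(x: np.ndarray) -> np.ndarray:
    return np.transpose(x, (0, 2, 3, 1))


def predict(clf: TrainedClassifier, images: np.ndarray) -> list[np.ndarray]:
    """Per-head softmax score matrices (rows on the simplex)."""
    return clf.predict_scores(images)


def accuracy(pred, truth, mode: str = "single") -> float:
    """Fraction of correct predictions.

    ``single`` compares one label column; ``exact-match-multilabel`` counts a
    cell correct only when every label column matches.
    """
    p = _as_label_frame(pred).astype(str).reset_index(drop=True)
    t = _as_label_frame(truth).astype(str).reset_index(drop=True)
    if len(p) != len(t):
        raise ValueError("prediction/truth length mismatch")
    if len(p) == 0:
        raise ValueError("empty input")
    if mode == "single":
        if p.shape[1] != 1 or t.shape[1] != 1:
            raise ValueError("single mode expects one label column")
        return float((p.iloc[:, 0].to_numpy() == t.iloc[:, 0].to_numpy()).mean())
    if mode == "exact-match-multilabel":
        ok = np.ones(len(p), dtype=bool)
        for col_p, col_t in zip(p.columns, t.columns):
            ok &= p[col_p].to_numpy() == t[col_t].to_numpy()
        return float(ok.mean())
    raise ValueError(f"unknown mode {mode!r}")


def confusion_matrix(pred, truth) -> pd.DataFrame:
    """Per-class confusion counts (rows = truth, cols = predicted)."""
    p = pd.Series(np.asarray(pred, dtype=object).ravel(), name="pred")
    t = pd.Series(np.asarray(truth, dtype=object).ravel(), name="truth")
    return pd.crosstab(t, p)
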