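"""Residual CNN tumor-type classifier and its training harness.

The downstream experiment trains a skip-connection classifier on real
(phantom) slices, optionally augmented with classic geometric transforms
and/or images sampled from the conditional generator, then evaluates it
as a confusion matrix.  ``resnet-small`` (three residual stages on a
stride-2 stem) is the desk default; ``resnet50-style`` stacks three
blocks per stage for full-scale runs.  Training uses categorical
cross-entropy with Adam (defaults: learning rate 1e-4, batch size 50).
"""

from __future__ import annotations

import csv
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .metrics import ConfusionMatrix
from .phantoms import CLASS_NAMES, LabeledDataset, augment_pixels

__all__ = ["build_classifier", "ResidualClassifier", "evaluate", "write_classifier_log"]

_ARCH_BLOCKS = {"resnet-small": 1, "resnet50-style": 3}


def build_classifier(architecture: str = "resnet-small", side: int = 32,
                     n_classes: int = 3, channels: Sequence[int] = (8, 16, 32),
                     dropout_rate: float = 0.0) -> nn.NetworkSpec:
    """Residual CNN NetworkSpec with a softmax-ready ``n_classes`` head.

    Topology: stride-2 stem convolution, then per stage an identity-skip
    residual block (two 3x3 convolutions) followed by a stride-2
    widening convolution between stages, a dropout layer, and a dense
    head.  Output of ``forward`` is logits; the estimator applies softmax.
    """
    if architecture not in _ARCH_BLOCKS:
        raise ValueError(f"unknown architecture {architecture!r}; "
                         f"expected one of {sorted(_ARCH_BLOCKS)}")
    blocks = _ARCH_BLOCKS[architecture]
    layers = [nn.conv2d(channels[0], kernel=3, stride=2), nn.relu()]
    for i, ch in enumerate(channels):
        for _ in range(blocks):
            layers.append(nn.residual([
                nn.conv2d(ch, kernel=3, stride=1), nn.relu(),
                nn.conv2d(ch, kernel=3, stride=1),
            ]))
            layers.append(nn.relu())
        if i + 1 < len(channels):
            layers += [nn.conv2d(channels[i + 1], kernel=3, stride=2), nn.relu()]
    if dropout_rate > 0:
        layers.append(nn.dropout(dropout_rate))
    layers += [nn.flatten(), nn.dense(n_classes)]
    return nn.NetworkSpec((side, side, 1), layers, name=f"classifier-{architecture}")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ResidualClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style residual CNN over square grayscale images.

    ``augment_classic`` applies random rotation/scaling to each training
    image on the fly; generated images are concatenated to the training
    set by passing ``generated=(images, labels)`` to ``fit``.

    Fitted attributes: ``network_``, ``train_log_`` (per-epoch loss,
    training accuracy, and validation accuracy when a validation set is
    supplied).
    """

    def __init__(self, architecture: str = "resnet-small", side: int = 32,
                 n_classes: int = 3, channels: Sequence[int] = (8, 16, 32),
                 epochs: int = 30, batch_size: int = 50, learning_rate: float = 1e-4,
                 dropout_rate: float = 0.0, augment_classic: bool = False,
                 random_state: int = 0):
        self.architecture = architecture
        self.side = side
        self.n_classes = n_classes
        self.channels = channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout_rate = dropout_rate
        self.augment_classic = augment_classic
        self.random_state = random_state

    def _coerce(self, X, y) -> Tuple[np.ndarray, np.ndarray]:
        if isinstance(X, LabeledDataset):
            return X.images(), X.label_indices()
        X = np.asarray(X, dtype=np.float64)
        if y is None:
            raise ValueError("y labels required when X is a raw array")
        return X, np.asarray(y, dtype=np.int64)

    def fit(self, X, y=None, val=None, val_y=None,
            generated: Optional[Tuple[np.ndarray, np.ndarray]] = None) -> "ResidualClassifier":
        images, labels = self._coerce(X, y)
        if images.shape[0] == 0:
            raise ValueError("cannot train a classifier on an empty dataset")
        if generated is not None:
            if isinstance(generated, LabeledDataset):
                g_img, g_lab = generated.images(), generated.label_indices()
            else:
                g_img, g_lab = generated
            images = np.concatenate([images, np.asarray(g_img, dtype=np.float64)])
            labels = np.concatenate([labels, np.asarray(g_lab, dtype=np.int64)])
        if val is not None:
            v_img, v_lab = self._coerce(val, val_y)
        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.arange(self.n_classes)
        self.network_ = build_classifier(self.architecture, self.side, self.n_classes,
                                         self.channels, self.dropout_rate).build(rng)
        opt = nn.Adam(self.network_.params, lr=self.learning_rate)
        n = images.shape[0]
        onehot = np.eye(self.n_classes)[labels]
        self.train_log_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            loss_sum = correct = 0
            for lo in range(0, n, self.batch_size):
                idx = order[lo: lo + self.batch_size]
                xb = images[idx]
                if self.augment_classic:
                    xb = np.stack([augment_pixels(im, rng) for im in xb])
                tb = onehot[idx]
                logits = self.network_.forward(xb[..., None], train=True, rng=rng)
                p = _softmax(logits)
                loss_sum += float(-np.log(np.clip(p[np.arange(len(idx)), labels[idx]],
                                                  1e-12, 1)).sum())
                correct += int((p.argmax(axis=1) == labels[idx]).sum())
                self.network_.backward((p - tb) / len(idx))
                opt.step(self.network_.grads)
            rec = {"epoch": epoch + 1, "loss": loss_sum / n, "train_acc": correct / n}
            if val is not None:
                rec["val_acc"] = float((self.predict(v_img) == v_lab).mean())
            self.train_log_.append(rec)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(getattr(X, "pixels", X), dtype=np.float64)
        if isinstance(X, np.ndarray) and X.ndim == 2:
            X = X[None]
        if hasattr(X, "images"):
            X = X.images()
        logits = self.network_.forward(np.asarray(X)[..., None])
        return _softmax(logits)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, LabeledDataset):
            X = X.images()
        # np.argmax breaks ties toward the lowest class index
        return np.argmax(self.predict_proba(X), axis=1)


def evaluate(clf, X, y=None, class_names: Sequence[str] = CLASS_NAMES) -> ConfusionMatrix:
    """Argmax predictions on a test set as a confusion matrix.

    Rows are true labels, columns predictions.
    """
    if isinstance(X, LabeledDataset):
        images, labels = X.images(), X.label_indices()
        class_names = X.class_names
    else:
        images, labels = np.asarray(X), np.asarray(y)
    if images.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty test set")
    pred = clf.predict(images)
    return ConfusionMatrix.from_labels(labels, pred, tuple(class_names))


def write_classifier_log(log, path) -> None:
    cols = list(log[0].keys()) if log else ["epoch", "loss", "train_acc"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        w.writerows(log)
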