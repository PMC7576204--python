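"""Training and evaluation of the attention classifier.

Protocol: a stratified random 80/20 trajectory split, Adam on the weighted
cross-entropy of the two-class softmax head, inverse-class-frequency sample
weights, and early stopping when the training loss stops improving.  All
randomness (split, weight initialization, batch order, dropout) derives from
one integer seed, so a run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import nn
from .errors import TrainingError, ValidationError
from .features import FeatureTensor
from .model import DeepHLNet, batch_tensors

__all__ = ["TrainConfig", "split", "train", "evaluate", "encode_labels"]


@dataclass(frozen=True)
class TrainConfig:
    test_fraction: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    early_stopping_patience: int = 10
    min_delta: float = 1e-4

    def validate(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValidationError("test_fraction must be in (0, 1)")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")


def encode_labels(labels: list[str]) -> tuple[np.ndarray, tuple]:
    """Map the two class labels (sorted) to integers 0/1."""
    classes = tuple(sorted(set(labels)))
    if len(classes) != 2:
        raise ValidationError(f"exactly two classes required, got {classes}")
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[l] for l in labels]), classes


def split(items: list, test_fraction: float, seed: int,
          labels: list[str] | None = None) -> tuple[list, list]:
    """Stratified random train/test split of trajectories or feature tensors.

    Stratification uses ``labels`` (default: each item's ``label`` attribute);
    both classes must appear in both parts.
    """
    if labels is None:
        labels = [it.label for it in items]
    y, classes = encode_labels(labels)
    for c in classes:
        if labels.count(c) < 2:
            raise ValidationError(f"class {c!r} needs >= 2 trajectories to split")
    idx = np.arange(len(items))
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=int(seed),
                              stratify=y, shuffle=True)
    for part, name in ((tr, "train"), (te, "test")):
        if len({labels[i] for i in part}) < 2:
            raise ValidationError(f"class missing from {name} split; adjust test_fraction")
    return [items[i] for i in sorted(tr)], [items[i] for i in sorted(te)]


def train(model: DeepHLNet, train_tensors: list[FeatureTensor],
          config: TrainConfig) -> pd.DataFrame:
    """Fit the model in place; returns a per-epoch history table.

    Columns: epoch, loss (mean weighted cross-entropy over minibatches) and
    train_accuracy (evaluation mode, dropout off).  Stops early when the loss
    has not improved by ``min_delta`` for ``early_stopping_patience`` epochs.
    """
    config.validate()
    if not train_tensors:
        raise ValidationError("empty training set")
    y, classes = encode_labels([ft.label for ft in train_tensors])
    model.class_labels = classes
    X, mask = batch_tensors(train_tensors)
    counts = np.bincount(y, minlength=2)
    class_w = len(y) / (2.0 * counts)  # inverse-frequency
    sample_w = class_w[y]
    rng = np.random.default_rng([int(config.seed), 0xA5A5A5])
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = []
    best, since_best = np.inf, 0
    n = len(y)
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, bs):
            sel = order[lo:lo + bs]
            out = model.forward(X[sel], mask[sel], training=True, rng=rng)
            loss = nn.cross_entropy_logits(out.logits, y[sel], sample_w[sel])
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}; "
                    "inspect learning rate / input standardization")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        epoch_loss = float(np.mean(losses))
        with nn.no_grad():
            pred = model.forward(X, mask).probabilities.argmax(axis=1)
        acc = float((pred == y).mean())
        history.append({"epoch": epoch, "loss": epoch_loss, "train_accuracy": acc})
        if epoch_loss < best - config.min_delta:
            best, since_best = epoch_loss, 0
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                break
    return pd.DataFrame(history, columns=["epoch", "loss", "train_accuracy"])


def evaluate(model: DeepHLNet, test_tensors: list[FeatureTensor]) -> tuple[float, pd.DataFrame]:
    """Held-out accuracy plus a per-trajectory prediction table.

    The table keeps predicted label and class-B probability so misclassified
    trajectories can be skipped when browsing highlights.
    """
    if not test_tensors:
        raise ValidationError("empty test set")
    out = model.predict(test_tensors)
    classes = model.class_labels
    pred_idx = out.probabilities.argmax(axis=1)
    rows = []
    for k, ft in enumerate(test_tensors):
        rows.append({
            "trajectory_id": ft.trajectory_id,
            "label": ft.label,
            "predicted": classes[pred_idx[k]],
            f"p_{classes[1]}": float(out.probabilities[k, 1]),
            "correct": classes[pred_idx[k]] == ft.label,
        })
    table = pd.DataFrame(rows)
    return float(table["correct"].mean()), table
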