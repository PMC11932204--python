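"""Four-branch multi-input convolutional classifier for target-site calls.

Each of the four 25x25 feature channels (duplex structure, DP scores, DP
substructure free energies, base-pair probabilities) is processed by its own
convolutional branch: three conv-ReLU-maxpool-dropout stages with 32, 64, and
128 filters and a uniform 3x3 kernel.  Size-preserving padding with 2x2
floor pooling takes each branch 25 -> 12 -> 6 -> 3 spatially.  The flattened
branch outputs are concatenated and passed through dense layers of 128 and
64 units, a dropout of 0.25, and a single sigmoid unit that outputs the
probability of binding.

Training is plain minibatch Adam on binary cross-entropy for exactly
``epochs`` epochs -- no early stopping -- recording per-epoch training loss
and validation AUPRC.  The classification threshold is chosen where the
precision and recall curves intersect on the validation split (falling back
to the training split), and is persisted with the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .pair_features import L, DuplexSample, pad_sequence
from .stacks import ChannelMinMaxScaler, build_stacks

__all__ = [
    "CNNConfig",
    "MultiInputCNNClassifier",
    "build_model",
    "train",
    "predict",
    "scan_utr",
    "grid_search_cnn",
]


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters of the multi-input network (defaults as tuned)."""

    conv_filters: tuple = (32, 64, 128)
    kernel: int = 3
    conv_dropout: float = 0.25
    dense_units: tuple = (128, 64)
    head_dropout: float = 0.25
    epochs: int = 20
    batch: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    scale_inputs: bool = True


class MultiInputCNNClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn style estimator over (n, 4, 25, 25) feature stacks."""

    def __init__(self, conv_filters=(32, 64, 128), kernel=3,
                 conv_dropout=0.25, dense_units=(128, 64), head_dropout=0.25,
                 epochs=20, batch_size=256, learning_rate=1e-3,
                 scale_inputs=True, random_state=None):
        self.conv_filters = conv_filters
        self.kernel = kernel
        self.conv_dropout = conv_dropout
        self.dense_units = dense_units
        self.head_dropout = head_dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.scale_inputs = scale_inputs
        self.random_state = random_state

    # -- architecture -------------------------------------------------------

    def _build(self, rng):
        side = L
        branches = []
        for _ in range(4):
            layers = []
            c_in = 1
            for f in self.conv_filters:
                layers += [nn.Conv2D(c_in, f, self.kernel, rng), nn.ReLU(),
                           nn.MaxPool2(), nn.Dropout(self.conv_dropout)]
                c_in = f
            layers.append(nn.Flatten())
            branches.append(nn.Sequential(layers))
        side = L
        for _ in self.conv_filters:
            side //= 2
        if side < 1:
            raise ValueError("too many pooling stages for a 25x25 input")
        feat = 4 * side * side * self.conv_filters[-1]
        head_layers = []
        n_in = feat
        for units in self.dense_units:
            head_layers += [nn.Dense(n_in, units, rng), nn.ReLU()]
            n_in = units
        head_layers += [nn.Dropout(self.head_dropout), nn.Dense(n_in, 1, rng)]
        head = nn.Sequential(head_layers)
        self.branches_ = branches
        self.head_ = head
        self.branch_feat_ = feat // 4
        self.n_parameters_ = int(sum(
            p.value.size for l in branches + [head] for p in l.params()))

    def _params(self):
        return [p for l in self.branches_ + [self.head_] for p in l.params()]

    def _forward(self, X, training=False, rng=None):
        feats = [br.forward(X[:, b:b + 1], training=training, rng=rng)
                 for b, br in enumerate(self.branches_)]
        concat = np.concatenate(feats, axis=1)
        logits = self.head_.forward(concat, training=training, rng=rng)
        return logits[:, 0]

    def _backward(self, grad):
        dconcat = self.head_.backward(grad[:, None])
        f = self.branch_feat_
        for b, br in enumerate(self.branches_):
            br.backward(dconcat[:, b * f:(b + 1) * f])

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 4 or X.shape[1:] != (4, L, L):
            raise ValueError(f"X must have shape (n, 4, {L}, {L})")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training split contains a single class")
        self.classes_ = classes
        rng = np.random.default_rng(self.random_state)
        self._build(rng)
        self.scaler_ = ChannelMinMaxScaler(enabled=self.scale_inputs).fit(X)
        Xs = self.scaler_.transform(X)
        val = None
        if validation_data is not None:
            Xv, yv = validation_data
            val = (self.scaler_.transform(np.asarray(Xv, dtype=np.float64)),
                   np.asarray(yv))
        opt = nn.Adam(self._params(), lr=self.learning_rate)
        n = len(y)
        history = {"loss": [], "val_auprc": []}
        from .evaluation import auprc, optimal_threshold, pr_curve

        for _ in range(self.epochs):  # exactly cfg.epochs; no early stopping
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                opt.zero_grad()
                logits = self._forward(Xs[idx], training=True, rng=rng)
                loss, grad, _ = nn.bce_loss_and_grad(logits, y[idx])
                self._backward(grad)
                opt.step()
                epoch_loss += loss * len(idx)
            history["loss"].append(epoch_loss / n)
            if val is not None:
                pv = nn.sigmoid(self._forward(val[0]))
                history["val_auprc"].append(auprc(pr_curve(val[1], pv)))
        self.history_ = history
        # threshold at the precision/recall intersection
        if val is not None and len(np.unique(val[1])) == 2:
            curve = pr_curve(val[1], nn.sigmoid(self._forward(val[0])))
        else:
            curve = pr_curve(y, nn.sigmoid(self._forward(Xs)))
        self.threshold_, self.threshold_metrics_ = optimal_threshold(curve)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self.scaler_.transform(np.asarray(X, dtype=np.float64))
        if X.ndim != 4 or X.shape[1:] != (4, L, L):
            raise ValueError(f"X must have shape (n, 4, {L}, {L})")
        probs = []
        for start in range(0, len(X), 512):
            probs.append(nn.sigmoid(self._forward(X[start:start + 512])))
        p = np.concatenate(probs) if probs else np.zeros(0)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold_).astype(int)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.value for i, p in enumerate(self._params())}
        np.savez(path / "parameters.npz", **arrays)
        (path / "config.json").write_text(json.dumps({
            "conv_filters": list(self.conv_filters),
            "kernel": self.kernel,
            "conv_dropout": self.conv_dropout,
            "dense_units": list(self.dense_units),
            "head_dropout": self.head_dropout,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "scale_inputs": self.scale_inputs,
            "random_state": self.random_state,
            "threshold": self.threshold_,
            "history": self.history_,
        }, indent=1))
        (path / "scaler.json").write_text(self.scaler_.to_json())

    @classmethod
    def load(cls, path) -> "MultiInputCNNClassifier":
        path = Path(path)
        cfg = json.loads((path / "config.json").read_text())
        model = cls(
            conv_filters=tuple(cfg["conv_filters"]), kernel=cfg["kernel"],
            conv_dropout=cfg["conv_dropout"],
            dense_units=tuple(cfg["dense_units"]),
            head_dropout=cfg["head_dropout"], epochs=cfg["epochs"],
            batch_size=cfg["batch_size"],
            learning_rate=cfg["learning_rate"],
            scale_inputs=cfg["scale_inputs"],
            random_state=cfg["random_state"])
        model._build(np.random.default_rng(0))
        with np.load(path / "parameters.npz") as z:
            for i, p in enumerate(model._params()):
                p.value[...] = z[f"p{i}"]
        model.scaler_ = ChannelMinMaxScaler.from_json(
            (path / "scaler.json").read_text())
        model.threshold_ = cfg["threshold"]
        model.history_ = cfg["history"]
        model.classes_ = np.array([0.0, 1.0])
        return model


# ---------------------------------------------------------------------------
# functional wrappers


def build_model(cfg: CNNConfig) -> MultiInputCNNClassifier:
    """An untrained classifier configured from a :class:`CNNConfig`."""
    return MultiInputCNNClassifier(
        conv_filters=cfg.conv_filters, kernel=cfg.kernel,
        conv_dropout=cfg.conv_dropout, dense_units=cfg.dense_units,
        head_dropout=cfg.head_dropout, epochs=cfg.epochs,
        batch_size=cfg.batch, learning_rate=cfg.learning_rate,
        scale_inputs=cfg.scale_inputs, random_state=cfg.seed)


def train(model: MultiInputCNNClassifier, train_stacks, train_labels,
          val_stacks=None, val_labels=None) -> MultiInputCNNClassifier:
    val = None if val_stacks is None else (val_stacks, val_labels)
    return model.fit(train_stacks, train_labels, validation_data=val)


def predict(model: MultiInputCNNClassifier, stacks) -> np.ndarray:
    """Binding probabilities, one per sample."""
    return model.predict_proba(stacks)[:, 1]


def scan_utr(model: MultiInputCNNClassifier, mic: str, utr: str, sd, turner,
             step: int = 1):
    """Slide a 25-nt window across a 3'UTR and score every window.

    Returns a list of ``(start, end, probability, call)`` records with
    0-based half-open coordinates on the given UTR string; calls use the
    model's stored threshold.
    """
    if len(utr) < L:
        raise ValueError(f"UTR shorter than the {L}-nt window: {len(utr)}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    mic25 = pad_sequence(mic)
    starts = list(range(0, len(utr) - L + 1, step))
    samples = [DuplexSample(mic=mic25, cts=utr[s:s + L], label=0,
                            id=f"win@{s}") for s in starts]
    stacks = build_stacks(samples, sd, turner)
    probs = predict(model, stacks)
    thr = model.threshold_
    return [(s, s + L, float(p), int(p >= thr))
            for s, p in zip(starts, probs)]


def grid_search_cnn(train_stacks, train_labels, val_stacks, val_labels,
                    epoch_grid=(5, 20, 30, 40),
                    batch_grid=(32, 64, 128, 256, 512),
                    seed=0, **model_kwargs):
    """Grid search over (epochs, batch size) by validation AUPRC."""
    from .evaluation import auprc, pr_curve

    results = {}
    best = None
    for epochs in sorted(epoch_grid):
        for batch in sorted(batch_grid):
            model = MultiInputCNNClassifier(
                epochs=epochs, batch_size=batch, random_state=seed,
                **model_kwargs)
            model.fit(train_stacks, train_labels,
                      validation_data=(val_stacks, val_labels))
            score = auprc(pr_curve(val_labels, predict(model, val_stacks)))
            results[(epochs, batch)] = score
            if best is None or score > best[0]:
                best = (score, (epochs, batch), model)
    return best[1], best[2], results
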