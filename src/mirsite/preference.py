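"""Learned base-pairing preferences of microRNA/target-site duplexes.

A single-neuron network (logistic regression over the 24,450 binary pairing
features, sigmoid output, binary cross-entropy loss) is trained to separate
validated target sites from decoys.  Its weights, one per feature, quantify
how strongly each positioned single/double/triple canonical pairing run is
associated with true targeting; they are then consumed by the duplex dynamic
program as its scoring dictionary.

The estimator follows scikit-learn conventions (``fit`` / ``predict_proba``,
``coef_`` / ``intercept_`` / ``loss_curve_``), with explicit minibatch Adam so
that epoch count, batch size, and seed are first-class, reproducible knobs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from . import pair_features as pf
from .constants import CANONICAL_PAIRS

__all__ = [
    "DuplexFeatureEncoder",
    "PairingPreferenceClassifier",
    "ScoreDict",
    "train_preference",
    "grid_search_preference",
    "score_lookup",
    "top_k_weights",
    "save_weights",
    "load_weights",
]

_TYPE_INDEX = {p: t for t, p in enumerate(CANONICAL_PAIRS)}


class DuplexFeatureEncoder(BaseEstimator, TransformerMixin):
    """Stateless transformer: duplex samples -> (n, 24450) binary matrix."""

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        out = np.zeros((len(X), pf.N_FEATURES), dtype=np.float32)
        for row, s in enumerate(X):
            mic, cts = (s.mic, s.cts) if isinstance(s, pf.DuplexSample) else s
            idx = pf.encode_indices(mic, cts)
            if idx:
                out[row, np.asarray(idx)] = 1.0
        return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class PairingPreferenceClassifier(BaseEstimator, ClassifierMixin):
    """Single-neuron pairing-preference network.

    Parameters
    ----------
    epochs, batch_size : int
        Training schedule; no early stopping is applied.
    learning_rate : float
        Adam step size.
    class_weight : None or "balanced"
        Optional reweighting of the minority class (off by default).
    random_state : int or None
        Seed for minibatch shuffling; weights start at zero, so the fit is
        fully reproducible given identical data, config, and seed.
    """

    def __init__(self, epochs: int = 5, batch_size: int = 128,
                 learning_rate: float = 1e-3, class_weight=None,
                 random_state=None):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(
                "training data contains a single class; both target and "
                "non-target samples are required")
        self.classes_ = classes
        n, d = X.shape
        self.n_features_in_ = d
        sw = np.ones(n)
        if self.class_weight == "balanced":
            for c in classes:
                sw[y == c] = n / (2.0 * np.sum(y == c))
        rng = np.random.default_rng(self.random_state)
        w = np.zeros(d)
        b = 0.0
        # Adam state
        mw = np.zeros(d); vw = np.zeros(d); mb = 0.0; vb = 0.0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        losses = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X[idx]
                yb = y[idx]
                wb = sw[idx]
                p = _sigmoid(xb @ w + b)
                err = (p - yb) * wb
                gw = xb.T @ err / len(idx)
                gb = float(np.mean(err))
                step += 1
                mw = beta1 * mw + (1 - beta1) * gw
                vw = beta2 * vw + (1 - beta2) * gw * gw
                mb = beta1 * mb + (1 - beta1) * gb
                vb = beta2 * vb + (1 - beta2) * gb * gb
                corr1 = 1 - beta1 ** step
                corr2 = 1 - beta2 ** step
                w -= self.learning_rate * (mw / corr1) / (np.sqrt(vw / corr2) + eps)
                b -= self.learning_rate * (mb / corr1) / (np.sqrt(vb / corr2) + eps)
                pc = np.clip(p, 1e-12, 1 - 1e-12)
                epoch_loss += float(
                    -np.sum(wb * (yb * np.log(pc) + (1 - yb) * np.log(1 - pc))))
            losses.append(epoch_loss / n)
        self.coef_ = w
        self.intercept_ = b
        self.loss_curve_ = losses
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=np.float32) @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        p = _sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def to_score_dict(self) -> "ScoreDict":
        """Expose the learned feature weights as the DP scoring dictionary."""
        return ScoreDict(self.coef_)


class ScoreDict:
    """Lookup from (run end position, pair-type run) to a learned weight.

    The view excludes the bias: a constant offset per match would distort the
    structure maximization.  Double/triple runs whose start offset d = j - i
    lies outside the feature window (|d| > 2 for doubles, |d| > 1 for
    triples) have no dedicated feature; they score as the sum of their
    constituent single-pair weights, which exist for every (i, j).
    """

    def __init__(self, weights: np.ndarray):
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (pf.N_FEATURES,):
            raise ValueError(
                f"expected {pf.N_FEATURES} weights, got {weights.shape}")
        self.weights = weights
        # dense views for the DP: singles[i, j, t]
        self.singles = weights[: pf.N_SINGLE].reshape(pf.L, pf.L, 6)
        self.doubles = weights[pf.N_SINGLE: pf.N_SINGLE + pf.N_DOUBLE].reshape(
            pf.L, 5, 6, 6)
        self.triples = weights[pf.N_SINGLE + pf.N_DOUBLE:].reshape(
            pf.L, 3, 6, 6, 6)

    @classmethod
    def uniform(cls, value: float = 1.0) -> "ScoreDict":
        """Neutral dictionary: every single-pair weight equals ``value``.

        Doubles/triples carry no dedicated weight and fall back to sums of
        singles, so each matched base pair contributes exactly ``value``.
        """
        w = np.zeros(pf.N_FEATURES)
        w[: pf.N_SINGLE] = value
        return cls(w)

    @classmethod
    def run_biased(cls, triple_weight: float = 6.0,
                   penalty: float = -9.0) -> "ScoreDict":
        """Neutral pre-training dictionary favoring contiguous pairing runs.

        Only near-diagonal triple runs carry positive weight; isolated and
        double pairings are penalized, so the DP predicts helix-like
        structures.  Used where a scoring dictionary is needed before any
        preferences have been learned (e.g. filtering decoy windows for
        thermodynamic plausibility).
        """
        w = np.full(pf.N_FEATURES, penalty)
        w[pf.N_SINGLE + pf.N_DOUBLE:] = triple_weight
        return cls(w)

    def lookup(self, i: int, j: int, run) -> float:
        """Weight of a run of 1-3 pair types ending at positions (i, j)."""
        k = len(run)
        if not 1 <= k <= 3:
            raise ValueError(f"run length must be 1-3, got {k}")
        if not (0 <= i < pf.L and 0 <= j < pf.L):
            raise ValueError(f"positions out of range: ({i}, {j})")
        ts = [_TYPE_INDEX[t] for t in run]
        i0, j0 = i - k + 1, j - k + 1
        if i0 < 0 or j0 < 0:
            raise ValueError(f"run of length {k} does not fit ending at ({i}, {j})")
        d = j0 - i0
        if k == 1:
            return float(self.singles[i, j, ts[0]])
        if k == 2 and -2 <= d <= 2:
            return float(self.doubles[i0, d + 2, ts[0], ts[1]])
        if k == 3 and -1 <= d <= 1:
            return float(self.triples[i0, d + 1, ts[0], ts[1], ts[2]])
        # out-of-window fallback: sum of constituent single-pair weights
        return float(sum(self.singles[i0 + a, j0 + a, ts[a]] for a in range(k)))


def score_lookup(sd: ScoreDict, i: int, j: int, run) -> float:
    """Functional form of :meth:`ScoreDict.lookup`."""
    return sd.lookup(i, j, run)


def train_preference(samples, epochs: int = 5, batch: int = 128,
                     seed: int = 0, learning_rate: float = 1e-3,
                     class_weight=None) -> PairingPreferenceClassifier:
    """Fit the single-neuron preference network on duplex samples."""
    X = DuplexFeatureEncoder().transform(samples)
    y = np.array([s.label for s in samples])
    model = PairingPreferenceClassifier(
        epochs=epochs, batch_size=batch, learning_rate=learning_rate,
        class_weight=class_weight, random_state=seed)
    return model.fit(X, y)


def grid_search_preference(samples, validation,
                           epoch_grid=(5, 10, 20, 30, 40),
                           batch_grid=(32, 64, 128, 256),
                           seed: int = 0, learning_rate: float = 1e-3):
    """Grid search over (epochs, batch size), selected by validation AUPRC.

    Ties break toward smaller epochs, then smaller batch size.  Returns
    ``(best_config, best_model, results)`` where results maps each grid
    point to its validation AUPRC.
    """
    from .evaluation import auprc, pr_curve

    if not len(epoch_grid) or not len(batch_grid):
        raise ValueError("epoch and batch grids must be non-empty")
    if not len(validation):
        raise ValueError("validation set must be non-empty")
    Xtr = DuplexFeatureEncoder().transform(samples)
    ytr = np.array([s.label for s in samples])
    Xva = DuplexFeatureEncoder().transform(validation)
    yva = np.array([s.label for s in validation])
    results = {}
    best = None
    for epochs in sorted(epoch_grid):
        for batch in sorted(batch_grid):
            model = PairingPreferenceClassifier(
                epochs=epochs, batch_size=batch,
                learning_rate=learning_rate, random_state=seed)
            model.fit(Xtr, ytr)
            score = auprc(pr_curve(yva, model.predict_proba(Xva)[:, 1]))
            results[(epochs, batch)] = score
            if best is None or score > best[0]:
                best = (score, (epochs, batch), model)
    return best[1], best[2], results


def top_k_weights(weights, k: int = 100):
    """The k largest weights with their decoded (kind, i, j, types) runs."""
    weights = np.asarray(weights)
    order = np.argsort(weights)[::-1][:k]
    return [(int(i), float(weights[i]), pf.decode_feature(int(i)))
            for i in order]


def save_weights(model: PairingPreferenceClassifier, path) -> None:
    """Persist weights as two-column text plus a JSON metadata sidecar."""
    path = Path(path)
    lines = ["index\tweight"]
    for i, w in enumerate(model.coef_):
        lines.append(f"{i}\t{float(w)!r}")
    path.write_text("\n".join(lines) + "\n")
    meta = {
        "intercept": model.intercept_,
        "epochs": model.epochs,
        "batch_size": model.batch_size,
        "learning_rate": model.learning_rate,
        "random_state": model.random_state,
        "loss_curve": getattr(model, "loss_curve_", None),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_weights(path) -> ScoreDict:
    """Load a persisted weight file into a ScoreDict."""
    w = np.zeros(pf.N_FEATURES)
    for line in Path(path).read_text().splitlines()[1:]:
        i, val = line.split("\t")
        w[int(i)] = float(val)
    return ScoreDict(w)
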