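"""Four-channel 25x25 input matrices for the classifier.

For each microRNA / candidate-site pair the stack holds, with microRNA
positions on rows and site positions on columns:

* ``mx1`` -- duplex structure matrix: the rRNA-derived pair probability at
  every (r, c) the predicted structure pairs, 0 elsewhere;
* ``dps`` -- the DP cumulative score table S1 (optimal substructure weight
  for every pair of prefixes);
* ``dpm`` -- the DP substructure free-energy table MFE1 (kcal/mol);
* ``bp`` -- the full base-pair probability matrix over all (r, c), canonical
  and non-canonical; pad rows/columns are 0.

Raw channels have incompatible ranges (probabilities in [0, 1], energies of
roughly -40..+5 kcal/mol, unbounded DP weights), so an optional per-channel
min-max scaler, fitted on training data only and persisted with the model,
maps each channel to [0, 1].  Disabling it restores raw inputs.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import BasePairProbTable, TurnerParams
from .duplex import backtrack, fill_tables
from .pair_features import L, DuplexSample
from .preference import ScoreDict

__all__ = [
    "build_stack",
    "build_stacks",
    "ChannelMinMaxScaler",
    "write_stacks",
    "read_stacks",
    "export_matrix_tsv",
    "CHANNELS",
]

CHANNELS = ("mx1", "dps", "dpm", "bp")


def build_stack(sample: DuplexSample, sd: ScoreDict, turner: TurnerParams,
                bp_table: BasePairProbTable | None = None) -> np.ndarray:
    """The (4, 25, 25) feature stack of one sample."""
    if bp_table is None:
        from .constants import default_bp_table
        bp_table = default_bp_table()
    tables = fill_tables(sample.mic, sample.cts, sd, turner)
    structure = backtrack(tables)
    stack = np.zeros((4, L, L), dtype=np.float32)
    for r, c, _ in structure.pairs:
        stack[0, r, c] = bp_table(sample.mic[r], sample.cts[c])
    stack[1] = tables.S1
    stack[2] = tables.MFE1
    for r in range(L):
        for c in range(L):
            stack[3, r, c] = bp_table(sample.mic[r], sample.cts[c])
    return stack


def build_stacks(samples, sd: ScoreDict, turner: TurnerParams,
                 bp_table: BasePairProbTable | None = None) -> np.ndarray:
    """Stacks for a collection of samples, shape (n, 4, 25, 25)."""
    return np.stack([build_stack(s, sd, turner, bp_table) for s in samples]) \
        if len(samples) else np.zeros((0, 4, L, L), dtype=np.float32)


class ChannelMinMaxScaler(BaseEstimator, TransformerMixin):
    """Per-channel affine min-max map over (n, 4, 25, 25) stacks.

    A channel that is constant on the fit data keeps an identity map (with a
    warning).  With ``enabled=False`` the transform is a bit-identical
    pass-through.
    """

    def __init__(self, enabled: bool = True):
        self.enabled = enabled

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[0] < 1:
            raise ValueError("need at least one stack of shape (4, 25, 25)")
        self.min_ = X.min(axis=(0, 2, 3))
        self.max_ = X.max(axis=(0, 2, 3))
        degenerate = self.max_ == self.min_
        if np.any(degenerate) and self.enabled:
            warnings.warn(
                f"constant channel(s) {np.nonzero(degenerate)[0].tolist()}: "
                "identity map kept", stacklevel=2)
        self.scale_ = np.where(degenerate, 1.0, self.max_ - self.min_)
        self.shift_ = np.where(degenerate, 0.0, self.min_)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        if not self.enabled:
            return X
        return ((X - self.shift_[None, :, None, None])
                / self.scale_[None, :, None, None]).astype(X.dtype)

    def to_json(self) -> str:
        return json.dumps({
            "enabled": self.enabled,
            "min": self.min_.tolist(), "max": self.max_.tolist(),
            "scale": self.scale_.tolist(), "shift": self.shift_.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "ChannelMinMaxScaler":
        d = json.loads(text)
        obj = cls(enabled=d["enabled"])
        obj.min_ = np.asarray(d["min"])
        obj.max_ = np.asarray(d["max"])
        obj.scale_ = np.asarray(d["scale"])
        obj.shift_ = np.asarray(d["shift"])
        return obj


def write_stacks(path, ids, labels, stacks) -> None:
    """Single-file archive of ids, labels, and stacks (lossless)."""
    np.savez_compressed(
        path, ids=np.asarray(ids, dtype=object),
        labels=np.asarray(labels, dtype=np.int8),
        stacks=np.asarray(stacks, dtype=np.float32))


def read_stacks(path):
    """Inverse of :func:`write_stacks`; returns (ids, labels, stacks)."""
    with np.load(path, allow_pickle=True) as z:
        return list(z["ids"]), z["labels"].astype(int), z["stacks"]


def export_matrix_tsv(stack: np.ndarray, channel: str, path) -> None:
    """Write one 25x25 channel of a stack as a TSV matrix for inspection."""
    idx = CHANNELS.index(channel)
    np.savetxt(path, np.asarray(stack)[idx], delimiter="\t", fmt="%.9g")
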