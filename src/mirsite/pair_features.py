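"""Binary pairing features of a microRNA / candidate-target-site duplex.

A sample is a 25-symbol microRNA string aligned against a 25-symbol candidate
target site (CTS), both over {A, C, G, U, pad}.  The feature vector indicates
every possible single, double, and triple run of canonical base pairs
(AU, CG, GC, GU, UA, UG; the microRNA base is written first):

* singles: any microRNA position i against any site position j
  (25 * 25 * 6 = 3750 features);
* doubles: two consecutive pairs starting at microRNA position i and site
  position j = i + d with offset d in [-2, 2] (25 * 5 * 36 = 4500);
* triples: three consecutive pairs with offset d in [-1, 1]
  (25 * 3 * 216 = 16200).

Total: 24,450 bits.  A bit is set iff every constituent position is in range,
none is the pad symbol, and each aligned position pair forms the named
canonical type.  Runs that would extend past position 24 on either strand are
simply infeasible: their index exists but the bit is permanently 0, keeping
the index space at the full printed size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CANONICAL_PAIRS, NUCLEOTIDES, PAD

__all__ = [
    "L",
    "DuplexSample",
    "canonical_pair_type",
    "encode_features",
    "encode_indices",
    "feature_count",
    "decode_feature",
    "pad_sequence",
    "read_samples_tsv",
    "write_samples_tsv",
]

#: Fixed aligned length of microRNA and candidate target site.
L = 25

N_SINGLE = L * L * 6            # 3750
N_DOUBLE = L * 5 * 36           # 4500
N_TRIPLE = L * 3 * 216          # 16200
N_FEATURES = N_SINGLE + N_DOUBLE + N_TRIPLE
DOUBLE_OFFSET = N_SINGLE
TRIPLE_OFFSET = N_SINGLE + N_DOUBLE

_TYPE_INDEX = {p: t for t, p in enumerate(CANONICAL_PAIRS)}
_ALPHABET = set(NUCLEOTIDES) | {PAD}


def _validate_seq(seq: str, name: str) -> None:
    if len(seq) != L:
        raise ValueError(f"{name} must have length {L}, got {len(seq)}")
    for pos, sym in enumerate(seq):
        if sym not in _ALPHABET:
            raise ValueError(
                f"{name} has invalid symbol {sym!r} at position {pos}")
    core = seq.rstrip(PAD)
    if PAD in core:
        raise ValueError(f"{name} has pad symbols before the 3' end")


def pad_sequence(seq: str) -> str:
    """Right-pad a sequence to the fixed aligned length of 25."""
    if len(seq) > L:
        raise ValueError(f"sequence longer than {L}: {len(seq)}")
    return seq + PAD * (L - len(seq))


@dataclass(frozen=True)
class DuplexSample:
    """One microRNA paired with a 25-nt candidate target site."""

    mic: str
    cts: str
    label: int = 0
    id: str = ""

    def __post_init__(self):
        _validate_seq(self.mic, "mic")
        _validate_seq(self.cts, "cts")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def canonical_pair_type(x: str, y: str) -> str | None:
    """Ordered canonical pair type of (microRNA base, site base), or None."""
    pair = x + y
    return pair if pair in _TYPE_INDEX else None


def feature_count() -> tuple[int, int, int, int]:
    """Block sizes (singles, doubles, triples) and the grand total."""
    return (N_SINGLE, N_DOUBLE, N_TRIPLE, N_FEATURES)


def single_index(i: int, j: int, t: int) -> int:
    return i * (L * 6) + j * 6 + t


def double_index(i: int, d: int, t1: int, t2: int) -> int:
    return DOUBLE_OFFSET + i * (5 * 36) + (d + 2) * 36 + t1 * 6 + t2


def triple_index(i: int, d: int, t1: int, t2: int, t3: int) -> int:
    return TRIPLE_OFFSET + i * (3 * 216) + (d + 1) * 216 + t1 * 36 + t2 * 6 + t3


def decode_feature(index: int):
    """Inverse of the index layout.

    Returns ``("single", i, j, (type,))``, ``("double", i, j, (t1, t2))`` or
    ``("triple", i, j, (t1, t2, t3))`` where (i, j) is the run start on the
    microRNA / site and types are pair-type strings.
    """
    if not 0 <= index < N_FEATURES:
        raise ValueError(f"feature index out of range: {index}")
    if index < DOUBLE_OFFSET:
        i, rem = divmod(index, L * 6)
        j, t = divmod(rem, 6)
        return ("single", i, j, (CANONICAL_PAIRS[t],))
    if index < TRIPLE_OFFSET:
        rem = index - DOUBLE_OFFSET
        i, rem = divmod(rem, 5 * 36)
        d, rem = divmod(rem, 36)
        t1, t2 = divmod(rem, 6)
        return ("double", i, i + d - 2,
                (CANONICAL_PAIRS[t1], CANONICAL_PAIRS[t2]))
    rem = index - TRIPLE_OFFSET
    i, rem = divmod(rem, 3 * 216)
    d, rem = divmod(rem, 216)
    t1, rem = divmod(rem, 36)
    t2, t3 = divmod(rem, 6)
    return ("triple", i, i + d - 1,
            (CANONICAL_PAIRS[t1], CANONICAL_PAIRS[t2], CANONICAL_PAIRS[t3]))


def _pair_type_grid(mic: str, cts: str) -> list[list[int]]:
    # type index per (i, j), -1 where non-canonical or pad
    grid = [[-1] * L for _ in range(L)]
    for i, x in enumerate(mic):
        if x == PAD:
            continue
        for j, y in enumerate(cts):
            t = _TYPE_INDEX.get(x + y, -1)
            grid[i][j] = t
    return grid


def encode_indices(mic: str, cts: str) -> list[int]:
    """Sorted indices of the set bits of the 24,450-bit feature vector."""
    _validate_seq(mic, "mic")
    _validate_seq(cts, "cts")
    grid = _pair_type_grid(mic, cts)
    out: list[int] = []
    for i in range(L):
        row = grid[i]
        for j in range(L):
            if row[j] >= 0:
                out.append(single_index(i, j, row[j]))
    for i in range(L - 1):
        for d in range(-2, 3):
            j = i + d
            if 0 <= j and j + 1 < L:
                t1 = grid[i][j]
                t2 = grid[i + 1][j + 1]
                if t1 >= 0 and t2 >= 0:
                    out.append(double_index(i, d, t1, t2))
    for i in range(L - 2):
        for d in range(-1, 2):
            j = i + d
            if 0 <= j and j + 2 < L:
                t1 = grid[i][j]
                t2 = grid[i + 1][j + 1]
                t3 = grid[i + 2][j + 2]
                if t1 >= 0 and t2 >= 0 and t3 >= 0:
                    out.append(triple_index(i, d, t1, t2, t3))
    return sorted(out)


def encode_features(sample: DuplexSample) -> np.ndarray:
    """The 24,450-bit binary feature vector of a duplex sample."""
    vec = np.zeros(N_FEATURES, dtype=np.uint8)
    idx = encode_indices(sample.mic, sample.cts)
    if idx:
        vec[np.asarray(idx)] = 1
    return vec


# ---------------------------------------------------------------------------
# sample table I/O (TSV with '#' comments; pad written as '-')


def write_samples_tsv(samples, path) -> None:
    df = pd.DataFrame(
        {
            "id": [s.id for s in samples],
            "mic_seq": [s.mic for s in samples],
            "cts_seq": [s.cts for s in samples],
            "label": [s.label for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> list[DuplexSample]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"id": str, "mic_seq": str, "cts_seq": str})
    return [
        DuplexSample(mic=row.mic_seq, cts=row.cts_seq,
                     label=int(row.label), id=row.id)
        for row in df.itertuples()
    ]
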