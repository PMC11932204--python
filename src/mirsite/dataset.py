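"""Sample construction: positives, thermodynamically plausible decoys,
deduplication, stratified splitting, and a synthetic corpus generator.

Positives pair a microRNA with the 25-nt window of the 3'UTR at the
validated binding location.  Negatives ("decoys") are up to ``max_n``
randomly chosen non-overlapping 25-nt windows of the same 3'UTR, disjoint
from the positive site, retained only when the predicted duplex with the
microRNA has dG37 < 0 -- thermodynamically feasible windows that are not
true sites, the hard negatives a detector must reject.  The dG filter is
computed with this package's own duplex predictor and nearest-neighbor
energy model.

The synthetic corpus emulates that construction without any downloads:
random microRNAs (20-25 nt), UTRs carrying one implanted site per positive
(complementary to the microRNA seed, positions 1-7, plus -- with probability
0.5 -- a 3'-compensatory motif complementary to positions 21-24, and 0-2
mismatches elsewhere), and decoy windows drawn by the same negative
generator.  Implant coordinates are recorded as ground truth for
localization tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .constants import TurnerParams, default_turner
from .duplex import predict_duplex
from .pair_features import L, DuplexSample, pad_sequence
from .preference import ScoreDict

__all__ = [
    "CorpusRecord",
    "SplitSpec",
    "extract_positive",
    "generate_negatives",
    "deduplicate",
    "stratified_split",
    "synth_corpus",
    "read_fasta",
    "write_fasta",
    "write_truth_tsv",
]

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class CorpusRecord:
    """One microRNA / 3'UTR pair, with the validated site for positives."""

    mic_id: str
    mic_seq: str
    utr_id: str
    utr_seq: str
    site_start: int | None = None

    def __post_init__(self):
        if not 18 <= len(self.mic_seq) <= L:
            raise ValueError(
                f"microRNA length must be in [18, {L}], got {len(self.mic_seq)}")
        if len(self.utr_seq) < L:
            raise ValueError(f"UTR must be at least {L} nt")
        if self.site_start is not None and not (
                0 <= self.site_start <= len(self.utr_seq) - L):
            raise ValueError(
                f"site window [{self.site_start}, {self.site_start + L}) "
                f"outside UTR of length {len(self.utr_seq)}")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (must sum to 1) and a seed."""

    fractions: tuple = (0.70, 0.10, 0.20)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1: {self.fractions}")


def extract_positive(rec: CorpusRecord) -> DuplexSample:
    """The labeled positive sample at the record's validated site."""
    if rec.site_start is None:
        raise ValueError("record has no validated site")
    cts = rec.utr_seq[rec.site_start: rec.site_start + L]
    return DuplexSample(mic=pad_sequence(rec.mic_seq), cts=cts, label=1,
                        id=f"{rec.mic_id}|{rec.utr_id}|pos@{rec.site_start}")


def generate_negatives(rec: CorpusRecord, sd: ScoreDict | None = None,
                       turner: TurnerParams | None = None,
                       max_n: int = 10, seed: int = 0) -> list[DuplexSample]:
    """Up to ``max_n`` decoy windows with predicted duplex dG37 < 0.

    Windows are sampled without replacement from all offsets, shuffled under
    the seed, accepted greedily if they do not overlap the positive site or
    any previously accepted window, and pass the energy filter.  May return
    fewer than ``max_n`` (including zero).
    """
    if sd is None:
        sd = ScoreDict.run_biased()
    if turner is None:
        turner = default_turner()
    rng = np.random.default_rng(seed)
    mic25 = pad_sequence(rec.mic_seq)
    candidates = list(range(0, len(rec.utr_seq) - L + 1))
    rng.shuffle(candidates)
    taken: list[int] = []
    if rec.site_start is not None:
        taken.append(rec.site_start)
    out: list[DuplexSample] = []
    for start in candidates:
        if len(out) >= max_n:
            break
        if any(abs(start - t) < L for t in taken):
            continue
        cts = rec.utr_seq[start:start + L]
        structure = predict_duplex(mic25, cts, sd, turner)
        if structure.dg37 < 0:
            taken.append(start)
            out.append(DuplexSample(
                mic=mic25, cts=cts, label=0,
                id=f"{rec.mic_id}|{rec.utr_id}|neg@{start}"))
    return out


def deduplicate(samples) -> list[DuplexSample]:
    """Collapse exact (mic, cts, label) duplicates, keeping first occurrence."""
    seen = set()
    out = []
    for s in samples:
        key = (s.mic, s.cts, s.label)
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out


def stratified_split(samples, spec: SplitSpec = SplitSpec()):
    """Class-preserving split into (train, validation, test).

    Per-class counts follow the fractions with largest-remainder rounding;
    the three parts are disjoint and exhaustive, deterministic given the
    seed.
    """
    import warnings

    labels = {s.label for s in samples}
    if labels != {0, 1}:
        raise ValueError("both classes must be present for a stratified split")
    rng = np.random.default_rng(spec.seed)
    parts: tuple[list, list, list] = ([], [], [])
    for cls in (1, 0):
        group = [s for s in samples if s.label == cls]
        order = rng.permutation(len(group))
        n = len(group)
        exact = [f * n for f in spec.fractions]
        counts = [int(e) for e in exact]
        remainders = sorted(range(3), key=lambda i: exact[i] - counts[i],
                            reverse=True)
        for i in remainders[: n - sum(counts)]:
            counts[i] += 1
        pos = 0
        for part, cnt in zip(parts, counts):
            if cnt == 0:
                warnings.warn(
                    f"class {cls} empty in one split under {spec.fractions}",
                    stacklevel=2)
            part.extend(group[k] for k in order[pos:pos + cnt])
            pos += cnt
    return parts


def _random_rna(rng, n: int) -> str:
    return "".join(rng.choice(("A", "C", "G", "U"), size=n))


def synth_corpus(n_pos: int = 100, n_neg_per_pos: int = 5,
                 utr_len: int = 300, seed: int = 0,
                 sd: ScoreDict | None = None,
                 turner: TurnerParams | None = None):
    """Generate a synthetic labeled corpus with known implant coordinates.

    Returns ``(records, samples, truth)`` where ``truth`` is a DataFrame
    with the implanted window of every positive (0-based half-open
    coordinates on its UTR) and which anchors (seed, 3'-compensatory) it
    carries.
    """
    rng = np.random.default_rng(seed)
    if turner is None:
        turner = default_turner()
    records = []
    samples = []
    truth_rows = []
    for p in range(n_pos):
        mic = _random_rna(rng, int(rng.integers(20, L + 1)))
        # implanted 25-nt window aligned with the (padded) microRNA
        window = list(_random_rna(rng, L))
        anchored = set()
        for k in range(1, 8):  # seed region, microRNA positions 1-7
            window[k] = _COMPLEMENT[mic[k]]
            anchored.add(k)
        compensatory = bool(rng.random() < 0.5)
        if compensatory and len(mic) == L:
            for k in range(21, 25):
                window[k] = _COMPLEMENT[mic[k]]
                anchored.add(k)
        elif compensatory:
            hi = min(len(mic), L)
            for k in range(max(0, hi - 4), hi):
                window[k] = _COMPLEMENT[mic[k]]
                anchored.add(k)
        free = [k for k in range(L) if k not in anchored]
        for k in rng.choice(free, size=int(rng.integers(0, 3)), replace=False):
            window[k] = str(rng.choice(
                [b for b in "ACGU" if b != window[k]]))
        site_start = int(rng.integers(0, utr_len - L + 1))
        utr = (_random_rna(rng, site_start) + "".join(window)
               + _random_rna(rng, utr_len - site_start - L))
        rec = CorpusRecord(mic_id=f"mir{p:04d}", mic_seq=mic,
                           utr_id=f"utr{p:04d}", utr_seq=utr,
                           site_start=site_start)
        records.append(rec)
        samples.append(extract_positive(rec))
        samples.extend(generate_negatives(
            rec, sd=sd, turner=turner, max_n=n_neg_per_pos,
            seed=int(rng.integers(2 ** 31))))
        truth_rows.append({
            "utr_id": rec.utr_id, "mic_id": rec.mic_id,
            "start": site_start, "end": site_start + L,
            "compensatory": compensatory,
        })
    samples = deduplicate(samples)
    truth = pd.DataFrame(truth_rows)
    return records, samples, truth


# ---------------------------------------------------------------------------
# FASTA / TSV I/O


def read_fasta(path) -> dict:
    """id -> uppercase RNA sequence (T transcribed to U)."""
    return {rec.id: str(rec.seq).upper().replace("T", "U")
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    """BED-like ground-truth table of implanted sites (0-based half-open)."""
    truth.to_csv(path, sep="\t", index=False)
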