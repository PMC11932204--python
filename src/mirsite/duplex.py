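"""Duplex secondary-structure prediction by dynamic programming.

Given a 25-symbol microRNA and candidate target site, the predictor finds
the set of non-crossing, strictly monotone canonical base pairs maximizing
the total learned pairing weight.  The recursion over prefixes
``mic[0:i] x cts[0:j]`` takes the maximum of

(a) skipping microRNA base i,
(b) skipping site base j,
(c) matching k consecutive base pairs (k in {1, 2, 3}) ending at (i, j),
    scored by the learned scoring dictionary.

Three 25x25 tables are produced: the cumulative score table S1, the
backpointer table BT1 (from which the structure is reconstructed), and MFE1,
the 37 degC free energy of the backtracked substructure at every cell.
Borders are zero and filling starts at cell [1, 1]: position 0 of either
strand never pairs, reflecting that the 5'-terminal microRNA nucleotide is
buried in Argonaute and unavailable for pairing.

Free energy of a structure (kcal/mol, 37 degC) is the sum of intermolecular
initiation (+4.09), nearest-neighbor stacking over adjacent pairs,
bulge / internal-loop initiation penalties for gapped steps, and a +0.45
penalty per helix terminus closed by a weak (AU/UA/GU/UG) pair.  An empty
structure has energy 0: with no pairs there is no initiation event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import CANONICAL_PAIRS, TurnerParams
from .pair_features import L, _validate_seq, canonical_pair_type
from .preference import ScoreDict

__all__ = [
    "DPTables",
    "DuplexStructure",
    "fill_tables",
    "backtrack",
    "duplex_dg37",
    "predict_duplex",
    "render_duplex",
    "parse_duplex_rendering",
]

# backpointer codes
BT_NONE, BT_UP, BT_LEFT, BT_DIAG1, BT_DIAG2, BT_DIAG3 = 0, 1, 2, 3, 4, 5

_WEAK_ENDS = {"AU", "UA", "GU", "UG"}
_PAIR_INDEX = {p: t for t, p in enumerate(CANONICAL_PAIRS)}


@dataclass
class DPTables:
    """Scoring, backtracking, and substructure-energy tables of one duplex."""

    mic: str
    cts: str
    S1: np.ndarray
    BT1: np.ndarray
    MFE1: np.ndarray


@dataclass
class DuplexStructure:
    """An ordered, non-crossing set of base pairs with score and energy."""

    pairs: list = field(default_factory=list)  # (r, c, type), r and c increasing
    total_weight: float = 0.0
    dg37: float = 0.0


def fill_tables(mic: str, cts: str, sd: ScoreDict,
                turner: TurnerParams, compute_mfe: bool = True) -> DPTables:
    """Fill S1 / BT1 / MFE1 for the duplex of ``mic`` and ``cts``.

    ``compute_mfe=False`` skips the per-cell substructure energies (used
    where only the final structure is needed).
    """
    _validate_seq(mic, "mic")
    _validate_seq(cts, "cts")
    tgrid = np.full((L, L), -1, dtype=np.int8)
    for i, x in enumerate(mic):
        for j, y in enumerate(cts):
            t = canonical_pair_type(x, y)
            if t is not None:
                tgrid[i, j] = _PAIR_INDEX[t]

    # run scores ending at (i, j); NaN where the run is not all-canonical
    run_ok = [None, tgrid >= 0]
    run_ok.append(run_ok[1] & np.roll(np.roll(run_ok[1], 1, 0), 1, 1))
    run_ok.append(run_ok[2] & np.roll(np.roll(run_ok[1], 2, 0), 2, 1))

    S1 = np.zeros((L, L))
    BT1 = np.zeros((L, L), dtype=np.int8)
    run_score = _run_score_fn(sd, tgrid)
    for i in range(1, L):
        for j in range(1, L):
            # precedence on ties: diag3 > diag2 > diag1 > up > left
            best = -np.inf
            best_bt = BT_NONE
            for k in (3, 2, 1):
                if i - k >= 0 and j - k >= 0 and run_ok[k][i, j]:
                    cand = S1[i - k, j - k] + run_score(i, j, k)
                    if cand > best:
                        best = cand
                        best_bt = BT_DIAG1 + k - 1
            up = S1[i - 1, j]
            if up > best:
                best, best_bt = up, BT_UP
            left = S1[i, j - 1]
            if left > best:
                best, best_bt = left, BT_LEFT
            S1[i, j] = best
            BT1[i, j] = best_bt

    tables = DPTables(mic=mic, cts=cts, S1=S1, BT1=BT1,
                      MFE1=np.zeros((L, L)))
    if compute_mfe:
        for i in range(1, L):
            for j in range(1, L):
                pairs = _trace_pairs(tables, i, j)
                tables.MFE1[i, j] = duplex_dg37_pairs(pairs, mic, cts, turner)
    return tables


def _run_score_fn(sd: ScoreDict, tgrid: np.ndarray):
    singles, doubles, triples = sd.singles, sd.doubles, sd.triples

    def run_score(i: int, j: int, k: int) -> float:
        i0, j0 = i - k + 1, j - k + 1
        d = j0 - i0
        if k == 1:
            return singles[i, j, tgrid[i, j]]
        if k == 2 and -2 <= d <= 2:
            return doubles[i0, d + 2, tgrid[i0, j0], tgrid[i, j]]
        if k == 3 and -1 <= d <= 1:
            return triples[i0, d + 1, tgrid[i0, j0],
                           tgrid[i0 + 1, j0 + 1], tgrid[i, j]]
        return sum(singles[i0 + a, j0 + a, tgrid[i0 + a, j0 + a]]
                   for a in range(k))

    return run_score


def _trace_pairs(tables: DPTables, i: int, j: int) -> list:
    """Backtrack from cell (i, j); returns pairs sorted by position."""
    mic, cts, BT1 = tables.mic, tables.cts, tables.BT1
    pairs = []
    while i > 0 and j > 0:
        bt = BT1[i, j]
        if bt == BT_UP:
            i -= 1
        elif bt == BT_LEFT:
            j -= 1
        elif bt in (BT_DIAG1, BT_DIAG2, BT_DIAG3):
            k = bt - BT_DIAG1 + 1
            for a in range(k):
                r, c = i - a, j - a
                pairs.append((r, c, canonical_pair_type(mic[r], cts[c])))
            i -= k
            j -= k
        else:  # BT_NONE only on borders
            break
    pairs.reverse()
    return pairs


def backtrack(tables: DPTables, sd: ScoreDict | None = None) -> DuplexStructure:
    """Reconstruct the optimal structure recorded in the backpointer table."""
    pairs = _trace_pairs(tables, L - 1, L - 1)
    for r, c, t in pairs:
        if t is None:
            raise RuntimeError(
                f"corrupted backpointers: non-canonical pair at ({r}, {c})")
    return DuplexStructure(pairs=pairs,
                           total_weight=float(tables.S1[L - 1, L - 1]))


def duplex_dg37_pairs(pairs, mic: str, cts: str,
                      turner: TurnerParams) -> float:
    """Free energy (kcal/mol, 37 degC) of an explicit pair list."""
    if not pairs:
        return 0.0
    pairs = sorted(pairs)
    for r, c, t in pairs:
        if canonical_pair_type(mic[r], cts[c]) != t:
            raise ValueError(
                f"pair type {t} at ({r}, {c}) inconsistent with sequences")
    dg = turner.init_dg
    for (r1, c1, t1), (r2, c2, t2) in zip(pairs, pairs[1:]):
        gap_r = r2 - r1 - 1
        gap_c = c2 - c1 - 1
        if gap_r < 0 or gap_c < 0:
            raise ValueError("pairs must be strictly increasing on both strands")
        if gap_r == 0 and gap_c == 0:
            dg += turner.stack(t1, t2)
        elif gap_r == 0 or gap_c == 0:
            dg += turner.loop("bulge", gap_r + gap_c)
        else:
            dg += turner.loop("internal", gap_r + gap_c)
    # weak-end penalty at each terminus of each helix (maximal stacked run)
    helix_start = pairs[0]
    prev = pairs[0]
    for cur in pairs[1:] + [None]:
        stacked = (cur is not None and cur[0] == prev[0] + 1
                   and cur[1] == prev[1] + 1)
        if not stacked:
            for end in (helix_start, prev):
                if end[2] in _WEAK_ENDS:
                    dg += turner.au_end_dg
            if cur is not None:
                helix_start = cur
        prev = cur if cur is not None else prev
    return dg


def duplex_dg37(structure: DuplexStructure, mic: str, cts: str,
                turner: TurnerParams) -> float:
    """Free energy of a predicted structure's pair list."""
    return duplex_dg37_pairs(structure.pairs, mic, cts, turner)


def predict_duplex(mic: str, cts: str, sd: ScoreDict,
                   turner: TurnerParams) -> DuplexStructure:
    """Fill tables, backtrack, and evaluate the energy in one call."""
    tables = fill_tables(mic, cts, sd, turner, compute_mfe=False)
    structure = backtrack(tables, sd)
    structure.dg37 = duplex_dg37(structure, mic, cts, turner)
    return structure


# ---------------------------------------------------------------------------
# text rendering


def render_duplex(structure: DuplexStructure, mic: str, cts: str) -> str:
    """Two-line alignment with pair bars plus a machine-readable pair list."""
    bars = [" "] * L
    for r, c, _ in structure.pairs:
        if r == c:
            bars[r] = "|"
        else:
            bars[r] = "*"
    lines = [
        f"mic 5' {mic} 3'",
        f"       {''.join(bars)}",
        f"cts    {cts}",
        f"# total_weight={structure.total_weight!r} dg37={structure.dg37!r}",
    ]
    for r, c, t in structure.pairs:
        lines.append(f"pair\t{r}\t{c}\t{t}")
    return "\n".join(lines) + "\n"


def parse_duplex_rendering(text: str) -> DuplexStructure:
    """Inverse of :func:`render_duplex` (pair list and scores)."""
    pairs = []
    total_weight = dg37 = 0.0
    for line in text.splitlines():
        if line.startswith("# total_weight="):
            head, tail = line[2:].split(" dg37=")
            total_weight = float(head.split("=")[1])
            dg37 = float(tail)
        elif line.startswith("pair\t"):
            _, r, c, t = line.split("\t")
            pairs.append((int(r), int(c), t))
    return DuplexStructure(pairs=pairs, total_weight=total_weight, dg37=dg37)

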