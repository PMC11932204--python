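"""Fixed numerical tables: rRNA base-pair statistics and Turner thermodynamics.

Two parameter sets live here, both shipped as plain-text TSV package data so
they are inspectable and diffable:

* :class:`BasePairProbTable` -- empirical probabilities of every unordered
  nucleotide pair (canonical and non-canonical) observed in human rRNA
  crystal structures.  These feed the base-pair probability channel of the
  classifier and the duplex-structure matrix.
* :class:`TurnerParams` -- the 37 degC nearest-neighbor free-energy subset
  needed to evaluate a two-strand duplex: intermolecular initiation
  (+4.09 kcal/mol), the weak-end (AU/GU terminal pair) penalty
  (+0.45 kcal/mol), the 6x6 canonical helix stacking table, and the
  length-dependent bulge / internal-loop initiation tables.  Loop penalties
  beyond the tabulated 30 nt are extrapolated with the Jacobson-Stockmayer
  form dG(n) = dG(30) + 1.75 * R * T * ln(n / 30).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "PAD",
    "NUCLEOTIDES",
    "CANONICAL_PAIRS",
    "BasePairProbTable",
    "TurnerParams",
    "bp_probability",
    "stack_energy",
    "loop_energy",
    "default_bp_table",
    "default_turner",
]

#: Pad character used to right-pad sequences shorter than 25 nt.
PAD = "-"

NUCLEOTIDES = ("A", "C", "G", "U")

#: The six canonical pair types (Watson-Crick plus GU wobble), ordered
#: alphabetically; first letter is the top-strand (microRNA) base.
CANONICAL_PAIRS = ("AU", "CG", "GC", "GU", "UA", "UG")

# gas constant (kcal/mol/K) * 310.15 K
_RT37 = 1.98717e-3 * 310.15
_LOOP_MAX_TABULATED = 30

INIT_DG37 = 4.09
AU_END_DG37 = 0.45


def _data_path(name: str) -> Path:
    return Path(resources.files("mirsite").joinpath("data", name))


def _check_symbol(sym: str) -> None:
    if sym not in NUCLEOTIDES and sym != PAD:
        raise ValueError(f"unknown nucleotide symbol: {sym!r}")


@dataclass(frozen=True)
class BasePairProbTable:
    """Symmetric lookup of base-pair formation probabilities.

    ``prob`` maps the unordered pair {X, Y} (stored under both orderings)
    to a probability in [0, 1].  Any query involving the pad character
    returns exactly 0.
    """

    prob: dict = field(repr=False)

    def __post_init__(self):
        keys = {frozenset(k) for k in self.prob}
        if len(keys) != 10:
            raise ValueError(f"expected 10 unordered pairs, got {len(keys)}")
        for k, v in self.prob.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability out of range for {k}: {v}")

    def __call__(self, x: str, y: str) -> float:
        _check_symbol(x)
        _check_symbol(y)
        if x == PAD or y == PAD:
            return 0.0
        return self.prob[x + y]

    @classmethod
    def from_tsv(cls, path) -> "BasePairProbTable":
        prob: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("pair\t"):
                continue
            pair, p = line.split("\t")
            prob[pair] = float(p)
            prob[pair[::-1]] = float(p)
        return cls(prob=prob)

    def to_tsv(self, path) -> None:
        lines = ["pair\tprobability"]
        seen = set()
        for pair in sorted(self.prob):
            key = frozenset(pair)
            if key in seen:
                continue
            seen.add(key)
            lines.append(f"{pair}\t{self.prob[pair]:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class TurnerParams:
    """37 degC Turner free-energy subset for intermolecular duplexes."""

    init_dg: float = INIT_DG37
    au_end_dg: float = AU_END_DG37
    stack_dg: dict = field(default=None, repr=False)
    bulge_dg: dict = field(default=None, repr=False)
    internal_dg: dict = field(default=None, repr=False)

    def stack(self, pair1: str, pair2: str) -> float:
        """Free energy of the nearest-neighbor step 5'-pair1, pair2-3'."""
        for p in (pair1, pair2):
            if p not in CANONICAL_PAIRS:
                raise ValueError(f"non-canonical pair in stack step: {p!r}")
        return self.stack_dg[(pair1, pair2)]

    def loop(self, kind: str, size: int) -> float:
        """Length-dependent loop initiation penalty (bulge or internal)."""
        if kind not in ("bulge", "internal"):
            raise ValueError(f"unknown loop kind: {kind!r}")
        if size < 1:
            raise ValueError(f"loop size must be >= 1, got {size}")
        table = self.bulge_dg if kind == "bulge" else self.internal_dg
        if size in table:
            return table[size]
        if size < min(table):
            # internal loops below the physical minimum (1x1 = 2 nt) cannot
            # arise from the structure decomposition; clamp to the smallest
            # tabulated size for totality.
            return table[min(table)]
        # Jacobson-Stockmayer logarithmic extrapolation
        return table[_LOOP_MAX_TABULATED] + 1.75 * _RT37 * math.log(
            size / _LOOP_MAX_TABULATED
        )

    @classmethod
    def from_tsv(cls, stacks_path, loops_path, init_dg=INIT_DG37,
                 au_end_dg=AU_END_DG37) -> "TurnerParams":
        stack: dict = {}
        for line in Path(stacks_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("pair1\t"):
                continue
            p1, p2, dg = line.split("\t")
            stack[(p1, p2)] = float(dg)
        bulge: dict = {}
        internal: dict = {}
        for line in Path(loops_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("kind\t"):
                continue
            kind, size, dg = line.split("\t")
            (bulge if kind == "bulge" else internal)[int(size)] = float(dg)
        return cls(init_dg=init_dg, au_end_dg=au_end_dg, stack_dg=stack,
                   bulge_dg=bulge, internal_dg=internal)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        lines = ["pair1\tpair2\tdg37_kcal_mol"]
        for (p1, p2), dg in sorted(self.stack_dg.items()):
            lines.append(f"{p1}\t{p2}\t{dg!r}")
        (path / "stacks.tsv").write_text("\n".join(lines) + "\n")
        lines = ["kind\tsize\tdg37_kcal_mol"]
        for size, dg in sorted(self.bulge_dg.items()):
            lines.append(f"bulge\t{size}\t{dg!r}")
        for size, dg in sorted(self.internal_dg.items()):
            lines.append(f"internal\t{size}\t{dg!r}")
        (path / "loops.tsv").write_text("\n".join(lines) + "\n")
        (path / "terms.json").write_text(json.dumps(
            {"init_dg": self.init_dg, "au_end_dg": self.au_end_dg}))

    @classmethod
    def from_dir(cls, path) -> "TurnerParams":
        path = Path(path)
        terms = json.loads((path / "terms.json").read_text())
        return cls.from_tsv(path / "stacks.tsv", path / "loops.tsv",
                            init_dg=terms["init_dg"],
                            au_end_dg=terms["au_end_dg"])


_BP_TABLE = None
_TURNER = None


def default_bp_table() -> BasePairProbTable:
    """The packaged rRNA-derived base-pair probability table."""
    global _BP_TABLE
    if _BP_TABLE is None:
        _BP_TABLE = BasePairProbTable.from_tsv(_data_path("bp_probabilities.tsv"))
    return _BP_TABLE


def default_turner() -> TurnerParams:
    """The packaged Turner 2004 parameter subset."""
    global _TURNER
    if _TURNER is None:
        _TURNER = TurnerParams.from_tsv(
            _data_path("turner_stacks.tsv"), _data_path("turner_loops.tsv"))
    return _TURNER


def bp_probability(x: str, y: str) -> float:
    """Probability that bases ``x`` and ``y`` pair (0 for the pad symbol)."""
    return default_bp_table()(x, y)


def stack_energy(pair1: str, pair2: str) -> float:
    """Nearest-neighbor stacking free energy of the step 5'-pair1, pair2-3'."""
    return default_turner().stack(pair1, pair2)


def loop_energy(kind: str, size: int) -> float:
    """Bulge or internal-loop initiation free energy for ``size`` unpaired nt."""
    return default_turner().loop(kind, size)
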