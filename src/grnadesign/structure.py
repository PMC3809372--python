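"""gRNA secondary-structure prediction and guide-availability scoring.

The default folding engine is base-pair maximization (Nussinov dynamic
program with deterministic traceback) over Watson-Crick plus G·U wobble
pairs, with a minimum hairpin loop of 3 and no pseudoknots.  It is a
structural proxy, not a thermodynamic model: users who want minimum-free-
energy structures from an external folder (e.g. RNAfold) can import its
dot-bracket output via :func:`import_structure` and score it identically.

The guide-availability metric counts how many of the 20 guide positions are
paired within the predicted guide+scaffold structure ("sequestered", i.e.
locked into intramolecular pairs and unavailable for DNA binding) and how
many are unpaired ("free").  Both counts are always reported because the
literature's loop-based wording is ambiguous about which is meant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import List, Tuple

import numpy as np

GUIDE_LEN = 20

_PAIRS_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_PAIRS_GU = {("G", "U"), ("U", "G")}


def _load_default_scaffold() -> str:
    text = resources.files("grnadesign.data").joinpath("sgrna_scaffold.txt").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith("#"))


def default_scaffold() -> str:
    """The canonical S. pyogenes tracrRNA-fusion scaffold (RNA alphabet)."""
    return _load_default_scaffold()


@dataclass(frozen=True)
class FoldParams:
    """min_loop: minimum unpaired bases inside a hairpin (default 3);
    allow_gu: include G·U wobble pairs; scaffold: RNA appended 3' of the
    guide before folding (empty string = guide-only mode)."""

    min_loop: int = 3
    allow_gu: bool = True
    scaffold: str = field(default_factory=_load_default_scaffold)

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")

    def pairable(self, a: str, b: str) -> bool:
        if (a, b) in _PAIRS_WC:
            return True
        return self.allow_gu and (a, b) in _PAIRS_GU


@dataclass(frozen=True)
class DotBracket:
    """An RNA sequence with a pseudoknot-free secondary structure."""

    sequence: str
    structure: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError("sequence and structure lengths differ")

    @property
    def pairs(self) -> List[Tuple[int, int]]:
        """1-based (i, j) base pairs, i < j, sorted by i."""
        stack: List[int] = []
        out: List[Tuple[int, int]] = []
        for idx, ch in enumerate(self.structure, start=1):
            if ch == "(":
                stack.append(idx)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {idx}")
                out.append((stack.pop(), idx))
            elif ch != ".":
                raise ValueError(f"illegal structure character {ch!r} at position {idx}")
        if stack:
            raise ValueError(f"unbalanced '(' at position {stack[-1]}")
        return sorted(out)

    @property
    def n_pairs(self) -> int:
        return sum(1 for ch in self.structure if ch == "(")

    def paired_mask(self) -> List[bool]:
        return [ch != "." for ch in self.structure]


def to_rna(seq: str) -> str:
    """DNA or mixed-case input to the RNA alphabet; validates characters."""
    rna = seq.upper().replace("T", "U")
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"illegal character(s) {sorted(bad)} in RNA sequence")
    return rna


def fold(sequence: str, params: FoldParams | None = None) -> DotBracket:
    """Base-pair-maximizing structure of an RNA string.

    Dynamic program over spans; among co-optimal structures the traceback
    prefers leaving the left index unpaired, then pairing it with the
    smallest partner index, so output is deterministic.
    """
    params = params or FoldParams(scaffold="")
    seq = to_rna(sequence)
    n = len(seq)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    gap = params.min_loop

    can_pair = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + gap + 1, n):
            can_pair[i, j] = params.pairable(seq[i], seq[j])

    dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # dp[i, j]: max pairs in seq[i..j-1] (0-based half-open)
    for span in range(gap + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # half-open end
            best = dp[i + 1, j]  # i unpaired
            ks = np.nonzero(can_pair[i, i : j])[0] + i  # partners for i
            if ks.size:
                vals = 1 + dp[i + 1, ks] + dp[ks + 1, j]
                best = max(best, int(vals.max()))
            dp[i, j] = best

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            target = dp[i, j]
            if target == 0:
                return
            if dp[i + 1, j] == target:
                i += 1
                continue
            for k in range(i + gap + 1, j):
                if can_pair[i, k] and 1 + dp[i + 1, k] + dp[k + 1, j] == target:
                    structure[i] = "("
                    structure[k] = ")"
                    traceback(i + 1, k)
                    i, j = k + 1, j
                    break
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("traceback failed to reproduce DP value")

    traceback(0, n)
    return DotBracket(seq, "".join(structure))


def fold_guide(guide: str, params: FoldParams | None = None) -> DotBracket:
    """Fold guide (DNA accepted) with the scaffold from ``params`` appended."""
    params = params or FoldParams()
    return fold(to_rna(guide) + to_rna(params.scaffold) if params.scaffold else to_rna(guide), params)


def import_structure(sequence: str, dot_bracket_text: str, min_loop: int = 3) -> DotBracket:
    """Validate an externally predicted dot-bracket string for ``sequence``.

    Unbalanced brackets, a length mismatch, or a hairpin loop shorter than
    ``min_loop`` are errors; non-complementary pairs are warnings only,
    since thermodynamic engines may emit noncanonical pairs.
    """
    import logging

    seq = to_rna(sequence)
    db = DotBracket(seq, dot_bracket_text.strip())
    params = FoldParams(scaffold="")
    for i, j in db.pairs:  # also raises on unbalanced brackets
        if j - i - 1 < min_loop:
            raise ValueError(
                f"pair ({i},{j}) closes a hairpin loop of {j - i - 1} < {min_loop}"
            )
        if not params.pairable(seq[i - 1], seq[j - 1]):
            logging.getLogger(__name__).warning(
                "noncanonical pair %s-%s at (%d,%d)", seq[i - 1], seq[j - 1], i, j
            )
    return db


def guide_loop_bases(structure: DotBracket, guide_len: int = GUIDE_LEN) -> Tuple[int, int]:
    """(sequestered, free) counts over the first ``guide_len`` positions.

    "Sequestered" guide bases are paired within the gRNA's own structure and
    therefore unavailable for DNA binding; "free" bases are unpaired.  The
    two always sum to ``guide_len``.
    """
    if len(structure.structure) < guide_len:
        raise ValueError(
            f"structure length {len(structure.structure)} shorter than guide ({guide_len})"
        )
    mask = structure.paired_mask()[:guide_len]
    sequestered = sum(mask)
    return sequestered, guide_len - sequestered


def at_content(guide: str) -> int:
    """AT percentage of a 20-nt guide: 100 * (A+T) / 20, a multiple of 5."""
    g = guide.upper()
    if len(g) != GUIDE_LEN:
        raise ValueError(f"guide must be {GUIDE_LEN} nt, got {len(g)}")
    bad = set(g) - set("ACGT")
    if bad:
        raise ValueError(f"guide contains non-ACGT character(s) {sorted(bad)}")
    return 100 * (g.count("A") + g.count("T")) // GUIDE_LEN
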