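"""FASTA I/O, coordinate conventions, and strand arithmetic.

All user-facing coordinates in this package are 1-based and inclusive, so a
23-bp target region satisfies ``end - start + 1 == 23`` and renders as
``chrom:start-end(strand)``.  Minus-strand regions keep forward-axis
coordinates; the strand only controls which sequence :func:`fetch` returns.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
#: IUPAC nucleotide one-letter codes (what a FASTA may legally contain).
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)(?:\((?P<strand>[+−-])\))?$")


@dataclass(frozen=True)
class GenomicRegion:
    """A closed 1-based interval on a named chromosome, with a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region bounds {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"

    @classmethod
    def parse(cls, text: str) -> "GenomicRegion":
        """Parse ``chrom:start-end`` or ``chrom:start-end(strand)``.

        Accepts an ASCII hyphen or a Unicode minus sign for the strand.
        """
        m = REGION_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse region {text!r}")
        strand = m.group("strand") or "+"
        if strand == "−":
            strand = "-"
        return cls(m.group("chrom"), int(m.group("start")), int(m.group("end")), strand)


@dataclass
class Genome:
    """An ordered collection of uppercase A/C/G/T/N chromosome sequences."""

    records: Dict[str, str] = field(default_factory=dict)

    def add(self, name: str, seq: str) -> None:
        if not name:
            raise ValueError("chromosome name must be non-empty")
        if name in self.records:
            raise ValueError(f"duplicate chromosome name {name!r}")
        seq = sanitize_sequence(seq, context=name)
        self.records[name] = seq

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def sanitize_sequence(seq: str, context: str = "") -> str:
    """Uppercase and map non-ACGTN IUPAC codes to N (logged); reject others."""
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - IUPAC_CODES
    if bad:
        raise ValueError(
            f"illegal non-IUPAC character(s) {sorted(bad)} in sequence {context or '<anonymous>'}"
        )
    n_amb = len(_NON_ACGTN.findall(seq))
    if n_amb:
        logger.warning(
            "%d ambiguous IUPAC base(s) converted to N in %s", n_amb, context or "sequence"
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"illegal character(s) {sorted(bad)} for reverse_complement")
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_fasta_text(path: Path) -> None:
    """Locate illegal characters with their line number before parsing."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                in_record = True
                continue
            if not in_record:
                raise ValueError(f"line {lineno}: sequence data before first '>' header")
            bad = set(line.upper().replace("U", "T")) - IUPAC_CODES
            if bad:
                raise ValueError(
                    f"line {lineno}: illegal non-IUPAC character(s) {sorted(bad)}"
                )


def read_fasta(path: Union[str, Path]) -> Genome:
    """Read a (multi-record) FASTA file into a :class:`Genome`.

    The chromosome name is the header token before the first whitespace.
    Sequences are uppercased; ambiguity codes other than N become N.
    """
    path = Path(path)
    _validate_fasta_text(path)
    genome = Genome()
    for record in SeqIO.parse(str(path), "fasta"):
        genome.add(record.id, str(record.seq))
    if len(genome) == 0:
        raise ValueError(f"no records in FASTA file {path}")
    return genome


def write_fasta(genome: Genome, path: Union[str, Path], width: int = 60) -> None:
    """Write a Genome back to FASTA, preserving record order."""
    with open(path, "w") as fh:
        for name, seq in genome.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch(genome: Genome, region: GenomicRegion) -> str:
    """Return the sequence of ``region``; minus strand reverse-complements."""
    if region.chrom not in genome:
        raise KeyError(f"unknown chromosome {region.chrom!r}")
    chrom_seq = genome.records[region.chrom]
    if region.end > len(chrom_seq):
        raise ValueError(
            f"region {region} out of bounds (chromosome length {len(chrom_seq)})"
        )
    sub = chrom_seq[region.start - 1 : region.end]
    return reverse_complement(sub) if region.strand == "-" else sub


def iter_query_records(path: Union[str, Path]) -> Iterable[tuple[str, str]]:
    """Yield (record_id, sequence) pairs from a query FASTA, sanitized."""
    genome = read_fasta(path)
    yield from genome.records.items()
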