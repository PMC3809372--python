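"""Mismatch-tolerant genome-wide search for 23-mer target sites.

Replaces the short-read-aligner step of a gRNA design pipeline with an
in-memory pigeonhole k-mer index: a 23-mer is split into ``max_mismatches+1``
parts so that any placement within the mismatch budget matches at least one
part exactly.  Candidate placements found through the index are verified by
a full Hamming comparison, which makes the search fully sensitive (matching
what an ungapped -v-mode alignment guarantees).  N in the genome never
matches any query base.

Defaults mirror the design pipeline's alignment settings: at most one
mismatch over the full 23-mer (PAM included), reporting up to 10 placements.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Tuple

from .genome import Genome, GenomicRegion, reverse_complement

TARGET_LEN = 23


@dataclass(frozen=True)
class SearchParams:
    """Off-target search settings.

    max_mismatches : Hamming budget over the full 23-mer (default 1).
    max_hits       : cap on reported placements (default 10).
    seed_length    : accepted for interface parity with aligner seeds; the
                     pigeonhole split already guarantees full sensitivity at
                     the mismatch budget, so it does not alter results.
    """

    max_mismatches: int = 1
    max_hits: int = 10
    seed_length: int = 16

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if not 1 <= self.seed_length <= TARGET_LEN:
            raise ValueError(f"seed_length must be in [1, {TARGET_LEN}]")


@dataclass(frozen=True)
class AlignmentHit:
    """One genomic placement of a 23-mer.

    ``mismatch_positions`` are 1-based offsets within the 23-mer, 5'->3' in
    guide orientation (i.e. relative to the query, not the forward genome).
    """

    region: GenomicRegion
    mismatches: int
    mismatch_positions: Tuple[int, ...] = ()


@dataclass
class HitSummary:
    hits: List[AlignmentHit] = field(default_factory=list)
    truncated: bool = False

    @property
    def n_hits_reported(self) -> int:
        return len(self.hits)


class Uniqueness(str, Enum):
    UNIQUE = "unique"
    MULTI = "multi"
    UNMAPPED = "unmapped"


def _part_bounds(n_parts: int) -> List[Tuple[int, int]]:
    """Split [0, 23) into n_parts near-equal contiguous pieces."""
    bounds = []
    base, rem = divmod(TARGET_LEN, n_parts)
    pos = 0
    for i in range(n_parts):
        size = base + (1 if i < rem else 0)
        bounds.append((pos, pos + size))
        pos += size
    return bounds


class TargetIndex:
    """Exact-k-mer pigeonhole index over the forward strand of a genome.

    One dictionary per pigeonhole part maps the genome substring of that
    part's length, at every offset, to its positions.  Reverse-strand
    placements are found by querying the reverse complement of the 23-mer.
    """

    def __init__(self, genome: Genome, params: SearchParams | None = None) -> None:
        if len(genome) == 0:
            raise ValueError("cannot index an empty genome")
        self.params = params or SearchParams()
        self.genome = genome
        self.bounds = _part_bounds(self.params.max_mismatches + 1)
        part_lengths = sorted({hi - lo for lo, hi in self.bounds})
        self._tables: Dict[int, Dict[str, List[Tuple[str, int]]]] = {}
        for k in part_lengths:
            table: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
            for chrom, seq in genome.records.items():
                for pos in range(len(seq) - k + 1):
                    kmer = seq[pos : pos + k]
                    if "N" not in kmer:
                        table[kmer].append((chrom, pos))
            self._tables[k] = dict(table)

    def _candidate_starts(self, query: str) -> set[Tuple[str, int]]:
        """0-based window starts where some pigeonhole part matches exactly."""
        starts: set[Tuple[str, int]] = set()
        lengths = self.genome.lengths
        for lo, hi in self.bounds:
            part = query[lo:hi]
            for chrom, pos in self._tables[hi - lo].get(part, ()):
                start = pos - lo
                if start >= 0 and start + TARGET_LEN <= lengths[chrom]:
                    starts.add((chrom, start))
        return starts


def build_index(genome: Genome, params: SearchParams | None = None) -> TargetIndex:
    """Build the in-memory search index (replaces an on-disk aligner index)."""
    return TargetIndex(genome, params)


def _hamming(a: str, b: str, limit: int) -> List[int] | None:
    """1-based mismatch offsets of a vs b, or None if they exceed ``limit``.

    N (in either string) never matches anything, including N.
    """
    positions: List[int] = []
    for i, (x, y) in enumerate(zip(a, b), start=1):
        if x != y or x == "N":
            positions.append(i)
            if len(positions) > limit:
                return None
    return positions


def find_hits(
    target_23mer: str, index: TargetIndex, params: SearchParams | None = None
) -> HitSummary:
    """All genomic placements of a 23-mer within the mismatch budget.

    Hits on both strands, ordered by (mismatches, chrom, start, '+' first),
    truncated to ``max_hits`` with the flag set when more placements exist.
    Results are identical to an exhaustive Hamming scan of every window.
    """
    params = params or index.params
    if len(target_23mer) != TARGET_LEN:
        raise ValueError(f"query must be {TARGET_LEN} bp, got {len(target_23mer)}")
    if "N" in target_23mer:
        raise ValueError("query 23-mer must not contain N")
    if params.max_mismatches != index.params.max_mismatches and params.max_mismatches > index.params.max_mismatches:
        # index split guarantees sensitivity only up to its own budget
        index = TargetIndex(index.genome, params)

    hits: List[AlignmentHit] = []
    seen: set[Tuple[str, int, str]] = set()
    for strand, query in (("+", target_23mer), ("-", reverse_complement(target_23mer))):
        for chrom, start0 in index._candidate_starts(query):
            if (chrom, start0, strand) in seen:
                continue
            window = index.genome.records[chrom][start0 : start0 + TARGET_LEN]
            mm = _hamming(query, window, params.max_mismatches)
            if mm is None:
                continue
            seen.add((chrom, start0, strand))
            if strand == "-":
                # report offsets in guide orientation
                mm = [TARGET_LEN + 1 - p for p in reversed(mm)]
            region = GenomicRegion(chrom, start0 + 1, start0 + TARGET_LEN, strand)
            hits.append(AlignmentHit(region, len(mm), tuple(mm)))
    hits.sort(
        key=lambda h: (h.mismatches, h.region.chrom, h.region.start, 0 if h.region.strand == "+" else 1)
    )
    truncated = len(hits) > params.max_hits
    return HitSummary(hits=hits[: params.max_hits], truncated=truncated)


def classify_uniqueness(summary: HitSummary) -> Uniqueness:
    """unique = exactly one placement (cap not reached); 0 = unmapped."""
    if summary.n_hits_reported == 0:
        return Uniqueness.UNMAPPED
    if summary.n_hits_reported == 1 and not summary.truncated:
        return Uniqueness.UNIQUE
    return Uniqueness.MULTI
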