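"""Scan query sequences for N20-NGG Cas9 target sites on both strands.

Every 23-bp window whose last two bases are GG (forward strand) or whose
first two bases are CC (reverse-strand site, reported in guide orientation)
is a candidate.  Overlapping windows are all reported — a run of GGG yields
two PAMs — and windows containing N are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional

from .genome import GenomicRegion, reverse_complement

logger = logging.getLogger(__name__)

TARGET_LEN = 23
GUIDE_LEN = 20
PAM_LEN = 3


@dataclass(frozen=True)
class CandidateTarget:
    """One N20-NGG site found in a query sequence.

    ``query_start``/``query_end`` are 1-based inclusive positions of the
    23-mer on the query's forward strand regardless of ``strand``; ``guide``
    and ``pam`` are given 5'->3' in guide orientation.
    """

    query_id: str
    query_start: int
    strand: str
    guide: str
    pam: str
    genomic_region: Optional[GenomicRegion] = None

    def __post_init__(self) -> None:
        if len(self.guide) != GUIDE_LEN:
            raise ValueError(f"guide must be {GUIDE_LEN} nt, got {len(self.guide)}")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM must match NGG, got {self.pam!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def query_end(self) -> int:
        return self.query_start + TARGET_LEN - 1

    @property
    def target_23mer(self) -> str:
        return self.guide + self.pam


def scan_candidates(query_id: str, query_seq: str) -> List[CandidateTarget]:
    """Return all candidate targets in ``query_seq``, both strands.

    Candidates are ordered by query_start, then strand ('+' before '-').
    A query shorter than 23 bp yields an empty list with a warning.
    """
    seq = query_seq.upper()
    n = len(seq)
    if n < TARGET_LEN:
        logger.warning("query %s shorter than %d bp; no candidates", query_id, TARGET_LEN)
        return []
    found: List[CandidateTarget] = []
    n_dropped = 0
    for start0 in range(n - TARGET_LEN + 1):
        window = seq[start0 : start0 + TARGET_LEN]
        # forward site: ...N20 NGG
        if window.endswith("GG", TARGET_LEN - 2):
            if "N" in window:
                n_dropped += 1
            else:
                found.append(
                    CandidateTarget(query_id, start0 + 1, "+", window[:GUIDE_LEN], window[GUIDE_LEN:])
                )
        # reverse site: CCN... on the forward strand
        if window.startswith("CC"):
            if "N" in window:
                n_dropped += 1
            else:
                rc = reverse_complement(window)
                found.append(
                    CandidateTarget(query_id, start0 + 1, "-", rc[:GUIDE_LEN], rc[GUIDE_LEN:])
                )
    if n_dropped:
        logger.info("query %s: dropped %d candidate window(s) containing N", query_id, n_dropped)
    found.sort(key=lambda c: (c.query_start, 0 if c.strand == "+" else 1))
    return found


def map_to_genome(
    candidate: CandidateTarget, query_region: Optional[GenomicRegion]
) -> CandidateTarget:
    """Annotate a candidate with genomic coordinates given the query's anchor.

    The anchor must be a plus-strand region covering the whole query; the
    candidate's strand composes with it (query '-' on a '+' anchor stays '-'
    on the genome).  With no anchor the candidate is returned unchanged.
    """
    if query_region is None:
        return candidate
    if query_region.strand != "+":
        raise ValueError("query anchor must be on the + strand")
    g_start = query_region.start + candidate.query_start - 1
    g_end = g_start + TARGET_LEN - 1
    if g_end > query_region.end:
        raise ValueError(
            f"candidate at query position {candidate.query_start} falls outside anchor {query_region}"
        )
    region = GenomicRegion(query_region.chrom, g_start, g_end, candidate.strand)
    return replace(candidate, genomic_region=region)
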