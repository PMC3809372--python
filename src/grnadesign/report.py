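"""Candidate scoring, multi-criteria ranking, and TSV/HTML report rendering.

Each candidate is scored by (i) its genome-wide placement count at the
mismatch budget, (ii) the variants overlapping its primary locus, (iii) how
many guide bases the predicted gRNA structure sequesters, and (iv) the
guide's AT%.  Ranking is a stable multi-key sort: fewer placements first
(unmapped candidates last), then fewer overlapping variants, then fewer
sequestered guide bases, then higher AT%, then query position.  The first
two keys are the classic uniqueness/SNP sort; the structure and AT keys are
extensions that can be switched off for a two-key sort.

Variants at off-target loci are listed per hit but do not enter
``n_variants``: the variant count belongs to the candidate's own
(0-mismatch, or best available) locus.
"""

from __future__ import annotations

import html as _html
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .candidates import CandidateTarget, map_to_genome, scan_candidates
from .genome import Genome, GenomicRegion, read_fasta
from .offtarget import (
    AlignmentHit,
    HitSummary,
    SearchParams,
    TargetIndex,
    Uniqueness,
    build_index,
    classify_uniqueness,
    find_hits,
)
from .structure import DotBracket, FoldParams, at_content, fold_guide, guide_loop_bases
from .variants import AnnotatedVariant, VariantRecord, count_snps, overlap_variants

logger = logging.getLogger(__name__)

DEFAULT_RANK_KEYS = ("hits", "snps", "structure", "at")

TSV_COLUMNS = [
    "rank", "query_id", "query_start", "strand", "guide", "pam",
    "genomic_region", "n_hits", "truncated", "n_variants", "variant_details",
    "loop_sequestered", "loop_free", "at_percent",
]


@dataclass
class ScoredCandidate:
    candidate: CandidateTarget
    hit_summary: HitSummary
    variants: List[AnnotatedVariant] = field(default_factory=list)
    variants_by_hit: List[List[AnnotatedVariant]] = field(default_factory=list)
    structure: Optional[DotBracket] = None
    loop_sequestered: int = 0
    loop_free: int = 20
    at_percent: int = 0
    unannotated: bool = False
    rank: int = 0

    @property
    def n_hits(self) -> int:
        return self.hit_summary.n_hits_reported

    @property
    def n_variants(self) -> int:
        return count_snps(self.variants)

    @property
    def uniqueness(self) -> Uniqueness:
        return classify_uniqueness(self.hit_summary)

    @property
    def primary_hit(self) -> Optional[AlignmentHit]:
        return self.hit_summary.hits[0] if self.hit_summary.hits else None


def score_candidate(
    candidate: CandidateTarget,
    index: TargetIndex,
    variants: Optional[Sequence[VariantRecord]] = None,
    fold_params: Optional[FoldParams] = None,
    search_params: Optional[SearchParams] = None,
    normalize_chr_prefix: bool = False,
) -> ScoredCandidate:
    """Run search, variant overlap, folding and AT% for one candidate.

    ``variants=None`` marks the result unannotated (no VCF supplied);
    variant overlap per hit region still requires genomic placements, so an
    unmapped candidate has no variant annotation either way.
    """
    summary = find_hits(candidate.target_23mer, index, search_params)
    variants_by_hit: List[List[AnnotatedVariant]] = []
    primary_variants: List[AnnotatedVariant] = []
    if variants is not None:
        for hit in summary.hits:
            variants_by_hit.append(
                overlap_variants(hit.region, list(variants), normalize_chr_prefix)
            )
        if variants_by_hit:
            primary_variants = variants_by_hit[0]
    structure = fold_guide(candidate.guide, fold_params)
    sequestered, free = guide_loop_bases(structure)
    return ScoredCandidate(
        candidate=candidate,
        hit_summary=summary,
        variants=primary_variants,
        variants_by_hit=variants_by_hit,
        structure=structure,
        loop_sequestered=sequestered,
        loop_free=free,
        at_percent=at_content(candidate.guide),
        unannotated=variants is None,
    )


def rank_candidates(
    scored: Sequence[ScoredCandidate],
    rank_keys: Sequence[str] = DEFAULT_RANK_KEYS,
) -> List[ScoredCandidate]:
    """Stable multi-key sort; assigns 1-based ranks.

    Key order (each optional except position): hits ascending with unmapped
    last, variant count ascending, sequestered guide bases ascending, AT%
    descending, query_start ascending.
    """
    unknown = set(rank_keys) - {"hits", "snps", "structure", "at"}
    if unknown:
        raise ValueError(f"unknown rank key(s): {sorted(unknown)}")

    def key(sc: ScoredCandidate):
        parts: List[int] = []
        if "hits" in rank_keys:
            parts.append(sc.n_hits if sc.n_hits > 0 else 10**9)  # unmapped last
            parts.append(1 if sc.hit_summary.truncated else 0)
        if "snps" in rank_keys:
            parts.append(sc.n_variants)
        if "structure" in rank_keys:
            parts.append(sc.loop_sequestered)
        if "at" in rank_keys:
            parts.append(-sc.at_percent)
        parts.append(sc.candidate.query_start)
        return tuple(parts)

    ordered = sorted(scored, key=key)  # sorted() is stable
    for i, sc in enumerate(ordered, start=1):
        sc.rank = i
    return ordered


def _variant_details(variants: Sequence[AnnotatedVariant]) -> str:
    return ";".join(
        f"{av.variant.id}({av.dist_3prime} bp to 3' end)" for av in variants
    )


def render_report(ordered: Sequence[ScoredCandidate], format: str = "tsv") -> str:
    if format == "tsv":
        return _render_tsv(ordered)
    if format == "html":
        return _render_html(ordered)
    raise ValueError(f"unknown report format {format!r} (expected 'tsv' or 'html')")


def _row_values(sc: ScoredCandidate) -> List[str]:
    c = sc.candidate
    return [
        str(sc.rank),
        c.query_id,
        str(c.query_start),
        c.strand,
        c.guide,
        c.pam,
        str(sc.primary_hit.region) if sc.primary_hit else (str(c.genomic_region) if c.genomic_region else "."),
        str(sc.n_hits),
        str(sc.hit_summary.truncated).lower(),
        str(sc.n_variants),
        _variant_details(sc.variants) or ".",
        str(sc.loop_sequestered),
        str(sc.loop_free),
        str(sc.at_percent),
    ]


def _render_tsv(ordered: Sequence[ScoredCandidate]) -> str:
    lines = ["\t".join(TSV_COLUMNS)]
    for sc in ordered:
        lines.append("\t".join(_row_values(sc)))
    return "\n".join(lines) + "\n"


def _render_html(ordered: Sequence[ScoredCandidate]) -> str:
    head = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>gRNA design report</title>"
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:3px 8px;font-family:monospace}</style></head><body>\n"
        "<h1>Candidate gRNA report</h1>\n"
    )
    rows = ["<table>\n<tr>" + "".join(f"<th>{c}</th>" for c in TSV_COLUMNS) + "</tr>"]
    for sc in ordered:
        cells = "".join(f"<td>{_html.escape(v)}</td>" for v in _row_values(sc))
        rows.append(f"<tr>{cells}</tr>")
    rows.append("</table>\n")
    sections = []
    by_query: Dict[str, List[ScoredCandidate]] = {}
    for sc in ordered:
        by_query.setdefault(sc.candidate.query_id, []).append(sc)
    for qid, group in by_query.items():
        sections.append(f"<h2>Query {_html.escape(qid)}</h2>")
        for sc in group:
            sections.append(
                f"<p>rank {sc.rank}: guide {sc.candidate.guide} "
                f"({sc.uniqueness.value})</p>"
            )
            if sc.structure is not None:
                sections.append(
                    "<pre>"
                    + _html.escape(sc.structure.sequence)
                    + "\n"
                    + _html.escape(sc.structure.structure)
                    + "</pre>"
                )
    return head + "\n".join(rows) + "\n".join(sections) + "\n</body></html>\n"


def run_pipeline(
    query_fasta: Union[str, Path],
    genome_fasta: Union[str, Path],
    vcf_path: Optional[Union[str, Path]] = None,
    anchor: Optional[GenomicRegion] = None,
    search_params: Optional[SearchParams] = None,
    fold_params: Optional[FoldParams] = None,
    rank_keys: Sequence[str] = DEFAULT_RANK_KEYS,
    format: str = "tsv",
    out_path: Optional[Union[str, Path]] = None,
    normalize_chr_prefix: bool = False,
) -> Tuple[str, List[ScoredCandidate]]:
    """End-to-end design run: scan, search, annotate, fold, rank, render.

    Returns (report text, ranked candidates); also writes the report when
    ``out_path`` is given.  Zero candidates is not an error (warning only).
    Ranks are assigned globally across all query records; the HTML report
    additionally groups per-record sections.
    """
    from .variants import read_vcf

    queries = read_fasta(query_fasta)
    genome = read_fasta(genome_fasta)
    index = build_index(genome, search_params)
    variant_records = read_vcf(vcf_path) if vcf_path is not None else None

    all_scored: List[ScoredCandidate] = []
    for qid, qseq in queries.records.items():
        cands = scan_candidates(qid, qseq)
        if anchor is not None:
            if len(anchor) != len(qseq):
                raise ValueError(
                    f"anchor length {len(anchor)} != query {qid} length {len(qseq)}"
                )
            cands = [map_to_genome(c, anchor) for c in cands]
        logger.info("query %s: %d candidate site(s)", qid, len(cands))
        for cand in cands:
            all_scored.append(
                score_candidate(
                    cand, index, variant_records, fold_params, search_params,
                    normalize_chr_prefix,
                )
            )
    if not all_scored:
        logger.warning("no candidate targets found in any query record")
    ranked = rank_candidates(all_scored, rank_keys)
    text = render_report(ranked, format)
    if out_path is not None:
        Path(out_path).write_text(text)
    return text, ranked
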