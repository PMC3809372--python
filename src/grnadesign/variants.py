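"""VCF reading and target-region variant overlap annotation.

A variant's reference span is ``[pos, pos + len(ref) - 1]``; it overlaps a
target region when the spans intersect.  The distance to the 3' end is
measured strand-aware on the forward genome axis, with the 3'-terminal base
of the 23-bp region (the PAM-proximal end) at distance 0.  For indels the
intersecting base nearest the 3' end is used.  This metric is a documented
convention of this package, not a claim about any external tool's counting.

Only the five mandatory VCF columns (CHROM, POS, ID, REF, ALT) are used;
INFO/FORMAT and genotypes are ignored.  Plain and gzip/bgzip text are both
accepted.  The columns are parsed directly so that malformed data lines can
be reported with their line number.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

from .genome import GenomicRegion


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based position of the first REF base
    id: str
    ref: str
    alt: Tuple[str, ...]

    @property
    def kind(self) -> str:
        """'snp' | 'indel' | 'other', from allele lengths."""
        if len(self.ref) == 1 and self.alt and all(len(a) == 1 for a in self.alt):
            return "snp"
        if self.alt and any(len(a) != len(self.ref) for a in self.alt):
            return "indel"
        return "other"

    @property
    def span(self) -> Tuple[int, int]:
        """1-based inclusive reference span."""
        return self.pos, self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: VariantRecord
    dist_3prime: int


def _open_text(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def read_vcf(path: Union[str, Path]) -> List[VariantRecord]:
    """Read VCF 4.x (plain or bgzipped) into VariantRecord objects.

    Multi-allelic records are kept as one record with multiple ALTs.
    Malformed data lines (fewer than 5 fields, non-integer POS, empty REF)
    raise ValueError naming the line number.
    """
    path = Path(path)
    records: List[VariantRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}: malformed VCF data line {lineno}: "
                    f"expected >= 5 fields, got {len(fields)}"
                )
            chrom, pos_s, vid, ref, alt_s = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer POS {pos_s!r}"
                ) from None
            if pos < 1 or not ref:
                raise ValueError(f"{path}: line {lineno}: invalid POS/REF")
            alts = tuple(a for a in alt_s.split(",") if a and a != ".")
            records.append(VariantRecord(chrom, pos, vid or ".", ref.upper(), alts))
    return records


def overlap_variants(
    region: GenomicRegion,
    variants: List[VariantRecord],
    normalize_chr_prefix: bool = False,
) -> List[AnnotatedVariant]:
    """Variants whose reference span intersects ``region``, with 3'-end distance.

    Output is sorted by dist_3prime ascending (ties by position, then id).
    Chromosomes are matched by exact name unless ``normalize_chr_prefix``
    strips a leading "chr" from both sides first.
    """

    def norm(name: str) -> str:
        return name[3:] if normalize_chr_prefix and name.startswith("chr") else name

    region_chrom = norm(region.chrom)
    out: List[AnnotatedVariant] = []
    for v in variants:
        if norm(v.chrom) != region_chrom:
            continue
        lo, hi = v.span
        if hi < region.start or lo > region.end:
            continue
        if region.strand == "+":
            nearest = min(hi, region.end)  # intersecting base nearest region.end
            dist = region.end - nearest
        else:
            nearest = max(lo, region.start)
            dist = nearest - region.start
        out.append(AnnotatedVariant(v, dist))
    out.sort(key=lambda av: (av.dist_3prime, av.variant.pos, av.variant.id))
    return out


def count_snps(annotated: List[AnnotatedVariant]) -> int:
    """Number of overlapping variants (SNPs and indels both count)."""
    return len(annotated)
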