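"""Seeded synthetic genomes, queries and VCFs with known ground truth.

These generators build the controlled study conditions every stage is
tested against: a random background genome with chosen 23-mers implanted as
exact / 1-mismatch / 2-mismatch copies, and a VCF with SNPs and indels at
known offsets inside and outside the implanted target regions.  The
generator verifies post hoc, by brute-force Hamming scan of both strands,
that no accidental near-copies of any implant exist in the background, and
regenerates the background if one does — so implant hit counts are exact
ground truth, not merely probable.

Also ships a transcription of eight experimentally reported human guides
(PVALB, AAVS1, VEGFA) with their published per-guide annotations, used as a
display-fidelity reference set.  The genomic coordinate strings and rsIDs
in it are carried as opaque text: they are facts about hg19/dbSNP builds
and are never used as computational ground truth here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome import Genome, GenomicRegion
from .offtarget import TARGET_LEN

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Implant:
    """A 23-mer to embed: n_exact perfect copies plus mutated copies."""

    seq: str
    n_exact: int = 1
    n_1mm: int = 0
    n_2mm: int = 0

    def __post_init__(self) -> None:
        if len(self.seq) != TARGET_LEN:
            raise ValueError(f"implant must be {TARGET_LEN} bp")
        if set(self.seq) - set("ACGT"):
            raise ValueError("implant must be over ACGT")

    @property
    def n_copies(self) -> int:
        return self.n_exact + self.n_1mm + self.n_2mm


@dataclass(frozen=True)
class VariantPlan:
    """A variant at a 0-based ``offset`` relative to one implant placement.

    Negative offsets or offsets >= 23 place the variant outside the target
    region (boundary-behaviour fixtures).  kind: snp | deletion | insertion.
    """

    implant_index: int
    copy_index: int
    offset: int
    kind: str = "snp"

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "deletion", "insertion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    genome_length: int
    gc_fraction: float = 0.5
    chrom: str = "chr1"
    implants: Tuple[Implant, ...] = ()
    variant_plan: Tuple[VariantPlan, ...] = ()


@dataclass(frozen=True)
class ImplantPlacement:
    implant_index: int
    copy_index: int
    sequence: str  # actual (possibly mutated) 23-mer placed
    region: GenomicRegion  # plus strand, forward axis
    mismatches: int
    mismatch_offsets: Tuple[int, ...]  # 1-based within the 23-mer


@dataclass(frozen=True)
class VariantTruth:
    plan: VariantPlan
    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    in_region: bool
    dist_3prime: Optional[int]  # None when outside the target region


@dataclass
class FixtureTruth:
    spec: FixtureSpec
    genome_seq: str
    placements: List[ImplantPlacement] = field(default_factory=list)
    variants: List[VariantTruth] = field(default_factory=list)

    def placements_of(self, implant_index: int) -> List[ImplantPlacement]:
        return [p for p in self.placements if p.implant_index == implant_index]


def _brute_hits(genome_seq: str, query: str, max_mm: int) -> List[Tuple[int, str, int]]:
    """All (0-based start, strand, mismatches) windows within max_mm (numpy scan)."""
    from .genome import reverse_complement

    g = np.frombuffer(genome_seq.encode(), dtype=np.uint8)
    out: List[Tuple[int, str, int]] = []
    n_win = len(g) - TARGET_LEN + 1
    if n_win <= 0:
        return out
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        mm = np.zeros(n_win, dtype=np.int16)
        for k in range(TARGET_LEN):
            mm += g[k : k + n_win] != qa[k]
        for pos in np.nonzero(mm <= max_mm)[0]:
            out.append((int(pos), strand, int(mm[pos])))
    return out


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> Tuple[str, Tuple[int, ...]]:
    positions = sorted(rng.choice(TARGET_LEN, size=n_mut, replace=False).tolist())
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(3))]
    return "".join(chars), tuple(p + 1 for p in positions)


def make_genome(spec: FixtureSpec, max_attempts: int = 50) -> Tuple[str, FixtureTruth]:
    """Deterministic (per seed) FASTA text plus its ground-truth table.

    Raises if the implant copies cannot be placed without overlap, or if no
    attempt produces a background free of accidental near-copies.
    """
    total_copies = sum(im.n_copies for im in spec.implants)
    if total_copies * (2 * TARGET_LEN) > spec.genome_length:
        raise ValueError("implants cannot be placed without overlap in genome_length")

    rng = np.random.default_rng(spec.seed)
    for _attempt in range(max_attempts):
        arr = _random_background(rng, spec.genome_length, spec.gc_fraction)

        # non-overlapping slots, left to right with random gaps
        n_slots = total_copies
        free = spec.genome_length - n_slots * TARGET_LEN
        gaps = rng.multinomial(free, np.ones(n_slots + 1) / (n_slots + 1))
        starts: List[int] = []
        cursor = 0
        for i in range(n_slots):
            cursor += int(gaps[i])
            starts.append(cursor)
            cursor += TARGET_LEN
        order = rng.permutation(n_slots)

        placements: List[ImplantPlacement] = []
        slot = 0
        for idx, im in enumerate(spec.implants):
            copies: List[Tuple[str, Tuple[int, ...]]] = [(im.seq, ())] * im.n_exact
            for _ in range(im.n_1mm):
                copies.append(_mutate(rng, im.seq, 1))
            for _ in range(im.n_2mm):
                copies.append(_mutate(rng, im.seq, 2))
            for copy_index, (seq, offs) in enumerate(copies):
                start0 = starts[int(order[slot])]
                slot += 1
                arr[start0 : start0 + TARGET_LEN] = np.frombuffer(seq.encode(), np.uint8)
                placements.append(
                    ImplantPlacement(
                        idx,
                        copy_index,
                        seq,
                        GenomicRegion(spec.chrom, start0 + 1, start0 + TARGET_LEN, "+"),
                        len(offs),
                        offs,
                    )
                )
        genome_seq = arr.tobytes().decode()

        if _verify(spec, genome_seq, placements):
            placements.sort(key=lambda p: (p.implant_index, p.copy_index))
            truth = FixtureTruth(spec, genome_seq, placements)
            fasta = _to_fasta(spec.chrom, genome_seq)
            return fasta, truth
    raise RuntimeError(f"no accidental-copy-free background found in {max_attempts} attempts")


def _verify(spec: FixtureSpec, genome_seq: str, placements: List[ImplantPlacement]) -> bool:
    """Planned <=1-mismatch occurrence set must be exactly what the scan finds."""
    for idx, im in enumerate(spec.implants):
        expected = {
            (p.region.start - 1, "+", p.mismatches)
            for p in placements
            if p.implant_index == idx and p.mismatches <= 1
        }
        found = set(_brute_hits(genome_seq, im.seq, 1))
        if found != expected:
            return False
        # mutated copies must differ at exactly the stated count
        for p in placements:
            if p.implant_index == idx:
                hd = sum(a != b for a, b in zip(p.sequence, im.seq))
                if hd != p.mismatches:
                    return False
    return True


def _to_fasta(name: str, seq: str, width: int = 70) -> str:
    lines = [f">{name}"]
    lines += [seq[i : i + width] for i in range(0, len(seq), width)]
    return "\n".join(lines) + "\n"


_ALT_SNP = {"A": "G", "C": "T", "G": "A", "T": "C"}


def make_vcf(spec: FixtureSpec, truth: FixtureTruth) -> str:
    """VCF 4.2 text realizing ``spec.variant_plan`` on the generated genome.

    REF always matches the genome at POS; each record's truth (position,
    whether it falls inside its implant region, and the expected distance to
    the region's 3' end) is appended to ``truth.variants``.
    """
    genome_seq = truth.genome_seq
    records: List[VariantTruth] = []
    for i, plan in enumerate(spec.variant_plan):
        anchors = [
            p for p in truth.placements
            if p.implant_index == plan.implant_index and p.copy_index == plan.copy_index
        ]
        if not anchors:
            raise ValueError(f"variant plan {i}: no placement for implant {plan.implant_index} copy {plan.copy_index}")
        region = anchors[0].region
        pos = region.start + plan.offset
        if pos < 1 or pos > len(genome_seq):
            raise ValueError(f"variant plan {i}: offset {plan.offset} outside genome")
        if plan.kind == "snp":
            ref = genome_seq[pos - 1]
            alt = _ALT_SNP[ref]
        elif plan.kind == "deletion":
            ref = genome_seq[pos - 1 : pos + 2]
            alt = ref[0]
        else:  # insertion
            ref = genome_seq[pos - 1]
            alt = ref + "ACG"
        if pos < 1 or pos - 1 + len(ref) > len(genome_seq):
            raise ValueError(f"variant plan {i}: offset {plan.offset} outside genome")
        span_lo, span_hi = pos, pos + len(ref) - 1
        inside = span_hi >= region.start and span_lo <= region.end
        dist = region.end - min(span_hi, region.end) if inside else None
        records.append(
            VariantTruth(plan, f"rs_fix{i}", spec.chrom, pos, ref, alt, inside, dist)
        )
    truth.variants = records

    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={spec.chrom},length={len(genome_seq)}>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    body = "".join(
        f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\n"
        for v in sorted(records, key=lambda v: v.pos)
    )
    return header + body


# ---------------------------------------------------------------------------
# bundled end-to-end fixture

#: implanted 23-mers: four experimentally reported human guides plus one more,
#: each given an NGG context so candidate discovery finds them.  Copy numbers
#: and variant placements emulate the published per-guide annotation patterns
#: (a unique 0-SNP guide, a unique 3-SNP guide, a 2-locus guide, ...).
BUNDLED_IMPLANTS = (
    Implant("ATTGGGTGTTCAGGGCAGAG" + "TGG", 1, 0, 0),  # unique, 1 SNP near 3' end
    Implant("GTGGCGAGAGGGGCCGAGAT" + "CGG", 1, 0, 0),  # unique, 3 SNPs
    Implant("GGGGCCACTAGGGACAGGAT" + "CGG", 1, 0, 0),  # unique, 0 SNPs
    Implant("GTCCCCTCCACCCCACAGTG" + "AGG", 1, 1, 0),  # one extra 1-mismatch locus
    Implant("GGTGAGTGAGTGTGTGCGTG" + "CGG", 1, 0, 1),  # unique at <=1 mm; SNP + indel
)

BUNDLED_VARIANT_PLAN = (
    VariantPlan(0, 0, 20, "snp"),       # inside, 2 bp to 3' end
    VariantPlan(0, 0, -5, "snp"),       # upstream of the region: excluded
    VariantPlan(0, 0, 23, "snp"),       # one past the region end: excluded
    VariantPlan(1, 0, 4, "snp"),        # 18 bp to 3' end
    VariantPlan(1, 0, 12, "snp"),       # 10 bp
    VariantPlan(1, 0, 13, "snp"),       # 9 bp
    VariantPlan(3, 1, 15, "snp"),       # on the off-target (1-mismatch) locus
    VariantPlan(4, 0, 19, "deletion"),  # 3-bp deletion, 1 bp to 3' end
    VariantPlan(4, 0, 10, "snp"),       # 12 bp
)

#: per query record: (record name, implant index, expected n_hits,
#: expected n_variants at the primary locus, expected sorted distances, rank)
BUNDLED_EXPECTATIONS = {
    "targetA": (0, 1, 1, (2,), 2),
    "targetB": (1, 1, 3, (9, 10, 18), 4),
    "targetC": (2, 1, 0, (), 1),
    "targetD": (3, 2, 0, (), 5),
    "targetE": (4, 1, 2, (1, 12), 3),
}


def bundled_fixture_spec(seed: int = 7) -> FixtureSpec:
    return FixtureSpec(
        seed=seed,
        genome_length=50_000,
        gc_fraction=0.5,
        implants=BUNDLED_IMPLANTS,
        variant_plan=BUNDLED_VARIANT_PLAN,
    )


def bundled_query_fasta() -> str:
    """Query FASTA: one record per implanted 23-mer, in guide orientation."""
    lines = []
    for name, (idx, *_rest) in sorted(BUNDLED_EXPECTATIONS.items()):
        lines.append(f">{name}")
        lines.append(BUNDLED_IMPLANTS[idx].seq)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# published reference guide set

@dataclass(frozen=True)
class ReferenceGuide:
    gene: str
    guide: str
    region: str  # opaque display string (external genome build coordinates)
    n_hits: int
    n_snps: int
    bp_in_loops: int
    at_percent: int
    efficiency: str
    assay: str
    low_efficiency: bool


def load_reference_set() -> List[ReferenceGuide]:
    """The eight experimentally reported human guides with their annotations."""
    path = resources.files("grnadesign.data").joinpath("reference_guides.tsv")
    with path.open() as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    if len(rows) != 8:
        raise ValueError(f"reference guide table corrupt: expected 8 rows, got {len(rows)}")
    out = []
    for r in rows:
        out.append(
            ReferenceGuide(
                gene=r["gene"],
                guide=r["guide"],
                region=r["region"],
                n_hits=int(r["n_hits"]),
                n_snps=int(r["n_snps"]),
                bp_in_loops=int(r["bp_in_loops"]),
                at_percent=int(r["at_percent"]),
                efficiency=r["efficiency"],
                assay=r["assay"],
                low_efficiency=r["low_efficiency"] == "yes",
            )
        )
    return out
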