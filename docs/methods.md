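# Methods

## Pipeline model

`grnadesign` implements the classic five-stage guide-RNA design procedure
for S. pyogenes Cas9: (1) scan query sequences on both strands for 23-bp
windows matching N₂₀NGG; (2) map each candidate 23-mer to the reference
genome within a mismatch budget to assess uniqueness; (3) intersect the
mapped regions with a VCF of known SNPs/indels; (4) predict a secondary
structure for the full gRNA (guide + scaffold) and count guide bases
locked into intramolecular pairs; (5) rank and report.

Assumptions: targets are ungapped 23-bp sites; the PAM is strictly NGG
(no NAG or other alternates); off-target similarity is Hamming distance
over the literal 23-mer including the PAM bases, so an off-target locus is
counted even if its own PAM is degenerate. Indels between a guide and a
genomic placement are not modeled.

## Coordinates and strand conventions

All user-facing coordinates are 1-based inclusive; a target region is
rendered `chrom:start-end(strand)` and always spans 23 bp. Minus-strand
regions keep forward-axis coordinates; the strand only selects whether a
fetch returns the forward substring or its reverse complement. FASTA input
is uppercased; IUPAC ambiguity codes other than N are converted to N with
a warning, and N never matches any base in the search (a conservative
choice that avoids phantom candidates at ambiguous positions). Candidate
windows containing N are dropped and counted in the log, since such guides
cannot be synthesized or scored meaningfully.

## Candidate discovery

A sliding-window scan (not a plain regex, which would miss overlapping
matches) reports every forward window ending in GG and every window
beginning with CC as a reverse-strand site in guide orientation, so a GGG
run yields two overlapping PAMs. Each occurrence of a repeated 23-mer is
reported separately. With a genomic anchor for the query
(`--anchor chrom:start-end`), candidates also get genome-space
coordinates by offset arithmetic.

## Off-target search

The genome-wide search is an in-memory pigeonhole k-mer index: the 23-mer
is split into `max_mismatches + 1` near-equal parts, so any placement
within the budget matches at least one part exactly; exact part lookups
propose window starts, and each proposal is verified by a full Hamming
comparison. This is fully sensitive at the configured budget — verified
against an exhaustive scan oracle in the test suite — while staying fast
enough to index a genome per run without an on-disk index. Defaults
(`max_mismatches=1`, `max_hits=10`, `seed_length=16`) mirror a
conventional short-read-aligner configuration for 23-bp queries;
`seed_length` is accepted for interface parity but does not change
results, because the pigeonhole split already guarantees sensitivity (as
an ungapped `-v`-mode alignment would). Hits are ordered deterministically
by (mismatches, chrom, start, strand) and truncated after `max_hits` with
a flag; a candidate is *unique* iff exactly one placement is reported and
the cap was not reached. The candidate's own locus counts as a hit, so a
well-behaved genome-derived guide reports one placement. Reverse-strand
mismatch offsets are reported in guide orientation (1 = guide 5′ end).

## Variant annotation

A variant's reference span is `[POS, POS + len(REF) − 1]`; it is annotated
onto a target region when the spans intersect. The distance metric places
the 3′-terminal base of the 23-bp region (PAM-proximal end) at distance 0
and measures strand-aware along the genome axis; for indels the
intersecting base nearest the 3′ end is used. This convention is
self-consistent (for a SNP inside a region the two strand readings sum
to 22) but is a documented package convention — published per-variant
distances from other tools may count from the 20-mer end or 1-based, and
we do not assert equivalence. Both SNPs and indels enter the per-candidate
variant count (the report distinguishes kind so users can filter). Only
variants at the candidate's primary locus (its best, normally 0-mismatch
placement) are counted for ranking; variants at off-target loci are listed
per hit but not scored, since they describe a different genomic site.
Chromosome names are matched exactly unless `--normalize-chr-prefix` is
given. The five mandatory VCF columns are parsed directly (plain or
bgzipped text) so malformed lines can be reported with line numbers;
INFO/FORMAT/genotypes are ignored.

## Structure scoring

The default folding engine is Nussinov-style base-pair maximization with
min_loop = 3, Watson-Crick plus G·U wobble pairs, and no pseudoknots,
computed by an O(n³) dynamic program (numpy-vectorized inner maximization)
with deterministic traceback: among co-optimal structures it prefers
leaving the left index unpaired, then pairing it with the smallest partner
index. Base-pair maximization is a structural proxy, not a thermodynamic
model — it finds the most-paired structure, not the minimum-free-energy
one, so its pair counts are not comparable to Turner-parameter folders.
Users wanting MFE structures can import external dot-bracket output via
`import_structure`, which validates balance, length and loop size and
downgrades noncanonical pairs to warnings.

The guide is folded together with a 3′ scaffold (default: the canonical
80-nt S. pyogenes tracrRNA-fusion scaffold shipped in
`grnadesign/data/sgrna_scaffold.txt`; replaceable with `--scaffold FILE`
or removable with `--no-scaffold`). Because the base-availability wording
in the field is ambiguous, both readings are reported per candidate:
`loop_sequestered` (guide bases paired inside the gRNA structure, i.e.
unavailable for DNA binding — the default ranking key) and `loop_free`
(unpaired guide bases); they always sum to 20.

## Ranking

Stable multi-key sort: placements ascending (unmapped candidates last,
since a query foreign to the chosen genome yields 0 hits), variant count
ascending, sequestered guide bases ascending, AT% descending (low AT
correlates with stronger off-target binding), then query position. The
first two keys are the classic uniqueness/SNP sort; the structure and AT%
keys are extensions of this package and can be disabled
(`--rank-keys hits,snps`) for the two-key behaviour. Ranks are assigned
globally across all query records of a batch; the HTML report additionally
groups per-record sections with each candidate's dot-bracket structure.

## Synthetic data generator

`grnadesign.fixtures` generates the study conditions the tests and the
acceptance script run under: an i.i.d. random background genome
(configurable length and GC fraction; defaults 50 kb, GC 0.5) with chosen
23-mers implanted as non-overlapping exact, 1-mismatch and 2-mismatch
copies, and a VCF 4.2 with SNPs/indels at chosen offsets inside and
outside the implanted regions (REF always taken from the generated
genome). After implanting, the generator brute-force-scans both strands
and regenerates the background if any accidental ≤1-mismatch copy of an
implant exists, so implant hit counts are exact ground truth. The bundled
end-to-end fixture implants five 23-mers (four experimentally reported
human guides given an NGG context, plus one more) whose copy numbers and
variant placements reproduce the canonical annotation patterns: a unique
0-SNP guide, unique guides with 1–3 SNPs at known 3′-end distances, and a
guide with one extra 1-mismatch locus.

What the generator does **not** emulate: real genome composition
(repeats, segmental duplications, GC heterogeneity), realistic variant
density or allele frequencies, and multi-chromosome structure. Passing
tests therefore demonstrate algorithmic correctness under controlled
conditions, not performance characteristics on mammalian genomes, where
repeat-rich regions will produce many more capped multi-hit candidates.

The eight-guide reference table (`data/reference_guides.tsv`) transcribes
experimentally reported human guides for PVALB, AAVS1 and VEGFA with their
published per-guide annotations. Its genomic coordinate strings and rsIDs
refer to external genome/dbSNP builds and are carried as opaque display
text, never used as computational ground truth; the AT% column, by
contrast, is recomputable from the guide sequence alone and is verified
8/8 by the tests and the acceptance script.

## Numerical and scale choices

Everything is integer arithmetic; there are no tolerances. Randomized
oracle-equivalence sweeps use seeded generators: the off-target search is
checked against an exhaustive Hamming scan on ≥1000 random
(genome ≤ 50 kb, query) instances — mostly 0.1–4 kb genomes with a few at
50 kb, sizes chosen so the brute-force oracle itself stays cheap while
covering the intended range; the folder against exhaustive structure
enumeration on ≥500 strings of length ≤12 (enumeration is infeasible much
beyond that); variant overlap against pairwise interval intersection on
≥1000 random region/variant sets.

## Known limitations

- No thermodynamic folding, partition-function metrics, or pseudoknots.
- No PAM-proximal seed-region weighting of mismatches; all 23 positions
  weigh equally in the Hamming count.
- Off-target placements are ungapped; bulged off-targets are invisible.
- No alternative PAMs (NAG, NGA, ...).
- Per-guide efficiency is not predicted; the ranking is a preference
  order over design-time risk factors, not an activity model.
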