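# grnadesign

Design candidate guide RNAs for CRISPR/Cas9 genome editing. Given one or
more query sequences (e.g. a gene or exon) and a reference genome,
`grnadesign` finds every 23-bp site matching the **N₂₀NGG** pattern (a
20-nt protospacer followed by the NGG PAM that *S. pyogenes* Cas9
requires), then evaluates each candidate on the factors that predict
editing success:

- **Uniqueness** — the full 23-mer is mapped genome-wide on both strands
  allowing at most one mismatch (Hamming distance over the literal 23-mer,
  PAM included), reporting up to 10 placements. A guide whose site occurs
  once is preferable to one with near-identical off-target loci.
- **Known variants** — SNPs and indels from a user VCF that overlap the
  target region are listed with their distance to the region's 3′
  (PAM-proximal) end; a variant under the guide can abolish recognition in
  some individuals.
- **Secondary structure** — the guide + scaffold gRNA is folded
  (base-pair maximization; see `docs/methods.md`) and the number of guide
  bases sequestered in intramolecular pairs, hence unavailable for DNA
  binding, is counted.
- **AT content** — AT% of the 20-nt guide; extremely GC-rich guides are
  flagged by a low value.

Candidates are ranked by a stable multi-key sort — fewest genomic
placements, then fewest overlapping variants, then fewest sequestered
guide bases, then highest AT% — and written as TSV or standalone HTML.

The package is a library first (`grnadesign.*` modules per pipeline
stage), with a thin `grna-design` CLI, and ships seeded synthetic-data
generators (`grnadesign.fixtures`) that implant chosen 23-mers and
variants into a random genome with exact ground truth.

## Worked example

Build a 50-kb toy genome with five implanted target sites and a matching
VCF, then run the pipeline:

```python
from pathlib import Path
from grnadesign.fixtures import bundled_fixture_spec, make_genome, make_vcf, bundled_query_fasta

spec = bundled_fixture_spec()
fasta, truth = make_genome(spec)
Path("genome.fa").write_text(fasta)
Path("variants.vcf").write_text(make_vcf(spec, truth))
Path("query.fa").write_text(bundled_query_fasta())
```

```sh
grna-design --query query.fa --genome genome.fa --vcf variants.vcf --format tsv
```

prints (abridged columns):

```
rank  query_id  guide                 n_hits  n_variants  variant_details                                   at_percent
1     targetC   GGGGCCACTAGGGACAGGAT  1       0           .                                                 35
2     targetA   ATTGGGTGTTCAGGGCAGAG  1       1           rs_fix0(2 bp to 3' end)                           45
3     targetE   GGTGAGTGAGTGTGTGCGTG  1       2           rs_fix7(1 bp to 3' end);rs_fix8(12 bp to 3' end)  40
4     targetB   GTGGCGAGAGGGGCCGAGAT  1       3           rs_fix5(9 bp to 3' end);...                       30
5     targetD   GTCCCCTCCACCCCACAGTG  2       0           .                                                 30
```

Read: `targetC` maps to exactly one genomic place with no overlapping
variants, so it ranks first. `targetA` is unique but carries a SNP 2 bp
from the PAM-proximal end. `targetD` maps to two places (an implanted
1-mismatch off-target copy), which outweighs its clean variant status and
sends it to the bottom.

The library surface mirrors the pipeline stages:

```python
from grnadesign import read_fasta, build_index, find_hits, classify_uniqueness, at_content

genome = read_fasta("genome.fa")
summary = find_hits("GGGGCCACTAGGGACAGGATCGG", build_index(genome))
classify_uniqueness(summary)   # Uniqueness.UNIQUE
at_content("GGGGCCACTAGGGACAGGAT")  # 35
```

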