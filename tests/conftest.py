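from types import SimpleNamespace

import pytest

from grnadesign.fixtures import (
    bundled_fixture_spec,
    bundled_query_fasta,
    make_genome,
    make_vcf,
)


@pytest.fixture(scope="session")
def bundled(tmp_path_factory):
    """The bundled end-to-end fixture: 50-kb genome, query FASTA, VCF, truth."""
    spec = bundled_fixture_spec()
    fasta, truth = make_genome(spec)
    vcf_text = make_vcf(spec, truth)
    d = tmp_path_factory.mktemp("bundled_fixture")
    genome_fa = d / "genome.fa"
    genome_fa.write_text(fasta)
    vcf = d / "variants.vcf"
    vcf.write_text(vcf_text)
    query_fa = d / "query.fa"
    query_fa.write_text(bundled_query_fasta())
    return SimpleNamespace(
        spec=spec,
        truth=truth,
        genome_fa=genome_fa,
        vcf=vcf,
        query_fa=query_fa,
        dir=d,
    )


def write_fasta_file(tmp_path, name: str, text: str):
    p = tmp_path / name
    p.write_text(text)
    return p
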