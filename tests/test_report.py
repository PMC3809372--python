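"""Candidate scoring, ranking semantics, and report rendering."""

import pytest

from grnadesign import GenomicRegion, rank_candidates, render_report, run_pipeline
from grnadesign.candidates import CandidateTarget
from grnadesign.offtarget import AlignmentHit, HitSummary
from grnadesign.report import TSV_COLUMNS, ScoredCandidate
from grnadesign.variants import AnnotatedVariant, VariantRecord


def make_scored(
    n_hits=1, n_snps=0, sequestered=0, at=50, query_start=1, query_id="q",
    truncated=False, dists=None,
):
    guide = ("AT" * 10)[:20]
    cand = CandidateTarget(query_id, query_start, "+", guide, "AGG")
    hits = [
        AlignmentHit(GenomicRegion("chr1", 100 + 30 * i, 122 + 30 * i, "+"), 0)
        for i in range(n_hits)
    ]
    dists = list(dists) if dists is not None else list(range(n_snps))
    variants = [
        AnnotatedVariant(VariantRecord("chr1", 100 + d, f"rs{i}", "A", ("G",)), d)
        for i, d in enumerate(sorted(dists))
    ]
    return ScoredCandidate(
        candidate=cand,
        hit_summary=HitSummary(hits=hits, truncated=truncated),
        variants=variants,
        loop_sequestered=sequestered,
        loop_free=20 - sequestered,
        at_percent=at,
    )


class TestRankCandidates:
    def test_fewer_snps_rank_first_at_equal_hits(self):
        a = make_scored(n_hits=1, n_snps=3)
        b = make_scored(n_hits=1, n_snps=0)
        assert rank_candidates([a, b]) == [b, a]
        assert (b.rank, a.rank) == (1, 2)

    def test_fewer_hits_dominate_snp_count(self):
        a = make_scored(n_hits=2, n_snps=0)
        b = make_scored(n_hits=1, n_snps=5)
        assert rank_candidates([a, b]) == [b, a]

    def test_full_tie_preserves_input_order(self):
        a = make_scored(query_start=1)
        b = make_scored(query_start=1)
        assert rank_candidates([a, b]) == [a, b]

    def test_unmapped_sort_last(self):
        mapped = make_scored(n_hits=3)
        unmapped = make_scored(n_hits=0)
        assert rank_candidates([unmapped, mapped]) == [mapped, unmapped]

    def test_structure_then_at_break_ties(self):
        loose = make_scored(sequestered=12, at=80)
        tight = make_scored(sequestered=3, at=20)
        high_at = make_scored(sequestered=3, at=60)
        assert rank_candidates([loose, tight, high_at]) == [high_at, tight, loose]

    def test_two_key_mode_ignores_extensions(self):
        a = make_scored(sequestered=19, at=0, query_start=1)
        b = make_scored(sequestered=0, at=100, query_start=2)
        assert rank_candidates([a, b], rank_keys=("hits", "snps")) == [a, b]

    def test_ranking_is_idempotent_and_gapless(self):
        cands = [make_scored(n_snps=k % 3, query_start=k + 1) for k in range(7)]
        once = rank_candidates(cands)
        twice = rank_candidates(once)
        assert once == twice
        assert [c.rank for c in twice] == list(range(1, 8))

    def test_unknown_key_errors(self):
        with pytest.raises(ValueError, match="unknown rank key"):
            rank_candidates([make_scored()], rank_keys=("hits", "bogus"))


class TestRenderReport:
    def test_tsv_row_contents(self):
        sc = make_scored(n_snps=1, dists=[2])
        sc.variants[0] = AnnotatedVariant(VariantRecord("chr1", 102, "rs_test", "A", ("G",)), 2)
        text = render_report(rank_candidates([sc]), "tsv")
        header, row = text.strip().split("\n")
        assert header.split("\t") == TSV_COLUMNS
        vals = dict(zip(TSV_COLUMNS, row.split("\t")))
        assert vals["variant_details"] == "rs_test(2 bp to 3' end)"
        assert vals["genomic_region"] == "chr1:100-122(+)"
        assert vals["rank"] == "1" and vals["n_variants"] == "1"

    def test_empty_list_is_header_only(self):
        assert render_report([], "tsv").strip() == "\t".join(TSV_COLUMNS)

    def test_region_rendering_minus_strand(self):
        sc = make_scored()
        sc.hit_summary.hits[0] = AlignmentHit(
            GenomicRegion("chr19", 55627117, 55627139, "-"), 0
        )
        text = render_report(rank_candidates([sc]), "tsv")
        assert "chr19:55627117-55627139(-)" in text

    def test_tsv_round_trip_numeric_fields(self):
        cands = rank_candidates(
            [make_scored(n_snps=2, sequestered=7, at=35, query_start=4)]
        )
        text = render_report(cands, "tsv")
        row = dict(zip(TSV_COLUMNS, text.strip().split("\n")[1].split("\t")))
        sc = cands[0]
        assert int(row["rank"]) == sc.rank
        assert int(row["query_start"]) == sc.candidate.query_start
        assert int(row["n_hits"]) == sc.n_hits
        assert int(row["n_variants"]) == sc.n_variants
        assert int(row["loop_sequestered"]) == sc.loop_sequestered
        assert int(row["loop_free"]) == sc.loop_free
        assert int(row["at_percent"]) == sc.at_percent

    def test_html_contains_table_and_structure(self):
        from grnadesign.structure import import_structure

        sc = make_scored()
        sc.structure = import_structure("GAAAC" * 5, "." * 25)
        html = render_report(rank_candidates([sc]), "html")
        assert html.startswith("<!DOCTYPE html>")
        assert "<table>" in html and "<pre>" in html

    def test_unknown_format_errors(self):
        with pytest.raises(ValueError, match="unknown report format"):
            render_report([], "pdf")


class TestRunPipeline:
    def test_end_to_end_smoke(self, bundled, tmp_path):
        out = tmp_path / "report.tsv"
        text, ranked = run_pipeline(
            bundled.query_fa, bundled.genome_fa, bundled.vcf, out_path=out
        )
        assert out.read_text() == text
        assert len(ranked) == 5
        assert [sc.rank for sc in ranked] == [1, 2, 3, 4, 5]

    def test_batch_reports_every_query_record(self, bundled):
        text, ranked = run_pipeline(bundled.query_fa, bundled.genome_fa, None, format="html")
        for qid in ("targetA", "targetB", "targetC", "targetD", "targetE"):
            assert f"Query {qid}" in text

    def test_no_vcf_marks_unannotated(self, bundled):
        _, ranked = run_pipeline(bundled.query_fa, bundled.genome_fa, None)
        assert all(sc.unannotated and sc.n_variants == 0 for sc in ranked)

    def test_zero_candidates_is_not_an_error(self, bundled, tmp_path, caplog):
        import logging

        q = tmp_path / "q.fa"
        q.write_text(">empty\n" + "AT" * 20 + "\n")
        with caplog.at_level(logging.WARNING):
            text, ranked = run_pipeline(q, bundled.genome_fa, None)
        assert ranked == [] and "no candidate" in caplog.text

    def test_anchor_length_mismatch_errors(self, bundled, tmp_path):
        q = tmp_path / "q.fa"
        q.write_text(">q\n" + "A" * 21 + "TGG\n")
        with pytest.raises(ValueError, match="anchor length"):
            run_pipeline(
                q, bundled.genome_fa, None, anchor=GenomicRegion("chr1", 1, 100, "+")
            )
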