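"""TcGT calling predicates, aggregation chaining, and driver enrichment."""

import pandas as pd
import pytest

from tcgtscope.repeats import TEInstance
from tcgtscope.stats import hypergeom_sf
from tcgtscope.tcgt import (
    TcGT,
    TranscriptModel,
    aggregate_tcgts,
    call_tcgts,
    tcgt_enrichment_table,
    transcript_tss,
)


def ltr(chrom, start, end, subfam="LTR12C", lid=None):
    return TEInstance(chrom=chrom, start=start, end=end, strand="+",
                      subfamily=subfam, family=".", te_class="LTR",
                      locus_id=lid or f"{subfam}:{start}")


GENES = pd.DataFrame(
    [("GENE1", "chr1", "+", 5000, 5300), ("GENE1", "chr1", "+", 7000, 7200),
     ("GENE2", "chr1", "+", 20000, 20400)],
    columns=["gene_id", "chrom", "strand", "start", "end"],
)
CATALOG = [ltr("chr1", 1000, 1600, lid="L1"), ltr("chr1", 15000, 15800, "THE1D", lid="L2")]


def tm(tid, exons, strand="+", sample="s1", chrom="chr1"):
    return TranscriptModel(tid, sample, chrom, strand, exons)


class TestTss:
    @pytest.mark.parametrize(
        "strand,exons,expected",
        [("+", [(100, 200), (300, 400)], 100),
         ("-", [(100, 200), (300, 400)], 399),
         ("+", [(50, 80)], 50)],
    )
    def test_strand_aware_five_prime(self, strand, exons, expected):
        assert transcript_tss(tm("t", exons, strand)) == expected


class TestCalling:
    def test_spliced_transcript_from_ltr_is_called(self):
        t = tm("t1", [(1100, 1250), (5000, 5300)])
        (call,) = call_tcgts([t], CATALOG, GENES)
        assert (call.driver_locus_id, call.gene_id, call.tss) == ("L1", "GENE1", 1100)

    def test_mono_exonic_transcript_rejected(self):
        t = tm("t1", [(1100, 1400)])
        assert call_tcgts([t], CATALOG, GENES) == []

    def test_tss_one_bp_outside_ltr_rejected(self):
        t = tm("t1", [(999, 1250), (5000, 5300)])
        assert call_tcgts([t], CATALOG, GENES) == []
        # half-open: the end coordinate itself is outside
        t2 = tm("t2", [(1600, 1700), (5000, 5300)])
        assert call_tcgts([t2], CATALOG, GENES) == []

    def test_junction_into_intergenic_rejected(self):
        t = tm("t1", [(1100, 1250), (9000, 9200)])
        assert call_tcgts([t], CATALOG, GENES) == []

    def test_cognate_gene_is_largest_downstream_overlap(self):
        genes = pd.DataFrame(
            [("GENEA", "chr1", "+", 5000, 5100), ("GENEB", "chr1", "+", 5050, 5400)],
            columns=["gene_id", "chrom", "strand", "start", "end"],
        )
        t = tm("t1", [(1100, 1250), (5050, 5400)])
        (call,) = call_tcgts([t], CATALOG, genes)
        assert call.gene_id == "GENEB"

    def test_minus_strand_call(self):
        # gene upstream of the LTR; transcript runs right-to-left
        t = tm("t1", [(5000, 5300), (15100, 15300)], strand="-")
        (call,) = call_tcgts([t], CATALOG, GENES)
        assert (call.driver_locus_id, call.tss) == ("L2", 15299)

    def test_every_call_satisfies_predicates(self, study, curated_catalog):
        """Brute-force recheck of containment and junction predicates."""
        transcripts = [m for ms in study.transcriptomes.values() for m in ms]
        calls = call_tcgts(transcripts, curated_catalog, study.annotation.genes)
        ltrs = [t for t in curated_catalog if t.te_class == "LTR"]
        by_tid = {t.transcript_id: t for t in transcripts}
        for c in calls:
            t = by_tid[c.transcript_id]
            assert t.n_junctions >= 1
            assert any(te.chrom == t.chrom and te.start <= c.tss < te.end for te in ltrs)


def mk(gene, tss, subfam="S", sample="s1", locus="l1"):
    return TcGT(driver_locus_id=locus, driver_subfamily=subfam, gene_id=gene,
                tss=tss, sample_id=sample)


class TestAggregation:
    def test_chain_breaks_beyond_window(self):
        calls = [mk("g", 100), mk("g", 150), mk("g", 260)]
        aggs = aggregate_tcgts(calls, window=100)
        assert sorted(a.member_tss for a in aggs) == [[100, 150], [260]]

    def test_single_linkage_chains_through(self):
        calls = [mk("g", 100), mk("g", 190), mk("g", 260)]
        (agg,) = aggregate_tcgts(calls, window=100)
        assert agg.member_tss == [100, 190, 260]
        assert agg.representative_tss == 100

    def test_one_call_one_aggregate(self):
        (agg,) = aggregate_tcgts([mk("g", 42)])
        assert agg.member_tss == [42]

    def test_permutation_invariant_and_group_counts(self):
        calls = [mk("g", 100, sample="a1"), mk("g", 150, sample="a2"), mk("g", 260, sample="b1")]
        groups = {"a1": "A", "a2": "A", "b1": "B"}
        fwd = aggregate_tcgts(calls, groups=groups)
        rev = aggregate_tcgts(list(reversed(calls)), groups=groups)
        assert [a.member_tss for a in fwd] == [a.member_tss for a in rev]
        by_rep = {a.representative_tss: a.group_counts for a in fwd}
        assert by_rep == {100: {"A": 2, "B": 0}, 260: {"A": 0, "B": 1}}

    def test_genes_and_subfamilies_never_co_aggregate(self):
        calls = [mk("g1", 100), mk("g2", 120), mk("g1", 130, subfam="T")]
        assert len(aggregate_tcgts(calls)) == 3


class TestEnrichment:
    def _catalog(self, n_s=20, n_other=180):
        cat = [ltr("chr1", 10_000 * i, 10_000 * i + 500, "S", lid=f"S{i}") for i in range(n_s)]
        cat += [ltr("chr2", 10_000 * i, 10_000 * i + 500, "O", lid=f"O{i}") for i in range(n_other)]
        return cat

    def test_planted_subfamily_has_smallest_padj(self):
        cat = self._catalog()
        calls = [mk(f"g{i}", 100, "S", "s1", f"S{i}") for i in range(8)]
        calls += [mk(f"h{i}", 100, "O", "s1", f"O{i}") for i in range(2)]
        aggs = aggregate_tcgts(calls, groups={"s1": "G"})
        rows = tcgt_enrichment_table(aggs, cat, {"s1": "G"})
        best = min(rows, key=lambda r: (r.padj, r.subfamily))
        assert best.subfamily == "S"
        s_row = next(r for r in rows if r.subfamily == "S")
        assert s_row.p == pytest.approx(hypergeom_sf(8, 20, 10, 200), rel=1e-12)
        assert s_row.tcgt_count == 8

    def test_single_subfamily_catalog_gives_p_one(self):
        cat = [ltr("chr1", 10_000 * i, 10_000 * i + 500, "S", lid=f"S{i}") for i in range(10)]
        calls = [mk(f"g{i}", 100, "S", "s1", f"S{i}") for i in range(4)]
        aggs = aggregate_tcgts(calls, groups={"s1": "G"})
        (row,) = tcgt_enrichment_table(aggs, cat, {"s1": "G"})
        assert row.p == pytest.approx(1.0)

    def test_group_without_calls_gets_count_zero_p_one(self):
        cat = self._catalog()
        rows = tcgt_enrichment_table([], cat, {"s1": "G"})
        assert {r.subfamily for r in rows} == {"S", "O"}
        assert all(r.tcgt_count == 0 and r.p == 1.0 for r in rows)
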