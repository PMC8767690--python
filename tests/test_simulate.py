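"""Generator determinism, internal consistency, and file round-trips."""

import dataclasses
import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tcgtscope import io as tio
from tcgtscope import simulate
from tcgtscope.pipeline import curate_catalog
from tcgtscope.repeats import merge_fragments, read_catalog
from tcgtscope.simulate import GroundTruth, SimulationConfig, simulate_annotation, simulate_study
from tcgtscope.tcgt import call_tcgts


def _key(t):
    return (t.chrom, t.start, t.end, t.strand, t.subfamily, t.is_solo_ltr, t.locus_id)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path, study):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate.write_study(study, d1)
        simulate.write_study(simulate_study(SimulationConfig(seed=42)), d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert filecmp.cmp(d1 / rel, d2 / rel, shallow=False), rel

    def test_different_seeds_differ(self):
        a = simulate_annotation(SimulationConfig(seed=1))
        b = simulate_annotation(SimulationConfig(seed=2))
        assert {_key(t) for t in a.truth_catalog} != {_key(t) for t in b.truth_catalog}


class TestAnnotation:
    def test_no_fragmentation_gives_truth_directly(self):
        cfg = SimulationConfig(seed=5, fragmentation_prob=0.0, n_exonic_tes=0)
        ann = simulate_annotation(cfg)
        standalone_truth = {_key(t) for t in ann.truth_catalog if len(t.merged_from) <= 1}
        standalone_raw = {
            (t.chrom, t.start, t.end, t.strand, t.subfamily) for t in ann.raw_records
            if "." not in t.locus_id
        }
        assert {k[:5] for k in standalone_truth} == standalone_raw

    def test_fragment_reassembly_round_trip(self):
        cfg = SimulationConfig(seed=6)
        ann = simulate_annotation(cfg)
        merged = merge_fragments(ann.raw_records, max_gap=100)
        merged_keys = {(t.chrom, t.start, t.end, t.subfamily) for t in merged
                       if not t.locus_id.startswith("AluY_exonic")}
        # every pre-fragmentation span is restored exactly
        for t in ann.truth_catalog:
            if len(t.merged_from) > 1:
                continue  # proviruses are assembled in a later step
            assert (t.chrom, t.start, t.end, t.subfamily) in merged_keys

    def test_curation_reproduces_truth(self):
        for seed in (11, 12, 13):
            ann = simulate_annotation(SimulationConfig(seed=seed))
            exons = [(r.chrom, r.start, r.end) for r in ann.genes.itertuples(index=False)]
            curated = curate_catalog(ann.raw_records, ann.ltr_int_pairs, exons)
            assert sorted(map(_key, curated)) == sorted(map(_key, ann.truth_catalog))

    def test_genes_and_tes_do_not_collide(self):
        ann = simulate_annotation(SimulationConfig(seed=7, n_exonic_tes=0))
        spans = [(t.chrom, t.start, t.end) for t in ann.truth_catalog]
        spans += [(r.chrom, r.start, r.end) for r in ann.genes.itertuples(index=False)]
        by_chrom = {}
        for c, s, e in spans:
            by_chrom.setdefault(c, []).append((s, e))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2


class TestTranscriptomes:
    def test_decoy_only_samples_yield_zero_calls(self, curated_catalog):
        cfg = SimulationConfig(seed=9)
        cfg.tcgt = dataclasses.replace(cfg.tcgt, planted_per_group=0, off_target_per_group=0)
        study = simulate_study(cfg)
        ann = study.annotation
        exons = [(r.chrom, r.start, r.end) for r in ann.genes.itertuples(index=False)]
        cat = curate_catalog(ann.raw_records, ann.ltr_int_pairs, exons)
        transcripts = [m for ms in study.transcriptomes.values() for m in ms]
        assert transcripts  # decoys are present
        assert call_tcgts(transcripts, cat, ann.genes) == []

    def test_empty_plan_gives_valid_empty_samples(self):
        cfg = SimulationConfig(seed=9)
        cfg.tcgt = dataclasses.replace(
            cfg.tcgt, planted_per_group=0, off_target_per_group=0, decoys_per_group=0
        )
        study = simulate_study(cfg)
        assert all(ms == [] for ms in study.transcriptomes.values())
        assert study.planted == []

    def test_planted_tss_inside_driver_locus(self, study):
        by_id = {t.locus_id: t for t in study.annotation.truth_catalog}
        for p in study.planted:
            t = by_id[p.locus_id]
            assert t.start <= p.tss < t.end
            assert t.subfamily == p.subfamily


class TestFileRoundTrips:
    def test_emitted_files_reparse_without_loss(self, tmp_path, study):
        out = tmp_path / "study"
        simulate.write_study(study, out)
        # TE catalog
        back = read_catalog(out / "repeats_truth.bed")
        assert sorted(map(_key, back)) == sorted(map(_key, study.annotation.truth_catalog))
        # gene annotation
        genes = tio.read_gene_annotation(out / "genes.gtf")
        pd.testing.assert_frame_equal(
            genes.sort_values(["gene_id", "start"]).reset_index(drop=True),
            study.annotation.genes.sort_values(["gene_id", "start"]).reset_index(drop=True),
        )
        # transcript models
        sid = next(iter(study.transcriptomes))
        models = tio.read_transcript_gtf(out / "transcriptomes" / f"{sid}.gtf", sample_id=sid)
        orig = {m.transcript_id: m.exons for m in study.transcriptomes[sid]}
        assert {m.transcript_id: m.exons for m in models} == orig
        # chrom sizes, peaks, CpGs, ground truth
        assert tio.read_chrom_sizes(out / "genome.chrom.sizes") == study.annotation.chrom_sizes
        peaks = tio.read_peaks(out / "peaks" / "rep1.bed")
        assert [(p.start, p.end) for p in peaks] == [
            (p.start, p.end) for p in study.peak_replicates["rep1"]
        ]
        rep = study.config.methyl.replicates[0]
        cpgs = tio.read_cpg_calls(out / f"cpg_{rep}.tsv", sample_id=rep)
        orig_cpgs = study.methylation_calls[study.methylation_calls["sample_id"] == rep]
        assert np.allclose(cpgs["meth_level"].to_numpy(), orig_cpgs["meth_level"].to_numpy())
        truth = GroundTruth.from_json(out / "truth.json")
        assert truth.enriched_subfamily == study.config.peaks.enriched_subfamily
        assert truth.methylation_sets == study.methylation_sets

    def test_ground_truth_scores_pipeline_without_config(self, study):
        gt = study.ground_truth
        assert len(gt.planted_tcgts) == 30
        assert set(gt.cluster_labels.values()) == {1, 2}
        assert len(gt.methylation_sets["set_a"]) == 50
        assert gt.n_true_loci == len(study.annotation.truth_catalog)
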