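"""End-to-end orchestration over a simulated study.

``curate_catalog`` is the repeat-curation recipe (fragment reassembly,
full-length ERV assembly, exon exclusion) applied in order; ``demo_report``
runs every stage of the pipeline on one simulated study and scores each
against the planted ground truth, returning a plain dict suitable for JSON
serialization.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from . import expression, methylation, peaks as peaks_mod, repeats, simulate, tcgt
from .orthologs import best_ortholog, hits_to_frame, score_synteny_table
from .repeats import TEInstance


def curate_catalog(
    raw: Sequence[TEInstance],
    ltr_int_pairs: Mapping[str, str],
    exons: Sequence[tuple[str, int, int]],
    fragment_gap: int = 100,
    erv_gap: int = 500,
) -> list[TEInstance]:
    """Fragment reassembly, then LTR/internal assembly, then exon exclusion."""
    merged = repeats.merge_fragments(raw, max_gap=fragment_gap)
    assembled = repeats.assemble_full_length_ervs(merged, ltr_int_pairs, max_gap=erv_gap)
    return repeats.exclude_exon_overlaps(assembled, exons)


def _catalog_key(t: TEInstance) -> tuple:
    return (t.chrom, t.start, t.end, t.strand, t.subfamily, t.is_solo_ltr)


def score_tcgt_calls(
    calls: Sequence[tcgt.TcGT],
    planted: Sequence[simulate.PlantedTcGT],
    groups: Mapping[str, str],
) -> dict[str, float]:
    """Precision/recall of calls against planted (locus, gene, group) triples."""
    truth = {(p.locus_id, p.gene_id, p.group) for p in planted}
    called = {(c.driver_locus_id, c.gene_id, groups[c.sample_id]) for c in calls}
    tp = len(called & truth)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(truth) if truth else 0.0
    return {"precision": precision, "recall": recall,
            "n_calls": float(len(called)), "n_planted": float(len(truth))}


def demo_report(seed: int = 42, cfg: simulate.SimulationConfig | None = None) -> dict:
    """Simulate, run every pipeline stage, score against ground truth."""
    cfg = cfg or simulate.SimulationConfig(seed=seed)
    study = simulate.simulate_study(cfg)
    ann = study.annotation
    report: dict = {"seed": cfg.seed}

    # --- repeat curation
    exons = [(r.chrom, r.start, r.end) for r in ann.genes.itertuples(index=False)]
    curated = curate_catalog(ann.raw_records, ann.ltr_int_pairs, exons)
    truth_keys = {_catalog_key(t) for t in ann.truth_catalog}
    curated_keys = {_catalog_key(t) for t in curated}
    report["curation"] = {
        "n_curated": len(curated),
        "n_truth": len(ann.truth_catalog),
        "catalog_matches_truth": curated_keys == truth_keys,
        "solo_ltr_count": sum(t.is_solo_ltr for t in curated),
    }
    catalog = curated

    # --- TcGT calling and enrichment
    transcripts = [m for models in study.transcriptomes.values() for m in models]
    calls = tcgt.call_tcgts(transcripts, catalog, ann.genes)
    aggregates = tcgt.aggregate_tcgts(calls, window=100, groups=study.groups)
    scores = score_tcgt_calls(calls, study.planted, study.groups)
    enr = tcgt.enrichment_to_frame(tcgt.tcgt_enrichment_table(aggregates, catalog, study.groups))
    planted_sf = study.config.tcgt.planted_subfamily
    per_group = {}
    for grp, sub in enr.groupby("group"):
        ranked = sub.sort_values(["padj", "subfamily"]).reset_index(drop=True)
        row = ranked[ranked["subfamily"] == planted_sf].iloc[0]
        per_group[grp] = {"padj": float(row["padj"]), "rank": int(ranked.index[ranked["subfamily"] == planted_sf][0]) + 1}
    report["tcgt"] = {**scores, "n_aggregates": len(aggregates),
                      "planted_subfamily": planted_sf, "per_group": per_group}

    # --- peak enrichment and consensus
    sizes = repeats.subfamily_sizes(catalog)
    genome_bp = sum(ann.chrom_sizes.values())
    rep_sets = list(study.peak_replicates.values())
    consensus = peaks_mod.consensus_peaks(rep_sets, min_support=2)
    pooled = [p for reps in rep_sets for p in reps]
    assignments = peaks_mod.assign_peaks(consensus, catalog)
    penr = peaks_mod.enrichment_to_frame(
        peaks_mod.subfamily_peak_enrichment(assignments, len(consensus), sizes, genome_bp)
    )
    ranked = penr.sort_values(["padj", "subfamily"]).reset_index(drop=True)
    target = study.config.peaks.enriched_subfamily
    prow = ranked[ranked["subfamily"] == target].iloc[0]
    report["peaks"] = {
        "n_pooled": len(pooled), "n_consensus": len(consensus),
        "enriched_subfamily": target,
        "padj": float(prow["padj"]),
        "rank": int(ranked.index[ranked["subfamily"] == target][0]) + 1,
    }

    # --- 50-kb proximity Fisher test on genes near planted driver loci
    from .io import gene_tss_table

    tss = gene_tss_table(ann.genes)
    driver_ids = {p.locus_id for p in study.planted}
    driver_loci = [t for t in catalog if t.locus_id in driver_ids]
    gene_set = sorted({p.gene_id for p in study.planted})
    table, fisher_p = peaks_mod.proximity_enrichment(gene_set, tss, driver_loci, window=50_000)
    report["proximity"] = {"table": table, "fisher_p": fisher_p}

    # --- expression clustering
    filtered = expression.filter_low_counts(study.expression)
    norm = expression.tmm_normalize(filtered)
    te_vals = norm.values.loc[norm.feature_kind == expression.TE_LOCUS]
    z, _ = expression.zscore_rows(te_vals)
    assign = expression.cluster_loci(z, k=2)
    common = assign.labels.index.intersection(study.cluster_labels.index)
    rand = simulate.rand_index(
        assign.labels.loc[common].to_numpy(), study.cluster_labels.loc[common].to_numpy()
    )
    report["expression"] = {
        "n_features_kept": int(filtered.counts.shape[0]),
        "tmm_factors": {k: float(v) for k, v in norm.factors.items()},
        "cluster_rand_index": rand,
    }

    # --- methylation contrast
    locus_table = methylation.locus_methylation(study.methylation_calls, catalog)
    averaged = methylation.average_replicates(
        locus_table, {r: "avg" for r in study.config.methyl.replicates}
    )
    res = methylation.compare_locus_sets(
        averaged, study.methylation_sets["set_a"], study.methylation_sets["set_b"]
    )
    report["methylation"] = {
        "p": res.pvalue, "method": res.method,
        "median_a": res.medians[0], "median_b": res.medians[1],
        "planted_delta": study.methylation_means["set_a"] - study.methylation_means["set_b"],
    }

    # --- ortholog scoring
    subfam_of = {t.locus_id: t.subfamily for t in catalog}
    family_map = {sf: spec.family for sf, spec in cfg.te_plan.items()}
    syn = study.synteny[study.synteny["human_locus_id"].isin(subfam_of)]
    hits = score_synteny_table(syn, study.consensus_lengths, subfam_of, family_map)
    hf = hits_to_frame(hits)
    fp_correct = 0
    for sp, cands in study.fingerprint_candidates.items():
        winner, _score = best_ortholog(study.fingerprint_query, cands)
        fp_correct += winner == study.fingerprint_truth[sp]
    report["orthologs"] = {
        "n_hits": len(hf),
        "mean_similarity_detected": float(hf.loc[hf["status"] != "not_detected", "similarity"].mean()),
        "fingerprint_orthologs_correct": fp_correct,
        "fingerprint_species": len(study.fingerprint_candidates),
    }
    return report
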