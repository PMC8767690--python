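"""Synthetic toy study with planted ground truth.

Generates, from a single seed, a self-consistent miniature of the kind of
dataset the pipeline targets: a two-chromosome toy genome with gene and TE
annotation (including fragmented integrants, full-length ERVs and solo
LTRs), per-sample transcriptomes carrying planted LTR-driven chimeric
transcripts plus decoys each violating exactly one calling predicate, ChIP
replicate peak sets enriched over a chosen subfamily, TE-locus expression
matrices with maternal-versus-ZGA temporal patterns, CpG methylation with a
planted between-set difference, and synteny/fingerprint tables — together
with a machine-readable ground-truth record sufficient to score every
pipeline stage.

Each section draws from its own substream spawned deterministically from
the top-level seed, so regenerating one section never perturbs another.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .repeats import TEInstance
from .tcgt import TranscriptModel
from .peaks import Peak
from .expression import GENE, TE_LOCUS, CountMatrix
from .orthologs import Fingerprint

_SECTIONS = ("annotation", "transcripts", "peaks", "expression", "methylation", "orthologs")


# ---------------------------------------------------------------- config

@dataclass
class SubfamilySpec:
    n_loci: int
    length: tuple[int, int]  # uniform bp range per locus
    te_class: str = "LTR"
    family: str = "."
    internal: str | None = None  # paired internal subfamily
    full_length_frac: float = 0.0  # fraction of loci emitted as LTR-int-LTR proviruses


@dataclass
class TcgtPlan:
    groups: tuple[str, ...] = ("oocyte", "fourcell", "eightcell")
    samples_per_group: int = 2
    planted_per_group: int = 10
    planted_subfamily: str = "LTR12C"
    off_target_subfamily: str = "THE1D"
    off_target_per_group: int = 1
    decoys_per_group: int = 20
    tss_jitter: int = 30


@dataclass
class PeakPlan:
    n_peaks: int = 500
    peak_width: int = 200
    enriched_subfamily: str = "LTR12C"
    enrichment_fraction: float = 0.4
    n_replicates: int = 3
    replicate_jitter: int = 10
    dropout_fraction: float = 0.2  # peaks present in a single replicate only


@dataclass
class ExprPlan:
    stages: tuple[str, ...] = ("oocyte", "twocell", "fourcell", "eightcell", "morula")
    replicates_per_stage: int = 2
    n_gene_rows: int = 150
    loci_per_cluster: int = 30
    base_mean: float = 200.0
    floor_mean: float = 2.0
    dispersion: float = 0.1
    # maternal: detected in oocyte, dropped from the 2-cell stage on
    maternal_template: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0)
    # ZGA: expressed from the 8-cell stage up to the morula
    zga_template: tuple[float, ...] = (0.0, 0.0, 0.0, 1.0, 1.0)


@dataclass
class MethylPlan:
    n_per_set: int = 50
    mean_a: float = 0.70
    mean_b: float = 0.40
    kappa: float = 20.0  # Beta concentration: sd ~0.10 at these means
    cpg_density: float = 0.01  # CpGs per bp of locus
    cpg_noise: float = 0.05
    replicates: tuple[str, ...] = ("rep1", "rep2")


def default_te_plan() -> dict[str, SubfamilySpec]:
    return {
        "LTR12C": SubfamilySpec(60, (800, 1600), "LTR", "LTR12", internal="HERV9-int",
                                full_length_frac=0.2),
        "LTR12B": SubfamilySpec(20, (700, 1400), "LTR", "LTR12"),
        "THE1D": SubfamilySpec(40, (300, 500), "LTR", "THE1"),
        "MLT1D": SubfamilySpec(30, (300, 600), "LTR", "MLT1"),
        "HERV9-int": SubfamilySpec(5, (3000, 6000), "LTR", "ERV9"),
        "AluY": SubfamilySpec(40, (280, 320), "SINE", "Alu"),
    }


@dataclass
class SimulationConfig:
    seed: int = 42
    genome: dict[str, int] = field(default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    n_genes: int = 120
    te_plan: dict[str, SubfamilySpec] = field(default_factory=default_te_plan)
    fragmentation_prob: float = 0.25
    n_exonic_tes: int = 5  # decoy TEs placed over gene exons; curation must drop them
    tcgt: TcgtPlan = field(default_factory=TcgtPlan)
    peaks: PeakPlan = field(default_factory=PeakPlan)
    expr: ExprPlan = field(default_factory=ExprPlan)
    methyl: MethylPlan = field(default_factory=MethylPlan)

    def rng(self, section: str) -> np.random.Generator:
        idx = _SECTIONS.index(section)
        child = np.random.SeedSequence(self.seed).spawn(len(_SECTIONS))[idx]
        return np.random.default_rng(child)


# ---------------------------------------------------------------- annotation

@dataclass
class SimulatedAnnotation:
    chrom_sizes: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, strand, start, end (one row per exon)
    raw_records: list[TEInstance]  # pre-curation, fragmented, incl. exonic decoys
    truth_catalog: list[TEInstance]  # expected curated catalog
    ltr_int_pairs: dict[str, str]
    intergenic_anchors: list[tuple[str, int]]


def _fragment(inst: TEInstance, linkage: str, rng: np.random.Generator) -> list[TEInstance]:
    """Split a record into two fragments inside its span, sharing a linkage id."""
    span = inst.length
    cut = inst.start + int(rng.integers(int(span * 0.3), int(span * 0.7)))
    gap = int(rng.integers(20, 81))
    gap = min(gap, inst.end - cut - 1)
    parts = []
    # the first fragment keeps the locus id, so reassembly restores it
    for lid, (s, e) in [(inst.locus_id, (inst.start, cut)),
                        (f"{inst.locus_id}.f2", (cut + gap, inst.end))]:
        parts.append(
            TEInstance(
                chrom=inst.chrom, start=s, end=e, strand=inst.strand,
                subfamily=inst.subfamily, family=inst.family, te_class=inst.te_class,
                locus_id=lid, linkage_id=linkage,
            )
        )
    return parts


def simulate_annotation(cfg: SimulationConfig) -> SimulatedAnnotation:
    rng = cfg.rng("annotation")
    min_gap, max_gap_between = 1200, 3000  # keeps distinct loci well clear of merge windows

    # build the feature schedule: genes, standalone TE loci, provirus triples
    schedule: list[tuple[str, object]] = [("gene", i) for i in range(cfg.n_genes)]
    counter = 0
    for subfam, spec in cfg.te_plan.items():
        n_full = int(round(spec.n_loci * spec.full_length_frac)) if spec.internal else 0
        for i in range(spec.n_loci - n_full):
            schedule.append(("te", (subfam, f"{subfam}_{i:04d}")))
        for i in range(n_full):
            schedule.append(("provirus", (subfam, f"{subfam}_fl{i:03d}")))
        counter += spec.n_loci
    order = rng.permutation(len(schedule))
    schedule = [schedule[i] for i in order]

    chroms = list(cfg.genome)
    chrom_idx = 0
    cursor = int(rng.integers(5_000, 20_000))
    gene_rows: list[tuple[str, str, str, int, int]] = []
    truth: list[TEInstance] = []
    unfragmented: list[TEInstance] = []
    anchors: list[tuple[str, int]] = []

    def advance(needed: int) -> str:
        nonlocal cursor, chrom_idx
        while cursor + needed + 10_000 > cfg.genome[chroms[chrom_idx]]:
            chrom_idx += 1
            if chrom_idx >= len(chroms):
                raise RuntimeError("toy genome too small for the requested annotation")
            cursor = int(rng.integers(5_000, 20_000))
        return chroms[chrom_idx]

    for kind, payload in schedule:
        if kind == "gene":
            gi = payload
            gene_id = f"GENE{gi:04d}"
            strand = "+" if gi % 2 == 0 else "-"
            n_exons = int(rng.integers(2, 4))
            exon_lens = rng.integers(150, 301, size=n_exons)
            intron_lens = rng.integers(1000, 3001, size=n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            chrom = advance(span)
            pos = cursor
            for i in range(n_exons):
                gene_rows.append((gene_id, chrom, strand, pos, pos + int(exon_lens[i])))
                pos += int(exon_lens[i])
                if i < n_exons - 1:
                    pos += int(intron_lens[i])
            cursor = pos + int(rng.integers(min_gap, max_gap_between))
            anchors.append((chrom, cursor - min_gap // 2))
        elif kind == "te":
            subfam, locus_id = payload
            spec = cfg.te_plan[subfam]
            length = int(rng.integers(spec.length[0], spec.length[1] + 1))
            chrom = advance(length)
            strand = "+" if rng.random() < 0.5 else "-"
            truth.append(
                TEInstance(chrom=chrom, start=cursor, end=cursor + length, strand=strand,
                           subfamily=subfam, family=spec.family, te_class=spec.te_class,
                           locus_id=locus_id)
            )
            cursor += length + int(rng.integers(min_gap, max_gap_between))
            anchors.append((chrom, cursor - min_gap // 2))
        else:  # provirus: LTR - internal - LTR, merged in the truth catalog
            subfam, locus_id = payload
            spec = cfg.te_plan[subfam]
            internal = spec.internal
            int_spec = cfg.te_plan[internal]
            ltr_len = int(rng.integers(spec.length[0], spec.length[1] + 1))
            ltr_len2 = int(rng.integers(spec.length[0], spec.length[1] + 1))
            int_len = int(rng.integers(int_spec.length[0], int_spec.length[1] + 1))
            g1, g2 = int(rng.integers(20, 101)), int(rng.integers(20, 101))
            span = ltr_len + g1 + int_len + g2 + ltr_len2
            chrom = advance(span)
            strand = "+" if rng.random() < 0.5 else "-"
            s = cursor
            parts = [
                TEInstance(chrom=chrom, start=s, end=s + ltr_len, strand=strand,
                           subfamily=subfam, family=spec.family, te_class=spec.te_class,
                           locus_id=f"{locus_id}.ltr5"),
                TEInstance(chrom=chrom, start=s + ltr_len + g1, end=s + ltr_len + g1 + int_len,
                           strand=strand, subfamily=internal, family=int_spec.family,
                           te_class=int_spec.te_class, locus_id=f"{locus_id}.int"),
                TEInstance(chrom=chrom, start=s + span - ltr_len2, end=s + span, strand=strand,
                           subfamily=subfam, family=spec.family, te_class=spec.te_class,
                           locus_id=f"{locus_id}.ltr3"),
            ]
            unfragmented.extend(parts)
            truth.append(
                TEInstance(chrom=chrom, start=s, end=s + span, strand=strand,
                           subfamily=internal, family=int_spec.family,
                           te_class=int_spec.te_class, locus_id=f"{locus_id}.ltr5",
                           is_solo_ltr=False,
                           merged_from=[p.locus_id for p in parts])
            )
            cursor += span + int(rng.integers(min_gap, max_gap_between))
            anchors.append((chrom, cursor - min_gap // 2))

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    pairs = {sf: spec.internal for sf, spec in cfg.te_plan.items() if spec.internal}
    internal_names = set(pairs.values())

    # solo flags on the truth catalog
    truth_flagged = []
    for t in truth:
        if t.merged_from != [t.locus_id]:  # assembled provirus
            truth_flagged.append(t)
        else:
            solo = t.te_class == "LTR" and t.subfamily not in internal_names
            truth_flagged.append(
                TEInstance(chrom=t.chrom, start=t.start, end=t.end, strand=t.strand,
                           subfamily=t.subfamily, family=t.family, te_class=t.te_class,
                           locus_id=t.locus_id, is_solo_ltr=solo)
            )

    # raw records: fragment standalone loci with the configured probability
    raw: list[TEInstance] = list(unfragmented)
    frag_counter = 0
    for t in truth_flagged:
        if len(t.merged_from) > 1:
            continue  # provirus components already in raw
        if t.length >= 200 and rng.random() < cfg.fragmentation_prob:
            frag_counter += 1
            raw.extend(_fragment(t, f"L{frag_counter:05d}", rng))
        else:
            raw.append(
                TEInstance(chrom=t.chrom, start=t.start, end=t.end, strand=t.strand,
                           subfamily=t.subfamily, family=t.family, te_class=t.te_class,
                           locus_id=t.locus_id)
            )

    # decoy TEs over gene exons: present in the raw annotation, absent from truth
    exon_pool = genes.sample(n=min(cfg.n_exonic_tes, len(genes)), random_state=int(rng.integers(2**31)))
    for i, row in enumerate(exon_pool.itertuples(index=False)):
        raw.append(
            TEInstance(chrom=row.chrom, start=max(0, row.start - 50), end=row.start + 100,
                       strand="+", subfamily="AluY", family="Alu", te_class="SINE",
                       locus_id=f"AluY_exonic_{i:02d}")
        )

    return SimulatedAnnotation(
        chrom_sizes=dict(cfg.genome), genes=genes, raw_records=raw,
        truth_catalog=truth_flagged, ltr_int_pairs=pairs, intergenic_anchors=anchors,
    )


# ---------------------------------------------------------------- transcriptomes

@dataclass
class PlantedTcGT:
    locus_id: str
    subfamily: str
    gene_id: str
    group: str
    tss: int


def simulate_transcriptomes(
    cfg: SimulationConfig, ann: SimulatedAnnotation
) -> tuple[dict[str, list[TranscriptModel]], list[PlantedTcGT], dict[str, str]]:
    """Per-sample transcript models with planted chimeras and decoys.

    Every planted chimera appears (with a jittered TSS within the
    aggregation window) in each sample of its group; decoys each violate
    exactly one calling predicate: mono-exonic start in an LTR, TSS outside
    any TE, or splicing into intergenic space.
    """
    rng = cfg.rng("transcripts")
    plan = cfg.tcgt
    groups_map: dict[str, str] = {}
    samples: dict[str, list[TranscriptModel]] = {}
    for g in plan.groups:
        for i in range(plan.samples_per_group):
            sid = f"{g}_s{i + 1}"
            groups_map[sid] = g
            samples[sid] = []

    gene_firsts = (
        ann.genes.groupby("gene_id", sort=True)
        .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
        .reset_index()
    )
    first_exons = {
        gid: (grp.sort_values("start").iloc[0]["start"], grp.sort_values("start").iloc[0]["end"])
        for gid, grp in ann.genes.groupby("gene_id", sort=True)
    }
    genes_by_chrom = {
        c: sub.sort_values("start").reset_index(drop=True)
        for c, sub in gene_firsts.groupby("chrom")
    }

    def downstream_gene(chrom: str, pos: int, used: set[str]) -> str | None:
        sub = genes_by_chrom.get(chrom)
        if sub is None:
            return None
        idx = bisect.bisect_right(sub["start"].tolist(), pos + 300)
        for j in range(idx, len(sub)):
            gid = sub.iloc[j]["gene_id"]
            if gid not in used:
                return gid
        return None

    def upstream_gene(chrom: str, pos: int, used: set[str]) -> str | None:
        sub = genes_by_chrom.get(chrom)
        if sub is None:
            return None
        idx = bisect.bisect_left(sub["end"].tolist(), pos - 300)
        for j in range(idx - 1, -1, -1):
            gid = sub.iloc[j]["gene_id"]
            if gid not in used:
                return gid
        return None

    solo = {sf: [t for t in ann.truth_catalog if t.subfamily == sf and t.is_solo_ltr]
            for sf in {plan.planted_subfamily, plan.off_target_subfamily}}
    for sf, pool in solo.items():
        rng.shuffle(pool)  # in-place deterministic shuffle
    used_loci: set[str] = set()
    used_genes: set[str] = set()
    planted: list[PlantedTcGT] = []
    tcounter = 0

    def make_chimera(locus: TEInstance, gene_id: str, sample: str, jitter: int) -> TranscriptModel:
        nonlocal tcounter
        tcounter += 1
        g = gene_firsts.set_index("gene_id").loc[gene_id]
        gstart, gend = first_exons[gene_id]
        if g["start"] > locus.end:  # gene downstream: plus-strand chimera
            tss = locus.start + int(np.clip(10 + jitter, 5, locus.length - 5))
            exon1 = (tss, tss + 150)
            exon2 = (int(gstart), int(gend))
            strand = "+"
        else:  # gene upstream: minus-strand chimera
            tss = locus.end - int(np.clip(10 + jitter, 5, locus.length - 5)) - 1
            exon1 = (tss - 149, tss + 1)
            exon2 = (int(gstart), int(gend))
            strand = "-"
        return TranscriptModel(
            transcript_id=f"TCGT{tcounter:05d}", sample_id=sample, chrom=locus.chrom,
            strand=strand, exons=sorted([exon1, exon2]),
        )

    for g in plan.groups:
        picks: list[TEInstance] = []
        n_on = plan.planted_per_group - plan.off_target_per_group
        for _ in range(n_on):
            picks.append(next(t for t in solo[plan.planted_subfamily] if t.locus_id not in used_loci))
            used_loci.add(picks[-1].locus_id)
        for _ in range(plan.off_target_per_group):
            picks.append(next(t for t in solo[plan.off_target_subfamily] if t.locus_id not in used_loci))
            used_loci.add(picks[-1].locus_id)
        for locus in picks:
            gene = downstream_gene(locus.chrom, locus.end, used_genes)
            if gene is None:
                gene = upstream_gene(locus.chrom, locus.start, used_genes)
            if gene is None:
                raise RuntimeError(f"no free cognate gene near {locus.locus_id}")
            used_genes.add(gene)
            base_jitter = int(rng.integers(0, max(1, locus.length - 200)))
            rep_tss = None
            for i in range(plan.samples_per_group):
                sid = f"{g}_s{i + 1}"
                jitter = base_jitter + int(rng.integers(-plan.tss_jitter, plan.tss_jitter + 1))
                tm = make_chimera(locus, gene, sid, jitter)
                samples[sid].append(tm)
                if rep_tss is None:
                    from .tcgt import transcript_tss

                    rep_tss = transcript_tss(tm)
            planted.append(PlantedTcGT(locus.locus_id, locus.subfamily, gene, g, int(rep_tss)))

    # decoys: cycle the three violation kinds across each group's samples
    ltr_pool = [t for t in ann.truth_catalog if t.te_class == "LTR"
                and t.locus_id not in used_loci and t.length >= 400]
    rng.shuffle(ltr_pool)
    anchors = list(ann.intergenic_anchors)
    rng.shuffle(anchors)
    a_iter = iter(anchors)
    l_iter = iter(ltr_pool)
    for g in plan.groups:
        sids = [f"{g}_s{i + 1}" for i in range(plan.samples_per_group)]
        for d in range(plan.decoys_per_group):
            tcounter += 1
            sid = sids[d % len(sids)]
            kind = d % 3
            if kind == 0:  # mono-exonic transcript starting in an LTR: no junction
                locus = next(l_iter)
                tss = locus.start + int(rng.integers(5, locus.length - 5))
                tm = TranscriptModel(f"DECOY{tcounter:05d}", sid, locus.chrom, "+",
                                     [(tss, tss + 300)])
            elif kind == 1:  # spliced transcript whose TSS is outside any TE
                gene = None
                while gene is None:
                    chrom, pos = next(a_iter)
                    gene = downstream_gene(chrom, pos, set())
                gstart, gend = first_exons[gene]
                tm = TranscriptModel(f"DECOY{tcounter:05d}", sid, chrom, "+",
                                     [(pos, pos + 150), (int(gstart), int(gend))])
            else:  # TSS in an LTR but splicing into intergenic space
                while True:
                    locus = next(l_iter)
                    downstream = [p for c, p in ann.intergenic_anchors
                                  if c == locus.chrom and p > locus.end + 400]
                    if downstream:
                        break
                tss = locus.start + int(rng.integers(5, locus.length - 5))
                tpos = min(downstream)
                tm = TranscriptModel(f"DECOY{tcounter:05d}", sid, locus.chrom, "+",
                                     [(tss, tss + 150), (tpos, tpos + 150)])
            samples[sid].append(tm)
    return samples, planted, groups_map


# ---------------------------------------------------------------- peaks

def simulate_peaks(
    cfg: SimulationConfig,
    catalog: Sequence[TEInstance],
    rng: np.random.Generator | None = None,
    enrichment_fraction: float | None = None,
) -> dict[str, list[Peak]]:
    """Replicate ChIP peak sets with a planted subfamily enrichment.

    A configured fraction of peaks is placed fully inside loci of the
    enriched subfamily (guaranteeing >50% overlap); the rest fall uniformly
    on the genome.  A dropout fraction of peaks appears in one replicate
    only; the remainder appear, jittered, in every replicate.
    """
    if rng is None:
        rng = cfg.rng("peaks")
    plan = cfg.peaks
    frac = plan.enrichment_fraction if enrichment_fraction is None else enrichment_fraction
    w = plan.peak_width
    targets = [t for t in catalog if t.subfamily == plan.enriched_subfamily
               and t.length >= w + 2 * plan.replicate_jitter + 10]
    if frac > 0 and not targets:
        raise ValueError(f"no locus of {plan.enriched_subfamily} can host a {w}-bp peak")
    chroms = list(cfg.genome)
    weights = np.array([cfg.genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    n_enriched = int(round(frac * plan.n_peaks))
    base: list[Peak] = []
    for i in range(plan.n_peaks):
        if i < n_enriched:
            t = targets[int(rng.integers(len(targets)))]
            margin = plan.replicate_jitter + 5
            start = int(rng.integers(t.start + margin, t.end - w - margin + 1))
            base.append(Peak(t.chrom, start, start + w))
        else:
            c = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, cfg.genome[c] - w))
            base.append(Peak(c, start, start + w))

    singleton = rng.random(plan.n_peaks) < plan.dropout_fraction
    home_rep = rng.integers(0, plan.n_replicates, size=plan.n_peaks)
    reps: dict[str, list[Peak]] = {f"rep{r + 1}": [] for r in range(plan.n_replicates)}
    for i, p in enumerate(base):
        for r in range(plan.n_replicates):
            if singleton[i] and r != home_rep[i]:
                continue
            j = int(rng.integers(-plan.replicate_jitter, plan.replicate_jitter + 1))
            reps[f"rep{r + 1}"].append(
                Peak(p.chrom, p.start + j, p.end + j, replicate_id=f"rep{r + 1}")
            )
    return reps


# ---------------------------------------------------------------- expression

def simulate_expression(
    cfg: SimulationConfig, catalog: Sequence[TEInstance]
) -> tuple[CountMatrix, pd.Series, dict[str, str]]:
    """Negative-binomial counts with planted maternal/ZGA TE-locus patterns.

    Gene rows with stage-independent means are included so that TMM
    normalization (gene counts as library size) is exercised; TE loci follow
    one of the two temporal templates scaled by a locus-specific size
    factor, with per-sample depth factors.
    """
    rng = cfg.rng("expression")
    plan = cfg.expr
    samples = [f"{st}_r{i + 1}" for st in plan.stages for i in range(plan.replicates_per_stage)]
    stage_of = {s: s.rsplit("_r", 1)[0] for s in samples}
    templates = {1: np.asarray(plan.maternal_template), 2: np.asarray(plan.zga_template)}
    for lab, tpl in templates.items():
        if tpl.size != len(plan.stages):
            raise ValueError("template length must match the number of stages")

    te_pool = [t.locus_id for t in catalog if t.te_class == "LTR"]
    needed = 2 * plan.loci_per_cluster
    if len(te_pool) < needed:
        raise ValueError(f"catalog has {len(te_pool)} LTR loci; need {needed}")
    chosen = [te_pool[i] for i in rng.permutation(len(te_pool))[:needed]]
    labels = pd.Series(
        [1] * plan.loci_per_cluster + [2] * plan.loci_per_cluster,
        index=chosen, name="cluster",
    )

    depth = np.exp(rng.normal(0.0, 0.2, size=len(samples)))
    disp = plan.dispersion
    r_shape = 1.0 / disp

    rows = {}
    kinds = {}
    for gi in range(plan.n_gene_rows):
        mu = float(np.exp(rng.normal(np.log(100.0), 1.0)))
        mean_vec = np.full(len(samples), mu) * depth
        p = r_shape / (r_shape + mean_vec)
        rows[f"G{gi:04d}"] = rng.negative_binomial(r_shape, p)
        kinds[f"G{gi:04d}"] = GENE
    for locus, lab in labels.items():
        size = float(np.exp(rng.normal(0.0, 0.3)))
        tpl = templates[lab]
        mean_vec = np.array(
            [plan.floor_mean + plan.base_mean * size * tpl[plan.stages.index(stage_of[s])]
             for s in samples]
        ) * depth
        p = r_shape / (r_shape + mean_vec)
        rows[locus] = rng.negative_binomial(r_shape, p)
        kinds[locus] = TE_LOCUS

    counts = pd.DataFrame(rows, index=samples).T.astype(int)
    matrix = CountMatrix(counts, pd.Series(kinds))
    return matrix, labels, stage_of


def simulate_cluster_profiles(
    rng: np.random.Generator,
    n_per_cluster: int = 10,
    noise_sd: float = 0.1,
    n_reps: int = 2,
    templates: tuple[tuple[float, ...], tuple[float, ...]] = (
        (1.0, 1.0, 0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0, 1.0, 1.0),
    ),
) -> tuple[pd.DataFrame, pd.Series]:
    """Noisy two-template profile matrix for planted-partition recovery tests.

    Rows follow one of two orthogonal temporal templates (amplitude 1)
    replicated ``n_reps`` times per stage, plus i.i.d. Gaussian noise of the
    given standard deviation.
    """
    t1 = np.repeat(np.asarray(templates[0]), n_reps)
    t2 = np.repeat(np.asarray(templates[1]), n_reps)
    data = np.vstack(
        [t1 + rng.normal(0, noise_sd, t1.size) for _ in range(n_per_cluster)]
        + [t2 + rng.normal(0, noise_sd, t2.size) for _ in range(n_per_cluster)]
    )
    index = [f"locus_{i:03d}" for i in range(2 * n_per_cluster)]
    cols = [f"s{j}" for j in range(t1.size)]
    labels = pd.Series([1] * n_per_cluster + [2] * n_per_cluster, index=index)
    return pd.DataFrame(data, index=index, columns=cols), labels


def rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Unadjusted Rand index between two partitions of the same items."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size:
        raise ValueError("partitions must label the same items")
    n = a.size
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    agree = (same_a[iu] == same_b[iu]).sum()
    return float(agree / iu[0].size)


# ---------------------------------------------------------------- methylation

def simulate_methylation(
    cfg: SimulationConfig,
    catalog: Sequence[TEInstance],
    rng: np.random.Generator | None = None,
    delta: float | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, float]]:
    """CpG calls with a planted between-set difference in locus methylation.

    Two disjoint locus sets draw their per-locus level from Beta
    distributions with means ``mean_b + delta`` and ``mean_b``; CpGs are
    placed at the configured density and observed per replicate with small
    Gaussian noise, clipped to [0,1].
    """
    if rng is None:
        rng = cfg.rng("methylation")
    plan = cfg.methyl
    mean_a = plan.mean_a if delta is None else plan.mean_b + delta
    pool = [t for t in catalog if t.length >= 200]
    if len(pool) < 2 * plan.n_per_set:
        raise ValueError("not enough loci for the two methylation sets")
    order = rng.permutation(len(pool))
    set_a = [pool[i].locus_id for i in order[: plan.n_per_set]]
    set_b = [pool[i].locus_id for i in order[plan.n_per_set: 2 * plan.n_per_set]]
    by_id = {t.locus_id: t for t in pool}

    rows = []
    for ids, mean in ((set_a, mean_a), (set_b, plan.mean_b)):
        alpha = mean * plan.kappa
        beta = (1.0 - mean) * plan.kappa
        for lid in ids:
            t = by_id[lid]
            level = float(rng.beta(alpha, beta))
            n_cpg = max(2, int(round(t.length * plan.cpg_density)))
            pos = np.sort(rng.choice(np.arange(t.start, t.end), size=n_cpg, replace=False))
            for rep in plan.replicates:
                obs = np.clip(level + rng.normal(0, plan.cpg_noise, size=n_cpg), 0.0, 1.0)
                for p, m in zip(pos, obs):
                    rows.append((t.chrom, int(p), float(m), rep))
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "meth_level", "sample_id"])
    truth_sets = {"set_a": set_a, "set_b": set_b}
    truth_means = {"set_a": mean_a, "set_b": plan.mean_b}
    return calls, truth_sets, truth_means


# ---------------------------------------------------------------- orthologs

_SPECIES = ("chimpanzee", "gorilla", "orangutan", "macaque")
_DETECT_PROB = {"chimpanzee": 0.95, "gorilla": 0.90, "orangutan": 0.80, "macaque": 0.45}
_AA_LIST = list("ACDEFGHIKLMNPQRSTVWY")


def simulate_synteny(
    cfg: SimulationConfig, catalog: Sequence[TEInstance], subfamily: str = "LTR12C"
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Synteny table (human locus x species) for conservation scoring."""
    rng = cfg.rng("orthologs")
    loci = [t for t in catalog if t.subfamily == subfamily]
    consensus = {subfamily: max(spec.length[1] for sf, spec in cfg.te_plan.items() if sf == subfamily)}
    rows = []
    for t in loci:
        for sp in _SPECIES:
            lifted = bool(rng.random() < _DETECT_PROB[sp])
            if lifted:
                aligned = max(1, int(round(t.length * rng.beta(8, 2))))
                u = rng.random()
                label = subfamily if u < 0.8 else ("LTR12B" if u < 0.9 else ".")
            else:
                aligned, label = 0, "."
            rows.append((t.locus_id, sp, int(lifted), label, aligned, t.length))
    df = pd.DataFrame(
        rows, columns=["human_locus_id", "species", "lifted", "foreign_label", "aligned_bp", "human_len"]
    )
    return df, consensus


def simulate_fingerprints(
    cfg: SimulationConfig, n_fingers: int = 12
) -> tuple[Fingerprint, dict[str, list[Fingerprint]], dict[str, str]]:
    """A query zinc fingerprint plus per-species candidate sets.

    In each species the true ortholog is the query with a species-distance-
    dependent number of fingers mutated; decoy candidates are unrelated
    random fingerprints.  Returns (query, candidates per species, truth).
    """
    rng = cfg.rng("orthologs")
    rng = np.random.default_rng(rng.integers(2**31))  # distinct stream from synteny

    def random_finger() -> str:
        return "".join(rng.choice(_AA_LIST, size=4))

    query = Fingerprint("ZNF_Q", [random_finger() for _ in range(n_fingers)])
    n_mut = {"chimpanzee": 1, "gorilla": 2, "orangutan": 3, "macaque": 5}
    candidates: dict[str, list[Fingerprint]] = {}
    truth: dict[str, str] = {}
    for sp in _SPECIES:
        fingers = list(query.fingers)
        for i in rng.choice(n_fingers, size=n_mut[sp], replace=False):
            fingers[int(i)] = random_finger()
        ortho = Fingerprint(f"{sp}_ZNF_true", fingers)
        decoys = [
            Fingerprint(f"{sp}_ZNF_d{j}", [random_finger() for _ in range(int(rng.integers(8, 15)))])
            for j in range(5)
        ]
        candidates[sp] = [ortho] + decoys
        truth[sp] = ortho.kzfp_id
    return query, candidates, truth


# ---------------------------------------------------------------- ground truth & file output

@dataclass
class GroundTruth:
    planted_tcgts: list[dict]
    enriched_subfamily: str
    enrichment_fraction: float
    cluster_labels: dict[str, int]
    methylation_sets: dict[str, list[str]]
    methylation_means: dict[str, float]
    ortholog_truth: dict[str, str]
    n_true_loci: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    annotation: SimulatedAnnotation
    transcriptomes: dict[str, list[TranscriptModel]]
    planted: list[PlantedTcGT]
    groups: dict[str, str]
    peak_replicates: dict[str, list[Peak]]
    expression: CountMatrix
    cluster_labels: pd.Series
    stage_of: dict[str, str]
    methylation_calls: pd.DataFrame
    methylation_sets: dict[str, list[str]]
    methylation_means: dict[str, float]
    synteny: pd.DataFrame
    consensus_lengths: dict[str, int]
    fingerprint_query: Fingerprint
    fingerprint_candidates: dict[str, list[Fingerprint]]
    fingerprint_truth: dict[str, str]

    @property
    def ground_truth(self) -> GroundTruth:
        return GroundTruth(
            planted_tcgts=[asdict(p) for p in self.planted],
            enriched_subfamily=self.config.peaks.enriched_subfamily,
            enrichment_fraction=self.config.peaks.enrichment_fraction,
            cluster_labels={k: int(v) for k, v in self.cluster_labels.items()},
            methylation_sets=self.methylation_sets,
            methylation_means=self.methylation_means,
            ortholog_truth=self.fingerprint_truth,
            n_true_loci=len(self.annotation.truth_catalog),
        )


def simulate_study(cfg: SimulationConfig | None = None) -> SimulatedStudy:
    """Run every generator section and bundle the results."""
    cfg = cfg or SimulationConfig()
    ann = simulate_annotation(cfg)
    transcriptomes, planted, groups = simulate_transcriptomes(cfg, ann)
    peak_reps = simulate_peaks(cfg, ann.truth_catalog)
    expr, labels, stage_of = simulate_expression(cfg, ann.truth_catalog)
    mcalls, msets, mmeans = simulate_methylation(cfg, ann.truth_catalog)
    synteny, consensus = simulate_synteny(cfg, ann.truth_catalog)
    query, candidates, ftruth = simulate_fingerprints(cfg)
    return SimulatedStudy(
        config=cfg, annotation=ann, transcriptomes=transcriptomes, planted=planted,
        groups=groups, peak_replicates=peak_reps, expression=expr,
        cluster_labels=labels, stage_of=stage_of, methylation_calls=mcalls,
        methylation_sets=msets, methylation_means=mmeans, synteny=synteny,
        consensus_lengths=consensus, fingerprint_query=query,
        fingerprint_candidates=candidates, fingerprint_truth=ftruth,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Emit the study as flat files (GTF, BED-style TSV, chrom.sizes, JSON truth)."""
    from . import io as _io
    from .repeats import write_catalog

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_chrom_sizes(study.annotation.chrom_sizes, out / "genome.chrom.sizes")
    _io.write_gene_annotation(study.annotation.genes, out / "genes.gtf")
    write_catalog(study.annotation.raw_records, out / "repeats_raw.bed")
    write_catalog(study.annotation.truth_catalog, out / "repeats_truth.bed")
    pd.DataFrame(
        [(ltr, internal) for ltr, internal in study.annotation.ltr_int_pairs.items()],
        columns=["ltr_subfamily", "internal_subfamily"],
    ).to_csv(out / "ltr_int_pairs.tsv", sep="\t", index=False)
    gtf_dir = out / "transcriptomes"
    gtf_dir.mkdir(exist_ok=True)
    for sid, models in study.transcriptomes.items():
        _io.write_transcript_gtf(models, gtf_dir / f"{sid}.gtf")
    pd.DataFrame(sorted(study.groups.items()), columns=["sample_id", "group"]).to_csv(
        out / "groups.tsv", sep="\t", index=False
    )
    peak_dir = out / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for rep, peaks in study.peak_replicates.items():
        _io.write_peaks(peaks, peak_dir / f"{rep}.bed")
    from .expression import write_count_matrix

    write_count_matrix(study.expression, out / "counts.tsv")
    _io.write_cpg_calls(
        study.methylation_calls[study.methylation_calls["sample_id"] == study.config.methyl.replicates[0]],
        out / f"cpg_{study.config.methyl.replicates[0]}.tsv",
    )
    study.synteny.to_csv(out / "synteny.tsv", sep="\t", index=False)
    from .orthologs import write_fingerprints

    fps = {study.fingerprint_query.kzfp_id: study.fingerprint_query}
    for sp, cands in study.fingerprint_candidates.items():
        for c in cands:
            fps[c.kzfp_id] = c
    write_fingerprints(fps, out / "fingerprints.tsv")
    study.ground_truth.to_json(out / "truth.json")
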