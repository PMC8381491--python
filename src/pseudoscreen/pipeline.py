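"""End-to-end orchestration: library design from a genome + annotation +
CAGE track, and the full screen workflow on synthetic fixtures.

These functions chain the per-module operations in the order a real screen
would: CAGE TSS assignment -> promoter-window guide design with the filter
cascade -> per-gene selection -> manifest; then (for fixture runs) screen
simulation -> FASTQ counting -> control normalization -> alpha-RRA gene
tests -> hit calling -> bidirectional-promoter exclusion -> off-target
confound audit.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats as screen_stats
from .annotation import (
    GeneModel,
    TssAssignment,
    assign_tss,
    design_window,
)
from .design import (
    ControlGuide,
    GenomeIndex,
    GuideCandidate,
    LibraryRecord,
    MIN_GUIDES_PER_GENE,
    ScoreModel,
    assemble_library,
    dedup_nearby,
    filter_candidates,
    scan_protospacers,
    score_candidates,
    select_per_gene,
)
from .offtarget import (
    ConfoundReport,
    audit_confounded_hit,
    find_sites,
    partner_window_hits,
)
from .quant import TrimSpec, quantify_fastq_files
from .synthetic import (
    FixtureConfig,
    ScreenSim,
    ToyFixture,
    make_toy_genome,
    plant_confound_counts,
    simulate_counts,
    write_screen_fastq,
)


@dataclass
class DesignResult:
    assignments: List[TssAssignment]
    selected: List[GuideCandidate]
    records: List[LibraryRecord]
    guides_per_gene: Dict[str, int]
    dropped_min_guides: List[str]


def gene_category(gene: GeneModel, parent_ids: Optional[set] = None) -> str:
    if gene.is_pseudogene:
        return "pseudogene"
    if parent_ids and gene.gene_id in parent_ids:
        return "parent"
    return "auxiliary"


def design_library(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    clusters: Sequence,
    score_model: Optional[ScoreModel] = None,
    max_offset_bp: int = 500,
    max_per_gene: int = 10,
    min_guides: int = MIN_GUIDES_PER_GENE,
    controls: Sequence[ControlGuide] = (),
) -> DesignResult:
    """Design the CRISPRi library for every gene in the annotation.

    For each gene, candidates are pooled over the 500-bp windows centered
    on its assigned TSSs (CAGE-based where available, annotated fallback
    otherwise), scored, run through the filter cascade and the 4-bp dedup,
    and the top ``max_per_gene`` are selected with TIEScore priority.
    Genes ending up with fewer than ``min_guides`` selected guides are
    dropped from the manifest (recorded in ``dropped_min_guides``).
    """
    score_model = score_model or ScoreModel()
    transcripts = [t for g in genes for t in g.transcripts]
    assignments = assign_tss(transcripts, clusters, max_offset_bp)
    index = GenomeIndex(genome)

    by_gene: Dict[str, List[TssAssignment]] = {}
    for a in assignments:
        by_gene.setdefault(a.gene_id, []).append(a)

    all_candidates: List[GuideCandidate] = []
    for gene in genes:
        cands: List[GuideCandidate] = []
        seen_tss = set()
        for a in by_gene.get(gene.gene_id, []):
            key = (a.source, a.cluster_id, a.tss)
            if key in seen_tss:
                continue
            seen_tss.add(key)
            window = design_window(a.tss - 1, len(genome[a.chrom]))
            cands.extend(
                scan_protospacers(
                    genome, a.chrom, window, gene.gene_id,
                    a.cluster_id if a.source == "cage" else "annotated",
                )
            )
        cands = score_candidates(cands, score_model)
        cands = filter_candidates(cands, index)
        cands = dedup_nearby(cands)
        all_candidates.extend(cands)

    selected = select_per_gene(all_candidates, assignments, max_per_gene)
    guides_per_gene: Dict[str, int] = {g.gene_id: 0 for g in genes}
    for c in selected:
        guides_per_gene[c.gene_id] = guides_per_gene.get(c.gene_id, 0) + 1
    dropped = sorted(
        g for g, n in guides_per_gene.items() if 0 < n < min_guides
    )
    kept = [c for c in selected if guides_per_gene[c.gene_id] >= min_guides]

    parent_ids = {g.parent_gene_id for g in genes if g.parent_gene_id}
    categories = {g.gene_id: gene_category(g, parent_ids) for g in genes}
    records = assemble_library(kept, controls, categories)
    return DesignResult(
        assignments=assignments,
        selected=kept,
        records=records,
        guides_per_gene=guides_per_gene,
        dropped_min_guides=dropped,
    )


def make_control_guides(
    rng: np.random.Generator,
    n_aavs1: int = 267,
    n_non_targeting: int = 83,
    existing: Optional[set] = None,
) -> List[ControlGuide]:
    """Random negative-control spacers (AAVS1-targeting stand-ins plus
    non-targeting), distinct from each other and from ``existing``."""
    from .synthetic import BASES

    existing = set(existing or ())
    controls = []
    specs = [("AAVS1", n_aavs1, "AAVS1"), ("non_targeting", n_non_targeting, "")]
    for category, n, gene in specs:
        for i in range(n):
            while True:
                sp = "".join(BASES[rng.integers(0, 4, size=20)].astype(str))
                if sp not in existing:
                    existing.add(sp)
                    break
            controls.append(
                ControlGuide(
                    guide_id=f"{category}_{i:04d}", spacer=sp,
                    category=category, gene_id=gene,
                )
            )
    return controls


@dataclass
class EndToEndResult:
    fixture: ToyFixture
    design: DesignResult
    sim: ScreenSim
    counts: pd.DataFrame  # measured from FASTQ
    sgrna_df: pd.DataFrame
    gene_df: pd.DataFrame  # with hit + excluded_bidirectional flags
    confound_reports: List[ConfoundReport]
    carrier_guide: Optional[str]
    band_guide: Optional[str]

    @property
    def hits(self) -> List[str]:
        return sorted(self.gene_df.index[self.gene_df["hit"]])

    @property
    def excluded_bidirectional(self) -> List[str]:
        return sorted(
            self.gene_df.index[self.gene_df["excluded_bidirectional"]]
        )

    @property
    def confounded_genes(self) -> List[str]:
        return sorted(r.gene_id for r in self.confound_reports if r.confounded)


def make_matrix_screen(
    seed: int,
    gene_lfc: Mapping[str, float],
    guides_per_gene: int = 5,
    n_controls: int = 350,
    depth: float = 500.0,
    dispersion: float = 0.05,
    n_replicates: int = 3,
) -> Tuple[ScreenSim, List[str], Dict[str, str]]:
    """Simulate a count-level screen directly (no reads): every gene gets
    ``guides_per_gene`` guides at its true lfc, plus null controls.

    Returns (simulation, control ids, guide -> gene map).
    """
    guide_lfc: Dict[str, float] = {}
    gene_map: Dict[str, str] = {}
    for gene, lfc in gene_lfc.items():
        for i in range(guides_per_gene):
            gid = f"{gene}_sg{i}"
            guide_lfc[gid] = lfc
            gene_map[gid] = gene
    control_ids = [f"ctrl_{i:04d}" for i in range(n_controls)]
    for gid in control_ids:
        guide_lfc[gid] = 0.0
        gene_map[gid] = ""
    cfg = FixtureConfig(
        seed=seed, depth=depth, dispersion=dispersion,
        n_replicates=n_replicates,
    )
    rng = np.random.default_rng((seed, 2))
    sim = simulate_counts(guide_lfc, cfg, rng)
    return sim, control_ids, gene_map


def null_calibration(
    seed: int,
    n_genes: int = 500,
    guides_per_gene: int = 5,
    n_permutations: int = 10000,
) -> Dict[str, float]:
    """All-null screen calibration.

    Permutation p-value uniformity is checked with the top-fraction cutoff
    disabled (alpha = 1), where the rank-aggregation score is continuous and
    null p-values are exactly uniform on the permutation grid; with a
    cutoff alpha < 1, genes with no guide in the top alpha fraction share a
    score of 1 and their p-values pile up conservatively at 1 by design.
    The hit rate is measured with the default pipeline (alpha = 0.05 and
    the standard p/FDR/fold-change thresholds).
    """
    from scipy.stats import kstest

    gene_lfc = {f"G{i:04d}": 0.0 for i in range(n_genes)}
    sim, control_ids, gene_map = make_matrix_screen(
        seed, gene_lfc, guides_per_gene
    )
    _, gene_unif = screen_stats.analyze_screen(
        sim.counts, control_ids, sim.d0_samples, sim.d21_samples, gene_map,
        alpha=1.0, n_permutations=n_permutations, seed=seed,
    )
    ks = kstest(gene_unif["p"].to_numpy(), "uniform")
    _, gene_def = screen_stats.analyze_screen(
        sim.counts, control_ids, sim.d0_samples, sim.d21_samples, gene_map,
        n_permutations=n_permutations, seed=seed,
    )
    return {
        "n_genes": float(n_genes),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "hit_rate": float(gene_def["hit"].mean()),
    }


def spike_recovery(
    seed: int,
    n_spiked: int = 20,
    n_null: int = 200,
    spike_lfc: float = -2.0,
    guides_per_gene: int = 5,
    n_permutations: int = 10000,
    n_screens: int = 1,
) -> Dict[str, float]:
    """Spiked-depletion recovery: power at the standard hit thresholds and
    accuracy of the mean estimated guide fold-change for spiked guides.

    Each of ``n_screens`` independent screens keeps the same study
    conditions (``n_spiked`` spiked genes among ``n_null`` nulls, three
    replicates at 500x); results pool over screens so the power estimate
    reflects the method rather than one screen's binomial draw
    (20 spiked genes per screen give a single-screen standard error of
    about 0.05 around a true power near 0.94).
    """
    spiked = [f"ESS{i:03d}" for i in range(n_spiked)]
    nulls = [f"NULL{i:03d}" for i in range(n_null)]
    gene_lfc = {g: spike_lfc for g in spiked}
    gene_lfc.update({g: 0.0 for g in nulls})
    spiked_hits = null_hits = 0
    lfc_sum = lfc_n = 0
    for i in range(n_screens):
        sim, control_ids, gene_map = make_matrix_screen(
            seed + i, gene_lfc, guides_per_gene
        )
        sgrna_df, gene_df = screen_stats.analyze_screen(
            sim.counts, control_ids, sim.d0_samples, sim.d21_samples,
            gene_map, n_permutations=n_permutations, seed=seed + i,
        )
        spiked_hits += int(gene_df.loc[spiked, "hit"].sum())
        null_hits += int(gene_df.loc[nulls, "hit"].sum())
        spiked_guides = sgrna_df.index[sgrna_df["gene"].isin(spiked)]
        lfc_sum += float(sgrna_df.loc[spiked_guides, "lfc"].sum())
        lfc_n += len(spiked_guides)
    mean_lfc = lfc_sum / lfc_n
    return {
        "power": spiked_hits / (n_spiked * n_screens),
        "mean_spiked_guide_lfc": mean_lfc,
        "mean_lfc_error": mean_lfc - spike_lfc,
        "null_hit_rate": null_hits / (n_null * n_screens),
    }


def default_end_to_end_config(seed: int) -> FixtureConfig:
    """Fixture conditions for the full workflow run: 110 parent/pseudogene
    pairs (20 spiked essential at lfc -2, the rest null), one planted
    bidirectional pair and one planted off-target confound, three
    replicates at 500x coverage. Dispersion 0.25 — high enough that the
    control fold-change distribution reaches below -log2(1.5), the regime
    in which a single-significant-sgRNA confound can exist at all."""
    return FixtureConfig(
        seed=seed,
        n_pairs=110,
        n_essential=20,
        dispersion=0.25,
    )


def run_end_to_end(
    seed: int,
    config: Optional[FixtureConfig] = None,
    n_permutations: int = 10000,
    workdir: Optional[str] = None,
    max_mismatches: int = 1,
) -> EndToEndResult:
    """Design -> simulate -> count -> stats -> bidirectional filter ->
    confound audit, all from one seed."""
    config = config or default_end_to_end_config(seed)
    fixture = make_toy_genome(config)
    rng = np.random.default_rng((config.seed, 1))

    design = design_library(fixture.genome, fixture.genes, fixture.clusters)
    lib_spacers = {r.spacer for r in design.records}
    controls = make_control_guides(rng, existing=lib_spacers)
    design.records.extend(
        assemble_library([], controls)
    )
    control_ids = [c.guide_id for c in controls]

    spacers = {r.guide_id: r.spacer for r in design.records}
    gene_map: Dict[str, str] = {}
    for r in design.records:
        gene_map[r.guide_id] = r.gene_ids[0] if r.gene_ids else ""
    for c in controls:
        gene_map[c.guide_id] = ""

    # ground-truth guide effects
    truth = fixture.truth
    guide_lfc = {}
    carrier_guide = band_guide = None
    neutral_guides: List[str] = []
    confound_gene_guides: List[str] = []
    if truth.confound is not None:
        confound_gene_guides = sorted(
            r.guide_id for r in design.records
            if truth.confound.gene_id in r.gene_ids
        )
        carrier_matches = [
            r.guide_id for r in design.records
            if r.spacer == truth.confound.carrier_spacer
        ]
        if not carrier_matches:
            raise RuntimeError("planted confound carrier missing from library")
        carrier_guide = carrier_matches[0]
    for guide_id, gene in gene_map.items():
        if guide_id == carrier_guide:
            guide_lfc[guide_id] = -5.0
        elif truth.confound is not None and gene == truth.confound.gene_id:
            guide_lfc[guide_id] = 0.0  # pinned after the draw
        else:
            guide_lfc[guide_id] = truth.gene_lfc.get(gene, 0.0)

    sim = simulate_counts(guide_lfc, config, rng)
    if carrier_guide is not None:
        others = [g for g in confound_gene_guides if g != carrier_guide]
        band_guide, neutral_guides = others[0], others[1:]
        sim = plant_confound_counts(
            sim, control_ids, band_guide, neutral_guides
        )

    own_tmp = workdir is None
    workdir = workdir or tempfile.mkdtemp(prefix="pseudoscreen_")
    try:
        fastqs = write_screen_fastq(
            sim, spacers, workdir, seed=config.seed,
            jitter_prob=config.jitter_prob,
        )
        cm = quantify_fastq_files(fastqs, spacers, TrimSpec())
    finally:
        if own_tmp:
            for f in os.listdir(workdir):
                os.unlink(os.path.join(workdir, f))
            os.rmdir(workdir)

    sgrna_df, gene_df = screen_stats.analyze_screen(
        cm.counts, control_ids, sim.d0_samples, sim.d21_samples, gene_map,
        n_permutations=n_permutations, seed=config.seed,
    )
    genes_by_id = {g.gene_id: g for g in fixture.genes}
    gene_df = screen_stats.bidirectional_filter(
        gene_df, genes_by_id, design.assignments
    )

    # confound audit: every surviving hit with a parent/pseudogene partner
    partner_of: Dict[str, str] = {}
    for g in fixture.genes:
        if g.parent_gene_id:
            partner_of[g.gene_id] = g.parent_gene_id
            partner_of[g.parent_gene_id] = g.gene_id
    tss_of: Dict[str, Tuple[str, int, str]] = {}
    for a in design.assignments:  # CAGE-assigned TSS preferred (sorted first)
        if a.gene_id not in tss_of:
            tss_of[a.gene_id] = (a.chrom, a.tss, a.strand)

    reports: List[ConfoundReport] = []
    sig = (sgrna_df["p"] < 0.05) & (sgrna_df["lfc"] <= -math.log2(1.5))
    for gene_id in sorted(gene_df.index[gene_df["hit"]]):
        partner = partner_of.get(gene_id)
        if partner is None or partner not in tss_of:
            continue
        gene_guides = sgrna_df.index[sgrna_df["gene"] == gene_id]
        pchrom, ptss, pstrand = tss_of[partner]
        offending = set()
        for guide in gene_guides[sig.loc[gene_guides]]:
            sites = find_sites(
                guide, spacers[guide], fixture.genome, max_mismatches,
            )
            sites = [s for s in sites if not s.is_intended_site]
            if partner_window_hits(sites, ptss, pstrand, pchrom):
                offending.add(guide)
        reports.append(
            audit_confounded_hit(
                gene_id, partner,
                [
                    (g, float(sgrna_df.at[g, "lfc"]), float(sgrna_df.at[g, "p"]))
                    for g in gene_guides
                ],
                offending,
            )
        )
    return EndToEndResult(
        fixture=fixture, design=design, sim=sim, counts=cm.counts,
        sgrna_df=sgrna_df, gene_df=gene_df, confound_reports=reports,
        carrier_guide=carrier_guide, band_guide=band_guide,
    )
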