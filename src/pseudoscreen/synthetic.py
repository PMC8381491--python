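"""Synthetic desk-scale fixtures with known ground truth.

Everything the pipeline consumes can be generated here: a toy genome of
parent/pseudogene pairs whose gene bodies share a configurable sequence
homology while their promoters stay divergent, CAGE clusters with positive
TIEScores planted near annotated 5' ends, a pooled screen simulated with
negative-binomial count noise and spiked depletion effects, and screen
reads laid out so the standard trim (20 nt 5', 30 nt 3' of a 75-nt read)
recovers the spacer.

Two artifacts are planted for the downstream confound controls:

* a *bidirectional pair* — two genes with annotated TSSs under 1 kb apart,
  one of them spiked essential, to exercise the TSS-proximity exclusion;
* an *off-target confound* — one pseudogene whose top designed guide gets a
  planted one-mismatch NGG site inside its parent's [-2 kb, +1 kb] promoter
  window. In the simulated screen that carrier guide is strongly depleted
  while the gene's remaining guides are planted so that exactly one guide
  is significant yet the gene still passes the second-best fold-change cut.
  Because "exactly one significant guide" is a property of the realized
  data, the secondary guide's final-timepoint counts are set
  deterministically to the midpoint of the band between the realized
  control 5th percentile and -log2(1.5); this requires enough count
  overdispersion for that band to exist (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats as screen_stats
from .annotation import CageCluster, GeneModel, TranscriptModel
from .design import (
    GenomeIndex,
    LibraryRecord,
    ScoreModel,
    dedup_nearby,
    filter_candidates,
    scan_protospacers,
    score_candidates,
)
from .annotation import design_window
from .design import LINKER_5, LINKER_3, SPACER_LEN
from .genome import revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: sgRNA library composition as published for the screen described here:
#: (category, number of guides, number of distinct genes; 0 = uncategorised)
PUBLISHED_COMPOSITION = (
    ("pseudogene", 5703, 850),
    ("parent", 3727, 380),
    ("positive_control", 568, 71),
    ("AAVS1", 267, 1),
    ("non_targeting", 83, 0),
    ("auxiliary", 1567, 0),
)


@dataclass
class FixtureConfig:
    seed: int
    n_pairs: int = 8
    homology: float = 0.85
    body_length: int = 600
    promoter_halfwidth: int = 250
    gene_spacing: int = 6000
    chrom_name: str = "chr1"
    plant_bidirectional: bool = True
    bidirectional_distance: int = 800
    plant_confound: bool = True
    n_essential: int = 2
    essential_lfc: float = -2.0
    # screen parameters
    n_replicates: int = 3
    depth: float = 500.0
    dispersion: float = 0.05
    jitter_prob: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.homology <= 1.0:
            raise ValueError("homology must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.body_length <= self.promoter_halfwidth + 50:
            raise ValueError("body_length too short for a divergent promoter")


@dataclass
class ConfoundPlant:
    gene_id: str
    partner_gene_id: str
    carrier_spacer: str
    carrier_locus: Tuple[str, str, int]  # (chrom, strand, start)
    offtarget_locus: Tuple[str, str, int]
    offtarget_mismatches: int = 1


@dataclass
class GroundTruth:
    gene_lfc: Dict[str, float] = field(default_factory=dict)
    essential_genes: List[str] = field(default_factory=list)
    null_genes: List[str] = field(default_factory=list)
    bidirectional_pair: Optional[Tuple[str, str]] = None
    bidirectional_spiked: Optional[str] = None
    confound: Optional[ConfoundPlant] = None
    duplications: List[Tuple[str, int, int, int]] = field(default_factory=list)


@dataclass
class ToyFixture:
    genome: Dict[str, str]
    genes: List[GeneModel]
    clusters: List[CageCluster]
    truth: GroundTruth
    config: FixtureConfig


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Per-base substitution at ``rate``, always to a different base."""
    out = arr.copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        idx = (np.searchsorted(BASES, out[hit]) + shift) % 4
        out[hit] = BASES[idx]
    return out


def _pam_occurrences(seq: str, spacer: str) -> int:
    """Exact NGG-adjacent occurrences of a spacer, both strands (slow path
    used only for a handful of candidates during fixture construction)."""
    n = 0
    i = seq.find(spacer)
    while i != -1:
        j = i + SPACER_LEN
        if j + 3 <= len(seq) and seq[j + 1 : j + 3] == "GG":
            n += 1
        i = seq.find(spacer, i + 1)
    rc = revcomp(spacer)
    i = seq.find(rc)
    while i != -1:
        if i >= 3 and seq[i - 3 : i - 1] == "CC":
            n += 1
        i = seq.find(rc, i + 1)
    return n


def _confound_carrier(
    seq: str, window: Tuple[int, int], chrom: str, gene_id: str, cluster_id: str
):
    """Pick the guide the design pipeline will rank first in this window.

    Mirrors the zero-score design path: scan, sequence filters, exact
    NGG-occurrence uniqueness, 4-bp dedup, then position order.
    """
    genome = {chrom: seq}
    cands = scan_protospacers(genome, chrom, window, gene_id, cluster_id)
    cands = score_candidates(cands, ScoreModel())

    class _Idx:
        def occurrences(self, spacer):
            return _pam_occurrences(seq, spacer)

    cands = filter_candidates(cands, _Idx())
    cands = dedup_nearby(cands)
    passing = sorted((c for c in cands if c.passes), key=lambda c: c.start)
    if len(passing) < 3:
        raise RuntimeError("confound window yielded fewer than 3 guides")
    return passing[0]


def make_toy_genome(config: FixtureConfig) -> ToyFixture:
    """Build the toy genome, annotation, CAGE track and ground truth.

    Layout: one chromosome; each gene occupies a ``gene_spacing`` slot with
    its TSS 2.5 kb into the slot, so neighboring TSSs sit ``gene_spacing``
    apart (well beyond the 1-kb bidirectional cutoff) except for the
    deliberately planted bidirectional pair. Pair i contributes a
    protein-coding parent and a pseudogene whose body downstream of the
    divergent promoter copies the parent at the configured homology.
    Every fourth pseudogene goes on the minus strand (without body
    homology) to exercise strand handling.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = 2 * config.n_pairs + (2 if config.plant_bidirectional else 0)
    chrom_len = (n_genes + 1) * config.gene_spacing
    chrom = config.chrom_name
    seq = _random_seq(rng, chrom_len)

    genes: List[GeneModel] = []
    clusters: List[CageCluster] = []
    truth = GroundTruth()
    classes = ("processed_pseudogene", "unprocessed_pseudogene", "unitary_pseudogene")

    def add_gene(gene_id, biotype, strand, tss0, body, parent_id=None):
        if strand == "+":
            start, end = tss0, tss0 + body
        else:
            start, end = tss0 - body + 1, tss0 + 1
        tx = TranscriptModel(f"{gene_id}_T1", gene_id, chrom, strand, start, end)
        genes.append(
            GeneModel(gene_id, gene_id, biotype, chrom, strand, start, end,
                      transcripts=[tx], parent_gene_id=parent_id)
        )
        # one CAGE cluster with its summit near the 5' end
        summit = tss0 + int(rng.integers(-20, 21))
        tie = float(np.round(rng.uniform(5, 50), 1))
        clusters.append(
            CageCluster(f"cage_{gene_id}", chrom, strand, summit - 15, summit + 16,
                        tie_score=tie, summit=summit)
        )
        return tss0

    slot = 0
    for i in range(config.n_pairs):
        par_id, psg_id = f"PAR_{i:03d}", f"PSG_{i:03d}"
        par_tss0 = slot * config.gene_spacing + 2500
        add_gene(par_id, "protein_coding", "+", par_tss0, config.body_length)
        slot += 1
        psg_strand = "-" if (i % 4 == 3 and i != 0) else "+"
        psg_tss0 = slot * config.gene_spacing + 2500
        add_gene(psg_id, classes[i % 3], psg_strand, psg_tss0,
                 config.body_length, parent_id=par_id)
        slot += 1
        if psg_strand == "+":
            # homologous body downstream of the divergent promoter
            off = config.promoter_halfwidth
            bl = config.body_length - off
            src = seq[par_tss0 + off : par_tss0 + off + bl]
            copied = _mutate(rng, src, 1.0 - config.homology)
            seq[psg_tss0 + off : psg_tss0 + off + bl] = copied
            if config.homology == 1.0:
                truth.duplications.append(
                    (chrom, par_tss0 + off, psg_tss0 + off, bl)
                )

    if config.plant_bidirectional:
        a_tss0 = slot * config.gene_spacing + 2500
        b_tss0 = a_tss0 + config.bidirectional_distance
        add_gene("BIDIR_A", "protein_coding", "+", a_tss0, 500)
        add_gene("BIDIR_B", "protein_coding", "+", b_tss0, 400)
        slot += 2  # both genes live in two slots' worth of space
        truth.bidirectional_pair = ("BIDIR_A", "BIDIR_B")
        truth.bidirectional_spiked = "BIDIR_A"

    gene_by_id = {g.gene_id: g for g in genes}
    confound_gene = "PSG_000" if config.plant_confound and config.n_pairs >= 1 else None

    if confound_gene is not None:
        psg = gene_by_id[confound_gene]
        par = gene_by_id[psg.parent_gene_id]
        cl = next(c for c in clusters if c.cluster_id == f"cage_{confound_gene}")
        window = design_window(cl.summit, chrom_len)
        carrier = _confound_carrier(
            seq.tobytes().decode(), window, chrom, confound_gene, cl.cluster_id
        )
        # one-mismatch copy of the carrier protospacer, NGG PAM, planted
        # upstream of the parent TSS inside its [-2 kb, +1 kb] window but
        # outside the parent's 500-bp design window
        mut = list(carrier.spacer)
        pos = 9
        mut[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mut[pos]]
        site = "".join(mut) + "TGG"
        par_tss0 = par.transcripts[0].five_prime_end - 1
        site_start = par_tss0 - 1500
        seq[site_start : site_start + len(site)] = np.frombuffer(
            site.encode(), dtype="S1"
        )
        truth.confound = ConfoundPlant(
            gene_id=confound_gene,
            partner_gene_id=par.gene_id,
            carrier_spacer=carrier.spacer,
            carrier_locus=(chrom, carrier.strand, carrier.start),
            offtarget_locus=(chrom, "+", site_start),
        )

    # essentiality roles: skip the confound gene and the bidirectional pair
    candidates = [
        g.gene_id for g in genes
        if g.gene_id not in {confound_gene, "BIDIR_A", "BIDIR_B"}
    ]
    truth.essential_genes = candidates[: config.n_essential]
    truth.null_genes = candidates[config.n_essential :]
    for g in truth.essential_genes:
        truth.gene_lfc[g] = config.essential_lfc
    for g in truth.null_genes:
        truth.gene_lfc[g] = 0.0
    if truth.bidirectional_spiked:
        truth.gene_lfc[truth.bidirectional_spiked] = config.essential_lfc
        truth.gene_lfc["BIDIR_B"] = 0.0

    genome = {chrom: seq.tobytes().decode()}
    return ToyFixture(genome=genome, genes=genes, clusters=clusters,
                      truth=truth, config=config)


# ---------------------------------------------------------------------------
# screen simulation


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with variance mu + phi*mu^2 (Poisson when phi=0)."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


@dataclass
class ScreenSim:
    counts: pd.DataFrame  # expected guide x sample matrix
    d0_samples: List[str]
    d21_samples: List[str]
    band_lfc: Optional[float] = None  # realized confound band target


def simulate_counts(
    guide_lfc: Mapping[str, float],
    config: FixtureConfig,
    rng: np.random.Generator,
) -> ScreenSim:
    """Draw D0/D21 count matrices around ``depth`` per guide.

    D0 means are ``depth``; D21 means are ``depth * 2**lfc`` per guide.
    """
    guides = sorted(guide_lfc)
    lfc = np.array([guide_lfc[g] for g in guides])
    d0s = [f"D0_r{r+1}" for r in range(config.n_replicates)]
    d21s = [f"D21_r{r+1}" for r in range(config.n_replicates)]
    data = {}
    for s in d0s:
        data[s] = _nb_draw(rng, np.full(len(guides), config.depth), config.dispersion)
    for s in d21s:
        data[s] = _nb_draw(rng, config.depth * np.power(2.0, lfc), config.dispersion)
    counts = pd.DataFrame(data, index=guides, dtype=int)
    return ScreenSim(counts=counts, d0_samples=d0s, d21_samples=d21s)


def plant_confound_counts(
    sim: ScreenSim,
    control_ids: Sequence[str],
    band_guide: str,
    neutral_guides: Sequence[str] = (),
    neutral_lfc: float = -0.1,
) -> ScreenSim:
    """Deterministically pin planted guides to target fold-changes.

    The band guide is pinned to the midpoint between the realized control
    lfc 5th percentile and -log2(1.5): depleted enough to pass the gene
    second-best cut, not depleted enough to be individually significant.
    Neutral guides are pinned just below zero so they can never satisfy the
    per-guide fold-change condition. Raises when the control distribution
    is too tight for the band to exist.
    """
    norm = screen_stats.normalize_control(sim.counts, control_ids)
    sg = screen_stats.sgrna_stats(
        norm, sim.d0_samples, sim.d21_samples, gene_map={}
    )
    ctrl_sorted = np.sort(sg.loc[list(control_ids), "lfc"].to_numpy())
    n_ctrl = ctrl_sorted.size
    thresh = -math.log2(1.5)
    # the band guide must keep >= k_min controls below it so its add-one
    # empirical p-value stays >= 0.05; add a buffer against count rounding
    k_min = int(math.ceil(0.05 * (n_ctrl + 1) - 1.0))
    k0 = min(n_ctrl - 1, k_min + max(5, n_ctrl // 35))
    floor = float(ctrl_sorted[k0])
    if floor >= thresh - 0.05:
        raise RuntimeError(
            "control lfc distribution is too tight below -log2(1.5); "
            "increase dispersion so a non-significant depleted guide can exist"
        )
    band = (floor + thresh) / 2.0
    counts = sim.counts.copy()
    sf = norm.size_factors

    def pin(guide: str, target: float) -> None:
        for d0, d21 in zip(sim.d0_samples, sim.d21_samples):
            n0 = counts.at[guide, d0] / sf[d0]
            n21 = (n0 + 1.0) * 2.0 ** target - 1.0
            counts.at[guide, d21] = max(0, int(round(n21 * sf[d21])))

    pin(band_guide, band)
    for g in neutral_guides:
        pin(g, neutral_lfc)
    return ScreenSim(counts=counts, d0_samples=sim.d0_samples,
                     d21_samples=sim.d21_samples, band_lfc=band)


# ---------------------------------------------------------------------------
# read-level simulation

READ_LENGTH = 75
_SUFFIX = LINKER_3  # 3' vector context


def reads_for_sample(
    counts_col: Mapping[str, int],
    spacers: Mapping[str, str],
    rng: np.random.Generator,
    jitter_prob: float = 0.1,
):
    """Yield 75-nt reads reproducing exactly the given per-guide counts.

    Each read is vector-prefix + spacer + vector-suffix with the spacer
    starting at position 20, or at 21/22 with probability ``jitter_prob``
    (split evenly) — within the 25-nt fragment the standard trim retains,
    exercising the substring-matching contract.
    """
    for guide in sorted(counts_col):
        spacer = spacers[guide]
        n = int(counts_col[guide])
        if n <= 0:
            continue
        starts = np.full(n, 20, dtype=int)
        if jitter_prob > 0:
            u = rng.random(n)
            starts[u < jitter_prob / 2] = 21
            starts[(u >= jitter_prob / 2) & (u < jitter_prob)] = 22
        for start in starts:
            read = LINKER_5[-int(start):] + spacer + _SUFFIX
            yield read[:READ_LENGTH]


def write_screen_fastq(
    sim: ScreenSim,
    spacers: Mapping[str, str],
    out_dir: str,
    seed: int,
    jitter_prob: float = 0.1,
) -> Dict[str, str]:
    """Write one plain FASTQ per sample; returns sample -> path."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    qual = "I" * READ_LENGTH
    paths = {}
    for i, sample in enumerate(sim.d0_samples + sim.d21_samples):
        rng = np.random.default_rng((seed, i))
        path = os.path.join(out_dir, f"{sample}.fq")
        with open(path, "w") as fh:
            for j, read in enumerate(
                reads_for_sample(sim.counts[sample].to_dict(), spacers, rng, jitter_prob)
            ):
                fh.write(f"@{sample}_{j}\n{read}\n+\n{qual}\n")
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# synthetic published-library manifest


def synthetic_library_manifest(seed: int = 0) -> List[LibraryRecord]:
    """Synthetic stand-in for the published sgRNA library manifest.

    Reproduces the published composition (guide and gene counts per
    category, 11,915 guides in total) with randomly generated distinct
    spacers; per-gene guide counts are spread evenly within the 3..10
    design bounds. The sequences are synthetic — only the accounting
    structure mirrors the real library table.
    """
    rng = np.random.default_rng(seed)
    seen = set()

    def fresh_spacer() -> str:
        while True:
            sp = "".join(BASES[rng.integers(0, 4, size=SPACER_LEN)].astype(str))
            if sp not in seen:
                seen.add(sp)
                return sp

    records: List[LibraryRecord] = []
    for category, n_guides, n_genes in PUBLISHED_COMPOSITION:
        if n_genes > 1:
            base, extra = divmod(n_guides, n_genes)
            per_gene = [base + 1] * extra + [base] * (n_genes - extra)
            genes = [
                ([f"{category[:3].upper()}{i:04d}"], c)
                for i, c in enumerate(per_gene)
            ]
        elif n_genes == 1:
            genes = [(["AAVS1"], n_guides)]
        else:
            genes = [([], n_guides)]
        idx = 0
        for gene_ids, count in genes:
            for _ in range(count):
                records.append(
                    LibraryRecord(
                        guide_id=f"{category}_{idx:05d}",
                        spacer=fresh_spacer(),
                        category=category,
                        gene_ids=list(gene_ids),
                    )
                )
                idx += 1
    return records
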