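"""SpCas9 protospacer scanning, scoring, the filter cascade, per-gene
selection, and library manifest assembly.

The design contract: within a 500-bp promoter window every 20-mer followed
by an NGG PAM (either strand) is a candidate. Candidates are scored
(pluggable linear position-weight model or an imported score table), then
filtered out when they (a) map to multiple genomic NGG-adjacent sites,
(b) contain Ns or four or more consecutive Ts, or (c) have GC >= 75% or
< 10%. Candidates within 4 bp of each other keep only the best scorer.
Per gene up to ``max_per_gene`` guides are selected, preferring TSS
clusters with higher TIEScore. Manifest oligos are 5'linker+spacer+3'linker.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, TextIO, Tuple, Union

import yaml

from .annotation import TssAssignment
from .genome import revcomp

SPACER_LEN = 20
PAM_LEN = 3
LINKER_5 = "CTTTATATATCTTGTGGAAAGGACGAAACACCG"
LINKER_3 = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCG"

FILTER_FLAGS = ("multi_mapping", "has_N", "poly_T", "gc_extreme", "dedup_removed")

GC_MAX = 0.75  # flagged when GC fraction >= this
GC_MIN = 0.10  # flagged when GC fraction < this
POLY_T_RUN = 4  # "more than three consecutive T"
DEDUP_DISTANCE = 4  # |delta start| <= 4 collapses to the best scorer
DEFAULT_MAX_PER_GENE = 10
MIN_GUIDES_PER_GENE = 3


@dataclass
class GuideCandidate:
    spacer: str
    pam: str
    chrom: str
    strand: str
    start: int  # 0-based half-open spacer interval
    end: int
    gene_id: str
    tss_source: str  # cluster_id or "annotated"
    score: float = 0.0
    filter_flags: frozenset = frozenset()

    def __post_init__(self):
        if len(self.spacer) != SPACER_LEN:
            raise ValueError("spacer must be 20 nt")
        if len(self.pam) != PAM_LEN or not self.pam.endswith("GG"):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")

    @property
    def passes(self) -> bool:
        return not self.filter_flags

    @property
    def guide_id(self) -> str:
        return f"sg_{self.chrom}_{self.start}_{self.strand}"


class ScoreModel:
    """Transparent guide scoring: linear position-nucleotide weights or an
    imported spacer -> score lookup table. Higher scores are better."""

    def __init__(
        self,
        weights: Optional[Mapping[Tuple[int, str], float]] = None,
        intercept: float = 0.0,
        table: Optional[Mapping[str, float]] = None,
    ):
        self.weights = dict(weights) if weights else {}
        self.intercept = intercept
        self.table = dict(table) if table is not None else None

    def score(self, spacer: str) -> float:
        if self.table is not None:
            if spacer not in self.table:
                raise KeyError(f"spacer {spacer} absent from imported score table")
            return self.table[spacer]
        total = self.intercept
        for pos, base in enumerate(spacer):
            total += self.weights.get((pos, base), 0.0)
        return total

    @classmethod
    def from_yaml(cls, source: Union[str, TextIO]) -> "ScoreModel":
        """Load ``{intercept: float, weights: {"<pos0>:<base>": w, ...}}``."""
        if isinstance(source, str):
            with open(source) as fh:
                cfg = yaml.safe_load(fh)
        else:
            cfg = yaml.safe_load(source)
        weights = {}
        for key, w in (cfg.get("weights") or {}).items():
            pos_s, base = key.split(":")
            weights[(int(pos_s), base)] = float(w)
        return cls(weights=weights, intercept=float(cfg.get("intercept", 0.0)))

    @classmethod
    def from_table_tsv(cls, source: Union[str, TextIO]) -> "ScoreModel":
        handle = open(source) if isinstance(source, str) else source
        try:
            table = {}
            for row in csv.reader(handle, delimiter="\t"):
                if not row or row[0].startswith("#") or row[0] == "spacer":
                    continue
                table[row[0]] = float(row[1])
        finally:
            if isinstance(source, str):
                handle.close()
        return cls(table=table)


class GenomeIndex:
    """Exact-occurrence counter for NGG-adjacent 20-mers, both strands.

    Only protospacers with an adjacent NGG PAM are indexed: a spacer's
    occurrence count is the number of CRISPRi-competent genomic sites whose
    protospacer matches it exactly.
    """

    def __init__(self, genome: Mapping[str, str]):
        counts: Counter = Counter()
        for seq in genome.values():
            n = len(seq)
            for i in range(n - SPACER_LEN - PAM_LEN + 1):
                if seq[i + SPACER_LEN + 1] == "G" and seq[i + SPACER_LEN + 2] == "G":
                    counts[seq[i : i + SPACER_LEN]] += 1
                if seq[i] == "C" and seq[i + 1] == "C":
                    counts[revcomp(seq[i + PAM_LEN : i + PAM_LEN + SPACER_LEN])] += 1
        self._counts = counts

    def occurrences(self, spacer: str) -> int:
        return self._counts.get(spacer, 0)


def scan_protospacers(
    genome: Mapping[str, str],
    chrom: str,
    interval: Tuple[int, int],
    gene_id: str,
    tss_source: str = "annotated",
) -> List[GuideCandidate]:
    """Emit every NGG-adjacent 20-mer protospacer fully inside ``interval``.

    Minus-strand candidates store the spacer as the reverse complement of
    the plus-strand genomic slice; candidates are unscored and unflagged.
    """
    seq = genome[chrom]
    start, end = interval
    if start < 0 or end > len(seq):
        raise ValueError(f"interval {interval} outside chromosome {chrom}")
    window = seq[start:end]
    out = []
    span = SPACER_LEN + PAM_LEN
    for i in range(len(window) - span + 1):
        # plus strand: [spacer 20][N G G]
        if window[i + SPACER_LEN + 1] == "G" and window[i + SPACER_LEN + 2] == "G":
            out.append(
                GuideCandidate(
                    spacer=window[i : i + SPACER_LEN],
                    pam=window[i + SPACER_LEN : i + span],
                    chrom=chrom,
                    strand="+",
                    start=start + i,
                    end=start + i + SPACER_LEN,
                    gene_id=gene_id,
                    tss_source=tss_source,
                )
            )
        # minus strand: [C C N][spacer' 20] on the plus strand
        if window[i] == "C" and window[i + 1] == "C":
            out.append(
                GuideCandidate(
                    spacer=revcomp(window[i + PAM_LEN : i + span]),
                    pam=revcomp(window[i : i + PAM_LEN]),
                    chrom=chrom,
                    strand="-",
                    start=start + i + PAM_LEN,
                    end=start + i + span,
                    gene_id=gene_id,
                    tss_source=tss_source,
                )
            )
    return out


def score_candidates(
    candidates: Iterable[GuideCandidate], model: ScoreModel
) -> List[GuideCandidate]:
    return [replace(c, score=model.score(c.spacer)) for c in candidates]


def gc_fraction(spacer: str) -> float:
    return (spacer.count("G") + spacer.count("C")) / len(spacer)


def filter_candidates(
    candidates: Iterable[GuideCandidate], genome_index: GenomeIndex
) -> List[GuideCandidate]:
    """Apply the sequence/uniqueness filter cascade, setting filter flags."""
    out = []
    for c in candidates:
        flags = set(c.filter_flags)
        flags.discard("multi_mapping")
        flags.discard("has_N")
        flags.discard("poly_T")
        flags.discard("gc_extreme")
        if "N" in c.spacer:
            flags.add("has_N")
        if "T" * POLY_T_RUN in c.spacer:
            flags.add("poly_T")
        gc = gc_fraction(c.spacer)
        if gc >= GC_MAX or gc < GC_MIN:
            flags.add("gc_extreme")
        if genome_index.occurrences(c.spacer) > 1:
            flags.add("multi_mapping")
        out.append(replace(c, filter_flags=frozenset(flags)))
    return out


def dedup_nearby(candidates: Iterable[GuideCandidate]) -> List[GuideCandidate]:
    """Collapse chains of passing candidates whose starts are within 4 bp.

    Within each maximal chain (consecutive sorted starts differing by <= 4)
    only the highest-scoring candidate survives; ties keep the leftmost
    start, then the lexicographically smallest spacer. Already-flagged
    candidates are ignored by the chaining, and output order follows the
    (chrom, start, strand) sort regardless of input order.
    """
    cands = list(candidates)
    passing = [c for c in cands if c.passes]
    flagged = [c for c in cands if not c.passes]
    passing.sort(key=lambda c: (c.chrom, c.start, c.strand, c.spacer))

    removed_keys = set()
    i = 0
    while i < len(passing):
        j = i
        while (
            j + 1 < len(passing)
            and passing[j + 1].chrom == passing[j].chrom
            and passing[j + 1].start - passing[j].start <= DEDUP_DISTANCE
        ):
            j += 1
        chain = passing[i : j + 1]
        if len(chain) > 1:
            best = max(chain, key=lambda c: (c.score, -c.start, c.spacer))
            for c in chain:
                if c is not best:
                    removed_keys.add(id(c))
        i = j + 1

    out = []
    for c in passing:
        if id(c) in removed_keys:
            out.append(replace(c, filter_flags=c.filter_flags | {"dedup_removed"}))
        else:
            out.append(c)
    out.extend(flagged)
    out.sort(key=lambda c: (c.chrom, c.start, c.strand, c.spacer))
    return out


def select_per_gene(
    candidates: Iterable[GuideCandidate],
    assignments: Iterable[TssAssignment],
    max_per_gene: int = DEFAULT_MAX_PER_GENE,
) -> List[GuideCandidate]:
    """Select up to ``max_per_gene`` passing guides per gene.

    Ordering: TIEScore of the candidate's TSS cluster descending (annotated
    fallback TSSs score 0), then guide score descending, then genomic start
    ascending. Guides tied to several TSS clusters of the same gene appear
    once under their highest-priority source.
    """
    if max_per_gene < 1:
        raise ValueError("max_per_gene must be >= 1")
    tie_by_key: Dict[Tuple[str, str], float] = {}
    for a in assignments:
        key = (a.gene_id, a.cluster_id if a.source == "cage" else "annotated")
        tie_by_key[key] = max(tie_by_key.get(key, 0.0), a.tie_score)

    by_gene: Dict[str, Dict[Tuple, GuideCandidate]] = {}
    for c in candidates:
        if not c.passes:
            continue
        locus = (c.chrom, c.start, c.strand)
        gene_bucket = by_gene.setdefault(c.gene_id, {})
        prev = gene_bucket.get(locus)
        tie = tie_by_key.get((c.gene_id, c.tss_source), 0.0)
        if prev is None or tie > tie_by_key.get((c.gene_id, prev.tss_source), 0.0):
            gene_bucket[locus] = c

    selected = []
    for gene_id in sorted(by_gene):
        cands = sorted(
            by_gene[gene_id].values(),
            key=lambda c: (
                -tie_by_key.get((c.gene_id, c.tss_source), 0.0),
                -c.score,
                c.start,
                c.spacer,
            ),
        )
        selected.extend(cands[:max_per_gene])
    return selected


@dataclass
class LibraryRecord:
    guide_id: str
    spacer: str
    category: str
    gene_ids: List[str] = field(default_factory=list)
    chrom: str = ""
    start: int = -1
    end: int = -1
    strand: str = ""
    pam: str = ""
    score: float = 0.0
    flags: str = ""

    @property
    def oligo(self) -> str:
        return LINKER_5 + self.spacer + LINKER_3


@dataclass(frozen=True)
class ControlGuide:
    guide_id: str
    spacer: str
    category: str  # positive_control | AAVS1 | non_targeting | auxiliary
    gene_id: str = ""


def assemble_library(
    selected: Sequence[GuideCandidate],
    control_spec: Sequence[ControlGuide] = (),
    gene_categories: Optional[Mapping[str, str]] = None,
) -> List[LibraryRecord]:
    """Build the oligo manifest: one record per distinct spacer.

    A spacer designed within the windows of several genes carries all gene
    annotations on one record; its category follows the first gene in sorted
    order (pseudogene wins over parent when mixed). Duplicate guide_ids
    raise ``ValueError``.
    """
    gene_categories = dict(gene_categories or {})
    by_spacer: Dict[str, LibraryRecord] = {}
    for c in sorted(selected, key=lambda c: (c.chrom, c.start, c.strand, c.gene_id)):
        rec = by_spacer.get(c.spacer)
        if rec is None:
            rec = LibraryRecord(
                guide_id=c.guide_id,
                spacer=c.spacer,
                category=gene_categories.get(c.gene_id, "pseudogene"),
                gene_ids=[c.gene_id],
                chrom=c.chrom,
                start=c.start,
                end=c.end,
                strand=c.strand,
                pam=c.pam,
                score=c.score,
                flags=",".join(sorted(c.filter_flags)),
            )
            by_spacer[c.spacer] = rec
        elif c.gene_id not in rec.gene_ids:
            rec.gene_ids.append(c.gene_id)
            if gene_categories.get(c.gene_id) == "pseudogene":
                rec.category = "pseudogene"

    records = list(by_spacer.values())
    for ctrl in control_spec:
        records.append(
            LibraryRecord(
                guide_id=ctrl.guide_id,
                spacer=ctrl.spacer,
                category=ctrl.category,
                gene_ids=[ctrl.gene_id] if ctrl.gene_id else [],
            )
        )
    seen = set()
    for rec in records:
        if rec.guide_id in seen:
            raise ValueError(f"duplicate guide_id {rec.guide_id}")
        seen.add(rec.guide_id)
    return records


MANIFEST_COLUMNS = [
    "guide_id", "spacer", "category", "gene_ids", "chrom", "start", "end",
    "strand", "pam", "score", "flags", "oligo",
]


def write_manifest(records: Sequence[LibraryRecord], dest: Union[str, TextIO]) -> None:
    def emit(fh):
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MANIFEST_COLUMNS)
        for r in records:
            w.writerow(
                [r.guide_id, r.spacer, r.category, ",".join(r.gene_ids), r.chrom,
                 r.start, r.end, r.strand, r.pam, repr(r.score), r.flags, r.oligo]
            )

    if isinstance(dest, str):
        with open(dest, "w") as fh:
            emit(fh)
    else:
        emit(dest)


def read_manifest(source: Union[str, TextIO]) -> List[LibraryRecord]:
    handle = open(source) if isinstance(source, str) else source
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        records = []
        for row in reader:
            rec = LibraryRecord(
                guide_id=row["guide_id"],
                spacer=row["spacer"],
                category=row["category"],
                gene_ids=[g for g in row["gene_ids"].split(",") if g],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                pam=row["pam"],
                score=float(row["score"]),
                flags=row["flags"],
            )
            if row.get("oligo") and rec.oligo != row["oligo"]:
                raise ValueError(f"manifest oligo mismatch for {rec.guide_id}")
            records.append(rec)
        return records
    finally:
        if isinstance(source, str):
            handle.close()
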