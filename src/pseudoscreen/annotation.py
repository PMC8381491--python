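"""Gene annotation, CAGE clusters, and TSS assignment.

The annotation model follows the GENCODE GTF dialect: a gene owns one or
more transcripts, each with a strand-correct 5' end. CAGE tag clusters
carrying a transcription initiation evidence score (TIEScore) are linked to
transcripts by summit proximity, and the resulting assignments define the
promoter windows used for CRISPRi guide design as well as the inter-gene TSS
distances used by the bidirectional-promoter filter.

Coordinate conventions: GTF is parsed as 1-based inclusive, BED as 0-based
half-open. Internally all intervals are 0-based half-open; single TSS
positions are kept 1-based (matching the GTF 5' end).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple, Union

import gffutils

PSEUDOGENE_BIOTYPES = (
    "processed_pseudogene",
    "unprocessed_pseudogene",
    "unitary_pseudogene",
)

DEFAULT_MAX_OFFSET = 500
WINDOW_SIZE = 500


def map_biotype(gene_type: str) -> str:
    """Collapse a GENCODE gene_type onto the biotype classes used here.

    ``transcribed_processed_pseudogene`` and friends collapse onto their
    base pseudogene class; anything that is neither protein-coding nor one
    of the three pseudogene classes becomes ``other``.
    """
    if gene_type == "protein_coding":
        return "protein_coding"
    # order matters: "unprocessed" ends with "processed"
    for bt in ("unitary_pseudogene", "unprocessed_pseudogene", "processed_pseudogene"):
        if gene_type == bt or gene_type.endswith("_" + bt):
            return bt
    return "other"


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span
    end: int

    @property
    def five_prime_end(self) -> int:
        """Strand-correct transcript 5' end, 1-based."""
        return self.start + 1 if self.strand == "+" else self.end


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span covering all transcripts
    end: int
    transcripts: List[TranscriptModel] = field(default_factory=list)
    parent_gene_id: Optional[str] = None

    @property
    def is_pseudogene(self) -> bool:
        return self.biotype in PSEUDOGENE_BIOTYPES

    def annotated_tss(self) -> List[int]:
        """Distinct transcript 5' ends (1-based), sorted."""
        return sorted({t.five_prime_end for t in self.transcripts})


class GtfParseError(ValueError):
    pass


def read_annotation(gtf_source: Union[str, TextIO, Iterable[str]]) -> List[GeneModel]:
    """Parse a GENCODE-dialect GTF into :class:`GeneModel` objects.

    Only ``gene`` and ``transcript`` features are consumed. Every record must
    carry ``gene_id``; transcripts must also carry ``transcript_id``; genes
    must carry ``gene_type``. A missing mandatory attribute raises
    :class:`GtfParseError` naming the offending line.
    """
    if isinstance(gtf_source, str):
        with open(gtf_source) as fh:
            lines = fh.readlines()
    else:
        lines = list(gtf_source)

    genes: Dict[str, GeneModel] = {}
    transcripts: List[TranscriptModel] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            feat = gffutils.feature.feature_from_line(line, dialect=None)
        except Exception as exc:  # malformed column count etc.
            raise GtfParseError(f"line {lineno}: unparseable GTF record: {exc}")
        if feat.featuretype not in ("gene", "transcript"):
            continue
        attrs = feat.attributes
        if "gene_id" not in attrs:
            raise GtfParseError(f"line {lineno}: missing mandatory attribute gene_id")
        gene_id = attrs["gene_id"][0]
        if feat.strand not in ("+", "-"):
            raise GtfParseError(f"line {lineno}: strand must be + or -")
        start0, end0 = feat.start - 1, feat.end  # GTF 1-based inclusive
        if feat.featuretype == "gene":
            if "gene_type" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: missing mandatory attribute gene_type"
                )
            genes[gene_id] = GeneModel(
                gene_id=gene_id,
                gene_name=attrs["gene_name"][0] if "gene_name" in attrs else gene_id,
                biotype=map_biotype(attrs["gene_type"][0]),
                chrom=feat.seqid,
                strand=feat.strand,
                start=start0,
                end=end0,
                parent_gene_id=(
                    attrs["parent_gene_id"][0] if "parent_gene_id" in attrs else None
                ),
            )
        else:
            if "transcript_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: missing mandatory attribute transcript_id"
                )
            transcripts.append(
                TranscriptModel(
                    transcript_id=attrs["transcript_id"][0],
                    gene_id=gene_id,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    start=start0,
                    end=end0,
                )
            )

    for tx in transcripts:
        gene = genes.get(tx.gene_id)
        if gene is None:
            raise GtfParseError(
                f"transcript {tx.transcript_id} references unknown gene {tx.gene_id}"
            )
        gene.transcripts.append(tx)
        gene.start = min(gene.start, tx.start)
        gene.end = max(gene.end, tx.end)
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def write_annotation(genes: Sequence[GeneModel], dest: Union[str, TextIO]) -> None:
    """Write genes/transcripts back out as GENCODE-dialect GTF."""

    def emit(fh):
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; gene_type "{g.biotype}";'
            if g.parent_gene_id:
                attrs += f' parent_gene_id "{g.parent_gene_id}";'
            fh.write(
                f"{g.chrom}\ttoy\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_type "{g.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\ttoy\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{tattrs}\n"
                )

    if isinstance(dest, str):
        with open(dest, "w") as fh:
            emit(fh)
    else:
        emit(dest)


@dataclass(frozen=True)
class CageCluster:
    cluster_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int
    tie_score: float
    summit: int  # 0-based position within [start, end)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"cluster {self.cluster_id}: start >= end")
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"cluster {self.cluster_id}: summit outside cluster")
        if self.tie_score < 0:
            raise ValueError(f"cluster {self.cluster_id}: negative TIEScore")


def read_cage_clusters(bed_source: Union[str, TextIO]) -> List[CageCluster]:
    """Read CAGE clusters from BED6+1 (TIEScore in column 7).

    The summit defaults to the cluster midpoint. Rows with an invalid strand
    or a degenerate interval raise ``ValueError``. Output is sorted by
    (chrom, start, cluster_id).
    """
    handle = open(bed_source) if isinstance(bed_source, str) else bed_source
    clusters = []
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"CAGE BED line {lineno}: expected >= 7 columns")
            chrom, start_s, end_s, name, _score, strand, tie_s = fields[:7]
            if strand not in ("+", "-"):
                raise ValueError(f"CAGE BED line {lineno}: strand must be + or -")
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(f"CAGE BED line {lineno}: start >= end")
            clusters.append(
                CageCluster(
                    cluster_id=name,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    tie_score=float(tie_s),
                    summit=(start + end) // 2,
                )
            )
    finally:
        if isinstance(bed_source, str):
            handle.close()
    return sorted(clusters, key=lambda c: (c.chrom, c.start, c.cluster_id))


def write_cage_clusters(clusters: Sequence[CageCluster], dest: Union[str, TextIO]) -> None:
    def emit(fh):
        for c in sorted(clusters, key=lambda c: (c.chrom, c.start, c.cluster_id)):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t0\t{c.strand}\t"
                f"{c.tie_score:g}\n"
            )

    if isinstance(dest, str):
        with open(dest, "w") as fh:
            emit(fh)
    else:
        emit(dest)


@dataclass(frozen=True)
class TssAssignment:
    gene_id: str
    transcript_id: str
    source: str  # "cage" | "annotated"
    tss: int  # 1-based coordinate
    chrom: str
    strand: str
    tie_score: float = 0.0
    cluster_id: Optional[str] = None

    def __post_init__(self):
        if self.source not in ("cage", "annotated"):
            raise ValueError(f"invalid TSS source {self.source!r}")
        if self.source == "annotated" and self.cluster_id is not None:
            raise ValueError("annotated TSS must not carry a cluster_id")


def assign_tss(
    transcripts: Iterable[TranscriptModel],
    clusters: Iterable[CageCluster],
    max_offset_bp: int = DEFAULT_MAX_OFFSET,
) -> List[TssAssignment]:
    """Assign CAGE clusters to transcripts by strand-matched summit proximity.

    A cluster is assigned to a transcript iff it shares chromosome and strand
    and its summit lies within ``max_offset_bp`` of the transcript 5' end.
    Transcripts with no assigned cluster fall back to their annotated 5' end
    with tie_score 0. A (gene, cluster) pair is emitted at most once; when a
    cluster matches several transcripts of a gene the smallest-offset match
    wins. The result is deterministic and independent of input order.
    """
    if max_offset_bp <= 0:
        raise ValueError("max_offset_bp must be positive")
    transcripts = sorted(transcripts, key=lambda t: t.transcript_id)
    clusters = sorted(clusters, key=lambda c: (c.chrom, c.start, c.cluster_id))

    # (gene, cluster) -> (offset, assignment); keep the smallest offset
    best: Dict[Tuple[str, str], Tuple[int, TssAssignment]] = {}
    assigned_tx = set()
    for tx in transcripts:
        tss0 = tx.five_prime_end - 1  # 0-based for comparison with summits
        for cl in clusters:
            if cl.chrom != tx.chrom or cl.strand != tx.strand:
                continue
            offset = abs(cl.summit - tss0)
            if offset > max_offset_bp:
                continue
            assigned_tx.add(tx.transcript_id)
            key = (tx.gene_id, cl.cluster_id)
            cand = TssAssignment(
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                source="cage",
                tss=cl.summit + 1,
                chrom=tx.chrom,
                strand=tx.strand,
                tie_score=cl.tie_score,
                cluster_id=cl.cluster_id,
            )
            prev = best.get(key)
            if prev is None or (offset, cand.transcript_id) < (prev[0], prev[1].transcript_id):
                best[key] = (offset, cand)

    out = [a for _, a in best.values()]
    for tx in transcripts:
        if tx.transcript_id not in assigned_tx:
            out.append(
                TssAssignment(
                    gene_id=tx.gene_id,
                    transcript_id=tx.transcript_id,
                    source="annotated",
                    tss=tx.five_prime_end,
                    chrom=tx.chrom,
                    strand=tx.strand,
                    tie_score=0.0,
                )
            )
    # rank within gene: higher TIEScore first, CAGE before annotated fallback
    out.sort(
        key=lambda a: (a.gene_id, a.source != "cage", -a.tie_score, a.tss, a.transcript_id)
    )
    return out


def tss_distance(
    gene_a: GeneModel,
    gene_b: GeneModel,
    assignments: Iterable[TssAssignment],
) -> float:
    """Minimum TSS distance (bp) between two genes.

    Defined as the minimum over all pairs of CAGE-assigned TSSs of the two
    genes and all pairs of annotated TSSs; whichever is smaller wins. Genes
    on different chromosomes are infinitely far apart.
    """
    if gene_a.chrom != gene_b.chrom:
        return math.inf
    cage: Dict[str, List[int]] = {gene_a.gene_id: [], gene_b.gene_id: []}
    for a in assignments:
        if a.source == "cage" and a.gene_id in cage:
            cage[a.gene_id].append(a.tss)
    dist = math.inf
    ca, cb = cage[gene_a.gene_id], cage[gene_b.gene_id]
    if ca and cb:
        dist = min(abs(x - y) for x in ca for y in cb)
    aa, ab = gene_a.annotated_tss(), gene_b.annotated_tss()
    if aa and ab:
        dist = min(dist, min(abs(x - y) for x in aa for y in ab))
    return dist


def design_window(tss0: int, chrom_length: int, size: int = WINDOW_SIZE) -> Tuple[int, int]:
    """Half-open window of ``size`` bp centered on a 0-based TSS position.

    Clipped at chromosome ends without shifting: a TSS near the start loses
    its upstream half rather than borrowing downstream sequence.
    """
    half = size // 2
    start = max(0, tss0 - half)
    end = min(chrom_length, tss0 + half)
    return start, end


TSS_TABLE_COLUMNS = [
    "gene_id",
    "transcript_id",
    "source",
    "tss",
    "chrom",
    "strand",
    "tie_score",
    "cluster_id",
]


def write_tss_table(assignments: Sequence[TssAssignment], dest: Union[str, TextIO]) -> None:
    def emit(fh):
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TSS_TABLE_COLUMNS)
        for a in assignments:
            w.writerow(
                [a.gene_id, a.transcript_id, a.source, a.tss, a.chrom, a.strand,
                 f"{a.tie_score:g}", a.cluster_id or ""]
            )

    if isinstance(dest, str):
        with open(dest, "w") as fh:
            emit(fh)
    else:
        emit(dest)


def read_tss_table(source: Union[str, TextIO]) -> List[TssAssignment]:
    handle = open(source) if isinstance(source, str) else source
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        out = []
        for row in reader:
            out.append(
                TssAssignment(
                    gene_id=row["gene_id"],
                    transcript_id=row["transcript_id"],
                    source=row["source"],
                    tss=int(row["tss"]),
                    chrom=row["chrom"],
                    strand=row["strand"],
                    tie_score=float(row["tie_score"]),
                    cluster_id=row["cluster_id"] or None,
                )
            )
        return out
    finally:
        if isinstance(source, str):
            handle.close()
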