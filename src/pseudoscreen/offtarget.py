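"""PAM-constrained mismatch off-target search and the partner-gene
confound audit.

``find_sites`` enumerates every genomic 20-mer abutting an NGG PAM (both
strands) within a Hamming-distance budget of a spacer — no bulges, matching
the SpCas9 search configuration used for the screen audit (mismatch budget
1 by default). A genomic N never matches a spacer base.

The confound audit asks, for a screen hit with a parent/pseudogene partner,
whether its significance rests entirely on one sgRNA whose predicted
off-target site falls in the partner's promoter window ([-2 kb, +1 kb]
around the partner TSS, oriented by the partner's strand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, TextIO, Tuple, Union

import numpy as np

from .genome import revcomp

SPACER_LEN = 20
PAM_LEN = 3
DEFAULT_MAX_MISMATCHES = 1
PARTNER_UPSTREAM = 2000
PARTNER_DOWNSTREAM = 1000
SGRNA_P_THRESH = 0.05
SGRNA_LFC_THRESH = -math.log2(1.5)


@dataclass(frozen=True)
class OffTargetSite:
    spacer_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open protospacer interval
    end: int
    mismatch_count: int
    pam: str
    is_intended_site: bool = False


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_sites(
    spacer_id: str,
    spacer: str,
    genome: Mapping[str, str],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    intended_locus: Optional[Tuple[str, str, int]] = None,
) -> List[OffTargetSite]:
    """All NGG-adjacent genomic sites within ``max_mismatches`` of ``spacer``.

    ``intended_locus`` is the guide's design locus as (chrom, strand, start);
    a zero-mismatch site there is marked ``is_intended_site`` so callers can
    exclude it from off-target counts.
    """
    if len(spacer) != SPACER_LEN:
        raise ValueError("spacer must be 20 nt")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    fwd = _encode(spacer)
    rev = _encode(revcomp(spacer))
    G, C = ord("G"), ord("C")
    sites = []
    for chrom, seq in genome.items():
        arr = _encode(seq)
        n = arr.size
        if n < SPACER_LEN + PAM_LEN:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, SPACER_LEN)
        # plus strand: spacer at p, PAM "NGG" at p+20..p+22
        pmax = n - SPACER_LEN - PAM_LEN
        pam_ok = (arr[SPACER_LEN + 1 : pmax + SPACER_LEN + 2] == G) & (
            arr[SPACER_LEN + 2 : pmax + SPACER_LEN + 3] == G
        )
        mism = (windows[: pmax + 1] != fwd).sum(axis=1)
        for p in np.flatnonzero(pam_ok & (mism <= max_mismatches)):
            p = int(p)
            intended = (
                intended_locus is not None
                and intended_locus == (chrom, "+", p)
                and mism[p] == 0
            )
            sites.append(
                OffTargetSite(
                    spacer_id=spacer_id,
                    chrom=chrom,
                    strand="+",
                    start=p,
                    end=p + SPACER_LEN,
                    mismatch_count=int(mism[p]),
                    pam=seq[p + SPACER_LEN : p + SPACER_LEN + PAM_LEN],
                    is_intended_site=bool(intended),
                )
            )
        # minus strand: plus-strand pattern "CCN" at q-3..q-1, protospacer'
        # (revcomp of spacer) at q..q+19
        qmin = PAM_LEN
        qmax = n - SPACER_LEN
        pam_ok_m = (arr[qmin - 3 : qmax - 2] == C) & (arr[qmin - 2 : qmax - 1] == C)
        mism_m = (windows[qmin : qmax + 1] != rev).sum(axis=1)
        for k in np.flatnonzero(pam_ok_m & (mism_m <= max_mismatches)):
            q = int(k) + qmin
            intended = (
                intended_locus is not None
                and intended_locus == (chrom, "-", q)
                and mism_m[k] == 0
            )
            sites.append(
                OffTargetSite(
                    spacer_id=spacer_id,
                    chrom=chrom,
                    strand="-",
                    start=q,
                    end=q + SPACER_LEN,
                    mismatch_count=int(mism_m[k]),
                    pam=revcomp(seq[q - PAM_LEN : q]),
                    is_intended_site=bool(intended),
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def partner_window(
    partner_tss: int, partner_strand: str,
    upstream: int = PARTNER_UPSTREAM, downstream: int = PARTNER_DOWNSTREAM,
) -> Tuple[int, int]:
    """Strand-oriented [-upstream, +downstream] promoter window, 0-based
    half-open, around a 1-based TSS. Boundaries inclusive; mirrored on '-'. """
    tss0 = partner_tss - 1
    if partner_strand == "+":
        return tss0 - upstream, tss0 + downstream + 1
    return tss0 - downstream, tss0 + upstream + 1


def partner_window_hits(
    sites: Iterable[OffTargetSite],
    partner_tss: int,
    partner_strand: str,
    partner_chrom: str,
    upstream: int = PARTNER_UPSTREAM,
    downstream: int = PARTNER_DOWNSTREAM,
) -> List[OffTargetSite]:
    """Sites whose interval overlaps the partner promoter window."""
    lo, hi = partner_window(partner_tss, partner_strand, upstream, downstream)
    return [
        s for s in sites
        if s.chrom == partner_chrom and s.start < hi and s.end > lo
    ]


@dataclass
class ConfoundReport:
    gene_id: str
    partner_gene_id: str
    n_significant_sgrnas: int
    offending_sgrnas: List[str]
    confounded: bool
    n_significant_after_removal: int


def audit_confounded_hit(
    hit_gene: str,
    partner_gene: str,
    sgrna_stats: Sequence[Tuple[str, float, float]],
    partner_site_sgrnas: Set[str],
    p_thresh: float = SGRNA_P_THRESH,
    lfc_thresh: float = SGRNA_LFC_THRESH,
) -> ConfoundReport:
    """Audit one hit for the single-significant-sgRNA off-target confound.

    ``sgrna_stats`` lists (sgrna_id, lfc, p) for every guide of the hit;
    ``partner_site_sgrnas`` is the set of guide ids with at least one
    predicted site inside the partner promoter window. A guide is
    significant-negative when p < ``p_thresh`` and lfc <= ``lfc_thresh``.
    The hit is confounded iff it has exactly one significant guide and that
    guide is offending.
    """
    if not sgrna_stats:
        raise ValueError(f"hit gene {hit_gene} has no sgRNAs")
    significant = [
        sid for sid, lfc, p in sgrna_stats if p < p_thresh and lfc <= lfc_thresh
    ]
    offending = sorted(set(significant) & partner_site_sgrnas)
    remaining = [s for s in significant if s not in partner_site_sgrnas]
    confounded = len(significant) == 1 and significant[0] in partner_site_sgrnas
    return ConfoundReport(
        gene_id=hit_gene,
        partner_gene_id=partner_gene,
        n_significant_sgrnas=len(significant),
        offending_sgrnas=offending,
        confounded=confounded,
        n_significant_after_removal=len(remaining),
    )


def write_sites_bed(sites: Sequence[OffTargetSite], dest: Union[str, TextIO]) -> None:
    """BED6 + mismatch count + intended flag."""

    def emit(fh):
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.spacer_id}\t0\t{s.strand}\t"
                f"{s.mismatch_count}\t{int(s.is_intended_site)}\n"
            )

    if isinstance(dest, str):
        with open(dest, "w") as fh:
            emit(fh)
    else:
        emit(dest)


def read_sites_bed(source: Union[str, TextIO]) -> List[OffTargetSite]:
    handle = open(source) if isinstance(source, str) else source
    try:
        sites = []
        for line in handle:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand, mm, intended = (
                line.rstrip("\n").split("\t")
            )
            sites.append(
                OffTargetSite(
                    spacer_id=name, chrom=chrom, strand=strand,
                    start=int(start), end=int(end), mismatch_count=int(mm),
                    pam="NGG", is_intended_site=bool(int(intended)),
                )
            )
        return sites
    finally:
        if isinstance(source, str):
            handle.close()
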