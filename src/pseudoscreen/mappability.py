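"""Unique-mappability masks, effective gene lengths, and the
mappability-aware FPKM used for pseudogene expression.

Pseudogenes share long stretches of sequence with their parent genes, so
naive FPKM over the annotated length under-counts them when only uniquely
mapped reads are kept. The remedy implemented here: a position contributes
to a gene's *effective length* only if the read-length k-mer starting there
occurs exactly once genome-wide (both strands), and

    FPKM = count * 1e9 / (effective_length * total_reads).

Genes whose effective length is zero get NaN rather than a division error.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, Iterable, Mapping, Sequence, Set, TextIO, Tuple, Union

import numpy as np
import pandas as pd

from .genome import revcomp

DEFAULT_READ_LENGTH = 75  # screen/NGS read length
DEFAULT_MIN_FPKM = 0.5
DEFAULT_MIN_GUIDES = 3


def mappability_mask(
    genome: Mapping[str, str], read_length: int = DEFAULT_READ_LENGTH
) -> Dict[str, np.ndarray]:
    """Per-chromosome boolean vectors of uniquely mappable read starts.

    Position p is True iff the ``read_length``-mer starting at p occurs
    exactly once genome-wide counting both strands: an identical k-mer or a
    reverse-complement copy anywhere (including a self-reverse-complement
    palindrome) makes the position non-unique. k-mers containing N are never
    mappable, and no full-length read starts within ``read_length - 1`` of a
    chromosome 3' end.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    census: Counter = Counter()
    for seq in genome.values():
        for i in range(len(seq) - read_length + 1):
            census[seq[i : i + read_length]] += 1

    masks = {}
    for chrom, seq in genome.items():
        mask = np.zeros(len(seq), dtype=bool)
        for i in range(len(seq) - read_length + 1):
            kmer = seq[i : i + read_length]
            if "N" in kmer:
                continue
            occ = census[kmer] + census.get(revcomp(kmer), 0)
            if occ == 1:
                mask[i] = True
        masks[chrom] = mask
    return masks


def effective_length(
    span: Tuple[str, int, int], mask: Mapping[str, np.ndarray]
) -> int:
    """Count uniquely mappable positions within a 0-based half-open span."""
    chrom, start, end = span
    if chrom not in mask:
        return 0
    return int(mask[chrom][start:end].sum())


def fpkm(count: float, effective_length_bp: float, total_reads: float) -> float:
    """Mappability-aware FPKM: count * 1e9 / (effective length * total)."""
    if count < 0 or effective_length_bp < 0 or total_reads <= 0:
        raise ValueError("counts and lengths must be non-negative, total positive")
    if effective_length_bp == 0:
        return math.nan
    return count * 1e9 / (effective_length_bp * total_reads)


def fpkm_table(
    counts: pd.DataFrame,
    effective_lengths: Mapping[str, int],
    totals: Mapping[str, float] = None,
) -> pd.DataFrame:
    """Gene x sample FPKM from a count table and effective lengths.

    ``totals`` defaults to the column sums of ``counts``.
    """
    if totals is None:
        totals = counts.sum(axis=0).to_dict()
    lens = pd.Series(
        {g: effective_lengths.get(g, 0) for g in counts.index}, dtype=float
    )
    out = {}
    for sample in counts.columns:
        col = counts[sample].astype(float) * 1e9 / (lens * float(totals[sample]))
        col[lens == 0] = math.nan
        out[sample] = col
    return pd.DataFrame(out, index=counts.index)


def expression_filter(
    fpkm_by_sample: pd.DataFrame,
    guides_per_gene: Mapping[str, int],
    min_fpkm: float = DEFAULT_MIN_FPKM,
    min_guides: int = DEFAULT_MIN_GUIDES,
) -> Set[str]:
    """Library inclusion rule: FPKM >= ``min_fpkm`` in at least one sample
    AND at least ``min_guides`` designed guides.

    Genes absent from the FPKM table count as unexpressed everywhere.
    """
    retained = set()
    for gene, n_guides in guides_per_gene.items():
        if n_guides < min_guides:
            continue
        if gene in fpkm_by_sample.index:
            values = fpkm_by_sample.loc[gene].to_numpy(dtype=float)
            if np.any(np.nan_to_num(values, nan=0.0) >= min_fpkm):
                retained.add(gene)
    return retained


def write_bedgraph(mask: Mapping[str, np.ndarray], dest: Union[str, TextIO]) -> None:
    """Export a mappability mask as BedGraph runs of 0/1."""

    def emit(fh):
        for chrom in sorted(mask):
            m = mask[chrom].astype(np.int8)
            if m.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(m)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [m.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{int(m[s])}\n")

    if isinstance(dest, str):
        with open(dest, "w") as fh:
            emit(fh)
    else:
        emit(dest)


def read_bedgraph(source: Union[str, TextIO]) -> Dict[str, np.ndarray]:
    handle = open(source) if isinstance(source, str) else source
    try:
        runs: Dict[str, list] = {}
        for line in handle:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split()
            runs.setdefault(chrom, []).append((int(s), int(e), int(float(v))))
        masks = {}
        for chrom, rr in runs.items():
            size = max(e for _, e, _ in rr)
            m = np.zeros(size, dtype=bool)
            for s, e, v in rr:
                if v:
                    m[s:e] = True
            masks[chrom] = m
        return masks
    finally:
        if isinstance(source, str):
            handle.close()
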