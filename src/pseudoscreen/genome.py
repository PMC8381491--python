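"""Genome sequence containers and FASTA I/O.

Sequences are held in memory as plain uppercase strings over {A,C,G,T,N},
keyed by chromosome name. Desk-scale genomes (up to a few megabases) are the
intended regime; nothing here streams.
"""

from __future__ import annotations

import io
from typing import Dict, Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_sequence(chrom: str, seq: str) -> str:
    """Uppercase ``seq`` and check it is non-empty and within the alphabet."""
    seq = seq.upper()
    if not seq:
        raise ValueError(f"empty sequence for chromosome {chrom!r}")
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(
            f"chromosome {chrom!r} contains disallowed characters {sorted(bad)}"
        )
    return seq


def read_fasta(source: Union[str, TextIO]) -> Dict[str, str]:
    """Read a FASTA file into a ``{chrom: sequence}`` dict (uppercased)."""
    handle = open(source) if isinstance(source, str) else source
    try:
        genome = {}
        for rec in SeqIO.parse(handle, "fasta"):
            genome[rec.id] = validate_sequence(rec.id, str(rec.seq))
    finally:
        if isinstance(source, str):
            handle.close()
    if not genome:
        raise ValueError("no FASTA records found")
    return genome


def write_fasta(genome: Dict[str, str], dest: Union[str, TextIO]) -> None:
    records: Iterable[SeqRecord] = (
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    )
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, dest, "fasta")


def fasta_string(genome: Dict[str, str]) -> str:
    buf = io.StringIO()
    write_fasta(genome, buf)
    return buf.getvalue()
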