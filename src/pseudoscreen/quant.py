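"""Screen read quantification: trim, match, count.

Emulates the original alignment contract for 75-nt single-end screen reads:
20 nt trimmed from the 5' end and 30 nt from the 3' end leave a 25-nt
fragment spanning the spacer; a fragment is assigned to a guide iff exactly
one library spacer occurs as a forward-orientation substring (the unique-
mapping and no-reverse-complement contracts). Fragments matching no spacer
are unassigned, fragments matching two or more are ambiguous and dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, TextIO, Tuple, Union

import pandas as pd
import pysam

SPACER_LEN = 20


@dataclass(frozen=True)
class TrimSpec:
    trim_5prime: int = 20
    trim_3prime: int = 30

    def __post_init__(self):
        if self.trim_5prime < 0 or self.trim_3prime < 0:
            raise ValueError("trims must be non-negative")


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # guide x sample, int
    qc: pd.DataFrame  # sample x {assigned, unassigned, ambiguous}

    def total_reads(self, sample: str) -> int:
        return int(self.qc.loc[sample].sum())


def trim_read(read: str, spec: TrimSpec) -> Optional[str]:
    """Remove the 5'/3' trims; return None (discard) when nothing remains."""
    if len(read) - spec.trim_5prime - spec.trim_3prime < 1:
        return None
    end = len(read) - spec.trim_3prime
    return read[spec.trim_5prime : end]


def _build_lookup(spacers: Mapping[str, str]) -> Dict[str, str]:
    if not spacers:
        raise ValueError("empty manifest: no spacers to match against")
    lookup: Dict[str, str] = {}
    for guide_id, spacer in spacers.items():
        if spacer in lookup:
            raise ValueError(f"manifest spacers not unique: {spacer}")
        lookup[spacer] = guide_id
    return lookup


def assign_fragment(
    fragment: str,
    lookup: Mapping[str, str],
    max_mismatches: int = 0,
) -> Tuple[str, Optional[str]]:
    """Classify one trimmed fragment.

    Returns ("assigned", guide_id), ("ambiguous", None) or
    ("unassigned", None). Matching is forward-orientation substring, exact
    by default; ``max_mismatches=1`` additionally accepts spacers one
    substitution away (via neighbor enumeration, so the cost is independent
    of library size).
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    matched = set()
    for i in range(len(fragment) - SPACER_LEN + 1):
        sub = fragment[i : i + SPACER_LEN]
        guide = lookup.get(sub)
        if guide is not None:
            matched.add(guide)
        if max_mismatches == 1:
            for pos in range(SPACER_LEN):
                orig = sub[pos]
                for base in "ACGT":
                    if base != orig:
                        guide = lookup.get(sub[:pos] + base + sub[pos + 1 :])
                        if guide is not None:
                            matched.add(guide)
        if len(matched) > 1:
            return "ambiguous", None
    if not matched:
        return "unassigned", None
    return "assigned", matched.pop()


def quantify_reads(
    reads_by_sample: Mapping[str, Iterable[str]],
    spacers: Mapping[str, str],
    spec: TrimSpec = TrimSpec(),
    max_mismatches: int = 0,
) -> CountMatrix:
    """Count spacer-matching reads per guide per sample.

    ``spacers`` maps guide_id -> 20-nt spacer (must be unique);
    ``reads_by_sample`` maps sample name -> iterable of read sequences.
    Per sample, assigned + unassigned + ambiguous equals reads in.
    """
    lookup = _build_lookup(spacers)
    guide_ids = sorted(spacers)
    samples = list(reads_by_sample)
    counts = {s: dict.fromkeys(guide_ids, 0) for s in samples}
    qc_rows = {}
    for sample, reads in reads_by_sample.items():
        assigned = unassigned = ambiguous = 0
        ctab = counts[sample]
        for read in reads:
            fragment = trim_read(read.upper(), spec)
            if fragment is None:
                unassigned += 1
                continue
            status, guide = assign_fragment(fragment, lookup, max_mismatches)
            if status == "assigned":
                ctab[guide] += 1
                assigned += 1
            elif status == "ambiguous":
                ambiguous += 1
            else:
                unassigned += 1
        qc_rows[sample] = {
            "assigned": assigned, "unassigned": unassigned, "ambiguous": ambiguous,
        }
    counts_df = pd.DataFrame(counts, dtype=int).reindex(index=guide_ids, columns=samples)
    qc_df = pd.DataFrame.from_dict(qc_rows, orient="index").reindex(samples)
    return CountMatrix(counts=counts_df, qc=qc_df)


def read_fastq(path: str) -> List[str]:
    """Read sequences from a FASTQ file (plain or gzip) via pysam."""
    with pysam.FastxFile(path) as fh:
        return [entry.sequence for entry in fh]


def quantify_fastq_files(
    fastq_by_sample: Mapping[str, str],
    spacers: Mapping[str, str],
    spec: TrimSpec = TrimSpec(),
    max_mismatches: int = 0,
) -> CountMatrix:
    return quantify_reads(
        {sample: read_fastq(path) for sample, path in fastq_by_sample.items()},
        spacers,
        spec,
        max_mismatches,
    )


def write_counts(counts: pd.DataFrame, dest: Union[str, TextIO]) -> None:
    counts.to_csv(dest, sep="\t", index_label="sgrna")


def read_counts(source: Union[str, TextIO]) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", index_col="sgrna")
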