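# pseudoscreen

CAGE-informed CRISPRi sgRNA library design and pooled-screen analysis for
pseudogenes.

Pseudogenes share most of their sequence with their parent genes, which makes
both loss-of-function screening and expression quantification treacherous:
RNAi and CRISPR knockout reagents cross-react with the parent transcript or
locus, and multi-mapping reads inflate or erase expression estimates. CRISPRi
sidesteps much of this because promoters diverge faster than gene bodies —
guides placed in a ±250 bp window around the transcription start site can
silence a pseudogene without touching its parent. This package implements the
complete computational workflow for such a screen, for genomicists building
promoter-targeted CRISPRi libraries and analyzing pooled fitness screens:

- **TSS assignment** — CAGE tag clusters (with their transcription initiation
  evidence score, TIEScore) are assigned to annotated transcripts by
  strand-matched summit proximity; genes without CAGE support fall back to
  annotated 5' ends.
- **Guide design** — every 20-nt protospacer abutting an NGG PAM inside the
  500-bp window centered on each TSS is scored and passed through the filter
  cascade: multi-mapping spacers, spacers with Ns or ≥4 consecutive Ts, and
  spacers with GC ≥ 75% or < 10% are removed; guides within 4 bp of each
  other keep only the best scorer; up to 10 guides per gene are selected,
  preferring higher-TIEScore clusters. Oligos are built as
  5'-linker + spacer + 3'-linker.
- **Mappability-aware expression** — a pseudogene-safe FPKM,
  `count × 10⁹ / (effective length × total reads)`, where the effective
  length counts only positions whose read-length k-mer is unique genome-wide
  (both strands). Genes with FPKM < 0.5 in all samples, or with fewer than
  3 designed guides, are excluded from the library.
- **Off-target audit** — exhaustive Hamming search for NGG-adjacent sites
  within a mismatch budget (no bulges), and a confound audit that flags hits
  whose single significant guide carries a predicted site within
  [−2 kb, +1 kb] of the partner gene's TSS.
- **Screen quantification** — 75-nt reads are trimmed (20 nt 5', 30 nt 3')
  and assigned to guides by unique forward-orientation spacer matching.
- **Hit calling** — counts are normalized to negative-control guides
  (median-of-ratios); per-guide log₂ fold-changes (D21 vs D0, mean over
  replicates, pseudocount 1) are tested against the control null; gene-level
  significance uses α-RRA — the minimum Beta order-statistic probability
  `min_j F_Beta(u_(j); j, k−j+1)` over normalized guide ranks `u_(j) ≤ α` —
  with permutation p-values, BH-FDR, and hits at
  `p < 0.05, FDR < 0.25, log₂FC ≤ −log₂ 1.5` (second-best guide fold-change).
  Hits whose TSS lies within 1 kb of another gene's TSS are excluded as
  bidirectional-promoter artifacts.
- **Synthetic fixtures** — toy genomes of parent/pseudogene pairs with
  tunable body homology and divergent promoters, CAGE tracks, and
  negative-binomial screen simulators with spiked effects and planted
  bidirectional/off-target confounds, so every stage is testable offline.

## Worked example

A 26-gene fixture (12 parent/pseudogene pairs, four spiked essential genes at
log₂FC −2, one planted bidirectional pair, one planted off-target confound)
run through the full workflow — design, screen simulation, FASTQ counting,
statistics, and both confound controls:

```python
from pseudoscreen.pipeline import run_end_to_end
from pseudoscreen.synthetic import FixtureConfig

cfg = FixtureConfig(seed=5, n_pairs=12, n_essential=4, dispersion=0.25)
res = run_end_to_end(5, cfg, n_permutations=2000)
print("genes tested:", len(res.gene_df))
print("negative-selection hits:", res.hits)
print("excluded as bidirectional-promoter artifacts:", res.excluded_bidirectional)
print("hits confounded by partner-promoter off-targets:", res.confounded_genes)
report = next(r for r in res.confound_reports if r.confounded)
print(f"{report.gene_id}: {report.n_significant_sgrnas} significant sgRNA, "
      f"offending {report.offending_sgrnas}, "
      f"{report.n_significant_after_removal} remain after removal")
```

prints

```
genes tested: 26
negative-selection hits: ['PAR_000', 'PAR_001', 'PAR_002', 'PSG_000', 'PSG_001']
excluded as bidirectional-promoter artifacts: ['BIDIR_A']
hits confounded by partner-promoter off-targets: ['PSG_000']
PSG_000: 1 significant sgRNA, offending ['sg_chr1_8263_-'], 0 remain after removal
```

All four spiked genes come out as hits. `BIDIR_A` is spiked too, but its TSS
sits 800 bp from a neighbor, so the bidirectional filter removes it. `PSG_000`
is a hit resting on exactly one significant guide, and that guide has a
one-mismatch NGG site in its parent's promoter window — the audit flags it as
a potential off-target confound rather than a clean pseudogene hit.

A command-line interface mirrors the modules
(`pseudoscreen annotate | design | mappability | expression-filter |
offtarget | count | stats | simulate`); run `pseudoscreen --help`.

## Layout

| Module | Contents |
| --- | --- |
| `pseudoscreen.annotation` | GTF/CAGE-BED parsing, TSS assignment, TSS distances, design windows |
| `pseudoscreen.design` | protospacer scan, scoring, filter cascade, dedup, selection, manifest |
| `pseudoscreen.mappability` | unique-mappability mask, effective length, FPKM, inclusion filter |
| `pseudoscreen.offtarget` | mismatch site search, partner-window confound audit |
| `pseudoscreen.quant` | read trimming and unique spacer counting |
| `pseudoscreen.stats` | control normalization, α-RRA permutation test, FDR, hit calling, bidirectional filter |
| `pseudoscreen.synthetic` | toy genomes, screen simulators, ground-truth registries |
| `pseudoscreen.pipeline` | end-to-end orchestration and calibration runs |

See `docs/methods.md` for the statistical model, parameter choices and known
limitations.
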