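"""Pooled-screen statistics: control normalization, sgRNA fold-changes and
control-null significance, alpha-RRA gene tests with permutation p-values,
BH-FDR, hit calling, and the bidirectional-promoter exclusion.

Guide counts are normalized by median-of-ratios size factors computed over
the negative-control guides only. Per-guide log2 fold-changes (final vs
initial population, mean over replicate pairs, pseudocount 1) are tested for
depletion against the empirical distribution of control-guide fold-changes.
Gene-level significance uses alpha-RRA: the guides of a gene are located in
the genome-wide depletion ranking, their normalized ranks u_(1) <= ... <=
u_(k) are converted to Beta order-statistic probabilities, and the gene
score rho is the minimum Beta CDF over the ranks falling in the top
``alpha`` fraction (rho = 1 when none do). Significance of rho comes from
permuting guide memberships; genes are then corrected with Benjamini-
Hochberg and called as hits at p < 0.05, FDR < 0.25 and a second-best
fold-change at or beyond log2(1.5) in the selection direction. Hits whose
TSS lies within 1 kb of any other gene's TSS are excluded as potential
bidirectional-promoter artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel, TssAssignment, tss_distance

LFC_THRESH = math.log2(1.5)  # ~0.585
DEFAULT_P_MAX = 0.05
DEFAULT_FDR_MAX = 0.25
DEFAULT_ALPHA = 0.05
DEFAULT_N_PERMUTATIONS = 10000
DEFAULT_PSEUDOCOUNT = 1.0
BIDIRECTIONAL_MAX_DISTANCE = 1000


@dataclass
class NormalizedCounts:
    counts: pd.DataFrame  # guide x sample, float (normalized)
    size_factors: pd.Series  # per sample
    control_ids: List[str]


def normalize_control(counts: pd.DataFrame, control_ids: Iterable[str]) -> NormalizedCounts:
    """Median-of-ratios normalization over control guides.

    Size factor for sample j = median over controls i of
    count(i, j) / geomean_samples(count(i, .)), where zero counts are
    excluded from each control's geometric mean. Controls that are zero in
    every sample are dropped from the reference set. A sample whose controls
    are all zero (size factor not strictly positive) raises ``ValueError``.
    """
    control_ids = [c for c in control_ids if c in counts.index]
    if len(control_ids) < 2:
        raise ValueError("need at least two control sgRNAs present in the matrix")
    ctrl = counts.loc[control_ids].astype(float)
    with np.errstate(divide="ignore"):
        logs = np.log(ctrl.to_numpy())
    logs[~np.isfinite(logs)] = np.nan
    geomean = np.exp(np.nanmean(logs, axis=1))  # per control, zeros excluded
    valid = np.isfinite(geomean) & (geomean > 0)
    if not valid.any():
        raise ValueError("all control sgRNAs are zero everywhere")
    ratios = ctrl.to_numpy()[valid] / geomean[valid, None]
    size_factors = pd.Series(np.median(ratios, axis=0), index=counts.columns)
    if (size_factors <= 0).any():
        bad = size_factors.index[size_factors <= 0].tolist()
        raise ValueError(f"non-positive control size factor in samples {bad}")
    return NormalizedCounts(
        counts=counts.astype(float) / size_factors,
        size_factors=size_factors,
        control_ids=control_ids,
    )


def sgrna_stats(
    norm: NormalizedCounts,
    d0_samples: Sequence[str],
    d21_samples: Sequence[str],
    gene_map: Mapping[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-guide log2 fold-change and control-null depletion p-value.

    Replicates pair by position in ``d0_samples``/``d21_samples``. The
    p-value is the add-one empirical percentile of the guide's lfc within
    the control guides' lfc distribution (one-sided, depletion).
    """
    if len(d0_samples) != len(d21_samples):
        raise ValueError("mismatched replicate counts between D0 and D21")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    m = norm.counts
    lfc_reps = [
        np.log2((m[d21] + pseudocount) / (m[d0] + pseudocount))
        for d0, d21 in zip(d0_samples, d21_samples)
    ]
    lfc = pd.concat(lfc_reps, axis=1).mean(axis=1)
    ctrl_lfc = np.sort(lfc.loc[norm.control_ids].to_numpy())
    n_ctrl = ctrl_lfc.size
    # p = (1 + #controls with lfc <= x) / (n_controls + 1)
    p = (1.0 + np.searchsorted(ctrl_lfc, lfc.to_numpy(), side="right")) / (n_ctrl + 1)
    return pd.DataFrame(
        {
            "sgrna": lfc.index,
            "gene": [gene_map.get(g, "") for g in lfc.index],
            "lfc": lfc.to_numpy(),
            "p": p,
        }
    ).set_index("sgrna")


def gene_secondbest_lfc(lfcs: Sequence[float], direction: str = "negative") -> float:
    """Second most extreme guide fold-change in the selection direction.

    A single-guide gene returns its own lfc.
    """
    if len(lfcs) == 0:
        raise ValueError("no sgRNA fold-changes supplied")
    ordered = sorted(lfcs, reverse=(direction == "positive"))
    return ordered[0] if len(ordered) == 1 else ordered[1]


def rho_score(ranks: Sequence[int], n_total: int, alpha: float) -> float:
    """Alpha-RRA gene score for one gene's guide ranks (1-based, tie-free).

    u_(j) = rank_(j) / n_total; only u_(j) <= alpha contribute;
    rho = min_j BetaCDF(u_(j); j, k - j + 1), or 1 when none contribute.
    """
    k = len(ranks)
    if k == 0:
        raise ValueError("gene has no ranked sgRNAs")
    u = np.sort(np.asarray(ranks, dtype=float)) / n_total
    j = np.arange(1, k + 1)
    contributing = u <= alpha
    if not contributing.any():
        return 1.0
    cdf = beta_dist.cdf(u[contributing], j[contributing], k - j[contributing] + 1)
    return float(cdf.min())


def null_rho_distribution(
    n_total: int,
    k: int,
    alpha: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sorted null rho scores for genes of ``k`` guides among ``n_total``.

    Each permutation draws k ranks without replacement from 1..n_total and
    scores them exactly as :func:`rho_score` does (vectorized).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    # k draws without replacement per row, via partial argsort of uniforms
    rhos = np.empty(n_permutations)
    chunk = max(1, min(n_permutations, int(5e6 // max(n_total, 1)) or 1))
    j = np.arange(1, k + 1, dtype=float)
    pos = 0
    while pos < n_permutations:
        m = min(chunk, n_permutations - pos)
        u = rng.random((m, n_total)).argpartition(k - 1, axis=1)[:, :k]
        u = np.sort(u + 1, axis=1) / n_total
        cdf = beta_dist.cdf(u, j, k - j + 1)
        cdf[u > alpha] = np.inf
        rho = cdf.min(axis=1)
        rho[~np.isfinite(rho)] = 1.0
        rhos[pos : pos + m] = rho
        pos += m
    return np.sort(rhos)


def rra_gene_test(
    ranks: Sequence[int],
    n_total: int,
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: Optional[int] = None,
    null: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """(rho, permutation p) for one gene.

    ``null`` may carry a precomputed sorted null rho distribution for this
    (n_total, k, alpha); otherwise one is sampled with ``seed``.
    """
    rho = rho_score(ranks, n_total, alpha)
    if null is None:
        rng = np.random.default_rng(seed)
        null = null_rho_distribution(n_total, len(ranks), alpha, n_permutations, rng)
    n_perm = null.size
    n_le = int(np.searchsorted(null, rho, side="right"))
    p = (1.0 + n_le) / (n_perm + 1.0)
    return rho, p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def rank_sgrnas(sgrna_df: pd.DataFrame, direction: str = "negative") -> pd.Series:
    """Tie-free 1..n depletion (or enrichment) ranks over all guides.

    Rank 1 is the most depleted guide for negative selection; ties in lfc
    break by sgRNA id so ranks form a permutation.
    """
    sign = 1.0 if direction == "negative" else -1.0
    order = sorted(sgrna_df.index, key=lambda s: (sign * sgrna_df.at[s, "lfc"], s))
    return pd.Series(np.arange(1, len(order) + 1), index=order, name="rank")


def gene_stats(
    sgrna_df: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: Optional[int] = None,
    direction: str = "negative",
) -> pd.DataFrame:
    """Gene-level alpha-RRA table from per-guide stats.

    Guides with an empty gene label (controls) take part in the ranking but
    are not tested as genes. Null rho distributions are shared across genes
    with the same guide count, so the permutation budget is spent once per
    distinct k. Fixed ``seed`` gives identical p-values.
    """
    ranks = rank_sgrnas(sgrna_df, direction)
    n_total = len(ranks)
    genes = sorted({g for g in sgrna_df["gene"] if g})
    rng = np.random.default_rng(seed)
    ks = sorted({int((sgrna_df["gene"] == g).sum()) for g in genes})
    nulls = {
        k: null_rho_distribution(n_total, k, alpha, n_permutations, rng) for k in ks
    }
    rows = []
    for gene in genes:
        guides = sgrna_df.index[sgrna_df["gene"] == gene]
        gene_ranks = ranks.loc[guides].tolist()
        rho, p = rra_gene_test(
            gene_ranks, n_total, alpha, n_permutations, null=nulls[len(gene_ranks)]
        )
        rows.append(
            {
                "gene": gene,
                "n_sgrnas": len(guides),
                "rho": rho,
                "p": p,
                "secondbest_lfc": gene_secondbest_lfc(
                    sgrna_df.loc[guides, "lfc"].tolist(), direction
                ),
            }
        )
    df = pd.DataFrame(rows).set_index("gene")
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def call_hits(
    gene_df: pd.DataFrame,
    p_max: float = DEFAULT_P_MAX,
    fdr_max: float = DEFAULT_FDR_MAX,
    lfc_thresh: float = LFC_THRESH,
    direction: str = "negative",
) -> pd.DataFrame:
    """Flag hits at p < p_max, FDR < fdr_max and second-best lfc at or
    beyond ``lfc_thresh`` in the selection direction."""
    df = gene_df.copy()
    if direction == "negative":
        lfc_ok = df["secondbest_lfc"] <= -lfc_thresh
    else:
        lfc_ok = df["secondbest_lfc"] >= lfc_thresh
    df["hit"] = (df["p"] < p_max) & (df["fdr"] < fdr_max) & lfc_ok
    return df


def bidirectional_filter(
    gene_df: pd.DataFrame,
    genes: Mapping[str, GeneModel],
    assignments: Sequence[TssAssignment],
    max_distance: int = BIDIRECTIONAL_MAX_DISTANCE,
) -> pd.DataFrame:
    """Exclude hits whose TSS lies within ``max_distance`` (inclusive) of
    any other annotated gene's TSS.

    Exclusions stay in the table with ``excluded_bidirectional = True`` and
    ``hit`` forced False; the TSS distance uses the minimum over CAGE-based
    and annotated TSS pairs.
    """
    df = gene_df.copy()
    df["excluded_bidirectional"] = False
    all_genes = list(genes.values())
    for gene_id in df.index[df["hit"]]:
        g = genes.get(gene_id)
        if g is None:
            continue
        for other in all_genes:
            if other.gene_id == gene_id:
                continue
            if tss_distance(g, other, assignments) <= max_distance:
                df.at[gene_id, "excluded_bidirectional"] = True
                df.at[gene_id, "hit"] = False
                break
    return df


def analyze_screen(
    counts: pd.DataFrame,
    control_ids: Sequence[str],
    d0_samples: Sequence[str],
    d21_samples: Sequence[str],
    gene_map: Mapping[str, str],
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: Optional[int] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    direction: str = "negative",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Full count-matrix -> (sgRNA table, gene table with hit flags)."""
    norm = normalize_control(counts, control_ids)
    sg = sgrna_stats(norm, d0_samples, d21_samples, gene_map, pseudocount)
    genes = gene_stats(sg, alpha, n_permutations, seed, direction)
    return sg, call_hits(genes, direction=direction)
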