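"""Control normalization, fold-changes, alpha-RRA, FDR, hit calling and the
bidirectional-promoter exclusion."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta as beta_dist

from pseudoscreen.annotation import read_annotation
from pseudoscreen.stats import (
    NormalizedCounts,
    bh_fdr,
    bidirectional_filter,
    call_hits,
    gene_secondbest_lfc,
    normalize_control,
    null_rho_distribution,
    rank_sgrnas,
    rho_score,
    rra_gene_test,
    sgrna_stats,
)

CTRL = ["c1", "c2", "c3"]


def counts_frame(rows, samples=("d0", "d21")):
    return pd.DataFrame(rows, columns=list(samples)).astype(float)


class TestNormalizeControl:
    def test_identical_columns_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]}, index=CTRL)
        norm = normalize_control(df, CTRL)
        assert np.allclose(norm.size_factors, 1.0)

    def test_doubled_sample_gets_double_factor(self):
        df = pd.DataFrame({"a": [10, 20, 30, 5], "b": [20, 40, 60, 7]},
                          index=CTRL + ["g"])
        norm = normalize_control(df, CTRL)
        assert norm.size_factors["b"] / norm.size_factors["a"] == pytest.approx(2.0)
        assert np.allclose(norm.counts.loc[CTRL, "a"], norm.counts.loc[CTRL, "b"])

    def test_median_control_ratio_is_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.poisson(100, size=(21, 4)).astype(float),
            index=[f"c{i}" for i in range(21)],
            columns=list("abcd"),
        )
        ctrl = list(df.index)
        norm = normalize_control(df, ctrl)
        geo = np.exp(np.log(df.where(df > 0)).mean(axis=1))
        for s in df.columns:
            assert np.median(norm.counts.loc[ctrl, s] / geo) == pytest.approx(1.0)

    def test_all_zero_controls_in_sample_error(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [0, 0, 0]}, index=CTRL)
        with pytest.raises(ValueError, match="size factor"):
            normalize_control(df, CTRL)

    def test_requires_two_controls(self):
        df = pd.DataFrame({"a": [10], "b": [10]}, index=["c1"])
        with pytest.raises(ValueError, match="two control"):
            normalize_control(df, ["c1"])


def norm_of(df, control_ids):
    return NormalizedCounts(
        counts=df.astype(float),
        size_factors=pd.Series(1.0, index=df.columns),
        control_ids=control_ids,
    )


class TestSgrnaStats:
    def test_lfc_arithmetic_single_replicate(self):
        df = pd.DataFrame({"d0": [100, 50, 60], "d21": [50, 50, 60]},
                          index=["g", "c1", "c2"])
        sg = sgrna_stats(norm_of(df, ["c1", "c2"]), ["d0"], ["d21"], {"g": "G"})
        assert sg.at["g", "lfc"] == pytest.approx(math.log2(51 / 101))
        assert sg.at["c1", "lfc"] == 0.0

    def test_depleted_beyond_all_controls_gets_minimum_p(self):
        n_ctrl = 349
        idx = [f"c{i}" for i in range(n_ctrl)] + ["g"]
        rng = np.random.default_rng(1)
        d0 = rng.poisson(100, n_ctrl + 1).astype(float)
        df = pd.DataFrame({"d0": d0, "d21": d0}, index=idx)
        df.loc["g", "d21"] = df.loc["g", "d0"] / 8  # far below any control
        sg = sgrna_stats(norm_of(df, idx[:-1]), ["d0"], ["d21"], {"g": "G"})
        assert sg.at["g", "p"] == pytest.approx(1 / 350)

    def test_replicate_mismatch_rejected(self):
        df = pd.DataFrame({"a": [1, 1], "b": [1, 1]}, index=["c1", "c2"])
        with pytest.raises(ValueError, match="replicate"):
            sgrna_stats(norm_of(df, ["c1", "c2"]), ["a"], [], {})


class TestSecondBest:
    @pytest.mark.parametrize("lfcs,expected", [
        ([-3, -2, -1], -2),
        ([-3], -3),
        ([-3, 0.5, 1], 0.5),
    ])
    def test_negative_direction(self, lfcs, expected):
        assert gene_secondbest_lfc(lfcs) == expected

    def test_positive_direction(self):
        assert gene_secondbest_lfc([3, 0.5, -1], "positive") == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_secondbest_lfc([])


class TestRra:
    def test_k1_rho_is_normalized_rank(self):
        assert rho_score([7], 100, alpha=0.1) == pytest.approx(0.07)
        assert rho_score([50], 100, alpha=0.1) == 1.0

    def test_rho_uses_best_order_statistic(self):
        u = np.array([1, 2, 3]) / 12
        expected = min(
            beta_dist.cdf(u[0], 1, 3),
            beta_dist.cdf(u[1], 2, 2),
            beta_dist.cdf(u[2], 3, 1),
        )
        assert rho_score([1, 2, 3], 12, alpha=0.5) == pytest.approx(expected)

    @pytest.mark.parametrize("ranks", [[1, 2, 3], [2, 5, 9], [4, 8, 12]])
    def test_permutation_p_matches_exhaustive_enumeration(self, ranks):
        n_total, alpha = 12, 0.4
        rho = rho_score(ranks, n_total, alpha)
        exact = np.mean([
            rho_score(list(subset), n_total, alpha) <= rho
            for subset in itertools.combinations(range(1, n_total + 1), 3)
        ])
        _, p = rra_gene_test(ranks, n_total, alpha, n_permutations=20000, seed=5)
        assert p == pytest.approx(exact, abs=0.02)

    def test_extreme_gene_gets_minimum_p(self):
        _, p = rra_gene_test([1, 2, 3, 4], 1000, alpha=0.05,
                             n_permutations=10000, seed=2)
        assert p == pytest.approx(1 / 10001)

    def test_deterministic_under_fixed_seed(self):
        a = rra_gene_test([3, 17, 40], 500, n_permutations=2000, seed=9)
        b = rra_gene_test([3, 17, 40], 500, n_permutations=2000, seed=9)
        assert a == b

    def test_rank_sgrnas_is_tie_free_permutation(self):
        sg = pd.DataFrame(
            {"gene": ["a", "a", "b", ""], "lfc": [-1.0, -1.0, 0.5, -1.0],
             "p": [0.1] * 4},
            index=["s3", "s1", "s2", "s0"],
        )
        ranks = rank_sgrnas(sg)
        assert sorted(ranks) == [1, 2, 3, 4]
        assert ranks["s0"] < ranks["s1"] < ranks["s3"]  # lfc ties break by id


class TestBhFdr:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_monotone_in_p_order(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.04])
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallHits:
    def frame(self, p, fdr, lfc):
        return pd.DataFrame(
            {"p": [p], "fdr": [fdr], "secondbest_lfc": [lfc]}, index=["g"]
        )

    def test_passing_gene_is_hit(self):
        assert call_hits(self.frame(0.01, 0.10, -1.0))["hit"].item()

    def test_lfc_above_threshold_not_hit(self):
        assert not call_hits(self.frame(0.01, 0.10, -0.5))["hit"].item()

    def test_p_above_threshold_not_hit(self):
        assert not call_hits(self.frame(0.06, 0.10, -1.0))["hit"].item()

    def test_boundary_lfc_inclusive(self):
        assert call_hits(self.frame(0.01, 0.10, -math.log2(1.5)))["hit"].item()

    def test_positive_direction_symmetric(self):
        df = self.frame(0.01, 0.10, 1.0)
        assert call_hits(df, direction="positive")["hit"].item()
        assert not call_hits(self.frame(0.01, 0.10, 0.5),
                             direction="positive")["hit"].item()


def genes_at(positions):
    rows = []
    for gid, tss in positions.items():
        attrs = f'gene_id "{gid}"; gene_type "protein_coding";'
        rows.append(f"chr1\ts\tgene\t{tss}\t{tss + 99}\t.\t+\t.\t{attrs}\n")
        rows.append(
            f"chr1\ts\ttranscript\t{tss}\t{tss + 99}\t.\t+\t.\t"
            f'gene_id "{gid}"; transcript_id "{gid}_t";\n'
        )
    return {g.gene_id: g for g in read_annotation(rows)}


class TestBidirectionalFilter:
    def run(self, positions, hit_gene="a"):
        genes = genes_at(positions)
        df = pd.DataFrame(
            {"p": 0.01, "fdr": 0.1, "secondbest_lfc": -1.0,
             "hit": [g == hit_gene for g in positions]},
            index=list(positions),
        )
        return bidirectional_filter(df, genes, [])

    def test_neighbor_within_1kb_excluded(self):
        out = self.run({"a": 1000, "b": 1800})
        assert out.at["a", "excluded_bidirectional"] and not out.at["a", "hit"]

    def test_distant_neighbor_retained(self):
        out = self.run({"a": 1000, "b": 2600})
        assert not out.at["a", "excluded_bidirectional"] and out.at["a", "hit"]

    def test_exactly_1kb_is_excluded(self):
        out = self.run({"a": 1000, "b": 2000})
        assert out.at["a", "excluded_bidirectional"]

    def test_non_hits_not_flagged(self):
        out = self.run({"a": 1000, "b": 1800}, hit_gene="b")
        assert not out.at["a", "excluded_bidirectional"]
        assert out.at["b", "excluded_bidirectional"]


def test_null_rho_distribution_matches_analytic_k1():
    rng = np.random.default_rng(3)
    null = null_rho_distribution(100, 1, alpha=1.0, n_permutations=5000, rng=rng)
    # k=1, alpha=1: rho = u uniform on {1/100..1}
    assert null.min() >= 1 / 100 and null.max() <= 1.0
    assert abs(null.mean() - 0.505) < 0.02
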