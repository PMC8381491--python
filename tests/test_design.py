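"""Protospacer scanning, scoring, the filter cascade, dedup, selection and
manifest assembly."""

import io
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from conftest import overlapping_count
from pseudoscreen.annotation import TssAssignment
from pseudoscreen.design import (
    LINKER_3,
    LINKER_5,
    ControlGuide,
    GenomeIndex,
    GuideCandidate,
    ScoreModel,
    assemble_library,
    dedup_nearby,
    filter_candidates,
    gc_fraction,
    read_manifest,
    scan_protospacers,
    score_candidates,
    select_per_gene,
    write_manifest,
)
from pseudoscreen.genome import revcomp

SPACER = "ATCGATCGATCGATCGATCG"  # GC 0.5, no GG/CC dinucleotide, no poly-T


def candidate(spacer=SPACER, start=100, score=0.0, gene="g1", strand="+",
              source="annotated", flags=frozenset()):
    return GuideCandidate(
        spacer=spacer, pam="AGG", chrom="chr1", strand=strand,
        start=start, end=start + 20, gene_id=gene, tss_source=source,
        score=score, filter_flags=flags,
    )


class TestScan:
    def test_plus_strand_ngg(self):
        genome = {"c": "AAAAA" + SPACER + "AGG" + "AAAAA"}
        cands = scan_protospacers(genome, "c", (0, len(genome["c"])), "g1")
        plus = [c for c in cands if c.strand == "+"]
        assert [(c.spacer, c.pam, c.start) for c in plus] == [(SPACER, "AGG", 5)]

    def test_minus_strand_revcomp(self):
        genome = {"c": "AAAAA" + "CCT" + revcomp(SPACER) + "AAAAA"}
        cands = scan_protospacers(genome, "c", (0, len(genome["c"])), "g1")
        minus = [c for c in cands if c.strand == "-"]
        assert [(c.spacer, c.pam, c.start) for c in minus] == [(SPACER, "AGG", 8)]

    def test_non_ngg_pam_skipped(self):
        genome = {"c": "AAAAA" + SPACER + "AAG" + "AAAAA"}
        cands = scan_protospacers(genome, "c", (0, len(genome["c"])), "g1")
        assert not any(c.spacer == SPACER for c in cands)

    def test_genome_consistency_on_fixture(self, toy):
        chrom = next(iter(toy.genome))
        seq = toy.genome[chrom]
        cands = scan_protospacers(toy.genome, chrom, (20000, 21000), "g")
        assert cands
        for c in cands:
            if c.strand == "+":
                assert seq[c.start : c.end] == c.spacer
                assert seq[c.end : c.end + 3] == c.pam
            else:
                assert revcomp(seq[c.start : c.end]) == c.spacer
                assert revcomp(seq[c.start - 3 : c.start]) == c.pam


class TestScoreModel:
    def test_zero_model(self):
        assert ScoreModel().score(SPACER) == 0.0

    def test_single_position_weight(self):
        model = ScoreModel(weights={(0, "A"): 0.5})
        assert model.score("A" * 20) == 0.5
        assert model.score("C" + "A" * 19) == 0.0

    def test_table_passthrough_and_missing(self):
        model = ScoreModel(table={SPACER: 0.73})
        assert model.score(SPACER) == 0.73
        with pytest.raises(KeyError, match="absent"):
            model.score("A" * 20)

    def test_yaml_round(self, tmp_path):
        path = tmp_path / "weights.yaml"
        path.write_text("intercept: 0.1\nweights:\n  '0:A': 0.5\n  '3:G': -0.2\n")
        model = ScoreModel.from_yaml(str(path))
        assert model.score("AAAG" + "C" * 16) == pytest.approx(0.1 + 0.5 - 0.2)


def run_filters(spacers, genome=None):
    # "CA" separators avoid creating poly-T runs or CC/GG at junctions
    genome = genome or {
        "c": "CA".join(sp + "AGG" for sp in spacers) + "CA"
    }
    cands = [candidate(sp, start=30 * i) for i, sp in enumerate(spacers)]
    return {c.spacer: c for c in filter_candidates(cands, GenomeIndex(genome))}


class TestFilterCascade:
    def test_four_consecutive_t_flagged_three_pass(self):
        four = "TTTT" + "ACGACGACGACGACGA"
        three = "TTTACGACGACGACGACGAC"[:20]
        out = run_filters([four, three])
        assert "poly_T" in out[four].filter_flags
        assert "poly_T" not in out[three].filter_flags

    def test_gc_boundaries(self):
        gc75 = "G" * 7 + "C" * 8 + "A" * 5        # exactly 0.75 -> flagged
        gc10 = "A" * 9 + "GC" + "A" * 9           # exactly 0.10 -> passes
        gc05 = "A" * 10 + "G" + "A" * 9           # 0.05 -> flagged
        assert gc_fraction(gc75) == 0.75 and gc_fraction(gc10) == 0.10
        out = run_filters([gc75, gc10, gc05])
        assert "gc_extreme" in out[gc75].filter_flags
        assert "gc_extreme" not in out[gc10].filter_flags
        assert "gc_extreme" in out[gc05].filter_flags

    def test_n_flagged(self):
        sp = "ATCGATCGATNGATCGATCG"
        out = run_filters([sp])
        assert "has_N" in out[sp].filter_flags

    def test_multi_mapping_matches_naive_occurrence_count(self):
        # same protospacer+NGG planted twice; a unique one planted once
        dup, uniq = SPACER, "TGCATGCATGCATGCATGCA"
        genome = {"c": "AT" + dup + "AGG" + "ATAT" + dup + "TGG" + uniq + "CGG" + "AT"}
        seq = genome["c"]
        for sp, expected_flag in [(dup, True), (uniq, False)]:
            naive = sum(
                1
                for i in range(len(seq) - 22)
                if seq[i : i + 20] == sp and seq[i + 21 : i + 23] == "GG"
            ) + sum(
                1
                for i in range(len(seq) - 22)
                if seq[i + 3 : i + 23] == revcomp(sp) and seq[i : i + 2] == "CC"
            )
            assert GenomeIndex(genome).occurrences(sp) == naive
            out = run_filters([sp], genome=genome)
            assert ("multi_mapping" in out[sp].filter_flags) is expected_flag
            assert naive == (2 if expected_flag else 1)


class TestDedup:
    def test_within_four_bp_keeps_best_score(self):
        a, b = candidate(start=100, score=0.9), candidate(
            "TGCATGCATGCATGCATGCA", start=103, score=0.4)
        out = {c.start: c for c in dedup_nearby([a, b])}
        assert out[100].passes
        assert "dedup_removed" in out[103].filter_flags

    def test_five_bp_apart_both_kept(self):
        a, b = candidate(start=100, score=0.9), candidate(
            "TGCATGCATGCATGCATGCA", start=105, score=0.4)
        assert all(c.passes for c in dedup_nearby([a, b]))

    def test_equal_scores_keep_leftmost(self):
        a, b = candidate(start=100, score=0.5), candidate(
            "TGCATGCATGCATGCATGCA", start=104, score=0.5)
        out = {c.start: c for c in dedup_nearby([b, a])}
        assert out[100].passes and not out[104].passes

    def test_chain_collapses_to_single_winner(self):
        cands = [
            candidate(sp, start=s, score=sc)
            for sp, s, sc in [
                (SPACER, 100, 0.2),
                ("TGCATGCATGCATGCATGCA", 103, 0.8),
                ("CATGCATGCATGCATGCATG", 106, 0.5),
            ]
        ]
        out = dedup_nearby(cands)
        assert [c.start for c in out if c.passes] == [103]

    @given(hst.permutations(range(6)))
    @settings(max_examples=20, deadline=None)
    def test_order_invariant_and_idempotent(self, order):
        base = [
            candidate(f"{'ACGT'[i % 4]}" * 20, start=100 + 3 * i, score=i * 0.1)
            for i in range(6)
        ]
        shuffled = [base[i] for i in order]
        ref = dedup_nearby(base)
        assert dedup_nearby(shuffled) == ref
        assert dedup_nearby(ref) == ref


def assignment(gene, cluster_id, tie):
    return TssAssignment(
        gene_id=gene, transcript_id=f"{gene}_t", source="cage", tss=1000,
        chrom="chr1", strand="+", tie_score=tie, cluster_id=cluster_id,
    )


class TestSelectPerGene:
    def test_top_ten_by_score_single_cluster(self):
        cands = [
            candidate(f"{'ACGT'[i % 4]}" * 20, start=100 + 10 * i,
                      score=i / 12, source="c1")
            for i in range(12)
        ]
        out = select_per_gene(cands, [assignment("g1", "c1", 30.0)], 10)
        assert len(out) == 10
        assert min(c.score for c in out) == pytest.approx(2 / 12)

    def test_higher_tiescore_cluster_preferred(self):
        hi = [candidate("A" * 20, start=100 + 10 * i, score=0.1, source="hi")
              for i in range(6)]
        lo = [candidate("C" * 20, start=400 + 10 * i, score=0.9, source="lo")
              for i in range(8)]
        out = select_per_gene(
            hi + lo,
            [assignment("g1", "hi", 30.0), assignment("g1", "lo", 20.0)],
            10,
        )
        assert sum(c.tss_source == "hi" for c in out) == 6
        assert sum(c.tss_source == "lo" for c in out) == 4

    def test_small_gene_keeps_all_guides(self):
        cands = [candidate(start=100), candidate("T" * 19 + "A", start=200)]
        out = select_per_gene(cands, [assignment("g1", "c1", 10.0)], 10)
        assert len(out) == 2  # below the 3-guide minimum, filtered downstream

    def test_flagged_candidates_never_selected(self):
        bad = candidate(start=100, flags=frozenset({"poly_T"}))
        assert select_per_gene([bad], [assignment("g1", "c1", 1.0)], 10) == []


class TestAssembleLibrary:
    def test_oligo_is_linker_spacer_linker(self):
        (rec,) = assemble_library([candidate()])
        assert rec.oligo == LINKER_5 + SPACER + LINKER_3

    def test_counts_and_categories(self):
        selected = [
            candidate("A" * 20, start=100, gene="p1"),
            candidate("C" * 20, start=200, gene="p1"),
            candidate("G" * 20, start=300, gene="p2"),
        ]
        controls = [
            ControlGuide("nt_1", "T" * 20, "non_targeting"),
            ControlGuide("nt_2", "TA" * 10, "non_targeting"),
        ]
        recs = assemble_library(selected, controls,
                                {"p1": "pseudogene", "p2": "pseudogene"})
        assert len(recs) == 5
        assert sum(r.category == "non_targeting" for r in recs) == 2

    def test_shared_locus_merges_gene_annotations(self):
        a = candidate(start=100, gene="g1")
        b = candidate(start=100, gene="g2")
        (rec,) = assemble_library([a, b])
        assert sorted(rec.gene_ids) == ["g1", "g2"]

    def test_duplicate_guide_id_rejected(self):
        controls = [
            ControlGuide("x", "A" * 20, "non_targeting"),
            ControlGuide("x", "C" * 20, "non_targeting"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            assemble_library([], controls)

    def test_manifest_round_trip(self):
        recs = assemble_library(
            [candidate(), candidate("TGCATGCATGCATGCATGCA", start=300, gene="g2")],
            [ControlGuide("nt_1", "T" * 19 + "A", "non_targeting")],
        )
        buf = io.StringIO()
        write_manifest(recs, buf)
        buf.seek(0)
        assert read_manifest(buf) == recs
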