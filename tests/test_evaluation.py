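"""Macro metrics, small-bin removal, cross-validation harness, consistency."""

import numpy as np
import pytest

from taxoplace.evaluation import (
    LabeledAssignment,
    chunk_intervals,
    consistency_analysis,
    cross_validate,
    evaluate,
    evaluate_rank,
    read_labeled_tsv,
    write_labeled_tsv,
)

from conftest import make_tree, random_tree
from taxoplace.taxonomy import NO_RANK


@pytest.fixture
def two_genus_tree():
    # root 1 > family 2 > genera {3, 4} > species {5,6} and {7,8}
    return make_tree([
        (1, 1, NO_RANK), (2, 1, "family"),
        (3, 2, "genus"), (4, 2, "genus"),
        (5, 3, "species"), (6, 3, "species"),
        (7, 4, "species"), (8, 4, "species"),
    ])


def la(sid, length, pred, true):
    return LabeledAssignment(sid, length, pred, true)


class TestEvaluateRank:
    def test_all_correct_single_bin(self, two_genus_tree):
        r = evaluate_rank([la("a", 100, 5, 5), la("b", 50, 5, 5)], two_genus_tree, "species")
        assert r.macro_precision == 1.0
        assert r.macro_recall == 1.0

    def test_two_bins_one_wrong(self, two_genus_tree):
        r = evaluate_rank(
            [la("a", 100, 5, 5), la("b", 100, 7, 5)], two_genus_tree, "species",
            small_bin_fraction=0.0,
        )
        assert r.macro_precision == 0.5

    def test_higher_rank_predictions_excluded_from_rank_bins(self, two_genus_tree):
        # a genus-level prediction is neither correct nor incorrect at species
        r = evaluate_rank([la("a", 100, 3, 5), la("b", 100, 5, 5)], two_genus_tree, "species")
        assert r.predicted_bin_count == 1
        assert r.macro_precision == 1.0
        # but it counts at genus
        rg = evaluate_rank([la("a", 100, 3, 5), la("b", 100, 5, 5)], two_genus_tree, "genus")
        assert rg.predicted_bin_count == 1
        assert rg.pooled_assigned_bp == 200

    def test_unassigned_hurts_recall_not_precision(self, two_genus_tree):
        r = evaluate_rank(
            [la("a", 100, 5, 5), la("b", 100, None, 5)], two_genus_tree, "species"
        )
        assert r.macro_precision == 1.0
        assert r.macro_recall == 0.5

    def test_small_bin_removal_one_percent_of_bp(self, two_genus_tree):
        # bin 7 holds 15 of 1015 bp (>1%): kept; a tiny 5 bp bin goes
        rows = [la("a", 1000, 5, 5), la("b", 15, 7, 5)]
        r = evaluate_rank(rows, two_genus_tree, "species")
        assert r.removed_bins == []
        rows2 = [la("a", 1000, 5, 5), la("b", 15, 7, 5), la("c", 5, 6, 6)]
        r2 = evaluate_rank(rows2, two_genus_tree, "species")
        assert r2.removed_bins == [6]  # 5 bp <= 1% of 1020; adding bin 7 would exceed
        assert 7 in r2.predicted_bins

    def test_empty_input_rejected(self, two_genus_tree):
        with pytest.raises(ValueError):
            evaluate_rank([], two_genus_tree, "species")

    def test_random_tables_match_naive_tally_oracle(self):
        rng = np.random.default_rng(109)
        for _ in range(15):
            tree = random_tree(rng, 40, strict=True)
            ids = [t for t in tree.nodes if tree.node(t).rank == "species"]
            if len(ids) < 3:
                continue
            rows = []
            for i in range(30):
                true = int(rng.choice(ids))
                pred = None if rng.random() < 0.2 else int(rng.choice(list(tree.nodes)[1:]))
                rows.append(la(f"s{i}", int(rng.integers(1, 500)), pred, true))
            for rank in ("species", "genus"):
                got = evaluate_rank(rows, tree, rank, small_bin_fraction=0.0)
                exp_p, exp_r = _tally_oracle(rows, tree, rank)
                assert got.macro_precision == pytest.approx(exp_p)
                assert got.macro_recall == pytest.approx(exp_r)

    def test_overall_precision_between_rank_precisions(self, two_genus_tree):
        rows = [la("a", 100, 5, 5), la("b", 100, 7, 5), la("c", 300, 3, 7)]
        report = evaluate(rows, two_genus_tree, ranks=("species", "genus", "family"))
        pooled = [
            r.pooled_correct_bp / r.pooled_assigned_bp
            for r in report.per_rank.values() if r.pooled_assigned_bp
        ]
        assert min(pooled) <= report.overall_precision <= max(pooled)


def _tally_oracle(rows, tree, rank):
    """Naive per-bin tally of macro-precision and macro-recall."""
    proj = lambda t: None if t is None else tree.ancestor_at_rank(t, rank)
    pred_bins, true_bins = {}, {}
    for r in rows:
        p, t = proj(r.predicted_taxon), proj(r.true_taxon)
        if p is not None:
            a, c = pred_bins.get(p, (0, 0))
            pred_bins[p] = (a + r.length, c + (r.length if p == t else 0))
        if t is not None:
            a, c = true_bins.get(t, (0, 0))
            true_bins[t] = (a + r.length, c + (r.length if p == t else 0))
    mp = (sum(c / a for a, c in pred_bins.values()) / len(pred_bins)) if pred_bins else None
    mr = (sum(c / a for a, c in true_bins.values()) / len(true_bins)) if true_bins else None
    return mp, mr


class TestCrossValidate:
    def test_idealized_scenario_sees_full_reference(self, two_genus_tree):
        seen = {}

        def spy(qid, allowed):
            seen[qid] = allowed
            return 5

        refs = {5, 6, 7, 8}
        cross_validate([("q", 100, 5)], refs, two_genus_tree, spy, scenarios=(None,))
        assert seen["q"] == frozenset(refs)

    def test_single_family_masked_to_zero_references(self, two_genus_tree):
        calls = []

        def classifier(qid, allowed):
            calls.append(allowed)
            return 5 if allowed else None

        report = cross_validate(
            [("q", 100, 5)], {5, 6, 7, 8}, two_genus_tree, classifier,
            scenarios=("family",), ranks=("species",),
        )
        assert calls == [frozenset()]
        assert report.per_rank["species"].predicted_bin_count == 0

    def test_masked_sets_match_lineage_filter(self):
        # three phyla, species leaves
        tree = make_tree(
            [(1, 1, NO_RANK)]
            + [(p, 1, "phylum") for p in (2, 3, 4)]
            + [(10 * p + i, p, "species") for p in (2, 3, 4) for i in range(2)]
        )
        refs = {t for t in tree.nodes if tree.node(t).rank == "species"}
        seen = {}

        def spy(qid, allowed):
            seen[qid] = allowed
            return None

        cross_validate([("q", 10, 20)], refs, tree, spy, scenarios=("phylum",))
        expected = {t for t in refs if tree.ancestor_at_rank(t, "phylum") != 2}
        assert seen["q"] == frozenset(expected)

    def test_assignments_pooled_across_scenarios(self, two_genus_tree):
        report = cross_validate(
            [("q", 100, 5)], {5, 6, 7, 8}, two_genus_tree,
            lambda qid, allowed: 5 if 5 in allowed else None,
            scenarios=(None, "species", "genus"), ranks=("species",),
        )
        # only the idealized scenario predicts; 1 of 3 pooled rows correct
        r = report.per_rank["species"]
        assert r.pooled_assigned_bp == 100
        assert r.macro_recall == pytest.approx(1 / 3)


class TestConsistency:
    def test_chunking_rule(self):
        assert chunk_intervals(10_000) == [(1, 10_000)]
        got = chunk_intervals(10_001)
        assert got[0] == (1, 2000)
        assert got[-1] == (10_001, 10_001)
        assert len(got) == 6

    def test_uniform_contig_fully_consistent(self, two_genus_tree):
        rep = consistency_analysis({"c": [(5, 2000), (5, 2000), (5, 1200)]}, two_genus_tree)
        assert rep.contig_taxa["c"] == 5
        assert rep.macro_consistency == 1.0
        assert rep.overall_consistency == 1.0

    def test_sibling_minority_chunk(self, two_genus_tree):
        rep = consistency_analysis({"c": [(5, 2000), (5, 2000), (6, 2000)]}, two_genus_tree)
        assert rep.contig_taxa["c"] == 5  # exact-match argmax beats ancestors
        assert rep.per_taxon_consistency[5] == 1.0
        assert rep.per_taxon_consistency[6] == 0.0
        assert rep.overall_consistency == pytest.approx(2 / 3)

    def test_tie_prefers_deepest_candidate(self, two_genus_tree):
        rng_rep = consistency_analysis({"c": [(5, 2000), (3, 2000)]}, two_genus_tree)
        # one chunk at species 5, one at its genus 3: both candidates match one
        # chunk exactly; the deeper species wins
        assert rng_rep.contig_taxa["c"] == 5

    def test_matches_exhaustive_candidate_scoring(self, two_genus_tree):
        rng = np.random.default_rng(113)
        taxa = [3, 4, 5, 6, 7, 8]
        for _ in range(20):
            chunks = [(int(rng.choice(taxa)), 2000)
                      for _ in range(int(rng.integers(1, 8)))]
            rep = consistency_analysis({"c": chunks}, two_genus_tree)
            cands = set()
            for t, _ in chunks:
                cands.update(two_genus_tree.path_to_root(t))
            best = max(
                sorted(cands),
                key=lambda c: (sum(1 for t, _ in chunks if t == c),
                               two_genus_tree.depth(c), -c),
            )
            assert rep.contig_taxa["c"] == best


def test_labeled_tsv_round_trip(tmp_path, two_genus_tree):
    rows = [la("a", 100, 5, 5), la("b", 50, None, 6)]
    p = tmp_path / "labeled.tsv"
    write_labeled_tsv(rows, p)
    assert read_labeled_tsv(p) == rows
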