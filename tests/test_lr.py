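"""Ligand-receptor screen: scores, permutation null, empirical p, chord output."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nichecomm import (
    CellAnnotation,
    LRPairTable,
    ScreenConfig,
    chord_adjacency,
    empirical_pvalue,
    group_means,
    interaction_score,
    permutation_null,
    results_to_frame,
    screen,
)
from nichecomm.errors import ParameterError, ValidationError
from nichecomm.lr import InteractionResult
from tests.conftest import make_norm


def _ann(ct, tp, ids):
    return CellAnnotation(
        pd.DataFrame(
            {"cell_type": ct, "time_point": tp}, index=pd.Index(ids, name="cell_id")
        )
    )


class TestInteractionScore:
    def test_mean_of_the_two_group_means(self):
        norm = make_norm(np.zeros((2, 2), dtype=int))
        norm.values[:] = [[2.0, 0.0], [0.0, 4.0]]
        ann = _ann(["microglia", "NSPC"], ["PT_D7", "PT_D7"], ["c0", "c1"])
        gm = group_means(norm, ann)
        s = interaction_score(gm, "g0", "g1", "microglia", "NSPC", "PT_D7")
        assert s == pytest.approx(3.0)

    def test_zero_when_both_means_zero(self):
        norm = make_norm(np.zeros((2, 2), dtype=int))
        ann = _ann(["microglia", "NSPC"], ["PT_D7", "PT_D7"], ["c0", "c1"])
        gm = group_means(norm, ann)
        assert interaction_score(gm, "g0", "g1", "microglia", "NSPC", "PT_D7") == 0.0

    def test_composition_with_log_normalization(self):
        # single sender cell with count 1 in library 4: mean = ln(2501)
        norm = make_norm([[1, 0], [3, 0]])
        ann = _ann(["microglia", "NSPC"], ["PT_D7", "PT_D7"], ["c0", "c1"])
        gm = group_means(norm, ann)
        s = interaction_score(gm, "g0", "g1", "microglia", "NSPC", "PT_D7")
        assert s == pytest.approx(math.log(2501) / 2, abs=1e-6)

    def test_gene_outside_universe_counts_as_zero(self):
        norm = make_norm([[1, 2]])
        ann = _ann(["microglia", "NSPC"], ["PT_D7", "PT_D7"], ["c0", "c1"])
        gm = group_means(norm, ann)
        expected = gm.get("NSPC", "PT_D7", "g0") / 2
        assert interaction_score(gm, "nope", "g0", "microglia", "NSPC", "PT_D7") == (
            pytest.approx(expected)
        )

    def test_unknown_group_is_a_lookup_error(self):
        norm = make_norm([[1]])
        gm = group_means(norm, _ann(["microglia"], ["PT_D7"], ["c0"]))
        with pytest.raises(KeyError):
            interaction_score(gm, "g0", "g0", "microglia", "NSPC", "PT_D7")


class TestEmpiricalPvalue:
    def test_proportion_of_null_at_least_observed(self):
        assert empirical_pvalue(5.0, np.arange(1, 11)) == pytest.approx(0.6)

    def test_observed_above_all_null_gives_zero(self):
        assert empirical_pvalue(99.0, np.arange(1, 11)) == 0.0

    def test_ties_count_toward_the_upper_set(self):
        assert empirical_pvalue(3.0, np.full(8, 3.0)) == 1.0

    def test_smoothing_option(self):
        assert empirical_pvalue(99.0, np.arange(1, 11), smooth=True) == pytest.approx(1 / 11)

    def test_empty_null_rejected(self):
        with pytest.raises(ParameterError):
            empirical_pvalue(1.0, np.array([]))


def _small_instance(seed=0):
    rng = np.random.default_rng(seed)
    values = rng.poisson(25, size=(4, 6))
    ids = [f"c{j}" for j in range(6)]
    norm = make_norm(values, cell_ids=ids)
    ann = _ann(["microglia"] * 3 + ["NSPC"] * 3, ["PT_D7"] * 6, ids)
    pairs = LRPairTable(pd.DataFrame({"ligand": ["g0"], "receptor": ["g1"]}))
    return norm, ann, pairs


class TestPermutationNull:
    def test_single_joint_label_null_is_degenerate(self):
        norm = make_norm(np.random.default_rng(1).poisson(10, size=(3, 5)))
        ann = _ann(["microglia"] * 5, ["PT_D7"] * 5, [f"c{j}" for j in range(5)])
        pairs = LRPairTable(pd.DataFrame({"ligand": ["g0"], "receptor": ["g1"]}))
        cfg = ScreenConfig("microglia", "microglia", n_perm=20, seed=0)
        null, conds = permutation_null(norm, ann, pairs, cfg)
        res = screen(norm, ann, pairs, cfg)
        assert np.allclose(null, res[0].score)
        assert all(r.p_value == 1.0 for r in res)

    def test_two_cells_two_labels_take_exactly_two_values(self):
        norm = make_norm([[4, 0], [0, 7]])
        ann = _ann(["microglia", "NSPC"], ["PT_D7", "PT_D7"], ["c0", "c1"])
        pairs = LRPairTable(pd.DataFrame({"ligand": ["g0"], "receptor": ["g1"]}))
        cfg = ScreenConfig("microglia", "NSPC", n_perm=400, seed=2,
                           direction_mode="ligand-in-sender")
        null, _ = permutation_null(norm, ann, pairs, cfg)
        # identity assignment: ligand in c0, receptor in c1; the swap puts
        # the labels on the opposite cells, where both genes are zero
        identity = 0.5 * (norm.values[0, 0] + norm.values[1, 1])
        swapped = 0.5 * (norm.values[0, 1] + norm.values[1, 0])
        assert set(np.round(null.ravel(), 12)) == set(
            np.round([identity, swapped], 12)
        )
        gm = group_means(norm, ann)
        a = interaction_score(gm, "g0", "g1", "microglia", "NSPC", "PT_D7")
        assert a == pytest.approx(identity)

    def test_same_seed_reproduces_null_exactly(self):
        norm, ann, pairs = _small_instance(3)
        cfg = ScreenConfig("microglia", "NSPC", n_perm=50, seed=42)
        n1, _ = permutation_null(norm, ann, pairs, cfg)
        n2, _ = permutation_null(norm, ann, pairs, cfg)
        assert np.array_equal(n1, n2)

    def test_sampled_p_within_binomial_ci_of_exhaustive_p(self):
        """Sampled null agrees with enumeration over all distinct labelings."""
        norm, ann, pairs = _small_instance(5)
        cfg = ScreenConfig("microglia", "NSPC", n_perm=500, seed=7,
                           direction_mode="ligand-in-sender")
        res = screen(norm, ann, pairs, cfg)[0]

        # oracle: brute-force score under every distinct assignment of the
        # label multiset to cells, each equally likely under a uniform shuffle
        lab = [tuple(ann.table.loc[c]) for c in norm.cell_ids]
        null_scores = []
        for assign in set(itertools.permutations(lab)):
            mg = [i for i, a in enumerate(assign) if a == ("microglia", "PT_D7")]
            ns = [i for i, a in enumerate(assign) if a == ("NSPC", "PT_D7")]
            s = 0.5 * (norm.values[0, mg].mean() + norm.values[1, ns].mean())
            null_scores.append(s)
        p_exact = np.mean([s >= res.score - 1e-12 for s in null_scores])

        half_width = 3 * math.sqrt(p_exact * (1 - p_exact) / cfg.n_perm) + 1 / cfg.n_perm
        assert abs(res.p_value - p_exact) <= half_width


class TestScreen:
    def test_one_result_per_pair_time_direction(self):
        norm, ann, pairs = _small_instance(0)
        cfg = ScreenConfig("microglia", "NSPC", n_perm=10, seed=0,
                           direction_mode="ligand-in-sender")
        assert len(screen(norm, ann, pairs, cfg)) == 1

    def test_both_directions_two_time_points_three_pairs_give_twelve(self):
        rng = np.random.default_rng(8)
        ids = [f"c{j}" for j in range(12)]
        norm = make_norm(rng.poisson(20, size=(6, 12)), cell_ids=ids)
        ann = _ann(["microglia", "NSPC"] * 6, ["uninjured"] * 6 + ["PT_D7"] * 6, ids)
        pairs = LRPairTable(pd.DataFrame(
            {"ligand": ["g0", "g2", "g4"], "receptor": ["g1", "g3", "g5"]}
        ))
        cfg = ScreenConfig("microglia", "NSPC", n_perm=10, seed=0)
        assert len(screen(norm, ann, pairs, cfg)) == 12

    def test_no_testable_pairs_is_an_error(self):
        norm, ann, _ = _small_instance(0)
        pairs = LRPairTable(pd.DataFrame({"ligand": ["nope"], "receptor": ["nada"]}))
        cfg = ScreenConfig("microglia", "NSPC", n_perm=10, seed=0)
        with pytest.raises(ValidationError, match="no testable pairs"):
            screen(norm, ann, pairs, cfg)

    def test_same_seed_gives_identical_result_table(self):
        norm, ann, pairs = _small_instance(4)
        cfg = ScreenConfig("microglia", "NSPC", n_perm=60, seed=9)
        f1 = results_to_frame(screen(norm, ann, pairs, cfg))
        f2 = results_to_frame(screen(norm, ann, pairs, cfg))
        pd.testing.assert_frame_equal(f1, f2)

    def test_p_value_times_n_perm_is_an_integer_count(self):
        norm, ann, pairs = _small_instance(6)
        cfg = ScreenConfig("microglia", "NSPC", n_perm=37, seed=1)
        for r in screen(norm, ann, pairs, cfg):
            assert 0.0 <= r.p_value <= 1.0
            assert r.p_value * r.n_perm == pytest.approx(round(r.p_value * r.n_perm))
            assert r.count_ge == round(r.p_value * r.n_perm)


def _result(sender, receiver, p, score=1.0):
    return InteractionResult("L", "R", sender, receiver, "PT_D7", score, p, 100,
                             int(p * 100), 0.0, 0.0)


class TestChordAdjacency:
    def test_nothing_passes_gives_zero_matrix(self):
        adj = chord_adjacency([_result("A", "B", 0.5)], p_max=0.05)
        assert (adj.to_numpy() == 0).all()

    def test_single_passing_result_single_entry(self):
        adj = chord_adjacency([_result("A", "B", 0.01)], p_max=0.05)
        assert adj.at["A", "B"] == 1 and adj.to_numpy().sum() == 1

    def test_reciprocal_interactions_are_asymmetric_entries(self):
        adj = chord_adjacency(
            [_result("A", "B", 0.0), _result("B", "A", 0.0)], p_max=0.05
        )
        assert adj.at["A", "B"] == 1 and adj.at["B", "A"] == 1
        assert adj.at["A", "A"] == 0 and adj.at["B", "B"] == 0

    def test_score_weighting_sums_scores(self):
        adj = chord_adjacency(
            [_result("A", "B", 0.0, 2.5), _result("A", "B", 0.0, 1.5)],
            p_max=0.05, weight="score",
        )
        assert adj.at["A", "B"] == pytest.approx(4.0)
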