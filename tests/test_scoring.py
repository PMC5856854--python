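import numpy as np
import pytest

from padif import (
    PadifScorer,
    combined_rank,
    make_padif,
    merge_references,
    rank_by_score,
    score_pose,
)
from padif.fingerprint import ReferencePADIF
from padif.io import N_TERMS

from conftest import make_atoms, padif_from_matrix, random_padif, table_from_matrix
from oracle import brute_force_score


def reference_from_weights(weight_map, n_atoms=2):
    """ReferencePADIF with favourable elements at the given (m, n): w."""
    med = np.zeros((n_atoms, N_TERMS))
    wts = np.zeros((n_atoms, N_TERMS))
    for (m, n), w in weight_map.items():
        med[m, n] = -1.0
        wts[m, n] = w
    return ReferencePADIF(atoms=make_atoms(n_atoms), median_values=med,
                          weights=wts, n_references=1)


class TestScorePose:
    def test_perfect_match_scores_sum_of_weights(self):
        ref = reference_from_weights({(0, 0): 0.8, (0, 3): 0.6, (1, 5): 1.0})
        pose = padif_from_matrix(np.where(ref.median_values < 0, -0.5, 0.0))
        b = score_pose(ref, pose)
        assert (b.O_max, b.O_real, b.O_rel) == (1.0, 1.0, 1.0)
        assert b.S_tot == pytest.approx(2.4)
        assert b.S_tot == pytest.approx(b.sum_S)

    def test_worked_example_partial_overlap_with_clash(self):
        # R = 3 with weights 1.0, 0.5, 0.4; pose favourable at the first two
        # plus one non-reference element, clashing (+0.2) at the third:
        # ΣS = 1.0 + 0.5 − 0.4 = 1.1, O_real = 2/3, O_max = 1,
        # S_tot = 1.1 − (1/3)·1.1
        ref = reference_from_weights({(0, 0): 1.0, (0, 1): 0.5, (1, 2): 0.4})
        values = np.zeros((2, N_TERMS))
        values[0, 0] = -1.0
        values[0, 1] = -0.3
        values[1, 2] = 0.2
        values[1, 6] = -0.7  # favourable outside the reference pattern
        b = score_pose(ref, padif_from_matrix(values))
        assert (b.R, b.P, b.overlap_count) == (3, 3, 2)
        assert b.sum_S == pytest.approx(1.1)
        assert b.O_max == 1.0
        assert b.O_real == pytest.approx(2 / 3)
        assert b.O_rel == pytest.approx(2 / 3)
        assert b.S_tot == pytest.approx(1.1 - (1 / 3) * 1.1)

    def test_empty_pose_scores_zero(self):
        ref = reference_from_weights({(0, 0): 1.0})
        b = score_pose(ref, padif_from_matrix(np.zeros((2, N_TERMS))))
        assert b.P == 0
        assert b.sum_S == 0.0
        assert b.S_tot == 0.0
        assert b.O_rel == 0.0

    def test_empty_pose_with_clashes_ranks_bottom(self):
        # P = 0 but positive values at reference elements: ΣS < 0 and the
        # zero-overlap penalty doubles it
        ref = reference_from_weights({(0, 0): 1.0, (1, 1): 0.5})
        values = np.zeros((2, N_TERMS))
        values[0, 0] = 0.3
        values[1, 1] = 0.9
        b = score_pose(ref, padif_from_matrix(values))
        assert b.sum_S == pytest.approx(-1.5)
        assert b.S_tot == pytest.approx(-3.0)

    def test_reference_without_favourable_elements_rejected(self):
        med = np.zeros((2, N_TERMS))
        wts = np.zeros((2, N_TERMS))
        ref = ReferencePADIF(atoms=make_atoms(2), median_values=med,
                             weights=wts, n_references=1)
        with pytest.raises(ValueError, match="R = 0"):
            score_pose(ref, padif_from_matrix(np.zeros((2, N_TERMS))))

    def test_mismatched_atom_list_names_offending_atom(self, rng):
        ref = reference_from_weights({(0, 0): 1.0})
        pose = random_padif(rng, 2)
        pose.atoms[1] = pose.atoms[1]._replace(atom_name="OXT")
        with pytest.raises(ValueError, match="OXT"):
            score_pose(ref, pose)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(300):
            n_atoms = int(rng.integers(1, 6))
            ref_fp = random_padif(rng, n_atoms, p_neg=0.4)
            if not np.any(ref_fp.values < 0):
                continue
            ref = merge_references([ref_fp])
            pose = random_padif(rng, n_atoms, p_neg=0.35, p_pos=0.3)
            b = score_pose(ref, pose)
            R, P, ov, o_max, o_real, o_rel, sum_s, s_tot = brute_force_score(
                ref.median_values.tolist(), ref.weights.tolist(),
                pose.values.tolist())
            assert (b.R, b.P, b.overlap_count) == (R, P, ov)
            assert b.O_max == pytest.approx(o_max, abs=1e-12)
            assert b.O_rel == pytest.approx(o_rel, abs=1e-12)
            assert b.sum_S == pytest.approx(sum_s, abs=1e-12)
            assert b.S_tot == pytest.approx(s_tot, abs=1e-12)

    def test_score_invariant_to_pose_magnitudes(self, rng):
        ref = merge_references([random_padif(rng, 3, p_neg=0.5)])
        pose = random_padif(rng, 3)
        scaled = padif_from_matrix(pose.values * 37.5)
        assert score_pose(ref, pose).S_tot == score_pose(ref, scaled).S_tot

    def test_perfect_subset_keeps_full_score(self, rng):
        # a small ligand realizing few, all-matching interactions is not
        # penalized: O_rel = 1 and S_tot = ΣS
        for _ in range(200):
            ref = merge_references([random_padif(rng, 3, p_neg=0.5)])
            fav = np.argwhere(ref.median_values < 0)
            if len(fav) < 2:
                continue
            take = fav[rng.random(len(fav)) < 0.5]
            if len(take) == 0:
                take = fav[:1]
            values = np.zeros_like(ref.median_values)
            values[tuple(take.T)] = -1.0
            b = score_pose(ref, padif_from_matrix(values))
            assert b.O_rel == 1.0
            assert b.S_tot == b.sum_S == pytest.approx(
                ref.weights[tuple(take.T)].sum())

    def test_completing_a_match_never_decreases_score(self, rng):
        # flip one non-matching reference element (pose value 0) to matching
        for _ in range(200):
            n_atoms = int(rng.integers(1, 5))
            ref = merge_references([random_padif(rng, n_atoms, p_neg=0.5)])
            pose = random_padif(rng, n_atoms, p_neg=0.3, p_pos=0.3)
            candidates = np.argwhere((ref.median_values < 0) & (pose.values == 0))
            if len(candidates) == 0:
                continue
            m, n = candidates[int(rng.integers(len(candidates)))]
            before = score_pose(ref, pose).S_tot
            flipped = pose.values.copy()
            flipped[m, n] = -0.4
            after = score_pose(ref, padif_from_matrix(flipped)).S_tot
            assert after >= before - 1e-12

    def test_bounds_and_penalty_direction(self, rng):
        for _ in range(100):
            ref = merge_references([random_padif(rng, 3, p_neg=0.5)])
            pose = random_padif(rng, 3)
            b = score_pose(ref, pose)
            for v in (b.O_max, b.O_real, b.O_rel):
                assert 0.0 <= v <= 1.0
            assert b.S_tot <= b.sum_S + 1e-12


class TestEstimatorInterface:
    def test_fit_on_raw_tables_matches_manual_pipeline(self, rng):
        tables = [table_from_matrix(rng.normal(size=(3, N_TERMS)),
                                    source_id=f"r{i}") for i in range(4)]
        pose_t = table_from_matrix(rng.normal(size=(3, N_TERMS)))
        scorer = PadifScorer().fit(tables)
        ref = merge_references([make_padif(t) for t in tables])
        expected = score_pose(ref, make_padif(pose_t)).S_tot
        assert scorer.decision_function([pose_t])[0] == pytest.approx(expected)

    def test_get_params_round_trip(self):
        scorer = PadifScorer(sign_normalized=True)
        params = scorer.get_params()
        assert params == {"sign_normalized": True}
        clone = PadifScorer().set_params(**params)
        assert clone.sign_normalized is True

    def test_unfitted_scorer_raises(self, rng):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            PadifScorer().decision_function([random_padif(rng, 2)])

    def test_mixed_input_kinds_rejected(self, rng):
        with pytest.raises(TypeError):
            PadifScorer(sign_normalized=False).fit([random_padif(rng, 2)])


class TestRanking:
    def test_descending_order(self):
        assert rank_by_score({"a": 1.0, "b": 2.0}).ids() == ["b", "a"]

    def test_tie_broken_by_id(self):
        assert rank_by_score({"b": 1.0, "a": 1.0}).ids() == ["a", "b"]

    def test_matches_independent_sort(self, rng):
        scores = {f"p{i:03d}": float(rng.normal()) for i in range(100)}
        expected = [pid for pid, _ in
                    sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))]
        assert rank_by_score(scores).ids() == expected
        assert [r for _, _, r in rank_by_score(scores).entries] == list(range(1, 101))


class TestCombinedRank:
    def test_head_is_best_conventional_poses(self, rng):
        conv = {f"p{i:03d}": float(rng.normal()) for i in range(100)}
        fp = {k: float(rng.normal()) for k in conv}
        ranking = combined_rank(conv, fp, top_fraction=0.03)
        best3 = rank_by_score(conv).ids()[:3]
        assert ranking.ids()[:3] == best3
        tail = [p for p in rank_by_score(fp).ids() if p not in best3]
        assert ranking.ids()[3:] == tail

    def test_small_list_keeps_at_least_one_conventional_pose(self, rng):
        conv = {f"p{i}": float(i) for i in range(10)}
        fp = {k: float(rng.normal()) for k in conv}
        ranking = combined_rank(conv, fp, top_fraction=0.03)
        assert ranking.ids()[0] == rank_by_score(conv).ids()[0]

    def test_identical_scores_reduce_to_plain_ranking(self, rng):
        scores = {f"p{i}": float(rng.normal()) for i in range(20)}
        assert combined_rank(scores, scores).ids() == rank_by_score(scores).ids()

    def test_mismatched_id_sets_rejected(self):
        with pytest.raises(ValueError, match="id sets"):
            combined_rank({"a": 1.0}, {"b": 1.0})
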