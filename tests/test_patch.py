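import copy

import numpy as np
import pytest

from conftest import rigid_transform_model
from nucscreen.contacts import dedupe_to_residue_pairs, find_atom_contacts
from nucscreen.fixtures import FixtureSpec, build_fixture
from nucscreen.patch import (
    AcidicPatchDefinition,
    PatchContactSet,
    benchmark_hit,
    binder_patch_residues,
    consistency_score,
    kabsch,
    locate_patch_faces,
    mode_rmsd,
    motif_windows,
    patch_centroid,
    patch_pair_set,
    patch_rmsd_matrix,
    select_representative_segment,
    superpose_on_histones,
)
from nucscreen.structio import AtomRecord


class TestPatchDefinition:
    def test_pocket_subsets(self):
        defn = AcidicPatchDefinition()
        assert defn.ap1 <= defn.ap_residues
        assert defn.ap2 <= defn.ap_residues
        assert defn.ap1 == {62, 91, 93}
        assert defn.ap2 == {62, 91, 65}

    def test_reference_positions_are_acidic(self):
        defn = AcidicPatchDefinition()
        for pos in sorted(defn.ap_residues):
            assert defn.reference_sequence[pos - 1] in "DE"

    def test_invalid_subsets_rejected(self):
        with pytest.raises(ValueError):
            AcidicPatchDefinition(ap1=frozenset({1, 2, 3}))


class TestPatchCentroid:
    def test_centroid_equals_independent_mean(self):
        model, _ = build_fixture(FixtureSpec(seed=8))
        defn = AcidicPatchDefinition()
        face, mapping = locate_patch_faces(model, defn)[0]
        chain = model.get_chain(face)
        coords = []
        for ref_pos in defn.pocket_residues:
            res = chain.get_residue(mapping[ref_pos])
            coords += [a.coords for a in res.heavy_atoms()]
        oracle = np.asarray(coords).mean(axis=0)
        assert np.allclose(patch_centroid(model, defn, face), oracle, atol=1e-12)

    def test_midpoint_of_two_atoms(self):
        model, _ = build_fixture(FixtureSpec(seed=8))
        defn = AcidicPatchDefinition()
        face, mapping = locate_patch_faces(model, defn)[0]
        chain = model.get_chain(face)
        # strip the pocket down to two atoms at (0,0,0) and (2,0,0)
        pocket = sorted(defn.pocket_residues)
        for ref_pos in pocket:
            chain.get_residue(mapping[ref_pos]).atoms = []
        chain.get_residue(mapping[pocket[0]]).atoms = [
            AtomRecord("C", "CA", np.zeros(3), 1.0, 50.0)
        ]
        chain.get_residue(mapping[pocket[1]]).atoms = [
            AtomRecord("C", "CA", np.array([2.0, 0.0, 0.0]), 1.0, 50.0)
        ]
        assert np.allclose(patch_centroid(model, defn, face), [1.0, 0.0, 0.0])

    def test_missing_patch_residue_raises(self):
        model, _ = build_fixture(FixtureSpec(seed=8, n_histone_res_per_chain=20))
        with pytest.raises(ValueError):
            patch_centroid(model)


class TestBinderPatchResidues:
    def test_planted_segments(self):
        spec = FixtureSpec(
            seed=9,
            binder_length=40,
            planted_patch_residues=[(10, 4.0), (11, 4.1), (12, 4.2),
                                    (13, 4.3), (14, 4.4), (30, 4.9)],
        )
        model, _ = build_fixture(spec)
        pcs = binder_patch_residues(model)
        assert pcs.binder_residues == [10, 11, 12, 13, 14, 30]
        assert pcs.segments == [[10, 11, 12, 13, 14], [30]]

    def test_no_binder_near_patch(self):
        model, _ = build_fixture(FixtureSpec(seed=10))
        pcs = binder_patch_residues(model)
        assert pcs.binder_residues == []
        assert pcs.segments == []

    def test_cutoff_boundary(self):
        model, _ = build_fixture(FixtureSpec(seed=9, planted_patch_residues=[(5, 4.9)]))
        assert binder_patch_residues(model, cutoff=5.0).binder_residues == [5]
        assert binder_patch_residues(model, cutoff=4.5).binder_residues == []


class TestRepresentativeSegment:
    def test_longest_wins(self):
        pcs = PatchContactSet("m", "A", [], [[1, 2, 3, 4, 5], list(range(10, 21))])
        assert select_representative_segment(pcs) == list(range(10, 21))

    def test_single_segment(self):
        pcs = PatchContactSet("m", "A", [], [[7, 8]])
        assert select_representative_segment(pcs) == [7, 8]

    def test_tie_break_is_seeded_and_repeatable(self):
        pcs = PatchContactSet("m", "A", [], [[1, 2, 3], [10, 11, 12], [20, 21, 22]])
        first = select_representative_segment(pcs, seed=123)
        assert all(
            select_representative_segment(pcs, seed=123) == first for _ in range(5)
        )
        assert first in pcs.segments

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_representative_segment(PatchContactSet("m", "A", [], []))


class TestSuperposition:
    def test_self_superposition_zero_rmsd(self):
        model, _ = build_fixture(FixtureSpec(seed=12))
        R, t, rmsd = superpose_on_histones(model, model)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_copy_recovers_zero_rmsd(self):
        model, _ = build_fixture(FixtureSpec(seed=12))
        moved = rigid_transform_model(model, seed=4)
        _, _, rmsd = superpose_on_histones(model, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_displaced_atom_matches_kabsch_oracle(self):
        """Single displaced histone CA: RMSD must equal an independent
        Kabsch implementation built on scipy's rotation fitting."""
        from scipy.spatial.transform import Rotation

        model, _ = build_fixture(FixtureSpec(seed=12))
        moved = copy.deepcopy(model)
        res = moved.chains_with_role("H3")[0].residues[5]
        res.get_atom("CA").coords = res.get_atom("CA").coords + np.array([0, 0, 1.0])
        _, _, rmsd = superpose_on_histones(model, moved)

        from nucscreen.patch import _histone_ca_map

        ca_a = _histone_ca_map(model)
        ca_b = _histone_ca_map(moved)
        shared = sorted(set(ca_a) & set(ca_b))
        fixed = np.array([ca_a[k] for k in shared])
        moving = np.array([ca_b[k] for k in shared])
        rot, _ = Rotation.align_vectors(
            fixed - fixed.mean(axis=0), moving - moving.mean(axis=0)
        )
        aligned = rot.apply(moving - moving.mean(axis=0)) + fixed.mean(axis=0)
        oracle = float(np.sqrt(np.mean(np.sum((aligned - fixed) ** 2, axis=1))))
        assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_kabsch_recovers_known_rotation(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-10, 10, size=(50, 3))
        from scipy.spatial.transform import Rotation

        R_true = Rotation.random(rng=rng).as_matrix()
        t_true = np.array([1.0, -2.0, 3.0])
        moved = pts @ R_true.T + t_true
        R, t = kabsch(moved, pts)
        assert np.allclose(R @ R_true, np.eye(3), atol=1e-9)
        assert np.allclose(R @ moved.T + t[:, None], pts.T, atol=1e-9)

    def test_too_few_shared_atoms_raises(self):
        model, _ = build_fixture(FixtureSpec(seed=12))
        stripped = copy.deepcopy(model)
        for chain in stripped.chains:
            if chain.role in ("H2A", "H2B", "H3", "H4"):
                chain.residues = chain.residues[:0]
        with pytest.raises(ValueError, match="histone CA"):
            superpose_on_histones(model, stripped)


def _cohort_models(distances, seed=14):
    """Five fixture models whose single patch residue sits at the given
    centroid distances; pairwise patch RMSD is then exactly |d_i - d_j|."""
    models, patch_sets = [], []
    for d in distances:
        spec = FixtureSpec(seed=seed, planted_patch_residues=[(3, d)])
        model, _ = build_fixture(spec)
        models.append(model)
        patch_sets.append(binder_patch_residues(model))
    return models, patch_sets


class TestConsistency:
    def test_identical_models_all_zero(self):
        models, pcs = _cohort_models([4.0] * 5)
        result = patch_rmsd_matrix(models, pcs, "p")
        assert len(result.rmsd_pairs) == 10
        assert result.rmsd_pairs == pytest.approx([0.0] * 10, abs=1e-9)
        assert result.mode_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_ten_pairs_for_five_models(self):
        models, pcs = _cohort_models([4.0, 4.2, 4.4, 4.6, 4.8])
        result = patch_rmsd_matrix(models, pcs, "p")
        assert len(result.rmsd_pairs) == 10

    def test_planted_displacements_match_oracle(self):
        distances = [4.9, 4.5, 4.1, 3.7, 3.3]
        models, pcs = _cohort_models(distances)
        result = patch_rmsd_matrix(models, pcs, "p")
        oracle = sorted(
            abs(distances[i] - distances[j])
            for i in range(5) for j in range(i + 1, 5)
        )
        assert sorted(result.rmsd_pairs) == pytest.approx(oracle, abs=1e-6)

    def test_permutation_leaves_rmsd_multiset(self):
        distances = [4.9, 4.5, 4.1, 3.7, 3.3]
        models, pcs = _cohort_models(distances)
        base = sorted(patch_rmsd_matrix(models, pcs, "p").rmsd_pairs)
        rng = np.random.default_rng(1)
        order = rng.permutation(5)
        permuted = sorted(
            patch_rmsd_matrix(
                [models[i] for i in order], [pcs[i] for i in order], "p"
            ).rmsd_pairs
        )
        assert permuted == pytest.approx(base, abs=1e-9)

    def test_empty_intersection_flagged(self):
        m1, pc1 = _cohort_models([4.0])
        m2, pc2 = _cohort_models([4.0])
        pc2[0].binder_residues = [7]  # disjoint from model 1's residue 3
        result = patch_rmsd_matrix(m1 + m2, pc1 + pc2, "p")
        assert result.omitted_pairs == [(0, 1)]
        assert not result.defined


class TestModeRmsd:
    def test_hand_histogram(self):
        # three values in [0.5, 0.6) beat the two singletons
        assert mode_rmsd([0.51, 0.52, 0.55, 2.0, 3.1]) == pytest.approx(0.55)

    def test_all_equal_returns_exact_value(self):
        assert mode_rmsd([0.73] * 6) == pytest.approx(0.73)

    def test_single_value(self):
        assert mode_rmsd([1.234]) == pytest.approx(1.234)

    def test_tie_goes_to_lowest_bin(self):
        assert mode_rmsd([0.51, 0.58, 1.21, 1.28]) == pytest.approx(0.55)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mode_rmsd([])


class TestConsistencyScore:
    @pytest.mark.parametrize(
        "mode,cmax,expected", [(0.0, 4.8, 1.0), (4.8, 4.8, 0.0), (1.2, 4.8, 0.75)]
    )
    def test_arithmetic(self, mode, cmax, expected):
        assert consistency_score(mode, cmax) == pytest.approx(expected)

    def test_clipped_to_unit_interval(self):
        assert consistency_score(9.9, 4.8) == 0.0

    def test_invalid_max_raises(self):
        with pytest.raises(ValueError):
            consistency_score(1.0, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_cohorts_stay_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        modes = rng.uniform(0, 5, size=20)
        cmax = modes.max() * rng.uniform(1.0, 2.0)
        for m in modes:
            assert 0.0 <= consistency_score(m, cmax) <= 1.0


class TestMotifWindows:
    def _model_with_anchor(self, position, length=40):
        seq = ["G"] * length
        seq[position - 1] = "R"
        spec = FixtureSpec(
            seed=15, binder_length=length, binder_sequence="".join(seq),
            planted_patch_residues=[(position, 4.0)],
        )
        model, _ = build_fixture(spec)
        contacts = dedupe_to_residue_pairs(find_atom_contacts(model), "m")
        return model, contacts

    def test_interior_window(self):
        model, contacts = self._model_with_anchor(15)
        windows = motif_windows(model, contacts)
        assert len(windows) == 1
        w = windows[0]
        assert len(w.window) == 21
        assert w.window[10] == "R"
        assert "-" not in w.window

    def test_terminal_padding(self):
        model, contacts = self._model_with_anchor(1)
        (w,) = motif_windows(model, contacts)
        assert w.window.startswith("-" * 10)
        assert w.window[10] == "R"

    def test_no_basic_anchor_gives_no_window(self):
        spec = FixtureSpec(
            seed=15, binder_length=40, binder_sequence="G" * 40,
            planted_patch_residues=[(15, 4.0)],
        )
        model, _ = build_fixture(spec)
        contacts = dedupe_to_residue_pairs(find_atom_contacts(model), "m")
        assert motif_windows(model, contacts) == []


class TestBenchmarkHit:
    def test_identical_sets_positive(self):
        pairs = {(3, 62), (3, 91), (4, 93)}
        call = benchmark_hit(pairs, set(pairs))
        assert call.jaccard == pytest.approx(1.0)
        assert call.positive

    def test_disjoint_sets_negative(self):
        call = benchmark_hit({(3, 62)}, {(9, 93)})
        assert call.jaccard == 0.0
        assert not call.positive

    def test_partial_overlap(self):
        call = benchmark_hit({(1, 62), (2, 91)}, {(1, 62), (2, 91), (3, 93), (4, 65)})
        assert call.jaccard == pytest.approx(0.5)
        assert call.positive

    def test_symmetry(self):
        a = {(1, 62), (2, 91), (5, 57)}
        b = {(1, 62), (9, 92)}
        assert benchmark_hit(a, b).jaccard == benchmark_hit(b, a).jaccard

    def test_both_empty_flagged_negative(self):
        call = benchmark_hit(set(), set())
        assert not call.positive
        assert not call.defined

    def test_patch_pair_set_from_fixture(self):
        spec = FixtureSpec(seed=16, planted_patch_residues=[(3, 4.0)])
        model, _ = build_fixture(spec)
        contacts = dedupe_to_residue_pairs(find_atom_contacts(model), "m")
        pairs = patch_pair_set(model, contacts)
        assert pairs  # the planted residue touches the pocket
        assert all(b == 3 and ref in {57, 62, 65, 91, 92, 93} for b, ref in pairs)
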