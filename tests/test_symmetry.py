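import copy

import numpy as np
import pytest

from conftest import random_rigid_transform
from trefoilforge import symmetry as sym
from trefoilforge import synthetic as syn
from trefoilforge.structio import structure_from_ca
from trefoilforge.superpose import kabsch


class TestExtractRepeats:
    def test_exact_fixture_pairwise_rmsd_zero(self, exact_c3_repeats):
        coords = [c for c, _ in exact_c3_repeats]
        for i in range(3):
            for j in range(i + 1, 3):
                assert kabsch(coords[i], coords[j]).rmsd < 1e-9

    def test_noise_on_one_repeat_localised(self, exact_c3, rng):
        st = copy.deepcopy(exact_c3)
        for res in st.chain("B"):
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0, 0.5, 3)
        rdef = sym.RepeatDefinition([("A", 1, 47), ("B", 1, 47), ("C", 1, 47)])
        coords = [c for c, _ in sym.extract_repeats(st, rdef)]
        assert kabsch(coords[0], coords[2]).rmsd < 1e-9  # A-C untouched
        assert kabsch(coords[0], coords[1]).rmsd > 0.2
        assert kabsch(coords[1], coords[2]).rmsd > 0.2

    def test_missing_residues_reported(self, exact_c3):
        st = copy.deepcopy(exact_c3)
        del st.chain("B")[10]
        rdef = sym.RepeatDefinition([("A", 1, 47), ("B", 1, 47), ("C", 1, 47)])
        with pytest.raises(Exception, match="gap|missing"):
            sym.extract_repeats(st, rdef)

    def test_unequal_ranges_rejected(self):
        with pytest.raises(ValueError):
            sym.RepeatDefinition([("A", 1, 46), ("A", 49, 94), ("A", 97, 143)])

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            sym.RepeatDefinition([("A", 1, 50), ("A", 40, 89), ("A", 95, 144)])


class TestFitC3Axis:
    def test_exact_fixture_about_z(self, exact_c3_repeats):
        axis = sym.fit_c3_axis([c for c, _ in exact_c3_repeats])
        assert abs(abs(axis.direction[2]) - 1.0) < 1e-6
        assert abs(axis.angle_deg - 120.0) < 1e-6
        # axis passes through the origin of the fixture
        assert np.linalg.norm(axis.point[:2]) < 1e-6

    def test_rigidly_moved_fixture_recovers_moved_axis(self, exact_c3_repeats, rng):
        coords = [c for c, _ in exact_c3_repeats]
        tr = random_rigid_transform(rng)
        moved = [tr.apply(c) for c in coords]
        axis = sym.fit_c3_axis(moved)
        expected = tr.rotation @ np.array([0.0, 0.0, 1.0])
        assert abs(np.dot(axis.direction, expected)) >= 1.0 - 1e-6

    def test_noisy_axis_recovery_within_2_degrees(self):
        errs = []
        for seed in range(20):
            st = syn.make_c3_backbone(syn.TrefoilParams(L=47, noise_sigma=0.3, seed=seed))
            rdef = sym.RepeatDefinition([("A", 1, 47), ("B", 1, 47), ("C", 1, 47)])
            coords = [c for c, _ in sym.extract_repeats(st, rdef)]
            axis = sym.fit_c3_axis(coords)
            errs.append(np.rad2deg(np.arccos(min(abs(axis.direction[2]), 1.0))))
        assert max(errs) < 2.0

    def test_not_threefold_rejected(self, rng):
        base = rng.normal(0, 5, (25, 3))
        from scipy.spatial.transform import Rotation

        r40 = Rotation.from_euler("z", 40, degrees=True).as_matrix()
        repeats = [base, base @ r40.T, base @ (r40 @ r40).T]
        with pytest.raises(sym.NotThreefoldError):
            sym.fit_c3_axis(repeats)


class TestSymmetrize:
    def test_self_consistency_reproduces_fixture(self, exact_c3_repeats):
        coords = [c for c, _ in exact_c3_repeats]
        axis = sym.fit_c3_axis(coords)
        bb = sym.symmetrize(exact_c3_repeats[0], axis)
        np.testing.assert_allclose(bb.ca_coords(), np.vstack(coords), atol=1e-6)

    def test_output_is_exactly_symmetric(self, exact_c3_repeats):
        axis = sym.fit_c3_axis([c for c, _ in exact_c3_repeats])
        bb = sym.symmetrize(exact_c3_repeats[0], axis)
        assert bb.max_asymmetry() < 1e-6

    def test_axis_fit_on_symmetrized_output_gives_exact_120(self, exact_c3_repeats):
        axis = sym.fit_c3_axis([c for c, _ in exact_c3_repeats])
        bb = sym.symmetrize(exact_c3_repeats[0], axis)
        refit = sym.fit_c3_axis([bb.repeat_ca_coords(k) for k in range(3)])
        assert abs(refit.angle_deg - 120.0) < 1e-6

    def test_symmetrize_noisy_template_repeat_rmsd_zero_by_construction(self):
        st = syn.make_c3_backbone(syn.TrefoilParams(L=47, noise_sigma=0.3, seed=3))
        rdef = sym.RepeatDefinition([("A", 1, 47), ("B", 1, 47), ("C", 1, 47)])
        reps = sym.extract_repeats(st, rdef)
        axis = sym.fit_c3_axis([c for c, _ in reps])
        bb = sym.symmetrize(reps[0], axis)
        assert bb.max_asymmetry() < 1e-6

    def test_rigid_search_strictly_improves_clashing_start(self):
        st = syn.make_c3_backbone(syn.TrefoilParams(L=24, radial_offset=6.0))
        rdef = sym.RepeatDefinition([("A", 1, 24), ("B", 1, 24), ("C", 1, 24)])
        reps = sym.extract_repeats(st, rdef)
        axis = sym.fit_c3_axis([c for c, _ in reps])
        plain = sym.symmetrize(reps[0], axis, rigid_search=False)
        obj_plain = sym.interface_objective(plain.repeat_ca_coords(0), plain.repeat_ca_coords(1))
        searched = sym.symmetrize(
            reps[0], axis, rigid_search=True,
            spin_step_deg=10.0, offset_range=1.5, offset_step=0.5,
        )
        obj_searched = sym.interface_objective(
            searched.repeat_ca_coords(0), searched.repeat_ca_coords(1)
        )
        assert obj_searched < obj_plain

    def test_unresolvable_clash_raises_packing_error(self, rng):
        blob = rng.normal(0, 2.0, (25, 3)) + np.array([1.5, 0.0, 0.0])
        axis = sym.SymmetryAxis(np.array([0.0, 0.0, 1.0]), np.zeros(3), 120.0)
        with pytest.raises(sym.PackingError):
            sym.symmetrize((blob, "A" * 25), axis)


class TestConcatenateWithLinkers:
    def test_single_glycine_scheme_gives_143(self):
        rep = "M" + "A" * 46  # 47-residue repeat
        result = sym.concatenate_with_linkers(rep, "G", n=3)
        assert result.length == 143
        assert result.sequence[47] == "G" and result.sequence[95] == "G"  # Gly48, Gly96
        assert result.numbering[48] == ("linker", 0, 1)
        assert result.numbering[96] == ("linker", 1, 1)

    def test_gly_asp_gly_scheme_gives_147(self):
        rep = "W" * 47
        result = sym.concatenate_with_linkers(rep, "GDG", n=3)
        assert result.length == 147
        assert result.sequence[47:50] == "GDG"  # positions 48-50
        assert result.sequence[97:100] == "GDG"  # positions 98-100 (1-based 98..100)
        assert [result.numbering[p][0] for p in range(48, 51)] == ["linker"] * 3

    def test_empty_linker_identity_blocks(self):
        result = sym.concatenate_with_linkers("ACD", "", n=3)
        assert result.sequence == "ACDACDACD"
        assert all(result.numbering[p][0] == "repeat" for p in result.numbering)

    def test_numbering_is_bijection(self):
        result = sym.concatenate_with_linkers("ACDEF", "GG", n=3)
        assert sorted(result.numbering) == list(range(1, result.length + 1))
        images = set(result.numbering.values())
        assert len(images) == result.length


class TestGraftLinker:
    @pytest.fixture
    def base_backbone(self, exact_c3_repeats):
        axis = sym.fit_c3_axis([c for c, _ in exact_c3_repeats])
        return sym.symmetrize(exact_c3_repeats[0], axis)

    def _donor_from_backbone(self, backbone, k):
        from trefoilforge.pipeline import make_synthetic_donor

        return make_synthetic_donor(backbone, k)

    def test_identical_donor_leaves_coordinates_unchanged(self, base_backbone):
        donor, drange = self._donor_from_backbone(base_backbone, 6)
        grafted = sym.graft_linker(base_backbone, donor, drange, 6)
        # regraft from the grafted model itself: linker must be reproduced
        st = grafted.to_structure()
        L = len(grafted.repeat)
        regraft = sym.graft_linker(grafted, st, ("A", L + 1, L + 6), 6)
        before = np.array([r.ca for r in grafted.linker])
        after = np.array([r.ca for r in regraft.linker])
        np.testing.assert_allclose(before, after, atol=1e-6)

    def test_six_residues_carry_donor_provenance(self, base_backbone):
        donor, drange = self._donor_from_backbone(base_backbone, 6)
        grafted = sym.graft_linker(base_backbone, donor, drange, 6)
        chain = grafted.residues()
        donor_res = [(k, r) for k, r in chain if r.provenance == "donor"]
        assert len(donor_res) == 12  # 6 per junction, 2 junctions in the open chain
        for junction in (0, 1):
            assert sum(1 for k, _ in donor_res if k == junction) == 6

    def test_nine_residue_graft_includes_donor_tryptophan(self, base_backbone):
        donor, drange = self._donor_from_backbone(base_backbone, 9)
        grafted = sym.graft_linker(base_backbone, donor, drange, 9)
        linker_seq = "".join(r.aa for r in grafted.linker)
        assert len(linker_seq) == 9 and "W" in linker_seq

    def test_bad_anchor_superposition_raises(self, base_backbone, rng):
        donor, drange = self._donor_from_backbone(base_backbone, 6)
        for res in donor.chain("D"):
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0, 4.0, 3)
        with pytest.raises(sym.GraftError):
            sym.graft_linker(base_backbone, donor, drange, 6)

    def test_graft_preserves_exact_symmetry(self, base_backbone):
        donor, drange = self._donor_from_backbone(base_backbone, 6)
        grafted = sym.graft_linker(base_backbone, donor, drange, 6)
        assert grafted.max_asymmetry() < 1e-6

    def test_invalid_k_rejected(self, base_backbone):
        donor, drange = self._donor_from_backbone(base_backbone, 6)
        with pytest.raises(ValueError):
            sym.graft_linker(base_backbone, donor, drange, 5)


class TestRegularizeBackbone:
    def test_ideal_geometry_does_not_move(self):
        coords, names = syn.ideal_extended_chain(6)
        out, trace = sym.regularize_backbone(coords, names, max_steps=50)
        assert np.abs(out - coords).max() < 1e-6

    def test_stretched_bond_restored_to_ideal(self):
        coords, names = syn.ideal_extended_chain(6)
        coords = coords.copy()
        # stretch the CA-C bond of residue 2 by 0.5 A along its direction
        i, j = 4, 5  # N CA C | N CA C -> indices 3,4,5 are residue 2
        v = coords[j] - coords[i]
        coords[j:] = coords[j:] + 0.5 * v / np.linalg.norm(v)
        out, _ = sym.regularize_backbone(coords, names, max_steps=2000)
        d = np.linalg.norm(out[j] - out[i])
        assert abs(d - sym.IDEAL_BONDS[("CA", "C")]) < 0.02

    def test_objective_strictly_decreases_under_jitter(self, rng):
        coords, names = syn.ideal_extended_chain(8)
        jittered = coords + rng.normal(0, 0.2, coords.shape)
        _, trace = sym.regularize_backbone(jittered, names, max_steps=100)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))
        assert trace[-1] < trace[0]

    def test_symmetric_regularisation_preserves_symmetry(self, exact_c3_repeats):
        axis = sym.fit_c3_axis([c for c, _ in exact_c3_repeats])
        bb = sym.symmetrize(exact_c3_repeats[0], axis)
        out = sym.regularize_symmetric(bb, max_steps=5)
        assert out.max_asymmetry() < 1e-6
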