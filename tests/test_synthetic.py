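import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pcsrefine.geometry import backbone_rmsd
from pcsrefine.structure import BACKBONE_ATOMS
from pcsrefine.synthetic import (
    DistortionSpec,
    JunctionDistortion,
    RepeatSpec,
    VirtualTagSpec,
    apply_distortion,
    build_repeat_protein,
    calibrate_distortion,
    generate_virtual_pcs,
    module_screw,
)
from pcsrefine.tensor import backcalc_pcs_many, fit_components


class TestBuilder:
    def test_single_module_counts(self):
        spec = RepeatSpec(n_internal_modules=1, include_caps=False)
        s = build_repeat_protein(spec)
        assert len(s.residues()) == 42
        backbone = s.atom_mask(atom_names=BACKBONE_ATOMS)
        assert int(backbone.sum()) == 168

    def test_deterministic(self, small_spec):
        a = build_repeat_protein(small_spec)
        b = build_repeat_protein(small_spec)
        assert np.array_equal(a.coords, b.coords)

    def test_consecutive_modules_screw_related(self, small_structure, small_spec):
        """Applying the generating screw to module i superposes it on module
        i+1 to numerical precision (the construction is torsion-periodic)."""
        rot, trans = module_screw(small_structure, small_spec)
        L = small_spec.residues_per_module
        for k in range(small_spec.n_modules - 1):
            mask_a = small_structure.atom_mask(
                [(k * L + 1, (k + 1) * L)], atom_names=["CA"]
            )
            mask_b = small_structure.atom_mask(
                [((k + 1) * L + 1, (k + 2) * L)], atom_names=["CA"]
            )
            moved = small_structure.coords[mask_a] @ rot.T + trans
            rmsd = np.sqrt(
                np.mean(np.sum((moved - small_structure.coords[mask_b]) ** 2, axis=1))
            )
            assert rmsd < 0.01

    def test_zero_twist_is_pure_translation(self):
        spec = RepeatSpec(n_internal_modules=2, include_caps=False, twist=0.0)
        s = build_repeat_protein(spec)
        rot, trans = module_screw(s, spec)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.linalg.norm(trans) > 1.0

    def test_overlapping_helices_rejected(self):
        with pytest.raises(ValueError, match="overlapping helix"):
            RepeatSpec(helix_segments=((1, 15), (12, 26), (29, 40)))

    def test_collapse_detected(self):
        spec = RepeatSpec(n_internal_modules=3, include_caps=False, rise=0.0, twist=0.0)
        with pytest.raises(ValueError, match="steric collapse"):
            build_repeat_protein(spec)


class TestDistortion:
    def test_empty_spec_identity(self, small_structure, small_segmentation):
        out = apply_distortion(small_structure, small_segmentation, DistortionSpec())
        assert np.array_equal(out.coords, small_structure.coords)

    def test_upstream_bitwise_unchanged(self, small_structure, small_segmentation):
        spec = DistortionSpec([JunctionDistortion(2, np.array([0.0, 0.0, 1.0]), 5.0)])
        out = apply_distortion(small_structure, small_segmentation, spec)
        pivot_res = small_segmentation.junction_residue(2)
        upstream = small_structure.residue_numbers <= pivot_res
        assert np.array_equal(out.coords[upstream], small_structure.coords[upstream])
        assert np.abs(out.coords[~upstream] - small_structure.coords[~upstream]).max() > 0.1

    def test_matches_independent_rigid_map(self, small_structure, small_segmentation):
        axis = np.array([0.6, -0.8, 0.0])
        axis /= np.linalg.norm(axis)
        angle = 7.0
        spec = DistortionSpec([JunctionDistortion(1, axis, angle)])
        out = apply_distortion(small_structure, small_segmentation, spec)
        pivot_res = small_segmentation.junction_residue(1)
        pivot = small_structure.position(
            small_structure.single_chain, pivot_res, "CA"
        )
        rot = Rotation.from_rotvec(axis * np.radians(angle)).as_matrix()
        moving = small_structure.residue_numbers > pivot_res
        expected = (small_structure.coords[moving] - pivot) @ rot.T + pivot
        assert np.allclose(out.coords[moving], expected, atol=1e-12)

    def test_preserves_intra_module_distances(self, small_structure, small_segmentation, rng):
        spec = DistortionSpec(
            [
                JunctionDistortion(j, ax / np.linalg.norm(ax), float(rng.uniform(2, 10)))
                for j, ax in zip((1, 2, 3), rng.normal(size=(3, 3)))
            ]
        )
        out = apply_distortion(small_structure, small_segmentation, spec)
        for m in small_segmentation:
            mask = small_structure.atom_mask([(m.first_residue, m.last_residue)])
            a = small_structure.coords[mask]
            b = out.coords[mask]
            da = np.linalg.norm(a[:, None] - a[None], axis=2)
            db = np.linalg.norm(b[:, None] - b[None], axis=2)
            assert np.abs(da - db).max() < 1e-9

    def test_unknown_junction_rejected(self, small_structure, small_segmentation):
        spec = DistortionSpec([JunctionDistortion(9, np.array([0, 0, 1.0]), 5.0)])
        with pytest.raises(ValueError, match="junction 9"):
            apply_distortion(small_structure, small_segmentation, spec)


class TestCalibration:
    def test_zero_target(self, small_structure, small_segmentation):
        spec = calibrate_distortion(small_structure, small_segmentation, 0.0, seed=1)
        assert all(j.angle == 0.0 for j in spec.junctions)

    @pytest.mark.parametrize("mode", ["single_junction", "all_junctions"])
    def test_moderate_target_reached(self, bench_structure, bench_segmentation, mode):
        spec = calibrate_distortion(
            bench_structure, bench_segmentation, 1.9, mode=mode, seed=4
        )
        achieved = backbone_rmsd(
            bench_structure, apply_distortion(bench_structure, bench_segmentation, spec)
        )
        assert 1.8 <= achieved <= 2.0

    def test_rmsd_monotone_in_rotation_magnitude(
        self, small_structure, small_segmentation
    ):
        spec = calibrate_distortion(
            small_structure, small_segmentation, 1.5, mode="all_junctions", seed=2
        )
        values = []
        for scale in np.linspace(0.0, 1.0, 8):
            scaled = DistortionSpec(
                [
                    JunctionDistortion(j.junction, j.axis, j.angle * scale)
                    for j in spec.junctions
                ]
            )
            values.append(
                backbone_rmsd(
                    small_structure,
                    apply_distortion(small_structure, small_segmentation, scaled),
                )
            )
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_unreachable_target(self, small_structure, small_segmentation):
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_distortion(
                small_structure, small_segmentation, 50.0, seed=1, angle_cap=5.0
            )


class TestVirtualPcs:
    def test_full_noiseless_equals_backcalc(self, small_structure, small_tags, small_pcs):
        dataset, truth = small_pcs
        chain = small_structure.single_chain
        for tag in dataset.tags():
            sub = dataset.for_tag(tag)
            pos = np.array(
                [
                    small_structure.position(chain, r.residue_number, r.atom_name)
                    for r in sub.records
                ]
            )
            calc = backcalc_pcs_many(truth[tag], pos)
            assert np.allclose([r.value for r in sub.records], calc, atol=1e-12)

    def test_assignment_fraction_floor_rule(self, small_structure, small_tags):
        tag = small_tags[:1]
        full, _ = generate_virtual_pcs(
            small_structure, tag, assignment_fraction=1.0, seed=3,
            pre_exclusion_radius=0.0,
        )
        n_eligible = len(full.residues())
        ds, _ = generate_virtual_pcs(
            small_structure, tag, assignment_fraction=0.4, seed=3,
            pre_exclusion_radius=0.0,
        )
        assert len(ds.residues()) == int(np.floor(0.4 * n_eligible))
        # H and N of a residue are kept or dropped together
        for res in ds.residues():
            atoms = {r.atom_name for r in ds.records if r.residue_number == res}
            assert atoms == {"H", "N"}

    def test_seed_reproducible(self, small_structure, small_tags):
        a, _ = generate_virtual_pcs(
            small_structure, small_tags, noise_sd=0.05, assignment_fraction=0.5, seed=9
        )
        b, _ = generate_virtual_pcs(
            small_structure, small_tags, noise_sd=0.05, assignment_fraction=0.5, seed=9
        )
        assert a == b

    def test_zero_fraction_rejected(self, small_structure, small_tags):
        with pytest.raises(ValueError, match="fraction"):
            generate_virtual_pcs(small_structure, small_tags, assignment_fraction=0.0)

    def test_missing_anchor_rejected(self, small_structure):
        bad = VirtualTagSpec(tag_id="x", anchor_residue=9999)
        with pytest.raises(ValueError, match="anchor"):
            generate_virtual_pcs(small_structure, [bad])

    def test_offset_tether_scale_enforced(self):
        with pytest.raises(ValueError, match="15 Å"):
            VirtualTagSpec(tag_id="x", anchor_residue=1, offset=(20.0, 0.0, 0.0))

    def test_closed_loop_fit_recovers_truth(self, small_structure, small_pcs):
        dataset, truth = small_pcs
        tag = dataset.tags()[-1]
        fit = fit_components(
            dataset.for_tag(tag), small_structure, truth[tag].metal_position
        )
        scale = np.abs(truth[tag].matrix).max()
        assert np.abs(fit.tensor.matrix - truth[tag].matrix).max() / scale < 1e-6
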