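import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pcsrefine.anneal import (
    AnnealSchedule,
    PerturbAmplitudes,
    anneal,
    calc_ensemble,
    compile_system,
    perturb_start,
    restraint_energy,
)
from pcsrefine.restraints import (
    AtomSelector,
    DistanceRestraint,
    regenerate_scaffold,
)
from pcsrefine.geometry import backbone_rmsd


@pytest.fixture(scope="module")
def system(small_structure, small_segmentation, small_pcs):
    dataset, truth = small_pcs
    restraints = regenerate_scaffold(small_structure, small_segmentation, truth)
    metals = {t: truth[t].metal_position for t in truth}
    return dataset, truth, restraints, metals


def brute_force_energy(structure, metals, restraints, pcs, tensors, segmentation):
    """Independent term-by-term oracle (plain loops, no shared code paths)."""
    from pcsrefine.restraints import dihedral_angle
    from pcsrefine.tensor import backcalc_pcs, DeltaChiTensor

    chain = structure.single_chain

    def pt(sel):
        if sel.is_metal:
            return metals[sel.tag]
        return structure.position(chain, sel.residue, sel.atom)

    e = dict.fromkeys(("upl", "lol", "aco", "pcs", "vdw", "tether"), 0.0)
    for r in restraints.upl + [x for x in restraints.ori if x.kind == "upper"]:
        v = np.linalg.norm(pt(r.a) - pt(r.b)) - r.limit
        if v > 0:
            e["upl"] += restraints.w_upl * r.weight * v * v
    for r in restraints.lol + [x for x in restraints.ori if x.kind == "lower"]:
        v = r.limit - np.linalg.norm(pt(r.a) - pt(r.b))
        if v > 0:
            e["lol"] += restraints.w_lol * r.weight * v * v
    for r in restraints.aco:
        if r.angle == "PHI":
            quad = [(r.residue - 1, "C"), (r.residue, "N"), (r.residue, "CA"), (r.residue, "C")]
        else:
            quad = [(r.residue, "N"), (r.residue, "CA"), (r.residue, "C"), (r.residue + 1, "N")]
        ang = dihedral_angle(*[structure.position(chain, q, a) for q, a in quad])
        dev = abs((ang - r.center + 180.0) % 360.0 - 180.0)
        v = math.radians(dev - r.halfwidth)
        if v > 0:
            e["aco"] += restraints.w_aco * v * v
    for rec in pcs.records:
        t = DeltaChiTensor(metals[rec.tag], tensors[rec.tag].matrix)
        calc = backcalc_pcs(t, structure.position(chain, rec.residue_number, rec.atom_name))
        v = abs(calc - rec.value) - rec.tolerance
        if v > 0:
            e["pcs"] += restraints.w_pcs * rec.weight * v * v
    heavy = [i for i in range(len(structure)) if not structure.atom_names[i].startswith("H")]
    for ii, i in enumerate(heavy):
        for j in heavy[ii + 1 :]:
            if abs(int(structure.residue_numbers[i]) - int(structure.residue_numbers[j])) < 2:
                continue
            v = 2.2 - np.linalg.norm(structure.coords[i] - structure.coords[j])
            if v > 0:
                e["vdw"] += restraints.w_vdw * v * v
    if restraints.tether_reference is not None:
        from pcsrefine.geometry import kabsch_superpose

        all_rows = []
        for m in segmentation:
            rows = np.nonzero(
                (structure.residue_numbers >= m.first_residue)
                & (structure.residue_numbers <= m.last_residue)
            )[0]
            all_rows.extend(rows.tolist())
            ref = restraints.tether_reference[rows]
            cur = structure.coords[rows]
            fitted = kabsch_superpose(cur, ref).apply(ref)
            over = np.maximum(
                np.linalg.norm(cur - fitted, axis=1) - restraints.regularize_cap, 0.0
            )
            e["tether"] += restraints.w_tether * float((over**2).sum())
        # pose prior: one global superposition over the whole covered selection
        ref = restraints.tether_reference[all_rows]
        cur = structure.coords[all_rows]
        fitted = kabsch_superpose(cur, ref).apply(ref)
        over_pose = np.maximum(
            np.linalg.norm(cur - fitted, axis=1) - restraints.regularize_cap, 0.0
        )
        e["tether"] += restraints.w_pose * float((over_pose**2).sum())
    return e


class TestEnergy:
    def test_source_structure_satisfies_restraints(
        self, small_structure, small_segmentation, system
    ):
        dataset, truth, restraints, metals = system
        eb = restraint_energy(
            small_structure, metals, restraints, dataset, truth, small_segmentation
        )
        for term in ("upl", "lol", "aco", "pcs", "tether"):
            assert getattr(eb, term) == 0.0

    def test_single_upl_violation_quadratic(
        self, small_structure, small_segmentation, small_pcs
    ):
        from pcsrefine.restraints import RestraintSet
        from pcsrefine.tensor import PcsDataset

        chain = small_structure.single_chain
        d = float(
            np.linalg.norm(
                small_structure.position(chain, 10, "CA")
                - small_structure.position(chain, 14, "CA")
            )
        )
        rs = RestraintSet(
            upl=[
                DistanceRestraint(
                    AtomSelector(10, "CA"), AtomSelector(14, "CA"), "upper", d - 0.5
                )
            ],
            w_vdw=0.0,
        )
        eb = restraint_energy(
            small_structure, {}, rs, PcsDataset([]), {}, small_segmentation
        )
        assert eb.upl == pytest.approx(0.25, abs=1e-9)
        assert eb.total == pytest.approx(0.25, abs=1e-9)

    def test_matches_bruteforce_oracle_on_perturbed_state(
        self, small_structure, small_segmentation, system
    ):
        dataset, truth, restraints, metals = system
        perturbed = perturb_start(
            small_structure, small_segmentation, PerturbAmplitudes(6.0, 1.0), seed=3
        )
        eb = restraint_energy(
            perturbed, metals, restraints, dataset, truth, small_segmentation
        )
        oracle = brute_force_energy(
            perturbed, metals, restraints, dataset, truth, small_segmentation
        )
        for term in ("upl", "lol", "aco", "pcs", "vdw", "tether"):
            assert getattr(eb, term) == pytest.approx(oracle[term], abs=1e-9), term
        assert eb.total == pytest.approx(sum(oracle.values()), abs=1e-9)

    def test_kernel_matches_reference(self, small_structure, small_segmentation, system):
        from pcsrefine import _kernels

        dataset, truth, restraints, metals = system
        perturbed = perturb_start(
            small_structure, small_segmentation, PerturbAmplitudes(5.0, 0.5), seed=9
        )
        sysc = compile_system(perturbed, restraints, dataset, truth, small_segmentation)
        a = sysc.arrays
        pos = sysc.initial_positions(perturbed, truth)
        pairs = _kernels.build_vdw_pairs(pos, a["vdw_rows"], a["vdw_resn"], a["vdw_rmin"])
        terms = _kernels.energy_terms(
            pos, a["up_i"], a["up_j"], a["up_lim"], a["up_w"],
            a["lo_i"], a["lo_j"], a["lo_lim"], a["lo_w"],
            a["aco_idx"], a["aco_c"], a["aco_h"],
            a["pcs_spin"], a["pcs_tag"], a["pcs_exp"], a["pcs_tol"], a["pcs_w"],
            a["chi"], a["metal_rows"], a["teth_ref"], a["teth_cap"],
            a["mod_start"], a["mod_end"], pairs, a["vdw_rmin"], 1.0, 1.0, a["weights"],
        )
        eb = restraint_energy(
            perturbed, metals, restraints, dataset, truth, small_segmentation
        )
        ref = [eb.upl, eb.lol, eb.aco, eb.pcs, eb.vdw, eb.tether]
        assert np.abs(np.array(terms) - np.array(ref)).max() < 1e-9

    def test_invariant_under_global_rigid_motion(
        self, small_structure, small_segmentation, system, rng
    ):
        dataset, truth, restraints, metals = system
        perturbed = perturb_start(
            small_structure, small_segmentation, PerturbAmplitudes(4.0, 0.5), seed=5
        )
        e0 = restraint_energy(
            perturbed, metals, restraints, dataset, truth, small_segmentation
        )
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        shift = rng.normal(scale=30.0, size=3)
        moved = perturbed.transformed(rot, shift)
        metals2 = {t: rot @ m + shift for t, m in metals.items()}
        truth2 = {
            t: type(truth[t])(rot @ truth[t].metal_position + shift, rot @ truth[t].matrix @ rot.T)
            for t in truth
        }
        e1 = restraint_energy(
            moved, metals2, restraints, dataset, truth2, small_segmentation
        )
        assert e1.total == pytest.approx(e0.total, abs=1e-9)


class TestPerturbStart:
    def test_zero_amplitudes_identity(self, small_structure, small_segmentation):
        out = perturb_start(
            small_structure, small_segmentation, PerturbAmplitudes(0.0, 0.0), seed=1
        )
        assert np.array_equal(out.coords, small_structure.coords)

    def test_same_seed_bit_identical(self, small_structure, small_segmentation):
        a = perturb_start(small_structure, small_segmentation, seed=7)
        b = perturb_start(small_structure, small_segmentation, seed=7)
        assert np.array_equal(a.coords, b.coords)

    def test_nonzero_amplitude_moves_structure(self, small_structure, small_segmentation):
        out = perturb_start(
            small_structure, small_segmentation, PerturbAmplitudes(10.0, 0.0), seed=2
        )
        assert backbone_rmsd(small_structure, out) > 0.1


class TestAnneal:
    def test_zero_steps_returns_start(self, small_structure, small_segmentation, system):
        dataset, truth, restraints, _ = system
        sched = AnnealSchedule.default(0)
        conf, traj = anneal(
            small_structure, restraints, dataset, truth, sched, seed=1,
            segmentation=small_segmentation,
        )
        assert np.array_equal(conf.structure.coords, small_structure.coords)
        assert len(traj.snapshots) == 1
        assert np.array_equal(traj.snapshots[0][1].coords, small_structure.coords)

    def test_same_seed_identical(self, small_structure, small_segmentation, system):
        dataset, truth, restraints, _ = system
        sched = AnnealSchedule.default(400)
        start = perturb_start(small_structure, small_segmentation, seed=4)
        a, ta = anneal(start, restraints, dataset, truth, sched, seed=42,
                       segmentation=small_segmentation)
        b, tb = anneal(start, restraints, dataset, truth, sched, seed=42,
                       segmentation=small_segmentation)
        assert np.array_equal(a.structure.coords, b.structure.coords)
        assert a.energy.total == b.energy.total
        for (sa, xa, ea), (sb, xb, eb) in zip(ta.snapshots, tb.snapshots):
            assert sa == sb and ea == eb
            assert np.array_equal(xa.coords, xb.coords)

    def test_minimization_does_not_increase_energy(
        self, small_structure, small_segmentation, system
    ):
        dataset, truth, restraints, metals = system
        start = perturb_start(
            small_structure, small_segmentation, PerturbAmplitudes(5.0, 0.5), seed=8
        )
        e_start = restraint_energy(
            start, metals, restraints, dataset, truth, small_segmentation,
            vdw_mult=1.0,
        ).total
        sched = AnnealSchedule.default(1500)
        conf, _ = anneal(start, restraints, dataset, truth, sched, seed=3,
                         segmentation=small_segmentation)
        assert conf.energy.total <= e_start + 1e-9

    def test_snapshot_cadence(self, small_structure, small_segmentation, system):
        dataset, truth, restraints, _ = system
        sched = AnnealSchedule.default(1000, snapshot_interval=200)
        _, traj = anneal(
            small_structure, restraints, dataset, truth, sched, seed=2,
            segmentation=small_segmentation,
        )
        steps = [s for s, _, _ in traj.snapshots]
        assert steps[0] == 0
        assert all(b - a == 200 for a, b in zip(steps, steps[1:]))


class TestEnsemble:
    def test_single_start(self, small_structure, small_segmentation, system):
        dataset, truth, restraints, _ = system
        confs = calc_ensemble(
            small_structure, restraints, dataset, truth, n_starts=1,
            schedule=AnnealSchedule.default(300), seed=5,
            segmentation=small_segmentation,
        )
        assert len(confs) == 1

    def test_sorted_by_energy(self, small_structure, small_segmentation, system):
        dataset, truth, restraints, _ = system
        confs = calc_ensemble(
            small_structure, restraints, dataset, truth, n_starts=6,
            schedule=AnnealSchedule.default(300), seed=5,
            segmentation=small_segmentation,
        )
        energies = [c.energy.total for c in confs]
        assert energies == sorted(energies)
        assert {c.provenance["start_index"] for c in confs} == set(range(6))
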