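import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pcsrefine.synthetic import generate_virtual_pcs
from pcsrefine.tensor import (
    DeltaChiTensor,
    PcsDataset,
    PcsRecord,
    backcalc_pcs,
    backcalc_pcs_many,
    consistency_filter,
    fit_components,
    fit_tensor,
    qfactor,
)


def random_tensor(rng, scale=40.0):
    pos = rng.normal(scale=10.0, size=3)
    ax = rng.uniform(5.0, scale) * rng.choice([-1.0, 1.0])
    rh = rng.uniform(0.0, 2.0 / 3.0) * abs(ax) * np.sign(ax)
    euler = rng.uniform(-180.0, 180.0, size=3)
    return DeltaChiTensor.from_axial_rhombic(pos, ax, rh, euler)


class TestBackcalc:
    def test_axial_on_axis(self):
        """Δχ_ax=40, spin on the tensor z-axis at r=20 Å: closed form
        10⁴/(12π·20³)·40·2 = 2.653 ppm."""
        t = DeltaChiTensor.from_axial_rhombic([0, 0, 0], 40.0, 0.0)
        assert backcalc_pcs(t, [0, 0, 20.0]) == pytest.approx(2.653, abs=5e-4)

    def test_magic_angle_vanishes(self):
        t = DeltaChiTensor.from_axial_rhombic([0, 0, 0], 40.0, 0.0)
        theta = np.arccos(1.0 / np.sqrt(3.0))
        for r in (5.0, 12.0, 30.0):
            spin = [r * np.sin(theta), 0.0, r * np.cos(theta)]
            assert backcalc_pcs(t, spin) == pytest.approx(0.0, abs=1e-12)

    def test_equatorial(self):
        t = DeltaChiTensor.from_axial_rhombic([0, 0, 0], 40.0, 0.0)
        assert backcalc_pcs(t, [20.0, 0, 0]) == pytest.approx(-1.326, abs=5e-4)

    def test_pre_cutoff(self):
        t = DeltaChiTensor.from_axial_rhombic([0, 0, 0], 40.0, 0.0)
        with pytest.raises(ValueError, match="PRE"):
            backcalc_pcs(t, [0, 0, 0.3])

    def test_rigid_motion_invariance(self, rng):
        """Simultaneous rigid motion of metal, frame and spin leaves PCS unchanged."""
        for _ in range(20):
            t = random_tensor(rng)
            spin = t.metal_position + rng.normal(scale=15.0, size=3)
            if np.linalg.norm(spin - t.metal_position) < 1.0:
                continue
            ref = backcalc_pcs(t, spin)
            rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
            shift = rng.normal(scale=20.0, size=3)
            t2 = DeltaChiTensor(rot @ t.metal_position + shift, rot @ t.matrix @ rot.T)
            assert backcalc_pcs(t2, rot @ spin + shift) == pytest.approx(ref, rel=1e-9)

    def test_linear_in_components_and_r3_decay(self):
        base = DeltaChiTensor.from_axial_rhombic([0, 0, 0], 10.0, 4.0, (20, 40, 60))
        double = DeltaChiTensor.from_axial_rhombic([0, 0, 0], 20.0, 8.0, (20, 40, 60))
        spin = np.array([4.0, 5.0, 7.0])
        assert backcalc_pcs(double, spin) == pytest.approx(
            2.0 * backcalc_pcs(base, spin), rel=1e-12
        )
        # along a fixed direction, PCS falls off as r^-3
        assert backcalc_pcs(base, 2.0 * spin) == pytest.approx(
            backcalc_pcs(base, spin) / 8.0, rel=1e-12
        )

    def test_vectorized_matches_scalar(self, rng):
        t = random_tensor(rng)
        pts = t.metal_position + rng.normal(scale=12.0, size=(30, 3))
        pts = pts[np.linalg.norm(pts - t.metal_position, axis=1) > 1.0]
        many = backcalc_pcs_many(t, pts)
        for p, v in zip(pts, many):
            assert backcalc_pcs(t, p) == pytest.approx(v, rel=1e-12)


class TestCanonicalization:
    def test_axial_rhombic_round_trip(self, rng):
        for _ in range(50):
            t = random_tensor(rng)
            ratio = t.rhombic / t.axial
            assert -1e-12 <= ratio <= 2.0 / 3.0 + 1e-12
            rebuilt = DeltaChiTensor.from_axial_rhombic(
                t.metal_position, t.axial, t.rhombic, t.euler_zyz_deg
            )
            assert np.allclose(rebuilt.matrix, t.matrix, atol=1e-9)

    def test_traceless_enforced(self):
        with pytest.raises(ValueError, match="traceless"):
            DeltaChiTensor([0, 0, 0], np.eye(3))


class TestFits:
    def test_all_zero_pcs_gives_zero_tensor(self, small_structure):
        chain = small_structure.single_chain
        records = [
            PcsRecord("t", r, "H", 0.0)
            for _, r in small_structure.residues()[:20]
            if small_structure.has_atom(chain, r, "H")
        ]
        fit = fit_components(PcsDataset(records), small_structure, [50.0, 50.0, 50.0])
        assert np.allclose(fit.tensor.matrix, 0.0, atol=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_underdetermined(self, small_structure):
        records = [PcsRecord("t", r, "H", 0.1) for r in (2, 3, 4, 5)]
        with pytest.raises(ValueError, match="underdetermined"):
            fit_components(PcsDataset(records), small_structure, [50.0, 50.0, 50.0])

    def test_components_recover_truth_noiseless(
        self, small_structure, small_tags, small_pcs
    ):
        dataset, truth = small_pcs
        for tag in dataset.tags():
            t_true = truth[tag]
            fit = fit_components(
                dataset.for_tag(tag), small_structure, t_true.metal_position
            )
            scale = np.abs(t_true.matrix).max()
            assert np.abs(fit.tensor.matrix - t_true.matrix).max() / scale < 1e-6
            assert fit.q_factor < 1e-8

    def test_full_fit_recovers_position_and_components(
        self, small_structure, small_pcs
    ):
        dataset, truth = small_pcs
        tag = dataset.tags()[0]
        t_true = truth[tag]
        fit = fit_tensor(
            dataset.for_tag(tag),
            small_structure,
            t_true.metal_position + np.array([3.0, -2.8, 2.4]),  # 4.8 Å off
        )
        assert np.linalg.norm(fit.tensor.metal_position - t_true.metal_position) < 0.2
        assert fit.tensor.axial == pytest.approx(t_true.axial, rel=0.01)
        assert fit.tensor.rhombic == pytest.approx(t_true.rhombic, rel=0.01)

    def test_full_fit_deterministic(self, small_structure, small_pcs):
        dataset, truth = small_pcs
        tag = dataset.tags()[0]
        x0 = truth[tag].metal_position + 2.0
        a = fit_tensor(dataset.for_tag(tag), small_structure, x0)
        b = fit_tensor(dataset.for_tag(tag), small_structure, x0)
        assert np.array_equal(a.tensor.metal_position, b.tensor.metal_position)
        assert np.array_equal(a.tensor.matrix, b.tensor.matrix)

    def test_noise_propagates_to_residuals(self, small_structure, small_tags):
        noise = 0.02
        dataset, truth = generate_virtual_pcs(
            small_structure, small_tags, noise_sd=noise, assignment_fraction=1.0, seed=5
        )
        tag = dataset.tags()[0]
        fit = fit_tensor(
            dataset.for_tag(tag), small_structure, truth[tag].metal_position + 1.0
        )
        rms = float(np.sqrt(np.mean(fit.residuals**2)))
        assert fit.q_factor > 0
        assert rms < 3 * noise


class TestQFactor:
    def test_exact_match_zero(self):
        assert qfactor([1.0, -2.0, 0.3], [1.0, -2.0, 0.3]) == 0.0

    def test_calc_zero_gives_one(self):
        assert qfactor([0.5, -1.5, 2.0], [0.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_worked_example(self):
        assert qfactor([1.0, 2.0], [1.0, 1.0]) == pytest.approx(np.sqrt(1.0 / 5.0))

    def test_matches_bruteforce_on_random_ensembles(self, rng):
        for _ in range(25):
            n_models = int(rng.integers(1, 5))
            n_atoms = int(rng.integers(2, 30))
            exp = rng.normal(size=(n_models, n_atoms))
            calc = exp + rng.normal(scale=0.3, size=exp.shape)
            num = sum(
                (sum(exp[m][i] - calc[m][i] for m in range(n_models))) ** 2
                for i in range(n_atoms)
            )
            den = sum(
                (sum(exp[m][i] for m in range(n_models))) ** 2 for i in range(n_atoms)
            )
            assert qfactor(exp, calc) == pytest.approx(np.sqrt(num / den), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            qfactor([], [])
        with pytest.raises(ValueError, match="denominator"):
            qfactor([0.0, 0.0], [1.0, 1.0])


class TestConsistencyFilter:
    def make(self, pairs):
        records = []
        for res, (h, n) in enumerate(pairs, start=1):
            if h is not None:
                records.append(PcsRecord("t", res, "H", h))
            if n is not None:
                records.append(PcsRecord("t", res, "N", n))
        return PcsDataset(records)

    def test_agreeing_pair_kept(self):
        kept, discarded = consistency_filter(self.make([(0.50, 0.50)]))
        assert len(kept) == 2 and not discarded

    def test_disagreeing_pair_discarded(self):
        kept, discarded = consistency_filter(self.make([(1.00, 1.30)]))
        assert len(kept) == 0
        (tag, res, rel), = discarded
        assert rel == pytest.approx(0.3 / 1.3, abs=1e-9)  # 0.231 > 0.2

    def test_small_shift_floor_keeps_pair(self):
        kept, discarded = consistency_filter(self.make([(0.010, -0.005)]))
        assert len(kept) == 2 and not discarded

    def test_unpaired_records_pass_through(self):
        kept, discarded = consistency_filter(self.make([(0.8, None), (None, -0.4)]))
        assert len(kept) == 2 and not discarded

    def test_filter_is_pure(self):
        ds = self.make([(1.0, 1.3), (0.5, 0.5)])
        before = list(ds.records)
        consistency_filter(ds)
        assert ds.records == before
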