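"""Restrained simulated-annealing Monte Carlo over rigid-module moves.

The sampler replaces torsion-angle dynamics with Metropolis Monte Carlo over
a move set matched to the physics of the problem: repeat modules are nearly
rigid, so the conformational degrees of freedom that matter are junction
re-orientations (solenoid curvature), small rigid module adjustments,
bounded backbone torsion moves and metal pseudo-atom translations.  The
target function mirrors the restraint classes of restrained structure
calculation: quadratic hinge penalties for UPL/LOL/ACO/PCS violations, a
soft-sphere van der Waals repulsion whose radius is scaled per phase by the
schedule multipliers (0.25, 0.25, 0.25, 1.0), and flat-bottom regularization
tethers.

"Temperature" is a unitless Metropolis scale: the schedule stores relative
temperatures and the absolute scale is auto-calibrated per run so that a
relative temperature of 1.0 accepts roughly 80 % of initial moves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pcsrefine import _kernels
from pcsrefine.restraints import RestraintSet, DistanceRestraint
from pcsrefine.structure import ModuleSegmentation, Structure
from pcsrefine.tensor import (
    DeltaChiTensor,
    PcsDataset,
    backcalc_pcs_many,
    qfactor,
    spin_positions,
)

VDW_RMIN = 2.2  # Å, heavy-heavy soft-sphere contact distance
DEFAULT_PHASE_FRACTIONS = (0.25, 0.25, 0.25, 0.25)
DEFAULT_VDW_MULTIPLIERS = (0.25, 0.25, 0.25, 1.0)
DEFAULT_POSE_MULTIPLIERS = (1.0, 1.0, 1.0, 1.0)


@dataclass
class AnnealPhase:
    """One phase of the annealing schedule (temperatures are relative scales)."""

    label: str
    steps: int
    t_start: float
    t_end: float
    vdw_mult: float
    pose_mult: float
    amp_junction_deg: float
    amp_module_rot_deg: float
    amp_module_trans: float
    amp_torsion_deg: float
    amp_metal: float
    amp_tensor_deg: float = 0.0  # free tensor-frame rotations (0: frame rides the module)

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.t_start <= 0 or self.t_end <= 0:
            raise ValueError("temperatures must be > 0")


@dataclass
class AnnealSchedule:
    phases: list[AnnealPhase]
    snapshot_interval: int = 200
    neighbor_interval: int = 100

    @property
    def total_steps(self) -> int:
        return sum(p.steps for p in self.phases)

    @classmethod
    def default(cls, total_steps: int = 5000, snapshot_interval: int = 200) -> "AnnealSchedule":
        """Four-phase schedule: warm start, two cooling phases, cold polish.

        Because every run starts from a perturbation of the current model
        (not a random coil), the schedule opens warm rather than hot and
        spends a quarter of the steps in a near-greedy polish; heavy-atom
        radii are reduced in the first three phases and restored in the last
        (multipliers 0.25, 0.25, 0.25, 1.0).
        """
        temps = [(0.1, 0.02), (0.02, 0.004), (0.004, 5e-4), (5e-4, 5e-5)]
        # (junction°, module rot°, module trans Å, torsion°, metal Å, tensor°);
        # tensor-frame moves default to 0: the tag frame rides its module.
        amps = [
            (4.0, 2.0, 0.3, 2.0, 0.4, 0.0),
            (1.5, 0.8, 0.1, 0.8, 0.15, 0.0),
            (0.5, 0.25, 0.04, 0.25, 0.06, 0.0),
            (0.15, 0.08, 0.012, 0.08, 0.02, 0.0),
        ]
        labels = ["warm", "cool1", "cool2", "polish"]
        steps = [int(round(f * total_steps)) for f in DEFAULT_PHASE_FRACTIONS]
        steps[-1] += total_steps - sum(steps)
        phases = [
            AnnealPhase(
                labels[i], steps[i], *temps[i],
                DEFAULT_VDW_MULTIPLIERS[i], DEFAULT_POSE_MULTIPLIERS[i], *amps[i],
            )
            for i in range(4)
        ]
        return cls(phases=phases, snapshot_interval=snapshot_interval)


@dataclass
class EnergyBreakdown:
    upl: float
    lol: float
    aco: float
    pcs: float
    vdw: float
    tether: float
    max_violations: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.upl + self.lol + self.aco + self.pcs + self.vdw + self.tether

    def __post_init__(self):
        for name in ("upl", "lol", "aco", "pcs", "vdw", "tether"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"negative energy term {name}")


@dataclass
class Conformer:
    structure: Structure
    metal_positions: dict[str, np.ndarray]
    energy: EnergyBreakdown
    per_tag_q: dict[str, float]
    tensors: dict[str, DeltaChiTensor] = field(default_factory=dict)  # as evolved
    provenance: dict = field(default_factory=dict)

    @property
    def mean_q(self) -> float:
        return float(np.mean(list(self.per_tag_q.values())))


@dataclass
class Trajectory:
    snapshots: list[tuple[int, Structure, float]]
    interval: int

    def __post_init__(self):
        steps = [s for s, _, _ in self.snapshots]
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("snapshot step indices must be strictly increasing")


# ---------------------------------------------------------------------------
# system compilation


@dataclass
class CompiledSystem:
    """Flattened restraint arrays shared by every start of an ensemble."""

    structure: Structure
    tag_order: list[str]
    n_at: int
    arrays: dict

    @property
    def n_total(self) -> int:
        return self.n_at + len(self.tag_order)

    def initial_positions(self, structure: Structure, tensors: dict[str, DeltaChiTensor]) -> np.ndarray:
        pos = np.empty((self.n_total, 3))
        pos[: self.n_at] = structure.coords
        for t, tag in enumerate(self.tag_order):
            pos[self.n_at + t] = tensors[tag].metal_position
        return pos


def _resolve(structure: Structure, sel, chain: str, n_at: int, tag_index: dict[str, int]) -> int:
    if sel.is_metal:
        if sel.tag not in tag_index:
            raise ValueError(f"restraint references unknown tag {sel.tag!r}")
        return n_at + tag_index[sel.tag]
    try:
        return structure.atom_index(chain, sel.residue, sel.atom)
    except KeyError:
        raise ValueError(
            f"restraint references atom {sel.atom} of residue {sel.residue} "
            "absent from the structure"
        ) from None


def compile_system(
    structure: Structure,
    restraints: RestraintSet,
    pcs: PcsDataset,
    tensors: dict[str, DeltaChiTensor],
    segmentation: ModuleSegmentation,
) -> CompiledSystem:
    """Flatten restraints, PCS data and move definitions into kernel arrays."""
    for tag in pcs.tags():
        if tag not in tensors:
            raise ValueError(f"missing tensor for tag {tag!r}")
    chain = structure.single_chain
    n_at = len(structure)
    tag_order = list(tensors)
    tag_index = {t: i for i, t in enumerate(tag_order)}

    def dist_arrays(rs: list[DistanceRestraint]):
        i = np.array([_resolve(structure, r.a, chain, n_at, tag_index) for r in rs], dtype=np.int64)
        j = np.array([_resolve(structure, r.b, chain, n_at, tag_index) for r in rs], dtype=np.int64)
        lim = np.array([r.limit for r in rs], dtype=float)
        w = np.array([r.weight for r in rs], dtype=float)
        return i, j, lim, w

    uppers = restraints.upl + [r for r in restraints.ori if r.kind == "upper"]
    lowers = restraints.lol + [r for r in restraints.ori if r.kind == "lower"]
    up_i, up_j, up_lim, up_w = dist_arrays(uppers)
    lo_i, lo_j, lo_lim, lo_w = dist_arrays(lowers)

    residues = sorted(r for _, r in structure.residues())
    res_set = set(residues)
    aco_rows, aco_c, aco_h = [], [], []
    for r in restraints.aco:
        res = r.residue
        if r.angle == "PHI":
            quad = [(res - 1, "C"), (res, "N"), (res, "CA"), (res, "C")]
        else:
            quad = [(res, "N"), (res, "CA"), (res, "C"), (res + 1, "N")]
        try:
            rows = [structure.atom_index(chain, q[0], q[1]) for q in quad]
        except KeyError:
            raise ValueError(
                f"dihedral restraint {r.angle} {res} references missing atoms"
            ) from None
        aco_rows.append(rows)
        aco_c.append(math.radians(r.center))
        aco_h.append(math.radians(r.halfwidth))
    aco_idx = np.array(aco_rows, dtype=np.int64).reshape(-1, 4)
    aco_c = np.array(aco_c, dtype=float)
    aco_h = np.array(aco_h, dtype=float)

    pcs_spin = np.array(
        [structure.atom_index(chain, r.residue_number, r.atom_name) for r in pcs.records],
        dtype=np.int64,
    )
    pcs_tag = np.array([tag_index[r.tag] for r in pcs.records], dtype=np.int64)
    pcs_exp = np.array([r.value for r in pcs.records], dtype=float)
    pcs_tol = np.array([r.tolerance for r in pcs.records], dtype=float)
    pcs_w = np.array([r.weight for r in pcs.records], dtype=float)

    chi = np.stack([tensors[t].matrix for t in tag_order]) if tag_order else np.zeros((0, 3, 3))
    metal_rows = np.array([n_at + i for i in range(len(tag_order))], dtype=np.int64)
    # metals ride with the module their nearest CA belongs to
    ca_rows = [i for i in range(n_at) if structure.atom_names[i] == "CA"]
    ca_xyz = structure.coords[ca_rows]
    metal_anchor_rows = np.array(
        [
            ca_rows[int(np.argmin(np.linalg.norm(ca_xyz - tensors[t].metal_position, axis=1)))]
            for t in tag_order
        ],
        dtype=np.int64,
    )

    if restraints.tether_reference is not None:
        teth_ref = np.asarray(restraints.tether_reference, dtype=float)
        if teth_ref.shape != (n_at, 3):
            raise ValueError("tether reference does not match the structure's atoms")
        w_tether = restraints.w_tether
        w_pose = restraints.w_pose
    else:
        teth_ref = np.zeros((n_at, 3))
        w_tether = 0.0
        w_pose = 0.0

    heavy = [i for i in range(n_at) if not structure.atom_names[i].startswith("H")]
    vdw_rows = np.array(heavy, dtype=np.int64)
    vdw_resn = structure.residue_numbers[vdw_rows]

    weights = np.array(
        [
            restraints.w_upl,
            restraints.w_lol,
            restraints.w_aco,
            restraints.w_pcs,
            restraints.w_vdw,
            w_tether,
            w_pose,
        ],
        dtype=float,
    )

    # --- move definitions ---------------------------------------------------
    resnums = structure.residue_numbers
    first_row = {}
    for i in range(n_at):
        first_row.setdefault(int(resnums[i]), i)

    junc_pivot, junc_start = [], []
    for j in segmentation.junctions():
        pr = segmentation.junction_residue(j)
        if pr in res_set and (pr + 1) in first_row:
            junc_pivot.append(structure.atom_index(chain, pr, "CA"))
            junc_start.append(first_row[pr + 1])
    mod_start, mod_end = [], []
    for m in segmentation:
        rows = np.nonzero(
            (resnums >= m.first_residue) & (resnums <= m.last_residue)
        )[0]
        if rows.size:
            mod_start.append(int(rows[0]))
            mod_end.append(int(rows[-1]) + 1)

    tor_a, tor_b, tor_start = _torsion_moves(structure, residues, chain)

    arrays = dict(
        up_i=up_i, up_j=up_j, up_lim=up_lim, up_w=up_w,
        lo_i=lo_i, lo_j=lo_j, lo_lim=lo_lim, lo_w=lo_w,
        aco_idx=aco_idx, aco_c=aco_c, aco_h=aco_h,
        pcs_spin=pcs_spin, pcs_tag=pcs_tag, pcs_exp=pcs_exp, pcs_tol=pcs_tol, pcs_w=pcs_w,
        chi=chi, metal_rows=metal_rows, metal_anchor_rows=metal_anchor_rows,
        teth_ref=teth_ref, teth_cap=restraints.regularize_cap,
        vdw_rows=vdw_rows, vdw_resn=vdw_resn, vdw_rmin=VDW_RMIN,
        weights=weights, n_at=n_at,
        junc_pivot=np.array(junc_pivot, dtype=np.int64),
        junc_start=np.array(junc_start, dtype=np.int64),
        mod_start=np.array(mod_start, dtype=np.int64),
        mod_end=np.array(mod_end, dtype=np.int64),
        tor_a=tor_a, tor_b=tor_b, tor_start=tor_start,
    )
    return CompiledSystem(structure=structure, tag_order=tag_order, n_at=n_at, arrays=arrays)


def _torsion_moves(structure: Structure, residues: list[int], chain: str):
    """φ/ψ move definitions, valid only for the tail-contiguous atom layout.

    A φ move rotates everything from the residue's C onward about N→CA; a ψ
    move rotates everything from the residue's O onward about CA→C.  This is
    exact for backbone-only layouts (N, [H], CA, C, O per residue); for other
    layouts torsion moves are disabled.
    """
    n_at = len(structure)
    tor_a, tor_b, tor_start = [], [], []
    for idx, res in enumerate(residues):
        try:
            n_row = structure.atom_index(chain, res, "N")
            ca_row = structure.atom_index(chain, res, "CA")
            c_row = structure.atom_index(chain, res, "C")
            o_row = structure.atom_index(chain, res, "O")
        except KeyError:
            return (np.zeros(0, np.int64),) * 3
        if not (n_row < ca_row < c_row < o_row):
            return (np.zeros(0, np.int64),) * 3
        nxt = residues[idx + 1] if idx + 1 < len(residues) else None
        nxt_first = (
            structure.atom_index(chain, nxt, "N") if nxt is not None else n_at
        )
        if o_row + 1 != nxt_first or c_row + 1 != o_row:
            return (np.zeros(0, np.int64),) * 3
        if idx > 0:  # phi defined
            tor_a.append(n_row)
            tor_b.append(ca_row)
            tor_start.append(c_row)
        if nxt is not None:  # psi defined
            tor_a.append(ca_row)
            tor_b.append(c_row)
            tor_start.append(o_row)
    return (
        np.array(tor_a, dtype=np.int64),
        np.array(tor_b, dtype=np.int64),
        np.array(tor_start, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# reference energy (plain numpy, mirrors the kernel term by term)


def restraint_energy(
    structure: Structure,
    metal_positions: dict[str, np.ndarray],
    restraints: RestraintSet,
    pcs: PcsDataset,
    tensors: dict[str, DeltaChiTensor],
    segmentation: ModuleSegmentation | None = None,
    vdw_mult: float = 1.0,
    vdw_rmin: float = VDW_RMIN,
    pose_mult: float = 1.0,
) -> EnergyBreakdown:
    """Energy of a conformer state under the full restraint target function.

    E = w_UPL Σ max(0, d−limit)² + w_LOL Σ max(0, limit−d)²
      + w_ACO Σ (circular violation, rad)² + w_PCS Σ max(0, |δ_calc−δ_exp|−tol)²
      + w_VdW Σ max(0, r_min−d)² + w_tether Σ max(0, |x−x_fit|−cap)²

    The tether deviation |x−x_fit| is measured against the reference module
    rigidly superposed onto the current module (module-internal
    regularization; module poses are unrestrained).  `segmentation` is
    required when the restraint set carries a tether reference.
    """
    for tag in pcs.tags():
        if tag not in tensors:
            raise ValueError(f"missing tensor for tag {tag!r}")
    chain = structure.single_chain

    def point(sel) -> np.ndarray:
        if sel.is_metal:
            return np.asarray(metal_positions[sel.tag], dtype=float)
        return structure.position(chain, sel.residue, sel.atom)

    max_v: dict[str, float] = {}

    def hinge_sum(rs, upper: bool) -> float:
        tot = 0.0
        worst = 0.0
        for r in rs:
            d = float(np.linalg.norm(point(r.a) - point(r.b)))
            v = (d - r.limit) if upper else (r.limit - d)
            if v > 0:
                tot += r.weight * v * v
                worst = max(worst, v)
        return tot, worst

    upl_list = restraints.upl + [r for r in restraints.ori if r.kind == "upper"]
    lol_list = restraints.lol + [r for r in restraints.ori if r.kind == "lower"]
    e_upl, max_v["upl"] = hinge_sum(upl_list, True)
    e_lol, max_v["lol"] = hinge_sum(lol_list, False)

    from pcsrefine.restraints import dihedral_angle

    e_aco = 0.0
    worst = 0.0
    for r in restraints.aco:
        res = r.residue
        if r.angle == "PHI":
            pts = [
                structure.position(chain, res - 1, "C"),
                structure.position(chain, res, "N"),
                structure.position(chain, res, "CA"),
                structure.position(chain, res, "C"),
            ]
        else:
            pts = [
                structure.position(chain, res, "N"),
                structure.position(chain, res, "CA"),
                structure.position(chain, res, "C"),
                structure.position(chain, res + 1, "N"),
            ]
        ang = dihedral_angle(*pts)
        dev = (ang - r.center + 180.0) % 360.0 - 180.0
        v = math.radians(abs(dev) - r.halfwidth)
        if v > 0:
            e_aco += v * v
            worst = max(worst, v)
    max_v["aco"] = worst

    e_pcs = 0.0
    worst = 0.0
    for tag in pcs.tags():
        sub = pcs.for_tag(tag)
        tensor = DeltaChiTensor(np.asarray(metal_positions[tag], dtype=float), tensors[tag].matrix)
        calc = backcalc_pcs_many(tensor, spin_positions(sub, structure))
        for rec, c in zip(sub.records, calc):
            v = abs(c - rec.value) - rec.tolerance
            if v > 0:
                e_pcs += rec.weight * v * v
                worst = max(worst, v)
    max_v["pcs"] = worst

    heavy = [i for i in range(len(structure)) if not structure.atom_names[i].startswith("H")]
    xyz = structure.coords[heavy]
    resn = structure.residue_numbers[heavy]
    from scipy.spatial import cKDTree

    rmin = vdw_rmin * vdw_mult
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(rmin, output_type="ndarray")
    e_vdw = 0.0
    worst = 0.0
    for i, j in pairs:
        if abs(int(resn[i]) - int(resn[j])) < 2:
            continue
        v = rmin - float(np.linalg.norm(xyz[i] - xyz[j]))
        e_vdw += v * v
        worst = max(worst, v)
    max_v["vdw"] = worst

    e_teth = 0.0
    e_pose = 0.0
    worst = 0.0
    if restraints.tether_reference is not None and (
        restraints.w_tether > 0 or restraints.w_pose > 0
    ):
        if segmentation is None:
            raise ValueError("segmentation required for the module-frame tether term")
        from pcsrefine.geometry import kabsch_superpose

        ref = np.asarray(restraints.tether_reference, dtype=float)
        covered = np.zeros(len(structure), dtype=bool)
        for m in segmentation:
            rows = np.nonzero(
                (structure.residue_numbers >= m.first_residue)
                & (structure.residue_numbers <= m.last_residue)
            )[0]
            if rows.size < 3:
                continue
            covered[rows] = True
            cur = structure.coords[rows]
            fit = kabsch_superpose(cur, ref[rows]).apply(ref[rows])
            dev = np.linalg.norm(cur - fit, axis=1)
            over = np.maximum(dev - restraints.regularize_cap, 0.0)
            e_teth += float(np.sum(over**2))
            if over.size:
                worst = max(worst, float(over.max()))
        if restraints.w_pose * pose_mult > 0:
            cur = structure.coords[covered]
            fit = kabsch_superpose(cur, ref[covered]).apply(ref[covered])
            dev = np.linalg.norm(cur - fit, axis=1)
            over = np.maximum(dev - restraints.regularize_cap, 0.0)
            e_pose = float(np.sum(over**2))
    max_v["tether"] = worst

    return EnergyBreakdown(
        upl=restraints.w_upl * e_upl,
        lol=restraints.w_lol * e_lol,
        aco=restraints.w_aco * e_aco,
        pcs=restraints.w_pcs * e_pcs,
        vdw=restraints.w_vdw * e_vdw,
        tether=(restraints.w_tether * e_teth + restraints.w_pose * pose_mult * e_pose)
        if restraints.tether_reference is not None
        else 0.0,
        max_violations=max_v,
    )


# ---------------------------------------------------------------------------
# starting-structure perturbation


@dataclass
class PerturbAmplitudes:
    """Start-structure diversity: mainly junction (curvature) space, with a
    small torsion jitter — the sampler's productive degrees of freedom."""

    junction_deg: float = 3.0
    torsion_deg: float = 0.2

    def __post_init__(self):
        if self.junction_deg < 0 or self.torsion_deg < 0:
            raise ValueError("amplitudes must be >= 0")


def perturb_start(
    model: Structure,
    segmentation: ModuleSegmentation,
    amplitudes: PerturbAmplitudes | None = None,
    seed: int = 0,
) -> Structure:
    """Randomly perturbed copy of the model: junction rotations plus torsion jitter.

    Plays the sampling role of random start structures: each annealing run
    begins from a differently perturbed copy of the current model.
    Deterministic in `seed`; zero amplitudes return the model unchanged.
    """
    amp = amplitudes or PerturbAmplitudes()
    rng = np.random.default_rng(seed)
    coords = model.coords.copy()
    chain = model.single_chain
    resnums = model.residue_numbers

    def rot(axis, angle_deg):
        from scipy.spatial.transform import Rotation

        return Rotation.from_rotvec(axis * math.radians(angle_deg)).as_matrix()

    if amp.junction_deg > 0:
        for j in segmentation.junctions():
            pr = segmentation.junction_residue(j)
            pivot = coords[model.atom_index(chain, pr, "CA")].copy()
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(-amp.junction_deg, amp.junction_deg)
            moving = resnums > pr
            coords[moving] = (coords[moving] - pivot) @ rot(axis, ang).T + pivot
    if amp.torsion_deg > 0:
        residues = sorted(r for _, r in model.residues())
        # row order per residue must put C before O before the next residue
        for idx, res in enumerate(residues[:-1]):
            for angle_name in ("PHI", "PSI"):
                if angle_name == "PHI" and idx == 0:
                    continue
                try:
                    if angle_name == "PHI":
                        a = coords[model.atom_index(chain, res, "N")]
                        b_row = model.atom_index(chain, res, "CA")
                        start_row = model.atom_index(chain, res, "C")
                    else:
                        a = coords[model.atom_index(chain, res, "CA")]
                        b_row = model.atom_index(chain, res, "C")
                        start_row = model.atom_index(chain, res, "O")
                except KeyError:
                    continue
                b = coords[b_row]
                axis = b - a
                axis /= np.linalg.norm(axis)
                ang = rng.uniform(-amp.torsion_deg, amp.torsion_deg)
                tail = slice(start_row, len(coords))
                coords[tail] = (coords[tail] - b) @ rot(axis, ang).T + b
    return model.with_coords(coords)


# ---------------------------------------------------------------------------
# annealing


def anneal(
    start: Structure,
    restraints: RestraintSet,
    pcs: PcsDataset,
    tensors: dict[str, DeltaChiTensor],
    schedule: AnnealSchedule,
    seed: int = 0,
    segmentation: ModuleSegmentation | None = None,
    system: CompiledSystem | None = None,
) -> tuple[Conformer, Trajectory]:
    """One annealing run; returns the lowest-energy state visited.

    `segmentation` defines the rigid-module move set (required unless a
    pre-compiled `system` is passed).  Deterministic in `seed`.
    """
    if system is None:
        if segmentation is None:
            raise ValueError("segmentation required to compile the move set")
        system = compile_system(start, restraints, pcs, tensors, segmentation)
    a = system.arrays
    pos0 = system.initial_positions(start, tensors)

    phases = schedule.phases
    kw = dict(
        phase_steps=np.array([p.steps for p in phases], dtype=np.int64),
        phase_t0=np.array([p.t_start for p in phases], dtype=float),
        phase_t1=np.array([p.t_end for p in phases], dtype=float),
        phase_vdw=np.array([p.vdw_mult for p in phases], dtype=float),
        phase_pose=np.array([p.pose_mult for p in phases], dtype=float),
        amp_junc=np.array([math.radians(p.amp_junction_deg) for p in phases], dtype=float),
        amp_mod_rot=np.array([math.radians(p.amp_module_rot_deg) for p in phases], dtype=float),
        amp_mod_trans=np.array([p.amp_module_trans for p in phases], dtype=float),
        amp_tor=np.array([math.radians(p.amp_torsion_deg) for p in phases], dtype=float),
        amp_metal=np.array([p.amp_metal for p in phases], dtype=float),
        amp_tensor=np.array([math.radians(p.amp_tensor_deg) for p in phases], dtype=float),
    )
    (
        best_pos,
        best_chi,
        best_terms,
        traj,
        traj_steps,
        traj_energy,
        accepts,
        t0_scale,
    ) = _kernels.run_anneal(
        pos0,
        a["up_i"], a["up_j"], a["up_lim"], a["up_w"],
        a["lo_i"], a["lo_j"], a["lo_lim"], a["lo_w"],
        a["aco_idx"], a["aco_c"], a["aco_h"],
        a["pcs_spin"], a["pcs_tag"], a["pcs_exp"], a["pcs_tol"], a["pcs_w"],
        a["chi"], a["metal_rows"], a["metal_anchor_rows"],
        a["teth_ref"], a["teth_cap"],
        a["vdw_rows"], a["vdw_resn"], a["vdw_rmin"],
        a["weights"], a["n_at"],
        a["junc_pivot"], a["junc_start"],
        a["mod_start"], a["mod_end"],
        a["tor_a"], a["tor_b"], a["tor_start"],
        kw["phase_steps"], kw["phase_t0"], kw["phase_t1"], kw["phase_vdw"],
        kw["phase_pose"], kw["amp_junc"], kw["amp_mod_rot"], kw["amp_mod_trans"], kw["amp_tor"],
        kw["amp_metal"], kw["amp_tensor"],
        schedule.snapshot_interval if schedule.snapshot_interval else 0,
        schedule.neighbor_interval,
        int(seed) % (2**31),
    )
    for p_idx, p in enumerate(phases):
        if p.steps > 0 and accepts[p_idx] == 0:
            warnings.warn(
                f"no move accepted in phase {p.label!r} "
                "(pathological energy surface or vanishing temperature)",
                RuntimeWarning,
                stacklevel=2,
            )

    n_at = system.n_at
    final = start.with_coords(best_pos[:n_at].copy())
    metals = {
        tag: best_pos[n_at + i].copy() for i, tag in enumerate(system.tag_order)
    }
    evolved = {
        tag: DeltaChiTensor(metals[tag], 0.5 * (best_chi[i] + best_chi[i].T))
        for i, tag in enumerate(system.tag_order)
    }
    names = ("upl", "lol", "aco", "pcs", "vdw", "tether")
    breakdown = EnergyBreakdown(**{n: float(v) for n, v in zip(names, best_terms)})
    per_tag_q = {}
    for tag in pcs.tags():
        sub = pcs.for_tag(tag)
        calc = backcalc_pcs_many(evolved[tag], spin_positions(sub, final))
        per_tag_q[tag] = qfactor(np.array([r.value for r in sub.records]), calc)
    conformer = Conformer(
        structure=final,
        metal_positions=metals,
        energy=breakdown,
        per_tag_q=per_tag_q,
        tensors=evolved,
        provenance={"seed": int(seed), "t0_scale": float(t0_scale)},
    )
    snapshots = [
        (int(traj_steps[k]), start.with_coords(traj[k, :n_at].copy()), float(traj_energy[k]))
        for k in range(traj.shape[0])
    ]
    return conformer, Trajectory(snapshots=snapshots, interval=schedule.snapshot_interval)


def calc_ensemble(
    model: Structure,
    restraints: RestraintSet,
    pcs: PcsDataset,
    tensors: dict[str, DeltaChiTensor],
    n_starts: int,
    schedule: AnnealSchedule,
    seed: int = 0,
    segmentation: ModuleSegmentation | None = None,
    perturb_amplitudes: PerturbAmplitudes | None = None,
) -> list[Conformer]:
    """Independent annealing runs from perturbed starts, ranked by energy.

    Child seeds are derived from the master seed; the returned list is
    sorted ascending by total energy with ties broken by start index.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if segmentation is None:
        raise ValueError("segmentation required")
    system = compile_system(model, restraints, pcs, tensors, segmentation)
    child = np.random.SeedSequence(seed).generate_state(2 * n_starts) % (2**31)
    conformers = []
    for k in range(n_starts):
        start_k = perturb_start(model, segmentation, perturb_amplitudes, seed=int(child[2 * k]))
        conf, _ = anneal(
            start_k, restraints, pcs, tensors, schedule,
            seed=int(child[2 * k + 1]), system=system,
        )
        conf.provenance["start_index"] = k
        conf.provenance["master_seed"] = int(seed)
        conformers.append(conf)
    conformers.sort(key=lambda c: (c.energy.total, c.provenance["start_index"]))
    return conformers
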