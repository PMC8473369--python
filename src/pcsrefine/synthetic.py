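"""Idealized α-solenoid repeat proteins, junction distortions and virtual PCSs.

The generator emulates the geometry of designed Armadillo-type repeat
proteins: N three-helix internal modules (M1..Mn) flanked by capping modules
(Y, A), stacked along a superhelix.  The backbone (N, H, CA, C, O) is built
by internal-coordinate chain construction with ideal bond geometry and a
torsion pattern that repeats every module, so consecutive modules are
related by one exact screw transform (the emergent superhelical twist and
rise).  The twist/rise can be overridden, which re-stacks rigid copies of
the module template along a modified screw.

Distortion operators ("twisting" the solenoid at inter-module junctions)
and calibrated distortions reproduce, programmatically, the kind of
mis-curved starting models the refinement protocol must correct.  Virtual
PCS datasets are produced from template Δχ-tensors placed at tag sites on
the module surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from pcsrefine.geometry import backbone_rmsd, kabsch_superpose
from pcsrefine.structure import ModuleSegmentation, Structure
from pcsrefine.tensor import DeltaChiTensor, PcsDataset, PcsRecord, backcalc_pcs_many

# Ideal backbone geometry (Engh/Huber-like values, Å and degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.020
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_N_H = 119.3
OMEGA = 180.0

HELIX_PHI_PSI = (-60.0, -45.0)
# Per-loop-residue turn torsions (pattern order), chosen so the three
# 12-residue helices close into a compact module (Cα radius of gyration
# ~9 Å) and modules stack on a superhelix of ~49° twist and ~6 Å rise per
# module without steric collapse.
DEFAULT_LOOP_TORSIONS = (
    (-90.0, 0.0),
    (-120.0, 130.0),
    (-140.0, 160.0),
    (-60.0, -30.0),
    (-75.0, 160.0),
    (-120.0, 130.0),
)


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Position atom d given bond d-c, angle d-c-b and torsion d-c-b-a (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class RepeatSpec:
    """Geometry of an idealized α-solenoid repeat protein.

    ``twist`` / ``rise`` default to ``None`` — the natural screw that the
    periodic torsion pattern generates.  Overriding them re-stacks rigid
    module copies along the modified screw (slightly straining the junction
    peptide bonds, which is intended: it is how curvature variants are made).
    """

    n_internal_modules: int = 4
    residues_per_module: int = 42
    helix_segments: Sequence[tuple[int, int]] = ((1, 12), (15, 26), (29, 40))
    helix_phi_psi: tuple[float, float] = HELIX_PHI_PSI
    loop_torsions: Sequence[tuple[float, float]] = DEFAULT_LOOP_TORSIONS
    twist: float | None = None  # degrees per module; None = natural
    rise: float | None = None  # Å per module; None = natural
    include_caps: bool = True
    include_amide_h: bool = True

    def __post_init__(self):
        if self.n_internal_modules < 1:
            raise ValueError("n_internal_modules must be >= 1")
        if self.twist is not None and not -180.0 < self.twist <= 180.0:
            raise ValueError("twist must lie in (-180, 180]")
        segs = sorted(self.helix_segments)
        for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
            if b0 <= a1:
                raise ValueError(f"overlapping helix definitions: {(a0, a1)}, {(b0, b1)}")
        for s, e in segs:
            if not (1 <= s <= e <= self.residues_per_module):
                raise ValueError(f"helix segment {(s, e)} outside the module")

    @property
    def n_modules(self) -> int:
        return self.n_internal_modules + (2 if self.include_caps else 0)

    @property
    def n_residues(self) -> int:
        return self.n_modules * self.residues_per_module

    def module_torsions(self) -> list[tuple[float, float]]:
        """Per-residue (φ, ψ) pattern of one module.

        Helix residues take `helix_phi_psi`; loop residues cycle through
        `loop_torsions` in sequence order.
        """
        in_helix = np.zeros(self.residues_per_module, dtype=bool)
        for s, e in self.helix_segments:
            in_helix[s - 1 : e] = True
        out: list[tuple[float, float]] = []
        k = 0
        for h in in_helix:
            if h:
                out.append(self.helix_phi_psi)
            else:
                out.append(tuple(self.loop_torsions[k % len(self.loop_torsions)]))
                k += 1
        return out

    def segmentation(self) -> ModuleSegmentation:
        return ModuleSegmentation.uniform(
            self.n_internal_modules, self.residues_per_module, self.include_caps
        )


def _build_chain(torsions: list[tuple[float, float]], include_h: bool) -> Structure:
    """NeRF construction of a poly-Ala backbone from a (φ, ψ) list."""
    n_res = len(torsions)
    pos: dict[tuple[int, str], np.ndarray] = {}
    # Seed the first three atoms in a canonical frame.
    pos[(1, "N")] = np.array([0.0, 0.0, 0.0])
    pos[(1, "CA")] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    pos[(1, "C")] = pos[(1, "CA")] + BOND_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(1, n_res + 1):
        phi, psi = torsions[i - 1]
        if i > 1:
            pos[(i, "C")] = place_atom(
                pos[(i - 1, "C")], pos[(i, "N")], pos[(i, "CA")], BOND_CA_C, ANGLE_N_CA_C, phi
            )
        if i < n_res:
            pos[(i + 1, "N")] = place_atom(
                pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")], BOND_C_N, ANGLE_CA_C_N, psi
            )
            pos[(i + 1, "CA")] = place_atom(
                pos[(i, "CA")], pos[(i, "C")], pos[(i + 1, "N")], BOND_N_CA, ANGLE_C_N_CA, OMEGA
            )
        # Carbonyl O: anti to the next amide nitrogen (ψ + 180 about CA-C).
        pos[(i, "O")] = place_atom(
            pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")], BOND_C_O, ANGLE_CA_C_O, psi + 180.0
        )
        if include_h:
            if i > 1:
                # Amide H anti to the carbonyl O across the peptide bond.
                pos[(i, "H")] = place_atom(
                    pos[(i - 1, "CA")], pos[(i - 1, "C")], pos[(i, "N")],
                    BOND_N_H, ANGLE_C_N_H, 0.0,
                )
            else:
                pos[(i, "H")] = place_atom(
                    pos[(1, "C")], pos[(1, "CA")], pos[(1, "N")], BOND_N_H, ANGLE_C_N_H, 180.0
                )
    chains, resnums, resnames, atnames, coords = [], [], [], [], []
    atom_order = ("N", "H", "CA", "C", "O") if include_h else ("N", "CA", "C", "O")
    for i in range(1, n_res + 1):
        for atom in atom_order:
            chains.append("A")
            resnums.append(i)
            resnames.append("ALA")
            atnames.append(atom)
            coords.append(pos[(i, atom)])
    return Structure(chains, resnums, resnames, atnames, np.array(coords))


def _screw_decompose(rot: np.ndarray, trans: np.ndarray):
    """Decompose a rigid map x ↦ Rx + t into screw (axis u, point p, angle, rise)."""
    rv = Rotation.from_matrix(rot).as_rotvec()
    angle = float(np.linalg.norm(rv))
    if angle < 1e-12:
        u = np.array([0.0, 0.0, 1.0])
        tn = float(np.linalg.norm(trans))
        u = trans / tn if tn > 0 else u
        return u, np.zeros(3), 0.0, tn
    u = rv / angle
    rise = float(trans @ u)
    p, *_ = np.linalg.lstsq(np.eye(3) - rot, trans - rise * u, rcond=None)
    return u, p, angle, rise


def _screw_transform(u: np.ndarray, p: np.ndarray, angle: float, rise: float):
    rot = Rotation.from_rotvec(u * angle).as_matrix()
    trans = p - rot @ p + rise * u
    return rot, trans


def module_screw(structure: Structure, spec: RepeatSpec) -> tuple[np.ndarray, np.ndarray]:
    """The generating screw transform mapping module i onto module i+1.

    Computed from the Cα traces of the first two modules (the N-terminal
    amide proton has no preceding peptide plane, so all-atom superposition
    would be biased by its arbitrary placement).
    """
    L = spec.residues_per_module
    m1 = structure.coords[structure.atom_mask([(1, L)], atom_names=["CA"])]
    m2 = structure.coords[structure.atom_mask([(L + 1, 2 * L)], atom_names=["CA"])]
    sup = kabsch_superpose(m2, m1)
    return sup.rotation, sup.translation


def build_repeat_protein(spec: RepeatSpec) -> Structure:
    """Backbone structure of the idealized solenoid described by `spec`."""
    torsions = spec.module_torsions() * spec.n_modules
    chain = _build_chain(torsions, spec.include_amide_h)

    if spec.twist is not None or spec.rise is not None:
        rot, trans = module_screw(chain, spec)
        u, p, angle, rise = _screw_decompose(rot, trans)
        new_angle = math.radians(spec.twist) if spec.twist is not None else angle
        new_rise = spec.rise if spec.rise is not None else rise
        rot2, trans2 = _screw_transform(u, p, new_angle, new_rise)
        L = spec.residues_per_module
        coords = chain.coords.copy()
        template = chain.coords[chain.atom_mask(residue_ranges=[(1, L)])]
        block = template
        per_mod = template.shape[0]
        for k in range(1, spec.n_modules):
            block = block @ rot2.T + trans2
            coords[k * per_mod : (k + 1) * per_mod] = block
        chain = chain.with_coords(coords)

    _check_collapse(chain, spec)
    return chain


def _check_collapse(structure: Structure, spec: RepeatSpec) -> None:
    """Reject geometries where non-adjacent modules collide (Cα-Cα < 2 Å)."""
    L = spec.residues_per_module
    ca = np.array(
        [
            structure.position("A", r, "CA")
            for r in range(1, spec.n_residues + 1)
        ]
    )
    mod_index = (np.arange(spec.n_residues)) // L
    for i in range(spec.n_modules):
        for j in range(i + 2, spec.n_modules):
            d = np.linalg.norm(
                ca[mod_index == i][:, None, :] - ca[mod_index == j][None, :, :], axis=2
            )
            if d.min() < 2.0:
                raise ValueError(
                    f"steric collapse: modules {i + 1} and {j + 1} overlap "
                    f"(min Cα-Cα {d.min():.2f} Å)"
                )


# ---------------------------------------------------------------------------
# distortions


@dataclass(frozen=True)
class JunctionDistortion:
    junction: int  # 1 .. n_modules - 1
    axis: np.ndarray  # unit vector
    angle: float  # degrees
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(ax)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("axis must be a unit vector")
        object.__setattr__(self, "axis", ax / norm)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )


@dataclass
class DistortionSpec:
    """Rigid 'twists' applied at inter-module junctions."""

    junctions: list[JunctionDistortion] = field(default_factory=list)


def apply_distortion(
    structure: Structure, segmentation: ModuleSegmentation, spec: DistortionSpec
) -> Structure:
    """Rigidly transform everything downstream of each listed junction.

    The pivot is the Cα of the junction's last upstream residue (its current,
    possibly already-moved position — junctions are applied in ascending
    order, so distortions compose downstream).  Upstream coordinates are
    bit-identical to the input.
    """
    n_junc = len(segmentation) - 1
    for d in spec.junctions:
        if not 1 <= d.junction <= n_junc:
            raise ValueError(f"junction {d.junction} outside segmentation (1..{n_junc})")
    coords = structure.coords.copy()
    chain = structure.single_chain
    resnums = structure.residue_numbers
    for d in sorted(spec.junctions, key=lambda x: x.junction):
        pivot_res = segmentation.junction_residue(d.junction)
        pivot_row = structure.atom_index(chain, pivot_res, "CA")
        pivot = coords[pivot_row].copy()
        rot = Rotation.from_rotvec(d.axis * math.radians(d.angle)).as_matrix()
        moving = resnums > pivot_res
        coords[moving] = (coords[moving] - pivot) @ rot.T + pivot + d.translation
    return structure.with_coords(coords)


def calibrate_distortion(
    structure: Structure,
    segmentation: ModuleSegmentation,
    target_rmsd: float,
    mode: str = "single_junction",
    seed: int = 0,
    angle_cap: float = 30.0,
    rmsd_tolerance: float = 0.1,
) -> DistortionSpec:
    """Find junction rotations reaching a target full-backbone RMSD.

    Random rotation axes are drawn once from `seed`; a bisection on the
    common rotation magnitude (capped at `angle_cap` degrees) brings the
    achieved RMSD within ± `rmsd_tolerance` Å of `target_rmsd`.  ``mode``
    twists either one central junction (``single_junction``) or every
    junction (``all_junctions``) — the two kinds of mis-curved model the
    refinement benchmark uses.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be >= 0")
    rng = np.random.default_rng(seed)
    n_junc = len(segmentation) - 1
    if n_junc < 1:
        raise ValueError("segmentation has no junctions")
    if mode == "single_junction":
        junctions = [max(1, (n_junc + 1) // 2)]
    elif mode == "all_junctions":
        junctions = list(range(1, n_junc + 1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    axes = rng.normal(size=(len(junctions), 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)

    def spec_at(scale: float) -> DistortionSpec:
        return DistortionSpec(
            [
                JunctionDistortion(j, ax, scale * angle_cap)
                for j, ax in zip(junctions, axes)
            ]
        )

    def rmsd_at(scale: float) -> float:
        return backbone_rmsd(structure, apply_distortion(structure, segmentation, spec_at(scale)))

    if target_rmsd == 0:
        return spec_at(0.0)
    hi_rmsd = rmsd_at(1.0)
    if hi_rmsd < target_rmsd - rmsd_tolerance:
        raise ValueError(
            f"target {target_rmsd} Å unreachable within ±{angle_cap}° "
            f"(max achievable {hi_rmsd:.2f} Å)"
        )
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = rmsd_at(mid)
        if abs(val - target_rmsd) <= rmsd_tolerance * 0.5:
            return spec_at(mid)
        if val < target_rmsd:
            lo = mid
        else:
            hi = mid
    return spec_at(0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# virtual PCS data


@dataclass
class VirtualTagSpec:
    """A virtual paramagnetic tag site with its template Δχ-tensor.

    The metal offset and the tensor orientation are expressed in the local
    backbone frame of the anchor residue (origin at Cα, x along N→C), so the
    tag follows the structure under rigid motion.  Template components are in
    10⁻³² m³, the scale of Tm-DOTA-type tags.
    """

    tag_id: str
    anchor_residue: int
    offset: Sequence[float] = (12.0, 3.0, 2.0)  # Å, local frame
    axial: float = 40.0
    rhombic: float = 8.0
    euler_zyz_deg: Sequence[float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if np.linalg.norm(np.asarray(self.offset, dtype=float)) > 15.0:
            raise ValueError("metal offset exceeds the 15 Å tag-tether scale")


def _anchor_frame(structure: Structure, residue: int) -> tuple[np.ndarray, np.ndarray]:
    """(origin, 3x3 frame matrix) of the anchor residue's backbone frame."""
    chain = structure.single_chain
    try:
        n = structure.position(chain, residue, "N")
        ca = structure.position(chain, residue, "CA")
        c = structure.position(chain, residue, "C")
    except KeyError:
        raise ValueError(f"tag anchor residue {residue} missing backbone atoms") from None
    e1 = c - n
    e1 = e1 / np.linalg.norm(e1)
    v = ca - 0.5 * (n + c)
    v = v - (v @ e1) * e1
    e2 = v / np.linalg.norm(v)
    e3 = np.cross(e1, e2)
    return ca, np.column_stack([e1, e2, e3])


def true_tensor(structure: Structure, tag: VirtualTagSpec) -> DeltaChiTensor:
    """Global-frame Δχ-tensor of a virtual tag on a given structure."""
    origin, frame = _anchor_frame(structure, tag.anchor_residue)
    metal = origin + frame @ np.asarray(tag.offset, dtype=float)
    local = DeltaChiTensor.from_axial_rhombic(
        metal, tag.axial, tag.rhombic, tag.euler_zyz_deg
    )
    return DeltaChiTensor(metal, frame @ local.matrix @ frame.T)


def default_tags(
    structure: Structure, segmentation: ModuleSegmentation
) -> list[VirtualTagSpec]:
    """Three tag sites spread over the solenoid (first/middle internal module
    and C-cap), mirroring typical attachment-site choices, with the metal
    offset pointing away from the solenoid core."""
    labels = segmentation.labels
    internals = [l for l in labels if l.startswith("M")]
    picks = []
    if internals:
        picks.append((internals[0], 18))
        if len(internals) >= 3:
            picks.append((internals[len(internals) // 2], 21))
    if "A" in labels:
        picks.append(("A", 21))
    while len(picks) < 3 and internals:
        picks.append((internals[-1], 10 + 3 * len(picks)))
    centroid = structure.coords.mean(axis=0)
    tags = []
    eulers = [(0.0, 0.0, 0.0), (40.0, 55.0, 20.0), (110.0, 35.0, 70.0)]
    for i, (label, pos_in_module) in enumerate(picks[:3]):
        mod = segmentation[label]
        residue = min(mod.first_residue + pos_in_module - 1, mod.last_residue)
        origin, frame = _anchor_frame(structure, residue)
        outward = origin - centroid
        outward /= np.linalg.norm(outward)
        offset_local = frame.T @ (12.0 * outward)
        tags.append(
            VirtualTagSpec(
                tag_id=f"tag{i + 1}",
                anchor_residue=residue,
                offset=tuple(offset_local),
                axial=40.0,
                rhombic=8.0,
                euler_zyz_deg=eulers[i % len(eulers)],
            )
        )
    return tags


def generate_virtual_pcs(
    structure: Structure,
    tags: Sequence[VirtualTagSpec],
    noise_sd: float = 0.0,
    assignment_fraction: float = 1.0,
    seed: int = 0,
    tolerance: float = 0.02,
    pre_exclusion_radius: float = 10.0,
    proline_residues: Sequence[int] = (),
) -> tuple[PcsDataset, dict[str, DeltaChiTensor]]:
    """Virtual PCS dataset from template tensors, plus the true tensors.

    For every tag, each eligible amide (residues with both H and N, not
    proline, farther than `pre_exclusion_radius` from the metal — closer
    spins are PRE-broadened and unobservable) receives a back-calculated
    ¹H and ¹⁵N PCS plus Gaussian noise of `noise_sd` ppm.  Partial
    assignment keeps ``floor(assignment_fraction × n_eligible)`` residues
    per tag, sampled without replacement; H and N of a residue are kept or
    dropped together.  Deterministic in `seed`.
    """
    if not 0.0 < assignment_fraction <= 1.0:
        raise ValueError("assignment_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    chain = structure.single_chain
    prolines = set(proline_residues)
    records: list[PcsRecord] = []
    tensors: dict[str, DeltaChiTensor] = {}
    for tag in tags:
        tensor = true_tensor(structure, tag)
        tensors[tag.tag_id] = tensor
        eligible = []
        for _, res in structure.residues():
            if res in prolines:
                continue
            if not (structure.has_atom(chain, res, "H") and structure.has_atom(chain, res, "N")):
                continue
            h = structure.position(chain, res, "H")
            if np.linalg.norm(h - tensor.metal_position) < pre_exclusion_radius:
                continue
            eligible.append(res)
        n_keep = int(math.floor(assignment_fraction * len(eligible)))
        if n_keep < 1:
            raise ValueError("assignment fraction leaves no residues")
        kept = sorted(rng.choice(eligible, size=n_keep, replace=False).tolist())
        pos = np.array(
            [
                [structure.position(chain, r, a) for a in ("H", "N")]
                for r in kept
            ]
        ).reshape(-1, 3)
        vals = backcalc_pcs_many(tensor, pos)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        for i, res in enumerate(kept):
            records.append(PcsRecord(tag.tag_id, res, "H", float(vals[2 * i]), tolerance))
            records.append(PcsRecord(tag.tag_id, res, "N", float(vals[2 * i + 1]), tolerance))
    return PcsDataset(records), tensors
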