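"""Scaffold, metal-position and regularization restraints.

The refinement protocol keeps each repeat module close to its canonical
geometry while PCSs re-orient modules relative to each other.  The scaffold
is expressed as:

* **UPL** — upper distance limits on intra-module atom pairs in the
  2.5–5.0 Å range, +0.5 Å tolerance;
* **ACO** — φ/ψ dihedral restraints at the model values ±5°, applied across
  the entire sequence;
* **ORI** — upper+lower limits tethering each metal pseudo-atom to its six
  nearest Cα atoms (±0.5 Å);
* regularization tethers — per-atom flat-bottom wells of width `regularize_cap`
  (default 0.3 Å) around the current model's coordinates;
* connectivity limits — tight upper+lower limits on every peptide C–N bond,
  which preserve chain integrity under the rigid-module move set of the
  sampler (torsion-angle engines get this for free; a Cartesian rigid-body
  sampler must restrain it explicitly).

All restraints generated from a structure are satisfied with zero violation
by that structure, by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from pcsrefine.structure import ModuleSegmentation, Structure
from pcsrefine.tensor import DeltaChiTensor

CHAIN_BREAK_DISTANCE = 2.5  # Å; larger C–N separations are treated as breaks


@dataclass(frozen=True)
class AtomSelector:
    """Selects a protein atom by (residue, atom name), or a metal pseudo-atom
    by tag id (``residue`` is 0 for metals)."""

    residue: int
    atom: str
    tag: str | None = None

    @property
    def is_metal(self) -> bool:
        return self.tag is not None

    def sort_key(self) -> tuple:
        return (self.residue, self.atom, self.tag or "")


@dataclass(frozen=True)
class DistanceRestraint:
    a: AtomSelector
    b: AtomSelector
    kind: str  # "upper" | "lower"
    limit: float  # Å
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in ("upper", "lower"):
            raise ValueError(f"kind must be 'upper' or 'lower', got {self.kind!r}")
        if self.limit < 0 or (self.kind == "upper" and self.limit <= 0):
            raise ValueError("upper limit must be > 0, lower limit >= 0")


@dataclass(frozen=True)
class DihedralRestraint:
    residue: int
    angle: str  # "PHI" | "PSI"
    lower: float  # degrees in (-180, 180]
    upper: float
    weight: float = 1.0

    def __post_init__(self):
        for v in (self.lower, self.upper):
            if not -180.0 < v <= 180.0:
                raise ValueError("bounds must lie in (-180, 180]")
        if self.angle not in ("PHI", "PSI"):
            raise ValueError("angle must be PHI or PSI")

    @property
    def center(self) -> float:
        up = self.upper if self.upper > self.lower else self.upper + 360.0
        c = 0.5 * (self.lower + up)
        return c - 360.0 if c > 180.0 else c

    @property
    def halfwidth(self) -> float:
        up = self.upper if self.upper > self.lower else self.upper + 360.0
        return 0.5 * (up - self.lower)


@dataclass
class RestraintSet:
    """All restraints plus the global weights of the annealing target function."""

    upl: list[DistanceRestraint] = field(default_factory=list)
    lol: list[DistanceRestraint] = field(default_factory=list)
    aco: list[DihedralRestraint] = field(default_factory=list)
    ori: list[DistanceRestraint] = field(default_factory=list)
    w_upl: float = 1.0
    w_lol: float = 1.0
    w_pcs: float = 1.0
    w_aco: float = 5.0
    w_vdw: float = 2.0
    w_tether: float = 1.0
    w_pose: float = 0.02  # weak prior on the inter-module arrangement
    regularize_cap: float = 0.3  # Å
    tether_reference: np.ndarray | None = None  # (n_atoms, 3) model coordinates

    def __post_init__(self):
        for name in ("w_upl", "w_lol", "w_pcs", "w_aco", "w_vdw", "w_tether", "w_pose"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.regularize_cap <= 0:
            raise ValueError("regularize_cap must be > 0")

    def __len__(self) -> int:
        return len(self.upl) + len(self.lol) + len(self.aco) + len(self.ori)


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return math.degrees(math.atan2(y, x))


def wrap_angle(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


# ---------------------------------------------------------------------------
# scaffold generation


def make_scaffold_upl(
    structure: Structure,
    segmentation: ModuleSegmentation,
    d_min: float = 2.5,
    d_max: float = 5.0,
    tolerance: float = 0.5,
    min_seq_sep: int = 2,
    include_hydrogens: bool = False,
) -> list[DistanceRestraint]:
    """Upper limits on intra-module pairs in the [d_min, d_max] range.

    Pairs within the same module, separated by at least `min_seq_sep`
    residues (closer pairs are covalently forced), get one upper restraint
    at d + tolerance.  Heavy atoms only unless `include_hydrogens`.
    """
    if len(segmentation) == 0:
        raise ValueError("empty segmentation")
    chain = structure.single_chain
    rows = [
        i
        for i in range(len(structure))
        if include_hydrogens or not structure.atom_names[i].startswith("H")
    ]
    coords = structure.coords[rows]
    resnums = structure.residue_numbers[rows]
    module_id = np.array(
        [segmentation.module_of(int(r)) or "" for r in resnums], dtype=object
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(d_max, output_type="ndarray")
    out = []
    for i, j in pairs:
        if module_id[i] != module_id[j] or module_id[i] == "":
            continue
        if abs(int(resnums[i]) - int(resnums[j])) < min_seq_sep:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < d_min:
            continue
        sa = AtomSelector(int(resnums[i]), structure.atom_names[rows[i]])
        sb = AtomSelector(int(resnums[j]), structure.atom_names[rows[j]])
        if sb.sort_key() < sa.sort_key():
            sa, sb = sb, sa
        out.append(DistanceRestraint(sa, sb, "upper", d + tolerance))
    out.sort(key=lambda r: (r.a.sort_key(), r.b.sort_key()))
    return out


def make_scaffold_aco(
    structure: Structure,
    tolerance: float = 5.0,
) -> list[DihedralRestraint]:
    """φ/ψ restraints at the model's dihedral values ± tolerance, whole sequence.

    The first residue has no φ, the last no ψ; angles spanning a chain break
    (C–N distance above 2.5 Å) are skipped with a warning.
    """
    chain = structure.single_chain
    residues = sorted(r for _, r in structure.residues())
    out = []
    pos = structure.position
    for idx, res in enumerate(residues):
        prev_res = residues[idx - 1] if idx > 0 else None
        next_res = residues[idx + 1] if idx < len(residues) - 1 else None
        if prev_res is not None:
            try:
                c_prev = pos(chain, prev_res, "C")
                n_cur = pos(chain, res, "N")
            except KeyError:
                c_prev = None
            if c_prev is not None:
                if np.linalg.norm(n_cur - c_prev) > CHAIN_BREAK_DISTANCE:
                    warnings.warn(
                        f"chain break before residue {res}; phi skipped", stacklevel=2
                    )
                else:
                    phi = dihedral_angle(
                        c_prev, n_cur, pos(chain, res, "CA"), pos(chain, res, "C")
                    )
                    out.append(
                        DihedralRestraint(
                            res, "PHI", wrap_angle(phi - tolerance), wrap_angle(phi + tolerance)
                        )
                    )
        if next_res is not None:
            try:
                n_next = pos(chain, next_res, "N")
            except KeyError:
                n_next = None
            if n_next is not None:
                c_cur = pos(chain, res, "C")
                if np.linalg.norm(n_next - c_cur) > CHAIN_BREAK_DISTANCE:
                    warnings.warn(
                        f"chain break after residue {res}; psi skipped", stacklevel=2
                    )
                else:
                    psi = dihedral_angle(
                        pos(chain, res, "N"), pos(chain, res, "CA"), c_cur, n_next
                    )
                    out.append(
                        DihedralRestraint(
                            res, "PSI", wrap_angle(psi - tolerance), wrap_angle(psi + tolerance)
                        )
                    )
    return out


def make_ori(
    metal_position: Sequence[float],
    structure: Structure,
    n_anchors: int = 6,
    tolerance: float = 0.5,
    tag: str = "tag",
) -> list[DistanceRestraint]:
    """Upper+lower limits from the metal pseudo-atom to its nearest Cα atoms."""
    chain = structure.single_chain
    metal = np.asarray(metal_position, dtype=float)
    ca = [
        (int(structure.residue_numbers[i]), structure.coords[i])
        for i in range(len(structure))
        if structure.atom_names[i] == "CA"
    ]
    if not ca:
        raise ValueError("structure has no CA atoms")
    if len(ca) < n_anchors:
        warnings.warn(
            f"only {len(ca)} CA atoms available for {n_anchors} ORI anchors",
            stacklevel=2,
        )
    ranked = sorted(ca, key=lambda t: float(np.linalg.norm(t[1] - metal)))
    out = []
    msel = AtomSelector(0, "LN", tag=tag)
    for res, xyz in ranked[:n_anchors]:
        d = float(np.linalg.norm(xyz - metal))
        asel = AtomSelector(res, "CA")
        out.append(DistanceRestraint(asel, msel, "upper", d + tolerance))
        out.append(DistanceRestraint(asel, msel, "lower", max(d - tolerance, 0.0)))
    return out


def make_connectivity_restraints(
    structure: Structure,
    tolerance: float = 0.05,
    weight: float = 10.0,
) -> tuple[list[DistanceRestraint], list[DistanceRestraint]]:
    """Tight upper/lower limits on every peptide C–N bond (chain integrity)."""
    chain = structure.single_chain
    residues = sorted(r for _, r in structure.residues())
    upl, lol = [], []
    for a, b in zip(residues, residues[1:]):
        try:
            c = structure.position(chain, a, "C")
            n = structure.position(chain, b, "N")
        except KeyError:
            continue
        d = float(np.linalg.norm(n - c))
        if d > CHAIN_BREAK_DISTANCE:
            continue
        sa, sb = AtomSelector(a, "C"), AtomSelector(b, "N")
        upl.append(DistanceRestraint(sa, sb, "upper", d + tolerance, weight))
        lol.append(DistanceRestraint(sa, sb, "lower", max(d - tolerance, 0.0), weight))
    return upl, lol


@dataclass
class ScaffoldParams:
    """Knobs of scaffold regeneration in the iterative protocol."""

    upl_d_min: float = 2.5
    upl_d_max: float = 5.0
    upl_tolerance: float = 0.5
    aco_tolerance: float = 5.0
    n_anchors: int = 6
    ori_tolerance: float = 0.5
    regularize_cap: float = 0.3
    w_upl: float = 1.0
    w_lol: float = 1.0
    w_pcs: float = 30.0  # iterative-phase PCS weight (30–50)
    w_aco: float = 5.0
    w_vdw: float = 2.0
    w_tether: float = 1.0
    w_pose: float = 0.02
    min_seq_sep: int = 2
    include_hydrogens: bool = False

    def __post_init__(self):
        if not 0 < self.upl_d_min < self.upl_d_max:
            raise ValueError("need 0 < upl_d_min < upl_d_max")


def regenerate_scaffold(
    current_model: Structure,
    segmentation: ModuleSegmentation,
    tensors: dict[str, DeltaChiTensor],
    params: ScaffoldParams | None = None,
) -> RestraintSet:
    """Scaffold + ORI + regularization restraints from the current model.

    Deterministic: two calls on an unchanged model return identical sets.
    The tether reference (regularization) is the model's own coordinates,
    with the flat-bottom cap `params.regularize_cap`.
    """
    p = params or ScaffoldParams()
    upl = make_scaffold_upl(
        current_model,
        segmentation,
        p.upl_d_min,
        p.upl_d_max,
        p.upl_tolerance,
        p.min_seq_sep,
        p.include_hydrogens,
    )
    conn_upl, conn_lol = make_connectivity_restraints(current_model)
    aco = make_scaffold_aco(current_model, p.aco_tolerance)
    ori: list[DistanceRestraint] = []
    for tag, tensor in tensors.items():
        ori.extend(
            make_ori(
                tensor.metal_position,
                current_model,
                p.n_anchors,
                p.ori_tolerance,
                tag=tag,
            )
        )
    return RestraintSet(
        upl=upl + conn_upl,
        lol=conn_lol,
        aco=aco,
        ori=ori,
        w_upl=p.w_upl,
        w_lol=p.w_lol,
        w_pcs=p.w_pcs,
        w_aco=p.w_aco,
        w_vdw=p.w_vdw,
        w_tether=p.w_tether,
        w_pose=p.w_pose,
        regularize_cap=p.regularize_cap,
        tether_reference=current_model.coords.copy(),
    )
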