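"""Rigid-body superposition and RMSD-based accuracy/precision metrics.

Accuracy of a refined model is the backbone RMSD between the selected
structure and the reference/target; precision is the mean pairwise backbone
RMSD within a bundle of best-ranked structures.  Both superpose on backbone
heavy atoms (N, CA, C, O by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from pcsrefine.structure import BACKBONE_ATOMS, Structure


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid transform mapping a mobile point set onto a reference."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of `mobile` onto `reference` (Kabsch/SVD).

    Both arguments are paired ``(n, 3)`` coordinate arrays, n >= 3 and not all
    collinear.  The returned rotation is proper (det +1); the RMSD is minimal
    over all rigid transforms.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"paired (n, 3) sets required, got {ref.shape} vs {mob.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("at least 3 points required")

    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    p = mob - mob_c
    q = ref - ref_c

    # Collinear (or coincident) point sets leave a rotation dof undetermined.
    if np.linalg.matrix_rank(q - q.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("degenerate (collinear or coincident) reference points")

    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mob_c
    rmsd = float(np.sqrt(np.mean(np.sum((p @ rot.T - q) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _paired_backbone(
    a: Structure,
    b: Structure,
    residue_ranges: Sequence[tuple[int, int]] | None,
    atom_names: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Matched coordinate arrays for the selected backbone atoms of two structures."""
    chain_a = a.single_chain
    chain_b = b.single_chain
    if residue_ranges is None:
        residues = sorted(r for _, r in a.residues())
    else:
        residues = sorted(
            {r for lo, hi in residue_ranges for r in range(lo, hi + 1)}
        )
    ia, ib = [], []
    for res in residues:
        for atom in atom_names:
            try:
                ia.append(a.atom_index(chain_a, res, atom))
                ib.append(b.atom_index(chain_b, res, atom))
            except KeyError:
                raise ValueError(
                    f"backbone atom {atom} of residue {res} missing from selection"
                ) from None
    return a.coords[ia], b.coords[ib]


def backbone_rmsd(
    a: Structure,
    b: Structure,
    residue_selection: Sequence[tuple[int, int]] | None = None,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> float:
    """Backbone-heavy-atom RMSD between two structures after superposition.

    `residue_selection` is a list of inclusive residue ranges; ``None`` means
    every residue present in `a`.  Structures are paired by residue number.
    """
    ca, cb = _paired_backbone(a, b, residue_selection, atom_names)
    return kabsch_superpose(ca, cb).rmsd


def bundle_precision(
    structures: Sequence[Structure],
    residue_selection: Sequence[tuple[int, int]] | None = None,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
    method: str = "pairwise_mean",
) -> float:
    """Precision of a structure bundle.

    ``pairwise_mean`` (default) is the mean backbone RMSD over all unordered
    pairs — independent of bundle order.  ``to_mean`` superposes every member
    onto the first, then reports the RMS deviation from the mean coordinates.
    """
    if len(structures) < 2:
        raise ValueError("at least 2 structures required")
    if method == "pairwise_mean":
        vals = [
            backbone_rmsd(x, y, residue_selection, atom_names)
            for x, y in combinations(structures, 2)
        ]
        return float(np.mean(vals))
    if method == "to_mean":
        ref, _ = _paired_backbone(
            structures[0], structures[0], residue_selection, atom_names
        )
        aligned = [ref]
        for s in structures[1:]:
            _, mob = _paired_backbone(structures[0], s, residue_selection, atom_names)
            aligned.append(kabsch_superpose(ref, mob).apply(mob))
        stack = np.stack(aligned)
        mean = stack.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2))))
    raise ValueError(f"unknown precision method {method!r}")
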