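"""Δχ-tensor fitting, PCS back-calculation, Q-factors and the H/N filter.

Units are fixed across the package: distances in Å, PCS values in ppm and
susceptibility anisotropies in 10⁻³² m³.  With those units the pseudocontact
shift of a nucleus at distance r from the paramagnetic centre is

    PCS = 10⁴ / (12 π r³) · [Δχ_ax (3 cos²θ − 1) + 3/2 Δχ_rh sin²θ cos 2φ]

with (θ, φ) the polar angles of the nucleus in the tensor principal frame,
or equivalently ``10⁴/(4π r⁵) · r̂ᵀ Δχ r̂`` for the traceless symmetric
tensor in an arbitrary frame.  The tensor is reported in the unique-axis
convention |χ_zz| ≥ |χ_yy| ≥ |χ_xx|, which bounds Δχ_rh/Δχ_ax to [0, 2/3].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

PCS_PREFACTOR = 1.0e4 / (4.0 * np.pi)  # ppm · Å³ per 10⁻³² m³, on r̂ᵀχr̂/r³
MIN_METAL_DISTANCE = 0.5  # Å; closer spins sit in the PRE-dominated regime


@dataclass(frozen=True)
class PcsRecord:
    """One pseudocontact shift: amide ¹H or ¹⁵N of one residue under one tag."""

    tag: str
    residue_number: int
    atom_name: str
    value: float  # ppm
    tolerance: float = 0.02  # ppm
    weight: float = 1.0

    def __post_init__(self):
        if self.residue_number < 1:
            raise ValueError("residue_number must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class PcsDataset:
    """PCS records grouped by tag; (tag, residue, atom) unique."""

    records: list[PcsRecord] = field(default_factory=list)

    def __post_init__(self):
        keys = {(r.tag, r.residue_number, r.atom_name) for r in self.records}
        if len(keys) != len(self.records):
            raise ValueError("duplicate (tag, residue, atom) in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, PcsDataset) and self.records == other.records

    def tags(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.tag, None)
        return list(seen)

    def for_tag(self, tag: str) -> "PcsDataset":
        return PcsDataset([r for r in self.records if r.tag == tag])

    def residues(self) -> list[int]:
        return sorted({r.residue_number for r in self.records})

    def merged(self, other: "PcsDataset") -> "PcsDataset":
        return PcsDataset(self.records + other.records)


@dataclass(frozen=True)
class DeltaChiTensor:
    """Anisotropic magnetic susceptibility tensor of a paramagnetic centre.

    Stored as the metal position (Å) plus the symmetric traceless 3×3 matrix
    in 10⁻³² m³ in the global frame; axial/rhombic components and ZYZ Euler
    angles are derived views in the unique-axis convention.
    """

    metal_position: np.ndarray
    matrix: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "metal_position", np.asarray(self.metal_position, dtype=float)
        )
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if abs(np.trace(m)) > 1e-9 * max(1.0, float(np.abs(m).max())):
            raise ValueError("matrix must be traceless")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))

    @classmethod
    def from_axial_rhombic(
        cls,
        metal_position: Sequence[float],
        axial: float,
        rhombic: float,
        euler_zyz_deg: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "DeltaChiTensor":
        """Tensor from (Δχ_ax, Δχ_rh) and a ZYZ Euler rotation of the principal frame."""
        pas = np.diag(
            [
                -axial / 3.0 + rhombic / 2.0,
                -axial / 3.0 - rhombic / 2.0,
                2.0 * axial / 3.0,
            ]
        )
        rot = Rotation.from_euler("ZYZ", euler_zyz_deg, degrees=True).as_matrix()
        return cls(np.asarray(metal_position, dtype=float), rot @ pas @ rot.T)

    def _principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues ordered |χ_xx| ≤ |χ_yy| ≤ |χ_zz| and the matching axes."""
        vals, vecs = np.linalg.eigh(self.matrix)
        order = np.argsort(np.abs(vals))
        vals = vals[order]
        vecs = vecs[:, order]
        if np.linalg.det(vecs) < 0:
            vecs[:, 0] = -vecs[:, 0]
        return vals, vecs

    @property
    def axial(self) -> float:
        """Δχ_ax = χ_zz − (χ_xx + χ_yy)/2 = (3/2) χ_zz (traceless)."""
        vals, _ = self._principal()
        return float(1.5 * vals[2])

    @property
    def rhombic(self) -> float:
        """Δχ_rh = χ_xx − χ_yy in the unique-axis convention."""
        vals, _ = self._principal()
        return float(vals[0] - vals[1])

    @property
    def euler_zyz_deg(self) -> np.ndarray:
        _, vecs = self._principal()
        return Rotation.from_matrix(vecs).as_euler("ZYZ", degrees=True)

    def with_position(self, position: Sequence[float]) -> "DeltaChiTensor":
        return DeltaChiTensor(np.asarray(position, dtype=float), self.matrix)


@dataclass
class TensorFitResult:
    tensor: DeltaChiTensor
    q_factor: float
    residuals: np.ndarray  # ppm, one per spin used
    n_spins_used: int

    def __post_init__(self):
        if self.q_factor < 0:
            raise ValueError("q_factor must be >= 0")


# ---------------------------------------------------------------------------
# back-calculation


def backcalc_pcs(tensor: DeltaChiTensor, spin_position: Sequence[float]) -> float:
    """Back-calculated PCS (ppm) of a single nucleus."""
    r = np.asarray(spin_position, dtype=float) - tensor.metal_position
    dist = float(np.linalg.norm(r))
    if dist < MIN_METAL_DISTANCE:
        raise ValueError(
            f"spin at {dist:.2f} Å from the metal (PRE-dominated, < "
            f"{MIN_METAL_DISTANCE} Å)"
        )
    return float(PCS_PREFACTOR * (r @ tensor.matrix @ r) / dist**5)


def backcalc_pcs_many(tensor: DeltaChiTensor, positions: np.ndarray) -> np.ndarray:
    """Vectorized :func:`backcalc_pcs` over an ``(n, 3)`` position array."""
    rv = np.asarray(positions, dtype=float) - tensor.metal_position
    dist = np.linalg.norm(rv, axis=1)
    if np.any(dist < MIN_METAL_DISTANCE):
        raise ValueError("spin(s) inside the PRE cutoff distance of the metal")
    quad = np.einsum("ni,ij,nj->n", rv, tensor.matrix, rv)
    return PCS_PREFACTOR * quad / dist**5


def spin_positions(dataset: PcsDataset, structure) -> np.ndarray:
    """(n, 3) coordinates of the dataset's spins, in record order."""
    chain = structure.single_chain
    out = np.empty((len(dataset), 3), dtype=float)
    for i, rec in enumerate(dataset.records):
        try:
            out[i] = structure.position(chain, rec.residue_number, rec.atom_name)
        except KeyError:
            raise ValueError(
                f"spin {rec.atom_name} of residue {rec.residue_number} absent "
                "from the structure"
            ) from None
    return out


# ---------------------------------------------------------------------------
# tensor fitting


def _design_matrix(rel: np.ndarray) -> np.ndarray:
    """Rows mapping the 5 free tensor components to PCS values.

    Components are ordered (χ_xx, χ_yy, χ_xy, χ_xz, χ_yz) with
    χ_zz = −χ_xx − χ_yy.
    """
    x, y, z = rel[:, 0], rel[:, 1], rel[:, 2]
    r5 = (x * x + y * y + z * z) ** 2.5
    c = PCS_PREFACTOR / r5
    return np.column_stack(
        [
            c * (x * x - z * z),
            c * (y * y - z * z),
            c * 2 * x * y,
            c * 2 * x * z,
            c * 2 * y * z,
        ]
    )


def _components_to_matrix(p: np.ndarray) -> np.ndarray:
    xx, yy, xy, xz, yz = p
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, -xx - yy]])


def fit_components(
    pcs: PcsDataset,
    structure,
    metal_position: Sequence[float],
) -> TensorFitResult:
    """Linear least-squares fit of the 5 tensor components at a fixed metal position.

    Requires a single-tag dataset with at least 5 spins whose geometry spans
    the angular space (non-singular design matrix).
    """
    tags = pcs.tags()
    if len(tags) != 1:
        raise ValueError(f"single-tag dataset required, got tags {tags}")
    pos = spin_positions(pcs, structure)
    metal = np.asarray(metal_position, dtype=float)
    rel = pos - metal
    dist = np.linalg.norm(rel, axis=1)
    if np.any(dist < MIN_METAL_DISTANCE):
        raise ValueError("spin(s) inside the PRE cutoff distance of the metal")
    if len(pcs) < 5:
        raise ValueError(f"underdetermined: {len(pcs)} spins, need >= 5")
    a = _design_matrix(rel)
    if np.linalg.matrix_rank(a, tol=1e-10 * max(1.0, float(np.abs(a).max()))) < 5:
        raise ValueError("singular design matrix (degenerate spin geometry)")
    values = np.array([r.value for r in pcs.records])
    p, *_ = np.linalg.lstsq(a, values, rcond=None)
    tensor = DeltaChiTensor(metal, _components_to_matrix(p))
    calc = a @ p
    residuals = values - calc
    if np.any(values != 0.0):
        q = qfactor(values, calc)
    else:
        # degenerate all-zero dataset: the zero tensor fits exactly
        q = 0.0 if np.allclose(residuals, 0.0) else float("inf")
    return TensorFitResult(tensor=tensor, q_factor=q, residuals=residuals, n_spins_used=len(pcs))


def fit_tensor(
    pcs: PcsDataset,
    structure,
    initial_position: Sequence[float],
    position_search_radius: float = 10.0,
    xatol: float = 0.01,
    maxiter: int = 2000,
) -> TensorFitResult:
    """Full 8-parameter fit: metal position plus the 5 tensor components.

    A derivative-free Nelder–Mead simplex walks the metal position; at every
    trial position the components are solved exactly by linear least squares.
    Converged when the simplex collapses below `xatol` Å.
    """
    if len(pcs) < 8:
        raise ValueError(f"underdetermined: {len(pcs)} spins, need >= 8 for a full fit")
    x0 = np.asarray(initial_position, dtype=float)
    lo = structure.coords.min(axis=0) - 25.0
    hi = structure.coords.max(axis=0) + 25.0
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("initial position outside the structure's bounding box + 25 Å")

    pos = spin_positions(pcs, structure)
    values = np.array([r.value for r in pcs.records])

    def objective(metal: np.ndarray) -> float:
        rel = pos - metal
        dist2 = np.sum(rel * rel, axis=1)
        if np.any(dist2 < MIN_METAL_DISTANCE**2):
            return 1e12
        a = _design_matrix(rel)
        p, *_ = np.linalg.lstsq(a, values, rcond=None)
        res = values - a @ p
        return float(res @ res)

    result = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": xatol,
            # convergence is judged on the simplex size in Å; the objective
            # plateau is data-dependent and must not block termination
            "fatol": np.inf,
            "maxiter": maxiter,
            "initial_simplex": x0
            + np.vstack([np.zeros(3), np.eye(3) * min(position_search_radius, 5.0)]),
        },
    )
    if not result.success:
        raise RuntimeError(
            f"position search did not converge within the iteration cap: {result.message}"
        )
    return fit_components(pcs, structure, result.x)


# ---------------------------------------------------------------------------
# quality metrics


def qfactor(exp_values: np.ndarray, calc_values: np.ndarray) -> float:
    """Q-factor over an ensemble.

    ``Q = sqrt( Σ_i (Σ_m [exp_{m,i} − calc_{m,i}])² / Σ_i (Σ_m exp_{m,i})² )``
    where i runs over atoms and m over ensemble models.  1-D inputs are
    treated as a single-model ensemble.
    """
    exp = np.atleast_2d(np.asarray(exp_values, dtype=float))
    calc = np.atleast_2d(np.asarray(calc_values, dtype=float))
    if exp.shape != calc.shape:
        raise ValueError(f"shape mismatch: {exp.shape} vs {calc.shape}")
    if exp.size == 0:
        raise ValueError("empty input")
    num = np.sum(np.sum(exp - calc, axis=0) ** 2)
    den = np.sum(np.sum(exp, axis=0) ** 2)
    if den == 0:
        raise ValueError("zero denominator: experimental sums all vanish")
    return float(np.sqrt(num / den))


def mean_q_over_tags(per_tag_q: dict[str, float]) -> float:
    """Arithmetic mean of per-tag Q-factors (the ranking score of the protocol)."""
    if not per_tag_q:
        raise ValueError("no per-tag Q-factors")
    return float(np.mean(list(per_tag_q.values())))


# ---------------------------------------------------------------------------
# consistency filter


def consistency_filter(
    pcs: PcsDataset,
    threshold: float = 0.2,
    floor: float = 0.02,
) -> tuple[PcsDataset, list[tuple[str, int, float]]]:
    """Discard amide groups whose ¹H and ¹⁵N PCSs disagree by more than 20 %.

    The ¹H and ¹⁵N PCS of one amide are nearly equal because the two nuclei
    are ~1 Å apart; a larger relative difference flags ¹⁵N CSA contamination.
    A pair is discarded when ``|H − N| / max(|H|, |N|) > threshold`` and
    ``max(|H|, |N|) >= floor`` (tiny shifts are kept — their relative
    difference is dominated by noise).  Unpaired records pass through.

    Returns the kept dataset plus ``(tag, residue, relative difference)`` for
    every discarded pair.
    """
    by_pair: dict[tuple[str, int], dict[str, PcsRecord]] = {}
    for rec in pcs.records:
        by_pair.setdefault((rec.tag, rec.residue_number), {})[rec.atom_name] = rec
    kept: list[PcsRecord] = []
    discarded: list[tuple[str, int, float]] = []
    dropped_keys: set[tuple[str, int]] = set()
    for (tag, res), group in by_pair.items():
        if "H" in group and "N" in group:
            h, n = group["H"].value, group["N"].value
            scale = max(abs(h), abs(n))
            if scale >= floor and scale > 0:
                rel = abs(h - n) / scale
                if rel > threshold:
                    discarded.append((tag, res, rel))
                    dropped_keys.add((tag, res))
    for rec in pcs.records:
        key = (rec.tag, rec.residue_number)
        if key in dropped_keys and rec.atom_name in ("H", "N"):
            continue
        kept.append(rec)
    return PcsDataset(kept), discarded
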