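"""Coordinate containers and module segmentation for repeat proteins.

A :class:`Structure` is a flat, ordered list of atom records backed by a
``(n, 3)`` numpy coordinate array, indexed by ``(chain, residue_number,
atom_name)``.  Repeat proteins are segmented into an N-terminal cap (``Y``),
internal modules (``M1`` ... ``Mn``) and a C-terminal cap (``A``) by a
:class:`ModuleSegmentation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus Cartesian coordinates in Å."""

    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    x: float
    y: float
    z: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class Structure:
    """Ordered atom records with an index by (chain, residue number, atom name).

    Parameters
    ----------
    chains, residue_numbers, residue_names, atom_names
        Per-atom identity arrays (equal length).
    coords
        ``(n, 3)`` array of Cartesian coordinates in Å.

    Invariants enforced at construction: coordinates are finite, index keys
    are unique, and residue numbers are non-decreasing within each chain.
    """

    def __init__(
        self,
        chains: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        atom_names: Sequence[str],
        coords: np.ndarray,
    ):
        n = len(atom_names)
        if not (len(chains) == len(residue_numbers) == len(residue_names) == n):
            raise ValueError("identity arrays must have equal length")
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (n, 3):
            raise ValueError(f"coords must have shape ({n}, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.chains = list(chains)
        self.residue_numbers = np.asarray(residue_numbers, dtype=np.int64)
        self.residue_names = list(residue_names)
        self.atom_names = list(atom_names)
        self.coords = coords

        index: dict[tuple[str, int, str], int] = {}
        last_res: dict[str, int] = {}
        for i in range(n):
            key = (self.chains[i], int(self.residue_numbers[i]), self.atom_names[i])
            if key in index:
                raise ValueError(f"duplicate atom {key}")
            index[key] = i
            prev = last_res.get(key[0])
            if prev is not None and key[1] < prev:
                raise ValueError(
                    f"residues out of order in chain {key[0]}: {key[1]} after {prev}"
                )
            last_res[key[0]] = key[1]
        self._index = index

    # -- basic container protocol ------------------------------------------

    def __len__(self) -> int:
        return len(self.atom_names)

    def __iter__(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield self.record(i)

    def record(self, i: int) -> AtomRecord:
        x, y, z = self.coords[i]
        return AtomRecord(
            self.chains[i],
            int(self.residue_numbers[i]),
            self.residue_names[i],
            self.atom_names[i],
            float(x),
            float(y),
            float(z),
        )

    @classmethod
    def from_records(cls, records: Iterable[AtomRecord]) -> "Structure":
        records = list(records)
        return cls(
            [r.chain for r in records],
            [r.residue_number for r in records],
            [r.residue_name for r in records],
            [r.atom_name for r in records],
            np.array([[r.x, r.y, r.z] for r in records], dtype=float).reshape(-1, 3),
        )

    # -- lookup -------------------------------------------------------------

    def atom_index(self, chain: str, residue_number: int, atom_name: str) -> int:
        """Row index of one atom; KeyError when absent."""
        return self._index[(chain, int(residue_number), atom_name)]

    def has_atom(self, chain: str, residue_number: int, atom_name: str) -> bool:
        return (chain, int(residue_number), atom_name) in self._index

    def position(self, chain: str, residue_number: int, atom_name: str) -> np.ndarray:
        return self.coords[self.atom_index(chain, residue_number, atom_name)]

    @property
    def single_chain(self) -> str:
        uniq = sorted(set(self.chains))
        if len(uniq) != 1:
            raise ValueError(f"expected a single chain, found {uniq}")
        return uniq[0]

    def residues(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue number) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chains, self.residue_numbers):
            seen.setdefault((c, int(r)), None)
        return list(seen)

    # -- derived structures ---------------------------------------------------

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same atoms, new coordinates (shares identity metadata)."""
        return Structure(
            self.chains, self.residue_numbers, self.residue_names, self.atom_names, coords
        )

    def copy(self) -> "Structure":
        return self.with_coords(self.coords.copy())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        return self.with_coords(self.coords @ np.asarray(rotation).T + translation)

    def atom_mask(
        self,
        residue_ranges: Sequence[tuple[int, int]] | None = None,
        atom_names: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Boolean mask selecting residue ranges (inclusive) and/or atom names."""
        mask = np.ones(len(self), dtype=bool)
        if residue_ranges is not None:
            sel = np.zeros(len(self), dtype=bool)
            for lo, hi in residue_ranges:
                sel |= (self.residue_numbers >= lo) & (self.residue_numbers <= hi)
            mask &= sel
        if atom_names is not None:
            wanted = set(atom_names)
            mask &= np.array([a in wanted for a in self.atom_names], dtype=bool)
        return mask


@dataclass(frozen=True)
class ModuleRange:
    label: str
    first_residue: int
    last_residue: int

    def __post_init__(self):
        if self.first_residue > self.last_residue:
            raise ValueError(f"empty module range {self.label}")

    def contains(self, residue: int) -> bool:
        return self.first_residue <= residue <= self.last_residue


@dataclass
class ModuleSegmentation:
    """Ordered, non-overlapping residue ranges labelling the repeat modules.

    Labels follow the repeat-protein convention: ``Y`` (N-cap), ``M1`` ...
    ``Mn`` (internal modules), ``A`` (C-cap).  Caps are optional.
    """

    modules: list[ModuleRange] = field(default_factory=list)

    def __post_init__(self):
        labels = [m.label for m in self.modules]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate module labels")
        for a, b in zip(self.modules, self.modules[1:]):
            if b.first_residue <= a.last_residue:
                raise ValueError(
                    f"module ranges overlap or are out of order: {a.label}, {b.label}"
                )

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[ModuleRange]:
        return iter(self.modules)

    def __getitem__(self, label: str) -> ModuleRange:
        for m in self.modules:
            if m.label == label:
                return m
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.modules]

    def module_of(self, residue: int) -> str | None:
        for m in self.modules:
            if m.contains(residue):
                return m.label
        return None

    def junctions(self) -> list[int]:
        """Junction indices 1..n_modules-1; junction j sits between modules j and j+1."""
        return list(range(1, len(self.modules)))

    def junction_residue(self, junction: int) -> int:
        """Last residue of the module upstream of `junction` (the pivot residue)."""
        if not 1 <= junction <= len(self.modules) - 1:
            raise ValueError(f"junction {junction} outside 1..{len(self.modules) - 1}")
        return self.modules[junction - 1].last_residue

    def internal_ranges(self) -> list[tuple[int, int]]:
        """Residue ranges of the internal (M) modules only."""
        return [
            (m.first_residue, m.last_residue)
            for m in self.modules
            if m.label.startswith("M")
        ]

    def ranges(self, exclude: Sequence[str] = ()) -> list[tuple[int, int]]:
        return [
            (m.first_residue, m.last_residue)
            for m in self.modules
            if m.label not in set(exclude)
        ]

    @classmethod
    def uniform(
        cls, n_internal: int, residues_per_module: int, include_caps: bool = True
    ) -> "ModuleSegmentation":
        """Equal-length segmentation: [Y] M1..Mn [A], numbering from 1."""
        labels = ["Y"] if include_caps else []
        labels += [f"M{i}" for i in range(1, n_internal + 1)]
        if include_caps:
            labels.append("A")
        mods = []
        start = 1
        for lab in labels:
            mods.append(ModuleRange(lab, start, start + residues_per_module - 1))
            start += residues_per_module
        return cls(mods)
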