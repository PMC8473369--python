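"""File formats: PDB coordinates, `.npc` PCS lists, restraint files, YAML config.

The restraint dialect is CYANA-like but self-defined (fixed column layout,
documented below); every writer/reader pair is a lossless round trip at the
declared precision.

* ``.upl`` / ``.lol`` — one distance limit per line:
  ``resnum resname atom  resnum resname atom  limit  weight``.
  Metal pseudo-atoms are written with residue number 0, residue name equal
  to the tag id and atom name ``LN``.
* ``.aco`` — ``resnum resname angle lower upper`` (degrees, PHI/PSI).
* ``.pcs`` — per-tag header lines
  ``TENSOR tag axial rhombic LN_tag`` (components in 10⁻³² m³), followed by
  data lines ``resnum atom value tolerance weight tag``.
* ``.npc`` — whitespace-delimited ``residue atom value [tolerance]``;
  ``#`` starts a comment; a missing tolerance defaults to 0.02 ppm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml

from pcsrefine.restraints import (
    AtomSelector,
    DihedralRestraint,
    DistanceRestraint,
    RestraintSet,
)
from pcsrefine.structure import ModuleRange, ModuleSegmentation, Structure
from pcsrefine.tensor import DeltaChiTensor, PcsDataset, PcsRecord

log = logging.getLogger("pcsrefine")

DEFAULT_NPC_TOLERANCE = 0.02  # ppm


# ---------------------------------------------------------------------------
# PDB


def read_pdb(path) -> Structure:
    """Read ATOM records from a fixed-column PDB file.

    Altloc indicators other than blank/'A' are dropped; insertion codes are
    rejected (repeat-protein models use plain sequential numbering); HETATM
    records are ignored.  Raises on unreadable files, missing ATOM records
    or duplicate (chain, residue, atom) keys.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as err:
        raise ValueError(f"unreadable PDB file {path}: {err}") from err
    chains, resnums, resnames, atnames, coords = [], [], [], [], []
    for model in st:
        for chain in model:
            for residue in chain:
                if residue.het_flag != "A":  # ATOM records only
                    continue
                if residue.seqid.icode not in (" ", ""):
                    raise ValueError(
                        f"insertion code {residue.seqid.icode!r} at residue "
                        f"{residue.seqid.num} not supported"
                    )
                for atom in residue:
                    if atom.altloc not in ("", "A", "\0"):
                        continue
                    chains.append(chain.name)
                    resnums.append(residue.seqid.num)
                    resnames.append(residue.name)
                    atnames.append(atom.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if not atnames:
        raise ValueError(f"no ATOM records in {path}")
    try:
        return Structure(chains, resnums, resnames, atnames, np.array(coords))
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_pdb(structure: Structure, path) -> None:
    """Write a single-model PDB file (coordinates at the format's 3 decimals)."""
    st = gemmi.Structure()
    st.name = "pcsrefine"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for rec in structure:
        chain = chains.get(rec.chain)
        if chain is None:
            chain = gemmi.Chain(rec.chain)
            chains[rec.chain] = chain
        if len(chain) == 0 or chain[-1].seqid.num != rec.residue_number:
            residue = gemmi.Residue()
            residue.name = rec.residue_name
            residue.seqid = gemmi.SeqId(rec.residue_number, " ")
            residue.het_flag = "A"
            chain.add_residue(residue)
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.element = gemmi.Element(rec.atom_name[0])
        atom.pos = gemmi.Position(rec.x, rec.y, rec.z)
        chain[-1].add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# .npc


def read_npc(path, tag_id: str, default_tolerance: float = DEFAULT_NPC_TOLERANCE) -> PcsDataset:
    """Read a whitespace-delimited PCS list into a single-tag dataset."""
    path = Path(path)
    records: list[PcsRecord] = []
    seen: dict[tuple[int, str], int] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise ValueError(
                f"{path}:{lineno}: expected 'residue atom value [tolerance]', got {raw!r}"
            )
        try:
            residue = int(parts[0])
            value = float(parts[2])
            tolerance = float(parts[3]) if len(parts) == 4 else default_tolerance
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed numeric field in {raw!r}") from None
        key = (residue, parts[1])
        if key in seen:
            raise ValueError(
                f"{path}:{lineno}: duplicate entry for residue {residue} atom "
                f"{parts[1]} (first seen at line {seen[key]})"
            )
        seen[key] = lineno
        records.append(PcsRecord(tag_id, residue, parts[1], value, tolerance))
    return PcsDataset(records)


def write_npc(dataset: PcsDataset, path) -> None:
    """Write a single-tag dataset as 4-column `.npc`."""
    tags = dataset.tags()
    if len(tags) != 1:
        raise ValueError(f"single-tag dataset required, got {tags}")
    lines = [
        f"{r.residue_number:5d} {r.atom_name:<4s} {r.value:12.6f} {r.tolerance:8.4f}"
        for r in dataset.records
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# restraint files


def _fmt_sel(structure: Structure, sel: AtomSelector) -> str:
    if sel.is_metal:
        return f"{0:4d} {sel.tag:>4s} {'LN':<4s}"
    chain = structure.single_chain
    if not structure.has_atom(chain, sel.residue, sel.atom):
        raise ValueError(
            f"restraint references atom {sel.atom} of residue {sel.residue} "
            "absent from the structure"
        )
    idx = structure.atom_index(chain, sel.residue, sel.atom)
    return f"{sel.residue:4d} {structure.residue_names[idx]:>4s} {sel.atom:<4s}"


def _parse_sel(res: str, name: str, atom: str) -> AtomSelector:
    resnum = int(res)
    if resnum == 0:
        return AtomSelector(0, "LN", tag=name)
    return AtomSelector(resnum, atom)


def write_restraints(
    restraints: RestraintSet,
    directory,
    structure: Structure,
    tensors: dict[str, DeltaChiTensor] | None = None,
    pcs: PcsDataset | None = None,
    stem: str = "scaffold",
) -> dict[str, Path]:
    """Write `.upl`/`.lol`/`.aco` (and `.pcs` when tensors+data are given).

    Every protein atom referenced must exist in `structure`; the set must be
    nonempty.  Returns the mapping of file kinds to paths.
    """
    if len(restraints) == 0:
        raise ValueError("empty restraint set")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    uppers = restraints.upl + [r for r in restraints.ori if r.kind == "upper"]
    lowers = restraints.lol + [r for r in restraints.ori if r.kind == "lower"]
    for kind, items in (("upl", uppers), ("lol", lowers)):
        lines = [
            f"{_fmt_sel(structure, r.a)}  {_fmt_sel(structure, r.b)} "
            f"{r.limit:8.2f} {r.weight:8.2f}"
            for r in items
        ]
        p = directory / f"{stem}.{kind}"
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        out[kind] = p

    aco_lines = []
    chain = structure.single_chain
    for r in restraints.aco:
        idx = structure.atom_index(chain, r.residue, "CA")
        aco_lines.append(
            f"{r.residue:4d} {structure.residue_names[idx]:>4s} {r.angle:<4s}"
            f"{r.lower:9.2f}{r.upper:9.2f}"
        )
    p = directory / f"{stem}.aco"
    p.write_text("\n".join(aco_lines) + ("\n" if aco_lines else ""))
    out["aco"] = p

    if tensors is not None and pcs is not None:
        lines = [
            f"TENSOR {tag} {t.axial:12.6f} {t.rhombic:12.6f} LN_{tag}"
            for tag, t in tensors.items()
        ]
        for r in pcs.records:
            lines.append(
                f"{r.residue_number:5d} {r.atom_name:<4s} {r.value:12.6f} "
                f"{r.tolerance:8.4f} {r.weight:6.2f} {r.tag}"
            )
        p = directory / f"{stem}.pcs"
        p.write_text("\n".join(lines) + "\n")
        out["pcs"] = p
    return out


def read_restraints(directory, stem: str = "scaffold") -> RestraintSet:
    """Read the `.upl`/`.lol`/`.aco` dialect back into a restraint set.

    ORI restraints (metal pseudo-atom partners) are recognised by residue
    number 0 and re-grouped under ``ori``.
    """
    directory = Path(directory)
    upl, lol, ori, aco = [], [], [], []
    for kind in ("upl", "lol"):
        p = directory / f"{stem}.{kind}"
        if not p.exists():
            continue
        for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
            if not raw.strip():
                continue
            t = raw.split()
            if len(t) != 8:
                raise ValueError(f"{p}:{lineno}: expected 8 columns, got {raw!r}")
            a = _parse_sel(t[0], t[1], t[2])
            b = _parse_sel(t[3], t[4], t[5])
            r = DistanceRestraint(
                a, b, "upper" if kind == "upl" else "lower", float(t[6]), float(t[7])
            )
            if a.is_metal or b.is_metal:
                ori.append(r)
            elif kind == "upl":
                upl.append(r)
            else:
                lol.append(r)
    p = directory / f"{stem}.aco"
    if p.exists():
        for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
            if not raw.strip():
                continue
            t = raw.split()
            if len(t) != 5:
                raise ValueError(f"{p}:{lineno}: expected 5 columns, got {raw!r}")
            aco.append(DihedralRestraint(int(t[0]), t[2], float(t[3]), float(t[4])))
    return RestraintSet(upl=upl, lol=lol, aco=aco, ori=ori)


def read_pcs_file(path) -> tuple[PcsDataset, dict[str, tuple[float, float]]]:
    """Read a `.pcs` file: (dataset, per-tag (axial, rhombic) components)."""
    path = Path(path)
    records = []
    components: dict[str, tuple[float, float]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        t = line.split()
        if t[0] == "TENSOR":
            components[t[1]] = (float(t[2]), float(t[3]))
            continue
        if len(t) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns, got {raw!r}")
        records.append(
            PcsRecord(t[5], int(t[0]), t[1], float(t[2]), float(t[3]), float(t[4]))
        )
    return PcsDataset(records), components


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TagConfig:
    tag_id: str
    attachment_residue: int
    initial_metal_position: tuple[float, float, float]


@dataclass
class ConfigBundle:
    """Module boundaries, tag definitions and engine parameters."""

    segmentation: ModuleSegmentation
    tags: list[TagConfig] = field(default_factory=list)
    engine: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    seed: int = 0

    def validate_against(self, structure: Structure) -> None:
        chain = structure.single_chain
        residues = {r for _, r in structure.residues()}
        for m in self.segmentation:
            for r in (m.first_residue, m.last_residue):
                if r not in residues:
                    raise ValueError(
                        f"segmentation {m.label}: residue {r} absent from structure"
                    )
        for t in self.tags:
            if t.attachment_residue not in residues:
                raise ValueError(
                    f"tag {t.tag_id}: attachment residue {t.attachment_residue} "
                    "absent from structure"
                )


def load_config(path) -> ConfigBundle:
    """Load a YAML config (segmentation, tags, engine parameters, paths)."""
    data = yaml.safe_load(Path(path).read_text())
    seg = ModuleSegmentation(
        [ModuleRange(str(m["label"]), int(m["first"]), int(m["last"])) for m in data["modules"]]
    )
    tags = [
        TagConfig(
            str(t["id"]),
            int(t["attachment_residue"]),
            tuple(float(x) for x in t["initial_metal_position"]),
        )
        for t in data.get("tags", [])
    ]
    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        raise ValueError("seed must be an integer")
    return ConfigBundle(
        segmentation=seg,
        tags=tags,
        engine=data.get("engine", {}),
        paths=data.get("paths", {}),
        seed=seed,
    )
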