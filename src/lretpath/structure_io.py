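"""Structure and trajectory I/O.

Atoms are normalized into a flat, file-order data model with coordinates in
Ångström (the PDB native unit); quantities the literature quotes in nm are
converted at the boundary. Residue and atom numbering is taken verbatim from
the file so that labels like "Y247" match crystallographic author numbering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np
import pandas as pd

WATER_RESIDUES = frozenset({"HOH", "WAT", "SOL", "H2O", "TIP3", "SPC"})

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "read_pdb",
    "read_trajectory",
    "write_ranking",
    "read_ranking",
    "resolve_atom",
    "WATER_RESIDUES",
]


class EmptyStructureError(ValueError):
    """Raised when a structure file contains no atoms."""


class FormatError(ValueError):
    """Raised on malformed multi-model or frame-stack input."""


@dataclass(frozen=True, eq=False)
class Atom:
    """One atom as printed in a coordinate file.

    ``position`` is Ångström. ``is_water`` is derived from the residue name
    (configurable water set), ``is_het`` from the HETATM record type.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    is_het: bool = False
    is_water: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}): empty element")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} ({self.name}): non-finite position")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """(chain, residue number, residue name) key used by selectors."""
        return (self.chain_id, self.residue_number, self.residue_name)


@dataclass
class Structure:
    """An ordered atom list plus optional extra coordinate models.

    ``atoms`` carry the first model's coordinates; additional models are
    stored as coordinate arrays in ``extra_models`` (same atom order).
    """

    atoms: list[Atom]
    extra_models: list[np.ndarray] = field(default_factory=list)
    identifier: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError("structure has no atoms")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials within a model")
        n = len(self.atoms)
        for i, coords in enumerate(self.extra_models):
            if coords.shape != (n, 3):
                raise FormatError(
                    f"model {i + 2} has {coords.shape[0]} atoms, expected {n}"
                )

    @property
    def model_count(self) -> int:
        return 1 + len(self.extra_models)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of first-model positions, Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure (single model) carrying ``coords``."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise FormatError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, identifier=self.identifier)

    def find_atoms(
        self,
        name: str | None = None,
        residue_name: str | None = None,
        residue_number: int | None = None,
        chain_id: str | None = None,
    ) -> list[Atom]:
        out = []
        for a in self.atoms:
            if name is not None and a.name != name:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            out.append(a)
        return out


@dataclass
class Trajectory:
    """A coordinate ensemble: fixed topology, per-frame (n_atoms, 3) arrays."""

    topology: Structure
    frames: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.frames:
            raise FormatError("trajectory has no frames")
        n = len(self.topology.atoms)
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise FormatError(
                    f"frame {i} has shape {f.shape}, topology has {n} atoms"
                )

    @property
    def frame_count(self) -> int:
        return len(self.frames)

    def iter_structures(self) -> Iterator[Structure]:
        for f in self.frames:
            yield self.topology.with_coordinates(f)

    @classmethod
    def from_structure(cls, structure: Structure) -> "Trajectory":
        """Treat a (possibly multi-model) structure as a trajectory."""
        frames = [structure.coordinates] + list(structure.extra_models)
        topo = Structure(atoms=structure.atoms, identifier=structure.identifier)
        return cls(topology=topo, frames=frames)


def resolve_atom(structure: Structure, selector) -> Atom:
    """Resolve a selector to exactly one atom.

    Accepts an :class:`Atom`, an integer serial, a ``(chain, residue_number,
    atom_name)`` triple, or a dict of :meth:`Structure.find_atoms` keywords.
    """
    if isinstance(selector, Atom):
        return selector
    if isinstance(selector, (int, np.integer)):
        for a in structure.atoms:
            if a.serial == int(selector):
                return a
        raise KeyError(f"no atom with serial {selector}")
    if isinstance(selector, dict):
        matches = structure.find_atoms(**selector)
    else:
        chain, resnum, name = selector
        matches = structure.find_atoms(
            chain_id=chain, residue_number=int(resnum), name=name
        )
    if len(matches) != 1:
        raise KeyError(
            f"selector {selector!r} matched {len(matches)} atoms, expected exactly 1"
        )
    return matches[0]


# --- PDB reading -----------------------------------------------------------

_NAME_ELEMENT_HINTS = {
    "FE": "Fe", "ZN": "Zn", "MG": "Mg", "MN": "Mn", "CA": "Ca", "NA": "Na",
    "CL": "Cl", "CU": "Cu", "K": "K", "BR": "Br", "I": "I", "SE": "Se",
}


def _element_from_name(name: str, residue_name: str, is_het: bool) -> str:
    """PDB atom-name fallback when columns 77-78 are blank.

    For standard residues the first letter of the stripped name is the
    element; greek-position digits ("1HG1") are skipped. HETATM metals use
    full-name lookup (heme "FE" is iron, while protein "CA" is carbon).
    """
    stripped = name.strip()
    if is_het and stripped.upper() in _NAME_ELEMENT_HINTS:
        return _NAME_ELEMENT_HINTS[stripped.upper()]
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return stripped[:1].upper() or "X"


def _select_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate conformers: highest occupancy wins, tie -> 'A'."""
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        key = atom.name
        if key not in by_name:
            by_name[key] = atom
            order.append(key)
            continue
        prev = by_name[key]
        if atom.occ > prev.occ or (
            atom.occ == prev.occ and (atom.altloc or "A") < (prev.altloc or "A")
        ):
            by_name[key] = atom
    return [by_name[k] for k in order]


def read_pdb(path: str | Path, water_residues: Iterable[str] = WATER_RESIDUES) -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`.

    Atoms keep file order; MODEL/ENDMDL blocks become extra coordinate
    models and must agree with the first model in atom count and order.
    Elements come from columns 77-78 when present, otherwise from the
    atom-name convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError on garbage
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for model in st for ch in model):
        raise EmptyStructureError(f"{path} contains no ATOM/HETATM records")

    water_set = frozenset(water_residues)
    atoms: list[Atom] = []
    first = st[0]
    for chain in first:
        for residue in chain:
            is_het = residue.het_flag == "H"
            for gatom in _select_altloc(residue):
                if gatom.element.is_hydrogen:
                    element = "H"
                elif gatom.element.name and gatom.element.name != "X":
                    element = gatom.element.name
                else:
                    element = _element_from_name(gatom.name, residue.name, is_het)
                atoms.append(
                    Atom(
                        serial=gatom.serial,
                        name=gatom.name,
                        element=element,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        is_het=is_het,
                        is_water=residue.name in water_set,
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{path} contains no atoms")

    n = len(atoms)
    extra = []
    for model in list(st)[1:]:
        coords = []
        for chain in model:
            for residue in chain:
                for gatom in _select_altloc(residue):
                    coords.append([gatom.pos.x, gatom.pos.y, gatom.pos.z])
        arr = np.asarray(coords, dtype=float)
        if arr.shape != (n, 3):
            raise FormatError(
                f"{path}: model with {arr.shape[0]} atoms, first model has {n}"
            )
        extra.append(arr)
    return Structure(atoms=atoms, extra_models=extra, identifier=path.stem)


def _read_xyz_frames(path: Path) -> list[np.ndarray]:
    """Parse an XYZ frame stack: repeated [count, comment, count*rows]."""
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path}: truncated frame at line {i + 1}")
        coords = np.empty((n, 3))
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: bad XYZ row: {ln!r}")
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return frames


def read_trajectory(path: str | Path, topology: Structure | None = None) -> Trajectory:
    """Read a coordinate ensemble.

    Multi-model PDB files need no topology; XYZ frame stacks require one.
    Frame order follows the file; coordinates are Å.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        if topology is None:
            raise ValueError("XYZ frame stacks require an explicit topology")
        frames = _read_xyz_frames(path)
        n = len(topology.atoms)
        for i, f in enumerate(frames):
            if f.shape[0] != n:
                raise FormatError(
                    f"{path}: frame {i} has {f.shape[0]} atoms, topology has {n}"
                )
        return Trajectory(topology=topology, frames=frames)
    structure = read_pdb(path)
    if topology is not None and len(topology.atoms) != len(structure.atoms):
        raise FormatError(
            f"{path}: file has {len(structure.atoms)} atoms per model, "
            f"topology has {len(topology.atoms)}"
        )
    traj = Trajectory.from_structure(structure)
    if topology is not None:
        traj = Trajectory(topology=topology, frames=traj.frames)
    return traj


# --- ranking serialization -------------------------------------------------

_RANKING_COLUMNS = [
    "chain", "residue_name", "residue_number", "acceptor_atom",
    "ln_k", "atom_count", "n_covalent", "n_hbond", "n_space", "uses_fe_his_link",
]


def ranking_to_frame(ranking) -> pd.DataFrame:
    """Flatten a ResidueRanking into a stable-column DataFrame."""
    rows = []
    for row in ranking.rows:
        chain, resnum, resname = row.residue_id
        kinds = row.path.kind_counts
        rows.append(
            {
                "chain": chain,
                "residue_name": resname,
                "residue_number": resnum,
                "acceptor_atom": row.acceptor_atom,
                "ln_k": row.path.ln_k,
                "atom_count": row.path.atom_count,
                "n_covalent": kinds.get("covalent", 0),
                "n_hbond": kinds.get("hbond", 0),
                "n_space": kinds.get("space", 0),
                "uses_fe_his_link": bool(row.uses_fe_his_link),
            }
        )
    return pd.DataFrame(rows, columns=_RANKING_COLUMNS)


def write_ranking(ranking, dest: str | Path, format: str = "tsv") -> None:
    """Serialize a residue ranking as TSV or JSON (one row per residue).

    The JSON form round-trips bit-exactly through :func:`read_ranking`.
    """
    if isinstance(ranking, pd.DataFrame):
        frame = ranking
    else:
        frame = ranking_to_frame(ranking)
    if frame.empty:
        raise ValueError("refusing to write an empty ranking")
    dest = Path(dest)
    if format == "tsv":
        frame.to_csv(dest, sep="\t", index=False)
    elif format == "json":
        records = frame.to_dict(orient="records")
        for rec in records:  # keep -inf JSON-representable
            if isinstance(rec["ln_k"], float) and math.isinf(rec["ln_k"]):
                rec["ln_k"] = None
        dest.write_text(json.dumps({"ranking": records}, indent=1) + "\n")
    else:
        raise ValueError(f"unknown ranking format: {format!r}")


def read_ranking(path: str | Path) -> pd.DataFrame:
    """Read a ranking written by :func:`write_ranking`."""
    path = Path(path)
    if path.suffix == ".json" or path.read_text(encoding="utf-8", errors="replace")[0] == "{":
        records = json.loads(path.read_text())["ranking"]
        for rec in records:
            if rec["ln_k"] is None:
                rec["ln_k"] = float("-inf")
        return pd.DataFrame(records, columns=_RANKING_COLUMNS)
    return pd.read_csv(path, sep="\t")
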