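"""Coordinate data model: atoms, structures, ensembles, selections and PDB I/O.

Structures are ordered atom lists with chain / residue bookkeeping.  Multi-model
files use the classic fixed-column PDB dialect with MODEL/ENDMDL delimiters
(read and written through biotite); negative residue numbers are supported, and
hydrogens are first-class atoms.
"""

from __future__ import annotations

import fnmatch
import io
import re
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


@dataclass
class Atom:
    """A single atom; position in Å, residue_number may be negative."""
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")


class Structure:
    """An ordered collection of atoms with fast array access."""

    def __init__(self, atoms: list[Atom], metadata: dict | None = None):
        self.atoms = list(atoms)
        self.metadata = dict(metadata or {})
        self._coords = np.array([a.position for a in self.atoms], dtype=float) \
            if self.atoms else np.zeros((0, 3))
        for a, row in zip(self.atoms, self._coords):
            a.position = row  # share storage

    def __len__(self):
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    @coords.setter
    def coords(self, value):
        value = np.asarray(value, dtype=float)
        if value.shape != self._coords.shape:
            raise ValueError("coordinate array shape mismatch")
        self._coords[:] = value

    @property
    def chain_ids(self) -> list[str]:
        seen = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def residue_numbers(self, chain_id: str | None = None) -> list[int]:
        seen = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if a.residue_number not in seen:
                seen.append(a.residue_number)
        return seen

    def copy(self) -> "Structure":
        return Structure(
            [Atom(a.name, a.element, a.residue_number, a.residue_name,
                  a.chain_id, a.position.copy()) for a in self.atoms],
            metadata=dict(self.metadata))

    def index_map(self) -> dict[tuple[str, int, str], int]:
        """(chain, residue_number, atom_name) -> atom index."""
        return {(a.chain_id, a.residue_number, a.name): i
                for i, a in enumerate(self.atoms)}

    def same_topology(self, other: "Structure") -> bool:
        if len(self) != len(other):
            return False
        return all(a.name == b.name and a.residue_number == b.residue_number
                   and a.chain_id == b.chain_id
                   for a, b in zip(self.atoms, other.atoms))


@dataclass
class ModelEnergies:
    """Decomposed energies of one annealed model (kcal mol⁻¹)."""
    e_total: float
    e_vdw: float = 0.0
    e_ncs: float = 0.0
    e_distance_restraints: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.e_total):
            raise ValueError("e_total must be finite")


@dataclass
class Ensemble:
    """Models with identical topology plus per-model energy records."""
    models: list[Structure]
    energies: list[ModelEnergies] = field(default_factory=list)

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        ref = self.models[0]
        for m in self.models[1:]:
            if not ref.same_topology(m):
                raise ValueError("ensemble models have heterogeneous topologies")
        if self.energies and len(self.energies) != len(self.models):
            raise ValueError("energies length must match models length")

    def __len__(self):
        return len(self.models)


# --- selections ------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"^(chain\s+\S+|resi\s+[-0-9,:]+|name\s+\S+)$", re.IGNORECASE)


@dataclass
class Selection:
    """Residue-range and atom-name selection with wildcards.

    Expression syntax: clauses joined by ``and``; clauses are
    ``chain <id>``, ``resi <ranges>`` (e.g. ``10:20,25,-9:0``) and
    ``name <patterns>`` (comma separated, ``*``/``?`` wildcards, e.g. ``HB*``).
    Residue ranges use ``:`` so negative numbers stay unambiguous.
    """
    expression: str

    def _parse(self):
        cached = getattr(self, "_parsed", None)
        if cached is not None and cached[0] == self.expression:
            return cached[1]
        spec = self._parse_uncached()
        object.__setattr__(self, "_parsed", (self.expression, spec))
        return spec

    def _parse_uncached(self):
        chain = None
        res_ranges = None
        patterns = None
        expr = self.expression.strip()
        if not expr:
            raise ValueError("empty selection expression")
        for clause in re.split(r"\s+and\s+", expr):
            clause = clause.strip()
            if not _TOKEN_RE.match(clause):
                raise ValueError(f"invalid selection clause: {clause!r}")
            key, arg = clause.split(None, 1)
            key = key.lower()
            if key == "chain":
                chain = arg
            elif key == "resi":
                res_ranges = []
                for part in arg.split(","):
                    if ":" in part:
                        lo, hi = part.split(":")
                        res_ranges.append((int(lo), int(hi)))
                    else:
                        v = int(part)
                        res_ranges.append((v, v))
            elif key == "name":
                patterns = [p.strip() for p in arg.split(",") if p.strip()]
        return chain, res_ranges, patterns

    def matches(self, atom: Atom) -> bool:
        chain, res_ranges, patterns = self._parse()
        if chain is not None and atom.chain_id != chain:
            return False
        if res_ranges is not None and not any(
                lo <= atom.residue_number <= hi for lo, hi in res_ranges):
            return False
        if patterns is not None and not any(
                fnmatch.fnmatchcase(atom.name, p) for p in patterns):
            return False
        return True


def select(structure: Structure, selection: Selection) -> list[int]:
    """Atom indices matching the selection, in structure order."""
    chain, res_ranges, patterns = selection._parse()
    out = []
    for i, a in enumerate(structure.atoms):
        if chain is not None and a.chain_id != chain:
            continue
        if res_ranges is not None and not any(
                lo <= a.residue_number <= hi for lo, hi in res_ranges):
            continue
        if patterns is not None and not any(
                fnmatch.fnmatchcase(a.name, p) for p in patterns):
            continue
        out.append(i)
    return out


def select_atoms(structure: Structure, selection: Selection) -> list[Atom]:
    return [structure.atoms[i] for i in select(structure, selection)]


# --- PDB I/O ---------------------------------------------------------------

def _stack_to_models(stack, metadata) -> list[Structure]:
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    models = []
    n = stack.array_length()
    for mi in range(stack.stack_depth()):
        atoms = []
        coord = stack.coord[mi]
        for k in range(n):
            elem = stack.element[k].upper()
            atoms.append(Atom(
                name=stack.atom_name[k],
                element=elem,
                residue_number=int(stack.res_id[k]),
                residue_name=stack.res_name[k],
                chain_id=stack.chain_id[k],
                position=coord[k],
            ))
        models.append(Structure(atoms, metadata=dict(metadata)))
    return models


def read_ensemble(text: str) -> Ensemble:
    """Parse a (possibly multi-model) PDB text into an Ensemble."""
    if not text.strip():
        raise ValueError("empty coordinate file")
    try:
        pdb = PDBFile.read(io.StringIO(text))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"malformed PDB record: {exc}") from exc
    models = _stack_to_models(stack, {"source": "pdb"})
    return Ensemble(models=models)


def read_structure(text: str) -> Structure:
    """Parse PDB text; returns the first model."""
    return read_ensemble(text).models[0]


def _structure_to_atom_array(s: Structure):
    n = len(s)
    arr = struc.AtomArray(n)
    arr.coord = s.coords.copy()
    arr.chain_id = np.array([a.chain_id for a in s.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_number for a in s.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in s.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in s.atoms], dtype="U6")
    # PDB element column is written capitalized
    arr.element = np.array([a.element.upper() for a in s.atoms], dtype="U2")
    arr.hetero = np.array([a.residue_name in ("ZN",) for a in s.atoms])
    return arr


def write_ensemble(ensemble: Ensemble) -> str:
    """Render an ensemble as multi-model PDB text (coordinates to 3 decimals)."""
    ref = ensemble.models[0]
    for m in ensemble.models[1:]:
        if not ref.same_topology(m):
            raise ValueError("ensemble models have heterogeneous topologies")
    arrays = [_structure_to_atom_array(m) for m in ensemble.models]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    buf = io.StringIO()
    pdb.write(buf)
    text = buf.getvalue()
    if len(ensemble.models) == 1 and "MODEL" not in text:
        # always delimit models, even for a single-model ensemble
        body = text.rstrip("\n")
        text = "MODEL        1\n" + body + "\nENDMDL\n"
    return text


def write_structure(structure: Structure) -> str:
    return write_ensemble(Ensemble(models=[structure]))
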