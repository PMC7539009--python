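"""Residue topology: ideal internal coordinates, chain building and bonded-term lists.

The annealing engine uses a deliberately small amino-acid alphabet (Gly, Ala,
Ser, Cys, Leu, Met and the seleno-Met variant) with explicit hydrogens.  Ideal
bond lengths and angles are taken from the same internal-coordinate table that
the chain builder uses, so structures built here satisfy the bonded force field
exactly by construction.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

# van der Waals-ish radii used by the repulsive nonbonded term and SASA (Å)
ELEMENT_RADII = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "ZN": 1.39,
}

# Uniform heavy mass (amu): standard practice in simulated-annealing structure
# calculation, removes fast hydrogen vibrations so a larger timestep is stable.
ATOM_MASS = 100.0

BACKBONE_NAMES = ("N", "CA", "C")
BACKBONE_NAMES_O = ("N", "CA", "C", "O")

# --- internal coordinate helpers ------------------------------------------


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: new atom D bonded to C, with angle B-C-D and
    torsion A-B-C-D (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        # collinear reference frame; pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        n_norm = np.linalg.norm(n)
    n = n / n_norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    cosa = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosa, -1.0, 1.0)))


# --- residue definitions ---------------------------------------------------
# Sidechain internal coordinates: atom -> (A, B, C, bond, angle, torsion).
# Torsion may be a float (degrees) or a string "chi1"/"chi2" resolved at build
# time from the requested rotamer.  Reference atoms may name backbone atoms.

_SC = {
    "GLY": {},
    "ALA": {
        "CB":  ("C", "N", "CA", 1.530, 110.5, -122.6),
        "HB1": ("N", "CA", "CB", 1.090, 109.5, "chi1"),
        "HB2": ("N", "CA", "CB", 1.090, 109.5, "chi1+120"),
        "HB3": ("N", "CA", "CB", 1.090, 109.5, "chi1-120"),
    },
    "CYS": {
        "CB":  ("C", "N", "CA", 1.530, 110.5, -122.6),
        "SG":  ("N", "CA", "CB", 1.808, 114.4, "chi1"),
        "HB2": ("SG", "CA", "CB", 1.090, 109.5, 120.0),
        "HB3": ("SG", "CA", "CB", 1.090, 109.5, -120.0),
    },
    "SER": {
        "CB":  ("C", "N", "CA", 1.530, 110.5, -122.6),
        "OG":  ("N", "CA", "CB", 1.417, 110.8, "chi1"),
        "HB2": ("OG", "CA", "CB", 1.090, 109.5, 120.0),
        "HB3": ("OG", "CA", "CB", 1.090, 109.5, -120.0),
        "HG":  ("CA", "CB", "OG", 0.960, 109.5, 180.0),
    },
    "LEU": {
        "CB":  ("C", "N", "CA", 1.530, 110.5, -122.6),
        "CG":  ("N", "CA", "CB", 1.530, 116.3, "chi1"),
        "HB2": ("CG", "CA", "CB", 1.090, 109.5, 120.0),
        "HB3": ("CG", "CA", "CB", 1.090, 109.5, -120.0),
        "CD1": ("CA", "CB", "CG", 1.530, 110.7, "chi2"),
        "CD2": ("CA", "CB", "CG", 1.530, 110.7, "chi2+120"),
        "HG":  ("CA", "CB", "CG", 1.090, 109.5, "chi2-120"),
        "HD11": ("CB", "CG", "CD1", 1.090, 109.5, 180.0),
        "HD12": ("CB", "CG", "CD1", 1.090, 109.5, 60.0),
        "HD13": ("CB", "CG", "CD1", 1.090, 109.5, -60.0),
        "HD21": ("CB", "CG", "CD2", 1.090, 109.5, 180.0),
        "HD22": ("CB", "CG", "CD2", 1.090, 109.5, 60.0),
        "HD23": ("CB", "CG", "CD2", 1.090, 109.5, -60.0),
    },
    "MET": {
        "CB":  ("C", "N", "CA", 1.530, 110.5, -122.6),
        "CG":  ("N", "CA", "CB", 1.520, 114.1, "chi1"),
        "HB2": ("CG", "CA", "CB", 1.090, 109.5, 120.0),
        "HB3": ("CG", "CA", "CB", 1.090, 109.5, -120.0),
        "SD":  ("CA", "CB", "CG", 1.803, 112.7, "chi2"),
        "HG2": ("SD", "CB", "CG", 1.090, 109.5, 120.0),
        "HG3": ("SD", "CB", "CG", 1.090, 109.5, -120.0),
        "CE":  ("CB", "CG", "SD", 1.791, 100.9, 180.0),
        "HE1": ("CG", "SD", "CE", 1.090, 109.5, 180.0),
        "HE2": ("CG", "SD", "CE", 1.090, 109.5, 60.0),
        "HE3": ("CG", "SD", "CE", 1.090, 109.5, -60.0),
    },
}
# seleno-methionine: same shape, selenium in place of SD (placement order matters)
_SC["MSE"] = {
    "CB":  ("C", "N", "CA", 1.530, 110.5, -122.6),
    "CG":  ("N", "CA", "CB", 1.520, 114.1, "chi1"),
    "HB2": ("CG", "CA", "CB", 1.090, 109.5, 120.0),
    "HB3": ("CG", "CA", "CB", 1.090, 109.5, -120.0),
    "SE":  ("CA", "CB", "CG", 1.950, 112.7, "chi2"),
    "HG2": ("SE", "CB", "CG", 1.090, 109.5, 120.0),
    "HG3": ("SE", "CB", "CG", 1.090, 109.5, -120.0),
    "CE":  ("CB", "CG", "SE", 1.950, 100.9, 180.0),
    "HE1": ("CG", "SE", "CE", 1.090, 109.5, 180.0),
    "HE2": ("CG", "SE", "CE", 1.090, 109.5, 60.0),
    "HE3": ("CG", "SE", "CE", 1.090, 109.5, -60.0),
}

_SC_BONDS = {
    "GLY": [],
    "ALA": [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3")],
    "CYS": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "SG")],
    "SER": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "OG"), ("OG", "HG")],
    "LEU": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"), ("CG", "HG"),
            ("CG", "CD1"), ("CD1", "HD11"), ("CD1", "HD12"), ("CD1", "HD13"),
            ("CG", "CD2"), ("CD2", "HD21"), ("CD2", "HD22"), ("CD2", "HD23")],
    "MET": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "HG2"), ("CG", "HG3"), ("CG", "SD"), ("SD", "CE"),
            ("CE", "HE1"), ("CE", "HE2"), ("CE", "HE3")],
}
_SC_BONDS["MSE"] = [(a.replace("SD", "SE"), b.replace("SD", "SE"))
                    for a, b in _SC_BONDS["MET"]]

# default sidechain rotamers used when none requested
_DEFAULT_CHI = {"chi1": -65.0, "chi2": 175.0}

SUPPORTED_RESIDUES = tuple(_SC.keys())

# equivalent-proton groups (wildcard name -> member atoms), used for ambiguous
# group restraints and NOE peak simulation
EQUIVALENT_GROUPS = {
    "GLY": {"HA*": ["HA2", "HA3"]},
    "ALA": {"HB*": ["HB1", "HB2", "HB3"]},
    "CYS": {"HB*": ["HB2", "HB3"]},
    "SER": {"HB*": ["HB2", "HB3"]},
    "LEU": {"HB*": ["HB2", "HB3"], "HD1*": ["HD11", "HD12", "HD13"],
            "HD2*": ["HD21", "HD22", "HD23"]},
    "MET": {"HB*": ["HB2", "HB3"], "HG*": ["HG2", "HG3"],
            "HE*": ["HE1", "HE2", "HE3"]},
}
EQUIVALENT_GROUPS["MSE"] = EQUIVALENT_GROUPS["MET"]


def _element_of(name: str, resname: str) -> str:
    if name == "SE" or (resname == "MSE" and name == "SE"):
        return "SE"
    if name.startswith("ZN"):
        return "ZN"
    return name[0]


def residue_atom_names(resname: str, n_terminal: bool = False) -> list[str]:
    """Ordered atom names for one residue (PDB-style ordering)."""
    if resname not in _SC:
        raise KeyError(f"unsupported residue type: {resname}")
    names = ["N", "H", "CA"]
    if resname == "GLY":
        names += ["HA2", "HA3"]
    else:
        names += ["HA"]
    names += ["C", "O"]
    sc = [n for n in _SC[resname] if n != "CB"]
    if resname != "GLY":
        names.insert(names.index("C"), "CB")
        for n in sc:
            names.insert(names.index("C"), n)
    else:
        pass
    return names


def build_chain(sequence: list[str],
                phi: np.ndarray, psi: np.ndarray, omega: np.ndarray | None = None,
                chi1: np.ndarray | None = None, chi2: np.ndarray | None = None):
    """Build an ideal-geometry peptide chain.

    Parameters are per-residue arrays in degrees; ``phi[0]`` and ``psi[-1]``
    are still used (for H/O placement) even though they are not true backbone
    torsions.  Returns (names, elements, resnames, resnums, coords).
    """
    n = len(sequence)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if omega is None:
        omega = np.full(n, 180.0)
    if chi1 is None:
        chi1 = np.full(n, _DEFAULT_CHI["chi1"])
    if chi2 is None:
        chi2 = np.full(n, _DEFAULT_CHI["chi2"])

    names: list[str] = []
    elements: list[str] = []
    resnames: list[str] = []
    resnums: list[int] = []
    coords: list[np.ndarray] = []
    index: dict[tuple[int, str], int] = {}

    def add(i, name, pos):
        names.append(name)
        elements.append(_element_of(name, sequence[i]))
        resnames.append(sequence[i])
        resnums.append(i + 1)
        coords.append(np.asarray(pos, dtype=float))
        index[(i, name)] = len(coords) - 1

    def pos(i, name):
        return coords[index[(i, name)]]

    for i, res in enumerate(sequence):
        if res not in _SC:
            raise KeyError(f"unsupported residue type: {res}")
        if i == 0:
            add(i, "N", [0.0, 0.0, 0.0])
            add(i, "H", place_atom(np.array([1.0, 1.0, 0.0]),
                                   np.array([1.0, 0.0, 0.0]),
                                   pos(i, "N"), 1.010, 119.0, 180.0))
            add(i, "CA", [1.458, 0.0, 0.0])
            cpos = place_atom(pos(i, "H"), pos(i, "N"),
                              pos(i, "CA"), 1.525, 111.2, phi[0] + 180.0)
            add(i, "C", cpos)
        else:
            npos = place_atom(pos(i - 1, "N"), pos(i - 1, "CA"),
                              pos(i - 1, "C"), 1.329, 116.2, psi[i - 1])
            add(i, "N", npos)
            capos = place_atom(pos(i - 1, "CA"), pos(i - 1, "C"),
                               pos(i, "N"), 1.458, 121.7, omega[i])
            add(i, "CA", capos)
            hpos = place_atom(pos(i - 1, "CA"), pos(i - 1, "C"),
                              pos(i, "N"), 1.010, 119.0, omega[i] + 180.0)
            add(i, "H", hpos)
            cpos = place_atom(pos(i - 1, "C"), pos(i, "N"),
                              pos(i, "CA"), 1.525, 111.2, phi[i])
            add(i, "C", cpos)

        # HA / HA2+HA3 and sidechain, all referenced to local frame
        chi_vals = {"chi1": chi1[i], "chi2": chi2[i]}

        def resolve_torsion(spec):
            if isinstance(spec, str):
                base = spec[:4]
                off = float(spec[4:]) if len(spec) > 4 else 0.0
                return chi_vals[base] + off
            return float(spec)

        if res == "GLY":
            add(i, "HA2", place_atom(pos(i, "C"), pos(i, "N"), pos(i, "CA"),
                                     1.090, 109.5, -122.6))
            add(i, "HA3", place_atom(pos(i, "C"), pos(i, "N"), pos(i, "CA"),
                                     1.090, 109.5, 118.3))
        else:
            for name, (a, b, c, bl, ang, tor) in _SC[res].items():
                p = place_atom(pos(i, a), pos(i, b), pos(i, c),
                               bl, ang, resolve_torsion(tor))
                add(i, name, p)
            add(i, "HA", place_atom(pos(i, "C"), pos(i, "N"), pos(i, "CA"),
                                    1.090, 109.5, 118.3))
        # carbonyl O in the peptide plane, anti to the next N direction
        add(i, "O", place_atom(pos(i, "N"), pos(i, "CA"), pos(i, "C"),
                               1.231, 120.5, psi[i] + 180.0))

    return (names, elements, resnames, resnums,
            np.array(coords, dtype=float))


def residue_bonds(resname: str) -> list[tuple[str, str]]:
    """Intra-residue bonds by atom name."""
    bonds = [("N", "H"), ("N", "CA"), ("CA", "C"), ("C", "O")]
    if resname == "GLY":
        bonds += [("CA", "HA2"), ("CA", "HA3")]
    else:
        bonds += [("CA", "HA")]
        bonds += _SC_BONDS[resname]
    return bonds


@lru_cache(maxsize=None)
def _reference_residue(resname: str):
    """An ALA-X-ALA reference build used to read off ideal geometry values."""
    seq = ("ALA", resname, "ALA")
    names, elements, resnames, resnums, coords = build_chain(
        list(seq), phi=np.array([-57.0] * 3), psi=np.array([-47.0] * 3))
    idx = {(resnums[k], names[k]): k for k in range(len(names))}
    return idx, coords


@lru_cache(maxsize=None)
def reference_geometry(resname: str):
    """Ideal bonded geometry for one residue type, read off a reference build.

    Returns dicts keyed by atom-name tuples:
      bonds[(a, b)] -> length (Å), intra-residue, plus peptide-link entries
        keyed with a "+"/"-" prefix for the neighbouring residue's atom;
      angles[(a, b, c)] -> degrees (b is the vertex);
      impropers[(a, b, c, d)] -> degrees (chirality/planarity dihedrals).
    """
    idx, coords = _reference_residue(resname)

    def p(res_i, name):
        return coords[idx[(res_i, name)]]

    bonds: dict[tuple[str, str], float] = {}
    for a, b in residue_bonds(resname):
        bonds[(a, b)] = float(np.linalg.norm(p(2, a) - p(2, b)))
    # peptide link: C(i)-N(i+1)
    bonds[("C", "+N")] = float(np.linalg.norm(p(2, "C") - p(3, "N")))

    # angle list: every connected triple within the residue
    neigh: dict[str, list[str]] = {}
    for a, b in residue_bonds(resname):
        neigh.setdefault(a, []).append(b)
        neigh.setdefault(b, []).append(a)
    angles: dict[tuple[str, str, str], float] = {}
    for b, nbrs in neigh.items():
        for ii in range(len(nbrs)):
            for jj in range(ii + 1, len(nbrs)):
                a, c = nbrs[ii], nbrs[jj]
                angles[(a, b, c)] = bond_angle(p(2, a), p(2, b), p(2, c))
    # peptide-link angles
    angles[("CA", "C", "+N")] = bond_angle(p(2, "CA"), p(2, "C"), p(3, "N"))
    angles[("O", "C", "+N")] = bond_angle(p(2, "O"), p(2, "C"), p(3, "N"))
    angles[("C", "+N", "+CA")] = bond_angle(p(2, "C"), p(3, "N"), p(3, "CA"))
    angles[("C", "+N", "+H")] = bond_angle(p(2, "C"), p(3, "N"), p(3, "H"))

    impropers: dict[tuple[str, str, str, str], float] = {}
    if resname != "GLY":
        # CA chirality (keeps the L-configuration under annealing)
        impropers[("N", "C", "CA", "CB")] = dihedral_angle(
            p(2, "N"), p(2, "C"), p(2, "CA"), p(2, "CB"))
    # carbonyl / amide planarity across the peptide link
    impropers[("CA", "+N", "C", "O")] = dihedral_angle(
        p(2, "CA"), p(3, "N"), p(2, "C"), p(2, "O"))
    impropers[("C", "+CA", "+N", "+H")] = dihedral_angle(
        p(2, "C"), p(3, "CA"), p(3, "N"), p(3, "H"))
    return bonds, angles, impropers
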