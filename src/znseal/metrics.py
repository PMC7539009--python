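"""Ensemble analysis: rigid superposition, pairwise / to-mean rmsd statistics,
restraint-violation tables and solvent-accessible / buried surface areas.

Superposition is closed-form least squares (Kabsch, via SVD).  Pairwise rmsd
superposes every unordered model pair independently on the evaluated
selection, matching the "average pairwise rmsd" convention of NMR ensemble
tables; rmsd-to-mean iterates superposition onto the coordinate average until
the mean structure converges.  SASA uses Shrake–Rupley sphere sampling with
960 points per atom and a 1.4 Å probe; hydrogens are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Ensemble, Selection, Structure, select
from .restraints import (DihedralRestraint, DistanceRestraint,
                         effective_distance)
from .topology import ELEMENT_RADII, dihedral_angle

BACKBONE_SCOPE = ("N", "CA", "C")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RmsdReport:
    selection: Selection
    mean_pairwise: float
    sd_pairwise: float
    mean_to_mean: float
    n_models: int


@dataclass
class ViolationReport:
    mean_distance_violation: float
    sd_distance_violation: float
    max_distance_violation: float
    mean_dihedral_violation: float
    max_dihedral_violation: float


@dataclass
class SasaResult:
    per_atom_area: np.ndarray
    total: float
    probe_radius: float


# --- superposition ----------------------------------------------------------

def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return rot, trans


def superpose(mobile: Structure | np.ndarray,
              reference: Structure | np.ndarray,
              selection: Selection | None = None) -> SuperpositionResult:
    """Optimal least-squares rigid superposition of mobile onto reference.

    With a selection, the transform is fitted on the selected atoms (mapped
    1:1 by order) and the rmsd reported on that selection.
    """
    if isinstance(mobile, Structure):
        if selection is not None:
            idx_m = select(mobile, selection)
            idx_r = select(reference, selection)
        else:
            idx_m = list(range(len(mobile)))
            idx_r = list(range(len(reference)))
        if len(idx_m) != len(idx_r):
            raise ValueError("selection does not map 1:1 between structures")
        pm = mobile.coords[idx_m]
        pr = reference.coords[idx_r]
    else:
        pm = np.asarray(mobile, float)
        pr = np.asarray(reference, float)
    if pm.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    span = np.linalg.matrix_rank(pm - pm.mean(axis=0), tol=1e-8)
    if span < 2:
        raise ValueError("degenerate (collinear) selection geometry")
    rot, trans = _kabsch(pm, pr)
    moved = pm @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - pr) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _selection_coords(model: Structure, selection: Selection,
                      atom_scope: tuple | None) -> np.ndarray:
    idx = select(model, selection)
    if atom_scope is not None:
        idx = [i for i in idx if model.atoms[i].name in atom_scope]
    if not idx:
        raise ValueError("selection matches no atoms")
    return model.coords[idx]


def pairwise_rmsd(ensemble: Ensemble, selection: Selection,
                  atom_scope: tuple | str | None = BACKBONE_SCOPE) -> RmsdReport:
    """Mean ± sd of rmsd over all unordered model pairs, each pair superposed
    independently on the evaluated selection.

    ``atom_scope`` may be the tuple of names, "backbone" (N, Cα, C′),
    "heavy" (all non-hydrogen atoms) or None (all selected atoms).
    """
    if len(ensemble) < 2:
        raise ValueError("need at least two models")
    scope = atom_scope
    if atom_scope == "backbone":
        scope = BACKBONE_SCOPE
    coords = []
    for m in ensemble.models:
        if atom_scope == "heavy":
            idx = [i for i in select(m, selection)
                   if m.atoms[i].element != "H"]
            if not idx:
                raise ValueError("selection matches no atoms")
            coords.append(m.coords[idx])
        else:
            coords.append(_selection_coords(m, selection, scope))
    vals = []
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            vals.append(superpose(coords[i], coords[j]).rmsd)
    vals = np.array(vals)
    mean_to_mean = float(np.mean(rmsd_to_mean_coords(coords)))
    return RmsdReport(selection=selection,
                      mean_pairwise=float(vals.mean()),
                      sd_pairwise=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                      mean_to_mean=mean_to_mean,
                      n_models=n)


def rmsd_to_mean_coords(coords: list[np.ndarray], tol: float = 1e-6,
                        max_iter: int = 100) -> np.ndarray:
    """Per-model rmsd to the iteratively converged mean structure."""
    aligned = [c.copy() for c in coords]
    ref = aligned[0]
    for c in aligned[1:]:
        sp = superpose(c, ref)
        c[:] = sp.apply(c)
    mean = np.mean(aligned, axis=0)
    for _ in range(max_iter):
        for c in aligned:
            sp = superpose(c, mean)
            c[:] = sp.apply(c)
        new_mean = np.mean(aligned, axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return np.array([
        np.sqrt(np.mean(np.sum((c - mean) ** 2, axis=1))) for c in aligned])


def rmsd_to_mean(ensemble: Ensemble, selection: Selection,
                 atom_scope: tuple | str | None = BACKBONE_SCOPE):
    """Per-model rmsd to the converged mean structure, plus the ensemble mean."""
    if len(ensemble) < 2:
        raise ValueError("need at least two models")
    scope = BACKBONE_SCOPE if atom_scope == "backbone" else atom_scope
    coords = [_selection_coords(m, selection, scope) for m in ensemble.models]
    per_model = rmsd_to_mean_coords(coords)
    return per_model, float(per_model.mean())


# --- restraint statistics ---------------------------------------------------

def dihedral_violation(structure: Structure,
                       restraint: DihedralRestraint) -> float:
    """Degrees outside [target − half_width, target + half_width], wrapped."""
    imap = structure.index_map()
    pts = [structure.coords[imap[k]] for k in restraint.atoms]
    ang = dihedral_angle(*pts)
    diff = (ang - restraint.target + 180.0) % 360.0 - 180.0
    return max(0.0, abs(diff) - restraint.half_width)


def restraint_statistics(ensemble: Ensemble,
                         restraints: list[DistanceRestraint],
                         dihedrals: list[DihedralRestraint] | None = None
                         ) -> ViolationReport:
    """Mean ± sd of per-restraint-per-model violations, plus maxima."""
    dist_viols = []
    for m in ensemble.models:
        for r in restraints:
            d = effective_distance(m, r)
            dist_viols.append(max(0.0, d - r.upper))
    dist_viols = np.array(dist_viols) if dist_viols else np.zeros(1)
    dihe_viols = []
    for m in ensemble.models:
        for r in (dihedrals or []):
            dihe_viols.append(dihedral_violation(m, r))
    dihe_viols = np.array(dihe_viols) if dihe_viols else np.zeros(1)
    return ViolationReport(
        mean_distance_violation=float(dist_viols.mean()),
        sd_distance_violation=float(dist_viols.std(ddof=1))
        if len(dist_viols) > 1 else 0.0,
        max_distance_violation=float(dist_viols.max()),
        mean_dihedral_violation=float(dihe_viols.mean()),
        max_dihedral_violation=float(dihe_viols.max()))


# --- solvent accessibility ---------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def sasa(structure: Structure, probe: float = 1.4,
         scope: Selection | None = None, n_points: int = 960,
         include_hydrogens: bool = False) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area (Å²).

    Occlusion is computed against every atom of the structure; per-atom areas
    are reported for the scope selection (default: all non-hydrogen atoms).
    """
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    atoms = structure.atoms
    mask = np.ones(len(atoms), dtype=bool)
    if not include_hydrogens:
        mask &= np.array([a.element != "H" for a in atoms])
    try:
        radii = np.array([ELEMENT_RADII[a.element] for a in atoms])
    except KeyError as exc:
        raise KeyError(f"no radius for element {exc.args[0]!r}") from exc
    coords = structure.coords
    ext = radii + probe
    occl_idx = np.where(mask)[0]
    tree = cKDTree(coords[occl_idx])
    sphere = _fibonacci_sphere(n_points)
    if scope is None:
        target_idx = occl_idx
    else:
        target_idx = np.array([i for i in select(structure, scope)
                               if mask[i]], dtype=int)
    per_atom = np.zeros(len(atoms))
    max_ext = ext[occl_idx].max() if len(occl_idx) else 0.0
    for i in target_idx:
        pts = coords[i] + ext[i] * sphere
        neigh = occl_idx[tree.query_ball_point(coords[i], ext[i] + max_ext)]
        neigh = neigh[neigh != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * np.pi * ext[i] ** 2
    return SasaResult(per_atom_area=per_atom[target_idx],
                      total=float(per_atom[target_idx].sum()),
                      probe_radius=probe)


def buried_surface(complex_structure: Structure, chain_a: Selection,
                   chain_b: Selection, probe: float = 1.4,
                   n_points: int = 960) -> float:
    """Two-sided buried surface: SASA(A) + SASA(B) − SASA(A∪B) (Å²)."""
    ia = select(complex_structure, chain_a)
    ib = select(complex_structure, chain_b)
    if not ia or not ib:
        raise ValueError("both chain selections must be non-empty")
    if set(ia) & set(ib):
        raise ValueError("chain selections overlap")
    sub_a = Structure([complex_structure.atoms[i] for i in ia])
    sub_b = Structure([complex_structure.atoms[i] for i in ib])
    sub_ab = Structure([complex_structure.atoms[i] for i in sorted(ia + ib)])
    a = sasa(sub_a, probe=probe, n_points=n_points).total
    b = sasa(sub_b, probe=probe, n_points=n_points).total
    ab = sasa(sub_ab, probe=probe, n_points=n_points).total
    return a + b - ab
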