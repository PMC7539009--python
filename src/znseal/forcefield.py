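"""Simplified annealing force field.

Terms: harmonic bonds / angles / impropers from ideal residue geometry, a
peptide-bond omega torsion well (trans by default, cis where requested), a
purely repulsive quartic nonbonded term with a ramped scale factor, ambiguous
r⁻⁶ NOE distance restraints (soft square well with a tiltable linear
asymptote, switchable to a hard square well), harmonic χ¹ dihedral
restraints, tiered template (NCS) restraints and Zn–S bond/angle terms.

No electrostatics, no attractive van der Waals term and no database torsion
potential: this matches common NMR structure-calculation practice where the
experimental restraints plus covalent geometry carry the information.

Units: kcal mol⁻¹, Å, radians internally for angles; AKMA-style time unit
(≈48.89 fs) for dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial import cKDTree

from .core import Structure
from .restraints import (DihedralRestraint, DistanceRestraint, NCSRestraint,
                         expand_group)
from .topology import ELEMENT_RADII, ATOM_MASS, reference_geometry, \
    residue_bonds

KB = 0.0019872041  # kcal mol⁻¹ K⁻¹

# default force constants (kcal mol⁻¹ per Å² or rad²)
K_BOND = 500.0
K_ANGLE = 100.0
K_IMPROPER = 50.0
K_OMEGA = 25.0
K_NOE = 50.0
K_DIHEDRAL = 50.0
K_ZN_BOND = 200.0
K_ZN_ANGLE = 30.0
ZN_S_LENGTH = 2.30       # Å
S_ZN_S_ANGLE = 109.5     # degrees
REPEL_SCALE_FULL = 4.0
REPEL_RADIUS_FACTOR = 0.80


def _wrap(delta):
    """Wrap angle difference to (-pi, pi]."""
    return (delta + np.pi) % (2.0 * np.pi) - np.pi


# --- vectorized geometry with gradients ------------------------------------

def _dihedrals_and_grads(coords, idx):
    """Signed dihedrals (rad) and gradients for index quadruples (n, 4)."""
    p0, p1, p2, p3 = (coords[idx[:, k]] for k in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    # angle
    m1 = np.cross(n1, b2 / b2n[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = -np.arctan2(y, x)  # matches topology.dihedral_angle convention
    # gradients of phi (standard rigid-rotation formulas, sign-matched)
    g0 = -(b2n / np.maximum(n1sq, 1e-12))[:, None] * n1
    g3 = (b2n / np.maximum(n2sq, 1e-12))[:, None] * n2
    f1 = np.einsum("ij,ij->i", b1, b2) / np.maximum(b2n ** 2, 1e-12)
    f2 = np.einsum("ij,ij->i", b3, b2) / np.maximum(b2n ** 2, 1e-12)
    g1 = -g0 - f1[:, None] * g0 + f2[:, None] * g3
    g2 = -g3 + f1[:, None] * g0 - f2[:, None] * g3
    return phi, (g0, g1, g2, g3)


# --- term containers --------------------------------------------------------

@dataclass
class HarmonicBonds:
    i: np.ndarray
    j: np.ndarray
    r0: np.ndarray
    k: np.ndarray

    def energy_forces(self, coords, forces):
        d = coords[self.i] - coords[self.j]
        r = np.linalg.norm(d, axis=1)
        dr = r - self.r0
        e = float(np.sum(self.k * dr ** 2))
        f = (-2.0 * self.k * dr / np.maximum(r, 1e-12))[:, None] * d
        np.add.at(forces, self.i, f)
        np.add.at(forces, self.j, -f)
        return e


@dataclass
class HarmonicAngles:
    idx: np.ndarray      # (n, 3): a, b (vertex), c
    theta0: np.ndarray   # radians
    k: np.ndarray

    def energy_forces(self, coords, forces):
        a, b, c = (coords[self.idx[:, t]] for t in range(3))
        u = a - b
        v = c - b
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cos_t = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 1e-10))
        dt = theta - self.theta0
        e = float(np.sum(self.k * dt ** 2))
        dedt = 2.0 * self.k * dt
        ga = (dedt / (nu * sin_t))[:, None] * (vh - cos_t[:, None] * uh)
        gc = (dedt / (nv * sin_t))[:, None] * (uh - cos_t[:, None] * vh)
        np.add.at(forces, self.idx[:, 0], ga)
        np.add.at(forces, self.idx[:, 2], gc)
        np.add.at(forces, self.idx[:, 1], -(ga + gc))
        return e


@dataclass
class HarmonicTorsions:
    """Harmonic well in the wrapped angle difference; optional flat half-width."""
    idx: np.ndarray       # (n, 4)
    target: np.ndarray    # radians
    k: np.ndarray
    half_width: np.ndarray | None = None
    scale: float = 1.0

    def energy_forces(self, coords, forces):
        if len(self.idx) == 0:
            return 0.0
        phi, grads = _dihedrals_and_grads(coords, self.idx)
        delta = _wrap(phi - self.target)
        if self.half_width is not None:
            mag = np.maximum(np.abs(delta) - self.half_width, 0.0)
            delta = np.sign(delta) * mag
        keff = self.scale * self.k
        e = float(np.sum(keff * delta ** 2))
        dedphi = 2.0 * keff * delta
        for t, g in enumerate(grads):
            np.add.at(forces, self.idx[:, t], -dedphi[:, None] * g)
        return e


@dataclass
class RepulsiveNonbonded:
    """Quartic repulsion E = scale · Σ (r₀² − r²)² for r < r₀,
    r₀ = factor · (R_i + R_j); bonded 1-2/1-3 pairs excluded."""
    radii: np.ndarray
    excluded: set          # frozenset pairs
    factor: float = REPEL_RADIUS_FACTOR
    scale: float = REPEL_SCALE_FULL

    def energy_forces(self, coords, forces):
        if self.scale <= 0.0:
            return 0.0
        rmax = 2.0 * self.factor * self.radii.max()
        tree = cKDTree(coords)
        pairs = tree.query_pairs(rmax, output_type="ndarray")
        if len(pairs) == 0:
            return 0.0
        ii, jj = pairs[:, 0], pairs[:, 1]
        keep = np.fromiter(
            ((int(a), int(b)) not in self.excluded for a, b in pairs),
            dtype=bool, count=len(pairs))
        ii, jj = ii[keep], jj[keep]
        d = coords[ii] - coords[jj]
        r2 = np.einsum("ij,ij->i", d, d)
        r0 = self.factor * (self.radii[ii] + self.radii[jj])
        ov = r0 ** 2 - r2
        act = ov > 0.0
        if not np.any(act):
            return 0.0
        ii, jj, d, ov = ii[act], jj[act], d[act], ov[act]
        e = float(self.scale * np.sum(ov ** 2))
        # dE/dx_i = scale * 2*ov * (-2*d)
        f = (4.0 * self.scale * ov)[:, None] * d
        np.add.at(forces, ii, f)
        np.add.at(forces, jj, -f)
        return e


@dataclass
class NOERestraints:
    """Ambiguous r⁻⁶ group restraints.

    Flattened cross-pair arrays (pair_i, pair_j) with a restraint id per pair;
    per-restraint upper bounds.  ``square_well=False`` uses the soft form whose
    violation branch turns linear with slope ``asymptote_slope`` beyond
    Δs = slope/(2k); True uses the hard harmonic square well.
    """
    pair_i: np.ndarray
    pair_j: np.ndarray
    rid: np.ndarray
    upper: np.ndarray
    n_restraints: int
    k: float = K_NOE
    square_well: bool = False
    asymptote_slope: float = 1.0

    def effective_distances(self, coords):
        d = coords[self.pair_i] - coords[self.pair_j]
        r2 = np.einsum("ij,ij->i", d, d)
        s = np.zeros(self.n_restraints)
        np.add.at(s, self.rid, r2 ** -3)
        return s ** (-1.0 / 6.0)

    def energy_forces(self, coords, forces):
        if len(self.pair_i) == 0:
            return 0.0
        dvec = coords[self.pair_i] - coords[self.pair_j]
        r2 = np.einsum("ij,ij->i", dvec, dvec)
        r2 = np.maximum(r2, 1e-8)
        inv6 = r2 ** -3
        s = np.zeros(self.n_restraints)
        np.add.at(s, self.rid, inv6)
        deff = s ** (-1.0 / 6.0)
        delta = deff - self.upper
        viol = delta > 0.0
        e_r = np.zeros(self.n_restraints)
        dedd = np.zeros(self.n_restraints)
        if self.square_well:
            e_r[viol] = self.k * delta[viol] ** 2
            dedd[viol] = 2.0 * self.k * delta[viol]
        else:
            ds = self.asymptote_slope / (2.0 * self.k)
            quad = viol & (delta <= ds)
            lin = viol & (delta > ds)
            e_r[quad] = self.k * delta[quad] ** 2
            dedd[quad] = 2.0 * self.k * delta[quad]
            e_r[lin] = (self.asymptote_slope * delta[lin]
                        - self.asymptote_slope ** 2 / (4.0 * self.k))
            dedd[lin] = self.asymptote_slope
        e = float(np.sum(e_r))
        # dd_eff/dr_pair = d_eff^7 * r^-7 ; chain rule through each pair
        ddeff = deff ** 7
        r = np.sqrt(r2)
        coeff = dedd[self.rid] * ddeff[self.rid] * r ** -7
        f = (-coeff)[:, None] * (dvec / r[:, None])
        np.add.at(forces, self.pair_i, f)
        np.add.at(forces, self.pair_j, -f)
        return e


@dataclass
class NCSTerm:
    """Harmonic restraint of selected atoms to stored template coordinates."""
    index: np.ndarray
    template: np.ndarray
    k: np.ndarray
    enabled: bool = True

    def energy_forces(self, coords, forces):
        if not self.enabled or len(self.index) == 0:
            return 0.0
        d = coords[self.index] - self.template
        e = float(np.sum(self.k * np.einsum("ij,ij->i", d, d)))
        np.add.at(forces, self.index, -2.0 * self.k[:, None] * d)
        return e


# --- force field ------------------------------------------------------------

@dataclass
class ForceField:
    n_atoms: int
    bonds: HarmonicBonds
    angles: HarmonicAngles
    impropers: HarmonicTorsions
    omegas: HarmonicTorsions
    repel: RepulsiveNonbonded
    noe: NOERestraints | None = None
    chi_restraints: HarmonicTorsions | None = None
    ncs: list = field(default_factory=list)
    zn_bonds: HarmonicBonds | None = None
    zn_angles: HarmonicAngles | None = None
    position_restraints: NCSTerm | None = None

    def energy_decomposition(self, coords):
        forces = np.zeros_like(coords)
        comps = {}
        comps["bond"] = self.bonds.energy_forces(coords, forces)
        comps["angle"] = self.angles.energy_forces(coords, forces)
        comps["improper"] = self.impropers.energy_forces(coords, forces)
        comps["omega"] = self.omegas.energy_forces(coords, forces)
        comps["vdw"] = self.repel.energy_forces(coords, forces)
        comps["noe"] = self.noe.energy_forces(coords, forces) if self.noe else 0.0
        comps["dihedral"] = (self.chi_restraints.energy_forces(coords, forces)
                             if self.chi_restraints else 0.0)
        comps["ncs"] = sum(t.energy_forces(coords, forces) for t in self.ncs)
        comps["zn"] = 0.0
        if self.zn_bonds is not None:
            comps["zn"] += self.zn_bonds.energy_forces(coords, forces)
        if self.zn_angles is not None:
            comps["zn"] += self.zn_angles.energy_forces(coords, forces)
        if self.position_restraints is not None:
            comps["posre"] = self.position_restraints.energy_forces(
                coords, forces)
        comps["total"] = float(sum(v for k, v in comps.items()))
        return comps, forces

    def energy(self, coords):
        comps, _ = self.energy_decomposition(coords)
        return comps["total"]

    def set_repel_scale(self, scale: float):
        self.repel.scale = scale

    def set_noe_square_well(self, on: bool = True):
        if self.noe is not None:
            self.noe.square_well = on

    def set_noe_asymptote_slope(self, slope: float):
        if self.noe is not None:
            self.noe.asymptote_slope = slope

    def set_torsion_scale(self, scale: float):
        if self.chi_restraints is not None:
            self.chi_restraints.scale = scale

    def set_ncs_enabled(self, on: bool):
        for t in self.ncs:
            t.enabled = on


def _bond_graph(structure: Structure):
    """Bond index pairs plus per-atom neighbour map, from residue topology."""
    imap = structure.index_map()
    by_res: dict[tuple[str, int], str] = {}
    for a in structure.atoms:
        by_res[(a.chain_id, a.residue_number)] = a.residue_name
    pairs = []
    for (chain, resnum), resname in by_res.items():
        if resname == "ZN":
            continue
        for na, nb in residue_bonds(resname):
            ka, kb = (chain, resnum, na), (chain, resnum, nb)
            if ka in imap and kb in imap:
                pairs.append((imap[ka], imap[kb]))
        nxt = (chain, resnum + 1)
        if nxt in by_res and by_res[nxt] != "ZN":
            kc, kn = (chain, resnum, "C"), (chain, resnum + 1, "N")
            if kc in imap and kn in imap:
                pairs.append((imap[kc], imap[kn]))
    neigh: dict[int, set] = {}
    for a, b in pairs:
        neigh.setdefault(a, set()).add(b)
        neigh.setdefault(b, set()).add(a)
    return pairs, neigh


def _excluded_pairs(neigh: dict) -> set:
    """1-2 and 1-3 pairs."""
    excl = set()
    for a, nbrs in neigh.items():
        for b in nbrs:
            excl.add((min(a, b), max(a, b)))
            for c in neigh.get(b, ()):  # 1-3
                if c != a:
                    excl.add((min(a, c), max(a, c)))
    return excl


def build_forcefield(structure: Structure,
                     noe_restraints: list[DistanceRestraint] | None = None,
                     dihedral_restraints: list[DihedralRestraint] | None = None,
                     ncs_restraints: list[NCSRestraint] | None = None,
                     cis_links: set | None = None,
                     zn_sites: list | None = None) -> ForceField:
    """Assemble the force field for a structure from residue topology.

    ``cis_links``: set of (chain, resnum) pairs whose peptide bond to the
    following residue is restrained cis (omega target 0 instead of 180).
    ``zn_sites``: ZnSite objects; adds Zn–S bonds and S–Zn–S angles.
    """
    coords = structure.coords
    imap = structure.index_map()
    cis_links = cis_links or set()
    pairs, neigh = _bond_graph(structure)

    bond_i, bond_j, bond_r0 = [], [], []
    ang_idx, ang_t0 = [], []
    imp_idx, imp_t0 = [], []
    om_idx, om_t0 = [], []

    by_res: dict[tuple[str, int], str] = {}
    for a in structure.atoms:
        by_res[(a.chain_id, a.residue_number)] = a.residue_name

    for (chain, resnum), resname in sorted(by_res.items()):
        if resname == "ZN":
            continue
        ref_bonds, ref_angles, ref_imps = reference_geometry(resname)

        def midx(name, offset=0):
            key = (chain, resnum + offset, name)
            return imap.get(key)

        def resolve(name):
            if name.startswith("+"):
                return midx(name[1:], +1)
            return midx(name)

        for (na, nb), r0 in ref_bonds.items():
            ia, ib = resolve(na), resolve(nb)
            if ia is not None and ib is not None:
                bond_i.append(ia)
                bond_j.append(ib)
                bond_r0.append(r0)
        for (na, nb, nc), t0 in ref_angles.items():
            ia, ib, ic = resolve(na), resolve(nb), resolve(nc)
            if ia is not None and ib is not None and ic is not None:
                ang_idx.append((ia, ib, ic))
                ang_t0.append(np.radians(t0))
        for quad, t0 in ref_imps.items():
            ids = [resolve(n) for n in quad]
            if all(i is not None for i in ids):
                imp_idx.append(ids)
                imp_t0.append(np.radians(t0))
        # omega torsion to the next residue
        nxt = (chain, resnum + 1)
        if nxt in by_res and by_res[nxt] != "ZN":
            ids = [midx("CA"), midx("C"), midx("N", +1), midx("CA", +1)]
            if all(i is not None for i in ids):
                om_idx.append(ids)
                target = 0.0 if (chain, resnum) in cis_links else 180.0
                om_t0.append(np.radians(target))

    n = len(structure)
    bonds = HarmonicBonds(np.array(bond_i, int), np.array(bond_j, int),
                          np.array(bond_r0), np.full(len(bond_r0), K_BOND))
    angles = HarmonicAngles(np.array(ang_idx, int).reshape(-1, 3),
                            np.array(ang_t0), np.full(len(ang_t0), K_ANGLE))
    impropers = HarmonicTorsions(np.array(imp_idx, int).reshape(-1, 4),
                                 np.array(imp_t0),
                                 np.full(len(imp_t0), K_IMPROPER))
    omegas = HarmonicTorsions(np.array(om_idx, int).reshape(-1, 4),
                              np.array(om_t0), np.full(len(om_t0), K_OMEGA))

    radii = np.array([ELEMENT_RADII[a.element] for a in structure.atoms])
    excluded = _excluded_pairs(neigh)

    # NOE restraints -> flattened pair arrays
    noe = None
    if noe_restraints:
        pi, pj, rid, upper = [], [], [], []
        for ridx, r in enumerate(noe_restraints):
            ia = expand_group(r.group_a, structure)
            ib = expand_group(r.group_b, structure)
            for a in ia:
                for b in ib:
                    pi.append(a)
                    pj.append(b)
                    rid.append(ridx)
            upper.append(r.upper)
        noe = NOERestraints(np.array(pi, int), np.array(pj, int),
                            np.array(rid, int), np.array(upper),
                            n_restraints=len(noe_restraints))

    chi = None
    if dihedral_restraints:
        idx, tgt, kk, hw = [], [], [], []
        for r in dihedral_restraints:
            ids = [imap[k] for k in r.atoms]
            idx.append(ids)
            tgt.append(np.radians(r.target))
            kk.append(r.force_constant)
            hw.append(np.radians(r.half_width))
        chi = HarmonicTorsions(np.array(idx, int).reshape(-1, 4),
                               np.array(tgt), np.array(kk),
                               half_width=np.array(hw))

    ncs_terms = []
    for r in (ncs_restraints or []):
        ids = [imap[k] for k in r.atom_keys]
        ncs_terms.append(NCSTerm(np.array(ids, int),
                                 r.template_positions.copy(),
                                 np.full(len(ids), r.force_constant)))

    zn_bonds = zn_angles = None
    if zn_sites:
        zi, zj, zr = [], [], []
        za_idx, za_t0 = [], []
        for site in zn_sites:
            zn_idx = imap[site.zn_key]
            s_idx = [imap[k] for k in site.sulfur_keys]
            for s in s_idx:
                zi.append(zn_idx)
                zj.append(s)
                zr.append(site.bond_length)
            for a_i in range(len(s_idx)):
                for b_i in range(a_i + 1, len(s_idx)):
                    za_idx.append((s_idx[a_i], zn_idx, s_idx[b_i]))
                    za_t0.append(np.radians(site.angle_target))
            # exclude Zn-S and S..S pairs from repulsion
            for s in s_idx:
                excluded.add((min(zn_idx, s), max(zn_idx, s)))
            for a_i in range(len(s_idx)):
                for b_i in range(a_i + 1, len(s_idx)):
                    a, b = s_idx[a_i], s_idx[b_i]
                    excluded.add((min(a, b), max(a, b)))
        zn_bonds = HarmonicBonds(np.array(zi, int), np.array(zj, int),
                                 np.array(zr), np.full(len(zr), K_ZN_BOND))
        zn_angles = HarmonicAngles(np.array(za_idx, int).reshape(-1, 3),
                                   np.array(za_t0),
                                   np.full(len(za_t0), K_ZN_ANGLE))

    repel = RepulsiveNonbonded(radii=radii, excluded=excluded)
    return ForceField(n_atoms=n, bonds=bonds, angles=angles,
                      impropers=impropers, omegas=omegas, repel=repel,
                      noe=noe, chi_restraints=chi, ncs=ncs_terms,
                      zn_bonds=zn_bonds, zn_angles=zn_angles)


# --- minimization & dynamics -------------------------------------------------

def minimize(ff: ForceField, coords: np.ndarray, n_steps: int,
             fixed_mask: np.ndarray | None = None):
    """Gradient-based minimization (monotone non-increasing total energy).

    Contract analogue of Powell minimization: bounded iteration count and a
    guaranteed energy decrease (the best-seen conformation is returned).
    """
    x0 = coords.copy()
    free = np.ones(len(coords), bool) if fixed_mask is None else ~fixed_mask
    free_idx = np.where(free)[0]
    work = coords.copy()

    def fun(xflat):
        work[free_idx] = xflat.reshape(-1, 3)
        comps, forces = ff.energy_decomposition(work)
        return comps["total"], -forces[free_idx].ravel()

    e0 = ff.energy(x0)
    res = scipy_minimize(fun, x0[free_idx].ravel(), jac=True,
                         method="L-BFGS-B",
                         options={"maxiter": n_steps, "maxcor": 20})
    out = x0.copy()
    out[free_idx] = res.x.reshape(-1, 3)
    e1 = ff.energy(out)
    if e1 > e0:  # safeguard: never return an uphill result
        return x0, e0
    return out, e1


def langevin_dynamics(ff: ForceField, coords: np.ndarray, temperature: float,
                      n_steps: int, rng: np.random.Generator,
                      dt: float = 0.015, friction: float = 0.5,
                      fixed_mask: np.ndarray | None = None,
                      velocities: np.ndarray | None = None):
    """BAOAB Langevin integration at constant temperature.

    dt in AKMA time units (1 ≈ 48.9 fs), friction in inverse time units.
    Uniform atomic mass removes fast hydrogen modes.  Returns coordinates and
    final velocities; raises FloatingPointError on non-finite energies.
    """
    x = coords.copy()
    m = ATOM_MASS
    free = np.ones(len(x), bool) if fixed_mask is None else ~fixed_mask
    if velocities is None:
        v = rng.normal(0.0, np.sqrt(KB * temperature / m), size=x.shape)
    else:
        v = velocities.copy()
    v[~free] = 0.0
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1 ** 2) * KB * temperature / m)
    _, forces = ff.energy_decomposition(x)
    for _ in range(n_steps):
        v[free] += 0.5 * dt * forces[free] / m
        x[free] += 0.5 * dt * v[free]
        v[free] = c1 * v[free] + c2 * rng.normal(size=v[free].shape)
        x[free] += 0.5 * dt * v[free]
        comps, forces = ff.energy_decomposition(x)
        if not np.isfinite(comps["total"]):
            raise FloatingPointError("non-finite energy during dynamics")
        v[free] += 0.5 * dt * forces[free] / m
    return x, v
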