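"""Staged restrained simulated annealing.

The protocol mirrors hybrid NMR/template structure calculation: randomized
peptide starts far from a template-restrained domain, a stage-1 anneal under
soft NOE restraints with van der Waals ramping and asymptote tilting, Zn-site
construction at the sulfur centroid followed by a stage-2 anneal, optional
tail addition with the core rigidly fixed, and acceptance of the lowest
total-energy models.

Shipped default protocols carry the published step counts (stage 1:
500-step minimization, 5000 steps of 1000 K Langevin dynamics, 1000-step
ramp cycles, square-well switch, cooling to 300 K in 500-step cycles,
500-step final minimization; stage 2 with 1000/2000-step torsion ramps and
250-step cooling cycles; tail stage at 500 K in a 200 Å cube).  Tests and
the acceptance script use ``scale_protocol`` to shrink step counts to desk
scale; the schedule structure is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Atom, Ensemble, ModelEnergies, Structure
from .forcefield import (ForceField, NCSTerm, build_forcefield,
                         langevin_dynamics, minimize, S_ZN_S_ANGLE,
                         ZN_S_LENGTH)
from .restraints import DihedralRestraint, DistanceRestraint, NCSRestraint
from .topology import (BACKBONE_NAMES, SUPPORTED_RESIDUES, _SC,
                       build_chain, place_atom, residue_bonds)


# --- configuration types ----------------------------------------------------

@dataclass
class StartConfig:
    """Randomized-start parameters: peptide φ/ψ randomized, centre placed at
    a Gaussian distance (mean 150 Å) from the template centre."""
    placement_distance_mean: float = 150.0
    placement_distance_sd: float = 15.0
    random_seed: int = 0
    phi_psi_randomization: bool = True


@dataclass
class ZnSite:
    """A 4-Cys Zn²⁺ site: tetrahedral S coordination, Zn at the S centroid."""
    chain_id: str
    cys_residues: tuple
    bond_length: float = ZN_S_LENGTH
    angle_target: float = S_ZN_S_ANGLE
    zn_residue: int | None = None

    def __post_init__(self):
        if len(self.cys_residues) != 4:
            raise ValueError("a Zn site requires exactly four cysteines")

    @property
    def sulfur_keys(self):
        return [(self.chain_id, r, "SG") for r in self.cys_residues]

    @property
    def zn_key(self):
        return (self.chain_id, self.zn_residue, "ZN")


@dataclass
class Minimize:
    steps: int


@dataclass
class Dynamics:
    temperature: float
    steps: int


@dataclass
class Ramp:
    """Dynamics cycles while geometrically ramping vdW scale, NOE asymptote
    tilt and/or the dihedral-restraint scale between start and end values."""
    temperature: float
    cycles: int
    steps_per_cycle: int
    vdw: tuple | None = None       # (start, end) repulsive scale
    tilt: tuple | None = None      # (start, end) NOE asymptote slope
    torsion: tuple | None = None   # (start, end) dihedral restraint scale


@dataclass
class RigidApproach:
    """Rigid-body (6-DOF) placement of one chain by minimizing the distance-
    restraint energy.  Collapses the slow diffusive approach of the peptide
    from its distant random placement — which full-length high-temperature
    dynamics accomplishes over many thousands of steps — into an equivalent
    deterministic rigid-body optimization, so scaled-down schedules retain
    the same behaviour."""
    chain_id: str = "B"
    maxiter: int = 300


@dataclass
class SwitchSquareWell:
    pass


@dataclass
class Cool:
    start_temperature: float
    target_temperature: float
    steps_per_cycle: int
    n_cycles: int = 7


@dataclass
class StageProtocol:
    steps: list
    init_vdw_scale: float = 0.01
    init_tilt: float = 1.0
    init_torsion_scale: float = 1.0
    init_square_well: bool = False


def default_stage1_protocol() -> StageProtocol:
    return StageProtocol(steps=[
        Minimize(500),
        RigidApproach(),
        Minimize(500),
        Dynamics(1000.0, 5000),
        Ramp(1000.0, cycles=4, steps_per_cycle=1000,
             vdw=(0.01, 4.0), tilt=(1.0, 20.0)),
        SwitchSquareWell(),
        Cool(1000.0, 300.0, steps_per_cycle=500),
        Minimize(500),
    ])


def default_stage2_protocol() -> StageProtocol:
    return StageProtocol(steps=[
        Minimize(500),
        Ramp(1000.0, cycles=1, steps_per_cycle=1000, torsion=(0.1, 0.4)),
        Ramp(1000.0, cycles=1, steps_per_cycle=2000, torsion=(0.4, 1.0)),
        SwitchSquareWell(),
        Cool(1000.0, 300.0, steps_per_cycle=250),
        Minimize(1000),
    ], init_vdw_scale=4.0, init_square_well=False)


def default_tail_protocol() -> StageProtocol:
    return StageProtocol(steps=[
        Minimize(1000),
        Dynamics(500.0, 5000),
        Ramp(500.0, cycles=4, steps_per_cycle=1000, vdw=(0.01, 4.0)),
        Cool(500.0, 300.0, steps_per_cycle=1000, n_cycles=2),
        Minimize(1000),
    ])


def scale_protocol(protocol: StageProtocol, factor: float,
                   min_steps: int = 20) -> StageProtocol:
    """Scale all step counts by ``factor`` (schedule shape preserved)."""
    def s(n):
        return max(min_steps, int(round(n * factor)))
    out = []
    for step in protocol.steps:
        if isinstance(step, Minimize):
            out.append(Minimize(s(step.steps)))
        elif isinstance(step, Dynamics):
            out.append(Dynamics(step.temperature, s(step.steps)))
        elif isinstance(step, Ramp):
            out.append(replace(step, steps_per_cycle=s(step.steps_per_cycle)))
        elif isinstance(step, Cool):
            out.append(replace(step, steps_per_cycle=s(step.steps_per_cycle)))
        else:
            out.append(step)
    return replace(protocol, steps=out)


def desk_scale_protocols(factor: float = 0.05
                         ) -> tuple[StageProtocol, StageProtocol]:
    """Stage-1/stage-2 schedules scaled to desk scale.

    Dynamics step counts shrink by ``factor``; the final minimizations keep
    a full convergence budget (800 / 1500 iterations) because acceptance and
    restraint statistics are read off minimized structures.
    """
    s1 = scale_protocol(default_stage1_protocol(), factor)
    s2 = scale_protocol(default_stage2_protocol(), factor)
    s1.steps[-1] = Minimize(800)
    s2.steps[-1] = Minimize(1500)
    return s1, s2


@dataclass
class RestraintSet:
    distance: list = field(default_factory=list)
    dihedral: list = field(default_factory=list)
    ncs: list = field(default_factory=list)


# --- template preparation ---------------------------------------------------

_MUTATE_DEFAULT = {"MSE": "MET"}
_ATOM_RENAME = {("MSE", "SE"): ("MET", "SD", "S")}


def add_hydrogens(structure: Structure) -> Structure:
    """Add missing hydrogens by standard geometry (ideal internal coordinates).

    Heavy-atom positions are untouched; amide H uses the preceding residue's
    carbonyl frame where available.
    """
    out_atoms = []
    imap = structure.index_map()

    def pos(chain, resnum, name):
        k = (chain, resnum, name)
        return structure.coords[imap[k]] if k in imap else None

    by_res: dict[tuple[str, int], str] = {}
    for a in structure.atoms:
        by_res[(a.chain_id, a.residue_number)] = a.residue_name

    for (chain, resnum), resname in sorted(by_res.items()):
        res_atoms = [a for a in structure.atoms
                     if a.chain_id == chain and a.residue_number == resnum]
        present = {a.name for a in res_atoms}
        out_atoms.extend(res_atoms)
        if resname not in SUPPORTED_RESIDUES:
            continue

        def put(name, p):
            out_atoms.append(Atom(name, "H", resnum, resname, chain, p))

        n, ca, c = (pos(chain, resnum, x) for x in BACKBONE_NAMES)
        if n is None or ca is None or c is None:
            continue
        if "H" not in present:
            prev_c = pos(chain, resnum - 1, "C")
            prev_ca = pos(chain, resnum - 1, "CA")
            if prev_c is not None and prev_ca is not None:
                put("H", place_atom(prev_ca, prev_c, n, 1.010, 119.0,
                                    np.degrees(0.0) + 180.0
                                    + _measured_omega(prev_ca, prev_c, n, ca)))
            else:
                put("H", place_atom(ca, c, n, 1.010, 119.0, 180.0))
        if resname == "GLY":
            for h, tor in (("HA2", -122.6), ("HA3", 118.3)):
                if h not in present:
                    put(h, place_atom(c, n, ca, 1.090, 109.5, tor))
        else:
            if "HA" not in present:
                put("HA", place_atom(c, n, ca, 1.090, 109.5, 118.3))
            # sidechain hydrogens from heavy-atom frames
            for name, (a_ref, b_ref, c_ref, bl, ang, tor) in _SC[resname].items():
                if not name.startswith("H") or name in present:
                    continue
                pa = pos(chain, resnum, a_ref)
                pb = pos(chain, resnum, b_ref)
                pc = pos(chain, resnum, c_ref)
                if pa is None or pb is None or pc is None:
                    continue
                if isinstance(tor, str):
                    continue  # rotamer-dependent; skip if frame incomplete
                put(name, place_atom(pa, pb, pc, bl, ang, tor))
    return Structure(out_atoms, metadata=dict(structure.metadata))


def _measured_omega(prev_ca, prev_c, n, ca):
    from .topology import dihedral_angle
    return dihedral_angle(prev_ca, prev_c, n, ca)


def prepare_template(raw: Structure, cis_bonds: list[tuple[int, int]],
                     mutate_rules: dict | None = None,
                     minimize_steps: int = 300,
                     position_k: float = 10.0) -> Structure:
    """Template preparation: mutate seleno-Met to Met, add hydrogens, enforce
    listed peptide bonds cis, and restrained-minimize so the backbone stays
    near the input conformation.
    """
    rules = dict(_MUTATE_DEFAULT)
    rules.update(mutate_rules or {})
    chain = raw.atoms[0].chain_id
    present = set(raw.residue_numbers(chain))
    for a, b in cis_bonds:
        if a not in present or b not in present:
            raise KeyError(f"cis-bond residues {(a, b)} absent from template")
        if b != a + 1:
            raise ValueError("cis peptide bonds must join consecutive residues")

    atoms = []
    for a in raw.atoms:
        resname = rules.get(a.residue_name, a.residue_name)
        name, element = a.name, a.element
        key = (a.residue_name, a.name)
        if key in _ATOM_RENAME:
            _, name, element = _ATOM_RENAME[key]
        atoms.append(Atom(name, element, a.residue_number, resname,
                          a.chain_id, a.position.copy()))
    st = add_hydrogens(Structure(atoms, metadata=dict(raw.metadata)))

    cis_links = {(chain, a) for a, _ in cis_bonds}
    ff = build_forcefield(st, cis_links=cis_links)
    # restrain heavy atoms except those near the adapting cis bonds
    # (those atoms must be free to flip the peptide plane)
    cis_res = {r for pair in cis_bonds for r in pair}
    cis_atom_pos = np.array([st.coords[i] for i, a in enumerate(st.atoms)
                             if a.residue_number in cis_res]) \
        if cis_res else np.zeros((0, 3))
    keep = []
    for i, a in enumerate(st.atoms):
        if a.element == "H":
            continue
        if len(cis_atom_pos) and np.min(np.linalg.norm(
                cis_atom_pos - st.coords[i], axis=1)) < 5.0:
            continue
        keep.append(i)
    idx = np.array(keep, int)
    ff.position_restraints = NCSTerm(idx, st.coords[idx].copy(),
                                     np.full(len(idx), position_k))
    coords, _ = minimize(ff, st.coords, minimize_steps)
    out = st.copy()
    out.coords = coords
    return out


# --- randomized starts ------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def build_peptide(sequence: list[str], phi, psi, chain_id: str = "B",
                  start_resnum: int = 1, omega=None, chi1=None,
                  chi2=None) -> Structure:
    names, elements, resnames, resnums, coords = build_chain(
        list(sequence), np.asarray(phi, float), np.asarray(psi, float),
        omega=omega, chi1=chi1, chi2=chi2)
    atoms = [Atom(n, e, start_resnum + r - 1, rn, chain_id, p)
             for n, e, rn, r, p in zip(names, elements, resnames, resnums,
                                       coords)]
    return Structure(atoms)


def randomize_start(template: Structure, peptide_sequence: list[str],
                    config: StartConfig, chain_id: str = "B",
                    start_resnum: int = 1) -> Structure:
    """Template plus a φ/ψ-randomized peptide at a random orientation and a
    Gaussian-distributed distance from the template centre.

    Fully deterministic given ``config.random_seed``.
    """
    rng = np.random.default_rng(config.random_seed)
    n = len(peptide_sequence)
    if config.phi_psi_randomization:
        phi = rng.uniform(-180.0, 180.0, size=n)
        psi = rng.uniform(-180.0, 180.0, size=n)
    else:
        phi = np.full(n, -120.0)
        psi = np.full(n, 130.0)
    pep = build_peptide(peptide_sequence, phi, psi, chain_id=chain_id,
                        start_resnum=start_resnum)
    rot = _random_rotation(rng)
    centred = pep.coords - pep.coords.mean(axis=0)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    distance = rng.normal(config.placement_distance_mean,
                          config.placement_distance_sd)
    centre = template.coords.mean(axis=0) + distance * direction
    pep.coords = centred @ rot.T + centre
    return Structure([a for a in template.atoms] + [a for a in pep.atoms],
                     metadata={"start_seed": config.random_seed})


# --- zinc placement ---------------------------------------------------------

def place_zinc(structure: Structure, site: ZnSite) -> tuple[Structure, ZnSite]:
    """Add a Zn atom at the geometric average of the four cysteinyl sulfurs."""
    imap = structure.index_map()
    keys = site.sulfur_keys
    missing = [k for k in keys if k not in imap]
    if missing:
        raise KeyError(f"missing zinc-binding sulfurs: {missing}")
    centroid = structure.coords[[imap[k] for k in keys]].mean(axis=0)
    zn_resnum = site.zn_residue
    if zn_resnum is None:
        zn_resnum = max(structure.residue_numbers(site.chain_id)) + 1
    zn_atom = Atom("ZN", "ZN", zn_resnum, "ZN", site.chain_id, centroid)
    new = Structure(list(structure.atoms) + [zn_atom],
                    metadata=dict(structure.metadata))
    return new, replace(site, zn_residue=zn_resnum)


# --- stage execution --------------------------------------------------------

def anneal_stage(structure: Structure, ff: ForceField,
                 protocol: StageProtocol, seed: int,
                 fixed_mask: np.ndarray | None = None
                 ) -> tuple[Structure, ModelEnergies]:
    """Run one annealing stage; returns the final conformation and the
    decomposed energies of its last (minimized) state.

    Non-finite energies raise FloatingPointError so the caller can flag the
    run failed without aborting a batch.
    """
    rng = np.random.default_rng(seed)
    coords = structure.coords.copy()
    ff.set_repel_scale(protocol.init_vdw_scale)
    ff.set_noe_square_well(protocol.init_square_well)
    ff.set_noe_asymptote_slope(protocol.init_tilt)
    ff.set_torsion_scale(protocol.init_torsion_scale)
    velocities = None
    for step in protocol.steps:
        if isinstance(step, Minimize):
            coords, _ = minimize(ff, coords, step.steps, fixed_mask)
            velocities = None
        elif isinstance(step, Dynamics):
            coords, velocities = langevin_dynamics(
                ff, coords, step.temperature, step.steps, rng,
                fixed_mask=fixed_mask, velocities=velocities)
        elif isinstance(step, Ramp):
            for c in range(step.cycles):
                frac = (c + 1) / step.cycles
                if step.vdw is not None:
                    lo, hi = step.vdw
                    ff.set_repel_scale(lo * (hi / lo) ** frac)
                if step.tilt is not None:
                    lo, hi = step.tilt
                    ff.set_noe_asymptote_slope(lo * (hi / lo) ** frac)
                if step.torsion is not None:
                    lo, hi = step.torsion
                    ff.set_torsion_scale(lo + (hi - lo) * frac)
                coords, velocities = langevin_dynamics(
                    ff, coords, step.temperature, step.steps_per_cycle, rng,
                    fixed_mask=fixed_mask, velocities=velocities)
        elif isinstance(step, RigidApproach):
            coords = _rigid_approach(structure, ff, coords, step)
            velocities = None
        elif isinstance(step, SwitchSquareWell):
            ff.set_noe_square_well(True)
        elif isinstance(step, Cool):
            temps = np.linspace(step.start_temperature,
                                step.target_temperature, step.n_cycles + 1)[1:]
            for t in temps:
                coords, velocities = langevin_dynamics(
                    ff, coords, t, step.steps_per_cycle, rng,
                    fixed_mask=fixed_mask, velocities=velocities)
        else:
            raise TypeError(f"unknown protocol step {step!r}")
    comps, _ = ff.energy_decomposition(coords)
    if not np.isfinite(comps["total"]):
        raise FloatingPointError("non-finite energy at stage end")
    out = structure.copy()
    out.coords = coords
    energies = ModelEnergies(e_total=comps["total"], e_vdw=comps["vdw"],
                             e_ncs=comps["ncs"],
                             e_distance_restraints=comps["noe"])
    return out, energies


def _rigid_approach(structure: Structure, ff: ForceField, coords: np.ndarray,
                    step: RigidApproach) -> np.ndarray:
    """Minimize the NOE restraint energy over rigid motions of one chain."""
    if ff.noe is None:
        return coords
    from scipy.optimize import minimize as scipy_minimize
    mobile = np.array([a.chain_id == step.chain_id for a in structure.atoms])
    midx = np.where(mobile)[0]
    base = coords[midx].copy()
    centre = base.mean(axis=0)

    def rotmat(w):
        theta = np.linalg.norm(w)
        if theta < 1e-12:
            return np.eye(3)
        k = w / theta
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx

    work = coords.copy()

    def fun(p):
        rot = rotmat(p[:3])
        work[midx] = (base - centre) @ rot.T + centre + p[3:]
        f = np.zeros_like(work)
        return ff.noe.energy_forces(work, f)

    res = scipy_minimize(fun, np.zeros(6), method="Powell",
                         options={"maxiter": step.maxiter, "xtol": 1e-3})
    rot = rotmat(res.x[:3])
    out = coords.copy()
    out[midx] = (base - centre) @ rot.T + centre + res.x[3:]
    return out


# --- tail addition ----------------------------------------------------------

def add_tails(core: Structure, tail_residues: list[tuple[str, int, str]],
              restraints: RestraintSet | None = None, n_repeats: int = 5,
              seeds: list[int] | None = None,
              protocol: StageProtocol | None = None,
              cube_edge: float = 200.0) -> tuple[Structure, ModelEnergies]:
    """Add flexible tail residues with the core rigidly fixed.

    Tails start at fully randomized positions inside a ``cube_edge`` Å cube
    centred on the core; the procedure is repeated ``n_repeats`` times with
    different seeds and the lowest-E(total) result returned.  Core
    coordinates are bitwise unchanged.  NCS terms are never active here.
    """
    if protocol is None:
        protocol = default_tail_protocol()
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    core_keys = set(core.index_map())
    for chain, resnum, _ in tail_residues:
        if any((chain, resnum, name) in core_keys
               for name in ("N", "CA", "C")):
            raise ValueError(
                f"tail residue {chain}:{resnum} overlaps core topology")

    from .topology import residue_atom_names, _element_of
    best = None
    for seed in seeds:
        rng = np.random.default_rng(seed)
        atoms = [Atom(a.name, a.element, a.residue_number, a.residue_name,
                      a.chain_id, a.position.copy()) for a in core.atoms]
        centre = core.coords.mean(axis=0)
        for chain, resnum, resname in tail_residues:
            for name in residue_atom_names(resname):
                p = centre + rng.uniform(-cube_edge / 2, cube_edge / 2, 3)
                atoms.append(Atom(name, _element_of(name, resname), resnum,
                                  resname, chain, p))
        st = Structure(atoms)
        ff = build_forcefield(
            st,
            noe_restraints=restraints.distance if restraints else None,
            dihedral_restraints=restraints.dihedral if restraints else None,
            ncs_restraints=None)  # no NCS terms during tail addition
        fixed = np.array([(a.chain_id, a.residue_number, a.name) in core_keys
                          for a in st.atoms])
        result, energies = anneal_stage(st, ff, protocol, seed,
                                        fixed_mask=fixed)
        if best is None or energies.e_total < best[1].e_total:
            best = (result, energies)
    final, energies = best
    # restore exact core coordinates (fixed atoms never moved, but be exact)
    imap = final.index_map()
    for a in core.atoms:
        final.coords[imap[(a.chain_id, a.residue_number, a.name)]] = a.position
    return final, energies


# --- full protocol ----------------------------------------------------------

def run_protocol(template: Structure, peptide_sequence: list[str],
                 restraints: RestraintSet, n_starts: int = 50,
                 n_accept: int = 25, master_seed: int = 0,
                 start_config: StartConfig | None = None,
                 zn_cys_residues: tuple | None = None,
                 peptide_chain: str = "B", peptide_start_resnum: int = 1,
                 stage1: StageProtocol | None = None,
                 stage2: StageProtocol | None = None,
                 tail_residues: list | None = None,
                 tail_protocol: StageProtocol | None = None,
                 n_tail_repeats: int = 5) -> Ensemble:
    """Full ensemble calculation.

    Per start: randomize_start → stage-1 anneal → Zn placement → stage-2
    anneal → (optional) tail addition, then acceptance of the ``n_accept``
    lowest-E(total) completed runs.  Fully deterministic given
    ``master_seed``.  Raises RuntimeError listing failures if fewer than
    ``n_accept`` runs complete.
    """
    if stage1 is None:
        stage1 = default_stage1_protocol()
    if stage2 is None:
        stage2 = default_stage2_protocol()
    base_config = start_config or StartConfig()
    completed = []
    failures = []
    for i in range(n_starts):
        seed = (master_seed * 100003 + i * 7919 + 1) % (2 ** 31)
        config = replace(base_config, random_seed=seed)
        try:
            start = randomize_start(template, peptide_sequence, config,
                                    chain_id=peptide_chain,
                                    start_resnum=peptide_start_resnum)
            ff = build_forcefield(start,
                                  noe_restraints=restraints.distance,
                                  dihedral_restraints=restraints.dihedral,
                                  ncs_restraints=restraints.ncs)
            model, _ = anneal_stage(start, ff, stage1, seed + 1)
            if zn_cys_residues:
                site = ZnSite(chain_id=peptide_chain,
                              cys_residues=tuple(zn_cys_residues))
                model, site = place_zinc(model, site)
                ff2 = build_forcefield(model,
                                       noe_restraints=restraints.distance,
                                       dihedral_restraints=restraints.dihedral,
                                       ncs_restraints=restraints.ncs,
                                       zn_sites=[site])
            else:
                ff2 = build_forcefield(model,
                                       noe_restraints=restraints.distance,
                                       dihedral_restraints=restraints.dihedral,
                                       ncs_restraints=restraints.ncs)
            model, energies = anneal_stage(model, ff2, stage2, seed + 2)
            if tail_residues:
                tail_seeds = [(seed + 10 + k) % (2 ** 31)
                              for k in range(n_tail_repeats)]
                model, tail_e = add_tails(model, tail_residues,
                                          restraints=restraints,
                                          n_repeats=n_tail_repeats,
                                          seeds=tail_seeds,
                                          protocol=tail_protocol)
                energies = ModelEnergies(
                    e_total=tail_e.e_total, e_vdw=tail_e.e_vdw,
                    e_ncs=energies.e_ncs,  # NCS recorded before tail stage
                    e_distance_restraints=tail_e.e_distance_restraints)
            completed.append((model, energies))
        except FloatingPointError as exc:
            failures.append((i, str(exc)))
    if len(completed) < n_accept:
        raise RuntimeError(
            f"only {len(completed)} of {n_starts} runs completed "
            f"(need {n_accept}); failures: {failures}")
    completed.sort(key=lambda me: me[1].e_total)
    accepted = completed[:n_accept]
    ensemble = Ensemble(models=[m for m, _ in accepted],
                        energies=[e for _, e in accepted])
    # bookkeeping for audits: energies of every completed run, sorted
    ensemble.completed_energies = [e.e_total for _, e in completed]
    ensemble.n_failures = len(failures)
    return ensemble
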