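"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here: a toy
template-domain + Zn-fingernail-peptide complex (rigid helical mini-domain,
12-residue peptide whose four cysteine sulfurs coordinate a Zn²⁺ at
near-tetrahedral geometry), NOE peak lists with r⁻⁶ intensities and a 5 Å
detection limit, amide shift tables with a localized interface perturbation,
and single-site binding data whose K_D(T) follows the linear van't Hoff
relation.  All generators are pure functions of their spec (seed included).

The toy domain is a generated helix-hairpin mini-fold, not real coordinates
of any deposited structure, keeping the test suite download-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anneal import ZnSite, build_peptide, place_zinc
from .core import Atom, Selection, Structure
from .forcefield import NCSTerm, build_forcefield, minimize
from .restraints import Peak, effective_distance
from .csp import ShiftRecord
from .thermo import (BindingIsotherm, KineticTrace, ThermoFit,
                     association_response, dissociation_response, predict_kd)
from .topology import EQUIVALENT_GROUPS

# default toy peptide: CxxxCxCxxC zinc motif plus two flanking residues
TOY_PEPTIDE_SEQUENCE = ("CYS", "ALA", "LEU", "SER", "CYS", "GLY",
                        "CYS", "ALA", "LEU", "CYS", "SER", "ALA")
TOY_CYS_POSITIONS = (1, 5, 7, 10)
# domain surface residues forming the docking patch (one helix face)
TOY_INTERFACE_RESIDUES = (10, 13, 14, 17, 18, 21)


@dataclass
class ToySystemSpec:
    template_size: int = 60
    peptide_length: int = 12
    zinc: bool = True
    interface_residues: tuple = TOY_INTERFACE_RESIDUES
    seed: int = 0


@dataclass
class PeakSimSpec:
    detection_limit: float = 5.0  # Å
    noise_cv: float = 0.0
    scale_k: float = 1.0e6        # intensity · Å⁶
    spectrum_tag: str = "unfiltered"
    seed: int = 0


def _domain_sequence(n: int) -> list[str]:
    base = ["ALA", "LEU", "SER", "ALA", "LEU", "ALA", "SER", "LEU"]
    return [base[i % len(base)] for i in range(n)]


def _domain_phi_psi(n: int):
    """Helix-hairpin: two helices joined by a short turn."""
    phi = np.full(n, -57.0)
    psi = np.full(n, -47.0)
    turn = range(n // 2 - 2, n // 2 + 2)
    for k, t in enumerate(turn):
        phi[t], psi[t] = ((-60.0, -30.0), (-90.0, 0.0),
                          (80.0, 20.0), (-100.0, 120.0))[k % 4]
    return phi, psi


def make_toy_domain(size: int = 60, chain_id: str = "A") -> Structure:
    phi, psi = _domain_phi_psi(size)
    return build_peptide(_domain_sequence(size), phi, psi,
                         chain_id=chain_id, start_resnum=1)


def contact_residues(structure: Structure, chain_a: str = "A",
                     chain_b: str = "B", cutoff: float = 5.0) -> list[int]:
    """Residues of chain_a with any heavy atom within ``cutoff`` Å of a
    chain_b heavy atom (the interfacial region a preliminary structure round
    would identify)."""
    from scipy.spatial import cKDTree
    ia = [i for i, a in enumerate(structure.atoms)
          if a.chain_id == chain_a and a.element != "H"]
    ib = [i for i, a in enumerate(structure.atoms)
          if a.chain_id == chain_b and a.element != "H"]
    if not ia or not ib:
        return []
    tree = cKDTree(structure.coords[ib])
    hits = tree.query_ball_point(structure.coords[ia], cutoff)
    return sorted({structure.atoms[i].residue_number
                   for i, h in zip(ia, hits) if h})


def toy_tier_table(spec: ToySystemSpec) -> dict:
    """NCS tier table for the toy domain: strong backbone over the rigid
    core, medium backbone near the interface, medium sidechains elsewhere and
    weak sidechains at the interface."""
    interface = set(spec.interface_residues)
    soft = interface | {r + d for r in interface for d in (-1, 1)}
    all_res = set(range(1, spec.template_size + 1))
    return {
        ("strong", "backbone"): sorted(all_res - soft),
        ("medium", "backbone"): sorted(soft & all_res),
        ("medium", "sidechain"): sorted(all_res - interface),
        ("weak", "sidechain"): sorted(interface),
    }


def make_toy_complex(spec: ToySystemSpec | None = None
                     ) -> tuple[Structure, dict, ZnSite]:
    """Ground-truth toy complex: rigid mini-domain plus a docked Zn-clasped
    peptide.  Returns (structure, NCS tier table, ZnSite with Zn placed).

    The peptide is folded so its four cysteinyl sulfurs sit at
    near-tetrahedral geometry around their centroid (Zn–S ≈ 2.30 Å by
    construction) and docked against the domain's interface patch.
    """
    spec = spec or ToySystemSpec()
    if spec.zinc and spec.peptide_length < max(TOY_CYS_POSITIONS):
        raise ValueError("peptide too short for the 4-Cys zinc motif")
    rng = np.random.default_rng(spec.seed)
    domain = make_toy_domain(spec.template_size)

    seq = list(TOY_PEPTIDE_SEQUENCE[:spec.peptide_length])
    while len(seq) < spec.peptide_length:
        seq.append("ALA")
    n = len(seq)
    # compact turn-like start so the sulfurs can clasp
    phi = np.array([-80.0 if i % 2 == 0 else -100.0 for i in range(n)])
    psi = np.array([60.0 if i % 2 == 0 else 10.0 for i in range(n)])
    pep = build_peptide(seq, phi, psi, chain_id="B", start_resnum=1)

    # dock: put peptide centroid just outside the interface patch centroid
    iface = [r for r in spec.interface_residues if r <= spec.template_size]
    if not iface:
        raise ValueError("no interface residues inside the template")
    imap_d = domain.index_map()
    patch = np.array([domain.coords[imap_d[("A", r, "CB")]]
                      for r in iface])
    patch_c = patch.mean(axis=0)
    outward = patch_c - domain.coords.mean(axis=0)
    outward /= np.linalg.norm(outward)
    pep.coords = pep.coords - pep.coords.mean(axis=0) \
        + patch_c + 11.0 * outward

    combined = Structure(list(domain.atoms) + list(pep.atoms))

    # restrained fold-and-dock minimization with the domain held in place
    from .restraints import DistanceRestraint
    contacts = []
    pep_anchor = [r for r in (2, 3, 4, 6, 8, 9, 11) if r <= n]
    for k, rp in enumerate(pep_anchor):
        rd = iface[k % len(iface)]
        name_p = "CB" if seq[rp - 1] != "GLY" else "CA"
        contacts.append(DistanceRestraint(
            Selection(f"chain B and resi {rp} and name {name_p}"),
            Selection(f"chain A and resi {rd} and name CB"),
            category="weak", kind="intermolecular"))
    ff = build_forcefield(combined, noe_restraints=contacts)
    if spec.zinc:
        # clasp restraints: all S-S pairs at the tetrahedral edge length
        ss_target = 2.0 * 2.30 * np.sin(np.radians(109.47 / 2.0))
        imap = combined.index_map()
        s_idx = [imap[("B", r, "SG")] for r in TOY_CYS_POSITIONS]
        import itertools
        from .forcefield import HarmonicBonds
        pairs = list(itertools.combinations(s_idx, 2))
        clasp = HarmonicBonds(
            np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]),
            np.full(len(pairs), ss_target), np.full(len(pairs), 100.0))
        base_bonds = ff.bonds
        ff.bonds = HarmonicBonds(
            np.concatenate([base_bonds.i, clasp.i]),
            np.concatenate([base_bonds.j, clasp.j]),
            np.concatenate([base_bonds.r0, clasp.r0]),
            np.concatenate([base_bonds.k, clasp.k]))
        for a, b in pairs:
            ff.repel.excluded.add((min(a, b), max(a, b)))
    domain_mask = np.array([a.chain_id == "A" for a in combined.atoms])
    didx = np.where(domain_mask)[0]
    ff.position_restraints = NCSTerm(didx, combined.coords[didx].copy(),
                                     np.full(len(didx), 50.0))
    ff.set_repel_scale(0.2)
    coords, _ = minimize(ff, combined.coords, 600)
    ff.set_repel_scale(4.0)
    coords, _ = minimize(ff, coords, 600)
    ff.set_repel_scale(16.0)
    coords, _ = minimize(ff, coords, 400)
    folded = combined.copy()
    folded.coords = coords

    site = ZnSite(chain_id="B", cys_residues=TOY_CYS_POSITIONS) \
        if spec.zinc else None
    if spec.zinc:
        folded, site = place_zinc(folded, site)
        # refine with explicit Zn terms; finish with an unrestrained
        # relaxation so the ground truth is a genuine force-field minimum
        ff2 = build_forcefield(folded, noe_restraints=contacts,
                               zn_sites=[site])
        ff2.position_restraints = NCSTerm(didx, folded.coords[didx].copy(),
                                          np.full(len(didx), 50.0))
        ff2.set_repel_scale(8.0)
        coords, _ = minimize(ff2, folded.coords, 600)
        ff2.position_restraints = None
        ff2.set_repel_scale(4.0)
        coords, _ = minimize(ff2, coords, 4000)
        imap = folded.index_map()
        s_pos = coords[[imap[k] for k in site.sulfur_keys]]
        coords[imap[site.zn_key]] = s_pos.mean(axis=0)
        folded.coords = coords

    # the interfacial region as a preliminary round would find it: actual
    # contact residues drive both the soft NCS tiers and template-side NOEs
    contacts_found = contact_residues(folded, "A", "B")
    eff_spec = ToySystemSpec(
        template_size=spec.template_size, peptide_length=spec.peptide_length,
        zinc=spec.zinc,
        interface_residues=tuple(sorted(set(spec.interface_residues)
                                        | set(contacts_found))),
        seed=spec.seed)
    folded.metadata["interface_residues"] = eff_spec.interface_residues
    tier_table = toy_tier_table(eff_spec)
    return folded, tier_table, site


# --- NOE peak simulation ----------------------------------------------------

def proton_groups(structure: Structure, chain_id: str,
                  residues=None) -> list[tuple]:
    """Proton groups for NOE simulation: equivalent/prochiral protons are one
    wildcard group, other protons are singletons.

    Returns (selection_expression, residue_number) tuples.
    """
    groups = []
    by_res = {}
    for a in structure.atoms:
        if a.chain_id != chain_id or a.element != "H":
            continue
        if residues is not None and a.residue_number not in residues:
            continue
        by_res.setdefault((a.residue_number, a.residue_name), []).append(a.name)
    for (resnum, resname), names in sorted(by_res.items()):
        eq = EQUIVALENT_GROUPS.get(resname, {})
        grouped = set()
        for pattern, members in eq.items():
            present = [m for m in members if m in names]
            if present:
                groups.append((
                    f"chain {chain_id} and resi {resnum} and name {pattern}",
                    resnum))
                grouped.update(present)
        for nm in names:
            if nm not in grouped:
                groups.append(
                    (f"chain {chain_id} and resi {resnum} and name {nm}",
                     resnum))
    return groups


def simulate_peaks(truth: Structure, spec: PeakSimSpec | None = None,
                   peptide_chain: str = "B", template_chain: str = "A",
                   template_residues=None) -> list[Peak]:
    """NOE peaks from ground-truth geometry: intensity = k·d_eff⁻⁶·(1+noise)
    for every proton-group pair with effective distance ≤ the detection
    limit.  Pair classes: intra-peptide, intermolecular, and intra-template
    restricted to ``template_residues`` (default: the actual interface
    contact residues, as in sparse template-side data).  Noise is
    multiplicative log-normal.
    """
    from .restraints import expand_group
    spec = spec or PeakSimSpec()
    rng = np.random.default_rng(spec.seed)
    if template_residues is None:
        template_residues = contact_residues(truth, template_chain,
                                             peptide_chain)
    pep_groups = proton_groups(truth, peptide_chain)
    tmpl_groups = proton_groups(truth, template_chain,
                                residues=template_residues)
    idx = {expr: np.array(expand_group(Selection(expr), truth), int)
           for expr, _ in pep_groups + tmpl_groups}
    coords = truth.coords
    peaks = []

    def emit(expr_a, expr_b):
        pa, pb = coords[idx[expr_a]], coords[idx[expr_b]]
        diff = pa[:, None, :] - pb[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", diff, diff)
        d = float(np.sum(r2 ** -3)) ** (-1.0 / 6.0)
        if d > spec.detection_limit:
            return
        intensity = spec.scale_k * d ** -6
        if spec.noise_cv > 0:
            sigma = np.sqrt(np.log1p(spec.noise_cv ** 2))
            intensity *= rng.lognormal(-0.5 * sigma ** 2, sigma)
        peaks.append(Peak(Selection(expr_a), Selection(expr_b),
                          float(intensity), spec.spectrum_tag))

    for i in range(len(pep_groups)):
        for j in range(i + 1, len(pep_groups)):
            emit(pep_groups[i][0], pep_groups[j][0])
    for expr_p, _ in pep_groups:
        for expr_t, _ in tmpl_groups:
            emit(expr_p, expr_t)
    for i in range(len(tmpl_groups)):
        for j in range(i + 1, len(tmpl_groups)):
            emit(tmpl_groups[i][0], tmpl_groups[j][0])
    return peaks


def make_reference_peaks(k: float, n: int = 5, reference_distance: float = 2.2,
                         noise_cv: float = 0.0, seed: int = 0,
                         spectrum_tag: str = "unfiltered") -> list[Peak]:
    """Calibration-reference peaks at a fixed known distance (e.g. the
    sequential Hα–HN distance of regular antiparallel β-sheet)."""
    rng = np.random.default_rng(seed)
    peaks = []
    for i in range(n):
        intensity = k * reference_distance ** -6
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv ** 2))
            intensity *= rng.lognormal(-0.5 * sigma ** 2, sigma)
        peaks.append(Peak(Selection(f"chain A and resi {i + 1} and name HA"),
                          Selection(f"chain A and resi {i + 2} and name H"),
                          float(intensity), spectrum_tag))
    return peaks


_CHI1_GAMMA = {"CYS": "SG", "SER": "OG", "LEU": "CG", "MET": "CG",
               "MSE": "CG"}


def simulate_chi1_restraints(truth: Structure, chain_id: str = "B",
                             half_width: float = 20.0):
    """χ¹ dihedral restraints measured from the ground truth, emulating
    J-coupling-derived rotamer restraints for the peptide."""
    from .restraints import DihedralRestraint
    from .topology import dihedral_angle
    imap = truth.index_map()
    out = []
    seen = set()
    for a in truth.atoms:
        key = (a.chain_id, a.residue_number)
        if a.chain_id != chain_id or key in seen:
            continue
        seen.add(key)
        gamma = _CHI1_GAMMA.get(a.residue_name)
        if gamma is None:
            continue
        refs = [(a.chain_id, a.residue_number, nm)
                for nm in ("N", "CA", "CB", gamma)]
        if not all(r in imap for r in refs):
            continue
        pts = [truth.coords[imap[r]] for r in refs]
        out.append(DihedralRestraint(atoms=tuple(refs),
                                     target=dihedral_angle(*pts),
                                     half_width=half_width))
    return out


# --- shift tables -----------------------------------------------------------

def simulate_shift_tables(residue_numbers, interface, max_csp: float,
                          seed: int = 0, max_residue: int | None = None,
                          variant_weight: float = 0.2):
    """Free and bound amide shift tables with a localized perturbation.

    The designated residue (``max_residue``, default the first interface
    residue) carries exactly ``max_csp`` combined CSP under the
    figure-variant weighting; other interface residues carry 10–80 % of it;
    off-interface residues get < 0.05 ppm of random jitter.
    """
    rng = np.random.default_rng(seed)
    interface = list(interface)
    if max_residue is None:
        max_residue = interface[0]
    if max_residue not in interface:
        raise ValueError("max_residue must be an interface residue")
    free, bound = [], []
    for res in residue_numbers:
        h = rng.normal(8.3, 0.45)
        n15 = rng.normal(119.0, 4.0)
        free.append(ShiftRecord(res, h, n15))
        if res == max_residue:
            csp = max_csp
        elif res in interface:
            csp = max_csp * rng.uniform(0.1, 0.8)
        else:
            csp = rng.uniform(0.0, 0.04)
        # split the combined CSP between 1H and 15N components
        f = rng.uniform(0.3, 0.9)
        dh = csp * np.sqrt(f)
        dn = csp * np.sqrt((1.0 - f) / variant_weight)
        bound.append(ShiftRecord(res, h + dh * rng.choice([-1, 1]),
                                 n15 + dn * rng.choice([-1, 1])))
    return free, bound


# --- binding data -----------------------------------------------------------

DEFAULT_TEMPERATURES_C = (4.0, 8.0, 12.0, 18.0, 25.0)
DEFAULT_CONCENTRATIONS_M = tuple(40e-6 / 2 ** i for i in range(8))  # 40→0.3 µM


@dataclass
class BindingSimResult:
    isotherms: list
    kinetic_traces: dict   # temperature -> list of KineticTrace
    true_kds: dict         # temperature -> K_D (mol L⁻¹)


def simulate_binding(delta_H: float = -20e3, delta_S: float = 36.0,
                     temperatures=None, concentrations=None,
                     R_max: float = 100.0, noise_cv: float = 0.0,
                     k_off: float = 0.1, seed: int = 0) -> BindingSimResult:
    """Equilibrium isotherms and 1:1 kinetic traces at several temperatures.

    K_D(T) follows ln K_D = ΔH/(R·T) − ΔS/R; kinetics use a chosen k_off with
    k_on = k_off/K_D.  Response noise is multiplicative log-normal.
    Defaults state the measured world: ΔH° ≈ −20 kJ mol⁻¹,
    ΔS° ≈ +36 J K⁻¹ mol⁻¹, analyte series 40→0.3 µM, 4–25 °C.
    """
    rng = np.random.default_rng(seed)
    if temperatures is None:
        temperatures = [t + 273.15 for t in DEFAULT_TEMPERATURES_C]
    if concentrations is None:
        concentrations = np.array(DEFAULT_CONCENTRATIONS_M)
    concentrations = np.asarray(concentrations, float)
    thermo = ThermoFit(delta_H=delta_H, delta_S=delta_S)

    def noisy(x):
        if noise_cv <= 0:
            return x
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        return x * rng.lognormal(-0.5 * sigma ** 2, sigma, size=np.shape(x))

    isotherms, traces, kds = [], {}, {}
    t_assoc = np.linspace(0.0, 300.0, 76)
    t_dissoc = np.linspace(0.0, 300.0, 76)
    for T in temperatures:
        kd = predict_kd(thermo, T)
        kds[T] = kd
        resp = R_max * concentrations / (kd + concentrations)
        isotherms.append(BindingIsotherm(concentrations, noisy(resp), T))
        k_on = k_off / kd
        tr = []
        for c in concentrations[::3]:
            ra = association_response(t_assoc, c, k_on, k_off, R_max)
            tr.append(KineticTrace(t_assoc, noisy(ra), c, "association"))
            rd = dissociation_response(t_dissoc, k_off, ra[-1])
            tr.append(KineticTrace(t_dissoc, noisy(rd), 0.0, "dissociation"))
        traces[T] = tr
    return BindingSimResult(isotherms=isotherms, kinetic_traces=traces,
                            true_kds=kds)
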