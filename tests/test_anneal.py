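"""Annealing engine: template preparation, randomized starts, stage
execution, Zn placement, tail addition and ensemble acceptance."""

import numpy as np
import pytest

from znseal import anneal as A
from znseal import forcefield as FF
from znseal import topology as T
from znseal.core import Atom, Selection, Structure
from znseal.restraints import build_ncs_restraints


def _heavy_template(seq, omega=None):
    n = len(seq)
    names, els, resn, resi, xyz = T.build_chain(
        seq, phi=np.full(n, -57.0), psi=np.full(n, -47.0), omega=omega)
    atoms = [Atom(nm, e, r, rn, "A", p)
             for nm, e, rn, r, p in zip(names, els, resn, resi, xyz)
             if e != "H"]
    return Structure(atoms)


# --- prepare_template -------------------------------------------------------

def test_prepare_template_mutates_seleno_met():
    raw = _heavy_template(["ALA", "MSE", "LEU", "ALA"])
    prep = A.prepare_template(raw, cis_bonds=[])
    assert not any(a.residue_name == "MSE" for a in prep.atoms)
    assert any(a.name == "SD" and a.element == "S" for a in prep.atoms)


def test_prepare_template_adds_hydrogens():
    raw = _heavy_template(["ALA", "LEU", "SER", "ALA"])
    prep = A.prepare_template(raw, cis_bonds=[])
    assert sum(1 for a in prep.atoms if a.element == "H") > 10
    # heavy atoms keep their identity and order relative to each other
    heavy = [a.name for a in prep.atoms if a.element != "H"]
    assert heavy == [a.name for a in raw.atoms]


def test_prepare_template_enforces_cis_bond():
    # start from a partially rotated peptide bond so the adaptation is local
    omega = np.full(6, 180.0)
    omega[3] = 40.0
    raw = _heavy_template(["ALA", "LEU", "SER", "CYS", "ALA", "LEU"],
                          omega=omega)
    prep = A.prepare_template(raw, cis_bonds=[(3, 4)], minimize_steps=800)
    imap = prep.index_map()
    om = T.dihedral_angle(prep.coords[imap[("A", 3, "CA")]],
                          prep.coords[imap[("A", 3, "C")]],
                          prep.coords[imap[("A", 4, "N")]],
                          prep.coords[imap[("A", 4, "CA")]])
    assert abs(om) < 10.0


def test_prepare_template_backbone_shift_small():
    raw = _heavy_template(["ALA", "LEU", "SER", "ALA", "LEU", "SER"])
    prep = A.prepare_template(raw, cis_bonds=[])
    bb = [i for i, a in enumerate(prep.atoms) if a.name in ("N", "CA", "C")]
    bbr = [i for i, a in enumerate(raw.atoms) if a.name in ("N", "CA", "C")]
    shift = np.sqrt(np.mean(np.sum(
        (prep.coords[bb] - raw.coords[bbr]) ** 2, axis=1)))
    assert shift < 0.5


def test_prepare_template_missing_cis_residue_errors():
    raw = _heavy_template(["ALA", "LEU"])
    with pytest.raises(KeyError):
        A.prepare_template(raw, cis_bonds=[(40, 41)])


# --- randomize_start --------------------------------------------------------

PEPTIDE = ["CYS", "ALA", "LEU", "SER"]


def _template():
    return _heavy_template(["ALA", "LEU", "SER", "ALA"])


def test_randomize_start_deterministic():
    tmpl = _template()
    cfg = A.StartConfig(random_seed=7)
    s1 = A.randomize_start(tmpl, PEPTIDE, cfg)
    s2 = A.randomize_start(tmpl, PEPTIDE, cfg)
    assert np.array_equal(s1.coords, s2.coords)
    s3 = A.randomize_start(tmpl, PEPTIDE, A.StartConfig(random_seed=8))
    assert not np.allclose(s3.coords, s1.coords)


def test_randomize_start_mean_placement_distance():
    """Over many seeds the peptide centre sits ~N(150 Å, 15 Å) from the
    template centre."""
    tmpl = _template()
    tc = tmpl.coords.mean(axis=0)
    dists = []
    for seed in range(500):
        s = A.randomize_start(tmpl, PEPTIDE, A.StartConfig(random_seed=seed))
        pep = np.array([a.position for a in s.atoms if a.chain_id == "B"])
        dists.append(np.linalg.norm(pep.mean(axis=0) - tc))
    assert abs(np.mean(dists) - 150.0) < 5.0
    assert 5.0 < np.std(dists) < 30.0


def test_randomize_start_ideal_covalent_geometry():
    tmpl = _template()
    s = A.randomize_start(tmpl, PEPTIDE, A.StartConfig(random_seed=3))
    pep = Structure([a for a in s.atoms if a.chain_id == "B"])
    imap = pep.index_map()
    for resnum, resname in enumerate(PEPTIDE, start=1):
        ref_bonds, _, _ = T.reference_geometry(resname)
        for (na, nb), r0 in ref_bonds.items():
            if na.startswith("+") or nb.startswith("+"):
                continue
            d = np.linalg.norm(pep.coords[imap[("B", resnum, na)]]
                               - pep.coords[imap[("B", resnum, nb)]])
            assert abs(d - r0) < 0.02


# --- place_zinc -------------------------------------------------------------

def _sulfur_structure(positions):
    atoms = []
    for i, p in enumerate(positions):
        res = i * 3 + 1
        atoms.append(Atom("CA", "C", res, "CYS", "B", np.add(p, [0, 0, 3])))
        atoms.append(Atom("SG", "S", res, "CYS", "B", p))
    return Structure(atoms), tuple(i * 3 + 1 for i in range(4))


def test_place_zinc_centroid():
    s, cys = _sulfur_structure([[1, 1, 0], [-1, 1, 0], [1, -1, 0],
                                [-1, -1, 0]])
    site = A.ZnSite(chain_id="B", cys_residues=cys)
    out, site2 = place_zinc_checked(s, site)
    assert np.allclose(out.coords[-1], [0, 0, 0], atol=1e-12)


def place_zinc_checked(s, site):
    out, site2 = A.place_zinc(s, site)
    assert out.atoms[-1].name == "ZN"
    return out, site2


def test_place_zinc_degenerate_point():
    s, cys = _sulfur_structure([[2.0, 1.0, -1.0]] * 4)
    out, _ = place_zinc_checked(
        s, A.ZnSite(chain_id="B", cys_residues=cys))
    assert np.allclose(out.coords[-1], [2.0, 1.0, -1.0])


def test_place_zinc_wrong_sulfur_count_errors():
    with pytest.raises(ValueError):
        A.ZnSite(chain_id="B", cys_residues=(1, 2, 3))
    s, cys = _sulfur_structure([[1, 1, 0], [-1, 1, 0], [1, -1, 0],
                                [-1, -1, 0]])
    with pytest.raises(KeyError):
        A.place_zinc(s, A.ZnSite(chain_id="B", cys_residues=(1, 4, 7, 99)))


# --- anneal_stage -----------------------------------------------------------

def test_stage_with_strong_ncs_stays_on_template():
    """With no distance restraints and strong NCS on all atoms, annealing
    returns essentially the template conformation."""
    tmpl = A.prepare_template(_template(), cis_bonds=[])
    tiers = {("strong", "backbone"): [1, 2, 3, 4],
             ("strong", "sidechain"): [1, 2, 3, 4]}
    # use one tier entry per scope covering everything
    ncs = build_ncs_restraints(tmpl, tiers)
    ff = FF.build_forcefield(tmpl, ncs_restraints=ncs)
    protocol = A.StageProtocol(steps=[
        A.Minimize(100), A.Dynamics(1000.0, 150),
        A.Cool(1000.0, 300.0, steps_per_cycle=50, n_cycles=3),
        A.Minimize(200)], init_vdw_scale=1.0)
    out, energies = A.anneal_stage(tmpl, ff, protocol, seed=0)
    bb = [i for i, a in enumerate(out.atoms) if a.name in ("N", "CA", "C")]
    rmsd = np.sqrt(np.mean(np.sum(
        (out.coords[bb] - tmpl.coords[bb]) ** 2, axis=1)))
    assert rmsd < 0.3
    assert np.isfinite(energies.e_total)


def test_minimizer_monotone_contract():
    tmpl = A.prepare_template(_template(), cis_bonds=[])
    ff = FF.build_forcefield(tmpl)
    rng = np.random.default_rng(0)
    x = tmpl.coords + rng.normal(0, 0.2, tmpl.coords.shape)
    e0 = ff.energy(x)
    x1, e1 = FF.minimize(ff, x, 50)
    assert e1 <= e0
    x2, e2 = FF.minimize(ff, x1, 200)
    assert e2 <= e1


def test_energy_decomposition_sums_to_total():
    tmpl = A.prepare_template(_template(), cis_bonds=[])
    tiers = {("medium", "backbone"): [1, 2, 3, 4]}
    ncs = build_ncs_restraints(tmpl, tiers)
    ff = FF.build_forcefield(tmpl, ncs_restraints=ncs)
    rng = np.random.default_rng(1)
    x = tmpl.coords + rng.normal(0, 0.3, tmpl.coords.shape)
    comps, _ = ff.energy_decomposition(x)
    parts = sum(v for k, v in comps.items() if k != "total")
    assert comps["total"] == pytest.approx(parts, rel=1e-12)


def test_ncs_convergence_monotone_under_minimization():
    """With only NCS terms active the restrained copy approaches the
    template monotonically over successive minimization blocks."""
    tmpl = A.prepare_template(_template(), cis_bonds=[])
    tiers = {("strong", "backbone"): [1, 2, 3, 4]}
    ncs = build_ncs_restraints(tmpl, tiers)
    ff = FF.build_forcefield(tmpl, ncs_restraints=ncs)
    ff.set_repel_scale(0.0)
    rng = np.random.default_rng(2)
    x = tmpl.coords + rng.normal(0, 1.0, tmpl.coords.shape)
    bb = [i for i, a in enumerate(tmpl.atoms) if a.name in ("N", "CA", "C")]

    def bb_rmsd(c):
        return np.sqrt(np.mean(np.sum((c[bb] - tmpl.coords[bb]) ** 2,
                                      axis=1)))
    start = prev = bb_rmsd(x)
    for _ in range(4):
        x, _ = FF.minimize(ff, x, 60)
        cur = bb_rmsd(x)
        # monotone to within tiny fluctuation once near the joint
        # bonded/NCS equilibrium
        assert cur <= prev + 5e-3
        prev = cur
    assert prev < start / 3.0


# --- add_tails --------------------------------------------------------------

def _tail_protocol():
    return A.StageProtocol(steps=[
        A.Minimize(150), A.Dynamics(500.0, 100),
        A.Cool(500.0, 300.0, steps_per_cycle=40, n_cycles=2),
        A.Minimize(300)], init_vdw_scale=1.0)


def test_add_tails_core_bitwise_fixed():
    core = A.prepare_template(_template(), cis_bonds=[])
    tails = [("A", 5, "ALA"), ("A", 6, "GLY")]
    final, energies = A.add_tails(core, tails, n_repeats=2, seeds=[4, 5],
                                  protocol=_tail_protocol())
    imap = final.index_map()
    for a in core.atoms:
        k = (a.chain_id, a.residue_number, a.name)
        assert np.array_equal(final.coords[imap[k]], a.position)
    assert len(final) > len(core)
    assert np.isfinite(energies.e_total)


def test_add_tails_selects_minimum_energy_repeat():
    core = A.prepare_template(_template(), cis_bonds=[])
    tails = [("A", 5, "ALA")]
    singles = [A.add_tails(core, tails, n_repeats=1, seeds=[s],
                           protocol=_tail_protocol())[1].e_total
               for s in (7, 8, 9)]
    _, best = A.add_tails(core, tails, n_repeats=3, seeds=[7, 8, 9],
                          protocol=_tail_protocol())
    assert best.e_total == pytest.approx(min(singles), rel=1e-9)


def test_add_tails_deterministic_single_repeat():
    core = A.prepare_template(_template(), cis_bonds=[])
    tails = [("A", 5, "ALA")]
    f1, e1 = A.add_tails(core, tails, n_repeats=1, seeds=[11],
                         protocol=_tail_protocol())
    f2, e2 = A.add_tails(core, tails, n_repeats=1, seeds=[11],
                         protocol=_tail_protocol())
    assert np.array_equal(f1.coords, f2.coords)
    assert e1.e_total == e2.e_total


def test_add_tails_overlapping_residue_errors():
    core = A.prepare_template(_template(), cis_bonds=[])
    with pytest.raises(ValueError):
        A.add_tails(core, [("A", 2, "ALA")], n_repeats=1, seeds=[0],
                    protocol=_tail_protocol())


# --- run_protocol acceptance bookkeeping ------------------------------------

def _cheap_protocols():
    s1 = A.StageProtocol(steps=[
        A.Minimize(80), A.RigidApproach(maxiter=60), A.Minimize(120),
        A.Cool(500.0, 300.0, steps_per_cycle=30, n_cycles=2),
        A.SwitchSquareWell(), A.Minimize(150)])
    s2 = A.StageProtocol(steps=[A.Minimize(150)], init_vdw_scale=2.0,
                         init_square_well=True)
    return s1, s2


def test_run_protocol_accepts_lowest_energy_half():
    tmpl = A.prepare_template(_template(), cis_bonds=[])
    tiers = {("strong", "backbone"): [1, 2, 3, 4]}
    rs = A.RestraintSet(ncs=build_ncs_restraints(tmpl, tiers))
    s1, s2 = _cheap_protocols()
    ens = A.run_protocol(tmpl, PEPTIDE, rs, n_starts=4, n_accept=2,
                         master_seed=5, zn_cys_residues=None,
                         stage1=s1, stage2=s2)
    assert len(ens.models) == 2
    accepted = [e.e_total for e in ens.energies]
    assert accepted == sorted(accepted)
    rejected = ens.completed_energies[2:]
    assert max(accepted) <= min(rejected)


def test_run_protocol_deterministic():
    tmpl = A.prepare_template(_template(), cis_bonds=[])
    rs = A.RestraintSet(ncs=build_ncs_restraints(
        tmpl, {("strong", "backbone"): [1, 2, 3, 4]}))
    s1, s2 = _cheap_protocols()
    kw = dict(n_starts=2, n_accept=1, master_seed=9, stage1=s1, stage2=s2)
    e1 = A.run_protocol(tmpl, PEPTIDE, rs, **kw)
    e2 = A.run_protocol(tmpl, PEPTIDE, rs, **kw)
    assert np.array_equal(e1.models[0].coords, e2.models[0].coords)
    assert e1.energies[0].e_total == e2.energies[0].e_total
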