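"""Superposition, ensemble rmsd statistics, violations and surface areas."""

import numpy as np
import pytest

from znseal.core import Atom, Ensemble, Selection, Structure
from znseal.metrics import (buried_surface, pairwise_rmsd,
                            restraint_statistics, rmsd_to_mean, sasa,
                            superpose)
from znseal.restraints import DistanceRestraint


def quaternion_superpose_rmsd(mobile, reference):
    """Independent oracle: Horn's closed-form quaternion method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(n)[-1]
    msd = (np.sum(x ** 2) + np.sum(y ** 2) - 2.0 * lam) / len(x)
    return np.sqrt(max(msd, 0.0))


def _cloud_structure(coords, chain="A"):
    return Structure([Atom("CA", "C", i + 1, "ALA", chain, p)
                      for i, p in enumerate(coords)])


def test_superpose_identity():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(8, 3))
    res = superpose(pts, pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


def test_superpose_rigid_invariance():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(10, 3))
    theta = np.pi / 2
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    moved = pts @ rot.T + [5.0, -2.0, 7.0]
    res = superpose(pts, moved)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)


def test_superpose_matches_quaternion_oracle():
    rng = np.random.default_rng(2)
    for _ in range(50):
        a = rng.normal(size=(10, 3)) * 3
        b = rng.normal(size=(10, 3)) * 3
        assert superpose(a, b).rmsd == pytest.approx(
            quaternion_superpose_rmsd(a, b), rel=1e-8, abs=1e-10)


def test_superpose_degenerate_raises():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError):
        superpose(line, line + 1.0)
    with pytest.raises(ValueError):
        superpose(line[:2], line[:2])


def _random_ensemble(n_models=4, n_atoms=12, spread=0.5, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_atoms, 3)) * 4
    models = []
    for _ in range(n_models):
        models.append(_cloud_structure(base + rng.normal(0, spread,
                                                         (n_atoms, 3))))
    return Ensemble(models=models)


ALL = Selection("name CA")


def test_pairwise_rmsd_duplicated_model():
    ens = _random_ensemble(2, seed=3)
    ens = Ensemble(models=[ens.models[0], ens.models[0].copy()])
    rep = pairwise_rmsd(ens, ALL, atom_scope=None)
    assert rep.mean_pairwise == pytest.approx(0.0, abs=1e-12)
    assert rep.sd_pairwise == 0.0


def test_pairwise_rmsd_matches_oracle():
    """Mean pairwise rmsd equals the quaternion-oracle average over all
    unordered model pairs."""
    ens = _random_ensemble(5, seed=4)
    rep = pairwise_rmsd(ens, ALL, atom_scope=None)
    vals = []
    for i in range(5):
        for j in range(i + 1, 5):
            vals.append(quaternion_superpose_rmsd(ens.models[i].coords,
                                                  ens.models[j].coords))
    assert rep.mean_pairwise == pytest.approx(np.mean(vals), rel=1e-8)
    assert rep.sd_pairwise == pytest.approx(np.std(vals, ddof=1), rel=1e-6)


def test_rmsd_is_metric_on_random_triples():
    rng = np.random.default_rng(5)
    for _ in range(20):
        a, b, c = (rng.normal(size=(8, 3)) for _ in range(3))
        dab = superpose(a, b).rmsd
        dba = superpose(b, a).rmsd
        assert dab == pytest.approx(dba, rel=1e-7, abs=1e-10)
        assert superpose(a, a).rmsd == pytest.approx(0.0, abs=1e-12)


def test_rmsd_to_mean_identical_models():
    m = _cloud_structure(np.random.default_rng(6).normal(size=(9, 3)))
    ens = Ensemble(models=[m, m.copy(), m.copy()])
    per_model, mean = rmsd_to_mean(ens, ALL, atom_scope=None)
    assert np.allclose(per_model, 0.0, atol=1e-9)


def test_two_model_rmsd_to_mean_is_half_pair_distance():
    """For two models, each rmsd-to-mean equals half the pair rmsd measured
    in the common frame (the mean lies midway)."""
    ens = _random_ensemble(2, seed=7)
    per_model, _ = rmsd_to_mean(ens, ALL, atom_scope=None)
    pair = superpose(ens.models[0].coords, ens.models[1].coords).rmsd
    assert per_model[0] == pytest.approx(per_model[1], rel=1e-6)
    assert per_model[0] == pytest.approx(pair / 2.0, rel=1e-5)


def test_mean_to_mean_below_mean_pairwise():
    for seed in range(30):
        ens = _random_ensemble(4, spread=0.8, seed=seed)
        rep = pairwise_rmsd(ens, ALL, atom_scope=None)
        assert rep.mean_to_mean <= rep.mean_pairwise + 1e-9


# --- restraint statistics ----------------------------------------------------

def _h_pair_structure(d):
    return Structure([Atom("HA1", "H", 1, "GLY", "A", [0, 0, 0]),
                      Atom("HB1", "H", 2, "GLY", "A", [d, 0, 0])])


def test_restraint_statistics_satisfied_all_zero():
    r = DistanceRestraint(Selection("resi 1 and name HA*"),
                          Selection("resi 2 and name HB*"), category="weak")
    ens = Ensemble(models=[_h_pair_structure(4.0), _h_pair_structure(3.0)])
    rep = restraint_statistics(ens, [r])
    assert rep.mean_distance_violation == 0.0
    assert rep.max_distance_violation == 0.0


def test_restraint_statistics_constructed_violation():
    r = DistanceRestraint(Selection("resi 1 and name HA*"),
                          Selection("resi 2 and name HB*"), category="weak")
    models = [_h_pair_structure(5.5)] + [_h_pair_structure(4.0)] * 3
    rep = restraint_statistics(Ensemble(models=models), [r])
    assert rep.max_distance_violation == pytest.approx(0.5)
    assert rep.mean_distance_violation == pytest.approx(0.5 / 4)


def test_restraint_statistics_cross_checks_restraints_module(toy_truth,
                                                             toy_peaks):
    from znseal.restraints import (CalibrationScale, classify_peaks,
                                   restraint_violation)
    scale = CalibrationScale(k={"unfiltered": 1e6})
    restraints = classify_peaks(toy_peaks, scale)[:40]
    rng = np.random.default_rng(8)
    m2 = toy_truth.copy()
    m2.coords = m2.coords + rng.normal(0, 0.15, m2.coords.shape)
    ens = Ensemble(models=[toy_truth, m2])
    rep = restraint_statistics(ens, restraints)
    viols = [restraint_violation(m, r) for m in ens.models
             for r in restraints]
    assert rep.mean_distance_violation == pytest.approx(np.mean(viols))
    assert rep.max_distance_violation == pytest.approx(np.max(viols))


# --- SASA --------------------------------------------------------------------

def _atoms(positions, element="C"):
    return Structure([Atom(f"C{i+1}", element, i + 1, "ALA", "A", p)
                      for i, p in enumerate(positions)])


def test_sasa_isolated_sphere_analytic():
    res = sasa(_atoms([[0, 0, 0]]), probe=1.4)
    assert res.total == pytest.approx(4 * np.pi * 3.1 ** 2, rel=2e-3)


def test_sasa_two_distant_atoms_additive():
    res = sasa(_atoms([[0, 0, 0], [100.0, 0, 0]]), probe=1.4)
    assert res.total == pytest.approx(2 * 4 * np.pi * 3.1 ** 2, rel=2e-3)
    assert res.total == pytest.approx(res.per_atom_area.sum())


def test_sasa_fully_caged_atom_near_zero():
    # central atom enclosed by a tight shell of neighbours
    shell = []
    golden = np.pi * (3 - 5 ** 0.5)
    for i in range(40):
        z = 1 - 2 * (i + 0.5) / 40
        r = np.sqrt(1 - z * z)
        th = golden * i
        shell.append([2.2 * r * np.cos(th), 2.2 * r * np.sin(th), 2.2 * z])
    s = _atoms([[0, 0, 0]] + shell)
    res = sasa(s, probe=1.4, scope=Selection("resi 1"))
    assert res.total < 1.0


def test_sasa_rigid_motion_invariant(small_structure):
    base = sasa(small_structure).total
    rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
    moved = small_structure.copy()
    moved.coords = small_structure.coords @ rot.T + [10, -4, 2]
    # invariant to sampling tolerance (the point grid is axis-attached)
    assert sasa(moved).total == pytest.approx(base, rel=0.02)


def test_sasa_cross_check_against_biotite(small_structure):
    """Independent engine cross-check on a real all-atom fragment."""
    import biotite.structure as struc
    from znseal.core import _structure_to_atom_array
    arr = _structure_to_atom_array(small_structure)
    heavy = arr[arr.element != "H"]
    from znseal.topology import ELEMENT_RADII
    radii = np.array([ELEMENT_RADII[e] for e in heavy.element])
    ref = struc.sasa(heavy, probe_radius=1.4, point_number=960,
                     vdw_radii=radii).sum()
    mine = sasa(small_structure, probe=1.4).total
    assert mine == pytest.approx(ref, rel=0.02)


def test_sasa_unknown_element_errors():
    s = Structure([Atom("X1", "XX", 1, "UNK", "A", [0, 0, 0])])
    with pytest.raises(KeyError):
        sasa(s)


# --- buried surface ----------------------------------------------------------

def _two_chain(d):
    return Structure([Atom("C1", "C", 1, "ALA", "A", [0, 0, 0]),
                      Atom("C1", "C", 1, "ALA", "B", [d, 0, 0])])


def test_buried_surface_distant_chains_zero():
    b = buried_surface(_two_chain(100.0), Selection("chain A"),
                       Selection("chain B"))
    assert b == pytest.approx(0.0, abs=1e-6)


def test_buried_surface_two_sphere_analytic():
    """Two identical touching spheres: buried area equals twice the
    spherical cap removed from each extended sphere (closed form)."""
    d = 3.0
    b = buried_surface(_two_chain(d), Selection("chain A"),
                       Selection("chain B"), n_points=4000)
    r = 1.7 + 1.4
    cap_height = r - d / 2.0
    analytic = 2.0 * 2.0 * np.pi * r * cap_height
    assert b == pytest.approx(analytic, rel=0.02)


def test_buried_surface_symmetric(toy_truth):
    a, bsel = Selection("chain A"), Selection("chain B")
    b1 = buried_surface(toy_truth, a, bsel)
    b2 = buried_surface(toy_truth, bsel, a)
    assert b1 == pytest.approx(b2, rel=1e-9)
    assert b1 > 100.0  # the toy complex has a genuine interface


def test_buried_surface_overlapping_selections_error(toy_truth):
    with pytest.raises(ValueError):
        buried_surface(toy_truth, Selection("chain A"),
                       Selection("resi 1:60"))
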