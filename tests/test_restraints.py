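"""NOE calibration, r⁻⁶ group distances, classification and NCS tiers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from znseal.core import Atom, Selection, Structure
from znseal.restraints import (CATEGORY_UPPER, CalibrationScale,
                               DistanceRestraint, Peak,
                               calibrate_intensity_scale, classify_peak,
                               effective_distance, expand_group,
                               restraint_violation, build_ncs_restraints,
                               vps29_tier_table)


def _two_group_structure(pos_a, pos_b):
    atoms = [Atom(f"HA{i+1}", "H", 1, "GLY", "A", p)
             for i, p in enumerate(pos_a)]
    atoms += [Atom(f"HB{i+1}", "H", 2, "GLY", "A", p)
              for i, p in enumerate(pos_b)]
    return Structure(atoms)


GROUP_A = Selection("resi 1 and name HA*")
GROUP_B = Selection("resi 2 and name HB*")


def _brute_force_r6(pos_a, pos_b):
    """Independent oracle: plain double loop over all cross pairs."""
    s = 0.0
    for p in pos_a:
        for q in pos_b:
            s += float(np.linalg.norm(np.asarray(p) - np.asarray(q))) ** -6
    return s ** (-1.0 / 6.0)


def test_single_pair_is_plain_distance():
    s = _two_group_structure([[0, 0, 0]], [[3.0, 0, 0]])
    assert effective_distance(s, GROUP_A, GROUP_B) == pytest.approx(3.0)


def test_two_equal_pairs_r6_sum():
    # two pairs both at 3.00 Å -> 3.00 * 2^(-1/6) ≈ 2.673 Å
    s = _two_group_structure([[0, 0, 0], [0, 50, 0]],
                             [[3.0, 0, 0], [3.0, 50, 0]])
    d = effective_distance(s, GROUP_A, GROUP_B)
    assert d == pytest.approx(3.0 * 2 ** (-1 / 6), abs=1e-3)
    assert d == pytest.approx(2.673, abs=1e-3)


def test_far_pair_negligible():
    s = _two_group_structure([[0, 0, 0]], [[3.0, 0, 0], [30.0, 0, 0]])
    assert effective_distance(s, GROUP_A, GROUP_B) == pytest.approx(3.0, abs=1e-3)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.integers(1, 4), st.integers(1, 4), st.integers(0, 10 ** 6))
def test_effective_distance_matches_brute_force(na, nb, seed):
    """Vectorized r⁻⁶ summation equals the double-loop oracle on random
    small instances, and never exceeds the minimum pairwise distance."""
    rng = np.random.default_rng(seed)
    pos_a = rng.uniform(-5, 5, (na, 3))
    pos_b = rng.uniform(6, 16, (nb, 3))
    s = _two_group_structure(pos_a, pos_b)
    d = effective_distance(s, GROUP_A, GROUP_B)
    assert d == pytest.approx(_brute_force_r6(pos_a, pos_b), rel=1e-9)
    dmin = min(np.linalg.norm(p - q) for p, q in
               itertools.product(pos_a, pos_b))
    assert d <= dmin + 1e-9


def test_effective_distance_monotone_under_group_growth():
    rng = np.random.default_rng(1)
    pos_b = rng.uniform(5, 10, (5, 3))
    prev = np.inf
    for nb in range(1, 6):
        s = _two_group_structure([[0, 0, 0]], pos_b[:nb])
        d = effective_distance(s, GROUP_A, GROUP_B)
        assert d <= prev + 1e-12
        prev = d


def test_empty_group_errors():
    s = _two_group_structure([[0, 0, 0]], [[3, 0, 0]])
    with pytest.raises((ValueError, KeyError)):
        effective_distance(s, Selection("resi 7 and name HZ*"), GROUP_B)


@pytest.mark.parametrize("d,category,expected", [
    (5.5, "weak", 0.5),
    (2.0, "very_strong", 0.0),
    (3.5, "medium", 0.0),   # exactly at the upper bound
])
def test_restraint_violation(d, category, expected):
    s = _two_group_structure([[0, 0, 0]], [[d, 0, 0]])
    r = DistanceRestraint(GROUP_A, GROUP_B, category=category)
    assert restraint_violation(s, r) == pytest.approx(expected, abs=1e-9)


def test_violation_zero_when_all_pairs_within_upper():
    rng = np.random.default_rng(2)
    for _ in range(50):
        pos_a = rng.uniform(0, 1.2, (2, 3))
        pos_b = pos_a.mean(axis=0) + rng.uniform(-1.2, 1.2, (3, 3))
        s = _two_group_structure(pos_a, pos_b)
        dmax = max(np.linalg.norm(p - q) for p, q in
                   itertools.product(pos_a, pos_b))
        if dmax <= 5.0:
            r = DistanceRestraint(GROUP_A, GROUP_B, category="weak")
            assert restraint_violation(s, r) == 0.0


# --- expansion ---------------------------------------------------------------

def test_expand_group_wildcard(small_structure):
    idx = expand_group(Selection("resi 3 and name HD1*"), small_structure)
    assert [small_structure.atoms[i].name for i in idx] == \
           ["HD11", "HD12", "HD13"]


def test_expand_group_singleton(small_structure):
    idx = expand_group(Selection("resi 2 and name SG"), small_structure)
    assert len(idx) == 1


def test_expand_group_matches_regex_scan(small_structure):
    import fnmatch
    idx = expand_group(Selection("resi 1:6 and name H*"), small_structure)
    oracle = [i for i, a in enumerate(small_structure.atoms)
              if fnmatch.fnmatchcase(a.name, "H*")]
    assert idx == oracle


def test_expand_group_missing_residue_errors(small_structure):
    with pytest.raises(KeyError):
        expand_group(Selection("resi 99 and name HB*"), small_structure)


# --- calibration -------------------------------------------------------------

def _peak(intensity, tag="unfiltered"):
    return Peak(GROUP_A, GROUP_B, intensity, tag)


def test_calibration_constant():
    cal = calibrate_intensity_scale([_peak(1000.0)], reference_distance=2.2)
    assert cal.k["unfiltered"] == pytest.approx(1000.0 * 2.2 ** 6)
    assert cal.k["unfiltered"] == pytest.approx(1.134e5, rel=1e-3)


def test_calibration_cross_spectrum_transfer():
    cal = calibrate_intensity_scale(
        [_peak(1000.0)], reference_distance=2.2,
        shared_peaks={"filtered": [(1000.0, 500.0)]})
    assert cal.k["filtered"] == pytest.approx(cal.k["unfiltered"] * 0.5)


def test_calibration_recovers_generator_constant():
    k_true = 5.0e5
    peaks = [_peak(k_true * 2.2 ** -6) for _ in range(7)]
    cal = calibrate_intensity_scale(peaks, reference_distance=2.2)
    assert cal.k["unfiltered"] == pytest.approx(k_true)


def test_calibration_empty_errors():
    with pytest.raises(ValueError):
        calibrate_intensity_scale([])


# --- classification ----------------------------------------------------------

@pytest.mark.parametrize("d,category", [
    (2.3, "very_strong"),   # boundary tie -> tighter bin
    (3.2, "medium"),
    (4.6, "weak"),
    (2.0, "very_strong"),
    (2.9, "strong"),
])
def test_classify_peak_bins(d, category):
    k = 1.0e6
    scale = CalibrationScale(k={"unfiltered": k})
    r = classify_peak(_peak(k * d ** -6), scale)
    assert r.category == category
    assert r.upper == CATEGORY_UPPER[category]
    assert r.lower == 0.0


def test_classify_beyond_detection_limit():
    k = 1.0e6
    scale = CalibrationScale(k={"unfiltered": k})
    p = _peak(k * 6.0 ** -6)
    assert classify_peak(p, scale).category == "weak"
    assert classify_peak(p, scale, discard_beyond_limit=True) is None


def test_classify_nonpositive_intensity_errors():
    with pytest.raises(ValueError):
        Peak(GROUP_A, GROUP_B, 0.0)


# --- NCS tiers ---------------------------------------------------------------

def _bare_template(n_res=181, chain="A"):
    atoms = []
    rng = np.random.default_rng(0)
    for r in range(1, n_res + 1):
        base = rng.uniform(0, 50, 3)
        for k, name in enumerate(("N", "CA", "C", "O", "CB")):
            atoms.append(Atom(name, name[0], r, "ALA", chain,
                              base + [k * 1.4, 0, 0]))
    return Structure(atoms)


def test_vps29_tier_force_constants():
    tmpl = _bare_template()
    restraints = build_ncs_restraints(tmpl, vps29_tier_table())
    by_tier = {}
    for r in restraints:
        by_tier.setdefault(r.tier, []).append(r)
    assert by_tier["strong"][0].force_constant == 100.0
    assert by_tier["medium"][0].force_constant == 2.0
    assert by_tier["weak"][0].force_constant == 0.1
    # residue 10 backbone is in the strong tier
    strong_res = {k[1] for r in by_tier["strong"] for k in r.atom_keys}
    assert 10 in strong_res
    # residue 25 sidechain is in the weak tier (interface residue)
    weak_res = {k[1] for r in by_tier["weak"] for k in r.atom_keys}
    assert 25 in weak_res
    # every restrained atom has a template position
    for r in restraints:
        assert len(r.atom_keys) == len(r.template_positions)


def test_ncs_missing_residue_errors():
    tmpl = _bare_template(n_res=50)
    with pytest.raises(KeyError):
        build_ncs_restraints(tmpl, {("strong", "backbone"): [60]})


# --- tabular I/O -------------------------------------------------------------

def test_peak_and_restraint_frames_round_trip():
    from znseal.restraints import (peaks_from_frame, peaks_to_frame,
                                   restraints_from_frame, restraints_to_frame)
    peaks = [_peak(123.0), _peak(45.0, tag="filtered")]
    back = peaks_from_frame(peaks_to_frame(peaks))
    assert [p.intensity for p in back] == [123.0, 45.0]
    rs = [DistanceRestraint(GROUP_A, GROUP_B, category="medium",
                            kind="intermolecular")]
    back_r = restraints_from_frame(restraints_to_frame(rs))
    assert back_r[0].upper == 3.5 and back_r[0].kind == "intermolecular"
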