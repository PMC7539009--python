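"""NOE peak calibration, ambiguous r⁻⁶ group distance restraints, dihedral
restraints and tiered template (NCS) harmonic restraints.

Calibration follows the classic secondary-structure-reference scheme: the
intensity scale of each spectrum is anchored to cross-peaks whose distance is
fixed by regular secondary structure (e.g. sequential Hα–HN in antiparallel
β-sheet ≈ 2.2 Å), and peaks are then classified into four upper-bound
categories (2.3 / 2.9 / 3.5 / 5.0 Å) from their implied distance
d = (k / I)^(1/6).  All lower bounds are zero.  Groups of equivalent or
non-stereoassigned protons are treated ambiguously with r⁻⁶ summation:
d_eff = (Σ_pairs r⁻⁶)^(−1/6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Selection, Structure, select
from .topology import BACKBONE_NAMES_O

# category -> upper bound (Å); lower bounds are always 0
CATEGORY_UPPER = {
    "very_strong": 2.3,
    "strong": 2.9,
    "medium": 3.5,
    "weak": 5.0,
}

# canonical reference distances for regular secondary structure (Å)
REFERENCE_DISTANCES = {
    "sequential_dan_antiparallel_beta": 2.2,
    "sequential_dnn_alpha_helix": 2.8,
    "i_i3_dan_alpha_helix": 3.4,
}

NCS_FORCE_CONSTANTS = {"strong": 100.0, "medium": 2.0, "weak": 0.1}

NOE_DETECTION_LIMIT = 5.0  # Å


@dataclass
class Peak:
    """An assigned NOE cross-peak between two (possibly ambiguous) groups."""
    group_a: Selection
    group_b: Selection
    intensity: float
    spectrum_tag: str = "unfiltered"

    def __post_init__(self):
        if self.intensity <= 0:
            raise ValueError("peak intensity must be positive")


@dataclass
class DistanceRestraint:
    group_a: Selection
    group_b: Selection
    category: str
    kind: str = "intermolecular"
    lower: float = 0.0
    upper: float = field(init=False)

    def __post_init__(self):
        if self.category not in CATEGORY_UPPER:
            raise ValueError(f"unknown category {self.category!r}")
        if self.lower != 0.0:
            raise ValueError("lower bounds are always zero")
        self.upper = CATEGORY_UPPER[self.category]


@dataclass
class DihedralRestraint:
    """Harmonic restraint on a dihedral (e.g. χ¹), degrees."""
    atoms: tuple  # four (chain, resnum, name) references
    target: float
    half_width: float = 20.0
    force_constant: float = 50.0  # kcal mol⁻¹ rad⁻²


@dataclass
class NCSRestraint:
    """Tiered harmonic similarity restraint to fixed template coordinates."""
    selection: Selection
    tier: str
    template_positions: np.ndarray  # (n, 3), same order as selection expansion
    atom_keys: list = field(default_factory=list)  # (chain, resnum, name)

    def __post_init__(self):
        if self.tier not in NCS_FORCE_CONSTANTS:
            raise ValueError(f"unknown NCS tier {self.tier!r}")
        self.template_positions = np.asarray(self.template_positions, float)

    @property
    def force_constant(self) -> float:
        return NCS_FORCE_CONSTANTS[self.tier]


@dataclass
class CalibrationScale:
    """Per-spectrum intensity ∝ k·r⁻⁶ proportionality constants."""
    k: dict  # spectrum_tag -> intensity·Å⁶
    reference_type: str = "sequential_dan_antiparallel_beta"
    reference_distance: float = REFERENCE_DISTANCES[
        "sequential_dan_antiparallel_beta"]

    def k_for(self, spectrum_tag: str) -> float:
        if spectrum_tag not in self.k:
            raise KeyError(f"no calibration for spectrum {spectrum_tag!r}")
        return self.k[spectrum_tag]


# --- group expansion and effective distances -------------------------------

def expand_group(selection: Selection, structure: Structure) -> list[int]:
    """Deterministic ordered atom-index list for an ambiguous group.

    Wildcards (``HB*``) expand to every matching proton; an expansion that
    references residues absent from the structure raises.
    """
    idx = select(structure, selection)
    if not idx:
        chain, res_ranges, _ = selection._parse()
        present = set()
        for a in structure.atoms:
            if chain is None or a.chain_id == chain:
                present.add(a.residue_number)
        if res_ranges is not None:
            wanted = {r for lo, hi in res_ranges for r in range(lo, hi + 1)}
            if not (wanted & present):
                raise KeyError(
                    f"selection {selection.expression!r} references residues "
                    "absent from the structure")
    return idx


def effective_distance(structure: Structure, restraint_or_groups,
                       group_b: Selection | None = None) -> float:
    """r⁻⁶-summed effective distance between two atom groups.

    Accepts a DistanceRestraint/Peak (with .group_a/.group_b) or two
    selections.  Result is always ≤ the minimum pairwise distance.
    """
    if group_b is None:
        ga, gb = restraint_or_groups.group_a, restraint_or_groups.group_b
    else:
        ga, gb = restraint_or_groups, group_b
    ia = expand_group(ga, structure)
    ib = expand_group(gb, structure)
    if not ia or not ib:
        raise ValueError("restraint group expands to no atoms")
    pa = structure.coords[ia]
    pb = structure.coords[ib]
    diff = pa[:, None, :] - pb[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.any(r2 < 1e-12):
        raise ValueError("coincident atoms in restraint groups")
    s = float(np.sum(r2 ** -3))
    return s ** (-1.0 / 6.0)


def restraint_violation(structure: Structure,
                        restraint: DistanceRestraint) -> float:
    """max(0, d_eff − upper); the zero lower bound can never be violated."""
    d = effective_distance(structure, restraint)
    return max(0.0, d - restraint.upper)


# --- calibration and classification ----------------------------------------

def calibrate_intensity_scale(
        reference_peaks: list[Peak],
        reference_distance: float = REFERENCE_DISTANCES[
            "sequential_dan_antiparallel_beta"],
        reference_type: str = "sequential_dan_antiparallel_beta",
        shared_peaks: dict | None = None) -> CalibrationScale:
    """Anchor the intensity scale: k = median(I_ref) · d_ref⁶.

    The median over the reference peaks is used (robust to outliers).  The
    scale is transferred to other spectra through ``shared_peaks``, a mapping
    ``tag -> [(I_in_reference_spectrum, I_in_other_spectrum), ...]`` of peaks
    observed free of overlap in both spectra: k_other = k_ref · median(ratio).
    """
    if not reference_peaks:
        raise ValueError("at least one reference peak required")
    if reference_distance <= 0:
        raise ValueError("reference distance must be positive")
    tags = {p.spectrum_tag for p in reference_peaks}
    if len(tags) != 1:
        raise ValueError("reference peaks must come from a single spectrum")
    ref_tag = tags.pop()
    k_ref = float(np.median([p.intensity for p in reference_peaks])
                  * reference_distance ** 6)
    k = {ref_tag: k_ref}
    for tag, pairs in (shared_peaks or {}).items():
        ratios = [other / ref for ref, other in pairs]
        k[tag] = k_ref * float(np.median(ratios))
    return CalibrationScale(k=k, reference_type=reference_type,
                            reference_distance=reference_distance)


def implied_distance(peak: Peak, scale: CalibrationScale) -> float:
    return (scale.k_for(peak.spectrum_tag) / peak.intensity) ** (1.0 / 6.0)


def classify_peak(peak: Peak, scale: CalibrationScale,
                  kind: str = "intermolecular",
                  discard_beyond_limit: bool = False) -> DistanceRestraint | None:
    """Bin a peak into the tightest distance category containing its implied
    distance.  Peaks implying d > 5 Å are put in the weak category (the 5 Å
    detection-limit convention) unless ``discard_beyond_limit``.

    Ties at a bin boundary go to the tighter bin.
    """
    d = implied_distance(peak, scale)
    for category in ("very_strong", "strong", "medium", "weak"):
        if d <= CATEGORY_UPPER[category]:
            return DistanceRestraint(peak.group_a, peak.group_b,
                                     category=category, kind=kind)
    if discard_beyond_limit:
        return None
    return DistanceRestraint(peak.group_a, peak.group_b,
                             category="weak", kind=kind)


def classify_peaks(peaks: list[Peak], scale: CalibrationScale,
                   peptide_chain: str = "B", template_chain: str = "A",
                   discard_beyond_limit: bool = False
                   ) -> list[DistanceRestraint]:
    """Classify a peak list, tagging each restraint's kind from the chains
    named in its group selections."""
    out = []
    for p in peaks:
        ca = p.group_a._parse()[0]
        cb = p.group_b._parse()[0]
        if ca == cb == peptide_chain:
            kind = "intramolecular_peptide"
        elif ca == cb == template_chain:
            kind = "intramolecular_template"
        else:
            kind = "intermolecular"
        r = classify_peak(p, scale, kind=kind,
                          discard_beyond_limit=discard_beyond_limit)
        if r is not None:
            out.append(r)
    return out


# --- NCS (template similarity) restraints ----------------------------------

def build_ncs_restraints(template: Structure, tier_table: dict,
                         chain_id: str | None = None) -> list[NCSRestraint]:
    """Tiered harmonic restraints to the template's own coordinates.

    ``tier_table`` maps ``(tier, scope)`` to residue-number lists, with scope
    ``"backbone"`` (N, CA, C, O) or ``"sidechain"`` (everything else,
    hydrogens included).  Force constants per tier: 100.0 / 2.0 / 0.1
    kcal mol⁻¹ Å⁻².
    """
    if chain_id is None:
        chain_id = template.atoms[0].chain_id
    present = set(template.residue_numbers(chain_id))
    restraints = []
    for (tier, scope), residues in tier_table.items():
        if tier not in NCS_FORCE_CONSTANTS:
            raise ValueError(f"unknown NCS tier {tier!r}")
        missing = [r for r in residues if r not in present]
        if missing:
            raise KeyError(f"tier residues absent from template: {missing}")
        resi = ",".join(str(r) for r in residues)
        if scope == "backbone":
            expr = f"chain {chain_id} and resi {resi} and name " \
                   + ",".join(BACKBONE_NAMES_O)
        elif scope == "sidechain":
            expr = f"chain {chain_id} and resi {resi}"
        else:
            raise ValueError(f"unknown scope {scope!r}")
        sel = Selection(expr)
        idx = select(template, sel)
        if scope == "sidechain":
            backbone = set(BACKBONE_NAMES_O) | {"H", "HA", "HA2", "HA3"}
            idx = [i for i in idx if template.atoms[i].name not in backbone]
        keys = [(template.atoms[i].chain_id, template.atoms[i].residue_number,
                 template.atoms[i].name) for i in idx]
        restraints.append(NCSRestraint(
            selection=sel, tier=tier,
            template_positions=template.coords[idx].copy(),
            atom_keys=keys))
    return restraints


def vps29_tier_table() -> dict:
    """The template-restraint tier scheme used for the VPS29 domain:
    strong backbone over the rigid core, medium backbone elsewhere, medium
    sidechains away from the interface and weak sidechains at the interface.
    """
    return {
        ("strong", "backbone"): list(range(7, 20)) + list(range(60, 149)),
        ("medium", "backbone"): (list(range(1, 7)) + list(range(20, 60))
                                 + list(range(149, 182))),
        ("medium", "sidechain"): (
            [1] + list(range(3, 7)) + list(range(20, 25)) + [26, 28, 29]
            + list(range(31, 60)) + list(range(149, 152)) + [153]
            + list(range(155, 161)) + [162, 164] + list(range(166, 172))
            + [173] + list(range(175, 182))),
        ("weak", "sidechain"): [2, 25, 27, 30, 152, 154, 161, 163, 165,
                                172, 174],
    }


# --- tabular I/O ------------------------------------------------------------

PEAK_COLUMNS = ["group_a", "group_b", "intensity", "spectrum_tag"]
RESTRAINT_COLUMNS = ["group_a", "group_b", "category", "kind", "lower", "upper"]


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.group_a.expression, p.group_b.expression, p.intensity,
          p.spectrum_tag) for p in peaks], columns=PEAK_COLUMNS)


def peaks_from_frame(df: pd.DataFrame) -> list[Peak]:
    return [Peak(Selection(r.group_a), Selection(r.group_b),
                 float(r.intensity), str(r.spectrum_tag))
            for r in df.itertuples()]


def restraints_to_frame(restraints: list[DistanceRestraint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.group_a.expression, r.group_b.expression, r.category, r.kind,
          r.lower, r.upper) for r in restraints], columns=RESTRAINT_COLUMNS)


def restraints_from_frame(df: pd.DataFrame) -> list[DistanceRestraint]:
    return [DistanceRestraint(Selection(r.group_a), Selection(r.group_b),
                              category=r.category, kind=r.kind)
            for r in df.itertuples()]
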