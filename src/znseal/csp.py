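"""Chemical-shift perturbation (CSP) mapping between free and bound amide
shift tables, with the half-max colour-ramp classification used for
structure-surface painting.

Two combined-shift variants are supported, differing in how the ¹⁵N
dimension is down-weighted against ¹H:

* ``figure``:  CSP = sqrt(Δδ(¹H)² + 0.2·Δδ(¹⁵N)²)
* ``methods``: CSP = sqrt(Δδ(¹H)² + (Δδ(¹⁵N)/5)²)

Both are always computable; the figure variant is the default because it is
the one tied to the published maximum of 0.662 ppm.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

VARIANT_N_WEIGHT = {"figure": 0.2, "methods": 1.0 / 25.0}


@dataclass
class ShiftRecord:
    residue_number: int
    delta_h: float  # amide 1H shift, ppm
    delta_n: float  # amide 15N shift, ppm


@dataclass
class CSPProfile:
    values: dict  # residue_number -> CSP (ppm); missing residues absent
    formula_variant: str
    max_value: float = field(init=False)
    max_residue: int = field(init=False)

    def __post_init__(self):
        if not self.values:
            raise ValueError("no matched residues")
        self.max_residue = max(self.values, key=self.values.get)
        self.max_value = self.values[self.max_residue]

    @property
    def half_max(self) -> float:
        return self.max_value / 2.0


def compute_csp(free: list[ShiftRecord], bound: list[ShiftRecord],
                variant: str = "figure") -> CSPProfile:
    """Per-residue combined amide CSP between two states.

    Residues present in only one table are excluded (reported via the
    returned profile's ``values`` keys).  CSP is symmetric in its inputs.
    """
    if variant not in VARIANT_N_WEIGHT:
        raise ValueError(f"unknown CSP variant {variant!r}")
    w = VARIANT_N_WEIGHT[variant]
    f = {r.residue_number: r for r in free}
    b = {r.residue_number: r for r in bound}
    common = sorted(set(f) & set(b))
    if not common:
        raise ValueError("no residues matched between the shift tables")
    values = {}
    for res in common:
        dh = f[res].delta_h - b[res].delta_h
        dn = f[res].delta_n - b[res].delta_n
        values[res] = math.sqrt(dh * dh + w * dn * dn)
    return CSPProfile(values=values, formula_variant=variant)


def csp_color_scale(profile: CSPProfile) -> dict:
    """Colour-ramp classification: linear ramp fraction on [0, half-max],
    saturated above half-max (the published yellow-saturation convention)."""
    out = {}
    hm = profile.half_max
    for res, v in profile.values.items():
        if v > hm:
            out[res] = {"fraction": 1.0, "saturated": True}
        else:
            out[res] = {"fraction": v / hm if hm > 0 else 0.0,
                        "saturated": False}
    return out


# --- input readers -----------------------------------------------------------

def read_shift_tsv(text: str) -> list[ShiftRecord]:
    """TSV fallback with columns residue, delta_h, delta_n."""
    from io import StringIO
    df = pd.read_csv(StringIO(text), sep="\t")
    cols = {c.lower(): c for c in df.columns}
    return [ShiftRecord(int(r[cols["residue"]]), float(r[cols["delta_h"]]),
                        float(r[cols["delta_n"]]))
            for _, r in df.iterrows()]


def read_nmrstar_amide_shifts(text: str) -> list[ShiftRecord]:
    """Extract amide H/N chemical shifts from an NMR-STAR chemical-shift loop.

    Minimal reader for the ``_Atom_chem_shift`` loop (tags ``Seq_ID`` /
    ``Comp_index_ID``, ``Atom_ID``, ``Val``); residues with both an H and an
    N entry yield one record.
    """
    lines = text.splitlines()
    records: dict[int, dict[str, float]] = {}
    i = 0
    while i < len(lines):
        if lines[i].strip() != "loop_":
            i += 1
            continue
        # collect tags
        tags = []
        i += 1
        while i < len(lines) and lines[i].strip().startswith("_"):
            tags.append(lines[i].strip())
            i += 1
        if not any("Atom_chem_shift" in t for t in tags):
            continue
        short = [t.split(".", 1)[1] if "." in t else t for t in tags]
        def col(*names):
            for n in names:
                if n in short:
                    return short.index(n)
            return None
        c_seq = col("Seq_ID", "Comp_index_ID")
        c_atom = col("Atom_ID")
        c_val = col("Val")
        if c_seq is None or c_atom is None or c_val is None:
            continue
        while i < len(lines):
            row = lines[i].strip()
            i += 1
            if row == "stop_":
                break
            if not row or row.startswith("#"):
                continue
            fields = re.split(r"\s+", row)
            if len(fields) < len(tags):
                continue
            try:
                seq = int(fields[c_seq])
                val = float(fields[c_val])
            except ValueError:
                continue
            atom = fields[c_atom]
            if atom in ("H", "N"):
                records.setdefault(seq, {})[atom] = val
    return [ShiftRecord(seq, d["H"], d["N"])
            for seq, d in sorted(records.items())
            if "H" in d and "N" in d]
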