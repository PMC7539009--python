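"""Single-site binding analysis and van't Hoff thermodynamics.

Equilibrium responses follow the one-site isotherm R = R_max·C/(K_D + C);
1:1 kinetics follow dR/dt = k_on·C·(R_max − R) − k_off·R during association
and dR/dt = −k_off·R during dissociation, with K_D = k_off/k_on.  The linear
van't Hoff form ln K_D = ΔH/(R·T) − ΔS/R (K_D in mol L⁻¹, T in K) yields the
binding enthalpy from the slope and entropy from the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

GAS_CONSTANT = 8.314  # J K⁻¹ mol⁻¹


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


@dataclass
class BindingIsotherm:
    concentrations: np.ndarray  # mol L⁻¹
    responses: np.ndarray       # response units
    temperature: float          # K

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, float)
        self.responses = np.asarray(self.responses, float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentration/response length mismatch")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")


@dataclass
class KineticTrace:
    times: np.ndarray
    responses: np.ndarray
    concentration: float        # mol L⁻¹ during association; 0 = dissociation
    phase: str                  # "association" | "dissociation"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.responses = np.asarray(self.responses, float)


@dataclass
class EquilibriumFit:
    K_D: float
    R_max: float
    residual_norm: float


@dataclass
class KineticFit:
    k_on: float   # M⁻¹ s⁻¹
    k_off: float  # s⁻¹

    @property
    def K_D(self) -> float:
        return self.k_off / self.k_on


@dataclass
class ThermoFit:
    delta_H: float  # J mol⁻¹
    delta_S: float  # J K⁻¹ mol⁻¹
    r_squared: float = field(default=np.nan)
    gas_constant: float = GAS_CONSTANT


def one_site_response(c, K_D, R_max):
    return R_max * c / (K_D + c)


def fit_equilibrium(isotherm: BindingIsotherm) -> EquilibriumFit:
    """Unweighted least-squares fit of the one-site isotherm.

    K_D is initialised at the geometric mean of the concentration range, with
    a small multistart grid for robustness.
    """
    c = isotherm.concentrations
    r = isotherm.responses
    if len(np.unique(c)) < 3:
        raise ValueError("need at least three distinct concentrations")
    rmax0 = max(r.max(), 1e-12)
    kd_grid = np.exp(np.log(np.sqrt(c.min() * c.max()))
                     + np.array([-2.0, 0.0, 2.0]))
    best = None
    for kd0 in kd_grid:
        try:
            popt, _ = optimize.curve_fit(
                one_site_response, c, r, p0=[kd0, rmax0],
                bounds=([1e-15, 1e-15], [np.inf, np.inf]), maxfev=10000)
        except RuntimeError:
            continue
        res = float(np.linalg.norm(one_site_response(c, *popt) - r))
        if best is None or res < best[1]:
            best = (popt, res)
    if best is None:
        raise RuntimeError("equilibrium fit did not converge")
    (kd, rmax), res = best
    return EquilibriumFit(K_D=float(kd), R_max=float(rmax), residual_norm=res)


def association_response(t, c, k_on, k_off, R_max, r0=0.0):
    """Closed-form 1:1 association at constant analyte concentration."""
    kobs = k_on * c + k_off
    req = R_max * k_on * c / kobs
    return req + (r0 - req) * np.exp(-kobs * t)


def dissociation_response(t, k_off, r0):
    return r0 * np.exp(-k_off * t)


def fit_kinetics(traces: list[KineticTrace], R_max: float) -> KineticFit:
    """Global 1:1 kinetic fit with R_max fixed from the equilibrium analysis."""
    assoc = [t for t in traces if t.phase == "association"]
    dissoc = [t for t in traces if t.phase == "dissociation"]
    if not assoc or not dissoc:
        raise ValueError("need both association and dissociation traces")

    def residuals(params):
        log_kon, log_koff = params
        k_on, k_off = np.exp(log_kon), np.exp(log_koff)
        out = []
        for tr in assoc:
            pred = association_response(tr.times, tr.concentration,
                                        k_on, k_off, R_max,
                                        r0=tr.responses[0])
            out.append(pred - tr.responses)
        for tr in dissoc:
            pred = dissociation_response(tr.times, k_off, tr.responses[0])
            out.append(pred - tr.responses)
        return np.concatenate(out)

    # initial k_off from the dissociation tail, k_on from typical K_D ~ C
    tr0 = dissoc[0]
    pos = tr0.responses > 0
    if pos.sum() >= 2:
        slope, intercept, *_ = stats.linregress(
            tr0.times[pos], np.log(tr0.responses[pos]))
        koff0 = max(-slope, 1e-6)
    else:
        koff0 = 1e-2
    c_typ = np.median([t.concentration for t in assoc])
    kon0 = koff0 / max(c_typ, 1e-12)
    sol = optimize.least_squares(
        residuals, x0=[np.log(kon0), np.log(koff0)], method="lm",
        max_nfev=20000)
    if not sol.success:
        raise RuntimeError("kinetic fit did not converge")
    k_on, k_off = np.exp(sol.x)
    return KineticFit(k_on=float(k_on), k_off=float(k_off))


def vant_hoff_fit(kds) -> ThermoFit:
    """Ordinary least squares of ln K_D against 1/T.

    ``kds``: iterable of (K_D in mol L⁻¹, temperature in K).  Slope = ΔH/R,
    intercept = −ΔS/R.
    """
    kds = list(kds)
    kd = np.array([x[0] for x in kds], float)
    temp = np.array([x[1] for x in kds], float)
    if len(np.unique(temp)) < 2:
        raise ValueError("need at least two distinct temperatures")
    x = 1.0 / temp
    y = np.log(kd)
    res = stats.linregress(x, y)
    return ThermoFit(delta_H=float(res.slope * GAS_CONSTANT),
                     delta_S=float(-res.intercept * GAS_CONSTANT),
                     r_squared=float(res.rvalue ** 2))


def predict_kd(thermo: ThermoFit, temperature: float) -> float:
    """K_D(T) = exp(ΔH/(R·T) − ΔS/R), mol L⁻¹."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    r = thermo.gas_constant
    return float(np.exp(thermo.delta_H / (r * temperature)
                        - thermo.delta_S / r))
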