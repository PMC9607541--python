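"""van't Hoff thermodynamics of the binding equilibrium.

ln Ka = −ΔH/(R·T) + ΔS/R fitted across temperatures gives the enthalpy and
entropy of binding; ΔG = ΔH − T·ΔS per temperature.  The signs of ΔH and ΔS
classify the dominant non-covalent force: (+,+) hydrophobic, (−,−) van der
Waals + hydrogen bonding, (−,+) electrostatic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import FitError, ValidationError

__all__ = [
    "GAS_CONSTANT",
    "ThermoResult",
    "ForceClassification",
    "GibbsComparison",
    "fit_vant_hoff",
    "compute_gibbs",
    "gibbs_comparison",
    "classify_binding_forces",
]

#: Gas constant, J/(mol·K).
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class ForceClassification:
    forces: frozenset[str]
    flag: str | None = None


@dataclass(frozen=True)
class ThermoResult:
    """van't Hoff fit output.

    dH in kJ/mol, dS in J/(mol·K); dG_per_T maps each input temperature (K)
    to the Gibbs energy ΔH − T·ΔS in kJ/mol.  A two-point fit is an exact
    solve (standard errors are NaN); three or more points use OLS of ln Ka
    on 1/T.
    """

    dH: float
    dH_se: float
    dS: float
    dS_se: float
    dG_per_T: dict[float, float]
    force_types: frozenset[str]
    force_flag: str | None
    spontaneous: dict[float, bool]
    r_squared: float
    gas_constant: float = GAS_CONSTANT


@dataclass(frozen=True)
class GibbsComparison:
    """ΔG by both routes with their disagreement."""

    from_ka: float
    from_enthalpy: float
    discrepancy: float
    flagged: bool


def classify_binding_forces(dH: float, dS: float) -> ForceClassification:
    """Map the signs of ΔH (kJ/mol) and ΔS (J/mol/K) to binding-force types."""
    if dH == 0 or dS == 0:
        return ForceClassification(frozenset(), flag="boundary case")
    if dH > 0 and dS > 0:
        return ForceClassification(frozenset({"hydrophobic"}))
    if dH < 0 and dS < 0:
        return ForceClassification(frozenset({"van der Waals", "hydrogen bond"}))
    if dH < 0 and dS > 0:
        return ForceClassification(frozenset({"electrostatic"}))
    # dH > 0, dS < 0: binding would be non-spontaneous at all T; outside the
    # canonical sign rules.
    return ForceClassification(frozenset(), flag="outside canonical sign rules")


def fit_vant_hoff(ka_by_temperature) -> ThermoResult:
    """Estimate (ΔH, ΔS) from binding constants at ≥2 temperatures.

    Parameters
    ----------
    ka_by_temperature : mapping
        Temperature in K -> association constant Ka in L/mol.
    """
    items = sorted(ka_by_temperature.items())
    temps = np.array([t for t, _ in items], dtype=float)
    kas = np.array([k for _, k in items], dtype=float)
    if temps.size < 2:
        raise FitError("need Ka at ≥2 temperatures")
    if np.unique(temps).size != temps.size or np.any(temps <= 0):
        raise ValidationError("temperatures must be positive and distinct")
    if np.any(kas <= 0):
        raise ValidationError("all Ka must be positive")

    x = 1.0 / temps
    y = np.log(kas)
    if temps.size == 2:
        slope = (y[0] - y[1]) / (x[0] - x[1])
        intercept = y[0] - slope * x[0]
        slope_se = intercept_se = float("nan")
        r2 = 1.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        slope_se, intercept_se = float(fit.stderr), float(fit.intercept_stderr)
        r2 = float(fit.rvalue**2)

    dH = -slope * GAS_CONSTANT / 1000.0  # kJ/mol
    dS = intercept * GAS_CONSTANT  # J/mol/K
    dG = {float(t): dH - t * dS / 1000.0 for t in temps}
    forces = classify_binding_forces(dH, dS)
    return ThermoResult(
        dH=dH,
        dH_se=abs(slope_se) * GAS_CONSTANT / 1000.0,
        dS=dS,
        dS_se=abs(intercept_se) * GAS_CONSTANT,
        dG_per_T=dG,
        force_types=forces.forces,
        force_flag=forces.flag,
        spontaneous={t: g < 0 for t, g in dG.items()},
        r_squared=r2,
    )


def compute_gibbs(
    mode: str,
    *,
    Ka: float | None = None,
    dH: float | None = None,
    dS: float | None = None,
    temperature: float,
) -> float:
    """Gibbs energy of binding in kJ/mol by one of two routes.

    ``from_ka``: ΔG = −R·T·ln Ka (Ka in L/mol).
    ``from_enthalpy``: ΔG = ΔH − T·ΔS (ΔH kJ/mol, ΔS J/mol/K).
    """
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    if mode == "from_ka":
        if Ka is None or Ka <= 0:
            raise ValidationError("from_ka mode needs Ka > 0")
        return float(-GAS_CONSTANT * temperature * np.log(Ka) / 1000.0)
    if mode == "from_enthalpy":
        if dH is None or dS is None:
            raise ValidationError("from_enthalpy mode needs dH and dS")
        return float(dH - temperature * dS / 1000.0)
    raise ValidationError(f"unknown mode {mode!r}; use 'from_ka' or 'from_enthalpy'")


def gibbs_comparison(
    Ka: float, dH: float, dS: float, temperature: float, warn_threshold: float = 0.5
) -> GibbsComparison:
    """ΔG via both routes; flagged (and warned) when they disagree by more
    than ``warn_threshold`` kJ/mol."""
    g_ka = compute_gibbs("from_ka", Ka=Ka, temperature=temperature)
    g_h = compute_gibbs("from_enthalpy", dH=dH, dS=dS, temperature=temperature)
    disc = abs(g_ka - g_h)
    flagged = disc > warn_threshold
    if flagged:
        warnings.warn(
            f"ΔG routes disagree by {disc:.2f} kJ/mol at {temperature} K "
            f"(−RT·lnKa = {g_ka:.2f}, ΔH−TΔS = {g_h:.2f})"
        )
    return GibbsComparison(g_ka, g_h, disc, flagged)
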