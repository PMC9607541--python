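"""Stern–Volmer regression, quenching-mechanism classification and the
double-logarithmic binding fit.

The Stern–Volmer relation F0/F = 1 + Ksv[Q] is fitted by ordinary least
squares with an intercept; the bimolecular quenching rate constant is
Kq = Ksv/τ0 with τ0 the unquenched fluorophore lifetime (~1e-8 s for
proteins).  The double-log relation log10((F0−F)/F) = log10(Ka) + n·log10[Q]
yields the association constant Ka and the binding-site number n.

Note on units: some of the literature prints Ksv and Ka with the unit
"mol/L"; both are association-type constants and carry L/mol here so that
Ksv·[Q] is dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FitError, ValidationError
from .spectra import TitrationSeries

__all__ = [
    "DEFAULT_TAU0",
    "DYNAMIC_KQ_CEILING",
    "QuenchingResult",
    "BindingResult",
    "MechanismCall",
    "fit_stern_volmer",
    "fit_double_log",
    "classify_quenching_mechanism",
]

#: Default unquenched fluorophore lifetime, seconds.
DEFAULT_TAU0 = 1e-8

#: Upper bound of diffusion-limited collisional quenching, L/mol/s. A fitted
#: Kq far above this ceiling indicates ground-state complex formation
#: (static quenching) rather than collisional (dynamic) quenching.
DYNAMIC_KQ_CEILING = 2.0e10


@dataclass(frozen=True)
class QuenchingResult:
    """Stern–Volmer fit output at one temperature."""

    Ksv: float  # L/mol
    Ksv_se: float
    tau0: float  # s
    Kq: float  # L/mol/s; always Ksv / tau0
    intercept: float
    r_squared: float
    temperature: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isclose(self.Kq * self.tau0, self.Ksv, rtol=1e-12, atol=0.0):
            raise ValidationError("Kq must equal Ksv / tau0")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class BindingResult:
    """Double-logarithmic fit output: association constant and site number."""

    Ka: float  # L/mol
    Ka_se: float
    n: float
    n_se: float
    r_squared: float
    temperature: float
    n_points: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.Ka <= 0:
            raise ValidationError("Ka must be positive")
        if self.n <= 0:
            raise ValidationError("binding-site number n must be positive")


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism classification with its evidence."""

    mechanism: str  # static | dynamic | indeterminate
    rationale: dict
    flags: tuple[str, ...] = ()


def fit_stern_volmer(series: TitrationSeries, tau0: float = DEFAULT_TAU0) -> QuenchingResult:
    """Fit F0/F = 1 + Ksv[Q] by OLS and derive Kq = Ksv/τ0.

    The fitted intercept is reported and a warning flag raised when it falls
    outside [0.9, 1.1] (an intercept far from 1 signals curvature or a bad
    F0).  A negative slope is reported as Ksv with a "no quenching detected"
    flag rather than an error.
    """
    if series.n_nonzero < 3:
        raise FitError("need ≥3 nonzero concentrations for a Stern-Volmer fit")
    if tau0 <= 0:
        raise ValidationError("tau0 must be positive")
    q = series.quencher_conc
    y = series.F0 / series.peak_intensity
    fit = stats.linregress(q, y)

    flags: list[str] = []
    if fit.slope < 0:
        flags.append("no quenching detected")
        warnings.warn("negative Stern-Volmer slope: no quenching detected")
    if not (0.9 <= fit.intercept <= 1.1):
        flags.append(f"intercept {fit.intercept:.3f} outside [0.9, 1.1]")
        warnings.warn(f"Stern-Volmer intercept {fit.intercept:.3f} far from 1")

    ksv = float(fit.slope)
    r2 = float(fit.rvalue**2)
    if np.isnan(r2):  # zero-variance response (constant F)
        r2 = 0.0
    return QuenchingResult(
        Ksv=ksv,
        Ksv_se=float(fit.stderr),
        tau0=tau0,
        Kq=ksv / tau0,
        intercept=float(fit.intercept),
        r_squared=r2,
        temperature=series.temperature,
        flags=tuple(flags),
    )


def fit_double_log(series: TitrationSeries) -> BindingResult:
    """Fit log10((F0−F)/F) = log10(Ka) + n·log10[Q] by OLS.

    Only nonzero concentrations with F < F0 enter the fit; excluded points
    are counted and named in the error if fewer than 3 usable points remain.
    The standard error of Ka follows from the intercept by the delta method,
    se(Ka) = ln(10)·Ka·se(intercept).
    """
    q = series.quencher_conc
    F = series.peak_intensity
    F0 = series.F0
    nonzero = q > 0
    usable = nonzero & (F < F0)
    excluded = np.flatnonzero(nonzero & ~usable)
    if np.count_nonzero(usable) < 3:
        raise FitError(
            "need ≥3 nonzero concentrations with F < F0; excluded points at "
            f"concentrations {q[excluded].tolist()}"
        )
    x = np.log10(q[usable])
    y = np.log10((F0 - F[usable]) / F[usable])
    fit = stats.linregress(x, y)
    ka = float(10.0 ** fit.intercept)
    return BindingResult(
        Ka=ka,
        Ka_se=float(np.log(10.0) * ka * fit.intercept_stderr),
        n=float(fit.slope),
        n_se=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
        temperature=series.temperature,
        n_points=int(np.count_nonzero(usable)),
        n_excluded=int(excluded.size),
    )


def classify_quenching_mechanism(
    results: list[QuenchingResult] | tuple[QuenchingResult, ...],
    kq_ceiling: float = DYNAMIC_KQ_CEILING,
) -> MechanismCall:
    """Call the quenching mechanism from the temperature trend of Ksv and Kq.

    Static quenching (ground-state complex): Ksv strictly decreases with
    temperature and every Kq exceeds the diffusion-collision ceiling.
    Dynamic (collisional): Ksv strictly increases and every Kq is at or below
    the ceiling.  Conflicting evidence is reported as indeterminate with both
    criteria spelled out.  A single temperature falls back on the Kq
    criterion alone, flagged.
    """
    if not results:
        raise ValidationError("need at least one QuenchingResult")
    ordered = sorted(results, key=lambda r: r.temperature)
    ksv = [r.Ksv for r in ordered]
    kq = [r.Kq for r in ordered]
    temps = [r.temperature for r in ordered]
    all_kq_above = all(k > kq_ceiling for k in kq)
    all_kq_below = all(k <= kq_ceiling for k in kq)

    rationale = {
        "temperatures_K": temps,
        "Ksv": ksv,
        "Kq": kq,
        "kq_ceiling": kq_ceiling,
        "all_Kq_above_ceiling": all_kq_above,
        "all_Kq_at_or_below_ceiling": all_kq_below,
    }

    if len(ordered) == 1:
        mech = "static" if all_kq_above else "dynamic"
        rationale["Ksv_trend"] = "unavailable"
        return MechanismCall(mech, rationale, flags=("temperature trend unavailable",))

    decreasing = all(a > b for a, b in zip(ksv, ksv[1:]))
    increasing = all(a < b for a, b in zip(ksv, ksv[1:]))
    rationale["Ksv_trend"] = (
        "decreasing" if decreasing else "increasing" if increasing else "non-monotone"
    )

    if decreasing and all_kq_above:
        return MechanismCall("static", rationale)
    if increasing and all_kq_below:
        return MechanismCall("dynamic", rationale)
    return MechanismCall("indeterminate", rationale)
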