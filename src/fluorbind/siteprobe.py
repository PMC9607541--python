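"""Site-marker displacement analysis for serum-albumin binding-site assignment.

Warfarin marks Sudlow site 1 (subdomain IIA), ibuprofen site 2 (subdomain
IIIA) and methyl orange site 3.  Re-fitting the ligand's association
constant with each marker pre-bound gives K'a; the ratio 100·K'a/Ka against
the probe-free constant drops sharply for the marker sharing the ligand's
site.  The per-point displacement statistic is the printed ratio convention
100·F2/F1 (intensity with probe over intensity without), not 1 − F2/F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, ValidationError
from .quenching import BindingResult, fit_double_log
from .spectra import TitrationSeries

__all__ = [
    "PROBE_SITES",
    "DisplacementExperiment",
    "DisplacementResult",
    "SiteAssignment",
    "probe_displacement_percent",
    "displacement_profile",
    "assign_primary_site",
    "assign_from_ratios",
]

#: Canonical probe -> albumin site number.
PROBE_SITES: dict[str, int] = {"warfarin": 1, "ibuprofen": 2, "methyl orange": 3}


@dataclass(frozen=True)
class DisplacementExperiment:
    """Paired titrations of the ligand with and without one site marker."""

    probe_name: str
    series_with_probe: TitrationSeries  # intensities in the F2 role
    series_without_probe: TitrationSeries  # intensities in the F1 role
    site_id: int | None = None
    probe_protein_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not np.array_equal(
            self.series_with_probe.quencher_conc, self.series_without_probe.quencher_conc
        ):
            raise ValidationError(
                f"{self.probe_name}: with/without-probe series must share one "
                "concentration grid"
            )
        if self.site_id is None:
            object.__setattr__(self, "site_id", PROBE_SITES.get(self.probe_name.lower()))


@dataclass(frozen=True)
class DisplacementValue:
    percent: float
    enhancement: bool = False


@dataclass(frozen=True)
class DisplacementResult:
    probe_name: str
    site_id: int | None
    displacement_percent: np.ndarray  # per concentration, ratio convention
    Ka_prime: float
    ratio_percent: float  # 100 * K'a / Ka
    binding_fit: BindingResult


@dataclass(frozen=True)
class SiteAssignment:
    assigned_site: int | None
    status: str  # 'assigned' | 'ambiguous'
    reason: str
    ratios: dict[str, float]  # probe -> 100*K'a/Ka
    results: tuple[DisplacementResult, ...] = ()
    Ka_reference: float | None = None


def probe_displacement_percent(F2: float, F1: float) -> DisplacementValue:
    """Ratio-convention displacement, 100·F2/F1.

    100% means the probe left the ligand-quenched intensity unchanged; values
    above 100% are flagged as enhancement rather than clipped.
    """
    if F1 <= 0:
        raise ValidationError("reference intensity F1 must be positive")
    percent = 100.0 * F2 / F1
    return DisplacementValue(percent=percent, enhancement=percent > 100.0)


def displacement_profile(experiment: DisplacementExperiment) -> np.ndarray:
    """Per-concentration displacement percentages for one experiment."""
    f1 = experiment.series_without_probe.peak_intensity
    f2 = experiment.series_with_probe.peak_intensity
    return 100.0 * f2 / f1


def _fit_ka_prime(experiment: DisplacementExperiment) -> BindingResult:
    try:
        return fit_double_log(experiment.series_with_probe)
    except (FitError, ValidationError) as exc:
        raise FitError(f"probe {experiment.probe_name!r}: {exc}") from exc


def assign_primary_site(
    experiments: list[DisplacementExperiment] | tuple[DisplacementExperiment, ...],
    ratio_threshold: float = 60.0,
    separation: float = 10.0,
) -> SiteAssignment:
    """Assign the ligand's primary binding site from marker competition.

    Ka is fitted from the probe-free series, K'a per probe from the
    probe-present series (both double-log fits).  The site of the probe with
    the minimum ratio 100·K'a/Ka is assigned provided that ratio falls below
    ``ratio_threshold`` and the next-lowest ratio is at least ``separation``
    percentage points higher; otherwise the call is ambiguous.
    """
    if len(experiments) < 2:
        raise ValidationError("need ≥2 probes for a site assignment")
    ka_ref = fit_double_log(experiments[0].series_without_probe).Ka
    results = []
    for exp in experiments:
        fit = _fit_ka_prime(exp)
        results.append(
            DisplacementResult(
                probe_name=exp.probe_name,
                site_id=exp.site_id,
                displacement_percent=displacement_profile(exp),
                Ka_prime=fit.Ka,
                ratio_percent=100.0 * fit.Ka / ka_ref,
                binding_fit=fit,
            )
        )
    ratios = {r.probe_name: r.ratio_percent for r in results}
    site_by_probe = {r.probe_name: r.site_id for r in results}
    decision = assign_from_ratios(ratios, ratio_threshold, separation, site_by_probe)
    return SiteAssignment(
        assigned_site=decision.assigned_site,
        status=decision.status,
        reason=decision.reason,
        ratios=ratios,
        results=tuple(results),
        Ka_reference=ka_ref,
    )


def assign_from_ratios(
    ratios: dict[str, float],
    ratio_threshold: float = 60.0,
    separation: float = 10.0,
    site_by_probe: dict[str, int | None] | None = None,
) -> SiteAssignment:
    """Minimum-ratio site assignment from already-computed K'a/Ka percentages."""
    if len(ratios) < 2:
        raise ValidationError("need ratios for ≥2 probes")
    if site_by_probe is None:
        site_by_probe = {p: PROBE_SITES.get(p.lower()) for p in ratios}
    ordered = sorted(ratios.items(), key=lambda kv: kv[1])
    (best_probe, best), (_, second) = ordered[0], ordered[1]
    if best >= ratio_threshold:
        return SiteAssignment(
            assigned_site=None,
            status="ambiguous",
            reason="no competing probe: no ratio below the assignment threshold "
            f"({ratio_threshold}%)",
            ratios=dict(ratios),
        )
    if second - best < separation:
        tied = [p for p, v in ordered if v - best < separation]
        return SiteAssignment(
            assigned_site=None,
            status="ambiguous",
            reason=f"tie: probes {tied} within {separation} percentage points",
            ratios=dict(ratios),
        )
    return SiteAssignment(
        assigned_site=site_by_probe.get(best_probe),
        status="assigned",
        reason=f"minimum ratio {best:.2f}% for {best_probe} "
        f"(next {second:.2f}%)",
        ratios=dict(ratios),
    )
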