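"""Inhibition-rate statistics for non-enzymatic glycation assays.

Covers the fructosamine (NBT, absorbance at 530 nm) early-stage readout, the
fluorescent AGE species panel, glycoxidation products (dityrosine,
kynurenine, N'-formylkynurenine) and the thioflavin-T fibril index, plus the
excitation/emission wavelength registry for each fluorescent species.

The inhibition rate is 100·(1 − reading_with_inhibitor / reading_without)
for both fluorescence and absorbance readouts: a value of 34% means the
inhibitor suppressed a third of the signal attributable to the glycation
product.  Negative values (signal enhancement) are reported, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "WavelengthRegistry",
    "DEFAULT_REGISTRY",
    "AssayPanel",
    "InhibitionResult",
    "inhibition_rate",
    "wavelength_lookup",
    "panel_inhibition",
    "tht_fibril_index",
    "anova_tukey",
]


def _canonical(species: str) -> str:
    # tolerate the typographic prime in N'-formylkynurenine
    return species.replace("′", "'").strip().lower()


@dataclass(frozen=True)
class WavelengthRegistry:
    """Species label -> (excitation nm, emission nm), emission > excitation."""

    pairs: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (ex, em) in self.pairs.items():
            if ex <= 0 or em <= 0:
                raise ValidationError(f"{name}: wavelengths must be positive")
            if em <= ex:
                raise ValidationError(f"{name}: emission ({em}) must exceed excitation ({ex})")

    def lookup(self, species: str) -> tuple[float, float]:
        key = _canonical(species)
        for name, pair in self.pairs.items():
            if _canonical(name) == key:
                return pair
        raise ValidationError(
            f"unknown species {species!r}; known: {sorted(self.pairs)}"
        )

    def species(self) -> list[str]:
        return sorted(self.pairs)


#: Excitation/emission registry: fluorescent AGE species, glycoxidation
#: products and the thioflavin-T fibril stain.
DEFAULT_REGISTRY = WavelengthRegistry(
    {
        "Total AGEs": (350.0, 440.0),
        "Vesperlysine": (350.0, 405.0),
        "Crossline": (380.0, 440.0),
        "Argpyrimidine": (320.0, 380.0),
        "Pentosidine": (335.0, 385.0),
        "Dityrosine": (330.0, 415.0),
        "Kynurenine": (365.0, 480.0),
        "N'-formylkynurenine": (325.0, 434.0),
        "ThT": (440.0, 485.0),
    }
)


def wavelength_lookup(
    species: str, registry: WavelengthRegistry = DEFAULT_REGISTRY
) -> tuple[float, float]:
    """Return the (excitation, emission) pair registered for a species."""
    return registry.lookup(species)


@dataclass(frozen=True)
class AssayPanel:
    """Condition-labelled replicate readings for inhibition statistics.

    ``readings`` is long-format with columns (condition, species, replicate,
    value); ``control_condition`` names the rows defining F0 (or A0).
    """

    readings: pd.DataFrame
    control_condition: str
    readout: str = "fluorescence"
    registry: WavelengthRegistry = DEFAULT_REGISTRY

    def __post_init__(self) -> None:
        required = {"condition", "species", "replicate", "value"}
        missing = required - set(self.readings.columns)
        if missing:
            raise ValidationError(f"panel readings missing columns {sorted(missing)}")
        if self.readout not in ("fluorescence", "absorbance"):
            raise ValidationError("readout must be 'fluorescence' or 'absorbance'")
        conditions = set(self.readings["condition"])
        if self.control_condition not in conditions:
            raise ValidationError(
                f"control condition {self.control_condition!r} absent from panel"
            )
        control_species = set(
            self.readings.loc[
                self.readings["condition"] == self.control_condition, "species"
            ]
        )
        for cond in conditions - {self.control_condition}:
            sp = set(self.readings.loc[self.readings["condition"] == cond, "species"])
            if not sp <= control_species:
                raise ValidationError(
                    f"species {sorted(sp - control_species)} in condition {cond!r} "
                    "lack control readings"
                )

    def values(self, condition: str, species: str) -> np.ndarray:
        mask = (self.readings["condition"] == condition) & (
            self.readings["species"] == species
        )
        return self.readings.loc[mask, "value"].to_numpy(dtype=float)


@dataclass(frozen=True)
class InhibitionResult:
    percent: float
    sd: float
    n_treated: int
    n_control: int
    enhancement: bool = False


def inhibition_rate(
    treated: Sequence[float], control: Sequence[float], readout: str = "fluorescence"
) -> InhibitionResult:
    """Inhibition percentage 100·(1 − mean(treated)/mean(control)) with its SD.

    The SD propagates the replicate standard deviations of both groups
    through the ratio; with single replicates it is 0.  Negative rates
    (treated signal above control) are flagged as enhancement.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 1 or c.size < 1:
        raise ValidationError("need ≥1 replicate in each group")
    mc = float(np.mean(c))
    if mc <= 0:
        raise ValidationError("control mean must be positive")
    mt = float(np.mean(t))
    ratio = mt / mc
    percent = 100.0 * (1.0 - ratio)

    sd_t = float(np.std(t, ddof=1)) if t.size > 1 else 0.0
    sd_c = float(np.std(c, ddof=1)) if c.size > 1 else 0.0
    if mt != 0.0:
        rel = np.hypot(sd_t / mt if mt else 0.0, sd_c / mc)
        sd = 100.0 * abs(ratio) * rel
    else:
        sd = 100.0 * sd_t / mc
    return InhibitionResult(
        percent=percent,
        sd=sd,
        n_treated=int(t.size),
        n_control=int(c.size),
        enhancement=percent < 0,
    )


def panel_inhibition(panel: AssayPanel) -> pd.DataFrame:
    """Per-(condition, species) inhibition table for every treated condition.

    Returns a DataFrame with inhibition percent, propagated SD, replicate
    counts and the registered excitation/emission wavelengths where the
    species is in the registry.
    """
    rows = []
    conditions = [
        c for c in pd.unique(panel.readings["condition"]) if c != panel.control_condition
    ]
    for cond in conditions:
        species_here = pd.unique(
            panel.readings.loc[panel.readings["condition"] == cond, "species"]
        )
        for sp in species_here:
            res = inhibition_rate(
                panel.values(cond, sp),
                panel.values(panel.control_condition, sp),
                readout=panel.readout,
            )
            try:
                ex, em = panel.registry.lookup(sp)
            except ValidationError:
                ex = em = np.nan
            rows.append(
                {
                    "condition": cond,
                    "species": sp,
                    "inhibition_percent": res.percent,
                    "sd": res.sd,
                    "n_treated": res.n_treated,
                    "n_control": res.n_control,
                    "enhancement": res.enhancement,
                    "excitation_nm": ex,
                    "emission_nm": em,
                }
            )
    return pd.DataFrame(rows)


def tht_fibril_index(treated: Sequence[float], control: Sequence[float]) -> float:
    """Relative thioflavin-T intensity (treated/control mean ratio).

    Values above 1 indicate more cross-β amyloid structure than the control;
    identical conditions give exactly 1.
    """
    c = float(np.mean(np.asarray(control, dtype=float)))
    if c <= 0:
        raise ValidationError("control mean must be positive")
    return float(np.mean(np.asarray(treated, dtype=float)) / c)


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA with Tukey HSD across labelled replicate groups.

    Convenience reporting layer over scipy.stats; returns the F statistic,
    its p-value, and a pairwise table of Tukey-adjusted p-values.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValidationError("need ≥2 groups for ANOVA")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs ≥2 replicates")
    f_stat, p_value = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairwise.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "p_adjusted": float(tukey.pvalue[i, j]),
                }
            )
    return {"F": float(f_stat), "p_value": float(p_value), "pairwise": pairwise}
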