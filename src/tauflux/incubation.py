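"""Batch-incubation time-series accounting.

Net concentration changes, no-sponge medium-control subtraction, wet-weight
normalization of dissolved pools, and the wet-weight <-> tissue-molarity
conversion (1.2 g sponge wet weight per cm3 by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ValidationError

logger = logging.getLogger(__name__)

ANALYTES = ("SO4", "NH4", "NO2", "taurine")

#: Default tissue density assumption: grams of sponge wet weight per cm3.
SPONGE_DENSITY_G_PER_CM3 = 1.2

#: Sampling times are matched exactly within this tolerance (hours).
TIME_TOLERANCE_H = 0.01


@dataclass(frozen=True)
class IncubationSample:
    """One analyte concentration measured at one time point."""

    time_h: float
    analyte: str
    conc_uM: float
    at_percent: float | None = None

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValidationError(
                f"analyte must be one of {ANALYTES}, got {self.analyte!r}"
            )
        if self.time_h < 0:
            raise ValidationError("sample time must be >= 0 h")
        if self.conc_uM < 0:
            raise ValidationError("concentrations must be >= 0 µM")


@dataclass
class IncubationSeries:
    """Time-resolved analyte concentrations for one incubation vessel.

    ``wet_wt_g`` is ``None`` for no-sponge medium controls.  ``treatment``
    encodes the medium chemistry and amendments (e.g. ``SFASW+taurine`` or
    ``FSW+taurine-13C15N``).
    """

    vessel: str
    treatment: str
    volume_l: float
    wet_wt_g: float | None = None
    samples: list[IncubationSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise ValidationError("medium volume must be > 0 l")
        if self.wet_wt_g is not None and self.wet_wt_g <= 0:
            raise ValidationError("wet weight must be > 0 g when a sponge is present")
        self.samples.sort(key=lambda s: s.time_h)

    @property
    def has_sponge(self) -> bool:
        return self.wet_wt_g is not None

    def times(self, analyte: str) -> list[float]:
        return [s.time_h for s in self.samples if s.analyte == analyte]

    def sample_at(
        self, analyte: str, t: float, tol: float = TIME_TOLERANCE_H
    ) -> IncubationSample:
        for s in self.samples:
            if s.analyte == analyte and abs(s.time_h - t) <= tol:
                return s
        raise LookupError(
            f"vessel {self.vessel}: no {analyte} sample at t = {t} h "
            f"(have {self.times(analyte)})"
        )

    def concentration(
        self, analyte: str, t: float, tol: float = TIME_TOLERANCE_H
    ) -> float:
        return self.sample_at(analyte, t, tol).conc_uM


def net_change(
    series: IncubationSeries,
    analyte: str,
    t0: float,
    t1: float,
    tol: float = TIME_TOLERANCE_H,
) -> float:
    """Concentration change c(t1) - c(t0) in µM; may be negative.

    Baseline-subtracting each vessel's own t = 0 value through this function
    absorbs carryover (e.g. residual sulfate released from sponge tissue into
    sulfate-free medium) without any external constant.
    """
    return series.concentration(analyte, t1, tol) - series.concentration(
        analyte, t0, tol
    )


def subtract_medium_control(
    sponge: IncubationSeries,
    control: IncubationSeries,
    analyte: str,
    t: float,
    tol: float = TIME_TOLERANCE_H,
) -> float:
    """Sponge-vessel concentration minus the matched no-sponge control (µM).

    Both vessels must share the same treatment chemistry; a negative
    difference is reported with a warning (sign convention preserved).
    """
    if sponge.treatment != control.treatment:
        raise ValidationError(
            f"treatment mismatch: {sponge.treatment!r} vs {control.treatment!r}"
        )
    diff = sponge.concentration(analyte, t, tol) - control.concentration(
        analyte, t, tol
    )
    if diff < 0:
        logger.warning(
            "control exceeds sponge vessel for %s at t=%g h (%.4g µM)",
            analyte, t, diff,
        )
    return diff


def concentration_to_per_biomass(conc: float, volume: float, wet_wt: float) -> float:
    """Convert a medium concentration (µM) to µmol per g explant wet weight."""
    if volume <= 0:
        raise ValidationError("volume must be > 0 l")
    if wet_wt <= 0:
        raise ValidationError("wet weight must be > 0 g")
    return conc * volume / wet_wt


def tissue_molarity(
    amount_per_wet_wt: float, density: float = SPONGE_DENSITY_G_PER_CM3
) -> float:
    """Convert µmol per g wet weight to mM using a tissue density in g cm-3.

    µmol g-1 × g cm-3 = µmol cm-3 ≡ mmol l-1.
    """
    if density <= 0:
        raise ValidationError("density must be > 0 g cm-3")
    return amount_per_wet_wt * density


@dataclass(frozen=True)
class TissueConcentration:
    """A per-wet-weight metabolite amount with its volumetric equivalent."""

    amount_per_wet_wt: float  # µmol g-1
    density: float = SPONGE_DENSITY_G_PER_CM3

    @property
    def molarity_mM(self) -> float:
        return tissue_molarity(self.amount_per_wet_wt, self.density)
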