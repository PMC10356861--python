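"""Two-pool isotope mixing model and tracer mass balance.

The workhorse of dual :sup:`13`\\ C/:sup:`15`\\ N taurine labeling experiments:
given bulk atom-fraction (at%) measurements of a pool (whole-tissue biomass,
nucleic acids, dissolved NH4+ or NO2-) together with its total elemental
content, the amount of that element derived from the labeled substrate is
attributed by linear two-pool mixing

    n_tracer = n_total * (a_sample - a_ctrl) / (a_source - a_ctrl)

where ``a_ctrl`` is the natural-abundance control and ``a_source`` the
atom-weighted at% of the added label mixture.  Amounts are carried in µmol
throughout; rates are converted to nmol only at reporting time.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateDenominatorError, UndefinedPoolError, ValidationError

logger = logging.getLogger(__name__)

#: Natural isotope abundances in atom percent (VPDB / atmospheric N2 scales).
NATURAL_ABUNDANCE_AT_PERCENT: dict[str, float] = {"C": 1.07, "N": 0.366}

#: Isotope ratios of the international reference standards, used by the
#: delta-notation helper only.
_REFERENCE_RATIO = {"C": 0.0111802, "N": 0.0036765}

_ELEMENTS = ("C", "N")
_POOLS = ("sponge-biomass", "nucleic-acids", "NH4", "NO2", "control")
_CONTEXTS = ("sponge", "seawater-control")


def _check_element(element: str) -> str:
    if element not in _ELEMENTS:
        raise ValidationError(f"element must be one of {_ELEMENTS}, got {element!r}")
    return element


@dataclass(frozen=True)
class IsotopeMeasurement:
    """A bulk atom-fraction measurement of one elemental pool.

    Parameters
    ----------
    element : {"C", "N"}
    pool : str
        One of ``sponge-biomass``, ``nucleic-acids``, ``NH4``, ``NO2`` or
        ``control`` (an unlabeled-substrate control explant).
    atom_fraction : float
        Heavy-isotope atom percent in ``[0, 100]``.
    n_total : float
        Total elemental amount of the pool in µmol (>= 0).
    context : {"sponge", "seawater-control"}
        Whether the pool was sampled from a vessel containing an explant or
        from a no-sponge medium control.
    """

    element: str
    pool: str
    atom_fraction: float
    n_total: float
    context: str = "sponge"
    replicate: str | None = None
    time_h: float | None = None

    def __post_init__(self) -> None:
        _check_element(self.element)
        if self.pool not in _POOLS:
            raise ValidationError(f"pool must be one of {_POOLS}, got {self.pool!r}")
        if self.context not in _CONTEXTS:
            raise ValidationError(
                f"context must be one of {_CONTEXTS}, got {self.context!r}"
            )
        if not 0.0 <= self.atom_fraction <= 100.0:
            raise ValidationError(
                f"atom_fraction must lie in [0, 100] at%, got {self.atom_fraction}"
            )
        if self.n_total < 0:
            raise ValidationError(f"n_total must be >= 0 µmol, got {self.n_total}")


@dataclass(frozen=True)
class TracerComponent:
    """One molecular species of the label mixture."""

    molar_fraction: float
    purity: float  # at% of the labeled positions
    labeled_atoms: int  # labeled positions per molecule
    total_atoms: int  # total atoms of the element per molecule

    def __post_init__(self) -> None:
        if not 0.0 <= self.molar_fraction <= 1.0:
            raise ValidationError("molar_fraction must lie in [0, 1]")
        if not 0.0 <= self.purity <= 100.0:
            raise ValidationError("purity must lie in [0, 100] at%")
        if self.labeled_atoms < 0 or self.total_atoms < 0:
            raise ValidationError("atom counts must be non-negative")
        if self.labeled_atoms > self.total_atoms:
            raise ValidationError("labeled_atoms cannot exceed total_atoms")


@dataclass(frozen=True)
class TracerSource:
    """The labeled-substrate mixture that defines the mixing-model source pool.

    For an equimolar :sup:`13`\\ C2-taurine / :sup:`15`\\ N-taurine addition the
    carbon source has two components: the 13C2 species (2 of 2 C labeled at
    99 at%) and the 15N species, whose carbon sits at natural abundance.
    """

    element: str
    components: tuple[TracerComponent, ...]
    natural_abundance: float | None = None

    def __post_init__(self) -> None:
        _check_element(self.element)
        if not self.components:
            raise ValidationError("TracerSource needs at least one component")
        total = sum(c.molar_fraction for c in self.components)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(
                f"component molar fractions must sum to 1, got {total}"
            )

    @property
    def nat(self) -> float:
        if self.natural_abundance is not None:
            return self.natural_abundance
        return NATURAL_ABUNDANCE_AT_PERCENT[self.element]

    def atom_fraction(self) -> float:
        return effective_label_atom_fraction(self)


def effective_label_atom_fraction(source: TracerSource) -> float:
    """Atom-weighted mean at% of the element across all mixture components.

    Labeled positions contribute at their isotopic purity; the remaining
    positions contribute at natural abundance.  Unlabeled components therefore
    enter at natural abundance throughout.
    """
    nat = source.nat
    heavy = 0.0
    atoms = 0.0
    for c in source.components:
        heavy += c.molar_fraction * (
            c.labeled_atoms * c.purity + (c.total_atoms - c.labeled_atoms) * nat
        )
        atoms += c.molar_fraction * c.total_atoms
    if atoms <= 0:
        raise UndefinedPoolError(
            f"label mixture contributes no {source.element} atoms"
        )
    return heavy / atoms


def tracer_derived_amount(
    sample: IsotopeMeasurement,
    control: IsotopeMeasurement,
    source_at: float,
    *,
    clip_negative: bool = False,
) -> float:
    """Amount (µmol) of the sample pool's element derived from the tracer.

    Applies the two-pool mixing attribution
    ``n_total * (a_sample - a_ctrl) / (a_source - a_ctrl)``.

    A sample enriched below the control (possible through measurement noise
    near natural abundance) yields a negative amount; with
    ``clip_negative=True`` the value is clipped to zero and a warning logged.
    """
    if sample.element != control.element:
        raise TypeError(
            f"element mismatch: sample is {sample.element}, control is "
            f"{control.element}"
        )
    if source_at <= control.atom_fraction:
        raise DegenerateDenominatorError(
            f"source at% ({source_at}) must exceed control at% "
            f"({control.atom_fraction})"
        )
    amount = (
        sample.n_total
        * (sample.atom_fraction - control.atom_fraction)
        / (source_at - control.atom_fraction)
    )
    if amount < 0 and clip_negative:
        logger.warning(
            "negative tracer-derived amount (%.4g µmol) for pool %s/%s "
            "clipped to 0 (sample at%% below control)",
            amount,
            sample.pool,
            sample.element,
        )
        return 0.0
    return amount


def ammonium_released(
    nh4_sponge: float, nh4_sw: float, no2_sponge: float, no2_sw: float
) -> float:
    """Net tracer-derived NH4+ released by the holobiont (µmol).

    Sums the seawater-control-corrected tracer-derived NH4+ and NO2- pools;
    the nitrite term accounts for taurine-derived ammonium already oxidized
    by the ammonia-oxidizing symbiont.  All four inputs are outputs of
    :func:`tracer_derived_amount` at matched time points.  A negative result
    is reported as-is with a warning.
    """
    released = (nh4_sponge - nh4_sw) + (no2_sponge - no2_sw)
    if released < 0:
        logger.warning(
            "net tracer-derived ammonium release is negative (%.4g µmol); "
            "control pools exceed sponge pools", released
        )
    return released


def normalize_to_wet_weight(n: float, wet_wt: float) -> float:
    """Normalize an amount (µmol) to explant wet weight (g) -> µmol g-1."""
    if wet_wt <= 0:
        raise ValidationError(f"wet weight must be > 0 g, got {wet_wt}")
    return n / wet_wt


def assimilation_rate(per_wet_weight: float, duration_h: float) -> float:
    """End-point assimilation rate in nmol min-1 g-1.

    ``per_wet_weight`` is the total tracer-derived amount per gram wet weight
    (µmol g-1) accumulated over ``duration_h`` hours of incubation.
    """
    if duration_h <= 0:
        raise ValidationError(f"duration must be > 0 h, got {duration_h}")
    return per_wet_weight * 1000.0 / (duration_h * 60.0)


def delta_to_atom_percent(delta: float, element: str) -> float:
    """Convert delta notation (‰ vs the international standard) to at%.

    Plumbing helper; calibration against working standards is out of scope.
    """
    ratio = _REFERENCE_RATIO[_check_element(element)] * (1.0 + delta / 1000.0)
    return 100.0 * ratio / (1.0 + ratio)


@dataclass(frozen=True)
class TracerAttribution:
    """A fully attributed tracer-derived pool for one replicate."""

    element: str
    pool: str
    replicate: str | None
    n_tracer_derived: float  # µmol
    per_wet_weight: float  # µmol g-1
    duration_min: float
    rate: float  # nmol min-1 g-1

    @classmethod
    def from_measurement(
        cls,
        sample: IsotopeMeasurement,
        control: IsotopeMeasurement,
        source_at: float,
        wet_wt: float,
        duration_h: float,
        *,
        clip_negative: bool = True,
    ) -> "TracerAttribution":
        n = tracer_derived_amount(
            sample, control, source_at, clip_negative=clip_negative
        )
        per_g = normalize_to_wet_weight(n, wet_wt)
        return cls(
            element=sample.element,
            pool=sample.pool,
            replicate=sample.replicate,
            n_tracer_derived=n,
            per_wet_weight=per_g,
            duration_min=duration_h * 60.0,
            rate=assimilation_rate(per_g, duration_h),
        )


def mean_se(values: Sequence[float] | Iterable[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error across replicate explants."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("mean_se needs at least one value")
    if arr.size == 1:
        return float(arr[0]), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))
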