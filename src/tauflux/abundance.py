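"""Symbiont abundance estimation.

FISH cell densities from ocular-grid field counts, relative abundance against
the general bacterial probe set, qPCR copy numbers per gram with volumetric
conversion, and metagenomic read-recruitment fractions.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .incubation import SPONGE_DENSITY_G_PER_CM3

logger = logging.getLogger(__name__)

#: Exact conversion from µm3 to cm3.
UM3_TO_CM3 = 1e-12


@dataclass(frozen=True)
class FishFieldCount:
    """Cell counts for one microscope field of view.

    ``target_count`` is the symbiont-specific probe count, ``eub_count`` the
    count with the general bacterial probe set.  The field volume is the
    ocular grid area times the optical section thickness.  The target probe
    need not be a subset of the general probe set, so ``target_count`` may
    exceed ``eub_count``.
    """

    field_id: str
    target_count: float
    eub_count: float
    grid_x_um: float = 146.25
    grid_y_um: float = 146.25
    thickness_um: float = 1.0

    def __post_init__(self) -> None:
        if self.target_count < 0 or self.eub_count < 0:
            raise ValidationError("counts must be >= 0")
        if min(self.grid_x_um, self.grid_y_um, self.thickness_um) <= 0:
            raise ValidationError("field geometry must be positive")

    @property
    def volume_cm3(self) -> float:
        return self.grid_x_um * self.grid_y_um * self.thickness_um * UM3_TO_CM3


def _field_densities(fields: list[FishFieldCount]) -> np.ndarray:
    if not fields:
        raise ValidationError("need at least one field of view")
    return np.array([f.target_count / f.volume_cm3 for f in fields])


def fish_density(fields: list[FishFieldCount]) -> tuple[float, float]:
    """Mean and SD of per-field cell densities (cells cm-3).

    The mean of per-field densities (rather than pooled counts over pooled
    volume) is used so the SD retains its per-field meaning; for uniform
    geometry and equal counts the two estimators coincide.
    """
    dens = _field_densities(fields)
    sd = float(dens.std(ddof=1)) if dens.size > 1 else 0.0
    return float(dens.mean()), sd


def fish_relative_fraction(fields: list[FishFieldCount]) -> tuple[float, float]:
    """Mean and SD over fields of 100 * target / EUB-positive cells (%).

    Fields with a zero general-probe count are excluded with a warning.
    """
    usable = []
    for f in fields:
        if f.eub_count <= 0:
            logger.warning("field %s has zero EUB count; excluded", f.field_id)
            continue
        usable.append(100.0 * f.target_count / f.eub_count)
    if not usable:
        raise ValidationError("no field with a positive EUB count")
    arr = np.array(usable)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def qpcr_volumetric(
    copies_per_g: float, density: float = SPONGE_DENSITY_G_PER_CM3
) -> float:
    """Convert 16S rRNA gene copies per g wet weight to copies per cm3."""
    if density <= 0:
        raise ValidationError("density must be > 0 g cm-3")
    return copies_per_g * density


@dataclass(frozen=True)
class QpcrResult:
    """Absolute abundance of one symbiont from a qPCR assay."""

    symbiont: str
    copies_per_g: float

    def __post_init__(self) -> None:
        if self.copies_per_g < 0:
            raise ValidationError("copy numbers must be >= 0")


def qpcr_shares(results: list[QpcrResult]) -> dict[str, float]:
    """Per-symbiont share (%) of the summed gene copies; shares sum to 100."""
    total = sum(r.copies_per_g for r in results)
    if total <= 0:
        raise ValidationError("summed copy numbers must be > 0")
    return {r.symbiont: 100.0 * r.copies_per_g / total for r in results}


def read_recruitment_fraction(mapped_fragments: int, total_fragments: int) -> float:
    """Relative abundance (%) of a genome bin: mapped / total read fragments."""
    if total_fragments <= 0:
        raise ValidationError("total fragments must be > 0")
    if mapped_fragments < 0:
        raise ValidationError("mapped fragments must be >= 0")
    if mapped_fragments > total_fragments:
        raise ValidationError(
            f"mapped fragments ({mapped_fragments}) exceed total "
            f"({total_fragments})"
        )
    return 100.0 * mapped_fragments / total_fragments
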