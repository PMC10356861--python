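"""NSAF metaproteome quantitation.

The normalized spectral abundance factor of protein *i* in one sample is

    SAF_i  = SpC_i / L_i
    NSAF_i = SAF_i / sum_j SAF_j

with SpC the spectral count and L the protein length in amino acids, so the
NSAF values of a sample sum to one.  Shares of a genome bin or of a named
protein set are sums of NSAF over that group, optionally renormalized to a
base set (e.g. within one symbiont MAG).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import UndefinedPoolError, ValidationError

CONTAMINANT_BIN = "contaminant"


@dataclass(frozen=True)
class SpectralCountRecord:
    """One protein's spectral count in one sample."""

    sample: str
    protein: str
    bin: str
    spectral_count: int
    length_aa: int

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise ValidationError("protein length must be > 0 aa")
        if self.spectral_count < 0:
            raise ValidationError("spectral counts must be >= 0")
        if self.spectral_count != int(self.spectral_count):
            raise ValidationError("spectral counts must be integral")


def nsaf(records: Sequence[SpectralCountRecord]) -> dict[str, float]:
    """NSAF per protein for the records of a single sample.

    Proteins with zero spectral counts receive NSAF 0; the values sum to 1.
    """
    if not records:
        raise ValidationError("need at least one spectral-count record")
    samples = {r.sample for r in records}
    if len(samples) > 1:
        raise ValidationError(
            f"records span multiple samples {sorted(samples)}; "
            "compute NSAF per sample and average afterwards"
        )
    saf = {r.protein: r.spectral_count / r.length_aa for r in records}
    total = sum(saf.values())
    if total <= 0:
        raise UndefinedPoolError("all spectral counts are zero")
    return {p: v / total for p, v in saf.items()}


def bin_share(
    nsaf_map: Mapping[str, float],
    bins: Mapping[str, str],
    target_bin: str,
    exclude_bins: Iterable[str] = (),
) -> float:
    """Percent of summed NSAF assigned to ``target_bin``.

    ``bins`` maps protein id -> bin id and must cover every protein.  Bins in
    ``exclude_bins`` (e.g. laboratory contaminants) are removed from the
    normalization base before the share is taken.
    """
    missing = [p for p in nsaf_map if p not in bins]
    if missing:
        raise ValidationError(f"proteins without a bin assignment: {missing[:5]}")
    known = set(bins.values())
    if target_bin not in known:
        raise ValidationError(f"unknown bin {target_bin!r}; have {sorted(known)}")
    excluded = set(exclude_bins)
    base = sum(v for p, v in nsaf_map.items() if bins[p] not in excluded)
    if base <= 0:
        raise UndefinedPoolError("normalization base is empty after exclusion")
    target = sum(
        v for p, v in nsaf_map.items()
        if bins[p] == target_bin and bins[p] not in excluded
    )
    return 100.0 * target / base


def protein_set_share(
    nsaf_map: Mapping[str, float],
    protein_set: Iterable[str],
    base: Iterable[str] | None = None,
) -> float:
    """Percent of NSAF carried by ``protein_set`` relative to ``base``.

    ``base`` defaults to the whole sample; pass a bin's protein set to
    renormalize within that bin.
    """
    proteins = set(protein_set)
    unknown = proteins - nsaf_map.keys()
    if unknown:
        raise ValidationError(f"unknown proteins in set: {sorted(unknown)[:5]}")
    if base is None:
        base_total = sum(nsaf_map.values())
    else:
        base_set = set(base)
        if not proteins <= base_set:
            raise ValidationError("protein set must be a subset of the base set")
        base_total = sum(nsaf_map[p] for p in base_set if p in nsaf_map)
    if base_total <= 0:
        raise UndefinedPoolError("normalization base has zero NSAF")
    return 100.0 * sum(nsaf_map[p] for p in proteins) / base_total


def mean_nsaf(per_sample: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Arithmetic mean of per-sample NSAF across replicates/samples.

    Proteins absent from a sample contribute 0 for that sample, so the means
    still sum to 1 across proteins.
    """
    if not per_sample:
        raise ValidationError("need at least one sample")
    proteins = sorted({p for m in per_sample for p in m})
    n = len(per_sample)
    return {p: sum(m.get(p, 0.0) for m in per_sample) / n for p in proteins}


def nsaf_by_sample(
    records: Sequence[SpectralCountRecord],
) -> dict[str, dict[str, float]]:
    """Group records by sample and compute NSAF for each."""
    groups: dict[str, list[SpectralCountRecord]] = {}
    for r in records:
        groups.setdefault(r.sample, []).append(r)
    return {s: nsaf(rs) for s, rs in sorted(groups.items())}
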