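"""Seeded forward simulator of labeled-taurine batch incubations.

Emulates the study design the analysis modules assume: 48-h batch incubations
of sponge explants in stirred vessels, pulsed additions of taurine (an
equimolar mixture of 13C2-taurine at 99 at% and 15N-taurine at 98 at% when
labeled), first-order (or zero-order) microbial uptake, partial assimilation
of taurine carbon and nitrogen into holobiont biomass, dissimilation of the
remainder to NH4+ (amine) and SO4^2- (sulfonate, via sulfite oxidation), and
oxidation of the released ammonium to NO2- by the ammonia-oxidizing symbiont,
gated by substrate inhibition at high NH4+.

Taurine stoichiometry is hard-coded as C2H7NO3S: 2 C, 1 N, 1 S per molecule.
The discrete-time integration tracks every pool in µmol together with its
heavy-isotope (13C / 15N) atom content, so the exact noiseless truth is
available alongside the noisy "measured" tables, and conservation of mass and
label can be asserted to floating-point accuracy.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import FishFieldCount
from .errors import StepSizeError, ValidationError
from .incubation import IncubationSample, IncubationSeries
from .isotope import (
    NATURAL_ABUNDANCE_AT_PERCENT,
    IsotopeMeasurement,
    TracerComponent,
    TracerSource,
    effective_label_atom_fraction,
)
from .proteomics import SpectralCountRecord

TAURINE_C = 2
TAURINE_N = 1
TAURINE_S = 1

LABELED_TREATMENT = "FSW+taurine-13C15N"
UNLABELED_TREATMENT = "FSW+taurine"


@dataclass(frozen=True)
class Pulse:
    """One taurine addition: time (h), amount (mM) and whether it is labeled."""

    time_h: float
    taurine_mM: float
    labeled: bool = True

    def __post_init__(self) -> None:
        if self.time_h < 0 or self.taurine_mM < 0:
            raise ValidationError("pulse time and amount must be >= 0")


#: The study's pulsed-addition schedule: 1 mM at t = 0 plus 0.6 mM at 36 h,
#: 1.6 mM in total.
DEFAULT_PULSES: tuple[Pulse, ...] = (Pulse(0.0, 1.0), Pulse(36.0, 0.6))


@dataclass(frozen=True)
class KineticParams:
    """Tunable parameters of the incubation simulator.

    Defaults reproduce the labeled 48-h experiment geometry: 1-l vessels,
    triplicate explants of 9.14 ± 2.4 g wet weight, pulses of 1 mM + 0.6 mM
    equimolar dual-labeled taurine, 10% CV multiplicative measurement noise on
    concentrations and elemental totals and 0.001 at% additive noise on atom
    fractions.
    """

    uptake_mode: str = "first-order"  # or "zero-order"
    uptake_k_per_h: float = 0.05  # first-order rate constant
    uptake_rate_uM_per_h: float = 20.0  # zero-order rate
    lag_h: float = 0.0  # uptake onset delay
    f_c: float = 0.02  # fraction of taken-up taurine C retained in biomass
    f_n: float = 0.02  # fraction of taken-up taurine N retained in biomass
    ammonia_oxidation_uM_per_h: float = 3.0
    inhibition_threshold_uM: float | None = 100.0  # NH4+ >= this stops oxidation
    sulfonate_efficiency: float = 1.0  # fraction of dissimilated S oxidized to SO4
    wet_wt_mean_g: float = 9.14
    wet_wt_sd_g: float = 2.4
    wet_weights: tuple[float, ...] | None = None  # explicit per-vessel weights
    volume_l: float = 1.0
    pulses: tuple[Pulse, ...] = DEFAULT_PULSES
    c13_purity: float = 99.0  # at% of the 13C2-taurine species
    n15_purity: float = 98.0  # at% of the 15N-taurine species
    biomass_c_umol_per_g: float = 5800.0  # explant C content per g wet wt
    biomass_n_umol_per_g: float = 1250.0  # explant N content per g wet wt
    initial_nh4_uM: float = 0.0
    initial_no2_uM: float = 0.0
    initial_so4_uM: float = 0.0
    noise_cv: float = 0.10  # multiplicative CV on concentrations and totals
    noise_cv_per_analyte: Mapping[str, float] | None = None
    atpct_noise_sd: float = 0.001  # additive SD on at% measurements
    dt_h: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.uptake_mode not in ("first-order", "zero-order"):
            raise ValidationError("uptake_mode must be first-order or zero-order")
        for name in ("f_c", "f_n", "sulfonate_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "uptake_k_per_h", "uptake_rate_uM_per_h", "ammonia_oxidation_uM_per_h",
            "noise_cv", "atpct_noise_sd", "wet_wt_sd_g", "lag_h",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.volume_l <= 0 or self.dt_h <= 0 or self.wet_wt_mean_g <= 0:
            raise ValidationError("volume, dt and mean wet weight must be > 0")
        if self.dt_h > 0.1:
            raise ValidationError("dt_h must be <= 0.1 h")
        if list(self.pulses) != sorted(self.pulses, key=lambda p: p.time_h):
            raise ValidationError("pulses must be sorted by time")

    def analyte_cv(self, analyte: str) -> float:
        if self.noise_cv_per_analyte and analyte in self.noise_cv_per_analyte:
            return self.noise_cv_per_analyte[analyte]
        return self.noise_cv


def tracer_sources(params: KineticParams) -> dict[str, TracerSource]:
    """Label-pool mixing sources from the cumulative nominal additions.

    Every labeled pulse is the same equimolar 13C2/15N mixture, so the source
    at% is constant in time; unlabeled pulses dilute it.  The C source mixes
    the 13C2 species (2 of 2 C labeled) with natural-abundance carbon from the
    15N species and any unlabeled taurine, and symmetrically for N.
    """
    labeled = sum(p.taurine_mM for p in params.pulses if p.labeled)
    unlabeled = sum(p.taurine_mM for p in params.pulses if not p.labeled)
    total = labeled + unlabeled
    if total <= 0:
        raise ValidationError("pulse schedule adds no taurine")
    f_lab = labeled / total

    def mix(purity: float, labeled_atoms: int, total_atoms: int, element: str):
        comps = []
        if f_lab > 0:
            comps.append(  # the species carrying the heavy isotope
                TracerComponent(0.5 * f_lab, purity, labeled_atoms, total_atoms)
            )
            comps.append(  # the co-added species, natural for this element
                TracerComponent(0.5 * f_lab, 0.0, 0, total_atoms)
            )
        if f_lab < 1:
            comps.append(TracerComponent(1.0 - f_lab, 0.0, 0, total_atoms))
        return TracerSource(element, tuple(comps))

    return {
        "C": mix(params.c13_purity, TAURINE_C, TAURINE_C, "C"),
        "N": mix(params.n15_purity, TAURINE_N, TAURINE_N, "N"),
    }


@dataclass
class VesselTruth:
    """Noiseless state of one simulated vessel."""

    vessel: str
    treatment: str
    wet_wt_g: float | None
    volume_l: float
    series: pd.DataFrame  # one row per time step, µmol / µM columns
    taurine_consumed_umol: float
    biomass_c_gain_umol: float
    biomass_n_gain_umol: float
    dissimilated_c_umol: float
    cum_nh4_produced_umol: float
    cum_no2_produced_umol: float
    cum_so4_produced_umol: float

    def rate(self, element: str, duration_h: float) -> float:
        """True end-point assimilation rate, nmol min-1 g-1."""
        if self.wet_wt_g is None:
            return 0.0
        gain = (
            self.biomass_c_gain_umol if element == "C" else self.biomass_n_gain_umol
        )
        return gain / self.wet_wt_g * 1000.0 / (duration_h * 60.0)


@dataclass
class SimulationTruth:
    """Exact bookkeeping of a simulated experiment, kept noiseless."""

    duration_h: float
    source_at: dict[str, float]
    vessels: dict[str, VesselTruth]

    def labeled_vessels(self) -> list[VesselTruth]:
        return [
            v for v in self.vessels.values()
            if v.wet_wt_g is not None and v.treatment == LABELED_TREATMENT
        ]

    def mean_rate(self, element: str) -> float:
        rates = [v.rate(element, self.duration_h) for v in self.labeled_vessels()]
        return float(np.mean(rates))

    def summary(self) -> dict:
        return {
            "duration_h": self.duration_h,
            "source_at_percent": self.source_at,
            "true_rate_c_nmol_min_g": self.mean_rate("C"),
            "true_rate_n_nmol_min_g": self.mean_rate("N"),
            "per_vessel": {
                name: {
                    "treatment": v.treatment,
                    "wet_wt_g": v.wet_wt_g,
                    "taurine_consumed_umol": v.taurine_consumed_umol,
                    "biomass_c_gain_umol": v.biomass_c_gain_umol,
                    "biomass_n_gain_umol": v.biomass_n_gain_umol,
                    "rate_c_nmol_min_g": v.rate("C", self.duration_h),
                    "rate_n_nmol_min_g": v.rate("N", self.duration_h),
                    "cum_nh4_produced_umol": v.cum_nh4_produced_umol,
                    "cum_no2_produced_umol": v.cum_no2_produced_umol,
                    "cum_so4_produced_umol": v.cum_so4_produced_umol,
                }
                for name, v in self.vessels.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


def _simulate_vessel(
    params: KineticParams,
    has_sponge: bool,
    duration_h: float,
    src_at: dict[str, float],
) -> pd.DataFrame:
    """Integrate one vessel; returns the per-step noiseless state table."""
    dt = params.dt_h
    n_steps = int(round(duration_h / dt))
    vol = params.volume_l
    nat_c = NATURAL_ABUNDANCE_AT_PERCENT["C"] / 100.0
    nat_n = NATURAL_ABUNDANCE_AT_PERCENT["N"] / 100.0

    # State, medium pools in µmol per vessel.
    tau = 0.0
    tau_hc = 0.0  # heavy (13C) atoms in the taurine pool, µmol
    tau_hn = 0.0
    nh4 = params.initial_nh4_uM * vol
    nh4_hn = nh4 * nat_n
    no2 = params.initial_no2_uM * vol
    no2_hn = no2 * nat_n
    so4 = params.initial_so4_uM * vol
    bio_c = bio_n = bio_hc = bio_hn = 0.0  # biomass gains over initial content
    dis_c = dis_hc = 0.0
    consumed = cum_nh4 = cum_no2 = cum_so4 = 0.0

    pulses = list(params.pulses)
    rows = []

    def add_pulses(t: float) -> None:
        nonlocal tau, tau_hc, tau_hn
        while pulses and pulses[0].time_h <= t + 1e-9:
            p = pulses.pop(0)
            amount = p.taurine_mM * 1000.0 * vol  # mM -> µM -> µmol
            a_c = src_at["C"] / 100.0 if p.labeled else nat_c
            a_n = src_at["N"] / 100.0 if p.labeled else nat_n
            tau += amount
            tau_hc += amount * TAURINE_C * a_c
            tau_hn += amount * TAURINE_N * a_n

    def record(t: float) -> None:
        rows.append(
            (
                t, tau / vol, nh4 / vol, no2 / vol, so4 / vol,
                tau, tau_hc, tau_hn, nh4, nh4_hn, no2, no2_hn, so4,
                bio_c, bio_hc, bio_n, bio_hn, dis_c, dis_hc,
                consumed, cum_nh4, cum_no2, cum_so4,
            )
        )

    add_pulses(0.0)
    record(0.0)
    for i in range(n_steps):
        t0 = i * dt
        t1 = (i + 1) * dt
        # Uptake over [t0, t1).
        if has_sponge and t0 >= params.lag_h:
            if params.uptake_mode == "first-order":
                u = params.uptake_k_per_h * tau * dt
            else:
                u = params.uptake_rate_uM_per_h * vol * dt
        else:
            u = 0.0
        if u > 0:
            frac_hc = tau_hc / (tau * TAURINE_C) if tau > 0 else nat_c
            frac_hn = tau_hn / (tau * TAURINE_N) if tau > 0 else nat_n
            tau -= u
            tau_hc -= u * TAURINE_C * frac_hc
            tau_hn -= u * TAURINE_N * frac_hn
            consumed += u
            # Assimilation into biomass.
            bio_c += params.f_c * u * TAURINE_C
            bio_hc += params.f_c * u * TAURINE_C * frac_hc
            bio_n += params.f_n * u * TAURINE_N
            bio_hn += params.f_n * u * TAURINE_N * frac_hn
            # Dissimilation: C respired, N released as NH4+, S -> SO4^2-.
            dis_c += (1.0 - params.f_c) * u * TAURINE_C
            dis_hc += (1.0 - params.f_c) * u * TAURINE_C * frac_hc
            nh4_add = (1.0 - params.f_n) * u * TAURINE_N
            nh4 += nh4_add
            nh4_hn += nh4_add * frac_hn
            cum_nh4 += nh4_add
            so4_add = params.sulfonate_efficiency * u * TAURINE_S
            so4 += so4_add
            cum_so4 += so4_add
        # Ammonia oxidation to nitrite (gated by substrate inhibition).
        if has_sponge and params.ammonia_oxidation_uM_per_h > 0 and nh4 > 0:
            inhibited = (
                params.inhibition_threshold_uM is not None
                and nh4 / vol >= params.inhibition_threshold_uM
            )
            if not inhibited:
                ox = min(params.ammonia_oxidation_uM_per_h * vol * dt, nh4)
                frac = nh4_hn / nh4
                nh4 -= ox
                nh4_hn -= ox * frac
                no2 += ox
                no2_hn += ox * frac
                cum_no2 += ox
        if min(tau, nh4, no2, so4) < -1e-9:
            raise StepSizeError(
                f"negative pool at t = {t1:.3f} h; reduce dt_h below "
                f"{params.dt_h}"
            )
        add_pulses(t1)
        record(t1)

    return pd.DataFrame(
        rows,
        columns=[
            "time_h", "taurine_uM", "nh4_uM", "no2_uM", "so4_uM",
            "taurine_umol", "taurine_13c_umol", "taurine_15n_umol",
            "nh4_umol", "nh4_15n_umol", "no2_umol", "no2_15n_umol", "so4_umol",
            "biomass_c_gain_umol", "biomass_13c_gain_umol",
            "biomass_n_gain_umol", "biomass_15n_gain_umol",
            "dissimilated_c_umol", "dissimilated_13c_umol",
            "taurine_consumed_umol", "cum_nh4_produced_umol",
            "cum_no2_produced_umol", "cum_so4_produced_umol",
        ],
    )


def draw_wet_weights(
    mean: float, sd: float, n: int, rng: np.random.Generator, lower: float = 0.5
) -> np.ndarray:
    """Explant wet weights from a normal truncated below at ``lower`` grams."""
    if sd == 0:
        return np.full(n, mean)
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _noisy_conc(value: float, cv: float, rng: np.random.Generator) -> float:
    return max(0.0, value * (1.0 + cv * rng.standard_normal())) if cv > 0 else value


def _noisy_at(value: float, sd: float, rng: np.random.Generator) -> float:
    return float(np.clip(value + sd * rng.standard_normal(), 0.0, 100.0)) if sd > 0 else value


def simulate_incubation(
    params: KineticParams,
    n_replicates: int = 3,
    duration_h: float = 48.0,
    sampling_times: Sequence[float] = (0.0, 12.0, 48.0),
) -> tuple[list[IncubationSeries], list[IsotopeMeasurement], SimulationTruth]:
    """Simulate a full labeled incubation experiment.

    Three vessel groups are produced, each with ``n_replicates`` vessels:
    sponge explants with labeled taurine, sponge explants with unlabeled
    taurine (the natural-abundance controls for the mixing model), and
    no-sponge medium controls with labeled taurine.  Returns the measured
    (noisy) incubation series and isotope measurements plus the noiseless
    :class:`SimulationTruth`.  Identical parameters give identical outputs.
    """
    if any(t < 0 or t > duration_h + 1e-9 for t in sampling_times):
        raise ValidationError("sampling times must lie within [0, duration]")
    rng = np.random.default_rng(params.seed)
    src = {el: effective_label_atom_fraction(s) for el, s in tracer_sources(params).items()}
    nat = NATURAL_ABUNDANCE_AT_PERCENT

    if params.wet_weights is not None:
        if len(params.wet_weights) < 2 * n_replicates:
            raise ValidationError(
                f"wet_weights needs {2 * n_replicates} entries "
                "(labeled then control explants)"
            )
        weights = np.asarray(params.wet_weights, dtype=float)
    else:
        weights = draw_wet_weights(
            params.wet_wt_mean_g, params.wet_wt_sd_g, 2 * n_replicates, rng
        )

    unlabeled_params = replace(
        params,
        pulses=tuple(replace(p, labeled=False) for p in params.pulses),
    )

    groups = (
        ("sponge-label", LABELED_TREATMENT, True, params),
        ("sponge-ctrl", UNLABELED_TREATMENT, True, unlabeled_params),
        ("sw-label", LABELED_TREATMENT, False, params),
    )

    series_out: list[IncubationSeries] = []
    measurements: list[IsotopeMeasurement] = []
    vessels: dict[str, VesselTruth] = {}
    t_end = float(max(sampling_times)) if len(sampling_times) else duration_h

    for gi, (tag, treatment, has_sponge, p) in enumerate(groups):
        for r in range(n_replicates):
            vessel = f"{tag}-{r + 1}"
            wet = float(weights[gi * n_replicates + r]) if has_sponge else None
            truth_df = _simulate_vessel(p, has_sponge, duration_h, src)
            final = truth_df.iloc[-1]
            vessels[vessel] = VesselTruth(
                vessel=vessel,
                treatment=treatment,
                wet_wt_g=wet,
                volume_l=p.volume_l,
                series=truth_df,
                taurine_consumed_umol=float(final["taurine_consumed_umol"]),
                biomass_c_gain_umol=float(final["biomass_c_gain_umol"]),
                biomass_n_gain_umol=float(final["biomass_n_gain_umol"]),
                dissimilated_c_umol=float(final["dissimilated_c_umol"]),
                cum_nh4_produced_umol=float(final["cum_nh4_produced_umol"]),
                cum_no2_produced_umol=float(final["cum_no2_produced_umol"]),
                cum_so4_produced_umol=float(final["cum_so4_produced_umol"]),
            )

            labeled = treatment == LABELED_TREATMENT
            samples = []
            for t in sampling_times:
                row = truth_df.iloc[(truth_df["time_h"] - t).abs().idxmin()]
                for analyte, col in (
                    ("SO4", "so4_uM"), ("NH4", "nh4_uM"),
                    ("NO2", "no2_uM"), ("taurine", "taurine_uM"),
                ):
                    conc = _noisy_conc(float(row[col]), p.analyte_cv(analyte), rng)
                    at = None
                    if labeled and analyte in ("NH4", "NO2"):
                        pool_umol = float(row[f"{analyte.lower()}_umol"])
                        heavy = float(row[f"{analyte.lower()}_15n_umol"])
                        true_at = (
                            100.0 * heavy / pool_umol if pool_umol > 0 else nat["N"]
                        )
                        at = _noisy_at(true_at, p.atpct_noise_sd, rng)
                    samples.append(IncubationSample(float(t), analyte, conc, at))
            series_out.append(
                IncubationSeries(
                    vessel=vessel,
                    treatment=treatment,
                    volume_l=p.volume_l,
                    wet_wt_g=wet,
                    samples=samples,
                )
            )

            # Dissolved 15N pools for the tracer mass balance at each time.
            if labeled:
                context = "sponge" if has_sponge else "seawater-control"
                for t in sampling_times:
                    row = truth_df.iloc[(truth_df["time_h"] - t).abs().idxmin()]
                    for pool in ("NH4", "NO2"):
                        pool_umol = float(row[f"{pool.lower()}_umol"])
                        heavy = float(row[f"{pool.lower()}_15n_umol"])
                        true_at = (
                            100.0 * heavy / pool_umol if pool_umol > 0 else nat["N"]
                        )
                        measurements.append(
                            IsotopeMeasurement(
                                element="N",
                                pool=pool,
                                atom_fraction=_noisy_at(true_at, p.atpct_noise_sd, rng),
                                n_total=_noisy_conc(pool_umol, p.noise_cv, rng),
                                context=context,
                                replicate=vessel,
                                time_h=float(t),
                            )
                        )

            # Bulk biomass at% at the end point (sacrificial sampling).
            if has_sponge:
                for element, per_g, gain_col, heavy_col in (
                    ("C", p.biomass_c_umol_per_g, "biomass_c_gain_umol",
                     "biomass_13c_gain_umol"),
                    ("N", p.biomass_n_umol_per_g, "biomass_n_gain_umol",
                     "biomass_15n_gain_umol"),
                ):
                    n0 = per_g * wet
                    gain = float(final[gain_col])
                    heavy = n0 * nat[element] / 100.0 + float(final[heavy_col])
                    true_at = 100.0 * heavy / (n0 + gain)
                    measurements.append(
                        IsotopeMeasurement(
                            element=element,
                            pool="sponge-biomass" if labeled else "control",
                            atom_fraction=_noisy_at(true_at, p.atpct_noise_sd, rng),
                            n_total=_noisy_conc(n0 + gain, p.noise_cv, rng),
                            context="sponge",
                            replicate=vessel,
                            time_h=t_end,
                        )
                    )

    truth = SimulationTruth(duration_h=duration_h, source_at=src, vessels=vessels)
    return series_out, measurements, truth


def calibrate_assimilated_fractions(
    params: KineticParams,
    target_c_rate: float,
    target_n_rate: float,
    wet_weights: Sequence[float],
    duration_h: float = 48.0,
) -> KineticParams:
    """Set ``f_c``/``f_n`` so the replicate-mean true rates hit the targets.

    Biomass gain is linear in the assimilated fractions while total uptake is
    independent of them, so a single noiseless vessel run gives the taurine
    consumption from which both fractions follow in closed form.  Targets are
    in nmol min-1 g-1 for explants with the supplied wet weights.
    """
    src = {el: effective_label_atom_fraction(s) for el, s in tracer_sources(params).items()}
    truth = _simulate_vessel(params, True, duration_h, src)
    consumed = float(truth["taurine_consumed_umol"].iloc[-1])
    if consumed <= 0:
        raise ValidationError("no taurine consumed; cannot calibrate fractions")
    inv_wt = float(np.mean([1.0 / w for w in wet_weights]))
    denom = consumed * 1000.0 * inv_wt / (duration_h * 60.0)
    f_c = target_c_rate / (TAURINE_C * denom)
    f_n = target_n_rate / (TAURINE_N * denom)
    if not (0 <= f_c <= 1 and 0 <= f_n <= 1):
        raise ValidationError(
            f"calibrated fractions out of range (f_c={f_c:.3g}, f_n={f_n:.3g}); "
            "adjust uptake kinetics"
        )
    return replace(params, f_c=f_c, f_n=f_n)


def calibrated_labeled_experiment(
    seed: int,
    target_c_rate: float = 1.38,
    target_n_rate: float = 0.74,
    n_replicates: int = 3,
    duration_h: float = 48.0,
    sampling_times: Sequence[float] = (0.0, 12.0, 48.0),
    **overrides,
) -> tuple[list[IncubationSeries], list[IsotopeMeasurement], SimulationTruth]:
    """Simulate the labeled 48-h triplicate design with calibrated true rates.

    Wet weights are drawn from the explant distribution, then the assimilated
    fractions are calibrated so the true replicate-mean C and N assimilation
    rates equal the requested targets (defaults: the whole-holobiont rates in
    nmol min-1 g-1).  Measurement noise stays at its configured level.
    """
    params = KineticParams(seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    weights = draw_wet_weights(
        params.wet_wt_mean_g, params.wet_wt_sd_g, 2 * n_replicates, rng
    )
    params = replace(params, wet_weights=tuple(weights))
    params = calibrate_assimilated_fractions(
        params, target_c_rate, target_n_rate, weights[:n_replicates], duration_h
    )
    return simulate_incubation(params, n_replicates, duration_h, sampling_times)


def make_fish_fixture(
    mean_count: float,
    sd: float,
    n_fields: int,
    geometry: tuple[float, float, float] = (146.25, 146.25, 1.0),
    seed: int = 0,
    target_eub_ratio: float = 0.24,
) -> list[FishFieldCount]:
    """Synthetic field-of-view counts with the given summary statistics.

    Counts are drawn from a normal truncated at zero and rounded to integers;
    the general-probe (EUB) count of each field is the target count divided by
    ``target_eub_ratio``.
    """
    if n_fields < 1:
        raise ValidationError("need at least one field")
    if mean_count < 0 or sd < 0:
        raise ValidationError("mean and sd must be >= 0")
    rng = np.random.default_rng(seed)
    if sd == 0:
        counts = np.full(n_fields, round(mean_count))
    else:
        a = (0.0 - mean_count) / sd
        counts = np.round(
            stats.truncnorm.rvs(
                a, np.inf, loc=mean_count, scale=sd, size=n_fields, random_state=rng
            )
        )
    gx, gy, th = geometry
    return [
        FishFieldCount(
            field_id=f"fov-{i + 1}",
            target_count=float(c),
            eub_count=float(round(c / target_eub_ratio)),
            grid_x_um=gx,
            grid_y_um=gy,
            thickness_um=th,
        )
        for i, c in enumerate(counts)
    ]


def make_proteome_fixture(
    n_proteins: int,
    n_bins: int = 4,
    seed: int = 0,
    target_bin: str = "bin-1",
    target_share: float = 0.357,
    mean_count: float = 20.0,
    sample: str = "S1",
) -> list[SpectralCountRecord]:
    """Synthetic spectral-count table with a controlled target-bin NSAF share.

    Lengths are uniform on 50-2000 aa and counts negative-binomial.  Proteins
    are assigned to the target bin in shuffled order until its NSAF share
    reaches ``target_share``; the remainder is spread over the other bins.
    At a few hundred proteins the realized share lands within a couple of
    percentage points of the request.
    """
    if n_proteins < 1 or n_bins < 1:
        raise ValidationError("need at least one protein and one bin")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(50, 2001, size=n_proteins)
    nb_n = 2.0
    counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mean_count), size=n_proteins)
    if counts.sum() == 0:
        counts[0] = 1
    saf = counts / lengths
    total = saf.sum()
    order = rng.permutation(n_proteins)
    bins = np.empty(n_proteins, dtype=object)
    acc = 0.0
    rest: list[int] = []
    for idx in order:
        if acc < target_share * total:
            bins[idx] = target_bin
            acc += saf[idx]
        else:
            rest.append(idx)
    other = [f"bin-{i + 2}" for i in range(max(n_bins - 1, 1))]
    for j, idx in enumerate(rest):
        bins[idx] = other[j % len(other)]
    return [
        SpectralCountRecord(
            sample=sample,
            protein=f"prot-{i + 1}",
            bin=str(bins[i]),
            spectral_count=int(counts[i]),
            length_aa=int(lengths[i]),
        )
        for i in range(n_proteins)
    ]
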