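"""End-to-end analysis orchestration.

Binds the incubation accounting and the tracer mass balance into the
reproducible reporting pipeline: per-replicate tracer attributions, net
ammonium release, sulfate accounting, and mean ± SE summaries across explants.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .incubation import IncubationSeries, net_change
from .isotope import (
    IsotopeMeasurement,
    TracerAttribution,
    ammonium_released,
    effective_label_atom_fraction,
    mean_se,
    normalize_to_wet_weight,
    tracer_derived_amount,
)
from .io import (
    RunConfig,
    read_atom_fractions_tsv,
    read_incubation_tsv,
    write_atom_fractions_tsv,
    write_fish_tsv,
    write_incubation_tsv,
    write_proteome_tsv,
)
from .simulate import (
    KineticParams,
    make_fish_fixture,
    make_proteome_fixture,
    simulate_incubation,
)

logger = logging.getLogger(__name__)


@dataclass
class TracerReport:
    """Per-replicate attributions plus the cross-explant summary."""

    attributions: pd.DataFrame
    summary: dict


def _control_measurement(
    measurements: Sequence[IsotopeMeasurement], element: str, config: RunConfig
) -> IsotopeMeasurement:
    """Mean at% of unlabeled-control explants; constants if none measured."""
    at_values = [
        m.atom_fraction
        for m in measurements
        if m.pool == "control" and m.element == element
    ]
    if at_values:
        at = float(np.mean(at_values))
    else:
        at = config.natural_abundance[element]
        logger.info(
            "no measured %s controls; using natural-abundance constant %.3f at%%",
            element, at,
        )
    return IsotopeMeasurement(
        element=element, pool="control", atom_fraction=at, n_total=0.0
    )


def _dissolved_amounts(
    measurements: Sequence[IsotopeMeasurement],
    pool: str,
    context: str,
    t: float,
    control: IsotopeMeasurement,
    source_at: float,
    config: RunConfig,
    tol: float,
) -> dict[str, float]:
    """Tracer-derived µmol per replicate for one dissolved pool at time t."""
    out = {}
    for m in measurements:
        if (
            m.pool == pool
            and m.context == context
            and m.time_h is not None
            and abs(m.time_h - t) <= tol
        ):
            out[m.replicate] = tracer_derived_amount(
                m, control, source_at, clip_negative=config.clip_negative
            )
    return out


def analyze_tracer(
    series: Sequence[IncubationSeries],
    measurements: Sequence[IsotopeMeasurement],
    config: RunConfig | None = None,
) -> TracerReport:
    """Run the full tracer mass balance on measured tables.

    Attributes biomass C and N to the label, normalizes to explant wet weight,
    converts to end-point assimilation rates, computes the seawater-corrected
    net tracer-derived ammonium release, and accounts net sulfate production.
    """
    config = config or RunConfig()
    if not series or not measurements:
        raise ValidationError("need incubation series and isotope measurements")
    by_vessel = {s.vessel: s for s in series}
    times = sorted({smp.time_h for s in series for smp in s.samples})
    t_end = config.duration_h if config.duration_h is not None else times[-1]
    tol = config.time_tolerance_h

    src = {
        el: effective_label_atom_fraction(config.tracer_source(el))
        for el in ("C", "N")
    }
    controls = {
        el: _control_measurement(measurements, el, config) for el in ("C", "N")
    }

    rows = []
    for m in measurements:
        if m.pool != "sponge-biomass":
            continue
        if m.time_h is not None and abs(m.time_h - t_end) > tol:
            continue
        vessel = by_vessel.get(m.replicate)
        if vessel is None or vessel.wet_wt_g is None:
            raise ValidationError(
                f"biomass measurement for unknown or weightless vessel "
                f"{m.replicate!r}"
            )
        att = TracerAttribution.from_measurement(
            m, controls[m.element], src[m.element], vessel.wet_wt_g, t_end,
            clip_negative=config.clip_negative,
        )
        rows.append({
            "replicate": att.replicate, "element": att.element, "pool": att.pool,
            "n_tracer_derived_umol": att.n_tracer_derived,
            "per_wet_weight_umol_g": att.per_wet_weight,
            "duration_min": att.duration_min,
            "rate_nmol_min_g": att.rate,
        })
    attributions = pd.DataFrame(rows)

    # Net tracer-derived ammonium release (seawater-control corrected).
    n_ctrl = controls["N"]
    released_per_g: dict[str, float] = {}
    nh4_sp = _dissolved_amounts(
        measurements, "NH4", "sponge", t_end, n_ctrl, src["N"], config, tol
    )
    no2_sp = _dissolved_amounts(
        measurements, "NO2", "sponge", t_end, n_ctrl, src["N"], config, tol
    )
    nh4_sw = _dissolved_amounts(
        measurements, "NH4", "seawater-control", t_end, n_ctrl, src["N"], config, tol
    )
    no2_sw = _dissolved_amounts(
        measurements, "NO2", "seawater-control", t_end, n_ctrl, src["N"], config, tol
    )
    nh4_sw_mean = float(np.mean(list(nh4_sw.values()))) if nh4_sw else 0.0
    no2_sw_mean = float(np.mean(list(no2_sw.values()))) if no2_sw else 0.0
    for rep in sorted(nh4_sp):
        vessel = by_vessel.get(rep)
        if vessel is None or vessel.wet_wt_g is None:
            continue
        released = ammonium_released(
            nh4_sp[rep], nh4_sw_mean, no2_sp.get(rep, 0.0), no2_sw_mean
        )
        released_per_g[rep] = normalize_to_wet_weight(released, vessel.wet_wt_g)

    # Net sulfate production, baseline-subtracted and control-corrected.
    so4_per_g: dict[str, float] = {}
    ctrl_net: dict[str, list[float]] = {}
    for s in series:
        if not s.has_sponge:
            try:
                ctrl_net.setdefault(s.treatment, []).append(
                    net_change(s, "SO4", times[0], t_end, tol)
                )
            except LookupError:
                pass
    for s in series:
        if not s.has_sponge or "taurine" not in s.treatment:
            continue
        try:
            net = net_change(s, "SO4", times[0], t_end, tol)
        except LookupError:
            continue
        ctrl = float(np.mean(ctrl_net[s.treatment])) if s.treatment in ctrl_net else 0.0
        so4_per_g[s.vessel] = (net - ctrl) * s.volume_l / s.wet_wt_g

    def _stat(values: dict[str, float]) -> dict:
        if not values:
            return {"mean": None, "se": None, "n": 0}
        mean, se = mean_se(values.values())
        return {"mean": mean, "se": se, "n": len(values)}

    summary = {
        "duration_h": t_end,
        "source_at_percent": src,
        "control_at_percent": {
            el: controls[el].atom_fraction for el in ("C", "N")
        },
        "rate_c_nmol_min_g": _stat({
            r["replicate"]: r["rate_nmol_min_g"]
            for r in rows if r["element"] == "C"
        }),
        "rate_n_nmol_min_g": _stat({
            r["replicate"]: r["rate_nmol_min_g"]
            for r in rows if r["element"] == "N"
        }),
        "nh4_released_umol_per_g": _stat(released_per_g),
        "so4_net_umol_per_g": _stat(so4_per_g),
    }
    return TracerReport(attributions=attributions, summary=summary)


def run_analyze(
    incubation_path: str | Path,
    atoms_path: str | Path,
    outdir: str | Path,
    config: RunConfig | None = None,
) -> TracerReport:
    """Read measured tables, run the tracer analysis and write the reports."""
    import json

    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series = read_incubation_tsv(incubation_path)
    measurements = read_atom_fractions_tsv(atoms_path)
    report = analyze_tracer(series, measurements, config)
    report.attributions.to_csv(outdir / "attributions.tsv", sep="\t", index=False)
    (outdir / "summary.json").write_text(
        json.dumps(report.summary, indent=2, sort_keys=True)
    )
    (outdir / "analyze.log").write_text(
        f"tauflux {__version__}\nseed {config.seed}\nconfig {config.hash()}\n"
        f"inputs {incubation_path} {atoms_path}\n"
    )
    return report


def run_simulate(
    outdir: str | Path,
    params: KineticParams | None = None,
    n_replicates: int = 3,
    duration_h: float = 48.0,
    sampling_times: Sequence[float] = (0.0, 12.0, 48.0),
    with_fixtures: bool = True,
) -> None:
    """Simulate the default labeled experiment and write all fixture tables."""
    params = params or KineticParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series, measurements, truth = simulate_incubation(
        params, n_replicates, duration_h, sampling_times
    )
    write_incubation_tsv(series, outdir / "incubation.tsv")
    write_atom_fractions_tsv(measurements, outdir / "atom_fractions.tsv")
    (outdir / "truth.json").write_text(truth.to_json())
    if with_fixtures:
        write_fish_tsv(
            make_fish_fixture(260.6, 73.0, 10, seed=params.seed),
            outdir / "fish.tsv",
        )
        write_proteome_tsv(
            make_proteome_fixture(600, seed=params.seed),
            outdir / "proteome.tsv",
        )
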