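"""Forward simulator: kinetics, conservation laws, label bookkeeping,
determinism, and the FISH/proteome fixture generators."""
import io as _io

import numpy as np
import pytest

from tauflux.errors import StepSizeError, ValidationError
from tauflux.io import write_atom_fractions_tsv, write_incubation_tsv
from tauflux.isotope import NATURAL_ABUNDANCE_AT_PERCENT
from tauflux.proteomics import bin_share, nsaf
from tauflux.simulate import (
    DEFAULT_PULSES,
    KineticParams,
    Pulse,
    calibrate_assimilated_fractions,
    make_fish_fixture,
    make_proteome_fixture,
    simulate_incubation,
    tracer_sources,
)
from tauflux.isotope import effective_label_atom_fraction

NOISELESS = dict(noise_cv=0.0, atpct_noise_sd=0.0)


def _run(params, **kw):
    kw.setdefault("n_replicates", 1)
    kw.setdefault("duration_h", 48.0)
    kw.setdefault("sampling_times", (0.0, 12.0, 48.0))
    return simulate_incubation(params, **kw)


class TestSourcePool:
    def test_equimolar_dual_label_at_percent(self):
        src = tracer_sources(KineticParams())
        assert effective_label_atom_fraction(src["C"]) == pytest.approx(50.035)
        assert effective_label_atom_fraction(src["N"]) == pytest.approx(49.183)

    def test_unlabeled_pulses_dilute_the_source(self):
        mixed = KineticParams(
            pulses=(Pulse(0.0, 1.0, labeled=True), Pulse(36.0, 1.0, labeled=False))
        )
        at = effective_label_atom_fraction(tracer_sources(mixed)["C"])
        assert NATURAL_ABUNDANCE_AT_PERCENT["C"] < at < 50.035

    def test_default_schedule_totals_1_6_mM(self):
        assert sum(p.taurine_mM for p in DEFAULT_PULSES) == pytest.approx(1.6)


class TestKinetics:
    def test_zero_uptake_keeps_analytes_flat(self):
        p = KineticParams(uptake_k_per_h=0.0, ammonia_oxidation_uM_per_h=0.0,
                          **NOISELESS)
        series, _, truth = _run(p)
        v = truth.vessels["sponge-label-1"]
        assert v.taurine_consumed_umol == 0.0
        assert v.rate("C", 48.0) == 0.0 and v.rate("N", 48.0) == 0.0
        tau = v.series["taurine_uM"].to_numpy()
        # flat at 1000 µM until the 36-h pulse raises it to 1600
        assert np.allclose(tau[v.series["time_h"] < 36.0], 1000.0)
        assert tau[-1] == pytest.approx(1600.0)
        assert np.allclose(v.series["so4_uM"], 0.0)

    def test_no_sponge_control_has_no_turnover(self):
        _, _, truth = _run(KineticParams(**NOISELESS))
        v = truth.vessels["sw-label-1"]
        assert v.taurine_consumed_umol == 0.0
        assert np.allclose(v.series["nh4_uM"], 0.0)

    def test_full_dissimilation_recovers_sulfonate(self):
        # a 100 µM addition fully taken up and dissimilated returns as SO4
        p = KineticParams(
            uptake_k_per_h=0.5, f_c=0.0, f_n=0.0, sulfonate_efficiency=1.0,
            ammonia_oxidation_uM_per_h=0.0, pulses=(Pulse(0.0, 0.1),), **NOISELESS
        )
        series, _, truth = _run(p, duration_h=96.0, sampling_times=(0.0, 96.0))
        sponge = next(s for s in series if s.vessel == "sponge-label-1")
        net = sponge.concentration("SO4", 96.0) - sponge.concentration("SO4", 0.0)
        assert net == pytest.approx(100.0, abs=1e-9)

    def test_lag_delays_uptake(self):
        p = KineticParams(lag_h=12.0, **NOISELESS)
        _, _, truth = _run(p)
        s = truth.vessels["sponge-label-1"].series
        before = s.loc[s["time_h"] <= 11.9, "taurine_consumed_umol"].max()
        assert before == 0.0
        assert truth.vessels["sponge-label-1"].taurine_consumed_umol > 0.0

    def test_inhibition_threshold_gates_nitrite(self):
        # high NH4+ shuts ammonia oxidation down; without a threshold the
        # same run makes strictly more nitrite
        base = dict(uptake_k_per_h=0.2, f_n=0.0, ammonia_oxidation_uM_per_h=5.0,
                    **NOISELESS)
        _, _, gated = _run(KineticParams(inhibition_threshold_uM=100.0, **base))
        _, _, open_ = _run(KineticParams(inhibition_threshold_uM=None, **base))
        assert (
            gated.vessels["sponge-label-1"].cum_no2_produced_umol
            < open_.vessels["sponge-label-1"].cum_no2_produced_umol
        )

    def test_step_size_error_on_overdraining_step(self):
        p = KineticParams(uptake_k_per_h=25.0, dt_h=0.05, **NOISELESS)
        with pytest.raises(StepSizeError):
            _run(p)

    def test_zero_order_mode_runs(self):
        p = KineticParams(uptake_mode="zero-order", uptake_rate_uM_per_h=10.0,
                          **NOISELESS)
        _, _, truth = _run(p)
        assert truth.vessels["sponge-label-1"].taurine_consumed_umol > 0


@pytest.fixture(scope="module")
def truth():
    p = KineticParams(uptake_k_per_h=0.08, f_c=0.3, f_n=0.4,
                      sulfonate_efficiency=0.9,
                      ammonia_oxidation_uM_per_h=4.0, **NOISELESS)
    _, _, truth = _run(p)
    return truth


class TestConservation:
    def test_carbon_balance(self, truth):
        v = truth.vessels["sponge-label-1"].series.iloc[-1]
        consumed_c = 2.0 * v["taurine_consumed_umol"]
        assert v["biomass_c_gain_umol"] + v["dissimilated_c_umol"] == pytest.approx(
            consumed_c, abs=1e-9
        )

    def test_nitrogen_balance(self, truth):
        v = truth.vessels["sponge-label-1"].series.iloc[-1]
        assert v["biomass_n_gain_umol"] + v["cum_nh4_produced_umol"] == pytest.approx(
            v["taurine_consumed_umol"], abs=1e-9
        )

    def test_sulfur_balance(self, truth):
        v = truth.vessels["sponge-label-1"].series.iloc[-1]
        assert v["cum_so4_produced_umol"] == pytest.approx(
            0.9 * v["taurine_consumed_umol"], abs=1e-9
        )

    def test_nitrite_bounded_by_ammonium_produced(self, truth):
        s = truth.vessels["sponge-label-1"].series
        assert (
            s["cum_no2_produced_umol"] <= s["cum_nh4_produced_umol"] + 1e-12
        ).all()

    def test_heavy_atom_inventory_constant_between_pulses(self, truth):
        src = truth.source_at
        s = truth.vessels["sponge-label-1"].series
        added_n = np.where(s["time_h"] >= 36.0, 1600.0, 1000.0) * src["N"] / 100.0
        inventory_n = (
            s["taurine_15n_umol"] + s["nh4_15n_umol"] + s["no2_15n_umol"]
            + s["biomass_15n_gain_umol"]
        )
        assert np.allclose(inventory_n, added_n, atol=1e-9)
        added_c = np.where(s["time_h"] >= 36.0, 3200.0, 2000.0) * src["C"] / 100.0
        inventory_c = (
            s["taurine_13c_umol"] + s["biomass_13c_gain_umol"]
            + s["dissimilated_13c_umol"]
        )
        assert np.allclose(inventory_c, added_c, atol=1e-9)


class TestDeterminism:
    @staticmethod
    def _tables(seed):
        p = KineticParams(seed=seed)
        series, meas, _ = _run(p, n_replicates=2)
        inc, atoms = _io.StringIO(), _io.StringIO()
        write_incubation_tsv(series, inc)
        write_atom_fractions_tsv(meas, atoms)
        return inc.getvalue(), atoms.getvalue()

    def test_same_seed_is_byte_identical(self):
        assert self._tables(11) == self._tables(11)

    def test_different_seed_differs(self):
        assert self._tables(11) != self._tables(12)

    def test_noiseless_measurements_equal_truth(self):
        series, _, truth = _run(KineticParams(**NOISELESS))
        sponge = next(s for s in series if s.vessel == "sponge-label-1")
        ts = truth.vessels["sponge-label-1"].series
        for t in (0.0, 12.0, 48.0):
            row = ts.iloc[(ts["time_h"] - t).abs().idxmin()]
            assert sponge.concentration("SO4", t) == pytest.approx(
                row["so4_uM"], abs=1e-12
            )


class TestCalibration:
    def test_calibrated_true_rates_hit_targets(self, labeled_experiment):
        _, _, truth = labeled_experiment
        assert truth.mean_rate("C") == pytest.approx(1.38, rel=1e-9)
        assert truth.mean_rate("N") == pytest.approx(0.74, rel=1e-9)

    def test_calibration_rejects_unreachable_targets(self):
        p = KineticParams(uptake_k_per_h=1e-6)
        with pytest.raises(ValidationError):
            calibrate_assimilated_fractions(p, 1000.0, 1000.0, [9.0, 9.0, 9.0])

    def test_wet_weight_list_must_cover_vessels(self):
        p = KineticParams(wet_weights=(9.0, 9.0))
        with pytest.raises(ValidationError):
            _run(p, n_replicates=3)

    def test_sampling_times_must_lie_in_window(self):
        with pytest.raises(ValidationError):
            _run(KineticParams(), sampling_times=(0.0, 72.0), duration_h=48.0)


class TestFishFixture:
    def test_zero_sd_gives_equal_fields(self):
        fields = make_fish_fixture(260.6, 0.0, 5, seed=1)
        assert [f.target_count for f in fields] == [261] * 5

    def test_sample_mean_near_target(self):
        fields = make_fish_fixture(260.6, 73.0, 200, seed=1)
        counts = np.array([f.target_count for f in fields])
        se = 73.0 / np.sqrt(len(counts))
        assert abs(counts.mean() - 260.6) < 3 * se

    def test_single_field(self):
        assert len(make_fish_fixture(100.0, 10.0, 1, seed=0)) == 1

    def test_eub_ratio(self):
        fields = make_fish_fixture(100.0, 0.0, 3, seed=0, target_eub_ratio=0.25)
        assert all(f.eub_count == pytest.approx(400) for f in fields)


class TestProteomeFixture:
    def test_target_share_realized(self):
        records = make_proteome_fixture(600, seed=2, target_share=0.357)
        shares = bin_share(
            nsaf(records), {r.protein: r.bin for r in records}, "bin-1"
        )
        assert shares == pytest.approx(35.7, abs=2.0)

    def test_single_protein(self):
        records = make_proteome_fixture(1, seed=0)
        assert nsaf(records)[records[0].protein] == pytest.approx(1.0)

    def test_reproducible(self):
        assert make_proteome_fixture(50, seed=5) == make_proteome_fixture(50, seed=5)
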