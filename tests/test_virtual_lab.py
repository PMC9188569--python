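"""Virtual-lab tests: turbidostat mass balance and nutrient coupling, the
culture-to-cytometry bridge, and plate-protocol conservation arithmetic."""

import numpy as np
import pytest
from scipy.optimize import brentq

from reacloop.cytometry import classify, GenotypeRule, generate_events
from reacloop.virtual_lab import (
    GrowthModel,
    PlateState,
    Strain,
    TurbidostatState,
    Well,
    clean_od,
    delta_mu_curve,
    evaporate,
    growth_rate,
    plate_dilution_protocol,
    run_competition,
    sample_culture,
    steady_state_histidine,
    treat_well,
    turbidostat_step,
)

AUX = Strain("mutant", mu_max=0.4, his_dependent=True, fluorophores={"mNeonGreen": 4000.0})
WT = Strain("wt", mu_max=0.4, fluorophores={"mCerulean": 16000.0})


def model(h_in=20.0, **kwargs):
    return GrowthModel(strains=(AUX, WT), h_in=h_in, **kwargs)


class TestTurbidostat:
    def test_zero_biomass_only_advances_time(self):
        state = TurbidostatState(densities={"mutant": 0.0, "wt": 0.0}, histidine=10.0)
        result = turbidostat_step(state, model(), 1.0)
        assert result.state.od == 0.0
        assert result.state.histidine == pytest.approx(10.0)
        assert result.state.time == pytest.approx(1.0)

    def test_prototroph_dilution_equals_mu_max_at_steady_state(self):
        state = TurbidostatState(densities={"wt": 0.5}, histidine=20.0, od_setpoint=0.5)
        proto_only = GrowthModel(strains=(WT,), h_in=20.0)
        result = turbidostat_step(state, proto_only, 5.0)
        # at the held setpoint D = mu; realized rates are reported
        assert result.state.od == pytest.approx(0.5, rel=1e-9)
        assert result.realized_mu["wt"] == pytest.approx(WT.mu_max, rel=1e-9)

    def test_auxotroph_steady_state_histidine_matches_bisection_oracle(self):
        m = GrowthModel(strains=(AUX,), h_in=20.0)
        od = 0.5
        state = TurbidostatState(densities={"mutant": od}, histidine=m.h_in, od_setpoint=od)
        result = turbidostat_step(state, m, 40.0)
        # flux balance D (h_in - h) = q mu(h) X with D = mu(h), solved by
        # bisection on the consumption-supply mismatch
        def balance(h):
            mu = growth_rate(AUX, h, m)
            return mu * (m.h_in - h) - m.yield_q * mu * od

        root = brentq(balance, 1e-6, m.h_in - 1e-9)
        assert result.state.histidine == pytest.approx(root, abs=1e-3)
        assert result.state.histidine == pytest.approx(steady_state_histidine(m, od), abs=1e-3)

    def test_mass_balance_and_nonnegative_histidine(self):
        state = TurbidostatState(
            densities={"mutant": 0.3, "wt": 0.2}, histidine=5.0, od_setpoint=0.5
        )
        m = model()
        for _ in range(30):
            od_before = state.od
            result = turbidostat_step(state, m, 0.25)
            state = result.state
            assert state.od - od_before == pytest.approx(
                result.growth - result.dilution, abs=1e-8
            )
            assert state.histidine >= 0.0

    def test_delta_mu_curve_reproduces_nutrient_limitation_structure(self):
        ods = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        rich = delta_mu_curve(model(h_in=20.0), ods)
        # near zero below OD 0.6, above 0.2/h at the 0.8 setpoint
        assert np.all(np.abs(rich[:6]) < 0.05)
        assert rich[-1] > 0.2
        scarce = delta_mu_curve(model(h_in=4.0), ods)
        # 4 uM feed: the mutant is outcompeted at every setpoint,
        # fully arrested (delta mu = WT growth rate) at most
        assert np.all(scarce > 0.05)
        assert np.all(scarce[1:] == pytest.approx(WT.mu_max, abs=1e-6))

    def test_competition_ratio_decays_at_growth_rate_difference(self):
        times, fractions, _ = run_competition(model(h_in=20.0), od_setpoint=0.8)
        log_odds = np.log(fractions / (1 - fractions))
        # once histidine is depleted the slope is -(mu_wt - 0)
        late = slice(5, 10)
        slope = np.polyfit(times[late], log_odds[late], 1)[0]
        assert slope == pytest.approx(-WT.mu_max, abs=0.02)


class TestSampleCulture:
    def test_single_strain_culture_fraction_one(self):
        state = TurbidostatState(densities={"wt": 0.5, "mutant": 0.0}, histidine=20.0)
        spec = sample_culture(state, model(), n_events=100)
        assert len(spec.strains) == 1
        assert spec.strains[0].name == "wt"
        assert spec.strains[0].fraction == 1.0

    def test_even_culture_gives_even_fractions(self):
        state = TurbidostatState(densities={"wt": 0.25, "mutant": 0.25}, histidine=20.0)
        spec = sample_culture(state, model(), n_events=100)
        assert {s.name: s.fraction for s in spec.strains} == {"wt": 0.5, "mutant": 0.5}

    def test_closed_loop_fractions_recovered_within_2_percent(self, signature, rpu_reference):
        from reacloop.cytometry import deconvolve, gate, to_rpu

        state = TurbidostatState(densities={"wt": 0.3, "mutant": 0.2}, histidine=20.0)
        spec = sample_culture(state, model(), n_events=10000, seed=0)
        events, _ = generate_events(spec, signature)
        table = events.subset(gate(events).mask)
        rpu = to_rpu(deconvolve(table, signature).amounts, table.fsc, rpu_reference)
        rules = GenotypeRule.threshold("mCerulean", 1.0, above="wt", below="mutant")
        result = classify(rpu.rpu, rules)
        assert result.fractions["wt"] == pytest.approx(0.6, abs=0.02)

    def test_invalid_requests_rejected(self):
        state = TurbidostatState(densities={"wt": 0.5}, histidine=20.0)
        with pytest.raises(ValueError):
            sample_culture(state, model(), n_events=0)
        empty = TurbidostatState(densities={"wt": 0.0}, histidine=20.0)
        with pytest.raises(ValueError):
            sample_culture(empty, model(), n_events=10)


class TestPlateProtocol:
    def test_below_threshold_and_recent_dilution_no_action(self):
        plate = PlateState(wells=(Well(od=0.05),), hours_since_dilution=2.0)
        action, after = plate_dilution_protocol(plate, threshold=0.1)
        assert action.kind == "none"
        assert after is plate

    def test_dilution_conserves_cells_and_restores_volume(self):
        # 1 h of evaporation at 10 uL/h: V = 190 uL at OD 0.12.
        plate = PlateState(wells=(Well(volume=190.0, od=0.12),), hours_since_dilution=1.0)
        action, after = plate_dilution_protocol(plate, threshold=0.1)
        assert action.kind == "dilute"
        well = after.wells[0]
        assert well.od == pytest.approx(0.12 * 190.0 / 290.0)  # ~0.0786
        assert action.removed_volumes[0] == pytest.approx(90.0)
        assert well.volume == pytest.approx(200.0)

    def test_forced_feed_after_10_hours_without_dilution(self):
        plate = PlateState(wells=(Well(volume=110.0, od=0.02),), hours_since_dilution=10.0)
        action, after = plate_dilution_protocol(plate, threshold=0.1)
        assert action.kind == "feed"
        assert after.wells[0].volume == pytest.approx(210.0)

    def test_excess_evaporation_estimate_clamps_removal(self):
        plate = PlateState(wells=(Well(volume=150.0, od=0.2),), hours_since_dilution=12.0)
        action, after = plate_dilution_protocol(plate, threshold=0.1)
        assert action.kind == "dilute" and action.warnings
        assert after.wells[0].volume == pytest.approx(250.0)  # nothing removed

    @staticmethod
    def _regrow(plate, od=0.2):
        from dataclasses import replace

        wells = tuple(replace(w, od=od) for w in plate.wells)
        return replace(plate, wells=wells)

    def test_volume_exactly_periodic_when_estimate_matches_truth(self):
        plate = PlateState(wells=(Well(od=0.2, media_antibiotic=1.0),))
        for _ in range(5):
            plate = self._regrow(evaporate(plate, 2.0))  # growth between dilutions
            action, plate = plate_dilution_protocol(plate, threshold=0.1)
            assert action.kind == "dilute"
            assert plate.wells[0].volume == pytest.approx(200.0)

    def test_estimate_mismatch_accumulates_linearly(self):
        plate = PlateState(wells=(Well(od=0.2),))
        for cycle in range(1, 5):
            plate = self._regrow(evaporate(plate, 2.0))
            _, plate = plate_dilution_protocol(plate, threshold=0.05, evaporation_estimate=8.0)
            # under-estimating evaporation removes (10-8)*2 = 4 uL too much
            # per cycle, so the deficit grows linearly
            assert plate.wells[0].volume == pytest.approx(200.0 - 4.0 * cycle)

    def test_treatment_mixing_conservation(self):
        plate = PlateState(wells=(Well(volume=200.0, od=0.1, antibiotic=0.0),))
        # 50 uL at 80 mg/L into 200 uL -> 16 mg/L final
        after = treat_well(plate, 0, dose=80.0)
        assert after.wells[0].antibiotic == pytest.approx(16.0)
        assert after.wells[0].od == pytest.approx(0.1 * 200.0 / 250.0)
        # media-only treatment leaves a drug-free well drug-free
        blank = treat_well(plate, 0, dose=0.0)
        assert blank.wells[0].antibiotic == 0.0

    def test_sequential_additions_commute(self):
        plate = PlateState(wells=(Well(volume=200.0, od=0.1),))
        ab = treat_well(treat_well(plate, 0, dose=40.0), 0, dose=0.0).wells[0]
        ba = treat_well(treat_well(plate, 0, dose=0.0), 0, dose=40.0).wells[0]
        assert ab.antibiotic == pytest.approx(ba.antibiotic)
        assert ab.od == pytest.approx(ba.od)


class TestCleanOd:
    def test_blank_equal_measurement_gives_zero(self):
        t = np.arange(0, 5, 0.5)
        y = np.full(t.size, 1e-3)
        result = clean_od(t, y, blank=y)
        np.testing.assert_allclose(result.od, 0.0)
        assert result.n_removed == 0

    def test_early_spikes_removed_exactly(self):
        t = np.arange(0.0, 6.0, 0.5)
        y = np.full(t.size, 1e-3)
        y[[0, 2, 3]] = 5e-3  # three aberrant early readings
        result = clean_od(t, y, blank=0.0)
        assert result.n_removed == 3
        assert result.times.size == t.size - 3

    def test_late_spike_retained(self):
        t = np.array([0.5, 1.0, 3.0])
        y = np.array([1e-3, 1e-3, 5e-3])  # spike at 3 h is real signal
        result = clean_od(t, y, blank=0.0)
        assert result.n_removed == 0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            clean_od([0.0, 1.0], [1e-3], blank=0.0)
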