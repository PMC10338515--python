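"""Virtual-pig physiology: strength-duration law, recruitment,
force-frequency gain, breath simulation and inter-animal sampling."""

from dataclasses import replace

import numpy as np
import pytest

from phrenosweep.scheduler import VentilatorSettings
from phrenosweep.virtual_pig import (
    ANIMAL_PRESETS,
    MandatoryBreath,
    PigParams,
    _SAMPLE_SPREAD,
    effective_pulse,
    excitation_voltage,
    frequency_gain,
    recruitment_fraction,
    sample_animal,
    sample_range,
    simulate_breath,
)
from phrenosweep.evaluation import tidal_volume
from phrenosweep.waveforms import (
    BurstSettings,
    Direction,
    PulseSettings,
    build_pulse_train,
)


def stim_waveform(width_ms, freq_hz, direction, *, v_end=10.0, v_start=6.5,
                  slope=1.0, duration=1.10):
    pulse = PulseSettings(v_end, width_ms, freq_hz, direction)
    burst = BurstSettings(v_start, v_end, slope, duration, 13.0)
    return build_pulse_train(pulse, burst)


class TestExcitationVoltage:
    def test_threshold_at_chronaxie_is_twice_rheobase(self, default_pig):
        v = excitation_voltage(default_pig.chronaxie_ms, default_pig)
        assert v == pytest.approx(2.0 * default_pig.rheobase_v)

    def test_long_pulse_approaches_rheobase(self, default_pig):
        assert excitation_voltage(1e6, default_pig) == pytest.approx(
            default_pig.rheobase_v, rel=1e-3
        )

    def test_lapicque_hyperbola_value(self):
        pig = PigParams(rheobase_v=4.0, chronaxie_ms=0.2)
        assert excitation_voltage(0.1, pig) == pytest.approx(12.0)

    def test_strictly_decreasing_in_width(self, default_pig):
        widths = np.logspace(-2, 1, 40)
        v = excitation_voltage(widths, default_pig)
        assert np.all(np.diff(v) < 0.0)

    def test_rejects_nonpositive_width(self, default_pig):
        with pytest.raises(ValueError):
            excitation_voltage(0.0, default_pig)


class TestRecruitment:
    def test_half_recruited_exactly_at_threshold(self, default_pig):
        v_exc = excitation_voltage(0.3, default_pig)
        assert recruitment_fraction(v_exc, 0.3, default_pig) == pytest.approx(0.5)

    def test_zero_voltage_gives_negligible_recruitment(self, default_pig):
        for width in (0.05, 0.3, 5.0, 1e5):
            assert recruitment_fraction(0.0, width, default_pig) < 0.05

    def test_saturates_towards_one(self, default_pig):
        assert recruitment_fraction(20.0, 1.0, default_pig) > 0.999

    def test_monotone_in_voltage_and_width(self, default_pig):
        volts = np.linspace(0.0, 20.0, 50)
        rec = recruitment_fraction(volts, 0.2, default_pig)
        assert np.all(np.diff(rec) >= 0.0)
        widths = np.linspace(0.05, 1.0, 50)
        rec_w = np.array(
            [recruitment_fraction(8.0, w, default_pig) for w in widths]
        )
        assert np.all(np.diff(rec_w) >= 0.0)


class TestFrequencyGain:
    def test_half_saturation_at_f50(self, default_pig):
        assert frequency_gain(default_pig.force_freq_half_hz, default_pig) == (
            pytest.approx(0.5)
        )

    def test_hill_value_at_eighty_hertz(self):
        pig = PigParams(force_freq_half_hz=25.0, force_freq_exponent=2.5)
        assert frequency_gain(80.0, pig) == pytest.approx(0.95, abs=0.005)

    def test_limits(self, default_pig):
        assert frequency_gain(0.0, default_pig) == 0.0
        assert frequency_gain(1e6, default_pig) == pytest.approx(1.0)


class TestEffectivePulse:
    def test_bip_halves_width(self):
        assert effective_pulse(Direction.BIP, 0.2, 100.0) == (0.1, 100.0)

    def test_bip_per_phase_convention(self):
        assert effective_pulse(Direction.BIP, 0.2, 100.0,
                               bip_total_width=False) == (0.2, 100.0)

    def test_alt_halves_rate(self):
        assert effective_pulse(Direction.ALT, 0.2, 100.0) == (0.2, 50.0)

    def test_uni_passthrough(self):
        assert effective_pulse(Direction.UNI, 0.2, 100.0) == (0.2, 100.0)


class TestSimulateBreath:
    def test_subthreshold_burst_moves_no_air(self, quiet_pig, vent):
        wf = stim_waveform(0.3, 100.0, Direction.BIP, v_end=1.0, v_start=1.0)
        trace = simulate_breath(wf, vent, quiet_pig, noise=False)
        assert tidal_volume(trace, quiet_pig.body_weight_kg) < 0.1

    def test_quasi_static_volume_equals_compliance_times_pressure(self, vent):
        """With tiny airway resistance and a long flat burst the lung
        equilibrates: V_T -> C * P_mus,peak."""
        pig = PigParams(airway_resistance_cmh2o_s_per_l=1.0).noiseless()
        wf = stim_waveform(0.5, 200.0, Direction.BIP, v_end=20.0, v_start=20.0,
                           slope=0.0, duration=3.0)
        vent_slow = VentilatorSettings(mandatory_rate_per_min=10.0)
        trace = simulate_breath(wf, vent_slow, pig, noise=False)
        from phrenosweep.virtual_pig import recruitment_fraction, frequency_gain
        p_peak = (
            pig.max_diaphragm_pressure_cmh2o
            * recruitment_fraction(20.0, 0.25, pig)
            * frequency_gain(200.0, pig)
        )
        expected_ml = pig.compliance_ml_per_cmh2o * p_peak
        vt = tidal_volume(trace, pig.body_weight_kg) * pig.body_weight_kg
        assert vt == pytest.approx(expected_ml, rel=0.01)

    def test_baseline_pattern_calibrated_window(self, default_pig, vent):
        """The reference pattern produces 5-6.5 mL/kg on the default animal."""
        wf = stim_waveform(4.0, 200.0, Direction.ALT)
        rng = np.random.default_rng(7)
        vts = []
        for _ in range(5):
            trace = simulate_breath(wf, vent, default_pig, rng)
            vts.append(tidal_volume(trace, default_pig.body_weight_kg))
        assert 5.0 <= np.mean(vts) <= 6.5

    def test_monotone_in_end_voltage_frequency_and_width(self, quiet_pig, vent):
        def vt(width, freq, v_end):
            wf = stim_waveform(width, freq, Direction.BIP, v_end=v_end,
                               v_start=min(6.5, v_end))
            trace = simulate_breath(wf, vent, quiet_pig, noise=False)
            return tidal_volume(trace, quiet_pig.body_weight_kg)

        by_voltage = [vt(0.2, 80.0, v) for v in (2.0, 6.0, 10.0, 14.0)]
        assert sorted(by_voltage) == by_voltage
        by_freq = [vt(0.2, f, 10.0) for f in (10.0, 40.0, 80.0, 120.0, 200.0)]
        assert sorted(by_freq) == by_freq
        by_width = [vt(w, 80.0, 10.0) for w in (0.05, 0.1, 0.15, 0.3, 1.0)]
        assert sorted(by_width) == by_width

    def test_frequency_saturation_plateau(self, quiet_pig, vent):
        """Above the plateau, raising f_p from 120 to 200 Hz changes the
        biphasic tidal volume by less than 5%."""
        for width in (0.15, 0.3, 1.0):
            vts = {}
            for freq in (120.0, 200.0):
                wf = stim_waveform(width, freq, Direction.BIP)
                trace = simulate_breath(wf, vent, quiet_pig, noise=False)
                vts[freq] = tidal_volume(trace, quiet_pig.body_weight_kg)
            assert vts[200.0] - vts[120.0] < 0.05 * vts[120.0]

    def test_alt_bip_asymmetry_at_shortest_width(self, quiet_pig, vent):
        """At T_pw=0.05 ms the halved biphasic phase width falls below
        threshold while alternating pulses still recruit."""
        vts = {}
        for direction in (Direction.ALT, Direction.BIP):
            wf = stim_waveform(0.05, 200.0, direction)
            trace = simulate_breath(wf, vent, quiet_pig, noise=False)
            vts[direction] = tidal_volume(trace, quiet_pig.body_weight_kg)
        assert vts[Direction.BIP] < 0.1          # ineffective
        assert vts[Direction.ALT] > 1.0          # clearly effective
        assert vts[Direction.ALT] > 10.0 * vts[Direction.BIP]

    def test_volume_conservation_over_full_breath(self, quiet_pig, vent):
        """Inspired volume equals expired volume once passive expiration
        completes (no air trapping)."""
        wf = stim_waveform(0.3, 100.0, Direction.BIP)
        trace = simulate_breath(wf, vent, quiet_pig, noise=False,
                                exp_duration_s=6.0)
        insp = np.trapezoid(np.clip(trace.flow_lps, 0.0, None), dx=trace.dt_s)
        exp = -np.trapezoid(np.clip(trace.flow_lps, None, 0.0), dx=trace.dt_s)
        assert exp == pytest.approx(insp, rel=0.01)

    def test_mandatory_breath_phases_and_pressure(self, quiet_pig, vent):
        trace = simulate_breath(MandatoryBreath(), vent, quiet_pig, noise=False)
        assert set(np.unique(trace.phase)) == {"mand_insp", "mand_exp"}
        insp = trace.phase == "mand_insp"
        assert np.allclose(trace.pressure_cmh2o[insp], vent.p_insp_cmh2o)
        assert np.allclose(trace.pressure_cmh2o[~insp], vent.p_peep_cmh2o)
        assert tidal_volume(trace, quiet_pig.body_weight_kg) > 3.0

    def test_ten_millisecond_sampling(self, quiet_pig, vent):
        wf = stim_waveform(0.3, 100.0, Direction.BIP)
        trace = simulate_breath(wf, vent, quiet_pig, noise=False)
        assert trace.dt_s == pytest.approx(0.01)

    def test_identical_seed_reproduces_trace(self, default_pig, vent):
        wf = stim_waveform(0.3, 100.0, Direction.BIP)
        a = simulate_breath(wf, vent, default_pig, 123)
        b = simulate_breath(wf, vent, default_pig, 123)
        assert np.array_equal(a.flow_lps, b.flow_lps)

    def test_unstable_integration_step_rejected(self, quiet_pig, vent):
        from phrenosweep.virtual_pig import IntegrationError

        wf = stim_waveform(0.3, 100.0, Direction.BIP)
        with pytest.raises(IntegrationError):
            simulate_breath(wf, vent, quiet_pig, noise=False, step_s=1.0)


class TestSampleAnimal:
    def test_same_seed_is_bitwise_identical(self):
        assert sample_animal(42) == sample_animal(42)

    def test_different_seeds_differ(self):
        assert sample_animal(1) != sample_animal(2)

    def test_draws_respect_configured_ranges(self):
        for seed in range(300):
            pig = sample_animal(seed)
            for name in _SAMPLE_SPREAD:
                lo, hi = sample_range("animal_I", name)
                assert lo <= getattr(pig, name) <= hi + 1e-12

    def test_animal_two_preset_is_alt_unstable(self):
        assert ANIMAL_PRESETS["animal_II"].alt_instability > 0.0
        assert sample_animal(5, "animal_II").alt_instability > 0.0


class TestPigParamsValidation:
    @pytest.mark.parametrize("field, value", [
        ("compliance_ml_per_cmh2o", 0.0),
        ("rheobase_v", -1.0),
        ("breath_noise_sd", -0.1),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            replace(PigParams(), **{field: value})
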