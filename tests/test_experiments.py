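"""Protocol stages, multisine synthesis, calibration and impedance study."""

import dataclasses

import numpy as np
import pytest

from earloop.experiments import (MultisineStimulus, calibrate_inner_ear,
                                 dynamic_range, impedance_study,
                                 make_multisine, run_protocol)
from earloop.middle_ear import metf
from earloop.network import FrequencyGrid
from earloop.transducer import pressure_from_spl, sensor_sensitivity


class TestMultisine:
    def test_single_component_is_a_sine(self):
        spec = MultisineStimulus(n_points=256, fs=1000.0, f_min=125.0,
                                 f_max=126.0, rms=1.0, seed=1)
        x, crest = make_multisine(spec)
        assert len(spec.bins) == 1
        # sampled sine: crest is at most sqrt(2), slightly less off-grid
        assert 1.3 < crest <= np.sqrt(2.0) + 1e-12
        # pure sine: spectrum has a single line
        spect = np.abs(np.fft.rfft(x)) / len(x)
        assert spect[spec.bins[0]] == pytest.approx(np.sqrt(2) / 2, rel=1e-9)
        spect[spec.bins[0]] = 0.0
        assert np.max(spect) < 1e-12

    def test_fft_recovers_flat_amplitudes_exactly(self):
        spec = MultisineStimulus(rms=0.02, seed=99)
        x, _ = make_multisine(spec)
        spect = np.abs(np.fft.rfft(x)) / len(x) * 2.0
        amps = spect[spec.bins]
        np.testing.assert_allclose(amps, amps[0], rtol=1e-9)
        off = np.delete(spect, spec.bins)
        assert np.max(off) < 1e-9 * amps[0]

    def test_seeds_change_phases_not_magnitudes(self):
        a, _ = make_multisine(MultisineStimulus(seed=1))
        b, _ = make_multisine(MultisineStimulus(seed=2))
        assert not np.allclose(a, b)
        np.testing.assert_allclose(np.abs(np.fft.rfft(a)),
                                   np.abs(np.fft.rfft(b)), atol=1e-6)

    def test_deterministic_for_fixed_seed(self):
        a, _ = make_multisine(MultisineStimulus(seed=7))
        b, _ = make_multisine(MultisineStimulus(seed=7))
        np.testing.assert_array_equal(a, b)

    def test_component_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            MultisineStimulus(fs=1000.0, f_max=600.0)

    def test_schroeder_phases_lower_crest(self):
        _, cr_rand = make_multisine(MultisineStimulus(seed=5))
        _, cr_sch = make_multisine(MultisineStimulus(seed="schroeder"))
        assert cr_sch < cr_rand


class TestInnerEarCalibration:
    def test_noiseless_estimate_recovers_velocity_within_1pc(self, cfg):
        """Applying the estimated pressure->velocity transfer to a fresh
        pressure record reproduces the simulated velocity."""
        cal = calibrate_inner_ear(cfg, seed=cfg.seed)
        fresh = calibrate_inner_ear(cfg, seed=cfg.seed + 1)
        n = cfg.experiment.multisine_points
        bins = (fresh.frequencies * n / cal.fs).round().astype(int)
        P = np.fft.rfft(fresh.pressure[-n:]) / n
        V = np.fft.rfft(fresh.velocity[-n:]) / n
        predicted = P[bins] * cal.transfer
        err = np.abs(predicted - V[bins]) / np.abs(V[bins])
        assert np.max(err) < 0.01

    def test_estimate_invariant_to_excitation_amplitude(self, cfg):
        a = calibrate_inner_ear(cfg, force_amp=1e-4)
        b = calibrate_inner_ear(cfg, force_amp=3e-4)
        np.testing.assert_allclose(a.transfer, b.transfer, rtol=1e-9)

    def test_zero_excitation_rejected(self, cfg):
        with pytest.raises(ValueError):
            calibrate_inner_ear(cfg, force_amp=0.0)


class TestProtocol:
    def test_stage1_equals_metf_intact(self, cfg, protocol_result):
        direct = metf(cfg.middle_ear.with_state("intact"),
                      protocol_result.grid)
        np.testing.assert_array_equal(protocol_result.metf_intact.values,
                                      direct.values)

    def test_functional_gain_above_30db_from_1khz(self, protocol_result):
        f = protocol_result.fg_frequencies
        hi = (f >= 1000.0) & (f <= 2500.0)
        assert np.min(protocol_result.functional_gain_db[hi]) > 30.0

    def test_low_frequency_functional_gain_moderate(self, protocol_result):
        """Frame recoil limits the aided gain below the crossover: the low
        band sits well under the >=1 kHz gain, in the 10-28 dB window."""
        f = protocol_result.fg_frequencies
        lo = f <= 800.0
        hi = (f >= 1000.0) & (f <= 2500.0)
        fg_lo = protocol_result.functional_gain_db[lo]
        assert np.all(fg_lo >= 10.0) and np.all(fg_lo <= 28.0)
        assert np.max(fg_lo) < np.min(
            protocol_result.functional_gain_db[hi])

    def test_idle_insertion_attenuates_transmission(self, protocol_result):
        """Mass loading: the idle-transducer chain transmits less than the
        intact chain over most of the band (aided-off sanity)."""
        loss = protocol_result.insertion_loss_db
        f = protocol_result.grid.frequencies
        hi = (f >= 1200.0) & (f <= 4500.0)
        assert np.all(loss[hi] < 0.0)
        assert np.min(loss[hi]) < -3.0

    def test_stage2_time_domain_sensitivity_consistent(self, cfg, plant):
        """Sensor sensitivity estimated from the sampled pipeline matches the
        frequency-domain curve within 1 dB at the multisine bins."""
        from earloop.experiments import _bin_spectrum
        chain = cfg.signal_chain
        spec = MultisineStimulus(2048, chain.sample_rate, 100.0, 2000.0,
                                 rms=pressure_from_spl(60.0), seed=3)
        period, _ = make_multisine(spec)
        stim = np.tile(period, 4)
        y = plant.simulate_open(stim, np.zeros_like(stim))
        V = _bin_spectrum(y[:, 2], spec.n_points, spec.bins)  # raw sensor V
        P = _bin_spectrum(stim, spec.n_points, spec.bins)
        est = np.abs(V / P) * 1e3  # mV/Pa
        grid = FrequencyGrid(spec.frequencies)
        ref = sensor_sensitivity(cfg.middle_ear, cfg.transducer,
                                 grid).magnitude
        err_db = 20 * np.log10(est / ref)
        assert np.max(np.abs(err_db)) < 1.0

    def test_msg_at_least_29p5_db(self, protocol_result):
        assert protocol_result.msg_report.msg_db >= 29.5


class TestDynamicRange:
    def test_upper_bound_reaches_120_and_lower_below_25(self, cfg,
                                                        protocol_result):
        dr = dynamic_range(protocol_result)
        band = (dr.frequencies >= cfg.experiment.calibrated_band[0]) & \
               (dr.frequencies <= cfg.experiment.calibrated_band[1])
        assert np.max(dr.upper_spl) == pytest.approx(120.0, abs=1.0)
        assert np.min(dr.lower_spl[band]) <= 25.0
        assert np.all(dr.span_db[band] > 0.0)
        assert np.max(dr.span_db[band]) >= 60.0

    def test_upper_bound_scales_6db_with_drive_voltage(self, cfg, grid):
        from earloop.transducer import actuator_response, equivalent_spl
        intact = metf(cfg.middle_ear, grid)
        td2 = dataclasses.replace(cfg.transducer, max_drive_voltage=2.0)
        a1 = actuator_response(cfg.middle_ear, cfg.transducer, 1.0, grid)
        a2 = actuator_response(cfg.middle_ear, td2, 2.0, grid)
        up1 = equivalent_spl(a1.magnitude * 1.0, intact)
        up2 = equivalent_spl(a2.magnitude * 2.0, intact)
        np.testing.assert_allclose(up2 - up1, 20 * np.log10(2.0), atol=1e-9)


class TestImpedanceStudy:
    def test_incus_side_movement_larger_below_800hz(self, cfg, grid):
        out = impedance_study(cfg, grid)
        low = grid.frequencies <= 800.0
        assert np.all(out["drive_incus"].magnitude[low]
                      > out["drive_stapes"].magnitude[low])
        assert np.all(out["force_incus"].magnitude[low]
                      > out["force_stapes"].magnitude[low])

    def test_fixed_frame_gain_small_above_1khz(self, cfg, grid):
        out = impedance_study(cfg, grid)
        hi = grid.frequencies > 1000.0
        diff = 20 * np.log10(out["drive_stapes_fixed_frame"].magnitude[hi]
                             / out["drive_stapes"].magnitude[hi])
        assert np.max(diff) <= 2.0

    def test_fixed_frame_approximates_sum_of_free_sides(self, cfg, grid):
        """Clamping the frame recovers roughly the combined motion of the two
        free-floating sides (within a few dB for compliant plates)."""
        out = impedance_study(cfg, grid)
        hi = grid.frequencies >= 2000.0
        total = (out["drive_incus"].magnitude + out["drive_stapes"].magnitude)
        err = 20 * np.log10(out["drive_stapes_fixed_frame"].magnitude[hi]
                            / total[hi])
        assert np.max(np.abs(err)) <= 1.5

    def test_linearity_in_drive(self, cfg, grid):
        from earloop.transducer import actuator_response
        td = dataclasses.replace(cfg.transducer, max_drive_voltage=2.0)
        one = actuator_response(cfg.middle_ear, td, 1.0, grid)
        # per-volt responses are identical regardless of drive level
        two = actuator_response(cfg.middle_ear, td, 2.0, grid)
        np.testing.assert_allclose(one.values, two.values, rtol=1e-12)
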