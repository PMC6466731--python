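"""Generator contracts: stimulus ladder, component amplitudes, reproducibility."""

import numpy as np
import pytest

import retinoscope as rs
from retinoscope.synth import deterministic_sweep, op_packet


class TestStimulus:
    def test_default_ladder_endpoints_and_length(self, stimulus):
        assert stimulus.n_steps == 13
        assert stimulus.intensities_log[0] == pytest.approx(-2.01)
        assert stimulus.intensities_log[-1] == pytest.approx(4.09)
        assert stimulus.lambda_max_nm == 459.0

    def test_equal_log_spacing(self, stimulus):
        diffs = np.diff(stimulus.intensities_log)
        assert np.allclose(diffs, (4.09 + 2.01) / 12)

    def test_step8_close_to_nominal_hardware_value(self, stimulus):
        # Exact equal spacing puts step 8 at 1.548; the nominal ladder lists
        # 1.56 there.  The two agree to better than 0.02 log units.
        assert abs(stimulus.intensities_log[7] - 1.56) < 0.02

    def test_non_increasing_ladder_rejected(self):
        with pytest.raises(ValueError):
            rs.StimulusSeries((0.0, 0.0, 1.0))


class TestSweep:
    def test_minimum_equals_hill_a_amplitude(self, clean_params, config, stimulus):
        for intensity in stimulus.intensities_log[::4]:
            tr = rs.synth_sweep(intensity, clean_params, config, rng=0)
            expected = clean_params.a_amplitude(intensity)
            assert -tr.v_uV.min() == pytest.approx(expected, rel=5e-3)

    def test_all_zero_components_give_zero_trace(self, config):
        p = rs.ComponentParams(a_Vmax_uV=0, b_Vmax_uV=0, op_amp_uV=0, mains_amp_uV=0, noise_sd_uV=0)
        tr = rs.synth_sweep(2.0, p, config, rng=0)
        assert np.all(tr.v_uV == 0)

    def test_pre_onset_deterministic_signal_is_zero(self, config, stimulus):
        p = rs.ComponentParams(mains_amp_uV=0, noise_sd_uV=0)
        for intensity in stimulus.intensities_log[::6]:
            tr = rs.synth_sweep(intensity, p, config, rng=0)
            assert np.all(tr.v_uV[tr.t_ms < config.onset_ms] == 0)

    def test_invalid_trace_config_rejected(self):
        with pytest.raises(ValueError):
            rs.TraceConfig(fs_hz=-1)
        with pytest.raises(ValueError):
            rs.TraceConfig(duration_ms=0)
        with pytest.raises(ValueError):
            rs.TraceConfig(onset_ms=400.0)

    def test_mains_removed_by_notch(self, config):
        p = rs.ComponentParams(a_Vmax_uV=0, b_Vmax_uV=0, op_amp_uV=0, mains_amp_uV=5.0, noise_sd_uV=0)
        tr = rs.synth_sweep(2.0, p, config, rng=1)
        out = rs.apply_filter(tr, rs.FilterSpec("notch", 60.0))
        spectrum = np.abs(np.fft.rfft(out.v_uV))
        freqs = np.fft.rfftfreq(out.v_uV.size, 1.0 / config.fs_hz)
        bin60 = np.argmin(np.abs(freqs - 60.0))
        raw_spectrum = np.abs(np.fft.rfft(tr.v_uV))
        assert spectrum[bin60] < 0.02 * raw_spectrum[bin60]


class TestEye:
    def test_sweep_set_counts(self, clean_params, stimulus, config):
        sets = rs.synth_eye(clean_params, stimulus, config, sweeps_per_intensity=5, rng=0)
        assert len(sets) == 13
        assert all(len(s) == 5 for s in sets)

    def test_same_seed_bit_identical(self, stimulus, config):
        p = rs.ComponentParams()
        a = rs.synth_eye(p, stimulus, config, rng=42)
        b = rs.synth_eye(p, stimulus, config, rng=42)
        for sa, sb in zip(a, b):
            for ta, tb in zip(sa, sb):
                assert np.array_equal(ta.v_uV, tb.v_uV)

    def test_different_seeds_share_deterministic_part(self, stimulus, config):
        p = rs.ComponentParams(mains_amp_uV=0.0, noise_sd_uV=6.0)
        a = rs.synth_eye(p, stimulus, config, rng=1)
        b = rs.synth_eye(p, stimulus, config, rng=2)
        resid = np.concatenate([ta.v_uV - tb.v_uV for sa, sb in zip(a, b) for ta, tb in zip(sa, sb)])
        # Difference of two independent noise realizations: SD = sqrt(2)*sd.
        assert np.std(resid) == pytest.approx(np.sqrt(2) * 6.0, rel=0.05)

    def test_fewer_than_five_sweeps_rejected(self, clean_params):
        with pytest.raises(ValueError):
            rs.synth_eye(clean_params, sweeps_per_intensity=3, rng=0)


class TestCohort:
    def test_zero_sd_gives_identical_eyes(self):
        g = rs.GroupSpec("G", eyes=3, means=rs.ComponentParams(), sds={})
        spec = rs.CohortSpec(groups=(g,), seed=5)
        cohort = rs.synth_cohort(spec)
        assert all(e.params == cohort.eyes[0].params for e in cohort.eyes)

    def test_drawn_means_match_group_truth(self):
        g = rs.default_ctr_group(eyes=15)
        cohort = rs.synth_cohort(rs.CohortSpec(groups=(g,), seed=7))
        vmax = np.array([e.params.a_Vmax_uV for e in cohort.eyes])
        se = 87.5 / np.sqrt(15)
        assert abs(vmax.mean() - 377.3) < 2 * se

    def test_zero_eyes_rejected(self):
        with pytest.raises(ValueError):
            rs.GroupSpec("G", eyes=0, means=rs.ComponentParams())

    def test_cohort_regeneration_and_serialization_round_trip(self, tmp_path):
        spec = rs.CohortSpec(groups=(rs.default_ctr_group(eyes=1),), seed=11)
        c1, c2 = rs.synth_cohort(spec), rs.synth_cohort(spec)
        p1 = rs.save_cohort(c1, tmp_path / "a")
        p2 = rs.save_cohort(c2, tmp_path / "b")
        f1 = sorted(p1.rglob("*.csv"))
        f2 = sorted(p2.rglob("*.csv"))
        assert [f.name for f in f1] == [f.name for f in f2]
        assert all(a.read_bytes() == b.read_bytes() for a, b in zip(f1, f2))
        back = rs.load_cohort(p1)
        orig = c1.eyes[0].sweep_sets[0][0]
        again = back.eyes[0].sweep_sets[0][0]
        assert np.array_equal(orig.v_uV, again.v_uV)
        assert back.eyes[0].params == c1.eyes[0].params


class TestOPPacket:
    def test_op_energy_above_120hz(self, op_only_params, config):
        tr = rs.synth_sweep(2.0, op_only_params, config, rng=0)
        spectrum = np.abs(np.fft.rfft(tr.v_uV)) ** 2
        freqs = np.fft.rfftfreq(tr.v_uV.size, 1.0 / config.fs_hz)
        assert spectrum[freqs > 120].sum() / spectrum.sum() >= 0.95

    def test_op_confined_to_window(self, op_only_params, config):
        t = config.time_base()
        v = op_packet(t, config.onset_ms, op_only_params)
        outside = (t < config.onset_ms) | (t > config.onset_ms + 120.0)
        assert np.all(v[outside] == 0)

    def test_highpass_preserves_and_lowpass_removes_op_area(self, op_only_params, config):
        tr = rs.synth_sweep(2.0, op_only_params, config, rng=0)
        bundle = rs.process_trace([tr] * 5)
        dt = 1000.0 / config.fs_hz

        def area(v):
            mask = (tr.t_ms >= config.onset_ms) & (tr.t_ms <= config.onset_ms + 120.0)
            w = v[mask]
            return np.sum(np.abs(0.5 * (w[:-1] + w[1:]))) * dt

        raw = area(tr.v_uV)
        assert area(bundle.op_isolated.v_uV) >= 0.90 * raw
        assert area(bundle.b_isolated.v_uV) <= 0.01 * raw

    def test_center_frequency_below_120_rejected(self):
        with pytest.raises(ValueError):
            rs.ComponentParams(op_center_freq_hz=100.0)
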