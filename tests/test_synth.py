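"""Generator properties: determinism, volume/flow consistency, truth/signal
agreement, event injection, SpO2/EEG/EMG/hypnogram/metabolic structure."""

import numpy as np
import pytest

from somnoresp.core import BreathLabel, ChannelRole, ConfigurationError, Stage
from somnoresp.metabolism import open_circuit_rates
from somnoresp.staging import EPOCH_LEN_S, Hypnogram
from somnoresp.synth import (
    ApneaParams,
    SynthConfig,
    generate_breath_train,
    generate_eeg_emg,
    generate_hypnogram,
    generate_metabolic_traces,
    generate_recording,
    generate_spo2,
    inject_apneas,
)

from conftest import quiet_config, wake_only_hypnogram_params


def flat_hypnogram(stage: Stage, duration_s: float) -> Hypnogram:
    return Hypnogram([stage] * int(duration_s / EPOCH_LEN_S), source="external")


class TestBreathTrain:
    def test_exact_breath_count_at_zero_rate_cv(self):
        cfg = quiet_config(duration_s=60.0)
        hyp = flat_hypnogram(Stage.NREM, 60.0)
        flow, _, _, truth = generate_breath_train(cfg, hyp)
        assert len(truth.breath_table) == 150  # 150/min for 60 s
        # independent zero-crossing scan of the emitted trace
        pos = flow > 0.05 * np.abs(flow).max()
        onsets = np.flatnonzero(np.diff(pos.astype(int)) == 1)
        assert abs(len(onsets) - 150) <= 1

    def test_volume_is_running_integral_of_flow(self):
        cfg = quiet_config(duration_s=30.0)
        flow, volume, _, _ = generate_breath_train(cfg, flat_hypnogram(Stage.NREM, 30.0))
        dt = 1.0 / cfg.sample_rate
        integral = np.concatenate(
            ([0.0], np.cumsum((flow[1:] + flow[:-1]) * 0.5 * dt))
        )
        assert np.max(np.abs(volume - integral)) <= 1e-6

    def test_degenerate_config_all_normal_half_sines(self):
        cfg = quiet_config(duration_s=30.0)
        _, _, _, truth = generate_breath_train(cfg, flat_hypnogram(Stage.REM, 30.0))
        assert all(b.label == BreathLabel.NORMAL for b in truth.breath_table)

    def test_full_severity_clips_middle_half_of_inspiration(self):
        cfg = quiet_config(duration_s=30.0)
        cfg.flow_limitation.probability = 1.0
        cfg.flow_limitation.plateau_severity = 1.0
        flow, _, _, truth = generate_breath_train(cfg, flat_hypnogram(Stage.REM, 30.0))
        fs = cfg.sample_rate
        fl = [b for b in truth.breath_table if b.label == BreathLabel.FLOW_LIMITED]
        assert fl
        for b in fl[:10]:
            i0, i1 = int(b.t_start * fs), int(b.t_insp_end * fs)
            n = i1 - i0
            mid = flow[i0 + n // 4 : i0 + (3 * n) // 4]
            assert np.ptp(mid) <= 1e-9  # noiseless: exactly constant

    def test_flow_limited_breaths_lose_volume_but_not_effort(self):
        cfg = quiet_config(duration_s=30.0)
        cfg.flow_limitation.probability = 1.0
        cfg.flow_limitation.plateau_severity = 0.9
        flow, _, effort, truth = generate_breath_train(cfg, flat_hypnogram(Stage.REM, 30.0))
        cfg0 = quiet_config(duration_s=30.0)
        _, _, _, truth0 = generate_breath_train(cfg0, flat_hypnogram(Stage.NREM, 30.0))
        vt_fl = np.mean([b.vt_ml for b in truth.breath_table])
        vt_normal = np.mean([b.vt_ml for b in truth0.breath_table])
        assert vt_fl < vt_normal  # clipping is not re-normalized
        fs = cfg.sample_rate
        b = truth.breath_table[5]
        i0, i1 = int(b.t_start * fs), int(b.t_insp_end * fs)
        eff = effort[i0:i1]
        assert np.all(np.diff(eff) >= -1e-12)  # effort rises through inspiration

    def test_sniffs_have_scaled_inspiration_time(self):
        cfg = quiet_config(duration_s=60.0)
        cfg.sniff.probability = 0.2
        _, _, _, truth = generate_breath_train(cfg, flat_hypnogram(Stage.NREM, 60.0))
        sniff_ti = [b.t_insp_end - b.t_start for b in truth.breath_table
                    if b.label == BreathLabel.SNIFF]
        normal_ti = [b.t_insp_end - b.t_start for b in truth.breath_table
                     if b.label == BreathLabel.NORMAL]
        assert sniff_ti
        assert np.mean(sniff_ti) == pytest.approx(
            cfg.sniff.ti_scale * np.mean(normal_ti), rel=0.05
        )

    @pytest.mark.parametrize("bad", ["duration", "rate"])
    def test_invalid_configuration_rejected(self, bad):
        cfg = quiet_config()
        if bad == "duration":
            cfg.duration_s = -5.0
        else:
            cfg.breath.rate_bpm = 0.0
        with pytest.raises(ConfigurationError):
            generate_breath_train(cfg, flat_hypnogram(Stage.NREM, 30.0))


class TestApneaInjection:
    def test_zero_rate_is_identity(self):
        cfg = quiet_config(duration_s=60.0)
        hyp = flat_hypnogram(Stage.REM, 60.0)
        flow, _, effort, truth = generate_breath_train(cfg, hyp)
        flow2, effort2, truth2 = inject_apneas(flow, effort, truth, cfg)
        assert np.array_equal(flow, flow2)
        assert np.array_equal(effort, effort2)
        assert truth2.apnea_events == []

    def test_injected_event_suppresses_flow_envelope(self):
        cfg = quiet_config(duration_s=120.0)
        cfg.apnea = ApneaParams(
            rate_per_h={"W": 0.0, "NREM": 0.0, "REM": 40.0},
            duration_mean_s=1.0, duration_sd_s=0.0, duration_min_s=1.0,
        )
        hyp = flat_hypnogram(Stage.REM, 120.0)
        flow, _, effort, truth = generate_breath_train(cfg, hyp)
        flow2, effort2, truth2 = inject_apneas(flow, effort, truth, cfg)
        assert truth2.apnea_events
        fs = cfg.sample_rate

        def rms(x):
            return np.sqrt(np.mean(x**2))

        for t0, dur, _ in truth2.apnea_events:
            i0, i1 = int(t0 * fs), int((t0 + dur) * fs)
            pre = flow2[max(0, i0 - int(10 * fs)) : i0]
            assert rms(flow2[i0:i1]) <= 0.05 * rms(pre)
            # obstructive: effort preserved or increased
            assert rms(effort2[i0:i1]) >= rms(effort[i0:i1]) * 0.999

    def test_impossible_placement_errors_after_bounded_retries(self):
        cfg = quiet_config(duration_s=60.0)
        # demand ~40 events of 15 s in 60 s: cannot avoid overlap
        cfg.apnea = ApneaParams(
            rate_per_h={"W": 0.0, "NREM": 0.0, "REM": 2400.0},
            duration_mean_s=15.0, duration_sd_s=0.0, duration_min_s=15.0,
            max_retries=20,
        )
        hyp = flat_hypnogram(Stage.REM, 60.0)
        flow, _, effort, truth = generate_breath_train(cfg, hyp)
        with pytest.raises(ConfigurationError, match="retries"):
            inject_apneas(flow, effort, truth, cfg)


class TestSpo2:
    def test_no_events_stays_near_baseline(self):
        cfg = quiet_config(duration_s=60.0)
        cfg.spo2.noise_sd_pct = 0.2
        truth_empty = generate_breath_train(cfg, flat_hypnogram(Stage.NREM, 60.0))[3]
        s = generate_spo2(truth_empty, cfg)
        assert s.min() >= cfg.spo2.baseline_pct - 3 * cfg.spo2.noise_sd_pct

    @pytest.mark.parametrize("depth,reaches", [(6.0, True), (2.0, False)])
    def test_dip_depth_relative_to_scoring_threshold(self, depth, reaches):
        cfg = quiet_config(duration_s=60.0)
        cfg.spo2.desat_depth_mean_pct = depth
        cfg.spo2.desat_depth_sd_pct = 0.0
        hyp = flat_hypnogram(Stage.REM, 60.0)
        _, _, _, truth = generate_breath_train(cfg, hyp)
        truth.apnea_events.append((20.0, 2.0, Stage.REM))
        s = generate_spo2(truth, cfg)
        below = s <= cfg.spo2.baseline_pct - 4.0
        assert below.any() == reaches


class TestEEGEMG:
    def test_nrem_band_dominates_in_every_epoch(self):
        from somnoresp.staging import epoch_features

        cfg = quiet_config(duration_s=60.0)
        hyp = flat_hypnogram(Stage.NREM, 60.0)
        eeg, emg = generate_eeg_emg(hyp, cfg)
        for i in range(len(hyp)):
            i0 = int(i * EPOCH_LEN_S * cfg.sample_rate)
            i1 = int((i + 1) * EPOCH_LEN_S * cfg.sample_rate)
            f = epoch_features(eeg[i0:i1], emg[i0:i1], cfg.sample_rate)
            assert f.p_low > 0.9 * (f.p_low + f.p_theta + f.p_high)

    def test_wake_emg_exceeds_rem_emg_for_same_seed(self):
        cfg = quiet_config(duration_s=60.0)
        rng_w = np.random.default_rng(9)
        rng_r = np.random.default_rng(9)
        _, emg_w = generate_eeg_emg(flat_hypnogram(Stage.WAKE, 60.0), cfg, rng_w)
        _, emg_r = generate_eeg_emg(flat_hypnogram(Stage.REM, 60.0), cfg, rng_r)
        assert np.sqrt(np.mean(emg_w**2)) > np.sqrt(np.mean(emg_r**2))

    def test_regeneration_is_bit_identical(self):
        cfg = quiet_config(duration_s=60.0)
        hyp, _ = generate_hypnogram(SynthConfig(seed=4, duration_s=60.0))
        a = generate_eeg_emg(hyp, cfg, np.random.default_rng(7))
        b = generate_eeg_emg(hyp, cfg, np.random.default_rng(7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestHypnogram:
    def test_wake_only_weights_give_all_wake(self):
        cfg = SynthConfig(seed=0, duration_s=600.0)
        cfg.hypnogram = wake_only_hypnogram_params()
        hyp, _ = generate_hypnogram(cfg)
        assert all(s == Stage.WAKE for s in hyp.stages)

    def test_one_hour_gives_720_epochs(self):
        hyp, _ = generate_hypnogram(SynthConfig(seed=1, duration_s=3600.0))
        assert len(hyp) == 720

    def test_rem_entered_only_from_nrem(self):
        hyp, _ = generate_hypnogram(SynthConfig(seed=2, duration_s=3600.0))
        for prev, cur in zip(hyp.stages, hyp.stages[1:]):
            if cur == Stage.REM and prev != Stage.REM:
                assert prev == Stage.NREM

    def test_fixed_seed_reproduces_sequence(self):
        a, _ = generate_hypnogram(SynthConfig(seed=5, duration_s=1200.0))
        b, _ = generate_hypnogram(SynthConfig(seed=5, duration_s=1200.0))
        assert a.stages == b.stages


class TestMetabolicTraces:
    def test_unity_rer_balances_molar_gas_exchange(self):
        cfg = quiet_config(duration_s=1320.0)
        cfg.metabolism.rer = 1.0
        chans = generate_metabolic_traces(cfg)
        vo2, vco2 = open_circuit_rates(
            chans[ChannelRole.FIO2_IN].samples,
            chans[ChannelRole.FIO2_OUT].samples,
            chans[ChannelRole.FICO2_IN].samples,
            chans[ChannelRole.FICO2_OUT].samples,
            cfg.metabolism.chamber_flow_ml_h,
        )
        assert np.allclose(vco2, vo2, rtol=1e-12)

    def test_zero_activity_rate_gives_zero_breaks(self):
        cfg = quiet_config(duration_s=1320.0)
        cfg.metabolism.activity_rate_per_min = 0.0
        chans = generate_metabolic_traces(cfg)
        assert chans[ChannelRole.ACTIVITY].samples.sum() == 0

    def test_round_trip_recovers_configured_vo2(self):
        cfg = quiet_config(duration_s=1320.0)
        cfg.metabolism.vo2_ml_h = 60.0
        chans = generate_metabolic_traces(cfg)
        vo2, _ = open_circuit_rates(
            chans[ChannelRole.FIO2_IN].samples,
            chans[ChannelRole.FIO2_OUT].samples,
            chans[ChannelRole.FICO2_IN].samples,
            chans[ChannelRole.FICO2_OUT].samples,
            cfg.metabolism.chamber_flow_ml_h,
        )
        assert vo2.mean() == pytest.approx(60.0, rel=0.01)


class TestFullRecording:
    def test_same_seed_yields_identical_recording(self):
        cfg1 = SynthConfig(seed=3, duration_s=60.0)
        cfg2 = SynthConfig(seed=3, duration_s=60.0)
        rec1, _ = generate_recording(cfg1)
        rec2, _ = generate_recording(cfg2)
        assert set(rec1.channels) == set(rec2.channels)
        for role, ch in rec1.channels.items():
            assert np.array_equal(ch.samples, rec2.channels[role].samples)

    def test_channels_validate_and_metadata_propagates(self, default_recording):
        rec, _ = default_recording
        rec.validate()
        assert rec.meta.chamber_temp_c == 29.0
        assert rec.meta.barometric_mmhg == 760.0

    def test_co2_protocol_scales_plateau_ventilation(self):
        from somnoresp.breaths import analyze_flow

        cfg = quiet_config(seed=6, duration_s=600.0)
        cfg.hypnogram = wake_only_hypnogram_params()
        cfg.co2_protocol = [(0.0, 300.0), (8.0, 300.0)]
        rec, truth = generate_recording(cfg)
        flow = rec.get(ChannelRole.FLOW)
        breaths = analyze_flow(flow.samples, flow.sample_rate)
        ve_base = np.mean([b.inst_ve for b in breaths if 120 <= b.t_start < 300])
        ve_co2 = np.mean([b.inst_ve for b in breaths if 420 <= b.t_start < 600])
        assert ve_co2 - ve_base == pytest.approx(8.0 * cfg.hcvr_gain, rel=0.05)
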