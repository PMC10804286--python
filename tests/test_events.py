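"""Apnea and desaturation scoring: closure on injected events, rejection of
sub-threshold candidates, index arithmetic."""

import numpy as np
import pytest

from somnoresp.breaths import analyze_flow
from somnoresp.core import ChannelRole, ConfigurationError, RespiratoryEvent, Stage
from somnoresp.events import (
    ApneaScoringConfig,
    apnea_index,
    detect_apneas,
    detect_desaturations,
)
from somnoresp.staging import EPOCH_LEN_S, Hypnogram
from somnoresp.synth import ApneaParams, generate_recording, generate_spo2

from conftest import quiet_config, rem_only_hypnogram_params


def rem_recording_with_apneas(seed=51, duration_s=600.0, rate=30.0):
    cfg = quiet_config(seed=seed, duration_s=duration_s)
    cfg.hypnogram = rem_only_hypnogram_params()
    cfg.breath.signal_noise_sd = 0.01
    cfg.apnea = ApneaParams(
        rate_per_h={"W": 0.0, "NREM": 0.0, "REM": rate},
        duration_mean_s=1.2, duration_sd_s=0.2, duration_min_s=0.9,
    )
    return generate_recording(cfg), cfg


def synthetic_dip(fs=1000.0, duration_s=60.0, dip_at=30.0, dip_len=1.0, depth=0.95):
    """Regular 2.5 Hz breathing with one rectangular flow reduction."""
    t = np.arange(int(duration_s * fs)) / fs
    flow = np.sin(2 * np.pi * 2.5 * t)
    i0, i1 = int(dip_at * fs), int((dip_at + dip_len) * fs)
    flow[i0:i1] *= 1.0 - depth
    return flow, fs


class TestApneaDetection:
    def test_injected_apneas_recovered_with_timing(self):
        (rec, truth), cfg = rem_recording_with_apneas()
        assert truth.apnea_events  # the configuration must actually inject
        ch = rec.get(ChannelRole.FLOW)
        breaths = analyze_flow(ch.samples, ch.sample_rate, hypnogram=truth.hypnogram_true)
        events = detect_apneas(
            ch.samples, ch.sample_rate, breaths, hypnogram=truth.hypnogram_true
        )
        assert len(events) == len(truth.apnea_events)
        for t0, dur, _ in truth.apnea_events:
            best = min(events, key=lambda e: abs(e.t_start - t0))
            assert abs(best.t_start - t0) <= 0.1
            assert abs(best.duration - dur) <= 0.1
            assert best.magnitude >= 90.0

    def test_short_dip_rejected_by_duration_rules(self):
        # 0.3 s of 95% reduction at RR=150: under both 0.7 s and 2 cycles
        flow, fs = synthetic_dip(dip_len=0.3, depth=0.95)
        breaths = analyze_flow(flow, fs)
        events = detect_apneas(flow, fs, breaths, baseline_rr=150.0)
        assert events == []

    def test_shallow_reduction_rejected_by_depth_rule(self):
        # 85% reduction for 2 s: long enough but not deep enough
        flow, fs = synthetic_dip(dip_len=2.0, depth=0.85)
        breaths = analyze_flow(flow, fs)
        events = detect_apneas(flow, fs, breaths, baseline_rr=150.0)
        assert events == []

    def test_one_second_event_at_150bpm_accepted(self):
        flow, fs = synthetic_dip(dip_len=1.0, depth=0.97)
        breaths = analyze_flow(flow, fs)
        events = detect_apneas(flow, fs, breaths, baseline_rr=150.0)
        assert len(events) == 1
        assert events[0].t_start == pytest.approx(30.0, abs=0.1)
        assert events[0].duration == pytest.approx(1.0, abs=0.15)

    def test_event_free_recordings_yield_no_events(self):
        for seed in range(3):
            cfg = quiet_config(seed=seed, duration_s=180.0)
            cfg.breath.rate_cv = 0.08
            cfg.breath.signal_noise_sd = 0.01
            rec, truth = generate_recording(cfg)
            ch = rec.get(ChannelRole.FLOW)
            breaths = analyze_flow(ch.samples, ch.sample_rate)
            assert detect_apneas(ch.samples, ch.sample_rate, breaths) == []

    def test_no_breaths_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_apneas(np.zeros(10000), 1000.0, [], baseline_rr=150.0)

    def test_both_rule_is_stricter_than_either(self):
        # 0.75 s event at RR=150 (2 cycles = 0.8 s): passes "either" (>=0.7 s),
        # fails "both" (needs >=0.8 s)
        flow, fs = synthetic_dip(dip_len=0.75, depth=0.97)
        breaths = analyze_flow(flow, fs)
        either = detect_apneas(flow, fs, breaths, baseline_rr=150.0,
                               cfg=ApneaScoringConfig(duration_rule="either"))
        both = detect_apneas(flow, fs, breaths, baseline_rr=150.0,
                             cfg=ApneaScoringConfig(duration_rule="both"))
        assert len(either) == 1
        assert both == []


class TestApneaIndex:
    @staticmethod
    def fake_events(n, stage):
        return [RespiratoryEvent("apnea", 10.0 * k, 1.0, stage, 95.0) for k in range(n)]

    def test_three_events_in_half_hour_give_index_six(self):
        hyp = Hypnogram([Stage.REM] * 360, source="external")  # 0.5 h REM
        assert apnea_index(self.fake_events(3, Stage.REM), hyp, Stage.REM) == 6.0

    def test_no_events_give_zero(self):
        hyp = Hypnogram([Stage.REM] * 360, source="external")
        assert apnea_index([], hyp, Stage.REM) == 0.0

    def test_doubling_stage_time_halves_index(self):
        ev = self.fake_events(4, Stage.REM)
        h1 = Hypnogram([Stage.REM] * 360, source="external")
        h2 = Hypnogram([Stage.REM] * 720, source="external")
        assert apnea_index(ev, h1, Stage.REM) == 2 * apnea_index(ev, h2, Stage.REM)

    def test_zero_stage_time_flagged(self):
        hyp = Hypnogram([Stage.NREM] * 100, source="external")
        with pytest.warns(UserWarning):
            assert np.isnan(apnea_index([], hyp, Stage.REM))

    def test_recovered_index_within_poisson_interval(self):
        (rec, truth), cfg = rem_recording_with_apneas(seed=52, duration_s=900.0, rate=24.0)
        ch = rec.get(ChannelRole.FLOW)
        breaths = analyze_flow(ch.samples, ch.sample_rate, hypnogram=truth.hypnogram_true)
        events = detect_apneas(ch.samples, ch.sample_rate, breaths,
                               hypnogram=truth.hypnogram_true)
        hyp = truth.hypnogram_true
        rem_h = hyp.stage_seconds(Stage.REM) / 3600.0
        idx = apnea_index(events, hyp, Stage.REM)
        lam = 24.0 * rem_h
        assert abs(idx * rem_h - lam) <= 1.96 * np.sqrt(lam) + 1


class TestDesaturations:
    def test_injected_deep_desat_scored_and_shallow_not(self):
        cfg = quiet_config(seed=53, duration_s=300.0)
        cfg.spo2.desat_depth_sd_pct = 0.0
        hyp = Hypnogram([Stage.REM] * int(300 / EPOCH_LEN_S), source="external")
        from somnoresp.synth import generate_breath_train

        _, _, _, truth = generate_breath_train(cfg, hyp)
        truth.apnea_events = [(60.0, 2.0, Stage.REM), (180.0, 2.0, Stage.REM)]
        cfg.spo2.desat_depth_mean_pct = 6.0
        deep = generate_spo2(truth, cfg, np.random.default_rng(0))
        breaths = []
        res = detect_desaturations(deep, cfg.sample_rate, hyp, breaths)
        assert len(res.events) == 2
        assert res.odi_per_h == pytest.approx(2 / (300 / 3600), rel=1e-9)

        truth.desat_events.clear()
        cfg.spo2.desat_depth_mean_pct = 3.0
        shallow = generate_spo2(truth, cfg, np.random.default_rng(0))
        res = detect_desaturations(shallow, cfg.sample_rate, hyp, breaths)
        assert res.events == []

    def test_wake_desats_excluded_from_odi(self):
        cfg = quiet_config(seed=54, duration_s=300.0)
        cfg.spo2.desat_depth_sd_pct = 0.0
        half = int(150 / EPOCH_LEN_S)
        hyp = Hypnogram([Stage.WAKE] * half + [Stage.NREM] * half, source="external")
        from somnoresp.synth import generate_breath_train

        _, _, _, truth = generate_breath_train(cfg, hyp)
        truth.apnea_events = [(60.0, 2.0, Stage.WAKE), (200.0, 2.0, Stage.NREM)]
        spo2 = generate_spo2(truth, cfg, np.random.default_rng(0))
        res = detect_desaturations(spo2, cfg.sample_rate, hyp, [])
        assert len(res.events) == 2  # both dips exist in the trace
        # but only the sleep-time dip counts: 1 event / 0.0417 h sleep
        assert res.odi_per_h == pytest.approx(1 / (150 / 3600), rel=1e-9)

    def test_empty_spo2_rejected(self):
        hyp = Hypnogram([Stage.NREM] * 10, source="external")
        with pytest.raises(ConfigurationError):
            detect_desaturations(np.zeros(0), 1000.0, hyp, [])
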