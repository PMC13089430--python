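"""Synthetic-data generator: geometry, calibration and determinism."""

import numpy as np
import pytest
from scipy import stats

from minisleep import synth
from minisleep.types import ART, MANDATORY_CHAR_STAGES, SimConfig, SubjectMeta

META = SubjectMeta("s0", "SIB", 30.0, "M", "famX")


class TestSampleHypnogram:
    def test_20min_segment_has_240_labels(self):
        cfg = SimConfig(record_duration=1200.0)
        hyp = synth.sample_hypnogram(cfg, META, 0)
        assert len(hyp) == 240
        assert hyp.duration == 1200.0

    def test_zero_rate_gives_constant_hypnogram(self):
        cfg = SimConfig(record_duration=3600.0, p_artifact=0.0,
                        transition_rate_target={"NT1": 0.0, "SIB": 0.0})
        hyp = synth.sample_hypnogram(cfg, META, 1)
        assert len(np.unique(hyp.labels)) == 1

    def test_transition_rate_calibrated_within_3_se(self):
        # 10 000 simulated minutes; switch events are i.i.d. per boundary so
        # the count is binomial(n_boundaries, rate*period/60)
        minutes = 10_000.0
        rate = 1.7
        cfg = SimConfig(record_duration=minutes * 60.0, p_artifact=0.0,
                        transition_rate_target={"NT1": rate, "SIB": rate})
        hyp = synth.sample_hypnogram(cfg, META, 2)
        n_trans = int((hyp.labels[1:] != hyp.labels[:-1]).sum())
        n_bound = len(hyp) - 1
        p = rate * cfg.period / 60.0
        se = np.sqrt(n_bound * p * (1 - p))
        assert abs(n_trans - n_bound * p) < 3 * se

    def test_duration_not_multiple_of_period_rejected(self):
        with pytest.raises(ValueError, match="multiple of period"):
            synth.sample_hypnogram(SimConfig(record_duration=1203.0), META, 0)

    def test_unreachable_rate_rejected(self):
        cfg = SimConfig(transition_rate_target={"NT1": 13.0, "SIB": 13.0})
        with pytest.raises(ValueError, match="unreachable"):
            synth.sample_hypnogram(cfg, META, 0)

    def test_char_flag_never_false_for_wake_and_n3(self):
        cfg = SimConfig(record_duration=7200.0, p_no_char=0.9)
        for seed in range(5):
            hyp = synth.sample_hypnogram(cfg, META, seed)
            mandatory = np.isin(hyp.labels, list(MANDATORY_CHAR_STAGES))
            assert hyp.char_flag[mandatory].all()

    def test_no_char_rate_matches_probability(self):
        cfg = SimConfig(record_duration=36_000.0, p_artifact=0.0)
        hyp = synth.sample_hypnogram(cfg, META, 3)
        sleepy = np.isin(hyp.labels, ["N1", "N2", "REM"])
        frac = (~hyp.char_flag[sleepy]).mean()
        n = int(sleepy.sum())
        se = np.sqrt(cfg.p_no_char * (1 - cfg.p_no_char) / n)
        assert abs(frac - cfg.p_no_char) < 4 * se

    def test_determinism(self):
        cfg = SimConfig(record_duration=3600.0)
        h1 = synth.sample_hypnogram(cfg, META, 42)
        h2 = synth.sample_hypnogram(cfg, META, 42)
        assert (h1.labels == h2.labels).all()
        assert (h1.char_flag == h2.char_flag).all()


class TestSegmentWindows:
    def _rng(self, seed=0):
        return np.random.default_rng(seed)

    def test_two_20min_segments_give_480_mini_epochs(self, subject):
        cfg = SimConfig(record_duration=3600.0, noise_scale=0.0)
        hyp = synth.sample_hypnogram(cfg, subject, 4)
        rec, _ = synth.synthesize_signals(hyp, cfg, 5, subject)
        rec.lights_off, rec.lights_on = cfg.lights_off, cfg.lights_on
        segs = synth.extract_segments(rec, hyp, 2, 20, 6)
        assert len(segs) == 2
        assert all(len(h) == 240 for _, h in segs)
        assert sum(len(h) for _, h in segs) == 480
        # non-overlap, both inside the lights window
        (r0, h0), (r1, h1) = segs
        assert h0.t0 + h0.duration <= h1.t0
        assert h0.t0 >= cfg.lights_off and h1.t0 + h1.duration <= cfg.lights_on

    def test_exact_fit_window_is_deterministic(self):
        starts = synth.select_segment_windows(
            n_epochs_total=480, period=5.0, lights_off=600.0, lights_on=1800.0,
            n_segments=1, segment_minutes=20, rng=self._rng())
        assert starts == [120]  # only one grid position: right at lights_off

    def test_too_small_window_rejected_with_available_minutes(self):
        with pytest.raises(ValueError, match="10.0 min available"):
            synth.select_segment_windows(480, 5.0, 600.0, 1200.0, 2, 20,
                                         self._rng())

    def test_uniform_placement_over_grid_positions(self):
        # 25-min lights window, 20-min segment -> 61 grid positions
        rng = self._rng(7)
        n_positions = 61
        counts = np.zeros(n_positions, int)
        for _ in range(2000):
            (s,) = synth.select_segment_windows(
                10_000, 5.0, 0.0, 1500.0, 1, 20, rng)
            counts[s] += 1
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.01


class TestSynthesizeSignals:
    def test_all_wake_plants_alpha_in_every_mini_epoch(self, subject):
        from minisleep import rules

        cfg = SimConfig(record_duration=300.0, p_artifact=0.0,
                        noise_scale=0.0,
                        transition_rate_target={"NT1": 0.0, "SIB": 0.0},
                        stage_prior={"W": 1.0, "N1": 0.0, "N2": 0.0,
                                     "N3": 0.0, "REM": 0.0})
        hyp = synth.sample_hypnogram(cfg, subject, 8)
        assert (hyp.labels == "W").all()
        rec, _ = synth.synthesize_signals(hyp, cfg, 9, subject)
        profiles = rules.detect_characteristics(rec, 5.0)
        assert all(p.alpha_fraction > 0.5 for p in profiles)

    def test_suppressed_mini_epochs_have_no_events(self, subject):
        cfg = SimConfig(record_duration=600.0, p_no_char=1.0, p_artifact=0.0,
                        noise_scale=0.0)
        hyp = synth.sample_hypnogram(cfg, subject, 10)
        _, events = synth.synthesize_signals(hyp, cfg, 11, subject)
        suppressed = set(np.nonzero(~hyp.char_flag)[0])
        for ev in events:
            assert int(ev.onset // 5.0) not in suppressed

    def test_events_lie_inside_matching_mini_epoch(self, clean_segment):
        rec, hyp, events = clean_segment
        stage_of_kind = {"ALPHA_RUN": "W", "DELTA_WAVE": "N3", "SEM": "N1",
                         "VERTEX": "N1", "SPINDLE": "N2", "KCOMPLEX": "N2",
                         "REM_EM": "REM"}
        for ev in events:
            i = int(ev.onset // hyp.period)
            assert ev.onset >= i * hyp.period - 1e-9
            assert ev.onset + ev.duration <= (i + 1) * hyp.period + 1e-9
            assert hyp.labels[i] == stage_of_kind[ev.kind]

    def test_unknown_stage_rejected(self, subject):
        cfg = SimConfig(record_duration=10.0)
        bad = synth.sample_hypnogram(cfg, subject, 0)
        bad.labels = np.array(["W", "XX"], dtype="<U3")
        with pytest.raises(ValueError):
            synth.synthesize_signals(bad, cfg, 0, subject)


class TestBuildDataset:
    def test_default_geometry_totals_48000(self, tmp_path):
        cfg = SimConfig(seed=1)
        man = synth.build_dataset(cfg, tmp_path / "d", include_signals=False)
        assert len(man.records) == 100
        assert man.n_mini_epochs == 48_000
        assert all(len(r["segments"]) == 2 for r in man.records)

    def test_same_seed_identical_labels(self, tmp_path):
        from minisleep import iohub

        cfg = SimConfig(n_recordings=4, record_duration=3600.0, seed=9)
        m1 = synth.build_dataset(cfg, tmp_path / "a", include_signals=False)
        m2 = synth.build_dataset(cfg, tmp_path / "b", include_signals=False)
        for r1, r2 in zip(m1.records, m2.records):
            for s1, s2 in zip(r1["segments"], r2["segments"]):
                h1 = iohub.read_hypnogram(tmp_path / "a" / s1["hypnogram"])
                h2 = iohub.read_hypnogram(tmp_path / "b" / s2["hypnogram"])
                assert (h1.labels == h2.labels).all()
                assert h1.t0 == h2.t0

    def test_output_collision_refused(self, tmp_path):
        cfg = SimConfig(n_recordings=2, record_duration=3600.0)
        synth.build_dataset(cfg, tmp_path / "d", include_signals=False)
        with pytest.raises(FileExistsError):
            synth.build_dataset(cfg, tmp_path / "d", include_signals=False)
        synth.build_dataset(cfg, tmp_path / "d", overwrite=True,
                            include_signals=False)
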