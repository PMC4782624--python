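import numpy as np
import pytest

from pcgkit import (
    AudioSignal,
    EventInterval,
    FDProfile,
    NoiseSpec,
    SynthSpec,
    add_noise,
    detect_events,
    extract_cycles,
    fd_profile,
    generate,
    label_events,
    segment_signal,
)


def make_profile(values, fs=1000.0, window_len=50, hop=10):
    values = np.asarray(values, dtype=float)
    starts = np.arange(len(values)) * hop
    return FDProfile(values=values, window_len=window_len, hop=hop, fs=fs, start_indices=starts)


class TestDetectEvents:
    def test_no_threshold_crossing_gives_empty(self):
        prof = make_profile([1.0, 1.1, 1.0, 1.1] * 5)
        assert detect_events(prof, k_sigma=3.0) == []

    def test_runs_map_back_to_sample_coordinates(self):
        # one run of 10 windows starting at window 5: samples [50, 50+9*10+50)
        v = np.ones(30)
        v[5:15] = 2.0
        events = detect_events(make_profile(v), k_sigma=0.5, min_event_s=0.0, merge_gap_s=0.0)
        assert len(events) == 1
        assert events[0].start_sample == 50
        assert events[0].end_sample == 14 * 10 + 50

    def test_close_runs_merge(self):
        # two runs separated by a 10 ms gap (< 30 ms merge gap)
        v = np.ones(40)
        v[5:10] = 2.0
        v[11:16] = 2.0  # gap: one window = 10 samples = 10 ms at 1 kHz
        events = detect_events(make_profile(v), min_event_s=0.0, merge_gap_s=0.03)
        assert len(events) == 1

    def test_short_runs_dropped(self):
        v = np.ones(40)
        v[5:7] = 2.0  # run spans 50+10 = 60 samples = 60 ms
        assert detect_events(make_profile(v), min_event_s=0.1, merge_gap_s=0.0) == []
        assert len(detect_events(make_profile(v), min_event_s=0.05, merge_gap_s=0.0)) == 1

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_events(make_profile([]))


class TestLabelEvents:
    @staticmethod
    def events_from_gaps(gaps_s, fs=8000.0, event_s=0.08):
        events = []
        t = 0.0
        for g in [0.0] + list(gaps_s):
            t += g
            events.append(EventInterval(int(t * fs), int((t + event_s) * fs)))
            t += event_s
        return events

    def test_short_gap_first_labels_s1_first(self):
        events = self.events_from_gaps([0.30, 0.50, 0.30, 0.50, 0.30])
        kinds = [e.kind for e in label_events(events, 8000.0)]
        assert kinds == ["S1", "S2", "S1", "S2", "S1", "S2"]

    def test_long_gap_first_flips_phase(self):
        events = self.events_from_gaps([0.50, 0.30, 0.50, 0.30, 0.50])
        kinds = [e.kind for e in label_events(events, 8000.0)]
        assert kinds == ["S2", "S1", "S2", "S1", "S2", "S1"]

    def test_fewer_than_three_events_unknown(self):
        events = self.events_from_gaps([0.30])
        assert all(e.kind == "unknown" for e in label_events(events, 8000.0))

    def test_synthetic_labels_all_correct(self, clean_record):
        sig, anns = clean_record
        events = label_events(detect_events(fd_profile(sig)), sig.fs)
        # match each detected event to the nearest planted event of its label
        truth = {(a.s1.start_sample, "S1") for a in anns} | {
            (a.s2.start_sample, "S2") for a in anns
        }
        for ev in events[: 2 * len(anns)]:
            nearest = min(truth, key=lambda t: abs(t[0] - ev.start_sample))
            assert ev.kind == nearest[1]


class TestExtractCycles:
    def test_duration_arithmetic(self):
        fs = 8000.0
        sig = AudioSignal(np.ones(8001), fs)
        events = [
            EventInterval(0, 800, "S1"),
            EventInterval(3200, 3840, "S2"),
            EventInterval(7200, 8000, "S1"),
        ]
        [(ann, seg)] = extract_cycles(sig, events)
        assert ann.d_s1 == pytest.approx(0.1)
        assert ann.d_sys == pytest.approx(0.3)
        assert ann.d_s2 == pytest.approx(0.08)
        assert ann.d_dia == pytest.approx(0.42)
        assert ann.cycle_duration == pytest.approx(0.9)
        assert len(seg) == 7200

    def test_single_s1_gives_no_cycle(self):
        sig = AudioSignal(np.ones(8000), 8000.0)
        events = [EventInterval(0, 800, "S1"), EventInterval(3200, 3840, "S2")]
        assert extract_cycles(sig, events) == []

    def test_unlabeled_rejected(self):
        sig = AudioSignal(np.ones(8000), 8000.0)
        with pytest.raises(ValueError, match="labeled"):
            extract_cycles(sig, [EventInterval(0, 800, "unknown")])

    def test_partition_identity_on_synthetic(self, clean_record):
        sig, _ = clean_record
        for ann, seg in segment_signal(sig):
            spans = (
                (ann.s1.end_sample - ann.s1.start_sample)
                + (ann.systole[1] - ann.systole[0])
                + (ann.s2.end_sample - ann.s2.start_sample)
                + (ann.diastole[1] - ann.diastole[0])
            )
            assert spans == ann.end_sample - ann.start_sample
            assert len(seg) == spans
            assert ann.cycle_duration == pytest.approx(
                ann.d_s1 + ann.d_sys + ann.d_s2 + ann.d_dia, abs=1e-12
            )
            assert ann.d_sys < ann.d_dia


class TestRecovery:
    def test_clean_recovery_at_75bpm(self, clean_record):
        sig, anns = clean_record
        cycles = segment_signal(sig)
        assert len(cycles) == len(anns)
        onsets = np.array([c[0].s1.start_sample for c in cycles])
        planted = np.array([a.s1.start_sample for a in anns])
        assert np.max(np.abs(onsets - planted)) / sig.fs <= 0.020

    def test_mean_cycle_duration_tracks_heart_rate(self):
        sig, _ = generate(SynthSpec(duration_s=8.3, heart_rate_bpm=75.0, seed=3))
        cycles = segment_signal(sig)
        mean_dur = np.mean([c[0].cycle_duration for c in cycles])
        assert mean_dur == pytest.approx(0.8, rel=0.05)

    def test_onset_error_degrades_with_noise(self):
        """Median onset error must not improve when SNR drops clean -> 0 dB."""

        def median_err(snr_db, n_rep=20):
            errs = []
            for seed in range(n_rep):
                sig, anns = generate(
                    SynthSpec(duration_s=4 * 60 / 90 + 0.3, heart_rate_bpm=90.0, seed=seed)
                )
                if snr_db is not None:
                    sig = add_noise(sig, NoiseSpec(snr_db=snr_db, seed=1000 + seed))
                cycles = segment_signal(sig)
                planted = np.array([a.s1.start_sample for a in anns])
                for ann, _ in cycles:
                    errs.append(np.min(np.abs(planted - ann.s1.start_sample)) / 8000.0)
            return np.median(errs) if errs else np.inf

        assert median_err(0.0) >= median_err(None)
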