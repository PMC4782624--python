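"""Cardiac cycle extraction from the fractal-dimension profile.

S1 and S2 transients raise the windowed Katz FD above the quiet-interval
baseline, so events are detected as contiguous runs of above-threshold FD
windows (threshold = mean + k_sigma * std of the profile). Runs closer
than a merge gap are fused, runs shorter than a minimum event length are
dropped, and the surviving intervals are labeled S1/S2 using the
physiological rule that systole (S1 -> S2) is shorter than diastole
(S2 -> next S1). One cardiac cycle spans S1 onset to the next S1 onset and
partitions exactly into S1, systole, S2 and diastole:

    C_d = d_s1 + d_sys + d_s2 + d_dia

All intervals are half-open ``[start, end)`` in 0-based sample
coordinates; durations are ``(end - start) / fs`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fractal import FDProfile
from .io import AudioSignal

__all__ = [
    "EventInterval",
    "CycleAnnotation",
    "detect_events",
    "label_events",
    "extract_cycles",
]


@dataclass(frozen=True)
class EventInterval:
    """A detected heart-sound event, half-open in sample coordinates."""

    start_sample: int
    end_sample: int
    kind: str = "unknown"  # "S1" | "S2" | "unknown"

    def __post_init__(self) -> None:
        if not self.start_sample < self.end_sample:
            raise ValueError("event must satisfy start_sample < end_sample")


@dataclass(frozen=True)
class CycleAnnotation:
    """One cardiac cycle: S1, systole, S2, diastole, chained without gaps.

    Boundaries are sample indices; durations are seconds. By construction
    ``cycle_duration == d_s1 + d_sys + d_s2 + d_dia`` and the four sample
    spans tile the S1-onset-to-next-S1-onset interval exactly.
    """

    s1: EventInterval
    systole: tuple[int, int]
    s2: EventInterval
    diastole: tuple[int, int]
    d_s1: float
    d_sys: float
    d_s2: float
    d_dia: float
    cycle_duration: float

    def __post_init__(self) -> None:
        if self.s1.end_sample != self.systole[0]:
            raise ValueError("end of S1 must merge with beginning of systole")
        if self.systole[1] != self.s2.start_sample:
            raise ValueError("end of systole must merge with beginning of S2")
        if self.s2.end_sample != self.diastole[0]:
            raise ValueError("end of S2 must merge with beginning of diastole")

    @property
    def start_sample(self) -> int:
        return self.s1.start_sample

    @property
    def end_sample(self) -> int:
        return self.diastole[1]


def detect_events(
    profile: FDProfile,
    k_sigma: float = 0.5,
    min_event_s: float = 0.04,
    merge_gap_s: float = 0.03,
) -> list[EventInterval]:
    """Detect heart-sound events as above-threshold runs of the FD profile.

    Windows with FD >= mean + k_sigma*std form candidate runs; runs whose
    sample gap is below *merge_gap_s* are merged (a burst split by one dip
    stays one event), then events shorter than *min_event_s* are dropped.
    Window indices map back to samples via the profile's start indices: an
    event spans the first above-threshold window's start to the last
    above-threshold window's start plus the window length.

    Returns an empty list when no window crosses the threshold.
    """
    v = profile.values
    if len(v) == 0:
        raise ValueError("empty FD profile")
    thr = float(np.mean(v) + k_sigma * np.std(v))
    mask = v >= thr
    if not mask.any():
        return []

    # contiguous runs of True in window-index space
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    run_starts = np.flatnonzero(padded == 1)
    run_ends = np.flatnonzero(padded == -1) - 1  # inclusive window index

    starts = profile.start_indices[run_starts]
    ends = profile.start_indices[run_ends] + profile.window_len

    merge_gap = int(round(merge_gap_s * profile.fs))
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])

    min_len = int(round(min_event_s * profile.fs))
    return [
        EventInterval(s, e) for s, e in merged if e - s >= min_len
    ]


def label_events(events: list[EventInterval], fs: float) -> list[EventInterval]:
    """Assign S1/S2 labels using the systole-shorter-than-diastole rule.

    The gaps between consecutive events alternate systole, diastole,
    systole, ... For each adjacent gap pair the shorter gap is taken as
    systole, which fixes the parity of the S1 events; a majority vote over
    all gap pairs makes the labeling robust to a single missed or spurious
    event. With fewer than 3 events the alternation cannot be anchored and
    every event is returned with ``kind="unknown"``.
    """
    if len(events) < 3:
        return [replace(e, kind="unknown") for e in events]
    gaps = np.array(
        [events[i + 1].start_sample - events[i].end_sample for i in range(len(events) - 1)],
        dtype=np.float64,
    )
    votes = [0, 0]  # votes[p]: events at index parity p are S1
    for i in range(len(gaps) - 1):
        if gaps[i] < gaps[i + 1]:
            votes[i % 2] += 1  # gap i is systole -> event i is S1
        elif gaps[i] > gaps[i + 1]:
            votes[(i + 1) % 2] += 1  # gap i+1 is systole -> event i+1 is S1
    s1_parity = 0 if votes[0] >= votes[1] else 1
    return [
        replace(e, kind="S1" if i % 2 == s1_parity else "S2")
        for i, e in enumerate(events)
    ]


def extract_cycles(
    signal: AudioSignal, labeled_events: list[EventInterval]
) -> list[tuple[CycleAnnotation, np.ndarray]]:
    """Assemble cardiac cycles from labeled events.

    Each consecutive pair of S1 events with exactly one S2 between them
    yields one cycle: the S1 interval, systole up to S2 onset, the S2
    interval, and diastole up to the next S1 onset. The waveform segment
    ``samples[S1 start : next S1 start)`` is returned alongside the
    annotation. A trailing S1 with no successor closes no cycle.

    Raises
    ------
    ValueError
        If any event is unlabeled.
    """
    if any(e.kind == "unknown" for e in labeled_events):
        raise ValueError("events must be labeled S1/S2 before cycle extraction")
    fs = signal.fs
    cycles: list[tuple[CycleAnnotation, np.ndarray]] = []
    s1_positions = [i for i, e in enumerate(labeled_events) if e.kind == "S1"]
    for a, b in zip(s1_positions, s1_positions[1:]):
        between = labeled_events[a + 1 : b]
        if len(between) != 1 or between[0].kind != "S2":
            continue  # malformed span (missed or doubled event): skip
        s1, s2 = labeled_events[a], between[0]
        next_s1 = labeled_events[b]
        if not (s1.end_sample < s2.start_sample and s2.end_sample < next_s1.start_sample):
            continue
        ann = CycleAnnotation(
            s1=s1,
            systole=(s1.end_sample, s2.start_sample),
            s2=s2,
            diastole=(s2.end_sample, next_s1.start_sample),
            d_s1=(s1.end_sample - s1.start_sample) / fs,
            d_sys=(s2.start_sample - s1.end_sample) / fs,
            d_s2=(s2.end_sample - s2.start_sample) / fs,
            d_dia=(next_s1.start_sample - s2.end_sample) / fs,
            cycle_duration=(
                (s1.end_sample - s1.start_sample)
                + (s2.start_sample - s1.end_sample)
                + (s2.end_sample - s2.start_sample)
                + (next_s1.start_sample - s2.end_sample)
            )
            / fs,
        )
        segment = signal.samples[s1.start_sample : next_s1.start_sample]
        cycles.append((ann, segment))
    return cycles


def segment_signal(
    signal: AudioSignal,
    window_s: float = 0.05,
    overlap: float = 0.99,
    k_sigma: float = 0.5,
    min_event_s: float = 0.04,
    merge_gap_s: float = 0.03,
) -> list[tuple[CycleAnnotation, np.ndarray]]:
    """Full segmentation chain: FD profile -> events -> labels -> cycles.

    Convenience wrapper; returns an empty list when too few events are
    found to label.
    """
    from .fractal import fd_profile

    profile = fd_profile(signal, window_s=window_s, overlap=overlap)
    events = detect_events(
        profile, k_sigma=k_sigma, min_event_s=min_event_s, merge_gap_s=merge_gap_s
    )
    labeled = label_events(events, signal.fs)
    if any(e.kind == "unknown" for e in labeled):
        return []
    return extract_cycles(signal, labeled)
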