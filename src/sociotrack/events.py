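"""Behavioral event primitives: gap-corrected label series, bouts,
intervals, transitions, compartment occupancy.

The hinge between tracking and analytics is the per-frame label series over
{none, stim1, stim2}.  Raw series are first gap-corrected: any interruption
of contact with a given stimulus shorter than 0.5 s (strictly, i.e. < 15
frames at 30 fps) is not considered to break the investigation bout, unless
the interruption contains a visit to the other stimulus.  Bouts, same-
stimulus intervals and between-stimulus transitions are then read off the
corrected series.  All times are frame counts / frame_rate, in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

NONE, STIM1, STIM2 = 0, 1, 2
LABEL_NAMES = {NONE: "none", STIM1: "stim1", STIM2: "stim2"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}


@dataclass(frozen=True)
class LabelSeries:
    """Per-frame investigation labels (codes 0=none, 1=stim1, 2=stim2)."""

    labels: np.ndarray
    frame_rate: float
    corrected: bool = False

    def __post_init__(self):
        arr = np.ascontiguousarray(self.labels, dtype=np.int8)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not np.isin(arr, (NONE, STIM1, STIM2)).all():
            raise ValueError("labels must be in {0, 1, 2}")
        object.__setattr__(self, "labels", arr)

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def total_time(self, stimulus: int) -> float:
        return int(np.count_nonzero(self.labels == stimulus)) / self.frame_rate


@dataclass(frozen=True)
class Bout:
    """Maximal contiguous investigation of one stimulus, [start_s, end_s)."""

    stimulus: int
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Interval:
    """Gap between consecutive bouts on the same stimulus (> gap_merge_s)."""

    stimulus: int
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Transition:
    """Start of a bout on a different stimulus than the previous bout."""

    time_s: float
    from_stimulus: int
    to_stimulus: int


def _runs(labels: np.ndarray):
    """(value, start, stop) for each maximal run; stop is exclusive."""
    n = labels.size
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [n]))
    return [(int(labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def correct_gaps(series: LabelSeries, gap_merge_s: float | None = 0.5,
                 allow_cross_stimulus_merge: bool = False) -> LabelSeries:
    """Merge sub-threshold interruptions of contact with a stimulus.

    A maximal run of frames not labeled ``s``, strictly shorter than
    ``gap_merge_s`` and flanked on both sides by ``s``, is relabeled ``s``.
    By default a run containing any other-stimulus frame is left untouched
    (a visit to the other stimulus always breaks the bout); set
    ``allow_cross_stimulus_merge`` to relax this for sensitivity analysis.
    """
    if series.corrected:
        raise ValueError("series is already gap-corrected")
    if gap_merge_s is None:
        return replace(series, corrected=True)
    out = series.labels.copy()
    max_gap_frames = gap_merge_s * series.frame_rate  # strict: run < this
    for stim in (STIM1, STIM2):
        other = STIM2 if stim == STIM1 else STIM1
        # gaps are maximal runs of non-stim frames (may span several raw
        # runs, e.g. none/other/none), flanked by stim on both sides
        is_stim = (out == stim).view(np.int8)
        for val, a, b in _runs(is_stim):
            if val == 1:
                continue
            if a == 0 or b == is_stim.size:
                continue
            seg = out[a:b]
            if not allow_cross_stimulus_merge and np.any(seg == other):
                continue
            if (b - a) < max_gap_frames:
                out[a:b] = stim
    return LabelSeries(out, series.frame_rate, corrected=True)


def extract_bouts(series: LabelSeries) -> list[Bout]:
    """One Bout per maximal run of stim1 or stim2 frames."""
    if not series.corrected:
        raise ValueError("extract_bouts requires a gap-corrected series")
    fps = series.frame_rate
    return [Bout(val, a / fps, b / fps)
            for val, a, b in _runs(series.labels) if val != NONE]


def extract_intervals(bouts: list[Bout], gap_merge_s: float = 0.5,
                      exclude_cross_stimulus: bool = False) -> list[Interval]:
    """Gaps between consecutive same-stimulus bouts, strictly > gap_merge_s.

    The span between two bouts of one stimulus may contain bouts of the
    other stimulus; these are included by default (an interval measures how
    long the animal stayed away from that particular stimulus).  Set
    ``exclude_cross_stimulus`` to drop spans interrupted by the other
    stimulus.
    """
    out: list[Interval] = []
    for stim in (STIM1, STIM2):
        mine = [b for b in bouts if b.stimulus == stim]
        for prev, nxt in zip(mine, mine[1:]):
            span = nxt.start_s - prev.end_s
            if span <= gap_merge_s:
                continue
            if exclude_cross_stimulus and any(
                b.stimulus != stim and b.start_s >= prev.end_s
                and b.end_s <= nxt.start_s for b in bouts
            ):
                continue
            out.append(Interval(stim, prev.end_s, nxt.start_s))
    out.sort(key=lambda iv: (iv.start_s, iv.stimulus))
    return out


def extract_transitions(bouts: list[Bout]) -> list[Transition]:
    """A Transition at the start of every bout whose stimulus differs from
    the immediately preceding bout's stimulus.  The first bout is never a
    transition."""
    out: list[Transition] = []
    for prev, nxt in zip(bouts, bouts[1:]):
        if nxt.stimulus != prev.stimulus:
            out.append(Transition(nxt.start_s, prev.stimulus, nxt.stimulus))
    return out


def compartment_occupancy(track, config) -> dict[str, float]:
    """Seconds spent in each compartment, by centroid point-in-polygon.

    Invalid frames contribute to neither compartment; frames whose centroid
    sits exactly on the shared edge go to the lower-indexed compartment.
    Returns ``{compartment_name: seconds, "out": seconds}`` where "out"
    counts valid frames outside both compartments.
    """
    from shapely import prepared
    from shapely.geometry import Point

    polys = config.compartment_polys()
    names = config.compartment_names
    preps = [prepared.prep(p) for p in polys]
    counts = [0] * len(polys)
    out_count = 0
    for obs in track.observations:
        if not obs.valid:
            continue
        pt = Point(obs.centroid)
        for i, pp in enumerate(preps):
            # covers() includes the boundary; first (lower-index) wins
            if pp.intersects(pt):
                counts[i] += 1
                break
        else:
            out_count += 1
    fps = config.frame_rate
    result = {name: c / fps for name, c in zip(names, counts)}
    result["out"] = out_count / fps
    return result


def labels_from_track(track) -> LabelSeries:
    """Raw (uncorrected) label series from a TrackingResult."""
    codes = np.array([obs.contact for obs in track.observations], dtype=np.int8)
    return LabelSeries(codes, track.config.frame_rate, corrected=False)


def bouts_to_frame(bouts: list[Bout]):
    import pandas as pd
    return pd.DataFrame(
        [(LABEL_NAMES[b.stimulus], b.start_s, b.end_s, b.duration_s)
         for b in bouts],
        columns=["stimulus", "start_s", "end_s", "duration_s"],
    )


def intervals_to_frame(intervals: list[Interval]):
    import pandas as pd
    return pd.DataFrame(
        [(LABEL_NAMES[iv.stimulus], iv.start_s, iv.end_s, iv.duration_s)
         for iv in intervals],
        columns=["stimulus", "start_s", "end_s", "duration_s"],
    )


def transitions_to_frame(transitions: list[Transition]):
    import pandas as pd
    return pd.DataFrame(
        [(t.time_s, LABEL_NAMES[t.from_stimulus], LABEL_NAMES[t.to_stimulus])
         for t in transitions],
        columns=["time_s", "from", "to"],
    )
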