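"""Per-session and group-level behavioral metrics.

Everything a social-preference (SP) or social-novelty-preference (SNP)
session yields once bouts and transitions exist: time-binned investigation
curves, the relative duration of investigation (RDI) preference index,
bout- and interval-duration distributions, transition dynamics, the
exploration/interaction phase split, and open-field measures (distance
traveled, center/periphery ratio).  Group pooling gives means +/- SEM and
Pearson correlations across subjects.

RDI convention: ``rdi(d_a, d_b) = (d_a - d_b) / (d_a + d_b)`` signed by
default, so the sign carries the direction of preference (the first-listed
stimulus minus the second); the unsigned variant |d_a - d_b| / (d_a + d_b)
is available where a magnitude-only index is wanted.  Both live in [-1, 1]
and are undefined (None) when the animal investigated neither stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .events import (STIM1, STIM2, LABEL_NAMES, Bout, Interval, Transition)

STIMULI = (STIM1, STIM2)


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# binned investigation time

def binned_time(bouts: list[Bout], session_length_s: float,
                bin_width_s: float = 20.0) -> dict[int, np.ndarray]:
    """Per-stimulus investigation time apportioned to half-open time bins
    [k*w, (k+1)*w) by exact temporal overlap.

    If the session length is not a multiple of the bin width the last bin
    is truncated (it still receives its overlap).
    """
    if bin_width_s <= 0:
        raise InputError("bin_width_s must be > 0")
    n_bins = int(np.ceil(session_length_s / bin_width_s - 1e-12))
    edges = np.arange(n_bins + 1) * bin_width_s
    edges[-1] = min(edges[-1], session_length_s)
    out = {s: np.zeros(n_bins) for s in STIMULI}
    for b in bouts:
        lo = np.minimum(np.maximum(b.start_s, edges[:-1]), edges[1:])
        hi = np.minimum(np.maximum(b.end_s, edges[:-1]), edges[1:])
        out[b.stimulus] += hi - lo
    return out


# ---------------------------------------------------------------------------
# RDI

def rdi(d_a: float, d_b: float, signed: bool = True) -> float | None:
    """Relative duration of investigation: difference of the two stimulus
    investigation durations over their sum; None when both are zero."""
    if d_a < 0 or d_b < 0:
        raise ValueError("investigation durations must be non-negative")
    total = d_a + d_b
    if total == 0:
        return None
    value = (d_a - d_b) / total
    return value if signed else abs(value)


def rdi_by_intervals(intervals: list[Interval],
                     prolonged_threshold_s: float = 20.0,
                     signed: bool = True) -> float | None:
    """RDI computed from per-stimulus total time spent in prolonged
    (> prolonged_threshold_s) intervals.  Lower prolonged-interval time on
    a stimulus means the animal kept returning to it, so this index runs
    opposite to the time-based RDI for a preferred stimulus."""
    totals = {s: 0.0 for s in STIMULI}
    for iv in intervals:
        if iv.duration_s > prolonged_threshold_s:
            totals[iv.stimulus] += iv.duration_s
    return rdi(totals[STIM1], totals[STIM2], signed=signed)


# ---------------------------------------------------------------------------
# duration histograms

def _categorize(duration: float, edges: list[float]) -> int:
    """Category index under (0, e1], (e1, e2], ..., (e_last, inf)."""
    for i, e in enumerate(edges):
        if duration <= e:
            return i
    return len(edges)


def bout_duration_histogram(bouts: list[Bout],
                            edges_s: list[float] = (6.0, 12.5, 19.0)
                            ) -> dict[int, np.ndarray]:
    """Total investigation time per stimulus per bout-duration category.

    Default categories: short (<= 6 s), two middle bins, long (> 19 s);
    each bout's full duration goes to the category containing it.
    """
    edges = list(edges_s)
    if any(b >= a for a, b in zip(edges[1:], edges[:-1])) or \
            any(e <= 0 for e in edges):
        raise InputError("edges must be positive and strictly increasing")
    out = {s: np.zeros(len(edges) + 1) for s in STIMULI}
    for b in bouts:
        out[b.stimulus][_categorize(b.duration_s, edges)] += b.duration_s
    return out


def interval_duration_histogram(intervals: list[Interval],
                                edges_s: list[float] = (10.0, 20.0)
                                ) -> dict[int, dict[str, np.ndarray]]:
    """Counts and total time per stimulus per interval-duration category
    (default: short <= 10 s, middle, long > 20 s)."""
    edges = list(edges_s)
    if any(b >= a for a, b in zip(edges[1:], edges[:-1])) or \
            any(e <= 0 for e in edges):
        raise InputError("edges must be positive and strictly increasing")
    out = {s: {"count": np.zeros(len(edges) + 1),
               "time": np.zeros(len(edges) + 1)} for s in STIMULI}
    for iv in intervals:
        k = _categorize(iv.duration_s, edges)
        out[iv.stimulus]["count"][k] += 1
        out[iv.stimulus]["time"][k] += iv.duration_s
    return out


# ---------------------------------------------------------------------------
# transitions and phases

def transition_dynamics(transitions: list[Transition],
                        session_length_s: float,
                        bin_width_s: float = 20.0,
                        windows: dict[str, tuple[float, float]] | None = None
                        ) -> dict:
    """Per-bin transition counts plus per-window totals.

    Windows default to the exploration/interaction split: [0, 120) and
    [120, session_end).  All boundaries are half-open.
    """
    if windows is None:
        windows = {"exploration": (0.0, 120.0),
                   "interaction": (120.0, session_length_s)}
    times = np.array([t.time_s for t in transitions], dtype=float)
    n_bins = int(np.ceil(session_length_s / bin_width_s - 1e-12))
    edges = np.arange(n_bins + 1) * bin_width_s
    counts, _ = np.histogram(times, bins=edges)
    window_totals = {
        name: int(np.count_nonzero((times >= a) & (times < b)))
        for name, (a, b) in windows.items()
    }
    return {"bin_counts": counts, "bin_edges": edges,
            "window_totals": window_totals,
            "total": len(transitions)}


def phase_summary(bouts: list[Bout], transitions: list[Transition],
                  exploration_window: tuple[float, float] = (0.0, 120.0),
                  interaction_window: tuple[float, float] = (120.0, 300.0),
                  short_max_s: float = 6.0, long_min_s: float = 19.0,
                  bin_width_s: float = 20.0) -> dict[str, dict]:
    """Per-phase statistics for the exploration/interaction split.

    Bouts are assigned to the window containing their start (the bout's
    duration is itself the analyzed quantity, so bouts are not split).
    Short bouts are strictly < short_max_s, long strictly > long_min_s,
    middle is the closed band in between, so the three classes partition
    the bout time of each window.
    """
    (e0, e1), (i0, i1) = exploration_window, interaction_window
    if max(e0, i0) < min(e1, i1):
        raise InputError("phase windows must be disjoint")
    windows = {"exploration": exploration_window,
               "interaction": interaction_window}
    ttimes = np.array([t.time_s for t in transitions], dtype=float)
    out: dict[str, dict] = {}
    for name, (a, b) in windows.items():
        in_win = [bt for bt in bouts if a <= bt.start_s < b]
        stats_ = {"transitions": int(np.count_nonzero((ttimes >= a) &
                                                      (ttimes < b))),
                  "transitions_per_bin": float(
                      np.count_nonzero((ttimes >= a) & (ttimes < b))
                      / max((b - a) / bin_width_s, 1e-12))}
        for s in STIMULI:
            mine = [bt for bt in in_win if bt.stimulus == s]
            short = sum(bt.duration_s for bt in mine
                        if bt.duration_s < short_max_s)
            long_ = sum(bt.duration_s for bt in mine
                        if bt.duration_s > long_min_s)
            mid = sum(bt.duration_s for bt in mine
                      if short_max_s <= bt.duration_s <= long_min_s)
            stats_[LABEL_NAMES[s]] = {"short_s": short, "middle_s": mid,
                                      "long_s": long_,
                                      "total_s": short + mid + long_}
        out[name] = stats_
    return out


def bout_class_timecourse(bouts: list[Bout], session_length_s: float,
                          bin_width_s: float = 60.0,
                          short_max_s: float = 6.0,
                          long_min_s: float = 19.0) -> dict:
    """Time in short (< short_max_s) and long (> long_min_s) bouts per
    time bin per stimulus, bouts assigned to bins by start time."""
    n_bins = int(np.ceil(session_length_s / bin_width_s - 1e-12))
    out = {s: {"short": np.zeros(n_bins), "long": np.zeros(n_bins)}
           for s in STIMULI}
    for b in bouts:
        k = min(int(b.start_s / bin_width_s), n_bins - 1)
        if b.duration_s < short_max_s:
            out[b.stimulus]["short"][k] += b.duration_s
        elif b.duration_s > long_min_s:
            out[b.stimulus]["long"][k] += b.duration_s
    return out


# ---------------------------------------------------------------------------
# open field

def open_field_metrics(track, config) -> dict:
    """Total distance traveled by the body center (cm) and the
    center/periphery time ratio.

    Distance sums Euclidean steps between consecutive valid frames; steps
    spanning invalid frames are skipped.  The center region is the centered
    rectangle with 25% of the arena area (sides scaled by 1/2); the ratio
    is inner time / outer time, None when outer time is zero.
    """
    pts = []
    prev_idx = None
    dist_px = 0.0
    for obs in track.observations:
        if not obs.valid:
            continue
        if prev_idx is not None and obs.frame_index == prev_idx + 1:
            dist_px += float(np.hypot(obs.centroid[0] - prev_pt[0],
                                      obs.centroid[1] - prev_pt[1]))
        prev_idx, prev_pt = obs.frame_index, obs.centroid
        pts.append(obs.centroid)
    total_distance_cm = dist_px / config.px_per_cm

    x, y, w, h = config.arena_rect
    cx0, cy0 = x + w / 4.0, y + h / 4.0
    cx1, cy1 = x + 3 * w / 4.0, y + 3 * h / 4.0
    inner = outer = 0
    for px, py in pts:
        if cx0 <= px <= cx1 and cy0 <= py <= cy1:
            inner += 1
        else:
            outer += 1
    fps = config.frame_rate
    ratio = (inner / outer) if outer > 0 else None
    return {"total_distance_cm": total_distance_cm,
            "center_time_s": inner / fps,
            "periphery_time_s": outer / fps,
            "center_periphery_ratio": ratio}


# ---------------------------------------------------------------------------
# session summary + group pooling

@dataclass
class SessionSummary:
    """All per-animal metrics for one SP/SNP (or open-field) session."""

    session: str
    test_type: str
    session_length_s: float
    bin_width_s: float
    total_time: dict[int, float]
    binned: dict[int, np.ndarray]
    rdi_time: float | None
    rdi_intervals: float | None
    bout_hist: dict[int, np.ndarray]
    interval_hist: dict[int, dict[str, np.ndarray]]
    transition_bins: np.ndarray
    total_transitions: int
    phases: dict[str, dict]
    compartment_time: dict[str, float] = field(default_factory=dict)
    open_field: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row: dict = {"session": self.session, "test_type": self.test_type,
                     "total_transitions": self.total_transitions,
                     "rdi_time": self.rdi_time,
                     "rdi_intervals": self.rdi_intervals}
        for s in STIMULI:
            row[f"time_{LABEL_NAMES[s]}_s"] = self.total_time[s]
        for name, ph in self.phases.items():
            row[f"transitions_{name}"] = ph["transitions"]
            for s in STIMULI:
                for k in ("short_s", "middle_s", "long_s"):
                    row[f"{name}_{LABEL_NAMES[s]}_{k}"] = ph[LABEL_NAMES[s]][k]
        for k, v in self.open_field.items():
            row[k] = v
        for k, v in self.compartment_time.items():
            row[f"compartment_{k}_s"] = v
        return row


def summarize_session(bouts: list[Bout], intervals: list[Interval],
                      transitions: list[Transition],
                      session_length_s: float, bin_width_s: float = 20.0,
                      session: str = "session", test_type: str = "SP",
                      compartment_time: dict | None = None,
                      open_field: dict | None = None) -> SessionSummary:
    total = {s: sum(b.duration_s for b in bouts if b.stimulus == s)
             for s in STIMULI}
    td = transition_dynamics(transitions, session_length_s, bin_width_s)
    return SessionSummary(
        session=session, test_type=test_type,
        session_length_s=session_length_s, bin_width_s=bin_width_s,
        total_time=total,
        binned=binned_time(bouts, session_length_s, bin_width_s),
        rdi_time=rdi(total[STIM1], total[STIM2]),
        rdi_intervals=rdi_by_intervals(intervals),
        bout_hist=bout_duration_histogram(bouts),
        interval_hist=interval_duration_histogram(intervals),
        transition_bins=td["bin_counts"],
        total_transitions=td["total"],
        phases=phase_summary(
            bouts, transitions,
            interaction_window=(120.0, session_length_s)),
        compartment_time=compartment_time or {},
        open_field=open_field or {},
    )


def pool_group(summaries: list[SessionSummary],
               scatter_pairs: list[tuple[str, str]] | None = None) -> dict:
    """Group means +/- SEM for the session summaries, plus Pearson r (with
    two-sided p) for requested scalar pairs across subjects.

    SEM uses the sample (n-1) standard deviation.  Missing (None) values
    are excluded pairwise from correlations and from means.
    """
    if len(summaries) < 2:
        raise InputError("pooling requires at least 2 sessions")
    bw = {s.bin_width_s for s in summaries}
    nb = {len(s.binned[STIM1]) for s in summaries}
    if len(bw) != 1 or len(nb) != 1:
        raise InputError("sessions have inconsistent binning")

    def mean_sem(values):
        vals = np.array([v for v in values if v is not None], dtype=float)
        if vals.size == 0:
            return None, None
        sem = (vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        return float(vals.mean()), float(sem)

    out: dict = {"n": len(summaries)}
    for s in STIMULI:
        stack = np.stack([sm.binned[s] for sm in summaries])
        out[f"binned_mean_{LABEL_NAMES[s]}"] = stack.mean(axis=0)
        out[f"binned_sem_{LABEL_NAMES[s]}"] = (
            stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0]))
        out[f"time_mean_{LABEL_NAMES[s]}"], out[f"time_sem_{LABEL_NAMES[s]}"] = \
            mean_sem([sm.total_time[s] for sm in summaries])
    tstack = np.stack([sm.transition_bins for sm in summaries])
    out["transition_bins_mean"] = tstack.mean(axis=0)
    out["transition_bins_sem"] = (tstack.std(axis=0, ddof=1)
                                  / np.sqrt(tstack.shape[0]))
    for key in ("rdi_time", "rdi_intervals", "total_transitions"):
        out[f"{key}_mean"], out[f"{key}_sem"] = mean_sem(
            [getattr(sm, key) for sm in summaries])

    rows = [sm.to_row() for sm in summaries]
    out["correlations"] = {}
    for a, b in (scatter_pairs or []):
        xs, ys = [], []
        for row in rows:
            if row.get(a) is not None and row.get(b) is not None:
                xs.append(row[a])
                ys.append(row[b])
        if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
            r, p = stats.pearsonr(xs, ys)
            out["correlations"][f"{a}~{b}"] = {"r": float(r), "p": float(p),
                                               "n": len(xs)}
        else:
            out["correlations"][f"{a}~{b}"] = {"r": None, "p": None,
                                               "n": len(xs)}
    return out
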