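"""Ground-truthed synthetic data: simulated behavior and rendered videos.

Two levels, so every stage of the pipeline can be tested without animal
data:

* :func:`simulate_behavior` draws a session-long alternation of roaming
  and stimulus-investigation segments with the two-phase structure seen in
  real social-preference sessions — an early *exploration* phase with
  frequent switching and short bouts, then an *interaction* phase with few
  switches and long bouts, dominated by the preferred stimulus.
* :func:`render_video` realizes a script as a top-down movie of a dark
  elliptical subject on a light floor, with an optional brighter tail
  (between the two detection thresholds, exercising the head/tail logic)
  and an optional thin dark cable from the head to a fixed anchor, plus a
  per-frame ground-truth log computed from the *rendered* geometry.

All randomness is driven by explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely

from .arena import ArenaConfig
from .events import NONE, STIM1, STIM2, LABEL_NAMES, Bout, LabelSeries, Transition

ROAM = 0  # segment states; investigation states reuse STIM1/STIM2


@dataclass(frozen=True)
class PhaseParams:
    """Generative rates for one phase of the session."""

    mean_bout_s: float
    mean_roam_s: float
    switch_propensity: float  # probability the next bout re-draws its target

    def __post_init__(self):
        if self.mean_bout_s <= 0 or self.mean_roam_s <= 0:
            raise ValueError("durations must be > 0")
        if not 0 <= self.switch_propensity <= 1:
            raise ValueError("switch_propensity must be in [0, 1]")


@dataclass(frozen=True)
class BehaviorParams:
    """Session-level generative parameters.

    ``preference`` is the fraction of investigation drive toward stim1,
    expressed through bout duration: a bout on stim1 has mean duration
    scaled by 2*preference, on stim2 by 2*(1-preference), while the
    investigation target itself re-draws without bias.  This duration
    channel keeps the preference index statistically independent of the
    subject's transition count, the decoupling seen in real social-
    preference sessions; ``count_bias`` mixes preference back into the
    target draw itself (1 = targets drawn Bernoulli(preference)) for
    sensitivity analyses.  ``recognition_difficulty`` (for social-novelty-
    style tests) jointly pushes the effective preference toward 0.5 and
    scales the switch propensity up, modelling a subject that keeps
    checking both stimuli because it cannot tell them apart.
    """

    session_length_s: float = 300.0
    phase_boundary_s: float = 120.0
    exploration: PhaseParams = field(
        default_factory=lambda: PhaseParams(3.0, 4.0, 0.9))
    interaction: PhaseParams = field(
        default_factory=lambda: PhaseParams(12.0, 8.0, 0.8))
    preference: float = 0.75
    recognition_difficulty: float = 0.0
    switch_scale: float = 1.0  # subject exploration-tendency trait
    count_bias: float = 0.0    # weight of preference in the target draw
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.preference <= 1:
            raise ValueError("preference must be in [0, 1]")
        if not 0 <= self.recognition_difficulty <= 1:
            raise ValueError("recognition_difficulty must be in [0, 1]")
        if not 0 <= self.count_bias <= 1:
            raise ValueError("count_bias must be in [0, 1]")
        if not 0 < self.phase_boundary_s <= self.session_length_s:
            raise ValueError("phase_boundary_s must lie within the session")

    def effective(self) -> tuple[float, dict, float]:
        """(preference, {phase: switch_propensity}, cycle shrink factor)
        after the difficulty knob is applied."""
        d = self.recognition_difficulty
        pref = self.preference + (0.5 - self.preference) * d
        k = (1 + d) * self.switch_scale
        prop = {
            "exploration": min(1.0, self.exploration.switch_propensity * k),
            "interaction": min(1.0, self.interaction.switch_propensity * k),
        }
        shrink = 1.0 - 0.7 * d  # difficulty shortens the whole bout/roam cycle
        return pref, prop, shrink


@dataclass(frozen=True)
class Segment:
    state: int  # ROAM, STIM1 or STIM2
    start_s: float
    end_s: float


@dataclass(frozen=True)
class BehaviorScript:
    """Segments tiling [0, session_length_s) without overlap."""

    segments: tuple[Segment, ...]
    session_length_s: float

    def __post_init__(self):
        t = 0.0
        for seg in self.segments:
            if abs(seg.start_s - t) > 1e-9 or seg.end_s <= seg.start_s:
                raise ValueError("segments must tile the session")
            t = seg.end_s
        if abs(t - self.session_length_s) > 1e-9:
            raise ValueError("segments must cover the whole session")


def _simulate(params: BehaviorParams, rng_shared: np.random.Generator,
              rng_target: np.random.Generator,
              antithetic: bool) -> BehaviorScript:
    """Core session draw.

    ``rng_shared`` drives durations and switch events; ``rng_target``
    yields the uniforms behind target draws.  With ``antithetic`` the
    target uniforms are flipped (u -> 1-u), which preserves the marginal
    Bernoulli(preference) law while anti-correlating the member of an
    antithetic pair — used by :func:`simulate_cohort` to stabilize
    small-cohort means.
    """
    pref, props, shrink = params.effective()
    p_target = 0.5 + params.count_bias * (pref - 0.5)

    def draw_target() -> int:
        u = float(rng_target.random())
        if antithetic:
            u = 1.0 - u
        return STIM1 if u < p_target else STIM2

    segments: list[Segment] = []
    t = 0.0
    target = draw_target()
    while t < params.session_length_s:
        phase = ("exploration" if t < params.phase_boundary_s
                 else "interaction")
        ph = getattr(params, phase)
        drive = pref if target == STIM1 else 1.0 - pref
        # roam mean compensates the drive-scaled bout mean so that the
        # mean cycle length is target-independent: without this, sessions
        # that draw more short minority bouts pack in more cycles, which
        # mechanically couples transition count to the preference index
        mb, mr = ph.mean_bout_s * shrink, ph.mean_roam_s * shrink
        roam_mean = max(0.5, mr + mb * (1.0 - 2.0 * drive))
        roam = float(rng_shared.exponential(roam_mean))
        end = min(t + roam, params.session_length_s)
        if end > t:
            segments.append(Segment(ROAM, t, end))
        t = end
        if t >= params.session_length_s:
            break
        phase = ("exploration" if t < params.phase_boundary_s
                 else "interaction")
        ph = getattr(params, phase)
        mb = ph.mean_bout_s * shrink
        bout = float(rng_shared.exponential(mb * max(2.0 * drive, 0.05)))
        end = min(t + bout, params.session_length_s)
        if end > t:
            segments.append(Segment(target, t, end))
        t = end
        if rng_shared.random() < props[phase]:
            target = draw_target()
    return BehaviorScript(tuple(segments), params.session_length_s)


def simulate_behavior(params: BehaviorParams) -> BehaviorScript:
    """Draw one session: alternating roam/investigate segments with
    exponential durations whose means switch at the phase boundary.

    The next bout's stimulus re-draws with the phase's switch propensity
    (unbiased by default, see ``count_bias``), and the mean bout duration
    is scaled by twice the drive fraction toward the chosen stimulus, so
    the preferred stimulus receives longer bouts.
    """
    root = np.random.default_rng(params.seed)
    rng_shared = np.random.default_rng(root.integers(2**31 - 1))
    rng_target = np.random.default_rng(root.integers(2**31 - 1))
    return _simulate(params, rng_shared, rng_target, antithetic=False)


# ---------------------------------------------------------------------------
# script -> frame labels + ground-truth events

def script_to_labels(script: BehaviorScript, frame_rate: float = 30.0):
    """Quantize a script to per-frame labels plus ground-truth events.

    Each frame takes the state of the segment containing its start time.
    Ground-truth bouts/transitions are read off the quantized labels by a
    direct run scan (adjacent same-stimulus segments separated by a
    sub-frame roam merge under quantization, so the quantized labels are
    the authoritative ground truth).
    """
    n = int(round(script.session_length_s * frame_rate))
    labels = np.zeros(n, dtype=np.int8)
    for seg in script.segments:
        if seg.state == ROAM:
            continue
        a = int(math.ceil(seg.start_s * frame_rate - 1e-9))
        b = int(math.ceil(seg.end_s * frame_rate - 1e-9))
        labels[a:b] = seg.state
    series = LabelSeries(labels, frame_rate, corrected=False)
    bouts: list[Bout] = []
    i = 0
    while i < n:
        if labels[i] != NONE:
            j = i
            while j < n and labels[j] == labels[i]:
                j += 1
            bouts.append(Bout(int(labels[i]), i / frame_rate, j / frame_rate))
            i = j
        else:
            i += 1
    transitions = [Transition(b.start_s, a.stimulus, b.stimulus)
                   for a, b in zip(bouts, bouts[1:])
                   if a.stimulus != b.stimulus]
    return series, bouts, transitions


# ---------------------------------------------------------------------------
# rendering

@dataclass(frozen=True)
class RenderParams:
    """Appearance of the rendered arena video.

    Gray levels must satisfy body < low threshold < tail < high threshold
    < background so the dual-threshold head/tail disambiguation has
    something to work with.
    """

    frame_shape: tuple[int, int] = (240, 320)  # (h, w)
    frame_rate: float = 30.0
    body_semi_major_px: float = 14.0
    body_semi_minor_px: float = 7.0
    body_gray: int = 40
    tail_length_px: float = 20.0
    tail_width_px: float = 2.0
    tail_gray: int = 110
    background_gray: int = 200
    draw_tail: bool = True
    cable_anchor: tuple[float, float] | None = None
    cable_width_px: float = 2.0
    cable_gray: int = 45
    noise_sd: float = 2.0
    seed: int = 0

    def validate_against(self, config: ArenaConfig) -> None:
        lo, hi = (config.detection_threshold_low,
                  config.detection_threshold_high)
        if not (self.body_gray < lo <= hi < self.background_gray):
            raise ValueError("gray levels must straddle the detection "
                             "thresholds: body < low <= high < background")
        if self.draw_tail and not (lo < self.tail_gray < hi):
            raise ValueError("tail gray must lie between the two "
                             "detection thresholds")


@dataclass
class Pose:
    center: np.ndarray  # (x, y)
    heading: np.ndarray  # unit vector, nose direction


def _ellipse_mask(shape, center, heading, a, b):
    h, w = shape
    cx, cy = center
    ux, uy = heading
    r = int(math.ceil(a)) + 2
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    u = dx * ux + dy * uy
    v = -dx * uy + dy * ux
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = inside
    return mask


def _stamp_line(canvas_mask, p0, p1, width):
    """Mark pixels within width/2 of the segment p0-p1."""
    h, w = canvas_mask.shape
    length = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    n = max(2, int(length * 2))
    lo = int(width) // 2          # a width-w stamp spans [-lo, hi]
    hi = int(width) - lo - 1
    for t in np.linspace(0, 1, n):
        x = p0[0] + t * (p1[0] - p0[0])
        y = p0[1] + t * (p1[1] - p0[1])
        xi, yi = int(round(x)), int(round(y))
        canvas_mask[max(0, yi - lo):min(h, yi + hi + 1),
                    max(0, xi - lo):min(w, xi + hi + 1)] = True
    return canvas_mask


class _ShapelyZoneMaps:
    """Per-pixel distances to each stimulus zone, computed with shapely —
    an independent geometric route from the tracker's own distance code,
    so the rendered ground truth is an honest oracle."""

    def __init__(self, config: ArenaConfig, shape):
        h, w = shape
        ys, xs = np.mgrid[0:h, 0:w]
        pts = shapely.points(np.column_stack([xs.ravel(), ys.ravel()])
                             .astype(float))
        self.lines = config.zone_lines()
        self.maps = [shapely.distance(pts, line).reshape(h, w)
                     for line in self.lines]
        self.contact_d = config.contact_distance_px

    def contact_of_mask(self, mask: np.ndarray) -> int:
        dmins = [float(m[mask].min()) for m in self.maps]
        return self._label(dmins)

    def contact_of_point(self, pt) -> int:
        dmins = [float(shapely.distance(shapely.points(pt), line))
                 for line in self.lines]
        return self._label(dmins)

    def _label(self, dmins) -> int:
        hits = [i for i, d in enumerate(dmins) if d <= self.contact_d]
        if not hits:
            return NONE
        if len(hits) == 2 and dmins[0] == dmins[1]:
            return NONE
        return (STIM1, STIM2)[min(hits, key=lambda i: dmins[i])]


def _zone_geometry(config: ArenaConfig):
    """Midpoint and inward unit normal for each zone."""
    x, y, w, h = config.arena_rect
    arena_c = np.array([x + w / 2, y + h / 2])
    out = []
    for seg in config.stimulus_zones.values():
        a, b = np.asarray(seg[0], float), np.asarray(seg[1], float)
        mid = (a + b) / 2
        d = b - a
        n = np.array([-d[1], d[0]])
        n /= np.hypot(*n)
        if (arena_c - mid) @ n < 0:
            n = -n
        out.append((mid, n))
    return out


def _closest_on_segment(p, seg):
    a = np.asarray(seg[0], float)
    b = np.asarray(seg[1], float)
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
    return a + t * ab


def _safe_roam_position(pose, config, render, rng, zone_segs):
    """One smooth random-walk step keeping the whole body away from both
    zone segments and inside the arena."""
    x, y, w, h = config.arena_rect
    a = render.body_semi_major_px
    margin = a + config.contact_distance_px + 6.0
    step = pose.heading * 2.0 + rng.normal(0, 1.2, 2)
    new = pose.center + step
    lo = np.array([x + a, y + a])
    hi = np.array([x + w - a, y + h - a])
    new = np.clip(new, lo, hi)
    for _ in range(3):  # pushing off one zone can approach the other
        moved = False
        for seg in zone_segs:
            q = _closest_on_segment(new, seg)
            d = new - q
            dist = float(np.hypot(*d))
            if dist < margin:
                new = q + d / max(dist, 1e-9) * margin
                new = np.clip(new, lo, hi)
                moved = True
        if not moved:
            break
    vel = new - pose.center
    nv = np.hypot(*vel)
    heading = vel / nv if nv > 1e-6 else pose.heading
    return Pose(new, heading)


def render_frames(script: BehaviorScript, config: ArenaConfig,
                  render: RenderParams):
    """Yield (frame, truth_row) pairs for a script.

    ``truth_row`` is a dict with the rendered-geometry ground truth:
    centroid of the painted body pixels, nose position, and contact labels
    for the body boundary and the head point.
    """
    render.validate_against(config)
    rng = np.random.default_rng(render.seed)
    h, w = render.frame_shape
    fps = render.frame_rate
    zone_geo = _zone_geometry(config)
    zmaps = _ShapelyZoneMaps(config, (h, w))
    n_frames = int(round(script.session_length_s * fps))

    seg_iter = iter(script.segments)
    seg = next(seg_iter)
    x, y, aw, ah = config.arena_rect
    pose = Pose(np.array([x + aw / 2, y + ah / 2]),
                np.array([1.0, 0.0]))
    a, b = render.body_semi_major_px, render.body_semi_minor_px

    for i in range(n_frames):
        t = i / fps
        while t >= seg.end_s - 1e-9:
            try:
                seg = next(seg_iter)
            except StopIteration:
                break
        if seg.state == ROAM:
            pose = _safe_roam_position(pose, config, render, rng,
                                       list(config.stimulus_zones.values()))
        else:
            mid, n = zone_geo[seg.state - 1]
            jitter = rng.normal(0, 0.5, 2)
            nose = mid + n * 0.5
            center = nose + n * a
            pose = Pose(center + jitter * np.array([0.1, 0.1]), -n)
        center = np.round(pose.center * 2) / 2  # half-pixel pose quantization
        nose = center + pose.heading * a

        body = _ellipse_mask((h, w), center, pose.heading, a, b)
        frame = np.full((h, w), render.background_gray, dtype=float)
        if render.draw_tail:
            rump = center - pose.heading * a
            tail_end = rump - pose.heading * render.tail_length_px
            tail = np.zeros((h, w), dtype=bool)
            _stamp_line(tail, rump, tail_end, render.tail_width_px)
            frame[tail & ~body] = render.tail_gray
        if render.cable_anchor is not None:
            cable = np.zeros((h, w), dtype=bool)
            _stamp_line(cable, nose, render.cable_anchor,
                        render.cable_width_px)
            frame[cable & ~body] = render.cable_gray
        frame[body] = render.body_gray
        if render.noise_sd > 0:
            frame = frame + rng.normal(0, render.noise_sd, frame.shape)
        frame = np.clip(np.round(frame), 0, 255).astype(np.uint8)

        ys, xs = np.nonzero(body)
        truth = {
            "frame": i,
            "time_s": t,
            "cx_px": float(xs.mean()),
            "cy_px": float(ys.mean()),
            "head_x_px": float(nose[0]),
            "head_y_px": float(nose[1]),
            "contact_body": zmaps.contact_of_mask(body),
            "contact_head": zmaps.contact_of_point(tuple(nose)),
            "state": int(seg.state),
        }
        yield frame, truth


def render_video(script: BehaviorScript, config: ArenaConfig,
                 render: RenderParams, path=None):
    """Render a script; optionally write an AVI + ground-truth CSV.

    Returns ``(frames, truth)`` where ``frames`` is a (n, h, w) uint8
    array and ``truth`` a DataFrame (one row per frame).  When ``path``
    is given the AVI is written there and the log to ``<path>.truth.csv``.
    """
    import pandas as pd

    frames = []
    rows = []
    for frame, truth in render_frames(script, config, render):
        frames.append(frame)
        rows.append(truth)
    stack = np.stack(frames)
    truth = pd.DataFrame(rows)
    truth["contact_body"] = truth["contact_body"].map(LABEL_NAMES)
    truth["contact_head"] = truth["contact_head"].map(LABEL_NAMES)
    if path is not None:
        from .video import write_avi
        write_avi(path, iter(stack), fps=render.frame_rate)
        truth.to_csv(f"{path}.truth.csv", index=False, float_format="%.3f")
    return stack, truth


# ---------------------------------------------------------------------------
# fixed scenarios for tracker validation

def static_pose_script(duration_s: float, state: int = ROAM
                       ) -> BehaviorScript:
    return BehaviorScript((Segment(state, 0.0, duration_s),), duration_s)


def render_tail_only_contact(config: ArenaConfig, render: RenderParams,
                             duration_s: float = 10.0, zone: int = STIM1):
    """A mouse parked with its rump (body boundary) touching a zone and
    its nose pointing away: body contact without head contact — the false
    investigation class the head algorithm exists to remove."""
    mid, n = _zone_geometry(config)[zone - 1]
    a = render.body_semi_major_px
    center = mid + n * (a + config.contact_distance_px * 0.4)
    heading = n  # nose points inward, away from the zone

    import pandas as pd
    h, w = render.frame_shape
    zmaps = _ShapelyZoneMaps(config, (h, w))
    rng = np.random.default_rng(render.seed)
    n_frames = int(round(duration_s * render.frame_rate))
    frames, rows = [], []
    for i in range(n_frames):
        body = _ellipse_mask((h, w), center, heading,
                             a, render.body_semi_minor_px)
        frame = np.full((h, w), render.background_gray, dtype=float)
        if render.draw_tail:
            rump = center - heading * a
            tail = np.zeros((h, w), dtype=bool)
            _stamp_line(tail, rump, rump - heading * render.tail_length_px,
                        render.tail_width_px)
            frame[tail & ~body] = render.tail_gray
        frame[body] = render.body_gray
        if render.noise_sd > 0:
            frame = frame + rng.normal(0, render.noise_sd, frame.shape)
        frames.append(np.clip(np.round(frame), 0, 255).astype(np.uint8))
        nose = center + heading * a
        ys, xs = np.nonzero(body)
        rows.append({"frame": i, "time_s": i / render.frame_rate,
                     "cx_px": float(xs.mean()), "cy_px": float(ys.mean()),
                     "head_x_px": float(nose[0]),
                     "head_y_px": float(nose[1]),
                     "contact_body": zmaps.contact_of_mask(body),
                     "contact_head": zmaps.contact_of_point(tuple(nose))})
    truth = pd.DataFrame(rows)
    truth["contact_body"] = truth["contact_body"].map(LABEL_NAMES)
    truth["contact_head"] = truth["contact_head"].map(LABEL_NAMES)
    return np.stack(frames), truth


def render_cable_over_zone(config: ArenaConfig, render: RenderParams,
                           duration_s: float = 10.0, zone: int = STIM1):
    """A stationary mouse far from both zones while its cable crosses one:
    the artifact the wired variant exists to suppress.  Ground-truth
    contact is none on every frame."""
    x, y, aw, ah = config.arena_rect
    mid, n = _zone_geometry(config)[zone - 1]
    center = np.array([x + aw / 2, y + ah / 2])
    heading = (mid - center) / np.hypot(*(mid - center))
    anchor = tuple(mid - n * 6.0)  # behind the zone: the cable crosses it
    params = replace(render, cable_anchor=anchor, draw_tail=False)
    script = static_pose_script(duration_s)

    import pandas as pd
    h, w = render.frame_shape
    zmaps = _ShapelyZoneMaps(config, (h, w))
    rng = np.random.default_rng(render.seed)
    a, b = render.body_semi_major_px, render.body_semi_minor_px
    n_frames = int(round(duration_s * render.frame_rate))
    frames, rows = [], []
    nose = center + heading * a
    for i in range(n_frames):
        body = _ellipse_mask((h, w), center, heading, a, b)
        frame = np.full((h, w), render.background_gray, dtype=float)
        cable = np.zeros((h, w), dtype=bool)
        _stamp_line(cable, nose, anchor, params.cable_width_px)
        frame[cable & ~body] = params.cable_gray
        frame[body] = render.body_gray
        if render.noise_sd > 0:
            frame = frame + rng.normal(0, render.noise_sd, frame.shape)
        frames.append(np.clip(np.round(frame), 0, 255).astype(np.uint8))
        ys, xs = np.nonzero(body)
        rows.append({"frame": i, "time_s": i / render.frame_rate,
                     "cx_px": float(xs.mean()), "cy_px": float(ys.mean()),
                     "head_x_px": float(nose[0]),
                     "head_y_px": float(nose[1]),
                     "contact_body": zmaps.contact_of_mask(body),
                     "contact_head": zmaps.contact_of_point(tuple(nose))})
    truth = pd.DataFrame(rows)
    truth["contact_body"] = truth["contact_body"].map(LABEL_NAMES)
    truth["contact_head"] = truth["contact_head"].map(LABEL_NAMES)
    return np.stack(frames), truth


# ---------------------------------------------------------------------------
# cohorts

def simulate_cohort(n_subjects: int, params: BehaviorParams, seed: int,
                    difficulty_range: tuple[float, float] | None = None,
                    antithetic: bool = True,
                    trait_sigma: float = 0.3) -> list[BehaviorScript]:
    """n subjects from shared session parameters.

    Subjects are generated in antithetic pairs by default: both members
    share the duration/switch random stream while their target-draw
    uniforms are mirrored (u vs 1-u).  Each subject's marginal behavior
    is unchanged, but pair-wise anti-correlation stabilizes cohort means
    — in particular the null (preference 0.5) cohort-mean preference
    index cancels exactly for even n.  Set ``antithetic=False`` for
    fully independent subjects.

    When ``difficulty_range`` is given each pair draws a recognition
    difficulty uniformly from it (heterogeneous cohort, SNP-style).
    Each pair also draws an exploration-tendency trait (``switch_scale``,
    lognormal around 1 with ``trait_sigma``) modelling stable individual
    differences in how often a subject switches stimuli, independent of
    its preference.
    """
    rng = np.random.default_rng(seed)
    scripts: list[BehaviorScript] = []
    while len(scripts) < n_subjects:
        p = params
        if trait_sigma > 0:
            p = replace(p, switch_scale=float(rng.lognormal(0.0, trait_sigma)))
        if difficulty_range is not None:
            d = float(rng.uniform(*difficulty_range))
            p = replace(p, recognition_difficulty=d)
        seed_shared = int(rng.integers(0, 2**31 - 1))
        seed_target = int(rng.integers(0, 2**31 - 1))
        for anti in (False, True) if antithetic else (False,):
            if len(scripts) >= n_subjects:
                break
            scripts.append(_simulate(
                p,
                np.random.default_rng(seed_shared),
                np.random.default_rng(seed_target),
                antithetic=anti,
            ))
    return scripts
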