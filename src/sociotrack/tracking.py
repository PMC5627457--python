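"""Per-frame subject tracking and stimulus-contact detection.

Three algorithm variants, all built on plain dark-on-light thresholding:

``body``
    Segment the subject as the largest dark connected component inside the
    arena and score contact between the body boundary and either stimulus
    zone.  Fast; the workhorse for unwired animals.
``head``
    Additionally estimate head direction: fit the moment ellipse to the
    body mask obtained with the *low* threshold (which excludes the
    brighter tail), take its major-axis endpoints as nose/rump candidates,
    and disambiguate them with the *high*-threshold mask (which includes
    the tail): the endpoint farther from the tail pixels is the head.
    Contact is then scored for the head point only, removing false
    investigation events caused by the rest of the body brushing a zone.
``wired_body``
    Body algorithm preceded by cable suppression (morphological opening
    that erases thin elongated protrusions such as a recording cable or
    optical fiber), so a tether crossing a zone does not score contact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .arena import ArenaConfig
from .events import NONE, STIM1, STIM2, LABEL_NAMES

log = logging.getLogger(__name__)

ALGORITHMS = ("body", "head", "wired_body")


class FitError(ValueError):
    """Ellipse fit is undefined for this mask."""


class InputError(ValueError):
    pass


@dataclass
class FrameObservation:
    frame_index: int
    time_s: float
    centroid: tuple[float, float] | None
    boundary: np.ndarray | None          # (N, 2) x,y pixel coords
    head: tuple[float, float] | None
    contact: int = NONE
    valid: bool = False


@dataclass
class TrackingResult:
    observations: list[FrameObservation]
    algorithm: str
    config: ArenaConfig

    @property
    def frame_count(self) -> int:
        return len(self.observations)

    @property
    def invalid_fraction(self) -> float:
        n = self.frame_count
        if n == 0:
            return 0.0
        return sum(not o.valid for o in self.observations) / n

    def to_frame(self):
        import pandas as pd
        rows = []
        for o in self.observations:
            cx, cy = o.centroid if o.centroid is not None else (np.nan, np.nan)
            hx, hy = o.head if o.head is not None else (np.nan, np.nan)
            rows.append((o.frame_index, o.time_s, o.valid, cx, cy, hx, hy,
                         LABEL_NAMES[o.contact], self.algorithm))
        return pd.DataFrame(rows, columns=[
            "frame", "time_s", "valid", "cx_px", "cy_px",
            "head_x_px", "head_y_px", "contact", "algorithm"])

    def write_csv(self, path) -> None:
        # full float repr so a reloaded CSV reproduces the analysis exactly
        self.to_frame().to_csv(path, index=False)


def track_from_csv(path, config: ArenaConfig) -> TrackingResult:
    """Rebuild a TrackingResult from a per-frame CSV written by
    :meth:`TrackingResult.write_csv` (boundaries are not stored, so
    boundary-dependent operations are unavailable, but contact labels,
    centroids and validity round-trip exactly)."""
    import pandas as pd
    df = pd.read_csv(path)
    obs = []
    for r in df.itertuples():
        valid = bool(r.valid)
        centroid = ((float(r.cx_px), float(r.cy_px))
                    if valid and np.isfinite(r.cx_px) else None)
        head = ((float(r.head_x_px), float(r.head_y_px))
                if np.isfinite(r.head_x_px) else None)
        contact = {"none": NONE, "stim1": STIM1, "stim2": STIM2}[r.contact]
        obs.append(FrameObservation(int(r.frame), float(r.time_s),
                                    centroid, None, head, contact, valid))
    algorithm = df["algorithm"].iloc[0] if len(df) else "body"
    return TrackingResult(obs, str(algorithm), config)


# ---------------------------------------------------------------------------
# segmentation

def segment_subject(frame: np.ndarray, threshold: float, min_area: int,
                    config: ArenaConfig,
                    prev_centroid: tuple[float, float] | None = None
                    ) -> np.ndarray | None:
    """Largest dark connected component inside the arena, or None.

    Components below ``min_area`` are rejected.  Equal-area ties go to the
    component whose centroid is nearest ``prev_centroid``, then to the
    lowest label index.
    """
    if frame.ndim != 2:
        raise InputError("frame must be a 2-D grayscale image")
    x, y, w, h = config.arena_rect
    if frame.shape[0] < y + h - 0.5 or frame.shape[1] < x + w - 0.5:
        raise InputError(
            f"frame shape {frame.shape} does not contain the configured "
            f"arena rect {config.arena_rect}")
    dark = frame > threshold if config.invert else frame < threshold
    inside = np.zeros_like(dark)
    y0, y1 = int(math.floor(y)), int(math.ceil(y + h))
    x0, x1 = int(math.floor(x)), int(math.ceil(x + w))
    inside[y0:y1, x0:x1] = dark[y0:y1, x0:x1]
    labels, n = ndimage.label(inside)
    if n == 0:
        return None
    areas = ndimage.sum_labels(inside, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    if keep.size == 0:
        return None
    best_area = areas[keep - 1].max()
    cands = keep[areas[keep - 1] == best_area]
    if cands.size > 1 and prev_centroid is not None:
        cents = ndimage.center_of_mass(inside, labels, index=cands)
        d = [np.hypot(c[1] - prev_centroid[0], c[0] - prev_centroid[1])
             for c in cents]
        cands = cands[np.argsort(d, kind="stable")]
    return labels == cands[0]


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    ys, xs = np.nonzero(mask)
    return float(xs.mean()), float(ys.mean())


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of the mask as an (N, 2) array of x,y coords."""
    er = ndimage.binary_erosion(mask, border_value=0)
    ys, xs = np.nonzero(mask & ~er)
    return np.column_stack([xs, ys]).astype(float)


# ---------------------------------------------------------------------------
# ellipse / head-tail

def fit_body_ellipse(mask: np.ndarray):
    """Moment-based (equivalent second-moment) ellipse of a binary mask.

    Returns ``(center, (semi_major, semi_minor), axis_unit, endpoints)``
    where ``endpoints`` are the two major-axis ends, the nose/rump
    candidates.  Raises :class:`FitError` for degenerate masks (fewer than
    3 pixels, or collinear pixels).
    """
    ys, xs = np.nonzero(mask)
    if xs.size < 3:
        raise FitError("mask too small for an ellipse fit")
    pts = np.column_stack([xs, ys]).astype(float)
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-9:  # collinear pixels
        raise FitError("degenerate (collinear) mask")
    semi_minor, semi_major = 2.0 * np.sqrt(evals)
    axis = evecs[:, 1]
    e1 = center + semi_major * axis
    e2 = center - semi_major * axis
    return (tuple(center), (float(semi_major), float(semi_minor)),
            tuple(axis), (tuple(e1), tuple(e2)))


def resolve_head_tail(endpoints, high_mask: np.ndarray,
                      low_mask: np.ndarray,
                      previous_head: tuple[float, float] | None = None,
                      min_tail_px: int = 3) -> tuple[float, float] | None:
    """Pick the head among the two major-axis endpoints.

    The high-threshold mask includes the brighter tail; the low-threshold
    one does not.  Their difference (restricted to the component of the
    high mask that contains the body) marks the tail, and the endpoint
    farther from those pixels is the head.  With no visible tail the
    endpoint closer to ``previous_head`` wins; with neither disambiguator
    the head is undetermined (None).
    """
    (e1, e2) = endpoints
    labels, n = ndimage.label(high_mask)
    tail = np.zeros_like(high_mask)
    if n:
        overlap = labels[low_mask]
        overlap = overlap[overlap > 0]
        if overlap.size:
            body_label = np.bincount(overlap).argmax()
            tail = (labels == body_label) & ~low_mask
    ys, xs = np.nonzero(tail)
    if xs.size >= min_tail_px:
        tp = np.column_stack([xs, ys]).astype(float)
        d1 = np.min(np.hypot(tp[:, 0] - e1[0], tp[:, 1] - e1[1]))
        d2 = np.min(np.hypot(tp[:, 0] - e2[0], tp[:, 1] - e2[1]))
        return tuple(e1) if d1 > d2 else tuple(e2)
    if previous_head is not None:
        d1 = math.hypot(e1[0] - previous_head[0], e1[1] - previous_head[1])
        d2 = math.hypot(e2[0] - previous_head[0], e2[1] - previous_head[1])
        return tuple(e1) if d1 <= d2 else tuple(e2)
    return None


# ---------------------------------------------------------------------------
# contact

def _segment_distances(points: np.ndarray, seg) -> np.ndarray:
    """Distance from each (x, y) point to a line segment ((x1,y1),(x2,y2))."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(seg[0], dtype=float)
    b = np.asarray(seg[1], dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.hypot(*(p - a).T)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(p - proj).T)


def _contact_from_distances(dmins: list[float], contact_distance_px: float
                            ) -> int:
    hits = [i for i, d in enumerate(dmins) if d <= contact_distance_px]
    if not hits:
        return NONE
    if len(hits) == 1:
        return (STIM1, STIM2)[hits[0]]
    if dmins[0] == dmins[1]:
        return NONE  # exact tie between zones: ambiguous, score nothing
    return (STIM1, STIM2)[int(np.argmin(dmins))]


def body_contact(boundary: np.ndarray, config: ArenaConfig) -> int:
    """Contact label for a body boundary: stim_k when the minimum distance
    from any boundary point to zone k is <= contact_distance_px (closed
    inequality); the nearer zone wins when both qualify, exact ties score
    none."""
    if len(boundary) == 0:
        return NONE
    dmins = [float(_segment_distances(boundary, seg).min())
             for seg in config.stimulus_zones.values()]
    return _contact_from_distances(dmins, config.contact_distance_px)


def head_contact(head: tuple[float, float], config: ArenaConfig) -> int:
    """As :func:`body_contact` but for the head point alone."""
    dmins = [float(_segment_distances([head], seg)[0])
             for seg in config.stimulus_zones.values()]
    return _contact_from_distances(dmins, config.contact_distance_px)


# ---------------------------------------------------------------------------
# cable suppression

def remove_cable(mask: np.ndarray, max_cable_width_px: float = 3.0
                 ) -> np.ndarray | None:
    """Erase thin elongated protrusions (a cable) from the subject mask.

    Morphological opening with a disk of radius ceil(width/2) removes
    structures thinner than the cable bound, then the largest remaining
    component is kept.  Fat blobs survive nearly unchanged (area change
    under ~15%).  Returns None when nothing survives.
    """
    radius = int(math.ceil(max_cable_width_px / 2.0))
    opened = ndimage.binary_opening(mask, structure=disk(radius))
    labels, n = ndimage.label(opened)
    if n == 0:
        return None
    areas = ndimage.sum_labels(opened, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(areas)) + 1)


# ---------------------------------------------------------------------------
# per-frame distance maps (cached per config + frame shape)

class _ZoneDistanceMaps:
    def __init__(self, config: ArenaConfig, shape):
        h, w = shape
        ys, xs = np.mgrid[0:h, 0:w]
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        self.maps = [
            _segment_distances(pts, seg).reshape(h, w).astype(np.float32)
            for seg in config.stimulus_zones.values()
        ]

    def boundary_contact(self, boundary: np.ndarray,
                         contact_distance_px: float) -> int:
        idx = boundary.astype(int)
        dmins = [float(m[idx[:, 1], idx[:, 0]].min()) for m in self.maps]
        return _contact_from_distances(dmins, contact_distance_px)


# ---------------------------------------------------------------------------
# top-level tracking

def track(video, config: ArenaConfig, algorithm: str = "body"
          ) -> TrackingResult:
    """Run one tracking algorithm over a video.

    ``video`` is a path to a supported container or any iterable of
    (h, w) uint8 frames.  Returns one FrameObservation per frame; frames
    with no acceptable blob are marked invalid (contact none) and a
    warning is logged when more than 20% of frames are invalid.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; "
                         f"choose from {ALGORITHMS}")
    if isinstance(video, (str, bytes)) or hasattr(video, "__fspath__"):
        from .video import open_frames
        frames, fps = open_frames(video)
        if fps is not None and abs(fps - config.frame_rate) > 0.5:
            log.warning("container frame rate %.2f differs from config "
                        "frame_rate %.2f; using config", fps,
                        config.frame_rate)
    else:
        frames = video

    fps = config.frame_rate
    thr_low = config.detection_threshold_low
    thr_high = config.detection_threshold_high
    observations: list[FrameObservation] = []
    prev_centroid = None
    prev_head = None
    dist_maps = None
    head_undetermined = 0

    for i, frame in enumerate(frames):
        frame = np.asarray(frame)
        if dist_maps is None:
            dist_maps = _ZoneDistanceMaps(config, frame.shape)
        obs = FrameObservation(i, i / fps, None, None, None)
        mask = segment_subject(frame, thr_low, config.min_blob_area_px,
                               config, prev_centroid)
        if mask is not None and algorithm == "wired_body":
            mask = remove_cable(mask, config.cable_max_width_px)
            if mask is not None and mask.sum() < config.min_blob_area_px:
                mask = None
        if mask is None:
            observations.append(obs)
            continue
        obs.valid = True
        obs.centroid = mask_centroid(mask)
        obs.boundary = mask_boundary(mask)
        prev_centroid = obs.centroid

        if algorithm in ("body", "wired_body"):
            obs.contact = dist_maps.boundary_contact(
                obs.boundary, config.contact_distance_px)
        else:  # head
            high = segment_subject(frame, thr_high,
                                   config.min_blob_area_px, config,
                                   prev_centroid)
            try:
                *_, endpoints = fit_body_ellipse(mask)
            except FitError:
                endpoints = None
            head = None
            if endpoints is not None and high is not None:
                head = resolve_head_tail(endpoints, high, mask, prev_head)
            if head is None:
                head_undetermined += 1
            else:
                obs.head = head
                prev_head = head
                obs.contact = head_contact(head, config)
        observations.append(obs)

    result = TrackingResult(observations, algorithm, config)
    if result.invalid_fraction > 0.20:
        log.warning("%.0f%% of frames had no acceptable subject blob",
                    100 * result.invalid_fraction)
    if algorithm == "head" and observations and \
            head_undetermined > 0.2 * len(observations):
        log.warning("head undetermined on %d/%d frames",
                    head_undetermined, len(observations))
    return result
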