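"""Arena geometry, calibration and detection parameters.

The two-chamber social preference arena is a light rectangular floor with
two triangular stimulus chambers in opposite corners.  Only the chambers'
front walls matter for scoring: investigation is contact between the
subject's body (or head) and one of those walls.  Each front wall is
represented here as a line segment ("stimulus zone") plus a contact
tolerance in pixels; the floor is split into two "compartments" (each half
of the arena) for occupancy analysis.

Coordinate convention: pixel coordinates are 0-based, x rightward,
y downward (image convention).  Geometry in the config file is in pixels;
calibrated outputs are in cm via ``px_per_cm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import split as shapely_split


class ConfigError(ValueError):
    """A config file is missing a field or has an unusable value."""


class GeometryError(ValueError):
    """Arena geometry violates an invariant (overlap, coverage, ...)."""


@dataclass(frozen=True)
class ArenaConfig:
    """Validated geometry + detection parameters for one camera setup.

    Parameters
    ----------
    arena_rect : (x, y, w, h) of the arena floor in pixels.
    arena_size_cm : physical floor size, cm (default 37 x 22).
    px_per_cm : calibration scalar (> 0).
    frame_rate : video frame rate, frames/s.
    stimulus_zones : mapping name -> segment ((x1, y1), (x2, y2)) in px.
        Exactly two zones; order defines stim1/stim2.
    compartments : mapping name -> polygon (list of (x, y)) in px.
        Exactly two; if omitted, the two halves of the arena split by the
        perpendicular bisector of the segment joining the zone centers.
    contact_distance_px : max body/head-to-zone distance that still counts
        as contact (closed inequality: d <= contact_distance_px).
    detection_threshold_low : grayscale cutoff for the mouse body (pixels
        darker than this are body); excludes the brighter tail.
    detection_threshold_high : cutoff that additionally includes the tail.
    min_blob_area_px : smallest acceptable subject component.
    gap_merge_s : investigation gaps shorter than this never break a bout.
    bin_width_s : bin width for time-binned investigation curves.
    cable_max_width_px : widest cable the wired algorithm removes.
    invert : set True for a light subject on a dark floor.
    """

    arena_rect: tuple[float, float, float, float]
    px_per_cm: float
    stimulus_zones: dict[str, tuple[tuple[float, float], tuple[float, float]]]
    compartments: dict[str, list[tuple[float, float]]] | None = None
    arena_size_cm: tuple[float, float] = (37.0, 22.0)
    frame_rate: float = 30.0
    contact_distance_px: float = 2.0
    detection_threshold_low: float = 90.0
    detection_threshold_high: float = 140.0
    min_blob_area_px: int = 50
    gap_merge_s: float = 0.5
    bin_width_s: float = 20.0
    cable_max_width_px: float = 3.0
    invert: bool = False

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ConfigError("px_per_cm must be > 0")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be > 0")
        if self.detection_threshold_low > self.detection_threshold_high:
            raise GeometryError(
                "detection_threshold_low must be <= detection_threshold_high"
            )
        if len(self.stimulus_zones) != 2:
            raise GeometryError("exactly 2 stimulus zones are required")
        if self.compartments is None:
            object.__setattr__(self, "compartments", self._default_compartments())
        if len(self.compartments) != 2:
            raise GeometryError("exactly 2 compartments are required")
        self._validate_geometry()

    # -- derived geometry ---------------------------------------------------

    @property
    def zone_names(self) -> list[str]:
        return list(self.stimulus_zones)

    @property
    def compartment_names(self) -> list[str]:
        return list(self.compartments)

    def zone_lines(self) -> list[LineString]:
        return [LineString(seg) for seg in self.stimulus_zones.values()]

    def compartment_polys(self) -> list[Polygon]:
        return [Polygon(pts) for pts in self.compartments.values()]

    def arena_box(self) -> Polygon:
        x, y, w, h = self.arena_rect
        return box(x, y, x + w, y + h)

    def _default_compartments(self) -> dict[str, list[tuple[float, float]]]:
        """Split the arena into halves by the perpendicular bisector of the
        line joining the two zone centers."""
        (a, b) = [np.asarray(LineString(s).centroid.coords[0])
                  for s in self.stimulus_zones.values()]
        mid = (a + b) / 2.0
        d = b - a
        n = np.array([-d[1], d[0]])  # bisector direction
        norm = np.hypot(*n)
        if norm == 0:
            raise GeometryError("stimulus zone centers coincide")
        n /= norm
        x, y, w, h = self.arena_rect
        span = 4.0 * (w + h)
        cut = LineString([tuple(mid - span * n), tuple(mid + span * n)])
        pieces = shapely_split(self.arena_box(), cut)
        polys = [g for g in pieces.geoms if g.area > 1e-9]
        if len(polys) != 2:
            raise GeometryError("could not split arena into two compartments")
        # name each half after the zone it contains (comp1 holds stim1)
        out: dict[str, list[tuple[float, float]]] = {}
        names = self.zone_names
        pa = polys[0] if polys[0].distance(Point(a)) <= polys[1].distance(Point(a)) \
            else polys[1]
        pb = polys[0] if pa is polys[1] else polys[1]
        out[f"comp_{names[0]}"] = [tuple(p) for p in pa.exterior.coords[:-1]]
        out[f"comp_{names[1]}"] = [tuple(p) for p in pb.exterior.coords[:-1]]
        return out

    def _validate_geometry(self) -> None:
        tol = self.contact_distance_px
        arena = self.arena_box().buffer(tol)
        zones = self.zone_lines()
        for name, z in zip(self.zone_names, zones):
            if not arena.contains(z):
                raise GeometryError(f"stimulus zone {name!r} lies outside the arena")
        if zones[0].distance(zones[1]) <= 2 * tol:
            raise GeometryError(
                "stimulus zones must be disjoint and separated by more than "
                "2 * contact_distance_px; single-stimulus labeling would be "
                "ill-defined"
            )
        comps = self.compartment_polys()
        for name, c in zip(self.compartment_names, comps):
            if not c.is_valid:
                raise GeometryError(f"compartment {name!r} polygon is invalid")
            if not arena.contains(c):
                raise GeometryError(f"compartment {name!r} lies outside the arena")
        inter = comps[0].intersection(comps[1]).area
        if inter > 1e-6 * self.arena_box().area:
            raise GeometryError("compartments overlap")
        union = comps[0].union(comps[1]).area
        if union < 0.999 * self.arena_box().area:
            raise GeometryError("compartments do not cover the arena")

    # -- calibration --------------------------------------------------------

    def px_to_cm(self, point) -> np.ndarray:
        """Convert pixel coordinates to cm, origin at the arena corner.

        Accepts a single (x, y) pair or an (N, 2) array.
        """
        p = np.asarray(point, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("coordinates must be finite")
        origin = np.array(self.arena_rect[:2], dtype=float)
        return (p - origin) / self.px_per_cm

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arena_rect"] = list(self.arena_rect)
        d["arena_size_cm"] = list(self.arena_size_cm)
        d["stimulus_zones"] = {
            k: [list(p) for p in v] for k, v in self.stimulus_zones.items()
        }
        d["compartments"] = {
            k: [list(p) for p in v] for k, v in self.compartments.items()
        }
        return d

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_REQUIRED = ("arena_rect", "px_per_cm", "stimulus_zones")


def config_from_dict(data: dict) -> ArenaConfig:
    for key in _REQUIRED:
        if key not in data:
            raise ConfigError(f"config is missing required field {key!r}")
    kwargs = dict(data)
    kwargs["arena_rect"] = tuple(float(v) for v in kwargs["arena_rect"])
    if "arena_size_cm" in kwargs:
        kwargs["arena_size_cm"] = tuple(float(v) for v in kwargs["arena_size_cm"])
    kwargs["stimulus_zones"] = {
        str(k): tuple(tuple(float(c) for c in p) for p in v)
        for k, v in kwargs["stimulus_zones"].items()
    }
    if kwargs.get("compartments") is not None:
        kwargs["compartments"] = {
            str(k): [tuple(float(c) for c in p) for p in v]
            for k, v in kwargs["compartments"].items()
        }
    allowed = set(ArenaConfig.__dataclass_fields__)
    unknown = set(kwargs) - allowed
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    return ArenaConfig(**kwargs)


def load_config(path) -> ArenaConfig:
    """Load and validate an arena config from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        if path.suffix == ".json":
            data = json.load(fh)
        else:
            data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return config_from_dict(data)


def default_config(frame_size: tuple[int, int] = (240, 320),
                   **overrides) -> ArenaConfig:
    """A ready-to-use config for a 320x240 top-down view of a 37x22 cm arena.

    The arena floor fills most of the frame; the two stimulus-zone segments
    sit diagonally across the front of the two chamber corners (top-left and
    bottom-right), mirroring chambers placed in opposite corners.
    """
    h, w = frame_size
    margin = 10
    x0, y0 = margin, margin
    aw, ah = w - 2 * margin, h - 2 * margin
    zlen = 40.0
    zones = {
        "stim1": ((x0 + zlen, y0), (x0, y0 + zlen)),
        "stim2": ((x0 + aw - zlen, y0 + ah), (x0 + aw, y0 + ah - zlen)),
    }
    kwargs: dict = dict(
        arena_rect=(float(x0), float(y0), float(aw), float(ah)),
        px_per_cm=aw / 37.0,
        stimulus_zones=zones,
    )
    kwargs.update(overrides)
    return ArenaConfig(**kwargs)
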