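"""Conditioning-chamber geometries, zone classification, and the synthetic
below-tank tracking path.

Each automated chamber variant is a rectangular tank subdivided into a
starting area, a corridor, a V-shaped (funnel) decision area, and two
choice areas. The published dimensions fix zone sizes but not vertex
coordinates; the polygons here realize those dimensions with the funnel as
a trapezoid widening from the corridor exit to the full chamber width, and
are checked against the declared start-exit -> choice-entrance distances.

Variants (width x length in cm, distance start-exit -> choice entrance):

* ``B`` — 12 x 16, 6 cm (baseline Skinner tank, also the reduced-load task
  sequence experiment)
* ``C`` — 16 x 32, 11.5 cm (decision-time elongation, with a transparent
  barrier to detour)
* ``D`` — 16 x 32, 17.5 cm (internal partitions removed; no corridor zone)
* ``E`` — 20 x 32, 18.5 cm (residency chamber built inside the home tank;
  the published zone depths add to 33 cm, so the start area is 9 cm deep
  here instead of 10 to honour both the chamber length and the declared
  distance)

A below-tank camera is emulated by rendering the fish as a dark ellipse on
a light background and recovering its position by intensity-weighted
centroid detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = [
    "ChamberGeometry",
    "ZoneEvent",
    "chamber_geometry",
    "zone_of",
    "trace_to_events",
    "synthesize_frame",
    "detect_centroid",
    "OutOfBoundsError",
    "NoBlobError",
    "ZONE_ORDER",
]

# Tie-break priority on shared edges: a boundary point belongs to the zone
# later in this order (checked in reverse).
ZONE_ORDER = ("start", "corridor", "decision", "choice_left", "choice_right")


class OutOfBoundsError(ValueError):
    pass


class NoBlobError(RuntimeError):
    pass


@dataclass(frozen=True)
class ChamberGeometry:
    """Zone polygons (cm, origin at the start-wall left corner, y running
    from the start wall toward the choice areas)."""

    variant: str
    width: float
    length: float
    zones: dict = dc_field(default_factory=dict)       # name -> Polygon
    feeders: tuple = ()                                # (x, y) positions
    barriers: tuple = ()                               # ((x0,y0),(x1,y1)) segments
    start_choice_distance: float = 0.0                 # declared value, cm

    def measured_start_choice_distance(self) -> float:
        """Start-exit -> choice-entrance distance recomputed from polygons:
        straight-line depth from the start area's far edge to the near edge
        of a choice area (the in-chamber path runs straight down the
        funnel)."""
        start_exit = self.zones["start"].bounds[3]        # max y of start
        choice_entry = self.zones["choice_left"].bounds[1]  # min y of choice
        return float(choice_entry - start_exit)

    def validate(self) -> None:
        measured = self.measured_start_choice_distance()
        if abs(measured - self.start_choice_distance) > 0.1:
            raise ValueError(
                f"variant {self.variant}: measured start->choice distance "
                f"{measured:.2f} != declared {self.start_choice_distance}")
        names = [n for n in ZONE_ORDER if n in self.zones]
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = self.zones[a].intersection(self.zones[b])
                if inter.area > 1e-9:
                    raise ValueError(f"zones {a} and {b} overlap")


def _box(x0, y0, x1, y1) -> Polygon:
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def _build(variant: str, width: float, start_d: float, corridor_d: float,
           corridor_w: float, decision_d: float, choice_d: float,
           choice_w: float, distance: float,
           barrier_w: float | None = None) -> ChamberGeometry:
    length = start_d + corridor_d + decision_d + choice_d
    cx0 = (width - corridor_w) / 2
    cx1 = (width + corridor_w) / 2
    y_start = start_d
    y_corr = start_d + corridor_d
    y_dec = y_corr + decision_d
    zones = {"start": _box(0, 0, width, y_start)}
    if corridor_d > 0:
        zones["corridor"] = _box(cx0, y_start, cx1, y_corr)
    # V-shaped decision area: a funnel widening from the corridor mouth to
    # the full chamber width at the choice entrance.
    zones["decision"] = Polygon([(cx0, y_corr), (cx1, y_corr),
                                 (width, y_dec), (0, y_dec)])
    gap = (width - 2 * choice_w) / 2
    zones["choice_left"] = _box(gap, y_dec, gap + choice_w, y_dec + choice_d)
    zones["choice_right"] = _box(width - gap - choice_w, y_dec,
                                 width - gap, y_dec + choice_d)
    feeders = ((gap + choice_w / 2, y_dec + choice_d / 2),
               (width - gap - choice_w / 2, y_dec + choice_d / 2))
    barriers = ()
    if barrier_w is not None:
        bx0 = (width - barrier_w) / 2
        barriers = (((bx0, y_dec), (bx0 + barrier_w, y_dec)),)
    geom = ChamberGeometry(variant, width, length, zones, feeders, barriers,
                           distance)
    geom.validate()
    return geom


def chamber_geometry(variant: str) -> ChamberGeometry:
    """Construct the zone geometry for one chamber variant (B, C, D, E)."""
    if variant == "B":
        return _build("B", 12.0, 5.5, 2.5, 4.0, 3.5, 4.5, 6.0, 6.0)
    if variant == "C":
        return _build("C", 16.0, 16.0, 3.0, 4.0, 8.5, 4.5, 8.0, 11.5,
                      barrier_w=9.0)
    if variant == "D":
        # all internal dividers removed: no corridor zone, an open 17.5 cm
        # decision field between the start wall and the choice areas
        return _build("D", 16.0, 10.0, 0.0, 16.0, 17.5, 4.5, 8.0, 17.5)
    if variant == "E":
        return _build("E", 20.0, 9.0, 2.0, 5.0, 16.5, 4.5, 10.0, 18.5)
    raise ValueError(f"unknown chamber variant {variant!r}")


def zone_of(point, geometry: ChamberGeometry) -> str | None:
    """Zone containing ``point``, or None for wall dead-space.

    Boundary points resolve to the zone later in the fixed order
    start < corridor < decision < choice (half-open convention).
    """
    x, y = float(point[0]), float(point[1])
    if not (0 <= x <= geometry.width and 0 <= y <= geometry.length):
        raise OutOfBoundsError(f"({x}, {y}) outside the chamber")
    p = Point(x, y)
    for name in reversed(ZONE_ORDER):
        poly = geometry.zones.get(name)
        if poly is not None and poly.covers(p):
            return name
    return None


@dataclass(frozen=True)
class ZoneEvent:
    timestamp: float
    zone: str


def trace_to_events(trace, geometry: ChamberGeometry,
                    min_dwell: float = 0.2) -> list[ZoneEvent]:
    """Collapse a time-stamped position trace into debounced zone entries.

    A zone entry is emitted only once the position has remained in the new
    zone for at least ``min_dwell`` seconds of consecutive samples, which
    suppresses boundary jitter. Samples in wall dead-space extend the
    current zone. Consecutive emitted events always differ in zone.
    """
    events: list[ZoneEvent] = []
    current: str | None = None
    cand: str | None = None
    cand_t = 0.0
    last_t = None
    for t, pos in trace:
        t = float(t)
        if last_t is not None and t <= last_t:
            raise ValueError("timestamps must be strictly increasing")
        last_t = t
        z = zone_of(pos, geometry)
        if z is None or z == current:
            cand = None
            continue
        if z != cand:
            cand, cand_t = z, t
        if t - cand_t >= min_dwell or current is None:
            events.append(ZoneEvent(cand_t, z))
            current, cand = z, None
    return events


# --- synthetic camera -------------------------------------------------------

_FISH_AXES = (0.9, 0.35)   # ellipse semi-axes, cm (adult female guppy body)
_BACKGROUND = 220.0
_FISH_LEVEL = 40.0


def synthesize_frame(position, geometry: ChamberGeometry,
                     noise_sigma: float = 0.0, noise_seed: int | None = None,
                     dots_per_cm: int = 5) -> np.ndarray:
    """Render a synthetic below-tank camera frame: a dark ellipse (the
    fish) on a light background with optional additive Gaussian noise."""
    x, y = float(position[0]), float(position[1])
    if not (0 <= x <= geometry.width and 0 <= y <= geometry.length):
        raise OutOfBoundsError(f"({x}, {y}) outside the chamber")
    W = int(round(geometry.width * dots_per_cm))
    H = int(round(geometry.length * dots_per_cm))
    jj, ii = np.meshgrid(np.arange(W), np.arange(H))
    cx = (jj + 0.5) / dots_per_cm
    cy = (ii + 0.5) / dots_per_cm
    a, b = _FISH_AXES
    mask = ((cx - x) / a) ** 2 + ((cy - y) / b) ** 2 <= 1.0
    img = np.full((H, W), _BACKGROUND)
    img[mask] = _FISH_LEVEL
    if noise_sigma > 0:
        rng = np.random.default_rng(noise_seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def detect_centroid(image: np.ndarray, dots_per_cm: int = 5) -> tuple[float, float]:
    """Recover the fish position from a synthetic frame by darkness-weighted
    centroid over pixels darker than the midpoint threshold."""
    img = np.asarray(image, dtype=float)
    thresh = 0.5 * (_BACKGROUND + _FISH_LEVEL)
    weight = np.where(img < thresh, thresh - img, 0.0)
    total = weight.sum()
    if total <= 0:
        raise NoBlobError("no dark blob found in frame")
    ii, jj = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    x = float(((jj + 0.5) * weight).sum() / total) / dots_per_cm
    y = float(((ii + 0.5) * weight).sum() / total) / dots_per_cm
    return (x, y)
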