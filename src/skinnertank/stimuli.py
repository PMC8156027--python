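"""Numerosity dot-array stimulus generation with non-numerical cue control.

A numerosity stimulus is a set of black dots on a white rectangular field.
Because continuous perceptual variables (cumulative surface area, convex
hull, dot density) co-vary with numerosity, discrimination stimuli must be
controlled for them: cumulative-area ratios are confined to prescribed
bands, and within each pair either the convex hull of the items or their
density is equated between the smaller and the larger set.

Two hull notions appear here and must not be confused:

* ``convex_hull_area(points)`` / ``density(array)`` operate on dot
  *centers* — the textbook quantities (4 dots at unit-square corners have
  center-hull area 1 and density 4).
* Pair *matching* uses the convex hull of the dot *disks* (the polygon that
  circumscribes the items, including their extent). The item-wise hull is
  well defined for two-dot arrays, whose center hull is degenerate, and is
  what an observer of the printed card actually sees.

Generation is constraint-driven: radii are drawn (and, for banded pairs,
jointly rescaled) to satisfy the area-band ratio, the larger array is
placed at a spatial scale that makes the matching target reachable, and the
smaller array is iteratively rescaled about its centroid until its item
hull (or density) matches within tolerance. Everything is re-verifiable
from the emitted geometry alone.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from shapely.geometry import MultiPoint, Point
from shapely.ops import unary_union

__all__ = [
    "DotArray",
    "StimulusPair",
    "StimulusSet",
    "FeatureStimulus",
    "Placement",
    "ConstraintError",
    "AREA_BANDS",
    "CONTRASTS",
    "MANUAL_CARD",
    "DISPLAY_WINDOW",
    "DIAMETER_RANGE",
    "FEATURE_TASKS",
    "cumulative_area",
    "convex_hull_area",
    "density",
    "item_hull_area",
    "item_density",
    "effective_diameter_range",
    "generate_pair",
    "build_stimulus_set",
    "position_variants",
    "rotation_order",
    "pair_to_dict",
    "pair_from_dict",
    "render_array",
    "array_to_svg",
]

# Stimulus fields in cm: printed laminated cards for the manual procedure,
# monitor windows behind each choice area for the automated chambers.
MANUAL_CARD = (3.0, 3.0)
DISPLAY_WINDOW = (6.0, 5.0)
DIAMETER_RANGE = (0.75, 0.95)
MIN_GAP = 0.1            # minimum edge-to-edge dot separation, cm
MATCH_TOL = 0.05         # relative tolerance for hull/density equating
PACKING_LIMIT = 0.4      # dot-area fraction above which diameters shrink

# Cumulative-surface-area ratio bands (smaller set / larger set).
AREA_BANDS = {"low": (0.76, 0.85), "mid": (0.86, 0.95), "high": (0.96, 1.05)}

CONTRASTS = {"3v12": (3, 12), "2v3": (2, 3), "3v4": (3, 4),
             "4v5": (4, 5), "5v6": (5, 6)}


class ConstraintError(RuntimeError):
    """Raised when stimulus generation cannot satisfy a named constraint."""

    def __init__(self, constraint: str, message: str):
        self.constraint = constraint
        super().__init__(f"[{constraint}] {message}")


@dataclass(frozen=True)
class DotArray:
    """A numerosity stimulus: dot centers and radii inside a field.

    Coordinates are continuous cm with the origin at the lower-left corner
    of the field.
    """

    numerosity: int
    centers: np.ndarray          # (n, 2)
    radii: np.ndarray            # (n,)
    field_size: tuple[float, float]
    relaxed: bool = False        # True when packing relaxation shrank diameters

    def __post_init__(self):
        object.__setattr__(self, "centers",
                           np.asarray(self.centers, dtype=float).reshape(-1, 2))
        object.__setattr__(self, "radii",
                           np.asarray(self.radii, dtype=float).reshape(-1))

    def validate(self, diameter_range: tuple[float, float] | None = None,
                 min_gap: float = MIN_GAP) -> None:
        n = self.numerosity
        if n < 1:
            raise ConstraintError("numerosity", "empty array")
        if len(self.centers) != n or len(self.radii) != n:
            raise ConstraintError("shape", "centers/radii length != numerosity")
        w, h = self.field_size
        x, y = self.centers[:, 0], self.centers[:, 1]
        r = self.radii
        if np.any(x - r < -1e-9) or np.any(x + r > w + 1e-9) \
                or np.any(y - r < -1e-9) or np.any(y + r > h + 1e-9):
            raise ConstraintError("containment", "dot extends outside the field")
        if n > 1:
            d = np.linalg.norm(self.centers[:, None] - self.centers[None], axis=-1)
            req = r[:, None] + r[None, :] + min_gap
            np.fill_diagonal(d, np.inf)
            if np.any(d < req - 1e-9):
                raise ConstraintError("overlap", "dots overlap or violate the gap")
        if diameter_range is not None and not self.relaxed:
            lo, hi = diameter_range
            if np.any(2 * r < lo - 1e-9) or np.any(2 * r > hi + 1e-9):
                raise ConstraintError("diameter", "diameter outside configured range")


@dataclass(frozen=True)
class Placement:
    """Position of a stimulus pair on the display: pair-center offsets (cm)
    relative to the display center, center-to-center separation, and whether
    the left/right assignment is mirrored."""

    dx: float
    dy: float
    separation: float
    mirrored: bool = False
    index: int = 0


@dataclass(frozen=True)
class StimulusPair:
    small: DotArray
    large: DotArray
    area_band: str | None         # "low" | "mid" | "high" | None
    control_type: str             # "hull_matched" | "density_matched"
    pair_id: str = ""
    seed: int | None = None

    def area_ratio(self) -> float:
        return cumulative_area(self.small) / cumulative_area(self.large)

    def verify(self, tol: float = MATCH_TOL) -> None:
        """Re-check every pair invariant from the raw geometry."""
        if self.small.numerosity >= self.large.numerosity:
            raise ConstraintError("numerosity", "small >= large")
        self.small.validate()
        self.large.validate()
        if self.area_band is not None:
            lo, hi = AREA_BANDS[self.area_band]
            ratio = self.area_ratio()
            if not lo - 1e-9 <= ratio <= hi + 1e-9:
                raise ConstraintError(
                    "area_band", f"ratio {ratio:.4f} outside {self.area_band}")
        m = matching_metrics(self)
        if self.control_type == "hull_matched":
            a, b = m["hull_small"], m["hull_large"]
            if abs(a - b) / b > tol:
                raise ConstraintError("hull", f"hull mismatch {a:.3f} vs {b:.3f}")
        elif self.control_type == "density_matched":
            a, b = m["density_small"], m["density_large"]
            if abs(a - b) / b > tol:
                raise ConstraintError("density", f"density mismatch {a:.3f} vs {b:.3f}")
        else:
            raise ConstraintError("control_type", self.control_type)


@dataclass(frozen=True)
class StimulusSet:
    contrast: tuple[int, int]
    pairs: tuple[StimulusPair, ...]
    seed: int | None = None

    @property
    def composition(self) -> dict:
        bands: dict = {}
        controls: dict = {}
        for p in self.pairs:
            bands[p.area_band] = bands.get(p.area_band, 0) + 1
            controls[p.control_type] = controls.get(p.control_type, 0) + 1
        return {"bands": bands, "controls": controls}


@dataclass(frozen=True)
class FeatureStimulus:
    """A non-numerical discrimination pair (Skinner-tank warm-up tasks)."""

    kind: str                     # shape | color | size | shape2
    positive: dict = dc_field(default_factory=dict)
    negative: dict = dc_field(default_factory=dict)


# The three warm-up discriminations plus the late-phase second shape task:
# circle vs triangle, red vs green, large vs small square (area ratio 0.25),
# cross vs horizontal bar.
FEATURE_TASKS = {
    "shape": FeatureStimulus(
        "shape",
        {"form": "circle", "diameter_cm": 3.0},
        {"form": "triangle", "size_cm": (3.0, 3.0)}),
    "color": FeatureStimulus(
        "color",
        {"form": "patch", "rgb": (255, 0, 0)},
        {"form": "patch", "rgb": (0, 255, 0)}),
    "size": FeatureStimulus(
        "size",
        {"form": "square", "size_cm": (3.0, 3.0)},
        {"form": "square", "size_cm": (1.5, 1.5), "area_ratio": 0.25}),
    "shape2": FeatureStimulus(
        "shape2",
        {"form": "cross", "size_cm": (3.0, 0.75)},
        {"form": "bar", "size_cm": (3.0, 1.5)}),
}


# ---------------------------------------------------------------------------
# metrics

def cumulative_area(array: DotArray) -> float:
    """Total dot surface, sum of pi r^2 over dots, in cm^2."""
    if array.numerosity < 1 or array.radii.size == 0:
        raise ConstraintError("numerosity", "cumulative area of an empty array")
    return float(np.pi * np.sum(array.radii ** 2))


def convex_hull_area(points) -> float:
    """Area of the convex hull of 2-D points; 0 for degenerate sets."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 1:
        raise ValueError("convex hull of an empty point set")
    if pts.shape[0] < 3:
        return 0.0
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    return float(getattr(hull, "area", 0.0))


def density(array: DotArray) -> float:
    """Dots per cm^2 of center convex hull. Requires >= 3 non-collinear dots."""
    if array.numerosity < 3:
        raise ConstraintError("density", "density needs >= 3 dots")
    hull = convex_hull_area(array.centers)
    if hull <= 0:
        raise ConstraintError("density", "degenerate (collinear) center hull")
    return array.numerosity / hull


def _disk_union(centers: np.ndarray, radii: np.ndarray):
    return unary_union([Point(c).buffer(r, quad_segs=24)
                        for c, r in zip(centers, radii)])


def item_hull_area(array: DotArray) -> float:
    """Area of the convex polygon circumscribing the dot disks, cm^2."""
    return float(_disk_union(array.centers, array.radii).convex_hull.area)


def item_density(array: DotArray) -> float:
    """Numerosity per cm^2 of item-wise (disk) convex hull."""
    return array.numerosity / item_hull_area(array)


def matching_hull(array: DotArray, use_centers: bool) -> float:
    """Hull area used for pair equating: center hull where defined, item
    (disk) hull for pairs involving 2-dot arrays whose center hull is
    degenerate."""
    return convex_hull_area(array.centers) if use_centers else item_hull_area(array)


def matching_metrics(pair: "StimulusPair") -> dict:
    """Hull areas and densities of both arrays under the pair's matching
    convention (center-based iff the smaller array has >= 3 dots)."""
    use_centers = pair.small.numerosity >= 3
    hs = matching_hull(pair.small, use_centers)
    hl = matching_hull(pair.large, use_centers)
    return {"use_centers": use_centers, "hull_small": hs, "hull_large": hl,
            "density_small": pair.small.numerosity / hs if hs > 0 else math.inf,
            "density_large": pair.large.numerosity / hl if hl > 0 else math.inf}


def effective_diameter_range(n: int, field_size, diameter_range=DIAMETER_RANGE,
                             packing_limit: float = PACKING_LIMIT
                             ) -> tuple[tuple[float, float], bool]:
    """Packing relaxation: shrink the diameter range uniformly when the
    nominal dot-area fraction of the field exceeds ``packing_limit``.

    Returns the (possibly rescaled) range and a flag telling whether the
    relaxation was applied.
    """
    w, h = field_size
    dmean = 0.5 * (diameter_range[0] + diameter_range[1])
    packing = n * math.pi * (dmean / 2) ** 2 / (w * h)
    if packing <= packing_limit:
        return diameter_range, False
    s = math.sqrt(packing_limit / packing)
    return (diameter_range[0] * s, diameter_range[1] * s), True


# ---------------------------------------------------------------------------
# placement machinery

def _pairwise_ok(pts: np.ndarray, radii: np.ndarray, gap: float) -> bool:
    if len(pts) < 2:
        return True
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    req = radii[:, None] + radii[None, :] + gap
    np.fill_diagonal(d, np.inf)
    return bool(np.all(d >= req))


def _clamp(pts: np.ndarray, radii: np.ndarray, w: float, h: float) -> np.ndarray:
    out = pts.copy()
    out[:, 0] = np.clip(out[:, 0], radii, w - radii)
    out[:, 1] = np.clip(out[:, 1], radii, h - radii)
    return out


def _repel(pts: np.ndarray, radii: np.ndarray, gap: float, w: float, h: float,
           iters: int = 80) -> np.ndarray | None:
    """Push overlapping dots apart until the spacing constraint holds."""
    pts = pts.copy()
    for _ in range(iters):
        moved = False
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                delta = pts[j] - pts[i]
                dist = float(np.hypot(*delta))
                req = radii[i] + radii[j] + gap
                if dist < req - 1e-12:
                    if dist < 1e-9:
                        delta = np.array([1.0, 0.0])
                        dist = 1.0
                    push = (req - dist) / 2 + 1e-6
                    step = delta / dist * push
                    pts[i] -= step
                    pts[j] += step
                    moved = True
        pts = _clamp(pts, radii, w, h)
        if not moved and _pairwise_ok(pts, radii, gap):
            return pts
    return pts if _pairwise_ok(pts, radii, gap) else None


def _dart_place(radii: np.ndarray, field_size, rng: np.random.Generator,
                box: tuple[float, float, float, float] | None = None,
                gap: float = MIN_GAP, restarts: int = 25) -> np.ndarray | None:
    """Random sequential placement inside ``box`` (default: whole field),
    with a jittered-grid + repulsion fallback for dense configurations."""
    w, h = field_size
    n = len(radii)
    if box is None:
        box = (0.0, 0.0, w, h)
    x0, y0, x1, y1 = box
    order = np.argsort(radii)[::-1]
    for _ in range(restarts):
        pts = np.empty((n, 2))
        ok = True
        for k, i in enumerate(order):
            r = radii[i]
            placed = False
            for _try in range(60):
                p = rng.uniform([max(x0 + r, r), max(y0 + r, r)],
                                [min(x1 - r, w - r), min(y1 - r, h - r)])
                cur = pts[[order[j] for j in range(k)]] if k else np.empty((0, 2))
                cur_r = radii[order[:k]] if k else np.empty(0)
                if k == 0 or np.all(np.linalg.norm(cur - p, axis=1)
                                    >= cur_r + r + gap):
                    pts[i] = p
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    # dense fallback: jittered grid inside the box, then repulsion
    bw, bh = x1 - x0, y1 - y0
    cols = max(1, round(math.sqrt(n * bw / max(bh, 1e-9))))
    rows = math.ceil(n / cols)
    while cols * rows < n:
        cols += 1
    cw, ch = bw / cols, bh / rows
    cells = [(x0 + (c + 0.5) * cw, y0 + (r_ + 0.5) * ch)
             for r_ in range(rows) for c in range(cols)]
    idx = rng.permutation(len(cells))[:n]
    pts = np.array([cells[i] for i in idx])
    pts += rng.uniform(-0.08, 0.08, size=pts.shape)
    pts = _clamp(pts, radii, w, h)
    return _repel(pts, radii, gap, w, h)


def _hull_area_of(pts: np.ndarray, radii: np.ndarray,
                  use_centers: bool = False) -> float:
    if use_centers:
        return convex_hull_area(pts)
    return float(_disk_union(pts, radii).convex_hull.area)


def _construct_with_hull(radii: np.ndarray, field_size, target: float,
                         rng: np.random.Generator, tol: float,
                         use_centers: bool = False,
                         gap: float = MIN_GAP) -> np.ndarray | None:
    """Place dots so their matching-hull area hits ``target``: random init,
    then repeated centroid scaling with boundary clamping and repulsion."""
    w, h = field_size
    inner_tol = 0.55 * tol
    for _restart in range(12):
        pts = _dart_place(radii, field_size, rng, gap=gap)
        if pts is None:
            continue
        for _it in range(80):
            cur = _hull_area_of(pts, radii, use_centers)
            if cur <= 0:
                break
            if abs(cur - target) / target <= inner_tol:
                if _pairwise_ok(pts, radii, gap):
                    return pts
                pts2 = _repel(pts, radii, gap, w, h)
                if pts2 is not None and \
                        abs(_hull_area_of(pts2, radii, use_centers) - target) / target <= tol:
                    return pts2
                break
            s = float(np.clip(math.sqrt(target / cur), 0.75, 1.35))
            c = pts.mean(axis=0)
            pts = c + (pts - c) * s
            # recenter so the scaled configuration can fit, then clamp
            lo = (pts - radii[:, None]).min(axis=0)
            hi = (pts + radii[:, None]).max(axis=0)
            shift = np.where(lo < 0, -lo, 0.0) - np.where(hi > (w, h), hi - (w, h), 0.0)
            pts = _clamp(pts + shift, radii, w, h)
            if not _pairwise_ok(pts, radii, gap):
                fixed = _repel(pts, radii, gap, w, h)
                if fixed is None:
                    break
                pts = fixed
    return None


def _radii_with_total(n: int, total_area: float, lo: float, hi: float,
                      rng: np.random.Generator) -> np.ndarray | None:
    """Draw n radii within [lo, hi] (radii bounds) whose disk areas sum to
    ``total_area``; None when infeasible."""
    amin, amax = n * math.pi * lo ** 2, n * math.pi * hi ** 2
    if not amin - 1e-9 <= total_area <= amax + 1e-9:
        return None
    for _ in range(60):
        r = rng.uniform(lo, hi, size=n)
        for _it in range(80):
            cur = math.pi * float(np.sum(r ** 2))
            s = math.sqrt(total_area / cur)
            r = np.clip(r * s, lo, hi)
            cur = math.pi * float(np.sum(r ** 2))
            if abs(cur - total_area) / total_area < 1e-6:
                return r
    return None


def generate_pair(n_small: int, n_large: int, area_band: str | None,
                  control_type: str, field_size=DISPLAY_WINDOW,
                  diameter_range=DIAMETER_RANGE, seed: int | None = None,
                  tol: float = MATCH_TOL, max_iter: int = 400,
                  pair_id: str = "") -> StimulusPair:
    """Generate one controlled stimulus pair.

    ``area_band`` confines the cumulative-area ratio small/large;
    ``control_type`` equates either the item-wise convex hull or the
    item-wise density of the two arrays within ``tol`` (relative).
    Deterministic given ``seed``.
    """
    if n_small >= n_large:
        raise ConstraintError("numerosity", f"{n_small} vs {n_large}: small must be < large")
    if area_band is not None and area_band not in AREA_BANDS:
        raise ConstraintError("area_band", f"unknown band {area_band!r}")
    if control_type not in ("hull_matched", "density_matched"):
        raise ConstraintError("control_type", repr(control_type))
    rng = np.random.default_rng(seed)
    w, h = field_size

    # Packing relaxation is applied pair-wide: when either array forces a
    # diameter rescale, both arrays share it, keeping dot sizes comparable
    # across the pair (and keeping hull/density equating feasible).
    rng_small, relaxed_s = effective_diameter_range(n_small, field_size, diameter_range)
    rng_large, relaxed_l = effective_diameter_range(n_large, field_size, diameter_range)
    if rng_large[0] < rng_small[0]:
        rng_small = rng_large
    elif rng_small[0] < rng_large[0]:
        rng_large = rng_small
    relaxed_s = relaxed_l = relaxed_s or relaxed_l
    rlo_s, rhi_s = rng_small[0] / 2, rng_small[1] / 2
    rlo_l, rhi_l = rng_large[0] / 2, rng_large[1] / 2

    # Matching metric convention: center hulls where defined, item (disk)
    # hulls when the small array has only 2 dots (degenerate center hull).
    use_centers = n_small >= 3

    # Smallest matching hull the small array can span (compact cluster),
    # used to reject unreachable matching targets quickly.
    _r_hi = np.full(n_small, rhi_s)
    _compact = _dart_place(_r_hi, field_size, rng, box=(0.0, 0.0, w, h))
    if _compact is not None:
        _compact = _repel(_compact * 0.01 + _compact.mean(axis=0) * 0.99,
                          _r_hi, MIN_GAP, w, h)
    min_small_hull = (_hull_area_of(_compact, _r_hi, use_centers)
                      if _compact is not None else 0.0)

    # Largest matching hull the small array can span (corner spread), and —
    # for hull matching — the smallest hull the large array can contract to.
    # Comparing the two catches infeasible requests (e.g. 12 relaxed dots
    # on the 3x3 manual card against a 3-dot hull) before the search runs.
    margin = rhi_s
    corners = np.array([[margin, margin], [w - margin, margin],
                        [w - margin, h - margin], [margin, h - margin],
                        [w / 2, margin], [w / 2, h - margin],
                        [margin, h / 2], [w - margin, h / 2]])[:n_small]
    max_small_hull = _hull_area_of(corners, np.full(len(corners), rhi_s),
                                   use_centers)
    if control_type == "hull_matched":
        _r_l = np.full(n_large, rlo_l)
        _cl = _dart_place(_r_l, field_size, rng, box=(0.0, 0.0, w, h))
        if _cl is not None:
            _cl = _repel(_cl * 0.01 + _cl.mean(axis=0) * 0.99, _r_l,
                         MIN_GAP, w, h)
        min_large_hull = (_hull_area_of(_cl, _r_l, use_centers)
                          if _cl is not None else math.inf)
        if 0.93 * min_large_hull > max_small_hull * (1 + tol):
            raise ConstraintError(
                "hull", f"hull matching infeasible: {n_large} dots cannot "
                f"contract below ~{min_large_hull:.2f} cm^2 while {n_small} "
                f"dots reach at most {max_small_hull:.2f} cm^2 on this field")

    # Spatial scale of the larger array: hull matching needs a compact
    # large configuration (the few-dot array cannot span an arbitrarily
    # large hull), density matching tolerates any spread.
    scale = 0.82 if control_type == "hull_matched" else 1.0
    last_error = ConstraintError("generation", "no attempt made")
    for attempt in range(max_iter):
        radii_l = rng.uniform(rlo_l, rhi_l, size=n_large)
        if area_band is None:
            radii_s = rng.uniform(rlo_s, rhi_s, size=n_small)
        else:
            blo, bhi = AREA_BANDS[area_band]
            ratio = rng.uniform(blo + 0.1 * (bhi - blo), bhi - 0.1 * (bhi - blo))
            radii_s = _radii_with_total(
                n_small, ratio * math.pi * float(np.sum(radii_l ** 2)),
                rlo_s, rhi_s, rng)
            if radii_s is None:
                last_error = ConstraintError(
                    "area_band", f"band {area_band} infeasible for these radii")
                continue
        box = ((1 - scale) / 2 * w, (1 - scale) / 2 * h,
               (1 + scale) / 2 * w, (1 + scale) / 2 * h)
        pts_l = _dart_place(radii_l, field_size, rng, box=box)
        if pts_l is None:
            scale = min(1.0, scale + 0.05)
            last_error = ConstraintError("placement", "large array placement failed")
            continue
        hull_l = _hull_area_of(pts_l, radii_l, use_centers)
        if control_type == "hull_matched":
            target = hull_l
        else:
            target = hull_l * n_small / n_large
        if target < 0.9 * min_small_hull:
            # unreachable: grow the large array's spread (raises its hull
            # and hence the density target) and retry
            scale = min(1.0, scale + 0.05)
            last_error = ConstraintError(
                "hull" if control_type == "hull_matched" else "density",
                f"target {target:.2f} cm^2 below the small array's minimum hull")
            continue
        pts_s = _construct_with_hull(radii_s, field_size, target, rng, tol,
                                     use_centers=use_centers)
        if pts_s is None:
            # hull matching fails when the large hull exceeds the small
            # array's reach -> compact the large array; density targets sit
            # near the small array's lower bound -> spread it instead
            if control_type == "hull_matched":
                scale = max(0.35, scale * 0.93)
            else:
                scale = min(1.0, scale + 0.05)
            last_error = ConstraintError(
                "hull" if control_type == "hull_matched" else "density",
                f"could not match target {target:.2f} cm^2 for the small array")
            continue
        small = DotArray(n_small, pts_s, radii_s, field_size, relaxed=relaxed_s)
        large = DotArray(n_large, pts_l, radii_l, field_size, relaxed=relaxed_l)
        pair = StimulusPair(small, large, area_band, control_type,
                            pair_id=pair_id, seed=seed)
        try:
            pair.verify(tol=tol)
        except ConstraintError as err:
            last_error = err
            continue
        return pair
    raise ConstraintError(last_error.constraint,
                          f"generation failed after {max_iter} attempts: {last_error}")


def build_stimulus_set(contrast: str, seed: int | None = None,
                       field_size=DISPLAY_WINDOW,
                       diameter_range=DIAMETER_RANGE) -> StimulusSet:
    """Build the full pair set for one numerical contrast.

    The 3 vs 12 contrast gets 18 pairs with no cumulative-area band (it is
    controlled for hull and density only); every other contrast gets 24
    pairs, 8 per area band. In every set exactly half the pairs are
    hull-matched and half density-matched.
    """
    if contrast not in CONTRASTS:
        raise ConstraintError("contrast", f"unknown contrast {contrast!r}")
    n_small, n_large = CONTRASTS[contrast]
    ss = np.random.SeedSequence(seed)
    if contrast == "3v12":
        layout: list[tuple[str | None, str]] = [
            (None, "hull_matched" if i % 2 == 0 else "density_matched")
            for i in range(18)]
    else:
        layout = []
        for band in ("low", "mid", "high"):
            for i in range(8):
                layout.append((band, "hull_matched" if i % 2 == 0 else "density_matched"))
    pairs = []
    for i, ((band, control), child) in enumerate(zip(layout, ss.spawn(len(layout)))):
        pair_seed = int(child.generate_state(1)[0] % (2 ** 31))
        pairs.append(generate_pair(
            n_small, n_large, band, control, field_size=field_size,
            diameter_range=diameter_range, seed=pair_seed,
            pair_id=f"{contrast}-{i:02d}"))
    return StimulusSet((n_small, n_large), tuple(pairs), seed=seed)


# ---------------------------------------------------------------------------
# positioning

# 18 positions = 3 horizontal offsets x 3 vertical offsets x 2 separations,
# the documented default grid for the varied-position presentation scheme.
_VARIED_DX = (-1.5, 0.0, 1.5)
_VARIED_DY = (-2.0, 0.0, 2.0)
_VARIED_SEP = (6.0, 9.0)
_DEFAULT_SEP = 6.0
# Display window spanning both choice-area monitors, cm.
DISPLAY_SPAN = (16.0, 10.0)
_PATCH_HALF = 1.5  # stimulus patch half-extent, cm


def position_variants(pair: StimulusPair, scheme: str,
                      display=DISPLAY_SPAN) -> list[Placement]:
    """Enumerate stimulus placements for a presentation scheme.

    ``fixed``: a single central placement (left/right mirroring is handled
    by the side schedule). ``varied18``: 18 distinct placements varying the
    pair's horizontal/vertical position and the separation between the two
    stimuli, presented in rotation.
    """
    if scheme == "fixed":
        placements = [Placement(0.0, 0.0, _DEFAULT_SEP, index=0)]
    elif scheme == "varied18":
        placements = []
        i = 0
        for sep in _VARIED_SEP:
            for dx in _VARIED_DX:
                for dy in _VARIED_DY:
                    placements.append(Placement(dx, dy, sep, index=i))
                    i += 1
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    w, h = display
    for p in placements:
        half_span = p.separation / 2 + _PATCH_HALF + abs(p.dx)
        if half_span > w / 2 + 1e-9 or abs(p.dy) + _PATCH_HALF > h / 2 + 1e-9:
            raise ValueError(f"placement {p} exceeds the display window")
    return placements


def rotation_order(n_trials: int, n_positions: int = 18) -> list[int]:
    """Rotation schedule cycling through placements: over 36 trials each of
    18 placements is used exactly twice."""
    return [i % n_positions for i in range(n_trials)]


# ---------------------------------------------------------------------------
# serialization and rendering

def _array_to_dict(a: DotArray) -> dict:
    return {"numerosity": a.numerosity,
            "centers": a.centers.tolist(),
            "radii": a.radii.tolist(),
            "field_size": list(a.field_size),
            "relaxed": a.relaxed}


def _array_from_dict(d: dict) -> DotArray:
    return DotArray(int(d["numerosity"]), np.array(d["centers"]),
                    np.array(d["radii"]), tuple(d["field_size"]),
                    bool(d.get("relaxed", False)))


def pair_to_dict(pair: StimulusPair) -> dict:
    return {"pair_id": pair.pair_id, "area_band": pair.area_band,
            "control_type": pair.control_type, "seed": pair.seed,
            "small": _array_to_dict(pair.small),
            "large": _array_to_dict(pair.large)}


def pair_from_dict(d: dict) -> StimulusPair:
    return StimulusPair(_array_from_dict(d["small"]), _array_from_dict(d["large"]),
                        d.get("area_band"), d["control_type"],
                        pair_id=d.get("pair_id", ""), seed=d.get("seed"))


def set_to_json(stimset: StimulusSet) -> str:
    return json.dumps({"contrast": list(stimset.contrast), "seed": stimset.seed,
                       "pairs": [pair_to_dict(p) for p in stimset.pairs]}, indent=1)


def set_from_json(text: str) -> StimulusSet:
    d = json.loads(text)
    return StimulusSet(tuple(d["contrast"]),
                       tuple(pair_from_dict(p) for p in d["pairs"]),
                       seed=d.get("seed"))


def render_array(array: DotArray, dots_per_cm: int = 20) -> np.ndarray:
    """Rasterize black dots on a white field to a grayscale uint8 image.

    Row 0 is the top of the field (image convention)."""
    w, h = array.field_size
    W, H = int(round(w * dots_per_cm)), int(round(h * dots_per_cm))
    ys, xs = np.mgrid[0:H, 0:W]
    cx = (xs + 0.5) / dots_per_cm
    cy = h - (ys + 0.5) / dots_per_cm
    img = np.full((H, W), 255, dtype=np.uint8)
    for c, r in zip(array.centers, array.radii):
        img[(cx - c[0]) ** 2 + (cy - c[1]) ** 2 <= r ** 2] = 0
    return img


def array_to_svg(array: DotArray, scale: float = 40.0) -> str:
    """Vector export: one SVG circle per dot, white background."""
    w, h = array.field_size
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" '
             f'width="{w * scale:.0f}" height="{h * scale:.0f}" '
             f'viewBox="0 0 {w} {h}">',
             f'<rect width="{w}" height="{h}" fill="white"/>']
    for c, r in zip(array.centers, array.radii):
        parts.append(f'<circle cx="{c[0]:.4f}" cy="{h - c[1]:.4f}" '
                     f'r="{r:.4f}" fill="black"/>')
    parts.append("</svg>")
    return "\n".join(parts)
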