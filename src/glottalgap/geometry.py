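"""Glottal-gap geometry: midline regression, collision points and gap lines.

The measurement pipeline for one recording:

1. areas per frame by pixel counting; reference frame = largest glottis;
2. contact points on the edge between the left and right fold;
3. a least-squares midline through the contact points, regressing x on y
   (minimizing *horizontal* residuals) so near-vertical glottides are
   representable;
4. collision points where the midline enters/exits the fold+glottis union
   and the glottis region;
5. at the reference frame, the fractional point (e.g. 10% from the rear)
   of the glottis collision segment is converted to a ratio on the fold
   collision segment and frozen;
6. in every frame the frozen ratio relocates the anchor on that frame's
   fold segment, and the chord of the glottis along the perpendicular
   through the anchor is the gap distance in pixels.

Freezing the ratio against the fold segment — rather than the glottis
segment, which vanishes on closure — keeps the measurement line at a fixed
anatomical position that moves, rotates and zooms with the folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mask_io import BACKGROUND, GLOTTIS, LEFT_FOLD, RIGHT_FOLD, LabeledFrame, MaskSequence

#: Tolerance (px) to which reported collision points track the true
#: line/region boundary intersections.
COLLISION_TOL = 0.25

#: Which end of the image holds the posterior (rear) commissure.  With a
#: 90-degree rigid transoral scope the posterior end is at the top of the
#: frame, hence "top" by default.
DEFAULT_REAR = "top"


class GeometryError(ValueError):
    """Raised when a frame offers no geometric evidence for a measurement."""


# ---------------------------------------------------------------------------
# areas


@dataclass(frozen=True)
class AreaRecord:
    """Pixel counts of the three segmented regions in one frame."""

    left_px: int
    right_px: int
    glottis_px: int
    frame_index: int = 0


def compute_areas(frame: LabeledFrame) -> AreaRecord:
    """Count pixels per region label."""
    counts = np.bincount(frame.labels.ravel(), minlength=4)
    return AreaRecord(
        left_px=int(counts[LEFT_FOLD]),
        right_px=int(counts[RIGHT_FOLD]),
        glottis_px=int(counts[GLOTTIS]),
        frame_index=frame.frame_index,
    )


def relative_glottal_area(areas: AreaRecord) -> float:
    """Glottal area divided by the summed areas of glottis and both folds."""
    total = areas.left_px + areas.right_px + areas.glottis_px
    if total == 0:
        raise GeometryError("no larynx in frame: all region areas are zero")
    return areas.glottis_px / total


def select_reference_frame(seq: MaskSequence) -> int:
    """Index of the frame with the biggest glottal opening.

    The maximal-area frame is a robust choice of reference: small
    segmentation fluctuations do not move the argmax.  Ties break to the
    lowest index.
    """
    if not seq.frames:
        raise GeometryError("empty sequence")
    areas = [compute_areas(fr).glottis_px for fr in seq.frames]
    best = int(np.argmax(areas))
    if areas[best] == 0:
        raise GeometryError("glottis never opens in this sequence")
    return best


# ---------------------------------------------------------------------------
# contact points and midline regression


def extract_contact_points(frame: LabeledFrame) -> tuple[np.ndarray, str]:
    """Midpoints of 8-adjacent (left fold, right fold) pixel pairs.

    Returns ``(points, source)`` where points is an (n, 2) array of (x, y)
    coordinates and source is ``"contact"`` or ``"glottis_midpoints"``.
    When fewer than 3 contact pairs exist (folds separated along their
    whole length) the per-row midpoints of the glottis region are used
    instead.
    """
    lab = frame.labels
    left = lab == LEFT_FOLD
    right = lab == RIGHT_FOLD
    pts: set[tuple[float, float]] = set()
    # 8-neighborhood offsets (dj, di); scanning left-fold cells against
    # shifted right-fold cells covers every unordered adjacent pair once.
    for dj in (-1, 0, 1):
        for di in (-1, 0, 1):
            if dj == 0 and di == 0:
                continue
            shifted = np.zeros_like(right)
            js = slice(max(dj, 0), lab.shape[0] + min(dj, 0))
            is_ = slice(max(di, 0), lab.shape[1] + min(di, 0))
            jd = slice(max(-dj, 0), lab.shape[0] + min(-dj, 0))
            id_ = slice(max(-di, 0), lab.shape[1] + min(-di, 0))
            shifted[jd, id_] = right[js, is_]
            jj, ii = np.nonzero(left & shifted)
            # midpoint between the left cell center and right cell center
            for j, i in zip(jj, ii):
                pts.add((i + 0.5 + di / 2.0, j + 0.5 + dj / 2.0))
    if len(pts) >= 3:
        arr = np.array(sorted(pts), dtype=float)
        return arr, "contact"

    glot = lab == GLOTTIS
    rows = np.nonzero(glot.any(axis=1))[0]
    if rows.size == 0:
        raise GeometryError("no midline evidence: no fold contact and no glottis")
    cols = np.arange(lab.shape[1], dtype=float) + 0.5
    mids = [
        (float(np.mean(cols[glot[j]])), j + 0.5) for j in rows
    ]
    return np.array(mids, dtype=float), "glottis_midpoints"


@dataclass
class MidlineModel:
    """A fitted glottal-axis line: anchor point plus unit direction.

    ``fit_mode`` is ``"x_over_y"`` for the regular x-on-y regression and
    ``"fallback_horizontal"`` when all source points share one row (the
    x-on-y slope is then undefined and the horizontal line through their
    mean is returned).  ``source`` records where the points came from.
    """

    anchor_point: np.ndarray  # (x̄, ȳ)
    direction: np.ndarray  # unit vector
    source_points: np.ndarray = field(repr=False, default=None)
    fit_mode: str = "x_over_y"
    source: str = "contact"

    def point_at(self, t: float | np.ndarray) -> np.ndarray:
        return self.anchor_point + np.multiply.outer(t, self.direction)


def fit_midline(points: np.ndarray, source: str = "contact") -> MidlineModel:
    """Least-squares line through 2D points, regressing x on y.

    The slope of x against y is ``b = sum((x-x̄)(y-ȳ)) / sum((y-ȳ)²)``;
    the line is ``x = x̄ + b (y - ȳ)`` and minimizes the sum of squared
    *horizontal* residuals.  This representation is exact for vertical
    point sets (b = 0), the case an ordinary y-on-x regression cannot
    express.  All-horizontal point sets fall back to the horizontal line
    through ȳ.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise GeometryError("midline fit needs at least 2 points")
    if len(np.unique(pts, axis=0)) < 2:
        raise GeometryError("midline fit needs at least 2 distinct points")
    x, y = pts[:, 0], pts[:, 1]
    xbar, ybar = float(np.mean(x)), float(np.mean(y))
    syy = float(np.sum((y - ybar) ** 2))
    if syy == 0.0:
        direction = np.array([1.0, 0.0])
        mode = "fallback_horizontal"
    else:
        b = float(np.sum((x - xbar) * (y - ybar)) / syy)
        direction = np.array([b, 1.0]) / np.hypot(b, 1.0)
        mode = "x_over_y"
    return MidlineModel(
        anchor_point=np.array([xbar, ybar]),
        direction=direction,
        source_points=pts,
        fit_mode=mode,
        source=source,
    )


# ---------------------------------------------------------------------------
# collision points along the midline


def _clip_line_to_frame(
    p0: np.ndarray, d: np.ndarray, width: int, height: int
) -> tuple[float, float]:
    """Parameter interval [t0, t1] where p0 + t*d lies inside the frame box."""
    t0, t1 = -np.inf, np.inf
    for k, bound in ((0, width), (1, height)):
        if abs(d[k]) < 1e-15:
            if not (0.0 <= p0[k] <= bound):
                raise GeometryError("midline misses larynx: line outside frame")
            continue
        ta = (0.0 - p0[k]) / d[k]
        tb = (bound - p0[k]) / d[k]
        t0 = max(t0, min(ta, tb))
        t1 = min(t1, max(ta, tb))
    if not np.isfinite(t0) or not np.isfinite(t1) or t0 >= t1:
        raise GeometryError("midline misses larynx: line outside frame")
    return float(t0), float(t1)


def _traverse_cells(
    frame: LabeledFrame, p0: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact grid traversal of the line p0 + t*d across the frame.

    Returns ``(breaks, labels)`` where ``breaks`` are the sorted parameter
    values at which the line crosses a pixel boundary (including the frame
    entry/exit), and ``labels[k]`` is the region code of the cell spanning
    ``(breaks[k], breaks[k+1])``.  Unlike fixed-step sampling this cannot
    skip a corner-clipped cell however short its chord, and it is exactly
    invariant under integer translations of the label grid.
    """
    t0, t1 = _clip_line_to_frame(p0, d, frame.width, frame.height)
    ts = [np.array([t0, t1])]
    for k in range(2):
        if abs(d[k]) < 1e-15:
            continue
        a, b = p0[k] + t0 * d[k], p0[k] + t1 * d[k]
        lo, hi = min(a, b), max(a, b)
        lines = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
        ts.append((lines - p0[k]) / d[k])
    breaks = np.unique(np.concatenate(ts))
    breaks = breaks[(breaks >= t0) & (breaks <= t1)]
    mids = p0[None, :] + ((breaks[:-1] + breaks[1:]) / 2.0)[:, None] * d[None, :]
    i = np.floor(mids[:, 0]).astype(int)
    j = np.floor(mids[:, 1]).astype(int)
    ok = (i >= 0) & (i < frame.width) & (j >= 0) & (j < frame.height)
    labels = np.full(len(mids), BACKGROUND, dtype=np.uint8)
    labels[ok] = frame.labels[j[ok], i[ok]]
    return breaks, labels


def _oriented_direction(direction: np.ndarray, rear: str) -> np.ndarray:
    """Flip the line direction so marching runs rear -> front."""
    d = np.asarray(direction, dtype=float)
    if rear not in ("top", "bottom"):
        raise ValueError("rear must be 'top' or 'bottom'")
    want_down = rear == "top"  # start at large y, move toward small y
    if abs(d[1]) > 1e-12:
        if (d[1] > 0) == want_down:
            d = -d
    elif d[0] < 0:  # horizontal line: deterministic tie-break, march +x
        d = -d
    return d


@dataclass
class CollisionSet:
    """Entry/exit points of the midline through the fold and glottis regions.

    "Upper" is the rear (posterior) end.  The fold points bound the union
    fold+glottis region; the glottis points bound the glottis alone and are
    absent for a fully closed glottis.  The upper fold and upper glottis
    collisions coincide when the glottis reaches the rear edge of the folds.
    """

    fold_upper: np.ndarray
    fold_lower: np.ndarray
    glottis_upper: np.ndarray | None = None
    glottis_lower: np.ndarray | None = None


def find_collision_points(
    line: MidlineModel,
    frame: LabeledFrame,
    rear: str = DEFAULT_REAR,
) -> CollisionSet:
    """Trace the midline through the frame and record region entry/exit.

    Marching runs from the rear end of the frame; the entry/exit of the
    fold+glottis union gives the fold collisions and the entry/exit of the
    glottis gives the glottis collisions.  Spanning first-to-last entry
    (rather than stopping at the first exit) makes re-entrant shapes such
    as hourglass glottides span their full extent.
    """
    d = _oriented_direction(line.direction, rear)
    breaks, labels = _traverse_cells(frame, line.anchor_point, d)

    def pt(t):
        return line.anchor_point + t * d

    inside = (labels == LEFT_FOLD) | (labels == RIGHT_FOLD) | (labels == GLOTTIS)
    if not inside.any():
        raise GeometryError("midline misses larynx: no fold or glottis on the line")
    idx = np.nonzero(inside)[0]
    cs = CollisionSet(fold_upper=pt(breaks[idx[0]]), fold_lower=pt(breaks[idx[-1] + 1]))
    gidx = np.nonzero(labels == GLOTTIS)[0]
    if gidx.size:
        cs.glottis_upper = pt(breaks[gidx[0]])
        cs.glottis_lower = pt(breaks[gidx[-1] + 1])
    return cs


# ---------------------------------------------------------------------------
# anchors and gap distances


@dataclass(frozen=True)
class AnchorSpec:
    """A measurement line position frozen at the reference frame.

    ``fraction`` is the requested distance from the rear along the glottis
    collision segment (0.10 = the 10% line).  ``stored_ratio`` is that
    point re-expressed as dist(P, fold_lower)/dist(fold_upper, fold_lower)
    on the fold collision segment, which exists in every frame, including
    fully closed ones.
    """

    fraction: float
    stored_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if not 0.0 <= self.stored_ratio <= 1.0:
            raise ValueError("stored_ratio must be in [0, 1]")


def compute_anchor_ratio(collisions: CollisionSet, fraction: float) -> AnchorSpec:
    """Convert a rear-fraction of the glottis segment into a fold-segment ratio.

    P sits ``fraction`` of the way from the upper (rear) to the lower
    glottis collision; the stored ratio is P's normalized position on the
    fold segment measured from the lower collision.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if collisions.glottis_upper is None or collisions.glottis_lower is None:
        raise GeometryError("glottis collisions absent: cannot place anchor fraction")
    fold_len = float(np.linalg.norm(collisions.fold_upper - collisions.fold_lower))
    if fold_len == 0.0:
        raise GeometryError("degenerate fold collision segment")
    p = collisions.glottis_upper + fraction * (
        collisions.glottis_lower - collisions.glottis_upper
    )
    ratio = float(np.linalg.norm(p - collisions.fold_lower)) / fold_len
    return AnchorSpec(fraction=fraction, stored_ratio=min(max(ratio, 0.0), 1.0))


def locate_anchor_point(collisions: CollisionSet, spec: AnchorSpec) -> np.ndarray:
    """Reapply a stored fold-segment ratio in a new frame's collision set."""
    seg = collisions.fold_upper - collisions.fold_lower
    if float(np.linalg.norm(seg)) == 0.0:
        raise GeometryError("degenerate fold collision segment")
    return collisions.fold_lower + spec.stored_ratio * seg


def perpendicular_gap_distance(
    frame: LabeledFrame,
    line: MidlineModel,
    anchor: np.ndarray,
) -> float:
    """Chord of the glottis along the perpendicular to the midline at anchor.

    The perpendicular is traced across the whole frame in both directions;
    the distance is the Euclidean length between the first entry into and
    the last exit from the glottis region, and 0 when the line meets no
    glottis cell (closed glottis — not an error).
    """
    d = np.asarray(line.direction, dtype=float)
    perp = np.array([-d[1], d[0]])
    anchor = np.asarray(anchor, dtype=float)
    breaks, labels = _traverse_cells(frame, anchor, perp)
    gidx = np.nonzero(labels == GLOTTIS)[0]
    if gidx.size == 0:
        return 0.0
    return float(breaks[gidx[-1] + 1] - breaks[gidx[0]])


# ---------------------------------------------------------------------------
# whole-sequence measurement


MEASUREMENT_COLUMNS = [
    "subject_id",
    "group",
    "frame_index",
    "fraction",
    "distance_px",
    "relative_glottal_area",
    "left_px",
    "right_px",
    "glottis_px",
    "fit_mode",
    "flagged",
]


def measure_sequence(
    seq: MaskSequence,
    fractions: list[float] = (0.10, 0.50),
    rear: str = DEFAULT_REAR,
) -> pd.DataFrame:
    """Measure gap distances at each rear-fraction line in every frame.

    The reference frame (largest glottis) fixes one anchor ratio per
    fraction; every frame is then processed independently — contact points,
    midline, collisions, anchor relocation, perpendicular chord.  Frames
    where no midline can be fitted are kept with a NaN distance and
    ``flagged=True``, never silently dropped.
    """
    fractions = list(fractions)
    if not fractions:
        raise ValueError("need at least one fraction")
    ref_idx = select_reference_frame(seq)
    ref = seq.frames[ref_idx]
    ref_pts, ref_src = extract_contact_points(ref)
    ref_line = fit_midline(ref_pts, source=ref_src)
    ref_coll = find_collision_points(ref_line, ref, rear=rear)
    specs = {f: compute_anchor_ratio(ref_coll, f) for f in fractions}

    rows = []
    for fr in seq.frames:
        areas = compute_areas(fr)
        total = areas.left_px + areas.right_px + areas.glottis_px
        rel = areas.glottis_px / total if total > 0 else np.nan
        try:
            pts, src = extract_contact_points(fr)
            line = fit_midline(pts, source=src)
            coll = find_collision_points(line, fr, rear=rear)
            mode = line.fit_mode if src == "contact" else f"{line.fit_mode}+{src}"
            dists = {}
            for f in fractions:
                anchor = locate_anchor_point(coll, specs[f])
                dists[f] = perpendicular_gap_distance(fr, line, anchor)
            failed = False
        except GeometryError:
            mode, dists, failed = "failed", {f: np.nan for f in fractions}, True
        for f in fractions:
            rows.append(
                {
                    "subject_id": seq.subject_id,
                    "group": seq.group,
                    "frame_index": fr.frame_index,
                    "fraction": f,
                    "distance_px": dists[f],
                    "relative_glottal_area": rel,
                    "left_px": areas.left_px,
                    "right_px": areas.right_px,
                    "glottis_px": areas.glottis_px,
                    "fit_mode": mode,
                    "flagged": failed or not np.isfinite(rel),
                }
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
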