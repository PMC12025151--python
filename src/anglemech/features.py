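"""Geometric mechanism features in physical units from a mask plus spur.

Three feature groups drive the mechanism classifiers:

* TPI (thick peripheral iris): local iris thickness where circles of radius
  500 and 750 um centred on the scleral spur cross the iris, plus a 500 um
  circle centred on the iris root.  "Thickness" is the physical chord
  between the anterior- and posterior-surface crossing points of the circle.
* PB (pupillary block): signed iris curvature — the maximal sagitta of the
  posterior iris surface over its root-to-pupil chord (positive = anterior
  bowing) — and the spur-to-root insertion distance.
* ALCB (anteriorly located ciliary body): the fraction of the anterior
  ciliary-body surface in contact with the posterior iris.

All distances go through the anisotropic physical spacing.  Undefined
sub-measurements (a circle that misses the iris) are carried as NaN markers
so a feature row is still emitted; classifiers impute them from training
medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

from .geometry import (
    CILIARY,
    IRIS,
    SCLERA,
    AngleMechError,
    PhysicalSpacing,
    PixelPoint,
    SegmentationMask,
    _insertion_zone,
    normalize_orientation,
    physical_distance,
    region_boundary,
    validate_mask,
)
from .spur import SpurPoint, locate_scleral_spur

__all__ = [
    "TpiFeatures",
    "PbFeatures",
    "AlcbFeatures",
    "FeatureRow",
    "FEATURE_COLUMNS",
    "MeasurementUndefinedError",
    "RootNotFoundError",
    "CenterlineError",
    "SurfaceNotFoundError",
    "ValidationFailedError",
    "circle_crossings",
    "iris_thickness_on_circle",
    "iris_root_point",
    "extract_tpi_features",
    "iris_centerline",
    "extract_pb_features",
    "ciliary_anterior_surface",
    "extract_alcb_features",
    "extract_feature_row",
]

#: contact tolerance between ciliary anterior surface and iris, in pixels
EPSILON_CONTACT_PX = 2.0
#: a surface point must have the iris as nearest tissue within this range
SURFACE_IRIS_RANGE_UM = 500.0
#: anterior-facing test: outward normal within this angle of image-up
SURFACE_MAX_NORMAL_DEG = 75.0
#: contour smoothing window (vertices) for normal estimation
_NORMAL_SMOOTH = 9
#: staircase vertices failing the facing test are bridged up to this run length
_SURFACE_CLOSE_PX = 4
#: crossing pairs enclosing less circle arc than this are tangential grazes,
#: not transversal thickness samples; they are dropped when alternatives exist
MIN_ARC_DEG = 10.0


class MeasurementUndefinedError(AngleMechError):
    pass


class RootNotFoundError(AngleMechError):
    pass


class CenterlineError(AngleMechError):
    pass


class SurfaceNotFoundError(AngleMechError):
    pass


class ValidationFailedError(AngleMechError):
    def __init__(self, report):
        super().__init__("mask failed validation: " + "; ".join(report.failures))
        self.report = report


# ---------------------------------------------------------------------------
# feature containers

@dataclass(frozen=True)
class TpiFeatures:
    it_spur500_um: float
    it_spur750_um: float
    it_root500_um: float


@dataclass(frozen=True)
class PbFeatures:
    iris_curvature_um: float
    root_insertion_um: float


@dataclass(frozen=True)
class AlcbFeatures:
    contact_len_um: float
    anterior_len_um: float
    contact_ratio: float


FEATURE_COLUMNS = [
    "it_spur500_um",
    "it_spur750_um",
    "it_root500_um",
    "iris_curvature_um",
    "root_insertion_um",
    "contact_len_um",
    "anterior_len_um",
    "contact_ratio",
]


@dataclass(frozen=True)
class FeatureRow:
    image_id: str
    tpi: TpiFeatures
    pb: PbFeatures
    alcb: AlcbFeatures
    spur: SpurPoint
    mode: str
    flipped: bool

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "it_spur500_um": self.tpi.it_spur500_um,
            "it_spur750_um": self.tpi.it_spur750_um,
            "it_root500_um": self.tpi.it_root500_um,
            "iris_curvature_um": self.pb.iris_curvature_um,
            "root_insertion_um": self.pb.root_insertion_um,
            "contact_len_um": self.alcb.contact_len_um,
            "anterior_len_um": self.alcb.anterior_len_um,
            "contact_ratio": self.alcb.contact_ratio,
            "spur_row": self.spur.point.row,
            "spur_col": self.spur.point.col,
            "flipped": self.flipped,
        }

    def values(self) -> np.ndarray:
        d = self.to_dict()
        return np.array([d[c] for c in FEATURE_COLUMNS], dtype=float)


# ---------------------------------------------------------------------------
# circle / contour intersections

def circle_crossings(
    contour: np.ndarray,
    center: PixelPoint,
    radius_um: float,
    spacing: PhysicalSpacing,
) -> list[PixelPoint]:
    """Subpixel points where a closed contour crosses a physical circle.

    Each contour segment is solved exactly: in physically scaled
    coordinates the squared distance to the center is quadratic in the
    segment parameter, so crossings are quadratic roots in [0, 1).  Points
    are returned in contour-traversal order.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    sy, sx = spacing.um_per_px_y, spacing.um_per_px_x
    pts = np.asarray(contour, dtype=float)
    # physically scaled coordinates relative to the center
    vy = (pts[:, 0] - center.row) * sy
    vx = (pts[:, 1] - center.col) * sx
    out: list[PixelPoint] = []
    for i in range(len(pts) - 1):
        p0 = np.array([vy[i], vx[i]])
        dv = np.array([vy[i + 1] - vy[i], vx[i + 1] - vx[i]])
        a = dv @ dv
        b = 2.0 * (p0 @ dv)
        c = p0 @ p0 - radius_um**2
        if a == 0.0:
            continue
        disc = b * b - 4.0 * a * c
        if disc < 0:
            continue
        sq = np.sqrt(disc)
        for t in sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a))):
            if 0.0 <= t < 1.0:
                out.append(
                    PixelPoint(
                        row=float(pts[i, 0] + t * (pts[i + 1, 0] - pts[i, 0])),
                        col=float(pts[i, 1] + t * (pts[i + 1, 1] - pts[i, 1])),
                    )
                )
    return out


def _label_at(mask: SegmentationMask, row: float, col: float) -> int:
    h, w = mask.shape
    i, j = int(round(row)), int(round(col))
    if not (0 <= i < h and 0 <= j < w):
        return -1
    return int(mask.labels[i, j])


def iris_thickness_on_circle(
    mask: SegmentationMask,
    center: PixelPoint,
    radius_um: float,
    toward: PixelPoint | None = None,
) -> float:
    """Local iris thickness where a physical circle crosses the iris.

    Among consecutive crossing pairs of the circle with the iris boundary
    (ordered by angle about the center) whose enclosed arc midpoint lies
    inside the iris, the pair whose midpoint is nearest ``toward`` (the
    spur-side reference) is selected; the physical chord between the two
    crossings is returned.
    """
    contour = region_boundary(mask, IRIS)
    crossings = circle_crossings(contour, center, radius_um, mask.spacing)
    if len(crossings) < 2:
        raise MeasurementUndefinedError(
            f"circle r={radius_um:.0f} um at ({center.row:.1f},{center.col:.1f}) "
            f"has {len(crossings)} iris crossing(s)"
        )
    sy, sx = mask.spacing.um_per_px_y, mask.spacing.um_per_px_x
    ang = np.array(
        [np.arctan2((p.row - center.row) * sy, (p.col - center.col) * sx) for p in crossings]
    )
    order = np.argsort(ang)
    ang = ang[order]
    crossings = [crossings[i] for i in order]
    candidates: list[tuple[float, float, float]] = []  # (d_ref, arc_deg, chord)
    for i in range(len(crossings)):
        j = (i + 1) % len(crossings)
        dth = (ang[j] - ang[i]) % (2.0 * np.pi)
        mid = ang[i] + dth / 2.0
        mid_pt = PixelPoint(
            row=center.row + radius_um * np.sin(mid) / sy,
            col=center.col + radius_um * np.cos(mid) / sx,
        )
        if _label_at(mask, mid_pt.row, mid_pt.col) != IRIS:
            continue
        chord = physical_distance(crossings[i], crossings[j], mask.spacing)
        d_ref = (
            physical_distance(mid_pt, toward, mask.spacing) if toward is not None else 0.0
        )
        candidates.append((d_ref, np.degrees(dth), chord))
    if not candidates:
        raise MeasurementUndefinedError(
            f"no circle arc of r={radius_um:.0f} um lies inside the iris"
        )
    transversal = [c for c in candidates if c[1] >= MIN_ARC_DEG]
    pool = transversal if transversal else candidates
    return min(pool, key=lambda c: c[0])[2]


# ---------------------------------------------------------------------------
# iris root and TPI features

def iris_root_point(mask: SegmentationMask) -> PixelPoint:
    """Centroid of iris pixels 8-adjacent to the ciliary body (insertion zone)."""
    zone = _insertion_zone(mask)
    if not zone.any():
        raise RootNotFoundError("iris is not adjacent to the ciliary body")
    rr, cc = np.nonzero(zone)
    return PixelPoint(row=float(rr.mean()), col=float(cc.mean()))


def extract_tpi_features(mask: SegmentationMask, spur: SpurPoint) -> TpiFeatures:
    """Spur-circle (500/750 um) and root-circle (500 um) iris thickness.

    A circle that misses the iris yields a NaN marker for that field; the
    row is still emitted.
    """
    root = iris_root_point(mask)

    def safe(center: PixelPoint, r: float, toward: PixelPoint) -> float:
        try:
            return iris_thickness_on_circle(mask, center, r, toward=toward)
        except MeasurementUndefinedError:
            return float("nan")

    return TpiFeatures(
        it_spur500_um=safe(spur.point, 500.0, root),
        it_spur750_um=safe(spur.point, 750.0, root),
        it_root500_um=safe(root, 500.0, spur.point),
    )


# ---------------------------------------------------------------------------
# iris centerline (skeleton pruned to its longest geodesic path)

def _neighbours(px: tuple[int, int], members: set) -> list[tuple[int, int]]:
    r, c = px
    return [
        (r + dr, c + dc)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr or dc) and (r + dr, c + dc) in members
    ]


def _prune_short_branches(skel: np.ndarray, half_thickness: np.ndarray) -> np.ndarray:
    """Delete terminal skeleton branches shorter than the local half-width.

    The skeleton of a band grows 45-degree branches into its end corners;
    walking from each tip to the nearest junction and deleting short walks
    leaves the spine intact."""
    members = set(zip(*(a.tolist() for a in np.nonzero(skel))))
    if not members:
        return skel
    thresh = float(np.ceil(half_thickness[skel].max())) * 1.8 + 3
    out = skel.copy()
    for start in list(members):
        if start not in members or len(_neighbours(start, members)) != 1:
            continue
        walk = [start]
        prev, cur = None, start
        while len(walk) <= thresh:
            nbrs = [p for p in _neighbours(cur, members) if p != prev]
            if len(nbrs) != 1:
                break
            prev, cur = cur, nbrs[0]
            if len(_neighbours(cur, members)) > 2:  # reached a junction
                for p in walk:
                    members.discard(p)
                    out[p] = False
                break
            walk.append(cur)
    return out


def _trim_corner_dives(line: np.ndarray, half_thickness: np.ndarray) -> np.ndarray:
    """Trim path ends where the medial axis dives toward a band corner.

    Along the spine the half-width profile changes slowly (a thickness taper
    is a few percent per pixel); a corner dive loses half-width at ~0.7 px
    per px.  Ends are trimmed while the 5-px half-width slope is steep."""
    vals = half_thickness[line[:, 0].astype(int), line[:, 1].astype(int)]
    n = len(vals)
    window, max_slope = 5, 0.25
    max_trim = int(2 * vals.max()) + window

    def trim_len(v: np.ndarray) -> int:
        stop = min(max_trim, n - window - 1)
        for i in range(stop):
            if (v[i + window] - v[i]) / window < max_slope:
                return i
        return stop

    a = trim_len(vals)
    b = trim_len(vals[::-1])
    if n - a - b >= 3:
        line = line[a: n - b]
    return line


def _extend_to_boundary(line: np.ndarray, region: np.ndarray, k: int = 15) -> np.ndarray:
    """Extend both path ends along their local tangent to the region edge.

    The medial axis stops about half a band-width short of the band's ends;
    straight extrapolation completes the centerline to its full extent."""
    h, w = region.shape

    def extension(end: np.ndarray, inner: np.ndarray) -> np.ndarray | None:
        d = end - inner
        norm = np.linalg.norm(d)
        if norm == 0:
            return None
        d = d / norm
        pts = []
        p = end.copy()
        for _ in range(10 * k):
            p = p + d
            i, j = int(round(p[0])), int(round(p[1]))
            if not (0 <= i < h and 0 <= j < w) or not region[i, j]:
                break
            pts.append(p.copy())
        return np.array(pts) if pts else None

    kk = min(k, len(line) - 1)
    head = extension(line[0], line[kk])
    tail = extension(line[-1], line[-1 - kk])
    parts = []
    if head is not None:
        parts.append(head[::-1])
    parts.append(line)
    if tail is not None:
        parts.append(tail)
    return np.vstack(parts)


def iris_centerline(mask: SegmentationMask) -> np.ndarray:
    """Ordered (row, col) polyline along the iris skeleton, root to pupil.

    Short terminal branches (skeleton artifacts at the band's end corners)
    are pruned before the longest geodesic path is extracted."""
    iris = mask.tissue(IRIS)
    skel = skeletonize(iris)
    half_thickness = ndi.distance_transform_edt(iris)
    skel = _prune_short_branches(skel, half_thickness)
    rr, cc = np.nonzero(skel)
    if len(rr) < 3:
        raise CenterlineError("iris skeleton degenerate (< 3 points)")
    idx = {(r, c): k for k, (r, c) in enumerate(zip(rr.tolist(), cc.tolist()))}
    edges = []
    for (r, c), k in idx.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                k2 = idx.get((r + dr, c + dc))
                if k2 is not None:
                    edges.append((k, k2))
    e = np.array(edges)
    n = len(rr)
    g = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)).tocsr()

    def farthest(src: int):
        dist, pred = dijkstra(g, indices=src, return_predecessors=True, unweighted=True)
        dist[np.isinf(dist)] = -1
        far = int(np.argmax(dist))
        return far, pred

    u, _ = farthest(0)
    v, pred = farthest(u)
    path = [v]
    while path[-1] != u:
        p = pred[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    line = np.column_stack([rr[path], cc[path]]).astype(float)
    line = _trim_corner_dives(line, half_thickness)
    line = _extend_to_boundary(line, iris)
    root = iris_root_point(mask)
    d_first = np.hypot(*(line[0] - root.as_array()))
    d_last = np.hypot(*(line[-1] - root.as_array()))
    if d_last < d_first:
        line = line[::-1]
    return line


# ---------------------------------------------------------------------------
# PB features

def _posterior_boundary(mask: SegmentationMask) -> np.ndarray:
    """Subpixel posterior iris surface, ordered root (left) to pupil (right).

    After orientation normalization the posterior surface is the side facing
    the ciliary body/lens (larger row).  The iris of a single-angle image is
    band-like (x-monotone), so the surface is the per-column deepest iris
    pixel, placed at the 0.5 iso-level."""
    iris = mask.tissue(IRIS)
    cols = np.flatnonzero(iris.any(axis=0))
    if len(cols) < 3:
        raise CenterlineError("iris too small for a posterior boundary")
    h = iris.shape[0]
    rows_idx = np.arange(h)[:, None]
    deepest = np.max(np.where(iris[:, cols], rows_idx, -1), axis=0)
    return np.column_stack([deepest + 0.5, cols]).astype(float)


def extract_pb_features(mask: SegmentationMask, spur: SpurPoint) -> PbFeatures:
    """Signed posterior-surface sagitta and spur-to-root insertion distance.

    Curvature is the extremal signed perpendicular physical distance from
    the posterior boundary to its root-to-pupil chord, positive toward the
    cornea/sclera side (anterior bowing).
    """
    sy, sx = mask.spacing.um_per_px_y, mask.spacing.um_per_px_x
    bnd = _posterior_boundary(mask)
    phys = np.column_stack([bnd[:, 1] * sx, bnd[:, 0] * sy])  # (x_um, y_um)
    a, b = phys[0], phys[-1]
    chord = b - a
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise CenterlineError("degenerate posterior chord")
    u = chord / norm
    n = np.array([u[1], -u[0]])
    if n[1] > 0:  # orient toward -y (anterior / cornea side)
        n = -n
    dev = (phys - a) @ n
    curvature = float(dev[np.argmax(np.abs(dev))])
    root = iris_root_point(mask)
    return PbFeatures(
        iris_curvature_um=curvature,
        root_insertion_um=physical_distance(spur.point, root, mask.spacing),
    )


# ---------------------------------------------------------------------------
# ALCB features

def _outward_normals(contour: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Unit outward normals at each vertex of a closed (row, col) contour.

    The contour is smoothed (cyclic moving average) before tangent
    estimation so marching-squares staircase steps do not dominate the
    normal direction."""
    c = ndi.uniform_filter1d(contour, size=_NORMAL_SMOOTH, axis=0, mode="wrap")
    tang = np.roll(c, -1, axis=0) - np.roll(c, 1, axis=0)
    nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
    lens = np.linalg.norm(nrm, axis=1)
    lens[lens == 0] = 1.0
    nrm = nrm / lens[:, None]
    # flip so normals point out of the region (majority vote on samples)
    probe = c + 1.5 * nrm
    h, w = region.shape
    ii = np.clip(np.round(probe[:, 0]).astype(int), 0, h - 1)
    jj = np.clip(np.round(probe[:, 1]).astype(int), 0, w - 1)
    inside_frac = region[ii, jj].mean()
    if inside_frac > 0.5:
        nrm = -nrm
    return nrm


def ciliary_anterior_surface(mask: SegmentationMask) -> np.ndarray:
    """Anterior ciliary-body surface as an ordered open (row, col) polyline.

    A ciliary boundary point belongs to the anterior surface when it faces
    anteriorly (outward normal within ``SURFACE_MAX_NORMAL_DEG`` of image-up
    after orientation normalization) and either its nearest non-ciliary,
    non-background tissue within ``SURFACE_IRIS_RANGE_UM`` is the iris, or
    nothing but background lies above it in its column.  The maximal
    connected arc of qualifying points is returned.
    """
    contour = region_boundary(mask, CILIARY)[:-1]
    cb = mask.tissue(CILIARY)
    normals = _outward_normals(contour, cb)
    upward = -normals[:, 0] >= np.cos(np.deg2rad(SURFACE_MAX_NORMAL_DEG))

    sy, sx = mask.spacing.um_per_px_y, mask.spacing.um_per_px_x
    d_iris = ndi.distance_transform_edt(~mask.tissue(IRIS), sampling=(sy, sx))
    d_scl = ndi.distance_transform_edt(~mask.tissue(SCLERA), sampling=(sy, sx))
    ii = np.clip(np.round(contour[:, 0]).astype(int), 0, cb.shape[0] - 1)
    jj = np.clip(np.round(contour[:, 1]).astype(int), 0, cb.shape[1] - 1)
    di = d_iris[ii, jj]
    ds = d_scl[ii, jj]
    iris_nearest = (di <= SURFACE_IRIS_RANGE_UM) & (di < ds)

    other = mask.tissue(IRIS) | mask.tissue(SCLERA)
    tissue_above = np.vstack(
        [np.zeros((1, other.shape[1]), dtype=bool), np.cumsum(other, axis=0)[:-1] > 0]
    )
    clear_above = ~tissue_above[ii, jj]

    ok = upward & (iris_nearest | clear_above)
    # bridge short staircase interruptions (cyclic morphological closing)
    if ok.any() and not ok.all():
        tiled = np.concatenate([ok, ok, ok])
        closed = ndi.binary_closing(tiled, structure=np.ones(2 * _SURFACE_CLOSE_PX + 1))
        ok = closed[len(ok): 2 * len(ok)]
    if not ok.any():
        raise SurfaceNotFoundError("no anterior ciliary surface found")

    # longest cyclic run of qualifying vertices
    n = len(ok)
    if ok.all():
        run = np.arange(n)
    else:
        start = int(np.flatnonzero(~ok)[0])
        rolled = np.roll(ok, -start)
        best_len, best_at, cur = 0, 0, 0
        for i, q in enumerate(rolled):
            cur = cur + 1 if q else 0
            if cur > best_len:
                best_len, best_at = cur, i - cur + 1
        run = (np.arange(best_at, best_at + best_len) + start) % n
    return contour[run]


def extract_alcb_features(mask: SegmentationMask) -> AlcbFeatures:
    """Contact length, anterior-surface length, and their ratio.

    Contact is where the anterior ciliary surface lies within
    ``EPSILON_CONTACT_PX`` pixels of the iris component; arc lengths are
    computed on the physically scaled polyline."""
    surf = ciliary_anterior_surface(mask)
    sy, sx = mask.spacing.um_per_px_y, mask.spacing.um_per_px_x
    d_iris = ndi.distance_transform_edt(~mask.tissue(IRIS), sampling=(sy, sx))
    ii = np.clip(np.round(surf[:, 0]).astype(int), 0, mask.shape[0] - 1)
    jj = np.clip(np.round(surf[:, 1]).astype(int), 0, mask.shape[1] - 1)
    di = d_iris[ii, jj]
    eps_um = EPSILON_CONTACT_PX * 0.5 * (sx + sy)
    d = np.diff(surf, axis=0)
    seg = np.hypot(d[:, 1] * sx, d[:, 0] * sy)
    seg_contact = 0.5 * (di[1:] + di[:-1]) <= eps_um
    anterior = float(seg.sum())
    contact = float(seg[seg_contact].sum())
    ratio = contact / anterior if anterior > 0 else float("nan")
    return AlcbFeatures(contact_len_um=contact, anterior_len_um=anterior, contact_ratio=ratio)


# ---------------------------------------------------------------------------
# orchestration

def extract_feature_row(mask: SegmentationMask, image_id: str = "image") -> FeatureRow:
    """Validate, normalize, localize the spur, and compute all feature groups.

    Undefined sub-measurements are carried as NaN; only hard validation
    failures abort (raising :class:`ValidationFailedError`).
    """
    report = validate_mask(mask)
    if not report.ok:
        raise ValidationFailedError(report)
    mask = normalize_orientation(mask)
    spur = locate_scleral_spur(mask)
    tpi = extract_tpi_features(mask, spur)
    pb = extract_pb_features(mask, spur)
    alcb = extract_alcb_features(mask)
    return FeatureRow(
        image_id=image_id,
        tpi=tpi,
        pb=pb,
        alcb=alcb,
        spur=spur,
        mode=mask.mode.value,
        flipped=mask.flipped,
    )
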