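"""Parametric renderer of single-angle anterior-segment label masks.

Clinical UBM datasets in this problem area are not publicly available, so
the package ships a phantom generator that emulates the anatomy of a single
anterior-chamber-angle image: a corneoscleral shell descending into the
angle recess, an iris band with a controllable linear thickness profile and
a circular-arc posterior surface (signed sagitta = bowing), and a ciliary
body wedge attached under the sclera whose tip advances along the posterior
iris by a controllable contact fraction.

Every mask comes with exact ground truth.  Ground truth is computed on the
*continuous* micrometre-space boundary curves (shapely does the
circle-boundary intersections), independently of rasterization, so the
measure-after-render loop compares two genuinely different code paths.
Boundary jitter is applied to the curves *before* both ground-truth
evaluation and rasterization, so ground truth stays analytic under noise.

All anatomy is laid out in physical micrometres (x right, y down, origin at
the image top-left) in the canonical orientation (angle recess on the left);
masks can be emitted mirrored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LinearRing, Point, Polygon

from .geometry import (
    BACKGROUND,
    CILIARY,
    IRIS,
    SCLERA,
    AcquisitionMode,
    AngleMechError,
    PixelPoint,
    SegmentationMask,
    spacing_for_mode,
)

__all__ = [
    "AnatomyParams",
    "GroundTruth",
    "CohortSpec",
    "CohortSample",
    "RenderError",
    "CohortSpecError",
    "render_mask",
    "sample_cohort",
    "INTEGRATED_CLASSES",
]


class RenderError(AngleMechError):
    pass


class CohortSpecError(AngleMechError):
    pass


# ---------------------------------------------------------------------------
# anatomy layout constants (micrometres, canonical orientation)

ROOT_X_UM = 2400.0          # x of the iris root edge
ROOT_Y_UM = 3000.0          # y of the posterior iris root corner
RECESS_GAP_UM = 120.0       # sclera-to-anterior-iris gap in the narrow angle
SCLERA_THICKNESS_UM = 800.0
PARALLEL_LEN_UM = 250.0     # length of the near-apposed recess segment
SCLERA_RISE_SLOPE = 0.45    # inner scleral surface rising away from the iris
SCLERA_DIVE_SLOPE = 2.5     # inner surface wrapping down behind the root
CB_SURFACE_LEN_UM = 1500.0  # anterior ciliary surface tracked along the iris
CB_GAP_MAX_UM = 300.0       # iris-ciliary gap beyond the contact zone
CB_GAP_RAMP_UM = 400.0      # arc length over which the gap opens
CB_TIP_DROP_UM = 600.0      # steep terminal edge of the ciliary wedge
CB_LEFT_TOP_Y_UM = 4000.0   # where the wedge pinches out under the sclera
CB_BELLY_Y_UM = 4350.0      # depth of the wedge belly
_GT_STEP_UM = 1.0           # sampling step of the continuous curves

#: generator label thresholds -- conventions for producing separable classes,
#: not claims about clinical cut-offs.
PB_SAGITTA_THRESHOLD_UM = 200.0
TPI_IT750_THRESHOLD_UM = 500.0
ALCB_CONTACT_THRESHOLD = 0.4

INTEGRATED_CLASSES = ("PURE_PB", "PURE_NON_PB", "MM", "OTHERS")


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class AnatomyParams:
    """Scene description for one rendered angle image.

    Defaults are a mid-range narrow-angle configuration on the standard
    half-frame raster.  ``offset_um`` rigidly translates the whole anatomy.
    """

    mode: AcquisitionMode = AcquisitionMode.HALF_FRAME
    width_px: int = 1024
    height_px: int = 655
    iris_thickness_root_um: float = 480.0
    iris_thickness_pupil_um: float = 360.0
    bowing_sagitta_um: float = 150.0
    iris_length_um: float = 4500.0
    ciliary_contact_fraction: float = 0.3
    offset_um: tuple[float, float] = (0.0, 0.0)
    boundary_jitter_px: float = 0.5
    orientation: str = "left"

    def validate(self) -> None:
        if self.iris_thickness_root_um <= 0 or self.iris_thickness_pupil_um <= 0:
            raise RenderError("iris thickness endpoints must be positive")
        if self.iris_length_um <= 0:
            raise RenderError("iris length must be positive")
        if not 0.0 <= self.ciliary_contact_fraction <= 1.0:
            raise RenderError("ciliary_contact_fraction must lie in [0, 1]")
        if self.orientation not in ("left", "right"):
            raise RenderError(f"orientation must be 'left' or 'right', got {self.orientation!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-image truth, evaluated on the continuous boundary curves."""

    spur: PixelPoint
    root: PixelPoint
    it_spur500_um: float
    it_spur750_um: float
    it_root500_um: float
    sagitta_um: float
    root_insertion_um: float
    contact_len_um: float
    anterior_len_um: float
    contact_ratio: float
    pb: bool
    tpi: bool
    alcb: bool
    seed: int
    params: AnatomyParams


# ---------------------------------------------------------------------------
# continuous scene model

def _arc_y(x: np.ndarray, x0: float, x1: float, y_chord: float, sagitta: float) -> np.ndarray:
    """Circular arc through (x0, y_chord)-(x1, y_chord), apex ``sagitta`` toward -y."""
    if abs(sagitta) < 1e-9:
        return np.full_like(np.asarray(x, dtype=float), y_chord)
    c = x1 - x0
    xm = 0.5 * (x0 + x1)
    r = ((c / 2.0) ** 2 + sagitta**2) / (2.0 * sagitta)  # signed radius
    yc = y_chord - sagitta + r
    inside = np.clip(r**2 - (np.asarray(x, dtype=float) - xm) ** 2, 0.0, None)
    return yc - np.sign(sagitta) * np.sqrt(inside)


def _gap_profile(u: np.ndarray) -> np.ndarray:
    """Quadratic ease-out: fast initial opening (so the contact zone ends
    crisply at the nominal contact length), smooth saturation at 1."""
    u = np.clip(u, 0.0, 1.0)
    return 1.0 - (1.0 - u) ** 2


class _Scene:
    """Continuous boundary curves for one (params, seed) pair, in micrometres."""

    def __init__(self, params: AnatomyParams, seed: int):
        params.validate()
        self.params = params
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        sp = spacing_for_mode(params.mode, params.width_px, params.height_px)
        self.spacing = sp
        ox, oy = params.offset_um
        self.xr = ROOT_X_UM + ox
        self.yr = ROOT_Y_UM + oy
        self.xp = self.xr + params.iris_length_um

        jitter_um = params.boundary_jitter_px * sp.um_per_px_y
        self._jit_post = self._make_jitter(rng, jitter_um, anchor=self.xr)
        self._jit_sc = self._make_jitter(rng, jitter_um, anchor=self.xr)

        # dense iris curves
        self.xs = np.arange(self.xr, self.xp + _GT_STEP_UM, _GT_STEP_UM)
        self.post = (
            _arc_y(self.xs, self.xr, self.xp, self.yr, params.bowing_sagitta_um)
            + self._jit_post(self.xs)
        )
        frac = (self.xs - self.xr) / (self.xp - self.xr)
        self.thick = (
            params.iris_thickness_root_um
            + (params.iris_thickness_pupil_um - params.iris_thickness_root_um) * frac
        )
        self.ant = self.post - self.thick

        # ciliary anterior surface: posterior curve + opening gap, tracked by arc length
        seg = np.hypot(np.diff(self.xs), np.diff(self.post))
        self.arclen = np.concatenate([[0.0], np.cumsum(seg)])
        self.contact_len_nominal = params.ciliary_contact_fraction * CB_SURFACE_LEN_UM
        self.gap = CB_GAP_MAX_UM * _gap_profile(
            (self.arclen - self.contact_len_nominal) / CB_GAP_RAMP_UM
        )
        self.on_surface = self.arclen <= CB_SURFACE_LEN_UM
        if self.arclen[-1] <= CB_SURFACE_LEN_UM:
            raise RenderError("iris too short for the ciliary anterior surface")
        self.x_tip = float(np.interp(CB_SURFACE_LEN_UM, self.arclen, self.xs))

        # geometric sanity
        if self.xp > params.width_px * sp.um_per_px_x - 200.0:
            raise RenderError("iris extends beyond the scan range")
        if np.max(self.post) > params.height_px * sp.um_per_px_y - 200.0:
            raise RenderError("iris extends below the scan range")
        if np.min(self.ant) < SCLERA_THICKNESS_UM:
            raise RenderError("iris bows into the corneoscleral shell")

    @staticmethod
    def _make_jitter(rng: np.random.Generator, amp_um: float, anchor: float):
        """Smooth low-frequency boundary perturbation with peak ~amp_um."""
        ks = np.array([1.0, 2.0, 3.0])
        w = rng.uniform(0.4, 1.0, size=3)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=3)
        lam = 6000.0
        norm = np.sum(w)

        def f(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            out = np.zeros_like(x)
            for k, wk, pk in zip(ks, w, phi):
                out += wk * np.sin(2.0 * np.pi * k * (x - anchor) / lam + pk)
            return amp_um * out / norm

        return f

    # -- scleral inner surface -------------------------------------------
    def y_sclera_inner(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        ant_at = np.interp(np.clip(x, self.xr, self.xp), self.xs, self.ant)
        x_v = self.xr + PARALLEL_LEN_UM
        ant_v = float(np.interp(x_v, self.xs, self.ant))
        ant_r = float(self.ant[0])
        y = np.where(
            x < self.xr,
            (ant_r - RECESS_GAP_UM) + SCLERA_DIVE_SLOPE * (self.xr - x),
            np.where(
                x <= x_v,
                ant_at - RECESS_GAP_UM,
                (ant_v - RECESS_GAP_UM) - SCLERA_RISE_SLOPE * (x - x_v),
            ),
        )
        return y + self._jit_sc(x)

    # -- ciliary wedge ----------------------------------------------------
    def cb_top(self, x: np.ndarray) -> np.ndarray:
        """Upper boundary of the ciliary body (valid on [x_cb0, x_tip])."""
        x = np.asarray(x, dtype=float)
        under_iris = np.interp(x, self.xs, self.post) + np.interp(
            x, self.xs, self.gap
        )
        return np.where(x < self.xr, self.y_sclera_inner(x), under_iris)

    @property
    def x_cb0(self) -> float:
        """Left end of the wedge: where the scleral dive reaches CB_LEFT_TOP_Y."""
        y0 = float(self.ant[0]) - RECESS_GAP_UM
        return self.xr - (CB_LEFT_TOP_Y_UM + (self.params.offset_um[1]) - y0) / SCLERA_DIVE_SLOPE

    def cb_bottom(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        oy = self.params.offset_um[1]
        x0 = self.x_cb0
        pts_x = np.array([x0, self.xr + 300.0, self.x_tip])
        pts_y = np.array(
            [
                CB_LEFT_TOP_Y_UM + oy + 40.0,
                CB_BELLY_Y_UM + oy,
                float(self.cb_top(np.array([self.x_tip]))[0]) + CB_TIP_DROP_UM,
            ]
        )
        return np.interp(x, pts_x, pts_y)

    # -- iris outline polygon (for ground-truth circle intersections) ----
    def iris_polygon(self) -> Polygon:
        top = np.column_stack([self.xs, self.ant])
        bottom = np.column_stack([self.xs[::-1], self.post[::-1]])
        ring = np.vstack([top, bottom])
        return Polygon(LinearRing(ring))


# ---------------------------------------------------------------------------
# ground truth on the continuous curves

def _circle_chord_um(
    poly: Polygon,
    center: tuple[float, float],
    radius_um: float,
    reference: tuple[float, float],
) -> float:
    """Chord between the circle/outline crossing pair selected like the
    measurement rule: consecutive crossings (by angle about the center) whose
    arc midpoint lies inside the region, nearest the reference point."""
    ring = poly.exterior
    circle = Point(center).buffer(radius_um, quad_segs=720).exterior
    inter = ring.intersection(circle)
    pts: list[tuple[float, float]] = []
    for geom in getattr(inter, "geoms", [inter]):
        if geom.is_empty:
            continue
        if geom.geom_type == "Point":
            pts.append((geom.x, geom.y))
        else:  # tangency segment: use its midpoint
            c = geom.centroid
            pts.append((c.x, c.y))
    if len(pts) < 2:
        return float("nan")
    cx, cy = center
    ang = np.array([np.arctan2(y - cy, x - cx) for x, y in pts])
    order = np.argsort(ang)
    pts_arr = np.asarray(pts)[order]
    ang = ang[order]
    candidates = []  # (d_ref, arc_deg, chord)
    for i in range(len(pts_arr)):
        j = (i + 1) % len(pts_arr)
        dth = (ang[j] - ang[i]) % (2.0 * np.pi)
        mid = ang[i] + dth / 2.0
        mx, my = cx + radius_um * np.cos(mid), cy + radius_um * np.sin(mid)
        if not poly.contains(Point(mx, my)):
            continue
        d_ref = float(np.hypot(mx - reference[0], my - reference[1]))
        chord = float(np.hypot(*(pts_arr[j] - pts_arr[i])))
        candidates.append((d_ref, np.degrees(dth), chord))
    if not candidates:
        return float("nan")
    # tangential grazes (tiny enclosed arc) are not thickness samples
    transversal = [c for c in candidates if c[1] >= 10.0]
    pool = transversal if transversal else candidates
    return min(pool, key=lambda c: c[0])[2]


def _spur_um(scene: _Scene) -> tuple[tuple[float, float], float]:
    """Analytic spur: the point of the sclerociliary interface (the inner
    scleral dive the ciliary body attaches under) closest to the iris.
    Returns the point and its distance to the iris in micrometres."""
    xs = np.arange(scene.x_cb0, scene.xr, _GT_STEP_UM)
    ys = scene.y_sclera_inner(xs)
    ant_r, post_r = float(scene.ant[0]), float(scene.post[0])
    # nearest iris point seen from left of the root edge: the edge segment
    # x = xr, y in [ant_r, post_r], or its anterior corner
    dx = scene.xr - xs
    dy = np.clip(ant_r - ys, 0.0, None) + np.clip(ys - post_r, 0.0, None)
    d = np.hypot(dx, dy)
    k = int(np.argmin(d))
    return (float(xs[k]), float(ys[k])), float(d[k])


def _ground_truth(scene: _Scene) -> GroundTruth:
    p = scene.params
    sp = scene.spacing

    spur_um, _spur_d = _spur_um(scene)

    # insertion zone: root edge (abutting the ciliary wall) + posterior
    # contact arc; the root is its arc-length-weighted centroid, mirroring
    # the measured definition (centroid of iris pixels adjacent to the CB).
    adj_tol = 1.5 * sp.um_per_px_y
    ys_edge = np.arange(scene.ant[0], scene.post[0], _GT_STEP_UM)
    edge_pts = np.column_stack([np.full_like(ys_edge, scene.xr), ys_edge])
    in_contact = scene.gap <= adj_tol
    cont_pts = np.column_stack([scene.xs[in_contact], scene.post[in_contact]])
    zone = np.vstack([edge_pts, cont_pts])
    root_um = tuple(zone.mean(axis=0))

    poly = scene.iris_polygon()
    it500 = _circle_chord_um(poly, spur_um, 500.0, root_um)
    it750 = _circle_chord_um(poly, spur_um, 750.0, root_um)
    it_root = _circle_chord_um(poly, root_um, 500.0, spur_um)

    # sagitta of the (jittered) posterior surface over its root-to-pupil chord
    a = np.array([scene.xs[0], scene.post[0]])
    b = np.array([scene.xs[-1], scene.post[-1]])
    u = (b - a) / np.linalg.norm(b - a)
    n = np.array([u[1], -u[0]])
    if n[1] > 0:  # orient the normal anteriorly (toward -y)
        n = -n
    dev = (np.column_stack([scene.xs, scene.post]) - a) @ n
    sag = float(dev[np.argmax(np.abs(dev))])

    # ciliary anterior surface bookkeeping on the offset curve
    ex = scene.xs[scene.on_surface]
    ey = (scene.post + scene.gap)[scene.on_surface]
    seg = np.hypot(np.diff(ex), np.diff(ey))
    gap_mid = 0.5 * (scene.gap[scene.on_surface][1:] + scene.gap[scene.on_surface][:-1])
    anterior_len = float(seg.sum())
    contact_len = float(seg[gap_mid <= adj_tol].sum())
    ratio = contact_len / anterior_len if anterior_len > 0 else float("nan")

    insertion = float(np.hypot(spur_um[0] - root_um[0], spur_um[1] - root_um[1]))

    def to_px(pt: tuple[float, float]) -> PixelPoint:
        col = pt[0] / sp.um_per_px_x
        row = pt[1] / sp.um_per_px_y
        if p.orientation == "right":
            col = (p.width_px - 1) - col
        return PixelPoint(row=row, col=col)

    return GroundTruth(
        spur=to_px(spur_um),
        root=to_px(root_um),
        it_spur500_um=it500,
        it_spur750_um=it750,
        it_root500_um=it_root,
        sagitta_um=sag,
        root_insertion_um=insertion,
        contact_len_um=contact_len,
        anterior_len_um=anterior_len,
        contact_ratio=ratio,
        pb=sag > PB_SAGITTA_THRESHOLD_UM,
        tpi=it750 > TPI_IT750_THRESHOLD_UM,
        alcb=p.ciliary_contact_fraction > ALCB_CONTACT_THRESHOLD,
        seed=scene.seed,
        params=p,
    )


# ---------------------------------------------------------------------------
# rasterization

def render_mask(params: AnatomyParams, seed: int = 0) -> tuple[SegmentationMask, GroundTruth]:
    """Render one label mask plus its exact ground truth.

    Deterministic for a given (params, seed): the seed drives only the
    boundary jitter, which is baked into the continuous curves before both
    rasterization and ground-truth evaluation.
    """
    scene = _Scene(params, seed)
    gt = _ground_truth(scene)
    sp = scene.spacing
    W, H = params.width_px, params.height_px
    x_cols = np.arange(W) * sp.um_per_px_x
    y_rows = (np.arange(H) * sp.um_per_px_y)[:, None]

    # sclera band
    y_in = scene.y_sclera_inner(x_cols)[None, :]
    sclera = (y_rows > y_in - SCLERA_THICKNESS_UM) & (y_rows <= y_in)

    # iris band
    in_iris_cols = (x_cols >= scene.xr) & (x_cols <= scene.xp)
    post = np.interp(x_cols, scene.xs, scene.post)
    ant = np.interp(x_cols, scene.xs, scene.ant)
    iris = in_iris_cols[None, :] & (y_rows > ant[None, :]) & (y_rows <= post[None, :])

    # ciliary wedge
    in_cb_cols = (x_cols >= scene.x_cb0) & (x_cols <= scene.x_tip)
    top = scene.cb_top(x_cols)
    bot = scene.cb_bottom(x_cols)
    cb = in_cb_cols[None, :] & (y_rows > top[None, :]) & (y_rows <= bot[None, :])

    if (iris & sclera).any() or (iris & cb).any() or (sclera & cb).any():
        raise RenderError("degenerate parameters: tissue regions overlap")

    labels = np.zeros((H, W), dtype=np.uint8)
    labels[cb] = CILIARY
    labels[sclera] = SCLERA
    labels[iris] = IRIS
    if params.orientation == "right":
        labels = labels[:, ::-1].copy()
    mask = SegmentationMask(labels=labels, mode=params.mode, spacing=sp, flipped=False)
    return mask, gt


# ---------------------------------------------------------------------------
# cohort sampling

@dataclass(frozen=True)
class CohortSpec:
    """Synthetic study cohort: class mixture, patient grouping, master seed."""

    n: int = 400
    class_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    mode: AcquisitionMode = AcquisitionMode.HALF_FRAME
    images_per_patient: int = 4
    boundary_jitter_px: float = 0.5

    def validate(self) -> None:
        if self.n < 1:
            raise CohortSpecError("cohort size must be >= 1")
        if abs(sum(self.class_weights) - 1.0) > 1e-9 or min(self.class_weights) < 0:
            raise CohortSpecError("class weights must be nonnegative and sum to 1")
        if not 1 <= self.images_per_patient <= 4:
            raise CohortSpecError("images_per_patient must be in 1..4")


@dataclass
class CohortSample:
    masks: list[SegmentationMask]
    ground_truths: list[GroundTruth]
    table: pd.DataFrame  # image_id, patient_id, integrated_class, pb, tpi, alcb


_COMBOS = {
    "PURE_PB": [(True, False, False)],
    "PURE_NON_PB": [(False, True, False), (False, False, True), (False, True, True)],
    "MM": [(True, True, False), (True, False, True), (True, True, True)],
    "OTHERS": [(False, False, False)],
}

# class-conditional parameter ranges; margins keep the generator's analytic
# labels away from the thresholds so classes are separable by construction
_SAGITTA_RANGE = {True: (250.0, 400.0), False: (-100.0, 120.0)}
_TROOT_RANGE = {True: (530.0, 600.0), False: (300.0, 410.0)}
_CONTACT_RANGE = {True: (0.5, 0.95), False: (0.0, 0.3)}
_TPI_MARGIN_UM = 30.0
_MAX_REDRAWS = 40


def _allocate(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items over the class weights."""
    raw = np.asarray(weights, dtype=float) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    return counts.tolist()


def _draw_params(
    rng: np.random.Generator, combo: tuple[bool, bool, bool], spec: CohortSpec
) -> tuple[AnatomyParams, int, GroundTruth]:
    """Draw parameters for one image until the analytic labels match ``combo``."""
    pb, tpi, alcb = combo
    for _ in range(_MAX_REDRAWS):
        sag = rng.uniform(*_SAGITTA_RANGE[pb])
        t_root = rng.uniform(*_TROOT_RANGE[tpi])
        t_pupil = t_root - rng.uniform(100.0, 200.0) if tpi else t_root - rng.uniform(0.0, 60.0)
        t_pupil = max(t_pupil, 250.0)
        f = rng.uniform(*_CONTACT_RANGE[alcb])
        params = AnatomyParams(
            mode=spec.mode,
            iris_thickness_root_um=t_root,
            iris_thickness_pupil_um=t_pupil,
            bowing_sagitta_um=sag,
            iris_length_um=rng.uniform(4200.0, 4800.0),
            ciliary_contact_fraction=f,
            boundary_jitter_px=spec.boundary_jitter_px,
        )
        seed = int(rng.integers(0, 2**31 - 1))
        gt = _ground_truth(_Scene(params, seed))
        ok = (gt.pb, gt.tpi, gt.alcb) == combo
        margin_ok = abs(gt.it_spur750_um - TPI_IT750_THRESHOLD_UM) >= _TPI_MARGIN_UM
        if ok and margin_ok:
            return params, seed, gt
    raise CohortSpecError(f"could not realise mechanism combination {combo}")


def sample_cohort(spec: CohortSpec) -> CohortSample:
    """Draw a patient-grouped synthetic cohort with known mechanism labels.

    Class counts follow largest-remainder allocation of the weights; image
    order is shuffled (seeded) and consecutive images share a synthetic
    patient id, at most ``images_per_patient`` each (the per-quadrant
    acquisition convention).  Fully reproducible from the master seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = _allocate(spec.n, spec.class_weights)

    assignments: list[tuple[str, tuple[bool, bool, bool]]] = []
    for cls, cnt in zip(INTEGRATED_CLASSES, counts):
        combos = _COMBOS[cls]
        assignments.extend((cls, combos[i % len(combos)]) for i in range(cnt))
    order = rng.permutation(len(assignments))
    assignments = [assignments[i] for i in order]

    masks, gts, rows = [], [], []
    for idx, (cls, combo) in enumerate(assignments):
        params, seed, _ = _draw_params(rng, combo, spec)
        mask, gt = render_mask(params, seed)
        masks.append(mask)
        gts.append(gt)
        rows.append(
            {
                "image_id": f"img_{idx:04d}",
                "patient_id": f"pat_{idx // spec.images_per_patient:04d}",
                "integrated_class": cls,
                "pb": gt.pb,
                "tpi": gt.tpi,
                "alcb": gt.alcb,
            }
        )
    return CohortSample(masks=masks, ground_truths=gts, table=pd.DataFrame(rows))
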