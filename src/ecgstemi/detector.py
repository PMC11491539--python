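"""Guideline-based ST-elevation detector with soft-NMS refinement.

Produces scored ``STE`` / ``lesser_STE`` bounding boxes per lead subregion
by digitizing each subregion, segmenting beats, and measuring the ST
deviation at the J point against the PR-segment baseline — the ACC/AHA
criterion (ST elevation >= 1 mm at the J point) applied literally.  The
detector sits behind a single ``detect(image) -> detections`` contract so a
learned object detector can be slotted in without touching downstream
encodings or clinical logic.

Also provided is the standard anchor-relative box-regression codec used by
two-stage object detectors::

    t_x = (x - x_a) / w_a     t_w = log(w / w_a)
    t_y = (y - y_a) / h_a     t_h = log(h / h_a)

kept here because detections may be exchanged with learned detectors that
represent boxes this way.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .digitizer import LeadSignal, estimate_baseline_row, extract_trace, suppress_grid
from .layout import CalibrationSpec, LeadID, PageLayout, Rect, crop_subregions
from .synthgen import (
    BOX_PAD_MM,
    BOX_POST_J_MS,
    BOX_PRE_QRS_MS,
    LESSER_STE,
    PR_BEFORE_ONSET_MS,
    STE,
)

__all__ = [
    "Beat",
    "BoundingBox",
    "Anchor",
    "RegressionTarget",
    "Detection",
    "encode_box",
    "decode_box",
    "detect_beats",
    "measure_st",
    "boxes_from_beats",
    "iou",
    "soft_nms",
    "detect",
    "GuidelineSTEDetector",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# box types and the regression codec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundingBox:
    """Center-parameterized box: (x, y) center, (w, h) extent, in px."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width and height must be positive")

    @classmethod
    def from_rect(cls, rect: Rect) -> "BoundingBox":
        return cls(rect.x0 + rect.width / 2, rect.y0 + rect.height / 2, rect.width, rect.height)

    def corners(self) -> tuple[float, float, float, float]:
        return (self.x - self.w / 2, self.y - self.h / 2, self.x + self.w / 2, self.y + self.h / 2)


class Anchor(BoundingBox):
    """Reference box for the regression codec; same parameterization."""


@dataclass(frozen=True)
class RegressionTarget:
    t_x: float
    t_y: float
    t_w: float
    t_h: float


def encode_box(box: BoundingBox, anchor: Anchor | BoundingBox) -> RegressionTarget:
    """Anchor-relative encoding of a box (dimensionless offsets/log-scales)."""
    return RegressionTarget(
        t_x=(box.x - anchor.x) / anchor.w,
        t_y=(box.y - anchor.y) / anchor.h,
        t_w=math.log(box.w / anchor.w),
        t_h=math.log(box.h / anchor.h),
    )


def decode_box(target: RegressionTarget, anchor: Anchor | BoundingBox) -> BoundingBox:
    """Exact inverse of :func:`encode_box`."""
    return BoundingBox(
        x=target.t_x * anchor.w + anchor.x,
        y=target.t_y * anchor.h + anchor.y,
        w=math.exp(target.t_w) * anchor.w,
        h=math.exp(target.t_h) * anchor.h,
    )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ax0, ay0, ax1, ay1 = a.corners()
    bx0, by0, bx1, by1 = b.corners()
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.w * a.h + b.w * b.h - inter
    return min(1.0, max(0.0, inter / union))


# ---------------------------------------------------------------------------
# beats and ST measurement
# ---------------------------------------------------------------------------


@dataclass
class Beat:
    """One segmented beat with its ST measurement geometry (times in ms)."""

    r_peak_t: float
    qrs_onset_t: float
    qrs_offset_t: float  # the J point
    pr_window: tuple[float, float]
    st_sample_t: float = float("nan")
    baseline_mV: float = float("nan")
    st_deviation_mm: float = float("nan")


@dataclass(frozen=True)
class Detection:
    """One scored detection in a lead subregion (absolute page coordinates)."""

    subregion_index: int
    lead: LeadID
    box: BoundingBox
    cls: str  # STE | lesser_STE
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def detect_beats(
    sig: LeadSignal,
    min_separation_ms: float = 300.0,
    height_fraction: float = 0.4,
    slope_fraction: float = 0.1,
    search_ms: float = 80.0,
) -> list[Beat]:
    """Segment R peaks and QRS boundaries from a digitized lead signal.

    R peaks are local maxima above baseline + ``height_fraction`` x signal
    range, separated by at least ``min_separation_ms``.  QRS onset/offset
    are found where |dv/dt| stays below ``slope_fraction`` of its QRS
    maximum (for a short run, to skip the momentary zero-slope instant at
    the S trough), searched within ``search_ms`` of the peak.
    """
    if sig.valid_mask.sum() * sig.dt < 600.0:
        return []
    v = np.asarray(sig.v, dtype=float)
    dt = sig.dt
    if dt <= 0:
        return []
    baseline = float(np.median(v))
    vrange = float(v.max() - v.min())
    if vrange <= 0:
        return []
    height = baseline + height_fraction * vrange
    distance = max(1, int(round(min_separation_ms / dt)))
    peaks, _ = find_peaks(v, height=height, distance=distance)

    dv = np.gradient(v, dt)
    half = max(1, int(round(search_ms / dt)))
    run = 3  # consecutive sub-threshold samples required
    beats: list[Beat] = []
    for p in peaks:
        lo = max(0, p - half)
        hi = min(len(v) - 1, p + half)
        seg_slope = np.abs(dv[lo : hi + 1])
        if seg_slope.size == 0:
            continue
        thr = slope_fraction * float(seg_slope.max())

        def _boundary(direction: int) -> int:
            idx = p
            streak = 0
            while lo < idx < hi:
                idx += direction
                if abs(dv[idx]) < thr:
                    streak += 1
                    if streak >= run:
                        # end of the quiet run: the trace has fully settled,
                        # so the J-point sample is not biased by QRS recovery
                        return idx
                else:
                    streak = 0
            return lo if direction < 0 else hi

        onset_i = _boundary(-1)
        offset_i = _boundary(+1)
        onset_t = float(sig.t[onset_i])
        offset_t = float(sig.t[offset_i])
        beats.append(
            Beat(
                r_peak_t=float(sig.t[p]),
                qrs_onset_t=onset_t,
                qrs_offset_t=offset_t,
                pr_window=(onset_t - PR_BEFORE_ONSET_MS, onset_t - 20.0),
            )
        )
    return beats


def measure_st(
    sig: LeadSignal,
    beat: Beat,
    calib: CalibrationSpec,
    j_offset_ms: float = 0.0,
) -> float | None:
    """ST deviation at the J point (+ optional offset), in signed mm.

    Baseline is the median voltage over the PR window; a positive result is
    elevation, negative depression.  Returns None when the PR window or the
    ST sample falls outside the signal (measurement unavailable).
    """
    t = sig.t
    pr_lo, pr_hi = beat.pr_window
    if pr_lo < t[0] or pr_hi > t[-1]:
        return None
    st_t = beat.qrs_offset_t + j_offset_ms
    if st_t < t[0] or st_t > t[-1]:
        return None
    pr_sel = (t >= pr_lo) & (t <= pr_hi)
    if not pr_sel.any():
        return None
    baseline = float(np.median(sig.v[pr_sel]))
    v_st = float(np.interp(st_t, t, sig.v))
    beat.st_sample_t = st_t
    beat.baseline_mV = baseline
    beat.st_deviation_mm = (v_st - baseline) * calib.gain
    return beat.st_deviation_mm


def _score(st_mm: float, cls: str, lesser_floor: float, ste_threshold: float, scale: float = 0.25) -> float:
    """Confidence: logistic margin above the class's lower boundary."""
    floor = ste_threshold if cls == STE else lesser_floor
    return 1.0 / (1.0 + math.exp(-(st_mm - floor) / scale))


def boxes_from_beats(
    sig: LeadSignal,
    beats: list[Beat],
    panel: Rect,
    calib: CalibrationSpec,
    lesser_floor: float = 0.5,
    ste_threshold: float = 1.0,
    st_window_ms: float = BOX_POST_J_MS,
    subregion_index: int = 0,
    lead: LeadID | None = None,
) -> list[Detection]:
    """Turn measured beats into class-labeled, scored detections.

    A beat yields a detection when its ST deviation exceeds ``lesser_floor``
    (mm): class ``STE`` above ``ste_threshold``, ``lesser_STE`` otherwise.
    The box spans [QRS onset - 40 ms, QRS offset + ``st_window_ms``]
    horizontally and the trace's vertical extent in that span padded by 2 mm,
    clipped to the subregion.  Coordinates are absolute page pixels.
    """
    lead = lead if lead is not None else sig.lead
    ms_per_px = calib.ms_per_px
    pad_px = BOX_PAD_MM * calib.px_per_mm_y
    out: list[Detection] = []
    for beat in beats:
        st = beat.st_deviation_mm
        if not np.isfinite(st) or st <= lesser_floor:
            continue
        cls = STE if st > ste_threshold else LESSER_STE
        t0 = beat.qrs_onset_t - BOX_PRE_QRS_MS
        t1 = beat.qrs_offset_t + st_window_ms
        x0 = max(panel.x0, panel.x0 + t0 / ms_per_px)
        x1 = min(panel.x1, panel.x0 + t1 / ms_per_px)
        if x1 - x0 < 2:
            continue
        span = (sig.t >= t0) & (sig.t <= t1)
        rows = sig.baseline_row - sig.v[span] * calib.px_per_mv
        y0 = max(panel.y0, panel.y0 + float(rows.min()) - pad_px)
        y1 = min(panel.y1, panel.y0 + float(rows.max()) + pad_px)
        if y1 - y0 < 2:
            continue
        box = BoundingBox((x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0)
        out.append(
            Detection(
                subregion_index=subregion_index,
                lead=lead,
                box=box,
                cls=cls,
                score=_score(st, cls, lesser_floor, ste_threshold),
            )
        )
    return out


# ---------------------------------------------------------------------------
# soft non-maximum suppression
# ---------------------------------------------------------------------------


def soft_nms(
    dets: list[Detection],
    iou_threshold: float = 0.5,
    score_threshold: float = 0.7,
    sigma: float = 0.5,
) -> list[Detection]:
    """Gaussian soft-NMS within each subregion.

    Iteratively selects the highest-scored box and decays every remaining
    box in the same subregion with IoU above ``iou_threshold`` by
    ``exp(-iou^2 / sigma)``; boxes whose (possibly decayed) score falls
    below ``score_threshold`` are discarded.  Output is sorted by score
    descending; scores never increase.
    """
    pool = [(d.score, i, d) for i, d in enumerate(dets)]
    kept: list[Detection] = []
    while pool:
        pool.sort(key=lambda e: (-e[0], e[1]))
        score, _, best = pool.pop(0)
        if score >= score_threshold:
            kept.append(replace(best, score=score) if score != best.score else best)
        rest = []
        for s, i, d in pool:
            if d.subregion_index == best.subregion_index:
                ov = iou(d.box, best.box)
                if ov > iou_threshold:
                    s = s * math.exp(-(ov**2) / sigma)
            if s >= score_threshold:
                rest.append((s, i, d))
        pool = rest
    return kept


# ---------------------------------------------------------------------------
# full-page detection pipeline
# ---------------------------------------------------------------------------


def detect(
    image: np.ndarray,
    layout: PageLayout,
    calib: CalibrationSpec,
    lesser_floor: float = 0.5,
    ste_threshold: float = 1.0,
    j_offset_ms: float = 0.0,
    st_window_ms: float = BOX_POST_J_MS,
    iou_threshold: float = 0.5,
    score_threshold: float = 0.7,
    sigma: float = 0.5,
    grid_threshold: float | None = None,
) -> list[Detection]:
    """Detect STE / lesser-STE boxes across all 16 subregions of a page.

    Composition: crop -> grid suppression -> trace extraction -> beat
    segmentation -> ST measurement -> box construction -> soft-NMS.  A
    subregion whose digitization fails contributes no detections (logged),
    rather than aborting the page.
    """
    detections: list[Detection] = []
    for index, (lead, crop) in enumerate(crop_subregions(image, layout)):
        try:
            mask = suppress_grid(crop, threshold=grid_threshold)
            if not mask.any():
                continue
            sig = extract_trace(mask, Rect(0, 0, crop.shape[1], crop.shape[0]), calib, lead=lead)
            beats = detect_beats(sig)
            for beat in beats:
                measure_st(sig, beat, calib, j_offset_ms=j_offset_ms)
            rect = layout.subregion_rects[index][1]
            detections.extend(
                boxes_from_beats(
                    sig,
                    beats,
                    rect,
                    calib,
                    lesser_floor=lesser_floor,
                    ste_threshold=ste_threshold,
                    st_window_ms=st_window_ms,
                    subregion_index=index,
                    lead=lead,
                )
            )
        except ValueError as exc:
            logger.warning("subregion %d (%s) skipped: %s", index, lead.name, exc)
    return soft_nms(detections, iou_threshold, score_threshold, sigma)


class GuidelineSTEDetector:
    """Deterministic STE detector with scikit-learn-style parameter handling.

    Wraps :func:`detect` so detector settings travel as one configured
    object; ``get_params``/``set_params`` make it composable with sklearn
    model-selection utilities.  There is nothing to fit.
    """

    def __init__(
        self,
        lesser_floor: float = 0.5,
        ste_threshold: float = 1.0,
        j_offset_ms: float = 0.0,
        st_window_ms: float = BOX_POST_J_MS,
        iou_threshold: float = 0.5,
        score_threshold: float = 0.7,
        sigma: float = 0.5,
        grid_threshold: float | None = None,
    ):
        self.lesser_floor = lesser_floor
        self.ste_threshold = ste_threshold
        self.j_offset_ms = j_offset_ms
        self.st_window_ms = st_window_ms
        self.iou_threshold = iou_threshold
        self.score_threshold = score_threshold
        self.sigma = sigma
        self.grid_threshold = grid_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "lesser_floor",
                "ste_threshold",
                "j_offset_ms",
                "st_window_ms",
                "iou_threshold",
                "score_threshold",
                "sigma",
                "grid_threshold",
            )
        }

    def set_params(self, **params) -> "GuidelineSTEDetector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def detect(
        self, image: np.ndarray, layout: PageLayout, calib: CalibrationSpec
    ) -> list[Detection]:
        return detect(image, layout, calib, **self.get_params())
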