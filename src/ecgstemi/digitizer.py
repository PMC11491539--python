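"""Lead sub-image -> physical-unit signal trace.

The deterministic detector works on digitized traces rather than raw pixels,
so each lead subregion is first reduced to a binary trace mask (grid and
background suppressed), then to one (time, voltage) sample per pixel column.

Grid suppression exploits the printout's contrast ordering: the trace is
drawn darker than the grid, which is darker than the paper.  A two-stage
Otsu threshold separates the dark trace from the light grid even when the
grid dominates the dark-pixel histogram; an explicit threshold can override
it for unusual scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .layout import CalibrationSpec, LeadID, Rect

__all__ = ["LeadSignal", "suppress_grid", "extract_trace", "estimate_baseline_row"]


@dataclass
class LeadSignal:
    """Digitized trace of one lead subregion.

    ``t`` is in ms from the subregion's left edge (one sample per pixel
    column), ``v`` in mV relative to the isoelectric baseline, and
    ``valid_mask`` flags columns where trace pixels were actually found
    (others are linearly interpolated).  ``baseline_row`` is the
    subregion-relative pixel row used as 0 mV.
    """

    lead: LeadID
    t: np.ndarray
    v: np.ndarray
    valid_mask: np.ndarray
    baseline_row: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.v) == len(self.valid_mask)):
            raise ValueError("t, v and valid_mask must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.v[self.valid_mask])):
            raise ValueError("v must be finite where valid")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0


def _to_gray(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        return image.mean(axis=2)
    return np.asarray(image, dtype=float)


def suppress_grid(
    sub_image: np.ndarray,
    threshold: float | None = None,
    max_mask_fraction: float = 0.08,
    min_trace_contrast: float = 100.0,
) -> np.ndarray:
    """Binary mask of trace pixels, with grid and background removed.

    A panel is considered traceless (all-false mask) unless its darkest
    pixel lies at least ``min_trace_contrast`` below its lightest: the ink
    trace is near-black while grid lines sit within ~25% of paper white.
    Otherwise Otsu's threshold is computed on the sub-image; if the
    resulting mask is implausibly dense (``> max_mask_fraction`` of pixels,
    i.e. grid lines were captured alongside the trace), a second Otsu pass
    on the dark pixels alone separates trace from grid.  Pass ``threshold``
    to bypass the automatic choice entirely.
    """
    if sub_image.size == 0:
        raise ValueError("empty sub-image")
    gray = _to_gray(sub_image)
    if threshold is not None:
        return gray < threshold
    if gray.max() - gray.min() < min_trace_contrast:  # blank or grid-only
        return np.zeros(gray.shape, dtype=bool)
    t1 = threshold_otsu(gray)
    mask = gray < t1
    if mask.mean() > max_mask_fraction:
        dark = gray[mask]
        if dark.max() - dark.min() >= 10:
            t2 = threshold_otsu(dark)
            mask = gray < t2
    return mask


def estimate_baseline_row(mask: np.ndarray) -> int:
    """Most frequent trace row: the isoelectric baseline.

    Robust to beats because the trace sits on the baseline most of the time
    (QRS complexes and T waves occupy well under half of the columns).  With
    two competing flat segments the longer one wins.
    """
    if not mask.any():
        raise ValueError("empty mask: no trace pixels")
    counts = mask.sum(axis=0)
    valid = counts > 0
    rows = np.arange(mask.shape[0], dtype=float)
    centroid = (rows[:, None] * mask).sum(axis=0)[valid] / counts[valid]
    hist = np.bincount(np.round(centroid).astype(int), minlength=mask.shape[0])
    return int(np.argmax(hist))


def extract_trace(
    mask: np.ndarray,
    panel: Rect,
    calib: CalibrationSpec,
    baseline_row: float | None = None,
    lead: LeadID = LeadID.I,
) -> LeadSignal:
    """Convert a trace mask to a calibrated :class:`LeadSignal`.

    Per column the trace row is the centroid of true pixels; empty columns
    are linearly interpolated from their neighbours and flagged invalid.
    Rows are converted to mV against ``baseline_row`` (estimated from the
    mask if not given), columns to ms via the paper speed.
    """
    if not mask.any():
        raise ValueError("empty mask: no trace to extract")
    if baseline_row is None:
        baseline_row = float(estimate_baseline_row(mask))
    counts = mask.sum(axis=0)
    valid = counts > 0
    rows = np.arange(mask.shape[0], dtype=float)
    centroid = np.full(mask.shape[1], np.nan)
    centroid[valid] = (rows[:, None] * mask).sum(axis=0)[valid] / counts[valid]
    cols = np.arange(mask.shape[1])
    if not valid.all():
        centroid[~valid] = np.interp(cols[~valid], cols[valid], centroid[valid])
    t = cols * calib.ms_per_px
    v = (baseline_row - centroid) / calib.px_per_mv
    return LeadSignal(lead=lead, t=t, v=v, valid_mask=valid, baseline_row=baseline_row)
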