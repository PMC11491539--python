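"""Geometry and calibration of a printed 12-lead ECG page.

A standard single-page printout arranges the 12 leads in a 3-row x 4-column
grid of short (~2.5 s) panels, with a long (~10 s) lead-II rhythm strip
printed beneath.  For detection the rhythm strip is split into four evenly
divided subregions, giving 16 lead subregions per page: 12 short panels plus
4 rhythm splits, all of which carry a lead identity.

Calibration follows the universal printout convention of 25 mm/s paper speed
and 10 mm/mV gain, so 1 mm horizontal = 40 ms and 1 mm vertical = 0.1 mV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator

import numpy as np

__all__ = [
    "LeadID",
    "CalibrationSpec",
    "Rect",
    "PageLayout",
    "InvalidGeometryError",
    "build_layout",
    "crop_subregions",
    "px_to_physical",
    "physical_to_px",
]


class InvalidGeometryError(ValueError):
    """Page dimensions too small (or otherwise unable) to host the layout."""


class LeadID(IntEnum):
    """The 12 standard ECG leads in canonical order.

    The integer value is the canonical index (0-11).  ``L1``/``L2``/``L3``
    are accepted as aliases for the limb leads I/II/III via :meth:`parse`.
    """

    I = 0
    II = 1
    III = 2
    aVR = 3
    aVL = 4
    aVF = 5
    V1 = 6
    V2 = 7
    V3 = 8
    V4 = 9
    V5 = 10
    V6 = 11

    @classmethod
    def parse(cls, name: str) -> "LeadID":
        aliases = {"L1": "I", "L2": "II", "L3": "III"}
        key = aliases.get(name.strip(), name.strip())
        for member in cls:
            if member.name.lower() == key.lower():
                return member
        raise ValueError(f"unknown lead name: {name!r}")


#: Panel placement on the page: column-major in canonical lead order, so the
#: rows read (I, aVR, V1, V4), (II, aVL, V2, V5), (III, aVF, V3, V6).
PANEL_GRID: tuple[tuple[LeadID, ...], ...] = (
    (LeadID.I, LeadID.aVR, LeadID.V1, LeadID.V4),
    (LeadID.II, LeadID.aVL, LeadID.V2, LeadID.V5),
    (LeadID.III, LeadID.aVF, LeadID.V3, LeadID.V6),
)


@dataclass(frozen=True)
class CalibrationSpec:
    """Printout calibration: paper speed, gain, and raster resolution.

    Parameters
    ----------
    paper_speed : float
        Horizontal scale in mm per second (default 25).
    gain : float
        Vertical scale in mm per mV (default 10).
    px_per_mm_x, px_per_mm_y : float
        Raster resolution of the scanned page.
    """

    paper_speed: float = 25.0
    gain: float = 10.0
    px_per_mm_x: float = 10.0
    px_per_mm_y: float = 10.0

    def __post_init__(self) -> None:
        for name in ("paper_speed", "gain", "px_per_mm_x", "px_per_mm_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def ms_per_px(self) -> float:
        """Milliseconds represented by one horizontal pixel."""
        return 1000.0 / (self.px_per_mm_x * self.paper_speed)

    @property
    def px_per_mv(self) -> float:
        """Vertical pixels representing one millivolt."""
        return self.px_per_mm_y * self.gain


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle: 0-based, origin top-left, half-open."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("Rect width and height must be positive")

    @property
    def x1(self) -> int:  # exclusive
        return self.x0 + self.width

    @property
    def y1(self) -> int:  # exclusive
        return self.y0 + self.height

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def intersection_area(self, other: "Rect") -> int:
        w = min(self.x1, other.x1) - max(self.x0, other.x0)
        h = min(self.y1, other.y1) - max(self.y0, other.y0)
        return max(w, 0) * max(h, 0)

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "width": self.width, "height": self.height}

    @classmethod
    def from_dict(cls, d: dict) -> "Rect":
        return cls(int(d["x0"]), int(d["y0"]), int(d["width"]), int(d["height"]))


@dataclass
class PageLayout:
    """Rectangles of the 13 figures (12 short panels + rhythm strip) and the
    16 detection subregions they induce."""

    image_height: int
    image_width: int
    short_panel_rects: dict[LeadID, Rect]
    rhythm_rect: Rect
    subregion_rects: list[tuple[LeadID, Rect]] = field(default_factory=list)

    def __iter__(self) -> Iterator[tuple[LeadID, Rect]]:
        return iter(self.subregion_rects)

    @property
    def n_subregions(self) -> int:
        return len(self.subregion_rects)

    def panel_column(self, lead: LeadID) -> int:
        """Column index (0-3) of a lead's short panel in the page grid."""
        for row in PANEL_GRID:
            if lead in row:
                return row.index(lead)
        raise ValueError(lead)

    def to_json(self) -> str:
        return json.dumps(
            {
                "image_height": self.image_height,
                "image_width": self.image_width,
                "short_panels": {l.name: r.to_dict() for l, r in self.short_panel_rects.items()},
                "rhythm_rect": self.rhythm_rect.to_dict(),
                "subregions": [
                    {"lead": l.name, **r.to_dict()} for l, r in self.subregion_rects
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PageLayout":
        d = json.loads(text)
        return cls(
            image_height=int(d["image_height"]),
            image_width=int(d["image_width"]),
            short_panel_rects={
                LeadID.parse(k): Rect.from_dict(v) for k, v in d["short_panels"].items()
            },
            rhythm_rect=Rect.from_dict(d["rhythm_rect"]),
            subregion_rects=[
                (LeadID.parse(s["lead"]), Rect.from_dict(s)) for s in d["subregions"]
            ],
        )


def build_layout(
    image_height: int = 1228,
    image_width: int = 2460,
    columns: int = 4,
    rows: int = 3,
    rhythm_splits: int = 4,
    top_margin: int = 0,
) -> PageLayout:
    """Construct the page layout for a given raster size.

    The page is divided vertically into ``rows + 1`` equal bands: ``rows``
    bands of short panels and one band for the lead-II rhythm strip, which
    spans the full width and is split into ``rhythm_splits`` even detection
    subregions (floor division; remainder pixels go to the last split).
    """
    if image_height < 100 or image_width < 100:
        raise InvalidGeometryError("image dimensions must each be at least 100 px")
    if rows * columns != 12:
        raise InvalidGeometryError("short-panel grid must hold exactly 12 leads")

    bands = rows + 1
    band_h = (image_height - top_margin) // bands
    col_w = image_width // columns
    if band_h < 10 or col_w < 10:
        raise InvalidGeometryError("page too small to allocate non-empty panels")

    short: dict[LeadID, Rect] = {}
    for r in range(rows):
        for c in range(columns):
            lead = PANEL_GRID[r][c]
            w = col_w if c < columns - 1 else image_width - col_w * (columns - 1)
            short[lead] = Rect(c * col_w, top_margin + r * band_h, w, band_h)

    rhythm_y0 = top_margin + rows * band_h
    rhythm = Rect(0, rhythm_y0, image_width, image_height - rhythm_y0)

    subregions: list[tuple[LeadID, Rect]] = [
        (lead, short[lead]) for lead in LeadID
    ]
    split_w = rhythm.width // rhythm_splits
    for i in range(rhythm_splits):
        w = split_w if i < rhythm_splits - 1 else rhythm.width - split_w * (rhythm_splits - 1)
        subregions.append(
            (LeadID.II, Rect(rhythm.x0 + i * split_w, rhythm.y0, w, rhythm.height))
        )

    return PageLayout(
        image_height=image_height,
        image_width=image_width,
        short_panel_rects=short,
        rhythm_rect=rhythm,
        subregion_rects=subregions,
    )


def crop_subregions(
    image: np.ndarray, layout: PageLayout
) -> list[tuple[LeadID, np.ndarray]]:
    """Cut an ECG page image into its 16 lead subregions, in layout order."""
    if image.shape[:2] != (layout.image_height, layout.image_width):
        raise ValueError(
            f"image shape {image.shape[:2]} does not match layout "
            f"({layout.image_height}, {layout.image_width})"
        )
    return [
        (lead, image[r.y0 : r.y1, r.x0 : r.x1]) for lead, r in layout.subregion_rects
    ]


def px_to_physical(
    x_px: float,
    y_px: float,
    calib: CalibrationSpec,
    panel: Rect,
    baseline_row: float,
) -> tuple[float, float]:
    """Map a pixel inside a panel to (time ms, voltage mV).

    Time is measured from the panel's left edge; voltage from the isoelectric
    baseline row, positive upward on paper.
    """
    if not panel.contains(x_px, y_px):
        raise ValueError(f"point ({x_px}, {y_px}) lies outside panel {panel}")
    t_ms = (x_px - panel.x0) / (calib.px_per_mm_x * calib.paper_speed) * 1000.0
    v_mv = (baseline_row - y_px) / (calib.px_per_mm_y * calib.gain)
    return t_ms, v_mv


def physical_to_px(
    t_ms: float,
    v_mv: float,
    calib: CalibrationSpec,
    panel: Rect,
    baseline_row: float,
) -> tuple[float, float]:
    """Inverse of :func:`px_to_physical`."""
    x_px = panel.x0 + t_ms / 1000.0 * calib.px_per_mm_x * calib.paper_speed
    y_px = baseline_row - v_mv * calib.px_per_mm_y * calib.gain
    return x_px, y_px
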