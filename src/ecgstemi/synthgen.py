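"""Seeded synthetic 12-lead ECG printout generator.

Emulates the study material this package targets: scanned single-page
printouts with a grid background, 12 short lead panels in a 3x4 grid, a long
lead-II rhythm strip, and per-beat ST-segment elevation of controllable
magnitude.  Each rendered case carries ground-truth bounding boxes (one per
beat per subregion, covering the QRS complex and ST segment) in two classes:

* ``STE``        — rendered ST elevation  > 1 mm,
* ``lesser_STE`` — rendered ST elevation in (lesser_floor, 1] mm,

together with a case-level STEMI/NSTEMI label and an infarction-territory
set that is consistent with the guideline lead criteria (see
:mod:`ecgstemi.clinical`), so the generator and the clinical rules close
over each other by construction.

The waveform is a sum-of-Gaussians PQRST model with an ST plateau between
QRS offset and T onset.  Downstream logic depends only on the measurable ST
deviation, so any morphologically plausible beat model suffices; the one
here keeps a clean isoelectric PR segment for baseline estimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .layout import CalibrationSpec, LeadID, PageLayout, Rect, build_layout

__all__ = [
    "WaveComponent",
    "BeatParams",
    "NoiseParams",
    "CaseSpec",
    "GroundTruthBox",
    "TERRITORY_LEADS",
    "TERRITORY_MIN_LEADS",
    "TERRITORIES",
    "beat_waveform",
    "lead_series",
    "territory_profile",
    "render_case",
    "case_ground_truth",
    "sample_case_spec",
    "generate_dataset",
]

# Annotation class names (shared with the detector's Detection.cls).
STE = "STE"
LESSER_STE = "lesser_STE"

#: Qualifying leads per infarction territory (guideline criteria).
TERRITORY_LEADS: dict[str, tuple[LeadID, ...]] = {
    "anterior": (LeadID.V1, LeadID.V2, LeadID.V3, LeadID.V4),
    "lateral": (LeadID.V5, LeadID.V6, LeadID.I, LeadID.aVL),
    "inferior": (LeadID.II, LeadID.III, LeadID.aVF),
    "suspected_LM": (LeadID.aVR,),
}
#: Minimum number of STE leads required for the territory rule to fire.
TERRITORY_MIN_LEADS: dict[str, int] = {
    "anterior": 2,
    "lateral": 2,
    "inferior": 2,
    "suspected_LM": 1,
}
TERRITORIES: tuple[str, ...] = tuple(TERRITORY_LEADS)

#: Default class-mix weights for sampled territories, proportional to the
#: territory prevalence structure of a hospital STEMI population
#: (anterior >> lateral > inferior > left-main).
DEFAULT_TERRITORY_MIX: dict[str, float] = {
    "anterior": 467.0,
    "lateral": 233.0,
    "inferior": 123.0,
    "suspected_LM": 49.0,
}


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian deflection: amplitude (mV), width (ms), center (ms)."""

    amplitude: float
    width: float
    center: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("wave width must be positive")

    @property
    def sigma(self) -> float:
        # width is the visually apparent duration; ~2.5 sigma spans it
        return self.width / 2.5


@dataclass(frozen=True)
class BeatParams:
    """Parameters of a single PQRST beat.

    ``st_offset`` (mV) is added as a plateau on [QRS offset, T onset] with
    half-cosine ramps of ``st_ramp_ms`` centered on the plateau boundaries,
    so the full offset is already present at the J point.
    """

    p: WaveComponent = WaveComponent(0.15, 40.0, 90.0)
    q: WaveComponent = WaveComponent(-0.10, 15.0, 225.0)
    r: WaveComponent = WaveComponent(1.20, 20.0, 250.0)
    s: WaveComponent = WaveComponent(-0.20, 15.0, 275.0)
    t: WaveComponent = WaveComponent(0.30, 70.0, 450.0)
    st_offset: float = 0.0
    rr_interval: float = 800.0
    st_ramp_ms: float = 20.0

    def __post_init__(self) -> None:
        if not (300.0 <= self.rr_interval <= 2000.0):
            raise ValueError("rr_interval must lie in [300, 2000] ms")

    @property
    def qrs_onset(self) -> float:
        return self.q.center - self.q.width

    @property
    def qrs_offset(self) -> float:
        """The J point of the model beat."""
        return self.s.center + self.s.width

    @property
    def t_onset(self) -> float:
        return self.t.center - self.t.width


def _half_cos_step(t: np.ndarray, edge: float, ramp: float) -> np.ndarray:
    """Smooth 0->1 step over [edge - ramp/2, edge + ramp/2]."""
    if ramp <= 0:
        return (t >= edge).astype(float)
    x = np.clip((t - (edge - ramp / 2)) / ramp, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def beat_waveform(params: BeatParams, t: np.ndarray) -> np.ndarray:
    """Evaluate one beat (mV) on a time grid ``t`` (ms) within [0, RR)."""
    t = np.asarray(t, dtype=float)
    v = np.zeros_like(t)
    for comp in (params.p, params.q, params.r, params.s, params.t):
        v += comp.amplitude * np.exp(-0.5 * ((t - comp.center) / comp.sigma) ** 2)
    if params.st_offset != 0.0:
        # ramps sit outside [QRS offset, T onset] so the full offset is
        # already present at the J point, where the guideline measures
        ramp = params.st_ramp_ms
        plateau = _half_cos_step(t, params.qrs_offset - ramp / 2, ramp) * (
            1.0 - _half_cos_step(t, params.t_onset + ramp / 2, ramp)
        )
        v += params.st_offset * plateau
    return v


def lead_series(params: BeatParams, t: np.ndarray) -> np.ndarray:
    """Periodic beat train: the beat waveform tiled at the RR interval."""
    return beat_waveform(params, np.asarray(t, dtype=float) % params.rr_interval)


def territory_profile(
    territories: set[str] | frozenset[str],
    elevation_mm: float,
    rng: np.random.Generator,
    gain: float = 10.0,
) -> dict[LeadID, float]:
    """Assign per-lead ST offsets (mV) realizing the requested territories.

    For each territory a random qualifying subset of its lead set is chosen,
    large enough to satisfy the clinical rule (>= 2 leads for anterior /
    lateral / inferior; aVR alone for suspected left-main disease).
    ``elevation_mm`` is the on-paper elevation; division by ``gain`` converts
    it to mV.
    """
    if elevation_mm < 0:
        raise ValueError("elevation_mm must be non-negative")
    offsets: dict[LeadID, float] = {}
    for terr in sorted(territories):
        if terr not in TERRITORY_LEADS:
            raise ValueError(f"unknown territory name: {terr!r}")
        leads = TERRITORY_LEADS[terr]
        k_min = TERRITORY_MIN_LEADS[terr]
        k = int(rng.integers(k_min, len(leads) + 1))
        chosen = rng.choice(len(leads), size=k, replace=False)
        for i in chosen:
            offsets[leads[i]] = elevation_mm / gain
    return offsets


@dataclass(frozen=True)
class NoiseParams:
    """Printout degradation model: baseline wander, trace jitter, grid contrast."""

    wander_amp_mV: float = 0.03
    wander_freq_hz: float = 0.4
    jitter_sd_px: float = 0.4
    grid_contrast: float = 1.0

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(wander_amp_mV=0.0, jitter_sd_px=0.0)


@dataclass(frozen=True)
class CaseSpec:
    """Full description of one synthetic case."""

    label: str  # "STEMI" | "NSTEMI"
    territories: frozenset[str]
    per_lead_st_mV: dict[LeadID, float]
    seed: int
    heart_rate_bpm: float = 75.0
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if self.label not in ("STEMI", "NSTEMI"):
            raise ValueError(f"label must be STEMI or NSTEMI, got {self.label!r}")
        if self.label == "STEMI" and not self.territories:
            raise ValueError("STEMI cases must declare at least one territory")
        if self.label == "NSTEMI" and self.territories:
            raise ValueError("NSTEMI cases must have an empty territory set")

    @property
    def rr_interval_ms(self) -> float:
        return 60000.0 / self.heart_rate_bpm


@dataclass(frozen=True)
class GroundTruthBox:
    """One annotated beat: a box over the QRS complex and ST segment."""

    rect: Rect
    cls: str  # STE | lesser_STE
    lead: LeadID
    subregion_index: int


# Box geometry shared with the detector: horizontal span of a beat box
# relative to QRS onset/offset, and vertical padding around the trace.
BOX_PRE_QRS_MS = 40.0
BOX_POST_J_MS = 120.0
BOX_PAD_MM = 2.0
# Fraction of panel height at which the isoelectric baseline is drawn.
BASELINE_FRAC = 0.62
# PR-window geometry mirrored from the detector's measurement availability.
PR_BEFORE_ONSET_MS = 80.0


def baseline_row_for(rect: Rect) -> int:
    """Absolute row of the isoelectric baseline within a panel."""
    return rect.y0 + int(round(BASELINE_FRAC * rect.height))


class _CaseRenderer:
    """Deterministic rasterizer for one case; also derives ground truth."""

    def __init__(
        self,
        spec: CaseSpec,
        layout: PageLayout,
        calib: CalibrationSpec,
        lesser_floor_mm: float = 0.5,
        ste_threshold_mm: float = 1.0,
    ):
        self.spec = spec
        self.layout = layout
        self.calib = calib
        self.lesser_floor_mm = lesser_floor_mm
        self.ste_threshold_mm = ste_threshold_mm
        rng = np.random.default_rng(spec.seed)
        # Fixed draw order keeps ground truth independent of rasterization.
        self.r_scale = {lead: rng.uniform(0.9, 1.1) for lead in LeadID}
        # Wander phase per figure: 12 short panels + the rhythm strip.
        self.wander_phase = {lead: rng.uniform(0, 2 * np.pi) for lead in LeadID}
        self.wander_phase["rhythm"] = rng.uniform(0, 2 * np.pi)
        self._jitter_rng = rng

    def beat_params(self, lead: LeadID) -> BeatParams:
        base = BeatParams(rr_interval=self.spec.rr_interval_ms)
        return replace(
            base,
            r=replace(base.r, amplitude=base.r.amplitude * self.r_scale[lead]),
            st_offset=self.spec.per_lead_st_mV.get(lead, 0.0),
        )

    def trace_mv(self, lead: LeadID, t_ms: np.ndarray, figure: str) -> np.ndarray:
        """Lead voltage over a global-time grid, including baseline wander."""
        v = lead_series(self.beat_params(lead), t_ms)
        noise = self.spec.noise
        if noise.wander_amp_mV > 0:
            phase = self.wander_phase[figure if figure == "rhythm" else lead]
            v = v + noise.wander_amp_mV * np.sin(
                2 * np.pi * noise.wander_freq_hz * t_ms / 1000.0 + phase
            )
        return v

    # -- ground truth -------------------------------------------------------

    def subregion_boxes(self, index: int, lead: LeadID, rect: Rect) -> list[GroundTruthBox]:
        st_mv = self.spec.per_lead_st_mV.get(lead, 0.0)
        elev_mm = st_mv * self.calib.gain
        if elev_mm <= self.lesser_floor_mm:
            return []
        cls = STE if elev_mm > self.ste_threshold_mm else LESSER_STE
        ms_per_px = self.calib.ms_per_px
        win_t0 = rect.x0 * ms_per_px
        win_t1 = rect.x1 * ms_per_px
        params = self.beat_params(lead)
        figure = "rhythm" if index >= 12 else "panel"
        baseline = baseline_row_for(rect)
        pad_px = int(round(BOX_PAD_MM * self.calib.px_per_mm_y))

        boxes: list[GroundTruthBox] = []
        rr = params.rr_interval
        k0 = int(np.floor(win_t0 / rr))
        for k in range(k0, int(np.ceil(win_t1 / rr)) + 1):
            start = k * rr
            r_time = start + params.r.center
            onset = start + params.qrs_onset
            offset = start + params.qrs_offset
            # visibility: mirrors the detector, which needs the R peak, a PR
            # window and the J-point sample inside the subregion
            if not (win_t0 <= r_time < win_t1):
                continue
            if onset - PR_BEFORE_ONSET_MS < win_t0 or offset >= win_t1:
                continue
            x0 = max(rect.x0, int(round((onset - BOX_PRE_QRS_MS) / ms_per_px)))
            x1 = min(rect.x1, int(round((offset + BOX_POST_J_MS) / ms_per_px)))
            if x1 - x0 < 2:
                continue
            t_span = np.arange(x0, x1) * ms_per_px
            v = self.trace_mv(lead, t_span, figure)
            rows = baseline - v * self.calib.px_per_mv
            y0 = max(rect.y0, int(np.floor(rows.min())) - pad_px)
            y1 = min(rect.y1, int(np.ceil(rows.max())) + pad_px)
            boxes.append(
                GroundTruthBox(Rect(x0, y0, x1 - x0, y1 - y0), cls, lead, index)
            )
        return boxes

    def ground_truth(self) -> list[GroundTruthBox]:
        out: list[GroundTruthBox] = []
        for i, (lead, rect) in enumerate(self.layout.subregion_rects):
            out.extend(self.subregion_boxes(i, lead, rect))
        return out

    # -- rasterization ------------------------------------------------------

    def _draw_grid(self, img: np.ndarray) -> None:
        c = self.spec.noise.grid_contrast
        minor = np.uint8(max(0, round(255 - 30 * c)))
        major = np.uint8(max(0, round(255 - 55 * c)))
        sx = int(round(self.calib.px_per_mm_x))
        sy = int(round(self.calib.px_per_mm_y))
        img[:, ::sx] = minor
        img[::sy, :] = minor
        img[:, :: 5 * sx] = major
        img[:: 5 * sy, :] = major

    def _draw_trace(self, img: np.ndarray, lead: LeadID, rect: Rect, figure: str) -> None:
        ms_per_px = self.calib.ms_per_px
        cols = np.arange(rect.x0, rect.x1)
        v = self.trace_mv(lead, cols * ms_per_px, figure)
        rows = baseline_row_for(rect) - v * self.calib.px_per_mv
        if self.spec.noise.jitter_sd_px > 0:
            rows = rows + self._jitter_rng.normal(
                0.0, self.spec.noise.jitter_sd_px, size=rows.shape
            )
        rows = np.clip(np.round(rows).astype(int), rect.y0 + 1, rect.y1 - 2)
        prev = rows[0]
        for j, x in enumerate(cols):
            y = rows[j]
            lo, hi = (prev, y) if prev <= y else (y, prev)
            img[lo : hi + 2, x] = 0  # 2-px-thick connected polyline
            prev = y

    def render(self) -> np.ndarray:
        img = np.full(
            (self.layout.image_height, self.layout.image_width), 255, dtype=np.uint8
        )
        self._draw_grid(img)
        for lead in LeadID:
            self._draw_trace(img, lead, self.layout.short_panel_rects[lead], "panel")
        self._draw_trace(img, LeadID.II, self.layout.rhythm_rect, "rhythm")
        return img


def render_case(
    spec: CaseSpec,
    layout: PageLayout | None = None,
    calib: CalibrationSpec | None = None,
    lesser_floor_mm: float = 0.5,
    ste_threshold_mm: float = 1.0,
) -> tuple[np.ndarray, list[GroundTruthBox]]:
    """Render one case to a grayscale page image with ground-truth boxes.

    Deterministic given ``spec.seed``: the same spec yields a bit-identical
    image and an identical box list.
    """
    layout = layout or build_layout()
    calib = calib or CalibrationSpec()
    renderer = _CaseRenderer(spec, layout, calib, lesser_floor_mm, ste_threshold_mm)
    boxes = renderer.ground_truth()
    return renderer.render(), boxes


def case_ground_truth(
    spec: CaseSpec,
    layout: PageLayout | None = None,
    calib: CalibrationSpec | None = None,
    lesser_floor_mm: float = 0.5,
    ste_threshold_mm: float = 1.0,
) -> list[GroundTruthBox]:
    """Ground-truth boxes of a case without rasterizing the page."""
    layout = layout or build_layout()
    calib = calib or CalibrationSpec()
    renderer = _CaseRenderer(spec, layout, calib, lesser_floor_mm, ste_threshold_mm)
    return renderer.ground_truth()


def sample_case_spec(
    rng: np.random.Generator,
    stemi_fraction: float = 677.0 / 888.0,
    territory_mix: dict[str, float] | None = None,
    elevation_range_mm: tuple[float, float] = (1.5, 3.0),
    lesser_range_mm: tuple[float, float] = (0.6, 0.9),
    nstemi_lesser_prob: float = 0.3,
    multi_territory_prob: float = 0.2,
    heart_rate_range_bpm: tuple[float, float] = (60.0, 95.0),
    noise: NoiseParams | None = None,
    gain: float = 10.0,
) -> CaseSpec:
    """Draw one case specification from the configured study mix.

    STEMI cases receive one territory (two with ``multi_territory_prob``)
    sampled by ``territory_mix`` weights and an on-paper elevation from
    ``elevation_range_mm``.  NSTEMI cases have no STE; a fraction carries a
    single lesser-STE lead (minor abnormality) from ``lesser_range_mm``.
    """
    mix = territory_mix or DEFAULT_TERRITORY_MIX
    names = [t for t in TERRITORIES if mix.get(t, 0.0) > 0]
    weights = np.array([mix[t] for t in names], dtype=float)
    weights /= weights.sum()

    is_stemi = rng.random() < stemi_fraction
    noise = noise if noise is not None else NoiseParams()
    heart_rate = rng.uniform(*heart_rate_range_bpm)
    seed = int(rng.integers(0, 2**31 - 1))

    if is_stemi:
        n_terr = 2 if (len(names) >= 2 and rng.random() < multi_territory_prob) else 1
        idx = rng.choice(len(names), size=n_terr, replace=False, p=weights)
        territories = frozenset(names[i] for i in idx)
        elevation = rng.uniform(*elevation_range_mm)
        per_lead = territory_profile(territories, elevation, rng, gain=gain)
        return CaseSpec(
            label="STEMI",
            territories=territories,
            per_lead_st_mV=per_lead,
            seed=seed,
            heart_rate_bpm=heart_rate,
            noise=noise,
        )
    per_lead: dict[LeadID, float] = {}
    if rng.random() < nstemi_lesser_prob:
        lead = LeadID(int(rng.integers(0, 12)))
        per_lead[lead] = rng.uniform(*lesser_range_mm) / gain
    return CaseSpec(
        label="NSTEMI",
        territories=frozenset(),
        per_lead_st_mV=per_lead,
        seed=seed,
        heart_rate_bpm=heart_rate,
        noise=noise,
    )


def generate_dataset(
    n_cases: int,
    stemi_fraction: float = 677.0 / 888.0,
    territory_mix: dict[str, float] | None = None,
    elevation_range_mm: tuple[float, float] = (1.5, 3.0),
    seed: int = 0,
    out_dir: str | Path | None = None,
    layout: PageLayout | None = None,
    calib: CalibrationSpec | None = None,
    noise: NoiseParams | None = None,
    write_images: bool = True,
    **sample_kwargs,
):
    """Generate a seeded synthetic dataset and (optionally) write it to disk.

    Writes one PNG page and one PASCAL VOC XML annotation file per case plus
    ``manifest.csv`` and a ``params.json`` record of every generation
    parameter.  Returns the manifest as a :class:`pandas.DataFrame`.
    """
    import pandas as pd

    from .io import write_voc_xml

    if not 0.0 <= stemi_fraction <= 1.0:
        raise ValueError("stemi_fraction must lie in [0, 1]")
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")

    layout = layout or build_layout()
    calib = calib or CalibrationSpec()
    rng = np.random.default_rng(seed)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "annotations").mkdir(parents=True, exist_ok=True)

    rows = []
    specs: list[CaseSpec] = []
    boxes_per_case: list[list[GroundTruthBox]] = []
    for i in range(n_cases):
        spec = sample_case_spec(
            rng,
            stemi_fraction=stemi_fraction,
            territory_mix=territory_mix,
            elevation_range_mm=elevation_range_mm,
            noise=noise,
            **sample_kwargs,
        )
        case_id = f"case_{i:04d}"
        if out is not None and write_images:
            image, boxes = render_case(spec, layout, calib)
            Image.fromarray(image).save(out / "images" / f"{case_id}.png")
        else:
            boxes = case_ground_truth(spec, layout, calib)
        if out is not None:
            write_voc_xml(
                boxes,
                out / "annotations" / f"{case_id}.xml",
                image_name=f"{case_id}.png",
                image_size=(layout.image_height, layout.image_width),
            )
        specs.append(spec)
        boxes_per_case.append(boxes)
        rows.append(
            {
                "case_id": case_id,
                "image_path": f"images/{case_id}.png",
                "annotation_path": f"annotations/{case_id}.xml",
                "label": spec.label,
                "territories": ";".join(sorted(spec.territories)),
                "seed": spec.seed,
                "n_boxes": len(boxes),
                "params": json.dumps(
                    {
                        "heart_rate_bpm": round(spec.heart_rate_bpm, 3),
                        "per_lead_st_mV": {
                            l.name: round(v, 6) for l, v in sorted(spec.per_lead_st_mV.items())
                        },
                    },
                    sort_keys=True,
                ),
            }
        )

    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        params = {
            "n_cases": n_cases,
            "stemi_fraction": stemi_fraction,
            "territory_mix": territory_mix or DEFAULT_TERRITORY_MIX,
            "elevation_range_mm": list(elevation_range_mm),
            "seed": seed,
            "noise": vars(noise or NoiseParams()),
            "image_size": [layout.image_height, layout.image_width],
            "calibration": vars(calib),
        }
        (out / "params.json").write_text(json.dumps(params, indent=1, sort_keys=True))
    manifest.attrs["specs"] = specs
    manifest.attrs["boxes"] = boxes_per_case
    return manifest
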