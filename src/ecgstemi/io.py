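"""File formats: PASCAL VOC XML annotations, detection CSV, manifests, config.

Boxes live on disk in the VOC dialect emitted by common annotation tools
(``object/name`` + ``bndbox`` with 1-based inclusive ``xmin/ymin/xmax/ymax``)
and in memory as 0-based half-open rectangles or center-parameterized boxes;
the conversion between the two conventions is localized here.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .detector import BoundingBox, Detection
from .layout import LeadID, Rect
from .synthgen import LESSER_STE, STE, GroundTruthBox

__all__ = [
    "read_voc_xml",
    "write_voc_xml",
    "normalize_class_name",
    "write_detections_csv",
    "read_detections_csv",
    "read_manifest",
    "PipelineConfig",
]

DETECTION_CSV_COLUMNS = ["case_id", "subregion", "lead", "cx", "cy", "w", "h", "cls", "score"]


def normalize_class_name(name: str) -> str:
    """Map annotation class spellings onto {STE, lesser_STE}."""
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    if key == "ste":
        return STE
    if key in ("lesser_ste", "lesserste"):
        return LESSER_STE
    raise ValueError(f"unknown annotation class name: {name!r}")


def write_voc_xml(
    boxes: list,
    path: str | Path,
    image_name: str = "",
    image_size: tuple[int, int] = (0, 0),
) -> None:
    """Write boxes (GroundTruthBox or Detection) as a VOC XML annotation file.

    Rect coordinates (0-based half-open) become 1-based inclusive pixel
    bounds: ``xmin = x0 + 1``, ``xmax = x0 + width``.  Center boxes are
    rounded to the nearest pixel rectangle first.
    """
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = image_name
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(image_size[1])
    etree.SubElement(size, "height").text = str(image_size[0])
    etree.SubElement(size, "depth").text = "1"
    for b in boxes:
        if isinstance(b, Detection):
            x0 = int(round(b.box.x - b.box.w / 2))
            y0 = int(round(b.box.y - b.box.h / 2))
            w = max(1, int(round(b.box.w)))
            h = max(1, int(round(b.box.h)))
            cls, lead, sub = b.cls, b.lead, b.subregion_index
            score = b.score
        else:
            x0, y0, w, h = b.rect.x0, b.rect.y0, b.rect.width, b.rect.height
            cls, lead, sub = b.cls, b.lead, b.subregion_index
            score = None
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = cls
        etree.SubElement(obj, "lead").text = lead.name
        etree.SubElement(obj, "subregion").text = str(sub)
        if score is not None:
            etree.SubElement(obj, "score").text = f"{score:.6f}"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(x0 + 1)
        etree.SubElement(bnd, "ymin").text = str(y0 + 1)
        etree.SubElement(bnd, "xmax").text = str(x0 + w)
        etree.SubElement(bnd, "ymax").text = str(y0 + h)
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


def read_voc_xml(path: str | Path) -> list[GroundTruthBox]:
    """Read a VOC XML annotation file back into ground-truth boxes.

    1-based inclusive bounds become 0-based half-open rects:
    ``x0 = xmin - 1``, ``width = xmax - xmin + 1``.  Class names are matched
    case-insensitively and tolerate hyphen/space variants.
    """
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed VOC XML in {path}: {exc}") from exc
    boxes: list[GroundTruthBox] = []
    for obj in root.iter("object"):
        cls = normalize_class_name(obj.findtext("name", default=""))
        lead_text = obj.findtext("lead")
        lead = LeadID.parse(lead_text) if lead_text else LeadID.I
        sub_text = obj.findtext("subregion")
        sub = int(sub_text) if sub_text is not None else 0
        bnd = obj.find("bndbox")
        xmin, ymin = int(bnd.findtext("xmin")), int(bnd.findtext("ymin"))
        xmax, ymax = int(bnd.findtext("xmax")), int(bnd.findtext("ymax"))
        boxes.append(
            GroundTruthBox(
                rect=Rect(xmin - 1, ymin - 1, xmax - xmin + 1, ymax - ymin + 1),
                cls=cls,
                lead=lead,
                subregion_index=sub,
            )
        )
    return boxes


def write_detections_csv(per_case: dict[str, list[Detection]], path: str | Path) -> None:
    """Flat CSV of detections across cases (fixed schema, header mandatory)."""
    rows = []
    for case_id, dets in per_case.items():
        for d in dets:
            rows.append(
                {
                    "case_id": case_id,
                    "subregion": d.subregion_index,
                    "lead": d.lead.name,
                    "cx": d.box.x,
                    "cy": d.box.y,
                    "w": d.box.w,
                    "h": d.box.h,
                    "cls": d.cls,
                    "score": d.score,
                }
            )
    pd.DataFrame(rows, columns=DETECTION_CSV_COLUMNS).to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> dict[str, list[Detection]]:
    df = pd.read_csv(path)
    missing = set(DETECTION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    out: dict[str, list[Detection]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.case_id), []).append(
            Detection(
                subregion_index=int(row.subregion),
                lead=LeadID.parse(str(row.lead)),
                box=BoundingBox(float(row.cx), float(row.cy), float(row.w), float(row.h)),
                cls=normalize_class_name(str(row.cls)),
                score=float(row.score),
            )
        )
    return out


def read_manifest(data_dir: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a dataset manifest written by the generator."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv", keep_default_na=False)
    for row in manifest.itertuples(index=False):
        if row.label == "NSTEMI" and row.territories:
            raise ValueError(f"{row.case_id}: NSTEMI case with non-empty territories")
        if check_paths:
            ann = data_dir / row.annotation_path
            if not ann.exists():
                raise FileNotFoundError(f"{row.case_id}: missing annotation {ann}")
    return manifest


@dataclass
class PipelineConfig:
    """Every named parameter of the pipeline, serializable to JSON.

    Detector thresholds, the NMS settings, the encoding choice and the
    territory-rule minimum all live here so a run can be reproduced from its
    recorded configuration alone.
    """

    image_height: int = 1228
    image_width: int = 2460
    paper_speed: float = 25.0
    gain: float = 10.0
    px_per_mm_x: float = 10.0
    px_per_mm_y: float = 10.0
    lesser_floor_mm: float = 0.5
    ste_threshold_mm: float = 1.0
    j_offset_ms: float = 0.0
    nms_iou_threshold: float = 0.5
    nms_score_threshold: float = 0.7
    nms_sigma: float = 0.5
    encoding_scheme: str = "Lead-Detailed Presence"
    anterior_min: int = 2
    cv_folds: int = 5
    cv_seed: int = 0

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def layout(self):
        from .layout import build_layout

        return build_layout(self.image_height, self.image_width)

    def calibration(self):
        from .layout import CalibrationSpec

        return CalibrationSpec(self.paper_speed, self.gain, self.px_per_mm_x, self.px_per_mm_y)
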