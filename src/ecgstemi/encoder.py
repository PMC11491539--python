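"""The six feature encodings of a page's STE detection results.

Detections (post soft-NMS) are aggregated into fixed-length integer vectors
for the downstream STEMI classifier.  Schemes differ along two axes:

* granularity — per image (totals) or per lead (12 clinical leads);
* detail     — STE class only, or STE and lesser-STE separately;
* value      — raw counts, or 0/1 presence indicators.

======================  ===  ==============================================
scheme                  dim  contents
======================  ===  ==============================================
Image-Detailed Count      2  (total STE count, total lesser-STE count)
Lead-STE Count           12  STE count per lead
Lead-Detailed Count      24  per lead: (STE count, lesser-STE count)
Image-Detailed Presence   2  presence version of Image-Detailed Count
Lead-STE Presence        12  presence version of Lead-STE Count
Lead-Detailed Presence   24  presence version of Lead-Detailed Count
======================  ===  ==============================================

Worked example: four STE and one lesser STE detected at the first lead and
two lesser STE at the second lead give [4, 3], [4, 0, ..., 0],
[4, 1, 0, 2, 0, ..., 0], [1, 1], [1, 0, ..., 0] and [1, 1, 0, 1, 0, ..., 0]
respectively.

Lead-indexed schemes use the canonical lead order (I, II, III, aVR, aVL,
aVF, V1-V6); 24-dim schemes are lead-major with the STE slot before the
lesser-STE slot.  Detections from the four rhythm-strip subregions aggregate
into lead II.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .detector import Detection
from .layout import LeadID
from .synthgen import LESSER_STE, STE

__all__ = ["EncodingScheme", "EncodingVector", "encode", "encode_all", "DetectionEncoder"]


class EncodingScheme(Enum):
    IMAGE_DETAILED_COUNT = "Image-Detailed Count"
    LEAD_STE_COUNT = "Lead-STE Count"
    LEAD_DETAILED_COUNT = "Lead-Detailed Count"
    IMAGE_DETAILED_PRESENCE = "Image-Detailed Presence"
    LEAD_STE_PRESENCE = "Lead-STE Presence"
    LEAD_DETAILED_PRESENCE = "Lead-Detailed Presence"

    @property
    def dimension(self) -> int:
        return {
            EncodingScheme.IMAGE_DETAILED_COUNT: 2,
            EncodingScheme.LEAD_STE_COUNT: 12,
            EncodingScheme.LEAD_DETAILED_COUNT: 24,
            EncodingScheme.IMAGE_DETAILED_PRESENCE: 2,
            EncodingScheme.LEAD_STE_PRESENCE: 12,
            EncodingScheme.LEAD_DETAILED_PRESENCE: 24,
        }[self]

    @property
    def is_presence(self) -> bool:
        return "Presence" in self.value

    @classmethod
    def parse(cls, name: str) -> "EncodingScheme":
        key = name.strip().lower().replace("_", "-").replace(" ", "-")
        for member in cls:
            if member.value.lower().replace(" ", "-") == key or member.name.lower().replace("_", "-") == key:
                return member
        raise ValueError(f"unknown encoding scheme: {name!r}")


@dataclass(frozen=True)
class EncodingVector:
    scheme: EncodingScheme
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != self.scheme.dimension:
            raise ValueError(
                f"{self.scheme.value} expects {self.scheme.dimension} values, "
                f"got {len(self.values)}"
            )


def _counts(dets: list[Detection]) -> np.ndarray:
    """24-dim lead-major (STE, lesser) count table; the master aggregate."""
    table = np.zeros(24, dtype=int)
    for d in dets:
        slot = 2 * int(d.lead) + (0 if d.cls == STE else 1)
        if d.cls not in (STE, LESSER_STE):
            raise ValueError(f"unknown detection class: {d.cls!r}")
        table[slot] += 1
    return table


def encode(dets: list[Detection], scheme: EncodingScheme) -> EncodingVector:
    """Aggregate a case's detections under one encoding scheme."""
    if not isinstance(scheme, EncodingScheme):
        scheme = EncodingScheme.parse(scheme)
    table = _counts(dets)
    ste, lesser = table[0::2], table[1::2]
    if scheme is EncodingScheme.IMAGE_DETAILED_COUNT:
        values = np.array([ste.sum(), lesser.sum()])
    elif scheme is EncodingScheme.LEAD_STE_COUNT:
        values = ste.copy()
    elif scheme is EncodingScheme.LEAD_DETAILED_COUNT:
        values = table.copy()
    elif scheme is EncodingScheme.IMAGE_DETAILED_PRESENCE:
        values = (np.array([ste.sum(), lesser.sum()]) > 0).astype(int)
    elif scheme is EncodingScheme.LEAD_STE_PRESENCE:
        values = (ste > 0).astype(int)
    elif scheme is EncodingScheme.LEAD_DETAILED_PRESENCE:
        values = (table > 0).astype(int)
    else:  # pragma: no cover
        raise ValueError(f"unknown encoding scheme: {scheme!r}")
    return EncodingVector(scheme, values)


def encode_all(dets: list[Detection]) -> dict[EncodingScheme, EncodingVector]:
    """All six encodings of one detection list."""
    return {scheme: encode(dets, scheme) for scheme in EncodingScheme}


class DetectionEncoder:
    """Scikit-learn-style transformer: detection lists -> feature matrix.

    ``transform`` takes a sequence of per-case detection lists and returns
    an ``(n_cases, scheme.dimension)`` integer array.  Stateless, so ``fit``
    is a no-op kept for pipeline compatibility.
    """

    def __init__(self, scheme: EncodingScheme | str = EncodingScheme.LEAD_DETAILED_PRESENCE):
        self.scheme = scheme

    def _resolved(self) -> EncodingScheme:
        s = self.scheme
        return s if isinstance(s, EncodingScheme) else EncodingScheme.parse(s)

    def fit(self, X, y=None) -> "DetectionEncoder":
        self.n_features_out_ = self._resolved().dimension
        return self

    def transform(self, X) -> np.ndarray:
        scheme = self._resolved()
        return np.vstack([encode(dets, scheme).values for dets in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"scheme": self.scheme}

    def set_params(self, **params) -> "DetectionEncoder":
        for k, v in params.items():
            if k != "scheme":
                raise ValueError(f"unknown parameter {k!r}")
            self.scheme = v
        return self
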