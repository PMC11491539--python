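"""Box codec, IoU, soft-NMS, beat segmentation and ST measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_case
from ecgstemi import (
    Anchor,
    BoundingBox,
    Detection,
    LeadID,
    NoiseParams,
    Rect,
    boxes_from_beats,
    crop_subregions,
    decode_box,
    detect,
    detect_beats,
    encode_box,
    extract_trace,
    iou,
    measure_st,
    render_case,
    soft_nms,
    suppress_grid,
)

finite_coord = st.floats(-500, 500)
positive_size = st.floats(0.5, 400)
boxes_strategy = st.builds(BoundingBox, x=finite_coord, y=finite_coord, w=positive_size, h=positive_size)


class TestBoxCodec:
    def test_identity_when_box_equals_anchor(self):
        a = Anchor(10, 20, 8, 6)
        t = encode_box(BoundingBox(10, 20, 8, 6), a)
        assert (t.t_x, t.t_y, t.t_w, t.t_h) == (0, 0, 0, 0)

    def test_hand_computed_targets(self):
        t = encode_box(BoundingBox(20, 10, 8, 4), Anchor(10, 10, 4, 4))
        assert t.t_x == pytest.approx(2.5)
        assert t.t_y == pytest.approx(0.0)
        assert t.t_w == pytest.approx(math.log(2))
        assert t.t_h == pytest.approx(0.0)

    @settings(max_examples=100, derandomize=True)
    @given(box=boxes_strategy, anchor=boxes_strategy)
    def test_decode_inverts_encode(self, box, anchor):
        restored = decode_box(encode_box(box, anchor), anchor)
        assert restored.x == pytest.approx(box.x, abs=1e-6)
        assert restored.y == pytest.approx(box.y, abs=1e-6)
        assert restored.w == pytest.approx(box.w, rel=1e-9)
        assert restored.h == pytest.approx(box.h, rel=1e-9)

    def test_nonpositive_extent_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(0, 0, -1, 5)


class TestIoU:
    def test_identical_boxes(self):
        b = BoundingBox(5, 5, 4, 4)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(10, 10, 2, 2)) == 0.0

    def test_half_offset_overlap_is_one_third(self):
        # corner boxes (0,0,2,2) and (1,0,2,2): areas 4, intersection 2
        a = BoundingBox(1, 1, 2, 2)
        b = BoundingBox(2, 1, 2, 2)
        assert iou(a, b) == pytest.approx(1 / 3)

    @settings(max_examples=100, derandomize=True)
    @given(a=boxes_strategy, b=boxes_strategy)
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b, a))


def _det(x, score, sub=0, cls="STE", w=10.0, h=10.0, y=0.0):
    return Detection(subregion_index=sub, lead=LeadID.I,
                     box=BoundingBox(x, y, w, h), cls=cls, score=score)


class TestSoftNMS:
    def test_single_detection_unchanged(self):
        d = _det(0, 0.9)
        assert soft_nms([d]) == [d]

    def test_identical_boxes_second_removed(self):
        # decay exp(-1/0.5) ~ 0.1353: 0.85 -> 0.115 < 0.7
        out = soft_nms([_det(0, 0.9), _det(0, 0.85)])
        assert len(out) == 1 and out[0].score == 0.9

    def test_disjoint_boxes_both_kept(self):
        out = soft_nms([_det(0, 0.9), _det(100, 0.8)])
        assert len(out) == 2

    def test_different_subregions_never_suppress(self):
        out = soft_nms([_det(0, 0.9, sub=0), _det(0, 0.9, sub=1)])
        assert len(out) == 2

    @settings(max_examples=50, derandomize=True)
    @given(scores=st.lists(st.floats(0.7, 1.0), min_size=1, max_size=6),
           xs=st.lists(st.floats(0, 50), min_size=1, max_size=6))
    def test_never_increases_scores_or_count_and_idempotent(self, scores, xs):
        n = min(len(scores), len(xs))
        dets = [_det(x, s) for x, s in zip(xs[:n], scores[:n])]
        out = soft_nms(dets)
        assert len(out) <= len(dets)
        in_scores = sorted(d.score for d in dets)
        for d in out:
            assert d.score <= max(in_scores) + 1e-12
        assert [d.score for d in out] == sorted((d.score for d in out), reverse=True)
        assert soft_nms(out) == out


class TestBeatSegmentation:
    def _signal(self, layout, calib, spec, lead):
        image, _ = render_case(spec, layout, calib)
        for l, crop in crop_subregions(image, layout):
            if l is lead:
                mask = suppress_grid(crop)
                return extract_trace(mask, Rect(0, 0, crop.shape[1], crop.shape[0]),
                                     calib, lead=lead)
        raise AssertionError

    def test_flat_signal_no_beats(self, calib):
        from ecgstemi.digitizer import LeadSignal

        n = 400
        sig = LeadSignal(LeadID.I, np.arange(n) * 4.0, np.zeros(n), np.ones(n, bool), 100)
        assert detect_beats(sig) == []

    def test_rhythm_strip_beat_count_at_hr75(self, layout, calib):
        # ~9.84 s of lead II at RR 800 ms -> 12 or 13 R peaks
        spec = make_case({}, seed=8, heart_rate=75.0)
        image, _ = render_case(spec, layout, calib)
        r = layout.rhythm_rect
        crop = image[r.y0 : r.y1, r.x0 : r.x1]
        sig = extract_trace(suppress_grid(crop), Rect(0, 0, r.width, r.height),
                            calib, lead=LeadID.II)
        assert len(detect_beats(sig)) in (12, 13)

    def test_beat_count_scales_with_heart_rate(self, layout, calib):
        counts = {}
        for hr in (60.0, 120.0):
            spec = make_case({}, seed=9, heart_rate=hr)
            image, _ = render_case(spec, layout, calib)
            r = layout.rhythm_rect
            crop = image[r.y0 : r.y1, r.x0 : r.x1]
            sig = extract_trace(suppress_grid(crop), Rect(0, 0, r.width, r.height),
                                calib, lead=LeadID.II)
            counts[hr] = len(detect_beats(sig))
        assert counts[120.0] / counts[60.0] == pytest.approx(2.0, abs=0.3)


class TestMeasureST:
    @pytest.mark.parametrize("elev,lo,hi", [(0.0, -0.3, 0.3), (2.0, 1.8, 2.2), (-1.0, -1.2, -0.8)])
    def test_injected_elevation_recovered(self, layout, calib, elev, lo, hi):
        spec = make_case({LeadID.V2: elev}, seed=3)
        image, _ = render_case(spec, layout, calib)
        lead_crop = dict((l, c) for l, c in crop_subregions(image, layout)[:12])
        crop = lead_crop[LeadID.V2]
        sig = extract_trace(suppress_grid(crop), Rect(0, 0, crop.shape[1], crop.shape[0]),
                            calib, lead=LeadID.V2)
        beats = detect_beats(sig)
        assert beats
        for beat in beats:
            st = measure_st(sig, beat, calib)
            if st is not None:
                assert lo <= st <= hi


class TestBoxesFromBeats:
    def _detections(self, layout, calib, elev_mm, seed=3):
        spec = make_case({LeadID.V2: elev_mm}, seed=seed)
        image, _ = render_case(spec, layout, calib)
        index = [i for i, (l, _) in enumerate(layout.subregion_rects) if l is LeadID.V2][0]
        _, crop = crop_subregions(image, layout)[index]
        sig = extract_trace(suppress_grid(crop), Rect(0, 0, crop.shape[1], crop.shape[0]),
                            calib, lead=LeadID.V2)
        beats = detect_beats(sig)
        for b in beats:
            measure_st(sig, b, calib)
        rect = layout.subregion_rects[index][1]
        return boxes_from_beats(sig, beats, rect, calib, subregion_index=index)

    def test_sub_floor_beats_yield_nothing(self, layout, calib):
        assert self._detections(layout, calib, 0.3) == []

    @pytest.mark.parametrize("elev,cls", [(2.0, "STE"), (0.8, "lesser_STE")])
    def test_class_split_at_one_mm(self, layout, calib, elev, cls):
        dets = self._detections(layout, calib, elev)
        assert dets and all(d.cls == cls for d in dets)

    def test_boxes_inside_subregion(self, layout, calib):
        dets = self._detections(layout, calib, 2.5)
        for d in dets:
            rect = layout.subregion_rects[d.subregion_index][1]
            x0, y0, x1, y1 = d.box.corners()
            assert x0 >= rect.x0 - 1e-6 and x1 <= rect.x1 + 1e-6
            assert y0 >= rect.y0 - 1e-6 and y1 <= rect.y1 + 1e-6


class TestFullPageDetect:
    def test_clean_nstemi_page_no_ste_detections(self, layout, calib):
        spec = make_case({}, seed=12)
        image, _ = render_case(spec, layout, calib)
        assert [d for d in detect(image, layout, calib) if d.cls == "STE"] == []

    def test_inferior_case_fires_in_qualifying_leads(self, inferior_case_rendered, layout, calib):
        _, image, _ = inferior_case_rendered
        dets = detect(image, layout, calib)
        ste_leads = {d.lead for d in dets if d.cls == "STE"}
        assert len(ste_leads & {LeadID.II, LeadID.III, LeadID.aVF}) >= 2

    def test_detection_sensitivity_on_clean_case(self, inferior_case_rendered, layout, calib):
        from ecgstemi import evaluate_detections

        _, image, boxes = inferior_case_rendered
        dets = detect(image, layout, calib)
        res = evaluate_detections([boxes], [dets])
        assert res["STE"].sensitivity >= 0.95
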