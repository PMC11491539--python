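"""Waveform model, territory profiles, rendering and dataset generation."""

import numpy as np
import pytest

from conftest import make_case
from ecgstemi import (
    BeatParams,
    LeadID,
    NoiseParams,
    beat_waveform,
    case_ground_truth,
    generate_dataset,
    render_case,
    territory_profile,
)
from ecgstemi.synthgen import TERRITORY_LEADS, WaveComponent, sample_case_spec


class TestBeatWaveform:
    def test_zero_amplitudes_give_zero_series(self):
        flat = BeatParams(
            p=WaveComponent(0, 40, 90),
            q=WaveComponent(0, 15, 225),
            r=WaveComponent(0, 20, 250),
            s=WaveComponent(0, 15, 275),
            t=WaveComponent(0, 70, 450),
        )
        t = np.arange(0, 800, 1.0)
        assert np.allclose(beat_waveform(flat, t), 0.0)

    def test_returns_to_baseline_between_beats(self):
        params = BeatParams()
        t = np.arange(0, 800, 1.0)
        v = beat_waveform(params, t)
        tail = v[(t > 650) & (t < 800)]
        assert np.abs(tail).max() < 0.01

    def test_st_plateau_mean_matches_offset(self):
        # mean over the ST window minus mean over the PR window ~ st_offset
        params = BeatParams(st_offset=0.2)
        t = np.arange(0, 800, 0.5)
        v = beat_waveform(params, t)
        st = v[(t >= params.qrs_offset + 20) & (t <= params.t_onset - 20)].mean()
        pr = v[(t >= params.qrs_onset - 80) & (t <= params.qrs_onset - 20)].mean()
        assert st - pr == pytest.approx(0.2, abs=0.01)

    def test_doubling_r_doubles_series_maximum(self):
        base = BeatParams()
        doubled = BeatParams(r=WaveComponent(2.4, 20, 250))
        t = np.arange(0, 800, 1.0)
        assert beat_waveform(doubled, t).max() == pytest.approx(
            2 * beat_waveform(base, t).max(), rel=1e-3
        )

    def test_invalid_rr_rejected(self):
        with pytest.raises(ValueError):
            BeatParams(rr_interval=100)


class TestTerritoryProfile:
    def test_inferior_assigns_qualifying_leads_only(self):
        rng = np.random.default_rng(0)
        offsets = territory_profile({"inferior"}, 2.0, rng)
        inferior = set(TERRITORY_LEADS["inferior"])
        assert len(set(offsets) & inferior) >= 2
        assert set(offsets) <= inferior
        assert all(v == pytest.approx(0.2) for v in offsets.values())

    def test_empty_set_gives_empty_map(self):
        assert territory_profile(set(), 3.0, np.random.default_rng(0)) == {}

    def test_suspected_lm_puts_elevation_in_avr(self):
        offsets = territory_profile({"suspected_LM"}, 1.5, np.random.default_rng(1))
        assert offsets == {LeadID.aVR: pytest.approx(0.15)}

    def test_unknown_territory_rejected(self):
        with pytest.raises(ValueError):
            territory_profile({"septal"}, 1.0, np.random.default_rng(0))


class TestRenderCase:
    def test_no_elevation_no_boxes(self, layout, calib):
        spec = make_case({}, seed=3)
        image, boxes = render_case(spec, layout, calib)
        assert boxes == []
        assert image.shape == (layout.image_height, layout.image_width)

    def test_deterministic_under_seed(self, layout, calib):
        spec = make_case({LeadID.V2: 2.0, LeadID.V3: 2.0}, seed=5,
                         territories=frozenset({"anterior"}))
        img1, boxes1 = render_case(spec, layout, calib)
        img2, boxes2 = render_case(spec, layout, calib)
        assert (img1 == img2).all()
        assert boxes1 == boxes2

    def test_distinct_seeds_distinct_images(self, layout, calib):
        a = make_case({LeadID.V2: 2.0, LeadID.V3: 2.0}, seed=5,
                      territories=frozenset({"anterior"}),
                      noise=NoiseParams())
        b = make_case({LeadID.V2: 2.0, LeadID.V3: 2.0}, seed=6,
                      territories=frozenset({"anterior"}),
                      noise=NoiseParams())
        assert (render_case(a, layout, calib)[0] != render_case(b, layout, calib)[0]).any()

    def test_every_visible_beat_in_qualifying_subregions_boxed(self, layout, calib):
        # HR 75 -> RR 800 ms; a 2.46 s window holds 3 beats with full PR+ST
        spec = make_case({LeadID.II: 2.0, LeadID.III: 2.0}, seed=7,
                         territories=frozenset({"inferior"}), heart_rate=75.0)
        _, boxes = render_case(spec, layout, calib)
        per_sub = {}
        for b in boxes:
            assert b.cls == "STE"
            per_sub.setdefault(b.subregion_index, 0)
            per_sub[b.subregion_index] += 1
        # lead II short panel + III panel + 4 rhythm splits all carry boxes
        assert set(per_sub) == {1, 2, 12, 13, 14, 15}
        assert all(2 <= n <= 4 for n in per_sub.values())

    def test_boxes_lie_within_their_subregions(self, inferior_case_rendered, layout):
        _, _, boxes = inferior_case_rendered
        for b in boxes:
            _, rect = layout.subregion_rects[b.subregion_index]
            assert b.rect.x0 >= rect.x0 and b.rect.x1 <= rect.x1
            assert b.rect.y0 >= rect.y0 and b.rect.y1 <= rect.y1

    def test_ground_truth_without_render_matches_render(self, layout, calib):
        spec = make_case({LeadID.V5: 1.8, LeadID.V6: 1.8}, seed=9,
                         territories=frozenset({"lateral"}), noise=NoiseParams())
        _, boxes = render_case(spec, layout, calib)
        assert case_ground_truth(spec, layout, calib) == boxes

    def test_lesser_class_floor(self, layout, calib):
        spec = make_case({LeadID.V1: 0.8}, seed=2)
        _, boxes = render_case(spec, layout, calib)
        assert boxes and all(b.cls == "lesser_STE" for b in boxes)
        sub = make_case({LeadID.V1: 0.4}, seed=2)
        _, none = render_case(sub, layout, calib)
        assert none == []


class TestGenerateDataset:
    def test_all_stemi_when_fraction_one(self, tmp_path):
        manifest = generate_dataset(6, stemi_fraction=1.0, seed=1, out_dir=tmp_path,
                                    write_images=False)
        assert (manifest.label == "STEMI").all()
        assert (manifest.territories != "").all()

    def test_manifest_regeneration_identical(self, tmp_path):
        m1 = generate_dataset(8, seed=42, out_dir=tmp_path / "a", write_images=False)
        m2 = generate_dataset(8, seed=42, out_dir=tmp_path / "b", write_images=False)
        assert (tmp_path / "a" / "manifest.csv").read_text() == (
            tmp_path / "b" / "manifest.csv"
        ).read_text()
        assert m1.drop(columns=[]).equals(m2)

    def test_class_mix_near_requested(self):
        rng = np.random.default_rng(0)
        labels = [sample_case_spec(rng, stemi_fraction=677 / 888).label for _ in range(888)]
        n_stemi = sum(l == "STEMI" for l in labels)
        # binomial(888, 0.762): mean 677, sd ~12.7; allow 4 sd
        assert abs(n_stemi - 677) < 51

    def test_multi_territory_cases_occur(self):
        rng = np.random.default_rng(3)
        specs = [sample_case_spec(rng, stemi_fraction=1.0, multi_territory_prob=0.5)
                 for _ in range(40)]
        assert any(len(s.territories) >= 2 for s in specs)

    def test_nstemi_cases_have_no_ste_boxes(self, layout, calib):
        rng = np.random.default_rng(5)
        for _ in range(10):
            spec = sample_case_spec(rng, stemi_fraction=0.0)
            boxes = case_ground_truth(spec, layout, calib)
            assert all(b.cls == "lesser_STE" for b in boxes)

    def test_invalid_arguments_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(0, seed=1, out_dir=tmp_path)
        with pytest.raises(ValueError):
            generate_dataset(5, stemi_fraction=1.5, seed=1, out_dir=tmp_path)
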