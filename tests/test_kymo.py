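"""Kymograph extraction, segmentation, linking and morphometry."""

import numpy as np
import pytest

from axomito import kymo
from axomito.kymo import (AxonFrameSeries, AxonPath, PathError,
                          branch_density, distal_sampling_window,
                          extract_profiles, link_tracks, measure_density,
                          mito_mass, segment_mitochondria, segment_series)
from axomito.synthetic import render_series, render_stack, simulate_dynamics

from conftest import clean_config


def straight_path(length_um: float, y_um: float) -> AxonPath:
    return AxonPath(np.array([[0.0, y_um], [length_um, y_um]]))


class TestAxonPath:
    def test_needs_two_vertices(self):
        with pytest.raises(PathError):
            AxonPath(np.array([[0.0, 0.0]]))

    def test_arc_length_of_a_bent_polyline(self):
        p = AxonPath(np.array([[0, 0], [3, 0], [3, 4]], dtype=float))
        assert p.length == pytest.approx(7.0)
        assert p.point_at(np.array([5.0]))[0] == pytest.approx([3, 2])

    def test_json_round_trip(self):
        p = AxonPath(np.array([[0.0, 1.0], [50.0, 2.0]]),
                     growth_cone_boundary=45.0)
        q = AxonPath.from_json(p.to_json())
        assert np.allclose(q.vertices, p.vertices)
        assert q.growth_cone_boundary == 45.0


class TestDistalWindow:
    def test_annotated_boundary(self):
        p = AxonPath(np.array([[0.0, 0.0], [100.0, 0.0]]),
                     growth_cone_boundary=90.0)
        assert distal_sampling_window(p) == (40.0, 90.0)

    def test_fallback_excludes_distal_10um(self):
        p = AxonPath(np.array([[0.0, 0.0], [100.0, 0.0]]))
        assert distal_sampling_window(p) == (40.0, 90.0)

    def test_short_path_raises(self):
        p = AxonPath(np.array([[0.0, 0.0], [55.0, 0.0]]),
                     growth_cone_boundary=50.0)
        with pytest.raises(PathError):
            distal_sampling_window(p)


class TestExtractProfiles:
    def test_uniform_stack_gives_flat_profile(self):
        stack = np.full((3, 9, 100), 42.0)
        series = extract_profiles(stack, straight_path(11.0, 0.54),
                                  pixel_size=0.12, frame_interval=3.0)
        assert np.allclose(series.data, 42.0)

    def test_one_pixel_transect_equals_raster_row(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 100, size=(2, 9, 80))
        y = 4.5 * 0.12    # centre of row 4
        series = extract_profiles(stack, straight_path(80 * 0.12, y),
                                  pixel_size=0.12, frame_interval=3.0,
                                  width=0.0)
        assert np.allclose(series.data, stack[:, 4, :], atol=1e-6)

    def test_peaks_match_true_centres_on_rendered_stack(self):
        cfg = clean_config(fission_prob_per_10min=0.0,
                           fusion_prob_per_10min=0.0,
                           motility_fractions=(1.0, 0, 0))
        truth = simulate_dynamics(cfg)
        stack = render_stack(truth, height=7)
        y = 3.5 * cfg.pixel_size
        series = extract_profiles(stack, straight_path(cfg.axon_length, y),
                                  cfg.pixel_size, cfg.frame_interval,
                                  width=0.36)
        segs = segment_mitochondria(series, 0)
        true_centres = sorted((a + b) / 2 for a, b in
                              (t.bounds[0] for t in truth.tracks))
        got = sorted(s.centre for s in segs)
        assert len(got) == len(true_centres)
        assert np.allclose(got, true_centres, atol=cfg.pixel_size)

    def test_path_outside_image_raises_with_frame(self):
        stack = np.zeros((2, 9, 50))
        with pytest.raises(PathError, match="frame"):
            extract_profiles(stack, straight_path(100.0, 0.54),
                             pixel_size=0.12, frame_interval=3.0)


class TestSegmentation:
    def test_all_background_frame_is_empty(self):
        data = np.full((5, 200), 7.0)
        data[0, 50:60] = 120.0      # give the series some dynamic range
        series = AxonFrameSeries(data, 0.12, 3.0)
        assert segment_mitochondria(series, 3) == []

    def test_noise_free_length_within_one_pixel(self):
        cfg = clean_config(n_mito=1, mito_length_dist=(2.0, 0.0),
                           fission_prob_per_10min=0.0,
                           motility_fractions=(1.0, 0, 0))
        series = render_series(simulate_dynamics(cfg))
        segs = segment_mitochondria(series, 0)
        assert len(segs) == 1
        assert segs[0].length == pytest.approx(2.0, abs=cfg.pixel_size)

    def test_lengths_match_truth_across_population(self):
        for seed in range(4):
            cfg = clean_config(seed=seed)
            truth = simulate_dynamics(cfg)
            series = render_series(truth)
            segs = segment_mitochondria(series, 0)
            true_lengths = sorted(b - a for a, b in
                                  (t.bounds[0] for t in truth.tracks
                                   if t.birth_frame == 0))
            got = sorted(s.length for s in segs)
            assert np.allclose(got, true_lengths, atol=cfg.pixel_size)

    def test_doubled_plateau_is_flagged_as_overlap(self, profile_builder):
        b = profile_builder(n_frames=4)
        b.add(slice(None), 8.0, 12.0, 100.0)
        b.add(slice(None), 9.0, 11.0, 100.0)   # overlapping pair: additive
        series = b.series()
        segs = segment_mitochondria(series, 0, ref_plateau=100.0)
        assert len(segs) == 1
        assert segs[0].excluded_overlap

    def test_density_invariant_to_pixel_size(self):
        import dataclasses
        cfg = clean_config(fission_prob_per_10min=0.0,
                           motility_fractions=(1.0, 0, 0))
        truth = simulate_dynamics(cfg)
        counts = {}
        for px in (0.12, 0.06):
            cfg2 = dataclasses.replace(cfg, pixel_size=px)
            truth2 = dataclasses.replace(truth, config=cfg2)
            series = render_series(truth2)
            counts[px] = len(segment_mitochondria(series, 0))
        assert counts[0.12] == counts[0.06] == cfg.n_mito


class TestLinking:
    def test_single_stationary_segment_spans_all_frames(self, profile_builder):
        b = profile_builder(n_frames=110)
        b.add(slice(None), 10.0, 13.0, 100.0)
        tracks, cands = link_tracks(segment_series(b.series()))
        assert len(tracks) == 1
        assert tracks[0].n_frames == 110
        assert cands == []

    def test_two_separated_mitochondria_stay_two_tracks(self, profile_builder):
        b = profile_builder(n_frames=40)
        b.add(slice(None), 5.0, 8.0, 100.0)
        b.add(slice(None), 20.0, 22.0, 120.0)
        tracks, cands = link_tracks(segment_series(b.series()))
        assert len(tracks) == 2
        assert cands == []

    def test_scripted_fission_yields_one_split_candidate(self, profile_builder):
        b = profile_builder(n_frames=60)
        b.add(slice(0, 40), 10.0, 18.0, 100.0)
        b.add(slice(40, 60), 10.0, 13.55, 100.0)
        b.add(slice(40, 60), 14.45, 18.0, 100.0)
        tracks, cands = link_tracks(segment_series(b.series()))
        splits = [c for c in cands if c.kind == "split"]
        assert len(splits) == 1
        assert splits[0].frame == 40

    def test_noninteracting_truth_gives_exactly_n_tracks(self):
        cfg = clean_config(fission_prob_per_10min=0.0,
                           fusion_prob_per_10min=0.0)
        truth = simulate_dynamics(cfg)
        tracks, cands = link_tracks(segment_series(render_series(truth)))
        assert len(tracks) == cfg.n_mito
        assert cands == []


class TestMorphometry:
    def test_density_examples(self):
        segs = [kymo.MitoSegment(0, i, i + 1.0, 10, 10) for i in range(5)]
        assert measure_density(segs, 25.0) == pytest.approx(2.0)
        assert measure_density([], 25.0) == 0.0
        with pytest.raises(ValueError):
            measure_density(segs, 0.0)

    def test_branch_rule_is_strictly_greater_than_10um(self):
        assert branch_density([5.0, 12.0, 30.0], 100.0) == pytest.approx(2.0)
        assert branch_density([10.0], 100.0) == 0.0
        assert branch_density([], 50.0) == 0.0
        with pytest.raises(ValueError):
            branch_density([5.0], 0.0)

    def test_mass_index_is_the_product(self):
        assert mito_mass(2.0, 1.0) == 2.0
        assert mito_mass(3.1, 0.0) == 0.0
        with pytest.raises(ValueError):
            mito_mass(-1.0, 2.0)
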