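"""Fission/fusion calling criteria, rates, and post-fission transport."""

import pytest

from axomito import events as ev, kymo
from axomito.events import (EventRecord, detect_fission, detect_fusion,
                            event_rate, match_events, post_fission_transport)
from axomito.kymo import link_tracks, segment_series
from axomito.synthetic import render_series, simulate_dynamics

from conftest import clean_config


def analyze(series):
    tracks, cands = link_tracks(segment_series(series))
    return tracks, cands


class TestFissionCriteria:
    def test_constant_single_track_has_no_events(self, profile_builder):
        b = profile_builder(n_frames=60)
        b.add(slice(None), 10.0, 18.0, 100.0)
        s = b.series()
        tracks, cands = analyze(s)
        assert detect_fission(tracks, cands, s) == []

    def test_scripted_fission_called_at_the_right_frame(self, profile_builder):
        # one interval splits at frame 40 with a 0.9 um final separation
        b = profile_builder(n_frames=60)
        b.add(slice(0, 40), 10.0, 18.0, 100.0)
        b.add(slice(40, 60), 10.0, 13.55, 100.0)
        b.add(slice(40, 60), 14.45, 18.0, 100.0)
        s = b.series()
        tracks, cands = analyze(s)
        events = detect_fission(tracks, cands, s)
        assert len(events) == 1
        assert abs(events[0].frame - 40) <= 1
        assert events[0].position == pytest.approx(14.0, abs=0.2)
        assert events[0].separation > 0.6

    def test_reclosing_constriction_is_not_fission(self, profile_builder):
        # the gap dims to 40% of the plateau but never reaches background,
        # the ends never separate beyond 0.6 um, and the constriction
        # re-closes: no event may be called
        b = profile_builder(n_frames=60)
        b.add(slice(None), 10.0, 18.0, 100.0)
        b.add(slice(20, 30), 13.8, 14.2, -60.0)
        s = b.series()
        tracks, cands = analyze(s)
        assert cands == []           # never segments into two
        assert detect_fission(tracks, cands, s) == []

    def test_full_depth_gap_below_separation_criterion_is_rejected(
            self, profile_builder):
        # with a sharp PSF a 0.5 um gap reaches background, but the
        # separation stays below 0.6 um and re-closes: still not fission
        b = profile_builder(n_frames=60, psf_sigma=0.05)
        b.add(slice(0, 20), 10.0, 18.0, 100.0)
        b.add(slice(20, 35), 10.0, 13.75, 100.0)
        b.add(slice(20, 35), 14.25, 18.0, 100.0)
        b.add(slice(35, 60), 10.0, 18.0, 100.0)
        s = b.series()
        tracks, cands = analyze(s)
        assert any(c.kind == "split" for c in cands)
        assert detect_fission(tracks, cands, s) == []

    def test_record_refuses_separation_at_or_below_criterion(self):
        with pytest.raises(ValueError, match="separation"):
            EventRecord(kind="fission", frame=5, position=1.0,
                        parent_ids=[0], child_ids=[1, 2], separation=0.6)


class TestFusionCriteria:
    def test_touching_without_mixing_is_not_fusion(self, profile_builder):
        # two mitochondria of unequal brightness touch (sub-resolution gap)
        # and later separate; the joint profile is never uniform
        b = profile_builder(n_frames=60)
        b.add(slice(0, 20), 10.0, 13.0, 100.0)
        b.add(slice(0, 20), 14.0, 17.0, 200.0)
        b.add(slice(20, 40), 10.0, 13.0, 100.0)
        b.add(slice(20, 40), 13.05, 16.05, 200.0)
        b.add(slice(40, 60), 10.0, 13.0, 100.0)
        b.add(slice(40, 60), 14.0, 17.0, 200.0)
        s = b.series()
        tracks, cands = analyze(s)
        assert detect_fusion(tracks, cands, s) == []

    def test_scripted_fusion_is_additive_and_uniform(self, profile_builder):
        b = profile_builder(n_frames=60)
        b.add(slice(0, 20), 10.0, 13.0, 100.0)
        b.add(slice(0, 20), 14.0, 17.0, 200.0)
        b.add(slice(20, 60), 11.0, 17.0, 150.0)   # merged: len 6 = 3 + 3
        s = b.series()
        tracks, cands = analyze(s)
        events = detect_fusion(tracks, cands, s)
        assert len(events) == 1
        e = events[0]
        assert abs(e.evidence["additivity_residual_um"]) <= 2 * 0.12
        # redistribution: post-merge CV below the parents' intensity CV
        assert e.evidence["cv_post"] < e.evidence["cv_pre_parents"]

    def test_simulated_fusions_are_recovered(self):
        hits = truths = 0
        for seed in range(12):
            cfg = clean_config(seed=seed, fusion_prob_per_10min=0.9,
                               fission_prob_per_10min=0.0,
                               motility_fractions=(0.5, 0.0, 0.5))
            truth = simulate_dynamics(cfg)
            s = render_series(truth)
            tracks, cands = analyze(s)
            m = match_events(detect_fusion(tracks, cands, s),
                             truth.fusion_events)
            assert m["precision"] == 1.0 and m["recall"] == 1.0
            truths += m["n_truth"]
        assert truths >= 5


class TestRates:
    def test_event_rate_arithmetic(self):
        events = [EventRecord("fission", 5, 1.0, [i], [100 + i, 200 + i],
                              separation=0.9) for i in range(20)]
        assert event_rate(events, 100, 600.0) == pytest.approx(20.0)
        assert event_rate([], 100, 600.0) == 0.0
        # a half window scales to the 10-min unit
        assert event_rate(events, 100, 300.0) == pytest.approx(40.0)
        with pytest.raises(ValueError):
            event_rate(events, 0, 600.0)

    def test_lineage_collapses_refissioning_daughters(self):
        events = [EventRecord("fission", 5, 1.0, [0], [1, 2], separation=0.9),
                  EventRecord("fission", 9, 1.2, [2], [3, 4], separation=0.9)]
        lineage = {0: 0, 1: 0, 2: 0, 3: 0, 4: 0}
        assert event_rate(events, 10, 600.0, lineage=lineage) == 10.0
        assert event_rate(events, 10, 600.0) == 20.0


class TestPostFissionTransport:
    def test_all_children_stationary_gives_zero(self):
        cfg = clean_config(seed=11, fission_prob_per_10min=0.9,
                           p_transport_after_fission=0.0,
                           motility_fractions=(1.0, 0, 0))
        truth = simulate_dynamics(cfg)
        assert truth.fission_events
        frac = post_fission_transport(truth.fission_events,
                                      truth.tracks_by_id(), 60.0,
                                      cfg.frame_interval)
        assert frac == 0.0

    def test_forced_transport_gives_one(self):
        found = False
        for seed in range(6):
            cfg = clean_config(seed=seed, axon_length=300.0, n_mito=3,
                               fission_prob_per_10min=0.9,
                               fusion_prob_per_10min=0.0,
                               p_transport_after_fission=1.0,
                               motility_fractions=(1.0, 0, 0))
            truth = simulate_dynamics(cfg)
            horizon_f = int(60.0 / cfg.frame_interval)
            events = [e for e in truth.fission_events
                      if e["frame"] + horizon_f <= cfg.n_frames - 1]
            if not events:
                continue
            found = True
            frac = post_fission_transport(events, truth.tracks_by_id(),
                                          60.0, cfg.frame_interval)
            assert frac == 1.0
        assert found


class TestEndToEndDetection:
    def test_noise_free_precision_and_recall_are_perfect(self):
        tot = 0
        for seed in range(10):
            truth = simulate_dynamics(clean_config(seed=seed))
            s = render_series(truth)
            tracks, cands = analyze(s)
            mf = match_events(detect_fission(tracks, cands, s),
                              truth.fission_events)
            mu = match_events(detect_fusion(tracks, cands, s),
                              truth.fusion_events)
            assert mf["precision"] == mf["recall"] == 1.0
            assert mu["precision"] == mu["recall"] == 1.0
            tot += mf["n_truth"] + mu["n_truth"]
        assert tot >= 10
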