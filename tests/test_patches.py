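"""Patch detection/classification and the random-overlap statistic."""

import numpy as np
import pytest

from axomito import patches as pt
from axomito.datasets import fission_overlap_arrays
from axomito.kymo import link_tracks, segment_series
from axomito.patches import (OverlapTable, build_overlap_table,
                             classify_patches, colocalization_fraction,
                             detect_patches, drp1_accumulations_per_mito,
                             patch_fate_stats, random_overlap_probability)
from axomito.synthetic import render_series, simulate_dynamics

from conftest import clean_config


class TestDetectPatches:
    def test_flat_channel_is_empty(self, profile_builder):
        series = profile_builder(n_frames=20).series("actin")
        assert detect_patches(series) == []

    def test_two_scripted_patches_recovered(self, profile_builder):
        b = profile_builder(n_frames=40)
        b.add(slice(5, 15), 8.0, 8.8, 120.0)
        b.add(slice(20, 32), 20.0, 20.6, 90.0)
        got = detect_patches(b.series("actin"))
        assert len(got) == 2
        assert abs(got[0].onset - 5) <= 1 and abs(got[0].offset - 14) <= 1
        assert abs(got[1].onset - 20) <= 1 and abs(got[1].offset - 31) <= 1
        assert got[0].position == pytest.approx(8.4, abs=0.2)
        assert got[0].duration_s == pytest.approx(30.0, abs=3.0)

    def test_single_frame_flicker_rejected(self, profile_builder):
        b = profile_builder(n_frames=40)
        b.add(slice(10, 11), 8.0, 8.8, 120.0)
        b.add(slice(20, 30), 20.0, 20.6, 90.0)
        got = detect_patches(b.series("actin"))
        assert len(got) == 1
        assert got[0].onset == 20


class TestClassification:
    def _fake_track(self, a, b, n_frames=40):
        class T:
            id = 0
            def interval_at(self, frame):
                return (a, b) if 0 <= frame < n_frames else None
        return T()

    def _patch(self, start, end, onset=10, offset=20):
        return pt.PatchRecord("actin", onset, offset, start, end,
                              peak_frame=onset, peak_intensity=50.0,
                              frame_interval=3.0)

    def _event(self, frame, position):
        return {"frame": frame, "position": position}

    def test_patch_over_fission_site_is_fission_associated(self):
        p = self._patch(9.0, 10.0)
        classify_patches([p], [self._fake_track(5, 12)],
                         [self._event(15, 9.5)], frame_interval=3.0)
        assert p.cls == "fission_associated"

    def test_patch_on_mitochondrion_without_event_is_mito_associated(self):
        p = self._patch(9.0, 10.0)
        classify_patches([p], [self._fake_track(5, 12)], [],
                         frame_interval=3.0)
        assert p.cls == "mito_associated"

    def test_patch_off_mitochondria_is_non_mito(self):
        p = self._patch(20.0, 21.0)
        classify_patches([p], [self._fake_track(5, 12)],
                         [self._event(15, 9.5)], frame_interval=3.0)
        assert p.cls == "non_mito"

    def test_detected_classes_match_truth_labels_at_zero_noise(self):
        agreed = total = 0
        for seed in range(6):
            cfg = clean_config(seed=seed, fission_prob_per_10min=0.8,
                               fusion_prob_per_10min=0.0,
                               motility_fractions=(1.0, 0, 0),
                               patch_rate=0.05, patch_duration_mean_s=60.0)
            truth = simulate_dynamics(cfg)
            mito = render_series(truth, "mito")
            actin = render_series(truth, "actin")
            tracks, _ = link_tracks(segment_series(mito))
            # classify detected patches against the exact event log, so
            # the comparison isolates the geometric rules from call lag
            got = classify_patches(detect_patches(actin), tracks,
                                   truth.fission_events,
                                   frame_interval=cfg.frame_interval)
            for p in got:
                match = [q for q in truth.actin_patches()
                         if min(q.end, p.end) > max(q.start, p.start)
                         and q.onset <= p.offset and q.offset >= p.onset]
                # abutting patches blur into one record and a patch whose
                # edge sits within one pixel of a mitochondrion boundary is
                # ambiguous at instrument resolution; compare only
                # unambiguous one-to-one matches
                if len(match) != 1 or abs(match[0].onset - p.onset) > 1:
                    continue
                q = match[0]
                margin = max(
                    (min(iv[1], q.end) - max(iv[0], q.start))
                    for t in truth.tracks for f in range(q.onset, q.offset + 1)
                    if (iv := t.interval_at(f)) is not None)
                if abs(margin) < cfg.pixel_size:
                    continue
                total += 1
                agreed += (q.cls == p.cls)
        assert total >= 10
        assert agreed == total


class TestFateStats:
    def _patch(self, cls, filo):
        p = pt.PatchRecord("actin", 0, 5, 1.0, 2.0, 0, 50.0, 3.0)
        p.cls, p.filopodium = cls, filo
        return p

    def test_all_filopodial_gives_probability_one(self):
        ps = [self._patch(c, True) for c in pt.PATCH_CLASSES for _ in range(4)]
        out = patch_fate_stats(ps)
        assert all(v == 1.0 for v in out["probabilities"].values())

    def test_identical_tables_give_fisher_p_one(self):
        ps = ([self._patch("fission_associated", i < 10) for i in range(20)]
              + [self._patch("mito_associated", i < 10) for i in range(20)])
        out = patch_fate_stats(ps)
        assert out["fisher_pairwise"][
            ("fission_associated", "mito_associated")] == pytest.approx(1.0)

    def test_empty_class_reports_missing(self):
        ps = [self._patch("mito_associated", True)] * 3
        out = patch_fate_stats(ps)
        assert out["probabilities"]["non_mito"] is None


class TestOverlapTable:
    def test_reference_dataset_summary(self):
        A, B = fission_overlap_arrays()
        t = OverlapTable.from_lengths(A, B)
        s = t.summary()
        assert s["mean_mito_length_um"] == pytest.approx(8.3, abs=0.05)
        assert s["sem_mito_length_um"] == pytest.approx(0.8, abs=0.05)
        assert s["mean_patch_length_um"] == pytest.approx(0.83, abs=0.005)
        assert s["sem_patch_length_um"] == pytest.approx(0.16, abs=0.005)

    def test_single_row_proportion_rounding(self):
        t = OverlapTable.from_lengths([8.15], [0.69])
        assert t.table["proportion_2dp"].iloc[0] == pytest.approx(0.08)

    def test_full_coverage_row_is_one(self):
        t = OverlapTable.from_lengths([5.0], [5.0])
        assert t.table["proportion"].iloc[0] == 1.0

    def test_patch_longer_than_mito_raises(self):
        with pytest.raises(ValueError):
            OverlapTable.from_lengths([2.0], [3.0])


class TestOverlapProbability:
    def test_reference_product_in_the_rounded_dialect(self):
        A, B = fission_overlap_arrays()
        prob = random_overlap_probability(OverlapTable.from_lengths(A, B))
        assert prob.rounded == pytest.approx(1.75e-21, rel=0.01)
        assert prob.full == pytest.approx(2.34e-21, rel=0.01)

    def test_single_certain_row_gives_one(self):
        prob = random_overlap_probability(OverlapTable.from_lengths([3.], [3.]))
        assert prob.rounded == 1.0 and prob.full == 1.0

    def test_log_domain_matches_direct_product_to_12_digits(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(3, 15, 12)
        B = A * rng.uniform(0.05, 0.5, 12)
        t = OverlapTable.from_lengths(A, B)
        direct = float(np.prod(B / A))
        prob = random_overlap_probability(t)
        assert prob.full == pytest.approx(direct, rel=1e-12)

    def test_zero_proportion_warns_and_zeroes(self):
        t = OverlapTable.from_lengths([5.0, 4.0], [1.0, 0.0])
        with pytest.warns(UserWarning):
            prob = random_overlap_probability(t)
        assert prob.full == 0.0

    def test_monte_carlo_site_draws_converge_to_row_proportion(self):
        # per-row oracle: uniform fission sites on the mitochondrion land
        # inside the patches at rate C
        rng = np.random.default_rng(1)
        a, b = 2.0, 10.0          # mitochondrion interval, A = 8
        spans = [(3.0, 3.7), (6.0, 6.5)]
        B = sum(e - s for s, e in spans)
        C = B / (b - a)
        sites = rng.uniform(a, b, 200_000)
        hit = np.zeros(len(sites), dtype=bool)
        for s, e in spans:
            hit |= (sites >= s) & (sites <= e)
        assert hit.mean() == pytest.approx(C, abs=3 * np.sqrt(
            C * (1 - C) / len(sites)))


class TestColocalization:
    def test_printed_count_fraction(self):
        events = [{"frame": 5, "position": i + 0.5} for i in range(25)]
        patches = [pt.PatchRecord("actin", 0, 10, i + 0.3, i + 0.7, 5,
                                  50.0, 3.0) for i in range(20)]
        assert colocalization_fraction(events, patches) == pytest.approx(0.80)

    def test_no_patches_gives_zero(self):
        events = [{"frame": 5, "position": 1.0}]
        assert colocalization_fraction(events, []) == 0.0

    def test_patch_biased_fission_colocalizes_always(self):
        hits = tot = 0
        for seed in range(5):
            cfg = clean_config(seed=seed, fission_prob_per_10min=0.9,
                               fusion_prob_per_10min=0.0,
                               motility_fractions=(1.0, 0, 0),
                               patch_rate=0.05, fission_patch_bias=1.0)
            truth = simulate_dynamics(cfg)
            if truth.fission_events:
                tot += len(truth.fission_events)
                hits += colocalization_fraction(
                    truth.fission_events, truth.actin_patches()) \
                    * len(truth.fission_events)
        assert tot >= 5
        assert hits / tot == 1.0


class TestDrp1:
    def _track(self, a, b):
        class T:
            def interval_at(self, frame):
                return (a, b)
        return T()

    def test_no_puncta_gives_zero(self):
        out = drp1_accumulations_per_mito([], [self._track(2, 6)],
                                          600.0, 3.0)
        assert out["mean"] == 0.0

    def test_five_minute_window_scales_to_ten(self):
        p = pt.PatchRecord("drp1", 10, 14, 3.0, 3.3, 10, 40.0, 3.0)
        out = drp1_accumulations_per_mito([p], [self._track(2, 6)],
                                          300.0, 3.0)
        assert out["mean"] == pytest.approx(2.0)

    def test_simulated_rate_within_poisson_interval(self):
        from scipy import stats as sps
        total = 0
        n_tracks = 0
        rate = 2.0
        for seed in range(20):
            cfg = clean_config(seed=seed, fission_prob_per_10min=0.0,
                               fusion_prob_per_10min=0.0, n_frames=201,
                               motility_fractions=(1.0, 0, 0),
                               drp1_rate_per_mito_per_10min=rate)
            truth = simulate_dynamics(cfg)
            out = drp1_accumulations_per_mito(
                truth.drp1_puncta(), truth.tracks, 600.0,
                cfg.frame_interval)
            total += out["per_track"].sum()
            n_tracks += out["n_tracks"]
        lam = rate * n_tracks
        lo, hi = sps.poisson.ppf(0.025, lam), sps.poisson.ppf(0.975, lam)
        assert lo <= total <= hi


class TestNullCalibration:
    def test_colocalization_rate_equals_mean_row_proportion(self):
        # with fission sites independent of patches, the empirical hit
        # rate matches the mean per-row C (the statistic's null model)
        rows_A, rows_B, hits, n_ev = [], [], 0.0, 0
        for seed in range(40):
            cfg = clean_config(
                seed=3000 + seed, axon_length=150.0, n_mito=4,
                mito_length_dist=(5.0, 0.2), min_mito_length=2.0,
                fission_prob_per_10min=0.8, fusion_prob_per_10min=0.0,
                patch_rate=0.6, patch_duration_mean_s=90.0,
                patch_length_dist=(0.8, 0.3), fission_patch_bias=0.0,
                motility_fractions=(1.0, 0, 0))
            truth = simulate_dynamics(cfg)
            if not truth.fission_events:
                continue
            table = build_overlap_table(truth.fission_events,
                                        truth.actin_patches(),
                                        truth.tracks_by_id())
            rows_A.extend(table.table["mito_length_um"])
            rows_B.extend(table.table["patch_length_um"])
            c = colocalization_fraction(truth.fission_events,
                                        truth.actin_patches())
            hits += c * len(truth.fission_events)
            n_ev += len(truth.fission_events)
        C = np.asarray(rows_B) / np.asarray(rows_A)
        emp = hits / n_ev
        se = np.sqrt(emp * (1 - emp) / n_ev)
        assert n_ev >= 80
        assert abs(emp - C.mean()) < 4 * se
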