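"""Probability maps, instance segmentation, linking and experiment QC."""

import numpy as np
import pytest

from neutromig import imaging as im
from neutromig import synthetic as syn
from neutromig.imaging import BACKGROUND, BOUNDARY, FOREGROUND, Detection

from conftest import make_traj


def _disk_frame(center_px=(40.0, 30.0), width=80, height=60, radius_um=4.0,
                noise_sd=0.0, seed=0):
    spec = syn.ImageSpec(width_px=width, height_px=height, cell_radius=radius_um,
                         noise_sd=noise_sd)
    gt = syn.GroundTruthTrajectory(
        cell_id=0, is_responder=False,
        positions=np.array([[center_px[0] * spec.pixel_size,
                             center_px[1] * spec.pixel_size]]))
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    return syn.render_frame([gt], 0, spec, rng), spec


class TestProbabilityMap:
    def test_probabilities_sum_to_one(self):
        frame, _ = _disk_frame()
        pm = im.compute_class_probabilities(frame)
        np.testing.assert_allclose(pm.probs.sum(axis=2), 1.0, atol=1e-9)
        assert (pm.probs >= 0).all()

    def test_invalid_map_rejected(self):
        bad = np.full((4, 4, 3), 0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            im.ProbabilityMap(bad)

    def test_blank_frame_all_background(self, caplog):
        with caplog.at_level("WARNING", logger="neutromig.imaging"):
            pm = im.compute_class_probabilities(np.full((30, 30), 7.0))
        assert (pm.argmax == BACKGROUND).all()
        assert any("background" in r.message for r in caplog.records)

    def test_disk_interior_foreground_rim_boundary(self):
        frame, spec = _disk_frame()
        pm = im.compute_class_probabilities(frame)
        yy, xx = np.mgrid[0:60, 0:80]
        d = np.hypot(xx - 40.0, yy - 30.0)
        r_px = spec.cell_radius / spec.pixel_size
        interior = d < r_px - 1.5
        assert (pm.probs[interior, FOREGROUND] > 0.5).all()
        assert (pm.argmax[interior] == FOREGROUND).all()
        # boundary-class pixels concentrate on the rim
        rim_dist = d[pm.argmax == BOUNDARY]
        assert rim_dist.size > 0
        assert (np.abs(rim_dist - r_px) < 2.5).all()

    def test_noisy_frame_agreement_with_ground_truth(self):
        """At noise_sd = 10% of contrast, the argmax map agrees with the
        rendered ground-truth mask on >= 95% of pixels."""
        spec = syn.ImageSpec(width_px=400, height_px=300, noise_sd=15.0)
        gen = np.random.default_rng(5)
        pos = np.column_stack([gen.uniform(30, 370, 12),
                               gen.uniform(30, 270, 12)]) * spec.pixel_size
        gts = [syn.GroundTruthTrajectory(cell_id=i, is_responder=False,
                                         positions=pos[i:i + 1])
               for i in range(12)]
        frame = syn.render_frame(gts, 0, spec, np.random.default_rng(1))
        yy, xx = np.mgrid[0:300, 0:400]
        mask = np.zeros((300, 400), bool)
        for x, y in pos / spec.pixel_size:
            mask |= np.hypot(xx - x, yy - y) <= spec.cell_radius / spec.pixel_size
        pm = im.compute_class_probabilities(frame)
        agreement = np.mean((pm.argmax != BACKGROUND) == mask)
        assert agreement >= 0.95


class TestSegmentInstances:
    def test_boundary_ridge_splits_touching_disks(self):
        """Two foreground disks separated by a 2-px boundary-class ridge are
        extracted as 2 instances, with ridge pixels re-assigned."""
        yy, xx = np.mgrid[0:40, 0:60]
        probs = np.zeros((40, 60, 3))
        probs[..., BACKGROUND] = 1.0
        for cx in (20, 33):
            sel = np.hypot(xx - cx, yy - 20) <= 6
            probs[sel] = [0, 0, 1]
        strip = np.abs(xx - 26.5) <= 1.0
        probs[strip & (probs[..., FOREGROUND] > 0)] = [0, 1, 0]
        dets = im.segment_instances(im.ProbabilityMap(probs), min_area=5,
                                    pixel_size=1.0)
        assert len(dets) == 2
        assert sorted(round(d.x_um) for d in dets) == [20, 33]

    def test_min_area_drops_small_instances(self):
        yy, xx = np.mgrid[0:30, 0:30]
        probs = np.zeros((30, 30, 3))
        probs[..., BACKGROUND] = 1.0
        probs[np.hypot(xx - 15, yy - 15) <= 2] = [0, 0, 1]  # ~13 px
        pm = im.ProbabilityMap(probs)
        assert im.segment_instances(pm, min_area=50.0, pixel_size=1.0) == []
        assert len(im.segment_instances(pm, min_area=5.0, pixel_size=1.0)) == 1

    def test_rendered_five_cell_centroids_subpixel(self):
        spec = syn.ImageSpec(width_px=300, height_px=200, noise_sd=0.0)
        pos_px = [(50, 50), (150, 50), (250, 50), (100, 150), (200, 150)]
        gts = [syn.GroundTruthTrajectory(
            cell_id=i, is_responder=False,
            positions=np.array([[x * spec.pixel_size, y * spec.pixel_size]]))
            for i, (x, y) in enumerate(pos_px)]
        frame = syn.render_frame(gts, 0, spec)
        dets = im.segment_frame(frame, min_area=20.0, pixel_size=spec.pixel_size)
        assert len(dets) == 5
        found = sorted((d.x_um / spec.pixel_size, d.y_um / spec.pixel_size)
                       for d in dets)
        for (fx, fy), (tx, ty) in zip(found, sorted(pos_px)):
            assert np.hypot(fx - tx, fy - ty) < 1.0


def _det(frame, x, y):
    return Detection(frame=frame, x_um=x, y_um=y, area_um2=50.0, label=0)


class TestLinkTracks:
    def test_empty_input(self):
        assert im.link_tracks([]) == []

    def test_two_distant_cells_keep_identity(self):
        dets = []
        for f in range(20):
            dets.append(_det(f, 10.0 + 0.5 * f, 10.0))
            dets.append(_det(f, 200.0 - 0.5 * f, 150.0))
        tracks = im.link_tracks(dets, max_disp=5.0, max_gap=2)
        assert len(tracks) == 2
        for t in tracks:
            assert len(t) == 20
            ys = t.positions[:, 1]
            assert np.ptp(ys) == 0  # never swaps between the two cells

    def test_gap_bridged_within_max_gap(self):
        """A missing frame-10 detection is bridged when max_gap = 2."""
        dets = [_det(f, 5.0 + 1.0 * f, 8.0) for f in range(21) if f != 10]
        tracks = im.link_tracks(dets, max_disp=3.0, max_gap=2)
        assert len(tracks) == 1
        assert len(tracks[0]) == 20

    def test_long_gap_starts_new_track(self):
        dets = [_det(f, 5.0 + 1.0 * f, 8.0) for f in range(21)
                if f not in (8, 9, 10, 11)]
        tracks = im.link_tracks(dets, max_disp=3.0, max_gap=2)
        assert len(tracks) == 2

    def test_relabeling_invariance(self):
        """Linking depends only on positions/frames, not on detection order."""
        gen = np.random.default_rng(3)
        dets = []
        for f in range(15):
            for c in range(6):
                dets.append(_det(f, 40.0 * c + gen.normal(0, 1), 30.0 + gen.normal(0, 1)))
        shuffled = list(dets)
        gen.shuffle(shuffled)
        a = im.link_tracks(dets, max_disp=6.0)
        b = im.link_tracks(shuffled, max_disp=6.0)
        key = lambda ts: sorted(tuple(map(tuple, t.positions.round(9))) for t in ts)
        assert key(a) == key(b)

    def test_ground_truth_recovery(self):
        """Tracking simulated walks at moderate density recovers >= 95% of
        ground-truth tracks with correct identity over the analysis window."""
        cfg = syn.SimulationConfig(n_cells=50, frac_responder=0.0,
                                   speed_mean=8.0, speed_sd=2.0, seed=21)
        gts = syn.simulate_trajectories(cfg)
        gx, gy = np.meshgrid(np.linspace(100, cfg.arena[0] - 100, 10),
                             np.linspace(80, cfg.arena[1] - 80, 5))
        starts = np.column_stack([gx.ravel(), gy.ravel()])
        gts = [syn.GroundTruthTrajectory(
            cell_id=g.cell_id, is_responder=g.is_responder,
            positions=g.positions - g.positions[0] + starts[i])
            for i, g in enumerate(gts)]
        dets = []
        for g in gts:
            for f, (x, y) in enumerate(g.positions):
                dets.append(_det(f, x, y))
        mean_step = cfg.speed_mean * cfg.frame_interval / 60.0
        tracks = im.link_tracks(dets, max_disp=3 * mean_step, max_gap=2)
        n_ok = 0
        for g in gts:
            for t in tracks:
                shared = min(len(t), 181)
                if len(t) == 181 and np.allclose(t.positions, g.positions):
                    n_ok += 1
                    break
        assert n_ok >= 0.95 * len(gts)


class TestQualityControl:
    def _tracks(self, lengths_in_window, drift=(1.0, 0.0), start_frame=90):
        """Tracks with a given number of window frames (90..180), moving by
        `drift` um per frame."""
        tracks = []
        for i, n in enumerate(lengths_in_window):
            frames = np.arange(start_frame, start_frame + n)
            pos = np.array([[50.0 + i * 30 + drift[0] * k, 50.0 + drift[1] * k]
                            for k in range(n)])
            tracks.append(make_traj(pos, frames=frames, track_id=i))
        return tracks

    def test_window_arithmetic_and_length_filter(self):
        """181-frame recording at 10 s: window = frames 90..180 (91 frames);
        a track seen in 45 of them (< 45.5) is removed, one seen in 46 kept."""
        tracks = self._tracks([91] * 30 + [45] * 5 + [46] * 3)
        qc, kept = im.apply_quality_control(tracks, recording_duration_min=30.0)
        assert qc.window_frames == (90, 180)
        assert qc.n_tracks_kept == 33
        assert qc.n_tracks_removed == 5
        assert qc.n_tracks_kept + qc.n_tracks_removed == len(tracks)
        assert not qc.low_cell_number

    def test_low_cell_number_flag(self):
        """24 surviving tracks trip the < 25-cell flag."""
        qc, _ = im.apply_quality_control(self._tracks([91] * 24),
                                         recording_duration_min=30.0)
        assert qc.low_cell_number
        qc25, _ = im.apply_quality_control(self._tracks([91] * 25),
                                           recording_duration_min=30.0)
        assert not qc25.low_cell_number

    def test_lateral_flow_flag(self):
        """A common +y drift of 10 um/min dominates every path: the median
        lateral migration index approaches 1 and the flag is set."""
        rng = np.random.default_rng(0)
        tracks = []
        for i in range(30):
            steps = rng.normal(0, 0.2, size=(90, 2))
            steps[:, 1] += 10.0 / 6.0  # 10 um/min at 10 s/frame
            pos = np.vstack([[0, 0], np.cumsum(steps, axis=0)]) + [200 + 5 * i, 50]
            tracks.append(make_traj(pos, frames=np.arange(90, 181), track_id=i))
        qc, _ = im.apply_quality_control(tracks, recording_duration_min=30.0)
        assert qc.lateral_flow
        assert qc.median_lateral_index > 0.9

    def test_pre_activated_flag(self):
        """Mostly static cells (path < one cell diameter) set the flag."""
        static = []
        for i in range(30):
            pos = np.tile([50.0 + 10 * i, 60.0], (91, 1))
            pos[:, 0] += np.linspace(0, 2.0, 91)  # 2 um total path < 8 um
            static.append(make_traj(pos, frames=np.arange(90, 181), track_id=i))
        qc, _ = im.apply_quality_control(static, recording_duration_min=30.0)
        assert qc.pre_activated

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            im.apply_quality_control(self._tracks([91]), recording_duration_min=20.0)

    def test_idempotent(self):
        tracks = self._tracks([91] * 26 + [50] * 4 + [30] * 3)
        qc1, kept1 = im.apply_quality_control(tracks, recording_duration_min=30.0)
        qc2, kept2 = im.apply_quality_control(kept1, recording_duration_min=30.0)
        assert qc2.n_tracks_kept == qc1.n_tracks_kept
        assert qc2.n_tracks_removed == 0
        for a, b in zip(kept1, kept2):
            np.testing.assert_array_equal(a.positions, b.positions)
        assert (qc1.low_cell_number, qc1.lateral_flow, qc1.pre_activated) == \
               (qc2.low_cell_number, qc2.lateral_flow, qc2.pre_activated)
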