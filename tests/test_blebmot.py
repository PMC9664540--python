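import numpy as np
import pytest
from scipy import stats

from nodule4d import blebmot, synthgen
from nodule4d.blebmot import BlebSpot
from nodule4d.stackio import Calibration

CAL_S = Calibration(voxel_size=(0.5, 0.5, 1.0), frame_interval=15.0, frame_unit="s")


def movie_with_bleb(n_frames=12, birth=4, span=5, r=4):
    """Static disk cell plus one bleb lasting `span` frames."""
    T, H = n_frames, 64
    yy, xx = np.mgrid[:H, :H]
    base = (np.hypot(yy - 32, xx - 32) < 12).astype(float)
    movie = np.tile(base, (T, 1, 1))
    bleb = np.hypot(yy - 32, xx - 48) < r
    for t in range(birth, birth + span):
        movie[t][bleb] = 1.0
    return movie


class TestDetectBlebs2d:
    def test_static_movie_no_tracks(self):
        movie = np.tile(np.random.default_rng(0).random((32, 32)), (10, 1, 1))
        assert blebmot.detect_blebs_2d(movie, CAL_S) == []

    def test_time_reversed_static_movie_no_tracks(self):
        movie = np.tile(np.random.default_rng(0).random((32, 32)), (10, 1, 1))
        assert blebmot.detect_blebs_2d(movie[::-1], CAL_S) == []

    def test_single_bleb_duration(self):
        tracks = blebmot.detect_blebs_2d(movie_with_bleb(span=5), CAL_S)
        assert len(tracks) == 1
        assert tracks[0].duration == pytest.approx(5 * 15.0)
        assert tracks[0].birth_frame == 4

    def test_max_area_is_max_of_frame_areas(self):
        tracks = blebmot.detect_blebs_2d(movie_with_bleb(), CAL_S)
        tr = tracks[0]
        assert tr.max_area == pytest.approx(max(tr.areas))

    def test_duration_invariant_to_frame_offset(self):
        movie = movie_with_bleb()
        lead = np.tile(movie[0], (3, 1, 1))
        shifted = np.concatenate([lead, movie])
        d0 = sorted(t.duration for t in blebmot.detect_blebs_2d(movie, CAL_S))
        d1 = sorted(t.duration for t in blebmot.detect_blebs_2d(shifted, CAL_S))
        assert d0 == d1

    def test_min_frames_filter(self):
        tracks = blebmot.detect_blebs_2d(movie_with_bleb(span=2), CAL_S, min_frames=3)
        assert tracks == []

    def test_needs_seconds_calibration(self):
        cal_h = Calibration(frame_interval=1.0, frame_unit="h")
        with pytest.raises(ValueError, match="seconds"):
            blebmot.detect_blebs_2d(np.zeros((3, 8, 8)), cal_h)

    def test_default_movie_duration_recovery(self, bleb_scene, bleb_tracks):
        _, truth = bleb_scene
        true_mean = np.mean([b.n_frames * 15.0 for b in truth.rendered_blebs()])
        det_mean = np.mean([t.duration for t in bleb_tracks])
        assert det_mean == pytest.approx(true_mean, rel=0.15)

    def test_default_movie_precision_recall(self, bleb_scene, bleb_tracks):
        stack, truth = bleb_scene
        events = truth.rendered_blebs()
        assert len(events) >= 80
        cells = {c.cell_id: np.array(c.centroid[:2]) for c in truth.cells}
        r_cell = truth.config.cell_radius_um

        def match(ev, tr):
            if abs(ev.birth_frame - tr.birth_frame) > 1:
                return False
            exp = cells[ev.cell_id] + np.array(ev.direction[:2]) * (
                r_cell + 0.8 * np.sqrt(ev.max_area_um2 / np.pi)
            )
            return float(np.hypot(*(np.array(tr.centroids[0]) - exp))) < 3.0

        matched_ev = sum(any(match(ev, tr) for tr in bleb_tracks) for ev in events)
        matched_tr = sum(any(match(ev, tr) for ev in events) for tr in bleb_tracks)
        assert matched_ev / len(events) >= 0.8  # recall
        assert matched_tr / len(bleb_tracks) >= 0.8  # precision


class TestDetectBlebs4d:
    def _empty_movie(self, T=4, Z=16, Y=32, X=32):
        return np.zeros((T, Z, Y, X))

    def test_no_blebs_no_spots(self):
        movie = self._empty_movie()
        spots = blebmot.detect_blebs_4d(
            movie, Calibration(), {0: (16.0, 16.0, 8.0)}
        )
        assert spots == []

    def test_no_cells_rejected(self):
        with pytest.raises(ValueError, match="host"):
            blebmot.detect_blebs_4d(self._empty_movie(), Calibration(), {})

    def test_equidistant_spot_assigned_to_lower_cell_id(self):
        movie = self._empty_movie()
        zz, yy, xx = np.ogrid[:16, :32, :32]
        sphere = (zz - 8) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 9
        movie[2][sphere] = 1.0
        hosts = {4: (10.0, 16.0, 8.0), 9: (22.0, 16.0, 8.0)}  # both 6 μm away
        spots = blebmot.detect_blebs_4d(movie, Calibration(), hosts, expected_radius_um=3.0)
        assert len(spots) == 1
        assert spots[0].cell_id == 4

    def test_blebs_on_single_cell_assigned_to_it(self):
        import dataclasses

        cfg = dataclasses.replace(synthgen.default_bleb4d_config(), n_cells_on=1, shape=(22, 48, 128, 128))
        cfg.kinetics = dataclasses.replace(cfg.kinetics, event_rate=0.9)
        stack, truth = synthgen.generate_bleb_movie(cfg, seed=9)
        events = [b for b in truth.rendered_blebs() if b.birth_frame >= 1]
        assert len(events) >= 10
        hosts = {c.cell_id: c.centroid for c in truth.cells}
        radii = {c.cell_id: float(np.prod(c.semi_axes)) ** (1 / 3) for c in truth.cells}
        spots = blebmot.detect_blebs_4d(stack.channel("EGFP"), stack.calibration, hosts, radii)
        hits = sum(
            any(s.cell_id == ev.cell_id and s.frame == ev.birth_frame for s in spots)
            for ev in events
        )
        assert hits >= 0.8 * len(events)


class TestBlebPolarity:
    HOST = {0: (0.0, 0.0, 0.0)}

    def test_east_spot_theta_xy_zero(self):
        spots = [BlebSpot(frame=1, position=(5.0, 0.0, 0.0), cell_id=0)]
        df, _, _ = blebmot.bleb_polarity(spots, self.HOST)
        assert df.theta_xy.iloc[0] == pytest.approx(0.0)

    def test_north_spot_theta_xy_90(self):
        spots = [BlebSpot(frame=1, position=(0.0, 5.0, 0.0), cell_id=0)]
        df, _, _ = blebmot.bleb_polarity(spots, self.HOST)
        assert df.theta_xy.iloc[0] == pytest.approx(90.0)

    def test_angles_in_half_open_range(self):
        spots = [BlebSpot(frame=1, position=(-5.0, 0.0, 0.0), cell_id=0)]
        df, _, _ = blebmot.bleb_polarity(spots, self.HOST)
        assert df.theta_xy.iloc[0] == pytest.approx(-180.0)  # -180 not +180

    def test_zero_displacement_skipped(self):
        spots = [BlebSpot(frame=1, position=(0.0, 0.0, 0.0), cell_id=0)]
        df, _, below = blebmot.bleb_polarity(spots, self.HOST)
        assert df.empty and below == 0.0

    def test_isotropic_spots_uniform_histograms(self):
        rng = np.random.default_rng(8)
        u = rng.normal(size=(3000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        spots = [
            BlebSpot(frame=1, position=tuple(6.0 * v), cell_id=0) for v in u
        ]
        _, hists, _ = blebmot.bleb_polarity(spots, self.HOST)
        for plane in ("theta_xy", "theta_zy", "theta_zx"):
            counts, _ = hists[plane]
            assert stats.chisquare(counts).pvalue > 0.01

    def test_exclusion_zone_scene_below_fraction(self, bleb4d_spots):
        spots, hosts = bleb4d_spots
        _, _, below = blebmot.bleb_polarity(spots, hosts)
        assert below <= 0.05

    def test_polarity_equivariant_under_xy_rotation(self, bleb4d_scene):
        stack, truth = bleb4d_scene
        movie = stack.channel("EGFP")
        hosts = {c.cell_id: c.centroid for c in truth.cells}
        spots = blebmot.detect_blebs_4d(movie, stack.calibration, hosts)
        # rotate 90 deg in XY: (x, y) -> (-y, x), then shift back into frame
        rot = np.rot90(movie, k=1, axes=(3, 2)).copy()
        W = (movie.shape[3] - 1) * stack.calibration.dx
        hosts_rot = {k: (W - y, x, z) for k, (x, y, z) in hosts.items()}
        spots_rot = blebmot.detect_blebs_4d(rot, stack.calibration, hosts_rot)
        df, _, _ = blebmot.bleb_polarity(spots, hosts)
        df_rot, _, _ = blebmot.bleb_polarity(spots_rot, hosts_rot)
        a = np.sort((df.theta_xy.to_numpy() + 90.0 + 180.0) % 360.0)
        b = np.sort((df_rot.theta_xy.to_numpy() + 180.0) % 360.0)
        assert len(a) == len(b)
        assert np.allclose(a, b, atol=1e-6)


class TestTrackCells:
    CAL_H = Calibration(frame_interval=0.5, frame_unit="h")

    def test_stationary_cell_zero_speed(self):
        frames = [[(0, (10.0, 10.0, 0.0))]] * 5
        tracks = blebmot.track_cells(frames, self.CAL_H)
        assert len(tracks) == 1
        assert tracks[0].mean_speed == 0.0

    def test_speed_arithmetic(self):
        frames = [
            [(0, (0.0, 0.0, 0.0))],
            [(0, (10.0, 0.0, 0.0))],
            [(0, (20.0, 0.0, 0.0))],
        ]
        tracks = blebmot.track_cells(frames, self.CAL_H)
        assert tracks[0].mean_speed == pytest.approx(20.0)  # 10 μm / 0.5 h

    def test_two_cells_stay_separate(self):
        frames = [
            [(0, (0.0, 0.0, 0.0)), (1, (50.0, 50.0, 0.0))],
            [(0, (2.0, 0.0, 0.0)), (1, (52.0, 50.0, 0.0))],
        ]
        tracks = blebmot.track_cells(frames, self.CAL_H)
        assert len(tracks) == 2

    def test_gate_fragments_tracks(self):
        frames = [
            [(0, (0.0, 0.0, 0.0))],
            [(0, (30.0, 0.0, 0.0))],  # jump beyond the gate
        ]
        tracks = blebmot.track_cells(frames, self.CAL_H, max_step_um=10.0)
        assert len(tracks) == 2

    def test_group_speed_separation(self):
        """On-matrix cells at 2x off-matrix speed: recovered ordering and a
        significant two-sample test at n = 20/20."""
        rng = np.random.default_rng(13)
        trajs = synthgen.sample_trajectories(
            field_um=(420.0, 420.0),
            n_on=20,
            n_off=20,
            motility=synthgen.Motility(on_matrix_um_h=20.0, off_matrix_um_h=10.0),
            n_frames=20,
            interval_h=0.5,
            rng=rng,
        )
        frames = [
            [(tr.cell_id, tuple(tr.positions[t])) for tr in trajs] for t in range(20)
        ]
        groups = {tr.cell_id: tr.group for tr in trajs}
        cal = Calibration(frame_interval=0.5, frame_unit="h")
        tracks = blebmot.track_cells(frames, cal, max_step_um=14.0, groups=groups)
        on = [t.mean_speed for t in tracks if t.group == "on-matrix"]
        off = [t.mean_speed for t in tracks if t.group == "off-matrix"]
        assert len(on) == 20 and len(off) == 20
        assert np.mean(on) > np.mean(off)
        from nodule4d import statkit

        _, p = statkit.two_sample_t(on, off)
        assert p < 0.05

    def test_trajectory_truth_speed_is_exact(self):
        rng = np.random.default_rng(14)
        trajs = synthgen.sample_trajectories(
            (300.0, 300.0), 3, 0, synthgen.Motility(12.0, 0.0), 10, 0.5, rng
        )
        for tr in trajs:
            steps = np.linalg.norm(np.diff(tr.positions[:, :2], axis=0), axis=1)
            assert tr.speed_um_h == pytest.approx(steps.mean() / 0.5)
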