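"""Spindle-frame registration: canonical transform, drift removal, merging."""

import numpy as np
import pytest

from digispindle import simulate_geometry, simulate_trajectories
from digispindle.models import AcquisitionSpec, GeometryModel, SpindleGeometryTrack
from digispindle.register import (
    RigidTransform,
    canonical_transform,
    merge_cells,
    register_series,
)
from digispindle.tracking import Track


def _tracks_from_truth(trajs):
    return [
        Track(id=t.id, start_frame=t.start_frame, positions_um=t.positions_um)
        for t in trajs
    ]


class TestCanonicalTransform:
    def test_axis_already_aligned(self):
        tf = canonical_transform(np.array([1.0, 1, 1]), np.array([3.0, 1, 1]))
        assert np.allclose(tf.apply([1.0, 1, 1]), [-1, 0, 0], atol=1e-12)
        assert np.allclose(tf.apply([3.0, 1, 1]), [1, 0, 0], atol=1e-12)

    def test_rigidity_preserves_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c1, c2 = rng.normal(0, 5, (2, 3))
            tf = canonical_transform(c1, c2)
            d = np.linalg.norm(c2 - c1)
            assert np.linalg.norm(tf.apply(c2) - tf.apply(c1)) == pytest.approx(
                d, abs=1e-9
            )

    def test_antiparallel_axis_uses_180_about_z(self):
        tf = canonical_transform(np.array([1.0, 0, 0]), np.array([-1.0, 0, 0]))
        rz = np.array([[-1.0, 0, 0], [0, -1.0, 0], [0, 0, 1.0]])
        assert np.allclose(tf.rotation, rz, atol=1e-12)
        assert np.allclose(tf.apply([1.0, 0, 0]), [-1, 0, 0], atol=1e-12)

    def test_coincident_centrosomes_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            canonical_transform(np.ones(3), np.ones(3))

    def test_compose_and_inverse_round_trip(self):
        rng = np.random.default_rng(1)
        c1, c2 = rng.normal(0, 5, (2, 3))
        tf = canonical_transform(c1, c2)
        pts = rng.normal(0, 5, (10, 3))
        assert np.allclose(tf.inverse().apply(tf.apply(pts)), pts, atol=1e-9)
        ident = tf.compose(tf.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(ident.translation, 0.0, atol=1e-9)


class TestRegisterSeries:
    @pytest.fixture()
    def static_config(self, metaphase_preset):
        acq = AcquisitionSpec(
            n_frames=40, voxel_pitch_um=(0.2, 0.2, 0.4),
            fov_extent_um=(80.0, 80.0, 80.0),
        )
        geom = GeometryModel(
            d_um=6.0, drift_translation_um_per_s=0.0, drift_rotation_deg_per_s=0.0
        )
        return metaphase_preset.with_(acquisition=acq, geometry=geom)

    def test_already_canonical_cell_maps_to_identity(self, static_config):
        cfg = static_config.with_(
            geometry=GeometryModel(
                d_um=6.0, center_um=(0.0, 0.0, 0.0),
                drift_translation_um_per_s=0.0, drift_rotation_deg_per_s=0.0,
            )
        )
        n = cfg.acquisition.n_frames
        c1 = np.tile([-3.0, 0.0, 0.0], (n, 1))
        c2 = np.tile([3.0, 0.0, 0.0], (n, 1))
        geom = SpindleGeometryTrack("metaphase", c1, c2)
        _, _, transforms = register_series([], geom, cfg.acquisition.interval_s)
        for tf in transforms:
            assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
            assert np.allclose(tf.translation, 0.0, atol=1e-9)

    def test_injected_rotation_and_drift_removed(self, static_config):
        drifting = static_config.with_(
            geometry=GeometryModel(
                d_um=6.0,
                drift_translation_um_per_s=0.05,
                drift_rotation_deg_per_s=0.5,
                drift_rotation_axis=(0.0, 0.0, 1.0),
            )
        )
        results = {}
        for name, cfg in (("static", static_config), ("drift", drifting)):
            geom = simulate_geometry(cfg, 21)
            trajs = simulate_trajectories(cfg, geom, 22)
            reg, reg_geom, _ = register_series(
                _tracks_from_truth(trajs), geom, cfg.acquisition.interval_s
            )
            results[name] = {t.id: t for t in reg}
            d = cfg.geometry.d_um
            assert np.allclose(reg_geom.centrosome1_um, [-d / 2, 0, 0], atol=1e-9)
            assert np.allclose(reg_geom.centrosome2_um, [d / 2, 0, 0], atol=1e-9)
        assert set(results["static"]) == set(results["drift"])
        for i, a in results["static"].items():
            b = results["drift"][i]
            assert a.n_points == b.n_points
            assert np.allclose(a.positions_um, b.positions_um, atol=1e-6)

    def test_registration_is_framewise_isometry(self, static_config):
        cfg = static_config.with_(
            geometry=GeometryModel(d_um=6.0, drift_translation_um_per_s=0.04,
                                   drift_rotation_deg_per_s=1.0)
        )
        geom = simulate_geometry(cfg, 5)
        trajs = simulate_trajectories(cfg, geom, 6)[:30]
        tracks = _tracks_from_truth(trajs)
        reg, _, transforms = register_series(tracks, geom,
                                             cfg.acquisition.interval_s)
        # same-frame pairwise distances preserved
        frame = max(t.start_frame for t in tracks)
        before, after = [], []
        for t, r in zip(tracks, reg):
            k = frame - t.start_frame
            if 0 <= k < t.n_points:
                before.append(t.positions_um[k])
                after.append(r.positions_um[k])
        before, after = np.array(before), np.array(after)
        d0 = np.linalg.norm(before[:, None] - before[None, :], axis=2)
        d1 = np.linalg.norm(after[:, None] - after[None, :], axis=2)
        assert np.allclose(d0, d1, atol=1e-9)
        # round trip restores lab coordinates
        for t, r in zip(tracks[:10], reg[:10]):
            back = np.array(
                [
                    transforms[f].inverse().apply(p)
                    for f, p in zip(r.frames, r.positions_um)
                ]
            )
            assert np.allclose(back, t.positions_um, atol=1e-9)

    def test_static_geometry_preserves_speeds(self, static_config):
        geom = simulate_geometry(static_config, 31)
        trajs = simulate_trajectories(static_config, geom, 32)[:40]
        tracks = _tracks_from_truth(trajs)
        for t in tracks:
            t.mean_travel_speed = np.nan
        reg, _, _ = register_series(tracks, geom, static_config.acquisition.interval_s)
        from digispindle.tracking import compute_mean_travel_speed

        dt = static_config.acquisition.interval_s
        for t, r in zip(tracks, reg):
            assert compute_mean_travel_speed(t, dt) == pytest.approx(
                r.mean_travel_speed, abs=1e-9
            )

    def test_track_outside_geometry_is_reported(self, static_config):
        geom = simulate_geometry(static_config, 1)
        stray = Track(id=7, start_frame=geom.n_frames - 1,
                      positions_um=np.zeros((3, 3)) + 40.0)
        with pytest.raises(ValueError, match="centrosome data"):
            register_series([stray], geom, 0.755)


class TestMergeCells:
    def _cell(self, cell_id, n_tracks, phase="metaphase", d=10.0, seed=0):
        rng = np.random.default_rng(seed)
        tracks = [
            Track(id=i, start_frame=0,
                  positions_um=rng.normal(0, 3, (5, 3)), cell_id="orig")
            for i in range(n_tracks)
        ]
        for t in tracks:
            t.mean_travel_speed = 0.4
        c = np.tile([[-d / 2, 0, 0], [d / 2, 0, 0]], (4, 1)).reshape(4, 2, 3)
        geom = SpindleGeometryTrack(phase, c[:, 0], c[:, 1])
        return (cell_id, tracks, geom)

    def test_track_counts_add_up(self):
        merged, d = merge_cells(
            [self._cell("a", 300), self._cell("b", 280), self._cell("c", 310)]
        )
        assert len(merged) == 890
        assert d == pytest.approx(10.0)
        assert {t.cell_id for t in merged} == {"a", "b", "c"}
        assert [t.id for t in merged] == list(range(890))

    def test_single_cell_merge_is_identity(self):
        cell = self._cell("solo", 17)
        merged, _ = merge_cells([cell])
        assert len(merged) == 17
        for orig, new in zip(cell[1], merged):
            assert np.array_equal(orig.positions_um, new.positions_um)

    def test_mixed_phases_need_override(self):
        cells = [self._cell("a", 5), self._cell("b", 5, phase="anaphase")]
        with pytest.raises(ValueError, match="phase"):
            merge_cells(cells)
        merged, _ = merge_cells(cells, allow_mixed_phases=True)
        assert len(merged) == 10

    def test_normalization_divides_by_each_cells_d(self):
        cell = self._cell("a", 3, d=8.0)
        merged, d = merge_cells([cell], normalize_by_d=True)
        assert d == pytest.approx(1.0)
        for orig, new in zip(cell[1], merged):
            assert np.allclose(new.positions_um, orig.positions_um / 8.0)

    def test_merged_speeds_match_configured_mixture(self, metaphase_preset):
        cells = []
        for i, cell_id in enumerate(["c1", "c2", "c3"]):
            geom = simulate_geometry(metaphase_preset, 50 + i)
            trajs = simulate_trajectories(metaphase_preset, geom, 60 + i)
            tracks = _tracks_from_truth(trajs)
            reg, reg_geom, _ = register_series(
                tracks, geom, metaphase_preset.acquisition.interval_s
            )
            cells.append((cell_id, reg, reg_geom))
        merged, _ = merge_cells(cells)
        speeds = np.array([t.mean_travel_speed for t in merged])
        mixture = metaphase_preset.motion.mixture_mean_speed()
        se = speeds.std(ddof=1) / np.sqrt(len(speeds))
        assert abs(speeds.mean() - mixture) < 3 * se
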