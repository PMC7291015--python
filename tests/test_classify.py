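"""Classification: speed bins, spherical zones, travel angles, subsampling."""

import math

import numpy as np
import pytest

from digispindle import simulate_geometry, simulate_trajectories
from digispindle.classify import (
    OUTSIDE,
    SpeedBinning,
    ZonePartition,
    assign_zones,
    bin_tracks_by_speed,
    compute_travel_angle,
    subsample_tracks,
    zone_angle_summary,
    AngleRecord,
)
from digispindle.models import GeometryModel, MotionModel
from digispindle.tracking import Track


def _track(track_id, start, end=None, speed=0.4):
    end = start if end is None else end
    pos = np.linspace(np.asarray(start, float), np.asarray(end, float), 5)
    t = Track(id=track_id, start_frame=0, positions_um=pos)
    t.mean_travel_speed = speed
    return t


class TestSpeedBinning:
    def test_default_is_ten_classes_spanning_unit_range(self):
        b = SpeedBinning()
        assert b.n_bins == 10
        assert np.allclose(b.edges, np.arange(0, 1.1, 0.1))

    def test_one_track_per_class(self):
        tracks = [_track(i, (0, 0, 0), speed=0.05 + 0.1 * i) for i in range(10)]
        groups, out = bin_tracks_by_speed(tracks)
        assert out == []
        assert all(len(groups[k]) == 1 for k in range(10))

    def test_half_open_convention_at_bin_edges(self):
        b = SpeedBinning()
        assert b.bin_of(0.3) == 3  # [0.3, 0.4)
        assert b.bin_of(0.0) == 0
        assert b.bin_of(1.0) == 9  # top edge closed

    def test_out_of_range_reported_not_dropped(self):
        tracks = [_track(0, (0, 0, 0), speed=1.4), _track(1, (0, 0, 0), speed=0.2)]
        groups, out = bin_tracks_by_speed(tracks)
        assert sum(len(g) for g in groups.values()) + len(out) == 2
        assert [t.id for t in out] == [0]

    def test_non_positive_width_rejected(self):
        with pytest.raises(ValueError):
            SpeedBinning(width=0.0)


class TestZonePartition:
    def test_default_is_ten_shells(self):
        assert ZonePartition(radius_um=10.0).n_zones == 10

    def test_zone_from_pole_distance(self):
        part = ZonePartition(radius_um=10.0)
        assert part.zone_of(2.5) == 3  # ceil(10 * 2.5 / 10)
        assert part.zone_of(0.0) == 1  # start exactly at a centrosome
        assert part.zone_of(10.0) == 10  # outer edge closed
        assert part.zone_of(10.5) == OUTSIDE

    def test_assignment_matches_brute_force_oracle(self):
        d = 10.0
        part = ZonePartition(n_zones=10, radius_um=d)
        pole1 = np.array([-d / 2, 0.0, 0.0])
        pole2 = np.array([d / 2, 0.0, 0.0])
        rng = np.random.default_rng(12345)
        points = rng.uniform(-d, d, size=(10_000, 3))
        tracks = [_track(i, p) for i, p in enumerate(points)]
        assignments = assign_zones(tracks, part, pole1, pole2)

        shell = d / part.n_zones
        for a, p in zip(assignments, points):
            r1 = float(np.linalg.norm(p - pole1))
            r2 = float(np.linalg.norm(p - pole2))
            pole, r = (1, r1) if r1 <= r2 else (2, r2)
            if r > d:
                expect = OUTSIDE
            elif r == 0.0:
                expect = 1
            else:  # exhaustive shell scan: (k-1)·d/n < r ≤ k·d/n
                expect = next(
                    k
                    for k in range(1, part.n_zones + 1)
                    if (k - 1) * shell < r <= k * shell
                )
            assert a.pole == pole
            assert a.zone == expect

    def test_equidistant_start_breaks_tie_to_pole_one(self):
        part = ZonePartition(radius_um=10.0)
        (a,) = assign_zones(
            [_track(0, (0.0, 2.0, 0.0))], part,
            np.array([-5.0, 0, 0]), np.array([5.0, 0, 0]),
        )
        assert a.pole == 1

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError):
            ZonePartition(radius_um=0.0)


class TestTravelAngle:
    P1 = np.array([-5.0, 0.0, 0.0])
    P2 = np.array([5.0, 0.0, 0.0])

    @pytest.mark.parametrize(
        "end,expect",
        [((1.0, 0.0, 0.0), 0.0), ((0.0, 1.0, 0.0), 90.0), ((-1.0, 0.0, 0.0), 180.0)],
    )
    def test_reference_directions(self, end, expect):
        rec = compute_travel_angle(_track(0, (0, 0, 0), end), 1, self.P1, self.P2)
        assert rec.angle_deg == pytest.approx(expect, abs=1e-9)

    def test_pole_two_reverses_reference_axis(self):
        rec = compute_travel_angle(_track(0, (0, 0, 0), (1.0, 0, 0)), 2,
                                   self.P1, self.P2)
        assert rec.angle_deg == pytest.approx(180.0)

    def test_zero_net_displacement_flagged_undefined(self):
        rec = compute_travel_angle(_track(0, (1.0, 1.0, 1.0)), 1, self.P1, self.P2)
        assert not rec.defined
        summary = zone_angle_summary([rec])
        assert summary.empty

    def test_invariance_under_roll_and_scaling(self):
        disp = np.array([0.4, 0.3, 0.2])
        base = compute_travel_angle(_track(0, (0, 0, 0), disp), 1, self.P1, self.P2)
        for theta in (0.3, 1.2, 2.9):
            rot = np.array(
                [
                    [1, 0, 0],
                    [0, math.cos(theta), -math.sin(theta)],
                    [0, math.sin(theta), math.cos(theta)],
                ]
            )
            for scale in (0.1, 3.0):
                rolled = compute_travel_angle(
                    _track(0, (0, 0, 0), scale * (rot @ disp)), 1, self.P1, self.P2
                )
                assert rolled.angle_deg == pytest.approx(base.angle_deg, abs=1e-9)

    def test_folded_angle_is_against_undirected_axis(self):
        rec = AngleRecord(track_id=0, angle_deg=150.0, zone=2)
        assert rec.angle_folded_deg == pytest.approx(30.0)


class TestZoneAngleSummary:
    def test_identical_angles_have_zero_spread(self):
        recs = [AngleRecord(i, 0.0, zone=4) for i in range(5)]
        summary = zone_angle_summary(recs)
        assert len(summary) == 1
        assert summary.loc[0, "mean_angle_deg"] == 0.0
        assert summary.loc[0, "circ_sd_deg"] == pytest.approx(0.0, abs=1e-9)
        assert summary.loc[0, "hist_0_10"] == 5

    def test_counts_conserved_across_zones(self):
        rng = np.random.default_rng(2)
        recs = [
            AngleRecord(i, float(rng.uniform(0, 180)), zone=int(rng.integers(1, 11)))
            for i in range(200)
        ]
        summary = zone_angle_summary(recs)
        assert summary["count"].sum() == 200
        hist_cols = [c for c in summary.columns if c.startswith("hist_")]
        assert summary[hist_cols].to_numpy().sum() == 200

    def test_isotropic_directions_give_ninety_degree_mean(self, metaphase_preset):
        # isotropic emitter: pooled travel angle vs a Monte-Carlo oracle
        cfg = metaphase_preset.with_(
            motion=MotionModel(axis_angle_concentration=0.0),
            geometry=GeometryModel(d_um=10.0, drift_translation_um_per_s=0.0,
                                   drift_rotation_deg_per_s=0.0),
        )
        geom = simulate_geometry(cfg, 71)
        trajs = simulate_trajectories(cfg, geom, 72)
        d = cfg.geometry.d_um
        center = 0.5 * (geom.centrosome1_um[0] + geom.centrosome2_um[0])
        p1 = center + [-d / 2, 0, 0]
        p2 = center + [d / 2, 0, 0]
        part = ZonePartition(radius_um=d)
        tracks = [
            Track(id=t.id, start_frame=t.start_frame, positions_um=t.positions_um)
            for t in trajs
        ]
        assign = {a.track_id: a for a in assign_zones(tracks, part, p1, p2)}
        recs = [
            compute_travel_angle(t, assign[t.id].pole, p1, p2, assign[t.id].zone)
            for t in tracks
        ]
        angles = np.array([r.angle_deg for r in recs if r.defined])

        oracle_rng = np.random.default_rng(9)
        z = oracle_rng.uniform(-1, 1, 200_000)
        oracle = np.degrees(np.arccos(z))
        se = angles.std(ddof=1) / np.sqrt(len(angles))
        assert abs(angles.mean() - oracle.mean()) < 3 * se


class TestSubsample:
    def _tracks(self, n):
        return [_track(i, (i, 0, 0)) for i in range(n)]

    def test_rounding_rule(self):
        assert len(subsample_tracks(self._tracks(2000), 0.20, 1)) == 400
        assert len(subsample_tracks(self._tracks(150), 0.13, 1)) == 20

    def test_full_fraction_is_identity(self):
        tracks = self._tracks(7)
        assert subsample_tracks(tracks, 1.0, 5) == tracks

    def test_seed_reproducible_and_without_replacement(self):
        tracks = self._tracks(100)
        a = subsample_tracks(tracks, 0.3, 42)
        b = subsample_tracks(tracks, 0.3, 42)
        assert [t.id for t in a] == [t.id for t in b]
        assert len({t.id for t in a}) == len(a)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            subsample_tracks(self._tracks(5), 0.0, 1)
        with pytest.raises(ValueError):
            subsample_tracks(self._tracks(5), 1.2, 1)
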