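"""Track metrics: IO dialects, MSD, directionality, displacement."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from tailbud.synthetic import TrackSimSpec, generate_tracks
from tailbud.tracks import (
    Track,
    TrackSet,
    classify_directional,
    compute_track_metrics,
    dv_displacement,
    intensity_dynamics,
    mean_angular_alignment,
    msd_curve,
    msd_exponent,
    read_tracks,
    select_tracks,
    straightness_corrected,
    track_alpha,
    ventral_fraction,
)


def _track(xyz, frames=None, dt=1.0, intensity=None, tid=0):
    xyz = np.asarray(xyz, dtype=float)
    if frames is None:
        frames = np.arange(len(xyz))
    return Track(id=tid, frames=np.asarray(frames),
                 t_s=np.asarray(frames, dtype=float) * dt, xyz_um=xyz,
                 intensity=intensity)


def _ballistic(n=20, v=(1.0, 2.0, -0.5)):
    t = np.arange(n + 1)
    return _track(np.outer(t, np.asarray(v)))


class TestReadTracks:
    def _generic_df(self):
        return pd.DataFrame({
            "id": [1, 1, 1, 2, 2, 2],
            "t": [0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
            "x": [0.0, 1, 2, 5, 6, 7],
            "y": [0.0] * 6,
            "z": [0.0] * 6,
        })

    def test_generic_dialect(self):
        ts = read_tracks(self._generic_df())
        assert len(ts) == 2
        assert [t.id for t in ts] == [1, 2]

    def test_trackmate_dialect(self, tmp_path):
        df = pd.DataFrame({
            "TRACK_ID": [3, 3, 3], "POSITION_T": [0.0, 30.0, 60.0],
            "POSITION_X": [1.0, 2.0, 3.0], "POSITION_Y": [0.0] * 3,
            "POSITION_Z": [0.0] * 3, "FRAME": [0, 1, 2],
        })
        path = tmp_path / "spots.csv"
        df.to_csv(path, index=False)
        ts = read_tracks(path)
        assert len(ts) == 1
        np.testing.assert_allclose(ts[0].xyz_um[:, 2], [1.0, 2.0, 3.0])

    def test_exporter_unit_rows_dropped(self):
        df = self._generic_df().astype(object)
        df.loc[-1] = ["Track ID", "seconds", "micron", "micron", "micron"]
        ts = read_tracks(df.sort_index())
        assert len(ts) == 2

    def test_missing_column_named(self):
        df = self._generic_df().drop(columns=["y"])
        with pytest.raises(ValueError, match="y"):
            read_tracks(df)

    def test_two_frame_gap_accepted_three_rejected(self):
        ok = pd.DataFrame({"id": 1, "frame": [0, 1, 4, 5], "t": [0.0, 1, 4, 5],
                           "x": [0.0] * 4, "y": [0.0] * 4, "z": [0.0] * 4})
        assert len(read_tracks(ok)) == 1
        bad = ok.assign(frame=[0, 1, 5, 6], t=[0.0, 1, 5, 6])
        with pytest.raises(ValueError, match="frame gap"):
            read_tracks(bad)

    def test_empty_table(self):
        assert len(read_tracks(pd.DataFrame())) == 0

    def test_nonmonotone_times_rejected(self):
        df = pd.DataFrame({"id": 1, "t": [0.0, 2.0, 1.0], "x": [0.0] * 3,
                           "y": [0.0] * 3, "z": [0.0] * 3})
        with pytest.raises(ValueError, match="non-monotone"):
            read_tracks(df)


class TestSelectTracks:
    def test_start_window_and_length(self):
        short = _track(np.zeros((5, 3)) + np.arange(5)[:, None], dt=1.0, tid=1)
        early = _track(np.arange(12)[:, None] * [1.0, 0, 0], dt=30.0, tid=2)
        late = Track(id=3, frames=np.arange(12), t_s=700.0 + np.arange(12.0),
                     xyz_um=np.zeros((12, 3)))
        ts = select_tracks(TrackSet([short, early, late]), (0.0, 600.0), 10)
        assert [t.id for t in ts] == [2]


class TestMsd:
    def test_ballistic_curve_is_exact_quadratic(self):
        v = np.array([1.0, 2.0, -0.5])
        lags, msd = msd_curve(_ballistic(20, v))
        np.testing.assert_allclose(msd, np.sum(v**2) * lags.astype(float) ** 2, rtol=1e-12)
        alpha, r2 = msd_exponent(lags, msd)
        assert alpha == pytest.approx(2.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_stationary_track_msd_zero_alpha_undefined(self):
        lags, msd = msd_curve(_track(np.zeros((15, 3))))
        np.testing.assert_array_equal(msd, 0.0)
        alpha, _ = msd_exponent(lags, msd)
        assert np.isnan(alpha)

    def test_linear_msd_gives_alpha_one(self):
        lags = np.arange(1, 20)
        alpha, _ = msd_exponent(lags, 3.7 * lags.astype(float))
        assert alpha == pytest.approx(1.0, abs=1e-12)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            msd_curve(_track(np.zeros((5, 3))))

    def test_gap_pairs_skipped(self):
        # 12 samples with frame 5 missing; hand-computed pair counts
        frames = np.array([0, 1, 2, 3, 4, 6, 7, 8, 9, 10, 11, 12])
        xyz = np.outer(frames, [1.0, 0, 0])
        lags, msd = msd_curve(_track(xyz, frames=frames))
        # positions linear in frame, so every available pair gives tau^2
        np.testing.assert_allclose(msd, lags.astype(float) ** 2, rtol=1e-12)

    def test_brownian_ensemble_msd_linear(self):
        # ensemble oracle: time-averaged MSD ~ 3 sigma^2 tau for iid steps
        spec = TrackSimSpec(kind="diffusive", n_tracks=150, n_steps=60,
                            step_sd_um=1.0, seed=21)
        curves = [msd_curve(t) for t in generate_tracks(spec)]
        lags = curves[0][0][:10]
        mean_msd = np.mean([m[:10] for _, m in curves], axis=0)
        np.testing.assert_allclose(mean_msd, 3.0 * lags, rtol=0.1)


class TestClassifyDirectional:
    @pytest.mark.parametrize("alpha,expected", [
        (1.05, False), (1.2, True), (1.1, False),  # strict boundary
    ])
    def test_threshold(self, alpha, expected):
        assert classify_directional(alpha) is expected

    def test_undefined_propagates(self):
        assert classify_directional(float("nan")) is None

    def test_monotone_in_alpha(self):
        grid = np.linspace(0.5, 2.5, 50)
        calls = [classify_directional(a) for a in grid]
        assert calls == sorted(calls)  # False... then True, never back


class TestStraightness:
    def test_straight_track_sqrt_duration(self):
        tr = _ballistic(16)
        assert straightness_corrected(tr) == pytest.approx(4.0)

    def test_closed_loop_is_zero(self):
        xyz = np.array([[0, 0, 0], [1.0, 0, 0], [1, 1.0, 0], [0, 0, 0]])
        assert straightness_corrected(_track(xyz)) == 0.0

    def test_stationary_is_zero_by_convention(self):
        assert straightness_corrected(_track(np.zeros((5, 3)))) == 0.0

    def test_diffusive_below_ballistic(self):
        diff = generate_tracks(TrackSimSpec(kind="diffusive", n_tracks=100,
                                            n_steps=50, seed=5))
        ball = generate_tracks(TrackSimSpec(kind="ballistic", n_tracks=100,
                                            n_steps=50, step_sd_um=0.1, seed=5))
        s_diff = np.mean([straightness_corrected(t) for t in diff])
        s_ball = np.mean([straightness_corrected(t) for t in ball])
        assert s_diff < s_ball


class TestAngularAlignment:
    def test_straight_plus_one(self):
        assert mean_angular_alignment(_ballistic(10)) == pytest.approx(1.0)

    def test_reversal_minus_one(self):
        xyz = np.array([[0, 0, 0], [1.0, 0, 0], [0, 0, 0], [1.0, 0, 0]])
        assert mean_angular_alignment(_track(xyz)) == pytest.approx(-1.0)

    def test_isotropic_walk_near_zero(self):
        rng = np.random.default_rng(8)
        xyz = np.cumsum(rng.normal(size=(6000, 3)), axis=0)
        assert abs(mean_angular_alignment(_track(xyz))) < 0.05

    def test_all_zero_steps_undefined(self):
        assert np.isnan(mean_angular_alignment(_track(np.zeros((4, 3)))))


class TestDvDisplacement:
    AXIS = (0.0, 1.0, 0.0)  # ventral along +y (zyx order)

    def test_pure_axis_motion(self):
        xyz = np.array([[0, 0, 0], [0, 5.0, 0]])
        assert dv_displacement(_track(xyz), self.AXIS) == pytest.approx(5.0)

    def test_orthogonal_motion_is_zero(self):
        xyz = np.array([[0, 0, 0], [3.0, 0, 4.0]])
        assert dv_displacement(_track(xyz), self.AXIS) == 0.0

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            dv_displacement(_ballistic(5), (0, 2.0, 0))

    def test_ventral_fraction_known_composition(self):
        tracks = []
        for i in range(50):
            sign = 1.0 if i < 40 else -1.0
            xyz = np.array([[0.0, 0, 0], [0.0, sign * 5.0, 0.0]])
            tracks.append(_track(xyz, tid=i))
        # one ineligible track far from the reference point
        far = _track(np.array([[0.0, 500.0, 0], [0.0, 505.0, 0]]), tid=99)
        frac, n = ventral_fraction(tracks + [far], self.AXIS, (0.0, 0.0, 0.0), 60.0)
        assert n == 50
        assert frac == pytest.approx(0.8)

    def test_no_eligible_tracks_flagged(self):
        frac, n = ventral_fraction([], self.AXIS, (0.0, 0.0, 0.0))
        assert np.isnan(frac) and n == 0


class TestIntensityDynamics:
    def test_zscore_at_mean_is_zero(self):
        tr = _track(np.zeros((3, 3)) + np.arange(3)[:, None],
                    intensity=np.array([2.0, 2.5, 3.0]))
        z, _ = intensity_dynamics(tr, embryo_mean=2.0, embryo_sd=1.0)
        assert z == 0.0

    def test_constant_intensity_change_zero(self):
        tr = _track(np.arange(4)[:, None] * [1.0, 0, 0], intensity=np.full(4, 5.0))
        _, change = intensity_dynamics(tr, 0.0, 1.0)
        assert change == 0.0

    def test_arithmetic_series_telescopes(self):
        tr = _track(np.arange(6)[:, None] * [1.0, 0, 0],
                    intensity=1.0 + 0.25 * np.arange(6))
        _, change = intensity_dynamics(tr, 0.0, 1.0)
        assert change == pytest.approx(0.25)

    def test_zero_sd_rejected(self):
        tr = _track(np.zeros((3, 3)), intensity=np.ones(3))
        with pytest.raises(ValueError, match="sd"):
            intensity_dynamics(tr, 0.0, 0.0)


class TestEnsembleCalibration:
    def test_diffusive_mean_alpha_near_one(self):
        spec = TrackSimSpec(kind="diffusive", n_tracks=100, n_steps=60, seed=13)
        alphas = [track_alpha(t)[0] for t in generate_tracks(spec)]
        assert np.mean(alphas) == pytest.approx(1.0, abs=0.1)

    def test_confined_alpha_below_one(self):
        spec = TrackSimSpec(kind="confined", n_tracks=60, n_steps=80,
                            step_sd_um=1.5, confinement_radius_um=4.0, seed=17)
        alphas = [track_alpha(t)[0] for t in generate_tracks(spec)]
        assert np.mean(alphas) < 1.0

    def test_metrics_invariant_under_rigid_motion(self):
        spec = TrackSimSpec(kind="persistent", n_tracks=10, n_steps=40, seed=19)
        ts = generate_tracks(spec)
        rot = Rotation.from_euler("xz", [30, 60], degrees=True).as_matrix()
        shift = np.array([12.0, -7.0, 3.0])
        for tr in ts:
            moved = Track(id=tr.id, frames=tr.frames, t_s=tr.t_s,
                          xyz_um=tr.xyz_um @ rot.T + shift)
            assert track_alpha(moved)[0] == pytest.approx(track_alpha(tr)[0], abs=1e-9)
            assert straightness_corrected(moved) == pytest.approx(
                straightness_corrected(tr), abs=1e-9)
            assert mean_angular_alignment(moved) == pytest.approx(
                mean_angular_alignment(tr), abs=1e-9)


class TestBatchMetrics:
    def test_columns_and_directional_counts(self):
        spec = TrackSimSpec(kind="ballistic", n_tracks=5, n_steps=20,
                            step_sd_um=0.0, seed=2)
        metrics = compute_track_metrics(generate_tracks(spec),
                                        dv_axis=(0, 1.0, 0),
                                        reference_point_um=(0, 0, 0))
        assert {"alpha", "fit_r2", "directional", "dv_displacement_um",
                "start_distance_um"} <= set(metrics.columns)
        assert metrics["directional"].all()
        np.testing.assert_allclose(metrics["alpha"], 2.0, atol=1e-9)
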