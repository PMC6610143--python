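"""Generator correctness: closed forms, determinism, photophysics limits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from livespot import synth


class TestMakeTracks:
    def test_zero_diffusion_is_stationary(self):
        tr = synth.make_tracks(synth.MotionModel("brownian", D=0.0), 5, 10, 1.0, seed=0)
        for _, g in tr.groupby("track_id"):
            assert g["x_um"].nunique() == 1 and g["y_um"].nunique() == 1

    def test_brownian_msd_closed_form(self):
        # mean squared frame-to-frame displacement = 4*D*dt (2-D)
        D, dt = 0.1, 1.0
        tr = synth.make_tracks(
            synth.MotionModel("brownian", D=D), 100, 101, dt, bounds=(1000.0, 1000.0), seed=1
        )
        dx = tr.groupby("track_id")["x_um"].diff().dropna()
        dy = tr.groupby("track_id")["y_um"].diff().dropna()
        msd = (dx**2 + dy**2).mean()
        n = len(dx)
        assert n == 10_000
        # Monte-Carlo tolerance: SEM of chi2-distributed squared jumps
        assert msd == pytest.approx(4 * D * dt, rel=0.05)

    def test_brownian_jumps_are_normal_at_matched_variance(self):
        D, dt = 0.05, 0.5
        tr = synth.make_tracks(
            synth.MotionModel("brownian", D=D), 100, 101, dt, bounds=(1000.0, 1000.0), seed=2
        )
        jumps = tr.groupby("track_id")["x_um"].diff().dropna().to_numpy()
        sd = math.sqrt(2 * D * dt)
        assert stats.kstest(jumps / sd, "norm").pvalue > 0.01
        assert np.var(jumps) == pytest.approx(sd**2, rel=0.1)

    def test_bound_tracks_stay_near_anchor(self):
        jit = 0.03
        tr = synth.make_tracks(synth.MotionModel("bound", jitter_sd=jit), 20, 200, 1.0, seed=3)
        for _, g in tr.groupby("track_id"):
            assert g["x_um"].std() == pytest.approx(jit, rel=0.5)
            assert (g["x_um"] - g["x_um"].mean()).abs().max() < 6 * jit

    def test_motored_follows_segment_schedule(self):
        segs = (("run", 5.0, 1.4, 0.0), ("pause", 5.0))
        tr = synth.make_tracks(
            synth.MotionModel("motored", D=0.0, segments=segs), 1, 11, 1.0, bounds=(1000.0, 1000.0), seed=4
        )
        x = tr["x_um"].to_numpy()
        # five directed steps of 1.4 µm along +x, then five stationary (D=0)
        assert np.allclose(np.diff(x[:6]), 1.4)
        assert np.allclose(np.diff(x[5:]), 0.0)

    def test_seed_determinism(self):
        a = synth.make_tracks(synth.MotionModel("brownian", D=0.2), 7, 13, 0.1, seed=42)
        b = synth.make_tracks(synth.MotionModel("brownian", D=0.2), 7, 13, 0.1, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_mobility_field_scales_local_diffusion(self):
        # slow periphery, fast interior of a 20x20 µm field
        field = lambda x, y: 0.05 if min(x, y, 20 - x, 20 - y) < 5 else 1.0
        model = synth.MotionModel("brownian", D=0.2, mobility_field=field)
        tr = synth.make_tracks(model, 150, 30, 1.0, bounds=(20.0, 20.0), seed=5)
        jumps = tr.assign(
            jump=np.hypot(
                tr.groupby("track_id")["x_um"].diff(), tr.groupby("track_id")["y_um"].diff()
            )
        ).dropna(subset=["jump"])
        edge = jumps[jumps[["x_um", "y_um"]].apply(lambda r: min(r.x_um, r.y_um, 20 - r.x_um, 20 - r.y_um) < 5, axis=1)]
        core = jumps.drop(edge.index)
        assert edge["jump"].mean() < 0.5 * core["jump"].mean()

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_nonfinite_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            synth.MotionModel("brownian", D=bad)
        with pytest.raises(ValueError):
            synth.make_tracks(synth.MotionModel(), 1, 2, bad)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_determinism_any_seed(self, seed):
        a = synth.make_tracks(synth.MotionModel("bound"), 2, 3, 1.0, seed=seed)
        b = synth.make_tracks(synth.MotionModel("bound"), 2, 3, 1.0, seed=seed)
        pd.testing.assert_frame_equal(a, b)


class TestRenderMovie:
    def test_noiseless_centroid_matches_emitter(self, single_spot_movie):
        movie, (x_true, y_true) = single_spot_movie
        img = movie.frame(0) - 10.0
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        cx = (xx * img).sum() / img.sum()
        cy = (yy * img).sum() / img.sum()
        assert abs(cx - x_true) < 0.01 and abs(cy - y_true) < 0.01

    def test_photon_budget(self, single_spot_movie, noiseless_optics):
        movie, _ = single_spot_movie
        o = noiseless_optics
        h, w = o.field_px
        expected = o.background_level * h * w + o.photons_per_spot * 2 * math.pi * o.psf_sigma_px**2
        assert movie.frame(0).sum() == pytest.approx(expected, rel=0.01)

    def test_zero_amplitude_equals_background_only(self, noiseless_optics):
        o = synth.Optics(**{**noiseless_optics.__dict__, "photons_per_spot": 0.0})
        tracks = pd.DataFrame(
            {"track_id": [0], "frame": [0], "x_um": [1.0], "y_um": [1.0], "channel": [0], "state": ["bound"]}
        )
        with_spot = synth.render_movie(tracks, o, seed=1, shot_noise=False)
        empty = synth.render_movie(tracks.iloc[:0], o, seed=1, shot_noise=False)
        np.testing.assert_array_equal(with_spot.frame(0), empty.frame(0))

    def test_empty_table_gives_pure_background(self, noiseless_optics):
        movie = synth.render_movie(pd.DataFrame(columns=synth.TRACK_COLUMNS), noiseless_optics, shot_noise=False)
        assert np.all(movie.frame(0) == noiseless_optics.background_level)

    def test_fast_bleaching_kills_emitter_after_first_frame(self, noiseless_optics):
        px = noiseless_optics.pixel_size_um
        tracks = pd.DataFrame(
            {
                "track_id": [0] * 5,
                "frame": range(5),
                "x_um": [20 * px] * 5,
                "y_um": [20 * px] * 5,
                "channel": [0] * 5,
                "state": ["bound"] * 5,
            }
        )
        photo = synth.PhotoKinetics(bleach_rate=1000.0, initially_dark_fraction=0.0)
        movie = synth.render_movie(tracks, noiseless_optics, photo, shot_noise=False)
        peak = movie.data[:, 0, 0].max(axis=(1, 2))
        assert peak[0] > noiseless_optics.background_level + 50
        assert np.all(peak[1:] == noiseless_optics.background_level)

    def test_negative_optics_rejected(self):
        with pytest.raises(ValueError):
            synth.Optics(photons_per_spot=-1)
        with pytest.raises(ValueError):
            synth.Optics(pixel_size_um=0)

    def test_render_determinism(self, noiseless_optics):
        tr = synth.make_tracks(synth.MotionModel("brownian", D=0.05), 3, 4, 1.0, bounds=(5.0, 5.0), seed=0)
        a = synth.render_movie(tr, noiseless_optics, seed=9)
        b = synth.render_movie(tr, noiseless_optics, seed=9)
        np.testing.assert_array_equal(a.data, b.data)


class TestKineticTraces:
    def test_frap_closed_form_when_noiseless(self):
        k, mf, depth = math.log(2) / 141.0, 0.8, 0.6
        tr = synth.make_frap_trace(k, mobile_fraction=mf, bleach_depth=depth, pre_frames=5, post_frames=50, dt=2.0)
        rel = (tr.roi_intensity - tr.background) / (tr.roi_intensity[0] - tr.background[0])
        t_post = tr.time_s[5:] - tr.time_s[5]
        expected = (1 - depth) + mf * depth * (1 - np.exp(-k * t_post))
        np.testing.assert_allclose(rel[5:], expected, rtol=1e-12)

    def test_frap_half_recovery_at_ln2_over_k(self):
        k = math.log(2) / 141.0
        tr = synth.make_frap_trace(k, mobile_fraction=1.0, bleach_depth=0.6, pre_frames=10, post_frames=400, dt=1.0)
        rel = (tr.roi_intensity - tr.background) / (tr.roi_intensity[0] - tr.background[0])
        post = rel[tr.bleach_frame:]
        half_level = post[0] + (1.0 - post[0]) / 2.0
        t_half = np.interp(half_level, post, np.arange(len(post)) * 1.0)
        assert t_half == pytest.approx(141.0, rel=0.01)

    def test_frap_immobile_stays_flat(self):
        tr = synth.make_frap_trace(0.1, mobile_fraction=0.0, bleach_depth=0.5, pre_frames=5, post_frames=30, dt=1.0)
        post = tr.roi_intensity[tr.bleach_frame:]
        assert np.all(post == post[0])

    def test_frap_instant_recovery_limit(self):
        tr = synth.make_frap_trace(k=1e6, bleach_depth=0.5, pre_frames=5, post_frames=10, dt=1.0)
        assert tr.roi_intensity[tr.bleach_frame + 1] == pytest.approx(tr.roi_intensity[0], rel=1e-6)

    def test_sensorgram_zero_concentration_flat(self):
        tr = synth.make_sensorgram(1e5, 1e-3, 100.0, 0.0, t_assoc=100, t_dissoc=100)
        assert np.all(tr.value == 0)

    def test_sensorgram_half_saturation_at_kd(self):
        k_on, k_off = 1e5, 1.47e-3
        kd = k_off / k_on
        tr = synth.make_sensorgram(k_on, k_off, 100.0, kd, t_assoc=50000, t_dissoc=10)
        r_end = tr.value[tr.time_s <= tr.t_assoc_end_s][-1]
        assert r_end == pytest.approx(50.0, rel=1e-3)

    def test_sensorgram_requil_closed_form(self):
        # K_D = 14.7 nM, C = 100 nM -> R_eq/R_max = 100/114.7
        k_on, k_off, c = 1e5, 1.47e-3, 100e-9
        tr = synth.make_sensorgram(k_on, k_off, 1.0, c, t_assoc=1e6, t_dissoc=10, dt=1000.0)
        r_eq = tr.value[tr.time_s <= tr.t_assoc_end_s].max()
        assert r_eq == pytest.approx(100.0 / 114.7, rel=1e-3)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            synth.make_sensorgram(-1.0, 1e-3, 100.0, 1e-9)
        with pytest.raises(ValueError):
            synth.make_frap_trace(k=0.1, dt=0.0)


class TestRunoffScene:
    def test_zero_rate_keeps_all_spots(self):
        scene = synth.RunoffScene(n_cells=2, spots_per_cell=5, n_frames=10, drug_time_s=30.0, runoff_rate=0.0)
        _, truth = synth.make_runoff_scene(scene, synth.Optics(field_px=(64, 64), frame_interval_s=10.0), seed=0)
        counts = truth[truth.channel == 0].groupby("frame").size()
        assert (counts == 10).all()

    def test_huge_rate_empties_channel_after_drug(self):
        scene = synth.RunoffScene(n_cells=2, spots_per_cell=5, n_frames=10, drug_time_s=30.0, runoff_rate=1e6)
        _, truth = synth.make_runoff_scene(scene, synth.Optics(field_px=(64, 64), frame_interval_s=10.0), seed=0)
        ch0 = truth[truth.channel == 0]
        assert ch0.frame.max() <= 3  # nothing survives past the drug frame
        mrna = truth[truth.channel == 1].groupby("frame").size()
        assert (mrna == 10).all()

    def test_survival_follows_exponential_law(self):
        rate = 0.05
        scene = synth.RunoffScene(n_cells=10, spots_per_cell=40, n_frames=20, drug_time_s=50.0, runoff_rate=rate)
        _, truth = synth.make_runoff_scene(scene, synth.Optics(field_px=(128, 128), frame_interval_s=10.0), seed=1)
        n0 = scene.n_cells * scene.spots_per_cell
        for frame in (6, 8, 10):
            t = frame * 10.0
            p = math.exp(-rate * (t - 50.0))
            n = (truth[(truth.channel == 0) & (truth.frame == frame)]).shape[0]
            assert abs(n - n0 * p) < 3 * math.sqrt(n0 * p * (1 - p))


class TestEmbryoSequence:
    def test_division_schedule_doubles_counts(self):
        _, truth = synth.make_embryo_sequence(
            n_start_nuclei=4, division_period_frames=10, n_frames=21, seed=0
        )
        counts = truth.groupby("frame")["nucleus_id"].size()
        assert counts[0] == 4 and counts[10] == 8 and counts[20] == 16

    def test_constant_ramp_gives_unity_ratio(self):
        _, truth = synth.make_embryo_sequence(expression_ramp=(1.0, 1.0), n_frames=5, seed=0)
        assert (truth.true_ratio == 1.0).all()

    def test_final_ratio_matches_ramp_end(self):
        _, truth = synth.make_embryo_sequence(expression_ramp=(1.0, 2.5), n_frames=12, seed=0)
        assert truth[truth.frame == 11].true_ratio.iloc[0] == pytest.approx(2.5)

    def test_tiny_radius_rejected(self):
        with pytest.raises(ValueError):
            synth.make_embryo_sequence(nucleus_radius_px=1.5)
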