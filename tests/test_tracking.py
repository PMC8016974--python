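"""Detection, linking, axial assignment, MSD/diffusion, viscosity."""

import numpy as np
import pytest

from selfipsf import (
    CameraConfig,
    ImagingSystem,
    Movie,
    ParticleModel,
    SubstrateStack,
    Trajectory,
    axialize,
    brownian_path,
    cumulative_displacement,
    detect_spots,
    fit_diffusion,
    link,
    msd,
    selfi_psf,
    synth_movie,
    viscosity,
)
from selfipsf.synth import expected_image, render_frame

D_REF = 0.0174  # um^2/s
DT = 0.1


def _movie_of(frames, pitch=65.0, dt=DT):
    return Movie(frames=np.asarray(frames, dtype=float), dt_s=dt, pixel_pitch_nm=pitch)


class TestDetect:
    def test_background_only_no_detections(self):
        rng = np.random.default_rng(0)
        frame = render_frame(np.full((96, 96), 2.0), CameraConfig(), rng).astype(float)
        assert detect_spots(frame, 65.0, k=5.0) == []

    def test_single_doughnut_detected_within_one_pixel(self, optics96, stack):
        img = ImagingSystem.from_config(optics96)
        psf = selfi_psf(ParticleModel(spacing_nm=154.9), stack, img, 455.0)
        exp, _ = expected_image(psf.frame(0), [(0.0, 0.0)], 1e4, 2.0, 65.0)
        frame = render_frame(exp, CameraConfig(), np.random.default_rng(1)).astype(float)
        dets = detect_spots(frame, 65.0)
        assert len(dets) == 1
        x, y, _ = dets[0]
        assert abs(x - 47.5) < 1.0 and abs(y - 47.5) < 1.0

    def test_two_separated_spots(self, optics96, stack):
        img = ImagingSystem.from_config(optics96)
        psf = selfi_psf(ParticleModel(spacing_nm=154.9), stack, img, 455.0)
        exp, _ = expected_image(
            psf.frame(0), [(-900.0, 0.0), (900.0, 0.0)], 1e4, 2.0, 65.0
        )
        frame = render_frame(exp, CameraConfig(), np.random.default_rng(2)).astype(float)
        assert len(detect_spots(frame, 65.0)) == 2


class TestLink:
    def test_single_persistent_particle(self):
        dets = [[(10.0 + 0.1 * f, 12.0, 1.0)] for f in range(20)]
        tracks = link(dets, 500.0, 65.0, DT)
        assert len(tracks) == 1
        assert len(tracks[0]) == 20

    def test_gap_longer_than_max_gap_splits(self):
        dets = [[(10.0, 10.0, 1.0)]] * 5 + [[]] * 3 + [[(10.0, 10.0, 1.0)]] * 5
        tracks = link(dets, 500.0, 65.0, DT, max_gap=1)
        assert len(tracks) == 2

    def test_gap_within_max_gap_bridged(self):
        dets = [[(10.0, 10.0, 1.0)]] * 5 + [[]] + [[(10.0, 10.0, 1.0)]] * 5
        tracks = link(dets, 500.0, 65.0, DT, max_gap=1)
        assert len(tracks) == 1
        assert any("gap_bridged" in f for f in tracks[0].flags)

    def test_crossing_particles_minimize_total_displacement(self):
        # two particles move toward each other and pass; oracle = exhaustive
        # evaluation of both assignments at every frame
        a = [(5.0 + f, 10.0) for f in range(11)]
        b = [(15.0 - f, 10.4) for f in range(11)]
        dets = [[(*pa, 1.0), (*pb, 1.0)] for pa, pb in zip(a, b)]
        tracks = link(dets, 200.0, 65.0, DT)
        assert len(tracks) == 2
        # straight-through assignment has the smaller per-step displacement
        t0 = tracks[0]
        dx = np.diff(t0.x_nm)
        assert np.allclose(dx, dx[0], atol=1e-6)
        total = sum(
            np.hypot(np.diff(t.x_nm), np.diff(t.y_nm)).sum() for t in tracks
        )
        # oracle: best possible total displacement over the 2 global assignments
        straight = sum(
            np.hypot(np.diff([p[0] * 65.0 for p in path]), np.diff([p[1] * 65.0 for p in path])).sum()
            for path in (a, b)
        )
        swapped_a = [*a[:5], *b[5:]]
        swapped_b = [*b[:5], *a[5:]]
        swapped = sum(
            np.hypot(np.diff([p[0] * 65.0 for p in path]), np.diff([p[1] * 65.0 for p in path])).sum()
            for path in (swapped_a, swapped_b)
        )
        assert total <= min(straight, swapped) + 1e-6


class TestDisplacementStats:
    def test_cumulative_static_zero(self):
        tr = Trajectory(
            t_s=np.arange(5) * DT, x_nm=np.zeros(5), y_nm=np.zeros(5), z_nm=np.zeros(5)
        )
        _, cum = cumulative_displacement(tr)
        assert np.all(cum == 0.0)

    def test_cumulative_uniform_motion_slope(self):
        t = np.arange(20) * DT
        tr = Trajectory(t_s=t, x_nm=300.0 * t, y_nm=np.zeros(20), z_nm=np.zeros(20))
        tt, cum = cumulative_displacement(tr)
        assert cum[-1] == pytest.approx(300.0 * t[-1], rel=1e-9)

    def test_cumulative_matches_direct_summation(self):
        p = brownian_path(D_REF, DT, 40, seed=3)
        tr = Trajectory(t_s=np.arange(41) * DT, x_nm=p[:, 0], y_nm=p[:, 1], z_nm=p[:, 2])
        _, cum = cumulative_displacement(tr)
        direct = np.cumsum(np.linalg.norm(np.diff(p, axis=0), axis=1))
        assert np.allclose(cum, direct)

    def test_msd_linear_motion_quadratic(self):
        t = np.arange(40) * DT
        v = 2.5  # um/s
        tr = Trajectory(t_s=t, x_nm=v * 1000 * t, y_nm=np.zeros(40), z_nm=np.zeros(40))
        lags, m = msd(tr)
        assert np.allclose(m, (v * lags) ** 2, rtol=1e-9)

    def test_msd_static_zero(self):
        tr = Trajectory(t_s=np.arange(20) * DT, x_nm=np.ones(20), y_nm=np.ones(20))
        _, m = msd(tr)
        assert np.allclose(m, 0.0)

    def test_msd_equals_double_loop_oracle(self):
        p = brownian_path(D_REF, DT, 30, seed=9)
        tr = Trajectory(t_s=np.arange(31) * DT, x_nm=p[:, 0], y_nm=p[:, 1], z_nm=p[:, 2])
        lags, m = msd(tr)
        pu = p / 1000.0
        for i, lag in enumerate(range(1, len(lags) + 1)):
            acc = [
                np.sum((pu[j + lag] - pu[j]) ** 2) for j in range(len(pu) - lag)
            ]
            assert m[i] == pytest.approx(np.mean(acc), rel=1e-12)

    def test_msd_brownian_matches_6dt(self):
        # average over several trajectories to beat the estimator variance
        acc = []
        for seed in range(12):
            p = brownian_path(D_REF, DT, 129, seed=seed)
            tr = Trajectory(
                t_s=np.arange(130) * DT, x_nm=p[:, 0], y_nm=p[:, 1], z_nm=p[:, 2]
            )
            lags, m = msd(tr)
            acc.append(m[:6])
        mean_msd = np.mean(acc, axis=0)
        expected = 6 * D_REF * lags[:6]
        assert np.allclose(mean_msd, expected, rtol=0.15)


class TestFitDiffusion:
    def test_exact_power_law_recovered(self):
        lags = np.arange(1, 33) * DT
        m = 6 * 0.02 * lags**1.0
        fit = fit_diffusion(lags, m, dimensions=3, n_boot=0)
        assert fit.d_um2_s == pytest.approx(0.02, rel=1e-12)
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)

    def test_ballistic_exponent(self):
        lags = np.arange(1, 33) * DT
        m = (1.4 * lags) ** 2
        fit = fit_diffusion(lags, m, dimensions=2, n_boot=0)
        assert fit.alpha == pytest.approx(2.0, abs=1e-9)

    def test_monte_carlo_ci_coverage_and_alpha(self):
        """D lies in the bootstrap 95% interval and alpha is near 1 for the
        canonical tracking protocol (130 frames at 10 Hz)."""
        in_ci = 0
        alpha_ok = 0
        n_seeds = 60
        for seed in range(n_seeds):
            p = brownian_path(D_REF, DT, 129, seed=seed)
            tr = Trajectory(
                t_s=np.arange(130) * DT, x_nm=p[:, 0], y_nm=p[:, 1], z_nm=p[:, 2]
            )
            lags, m = msd(tr)
            fit = fit_diffusion(lags, m, dimensions=3, n_boot=60, boot_seed=seed)
            if fit.d_ci95[0] <= D_REF <= fit.d_ci95[1]:
                in_ci += 1
            if abs(fit.alpha - 1.0) <= 0.15:
                alpha_ok += 1
        assert in_ci >= 0.85 * n_seeds
        assert alpha_ok >= 0.9 * n_seeds

    def test_nonpositive_msd_flagged(self):
        lags = np.arange(1, 13) * DT
        m = 6 * 0.02 * lags
        m[5] = 0.0
        fit = fit_diffusion(lags, m, fit_range=(0, 12), n_boot=0)
        assert "nonpositive_msd_excluded" in fit.flags

    def test_summary_mentions_estimates(self):
        lags = np.arange(1, 33) * DT
        fit = fit_diffusion(lags, 6 * 0.02 * lags, n_boot=0)
        s = fit.summary()
        assert "D" in s and "alpha" in s


class TestViscosity:
    def test_inverse_proportionality(self):
        v1 = viscosity(0.02, 16.5)
        v2 = viscosity(0.01, 16.5)
        assert v2.eta_cp == pytest.approx(2 * v1.eta_cp)

    def test_water_round_trip(self):
        # eta = 1 cP, r_h = 500 nm, T = 293 K -> D ~ 4.3e-13 m^2/s
        k_b = 1.380649e-23
        d_si = k_b * 293.0 / (6 * np.pi * 1e-3 * 500e-9)
        assert d_si == pytest.approx(4.3e-13, rel=0.01)
        res = viscosity(d_si * 1e12, 500.0, 293.0)
        assert res.eta_cp == pytest.approx(1.0, rel=1e-9)

    def test_reference_diffusion_gives_hundreds_of_cp(self):
        # the glycerol-solution regime: order 1e2 cP for tens-of-nm particles
        res = viscosity(D_REF, 33.0, 293.0)
        assert 200.0 < res.eta_cp < 600.0
        assert res.d_um2_s == D_REF and res.hydrodynamic_radius_nm == 33.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            viscosity(0.0, 16.5)


class TestAxialize:
    def test_noiseless_static_movie_recovers_spacing(self, optics96, stack, calib_noiseless):
        img = ImagingSystem.from_config(optics96)
        z0 = 240.0
        path = np.tile([0.0, 0.0, z0], (6, 1))
        mv = synth_movie(
            ParticleModel(spacing_nm=z0), stack, img, 455.0, path, DT,
            photons=2e5, background=0.0, seed=4,
        )
        movie = _movie_of(mv.frames)
        dets = [detect_spots(f, 65.0) for f in movie.frames]
        traj = max(link(dets, 2000.0, 65.0, DT), key=len)
        traj = axialize(traj, movie, calib_noiseless)
        assert np.nanmax(np.abs(traj.z_nm - z0)) < 4.0

    def test_focus_stepping_does_not_corrupt_axial_readout(
        self, optics96, stack, calib_noisy
    ):
        """Stage stepped over a 200 nm range in 20 nm increments while the
        particle stays put: the axial readout is unaffected for the bulk of
        the frames (median).  At the extreme drifts the feature quadruple can
        alias a neighbouring interference branch; those frames carry flags."""
        img = ImagingSystem.from_config(optics96)
        z0 = 180.0
        steps = np.arange(-100.0, 101.0, 20.0)
        path = np.tile([0.0, 0.0, z0], (len(steps), 1))
        mv = synth_movie(
            ParticleModel(spacing_nm=z0), stack, img, 455.0, path, DT,
            photons=1e4, background=2.0, seed=3, focus_offsets_nm=steps,
        )
        movie = _movie_of(mv.frames)
        dets = [detect_spots(f, 65.0) for f in movie.frames]
        traj = max(link(dets, 2000.0, 65.0, DT), key=len)
        traj = axialize(traj, movie, calib_noisy)
        assert np.nanmedian(np.abs(traj.z_nm - z0)) < 10.0


class TestEndToEnd:
    def test_brownian_movie_recovery(self, optics96, stack, calib_noisy):
        """Full chain on synthetic movies: lateral diffusion within 25% and
        alpha in [0.85, 1.15] for most seeds; median axial error <= 5 nm."""
        img = ImagingSystem.from_config(optics96)
        ok = 0
        n_seeds = 5
        med_errors = []
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            path = brownian_path(
                D_REF, DT, 129, start_nm=(0.0, 0.0, 180.0), seed=rng,
                reflect_z_nm=(110.0, 250.0),
            )
            mv = synth_movie(
                ParticleModel(spacing_nm=180.0), stack, img, 455.0, path, DT,
                photons=1e4, background=2.0, seed=rng,
            )
            movie = _movie_of(mv.frames)
            dets = [detect_spots(f, 65.0) for f in movie.frames]
            traj = max(link(dets, 2000.0, 65.0, DT, max_gap=1), key=len)
            traj = axialize(traj, movie, calib_noisy)
            fi = np.asarray(traj.frame_index)
            med_errors.append(np.nanmedian(np.abs(traj.z_nm - path[fi, 2])))
            lateral = Trajectory(t_s=traj.t_s, x_nm=traj.x_nm, y_nm=traj.y_nm)
            lags, m = msd(lateral)
            fit = fit_diffusion(lags, m, dimensions=2, n_boot=0)
            if abs(fit.d_um2_s - D_REF) / D_REF <= 0.25 and 0.85 <= fit.alpha <= 1.15:
                ok += 1
        assert ok >= n_seeds - 1
        assert np.median(med_errors) <= 5.0

    def test_focus_drift_immunity_end_to_end(self, optics96, stack, calib_noisy):
        """A +-100 nm sinusoidal focus drift barely changes the recovered
        axial series (median absolute error shifts by < 2 nm)."""
        img = ImagingSystem.from_config(optics96)

        def run(drift):
            rng = np.random.default_rng(55)
            path = brownian_path(
                D_REF, DT, 59, start_nm=(0.0, 0.0, 180.0), seed=rng,
                reflect_z_nm=(110.0, 250.0),
            )
            foff = 100.0 * np.sin(2 * np.pi * np.arange(60) / 20.0) if drift else None
            mv = synth_movie(
                ParticleModel(spacing_nm=180.0), stack, img, 455.0, path, DT,
                photons=1e4, background=2.0, seed=np.random.default_rng(56),
                focus_offsets_nm=foff,
            )
            movie = _movie_of(mv.frames)
            dets = [detect_spots(f, 65.0) for f in movie.frames]
            traj = max(link(dets, 2000.0, 65.0, DT, max_gap=1), key=len)
            traj = axialize(traj, movie, calib_noisy)
            fi = np.asarray(traj.frame_index)
            return np.nanmedian(np.abs(traj.z_nm - path[fi, 2]))

        assert abs(run(True) - run(False)) < 2.0
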