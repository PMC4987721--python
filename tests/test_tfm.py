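"""Pillar mechanics, localization, grid fitting, tracking, and force statistics."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.spatial import cKDTree

from fadynamics import synthetic, tfm
from fadynamics.tfm import (
    AutocorrFit,
    PillarSpec,
    compare_forces,
    compare_halftimes,
    compute_deflections,
    detect_pillars,
    effective_young_modulus,
    fit_exponential_decay,
    fit_reference_grid,
    force_autocorrelation,
    force_timeseries_summary,
    pillar_stiffness,
    segment_cell_mask,
    select_top_deflected,
    track_pillars,
)


class TestMechanics:
    def test_stiffness_linear_in_modulus(self):
        assert pillar_stiffness(4.1, 2.0, 4.0) == pytest.approx(
            2.0 * pillar_stiffness(4.1, 2.0, 2.0)
        )

    def test_stiffness_closed_form(self):
        # k = 3 pi E r^4 / (4 h^3), E=2 MPa, r=1 um, h=4.1 um
        assert pillar_stiffness(4.1, 2.0, 2.0) == pytest.approx(68.4, abs=0.05)

    def test_printed_stiffness_from_inverse_modulus(self):
        # the modulus that reproduces the production stiffness
        assert pillar_stiffness(4.1, 2.0, 1.925) == pytest.approx(65.8, abs=0.05)

    def test_effective_modulus_from_printed_stiffness(self):
        assert effective_young_modulus(65.8, 1.0) == pytest.approx(47.2, rel=0.005)

    def test_effective_modulus_zero_and_closed_form(self):
        assert effective_young_modulus(0.0, 1.0) == 0.0
        # k = 0.1 N/m = 100 nN/um at r = 2 um
        assert effective_young_modulus(100.0, 2.0) == pytest.approx(35.8, abs=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pillar_stiffness(-1.0, 2.0, 2.0)
        with pytest.raises(ValueError):
            effective_young_modulus(1.0, 0.0)

    def test_spec_consistency_enforced(self):
        PillarSpec()  # defaults are self-consistent
        with pytest.raises(ValueError):
            PillarSpec(effective_young_kPa=60.0)


class TestDetection:
    def test_blank_frame_empty_with_warning(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning):
            out = detect_pillars(rng.normal(100.0, 1.0, (128, 128)))
        assert out.shape == (0, 2)

    def test_single_disc_subpixel_accuracy(self):
        img = np.zeros((200, 200))
        synthetic._add_disc(img, 10.07 / 0.2, 20.03 / 0.2, 5.0, 1.5, 1.0)
        noisy = synthetic._apply_noise(img, 20.0, np.random.default_rng(1))
        det = detect_pillars(noisy)
        assert len(det) == 1
        assert det[0] == pytest.approx([10.07, 20.03], abs=0.05)

    def test_full_lattice_detected(self, small_pillar_movie):
        mv = small_pillar_movie
        det = detect_pillars(mv.pillar_movie[0])
        assert len(det) == len(mv.pillars)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            detect_pillars(np.zeros((4, 4, 4)))


class TestReferenceGrid:
    def _lattice(self, rotation_deg=0.0, n=10, pitch=4.0):
        th = math.radians(rotation_deg)
        a1 = pitch * np.array([math.cos(th), math.sin(th)])
        a2 = pitch * np.array([math.cos(th + math.pi / 3),
                               math.sin(th + math.pi / 3)])
        pts = [i * a1 + j * a2 for i in range(n) for j in range(n)]
        return np.asarray(pts)

    def test_perfect_lattice_exact_fit(self):
        grid = fit_reference_grid(self._lattice())
        assert grid.residual_rms_um == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.norm(grid.a1) == pytest.approx(4.0, abs=1e-9)
        assert np.linalg.norm(grid.a2) == pytest.approx(4.0, abs=1e-9)

    def test_rotation_recovered_with_excluded_outliers(self):
        rng = np.random.default_rng(3)
        pts = self._lattice(rotation_deg=13.0)
        n = len(pts)
        perturbed = rng.choice(n, size=int(0.3 * n), replace=False)
        pts2 = pts.copy()
        pts2[perturbed] += rng.normal(0, 0.8, (len(perturbed), 2))
        exclude = np.zeros(n, dtype=bool)
        exclude[perturbed] = True
        grid = fit_reference_grid(pts2, exclude=exclude)
        assert grid.rotation_deg == pytest.approx(13.0, abs=0.5)

    def test_noisy_lattice_pitch_within_1pct(self):
        rng = np.random.default_rng(4)
        pts = self._lattice() + rng.normal(0, 0.05, (100, 2))
        grid = fit_reference_grid(pts)
        assert grid.pitch_um == pytest.approx(4.0, rel=0.01)

    def test_few_free_pillars_falls_back_with_warning(self):
        pts = self._lattice(n=5)
        exclude = np.ones(len(pts), dtype=bool)
        exclude[:5] = False
        with pytest.warns(UserWarning):
            grid = fit_reference_grid(pts, exclude=exclude)
        assert grid.pitch_um == pytest.approx(4.0, rel=0.01)

    def test_grid_rotation_equivariance(self):
        base = fit_reference_grid(self._lattice())
        rot = fit_reference_grid(self._lattice(rotation_deg=20.0))
        assert rot.rotation_deg == pytest.approx(base.rotation_deg + 20.0,
                                                 abs=0.01)
        assert rot.pitch_um == pytest.approx(base.pitch_um, rel=1e-6)


class TestDeflections:
    def _grid(self):
        return tfm.PillarGrid(
            origin=np.zeros(2),
            a1=np.array([4.0, 0.0]),
            a2=np.array([2.0, 2.0 * math.sqrt(3.0)]),
        )

    def test_on_lattice_zero_force(self):
        res = compute_deflections(np.array([[8.0, 0.0]]), self._grid(), 65.8)
        assert res["force_mag_nN"][0] == pytest.approx(0.0, abs=1e-9)

    def test_half_micron_deflection_printed_force(self):
        res = compute_deflections(np.array([[4.5, 0.0]]), self._grid(), 65.8)
        assert res["force_mag_nN"][0] == pytest.approx(32.9)

    def test_oversized_deflection_flagged(self):
        res = compute_deflections(np.array([[4.0 + 2.5, 0.0]]), self._grid(),
                                  65.8, indices=np.array([[1, 0]]))
        assert not res["valid"][0]

    def test_force_linearity(self):
        pts = np.array([[4.3, 0.2], [8.1, -0.4]])
        r1 = compute_deflections(pts, self._grid(), 65.8)
        r2 = compute_deflections(pts, self._grid(), 131.6)
        assert np.allclose(2.0 * r1["force_mag_nN"], r2["force_mag_nN"])


class TestTracking:
    def test_static_detections_fully_tracked(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        tracks = track_pillars([pts] * 10)
        assert len(tracks) == 3
        assert all(tr.n_frames == 10 for tr in tracks)

    def test_gate_prevents_swaps(self):
        # two pillars 1.5 um apart; both drift 0.4 um: assignment keeps order
        a = np.array([[0.0, 0.0], [1.5, 0.0]])
        b = a + [0.4, 0.0]
        tracks = track_pillars([a, b])
        assert len(tracks) == 2
        for tr, x0 in zip(tracks, [0.0, 1.5]):
            assert tr.x_um == pytest.approx([x0, x0 + 0.4])

    def test_gap_closing_bridges_single_miss(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0]])
        middle = np.array([[4.0, 0.0]])  # first pillar missing in frame 1
        tracks = track_pillars([pts, middle, pts])
        spans = sorted(tr.frames for tr in tracks)
        assert [0, 1, 2] in spans and [0, 2] in spans

    def test_conservation_no_double_assignment(self, small_pillar_movie):
        mv = small_pillar_movie
        detections = [detect_pillars(f) for f in mv.pillar_movie[:10]]
        tracks = track_pillars(detections)
        for t in range(10):
            used = [
                (tr.pillar_id, i)
                for tr in tracks
                for i, f in enumerate(tr.frames) if f == t
            ]
            per_track = [tr for tr, _ in used]
            assert len(per_track) == len(set(per_track))
            assert len(used) == len(detections[t])

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            track_pillars([np.zeros((3, 2))])

    def test_two_percent_misses_over_90pct_full_length(self):
        cfg = synthetic.PillarSimConfig(
            n_pillars=150, n_frames=40, ou_sd_um=0.3, ou_tau_min=30.0,
            detection_noise_um=0.05, miss_rate=0.02, seed=21,
        )
        mv = synthetic.generate_pillar_movie(cfg)
        detections = [detect_pillars(f) for f in mv.pillar_movie]
        tracks = track_pillars(detections)
        full = [tr for tr in tracks if tr.spans(cfg.n_frames)]
        assert len(full) / len(mv.pillars) > 0.90


class TestCellMaskAndSelection:
    def test_blank_frame_empty_mask(self):
        rng = np.random.default_rng(0)
        blank = synthetic._apply_noise(np.zeros((100, 100)), 20.0, rng)
        assert not segment_cell_mask(blank).any()

    def test_footprint_iou(self, small_pillar_movie):
        mv = small_pillar_movie
        mask = segment_cell_mask(mv.actin_movie[0])
        gt = mv.footprint_mask
        iou = (mask & gt).sum() / (mask | gt).sum()
        assert iou >= 0.8

    def test_two_cells_two_components(self):
        img = np.zeros((220, 220))
        synthetic._add_disc(img, 60, 60, 35, 3, 1.0)
        synthetic._add_disc(img, 160, 160, 30, 3, 1.0)
        noisy = synthetic._apply_noise(img, 20.0, np.random.default_rng(3))
        from scipy import ndimage
        _, n = ndimage.label(segment_cell_mask(noisy, min_area_px=200))
        assert n == 2

    def _tracks_with_deflections(self, mags, n_frames=10):
        out = []
        for i, m in enumerate(mags):
            tr = tfm.PillarTrack(pillar_id=i)
            tr.frames = list(range(n_frames))
            tr.x_um = [5.0] * n_frames
            tr.y_um = [5.0] * n_frames
            tr.deflection_um = np.full((n_frames, 2), m / math.sqrt(2.0))
            tr.force_mag_nN = np.full(n_frames, m * 65.8)
            out.append(tr)
        return out

    def test_fraction_one_selects_all_coupled(self):
        tracks = self._tracks_with_deflections([0.1, 0.2, 0.3])
        sel = select_top_deflected(tracks, None, fraction=1.0)
        assert len(sel) == 3

    def test_top_5pct_of_40_is_2(self):
        tracks = self._tracks_with_deflections(np.linspace(0.05, 0.5, 40))
        sel = select_top_deflected(tracks, None, fraction=0.05)
        assert len(sel) == 2

    def test_planted_high_deflectors_selected(self):
        rng = np.random.default_rng(5)
        mags = list(rng.uniform(0.02, 0.1, 97)) + [0.6, 0.7, 0.8]
        tracks = self._tracks_with_deflections(mags)
        sel = select_top_deflected(tracks, None, fraction=0.05)
        assert len(sel) == 5
        assert {97, 98, 99} <= {tr.pillar_id for tr in sel}

    def test_no_coupled_pillars_warns(self):
        tracks = self._tracks_with_deflections([0.1])
        mask = np.zeros((100, 100), dtype=bool)  # nothing under the cell
        with pytest.warns(UserWarning):
            sel = select_top_deflected(tracks, mask)
        assert sel == []


class TestForceSummaries:
    def _track(self, forces, frames=None):
        tr = tfm.PillarTrack(pillar_id=0)
        tr.frames = frames or list(range(len(forces)))
        tr.x_um = [0.0] * len(tr.frames)
        tr.y_um = [0.0] * len(tr.frames)
        tr.force_mag_nN = np.asarray(forces, dtype=float)
        return tr

    def test_constant_force_constant_series(self):
        tr = self._track([7.0] * 5)
        out = force_timeseries_summary([tr], 5)
        assert np.allclose(out["mean_force_per_frame"], 7.0)
        assert np.allclose(out["force_values"], 7.0)

    def test_two_pillar_mean(self):
        a, b = self._track([10.0] * 4), self._track([30.0] * 4)
        b.pillar_id = 1
        out = force_timeseries_summary([a, b], 4)
        assert np.allclose(out["mean_force_per_frame"], 20.0)
        assert sorted(out["per_pillar_mean_force"]) == [10.0, 30.0]

    def test_time_mean_matches_ground_truth(self, small_pillar_movie):
        mv = small_pillar_movie
        res = tfm.analyze_pillar_movie(mv.pillar_movie, mv.actin_movie)
        tree = cKDTree(mv.pillars[["x0_um", "y0_um"]].to_numpy())
        for tr in res["selected"]:
            _, pid = tree.query([np.mean(tr.x_um), np.mean(tr.y_um)])
            gt = np.linalg.norm(mv.deflections[:, pid, :], axis=1) * 65.8
            assert np.mean(tr.force_mag_nN) == pytest.approx(np.mean(gt), rel=0.05)


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(0)
        series = [rng.normal(10.0, 2.0, 40) for _ in range(5)]
        fit = force_autocorrelation(series, 5.0)
        assert fit.mean_autocorr[0] == pytest.approx(1.0)

    def test_window_holds_25_points_at_5min(self):
        rng = np.random.default_rng(1)
        series = [rng.normal(10.0, 2.0, 30) for _ in range(3)]
        fit = force_autocorrelation(series, 5.0, fit_window_min=120.0)
        assert len(fit.lags_min) == 25
        assert fit.lags_min[-1] == 120.0

    def test_noise_free_exponential_recovers_22min_exactly(self):
        lags = np.arange(25) * 5.0
        values = np.exp(-lags * math.log(2.0) / 22.0)
        a, lam, c, sse = fit_exponential_decay(lags, values)
        assert math.log(2.0) / lam == pytest.approx(22.0, rel=1e-6)
        assert a == pytest.approx(1.0, rel=1e-6)
        assert c == pytest.approx(0.0, abs=1e-6)

    def test_zero_variance_series_excluded(self):
        rng = np.random.default_rng(2)
        series = [np.full(30, 5.0), rng.normal(10.0, 2.0, 30)]
        with pytest.warns(UserWarning):
            fit = force_autocorrelation(series, 5.0)
        assert fit.n_series == 1
        with pytest.raises(ValueError):
            force_autocorrelation([np.full(30, 5.0)], 5.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            force_autocorrelation([np.ones(10)], 5.0, fit_window_min=120.0)

    def test_ou_halftime_within_25pct_of_closed_form(self):
        # mean fitted half-time over replicates vs tau*ln2 for a scalar
        # exponentially correlated force series
        rng = np.random.default_rng(3)
        target = 40.0 * math.log(2.0)
        estimates = []
        for _ in range(20):
            s = synthetic._ou_series(rng, 80, 20, sd=5.0, tau=40.0, dt=5.0) + 20.0
            fit = force_autocorrelation([s[:, i] for i in range(20)], 5.0)
            estimates.append(fit.halftime_min)
        assert np.mean(estimates) == pytest.approx(target, rel=0.25)


class TestComparisons:
    def _fit(self, halftime, noise_sd, rng):
        lags = np.arange(25) * 5.0
        y = np.exp(-lags * math.log(2.0) / halftime) + rng.normal(0, noise_sd, 25)
        a, lam, c, sse = fit_exponential_decay(lags, y)
        return AutocorrFit(lags, y, a, lam, c, math.log(2.0) / lam, sse, 1)

    def test_identical_fits_null(self):
        rng = np.random.default_rng(0)
        f = self._fit(22.0, 0.03, rng)
        out = compare_halftimes(f, f)
        assert out["f_stat"] == pytest.approx(0.0, abs=1e-6)
        assert out["p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_22_vs_45_min_distinguished(self):
        rng = np.random.default_rng(1)
        out = compare_halftimes(self._fit(22.0, 0.05, rng),
                                self._fit(45.0, 0.05, rng))
        assert out["p_value"] < 0.05

    def test_f_test_type_i_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(200):
            out = compare_halftimes(self._fit(22.0, 0.05, rng),
                                    self._fit(22.0, 0.05, rng))
            rejections += out["p_value"] < 0.05
        assert 0.02 <= rejections / 200 <= 0.09

    def test_welch_identical_groups_null(self):
        a = np.array([10.0, 11.0, 12.0, 13.0])
        out = compare_forces(a, a)
        assert out["p_value"] == pytest.approx(1.0)

    def test_welch_shifted_groups_vs_permutation_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(20.0, 3.0, 15)
        b = rng.normal(30.0, 5.0, 15)
        out = compare_forces(a, b)
        assert out["p_value"] < 0.05
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = sum(
            abs(p[:15].mean() - p[15:].mean()) >= obs
            for p in (rng.permutation(pooled) for _ in range(5000))
        )
        assert count / 5000 < 0.05

    def test_welch_antisymmetric(self):
        rng = np.random.default_rng(3)
        a = rng.normal(20.0, 3.0, 10)
        b = rng.normal(25.0, 4.0, 10)
        assert compare_forces(a, b)["t_stat"] == pytest.approx(
            -compare_forces(b, a)["t_stat"]
        )

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError):
            compare_forces([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestEndToEnd:
    def test_scaling_deflections_scales_forces_not_halftime(self, small_pillar_movie):
        mv = small_pillar_movie
        res = tfm.analyze_pillar_movie(mv.pillar_movie, mv.actin_movie)
        spec2 = PillarSpec(
            bending_stiffness_nN_um=131.6,
            effective_young_kPa=effective_young_modulus(131.6, 1.0),
        )
        res2 = tfm.analyze_pillar_movie(mv.pillar_movie, mv.actin_movie, spec=spec2)
        f1 = res["summary"]["per_pillar_mean_force"]
        f2 = res2["summary"]["per_pillar_mean_force"]
        assert np.allclose(np.sort(f2), 2.0 * np.sort(f1), rtol=1e-6)
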