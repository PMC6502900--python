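"""Ridge tracing: smoothing, picking, clustering (vs an exhaustive oracle),
ridge building, raw mapping, and full-procedure recovery."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from civmtrace.errors import EmptyResultError, SpecValidationError
from civmtrace.ridge_tracing import (
    Ridge,
    RidgePoint,
    TraceConfig,
    cluster_peak_points,
    gaussian_smooth_2d,
    map_ridge_to_raw,
    mark_ridges,
    pick_local_maxima,
    ridges_from_clusters,
    trace_region,
)
from civmtrace.synthetic import (
    Constant,
    LinearDrift,
    SigmoidDrift,
    SyntheticPeakSpec,
    SyntheticSeriesSpec,
    simulate_series,
)

from conftest import make_series
from oracles import (
    canonical_partition,
    gaussian_smooth_dense,
    minmax_weighted,
    single_linkage_labels,
)


class TestTraceConfigValidation:
    def test_requires_exactly_one_cut_mode(self):
        with pytest.raises(SpecValidationError):
            TraceConfig(region=(1.0, 2.0))
        with pytest.raises(SpecValidationError):
            TraceConfig(region=(1.0, 2.0), n_clusters=2, linkage_cut=0.1)
        TraceConfig(region=(1.0, 2.0), n_clusters=2)  # ok

    def test_rejects_bad_fields(self):
        with pytest.raises(SpecValidationError):
            TraceConfig(region=(2.0, 1.0), n_clusters=1)
        with pytest.raises(SpecValidationError):
            TraceConfig(region=(1.0, 2.0), n_clusters=1, sigma_ppm=0.0)
        with pytest.raises(SpecValidationError):
            TraceConfig(region=(1.0, 2.0), n_clusters=1, weights=(0, 0, 0))
        with pytest.raises(SpecValidationError):
            TraceConfig(region=(1.0, 2.0), n_clusters=1, map_window_indices=61)


class TestGaussianSmooth:
    def test_constant_matrix_unchanged(self):
        s = make_series(np.full((6, 200), 3.7))
        sm, _ = gaussian_smooth_2d(s, (0.0, 1.5), sigma_ppm=0.01, sigma_time=0.2)
        assert np.allclose(sm.intensities, 3.7)

    def test_impulse_matches_dense_convolution_oracle(self):
        mat = np.zeros((21, 61))
        mat[10, 30] = 1.0
        s = make_series(mat, ppm_lo=0.0, ppm_hi=1.0, dt_h=0.1)
        sigma_ppm, sigma_time = 0.05, 0.25
        sm, _ = gaussian_smooth_2d(s, (0.0, 1.0), sigma_ppm, sigma_time)
        step_p = abs(s.ppm_axis[1] - s.ppm_axis[0])
        oracle = gaussian_smooth_dense(
            mat, (sigma_time / 0.1, sigma_ppm / step_p))
        assert np.allclose(sm.intensities, oracle, atol=1e-12)
        # kernel is unit-sum: total intensity preserved within truncation error
        assert sm.intensities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_tiny_sigma_is_near_identity(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(size=(5, 100))
        s = make_series(mat, ppm_lo=0.0, ppm_hi=1.0)
        step = abs(s.ppm_axis[1] - s.ppm_axis[0])
        sm, _ = gaussian_smooth_2d(s, (0.0, 1.0), sigma_ppm=step * 1e-3,
                                   sigma_time=1e-4)
        assert np.allclose(sm.intensities, mat, atol=1e-8)

    def test_empty_region_errors(self):
        s = make_series(np.ones((2, 50)))
        with pytest.raises(EmptyResultError):
            gaussian_smooth_2d(s, (50.0, 51.0), 0.01, 0.1)


class TestPickLocalMaxima:
    def _one_peak_series(self, n_times=5):
        spec = SyntheticSeriesSpec(
            peaks=(SyntheticPeakSpec(name="p", center=Constant(1.0),
                                     amplitude=Constant(5.0), fwhm_ppm=0.02),),
            ppm_min=0.0, ppm_max=2.0, ppm_step=1e-3,
            duration_h=n_times * 4.23 / 60 - 1e-6, dss_amplitude=0.0)
        return simulate_series(spec)[0]

    def test_single_lorentzian_one_candidate_per_timepoint(self):
        s = self._one_peak_series()
        pts = pick_local_maxima(s, peak_floor=0.1)
        assert len(pts) == s.n_times
        for p in pts:
            assert s.ppm_axis[p.ppm_index] == pytest.approx(1.0, abs=1e-3)

    def test_floor_above_max_gives_empty(self):
        s = self._one_peak_series()
        assert pick_local_maxima(s, peak_floor=100.0) == []

    def test_two_separated_peaks_two_candidates(self):
        spec = SyntheticSeriesSpec(
            peaks=(
                SyntheticPeakSpec(name="a", center=Constant(0.5),
                                  amplitude=Constant(5.0), fwhm_ppm=0.02),
                SyntheticPeakSpec(name="b", center=Constant(1.5),
                                  amplitude=Constant(3.0), fwhm_ppm=0.02),
            ),
            ppm_min=0.0, ppm_max=2.0, ppm_step=1e-3,
            duration_h=3 * 4.23 / 60, dss_amplitude=0.0)
        s, _ = simulate_series(spec)
        pts = pick_local_maxima(s, peak_floor=0.5)
        per_t = {}
        for p in pts:
            per_t.setdefault(p.time_index, []).append(p.ppm)
        assert all(len(v) == 2 for v in per_t.values())

    def test_edge_columns_never_picked(self):
        mat = np.zeros((2, 10))
        mat[:, 0] = 5.0
        mat[:, -1] = 5.0
        s = make_series(mat)
        assert pick_local_maxima(s, 0.0) == []

    def test_col_offset_applied(self):
        s = self._one_peak_series(n_times=1)
        pts = pick_local_maxima(s, 0.1, col_offset=100)
        assert pts[0].ppm_index == s.index_of_ppm(pts[0].ppm) + 100


def _random_points(rng, n):
    ppm = rng.uniform(0.0, 1.0, n)
    th = rng.uniform(0.0, 11.0, n)
    inten = rng.uniform(0.0, 5.0, n)
    return [
        RidgePoint(time_index=i, time_h=th[i], ppm_index=i, ppm=ppm[i],
                   smoothed_intensity=inten[i])
        for i in range(n)
    ], np.stack([ppm, th, inten], axis=1)


class TestClustering:
    def test_one_cluster_one_label(self):
        pts, _ = _random_points(np.random.default_rng(0), 20)
        labels = cluster_peak_points(pts, (1, 1, 0.3), n_clusters=1)
        assert set(labels) == {0}

    def test_matches_exhaustive_oracle_on_random_instances(self):
        """Weighted single-linkage labels equal those of an exhaustive
        pairwise-merge implementation on seeded random instances."""
        rng = np.random.default_rng(1234)
        for _ in range(50):
            n = int(rng.integers(5, 120))
            k = int(rng.integers(1, min(8, n) + 1))
            pts, feats = _random_points(rng, n)
            w = (1.0, 1.0, 0.3)
            labels = cluster_peak_points(pts, w, n_clusters=k)
            oracle = single_linkage_labels(minmax_weighted(feats, w), k)
            assert canonical_partition(labels) == canonical_partition(oracle)

    def test_two_drifting_traces_separate_cleanly(self):
        # two traces 0.5 ppm apart, within-trace spacing ~0.003 ppm
        rng = np.random.default_rng(5)
        pts = []
        for trace_id, base in enumerate([1.0, 1.5]):
            for i in range(40):
                pts.append(RidgePoint(
                    time_index=i, time_h=i * 0.2, ppm_index=i,
                    ppm=base + 0.003 * i / 40 + rng.normal(0, 1e-4),
                    smoothed_intensity=3.0 + rng.normal(0, 0.05)))
        labels = cluster_peak_points(pts, (1.0, 0.2, 0.1), n_clusters=2)
        first, second = labels[:40], labels[40:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert set(first) != set(second)

    def test_zero_intensity_weight_invariance(self):
        pts, _ = _random_points(np.random.default_rng(3), 30)
        labels_a = cluster_peak_points(pts, (1, 1, 0), n_clusters=3)
        scaled = [
            RidgePoint(p.time_index, p.time_h, p.ppm_index, p.ppm,
                       p.smoothed_intensity * 1e6)
            for p in pts
        ]
        labels_b = cluster_peak_points(scaled, (1, 1, 0), n_clusters=3)
        assert canonical_partition(labels_a) == canonical_partition(labels_b)

    def test_too_many_clusters_errors(self):
        pts, _ = _random_points(np.random.default_rng(4), 5)
        with pytest.raises(SpecValidationError):
            cluster_peak_points(pts, (1, 1, 0.3), n_clusters=6)


class TestRidgesFromClusters:
    def _series(self, n_times=5, n_points=101):
        return make_series(np.zeros((n_times, n_points)), ppm_lo=0.0,
                           ppm_hi=2.0, dt_h=1.0)

    def test_duplicate_time_keeps_highest(self):
        s = self._series()
        pts = [
            RidgePoint(0, 0.0, 10, 1.0, 5.0),
            RidgePoint(0, 0.0, 12, 1.04, 7.0),
        ]
        (ridge,) = ridges_from_clusters(pts, np.zeros(2, dtype=int), s)
        assert len(ridge.points) == 1
        assert ridge.points[0].smoothed_intensity == 7.0

    def test_tie_broken_toward_higher_ppm(self):
        s = self._series()
        pts = [
            RidgePoint(0, 0.0, 10, 1.0, 5.0),
            RidgePoint(0, 0.0, 12, 1.04, 5.0),
        ]
        (ridge,) = ridges_from_clusters(pts, np.zeros(2, dtype=int), s)
        assert ridge.points[0].ppm == 1.04

    def test_gap_interpolated_linearly(self):
        s = self._series()
        pts = [
            RidgePoint(1, 1.0, 50, 1.00, 5.0),
            RidgePoint(3, 3.0, 51, 1.02, 5.0),
        ]
        (ridge,) = ridges_from_clusters(pts, np.zeros(2, dtype=int), s)
        assert [p.time_index for p in ridge.points] == [1, 2, 3]
        mid = ridge.points[1]
        assert mid.interpolated
        assert mid.ppm == pytest.approx(1.01)
        assert np.isnan(mid.smoothed_intensity)

    def test_no_extrapolation_before_first_point(self):
        s = self._series()
        pts = [RidgePoint(2, 2.0, 50, 1.0, 5.0), RidgePoint(3, 3.0, 50, 1.0, 5.0)]
        (ridge,) = ridges_from_clusters(pts, np.zeros(2, dtype=int), s)
        assert [p.time_index for p in ridge.points] == [2, 3]

    def test_interior_is_gap_free_for_every_cluster(self):
        rng = np.random.default_rng(11)
        s = self._series(n_times=30)
        pts, labels = [], []
        for lab in range(3):
            for t in sorted(rng.choice(30, size=12, replace=False)):
                pts.append(RidgePoint(int(t), float(t), 50 + lab, 1.0 + lab * 0.02,
                                      rng.uniform(1, 5)))
                labels.append(lab)
        ridges = ridges_from_clusters(pts, np.array(labels), s)
        for r in ridges:
            idx = r.time_indices
            assert np.all(np.diff(idx) == 1)
            assert len(set(idx.tolist())) == len(idx)


class TestMapToRaw:
    def test_window_one_returns_smoothed_position_value(self):
        mat = np.zeros((1, 101))
        mat[0, 50] = 2.0
        mat[0, 52] = 9.0
        s = make_series(mat, ppm_lo=0.0, ppm_hi=1.0)
        ridge = Ridge(id="r", points=[RidgePoint(0, 0.0, 50, float(s.ppm_axis[50]), 1.0)])
        out = map_ridge_to_raw(ridge, s, window_indices=1)
        assert out.points[0].raw_intensity == 2.0
        assert out.points[0].ppm_index == 50

    def test_refines_to_true_maximum_within_window(self):
        mat = np.zeros((1, 101))
        mat[0, 50] = 2.0
        mat[0, 52] = 9.0  # true max 2 indices away
        s = make_series(mat, ppm_lo=0.0, ppm_hi=1.0)
        ridge = Ridge(id="r", points=[RidgePoint(0, 0.0, 50, float(s.ppm_axis[50]), 1.0)])
        out = map_ridge_to_raw(ridge, s, window_indices=10)
        assert out.points[0].ppm_index == 52
        assert out.points[0].raw_intensity == 9.0

    def test_mapping_never_decreases_intensity(self):
        rng = np.random.default_rng(13)
        mat = rng.uniform(size=(4, 101))
        s = make_series(mat, ppm_lo=0.0, ppm_hi=1.0)
        pts = [RidgePoint(t, float(s.times_h[t]), 50, float(s.ppm_axis[50]), 1.0)
               for t in range(4)]
        out = map_ridge_to_raw(Ridge(id="r", points=pts), s, window_indices=10)
        for t, p in enumerate(out.points):
            assert p.raw_intensity >= mat[t, 50]


class TestTraceRegion:
    def _three_peak_series(self):
        spec = SyntheticSeriesSpec(
            peaks=(
                SyntheticPeakSpec(name="a",
                                  center=SigmoidDrift(0.90, 0.92, 5.0, 1.0),
                                  amplitude=Constant(8.0), fwhm_ppm=0.01),
                SyntheticPeakSpec(name="b",
                                  center=LinearDrift(1.20, 1.19, 11.0),
                                  amplitude=Constant(5.0), fwhm_ppm=0.01),
                SyntheticPeakSpec(name="c", center=Constant(1.50),
                                  amplitude=Constant(3.0), fwhm_ppm=0.01),
            ),
            ppm_min=0.5, ppm_max=2.0, ppm_step=2.9e-4,
            duration_h=11.0, dss_amplitude=0.0, noise_sd=0.005, seed=77)
        return simulate_series(spec)

    def test_recovers_three_known_drifting_peaks(self):
        series, truth = self._three_peak_series()
        cfg = TraceConfig(region=(0.7, 1.7), sigma_ppm=0.002, sigma_time=0.3,
                          n_clusters=3, peak_floor=0.5)
        ridges = trace_region(series, cfg)
        assert len(ridges) == 3
        step = series.ppm_step
        matched = set()
        for r in ridges:
            name = min(truth.centers,
                       key=lambda n: abs(np.mean(truth.centers[n]) - r.ppms.mean()))
            matched.add(name)
            tc = np.interp(r.times_h, truth.times_h, truth.centers[name])
            within = np.abs(r.ppms - tc) <= step
            assert within.mean() >= 0.95
        assert matched == {"a", "b", "c"}

    def test_flat_noise_with_high_floor_gives_no_ridges(self):
        rng = np.random.default_rng(21)
        s = make_series(rng.normal(0, 0.01, size=(20, 400)), ppm_lo=0.0, ppm_hi=2.0)
        cfg = TraceConfig(region=(0.2, 1.8), sigma_ppm=0.02, sigma_time=0.2,
                          n_clusters=2, peak_floor=1.0)
        assert trace_region(s, cfg) == []

    def test_deterministic(self):
        series, _ = self._three_peak_series()
        cfg = TraceConfig(region=(0.7, 1.7), sigma_ppm=0.002, sigma_time=0.3,
                          n_clusters=3, peak_floor=0.5)
        a = trace_region(series, cfg)
        b = trace_region(series, cfg)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.ppms, rb.ppms)
            assert np.array_equal(ra.raw_intensities, rb.raw_intensities)

    def test_provenance_snapshot_attached(self):
        series, _ = self._three_peak_series()
        cfg = TraceConfig(region=(0.7, 1.7), sigma_ppm=0.002, sigma_time=0.3,
                          n_clusters=3, peak_floor=0.5)
        ridges = trace_region(series, cfg)
        assert all(r.provenance["region"] == (0.7, 1.7) for r in ridges)

    def test_qc_marking(self):
        series, _ = self._three_peak_series()
        cfg = TraceConfig(region=(0.7, 1.7), sigma_ppm=0.002, sigma_time=0.3,
                          n_clusters=3, peak_floor=0.5)
        ridges = trace_region(series, cfg)
        mark_ridges(ridges, reject=[ridges[0].id])
        assert ridges[0].qc["manually_rejected"]
        assert len(ridges) == 3  # flagged, not deleted
        with pytest.raises(SpecValidationError):
            mark_ridges(ridges, accept=["nope"])
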