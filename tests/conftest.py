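import numpy as np
import pytest

from civmtrace.preprocess import PreprocessConfig, preprocess_pipeline
from civmtrace.ridge_tracing import TraceConfig, trace_region
from civmtrace.series import SpectrumSeries
from civmtrace.synthetic import (
    Constant,
    SyntheticPeakSpec,
    SyntheticSeriesSpec,
    simulate_series,
    standard_fixtures,
)


def make_series(
    intensities: np.ndarray,
    ppm_lo: float = -1.0,
    ppm_hi: float = 2.0,
    dt_h: float = 0.1,
) -> SpectrumSeries:
    """Small hand-rolled series: given a T x P matrix, attach a uniform
    descending ppm axis and uniform time axis."""
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    T, P = intensities.shape
    ppm = np.linspace(ppm_hi, ppm_lo, P)
    times = np.arange(T) * dt_h
    return SpectrumSeries(intensities=intensities, ppm_axis=ppm, times_h=times)


def dss_series(
    n_times: int = 4,
    n_points: int = 2001,
    dss_amp: float = 2.0,
    extra_peaks: tuple = (),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SpectrumSeries:
    """Series with a DSS-like reference at 0 ppm plus optional extra peaks,
    built through the synthetic generator."""
    spec = SyntheticSeriesSpec(
        peaks=tuple(extra_peaks),
        ppm_min=-1.0,
        ppm_max=9.0,
        ppm_step=10.0 / (n_points - 1),
        duration_h=(n_times - 1) * 4.23 / 60.0 + 1e-6,
        spacing_min=4.23,
        dss_amplitude=dss_amp,
        dss_fwhm_ppm=0.02,
        noise_sd=noise_sd,
        seed=seed,
    )
    series, _ = simulate_series(spec)
    return series


@pytest.fixture(scope="session")
def fixtures():
    return standard_fixtures()


@pytest.fixture(scope="session")
def two_peaks_run(fixtures):
    """Simulate, preprocess and trace the two_drifting_peaks fixture once
    for the whole session."""
    spec = fixtures["two_drifting_peaks"]
    series, truth = simulate_series(spec)
    processed = preprocess_pipeline(series, PreprocessConfig(keep_ppm=(-0.5, 1.6)))
    cfg = TraceConfig(
        region=(0.6, 1.4), sigma_ppm=0.002, sigma_time=0.3,
        n_clusters=2, peak_floor=0.05,
    )
    ridges = trace_region(processed, cfg)
    return spec, truth, processed, ridges


@pytest.fixture(scope="session")
def glucose_ethanol_run(fixtures):
    spec = fixtures["glucose_ethanol"]
    series, truth = simulate_series(spec)
    processed = preprocess_pipeline(series, PreprocessConfig(keep_ppm=(-0.5, 5.6)))
    return spec, truth, processed
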