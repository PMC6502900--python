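"""Synthetic CIVM-NMR-like spectral time series with known ground truth.

The generator emulates what the pipeline actually sees after upstream
Fourier processing: a dense ppm axis, a constant DSS reference peak at
0 ppm, drifting Lorentzian/Gaussian analyte peaks whose centers follow
pH-like sigmoidal drifts and whose heights follow logistic
depletion/accumulation trajectories (glucose falling to zero near 6 h,
ethanol rising), an optional polynomial baseline, and additive Gaussian
noise, at ~4-min spacing over ~11 h.

Defaults mirror the acquisition geometry of a typical run: 4.23-min
spacing, 11-h duration, 2.9e-4 ppm/point axis density — so tests exercise
realistic index arithmetic. Peak "amplitude" means height, not area,
consistent with the pipeline's maximum-based quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Literal

import numpy as np

from .errors import SpecValidationError
from .series import SpectrumSeries

__all__ = [
    "Constant",
    "LinearDrift",
    "SigmoidDrift",
    "LogisticGrowth",
    "LogisticDepletion",
    "ExponentialDecay",
    "SampledTrajectory",
    "SyntheticPeakSpec",
    "SyntheticSeriesSpec",
    "GroundTruth",
    "peak_profile",
    "simulate_series",
    "standard_fixtures",
    "synthetic_citrate_titration",
    "spec_from_dict",
    "spec_to_dict",
]


# --------------------------------------------------------------------------
# Trajectory function families
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Constant:
    value: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(t, dtype=float), self.value)


@dataclass(frozen=True)
class LinearDrift:
    """Linear from ``start`` at t=0 to ``end`` at t=duration_h."""

    start: float
    end: float
    duration_h: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.start + (self.end - self.start) * t / self.duration_h


@dataclass(frozen=True)
class SigmoidDrift:
    """Sigmoidal transition from ``start`` to ``end`` centered at
    ``midpoint_h`` with ``steepness`` per hour."""

    start: float
    end: float
    midpoint_h: float
    steepness: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        s = 1.0 / (1.0 + np.exp(-self.steepness * (t - self.midpoint_h)))
        return self.start + (self.end - self.start) * s


@dataclass(frozen=True)
class LogisticGrowth:
    """L / (1 + exp(-k (t - t0))): accumulation reaching plateau L."""

    L: float
    k: float
    t0: float
    floor: float = 0.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.floor + self.L / (1.0 + np.exp(-self.k * (t - self.t0)))


@dataclass(frozen=True)
class LogisticDepletion:
    """L - logistic: starts near L, falls toward ``floor`` around t0
    (e.g. glucose exhausted near 6 h)."""

    L: float
    k: float
    t0: float
    floor: float = 0.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.floor + self.L / (1.0 + np.exp(self.k * (t - self.t0)))


@dataclass(frozen=True)
class ExponentialDecay:
    a0: float
    rate_per_h: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a0 * np.exp(-self.rate_per_h * t)


@dataclass(frozen=True)
class SampledTrajectory:
    """Arbitrary trajectory given as a sampled table, linearly interpolated
    (used e.g. for a peak center driven through a titration curve by a pH
    schedule)."""

    times_h: tuple[float, ...]
    values: tuple[float, ...]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times_h, self.values)


_TRAJECTORY_KINDS = {
    "constant": Constant,
    "linear": LinearDrift,
    "sigmoid": SigmoidDrift,
    "logistic_growth": LogisticGrowth,
    "logistic_depletion": LogisticDepletion,
    "exp_decay": ExponentialDecay,
    "sampled": SampledTrajectory,
}


# --------------------------------------------------------------------------
# Peak and series specs
# --------------------------------------------------------------------------

Lineshape = Literal["lorentzian", "gaussian", "pseudo_voigt"]


@dataclass(frozen=True)
class SyntheticPeakSpec:
    """One simulated resonance.

    ``response_factor`` multiplies the amplitude trajectory, so several
    peaks of one ``compound`` can share a true concentration curve while
    differing in height (different proton counts / lineshapes).
    """

    name: str
    center: Any  # trajectory of ppm position
    amplitude: Any  # trajectory of peak height
    fwhm_ppm: float = 0.01
    lineshape: Lineshape = "lorentzian"
    eta: float = 0.5  # pseudo-Voigt Lorentzian fraction
    compound: str | None = None
    response_factor: float = 1.0

    def validate(self, times: np.ndarray) -> list[str]:
        bad = []
        if self.fwhm_ppm <= 0:
            bad.append(f"{self.name}.fwhm_ppm")
        if self.lineshape not in ("lorentzian", "gaussian", "pseudo_voigt"):
            bad.append(f"{self.name}.lineshape")
        if not (0.0 <= self.eta <= 1.0):
            bad.append(f"{self.name}.eta")
        if self.response_factor <= 0:
            bad.append(f"{self.name}.response_factor")
        if np.any(np.asarray(self.amplitude(times)) < 0):
            bad.append(f"{self.name}.amplitude (negative values)")
        return bad


@dataclass(frozen=True)
class SyntheticSeriesSpec:
    """Declarative description of a simulated spectral time series."""

    peaks: tuple[SyntheticPeakSpec, ...]
    ppm_min: float = -0.5
    ppm_max: float = 10.0
    ppm_step: float = 2.9e-4
    duration_h: float = 11.0
    spacing_min: float = 4.23
    dss_amplitude: float = 1.0
    dss_fwhm_ppm: float = 0.002
    noise_sd: float = 0.0
    baseline_coeffs: tuple[float, ...] = ()
    seed: int = 0

    @property
    def times_h(self) -> np.ndarray:
        n = int(math.floor(self.duration_h * 60.0 / self.spacing_min)) + 1
        return np.arange(n) * self.spacing_min / 60.0

    @property
    def ppm_axis(self) -> np.ndarray:
        """Canonical descending axis covering [ppm_min, ppm_max]."""
        n = int(round((self.ppm_max - self.ppm_min) / self.ppm_step)) + 1
        return self.ppm_max - np.arange(n) * self.ppm_step

    def validate(self) -> None:
        bad = []
        if self.spacing_min <= 0:
            bad.append("spacing_min")
        if self.duration_h <= 0:
            bad.append("duration_h")
        if self.ppm_step <= 0 or self.ppm_min >= self.ppm_max:
            bad.append("ppm_axis")
        elif self.ppm_axis.size < 64:
            bad.append("ppm_axis (fewer than 64 points)")
        if self.noise_sd < 0:
            bad.append("noise_sd")
        if self.dss_amplitude < 0:
            bad.append("dss_amplitude")
        times = self.times_h if self.spacing_min > 0 and self.duration_h > 0 else np.array([0.0])
        for p in self.peaks:
            bad.extend(p.validate(times))
        if bad:
            raise SpecValidationError(f"invalid SyntheticSeriesSpec fields: {bad}", bad)


@dataclass
class GroundTruth:
    """True per-peak centers/heights and per-compound concentration curves,
    aligned with the generated series' time axis."""

    times_h: np.ndarray
    centers: dict[str, np.ndarray]
    amplitudes: dict[str, np.ndarray]
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Lineshapes
# --------------------------------------------------------------------------

def peak_profile(
    lineshape: Lineshape,
    center: float,
    fwhm: float,
    amplitude: float,
    axis: np.ndarray,
    eta: float = 0.5,
) -> np.ndarray:
    """Evaluate a height-normalized lineshape on ``axis``.

    The value at the exact center equals ``amplitude`` (so at the nearest
    axis point it matches within discretization error); the value one
    half-width from center is ``amplitude / 2`` for both pure shapes.
    """
    if fwhm <= 0:
        raise SpecValidationError("fwhm must be > 0", ["fwhm"])
    x = np.asarray(axis, dtype=np.float64) - center
    hwhm = fwhm / 2.0
    lor = hwhm * hwhm / (x * x + hwhm * hwhm)
    if lineshape == "lorentzian":
        shape = lor
    else:
        gau = np.exp(-4.0 * math.log(2.0) * (x * x) / (fwhm * fwhm))
        if lineshape == "gaussian":
            shape = gau
        elif lineshape == "pseudo_voigt":
            shape = eta * lor + (1.0 - eta) * gau
        else:
            raise SpecValidationError(f"unknown lineshape {lineshape!r}", ["lineshape"])
    return amplitude * shape


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def simulate_series(spec: SyntheticSeriesSpec) -> tuple[SpectrumSeries, GroundTruth]:
    """Render a spectral time series and its ground truth.

    Each spectrum is the sum of all peak profiles at that time's true
    centers and heights, plus the constant DSS reference at 0 ppm, an
    optional polynomial baseline, and seeded additive Gaussian noise.
    Identical specs (same seed) produce bitwise-identical output.
    """
    spec.validate()
    times = spec.times_h
    axis = spec.ppm_axis
    T, P = times.size, axis.size

    centers = {p.name: np.asarray(p.center(times), dtype=float) for p in spec.peaks}
    amplitudes = {
        p.name: p.response_factor * np.asarray(p.amplitude(times), dtype=float)
        for p in spec.peaks
    }
    concentrations: dict[str, np.ndarray] = {}
    for p in spec.peaks:
        if p.compound is not None and p.compound not in concentrations:
            concentrations[p.compound] = np.asarray(p.amplitude(times), dtype=float)

    mat = np.zeros((T, P))
    for p in spec.peaks:
        for t in range(T):
            mat[t] += peak_profile(
                p.lineshape, centers[p.name][t], p.fwhm_ppm,
                amplitudes[p.name][t], axis, p.eta,
            )
    if spec.dss_amplitude > 0 and axis.min() <= 0.0 <= axis.max():
        dss = peak_profile("lorentzian", 0.0, spec.dss_fwhm_ppm, spec.dss_amplitude, axis)
        mat += dss[None, :]
    if spec.baseline_coeffs:
        mat += np.polynomial.polynomial.polyval(axis, spec.baseline_coeffs)[None, :]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        mat += rng.normal(0.0, spec.noise_sd, size=(T, P))

    series = SpectrumSeries(
        intensities=mat,
        ppm_axis=axis,
        times_h=times,
        meta={"synthetic": True, "seed": spec.seed},
        history=[f"simulate_series(seed={spec.seed}, n_peaks={len(spec.peaks)})"],
    )
    truth = GroundTruth(
        times_h=times, centers=centers, amplitudes=amplitudes,
        concentrations=concentrations,
    )
    return series, truth


# --------------------------------------------------------------------------
# Fixtures
# --------------------------------------------------------------------------

def synthetic_citrate_titration() -> tuple[np.ndarray, np.ndarray]:
    """SYNTHETIC stand-in for a citrate titration table (pH, peak ppm).

    Points lie on a strictly monotone cubic over pH 4.5–7.5, in the ppm
    neighbourhood of the upfield citrate resonance. This is a constructed
    calibration for testing the mechanism, not measured data.
    """
    ph = np.arange(4.5, 7.5 + 1e-9, 0.25)
    ppm = 2.20 + 0.09 * ph - 0.004 * ph**2 + 0.0002 * ph**3
    return ph, ppm


#: pH schedule used by the "ph_drift_citrate" fixture.
PH_SCHEDULE = SigmoidDrift(start=6.3, end=5.3, midpoint_h=3.0, steepness=1.5)


def _citrate_center_trajectory(times: np.ndarray) -> SampledTrajectory:
    ph_t = PH_SCHEDULE(times)
    coeff_ph, coeff_ppm = synthetic_citrate_titration()
    coeffs = np.polynomial.polynomial.polyfit(coeff_ph, coeff_ppm, 3)
    ppm_t = np.polynomial.polynomial.polyval(ph_t, coeffs)
    return SampledTrajectory(tuple(times), tuple(ppm_t))


def standard_fixtures() -> dict[str, SyntheticSeriesSpec]:
    """Named presets covering the pipeline's test scenarios.

    * ``two_drifting_peaks`` — two well-separated resonances with opposite
      sigmoidal drifts (<= 0.03 ppm over 11 h) and opposite logistic height
      trends; the tracing-recovery testbed.
    * ``glucose_ethanol`` — inverse trajectories: a glucose-like peak
      depleting to near zero around 6 h and an ethanol-like peak rising.
    * ``ph_drift_citrate`` — a citrate-like peak whose drift is driven by a
      known pH schedule through the synthetic titration curve; pH-module
      end-to-end testbed.
    * ``crowded_region`` — two peaks closer than their linewidth: the
      documented overlap failure mode of maximum-based tracing.
    """
    t_grid = (np.arange(157) * 4.23 / 60.0)

    two_drifting = SyntheticSeriesSpec(
        peaks=(
            SyntheticPeakSpec(
                name="A",
                center=SigmoidDrift(1.200, 1.230, midpoint_h=5.0, steepness=1.0),
                amplitude=LogisticDepletion(L=9.5, k=1.5, t0=6.0, floor=0.5),
                fwhm_ppm=0.010,
                compound="A",
            ),
            SyntheticPeakSpec(
                name="B",
                center=SigmoidDrift(0.800, 0.780, midpoint_h=5.0, steepness=1.0),
                amplitude=LogisticGrowth(L=9.5, k=1.5, t0=6.0, floor=0.5),
                fwhm_ppm=0.010,
                compound="B",
            ),
        ),
        ppm_min=-0.5,
        ppm_max=1.6,
        noise_sd=0.025,
        seed=17,
    )

    glucose_ethanol = SyntheticSeriesSpec(
        peaks=(
            SyntheticPeakSpec(
                name="glucose_anomeric",
                center=Constant(5.23),
                amplitude=LogisticDepletion(L=8.0, k=2.0, t0=6.0),
                fwhm_ppm=0.008,
                compound="glucose",
            ),
            SyntheticPeakSpec(
                name="glucose_ring",
                center=Constant(3.40),
                amplitude=LogisticDepletion(L=8.0, k=2.0, t0=6.0),
                fwhm_ppm=0.008,
                compound="glucose",
                response_factor=2.5,
            ),
            SyntheticPeakSpec(
                name="ethanol_ch3",
                center=Constant(1.19),
                amplitude=LogisticGrowth(L=6.0, k=2.0, t0=6.0),
                fwhm_ppm=0.008,
                compound="ethanol",
            ),
        ),
        ppm_min=-0.5,
        ppm_max=5.6,
        noise_sd=0.02,
        seed=23,
    )

    ph_drift = SyntheticSeriesSpec(
        peaks=(
            SyntheticPeakSpec(
                name="citrate_upfield",
                center=_citrate_center_trajectory(t_grid),
                amplitude=Constant(5.0),
                fwhm_ppm=0.006,
                compound="citrate",
            ),
        ),
        ppm_min=-0.5,
        ppm_max=3.2,
        noise_sd=0.0,
        seed=5,
    )

    crowded = SyntheticSeriesSpec(
        peaks=(
            SyntheticPeakSpec(
                name="X1",
                center=Constant(1.000),
                amplitude=LogisticDepletion(L=5.0, k=1.0, t0=5.0, floor=1.0),
                fwhm_ppm=0.012,
            ),
            SyntheticPeakSpec(
                name="X2",
                center=Constant(1.006),
                amplitude=LogisticGrowth(L=5.0, k=1.0, t0=5.0, floor=1.0),
                fwhm_ppm=0.012,
            ),
        ),
        ppm_min=-0.5,
        ppm_max=1.6,
        noise_sd=0.01,
        seed=31,
    )

    return {
        "two_drifting_peaks": two_drifting,
        "glucose_ethanol": glucose_ethanol,
        "ph_drift_citrate": ph_drift,
        "crowded_region": crowded,
    }


# --------------------------------------------------------------------------
# Dict/YAML round trip for CLI use
# --------------------------------------------------------------------------

def _traj_to_dict(traj: Any) -> dict:
    for kind, cls in _TRAJECTORY_KINDS.items():
        if isinstance(traj, cls):
            d = {"kind": kind}
            d.update({k: getattr(traj, k) for k in traj.__dataclass_fields__})
            if kind == "sampled":
                d["times_h"] = list(d["times_h"])
                d["values"] = list(d["values"])
            return d
    raise SpecValidationError(f"unserializable trajectory {type(traj).__name__}")


def _traj_from_dict(d: dict) -> Any:
    kind = d.get("kind")
    if kind not in _TRAJECTORY_KINDS:
        raise SpecValidationError(f"unknown trajectory kind {kind!r}")
    params = {k: v for k, v in d.items() if k != "kind"}
    if kind == "sampled":
        params["times_h"] = tuple(params["times_h"])
        params["values"] = tuple(params["values"])
    return _TRAJECTORY_KINDS[kind](**params)


def spec_to_dict(spec: SyntheticSeriesSpec) -> dict:
    d = {
        k: getattr(spec, k)
        for k in spec.__dataclass_fields__
        if k != "peaks"
    }
    d["baseline_coeffs"] = list(d["baseline_coeffs"])
    d["peaks"] = []
    for p in spec.peaks:
        pd = {k: getattr(p, k) for k in p.__dataclass_fields__}
        pd["center"] = _traj_to_dict(p.center)
        pd["amplitude"] = _traj_to_dict(p.amplitude)
        d["peaks"].append(pd)
    return d


def spec_from_dict(d: dict) -> SyntheticSeriesSpec:
    d = dict(d)
    peaks = []
    for pd in d.pop("peaks", []):
        pd = dict(pd)
        pd["center"] = _traj_from_dict(pd["center"])
        pd["amplitude"] = _traj_from_dict(pd["amplitude"])
        peaks.append(SyntheticPeakSpec(**pd))
    d["peaks"] = tuple(peaks)
    d["baseline_coeffs"] = tuple(d.get("baseline_coeffs", ()))
    return SyntheticSeriesSpec(**d)


def with_overrides(spec: SyntheticSeriesSpec, **changes: Any) -> SyntheticSeriesSpec:
    """Copy of a spec with fields replaced (e.g. ``noise_sd=0`` or a new
    seed) — fixtures stay immutable."""
    return replace(spec, **changes)
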