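"""Chemical-shift-based pH estimation.

pH-sensitive resonances (classically the upfield citrate peak) move
predictably with pH. Calibration measures peak position across a titration,
fits a cubic polynomial ppm = f(pH), and checks that f is strictly monotone
over the calibrated range so it can be inverted uniquely. Applying the
curve to a traced ridge's ppm trajectory yields per-timepoint pH. There is
no extrapolation: positions outside the calibrated span are an error, since
titration behaviour outside the measured range cannot be assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, OutOfRangeError

__all__ = ["TitrationCurve", "fit_titration", "ppm_to_ph", "read_titration_csv"]


@dataclass
class TitrationCurve:
    """Cubic chemical-shift-vs-pH calibration.

    ``coeffs`` are ascending-power coefficients (a0..a3) of
    ppm = a0 + a1*pH + a2*pH^2 + a3*pH^3; the polynomial is strictly
    monotone over ``ph_range``.
    """

    ph: np.ndarray
    ppm: np.ndarray
    coeffs: np.ndarray
    r_squared: float
    ph_range: tuple[float, float]

    def predict(self, ph: np.ndarray | float) -> np.ndarray | float:
        """ppm at the given pH value(s)."""
        return np.polynomial.polynomial.polyval(ph, self.coeffs)

    @property
    def ppm_span(self) -> tuple[float, float]:
        lo, hi = self.ph_range
        ends = sorted((float(self.predict(lo)), float(self.predict(hi))))
        return (ends[0], ends[1])


def _check_monotone(coeffs: np.ndarray, ph_range: tuple[float, float]) -> None:
    """Strict monotonicity of the cubic over ph_range via its derivative's
    sign: the quadratic derivative must not change sign (and never vanish
    on an interval) inside the range."""
    deriv = np.polynomial.polynomial.polyder(coeffs)
    grid = np.linspace(ph_range[0], ph_range[1], 512)
    d = np.polynomial.polynomial.polyval(grid, deriv)
    if np.all(d > 0) or np.all(d < 0):
        return
    raise CalibrationError(
        "fitted cubic is not strictly monotone over the calibrated pH range; "
        "the curve cannot be inverted uniquely"
    )


def fit_titration(ph: np.ndarray, ppm: np.ndarray) -> TitrationCurve:
    """Least-squares cubic fit of peak position on pH.

    Requires at least 4 distinct pH values. Reports R^2 = 1 - SS_res/SS_tot
    and verifies strict monotonicity over [min(pH), max(pH)].
    """
    ph = np.asarray(ph, dtype=np.float64)
    ppm = np.asarray(ppm, dtype=np.float64)
    if ph.shape != ppm.shape or ph.ndim != 1:
        raise CalibrationError("ph and ppm must be equal-length vectors")
    if np.unique(ph).size < 4:
        raise CalibrationError("need at least 4 distinct pH points for a cubic fit")
    coeffs = np.polynomial.polynomial.polyfit(ph, ppm, 3)
    fitted = np.polynomial.polynomial.polyval(ph, coeffs)
    ss_res = float(np.sum((ppm - fitted) ** 2))
    ss_tot = float(np.sum((ppm - ppm.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    ph_range = (float(ph.min()), float(ph.max()))
    _check_monotone(coeffs, ph_range)
    return TitrationCurve(
        ph=ph, ppm=ppm, coeffs=coeffs, r_squared=r2, ph_range=ph_range
    )


def ppm_to_ph(
    curve: TitrationCurve, ppm_trajectory: np.ndarray, tol: float = 1e-6
) -> np.ndarray:
    """Invert the calibration for each element of ``ppm_trajectory``.

    Monotonicity guarantees a unique root of f(x) = ppm on ``ph_range``;
    it is bracketed and found by Brent's method to ``tol`` in pH.

    Raises
    ------
    OutOfRangeError
        Naming the first offending timepoint when a ppm lies outside the
        calibrated span (no extrapolation).
    """
    traj = np.atleast_1d(np.asarray(ppm_trajectory, dtype=np.float64))
    lo, hi = curve.ph_range
    span_lo, span_hi = curve.ppm_span
    # tolerate float round-off at the span edges
    eps = 1e-12 * max(1.0, abs(span_hi))
    out = np.empty_like(traj)
    for i, target in enumerate(traj):
        if target < span_lo - eps or target > span_hi + eps:
            raise OutOfRangeError(
                f"ppm {target:.6g} at timepoint {i} outside calibrated span "
                f"[{span_lo:.6g}, {span_hi:.6g}]",
                timepoint=i,
            )
        clipped = float(np.clip(target, span_lo, span_hi))
        f = lambda x: float(curve.predict(x)) - clipped
        flo, fhi = f(lo), f(hi)
        if flo == 0.0:
            out[i] = lo
        elif fhi == 0.0:
            out[i] = hi
        else:
            out[i] = brentq(f, lo, hi, xtol=tol)
    return out


def read_titration_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (pH, ppm) calibration table."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "ph" in cols and "ppm" in cols:
        return df[cols["ph"]].to_numpy(float), df[cols["ppm"]].to_numpy(float)
    if df.shape[1] >= 2:
        return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    raise CalibrationError(f"{path}: expected columns (pH, ppm)")
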