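"""Core containers: acquisition metadata and the spectral time-series matrix.

A :class:`SpectrumSeries` is the object every pipeline stage consumes and
returns: a ``T x P`` real intensity matrix with a shared ppm axis (stored
descending, the standard NMR display order) and a strictly increasing time
axis in hours. Transforms never mutate in place; each returns a new series
with one entry appended to ``history``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from .errors import SpecValidationError

__all__ = ["AcquisitionRecord", "SpectrumSeries"]


@dataclass(frozen=True)
class AcquisitionRecord:
    """Per-spectrum acquisition metadata pulled from Bruker acqus parameters.

    ``start_clock`` is an absolute timestamp in seconds since the epoch;
    durations are seconds, the pulse width is microseconds. Optional fields
    are ``None`` when the source text does not carry them — values are never
    fabricated.
    """

    start_clock: float
    n_scans: int
    n_dummy_scans: int | None = None
    acquisition_time_s: float | None = None
    recycle_delay_s: float | None = None
    pulse_width_us: float | None = None
    offset_ppm: float | None = None
    spin_rate_hz: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise SpecValidationError("n_scans must be >= 1", ["n_scans"])
        for name in ("acquisition_time_s", "recycle_delay_s", "pulse_width_us"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise SpecValidationError(f"{name} must be >= 0", [name])


@dataclass
class SpectrumSeries:
    """T timepoints x P ppm points of real spectral intensities.

    Invariants (enforced by :meth:`validate`, called on construction):

    * ``intensities.shape == (len(times_h), len(ppm_axis))``
    * ``times_h`` strictly increasing
    * ``ppm_axis`` strictly descending (canonical NMR orientation)
    """

    intensities: np.ndarray
    ppm_axis: np.ndarray
    times_h: np.ndarray
    records: list[AcquisitionRecord] | None = None
    meta: dict[str, Any] = field(default_factory=dict)
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=np.float64)
        self.times_h = np.asarray(self.times_h, dtype=np.float64)
        if self.intensities.ndim == 1:
            self.intensities = self.intensities[None, :]
        self.validate()

    def validate(self) -> None:
        T, P = self.intensities.shape
        if self.ppm_axis.shape != (P,):
            raise SpecValidationError(
                f"ppm_axis length {self.ppm_axis.shape} does not match P={P}",
                ["ppm_axis"],
            )
        if self.times_h.shape != (T,):
            raise SpecValidationError(
                f"times_h length {self.times_h.shape} does not match T={T}",
                ["times_h"],
            )
        if T > 1 and not np.all(np.diff(self.times_h) > 0):
            raise SpecValidationError("times_h must be strictly increasing", ["times_h"])
        if P > 1 and not np.all(np.diff(self.ppm_axis) < 0):
            raise SpecValidationError(
                "ppm_axis must be strictly descending (canonical orientation)",
                ["ppm_axis"],
            )
        if self.records is not None and len(self.records) != T:
            raise SpecValidationError("records length must equal T", ["records"])

    # -- convenience ----------------------------------------------------

    @property
    def n_times(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    @property
    def ppm_step(self) -> float:
        """Median absolute spacing of the ppm axis (ppm per index)."""
        if self.n_points < 2:
            return 0.0
        return float(np.median(np.abs(np.diff(self.ppm_axis))))

    def index_of_ppm(self, ppm: float) -> int:
        """Index of the axis point nearest ``ppm``."""
        return int(np.argmin(np.abs(self.ppm_axis - ppm)))

    def window_indices(self, lo: float, hi: float) -> np.ndarray:
        """Column indices with ppm in the closed interval [lo, hi]."""
        lo, hi = min(lo, hi), max(lo, hi)
        return np.nonzero((self.ppm_axis >= lo) & (self.ppm_axis <= hi))[0]

    def with_history(self, entry: str, **changes: Any) -> "SpectrumSeries":
        """Copy of the series with ``changes`` applied and ``entry`` appended
        to the processing history."""
        new = replace(
            self,
            meta=dict(self.meta),
            history=[*self.history, entry],
            **changes,
        )
        return new

    def copy(self) -> "SpectrumSeries":
        return replace(
            self,
            intensities=self.intensities.copy(),
            ppm_axis=self.ppm_axis.copy(),
            times_h=self.times_h.copy(),
            meta=dict(self.meta),
            history=list(self.history),
        )


def canonicalize_orientation(
    ppm: np.ndarray, intensities: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return (ppm, intensities) with the ppm axis descending.

    Accepts a 1-D or 2-D intensity array (columns are the ppm dimension).
    """
    ppm = np.asarray(ppm, dtype=np.float64)
    intensities = np.asarray(intensities, dtype=np.float64)
    if ppm.size > 1 and ppm[0] < ppm[-1]:
        ppm = ppm[::-1].copy()
        intensities = intensities[..., ::-1].copy()
    return ppm, intensities


def mean_of(values: Sequence[float]) -> float:
    return float(np.mean(np.asarray(values, dtype=np.float64)))
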