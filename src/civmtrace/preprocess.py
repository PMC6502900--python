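"""Post-acquisition processing chain for in vivo NMR spectral series.

The chain, in order: reference each spectrum to DSS (0 ppm), trim spectral
ends to the retained ppm interval, zero the residual water region, drop
late timepoints, normalize each spectrum to its DSS peak height, and sum
consecutive blocks of spectra for signal-to-noise. The same module provides
the targeted region-maximum trajectory used for isotope-edited experiments.

All interval endpoints are inclusive. All operations return new series and
append to the processing history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyResultError,
    InsufficientDataError,
    ReferenceNotFoundError,
    SpecValidationError,
)
from .series import AcquisitionRecord, SpectrumSeries

__all__ = [
    "PreprocessConfig",
    "reference_to_dss",
    "trim_ppm",
    "zero_region",
    "truncate_time",
    "normalize_to_reference",
    "block_sum",
    "region_max_trajectory",
    "preprocess_pipeline",
]

#: A window maximum must exceed this multiple of the window's median absolute
#: intensity to count as a detectable reference peak.
REFERENCE_FLOOR_FACTOR = 5.0


@dataclass
class PreprocessConfig:
    """Configuration of the standard processing chain.

    Defaults mirror the usual in vivo protocol: keep [-0.5, 10] ppm, zero
    water at [4.7, 5.0] ppm, drop timepoints after 11 h, search DSS within
    +/-0.25 ppm of 0, and sum every 3 spectra.
    """

    keep_ppm: tuple[float, float] = (-0.5, 10.0)
    water_ppm: tuple[float, float] = (4.7, 5.0)
    max_time_h: float = 11.0
    dss_search_ppm: float = 0.25
    block: int = 3
    #: optional manual per-spectrum index-shift overrides {time_index: shift}
    shift_overrides: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = []
        if self.keep_ppm[0] >= self.keep_ppm[1]:
            bad.append("keep_ppm")
        if self.water_ppm[0] >= self.water_ppm[1]:
            bad.append("water_ppm")
        if self.max_time_h <= 0:
            bad.append("max_time_h")
        if self.dss_search_ppm <= 0:
            bad.append("dss_search_ppm")
        if self.block < 1:
            bad.append("block")
        if bad:
            raise SpecValidationError(f"invalid PreprocessConfig fields: {bad}", bad)


def _reference_window_max(
    series: SpectrumSeries, halfwidth: float, t: int
) -> tuple[int, float]:
    """(full-axis argmax index, max value) of spectrum ``t`` within
    [-halfwidth, +halfwidth] ppm; raises if no detectable peak."""
    cols = series.window_indices(-halfwidth, halfwidth)
    if cols.size == 0:
        raise ReferenceNotFoundError(
            f"reference window +/-{halfwidth} ppm does not overlap the axis", t
        )
    window = series.intensities[t, cols]
    floor = REFERENCE_FLOOR_FACTOR * np.median(np.abs(window))
    mx = float(window.max())
    if mx <= 0 or mx < floor:
        raise ReferenceNotFoundError(
            f"no detectable reference peak at timepoint {t} "
            f"(max {mx:.3g} vs floor {floor:.3g})",
            t,
        )
    return int(cols[int(np.argmax(window))]), mx


def _shift_row(row: np.ndarray, shift: int) -> np.ndarray:
    """Shift a spectrum ``shift`` indices toward higher index, filling
    vacated positions with the nearest edge value (no wrap-around)."""
    if shift == 0:
        return row.copy()
    out = np.empty_like(row)
    if shift > 0:
        out[shift:] = row[:-shift]
        out[:shift] = row[0]
    else:
        out[:shift] = row[-shift:]
        out[shift:] = row[-1]
    return out


def reference_to_dss(
    series: SpectrumSeries,
    search_halfwidth: float = 0.25,
    shift_overrides: dict[int, int] | None = None,
) -> SpectrumSeries:
    """Shift each spectrum by whole axis indices so its DSS maximum sits at
    the axis point nearest 0 ppm.

    Whole-index shifting (no re-interpolation) preserves raw intensities for
    downstream maximum-based quantification. ``shift_overrides`` supplies a
    manual shift for specific timepoints, replacing the automatic one.
    """
    overrides = shift_overrides or {}
    target = series.index_of_ppm(0.0)
    out = series.intensities.copy()
    shifts = []
    for t in range(series.n_times):
        if t in overrides:
            shift = int(overrides[t])
        else:
            argmax, _ = _reference_window_max(series, search_halfwidth, t)
            shift = target - argmax
        out[t] = _shift_row(series.intensities[t], shift)
        shifts.append(shift)
    return series.with_history(
        f"reference_to_dss(hw={search_halfwidth}, shifts={shifts})",
        intensities=out,
    )


def trim_ppm(series: SpectrumSeries, keep: tuple[float, float] = (-0.5, 10.0)) -> SpectrumSeries:
    """Retain only columns whose ppm lies in the closed interval ``keep``."""
    cols = series.window_indices(*keep)
    if cols.size == 0:
        raise EmptyResultError(f"keep interval {keep} does not overlap the ppm axis")
    return series.with_history(
        f"trim_ppm(keep={keep})",
        intensities=series.intensities[:, cols],
        ppm_axis=series.ppm_axis[cols],
    )


def zero_region(series: SpectrumSeries, region: tuple[float, float] = (4.7, 5.0)) -> SpectrumSeries:
    """Replace intensities in the closed ppm ``region`` (e.g. residual water)
    with exact zeros in every spectrum. Empty overlap is a no-op."""
    cols = series.window_indices(*region)
    out = series.intensities.copy()
    out[:, cols] = 0.0
    return series.with_history(f"zero_region(region={region})", intensities=out)


def truncate_time(series: SpectrumSeries, max_h: float = 11.0) -> SpectrumSeries:
    """Drop timepoints later than ``max_h`` hours (inclusive cut)."""
    keep = np.nonzero(series.times_h <= max_h)[0]
    if keep.size == 0:
        raise EmptyResultError(f"no timepoints at or before {max_h} h")
    return series.with_history(
        f"truncate_time(max_h={max_h})",
        intensities=series.intensities[keep],
        times_h=series.times_h[keep],
        records=[series.records[i] for i in keep] if series.records else None,
    )


def normalize_to_reference(
    series: SpectrumSeries, ref_halfwidth: float = 0.25
) -> SpectrumSeries:
    """Divide each spectrum by its own DSS peak height so the reference
    maximum becomes exactly 1.0, enabling relative quantification across
    time and samples."""
    out = series.intensities.copy()
    for t in range(series.n_times):
        _, mx = _reference_window_max(series, ref_halfwidth, t)
        out[t] = out[t] / mx
    return series.with_history(
        f"normalize_to_reference(hw={ref_halfwidth})", intensities=out
    )


def _summarize_records(records: list[AcquisitionRecord]) -> AcquisitionRecord:
    return AcquisitionRecord(
        start_clock=records[0].start_clock,
        n_scans=sum(r.n_scans for r in records),
        n_dummy_scans=records[0].n_dummy_scans,
        acquisition_time_s=records[0].acquisition_time_s,
        recycle_delay_s=records[0].recycle_delay_s,
        pulse_width_us=records[0].pulse_width_us,
        offset_ppm=records[0].offset_ppm,
        spin_rate_hz=records[0].spin_rate_hz,
        label=f"block[{records[0].label}x{len(records)}]",
    )


def block_sum(series: SpectrumSeries, block: int = 3) -> SpectrumSeries:
    """Sum consecutive non-overlapping blocks of ``block`` spectra.

    The trailing incomplete block is dropped; each output time is the mean
    of its constituent times; records are replaced by per-block summaries
    (scan counts summed).
    """
    if block < 1:
        raise SpecValidationError("block must be >= 1", ["block"])
    T = series.n_times
    if T < block:
        raise InsufficientDataError(f"need at least {block} timepoints, have {T}")
    n_out = T // block
    used = n_out * block
    mat = series.intensities[:used].reshape(n_out, block, series.n_points).sum(axis=1)
    times = series.times_h[:used].reshape(n_out, block).mean(axis=1)
    records = None
    if series.records is not None:
        records = [
            _summarize_records(series.records[i * block : (i + 1) * block])
            for i in range(n_out)
        ]
    return series.with_history(
        f"block_sum(block={block}, dropped={T - used})",
        intensities=mat,
        times_h=times,
        records=records,
    )


def region_max_trajectory(
    series: SpectrumSeries, region: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Raw maximum spectral intensity within ``region`` at each timepoint.

    Returns ``(values, argmax_ppm)``: the per-timepoint maximum and the ppm
    where it occurs. This is the targeted quantification used when a peak's
    position is known a priori (e.g. isotope-edited methyl resonances).
    """
    cols = series.window_indices(*region)
    if cols.size == 0:
        raise EmptyResultError(f"region {region} does not overlap the ppm axis")
    sub = series.intensities[:, cols]
    arg = np.argmax(sub, axis=1)
    values = sub[np.arange(series.n_times), arg]
    return values, series.ppm_axis[cols[arg]]


def preprocess_pipeline(series: SpectrumSeries, cfg: PreprocessConfig | None = None) -> SpectrumSeries:
    """Apply the full chain in the canonical order: reference -> trim ->
    zero water -> truncate time -> normalize -> block-sum."""
    cfg = cfg or PreprocessConfig()
    s = reference_to_dss(series, cfg.dss_search_ppm, cfg.shift_overrides)
    s = trim_ppm(s, cfg.keep_ppm)
    s = zero_region(s, cfg.water_ppm)
    s = truncate_time(s, cfg.max_time_h)
    s = normalize_to_reference(s, cfg.dss_search_ppm)
    s = block_sum(s, cfg.block)
    return s
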