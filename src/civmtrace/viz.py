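"""Static visualization of spectral series and traced ridges.

Two figure styles: the *mirror plot* (one condition upright, the other
vertically inverted on a shared, reversed ppm axis, for direct visual
comparison) and the ridge overlay (stacked spectra with traced ridge
polylines). All exports are static files; ppm increases right-to-left per
NMR convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import EmptyResultError, SpecValidationError
from .ridge_tracing import Ridge
from .series import SpectrumSeries

__all__ = ["mirror_plot", "ridge_overlay_plot"]


def mirror_plot(
    series_a: SpectrumSeries,
    series_b: SpectrumSeries,
    times: Sequence[int],
    path: str | Path,
    labels: tuple[str, str] = ("A", "B"),
) -> Path:
    """Render ``series_a`` upright and ``series_b`` inverted on a shared
    reversed ppm axis for the selected timepoint indices.

    Both series must cover overlapping ppm ranges; an empty time selection
    is an error.
    """
    times = list(times)
    if not times:
        raise EmptyResultError("empty timepoint selection")
    lo = max(series_a.ppm_axis.min(), series_b.ppm_axis.min())
    hi = min(series_a.ppm_axis.max(), series_b.ppm_axis.max())
    if lo >= hi:
        raise SpecValidationError("series ppm ranges do not overlap")
    for t in times:
        if t >= series_a.n_times or t >= series_b.n_times:
            raise SpecValidationError(f"timepoint index {t} out of range")

    fig, ax = plt.subplots(figsize=(10, 4))
    for i, t in enumerate(times):
        alpha = 0.4 + 0.6 * (i + 1) / len(times)
        ax.plot(series_a.ppm_axis, series_a.intensities[t], color="C3", lw=0.6, alpha=alpha)
        ax.plot(series_b.ppm_axis, -series_b.intensities[t], color="C0", lw=0.6, alpha=alpha)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlim(hi, lo)  # reversed ppm axis, high field left
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel(f"{labels[0]} (up) / {labels[1]} (down), relative intensity")
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def ridge_overlay_plot(
    series: SpectrumSeries,
    ridges: Sequence[Ridge],
    path: str | Path,
    region: tuple[float, float] | None = None,
    stride: int = 1,
) -> Path:
    """Stacked (waterfall) spectra with ridge polylines overlaid.

    Each spectrum is offset proportionally to its time; ridge points are
    drawn at their refined (ppm, intensity + offset) positions. Ridges
    whose indices do not fit the series are an error.
    """
    for r in ridges:
        for p in r.points:
            if not (0 <= p.time_index < series.n_times) or not (
                0 <= p.ppm_index < series.n_points
            ):
                raise SpecValidationError(
                    f"ridge {r.id} references point outside the series"
                )
    if region is not None:
        cols = series.window_indices(*region)
        if cols.size == 0:
            raise EmptyResultError(f"region {region} does not overlap the axis")
    else:
        cols = np.arange(series.n_points)

    span = float(np.ptp(series.intensities[:, cols])) or 1.0
    offset_step = 0.15 * span
    fig, ax = plt.subplots(figsize=(9, 6))
    for t in range(0, series.n_times, max(1, stride)):
        ax.plot(
            series.ppm_axis[cols],
            series.intensities[t, cols] + t * offset_step,
            color="0.6",
            lw=0.4,
        )
    for i, r in enumerate(ridges):
        xs = [p.ppm for p in r.points]
        ys = [p.raw_intensity + p.time_index * offset_step for p in r.points]
        ax.plot(xs, ys, color=f"C{i % 10}", lw=1.2, label=r.id)
    if ridges:
        ax.legend(fontsize=7, loc="upper right")
    ax.set_xlim(series.ppm_axis[cols].max(), series.ppm_axis[cols].min())
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("relative intensity + time offset")
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
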