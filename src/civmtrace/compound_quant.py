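"""Compositing multiple ridges of one compound into a single trajectory.

A metabolite usually shows several NMR peaks; each traced ridge of that
compound is an independent, differently-scaled measurement of the same
concentration curve. The compositing rule: over the timepoints shared by
the most ridges, compute each ridge's mean raw intensity; scale every ridge
by the ratio of the highest mean to its own mean (so all support means
become equal, the highest-mean ridge keeping factor 1); then average the
scaled ridges timepoint-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ScalingError, SpecValidationError
from .ridge_tracing import Ridge

__all__ = [
    "CompoundTrajectory",
    "shared_timepoints",
    "scale_factors",
    "composite_trajectory",
    "composite_from_ridges",
]


@dataclass
class CompoundTrajectory:
    """Composite relative-concentration time series for one compound."""

    compound: str
    ridge_ids: list[str]
    scale_factors: np.ndarray
    support: np.ndarray  # time indices used for scaling
    times_h: np.ndarray
    value: np.ndarray
    n_contributing: np.ndarray


def _ridge_time_indices(ridge: Ridge, include_interpolated: bool) -> dict[int, float]:
    return {
        p.time_index: p.raw_intensity
        for p in ridge.points
        if include_interpolated or not p.interpolated
    }


def shared_timepoints(
    ridges: Sequence[Ridge], include_interpolated: bool = True
) -> np.ndarray:
    """Timepoint indices attained by the maximal number of ridges.

    With full mutual coverage this is simply the common support; under
    partial coverage it is the union of timepoints reaching the maximal
    ridge count.
    """
    if not ridges:
        raise SpecValidationError("need at least one ridge")
    counts: dict[int, int] = {}
    for r in ridges:
        for t in _ridge_time_indices(r, include_interpolated):
            counts[t] = counts.get(t, 0) + 1
    peak = max(counts.values())
    if len(ridges) > 1 and peak < 2:
        raise ScalingError(
            "candidate ridges share no timepoints; cannot define a scaling support"
        )
    return np.array(sorted(t for t, c in counts.items() if c == peak), dtype=int)


def scale_factors(
    ridges: Sequence[Ridge],
    support: np.ndarray,
    include_interpolated: bool = True,
) -> np.ndarray:
    """Per-ridge factor s_i = max_j(m_j) / m_i where m_i is ridge i's mean
    raw intensity over the shared support. The highest-mean ridge gets 1."""
    if support.size == 0:
        raise ScalingError("empty support: candidate ridges share no timepoints")
    means = []
    for r in ridges:
        vals = _ridge_time_indices(r, include_interpolated)
        on_support = [vals[t] for t in support if t in vals]
        if not on_support:
            raise ScalingError(f"ridge {r.id} has no points on the shared support")
        m = float(np.mean(on_support))
        if m <= 0:
            raise ScalingError(f"ridge {r.id} has nonpositive support mean {m:.3g}")
        means.append(m)
    means_arr = np.array(means)
    return means_arr.max() / means_arr


def composite_trajectory(
    ridges: Sequence[Ridge],
    factors: np.ndarray,
    compound: str = "unknown",
    support: np.ndarray | None = None,
    include_interpolated: bool = True,
) -> CompoundTrajectory:
    """Average the scaled ridges timepoint-wise.

    At each timepoint attained by at least one ridge the composite value is
    the mean of ``s_i * y_i(t)`` over the ridges present there;
    ``n_contributing`` records how many that was, so low-support times can
    be masked downstream.
    """
    if len(ridges) != len(factors):
        raise SpecValidationError("factors do not align with ridges")
    series: list[dict[int, float]] = [
        _ridge_time_indices(r, include_interpolated) for r in ridges
    ]
    time_map: dict[int, float] = {}
    for r in ridges:
        for p in r.points:
            time_map[p.time_index] = p.time_h
    all_t = sorted({t for s in series for t in s})
    values, counts = [], []
    for t in all_t:
        present = [f * s[t] for f, s in zip(factors, series) if t in s]
        values.append(float(np.mean(present)))
        counts.append(len(present))
    return CompoundTrajectory(
        compound=compound,
        ridge_ids=[r.id for r in ridges],
        scale_factors=np.asarray(factors, dtype=np.float64),
        support=np.asarray(support if support is not None else [], dtype=int),
        times_h=np.array([time_map[t] for t in all_t]),
        value=np.array(values),
        n_contributing=np.array(counts, dtype=int),
    )


def composite_from_ridges(
    ridges: Sequence[Ridge],
    compound: str = "unknown",
    include_interpolated: bool = True,
) -> CompoundTrajectory:
    """Convenience wrapper: shared support -> scale factors -> composite."""
    support = shared_timepoints(ridges, include_interpolated)
    factors = scale_factors(ridges, support, include_interpolated)
    return composite_trajectory(
        ridges, factors, compound, support, include_interpolated
    )
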