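"""Semi-automated ridge tracing of drifting NMR resonances.

A *ridge* is the trajectory of one peak through the (chemical shift, time,
intensity) space of a spectral time series. Peaks in vivo drift (pH, ionic
strength) and change height (metabolism), so a fixed-ppm integral would mix
neighbours; tracing follows each maximum instead.

The procedure:

1. Gaussian-smooth a user-chosen region (~0.5–1 ppm wide) in both the ppm
   and time dimensions.
2. Pick per-timepoint local maxima on the smoothed surface, deliberately
   permissive (some noise points are tolerated).
3. Cluster the picked points by single-linkage agglomerative clustering on
   Euclidean distances in weighted, min-max-scaled (ppm, time, intensity)
   space; each cluster is one candidate ridge.
4. Per cluster, keep the highest point per timepoint, linearly interpolate
   peak positions across interior temporal gaps.
5. Map each ridge position back onto the unsmoothed data by taking the raw
   maximum within a small index window around the smoothed position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import pdist

from .errors import EmptyResultError, SpecValidationError
from .series import SpectrumSeries

__all__ = [
    "TraceConfig",
    "RidgePoint",
    "Ridge",
    "gaussian_smooth_2d",
    "pick_local_maxima",
    "cluster_peak_points",
    "ridges_from_clusters",
    "map_ridge_to_raw",
    "trace_region",
    "mark_ridges",
]

#: Gaussian kernels are truncated at this many standard deviations.
KERNEL_TRUNCATE = 4.0


@dataclass
class TraceConfig:
    """Parameters of one tracing run on one spectral region.

    Exactly one of ``n_clusters`` (manual cluster count, the standard mode)
    or ``linkage_cut`` (normalized-distance threshold, an automated
    alternative) must be set. ``weights`` order is (ppm, time, intensity);
    each dimension is min-max scaled to [0, 1] before weighting, so weights
    are comparable across regions.
    """

    region: tuple[float, float]
    sigma_ppm: float = 0.002
    sigma_time: float = 0.2
    weights: tuple[float, float, float] = (1.0, 1.0, 0.3)
    n_clusters: int | None = None
    linkage_cut: float | None = None
    peak_floor: float = 0.0
    map_window_indices: int = 10

    def __post_init__(self) -> None:
        bad = []
        if self.region[0] >= self.region[1]:
            bad.append("region")
        if self.sigma_ppm <= 0:
            bad.append("sigma_ppm")
        if self.sigma_time <= 0:
            bad.append("sigma_time")
        if any(w < 0 for w in self.weights) or not any(w > 0 for w in self.weights):
            bad.append("weights")
        if (self.n_clusters is None) == (self.linkage_cut is None):
            bad.append("n_clusters/linkage_cut (exactly one must be set)")
        if not (1 <= self.map_window_indices <= 60):
            bad.append("map_window_indices")
        if bad:
            raise SpecValidationError(f"invalid TraceConfig fields: {bad}", bad)


@dataclass
class RidgePoint:
    """One traced point: indices into the full series plus physical values.

    ``interpolated`` points carry a position estimated across a temporal gap;
    their ``smoothed_intensity`` is NaN (they were never picked) and their
    raw intensity comes from the mapping step like any other point.
    """

    time_index: int
    time_h: float
    ppm_index: int
    ppm: float
    smoothed_intensity: float
    raw_intensity: float = np.nan
    interpolated: bool = False


@dataclass
class Ridge:
    """A traced peak: time-ordered points, at most one per timepoint."""

    id: str
    points: list[RidgePoint]
    annotation: str = "unknown"
    cluster_label: int = -1
    qc: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def times_h(self) -> np.ndarray:
        return np.array([p.time_h for p in self.points])

    @property
    def time_indices(self) -> np.ndarray:
        return np.array([p.time_index for p in self.points], dtype=int)

    @property
    def ppms(self) -> np.ndarray:
        return np.array([p.ppm for p in self.points])

    @property
    def raw_intensities(self) -> np.ndarray:
        return np.array([p.raw_intensity for p in self.points])

    def validate(self) -> None:
        idx = self.time_indices
        if len(idx) and (np.any(np.diff(idx) <= 0)):
            raise SpecValidationError(f"ridge {self.id}: times not strictly increasing")


# --------------------------------------------------------------------------
# 1. Smoothing
# --------------------------------------------------------------------------

def _region_columns(series: SpectrumSeries, region: tuple[float, float]) -> np.ndarray:
    cols = series.window_indices(*region)
    if cols.size == 0:
        raise EmptyResultError(f"region {region} does not overlap the ppm axis")
    return cols


def gaussian_smooth_2d(
    series: SpectrumSeries,
    region: tuple[float, float],
    sigma_ppm: float,
    sigma_time: float,
) -> tuple[SpectrumSeries, int]:
    """Separable Gaussian smoothing of a spectral region in ppm and time.

    Sigmas are given in physical units (ppm, hours) and converted to index
    units via the median axis spacings. Boundaries use edge replication;
    kernels are truncated at ``KERNEL_TRUNCATE`` sigma.

    Returns the smoothed sub-series and the column offset of the region's
    first point in the full series (for mapping back to raw indices).
    """
    if sigma_ppm <= 0 or sigma_time <= 0:
        raise SpecValidationError("sigmas must be > 0", ["sigma_ppm", "sigma_time"])
    cols = _region_columns(series, region)
    sub = series.intensities[:, cols]
    ppm_step = series.ppm_step or 1.0
    dt = np.diff(series.times_h)
    time_step = float(np.median(dt)) if dt.size else 1.0
    sig = (sigma_time / time_step, sigma_ppm / ppm_step)
    smoothed = gaussian_filter(sub, sigma=sig, mode="nearest", truncate=KERNEL_TRUNCATE)
    out = SpectrumSeries(
        intensities=smoothed,
        ppm_axis=series.ppm_axis[cols],
        times_h=series.times_h,
        history=[*series.history, f"gaussian_smooth_2d(region={region}, "
                 f"sigma_ppm={sigma_ppm}, sigma_time={sigma_time})"],
    )
    return out, int(cols[0])


# --------------------------------------------------------------------------
# 2. Peak picking
# --------------------------------------------------------------------------

def pick_local_maxima(
    smoothed: SpectrumSeries, peak_floor: float = 0.0, col_offset: int = 0
) -> list[RidgePoint]:
    """Per-timepoint strict interior local maxima along the ppm dimension.

    A point qualifies if it exceeds both immediate neighbours and is at
    least ``peak_floor`` high; the region's edge columns never qualify.
    ``col_offset`` converts region-local column indices to full-series
    indices stored on the returned points.
    """
    mat = smoothed.intensities
    if mat.size == 0:
        raise EmptyResultError("empty smoothed region")
    points: list[RidgePoint] = []
    if mat.shape[1] < 3:
        return points
    interior = mat[:, 1:-1]
    is_max = (interior > mat[:, :-2]) & (interior > mat[:, 2:]) & (interior >= peak_floor)
    for t, j_in in zip(*np.nonzero(is_max)):
        j = int(j_in) + 1
        points.append(
            RidgePoint(
                time_index=int(t),
                time_h=float(smoothed.times_h[t]),
                ppm_index=j + col_offset,
                ppm=float(smoothed.ppm_axis[j]),
                smoothed_intensity=float(mat[t, j]),
            )
        )
    return points


# --------------------------------------------------------------------------
# 3. Clustering
# --------------------------------------------------------------------------

def _scaled_features(
    points: Sequence[RidgePoint], weights: tuple[float, float, float]
) -> np.ndarray:
    feats = np.array(
        [[p.ppm, p.time_h, p.smoothed_intensity] for p in points], dtype=np.float64
    )
    lo = feats.min(axis=0)
    span = feats.max(axis=0) - lo
    span[span == 0] = 1.0  # constant dimension scales to 0
    return (feats - lo) / span * np.asarray(weights, dtype=np.float64)


def cluster_peak_points(
    points: Sequence[RidgePoint],
    weights: tuple[float, float, float] = (1.0, 1.0, 0.3),
    n_clusters: int | None = None,
    linkage_cut: float | None = None,
) -> np.ndarray:
    """Single-linkage agglomerative clustering of picked points.

    Each dimension (ppm, time, smoothed intensity) is min-max scaled to
    [0, 1] over the point set, multiplied by its weight, and the
    single-linkage hierarchy of Euclidean distances is cut either to
    ``n_clusters`` groups or at normalized distance ``linkage_cut``.

    Returns contiguous integer labels (0-based, in order of first
    appearance).
    """
    if len(points) == 0:
        raise EmptyResultError("no points to cluster")
    if (n_clusters is None) == (linkage_cut is None):
        raise SpecValidationError("exactly one of n_clusters / linkage_cut required")
    if n_clusters is not None and n_clusters > len(points):
        raise SpecValidationError(
            f"n_clusters={n_clusters} exceeds number of points ({len(points)})"
        )
    if len(points) == 1:
        return np.zeros(1, dtype=int)

    X = _scaled_features(points, weights)
    Z = linkage(pdist(X), method="single")
    if n_clusters is not None:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        raw = fcluster(Z, t=linkage_cut, criterion="distance")
    # relabel contiguously in order of first appearance
    labels = np.empty(len(raw), dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(raw):
        labels[i] = seen.setdefault(int(r), len(seen))
    return labels


# --------------------------------------------------------------------------
# 4. Ridge building: dedup + gap interpolation
# --------------------------------------------------------------------------

def ridges_from_clusters(
    points: Sequence[RidgePoint],
    labels: np.ndarray,
    series: SpectrumSeries,
) -> list[Ridge]:
    """Build one ridge per cluster.

    Per timepoint the highest-smoothed-intensity point is retained (ties
    broken toward higher ppm). Interior temporal gaps get interpolated
    points whose ppm is linear in time between the flanking retained
    points; there is no extrapolation beyond the first/last retained point.
    """
    if len(points) != len(labels):
        raise SpecValidationError("labels do not align with points")
    ridges: list[Ridge] = []
    for lab in sorted(set(int(l) for l in labels)):
        members = [p for p, l in zip(points, labels) if int(l) == lab]
        if not members:
            continue
        best: dict[int, RidgePoint] = {}
        for p in members:
            cur = best.get(p.time_index)
            if (
                cur is None
                or p.smoothed_intensity > cur.smoothed_intensity
                or (p.smoothed_intensity == cur.smoothed_intensity and p.ppm > cur.ppm)
            ):
                best[p.time_index] = p
        kept = [replace(best[t]) for t in sorted(best)]
        filled: list[RidgePoint] = [kept[0]]
        for prev, nxt in zip(kept, kept[1:]):
            for t in range(prev.time_index + 1, nxt.time_index):
                th = float(series.times_h[t])
                frac = (th - prev.time_h) / (nxt.time_h - prev.time_h)
                ppm = prev.ppm + frac * (nxt.ppm - prev.ppm)
                filled.append(
                    RidgePoint(
                        time_index=t,
                        time_h=th,
                        ppm_index=series.index_of_ppm(ppm),
                        ppm=ppm,
                        smoothed_intensity=np.nan,
                        interpolated=True,
                    )
                )
            filled.append(nxt)
        ridge = Ridge(id=f"R{lab}", points=filled, cluster_label=lab)
        ridge.validate()
        ridges.append(ridge)
    return ridges


# --------------------------------------------------------------------------
# 5. Mapping smoothed positions onto raw data
# --------------------------------------------------------------------------

def map_ridge_to_raw(
    ridge: Ridge,
    raw: SpectrumSeries,
    window_indices: int = 10,
    region: tuple[float, float] | None = None,
) -> Ridge:
    """Refine each ridge point against the unsmoothed data.

    For every point (interpolated ones included) the raw maximum within
    +/- floor(window/2) indices of the smoothed position — clipped to the
    region bounds — supplies ``raw_intensity`` and the refined ppm.
    """
    if window_indices < 1:
        raise SpecValidationError("window_indices must be >= 1", ["map_window_indices"])
    half = window_indices // 2
    if region is not None:
        cols = _region_columns(raw, region)
        lo_bound, hi_bound = int(cols[0]), int(cols[-1])
    else:
        lo_bound, hi_bound = 0, raw.n_points - 1
    new_points = []
    for p in ridge.points:
        lo = max(p.ppm_index - half, lo_bound)
        hi = min(p.ppm_index + half, hi_bound)
        window = raw.intensities[p.time_index, lo : hi + 1]
        j = lo + int(np.argmax(window))
        new_points.append(
            replace(
                p,
                raw_intensity=float(raw.intensities[p.time_index, j]),
                ppm_index=j,
                ppm=float(raw.ppm_axis[j]),
            )
        )
    return replace(ridge, points=new_points)


# --------------------------------------------------------------------------
# Full procedure
# --------------------------------------------------------------------------

def trace_region(series: SpectrumSeries, cfg: TraceConfig) -> list[Ridge]:
    """Run the full tracing procedure on one region.

    Composes smoothing, picking, clustering, ridge building and raw
    mapping; each returned ridge carries a provenance snapshot of the
    configuration. Deterministic: identical input and config give
    identical ridges.
    """
    smoothed, col_offset = gaussian_smooth_2d(
        series, cfg.region, cfg.sigma_ppm, cfg.sigma_time
    )
    points = pick_local_maxima(smoothed, cfg.peak_floor, col_offset)
    if not points:
        return []
    labels = cluster_peak_points(
        points, cfg.weights, n_clusters=cfg.n_clusters, linkage_cut=cfg.linkage_cut
    )
    ridges = ridges_from_clusters(points, labels, series)
    snapshot = {
        "region": cfg.region,
        "sigma_ppm": cfg.sigma_ppm,
        "sigma_time": cfg.sigma_time,
        "weights": cfg.weights,
        "n_clusters": cfg.n_clusters,
        "linkage_cut": cfg.linkage_cut,
        "peak_floor": cfg.peak_floor,
        "map_window_indices": cfg.map_window_indices,
    }
    out = []
    for r in ridges:
        mapped = map_ridge_to_raw(r, series, cfg.map_window_indices, cfg.region)
        mapped.provenance = dict(snapshot)
        out.append(mapped)
    return out


def mark_ridges(
    ridges: list[Ridge],
    accept: Sequence[str] = (),
    reject: Sequence[str] = (),
) -> list[Ridge]:
    """Record visual-inspection outcomes as QC flags (no deletion).

    Unknown ids raise; a ridge in ``reject`` gets ``manually_rejected`` set,
    one in ``accept`` gets ``inspected`` set.
    """
    known = {r.id for r in ridges}
    unknown = (set(accept) | set(reject)) - known
    if unknown:
        raise SpecValidationError(f"unknown ridge ids: {sorted(unknown)}")
    for r in ridges:
        if r.id in reject:
            r.qc["manually_rejected"] = True
        if r.id in accept:
            r.qc["inspected"] = True
    return ridges
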