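"""Reading and writing spectral series, acquisition metadata and trajectories.

Supported spectral inputs:

* Bruker ``acqus`` parameter text (JCAMP-like ``##$KEY= value`` dialect) for
  per-spectrum metadata — :func:`parse_acqus`.
* NMRPipe 1D frequency-domain files (``.ft``) — :func:`read_nmrpipe_1d`.
  Time-domain (FID) files are rejected: apodization/FT/phasing/baseline
  correction belong upstream.
* Plain interchange formats: delimited text (ppm axis header row, one row per
  timepoint) and an HDF5 layout with datasets ``intensities``, ``ppm``,
  ``time_h``.

Trajectory (ridge / composite) output is long-format TSV.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import (
    AcqusParseError,
    AxisMismatchError,
    DuplicateTimeError,
    EmptyResultError,
)
from .series import AcquisitionRecord, SpectrumSeries, canonicalize_orientation

__all__ = [
    "parse_acqus",
    "read_acqus",
    "assemble_series",
    "read_nmrpipe_1d",
    "write_nmrpipe_1d",
    "write_series_csv",
    "read_series_csv",
    "write_series_hdf5",
    "read_series_hdf5",
    "write_trajectories",
    "read_trajectories",
]

# --------------------------------------------------------------------------
# Bruker acqus parameter text
# --------------------------------------------------------------------------

_KEY_RE = re.compile(r"^##\$?(?P<key>[A-Za-z0-9_]+)\s*=\s*(?P<val>.*)$")


def _parse_acqus_dict(text: str) -> dict[str, str]:
    """Collect ``##$KEY= value`` entries; multi-line array values (starting
    with a ``(0..N)`` size declaration) are joined onto one line."""
    entries: dict[str, str] = {}
    key = None
    buf: list[str] = []
    for line in text.splitlines():
        m = _KEY_RE.match(line.strip())
        if m:
            if key is not None:
                entries[key] = " ".join(buf).strip()
            key = m.group("key")
            buf = [m.group("val").strip()]
        elif key is not None and line.strip() and not line.startswith("$$"):
            buf.append(line.strip())
    if key is not None:
        entries[key] = " ".join(buf).strip()
    return entries


def _array_values(raw: str) -> list[float]:
    """Values of a Bruker array entry like ``(0..63) 12.5 10 ...``."""
    body = re.sub(r"^\(\d+\.\.\d+\)", "", raw).strip()
    return [float(tok) for tok in body.split()] if body else []


def _get_float(entries: dict[str, str], key: str) -> float | None:
    if key not in entries:
        return None
    try:
        return float(entries[key])
    except ValueError:
        return None


def parse_acqus(text: str, label: str = "") -> AcquisitionRecord:
    """Parse Bruker acqus parameter text into an :class:`AcquisitionRecord`.

    Required keys: ``##$DATE`` (epoch seconds of the acquisition start) and
    ``##$NS`` (scan count). Everything else is optional and left ``None``
    when absent. The acquisition time is derived from TD and SW_h
    (``AQ = TD / (2 * SW_h)``) when both are present; the pulse width is P[1]
    of the ``##$P`` array; the carrier offset in ppm is O1 / SFO1.

    Raises
    ------
    AcqusParseError
        Naming ``start_clock`` or ``n_scans`` when the corresponding key is
        missing or malformed.
    """
    entries = _parse_acqus_dict(text)

    date = _get_float(entries, "DATE")
    if date is None:
        raise AcqusParseError("missing or malformed start_clock (##$DATE)")
    ns = _get_float(entries, "NS")
    if ns is None or ns < 1:
        raise AcqusParseError("missing or malformed n_scans (##$NS)")

    ds = _get_float(entries, "DS")
    td = _get_float(entries, "TD")
    sw_h = _get_float(entries, "SW_h")
    aq = td / (2.0 * sw_h) if (td and sw_h) else None

    d_arr = _array_values(entries["D"]) if "D" in entries else []
    recycle = d_arr[1] if len(d_arr) > 1 else None
    p_arr = _array_values(entries["P"]) if "P" in entries else []
    p1 = p_arr[1] if len(p_arr) > 1 else None

    o1 = _get_float(entries, "O1")
    sfo1 = _get_float(entries, "SFO1")
    offset_ppm = o1 / sfo1 if (o1 is not None and sfo1) else None

    return AcquisitionRecord(
        start_clock=date,
        n_scans=int(ns),
        n_dummy_scans=int(ds) if ds is not None else None,
        acquisition_time_s=aq,
        recycle_delay_s=recycle,
        pulse_width_us=p1,
        offset_ppm=offset_ppm,
        spin_rate_hz=_get_float(entries, "MASR"),
        label=label or entries.get("PULPROG", "").strip("<>"),
    )


def read_acqus(path: str | Path) -> AcquisitionRecord:
    p = Path(path)
    return parse_acqus(p.read_text(), label=p.parent.name)


# --------------------------------------------------------------------------
# Series assembly
# --------------------------------------------------------------------------

def assemble_series(
    spectra: Sequence[tuple[np.ndarray, np.ndarray]],
    records: Sequence[AcquisitionRecord],
    origin: float,
    meta: dict | None = None,
) -> SpectrumSeries:
    """Assemble per-timepoint ``(ppm_axis, intensity)`` pairs into a
    :class:`SpectrumSeries` ordered by acquisition start time.

    ``times_h[i] = (records[i].start_clock - origin) / 3600`` after sorting.
    All spectra must share one ppm axis (exact equality after orientation
    canonicalization).
    """
    if len(spectra) != len(records):
        raise AxisMismatchError("spectra and records differ in length")
    if not spectra:
        raise EmptyResultError("no spectra to assemble")

    canon = [canonicalize_orientation(p, y) for p, y in spectra]
    ref_ppm = canon[0][0]
    for i, (p, _) in enumerate(canon):
        if p.shape != ref_ppm.shape or not np.array_equal(p, ref_ppm):
            raise AxisMismatchError(f"spectrum {i} ppm axis differs from spectrum 0")

    clocks = np.array([r.start_clock for r in records], dtype=np.float64)
    if len(np.unique(clocks)) != len(clocks):
        raise DuplicateTimeError("duplicate start_clock among records")
    order = np.argsort(clocks)

    intensities = np.vstack([canon[i][1] for i in order])
    times_h = (clocks[order] - origin) / 3600.0
    return SpectrumSeries(
        intensities=intensities,
        ppm_axis=ref_ppm,
        times_h=times_h,
        records=[records[i] for i in order],
        meta=dict(meta or {}),
        history=[f"assemble_series(n={len(records)}, origin={origin})"],
    )


# --------------------------------------------------------------------------
# NMRPipe 1D frequency-domain files
# --------------------------------------------------------------------------
# The 512-word float32 header; word offsets follow the NMRPipe fdatap
# definition. Only the handful needed for a real 1D frequency-domain
# spectrum are touched.

_FD_MAGIC = 0
_FD_FLTFORMAT = 2
_FD_FLTORDER = 3
_FD_DIMCOUNT = 9
_FD_F2QUADFLAG = 56
_FD_F2CAR = 66
_FD_SIZE = 99
_FD_F2SW = 100
_FD_F2ORIG = 101
_FD_F2OBS = 119
_FD_F2FTFLAG = 220

_FLTFORMAT_VALUE = np.float32(4008636160.0)
_FLTORDER_VALUE = np.float32(2.345)


def read_nmrpipe_1d(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 1D frequency-domain NMRPipe file.

    Returns ``(ppm_axis, intensities)`` in canonical (descending-ppm) order.
    The axis is reconstructed from SW / OBS / ORIG: point ``i`` (i = 0 first
    stored point) resonates at ``orig + (size - 1 - i) * sw / size`` Hz, so
    stored order is already high-to-low ppm.

    Raises
    ------
    AcqusParseError
        If the file is not a 1D real frequency-domain NMRPipe file (in
        particular, FID-domain input is rejected, not processed).
    """
    raw = np.fromfile(str(path), dtype=np.float32)
    if raw.size < 512:
        raise AcqusParseError(f"{path}: too short for an NMRPipe header")
    hdr = raw[:512]
    if not np.isclose(hdr[_FD_FLTORDER], _FLTORDER_VALUE):
        raise AcqusParseError(f"{path}: not a native-byte-order NMRPipe file")
    if int(hdr[_FD_DIMCOUNT]) != 1:
        raise AcqusParseError(f"{path}: expected 1D data, got {int(hdr[_FD_DIMCOUNT])}D")
    if int(hdr[_FD_F2FTFLAG]) != 1:
        raise AcqusParseError(
            f"{path}: FID (time-domain) input is rejected; supply frequency-domain data"
        )
    size = int(hdr[_FD_SIZE])
    if raw.size < 512 + size:
        raise AcqusParseError(f"{path}: truncated data section")
    data = raw[512 : 512 + size].astype(np.float64)

    sw = float(hdr[_FD_F2SW])
    obs = float(hdr[_FD_F2OBS])
    orig = float(hdr[_FD_F2ORIG])
    if obs == 0:
        raise AcqusParseError(f"{path}: observe frequency is zero")
    idx = np.arange(size)
    hz = orig + (size - 1 - idx) * sw / size
    ppm = hz / obs
    return canonicalize_orientation(ppm, data)


def write_nmrpipe_1d(
    path: str | Path,
    ppm_axis: np.ndarray,
    intensities: np.ndarray,
    obs_mhz: float = 600.0,
) -> None:
    """Write a real 1D frequency-domain NMRPipe file.

    The ppm axis must be uniformly spaced; SW/ORIG/CAR are derived from it
    and ``obs_mhz``. Intended for interchange and round-trip testing.
    """
    ppm, data = canonicalize_orientation(np.asarray(ppm_axis), np.asarray(intensities))
    size = ppm.size
    steps = np.diff(ppm)
    if size < 2 or not np.allclose(steps, steps[0], rtol=0, atol=1e-9 * abs(steps[0])):
        raise ValueError("ppm axis must be uniform to write NMRPipe format")
    step_hz = abs(steps[0]) * obs_mhz
    sw = step_hz * size
    orig = ppm[-1] * obs_mhz  # frequency of the last stored point, Hz
    car = (orig + sw * (size - 1) / size / 2.0) / obs_mhz

    hdr = np.zeros(512, dtype=np.float32)
    hdr[_FD_MAGIC] = 0.0
    hdr[_FD_FLTFORMAT] = _FLTFORMAT_VALUE
    hdr[_FD_FLTORDER] = _FLTORDER_VALUE
    hdr[_FD_DIMCOUNT] = 1.0
    hdr[_FD_F2QUADFLAG] = 1.0  # real data
    hdr[_FD_SIZE] = float(size)
    hdr[_FD_F2SW] = np.float32(sw)
    hdr[_FD_F2OBS] = np.float32(obs_mhz)
    hdr[_FD_F2ORIG] = np.float32(orig)
    hdr[_FD_F2CAR] = np.float32(car)
    hdr[_FD_F2FTFLAG] = 1.0
    with open(path, "wb") as fh:
        hdr.tofile(fh)
        data.astype(np.float32).tofile(fh)


# --------------------------------------------------------------------------
# Plain interchange: delimited text and HDF5
# --------------------------------------------------------------------------

def write_series_csv(series: SpectrumSeries, path: str | Path, sep: str = ",") -> None:
    """Delimited-text layout: header row ``time_h`` + ppm values (17
    significant digits, so float64 round-trips bitwise), one row per
    timepoint."""
    with open(path, "w") as fh:
        fh.write(sep.join(["time_h"] + [f"{p:.17g}" for p in series.ppm_axis]) + "\n")
        for t, row in zip(series.times_h, series.intensities):
            fh.write(sep.join([f"{t:.17g}"] + [f"{v:.17g}" for v in row]) + "\n")


def read_series_csv(path: str | Path, sep: str = ",") -> SpectrumSeries:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        if header[0] != "time_h":
            raise AcqusParseError(f"{path}: first header field must be 'time_h'")
        ppm = np.array([float(x) for x in header[1:]])
        times, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(sep)
            times.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])
    ppm, mat = canonicalize_orientation(ppm, np.array(rows, dtype=np.float64))
    return SpectrumSeries(
        intensities=mat,
        ppm_axis=ppm,
        times_h=np.array(times),
        history=[f"read_series_csv({Path(path).name})"],
    )


def write_series_hdf5(series: SpectrumSeries, path: str | Path) -> None:
    """HDF5 layout: datasets ``intensities`` (T x P), ``ppm`` (P), ``time_h``
    (T); processing history as a root attribute."""
    with h5py.File(path, "w") as f:
        # track_times off so identical series give byte-identical files
        f.create_dataset("intensities", data=series.intensities, track_times=False)
        f.create_dataset("ppm", data=series.ppm_axis, track_times=False)
        f.create_dataset("time_h", data=series.times_h, track_times=False)
        f.attrs["history"] = "\n".join(series.history)
        for k, v in series.meta.items():
            if isinstance(v, (str, int, float)):
                f.attrs[f"meta_{k}"] = v


def read_series_hdf5(path: str | Path) -> SpectrumSeries:
    with h5py.File(path, "r") as f:
        ppm, mat = canonicalize_orientation(f["ppm"][()], f["intensities"][()])
        history = [ln for ln in str(f.attrs.get("history", "")).split("\n") if ln]
        meta = {
            k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")
        }
        return SpectrumSeries(
            intensities=mat,
            ppm_axis=ppm,
            times_h=f["time_h"][()],
            meta=meta,
            history=history + [f"read_series_hdf5({Path(path).name})"],
        )


# --------------------------------------------------------------------------
# Trajectory tables (ridges and composite compound trajectories)
# --------------------------------------------------------------------------

_TRAJ_COLUMNS = [
    "id",
    "annotation",
    "time_h",
    "ppm",
    "intensity",
    "interpolated",
    "time_index",
    "ppm_index",
    "smoothed_intensity",
]


def write_trajectories(trajectories: Iterable, path: str | Path, sep: str = "\t") -> None:
    """Write ridges and/or compound trajectories as one long-format table.

    Columns: id, annotation, time_h, ppm, intensity, interpolated, plus the
    index/smoothed-value columns needed for a lossless ridge round trip.
    Composite trajectories have no single ppm; those fields are left empty.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise EmptyResultError("no trajectories to write")
    rows = []
    for traj in trajectories:
        if hasattr(traj, "points"):  # Ridge
            for pt in traj.points:
                rows.append(
                    {
                        "id": traj.id,
                        "annotation": traj.annotation,
                        "time_h": pt.time_h,
                        "ppm": pt.ppm,
                        "intensity": pt.raw_intensity,
                        "interpolated": int(pt.interpolated),
                        "time_index": pt.time_index,
                        "ppm_index": pt.ppm_index,
                        "smoothed_intensity": pt.smoothed_intensity,
                    }
                )
        else:  # CompoundTrajectory
            for t, v, n in zip(traj.times_h, traj.value, traj.n_contributing):
                rows.append(
                    {
                        "id": traj.compound,
                        "annotation": traj.compound,
                        "time_h": t,
                        "ppm": np.nan,
                        "intensity": v,
                        "interpolated": 0,
                        "time_index": -1,
                        "ppm_index": -1,
                        "smoothed_intensity": np.nan,
                    }
                )
    df = pd.DataFrame(rows, columns=_TRAJ_COLUMNS)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_trajectories(path: str | Path, sep: str = "\t") -> list:
    """Read a trajectory table written by :func:`write_trajectories` back
    into :class:`~civmtrace.ridge_tracing.Ridge` objects (rows carrying ppm
    positions) — the inverse of the ridge writer."""
    from .ridge_tracing import Ridge, RidgePoint

    df = pd.read_csv(path, sep=sep)
    ridges = []
    for rid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("time_h")
        if grp["ppm_index"].iloc[0] < 0:
            continue  # composite trajectory rows: no per-point ppm to rebuild
        points = [
            RidgePoint(
                time_index=int(r.time_index),
                time_h=float(r.time_h),
                ppm_index=int(r.ppm_index),
                ppm=float(r.ppm),
                smoothed_intensity=float(r.smoothed_intensity),
                raw_intensity=float(r.intensity),
                interpolated=bool(r.interpolated),
            )
            for r in grp.itertuples()
        ]
        ridges.append(Ridge(id=str(rid), points=points, annotation=str(grp["annotation"].iloc[0])))
    return ridges
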