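"""End-to-end pipeline orchestration with a reproducibility manifest.

A :class:`RunConfig` names a data source (a standard synthetic fixture, or
a series file), the preprocessing configuration, one trace configuration
per spectral region (with an optional compound annotation), and optionally
a pH-estimation step. :func:`run_pipeline` executes
simulate/load -> preprocess -> trace -> quantify -> pH -> plots and writes
a machine-readable manifest (config, seed, package version, SHA-256 of
every tabular output) so a run can be re-executed and checked for exact
reproduction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chemshift_ph import fit_titration, ppm_to_ph, read_titration_csv
from .compound_quant import composite_from_ridges
from .errors import CivmError, SpecValidationError
from .preprocess import PreprocessConfig, preprocess_pipeline
from .ridge_tracing import Ridge, TraceConfig, trace_region
from .series import SpectrumSeries
from .spectra_io import (
    read_series_csv,
    read_series_hdf5,
    write_series_hdf5,
    write_trajectories,
)
from .synthetic import simulate_series, standard_fixtures, with_overrides

log = logging.getLogger("civmtrace")

__all__ = ["RunConfig", "TraceJob", "run_pipeline", "load_series"]


@dataclass
class TraceJob:
    """One region to trace, optionally annotated to a compound."""

    trace: TraceConfig
    annotation: str = "unknown"


@dataclass
class RunConfig:
    source: str  # fixture name, or path to a series file (.csv/.h5)
    outdir: str
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    traces: list[TraceJob] = field(default_factory=list)
    titration_csv: str | None = None
    ph_ridge_id: str | None = None  # "<annotation>/<ridge id>" not needed: plain id
    make_plots: bool = True


def load_series(source: str, seed: int = 0) -> SpectrumSeries:
    """Resolve a data source: a standard fixture name (simulated with
    ``seed``) or a path to a .csv / .h5 interchange file."""
    fixtures = standard_fixtures()
    if source in fixtures:
        spec = with_overrides(fixtures[source], seed=seed)
        series, _ = simulate_series(spec)
        return series
    p = Path(source)
    if not p.exists():
        raise SpecValidationError(f"input {source!r} is neither a fixture nor a file")
    if p.suffix in (".h5", ".hdf5"):
        return read_series_hdf5(p)
    return read_series_csv(p)


def _config_dict(cfg: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    return enc(cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured pipeline; returns the artifact directory.

    Stage failures abort with the stage name while keeping partial outputs
    and the manifest on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "stages": [],
        "outputs": {},
    }
    manifest_path = outdir / "manifest.json"

    def finish_stage(name: str) -> None:
        manifest["stages"].append(name)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def fail(stage: str, err: Exception) -> None:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        series = load_series(cfg.source, cfg.seed)
    except CivmError as e:
        fail("load", e)
        raise
    finish_stage("load")

    try:
        processed = preprocess_pipeline(series, cfg.preprocess)
    except CivmError as e:
        fail("preprocess", e)
        raise
    series_path = outdir / "preprocessed.h5"
    write_series_hdf5(processed, series_path)
    manifest["outputs"]["preprocessed.h5"] = _sha256(series_path)
    finish_stage("preprocess")

    ridges: list[Ridge] = []
    by_compound: dict[str, list[Ridge]] = {}
    try:
        for j, job in enumerate(cfg.traces):
            found = trace_region(processed, job.trace)
            for r in found:
                r.id = f"T{j}_{r.id}"
                r.annotation = job.annotation
                ridges.append(r)
                if job.annotation != "unknown":
                    by_compound.setdefault(job.annotation, []).append(r)
            log.info("trace region %s: %d ridges", job.trace.region, len(found))
    except CivmError as e:
        fail("trace", e)
        raise
    if ridges:
        write_trajectories(ridges, outdir / "ridges.tsv")
        manifest["outputs"]["ridges.tsv"] = _sha256(outdir / "ridges.tsv")
    finish_stage("trace")

    try:
        compounds = [
            composite_from_ridges(rs, compound=name)
            for name, rs in by_compound.items()
        ]
    except CivmError as e:
        fail("quantify", e)
        raise
    if compounds:
        write_trajectories(compounds, outdir / "compounds.tsv")
        manifest["outputs"]["compounds.tsv"] = _sha256(outdir / "compounds.tsv")
    finish_stage("quantify")

    if cfg.titration_csv and cfg.ph_ridge_id:
        try:
            ph_vec, ppm_vec = read_titration_csv(cfg.titration_csv)
            curve = fit_titration(ph_vec, ppm_vec)
            target = next((r for r in ridges if r.id == cfg.ph_ridge_id), None)
            if target is None:
                raise SpecValidationError(f"ridge id {cfg.ph_ridge_id!r} not found")
            ph_est = ppm_to_ph(curve, target.ppms)
            lines = ["time_h\tppm\tph"]
            lines += [
                f"{t:.17g}\t{p:.17g}\t{v:.17g}"
                for t, p, v in zip(target.times_h, target.ppms, ph_est)
            ]
            (outdir / "ph.tsv").write_text("\n".join(lines) + "\n")
            manifest["outputs"]["ph.tsv"] = _sha256(outdir / "ph.tsv")
        except CivmError as e:
            fail("ph", e)
            raise
        finish_stage("ph")

    if cfg.make_plots:
        try:
            from .viz import ridge_overlay_plot

            if ridges:
                region_lo = min(j.trace.region[0] for j in cfg.traces)
                region_hi = max(j.trace.region[1] for j in cfg.traces)
                ridge_overlay_plot(
                    processed, ridges, outdir / "ridges.png",
                    region=(region_lo, region_hi), stride=4,
                )
        except CivmError as e:
            fail("plot", e)
            raise
        finish_stage("plot")

    np_state = {"numpy": np.__version__}
    manifest["environment"] = np_state
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
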