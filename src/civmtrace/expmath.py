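"""Closed-form experiment arithmetic for CIVM-NMR planning numbers.

Pure scalar utilities: temporal resolution from scan counts, centrifugal
load of an HR-MAS rotor, media molarity from mass fraction, inoculum
density, and index-window width in ppm. All return full precision; rounding
is the caller's concern.
"""

from __future__ import annotations

import math

__all__ = [
    "experiment_duration_minutes",
    "block_resolution_minutes",
    "centrifugal_g",
    "mass_percent_to_molar",
    "inoculum_concentration",
    "index_window_to_ppm",
]

#: Standard gravity, m/s^2.
G0 = 9.81

#: Molar mass of D-glucose, g/mol (used in fixtures and docs).
GLUCOSE_MOLAR_MASS = 180.16


def experiment_duration_minutes(n_scans: int, seconds_per_scan: float) -> float:
    """Duration of one summed experiment, minutes.

    E.g. 64 scans at ~3.97 s/scan -> ~4.23 min per saved spectrum.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if seconds_per_scan <= 0:
        raise ValueError("seconds_per_scan must be > 0")
    return n_scans * seconds_per_scan / 60.0


def block_resolution_minutes(experiment_minutes: float, block: int) -> float:
    """Effective temporal resolution after summing ``block`` consecutive
    experiments (e.g. 3 x 4.23 min -> 12.7 min)."""
    if block < 1:
        raise ValueError("block must be >= 1")
    if experiment_minutes <= 0:
        raise ValueError("experiment_minutes must be > 0")
    return block * experiment_minutes


def centrifugal_g(radius_mm: float, spin_hz: float) -> float:
    """Centrifugal acceleration at ``radius_mm`` from the spinning axis, in
    multiples of standard gravity: (2*pi*f)^2 * r / g0."""
    if radius_mm < 0 or spin_hz < 0:
        raise ValueError("radius and spin rate must be >= 0")
    omega = 2.0 * math.pi * spin_hz
    return omega * omega * radius_mm * 1e-3 / G0


def mass_percent_to_molar(percent_wv: float, molar_mass: float) -> float:
    """Convert % w/v (g per 100 mL) to mol/L: 10 * pct / M."""
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    if percent_wv < 0:
        raise ValueError("percent_wv must be >= 0")
    return 10.0 * percent_wv / molar_mass


def inoculum_concentration(
    vol_added_uL: float, stock_cells_per_mL: float, culture_vol_mL: float
) -> float:
    """Final cell density after adding ``vol_added_uL`` of stock suspension
    to ``culture_vol_mL`` of culture, cells/mL."""
    if vol_added_uL <= 0 or stock_cells_per_mL <= 0 or culture_vol_mL <= 0:
        raise ValueError("all inputs must be > 0")
    v_add_mL = vol_added_uL * 1e-3
    return v_add_mL * stock_cells_per_mL / (culture_vol_mL + v_add_mL)


def index_window_to_ppm(window_indices: int, ppm_per_index: float) -> float:
    """Width in ppm of a search window of ``window_indices`` axis points."""
    if window_indices <= 0 or ppm_per_index <= 0:
        raise ValueError("inputs must be > 0")
    return window_indices * ppm_per_index
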