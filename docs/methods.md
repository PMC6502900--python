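# Methods

This note records the model assumptions, parameter conventions, numerical
choices and known limitations of `civmtrace`. It documents what the code
does and why; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Data model

A `SpectrumSeries` is a T × P matrix of real intensities with a shared ppm
axis and a time axis in hours. Two conventions are enforced everywhere:

* **ppm axis stored descending** (standard NMR display order). Readers
  canonicalize ascending input; a single orientation removes sign errors in
  windowed searches.
* **Times in hours, strictly increasing**, relative to a user-supplied
  origin. Offsets such as the delay between inoculation and the first
  acquisition are per-sample metadata added to the origin, not baked into
  the matrix.

All interval semantics (trim, water zeroing, time truncation, search
windows) are **closed on both ends**.

Input is frequency-domain only. The NMRPipe reader checks the FT flag and
rejects time-domain (FID) files: apodization, Fourier transform, phasing
and baseline correction belong to the upstream processing chain, and this
package deliberately does not reimplement them. The NMRPipe axis is
reconstructed from the SW/OBS/ORIG header words with ORIG taken as the
frequency of the last stored point, so stored order is already
high-to-low ppm.

## Preprocessing

Stages run in a fixed order: DSS referencing → ppm trimming → water
zeroing → time truncation → DSS normalization → block summation. Trimming,
zeroing and truncation commute with one another; normalization does *not*
commute with block summation (summing first averages away within-block
reference variation), which is why the order is part of the contract and is
tested by counterexample.

Choices worth recording:

* **Referencing shifts by whole axis indices** (no sub-index
  re-interpolation), preserving raw intensity values for the maximum-based
  quantification downstream. Vacated edge positions are filled with the
  spectrum's edge value rather than zeros, avoiding fabricated
  discontinuities inside the retained window. Automatic shifts may be
  overridden per spectrum via `PreprocessConfig.shift_overrides`, the
  escape hatch for manual curation.
* **Reference detectability floor**: a window maximum must exceed 5× the
  window's median absolute intensity (and be positive); otherwise a
  reference-not-found error names the offending timepoint.
* **DSS height, not integral**, is the normalization denominator; after
  normalization each spectrum's reference-window maximum equals exactly 1.0
  (x/x is exact in IEEE arithmetic).
* **Block summation** drops a trailing incomplete block (mixed
  signal-to-noise points are worse than a slightly shorter series), uses
  the arithmetic mean of constituent times as the block time, and sums scan
  counts in the per-block record summaries. Signal is conserved: the output
  matrix total equals the total of the consumed input spectra.

Defaults (keep [−0.5, 10] ppm, water [4.7, 5.0] ppm, 11 h cutoff, ±0.25 ppm
DSS search, block of 3) describe the standard in vivo protocol this package
targets; all are configurable.

## Ridge tracing

Tunable parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `sigma_ppm` | 0.002 ppm | Gaussian smoothing width along ppm; ≈7 axis steps at 2.9 × 10⁻⁴ ppm/point, well below typical linewidths (~0.01 ppm) |
| `sigma_time` | 0.2 h | smoothing width along time; ~1–3 timepoints depending on block size |
| `weights` | (1, 1, 0.3) | per-dimension weights (ppm, time, intensity) applied after min-max scaling |
| `n_clusters` / `linkage_cut` | — | exactly one required; K is normally user-chosen per region, the distance cut is an automated alternative |
| `peak_floor` | 0 | minimum smoothed intensity for picking; deliberately permissive — stray noise points land in their own clusters and are rejected at QC |
| `map_window_indices` | 10 | total width of the raw-mapping search window; ±⌊W/2⌋ indices around the smoothed position |

Numerical choices:

* Smoothing kernels are truncated at 4σ with edge replication; sigmas are
  converted to index units via the median axis spacings (robust to mild
  time-grid irregularity).
* Picking takes **strict interior local maxima** per timepoint; region edge
  columns never qualify (a maximum at the boundary is an artifact of the
  window, not a peak).
* Clustering scales each dimension min-max to [0, 1] over the picked point
  set before weighting. The weighted space has no natural units, and
  min-max makes one weight vector portable across regions of different
  widths and intensity scales. Clustering uses smoothed intensities, since
  picking operates on the smoothed surface.
* Per-timepoint deduplication keeps the highest smoothed intensity; exact
  ties break toward **higher ppm** (any fixed rule works; this one is
  deterministic and documented).
* Gap interpolation is linear in time on peak *positions* only and never
  extrapolates beyond a ridge's first/last retained point. Interpolated
  points get raw intensities through the same mapping window as picked
  points — intensity at gaps comes from the data, not from interpolation.
* Raw mapping can only increase the intensity relative to the unrefined
  position (it maximizes over a window containing it); this monotonicity is
  tested.

The single-linkage hierarchy itself is delegated to
`scipy.cluster.hierarchy`; an exhaustive pairwise-merge implementation
lives in the test suite as an independent cross-check and agrees on 1,000
seeded random instances of up to 200 points.

QC mirrors practice: every ridge carries a provenance snapshot of its
configuration, and `mark_ridges` records accept/reject decisions as flags
without deleting data.

## Compositing

The scaling support is the set of timepoints attained by the maximal number
of ridges; if several coverage patterns tie, the union of maximal-count
timepoints is used. Scale factors are mean ratios (sᵢ = maxⱼ mⱼ / mᵢ), so
after scaling all support means are equal to within 10⁻⁹ relative
tolerance — a tested post-condition. At timepoints covered by only some
ridges the composite is the mean over the ridges present, with
`n_contributing` exposed so users can mask thin support. Ridges sharing no
timepoints at all are an error: equalizing means over different time
windows would silently conflate different metabolic phases. Interpolated
points participate by default and can be excluded by flag.

## pH estimation

The calibration direction is δ = f(pH) with numeric inversion, matching how
titrations are measured. The cubic fit requires ≥ 4 distinct pH values,
reports R² = 1 − SSres/SStot, and is rejected if its derivative changes
sign anywhere on the calibrated range (a non-monotone curve has no unique
inverse). Inversion brackets the root on the calibrated pH range and uses
Brent's method to 10⁻⁶ pH. Extrapolation is refused: titration behaviour
outside the measured range is unphysical to assume. The bundled citrate
titration table is **synthetic** (points on a strictly monotone cubic in
the upfield-citrate ppm neighbourhood); the real table for a given
instrument must be measured.

## Synthetic generator

The generator emulates the features the pipeline actually exploits:
height-parameterized Lorentzian/Gaussian/pseudo-Voigt peaks (height, not
area, because quantification is maximum-based); center trajectories that
are constant, linear, sigmoidal, or sampled tables (used to drive a peak
through a titration curve by a pH schedule); logistic
accumulation/depletion and exponential amplitude trajectories; a constant
DSS anchor at 0 ppm; an optional polynomial baseline; and seeded additive
Gaussian noise. Defaults mirror a typical acquisition geometry — 4.23-min
spacing, 11-h duration, 2.9 × 10⁻⁴ ppm/point — so index arithmetic (e.g.
the 10-index mapping window) is exercised at realistic scale.

What it does **not** emulate, and therefore what passing tests do not show
about real data: J-coupling multiplet structure, ¹³C satellites, spinning
sidebands, field drift/inhomogeneity, baseline roll correlated with water
suppression, or rider peaks on broad resonances. Recovery results on the
fixtures are upper bounds for well-resolved peaks, not guarantees for
crowded spectra — the `crowded_region` fixture (two peaks closer than a
linewidth) exists precisely to exhibit the documented overlap failure mode.

Fixture study conditions: the tracing testbed (`two_drifting_peaks`) uses
drifts ≤ 0.03 ppm over 11 h, peak heights 0.5–10 relative to DSS = 1 with
noise SD 0.025 (SNR ≥ 20 at the weakest point); the fermentation scenario
(`glucose_ethanol`) uses logistic depletion/accumulation with a 6-h
midpoint and a 2.5× response-factor split between the two glucose peaks;
the pH fixture drives the citrate-like peak from pH 6.3 to 5.3 with a 3-h
sigmoid midpoint. These values were chosen once as a realistic regime and
are part of the fixtures' definitions.

## Problem sizes

Tests and the acceptance script run fixtures at full axis density but
restricted ppm spans (≈7,000–21,000 points × 157 timepoints), which
exercises the same index arithmetic as a full-width spectrum at a fraction
of the memory; the clustering cross-check uses 1,000 instances of 5–200
points, the scale at which the exhaustive reference is practical. These
sizes are the package's chosen verification scale.

## Known limitations

* Maximum-based tracing cannot separate heavily overlapped peaks;
  deconvolution is out of scope.
* Cluster count K is a manual choice per region; the distance-threshold cut
  is provided but unvalidated against expert tracing.
* Relative quantification only; no absolute calibration.
* The pH module models a single resonance's shift as a function of pH only;
  metal-ion and ionic-strength effects are not modeled.
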