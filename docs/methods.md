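# Methods

This note documents the models behind chemokit, the parameters that matter,
the numerical choices made where the design was genuinely open, and what the
synthetic-data validation does and does not demonstrate about real data.

## Run-and-tumble simulator

Motile cells are point particles in a 2-D arena. Each cell draws a constant
swimming speed from Normal(`mean_speed`, `speed_sd`) (default 40 ± 8 µm/s,
within the 20–60 µm/s range typical of marine isolates) and an initial
heading uniform on the circle. Tumbles arrive as a homogeneous Poisson
process at `tumble_rate` (default 0.5 s⁻¹). A tumble multiplies the speed by
`tumble_speed_fraction` (default 0.2) for `tumble_duration` frames (default
2 frames, ≈70 ms at 30 fps — the scale of flagellar unbundling) and then
deflects the heading by a wrapped-normal angle of width `turn_angle_sd`
(default 90°). Between tumbles the heading is constant: rotational diffusion
is deliberately omitted, keeping the simulated process exactly the one the
reorientation detector is specified to measure, so that detector validation
is a clean parameter-recovery problem.

`turn_angle_min` (default 0°, i.e. off) floors the turn magnitude by
rejection sampling. It exists because a wrapped-normal(90°) turn
distribution places ~22% of turns below the detector's 25° threshold; rate-
recovery validation runs set `turn_angle_min=45` so that every simulated
tumble is detectable in principle. This is a validation convenience, not a
claim about flagellar mechanics.

Non-motile cells (fraction `nonmotile_fraction`, drawn per cell) jitter
i.i.d. Gaussian (`nonmotile_jitter_sd`, default 0.15 µm) about a fixed
point. Uniform drift (`drift_velocity`) is added to all positions, then
per-coordinate Gaussian localisation noise (`noise_sd`, default 0.1 µm ≈ 0.3
px — typical sub-pixel centroid precision). An optional reflecting boundary
(`boundary="reflect"`) folds trajectories into the arena by the unfolding
construction, which preserves per-frame displacement magnitudes exactly.

Randomness: one root `numpy.random.SeedSequence(seed)` spawns an independent
child stream per cell (per plate in the count generator), and each cell
consumes draws in a fixed order independent of parameter values.
Consequences: identical seeds give byte-identical outputs, enlarging
`n_cells` never perturbs existing cells, and with `speed_sd = noise_sd = 0`
scaling `mean_speed` by k scales every displacement by exactly k.

Sampling: `n_frames = round(duration * frame_rate) + 1` positions at spacing
`1/frame_rate`, so the observed time span equals `duration` exactly and the
expected ground-truth tumble count is `tumble_rate * n_cells * duration`.

## Video rendering

Each frame is `background_level` (+ optional static pattern) plus one
isotropic Gaussian spot per cell (width `psf_sigma`, default 1.5 px; peak
`spot_amplitude`) plus Gaussian read noise, quantised to uint16. Default
frame geometry is 2044×2048 px at 0.326 µm/px, freely scalable down (tests
use 256×256). Out-of-frame positions warn and are dropped (or clipped, per
config). The renderer models neither motion blur, defocus, halo artefacts
of phase contrast, nor intensity variation between cells.

## Tracking

1. **Background**: per-pixel median over the whole video, subtracted with
   clamping at zero (dtype preserved). The median is insensitive to a
   moving cell as long as it occupies a given pixel in under half the
   frames.
2. **Detection**: local maxima above a threshold, refined to intensity-
   weighted centroids in a ±3 px window, with a minimum pairwise separation
   (default 51 px; brighter spot wins). The thresholding scheme is not part
   of the tracking specification this stage reproduces, so it is explicit
   config: the default `"sigma"` mode thresholds at mean + 10 sd of the
   background-subtracted frame, which adapts to the noise level without
   tuning; `"quantile"` and `"absolute"` modes are available.
3. **Linking**: per frame pair, an optimal bipartite assignment that first
   maximises the number of links whose displacement is within
   `max_displacement` px/frame (default 31) and then minimises the total
   squared displacement (solved by the Hungarian algorithm on a padded
   matrix; the "unmatched" pad cost exceeds the largest possible total
   feasible cost so that link count always dominates). Unmatched detections
   open new tracks; a track unseen for more than `memory` frames (default
   0: no gap closing) is closed; tracks shorter than `min_track_length` are
   discarded. Ties are broken deterministically by processing detections in
   sorted order. A greedy nearest-first fallback is available
   (`assignment="greedy"`).
4. **Drift correction**: the per-frame ensemble drift is the median over
   co-present particles of their frame-to-frame displacement, cumulatively
   summed and subtracted. With dense, randomly-oriented swimmers the median
   is a nearly unbiased drift estimator; with few particles its sampling
   noise accumulates as a random walk, which is why the tracking round-trip
   validation (no drift injected) runs without this stage.

The 31 px/frame gate is glossed as ~200 µm/s in the field; that conversion
is exact only near 20 fps, so the pixel gate is authoritative here and the
µm/s figure is informative only.

## Motility statistics

Operator chain per trajectory (all thresholds on `MotilityConfig`):

* **Smoothing**: second-order Savitzky–Golay filter, window 5 frames, both
  coordinates; endpoints use the polynomial fitted to the terminal window
  (`mode="interp"`), so polynomials up to order 2 are reproduced exactly and
  i.i.d. noise variance is reduced by the factor Σh² = 17/35 at interior
  points.
* **Speed**: positions boxcar-averaged over 9 frames; speed = displacement
  between consecutive window means / frame interval, in µm/s via the
  calibration object. A cell whose mean speed is below 12 µm/s is
  **non-motile** (the boundary value 12.0 itself is motile — the criterion
  is a strict "less than"). Non-motile cells keep their speeds (for
  population speed distributions) but are excluded from reorientation
  statistics.
* **Reorientation events**: at each interior time point of the smoothed
  track, the unsigned angle between the incoming and outgoing displacement
  vectors must exceed `angle_threshold` (25°) **and** the local filtered
  speed (mean of the two adjacent segment speeds) must fall below
  `speed_fraction` (0.70) of the trajectory's mean filtered speed, computed
  over the whole trajectory including tumble frames. Events closer than
  `min_event_gap` frames (2) are merged keeping the earliest — the
  deterministic, order-independent choice. Zero-length displacements have
  no defined angle; those points are skipped and logged. The phrase
  "minimal absolute change in angle" admits a second reading — the minimum
  of the pointwise angles over a short window — which is implemented as
  `angle_mode="window_min"`; the default is the pointwise reading, and no
  attempt is made to guess which was originally intended.
* **Runs and frequency**: runs are the intervals between consecutive
  events; the first and last segments touch the track boundary and are
  censored lower bounds. The per-cell reorientation frequency is the
  inverse of the mean run time, censored runs **included** by default
  (`include_censored_runs=False` restricts to interior runs).

### Bias of the per-cell frequency, and the rate estimator

For Poisson tumbling at rate λ observed for time T, a track with n events
has n+1 runs whose durations sum to T, so the per-cell frequency is
(n+1)/T with expectation λ + 1/T — biased upward by one boundary event's
worth per track (≈+7% at λ=0.5, T=30 s; ≈+17% at λ=0.2). Excluding censored
runs does not remove this bias (the expected mean spacing is still
T/(n+1)). For recovering the underlying tumble **rate** the package
therefore provides `population_tumble_rate` = total events / total observed
time over motile cells, whose event counts are Poisson and whose expectation
is exactly λ; validation shows it recovers λ ∈ {0.2, 0.5, 1.0} s⁻¹ within
10% at 200 cells × 30 s. The per-cell frequency is retained unchanged as
the assay's conventional per-cell statistic.

## ISCA statistics

* **Counts model**: pooled per-well counts are negative binomial with mean
  m = `control_mean` × effect × `sample_volume_ml` and variance
  m(1 + αm), α = `dispersion`. α → 0 approaches Poisson counting
  statistics; α = 0 is the deterministic limit (counts equal rounded
  means). The default α = 4·10⁻⁴ yields ≈20% between-plate CV at the
  default concentration (10⁵ cells/mL, 30 µL counted), matching the spread
  of biological ISCA replicates. Pooling of the five same-treatment wells
  is modelled as a single pooled measurement per plate × treatment.
* **I_C**: per plate, treatment concentration / same-plate control
  concentration; summarised across plates as mean ± SD. Exactly one
  control row per plate is required, with strictly positive concentration.
  Note E[T/C] = effect × (1 + CV²_control): the ratio estimator carries a
  small positive bias that is negligible at low dispersion but reaches the
  percent scale at the default CV — mean-recovery calibration checks
  therefore run at low dispersion (α = 2.5·10⁻⁵, larger counted volume),
  where the procedure's correctness is what is being tested.
* **Attraction test**: "one-sided ANOVA" against the control is realised as
  the one-sided treatment-versus-control contrast on per-plate
  concentrations — for two groups the one-sided Welch t-test — with the
  global one-way F-test reported alongside. With only I_C replicates
  available, a one-sample t-test of mean I_C > 1 is used. Identical
  constant samples return p = 1 (no evidence) rather than NaN.
* **Fold change**: ratio of mean I_C values, full precision in machine
  output, one decimal in summaries (the field's reporting convention).
* **Molarity**: mM = (mg/mL)/(g/mol)×1000. For polydisperse polymers the
  n-mer molecular weight is n × residue mass; laminarin (15–33 glucose
  units) uses the anhydro-glucose residue mass 162.14 g/mol, giving
  1.9–4.1 mM at 10 mg/mL.
* **Environmental screen**: per covariate, pairwise deletion of missing
  values (≥4 pairs required), Spearman's rank correlation with average
  ranks on ties, two-sided p, then Benjamini–Hochberg adjustment across all
  testable covariates (the adjustment method is recorded in the output
  metadata; constant covariates are reported as missing with a reason).

The environment-table generator plants covariates at a target Spearman ρ
via the Gaussian-copula relation r = 2 sin(πρ/6); |ρ| = 1 uses a monotone
transform of the index series and is therefore exact.

## Validation scope and problem sizes

The test suite and `scripts/acceptance.py` validate: exhaustive-enumeration
equivalence of the linker on 1000 random instances (≤6 particles × 10
frames); a simulate→render→track round trip on a 256×256 px field (12–20
cells, 1.5–2 s) recovering ≥95% of identities and positions within 0.5 px
RMS whenever the true tracks stay at least the detection separation apart
and per-frame motion is below half the gate; tumble-rate recovery within
10% at 200 cells × 30 s; attraction-test type-I error within 3 binomial SE
of 5% over 1000 null simulations and >80% power at a 2.6-fold effect;
and false-discovery control plus rank recovery of a planted ρ≈0.9 covariate
in the 61-variable screen (7-day null tables; 24-day tables for rank
recovery, matching daily sampling over a ~3-week campaign). These sizes
keep the full suite under two minutes while leaving every statistical band
at ≥3σ.

Passing these checks shows the operators are correct on data generated by
the stated models. It does not establish performance on real microscopy:
the renderer omits phase-contrast halos, motion blur and cell-to-cell
intensity variation; the simulator omits rotational diffusion (real runs
curve), speed fluctuation within a run, and chemotactic bias (tumble-rate
modulation along gradients — explicitly out of scope); and real tumbles
have continuous angle distributions, so a fraction of shallow real turns
will always fall below the 25° criterion and event counts are best read as
detector-defined, not mechanistically complete.

## Degenerate inputs and tie-breaking (summary)

Single-frame stacks, sub-window tracks, zero control counts, constant
covariates, non-finite parameters and empty detection frames are rejected
or reported with reasons rather than propagated. Detection conflicts keep
the brighter spot; linking ties resolve by sorted processing order; event
merging keeps the earliest frame. Tracks shorter than
max(`sg_window`, `speed_window`+1, `min_track_frames`) are dropped and
counted in the QC report.
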