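# Methods

## The decay model

Per cell, NAD(P)H fluorescence is modelled as a two-component mixture:
free NAD(P)H with lifetime τ_free and protein-bound NAD(P)H with
lifetime τ_bound, with amplitude fractions a1 and a2 = 1 − a1. The
per-cell summary is the amplitude-weighted mean lifetime
τ_mean = a1·τ_free + a2·τ_bound; a1/a2 is the redox proxy.

The expected arrival-time distribution over one laser repetition period
T is the periodised decay convolved with the instrument response:

- each component exp(−t/τ) is periodised with the geometric wrap factor
  1/(1 − e^(−T/τ)) — photons from earlier pulses that arrive in the
  current period are counted, which matters for τ_bound values that are
  an appreciable fraction of T;
- the mixture a1·e^(−t/τf) + a2·e^(−t/τb) is circularly convolved with
  a Gaussian IRF (FWHM `irf_fwhm`, centred at `irf_center`) on a fine
  grid (8× oversampled relative to the bin width, FFT convolution),
  integrated into the acquisition's bins and normalised to sum 1 over
  the binned window.

No pile-up or afterpulsing model is included: at the photon rates and
τ ≪ T regimes simulated here those corrections are second-order.

Note that normalising the *mixture* means a1 is an amplitude fraction,
not a photon fraction: the photon share of component 1 is
a1·τf / (a1·τf + a2·τb). All quantities reported by the package follow
the amplitude convention throughout.

## Acquisition defaults

Typical 80 MHz two-photon TCSPC settings, all overridable via
`AcquisitionConfig`: period 12.5 ns; 250 bins × 50 ps (window = full
period); Gaussian IRF FWHM 150 ps centred at 1.0 ns; background 0.02
expected counts per bin per pixel. `background_rate` may be zero (exact
zero-background simulations are useful for oracle comparisons), a
deliberate relaxation of strict positivity.

## Synthetic fields

`simulate_field` draws everything from a single `numpy` generator
seeded by `FieldLayout.seed`, in a fixed order (placement → per-cell
parameters → background counts → per-cell photons), so stacks are
bit-reproducible. Cells are random ellipses (semi-axes uniform in the
radius range, uniform orientation) placed by rejection sampling with a
bounding-circle overlap test and a 300-attempts-per-cell budget
(`PlacementError` beyond that). Photons are distributed over a cell's
pixels proportionally to the radial profile 0.25 + 0.75·(1 − ρ²)
(bright centre, dim rim, strictly positive inside the footprint);
per-pixel per-bin counts are independent Poisson draws.

Per-cell biological variability: a1 ~ Normal(a1_mean, a1_sd) clipped to
(0.01, 0.99); τ_bound ~ Normal clipped to (0.5, 6.0) ns. For condition
presets defined only by a published τ_mean mean ± SD, τ_mean is drawn
from that Normal and τ_bound solved per cell from the mixture identity
at the drawn a1.

### Presets

The two species presets store exactly solved parameters: a1 = 2.23/3.23
and a1 = 3.40/4.40 from the published a1/a2 values, with τ_bound from
inverting the τ_mean identity at τ_free = 0.4 ns (3.016 ns and
2.778 ns), so the identities return the published 1.21 / 0.94 ns and
2.23 / 3.40 exactly. Between-cell SDs (a1_sd 0.08 / 0.06, τ_bound_sd
0.55 ns) were calibrated once, analytically, via the delta method
var(τ_mean) ≈ (τb−τf)²·σ_a1² + a2²·σ_τb², to land the population τ_mean
SD on the published 0.27 and 0.19 ns.

The stress/temperature presets (`km_30C`, `km_45C`, `km_h2o2`,
`km_control`) and the secretion-strain presets built with
`preset_from_summary` carry only a published τ_mean mean ± SD; their
free fraction (0.70 ± 0.05) is a nominal yeast value, flagged here as
invented because no a1 was published for those conditions. The default
photon budget is 5×10⁴ signal photons per cell: pooled-ROI fitting at
that budget gives a per-fit τ_mean standard error well under 2%.

## Fitting

`fit_biexponential` maximises the Poisson likelihood of the per-bin
counts under μ = A·curve(a1, τf, τb) + b (flat background b ≥ 0),
which is the correct noise model for photon counting. Parameters are
transformed for unconstrained optimisation — logit(a1) bounded to
(0.001, 0.999), log τ_bound bounded to [0.5, 6.0] ns, log amplitude —
and minimised with L-BFGS-B from the fixed start (a1 = 0.7,
τb = 2.5 ns, A = total counts, b = 10⁻³). On optimizer failure one
restart is taken from a coarse grid-search optimum; persistent failure
is reported as `converged=False`, never silently. τ_free is fixed at
0.4 ns by default (the field's convention); when floated it is
log-transformed and bounded to [0.1, 2.0] ns, and components are
canonically reordered afterwards so component 1 is always the shorter
lifetime. Histograms below 500 photons are rejected outright
(`LowPhotonError`); the pipeline-level `fit_rois` drops such ROIs
(spurious specks) rather than aborting a whole field.

Goodness of fit is the Pearson reduced χ²: Σ(k−μ)²/μ over bins with
μ > 0, divided by (usable bins − number of free parameters).

The flat background is only weakly identified against the slow-decay
tail within a 12.5 ns period (per-fit SD ≈ 1 count/bin); it is unbiased
on average and τ_mean is insensitive to the trade-off, which is why the
background is fitted rather than fixed.

### Independent checks

- `fit_gridsearch_oracle` scans a1 × τ_bound on a fixed grid (default
  0.01 × 0.02 ns), profiling the amplitude analytically (for a unit-sum
  curve the Poisson amplitude MLE is the total count, reducing the
  profiled log-likelihood to Σ k·log p). It models no background and
  exists purely as a transparent reference: the MLE must agree with it
  to within the grid resolution in τ_mean.
- `phasor_transform` maps a histogram to (g, s) Fourier coordinates at
  ω = 2π/T, corrected by the analytic Gaussian IRF phasor.
  Mono-exponential decays land on the universal semicircle g² + s² = g;
  mixtures on the chord between component points at photon-weighted
  position. The phase lifetime s/(ωg) of the data is checked against
  the phase lifetime predicted from the fitted parameters (within 5% at
  ≥10⁵ photons). For a multi-exponential decay the phase lifetime is
  *not* the intensity-weighted mean lifetime, so no such equality is
  asserted — at ω = 2π/12.5 ns the two differ by ~25% for the
  K. marxianus mixture.

## Segmentation

Hand-drawn ROIs are replaced by a deterministic substitute: Otsu
threshold on the total-intensity image, 8-connected labelling, area
gate [30, 5000] px, border-touching components removed, relabelling in
raster order of first pixel. Because Otsu always produces a split even
on pure background noise, a contrast gate requires the foreground mean
to exceed 3× the background mean, otherwise the field is declared
empty. Touching cells merge into one component (no watershed
splitting); the simulator's non-overlap guarantee makes this moot for
synthetic fields. Whole-component masks are used — no attempt to
exclude vacuoles or restrict to cytoplasm. A label-image TIFF import
path supports externally drawn ROIs.

Lifetime maps use a fixed 256-entry blue→green→yellow→red ramp, linear
over 1.5–4.0 ns by default and clamped at the ends; the original
instrument vendor's exact LUT is not public, so colours are comparable
within this package only.

## Statistics

`choose_and_run_test`: Shapiro–Wilk on each group at α (default 0.05);
if either rejects — or a group is constant, where normality testing is
undefined (warned) — a two-sided Mann–Whitney U test is run (exact
enumeration for tie-free samples with both n ≤ 20, normal approximation
with tie correction otherwise). Otherwise Levene's median-centred test
at α decides between the unpaired t-test and Welch's t-test. All tests
two-sided; no multiple-testing correction (comparisons are reported
pairwise and unadjusted). Star labels follow the GraphPad convention
(ns > 0.05 ≥ * ≥ 0.01 > ** ≥ 0.001 > *** ≥ 0.0001 > ****). The whole
tree's type-I error stays near nominal (checked at [0.03, 0.07] over
1000 null simulations), even though the pre-tests condition the choice.

Group summaries are mean ± sample SD (n−1) over converged fits only;
a1/a2 is averaged per cell (not the ratio of group means), matching the
per-cell philosophy of violin summaries — with n = 1 the SD is reported
as 0 with an explicit `sd_defined=False` flag.

`compute_redox_ratios`: NADH/NAD⁺ and NADPH/NADP⁺ per replicate; the
combined NAD(P)H/NAD(P)⁺ uses the pooled-sum convention
(NADH+NADPH)/(NAD⁺+NADP⁺) by default, with the mean-of-pair-ratios
alternative behind `pooled=False` (sources rarely state which
convention was used; the two differ whenever the pair ratios differ).

## Pipeline and reproducibility

`run_experiment` derives per-condition integer seeds from the config
seed via `SeedSequence`, and writes per-condition stacks, ground truth,
labels, per-cell CSVs (fixed 6-decimal formatting), lifetime maps, a
comparisons JSON and a manifest (config echo, per-stage record counts
and wall times, SHA-256 of every output). CSV/JSON outputs are
byte-identical across reruns of the same config+seed; PNGs are
pixel-identical. The manifest is written on failure too, recording the
failing stage.

`reproduce_paper_suite` re-enacts five published two-group comparisons
at their published cell counts: species (101 vs 52), 45 °C vs 30 °C
(112 vs 68), H₂O₂ vs control (69 vs 66), and high- vs low-yield
secretion strains at day 1 (105 vs 94) and day 3 (79 vs 91). The day-1
and day-3 experiments compare the two secreting strains only: the
empty-vector control summaries needed to simulate all published
four-group pairs are not all available (the day-1 low-yield control
mean was not printed), so those pairs are out of scope. Full-scale, the
suite runs in a few minutes on one CPU; `n_scale` and
`photons_per_cell` shrink it for smoke tests.

## What the synthetic data does and does not show

The generator reproduces the statistical structure of pooled-ROI TCSPC
data — IRF convolution, wrap-around, Poisson noise, uniform background,
between-cell parameter spread, cell-shaped footprints — so passing
tests demonstrate that the fitting and statistics recover known truth
under that model. It does not emulate detector afterpulsing or pile-up,
scanner distortion, intra-cell lifetime heterogeneity (vacuoles,
mitochondria), cell-cycle or focus effects, or any deviation of real
decays from a clean two-component mixture. Agreement on synthetic data
therefore validates the analysis chain, not the biology; applying the
chain to real stacks requires the usual instrument-specific IRF
calibration.

## Problem sizes used by the reference scripts

The acceptance script fits 100 histograms of 5×10⁴ photons per species
(the per-ROI budget that gives <2% τ_mean error), one 10⁵-photon
mono-exponential control, and 50 repetitions of each group comparison
at the published n; this completes in seconds. The default test suite
uses the same budgets with fewer replicates plus reduced-size field
simulations, chosen to keep the whole suite well under a minute of
simulation time while leaving every statistical margin comfortable.
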