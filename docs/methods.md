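# Methods

## The releaser–consumer–organosulfur model

The core object is the pool balance for a metabolite shared between a
releasing population *R* and a consuming population *C*:

    dO/dt = r·R − c·g_C(O)·C − d_eff·O

with per-cell release rate *r* (fmole GSH-equivalent·cell⁻¹·h⁻¹) and
consumption charged per consumer birth, i.e. at rate c·g_C·C
(*c* in fmole·cell⁻¹). At steady state, where both genotypes grow at the
shared rate *g*, the balance reduces to r·R = c·g·C and predicts
C/R = r/(c·g) (`predict_steady_ratio`).

The balance alone does not close the dynamics: consumer growth below steady
state and the dilution regime during competition are not observable from
steady-state measurements. We close them as model decisions:

- **Consumer uptake**: Monod, g_C(O) = g_max·O/(K + O). Defaults
  g_max = 0.35 h⁻¹ (a plausibly unrestricted doubling time of ~2 h) and
  K = 10⁵ fmole/mL. Both are free parameters; the predicted steady-state
  *ratio* does not depend on them (they only set O* = K·g/(g_max − g) and
  the relaxation speed).
- **Dilution** (`simulate_coculture` modes): `serial` chooses d_eff at each
  instant so total cell density stays constant, mimicking batch cocultures
  periodically diluted to a fixed OD; `chemostat` uses the fixed device
  rate; `batch` uses zero (for mass-budget checks). The pool is diluted
  alongside the cells.
- **Releaser growth** is pinned at *g*: the releaser is limited by its own
  auxotrophic nutrient (lysine), not by the organosulfur pool.

Because the pool itself washes out, the closed model's fixed point sits
slightly below the idealized ratio: solving r·R = c·g·C + g·O* at total
density N gives

    C/R = (r − g·O*/N) / (c·g + g·O*/N),

exposed as `coculture_fixed_point`. The correction g·O*/N is the pool
washout charged per releaser cell; with the default parameters it is ≈5 %
at N = 3×10⁶ cells/mL and <2 % at 10⁷ cells/mL, and vanishes as N grows.
Tests of the idealized 5 %-agreement property therefore run at
chemostat-like densities (10⁷/mL), while convergence tests at 3×10⁶/mL pin
the exact closed-model fixed point.

**Integration**: `scipy.solve_ivp` (LSODA), rtol 10⁻⁸, absolute tolerance
scaled to the initial state. Two auxiliary integrals (releaser cell-hours
and consumer births) ride along so the organosulfur budget
r·∫R dt − c·births − ΔO can be checked to solver tolerance in batch mode.
Tiny negative excursions are clipped; anything beyond 10⁻⁶ of the state
scale raises a numerical error. Halving the output step changes the final
ratio by far less than 0.1 %.

**Units**: concentrations internally in fmole/mL (1 μM = 10⁶ fmole/mL),
densities in cells/mL, time in hours, generations = t·g/ln 2.

## Measurement stack

**Release rate** (`estimate_release_rate`): r = dil × mean(O)/mean(live)
over a steady-state window, by default the last quarter of the series
(user-overridable). Requires strictly positive live density in the window.

**Device math**: f = ln 2·V/T_D; dil = ln 2/T_D; OD = log₁₀(I/I₀) exactly
as the culture device logs it (the sign convention of the instrument is
kept literally; `conventional=True` flips to −log₁₀(I/I₀)).

**Dead-cell attribution**: the lysis bound is dead density × mean per-cell
content; a measured supernatant pool above that bound cannot be explained
by lysis of every dead cell and is flagged as live-cell release.

**HPLC** (`hplc_quant`): analysis restricted to a half-open retention-time
window, default [6.5, 8.0) min around the ~7-min glutathione conjugate.
Peak = global maximum in the window that is also a strict local maximum;
plateaus use their center index, ties among separate equal maxima resolve
to the earliest retention time; an edge maximum means "no peak". Baseline =
the straight line through the nearest local minima flanking the peak
(plateau centers again); when a flank reaches the data boundary without a
local minimum the boundary point is used and flagged. Corrected signal is
exactly zero at both anchors. Area = trapezoid rule (the convention for
finely sampled traces; matches closed-form Gaussian areas to <0.1 % at fine
sampling). Standard curve = OLS of area vs concentration; the calibrated
range (default 0.03–1 μM) bounds trustworthy back-calculation, and
out-of-range estimates are reported with flags rather than censored —
downstream arithmetic needs the numerics, the flags carry the caveat.
Negative corrected samples are kept and flagged, not clipped. No smoothing
is applied by default. Replicate areas of one derivatized sample re-run
over a day are expected to agree within 10 % (`REPLICATE_AREA_TOLERANCE`,
a documented constant, not something the package re-measures).

**LC–MS**: isotope-dilution ratio, conc = (A_analyte/A_IS)·n_IS/V, with
pmole/μL ≡ μM.

**Bioassays** (`bioassay`): yield mode fits mean final OD vs concentration
by OLS over an explicit linear range (default 0–2 μM GSH); the detection
floor is blank mean + 2·blank SD (our convention; with no blanks the lowest
standard stands in, with a warning). Replicates are summarized by the mean,
with fit covariance propagated to a reported standard error. GS-SG counts
as exactly two GSH equivalents everywhere. Rate mode inverts a monotone
(concentration, max growth rate) calibration by piecewise-linear
interpolation — no parametric form is imposed — so its accuracy depends on
the density of the standard series relative to the curvature of the
rate–concentration relation.

**Window statistics** (`kinetics_fitness`): slopes inside windows are
always least squares on the (possibly uneven) time or generation axis.
Maximal growth rate uses 4-point windows whose *last* point is at or below
25 % of the series maximum, guaranteeing at least two doublings of headroom
before saturation; if no window qualifies (a flat series has none) all
windows are used and a warning is raised, so a constant series reports 0
rather than failing. Relative fitness is the steepest 3-point-window slope
of ln(count ratio) per generation divided by ln 2; windows containing a
zero count are skipped (no pseudocounts), equally steep windows resolve to
the earliest, and the starting fraction is taken at the chosen window's
first point. The generation/hour axis is explicit input, never inferred.
Death rate is −slope of ln intensity from the global peak (first
occurrence) to the end; a never-declining series reports 0 with a flag.
Auxotroph frequency is the colony-count-weighted mean of per-size-class
auxotroph fractions.

## Synthetic data

The generators emulate the study conditions, not any particular dataset:

- **Chemostat** (`gen_chemostat_series`): Monod growth on the limiting
  nutrient (default g_max = ln 2/1.6 h⁻¹, K = 0.5 μM), reservoir 21 μM,
  yield 7×10⁶/21 ≈ 3.33×10⁵ cells·mL⁻¹·μM⁻¹ — the only pair consistent
  with a 7×10⁶ cells/mL target density — inoculum 10⁵/mL, constant
  per-capita death with presets 0.10 h⁻¹ (lysine-limited) vs 0.01 h⁻¹
  (glucose-limited) to mirror the qualitative death contrast between the
  two limitations. The presets are illustrative, not measurements; note
  the lysine preset implies a large dead pool at 8-h dilution. The pool
  obeys dO/dt = r·N_live − dil·O, so release is attributed to live cells
  by construction.
- **Chromatogram**: Gaussian peaks (default one at 7.0 min, σ 0.05 min) on
  a linear drifting baseline, additive Gaussian detector noise.
- **Plate**: OD = min(blank + slope·conc_equiv, saturation), GS-SG wells at
  twice the equimolar GSH response, log-normal multiplicative noise.
- **Competition**: deterministic consumer fraction from the coculture model
  sampled once per generation; with noise enabled, counts are binomial
  draws of `sampling_counts` events (flow-cytometry counting statistics);
  with noise silent, exact expected counts are emitted so monotonicity
  properties hold sample-to-sample.
- **Fluorescence**: exponential growth to a switch time, exponential decline
  after; re-normalized so the first sample is exactly 1 even under noise.

Noise is multiplicative log-normal with unit mean on positive-valued
measurements and additive Gaussian on detector signal. The magnitudes are
free parameters — the study reports none — so passing recovery tests
demonstrate correctness of the estimators under the assumed noise
structure, not instrument-level realism. Real data additionally carry
retention-time drift between runs, plate position effects, matrix effects
in rate-mode bioassays and non-stationary chemostat upsets, none of which
are modelled. Fixed seed + parameters ⇒ bit-identical output everywhere.

## Problem sizes

Defaults keep everything desk-scale: coculture simulations of 60–110
generations (≤900 h) at 1–4 h output steps, chemostat runs of 120–400 h,
chromatograms of ~600–1500 points, plates of ≤36 wells. The full test
suite and the acceptance script each complete in seconds.

## Known limitations

- The Monod closure parameters (g_max, K) are not identifiable from
  steady-state data; only ratio predictions, not transient time scales,
  should be trusted.
- The serial-dilution mode holds total density exactly constant; real
  periodic dilution oscillates around a set point.
- Rate-mode bioassay accuracy is bounded by the interpolation grid of the
  standard series (a few percent for two-fold dilution series near the
  half-saturation region).
- The colony-screen estimator assumes size classes are screened
  representatively; it propagates no sampling uncertainty.
- Evolutionary dynamics (new mutations, invasion probabilities), lysine
  dynamics of the partner strain, and spatial structure are out of scope.
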