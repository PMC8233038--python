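# Methods

## Model

The package treats an actin cable as a single length coordinate
L_cable(t) growing from the bud neck (L = 0 at t = 0, the moment of
emergence). The net extension rate is the difference between assembly and
disassembly, summarised by a feedback function of the normalized length
x = L_cable/L_cell:

    dL_cable/dt = f(x),   x = L_cable / L_cell.

Scale invariance of f is the only structural assumption: because f
depends on the ratio alone, the steady state x\* (the zero of f) yields
L\* = x\* L_cell, i.e. proportionality of cable length to cell length.
Early-time expansion f(x) ≈ f(0) + f'(0)x gives the exponential solution
used throughout (`closed_form_length`, `closed_form_rate`) and the
initial deceleration d0 = f(0) f'(0)/L_cell. For the `linear` and
`gradient_linear` families f is exactly linear in x, so these "early
time" formulas are exact at all times; for `gradient_exp` they are a
small-x approximation and the package integrates the ODE (RK4) where
exact lengths are needed.

Feedback families and their parameters (units µm/s unless noted):

| family | form | parameters |
|---|---|---|
| `linear` | f0 (1 − x/x\*) | f0 > 0 plus either x\* > 0 or f'(0) < 0 (the other is derived via f'(0) = −f0/x\*) |
| `gradient_linear` | f0 − k_dis·x | assembly f0, disassembly slope k_dis > 0; x\* = f0/k_dis |
| `gradient_exp` | f0 − A e^{(x−1)/λ}, A = f0 e^{(1−x\*)/λ} | gradient highest at the rear (x = 1), amplitude normalised so f(x\*) = 0; λ > 0 dimensionless decay length |
| `boundary` | f0 for x < x_max, else 0 | the boundary-sensing alternative; no smooth kinetics |

For `gradient_exp` the parameter f0 is the constant assembly term, not
the initial rate; f(0) = f0(1 − e^{−x\*/λ}) and f'(0) are exposed as
`rate_at_zero` / `slope_at_zero` and are what the closed forms use.

The `linear` family is deliberately constructible from (f0, f'(0)) as
well as (f0, x\*): the two deceleration predictions compare strains that
share a slope but differ in initial rate, which the (f0, x\*)
parameterisation cannot express.

Cell geometry: mother cells are ellipsoids whose measured length, width
and height are diameters; volume = (π/6)·L·W·H, aspect ratio = L/W. The
neck-to-rear cortical arc (half the meridian-ellipse perimeter,
Ramanujan's second approximation, error < 1e−5) is provided because
cables running along the cortex can exceed the straight cell length;
whether steady-state cables are compared to the cell length or the
cortical path is left to the caller — the kinetics always normalize by
cell length.

## Synthetic data

The generators emulate two acquisition modes.

**Live-imaging trajectories** (`simulate_cohort`,
`simulate_observed_trajectory`): frames every 3.0 s (middle of the
0.30–0.43 frames/s acquisition range) for 120 s; default cohort 82
cables. Per frame the latent length advances by the model's exact
noise-free growth over the interval, multiplied by (1 + ε) with
ε ~ N(0, rate_noise_cv) and floored at zero (polymerisation
stochasticity); observed lengths add N(0, tip_noise_sd_um) localisation
noise, clipped at zero (tracking error). Defaults rate_noise_cv = 0.3 and
tip_noise_sd = 0.05 µm give mean-rate confidence bands of the same order
as measured curves. Two deliberate choices:

* The deterministic part of each increment is the exact interval
  solution (closed-form relaxation step for the linear families, RK4
  substeps for `gradient_exp`), not a first-order Euler step. An
  Euler-discretised latent process at 3 s frames is a *different* model
  from the ODE and biases downstream length-space fits by ~10%; with the
  exact step, zero noise reduces the generator to the noise-free model
  identically and estimates are unbiased.
* A consequence worth knowing: the measured "initial rate" — the
  first-interval rate, exactly as a tracking pipeline computes it — is
  the interval average L(Δt)/Δt (≈ 0.32 µm/s for f0 = 0.36 at 3 s
  frames), slightly below the instantaneous f(0). The same attenuation
  affects real tracking data.

**Fixed-cell snapshots** (`simulate_fixed_snapshot`): each cable is
observed at a time drawn uniformly on [0, window] and reports the
noise-free model length — the simplest account of why fixed ensembles
show a wide range of cable lengths (cables caught at different growth
stages) but a narrow range of cell lengths. The uniform observation-time
and one-cable-per-cell assumptions are invented simplifications; cable
nucleation statistics and per-cell cable counts are not modelled.

**Steady-state fluctuations** (`simulate_steady_state_fluctuations`):
Euler–Maruyama integration of the feedback linearised about L\*,
dL = f'(x\*)(L − L\*)/L_cell dt + σ dW — an Ornstein–Uhlenbeck process
whose stationary variance σ²L_cell/(2|f'(x\*)|) grows with cell length
because the feedback weakens. σ (µm/√s) is a free noise amplitude, not a
measured quantity. The recursion is evaluated as an AR(1) filter, so long
(10⁵ s) traces are cheap; the step is rejected when dt·|f'(x\*)|/L ≥ 2.

**Strain presets** (`PRESETS`): published mean mother-cell lengths,
length ranges, volumes and initial rates for haploid, diploid, uninduced
and induced *cdc28-13ts*, and *smy1Δ* cells. Cell lengths are sampled
from a normal truncated to the published range (sd = range/4), widths via
a truncated-normal aspect ratio (mean 1.2, sd 0.15, floor 1.0), height =
width. Only the haploid range is published; other ranges rescale it
proportionally, and the diploid mean length is taken from its mean cable
length (cables grow to cell length). Two wild-type initial rates coexist
in the literature values (0.36 µm/s in the main live-imaging cohort,
0.35 µm/s in the series matched to *smy1Δ*); the haploid preset carries
0.36 and `WT_RATE_SMY1_EXPERIMENTS` = 0.35 is used for the *smy1Δ*
comparisons.

What passing tests on these data do **not** show: robustness to tracking
drop-outs, crossing cables, photobleaching, cable-cable competition for
monomers, or cell-to-cell parameter heterogeneity — none of which the
generator produces.

## Quantification

* Arc length of traced cables: Euclidean polyline sum.
* Interval rates: (L_{i+1} − L_i)/(t_{i+1} − t_i), attributed to the
  interval start (the tracking convention); the first element is the
  initial rate.
* Initial deceleration: OLS slope of rate vs time over the first 10 s
  (configurable), 95% CI from the slope standard error. Note the
  estimator is *attenuated*: over a 10 s window at 3 s frames the
  exponential curvature plus interval averaging shrink the slope to
  ~0.63 of the true d0 (noise-free, wild-type parameters), and the
  4.3-vs-8.2 µm slope ratio to ~1.5 versus the exact inverse-length
  ratio 1.9. The exact ratios are properties of d0 = f(0)f'(0)/L_cell
  itself (`initial_deceleration`); the regression converges to them as
  the window and frame interval shrink, which the tests verify. This
  attenuation also explains why regression-based d0 magnitudes
  (≈ −0.018 µm/s² at these settings) sit below f(0)f'(0)/L_cell
  (−0.0288 µm/s²) — a feature shared with any tracking pipeline using
  the same window.
* Aggregated rate curves: binned along time, length, or normalized
  length (default bin 0.5 µm; length axes require an explicit bin
  width). Cables are the unit of replication: within a bin each cable is
  averaged first and the 95% CI is the t-interval over per-cable means.
  Cables contribute only while still tracked; empty bins are dropped.
* Length-ratio statistics: elementwise cable/cell ratios, t-based CI,
  Gaussian KDE (Silverman bandwidth) on a fixed grid.

The normalized-length collapse — rate-vs-x curves from cells of
different size coincide — is exact only as a statement about the
underlying dimensionless dynamics. Finite 3 s frames sample different x
values in cells of different length, so binned curves from fixed-interval
recordings collapse to discretisation accuracy (~percent), while sampling
on a shared dimensionless grid (frame interval ∝ cell length) collapses
them to machine precision; the test suite demonstrates both.

## Inference

`CableGrowthModel.fit()` estimates (f(0), f'(0)) shared across cables by
nonlinear least squares of observed lengths against the early-time
solution, each cable's L_cell fixed to its own cell (`method="length"`,
default; analytic Jacobian, 5 seeded multi-starts within ±50% of a
data-driven start, tolerances 1e−12, bounds f0 > 0, f'(0) < 0). Fitting
in length space integrates out frame-level noise; because growth noise
accumulates along a cable, residuals are correlated within cables and the
covariance is the cable-clustered sandwich estimator with t critical
values on n_cables − 2 df. Monte-Carlo calibration at the default noise
level puts 95% CI coverage of f0 at ~92–96%. `method="rate"` is an
independent cross-check: pooled regression of interval rates on the
interval-*midpoint* normalized length (midpoint attribution cancels the
interval-averaging slope attenuation, ~0.89 at 3 s frames, to < 1%).

`select_model` fits the pooled interval rates under both hypotheses —
exponential decay f(0)e^{f'(0)t/L_cell} (balance point) vs constant rate
with a changepoint in normalized length found by exhaustive search
(boundary sensing), two shape parameters each — and compares
Gaussian-likelihood BIC (AIC by flag). Degenerate inputs (all rates
equal) are reported as a flagged tie resolved toward boundary sensing by
parsimony. At noise CV 0.2 with 82-cable sets both generators are
identified essentially always.

## Scaling analysis

Power laws y = A xᵃ are fitted by OLS of log₁₀y on log₁₀x (a = slope,
A = 10^intercept, R² of the log-log fit, CI from the slope standard
error) — matching plain double-log fitting. No errors-in-variables
correction is applied; noise in x attenuates the exponent toward zero,
which is a caveat when x is itself a measured length. Shape
stratification bins cells by aspect ratio rounded to the nearest quarter
(midpoints round up); classes with n < 3 are reported without a fit and
flagged. Isometric synthetic data fit against the volume of self-similar
cells return a ≈ 1/3 — the hypoallometric signature of a structure
tracking a linear dimension.

## Numerical choices

* RK4 fixed-step integration; `integrate_growth` raises if a step ever
  decreases the length by > 1e−9 µm.
* `gradient_exp` steady state located by Brent root-finding on
  (0, 10x\*] at relative tolerance 1e−12 (an internal consistency check;
  the parameterisation places the zero at x\* analytically).
* CSV round-trips are exact: floats written as %.17g and parsed with
  pandas' `round_trip` converter.
* Degenerate regressions (two points, zero residual df) report an
  infinite CI half-width rather than a spurious zero.

## Problem sizes

The test suite and acceptance checks use the study-scale defaults —
82-cable cohorts, 120 s recordings at 3 s frames, 200 replicates for CI
calibration, 100 trajectory sets per generator for model-selection
accuracy, 10⁵ s Langevin traces, snapshot ensembles of 10⁴ — which run
in well under a minute each on one CPU.

## Known limitations

* The true shape of f is not identified by the data this package
  emulates: measured decelerations suggest |f'(0)| below the
  linear-family value f0/x\*, i.e. a nonlinear f. Both (f0, x\*) and
  (f0, f'(0)) parameterisations are exposed; no particular shape is
  claimed.
* One cable per cell; no competition for a shared monomer pool, no
  molecular mechanism (formin kinetics, Smy1 transport, disassembly-
  factor gradients are phenomenological only).
* No Bayesian or hierarchical (per-cable random effect) inference.
* The boundary-model changepoint search assumes a single shared
  normalized stopping length across cables.
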