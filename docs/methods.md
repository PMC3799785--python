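# Methods

## The rigid-body drag model

The model applies to fishes that hold the body rigid while powering
prolonged swimming with oscillating pectoral fins, so that the body is
hydrodynamically a towed streamline body of revolution and the only body
force relevant to shape optimisation is parasite drag.  Its two parts are:

1. **Drag on a body of revolution.**  The volume-specific drag coefficient
   is `C_D = C_f(Re) * g(f)`, drag referenced to `V^(2/3)`.  The
   skin-friction laws are the Blasius laminar solution
   `C_f = 1.328 Re^-0.5` (calibration band Re 1e4-1e5) and the
   semi-empirical transitional law `C_f = 0.427 (log10 Re - 0.407)^-2.64`
   (band 1e5-1e6).  The fineness polynomials are the classical
   streamline-body forms: transitional
   `g(f) = 4 f^(1/3) + 6 f^(-7/6) + 24 f^(-8/3)` (the volume-specific
   equation whose fixed-Re minimum, f = 4.65, is the "traditional" optimal
   fineness of the fish literature), and laminar
   `g(f) = 4 f^(1/3) (1 + 1.5 f^(-3/2) + 7 f^(-3))`, i.e. the wetted-area
   form factor combined with the wetted-area-to-volume conversion
   `S / V^(2/3) ~ 4 f^(1/3)`.  Both transcriptions were validated against
   two independent anchors before anything was built on them: the fixed-Re
   transitional minimum at f = 4.6-4.7, and the strict monotone decrease of
   the laminar constant-volume C_D(f).
2. **From drag to speed.**  Froude efficiency `eta = D U / P` rearranges,
   with `D = 0.5 rho U^2 V^(2/3) C_D`, to
   `U_max = (2 eta P_max / (rho V^(2/3) C_D))^(1/3)`.  Because `C_D`
   needs `Re(U_max)`, the speed is a fixed point, found by iterating from a
   seed of two body lengths per second to a tolerance of 0.001 m/s
   (typically 3-5 iterations; non-convergence after `max_iter` = 100 is
   reported, never silently truncated).  With `C_D` frozen the closed form
   is returned in one step.

Regime choice is always explicit.  The laminar model is the appropriate
one for small reef fishes (measured Re about 6e3-8e4); the transitional
model is kept for comparison with the traditional optimum.  Warnings (not
errors) flag Reynolds numbers outside a law's calibration band.

### Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| rho (water density) | 1025 | kg m^-3 | seawater; cancels out of modeled U_max when M = rho V |
| nu (kinematic viscosity) | 8.8e-7 | m^2 s^-1 | seawater at ~27 degC, 35 g/kg — tropical reef conditions |
| Cp (prismatic coefficient) | 0.65 | — | typical streamline body; admissible up to 4/pi (the exact cube-equivalent body) |
| eta (Froude efficiency) | 0.34 | — | mean of simulated peak efficiencies of rowing (0.09) and flapping (0.59) pectoral fins |
| muscle power | 16.5 | W kg^-1 muscle | sustained pectoral-fin muscle output (bluegill) |
| muscle fraction | 0.019 | — | propulsive pectoral muscle mass / body mass |

The viscosity default deserves a note: tabulated 1.0e-6 m^2 s^-1 is fresh
water at 20 degC, whereas the fishes modelled here live and were tested in
tropical seawater, for which nu ~ 0.88e-6 m^2 s^-1.  The constant-volume
optima shift by roughly +0.05 units of fineness per 10% increase in nu, so
the physically appropriate value matters at the 0.1-fineness resolution
the sweeps report.  With the defaults, the transitional sweeps give a
C_D-minimising fineness of 6.3 and a U_max-maximising fineness of 6.4
(grid 1-20 by 0.1, quadratic-refined, reported to 0.1); the efficiency and
power parameters set only the elevation of U_max(f), not the location of
its optimum.

### Slope table

`slope_table` reports central-difference slopes of U_max(f) at integer
finenesses.  Two normalisations are provided, because either reading is
defensible: `percent` (default) expresses the slope as a percentage of the
local U_max per unit fineness, `raw` leaves m/s per unit fineness; a
standardised slope `alpha * SD(f) / SD(U)` is added when the caller
supplies trait SDs from a comparative sample.  Points without a
central-difference margin inside the sweep grid are rejected, so slopes
start at f = 2 when the grid starts at the physical lower bound f = 1.

## Morphometrics

Fineness of a real (elliptical-section) fish uses an equivalent diameter
matched to propulsion mode: geometric mean `sqrt(d b)` (equal-area circle)
for rigid-bodied MPF swimmers, for whom the narrower dimension dominates
flow separation; elliptical mean (equal-perimeter circle) for undulating
BCF swimmers, whose attached flow makes wetted surface the relevant
standard.  The elliptical mean defaults to the first-order perimeter
approximation `d_e = sqrt((d^2 + b^2)/2)`; an exact elliptic-integral
option exists, and the approximation overestimates it by <1% below 1.5:1
depth:breadth, ~2.5% at 2:1 and ~5% at 3:1 — an acceptable bias given that
the choice of equivalent-diameter convention itself shifts fineness far
more.  Pectoral-fin aspect ratio is doubled (`2 L^2 / A`) to match the
aerodynamic wing convention; caudal AR is `h^2 / A`.

## Statistical pipeline

* **Design.** Within each gait, `log U_max` is regressed on `f`, `f^2`,
  `AR`, `log M`; all variables are mean-centred and scaled to unit SD, and
  `f^2` is squared *after* centring but *before* scaling so the linear
  coefficient is the slope at the mean fineness.
* **pGLS.** Residual covariance is the Brownian tree covariance with
  off-diagonals scaled by Pagel's lambda; lambda is re-estimated per
  candidate model by maximising the ML profile likelihood on [0, 1]
  (bounded scalar search, endpoints checked).  lambda = 0 reduces exactly
  to OLS; on an ultrametric tree the constant diagonal is absorbed into
  sigma^2.  Coefficient P values are two-sided t tests with df = n - p.
* **Selection and averaging.** All 16 subsets (including intercept-only;
  `f^2` allowed without `f`) are ranked by
  `AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)`, k counting coefficients,
  sigma^2, and lambda when a tree is supplied.  Retention keeps
  dAICc <= 2 plus a soft margin (default 0.2) that admits just-over-the-
  line models; averaging is *conditional* — per predictor, Akaike weights
  are renormalised over retained models containing it, and a predictor in
  no retained model is reported absent, not zero.  The unconditional
  (selection-aware) SE `sqrt(sum w (se^2 + (b - bbar)^2))` accompanies
  each average.
* **Bootstrap.** Species rows are resampled with replacement; each
  pseudo-sample is re-standardised and re-run through the full enumeration
  before averaging (a flag freezes the original model set instead), so the
  50/75/95% percentile intervals include model-selection uncertainty.
  Replicates in which a predictor drops out of every retained model
  contribute no draw for it (counted and reported).
* **Mechanistic fit.** Measured speeds are adjusted by the residuals of
  OLS of raw `U_max` on `M^(1/3)` and `AR` (re-anchored at the grand
  mean); the drag model, evaluated at the group-mean body volume and each
  species' fineness, is re-centred to the adjusted mean and scored as
  `R^2 = 1 - SS_res / SS_tot` (negative values are reported as computed).
  Significance uses permutations of the adjusted speeds with
  `P = (g + 1)/(N + 1)`, which is strictly positive and exact under
  exchangeability.
* **Contrasts.** Felsenstein's independent contrasts (weighted ancestral
  averages, branch lengthening, contrasts standardised by sqrt of summed
  branch lengths) with correlations through the origin; polytomies are
  resolved with zero-length branches, under which a star phylogeny
  reproduces the raw Pearson correlation exactly.  A zero-length sister
  pair with unequal values has no defined contrast and raises.
* **Quadratic optimum.** The averaged `f`/`f^2` coefficients are mapped
  back through the standardisation metadata to the raw fineness scale:
  the response is stationary at `f = c - b1 s_q / (2 b2 s_f)`; the
  combined standardised linear effect `b1 + 2 b2 (s_f/s_q)(f0 - c)` is
  reported at the sample's fineness extremes, and an upward-opening
  quadratic is flagged as having no interior maximum.

## Synthetic data

The generator emulates the structure the analysis assumes, not any real
dataset: two gait groups (default n = 55 MPF / 29 BCF), predictors drawn
multivariate normal with correlations (f,AR) = 0.3, (f,logM) = -0.3,
(AR,logM) = 0.3, default true standardised coefficients
(0.1, -0.25, 0.75, 0.2) and residual SD 0.447 — chosen so the linear
predictor has approximately unit variance and the model explains ~80% of
the response, a strongly fin-driven system.  Trait scales mimic small reef
fishes (fineness ~1.5-8, U_max ~0.1-1 m/s, masses ~1-200 g).  Fineness is
drawn first and depth/breadth are back-solved (breadth:depth uniform on
0.3-1.0) so the morphometric derivation returns the drawn fineness
exactly, keeping that module inside every tested loop.  Residuals are
white noise or, for lambda_true > 0, a sqrt(lambda)/sqrt(1-lambda) mixture
of Brownian motion on a pure-birth (Yule) tree and white noise, which
realises the lambda covariance model exactly.  A second generator draws
U_max from the drag model itself (plus lognormal noise) to cross-validate
the mechanistic and statistical halves.

What the generator does **not** emulate: measurement error in the
morphometrics, non-normal trait distributions, correlation between
phylogeny and the predictors (only the residuals carry signal), or the
real study's species composition.  Passing tests therefore demonstrate
that the pipeline recovers known truth under its own assumptions, not that
those assumptions hold for reef fishes.

## Problem sizes and numerical choices

Fineness sweeps use grid 1-20 by 0.1 (0.01 for the fixed-Re bracket) with
3-point quadratic refinement of the best grid point, reported at 0.1
resolution.  Recovery simulations in the test suite use n = 200 species
and 100 replicates for lambda, n = 100 and 200 replicates for coefficient
coverage, 199-permutation tests over 200 seeds for null uniformity, and
reduced bootstrap sizes (B = 99-199) for interval behaviour; these sizes
give Monte-Carlo error comfortably inside the asserted tolerances.  Ties
in the quadratic refinement (flat three-point neighbourhoods) fall back to
the grid point.  Bootstrap covariance matrices for resamples with
duplicated species are handled by the lambda < 1 covariance remaining
positive definite; a singular lambda = 1 candidate is rejected inside the
ML search.

## Known limitations

* The drag model ignores fin-wake/boundary-layer interaction, flutter,
  and eccentricity of the transverse section (drag equations are for
  axisymmetric bodies).
* Thrust-producing undulating bodies (BCF swimmers at speed) violate the
  rigid-body assumption; for them the package offers only the statistical
  pipeline, not a mechanistic prediction.
* Published tabulations of the slope of U_max(f) mix normalisations; both
  are implemented, and only the sign/ordering pattern (positive and
  decreasing laminar slopes; transitional sign change between f = 6 and 7)
  is asserted.
* AICc *levels* depend on the parameter-counting convention for k; the
  ranking (dAICc) does not, provided the convention is consistent, which
  is what model retention and averaging rely on.
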