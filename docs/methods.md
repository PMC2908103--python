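# Methods

## Response model

A scanner reading a spot of dye at surface density *x*
(fluorophores/µm²) is modelled as

    SI(x) = B·x^a + g

with sensitivity B > 0 (counts per (fluorophores/µm²)^a), curvature
exponent a > 0 (dimensionless; a = 1 is a linear detector), and
autofluorescence offset g ≥ 0 (counts). The model assumes the dye and
background contributions add, that the background is uniform across the
slide, and that the power law holds over the whole unsaturated range.
Signal intensities are treated as continuous non-negative reals; integer
ADC quantization is available in the simulator (`quantize=True`) but not
imposed by the model. Inversion (signal → density) is defined only above
g: a signal at or below the background floor carries no information
about dye quantity, and the package refuses to extrapolate there.

Consequences used by the diagnostics: in log-log coordinates
log(SI − g) is linear in log x with slope a; where B·x^a ≪ g the
measured signal plateaus at g (the plateau is a slide artifact, not
detector nonlinearity); 16-bit detectors clip at 65535 counts (the
default ceiling, configurable).

## Merit function and fitting

Calibration data span ~8 decades in x and ~5 in SI, so ordinary least
squares is dominated by the few brightest columns. The fit minimizes the
sum of squared relative residuals

    E = Σ_i [(SI_i − f(x_i)) / f(x_i)]²,   f(x) = B·x^a + g,

equivalent to weighted least squares with weights 1/f². E is invariant
under a common rescaling of all signals together with B and g, which is
what makes merit values comparable across PMT gains.

Numerics:

* Optimization runs in (log B, a, g) coordinates with
  `scipy.optimize.least_squares` (trust-region reflective, analytic
  Jacobian), bounds a ∈ [0.1, 2], g ≥ 0, tolerances ftol 1e-10,
  xtol 1e-8, at most 10000 evaluations. Convergence status is reported,
  never silently ignored.
* Initialization: g₀ = median signal of blank spots (or the
  lowest-density column when no blanks exist); a₀ and B₀ from an
  ordinary regression of log(SI − g₀) on log x over spots more than
  twofold above g₀. If no spot clears 2·g₀, the data are declared
  all-background — nothing about B or a is identifiable.
* A 5-point multi-start scales a₀ by {0.8, 0.9, 1.0, 1.1, 1.2}; the
  lowest merit wins, ties (relative 1e-9) broken toward the smallest a.
* The residual denominator is floored at 1e-9 × max(signal). Without
  this, a dataset whose true g is 0 is unfittable: blank spots with zero
  signal have relative residual exactly −1 for every g > 0 and 0 at
  g = 0, a discontinuity at the boundary. The floor makes the objective
  continuous there and is far below any real prediction otherwise; tying
  it to the data maximum preserves scale equivariance.
* Observations are canonically sorted before fitting, so the result is
  independent of input order; saturated spots (signal ≥ ceiling) are
  excluded by default because clipped values are censored, not noisy.
  Buffer and marker spots carry no nominal density and never enter fits;
  blanks enter at x = 0 and inform g.
* Spot-level data are fitted by default; `series_means=True` fits
  per-column means instead.

### Bias correction

Under mean-1 multiplicative noise with coefficient of variation cv, the
minimizer of E does not converge to f but to f·(1+cv²): for a constant
target, E is minimized by Σs²/Σs, the mean inflated by (1+cv²). Because
E is scale-equivariant the inflation is exactly a common factor on B and
g (a is untouched). The fit therefore rescales B and g by one plus the
mean relative residual after minimization — an unbiased first-order
correction, since the mean relative residual estimates −cv²/(1+cv²) —
and reports merit and residuals at the corrected parameters. The
correction is an exact no-op on noise-free data and can be disabled
(`bias_correction=False`). At 10% CV it is a ~1% shift, which matters
because it is comparable to the parameters' sampling standard errors:
without it, bootstrap intervals of any construction undercover the
truth.

### Bootstrap

Uncertainty comes from a nonparametric bootstrap that resamples spots
with replacement *within* each series, preserving the dilution design.
Refits start from the point estimate with a single start (the point
estimate is an excellent initial guess; the multi-start exists to guard
the initial fit against local minima, not resampled replicates).
Percentile intervals are the default; reflected ("basic") intervals are
available. Fewer than 50% converged refits flags the result unstable.

## Simulator

`simulate_scan` emulates a 32-column commercial calibration slide:
columns 1–27 a two-fold dilution series from 1.47e5 down to ~2.19e-3
fluorophores/µm² (matching the vendor's printed description to 3
significant figures at every step), column 28 spotting buffer, columns
29–31 blank, column 32 position markers. Each spot draws

    SI = clip( f(x)·L + N, 0, ceiling )

with L lognormal (mean 1, CV `noise_cv`, default 0.10 — a typical
spot-to-spot scatter for such slides, roughly constant on a log scale)
and N Gaussian read noise (`additive_sd`, default 0). Buffer spots sit
at g plus a configurable extra offset, so both readings of the
"do buffer spots contain dye?" dispute can be generated. Marker spots
are rendered at the ceiling, as the bright gridding fiducials they are.
Replicates per column default to 20 — the real slide's replicate count
is not documented, and 20 gives series-mean standard errors of ~2% at
the default noise. Seeds are mandatory; there is no global RNG state.

What the simulator does **not** emulate: spatial intensity gradients and
spot morphology, channel crosstalk, scanner-specific nonlinearity beyond
the power law, batch-to-batch slide variation, or the "shoulder"
behaviour some scanners show in one channel. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
noise model, not robustness to every artifact of real scans.

## Diagnostics policy

* **Usable range**: lower bound where the dye signal is k× the
  background (`B·x^a = k·g`, default k = 3), upper bound where the full
  signal reaches the ceiling. For the reference Cy3/gain-100
  characteristics this puts the bottom eight dilution series below the
  floor — most of the slide's dynamic range is wasted on densities the
  slide itself renders unmeasurable.
* **Invariance verdicts**: when every fit carries bootstrap intervals,
  "invariant" means all pairwise intervals overlap; otherwise the
  relative spread (max−min)/min must stay below a threshold, default
  15%. The threshold is tool policy for a qualitative judgement; the
  numeric evidence is always attached to the verdict. Expected pattern:
  g and a invariant across gains, B emphatically not.
* **Channel ratio**: background-corrected ratio of ideal responses,
  exactly B₁/B₂ when curvatures agree; "constant" means max/min < 1.05
  over the grid (default: the dilution densities inside both usable
  ranges). A constant ratio is what justifies using plain two-channel
  intensity ratios without per-channel calibration.

## Test problem sizes

The suite simulates the standard slide at 20 replicates per column
(640 spots, ~440 entering a fit after saturation and control-column
exclusion). The law-of-large-numbers check uses 10⁴ replicates of one
column. Interval coverage is assessed over 50 independent simulated
scans with 200 bootstrap resamples each — enough to detect gross
miscalibration (binomial SE ~4% at nominal 95%) while keeping the whole
suite under a minute.

## Known limitations

* The noise model is the simulator's own; real scanners add
  signal-dependent read noise and occasional outlier spots, for which no
  robust loss is provided (by design — raw intensities, no trimming).
* Saturated spots are discarded rather than treated as censored
  observations; at very high gain this can leave few usable series.
* The GAL reader covers the calibration-slide dialect (Block/Column/Row/
  Name/ID), not the full GenePix results format.
* Densities are taken at their nominal values; pipetting error in the
  dilution series is not modelled and would alias into curvature.
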