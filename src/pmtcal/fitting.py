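"""Estimation of the scanner response parameters (B, a, g).

Calibration data span roughly eight orders of magnitude in surface density
and five in signal, so ordinary least squares is dominated by the brightest
spots and fits the plateau badly.  The merit function used here is the sum
of squared *relative* residuals,

    E = sum_i [ (SI_i - f(x_i)) / f(x_i) ]**2 ,     f(x) = B*x**a + g,

i.e. weighted least squares with weights 1/f(x)**2.  E is invariant under a
common rescaling of all signals together with B and g, which is what makes
it usable across PMT gains.

Minimization runs in (log B, a, g) coordinates with a bounded trust-region
reflective solver (analytic Jacobian), started from a log-log regression
initialization and a small multi-start over the curvature to guard against
local minima.  Saturated spots (signal at the detector ceiling) carry no
information about the response above the ceiling and are excluded by
default.

Under mean-1 multiplicative noise with coefficient of variation cv, the
minimizer of E converges not to f(x) but to f(x)*(1+cv^2): for a constant
target the criterion is minimized by sum(s^2)/sum(s), the mean inflated by
(1+cv^2).  Because E is scale-equivariant this inflation is a common
factor on B and g (a is untouched).  The fit therefore applies a
first-order multiplicative bias correction by default: the mean relative
residual m satisfies E[m] = -cv^2/(1+cv^2), so scaling B and g by (1+m)
undoes the inflation, exactly so in the noise-free limit (m = 0).

Uncertainty is quantified by a within-series nonparametric bootstrap:
spots are resampled with replacement inside each dilution column, the fit
is repeated, and percentile intervals are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import AllBackgroundError, InsufficientDataError
from .model import DEFAULT_CEILING, ScannerResponseModel

__all__ = [
    "ScanObservation",
    "FitResult",
    "merit",
    "default_initialization",
    "fit_response",
    "bootstrap_fit",
]

# bounds of the optimizer: B > 0 (via log), a in [0.1, 2], g >= 0
_A_LO, _A_HI = 0.1, 2.0
_MULTISTART_A_SCALES = (0.8, 0.9, 1.0, 1.1, 1.2)
_F_FLOOR = 1e-12  # guard against division by a zero prediction


@dataclass(frozen=True)
class ScanObservation:
    """One spot's readout from a calibration scan.

    ``x_nominal`` is the nominal surface density in fluorophores/µm²:
    0 for blank spots, ``None`` for spots with no assigned density
    (buffer and position-marker columns).
    """

    series_index: int
    x_nominal: float | None
    signal: float
    channel: str = ""
    pmt_gain: float | None = None
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"signal must be >= 0, got {self.signal}")
        if self.x_nominal is not None and self.x_nominal < 0:
            raise ValueError(f"x_nominal must be >= 0, got {self.x_nominal}")


@dataclass
class FitResult:
    """Outcome of a response-curve fit."""

    model: ScannerResponseModel
    merit: float
    n_used: int
    n_excluded_saturated: int
    residuals: np.ndarray
    converged: bool
    initialization: tuple[float, float, float]
    bias_correction_factor: float = 1.0
    bootstrap_ci: dict[str, tuple[float, float]] | None = None
    n_boot: int = 0
    n_boot_converged: int = 0
    unstable: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.model.B, self.model.a, self.model.g)


# ---------------------------------------------------------------------------
# data marshalling


def _arrays(observations: Iterable[ScanObservation],
            exclude_saturated: bool,
            ceiling: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Usable (x, signal, series) arrays in a canonical sort order.

    Usable means: defined nominal density, and (if requested) not
    saturated.  Saturation is the stored flag or a signal at/above the
    ceiling.  Returns the number of saturated spots excluded.
    """
    xs, ss, ks = [], [], []
    n_sat = 0
    for ob in observations:
        if ob.x_nominal is None:
            continue
        sat = ob.saturated or ob.signal >= ceiling
        if exclude_saturated and sat:
            n_sat += 1
            continue
        xs.append(ob.x_nominal)
        ss.append(ob.signal)
        ks.append(ob.series_index)
    x = np.asarray(xs, dtype=float)
    s = np.asarray(ss, dtype=float)
    k = np.asarray(ks, dtype=int)
    # canonical order → fit result independent of observation order
    order = np.lexsort((s, x, k))
    return x[order], s[order], k[order], n_sat


def _infer_metadata(observations: Sequence[ScanObservation]) -> tuple[str, float | None]:
    channels = {ob.channel for ob in observations}
    gains = {ob.pmt_gain for ob in observations}
    channel = channels.pop() if len(channels) == 1 else ""
    gain = gains.pop() if len(gains) == 1 else None
    return channel, gain


# ---------------------------------------------------------------------------
# merit


def _floor(s: np.ndarray) -> float:
    """Denominator floor, scaled to the data so the relative residual
    stays continuous as predictions approach zero (blank spots with zero
    signal under g -> 0) without breaking scale equivariance."""
    top = float(s.max()) if s.size else 0.0
    return max(_F_FLOOR, 1e-9 * top)


def _relative_residuals(theta: np.ndarray, x: np.ndarray, s: np.ndarray) -> np.ndarray:
    logB, a, g = theta
    f = math.exp(logB) * np.power(x, a) + g
    return (s - f) / np.maximum(f, _floor(s))


def _jacobian(theta: np.ndarray, x: np.ndarray, s: np.ndarray) -> np.ndarray:
    logB, a, g = theta
    B = math.exp(logB)
    pw = np.power(x, a)
    f = B * pw + g
    floor = _floor(s)
    # r = (s - f)/max(f, floor):
    #   f > floor: r = s/f - 1   => dr = -(s/f**2) df
    #   f <= floor: r linear     => dr = -df/floor
    common = np.where(f > floor, -s / np.maximum(f, floor) ** 2,
                      -1.0 / floor)
    with np.errstate(divide="ignore"):
        logx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), 0.0)
    J = np.empty((x.size, 3))
    J[:, 0] = common * B * pw            # d f / d logB
    J[:, 1] = common * B * pw * logx     # d f / d a
    J[:, 2] = common                     # d f / d g
    return J


def merit(model: ScannerResponseModel,
          observations: Iterable[ScanObservation],
          exclude_saturated: bool = True,
          ceiling: float = DEFAULT_CEILING) -> float:
    """Sum of squared relative residuals E over usable observations.

    Raises :class:`InsufficientDataError` if no usable observation
    remains.
    """
    x, s, _, _ = _arrays(observations, exclude_saturated, ceiling)
    if x.size == 0:
        raise InsufficientDataError("no usable observations to evaluate merit")
    theta = np.array([math.log(model.B), model.a, model.g])
    r = _relative_residuals(theta, x, s)
    return float(np.dot(r, r))


# ---------------------------------------------------------------------------
# initialization


def default_initialization(observations: Iterable[ScanObservation],
                           exclude_saturated: bool = True,
                           ceiling: float = DEFAULT_CEILING
                           ) -> tuple[float, float, float]:
    """Data-driven starting triple (B0, a0, g0).

    g0 is the median signal of the blank spots (or, lacking blanks, of the
    lowest-density column); a0 and B0 come from a least-squares line of
    log(SI - g0) against log x over spots at least twofold above g0.  If no
    spot clears 2*g0 the data are all background and no slope is
    identifiable.
    """
    x, s, _, _ = _arrays(observations, exclude_saturated, ceiling)
    if x.size == 0:
        raise InsufficientDataError("no usable observations")

    blanks = s[x == 0]
    if blanks.size:
        g0 = float(np.median(blanks))
    else:
        g0 = float(np.median(s[x == np.min(x)]))

    above = (x > 0) & (s > 2.0 * g0)
    if not np.any(above):
        raise AllBackgroundError(
            "no spot rises above twice the background estimate "
            f"g0={g0:.4g}; the dataset is entirely below the "
            "autofluorescence floor"
        )
    xu, su = x[above], s[above]
    if np.unique(xu).size < 2:
        raise InsufficientDataError(
            "fewer than two distinct densities above background; "
            "slope is not identifiable"
        )
    slope, intercept = np.polyfit(np.log(xu), np.log(su - g0), 1)
    a0 = float(np.clip(slope, _A_LO, _A_HI))
    B0 = float(np.exp(intercept))
    return B0, a0, max(g0, 0.0)


# ---------------------------------------------------------------------------
# fitting


def _minimize(x: np.ndarray, s: np.ndarray,
              theta0: np.ndarray,
              g_hi: float) -> tuple[np.ndarray, float, bool]:
    res = least_squares(
        _relative_residuals, theta0, jac=_jacobian, args=(x, s),
        bounds=([-np.inf, _A_LO, 0.0], [np.inf, _A_HI, g_hi]),
        method="trf", ftol=1e-10, xtol=1e-8, gtol=1e-12, max_nfev=10000,
    )
    return res.x, float(2.0 * res.cost), res.status > 0


def _fit_arrays(x: np.ndarray, s: np.ndarray,
                init: tuple[float, float, float],
                multistart: bool,
                g_hi: float) -> tuple[np.ndarray, float, bool]:
    """Minimize E over (log B, a, g); returns (theta, merit, converged)."""
    B0, a0, g0 = init
    theta0 = np.array([math.log(B0), float(np.clip(a0, _A_LO, _A_HI)),
                       min(max(g0, 0.0), g_hi)])
    scales = _MULTISTART_A_SCALES if multistart else (1.0,)
    candidates = []
    for c in scales:
        t0 = theta0.copy()
        t0[1] = float(np.clip(a0 * c, _A_LO, _A_HI))
        candidates.append(_minimize(x, s, t0, g_hi))
    best_merit = min(m for _, m, _ in candidates)
    # ties (to relative 1e-9) broken by smallest curvature a
    tol = best_merit * 1e-9 + 1e-300
    viable = [c for c in candidates if c[1] <= best_merit + tol]
    theta, m, ok = min(viable, key=lambda c: c[0][1])
    return theta, m, ok


def _estimate(x: np.ndarray, s: np.ndarray,
              init: tuple[float, float, float],
              multistart: bool, g_hi: float,
              bias_correction: bool
              ) -> tuple[tuple[float, float, float], float, bool,
                         np.ndarray, float]:
    """Minimize E, then optionally undo the multiplicative-noise bias.

    Returns ((B, a, g), merit, converged, residuals, correction_factor),
    with merit and residuals evaluated at the reported parameters.
    """
    theta, m, ok = _fit_arrays(x, s, init, multistart, g_hi)
    r = _relative_residuals(theta, x, s)
    factor = 1.0
    if bias_correction:
        c = 1.0 + float(np.mean(r))
        if c > 0:
            factor = c
            theta = np.array([theta[0] + math.log(c), theta[1],
                              theta[2] * c])
            r = _relative_residuals(theta, x, s)
            m = float(np.dot(r, r))
    params = (math.exp(theta[0]), float(theta[1]), float(theta[2]))
    return params, m, ok, r, factor


def fit_response(observations: Sequence[ScanObservation],
                 init: tuple[float, float, float] | None = None,
                 bounds: dict[str, tuple[float, float]] | None = None,
                 exclude_saturated: bool = True,
                 series_means: bool = False,
                 bias_correction: bool = True,
                 ceiling: float = DEFAULT_CEILING) -> FitResult:
    """Fit (B, a, g) to spot-level observations by minimizing E.

    Parameters
    ----------
    observations
        Spot readouts; only those with a defined nominal density enter
        the fit (buffer and marker spots never do).
    init
        Optional (B0, a0, g0) starting triple; by default
        :func:`default_initialization` plus a 5-point multi-start over
        the curvature.
    bounds
        Optional override of the ``g`` upper bound as ``{"g": (lo, hi)}``;
        B > 0 and a in [0.1, 2] are structural.
    exclude_saturated
        Drop spots at/above the ceiling (default).  Clipped signals are
        censored, not noisy, and would bias the fit downward.
    series_means
        Fit per-series mean signals instead of spot-level data.
    bias_correction
        Rescale B and g by one plus the mean relative residual after
        minimization (default), undoing the first-order (1+cv^2)
        inflation that relative least squares acquires under
        multiplicative noise.  A no-op on noise-free data.

    The fit is deterministic given identical inputs (observation order
    does not matter) and reports convergence honestly.  ``merit`` and
    ``residuals`` in the result are evaluated at the reported
    parameters.
    """
    observations = list(observations)
    x, s, k, n_sat = _arrays(observations, exclude_saturated, ceiling)
    if x.size < 4:
        raise InsufficientDataError(
            f"need at least 4 usable observations, have {x.size}"
        )
    if np.unique(x[x > 0]).size < 2:
        raise InsufficientDataError(
            "need at least 2 distinct nonzero densities"
        )
    if series_means:
        ks = np.unique(k)
        x = np.array([x[k == kk].mean() for kk in ks])
        s = np.array([s[k == kk].mean() for kk in ks])

    g_hi = np.inf
    if bounds and "g" in bounds:
        g_hi = float(bounds["g"][1])

    notes: list[str] = []
    if init is None:
        init = default_initialization(observations, exclude_saturated, ceiling)
        multistart = True
    else:
        multistart = False

    (B, a, g), m, ok, resid, factor = _estimate(x, s, init, multistart,
                                                g_hi, bias_correction)
    channel, gain = _infer_metadata(observations)
    model = ScannerResponseModel(B=B, a=a, g=g, channel=channel, pmt_gain=gain)
    if not ok:
        notes.append("optimizer did not report convergence")
    return FitResult(model=model, merit=m, n_used=int(x.size),
                     n_excluded_saturated=n_sat, residuals=resid,
                     converged=ok, initialization=tuple(init),
                     bias_correction_factor=factor, notes=notes)


def bootstrap_fit(observations: Sequence[ScanObservation],
                  n_boot: int = 200,
                  seed: int | np.random.Generator | None = None,
                  level: float = 0.95,
                  method: str = "percentile",
                  exclude_saturated: bool = True,
                  series_means: bool = False,
                  bias_correction: bool = True,
                  ceiling: float = DEFAULT_CEILING) -> FitResult:
    """Point fit plus within-series bootstrap confidence intervals.

    Spots are resampled with replacement inside each dilution column,
    preserving the design (which densities are present and how many
    replicates each has).  Refits start from the point estimate (single
    start) and apply the same bias correction as the point fit.  With
    ``n_boot=0`` this is exactly :func:`fit_response`.  Reproducible
    under a fixed seed.

    ``method``: ``"percentile"`` (default) reports raw bootstrap
    quantiles; ``"basic"`` reflects them around the point estimate,
    ``(2*est - q_hi, 2*est - q_lo)``.  Lower bounds for g are clipped
    at 0.
    """
    if method not in ("basic", "percentile"):
        raise ValueError(f"unknown interval method {method!r}")
    point = fit_response(observations, exclude_saturated=exclude_saturated,
                         series_means=series_means,
                         bias_correction=bias_correction, ceiling=ceiling)
    if n_boot == 0:
        return point
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, s, k, _ = _arrays(observations, exclude_saturated, ceiling)
    series = np.unique(k)
    groups = [np.flatnonzero(k == kk) for kk in series]
    init = (point.model.B, point.model.a, point.model.g)

    samples = []
    n_ok = 0
    for _ in range(n_boot):
        picks = [rng.choice(gr, size=gr.size, replace=True) for gr in groups]
        if series_means:
            xb = np.array([x[gr].mean() for gr in groups])
            sb = np.array([s[p].mean() for p in picks])
        else:
            idx = np.concatenate(picks)
            xb, sb = x[idx], s[idx]
        try:
            params, _, ok, _, _ = _estimate(xb, sb, init, multistart=False,
                                            g_hi=np.inf,
                                            bias_correction=bias_correction)
        except Exception:
            continue
        if ok:
            n_ok += 1
            samples.append(params)

    result = replace(point, n_boot=n_boot, n_boot_converged=n_ok)
    if n_ok == 0:
        result.unstable = True
        result.notes = point.notes + ["no bootstrap refit converged"]
        return result
    arr = np.asarray(samples)
    alpha = (1.0 - level) / 2.0
    q_lo = np.quantile(arr, alpha, axis=0)
    q_hi = np.quantile(arr, 1.0 - alpha, axis=0)
    if method == "basic":
        est = np.array(init)
        lo, hi = 2.0 * est - q_hi, 2.0 * est - q_lo
    else:
        lo, hi = q_lo, q_hi
    lo[2] = max(lo[2], 0.0)  # g >= 0
    result.bootstrap_ci = {name: (float(lo[j]), float(hi[j]))
                           for j, name in enumerate(("B", "a", "g"))}
    if n_ok < 0.5 * n_boot:
        result.unstable = True
        result.notes = point.notes + [
            f"only {n_ok}/{n_boot} bootstrap refits converged"
        ]
    return result
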