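"""Scanner diagnostics built on fitted response models.

These functions turn fitted (B, a, g) triples into the operational
questions a core facility actually asks:

* over which density range is the slide informative at all
  (:func:`usable_range`) — below a signal-to-background threshold the
  dilution series reads as pure autofluorescence, and above the detector
  ceiling it is clipped;
* is the autofluorescence estimate a property of the slide rather than
  the detector, i.e. invariant across PMT gains (:func:`gain_invariance`)
  — while the sensitivity B scales with gain and must *fail* the same
  test;
* is the curvature exponent shared across channels and gains
  (:func:`curvature_comparison`), which justifies using simple two-channel
  intensity ratios without per-channel calibration;
* how constant is the background-corrected two-channel ratio across
  densities (:func:`channel_ratio_profile`) — exactly ``B1/B2`` when the
  curvatures agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import DomainError, PmtcalError
from .fitting import FitResult
from .model import DEFAULT_CEILING, ScannerResponseModel, ideal_signal

__all__ = [
    "DensityInterval",
    "InvarianceVerdict",
    "RatioProfile",
    "DiagnosticsReport",
    "usable_range",
    "gain_invariance",
    "curvature_comparison",
    "channel_ratio_profile",
    "build_report",
]

DEFAULT_SPREAD_THRESHOLD = 0.15
DEFAULT_RATIO_THRESHOLD = 1.05


@dataclass(frozen=True)
class DensityInterval:
    """Closed density interval [lower, upper]; empty when lower >= upper."""

    lower: float
    upper: float

    @property
    def empty(self) -> bool:
        return not (self.lower < self.upper)

    def contains(self, x: float) -> bool:
        return (not self.empty) and self.lower <= x <= self.upper


@dataclass(frozen=True)
class InvarianceVerdict:
    """Spread statistics and verdict for one parameter across fits."""

    parameter: str
    values: tuple[float, ...]
    spread: float                      # (max - min) / min
    invariant: bool
    threshold: float
    used_intervals: bool
    intervals: tuple[tuple[float, float], ...] | None = None
    detail: str = ""


@dataclass(frozen=True)
class RatioProfile:
    """Background-corrected two-channel ratio across a density grid."""

    densities: np.ndarray
    ratios: np.ndarray
    constant: bool
    max_over_min: float
    threshold: float


def usable_range(model: ScannerResponseModel,
                 signal_to_background: float = 3.0,
                 ceiling: float = DEFAULT_CEILING) -> DensityInterval:
    """Density interval over which the slide is informative.

    Lower bound: the density where the dye signal is ``k`` times the
    autofluorescence floor, ``B*x**a = k*g``, i.e. ``(k*g/B)**(1/a)``
    (0 when ``g = 0`` — no floor).  Upper bound: where the full signal
    reaches the ceiling.  The interval is empty when the floor meets the
    ceiling first.
    """
    k = signal_to_background
    if not k > 1:
        raise DomainError(f"signal_to_background must exceed 1, got {k}")
    lower = 0.0 if model.g == 0 else (k * model.g / model.B) ** (1.0 / model.a)
    if ceiling <= model.g:
        return DensityInterval(lower=lower, upper=0.0)
    upper = ((ceiling - model.g) / model.B) ** (1.0 / model.a)
    return DensityInterval(lower=lower, upper=upper)


def _param_values(fits: Sequence[FitResult], parameter: str) -> tuple[float, ...]:
    if parameter not in ("B", "a", "g"):
        raise DomainError(f"unknown parameter {parameter!r}")
    return tuple(getattr(f.model, parameter) for f in fits)


def _spread(values: Sequence[float]) -> float:
    lo, hi = min(values), max(values)
    if hi == lo:
        return 0.0
    if lo <= 0:
        return float("inf")
    return (hi - lo) / lo


def _invariance(fits: Sequence[FitResult], parameter: str,
                threshold: float) -> InvarianceVerdict:
    values = _param_values(fits, parameter)
    spread = _spread(values)
    intervals = None
    used_intervals = all(f.bootstrap_ci is not None
                         and parameter in f.bootstrap_ci for f in fits)
    if used_intervals:
        intervals = tuple(f.bootstrap_ci[parameter] for f in fits)
        overlaps = all(max(i1[0], i2[0]) <= min(i1[1], i2[1])
                       for i1, i2 in combinations(intervals, 2))
        invariant = overlaps
        detail = (f"all pairwise bootstrap intervals "
                  f"{'overlap' if overlaps else 'do not all overlap'}; "
                  f"spread {spread:.3G}")
    else:
        invariant = spread < threshold
        detail = (f"spread {spread:.3G} "
                  f"{'<' if invariant else '>='} threshold {threshold:.3G} "
                  "(no bootstrap intervals available)")
    return InvarianceVerdict(parameter=parameter, values=values,
                             spread=spread, invariant=invariant,
                             threshold=threshold,
                             used_intervals=used_intervals,
                             intervals=intervals, detail=detail)


def gain_invariance(fits: Sequence[FitResult],
                    parameter: str = "g",
                    threshold: float = DEFAULT_SPREAD_THRESHOLD,
                    allow_mixed_channels: bool = False) -> InvarianceVerdict:
    """Is ``parameter`` invariant across PMT gains?

    Requires at least two fits sharing a channel (unless
    ``allow_mixed_channels``).  With bootstrap intervals on every fit the
    verdict is "invariant" iff all intervals pairwise overlap; otherwise
    iff the relative spread (max-min)/min is below ``threshold``.

    The autofluorescence ``g`` is a property of the slide and should pass;
    the sensitivity ``B`` scales with gain and should fail.
    """
    if len(fits) < 2:
        raise DomainError("need at least 2 fits to assess invariance")
    channels = {f.model.channel for f in fits}
    if len(channels) > 1 and not allow_mixed_channels:
        raise DomainError(
            f"fits mix channels {sorted(channels)}; pass "
            "allow_mixed_channels=True to compare across channels")
    return _invariance(fits, parameter, threshold)


def curvature_comparison(fits: Sequence[FitResult],
                         threshold: float = DEFAULT_SPREAD_THRESHOLD
                         ) -> tuple[InvarianceVerdict, tuple[float, ...]]:
    """Spread verdict for the curvature ``a`` across channels/gains.

    Also returns each fit's deviation from the straight-line response
    ``|a - 1|``.  Channels may be mixed by design: shared curvature across
    channels is exactly the claim under test.
    """
    if len(fits) < 2:
        raise DomainError("need at least 2 fits to compare curvature")
    verdict = _invariance(fits, "a", threshold)
    deviations = tuple(abs(f.model.a - 1.0) for f in fits)
    return verdict, deviations


def channel_ratio_profile(model_1: ScannerResponseModel,
                          model_2: ScannerResponseModel,
                          densities: Sequence[float],
                          threshold: float = DEFAULT_RATIO_THRESHOLD
                          ) -> RatioProfile:
    """Background-corrected signal ratio between two channels.

    Computes ``ideal_signal(x; model_1) / ideal_signal(x; model_2)``
    across a positive density grid.  When the curvatures agree the
    density dependence cancels and the ratio is exactly ``B1/B2``
    everywhere; otherwise it drifts as ``x**(a1-a2)``.  Verdict
    "constant" iff max/min ratio is below ``threshold``.
    """
    x = np.asarray(densities, dtype=float)
    if x.size == 0 or np.any(x <= 0):
        raise DomainError("density grid must be nonempty and positive")
    ratios = np.asarray(ideal_signal(x, model_1)) / np.asarray(
        ideal_signal(x, model_2))
    max_over_min = float(ratios.max() / ratios.min())
    return RatioProfile(densities=x, ratios=ratios,
                        constant=max_over_min < threshold,
                        max_over_min=max_over_min, threshold=threshold)


@dataclass
class DiagnosticsReport:
    """Fitted-parameter table plus invariance verdicts, with evidence.

    Every verdict carries the numeric values it was decided on; nothing
    is reduced to a bare boolean.
    """

    rows: list[dict]
    g_invariance: InvarianceVerdict | None = None
    B_invariance: InvarianceVerdict | None = None
    curvature: InvarianceVerdict | None = None
    curvature_deviation_from_line: tuple[float, ...] = ()
    usable_ranges: list[dict] = field(default_factory=list)
    ratio: RatioProfile | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def verdict_dict(v: InvarianceVerdict | None):
            if v is None:
                return None
            return {"parameter": v.parameter, "values": list(v.values),
                    "spread": v.spread, "invariant": v.invariant,
                    "threshold": v.threshold,
                    "used_intervals": v.used_intervals,
                    "intervals": ([list(i) for i in v.intervals]
                                  if v.intervals else None),
                    "detail": v.detail}

        d = {"fits": self.rows,
             "g_invariance": verdict_dict(self.g_invariance),
             "B_invariance": verdict_dict(self.B_invariance),
             "curvature": verdict_dict(self.curvature),
             "curvature_deviation_from_line":
                 list(self.curvature_deviation_from_line),
             "usable_ranges": self.usable_ranges,
             "notes": list(self.notes)}
        if self.ratio is not None:
            d["ratio"] = {"densities": self.ratio.densities.tolist(),
                          "ratios": self.ratio.ratios.tolist(),
                          "constant": self.ratio.constant,
                          "max_over_min": self.ratio.max_over_min}
        return d

    def to_text(self) -> str:
        lines = ["Fitted scanner characteristics:",
                 f"  {'channel':>8} {'gain':>6} {'B':>10} {'a':>6} "
                 f"{'g':>8} {'merit':>10} {'n':>5}"]
        for r in self.rows:
            gain = r["pmt_gain"] if r["pmt_gain"] is not None else "-"
            lines.append(f"  {r['channel']:>8} {gain!s:>6} {r['B']:>10.4G} "
                         f"{r['a']:>6.3F} {r['g']:>8.4G} "
                         f"{r['merit']:>10.4G} {r['n_used']:>5}")
        for label, v in (("autofluorescence g", self.g_invariance),
                         ("sensitivity B", self.B_invariance),
                         ("curvature a", self.curvature)):
            if v is not None:
                word = "invariant" if v.invariant else "NOT invariant"
                lines.append(f"{label}: {word} ({v.detail})")
        for u in self.usable_ranges:
            lines.append(
                f"usable range ({u['channel']}/gain {u['pmt_gain']}): "
                f"[{u['lower']:.4G}, {u['upper']:.4G}] fluorophores/um^2"
                + (" — EMPTY" if u["empty"] else ""))
        if self.ratio is not None:
            word = "constant" if self.ratio.constant else "NOT constant"
            lines.append(f"channel ratio: {word} "
                         f"(max/min = {self.ratio.max_over_min:.4G})")
        lines.extend(f"note: {n}" for n in self.notes)
        return "\n".join(lines)


def build_report(fits: Sequence[FitResult],
                 signal_to_background: float = 3.0,
                 ceiling: float = DEFAULT_CEILING,
                 spread_threshold: float = DEFAULT_SPREAD_THRESHOLD
                 ) -> DiagnosticsReport:
    """Assemble the standard diagnostics report from a set of fits.

    Rows are sorted by (channel, gain) so the report is independent of
    the order fits are supplied in.  Gain-invariance verdicts for g and B
    are computed per channel group with >= 2 fits; the curvature
    comparison pools all fits.
    """
    fits = sorted(fits, key=lambda f: (f.model.channel,
                                       f.model.pmt_gain or 0.0))
    rows = []
    ranges = []
    for f in fits:
        m = f.model
        rows.append({"channel": m.channel, "pmt_gain": m.pmt_gain,
                     "B": m.B, "a": m.a, "g": m.g, "merit": f.merit,
                     "n_used": f.n_used,
                     "n_excluded_saturated": f.n_excluded_saturated,
                     "converged": f.converged,
                     "bootstrap_ci": f.bootstrap_ci})
        u = usable_range(m, signal_to_background, ceiling)
        ranges.append({"channel": m.channel, "pmt_gain": m.pmt_gain,
                       "lower": u.lower, "upper": u.upper,
                       "empty": u.empty})

    report = DiagnosticsReport(rows=rows, usable_ranges=ranges)
    by_channel: dict[str, list[FitResult]] = {}
    for f in fits:
        by_channel.setdefault(f.model.channel, []).append(f)
    multi = [grp for grp in by_channel.values() if len(grp) >= 2]
    if multi:
        # report the largest same-channel group across gains
        grp = max(multi, key=len)
        report.g_invariance = gain_invariance(grp, "g", spread_threshold)
        report.B_invariance = gain_invariance(grp, "B", spread_threshold)
    if len(fits) >= 2:
        report.curvature, report.curvature_deviation_from_line = \
            curvature_comparison(fits, spread_threshold)
    if len(by_channel) == 2:
        m1, m2 = (grp[0].model for grp in by_channel.values())
        grid = _default_grid(fits, ceiling, signal_to_background)
        if grid:
            report.ratio = channel_ratio_profile(m1, m2, grid)
    return report


def _default_grid(fits: Sequence[FitResult], ceiling: float,
                  k: float) -> list[float]:
    """Dilution densities inside every fit's usable range."""
    from .simulate import N_DILUTION, density_for_series

    densities = [density_for_series(i) for i in range(1, N_DILUTION + 1)]
    out = []
    for x in densities:
        if all(usable_range(f.model, k, ceiling).contains(x) for f in fits):
            out.append(x)
    return out
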