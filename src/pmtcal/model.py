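"""Forward model of microarray scanner response.

A fluorescence scanner reading a spot of dye at surface density ``x``
(fluorophores/µm²) reports a signal intensity

    SI(x) = B * x**a + g

where ``B`` is the sensitivity of the photomultiplier (counts per
(fluorophores/µm²)**a), ``a`` is a dimensionless curvature exponent
(``a = 1`` is a perfectly linear detector), and ``g`` is the
autofluorescence of the spotting buffer/slide in counts — a floor that is
present even with zero dye.  The model is deliberately minimal: it is fit
to raw, untransformed intensities, and the only nonlinearity it admits is
the power law.

Two consequences drive the diagnostics elsewhere in the package:

* for densities where ``B*x**a << g`` the measured signal plateaus at
  ``g`` — the "lower plateau" is a property of the slide, not the PMT;
* 16-bit detectors clip at a ceiling (typically 65535 counts), which
  removes the top of the dilution series at high gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BelowBackgroundError, DomainError

__all__ = [
    "ScannerResponseModel",
    "predict_signal",
    "ideal_signal",
    "invert_signal",
    "apply_saturation",
    "DEFAULT_CEILING",
]

#: Saturation ceiling of a 16-bit scanner ADC, in counts.
DEFAULT_CEILING = 65535.0


@dataclass(frozen=True)
class ScannerResponseModel:
    """Parameter triple (B, a, g) of the scanner response, with metadata.

    Parameters
    ----------
    B : float
        Sensitivity, counts per (fluorophores/µm²)**a.  Scales with PMT
        gain.  Must be positive.
    a : float
        Curvature exponent (dimensionless); ``a = 1`` means the response
        is a straight line in non-transformed coordinates.  Must be
        positive.
    g : float
        Autofluorescence offset in counts; the signal of a dye-free spot.
        Must be non-negative.
    channel : str
        Dye channel label, e.g. ``"Cy3"`` or ``"Cy5"``.
    pmt_gain : float or None
        Photomultiplier gain setting the parameters were measured at.
    """

    B: float
    a: float
    g: float
    channel: str = ""
    pmt_gain: float | None = None

    def __post_init__(self) -> None:
        if not (self.B > 0):
            raise DomainError(f"sensitivity B must be positive, got {self.B}")
        if not (self.a > 0):
            raise DomainError(f"curvature a must be positive, got {self.a}")
        if not (self.g >= 0):
            raise DomainError(f"autofluorescence g must be >= 0, got {self.g}")

    def with_params(self, B: float, a: float, g: float) -> "ScannerResponseModel":
        """Return a copy with new (B, a, g) but the same metadata."""
        return ScannerResponseModel(B=B, a=a, g=g, channel=self.channel,
                                    pmt_gain=self.pmt_gain)


def _check_density(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("surface density x must be non-negative")
    return x


def predict_signal(x, model: ScannerResponseModel):
    """Signal intensity ``B*x**a + g`` at surface density ``x``.

    Vectorizes over ``x``; a scalar input returns a scalar.  Strictly
    increasing in ``x`` and equal to ``g`` at ``x = 0``.
    """
    xa = _check_density(x)
    out = model.B * np.power(xa, model.a) + model.g
    return out if np.ndim(x) else float(out)


def ideal_signal(x, model: ScannerResponseModel):
    """Autofluorescence-free response ``B*x**a``.

    This is the scanner response a zero-background slide would show —
    the idealized line the calibration is actually after.  Identity:
    ``ideal_signal(x) == predict_signal(x) - g``.
    """
    xa = _check_density(x)
    out = model.B * np.power(xa, model.a)
    return out if np.ndim(x) else float(out)


def invert_signal(SI, model: ScannerResponseModel):
    """Surface density producing signal ``SI``: ``((SI - g)/B)**(1/a)``.

    Defined only above the autofluorescence floor: a signal at or below
    ``g`` is indistinguishable from background and raises
    :class:`~pmtcal.errors.BelowBackgroundError`.  Round-trips with
    :func:`predict_signal` to numerical precision.
    """
    s = np.asarray(SI, dtype=float)
    if np.any(s <= model.g):
        raise BelowBackgroundError(
            f"signal {s[s <= model.g].min() if s.ndim else float(s)} is at or "
            f"below the autofluorescence floor g={model.g}; surface density "
            "is not identifiable"
        )
    out = np.power((s - model.g) / model.B, 1.0 / model.a)
    return out if np.ndim(SI) else float(out)


def apply_saturation(SI, ceiling: float = DEFAULT_CEILING):
    """Clip signal at the detector ceiling: ``min(SI, ceiling)``.

    Idempotent.  ``ceiling`` must be positive.
    """
    if not (ceiling > 0):
        raise DomainError(f"saturation ceiling must be positive, got {ceiling}")
    out = np.minimum(np.asarray(SI, dtype=float), ceiling)
    return out if np.ndim(SI) else float(out)
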