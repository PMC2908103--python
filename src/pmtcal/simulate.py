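"""Synthetic calibration slides and simulated scanner readouts.

The simulated slide follows the layout of a commercial dye calibration
slide (Full Moon BioSystems style): 32 columns of replicate spots, of
which columns 1–27 hold a two-fold dilution series of dye starting at
1.47e5 fluorophores/µm² and ending at 2.19e-3, column 28 holds spotting
buffer (intended as a negative control), columns 29–31 are blank, and
column 32 carries position markers used for gridding.

A scan is simulated through the forward response model plus a noise model:

    SI = clip( f(x) * L + N, 0, ceiling )

with ``f(x) = B*x**a + g``, ``L`` lognormal with mean 1 and coefficient of
variation ``noise_cv`` (multiplicative spot/scanner noise, roughly constant
scatter on a log scale), and ``N`` centered Gaussian with standard
deviation ``additive_sd`` (read noise; off by default).  Buffer spots
carry an extra autofluorescence term on top of the slide-wide ``g``, so a
"buffer spots actually contain dye or extra fluorescence" scenario can be
simulated.  Marker spots are rendered at the ceiling — in a real scan they
are bright fiducials — and are flagged saturated.

Every simulation requires an explicit seed; there is no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainError
from .fitting import ScanObservation
from .model import DEFAULT_CEILING, ScannerResponseModel, predict_signal

__all__ = [
    "Role",
    "SlideColumn",
    "SlideLayout",
    "SimulationConfig",
    "SCANNER_PRESETS",
    "TOP_DENSITY",
    "density_for_series",
    "make_slide_layout",
    "simulate_scan",
    "write_fixture_bundle",
]

#: Density of the first dilution column, fluorophores/µm².
TOP_DENSITY = 1.47e5

#: Dilution columns 1..27; 28 buffer; 29–31 blank; 32 position marker.
N_DILUTION = 27
BUFFER_SERIES = 28
BLANK_SERIES = (29, 30, 31)
MARKER_SERIES = 32

#: Ground-truth response triples for three commercial scanners, as fitted
#: characteristics (B, a, g) per channel and PMT gain.  Used as realistic
#: simulation truths throughout the test-suite and diagnostics examples.
SCANNER_PRESETS: dict[tuple[str, str, int], ScannerResponseModel] = {
    ("Agilent", "Cy3", 100): ScannerResponseModel(106, 0.95, 11.90, "Cy3", 100),
    ("Agilent", "Cy3", 50): ScannerResponseModel(52, 0.95, 12.14, "Cy3", 50),
    ("Agilent", "Cy3", 20): ScannerResponseModel(21, 0.94, 12.12, "Cy3", 20),
    ("Agilent", "Cy5", 100): ScannerResponseModel(54, 0.98, 3.90, "Cy5", 100),
    ("Agilent", "Cy5", 50): ScannerResponseModel(28, 0.98, 4.04, "Cy5", 50),
    ("Agilent", "Cy5", 20): ScannerResponseModel(11, 0.99, 4.76, "Cy5", 20),
    ("GenePix", "Cy3", 500): ScannerResponseModel(208, 0.74, 7.45, "Cy3", 500),
    ("Bio-Rad", "Cy3", 500): ScannerResponseModel(4, 0.84, 8.33, "Cy3", 500),
    ("Bio-Rad", "Cy5", 500): ScannerResponseModel(11, 0.86, 3.85, "Cy5", 500),
}


class Role:
    """Column roles on the slide."""
    DILUTION = "dilution"
    BUFFER = "buffer"
    BLANK = "blank"
    MARKER = "marker"

    ALL = (DILUTION, BUFFER, BLANK, MARKER)


@dataclass(frozen=True)
class SlideColumn:
    """One slide column: a set of replicate spots sharing role and density.

    ``density`` is ``None`` for buffer and marker columns (no nominal
    dye density is assigned to them) and exactly 0.0 for blanks.
    """

    index: int
    role: str
    dye: str = "Cy3"
    density: float | None = None

    def __post_init__(self) -> None:
        if self.role not in Role.ALL:
            raise DomainError(f"unknown column role {self.role!r}")
        if self.role == Role.BLANK and self.density != 0.0:
            raise DomainError("blank columns must have density exactly 0")
        if self.role == Role.DILUTION and (self.density is None or self.density <= 0):
            raise DomainError("dilution columns need a positive density")


@dataclass(frozen=True)
class SlideLayout:
    """Spot grid of a calibration slide: columns plus a replicate count."""

    columns: tuple[SlideColumn, ...]
    replicates_per_column: int = 20

    def __post_init__(self) -> None:
        if self.replicates_per_column < 1:
            raise DomainError("replicates_per_column must be >= 1")
        idx = [c.index for c in self.columns]
        if len(set(idx)) != len(idx):
            raise DomainError("duplicate column indices in layout")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def n_spots(self) -> int:
        return self.n_columns * self.replicates_per_column

    def column(self, index: int) -> SlideColumn:
        for c in self.columns:
            if c.index == index:
                return c
        raise KeyError(f"no column with index {index}")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and noise model for a simulated scan.

    ``noise_cv`` is the coefficient of variation of the mean-1 lognormal
    multiplicative noise; ``additive_sd`` the SD of additive Gaussian read
    noise in counts; ``buffer_autofluorescence`` extra counts (pre-noise)
    on buffer spots beyond the slide-wide ``g``.  ``quantize`` rounds
    signals to integer counts as a scanner ADC would.  ``seed`` is
    mandatory.
    """

    truth: ScannerResponseModel
    seed: int
    noise_cv: float = 0.10
    additive_sd: float = 0.0
    buffer_autofluorescence: float = 0.0
    ceiling: float = DEFAULT_CEILING
    quantize: bool = False

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.additive_sd < 0:
            raise DomainError("noise parameters must be >= 0")
        if self.ceiling <= 0:
            raise DomainError("ceiling must be positive")


def density_for_series(k: int, top_density: float = TOP_DENSITY) -> float:
    """Nominal surface density of dilution series ``k`` (1..27).

    The dilution series is geometric with ratio 1/2:
    ``top_density / 2**(k-1)``, i.e. 1.47e5 for k=1 down to ~2.19e-3 for
    k=27.  Series 28 (buffer), 29–31 (blank) and 32 (marker) carry no
    dilution density and are rejected.
    """
    if not (1 <= k <= N_DILUTION):
        raise DomainError(
            f"series index {k} outside the dilution range 1..{N_DILUTION} "
            "(28 is buffer, 29-31 blank, 32 position marker)"
        )
    return top_density / 2.0 ** (k - 1)


def make_slide_layout(replicates_per_column: int = 20,
                      dye: str = "Cy3",
                      top_density: float = TOP_DENSITY) -> SlideLayout:
    """The standard 32-column calibration slide layout."""
    cols = []
    for k in range(1, N_DILUTION + 1):
        cols.append(SlideColumn(k, Role.DILUTION, dye,
                                density_for_series(k, top_density)))
    cols.append(SlideColumn(BUFFER_SERIES, Role.BUFFER, dye, None))
    for k in BLANK_SERIES:
        cols.append(SlideColumn(k, Role.BLANK, dye, 0.0))
    cols.append(SlideColumn(MARKER_SERIES, Role.MARKER, dye, None))
    return SlideLayout(columns=tuple(cols),
                       replicates_per_column=replicates_per_column)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def simulate_scan(layout: SlideLayout,
                  config: SimulationConfig) -> list[ScanObservation]:
    """Simulate one scan of ``layout`` under ``config``.

    Column means: dilution spots follow ``predict_signal(x)``; blanks sit
    at ``g``; buffer spots at ``g + buffer_autofluorescence``; marker
    spots at the ceiling.  Noise, clamping at zero, saturation clipping
    and (optionally) integer quantization are applied per spot.
    Bit-for-bit reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    truth = config.truth
    out: list[ScanObservation] = []
    n_rep = layout.replicates_per_column
    for col in sorted(layout.columns, key=lambda c: c.index):
        if col.role == Role.DILUTION:
            mean, x_nom = predict_signal(col.density, truth), col.density
        elif col.role == Role.BLANK:
            mean, x_nom = truth.g, 0.0
        elif col.role == Role.BUFFER:
            mean, x_nom = truth.g + config.buffer_autofluorescence, None
        else:  # marker: bright gridding fiducial
            mean, x_nom = config.ceiling, None
        L = _lognormal_factors(rng, config.noise_cv, n_rep)
        N = (rng.normal(0.0, config.additive_sd, n_rep)
             if config.additive_sd > 0 else np.zeros(n_rep))
        si = np.maximum(mean * L + N, 0.0)
        si = np.minimum(si, config.ceiling)
        if config.quantize:
            si = np.rint(si)
        sat = si >= config.ceiling
        for r in range(n_rep):
            out.append(ScanObservation(
                series_index=col.index, x_nominal=x_nom,
                signal=float(si[r]), channel=truth.channel,
                pmt_gain=truth.pmt_gain, saturated=bool(sat[r])))
    return out


def write_fixture_bundle(layout: SlideLayout,
                         observations: list[ScanObservation],
                         directory: str | Path) -> dict[str, Path]:
    """Write a GAL file and an intensity CSV for ``layout``/``observations``.

    Also writes the slide description table (the "manual" view of the
    layout).  Returns the paths written.  Everything round-trips through
    the readers in :mod:`pmtcal.galio`.
    """
    from . import galio  # deferred: galio imports our dataclasses

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gal": directory / "layout.gal",
        "intensities": directory / "intensities.csv",
        "manual": directory / "slide_description.csv",
    }
    galio.write_gal(layout, paths["gal"])
    galio.write_intensity_table(observations, layout, paths["intensities"])
    galio.write_manual_table(layout, paths["manual"])
    return paths
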