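# pmtcal — microarray scanner response calibration

Fluorescence microarray scanners are calibrated with dye slides: glass
spotted with Cy3/Cy5 at known surface densities, scanned without
hybridization. Interpreting such scans naively goes wrong in two ways:
the spotting buffer autofluoresces, so low-density spots read a constant
background instead of dye signal (a "lower plateau" that belongs to the
slide, not the detector), and the detector clips at its 16-bit ceiling.
`pmtcal` models, fits, simulates, and audits this situation.

## The model

Signal intensity as a function of fluorophore surface density
*x* (fluorophores/µm²):

```
SI(x) = B·xᵃ + g
```

* **B** — photomultiplier sensitivity (counts per (fluorophores/µm²)ᵃ);
  scales with PMT gain.
* **a** — curvature exponent; *a* = 1 is a perfectly linear detector.
* **g** — autofluorescence of the buffer/slide (counts); a property of
  the slide, independent of the PMT gain.

Because the data span many orders of magnitude in both axes, the triple
is fitted by minimizing the sum of squared **relative** residuals

```
E = Σᵢ [(SIᵢ − SI(xᵢ)) / SI(xᵢ)]²
```

(weighted least squares with weights 1/SI²), with saturated spots
excluded and a first-order correction for the multiplicative-noise bias
of this criterion (see `docs/methods.md`). Within-series bootstrap
resampling provides confidence intervals.

The package contains five parts:

| module | what it does |
| --- | --- |
| `pmtcal.model` | forward model, inversion (signal → density), saturation |
| `pmtcal.fitting` | merit function, initialization, bounded fit, bootstrap |
| `pmtcal.simulate` | 32-column calibration-slide simulator (2-fold dilution series 1.47E+05 → 2.19E−03, buffer, blanks, markers; lognormal noise; 16-bit clipping) |
| `pmtcal.galio` | GAL (GenePix Array List) and intensity-CSV I/O, plus a manual-vs-GAL consistency audit |
| `pmtcal.diagnostics` | usable density range, gain invariance of g (vs B), cross-channel curvature comparison, two-channel ratio profiles |

## Worked example

```python
from pmtcal import (ScannerResponseModel, SimulationConfig, fit_response,
                    make_slide_layout, simulate_scan, usable_range)

truth = ScannerResponseModel(B=106, a=0.95, g=11.90, channel="Cy3", pmt_gain=100)
layout = make_slide_layout(replicates_per_column=20)
scan = simulate_scan(layout, SimulationConfig(truth=truth, seed=42, noise_cv=0.10))

fit = fit_response(scan)
m = fit.model
print(f"B = {m.B:.2f}   a = {m.a:.4f}   g = {m.g:.2f}")
print(f"merit E = {fit.merit:.3f}  n_used = {fit.n_used}  "
      f"saturated excluded = {fit.n_excluded_saturated}")
rng = usable_range(m, signal_to_background=3.0)
print(f"usable range: {rng.lower:.3f} to {rng.upper:.1f} fluorophores/um^2")
```

prints

```
B = 106.54   a = 0.9493   g = 11.81
merit E = 4.489  n_used = 440  saturated excluded = 160
usable range: 0.314 to 866.7 fluorophores/um^2
```

All three parameters are recovered to well under 1% despite 10% spot
noise; the 160 excluded spots are the eight brightest dilution columns,
which clip at 65535 counts. The usable range says that below ~0.31
fluorophores/µm² the dye signal never reaches three times the
autofluorescence floor — the bottom eight dilution series of this slide
are unusable — and above ~870 the detector saturates at this gain.

The same workflow is available from the shell:

```sh
pmtcal simulate --scanner Agilent --channel Cy3 --gain 100 --seed 42 --out scan/
pmtcal fit scan/intensities.csv --boot 200 --seed 1 --plot fit.png
pmtcal diagnose scan_g100/intensities.csv scan_g50/intensities.csv --out report.json
pmtcal check-layout scan/slide_description.csv scan/layout.gal
```

`check-layout` exits nonzero when the vendor's description table and GAL
layout file disagree — e.g. a column documented as buffer (negative
control) to which the GAL file assigns a dye concentration.

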