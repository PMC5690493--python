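# oofrecon

Out-of-field response correction and QA statistics for measurement-guided
3D dose reconstruction with cylindrical diode arrays.

## The problem

Diode arrays used for patient-specific IMRT/VMAT quality assurance are not
water-equivalent: out of the direct beam, where the photon spectrum
softens, diodes over-respond to scattered radiation. Dose-reconstruction
software built on measurements from one hardware generation implicitly
compensates for that over-response; when a hardware redesign reduces it
(for example by removing high-Z material near the diodes), the old
compensation over-corrects and reconstructed dose comes out systematically
low in collimated regions. Rather than rebuilding every beam model, the
reconstruction can carry a single user-set **out-of-field correction
factor** (OOFCF) that "adds back" small amounts of dose, only where the
beam's-eye-view (BEV) ray was under an MLC leaf or jaw.

`oofrecon` implements that correction and the machinery needed to validate
and commission it: a treatment-plan model with subbeam segmentation, BEV
fluence accumulation and the composite correction mask, divergent mask
application with a surface taper, gamma-index analysis with global/local
dose-error normalization, TG-119-style confidence-limit statistics, the
OOFCF tuning scan, and a synthetic module (plans, a toy dose engine on the
cylindrical phantom, and a virtual diode response model) that exercises the
whole pipeline without measured data.

## The correction in standard notation

For each time-resolved subbeam, corrected dose at a point (x, y, z) in beam
coordinates is

```
D_corr(x,y,z) = D_uncorr(x,y,z) · C(x,y)
```

where the composite correction `C` is constant with depth and given by the
ratio of MU-integrated corrected to uncorrected fluence,

```
C(x,y) = ∫ F_corr(x,y,MU) dMU / ∫ F_uncorr(x,y,MU) dMU .
```

Uncorrected fluence is the MU-weighted exposure of a BEV ray — 1.0 per MU
inside the open aperture, the MLC (or jaw) transmission fraction `T` under
collimation. Corrected fluence adds, per MU under collimation,

```
ΔF = (OOFCF − 1) · EDF ,
```

with `EDF` a small per-energy scalar (~0.01–0.025) that keeps the single
user factor energy-independent. Hence `C ≡ 1` where a pixel was open the
whole subbeam, and `C = (T + (OOFCF−1)·EDF)/T` for a pixel blocked
throughout. The 2D mask is applied to the 3D subbeam dose along divergent
source rays and tapered linearly back to unity at the curved entry/exit
surfaces of the detector-array cylinder.

Validation metrics follow the field's conventions: gamma index
γ = min √((Δd/DTA)² + (ΔD/tol)²) with a 10% low-dose threshold and the
tolerance normalized globally (percent of the reference maximum) or
locally; populations of per-plan results are summarized as mean ± 1.96·SD
(two-sided) or mean − 1.96·SD (one-sided pass-rate bound).

## Worked example

A 5 mm wide aperture is parked so the isocenter sits 10 mm outside the
field edge — the classic out-of-field sensitivity geometry. With
`OOFCF = 1.17`, MLC transmission 0.02 and `EDF = 0.02`, the correction at
the blocked measurement point is (0.02 + 0.17·0.02)/0.02 = 1.17, while
directly irradiated pixels are untouched:

```python
import numpy as np
from oofrecon import (BeamModelParams, BEVGrid, OOFSettings, composite_mask,
                      generate_plan, segment_subbeams)

model = BeamModelParams(energy_label="6X", edf=0.02, mlc_transmission=0.02)
plan = generate_plan("oof_test", aperture_width=5.0, point_offset=10.0)
beam = plan.beams[0]
subbeam = segment_subbeams(beam)[0]
grid = BEVGrid.from_extent(-30.0, 10.0, -30.0, 30.0, 2.0)
mask = composite_mask(subbeam, beam, grid, model,
                      OOFSettings(nominal_oofcf=1.17, edf=model.edf))
iy = int(np.argmin(np.abs(grid.y)))
print(f"correction at the out-of-field measurement point: "
      f"{mask.values[iy, int(np.argmin(np.abs(grid.x)))]:.4f}")
print(f"correction inside the open aperture:              "
      f"{mask.values[iy, int(np.argmin(np.abs(grid.x + 12.5)))]:.4f}")
```

prints

```
correction at the out-of-field measurement point: 1.1700
correction inside the open aperture:              1.0000
```

The commissioning loop — simulate a sliding-window delivery, build a
reference carrying a known over-response ratio, scan the factor, and pick
the |median ΔD| minimizer — runs from the command line:

```
$ oofrecon tune --out-dir out --true-factor 1.17
selected factor 1.17 (true 1.17); scan written to out/scan.csv
```

`out/scan.csv` holds the factor grid with its pass rates and median dose
differences (the machine-readable tuning curve). Other subcommands:
`simulate`, `mask`, `correct`, `gamma`, `stats`, `tables`, `pipeline`
(see `oofrecon --help`).

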