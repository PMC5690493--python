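# Methods

## Model

A treatment beam is an ordered sequence of control points: cumulative
meterset (MU), gantry angle, per-leaf MLC tip positions and jaw edges, all
in mm projected to the isocenter plane (IEC-style beam coordinates, BEV x
along leaf travel, BEV y along the leaf boundaries). Delivery between
control points is linear in meterset. Leaves are rectangular faces — no
tongue-and-groove, no rounded-tip offset — because the fluence model is
binary in/out plus a transmission fraction, and those refinements are
below the 1 mm default BEV resolution.

Each control-point interval with nonzero MU is one **subbeam** (the finest
granularity the plan defines); an optional MU cap splits long intervals
into equal parts. Zero-MU intervals (step-and-shoot repositioning) produce
no subbeam.

Per subbeam, every BEV pixel accumulates two MU integrals:

* *uncorrected fluence* — ΔMU × {1 open, `T_mlc` under a leaf, `T_jaw`
  under a jaw}, jaw blocking taking precedence;
* *blocked MU* — the raw MU spent under any collimation.

The corrected fluence adds `(OOFCF − 1)·EDF` per blocked MU, and the
composite correction mask is the pixelwise ratio corrected/uncorrected.
The mask is pure geometry: 1 exactly where a pixel stayed open, bounded by
`(T + (OOFCF−1)·EDF)/T` at the always-blocked extreme, monotone in OOFCF,
and identically 1 at the default OOFCF = 1.

The mask multiplies the 3D subbeam dose along divergent rays from the
source (central projection onto the isocenter plane, bilinear mask
sampling), constant with depth except for a linear taper to unity over
`taper_distance` of ray path at the entry/exit surfaces of the
detector-array cylinder (radius 104 mm, axis along the couch): the applied
factor is `1 + w·(mask − 1)` with `w ∈ [0, 1]`. Corrected subbeam grids
are summed voxelwise.

## Numerical choices

**Event-exact fluence integration.** Because leaf and jaw motion is linear
in meterset between control points, each pixel's exposure state is
piecewise constant with breakpoints where one of six linear margins (two
leaf tips, four jaw edges) crosses zero. The state-occupancy integrals are
accumulated exactly from those crossings. A midpoint-sampled MU stepping
scheme was evaluated first and rejected: it converges only at O(1/n), and
at pixels a leaf tip grazes the error is amplified by 1/T in the mask
ratio (64 steps leave ~1e-2 mask errors; even 4096 steps leave ~4e-4).
With event integration the mask is independent of the substep count; the
test suite checks it against an independent brute-force MU-stepped oracle
at 65536 steps (oracle discretization ~3e-5) within 1e-4. `n_substeps`
remains in the API as a pure subdivision parameter; integration ranges are
additionally split at interior control points.

**Boundary conventions.** The jaw rectangle is closed (a pixel exactly on
the edge counts inside); the leaf opening is open (`A < x < B`), so abutted
leaf tips block their own line. Ties are measure-zero for moving edges and
only matter for static edges exactly on pixel centers.

**Mask application.** Voxels are projected individually (no fan-line
bucketing); voxels projecting outside the mask footprint are left
unchanged with a logged count — callers who need full coverage widen the
BEV grid margin. The taper operates on per-ray path length inside the
cylinder (entry and exit handled symmetrically); `taper_distance` defaults
to 10 mm, a shape choice only loosely constrained by the requirement that
the correction vanish at the measured surfaces.

**Gamma analysis.** γ is the minimum over a lattice of offsets (spacing
`interp_fraction·DTA`, default 1/10; extent `search_radius_factor·DTA`,
default 3) of √((Δd/DTA)² + (ΔD/tol)²), with the evaluated grid sampled by
trilinear interpolation and `tol` the dose criterion as a percent of the
reference maximum (global) or the local reference dose (local). The
reference is the measurement; threshold (default 10% of the reference
maximum) and global normalization both use the reference maximum, and the
median signed local dose difference is computed over the same
above-threshold set. A point passes at γ ≤ 1 inclusive. The search walks
offsets in radial shells with an exact early exit (a point stops once the
distance term alone exceeds its running minimum), so it equals exhaustive
search over the same lattice — asserted against a brute-force oracle.

**Summary statistics.** Sample (n−1) standard deviation throughout — it is
what reproduces the packaged tables' printed SD rows; population SD does
not. Reported table values are rounded half-away-from-zero to one decimal;
full precision is kept internally. Confidence limits follow the TG-119
convention: mean ± 1.96·SD two-sided, and for pass rates the one-sided
bound mean − 1.96·SD (equivalently CL = (100 − mean) + 1.96·SD).

**Tuning.** The scan rebuilds the correction per candidate factor and
scores 2% local / 2 mm pass rate and median ΔD against the reference.
Since the per-MU adjustment, the mask ratio's numerator, and the taper all
act linearly in `(OOFCF − 1)`, the corrected total equals
`D_uncorr + (OOFCF − 1)·G` with `G` computed once; the scan uses this
exact decomposition (a test asserts equality with explicit per-factor mask
rebuilds). Selection minimizes |median ΔD| — the pass-rate curve plateaus
near the optimum while the median localizes it — with ties to the smaller
factor and a cap at the largest measured sensitivity ratio. With multiple
comparisons the objective averages |median ΔD| over them.

## Synthetic study conditions

The synthetic module emulates, and stands in for, the measured inputs:

* **Plans**: static fields, sliding-window sweeps, arcs (2° control-point
  increments for a full arc, 181 control points), and the narrow
  out-of-field test apertures (0.5–3 cm wide, measurement point 1–2 cm
  outside the field). Deterministic given a seed.
* **Toy dose engine**: divergent primary with inverse-square and
  exponential attenuation along the water-equivalent path through the
  26.6 cm phantom cylinder (relative density 1.15), plus a flat
  transmission/scatter floor under collimation, aperture frozen at the
  subbeam midpoint. The default attenuation coefficient (0.00405/mm water)
  is calibrated so the exit diode shell receives one quarter of the
  entrance dose, the characteristic ratio of the plugged phantom. It has
  no head scatter, no penumbra, no buildup — passing tests show the
  correction/analysis chain is self-consistent, not that the engine
  predicts clinical dose.
* **Virtual diodes**: readings are true dose times independent
  multiplicative sensitivities — per-segment low-MU nonlinearity,
  dose-per-pulse (via source-to-detector distance), repetition rate, and
  an out-of-field over-response applied to the collimated dose component
  only — plus optional seeded multiplicative Gaussian noise. Packaged CSV
  anchors pin the curves (0.978 at 5 MU/min normalized at 400 MU/min;
  1.012→0.992 over 746–1196 mm SDD for 6 MV normalized at 896 mm; −2.8%
  at 2 MU on the entrance diode with default acquisition, halved with
  extended integration; over-response ratio up to 1.17 between hardware
  versions); between anchors the curves are monotone PCHIP interpolations,
  not ground truth. No cross-terms are modeled, since the effects are
  characterized as separately normalized ratios.

**Closed-loop tuning conditions.** The recovery studies use a 60 mm
sliding-window beam with a 20 mm gap over 5 control points and 50 MU on a
10 mm dose lattice, and a biplanar-array stand-in (two orthogonal interior
planes, 10 mm pitch) spanning the irradiated region as reference. Two
geometric facts drive those choices: the surface diode shell lies exactly
on the taper cylinder where the applied correction is tapered to unity, so
surface diodes carry no tuning signal by construction — the reference must
sample the interior, as the biplanar dosimeter does; and the gap width sets
the in-field dose build-up (~7× the scatter floor), which keeps
out-of-field dose below the 10% analysis threshold as in clinical plans —
with a much narrower gap, jaw-shadow scatter crosses the threshold and the
jaw-region mask extreme ((T_jaw + (OOFCF−1)·EDF)/T_jaw = 2.7 at the
defaults) dominates the median, a regime the validation metrics are never
operated in.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `mlc_transmission` | 0.02 | – | typical MLC leakage fraction |
| `jaw_transmission` | 0.002 | – | jaws attenuate ~10× more than leaves |
| `edf` | 0.02 | – | mid-range of the per-energy 0.01–0.025 scale |
| `nominal_oofcf` | 1.0 | – | "no change"; commissioned value ≤ 1.17 |
| BEV resolution | 1.0 | mm | below this, partial-pixel effects are negligible |
| `taper_distance` | 10 | mm | ramp extent at the array surfaces |
| dose grid spacing | 2.5 | mm | conventional reconstruction resolution |
| gamma defaults | 2%/2 mm, local, 10% threshold | – | the most stringent criteria used for array cross-comparison |
| factor grid | 1.00–1.25 step 0.01 | – | brackets all measured sensitivity ratios |

## Limitations

* The dose engine and response model are deliberately minimal stand-ins;
  agreement in the closed loop demonstrates internal consistency of the
  correction/tuning/analysis chain, not dosimetric accuracy on real data.
* The reconstruction module corrects *supplied* subbeam dose grids; the
  measurement-guided perturbation that produces them is out of scope.
* DICOM support is a read subset (dynamic MLC/jaw RT Plans, RT Dose grids)
  plus a minimal RT Dose writer; anything else is ignored with a notice.
* Gantry angles are interpolated as raw degrees; arcs crossing the 0/360°
  seam must be expressed with continuous angles.
* The low-MU and out-of-field anchor tables are sparse; intermediate
  values are interpolation.
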