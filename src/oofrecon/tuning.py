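"""Tuning the user out-of-field correction factor against a reference.

The commissioning procedure scans the nominal correction factor over a
grid, rebuilds the per-subbeam correction and the accumulated corrected
dose for each value, and compares against a reference measurement (or a
simulated stand-in) with local-normalization gamma analysis.  The
operating factor is the one minimizing the absolute median dose
difference — the passing-rate curve typically plateaus near the optimum
while the median difference localizes it — clamped to a cap, normally
the maximum out-of-field sensitivity ratio actually measured for the
hardware pair.

Implementation note: the corrected dose is exactly linear in
``(factor - 1)`` (the per-MU adjustment, the mask and the taper all act
linearly), so the scan computes the uncorrected total and the
unit-correction increment once and synthesizes every factor's dose from
them.  This is algebraically identical to rebuilding masks per factor;
a test asserts the equivalence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fluence_mask import (BEVGrid, OOFSettings, fluence_components,
                           mask_from_components)
from .gamma import GammaParams, gamma_map, median_dose_diff
from .plan_model import Beam, BeamModelParams, SubBeam
from .reconstruction import BeamGeometry, DoseGrid, TaperSpec, apply_mask, accumulate

__all__ = ["TuningScan", "scan_oofcf", "select_oofcf", "corrected_total_dose"]

DEFAULT_FACTOR_GRID = np.round(np.arange(1.00, 1.25 + 1e-9, 0.01), 2)


@dataclass
class TuningScan:
    """Result of one correction-factor scan (the machine twin of a
    factor-vs-agreement commissioning plot)."""

    factors: np.ndarray
    pass_rates: np.ndarray
    median_diffs: np.ndarray
    selected: float | None = None

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(np.diff(self.factors) <= 0):
            raise ValueError("factor grid must be strictly increasing")
        if not (len(self.factors) == len(self.pass_rates) == len(self.median_diffs)):
            raise ValueError("scan arrays must be aligned")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["factor", "pass_rate", "median_diff"])
            for f, p, m in zip(self.factors, self.pass_rates, self.median_diffs):
                w.writerow([f"{f:.4g}", f"{p:.4f}", f"{m:.6f}"])


def _dose_decomposition(contributions, bev_grid: BEVGrid, model: BeamModelParams,
                        taper: TaperSpec | None,
                        n_substeps: int | None) -> tuple[DoseGrid, DoseGrid]:
    """(uncorrected total, per-unit-factor increment) over all subbeams.

    ``contributions`` is a list of ``(beam, subbeam, dose_grid)``.  The
    increment G satisfies: corrected total at factor c = uncorrected + (c-1)*G.
    """
    total_u: DoseGrid | None = None
    total_g: DoseGrid | None = None
    for beam, subbeam, dose in contributions:
        geometry = BeamGeometry(gantry_angle=subbeam.gantry_mid, sad=model.source_axis_distance)
        uncorr, blocked = fluence_components(subbeam, beam, bev_grid, model, n_substeps)
        # mask at a probe factor 2.0 gives 1 + F with F the unit-factor slope
        probe = mask_from_components(uncorr, blocked, OOFSettings(2.0, model.edf), bev_grid)
        corrected_probe = apply_mask(dose, probe, geometry, taper)
        increment = dose.copy()
        increment.values = corrected_probe.values - dose.values
        if total_u is None:
            total_u, total_g = dose.copy(), increment
        else:
            total_u = accumulate([total_u, dose])
            total_g = accumulate([total_g, increment])
    if total_u is None:
        raise ValueError("no subbeam contributions supplied")
    return total_u, total_g


def corrected_total_dose(contributions, factor: float, bev_grid: BEVGrid,
                         model: BeamModelParams, taper: TaperSpec | None = None,
                         n_substeps: int | None = None) -> DoseGrid:
    """Accumulated corrected dose at one nominal correction factor.

    Explicit route: per subbeam, build the composite mask at ``factor``,
    apply it with the surface taper, and sum.
    """
    settings = OOFSettings(factor, model.edf)
    corrected = []
    for beam, subbeam, dose in contributions:
        geometry = BeamGeometry(gantry_angle=subbeam.gantry_mid, sad=model.source_axis_distance)
        uncorr, blocked = fluence_components(subbeam, beam, bev_grid, model, n_substeps)
        mask = mask_from_components(uncorr, blocked, settings, bev_grid)
        corrected.append(apply_mask(dose, mask, geometry, taper))
    return accumulate(corrected)


def scan_oofcf(contributions, reference, factor_grid=None,
               gamma_params: GammaParams | None = None,
               bev_grid: BEVGrid | None = None,
               model: BeamModelParams | None = None,
               taper: TaperSpec | None = None,
               n_substeps: int | None = None) -> TuningScan:
    """Score each candidate correction factor against the reference.

    Parameters
    ----------
    contributions : list of (Beam, SubBeam, DoseGrid)
        Uncorrected subbeam dose grids with their provenance.
    reference : DoseGrid or (positions, doses)
        The measurement (or simulated stand-in) to compare against.
    factor_grid : increasing factors to scan (default 1.00-1.25, step 0.01).
    gamma_params : criteria for the pass rate (default 2% local / 2 mm).
    """
    if factor_grid is None:
        factor_grid = DEFAULT_FACTOR_GRID
    factor_grid = np.asarray(factor_grid, dtype=float)
    if factor_grid.size == 0:
        raise ValueError("factor_grid must be non-empty")
    if gamma_params is None:
        gamma_params = GammaParams(dose_criterion=2.0, dta=2.0, normalization="local")
    if model is None:
        model = BeamModelParams()
    if bev_grid is None:
        bev_grid = BEVGrid.for_beam(contributions[0][0])

    total_u, total_g = _dose_decomposition(contributions, bev_grid, model, taper, n_substeps)
    pass_rates = np.empty(factor_grid.size)
    medians = np.empty(factor_grid.size)
    for i, c in enumerate(factor_grid):
        evaluated = total_u.copy()
        evaluated.values = total_u.values + (c - 1.0) * total_g.values
        res = gamma_map(reference, evaluated, gamma_params)
        pass_rates[i] = res.pass_rate
        medians[i] = median_dose_diff(reference, evaluated, gamma_params.threshold)
    return TuningScan(factors=factor_grid, pass_rates=pass_rates, median_diffs=medians)


def select_oofcf(scan: TuningScan, cap: float | None = None) -> float:
    """Operating factor: minimizer of |median dose difference|.

    Ties go to the smaller factor; the result is clamped to ``cap``
    (normally the maximum measured out-of-field sensitivity ratio).
    The selection is also recorded on the scan.
    """
    if scan.factors.size == 0:
        raise ValueError("empty scan")
    best = float(scan.factors[int(np.argmin(np.abs(scan.median_diffs)))])
    if cap is not None:
        best = min(best, float(cap))
    scan.selected = best
    return best
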