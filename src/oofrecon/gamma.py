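"""Gamma-index comparison of dose distributions.

For every reference point above the low-dose threshold,

    gamma = min over the search region of
            sqrt((distance / dta)^2 + (dose difference / tol)^2)

with ``tol`` the dose criterion as a percent of either the reference
maximum (*global* normalization) or the local reference dose (*local*).
A point passes when gamma <= 1 (inclusive).  The evaluated distribution
is sampled on a lattice of spacing ``interp_fraction * dta`` (linear
interpolation) out to ``search_radius_factor * dta``.

The search enumerates candidate offsets in shells of increasing radius
and stops per point once the distance term alone exceeds the running
minimum — an exact early exit, so the result equals an exhaustive scan
of the same offset lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .reconstruction import DoseGrid

__all__ = ["GammaParams", "GammaResult", "gamma_map", "median_dose_diff", "write_report_row"]


@dataclass(frozen=True)
class GammaParams:
    """Gamma criteria.

    dose_criterion : percent dose tolerance (e.g. 2 or 3)
    dta : distance-to-agreement in mm
    normalization : "global" (percent of reference maximum) or "local"
    threshold : low-dose cutoff, percent of the reference maximum
    search_radius_factor : search extent as a multiple of dta
    interp_fraction : evaluated sampling step as a fraction of dta
    """

    dose_criterion: float = 2.0
    dta: float = 2.0
    normalization: str = "local"
    threshold: float = 10.0
    search_radius_factor: float = 3.0
    interp_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.dose_criterion <= 0 or self.dta <= 0:
            raise ValueError("dose_criterion and dta must be positive")
        if not 0 <= self.threshold < 100:
            raise ValueError("threshold must be in [0, 100)")
        if self.normalization not in ("global", "local"):
            raise ValueError(f"normalization must be 'global' or 'local': {self.normalization}")
        if self.search_radius_factor <= 0 or self.interp_fraction <= 0:
            raise ValueError("search_radius_factor and interp_fraction must be positive")

    def label(self) -> str:
        tag = "G" if self.normalization == "global" else "L"
        return f"{self.dose_criterion:g}% {tag}/{self.dta:g} mm"


@dataclass
class GammaResult:
    per_point_gamma: np.ndarray
    pass_rate: float
    n_evaluated: int
    median_dose_diff: float


def _as_points(reference) -> tuple[np.ndarray, np.ndarray]:
    """Reference as (positions (N,3), doses (N,)); accepts a DoseGrid or a pair."""
    if isinstance(reference, DoseGrid):
        return reference.voxel_centers(), reference.values.ravel()
    pos, dose = reference
    return np.atleast_2d(np.asarray(pos, dtype=float)), np.asarray(dose, dtype=float).ravel()


def _offset_shells(radius: float, step: float) -> list[tuple[float, np.ndarray]]:
    """Offset lattice within ``radius`` grouped into shells of increasing
    distance; each entry is (min distance in shell, (k, 3) offsets)."""
    n = int(np.floor(radius / step + 1e-9))
    ax = step * np.arange(-n, n + 1)
    OX, OY, OZ = np.meshgrid(ax, ax, ax, indexing="ij")
    offsets = np.stack([OX.ravel(), OY.ravel(), OZ.ravel()], axis=1)
    r = np.linalg.norm(offsets, axis=1)
    keep = r <= radius + 1e-9
    offsets, r = offsets[keep], r[keep]
    order = np.argsort(r)
    offsets, r = offsets[order], r[order]
    shells = []
    # group into bins of one lattice step in radius; the final boundary is
    # the offset count so the outermost shell keeps its boundary offsets
    edges = np.arange(0.0, r[-1] + step, step)
    idx = np.append(np.searchsorted(r, edges), len(offsets))
    for a, b in zip(idx[:-1], idx[1:]):
        if b > a:
            shells.append((float(r[a]), offsets[a:b]))
    return shells


def gamma_map(reference, evaluated: DoseGrid, params: GammaParams) -> GammaResult:
    """Per-point gamma of ``evaluated`` against ``reference``.

    ``reference`` is the measurement (a ``DoseGrid`` or a
    ``(positions, doses)`` pair); ``evaluated`` the reconstructed or
    calculated grid.  Threshold and global normalization both use the
    reference maximum.  Raises if no reference point clears the
    threshold.
    """
    ref_pos, ref_dose = _as_points(reference)
    ref_max = float(ref_dose.max())
    sel = ref_dose > params.threshold / 100.0 * ref_max
    if not sel.any():
        raise ValueError("no evaluable points above the low-dose threshold")
    ref_pos, ref_dose = ref_pos[sel], ref_dose[sel]

    if params.normalization == "global":
        tol = np.full(ref_dose.shape, params.dose_criterion / 100.0 * ref_max)
    else:
        tol = params.dose_criterion / 100.0 * ref_dose

    interp = evaluated.interpolator()
    dta2 = params.dta**2

    # zero-offset start
    d0 = interp(ref_pos)
    gamma2 = ((d0 - ref_dose) / tol) ** 2
    gamma2 = np.where(np.isnan(gamma2), np.inf, gamma2)

    step = params.interp_fraction * params.dta
    radius = params.search_radius_factor * params.dta
    for r_min, offsets in _offset_shells(radius, step):
        if r_min == 0.0:
            continue
        active = np.nonzero(gamma2 > r_min**2 / dta2)[0]
        if active.size == 0:
            break
        pts = ref_pos[active, None, :] + offsets[None, :, :]
        vals = interp(pts.reshape(-1, 3)).reshape(active.size, len(offsets))
        dist2 = np.sum(offsets**2, axis=1)
        g2 = dist2[None, :] / dta2 + ((vals - ref_dose[active, None]) / tol[active, None]) ** 2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        gamma2[active] = np.minimum(gamma2[active], g2.min(axis=1))

    gamma = np.sqrt(gamma2)
    # tiny numerical slack so exact-boundary cases (gamma == 1) pass
    pass_rate = 100.0 * float(np.mean(gamma <= 1.0 + 1e-12))
    ok = ~np.isnan(d0)
    med = float(np.median(100.0 * (d0[ok] - ref_dose[ok]) / ref_dose[ok]))
    return GammaResult(per_point_gamma=gamma, pass_rate=pass_rate,
                       n_evaluated=int(ref_dose.size), median_dose_diff=med)


def median_dose_diff(reference, evaluated: DoseGrid, threshold: float = 10.0) -> float:
    """Median signed local percent dose difference over above-threshold points.

    ``100 * (evaluated - reference) / reference`` at each reference point
    whose dose exceeds ``threshold`` percent of the reference maximum.
    """
    ref_pos, ref_dose = _as_points(reference)
    sel = ref_dose > threshold / 100.0 * float(ref_dose.max())
    if not sel.any():
        raise ValueError("no evaluable points above the low-dose threshold")
    ref_pos, ref_dose = ref_pos[sel], ref_dose[sel]
    ev = evaluated.interpolator()(ref_pos)
    ok = ~np.isnan(ev)
    return float(np.median(100.0 * (ev[ok] - ref_dose[ok]) / ref_dose[ok]))


def write_report_row(path: str | Path, plan: str, energy: str, technique: str,
                     params: GammaParams, result: GammaResult,
                     append: bool = True) -> None:
    """Append one per-comparison CSV report row (table-style)."""
    path = Path(path)
    header = "plan,energy,technique,criteria,pass_rate,median_dd,n_evaluated\n"
    line = (f"{plan},{energy},{technique},{params.label()},"
            f"{result.pass_rate:.1f},{result.median_dose_diff:.1f},{result.n_evaluated}\n")
    if append and path.exists():
        path.open("a").write(line)
    else:
        path.write_text(header + line)
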