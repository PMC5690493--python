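"""BEV fluence accumulation and the composite out-of-field correction mask.

For each subbeam, a pixel's *uncorrected fluence* is its MU-weighted
exposure: a pixel contributes 1.0 per MU while inside the open aperture,
the MLC transmission fraction while under a leaf, and the jaw
transmission fraction while under a jaw.  The *corrected fluence* adds,
per MU under collimation, an out-of-field adjustment

    (nominal_oofcf - 1) * edf

where ``nominal_oofcf`` is the user's single out-of-field correction
factor (1.0 = no change) and ``edf`` the small per-energy scalar that
keeps that factor energy-independent.  The composite correction mask is
the pixelwise ratio of MU-integrated corrected to uncorrected fluence:
exactly 1 where a pixel was open for the whole subbeam, and up to
``(T + (oofcf-1)*edf) / T`` for a pixel blocked throughout (``T`` its
governing transmission).

The mask is pure geometry + meterset: it does not depend on dose
magnitude.  Because leaf and jaw motion is linear in meterset between
control points, each pixel's exposure state is piecewise constant with
breakpoints at the metersets where a leaf tip or jaw edge crosses the
pixel center; the MU integrals are accumulated exactly from those
crossing events.  (A midpoint-sampled sum converges to the same values
only at first order in the substep count, with the error amplified by
the reciprocal transmission at pixels a leaf tip grazes, which is why
the integration is event-exact rather than stepped.)  ``n_substeps``
merely subdivides the integration range and does not change the result
for plans with linear motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np

from .plan_model import Aperture, Beam, BeamModelParams, SubBeam, aperture_at

__all__ = [
    "ExposureState",
    "BEVGrid",
    "FluenceMap",
    "CorrectionMask",
    "OOFSettings",
    "exposure_state",
    "oof_adjustment",
    "fluence_components",
    "uncorrected_fluence",
    "corrected_fluence",
    "composite_mask",
    "mask_from_components",
]

class ExposureState(IntEnum):
    OPEN = 0
    UNDER_MLC = 1
    UNDER_JAW = 2


@dataclass(frozen=True)
class BEVGrid:
    """Regular pixel grid in the isocenter plane (mm), beam's-eye view."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.size == 0 or self.y.size == 0:
            raise ValueError("BEV grid must be non-empty")
        for c in (self.x, self.y):
            if c.size > 1 and np.any(np.diff(c) <= 0):
                raise ValueError("BEV grid coordinates must be strictly increasing")

    @classmethod
    def from_extent(cls, xmin: float, xmax: float, ymin: float, ymax: float,
                    resolution: float = 1.0) -> "BEVGrid":
        nx = max(int(round((xmax - xmin) / resolution)) + 1, 2)
        ny = max(int(round((ymax - ymin) / resolution)) + 1, 2)
        return cls(np.linspace(xmin, xmax, nx), np.linspace(ymin, ymax, ny))

    @classmethod
    def for_beam(cls, beam: Beam, margin: float = 20.0, resolution: float = 1.0) -> "BEVGrid":
        """Grid covering the union of all jaw rectangles plus a margin."""
        jaws = np.array([cp.jaw_positions for cp in beam.control_points])
        return cls.from_extent(jaws[:, 0].min() - margin, jaws[:, 1].max() + margin,
                               jaws[:, 2].min() - margin, jaws[:, 3].max() + margin,
                               resolution)

    @property
    def resolution(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else 0.0

    @property
    def shape(self) -> tuple[int, int]:
        # (ny, nx): row index runs along y
        return (self.y.size, self.x.size)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y, indexing="xy")


@dataclass
class FluenceMap:
    """MU-weighted exposure per BEV pixel (MU units), values >= 0."""

    grid: BEVGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")


@dataclass
class CorrectionMask:
    """Dimensionless per-pixel composite out-of-field correction."""

    grid: BEVGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")

    def to_csv(self, path: str | Path) -> None:
        export_bev_csv(self.grid, self.values, path)


def export_bev_csv(grid: BEVGrid, values: np.ndarray, path: str | Path) -> None:
    """Write a BEV matrix as CSV with a coordinate header block."""
    with open(path, "w") as fh:
        fh.write("# x_mm," + ",".join(f"{v:.6g}" for v in grid.x) + "\n")
        fh.write("# y_mm," + ",".join(f"{v:.6g}" for v in grid.y) + "\n")
        np.savetxt(fh, values, delimiter=",", fmt="%.9g")


@dataclass
class OOFSettings:
    """User-facing out-of-field correction settings.

    ``nominal_oofcf`` is the single correction factor set by the user
    (default 1.0, meaning no change); ``edf`` is taken from the beam
    model's energy dependence factor.
    """

    nominal_oofcf: float = 1.0
    edf: float = 0.02

    def __post_init__(self) -> None:
        if self.nominal_oofcf <= 0:
            raise ValueError(f"nominal_oofcf must be positive: {self.nominal_oofcf}")

    @classmethod
    def for_model(cls, model: BeamModelParams, nominal_oofcf: float = 1.0) -> "OOFSettings":
        return cls(nominal_oofcf=nominal_oofcf, edf=model.edf)


# ---------------------------------------------------------------------------
# Pixel classification
# ---------------------------------------------------------------------------

def _classify(aperture: Aperture, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized pixel-center classification; jaw blocking takes precedence."""
    x1, x2, y1, y2 = aperture.jaw_positions
    under_jaw = (X < x1) | (X > x2) | (Y < y1) | (Y > y2)
    # leaf index from the transverse coordinate; pixels beyond the MLC span
    # behave like the nearest (closed) edge leaf
    idx = np.clip(np.searchsorted(aperture.leaf_boundaries, Y, side="right") - 1,
                  0, aperture.leaf_positions.shape[1] - 1)
    inside_leaf_gap = ((aperture.leaf_positions[0][idx] < X)
                       & (X < aperture.leaf_positions[1][idx]))
    state = np.full(np.shape(X), int(ExposureState.UNDER_MLC))
    state[inside_leaf_gap] = int(ExposureState.OPEN)
    state[under_jaw] = int(ExposureState.UNDER_JAW)
    return state


def exposure_state(aperture: Aperture, pixel: tuple[float, float],
                   model: BeamModelParams | None = None) -> ExposureState:
    """Classify one BEV point as open / under MLC / under jaw."""
    x, y = pixel
    return ExposureState(int(_classify(aperture, np.array(x), np.array(y))))


def oof_adjustment(state: ExposureState, settings: OOFSettings) -> float:
    """Out-of-field fluence increment per unit MU for one exposure state.

    Zero for directly irradiated pixels; ``(nominal_oofcf - 1) * edf``
    for pixels under the MLC or a jaw.
    """
    if state == ExposureState.OPEN:
        return 0.0
    return (settings.nominal_oofcf - 1.0) * settings.edf


# ---------------------------------------------------------------------------
# Fluence accumulation
# ---------------------------------------------------------------------------

def _segment_edges(beam: Beam, mu_a: float, mu_b: float, n_substeps: int) -> np.ndarray:
    """Integration edges: the requested subdivision plus any control-point
    metersets inside the range (leaf motion is only linear between them)."""
    edges = np.linspace(mu_a, mu_b, n_substeps + 1)
    interior = beam.metersets
    interior = interior[(interior > mu_a) & (interior < mu_b)]
    return np.unique(np.concatenate([edges, interior]))


def _exact_state_measures(beam: Beam, mu_a: float, mu_b: float,
                          X: np.ndarray, Y: np.ndarray,
                          weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-pixel MU integrals over [mu_a, mu_b] (no control point inside).

    Each of the six blocking constraints (two leaf tips, four jaw edges)
    is linear in meterset, so a pixel's exposure state changes only at
    their crossing metersets; the state is evaluated once per constant
    segment and the segment lengths are accumulated exactly.
    Returns flat arrays ``(uncorrected, blocked_mu)``.
    """
    ap0 = aperture_at(beam, mu_a)
    ap1 = aperture_at(beam, mu_b)
    idx = np.clip(np.searchsorted(ap0.leaf_boundaries, Y, side="right") - 1,
                  0, ap0.leaf_positions.shape[1] - 1)

    # linear "inside" margins g(f) = g0 + f*dg, f in [0,1]; inside <=> g > 0
    a0, a1 = ap0.leaf_positions[0][idx], ap1.leaf_positions[0][idx]
    b0, b1 = ap0.leaf_positions[1][idx], ap1.leaf_positions[1][idx]
    j0, j1 = np.asarray(ap0.jaw_positions), np.asarray(ap1.jaw_positions)
    g0s, dgs = [], []
    for v0, v1, sign, coord in (
        (a0, a1, +1.0, X),        # x - A > 0
        (b0, b1, -1.0, X),        # B - x > 0
        (j0[0], j1[0], +1.0, X),  # x - x1 > 0
        (j0[1], j1[1], -1.0, X),  # x2 - x > 0
        (j0[2], j1[2], +1.0, Y),  # y - y1 > 0
        (j0[3], j1[3], -1.0, Y),  # y2 - y > 0
    ):
        g0 = sign * (coord - v0)
        dg = sign * (v0 - v1) + np.zeros_like(g0)
        g0s.append(g0)
        dgs.append(dg)
    G0 = np.stack(g0s, axis=1)  # (npix, 6)
    DG = np.stack(dgs, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        crossings = np.where(DG != 0.0, -G0 / DG, 0.0)
    crossings = np.clip(crossings, 0.0, 1.0)
    npix = X.size
    edges = np.concatenate([np.zeros((npix, 1)), crossings, np.ones((npix, 1))], axis=1)
    edges.sort(axis=1)
    mids = 0.5 * (edges[:, :-1] + edges[:, 1:])            # (npix, 7)
    lengths = np.diff(edges, axis=1) * (mu_b - mu_a)       # MU per segment

    margins = G0[:, :, None] + DG[:, :, None] * mids[:, None, :]  # (npix, 6, 7)
    leaf_open = (margins[:, 0] > 0) & (margins[:, 1] > 0)
    # jaw rectangle is closed (a pixel exactly on the edge counts inside),
    # matching the point classifier's strict-outside convention
    in_jaw = np.all(margins[:, 2:] >= 0, axis=1)
    open_seg = leaf_open & in_jaw
    w = np.where(open_seg, weights[0], np.where(in_jaw, weights[1], weights[2]))
    uncorr = np.sum(w * lengths, axis=1)
    blocked = np.sum(np.where(open_seg, 0.0, lengths), axis=1)
    return uncorr, blocked


def fluence_components(subbeam: SubBeam, beam: Beam, grid: BEVGrid,
                       model: BeamModelParams,
                       n_substeps: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate the two MU integrals the correction is built from.

    Returns ``(uncorrected, blocked_mu)`` over the grid: the
    transmission-weighted MU exposure, and the raw MU each pixel spent
    under collimation (MLC or jaw).  State occupancies are integrated
    exactly from leaf/jaw crossing events, so the result is independent
    of ``n_substeps`` (which only subdivides the range).
    """
    if n_substeps is None:
        n_substeps = 1
    if n_substeps < 1:
        raise ValueError("n_substeps must be >= 1")
    X, Y = grid.meshgrid()
    Xf, Yf = X.ravel(), Y.ravel()
    uncorr = np.zeros(Xf.shape)
    blocked = np.zeros(Xf.shape)
    weights = np.array([1.0, model.mlc_transmission, model.jaw_transmission])
    edges = _segment_edges(beam, subbeam.mu_start, subbeam.mu_end, n_substeps)
    for a, b in zip(edges[:-1], edges[1:]):
        u, bl = _exact_state_measures(beam, float(a), float(b), Xf, Yf, weights)
        uncorr += u
        blocked += bl
    return uncorr.reshape(grid.shape), blocked.reshape(grid.shape)


def uncorrected_fluence(subbeam: SubBeam, beam: Beam, grid: BEVGrid,
                        model: BeamModelParams, n_substeps: int | None = None) -> FluenceMap:
    """MU-weighted exposure map for one subbeam (no OOF adjustment)."""
    uncorr, _ = fluence_components(subbeam, beam, grid, model, n_substeps)
    return FluenceMap(grid, uncorr)


def corrected_fluence(subbeam: SubBeam, beam: Beam, grid: BEVGrid,
                      model: BeamModelParams, settings: OOFSettings,
                      n_substeps: int | None = None) -> FluenceMap:
    """Exposure map with the per-MU out-of-field adjustment added under collimation."""
    uncorr, blocked = fluence_components(subbeam, beam, grid, model, n_substeps)
    adj = (settings.nominal_oofcf - 1.0) * settings.edf
    return FluenceMap(grid, uncorr + adj * blocked)


def mask_from_components(uncorrected: np.ndarray, blocked_mu: np.ndarray,
                         settings: OOFSettings, grid: BEVGrid) -> CorrectionMask:
    """Composite mask from precomputed fluence components.

    The corrected fluence is linear in ``nominal_oofcf``, so one
    ``(uncorrected, blocked_mu)`` pair yields the mask for any factor.
    """
    if np.any(uncorrected <= 0):
        j, i = np.argwhere(uncorrected <= 0)[0]
        raise ValueError(
            f"uncorrected fluence is zero at pixel (x={grid.x[i]}, y={grid.y[j]}); "
            "check that transmissions are positive"
        )
    adj = (settings.nominal_oofcf - 1.0) * settings.edf
    return CorrectionMask(grid, (uncorrected + adj * blocked_mu) / uncorrected)


def composite_mask(subbeam: SubBeam, beam: Beam, grid: BEVGrid,
                   model: BeamModelParams, settings: OOFSettings,
                   n_substeps: int | None = None) -> CorrectionMask:
    """Single 2D composite out-of-field correction mask for one subbeam.

    Pixelwise ratio of MU-integrated corrected to uncorrected fluence;
    1.0 exactly wherever the pixel was open for the whole subbeam.
    """
    uncorr, blocked = fluence_components(subbeam, beam, grid, model, n_substeps)
    return mask_from_components(uncorr, blocked, settings, grid)
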