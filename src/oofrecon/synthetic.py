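"""Synthetic study conditions: plans, a toy dose engine, and virtual diodes.

Nothing here touches measured data.  The module generates:

* treatment plans (static, sliding-window, arc, and narrow out-of-field
  test apertures) in the package's plan model;
* toy 3D subbeam dose on the cylindrical phantom — a divergent primary
  beam with exponential attenuation along the water-equivalent path plus
  a flat transmission/scatter floor under collimation.  The default
  attenuation is calibrated so the exit diode shell receives about one
  quarter of the entrance dose, the characteristic entrance/exit ratio
  of the plugged cylindrical phantom;
* virtual diode readings that perturb true dose with the measurable
  diode response effects: per-segment low-MU nonlinearity, dose-per-pulse
  (source-to-detector distance), repetition rate, and out-of-field
  overresponse, composited multiplicatively and independently;
* the normalized sensitivity-ratio analyses used to characterize those
  effects from device/reference reading pairs.

Packaged CSV anchor tables pin the curves to printed characterization
values (for example a diode/chamber ratio of 0.978 at 5 MU/min when
normalized at 400 MU/min, and 1.012 -> 0.992 over source-to-detector
distances 74.6 -> 119.6 cm for the 6 MV beam, normalized at 89.6 cm);
between anchors the curves are monotone (PCHIP) interpolations, not
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .fluence_mask import ExposureState, _classify
from .plan_model import (Beam, BeamModelParams, ControlPoint, DetectorGeometry,
                         SubBeam, TreatmentPlan, aperture_at)
from .reconstruction import BeamGeometry, DoseGrid

__all__ = [
    "ResponseModel",
    "ToyDoseParams",
    "generate_plan",
    "toy_subbeam_dose",
    "diode_positions",
    "virtual_diode_readings",
    "sensitivity_ratio_analysis",
    "ratio_of_ratios",
    "load_anchor_table",
]

#: Normalization anchors for the packaged response curves.
CALIBRATION_SDD_MM = 896.0
CALIBRATION_REP_RATE = 400.0


def load_anchor_table(name: str) -> pd.DataFrame:
    """Load a packaged anchor CSV (``rep_rate``, ``dpp_sdd``, ``low_mu``,
    ``table1`` ... ``table3_summary``)."""
    ref = resources.files("oofrecon.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def _pchip(x, y) -> PchipInterpolator:
    return PchipInterpolator(np.asarray(x, float), np.asarray(y, float), extrapolate=False)


@dataclass
class ResponseModel:
    """Multiplicative diode response perturbations.

    Each curve maps a delivery condition to a relative sensitivity
    (dimensionless, 1.0 = no perturbation):

    low_mu_curve : segment MU -> sensitivity (per-segment nonlinearity)
    dpp_curve : source-to-detector distance in mm -> sensitivity,
        1.0 at the 896 mm calibration distance
    rep_rate_curve : MU/min -> sensitivity, 1.0 at 400 MU/min
    oof_overresponse : factor applied to the dose a diode receives while
        collimated (hardware-version dependent; 1.0 for the redesigned
        low-Z version, up to ~1.17 for the original)
    noise_sd : relative SD of optional multiplicative Gaussian noise
    """

    low_mu_curve: PchipInterpolator | None = None
    dpp_curve: PchipInterpolator | None = None
    rep_rate_curve: PchipInterpolator | None = None
    oof_overresponse: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    @classmethod
    def identity(cls, seed: int = 0) -> "ResponseModel":
        return cls(seed=seed)

    @classmethod
    def from_packaged(cls, hardware_version: str = "v2", energy: str = "6X",
                      acquisition: str = "modified", diode: str = "entrance",
                      noise_sd: float = 0.0, seed: int = 0) -> "ResponseModel":
        """Build the packaged anchor-curve model.

        ``hardware_version`` sets the out-of-field overresponse: the
        original design ("v1") overresponds by up to 17% relative to the
        redesigned one ("v2", factor 1.0).  ``acquisition`` selects the
        default or extended-integration low-MU curve.
        """
        low = load_anchor_table("low_mu")
        dpp = load_anchor_table("dpp_sdd")
        rep = load_anchor_table("rep_rate")
        oof = {"v1": 1.17, "v2": 1.0}[hardware_version]
        dpp_col = {"6X": "ratio_6x", "10XFFF": "ratio_10xfff"}[energy]
        return cls(
            low_mu_curve=_pchip(low["mu"], low[f"{diode}_{acquisition}"]),
            dpp_curve=_pchip(dpp["sdd_mm"], dpp[dpp_col]),
            rep_rate_curve=_pchip(rep["mu_per_min"], rep["ratio"]),
            oof_overresponse=oof, noise_sd=noise_sd, seed=seed,
        )

    # curve evaluation with clamp-to-range (flat extrapolation)
    def _eval(self, curve: PchipInterpolator | None, x) -> np.ndarray:
        if curve is None:
            return np.ones_like(np.asarray(x, dtype=float))
        xs = curve.x
        return np.asarray(curve(np.clip(x, xs[0], xs[-1])), dtype=float)

    def low_mu(self, segment_mu) -> np.ndarray:
        return self._eval(self.low_mu_curve, segment_mu)

    def dpp(self, sdd_mm) -> np.ndarray:
        return self._eval(self.dpp_curve, sdd_mm)

    def rep_rate(self, mu_per_min) -> np.ndarray:
        return self._eval(self.rep_rate_curve, mu_per_min)


@dataclass
class ToyDoseParams:
    """Toy dose engine parameters.

    ``attenuation_coeff`` (per mm of water) defaults to the value that
    puts the exit diode-shell dose at about one quarter of the entrance
    one for the plugged phantom (208 mm of density-1.15 material between
    the shells plus inverse square).  ``scatter_floor`` is the flat
    fraction of open-field dose that reaches collimated rays.
    """

    mu_to_gy: float = 0.01
    attenuation_coeff: float = 0.00405
    scatter_floor: float = 0.03
    sad: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.mu_to_gy, self.attenuation_coeff, self.sad) <= 0:
            raise ValueError("toy dose parameters must be positive")
        if not 0 <= self.scatter_floor < 1:
            raise ValueError("scatter_floor must be in [0, 1)")


# ---------------------------------------------------------------------------
# Plan generation
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDARIES = np.arange(-100.0, 101.0, 10.0)  # 20 leaf pairs, 10 mm width


def _closed_leaves(n_leaves: int, park_x: float = -200.0) -> np.ndarray:
    return np.vstack([np.full(n_leaves, park_x), np.full(n_leaves, park_x)])


def _open_rect(boundaries: np.ndarray, x_lo: float, x_hi: float,
               y_lo: float, y_hi: float, park_x: float = -200.0) -> np.ndarray:
    n = len(boundaries) - 1
    leaves = _closed_leaves(n, park_x)
    centers = 0.5 * (boundaries[:-1] + boundaries[1:])
    sel = (centers > y_lo) & (centers < y_hi)
    leaves[0, sel] = x_lo
    leaves[1, sel] = x_hi
    return leaves


def generate_plan(kind: str = "static", field_size: tuple[float, float] = (100.0, 100.0),
                  n_control_points: int = 2, total_mu: float = 100.0, seed: int = 0,
                  energy: str = "6X", aperture_width: float = 10.0,
                  point_offset: float = 10.0, arc_span: float = 360.0,
                  leaf_jitter: float = 0.0) -> TreatmentPlan:
    """Deterministic plan generator.

    kind
        ``static``: one rectangular field, 2 control points.
        ``sliding_window``: a leaf gap sweeping across the field.
        ``arc``: rotational delivery (``arc_span`` degrees over
        ``n_control_points`` control points), optional per-control-point
        random leaf jitter for modulation.
        ``oof_test``: narrow aperture (``aperture_width`` mm) positioned
        so the isocenter sits ``point_offset`` mm outside the field edge,
        mirroring out-of-field sensitivity test geometries.
    """
    rng = np.random.default_rng(seed)
    fx, fy = field_size
    bounds = _DEFAULT_BOUNDARIES
    jaws_open = (-fx / 2, fx / 2, -fy / 2, fy / 2)

    def cp(mu, gantry, leaves, jaws):
        return ControlPoint(mu, gantry, leaves, jaws, bounds.copy())

    if kind == "static":
        leaves = _open_rect(bounds, -fx / 2, fx / 2, -fy / 2, fy / 2)
        cps = [cp(0.0, 0.0, leaves, jaws_open), cp(total_mu, 0.0, leaves.copy(), jaws_open)]
    elif kind == "sliding_window":
        n = max(n_control_points, 2)
        gap = max(aperture_width, 5.0)
        cps = []
        for i in range(n):
            f = i / (n - 1)
            x_lo = -fx / 2 + f * (fx - gap)
            leaves = _open_rect(bounds, x_lo, x_lo + gap, -fy / 2, fy / 2)
            cps.append(cp(f * total_mu, 0.0, leaves, jaws_open))
    elif kind == "arc":
        n = max(n_control_points, 2)
        cps = []
        for i in range(n):
            f = i / (n - 1)
            leaves = _open_rect(bounds, -fx / 2, fx / 2, -fy / 2, fy / 2)
            if leaf_jitter > 0:
                sel = leaves[1] > leaves[0]
                leaves[0, sel] += rng.uniform(0, leaf_jitter, sel.sum())
                leaves[1, sel] -= rng.uniform(0, leaf_jitter, sel.sum())
            cps.append(cp(f * total_mu, f * arc_span, leaves, jaws_open))
    elif kind == "oof_test":
        # aperture entirely to one side: far edge at -point_offset, so the
        # isocenter is point_offset mm outside the field
        x_hi = -point_offset
        x_lo = x_hi - aperture_width
        leaves = _open_rect(bounds, x_lo, x_hi, -fy / 2, fy / 2)
        # X jaws stay clear of the measurement point so it sits under the
        # closed leaves, as in the out-of-field sensitivity geometry
        jaws = (x_lo - 5.0, point_offset / 2, -fy / 2, fy / 2)
        cps = [cp(0.0, 0.0, leaves, jaws), cp(total_mu, 0.0, leaves.copy(), jaws)]
    else:
        raise ValueError(f"unknown plan kind: {kind!r}")

    beam = Beam(name=f"{kind}-1", energy=energy, control_points=cps)
    return TreatmentPlan(name=f"synthetic-{kind}-{seed}", beams=[beam])


# ---------------------------------------------------------------------------
# Toy dose engine
# ---------------------------------------------------------------------------

def _ray_classify_and_attenuate(points: np.ndarray, geometry: BeamGeometry,
                                aperture, phantom: DetectorGeometry,
                                params: ToyDoseParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per point: (exposure state, inverse-square factor, attenuation factor)."""
    from .reconstruction import project_to_bev

    s = geometry.source_position
    rel = points - s
    dist = np.linalg.norm(rel, axis=1)
    invsq = (params.sad / dist) ** 2
    bev = project_to_bev(points, geometry)
    state = _classify(aperture, bev[:, 0], bev[:, 1])

    # water-equivalent depth: path from outer-cylinder entry to the point
    r_out = phantom.phantom_outer_diameter / 2
    w_dir = rel / dist[:, None]
    a = w_dir[:, 0] ** 2 + w_dir[:, 2] ** 2
    b = 2.0 * (s[0] * w_dir[:, 0] + s[2] * w_dir[:, 2])
    c = s[0] ** 2 + s[2] ** 2 - r_out**2
    disc = b**2 - 4 * a * c
    inside = points[:, 0] ** 2 + points[:, 2] ** 2 <= r_out**2
    depth = np.zeros(len(points))
    ok = inside & (disc > 0) & (a > 0)
    t1 = np.where(ok, (-b - np.sqrt(np.maximum(disc, 0.0))) / np.where(a > 0, 2 * a, 1.0), 0.0)
    depth[ok] = np.maximum(dist[ok] - t1[ok], 0.0)
    atten = np.where(inside,
                     np.exp(-params.attenuation_coeff * phantom.relative_density * depth),
                     0.0)
    return state, invsq, atten


def toy_dose_at_points(points: np.ndarray, subbeam: SubBeam, beam: Beam,
                       phantom: DetectorGeometry, params: ToyDoseParams,
                       model: BeamModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Toy subbeam dose at arbitrary phantom points.

    Returns ``(dose, collimated)``: per point, the deposited dose in Gy
    and whether the point's ray was under collimation at the subbeam
    midpoint aperture.
    """
    ap = aperture_at(beam, subbeam.mu_mid)
    geometry = BeamGeometry(gantry_angle=subbeam.gantry_mid, sad=params.sad)
    state, invsq, atten = _ray_classify_and_attenuate(
        np.atleast_2d(points), geometry, ap, phantom, params)
    trans = np.array([0.0, model.mlc_transmission, model.jaw_transmission])
    open_ray = state == int(ExposureState.OPEN)
    factor = np.where(open_ray, 1.0, params.scatter_floor + trans[state])
    dose = subbeam.mu * params.mu_to_gy * invsq * atten * factor
    return dose, ~open_ray


def toy_subbeam_dose(subbeam: SubBeam, beam: Beam, phantom: DetectorGeometry,
                     grid: DoseGrid, params: ToyDoseParams,
                     model: BeamModelParams) -> DoseGrid:
    """Toy 3D dose for one subbeam on the lattice of ``grid``."""
    pts = grid.voxel_centers()
    dose, _ = toy_dose_at_points(pts, subbeam, beam, phantom, params, model)
    out = grid.copy()
    out.values = dose.reshape(grid.shape)
    return out


def biplanar_positions(spacing: float = 10.0, half_extent: float = 80.0,
                       y_half_extent: float = 90.0) -> np.ndarray:
    """Detector positions of a biplanar dosimeter stand-in.

    Two orthogonal planes of points intersecting along the cylinder (y)
    axis, the layout of the biplanar diode arrays used as independent
    references in commissioning comparisons.  Unlike the surface diode
    shell, these points sample the interior of the reconstruction volume
    where the out-of-field correction is not tapered away.
    """
    t = np.arange(-half_extent, half_extent + spacing / 2, spacing)
    y = np.arange(-y_half_extent, y_half_extent + spacing / 2, spacing)
    T, Yg = np.meshgrid(t, y, indexing="ij")
    plane_xz0 = np.stack([T.ravel(), Yg.ravel(), np.zeros(T.size)], axis=1)
    plane_x0z = np.stack([np.zeros(T.size), Yg.ravel(), T.ravel()], axis=1)
    return np.concatenate([plane_xz0, plane_x0z], axis=0)


def diode_positions(geometry: DetectorGeometry, n: int | None = None) -> np.ndarray:
    """Deterministic helical diode layout on the detector cylinder.

    Points wind around the cylinder (axis along y) from y = -100 mm to
    +100 mm, approximating a helical-grid array.
    """
    if n is None:
        n = geometry.n_detectors
    i = np.arange(n)
    y = -100.0 + 200.0 * (i + 0.5) / n
    theta = 2 * np.pi * (i * 21 / n) % (2 * np.pi)
    r = geometry.array_radius
    return np.stack([r * np.sin(theta), y, r * np.cos(theta)], axis=1)


# ---------------------------------------------------------------------------
# Virtual diode readings
# ---------------------------------------------------------------------------

def virtual_diode_readings(true_dose: np.ndarray, segment_mu: np.ndarray,
                           rep_rate: float, sdd_mm: np.ndarray,
                           collimated: np.ndarray,
                           response: ResponseModel) -> np.ndarray:
    """Simulated diode readings from true per-segment dose.

    Parameters
    ----------
    true_dose : (n_segments, n_diodes)
        True dose each diode receives in each segment.
    segment_mu : (n_segments,)
        MU per segment; drives the per-segment low-MU nonlinearity.
    rep_rate : float
        Delivery repetition rate in MU/min.
    sdd_mm : (n_diodes,)
        Source-to-detector distance per diode, mm.
    collimated : (n_segments, n_diodes) bool
        True where the diode was out of field for that segment; only that
        dose component receives the out-of-field overresponse factor.

    Returns per-diode readings (summed over segments).  With all curves
    absent and no noise, readings equal the summed true dose exactly.
    """
    true_dose = np.atleast_2d(np.asarray(true_dose, dtype=float))
    collimated = np.atleast_2d(np.asarray(collimated, dtype=bool))
    segment_mu = np.atleast_1d(np.asarray(segment_mu, dtype=float))
    factors = (response.low_mu(segment_mu)[:, None]
               * response.dpp(sdd_mm)[None, :]
               * response.rep_rate(rep_rate))
    oof = np.where(collimated, response.oof_overresponse, 1.0)
    readings = (true_dose * factors * oof).sum(axis=0)
    if response.noise_sd > 0:
        rng = np.random.default_rng(response.seed)
        readings = readings * (1.0 + response.noise_sd * rng.standard_normal(readings.shape))
    return readings


# ---------------------------------------------------------------------------
# Sensitivity-ratio analyses
# ---------------------------------------------------------------------------

def sensitivity_ratio_analysis(conditions: np.ndarray, device_readings: np.ndarray,
                               reference_readings: np.ndarray,
                               normalize_at: float) -> pd.DataFrame:
    """Normalized device/reference sensitivity ratios versus a condition.

    Divides device by reference readings condition-by-condition and
    normalizes the ratio series to 1.0 at ``normalize_at`` (for example
    400 MU/min for repetition rate, 896 mm for source-to-detector
    distance, or the open-field condition for out-of-field scans).  The
    normalization condition must be present in ``conditions``.
    """
    conditions = np.asarray(conditions, dtype=float)
    device = np.asarray(device_readings, dtype=float)
    reference = np.asarray(reference_readings, dtype=float)
    if not (conditions.shape == device.shape == reference.shape):
        raise ValueError("conditions, device and reference must be matched 1D series")
    ratio = device / reference
    at = np.isclose(conditions, normalize_at)
    if not at.any():
        raise ValueError(f"normalization condition {normalize_at} not in the series")
    norm = ratio[at].mean()
    return pd.DataFrame({"condition": conditions, "ratio": ratio / norm})


def ratio_of_ratios(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Condition-wise ratio of two normalized sensitivity-ratio tables.

    Used to compare two hardware versions measured against the same
    reference: the result is version A's overresponse relative to B.
    """
    merged = table_a.merge(table_b, on="condition", suffixes=("_a", "_b"))
    merged["ratio"] = merged["ratio_a"] / merged["ratio_b"]
    return merged[["condition", "ratio"]]
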