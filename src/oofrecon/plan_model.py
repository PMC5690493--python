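"""Treatment-plan data model: beams, control points, subbeams, machine geometry.

A plan is an ordered sequence of control points per beam.  Each control
point snapshots the machine state (MLC leaf tips, jaw edges, gantry angle)
at a cumulative meterset value (MU).  Delivery between two control points
is modeled as linear motion in meterset, which is the convention used by
dynamic-delivery (VMAT / sliding-window) plan formats.

Positions are expressed in mm projected to the isocenter plane, IEC-style
beam coordinates: BEV x is the leaf-travel direction, BEV y the
leaf-boundary (cross-leaf) direction.  Leaves are rectangular faces with
no tongue-and-groove or rounded-tip modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PlanParseError",
    "PlanValidationError",
    "ControlPoint",
    "Aperture",
    "Beam",
    "TreatmentPlan",
    "SubBeam",
    "BeamModelParams",
    "DetectorGeometry",
    "load_plan",
    "save_plan",
    "read_dicom_plan",
    "segment_subbeams",
    "aperture_at",
]


class PlanParseError(ValueError):
    """A plan file could not be parsed in the declared dialect."""


class PlanValidationError(ValueError):
    """A plan violates a structural invariant (meterset order, leaf gaps, jaws)."""


@dataclass
class ControlPoint:
    """Machine snapshot at one cumulative meterset value.

    Parameters
    ----------
    cumulative_meterset : float
        Absolute MU delivered when this control point is reached;
        non-decreasing along a beam.
    gantry_angle : float
        Gantry angle in degrees (0 = beam pointing straight down).
    leaf_positions : (2, n_leaves) array
        Leaf-tip x positions in mm at isocenter; row 0 is bank A (lower x),
        row 1 is bank B.  ``A <= B`` per pair; equality means a closed pair.
    jaw_positions : (x1, x2, y1, y2)
        Jaw edges in mm at isocenter, ``x1 <= x2`` and ``y1 <= y2``.
    leaf_boundaries : (n_leaves + 1,) array
        Transverse (y) edges of the leaves, mm at isocenter, increasing.
    """

    cumulative_meterset: float
    gantry_angle: float
    leaf_positions: np.ndarray
    jaw_positions: tuple[float, float, float, float]
    leaf_boundaries: np.ndarray

    def __post_init__(self) -> None:
        self.leaf_positions = np.asarray(self.leaf_positions, dtype=float)
        self.leaf_boundaries = np.asarray(self.leaf_boundaries, dtype=float)
        self.jaw_positions = tuple(float(v) for v in self.jaw_positions)
        self.validate()

    @property
    def n_leaves(self) -> int:
        return self.leaf_positions.shape[1]

    def validate(self) -> None:
        if self.leaf_positions.ndim != 2 or self.leaf_positions.shape[0] != 2:
            raise PlanValidationError(
                f"leaf_positions must have shape (2, n_leaves), got {self.leaf_positions.shape}"
            )
        if self.leaf_boundaries.shape != (self.n_leaves + 1,):
            raise PlanValidationError(
                f"leaf_boundaries must have n_leaves+1={self.n_leaves + 1} entries, "
                f"got {self.leaf_boundaries.shape}"
            )
        if np.any(np.diff(self.leaf_boundaries) <= 0):
            raise PlanValidationError("leaf_boundaries must be strictly increasing")
        bad = self.leaf_positions[0] > self.leaf_positions[1]
        if np.any(bad):
            raise PlanValidationError(
                f"bank A leaf beyond bank B at leaf indices {np.nonzero(bad)[0].tolist()}"
            )
        x1, x2, y1, y2 = self.jaw_positions
        if x1 > x2 or y1 > y2:
            raise PlanValidationError(f"jaws do not form a rectangle: {self.jaw_positions}")


@dataclass
class Aperture:
    """Instantaneous collimation state (leaf tips + jaws) at some meterset."""

    gantry_angle: float
    leaf_positions: np.ndarray
    jaw_positions: tuple[float, float, float, float]
    leaf_boundaries: np.ndarray

    def open_area(self) -> float:
        """Open aperture area in mm^2 (leaf openings clipped to the jaws)."""
        x1, x2, y1, y2 = self.jaw_positions
        lo = np.clip(self.leaf_positions[0], x1, x2)
        hi = np.clip(self.leaf_positions[1], x1, x2)
        widths = np.maximum(hi - lo, 0.0)
        bounds = np.clip(self.leaf_boundaries, y1, y2)
        heights = np.maximum(np.diff(bounds), 0.0)
        return float(np.sum(widths * heights))


@dataclass
class Beam:
    """One treatment beam: an ordered, validated control-point sequence."""

    name: str
    energy: str
    control_points: list[ControlPoint]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.control_points:
            raise PlanValidationError(f"beam {self.name!r} has no control points")
        ms = self.metersets
        if np.any(np.diff(ms) < 0):
            raise PlanValidationError(
                f"beam {self.name!r}: cumulative meterset decreases at control point "
                f"{int(np.nonzero(np.diff(ms) < 0)[0][0]) + 1}"
            )
        n = self.control_points[0].n_leaves
        for i, cp in enumerate(self.control_points):
            if cp.n_leaves != n:
                raise PlanValidationError(
                    f"beam {self.name!r}: control point {i} has {cp.n_leaves} leaves, expected {n}"
                )

    @property
    def metersets(self) -> np.ndarray:
        return np.array([cp.cumulative_meterset for cp in self.control_points])

    @property
    def total_mu(self) -> float:
        ms = self.metersets
        return float(ms[-1] - ms[0])

    @property
    def n_leaves(self) -> int:
        return self.control_points[0].n_leaves


@dataclass
class TreatmentPlan:
    name: str
    beams: list[Beam] = field(default_factory=list)

    @property
    def total_mu(self) -> float:
        return float(sum(b.total_mu for b in self.beams))


@dataclass(frozen=True)
class SubBeam:
    """A time-resolved meterset slice of a beam, reconstructed independently.

    ``control_point_interval`` is the (i, i+1) index pair of the bracketing
    control points; a subbeam never spans more than one interval.
    """

    mu_start: float
    mu_end: float
    control_point_interval: tuple[int, int]
    gantry_start: float
    gantry_end: float

    def __post_init__(self) -> None:
        if not self.mu_start < self.mu_end:
            raise PlanValidationError(
                f"subbeam requires mu_start < mu_end, got [{self.mu_start}, {self.mu_end}]"
            )

    @property
    def mu(self) -> float:
        return self.mu_end - self.mu_start

    @property
    def mu_mid(self) -> float:
        return 0.5 * (self.mu_start + self.mu_end)

    @property
    def gantry_span(self) -> float:
        return self.gantry_end - self.gantry_start

    @property
    def gantry_mid(self) -> float:
        return 0.5 * (self.gantry_start + self.gantry_end)


@dataclass
class BeamModelParams:
    """Per-energy machine/beam-model scalars used by the correction.

    ``edf`` is the energy dependence factor: a small per-energy fraction
    (order 0.01-0.025, increasing with energy) that scales the out-of-field
    adjustment so a single user correction factor works across energies.
    """

    energy_label: str = "6X"
    edf: float = 0.02
    mlc_transmission: float = 0.02
    jaw_transmission: float = 0.002
    source_axis_distance: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mlc_transmission < 1.0:
            raise PlanValidationError(f"mlc_transmission out of (0,1): {self.mlc_transmission}")
        if not 0.0 <= self.jaw_transmission <= self.mlc_transmission:
            raise PlanValidationError(
                f"jaw_transmission must be in [0, mlc_transmission]: {self.jaw_transmission}"
            )
        if not 0.0 < self.edf < 0.1:
            raise PlanValidationError(f"edf out of (0, 0.1): {self.edf}")
        if self.source_axis_distance <= 0:
            raise PlanValidationError("source_axis_distance must be positive")


@dataclass
class DetectorGeometry:
    """Cylindrical diode array inside a doughnut-shaped phantom.

    Defaults describe a 1386-diode helical array on a 10.4 cm radius
    cylinder inside a 26.6 cm outer-diameter phantom with the central plug
    inserted, modelled as uniform relative density 1.15.
    """

    array_radius: float = 104.0
    n_detectors: int = 1386
    phantom_outer_diameter: float = 266.0
    plug_present: bool = True
    relative_density: float = 1.15

    def __post_init__(self) -> None:
        if self.array_radius >= self.phantom_outer_diameter / 2:
            raise PlanValidationError("array_radius must be inside the phantom")
        if self.n_detectors <= 0:
            raise PlanValidationError("n_detectors must be positive")


# ---------------------------------------------------------------------------
# Simple plan dialect (YAML)
# ---------------------------------------------------------------------------

def _cp_to_dict(cp: ControlPoint) -> dict:
    return {
        "cumulative_meterset": float(cp.cumulative_meterset),
        "gantry_angle": float(cp.gantry_angle),
        "leaf_positions": [[float(v) for v in bank] for bank in cp.leaf_positions],
        "jaw_positions": [float(v) for v in cp.jaw_positions],
        "leaf_boundaries": [float(v) for v in cp.leaf_boundaries],
    }


def _cp_from_dict(d: dict, where: str) -> ControlPoint:
    try:
        return ControlPoint(
            cumulative_meterset=d["cumulative_meterset"],
            gantry_angle=d["gantry_angle"],
            leaf_positions=np.array(d["leaf_positions"], dtype=float),
            jaw_positions=tuple(d["jaw_positions"]),
            leaf_boundaries=np.array(d["leaf_boundaries"], dtype=float),
        )
    except KeyError as exc:
        raise PlanParseError(f"{where}: missing key {exc}") from exc


def save_plan(plan: TreatmentPlan, path: str | Path) -> None:
    """Write a plan in the simple YAML dialect (lossless round trip)."""
    doc = {
        "plan": {
            "name": plan.name,
            "beams": [
                {
                    "name": b.name,
                    "energy": b.energy,
                    "control_points": [_cp_to_dict(cp) for cp in b.control_points],
                }
                for b in plan.beams
            ],
        }
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_plan(path: str | Path, dialect: str = "simple") -> TreatmentPlan:
    """Read a treatment plan.

    Parameters
    ----------
    path : path
        Plan file.
    dialect : {"simple", "dicom-rt-plan"}
        ``simple`` is the package's YAML dialect; ``dicom-rt-plan`` reads a
        subset of DICOM RT Plan (dynamic MLC/jaw sequences only).
    """
    if dialect == "simple":
        return _load_simple(Path(path))
    if dialect == "dicom-rt-plan":
        return read_dicom_plan(path)
    raise ValueError(f"unknown plan dialect: {dialect!r}")


def _load_simple(path: Path) -> TreatmentPlan:
    if not path.exists():
        raise PlanParseError(f"plan file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise PlanParseError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "plan" not in doc:
        raise PlanParseError(f"{path}: missing top-level 'plan' record")
    pd = doc["plan"]
    beams = []
    for bi, bd in enumerate(pd.get("beams", [])):
        where = f"{path}: beam[{bi}]"
        cps = [
            _cp_from_dict(cd, f"{where}.control_points[{ci}]")
            for ci, cd in enumerate(bd.get("control_points", []))
        ]
        beams.append(Beam(name=bd.get("name", f"beam{bi}"), energy=bd.get("energy", "6X"),
                          control_points=cps))
    return TreatmentPlan(name=pd.get("name", path.stem), beams=beams)


# ---------------------------------------------------------------------------
# DICOM RT Plan subset
# ---------------------------------------------------------------------------

def read_dicom_plan(path: str | Path) -> TreatmentPlan:
    """Read the dynamic MLC/jaw subset of a DICOM RT Plan.

    Supported: BeamSequence with ControlPointSequence, cumulative meterset
    weights scaled to absolute MU via the FractionGroupSequence beam
    metersets, MLCX leaf positions/boundaries and X/Y (or ASYMX/ASYMY)
    jaws.  Anything else is ignored with a logged notice.
    """
    import pydicom

    ds = pydicom.dcmread(str(path), force=True)
    if "BeamSequence" not in ds:
        raise PlanParseError(f"{path}: no BeamSequence")

    meterset_by_number: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                meterset_by_number[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    beams: list[Beam] = []
    for bd in ds.BeamSequence:
        boundaries = None
        for bld in getattr(bd, "BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType == "MLCX":
                boundaries = np.asarray(bld.LeafPositionBoundaries, dtype=float)
            elif bld.RTBeamLimitingDeviceType not in ("X", "Y", "ASYMX", "ASYMY"):
                logger.info(
                    "ignoring beam limiting device %s in beam %s",
                    bld.RTBeamLimitingDeviceType, bd.BeamName,
                )
        if boundaries is None:
            raise PlanParseError(f"beam {bd.BeamName}: no MLCX LeafPositionBoundaries")
        n_leaves = len(boundaries) - 1

        total = meterset_by_number.get(int(bd.BeamNumber), 1.0)
        final_w = float(getattr(bd, "FinalCumulativeMetersetWeight", 1.0)) or 1.0

        cps: list[ControlPoint] = []
        gantry = 0.0
        jaws = [-200.0, 200.0, -200.0, 200.0]
        leaves = np.zeros((2, n_leaves))
        for cp in bd.ControlPointSequence:
            if hasattr(cp, "GantryAngle"):
                gantry = float(cp.GantryAngle)
            for dev in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                kind = dev.RTBeamLimitingDeviceType
                vals = np.asarray(dev.LeafJawPositions, dtype=float)
                if kind == "MLCX":
                    leaves = vals.reshape(2, n_leaves)
                elif kind in ("X", "ASYMX"):
                    jaws[0], jaws[1] = vals
                elif kind in ("Y", "ASYMY"):
                    jaws[2], jaws[3] = vals
                else:
                    logger.info("ignoring device positions %s", kind)
            mu = float(cp.CumulativeMetersetWeight) / final_w * total
            cps.append(ControlPoint(
                cumulative_meterset=mu,
                gantry_angle=gantry,
                leaf_positions=leaves.copy(),
                jaw_positions=tuple(jaws),
                leaf_boundaries=boundaries.copy(),
            ))
        beams.append(Beam(
            name=str(getattr(bd, "BeamName", bd.BeamNumber)),
            energy=f"{getattr(bd, 'NominalBeamEnergy', 6):g}X",
            control_points=cps,
        ))
    return TreatmentPlan(name=str(getattr(ds, "RTPlanLabel", "plan")), beams=beams)


# ---------------------------------------------------------------------------
# Segmentation and aperture interpolation
# ---------------------------------------------------------------------------

def segment_subbeams(beam: Beam, max_mu_per_subbeam: float | None = None) -> list[SubBeam]:
    """Slice a beam into time-resolved subbeams.

    The default segmentation is one subbeam per control-point interval
    (the finest granularity the plan defines); intervals exceeding
    ``max_mu_per_subbeam`` are split into equal parts.  Zero-MU intervals
    (instantaneous aperture changes, as in step-and-shoot plans) produce
    no subbeam.  The returned subbeams tile the beam's meterset range.
    """
    if len(beam.control_points) < 2:
        raise PlanValidationError(f"beam {beam.name!r} needs >=2 control points to segment")
    if beam.total_mu == 0:
        logger.warning("beam %r delivers 0 MU; no subbeams", beam.name)
        return []
    out: list[SubBeam] = []
    cps = beam.control_points
    for i in range(len(cps) - 1):
        mu0, mu1 = cps[i].cumulative_meterset, cps[i + 1].cumulative_meterset
        dmu = mu1 - mu0
        if dmu <= 0:
            continue
        n_split = 1
        if max_mu_per_subbeam is not None and max_mu_per_subbeam > 0:
            n_split = int(np.ceil(dmu / max_mu_per_subbeam - 1e-12))
        edges = np.linspace(mu0, mu1, n_split + 1)
        g0, g1 = cps[i].gantry_angle, cps[i + 1].gantry_angle
        for a, b in zip(edges[:-1], edges[1:]):
            fa = (a - mu0) / dmu
            fb = (b - mu0) / dmu
            out.append(SubBeam(
                mu_start=float(a), mu_end=float(b),
                control_point_interval=(i, i + 1),
                gantry_start=g0 + fa * (g1 - g0),
                gantry_end=g0 + fb * (g1 - g0),
            ))
    return out


def aperture_at(beam: Beam, mu: float) -> Aperture:
    """Instantaneous aperture at cumulative meterset ``mu``.

    Leaf tips, jaws and gantry angle are interpolated linearly in
    cumulative meterset between the bracketing control points; at a
    control point exactly, its stored positions are returned verbatim.
    """
    ms = beam.metersets
    if mu < ms[0] - 1e-9 or mu > ms[-1] + 1e-9:
        raise ValueError(f"mu={mu} outside beam meterset range [{ms[0]}, {ms[-1]}]")
    mu = float(np.clip(mu, ms[0], ms[-1]))
    idx = int(np.searchsorted(ms, mu, side="left"))
    if idx < len(ms) and ms[idx] == mu:
        cp = beam.control_points[idx]
        return Aperture(cp.gantry_angle, cp.leaf_positions.copy(),
                        cp.jaw_positions, cp.leaf_boundaries.copy())
    c0, c1 = beam.control_points[idx - 1], beam.control_points[idx]
    f = (mu - c0.cumulative_meterset) / (c1.cumulative_meterset - c0.cumulative_meterset)
    leaves = (1 - f) * c0.leaf_positions + f * c1.leaf_positions
    jaws = tuple((1 - f) * np.asarray(c0.jaw_positions) + f * np.asarray(c1.jaw_positions))
    gantry = (1 - f) * c0.gantry_angle + f * c1.gantry_angle
    return Aperture(gantry, leaves, jaws, c0.leaf_boundaries.copy())
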