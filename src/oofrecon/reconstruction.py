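"""Apply the composite correction mask to 3D subbeam dose and accumulate.

The 2D BEV mask is constant with depth: every voxel is projected along
the divergent ray from the source onto the isocenter plane and picks up
the mask value there (bilinear interpolation).  Near the curved entry
and exit surfaces of the detector-array cylinder the applied correction
is tapered back to unity with a linear ramp over ``taper_distance`` of
ray path, so the correction vanishes exactly at the surfaces:

    corrected = dose * (1 + w * (mask - 1)),   w in [0, 1].

Coordinates: fixed phantom frame with x to the left, y along the
cylinder/couch axis, z up; the source sits at distance SAD from the
isocenter and rotates about y (gantry angle 0 = beam pointing down).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .fluence_mask import CorrectionMask

logger = logging.getLogger(__name__)

__all__ = [
    "DoseGrid",
    "BeamGeometry",
    "TaperSpec",
    "project_to_bev",
    "taper_weight",
    "apply_mask",
    "accumulate",
]


@dataclass
class DoseGrid:
    """Scalar dose (Gy) on a regular 3D lattice in phantom coordinates.

    ``values`` is indexed ``[ix, iy, iz]``; axis coordinates are
    ``origin + index * spacing``.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be length-3")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive: {self.spacing}")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.values.shape[axis])

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers as an (N, 3) array in C order of the value array."""
        xs, ys, zs = (self.axis_coords(i) for i in range(3))
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def same_lattice(self, other: "DoseGrid") -> bool:
        return (self.values.shape == other.values.shape
                and np.allclose(self.origin, other.origin)
                and np.allclose(self.spacing, other.spacing))

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.origin.copy(), self.spacing.copy(), self.values.copy())

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            tuple(self.axis_coords(i) for i in range(3)), self.values,
            bounds_error=False, fill_value=np.nan)

    # -- plain-text container ------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Self-describing CSV container: header lines, then z-slices flattened."""
        with open(path, "w") as fh:
            fh.write("# dose_grid_v1\n")
            fh.write("# origin_mm," + ",".join(f"{v:.9g}" for v in self.origin) + "\n")
            fh.write("# spacing_mm," + ",".join(f"{v:.9g}" for v in self.spacing) + "\n")
            fh.write("# shape," + ",".join(str(s) for s in self.values.shape) + "\n")
            np.savetxt(fh, self.values.reshape(self.values.shape[0], -1),
                       delimiter=",", fmt="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseGrid":
        header: dict[str, list[str]] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            parts = line[1:].strip().split(",")
            header[parts[0]] = parts[1:]
        shape = tuple(int(s) for s in header["shape"])
        values = np.loadtxt(lines[body_start:], delimiter=",").reshape(shape)
        return cls(np.array([float(v) for v in header["origin_mm"]]),
                   np.array([float(v) for v in header["spacing_mm"]]), values)

    # -- DICOM RT Dose subset ------------------------------------------------
    def to_dicom(self, path: str | Path) -> None:
        """Write a minimal DICOM RT Dose (GRID, 32-bit, mm units)."""
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import UID, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = UID("1.2.840.10008.5.1.4.1.1.481.2")
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTDOSE"
        ds.DoseUnits = "GY"
        ds.DoseType = "PHYSICAL"
        ds.DoseSummationType = "PLAN"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 32
        ds.BitsStored = 32
        ds.HighBit = 31
        ds.PixelRepresentation = 0
        nx, ny, nz = self.values.shape
        ds.Columns = nx
        ds.Rows = ny
        ds.NumberOfFrames = nz
        ds.ImagePositionPatient = [float(v) for v in self.origin]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [float(self.spacing[1]), float(self.spacing[0])]
        ds.GridFrameOffsetVector = [float(self.spacing[2] * k) for k in range(nz)]
        scale = float(self.values.max()) / (2**32 - 1) if self.values.max() > 0 else 1.0
        ds.DoseGridScaling = scale
        pixels = np.round(self.values / scale).astype(np.uint32)
        # DICOM frame layout: [frame(z), row(y), col(x)]
        ds.PixelData = np.ascontiguousarray(pixels.transpose(2, 1, 0)).tobytes()
        ds.save_as(str(path), enforce_file_format=True)

    @classmethod
    def from_dicom(cls, path: str | Path) -> "DoseGrid":
        import pydicom

        ds = pydicom.dcmread(str(path), force=True)
        scale = float(getattr(ds, "DoseGridScaling", 1.0))
        raw = ds.pixel_array  # (frames, rows, cols)
        values = (raw.astype(float) * scale).transpose(2, 1, 0)
        origin = np.array([float(v) for v in ds.ImagePositionPatient])
        offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
        dz = float(offsets[1] - offsets[0]) if offsets.size > 1 else 1.0
        spacing = np.array([float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz])
        return cls(origin, spacing, values)


@dataclass(frozen=True)
class BeamGeometry:
    """Source position for one (sub)beam: gantry angle and SAD."""

    gantry_angle: float = 0.0
    sad: float = 1000.0

    @property
    def source_position(self) -> np.ndarray:
        g = np.deg2rad(self.gantry_angle)
        return self.sad * np.array([np.sin(g), 0.0, np.cos(g)])

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(beam axis unit vector, BEV x unit, BEV y unit) in the fixed frame."""
        g = np.deg2rad(self.gantry_angle)
        u = -np.array([np.sin(g), 0.0, np.cos(g)])
        ex = np.array([np.cos(g), 0.0, -np.sin(g)])
        ey = np.array([0.0, 1.0, 0.0])
        return u, ex, ey


@dataclass(frozen=True)
class TaperSpec:
    """Linear surface taper of the applied correction.

    ``cylinder_radius`` is the detector-array cylinder (axis along y
    through the isocenter); ``taper_distance`` the ray path length over
    which the correction ramps from nothing at the entry/exit surface to
    full strength inside.  ``taper_distance = 0`` disables the ramp.
    """

    taper_distance: float = 10.0
    cylinder_radius: float = 104.0

    def __post_init__(self) -> None:
        if self.taper_distance < 0:
            raise ValueError("taper_distance must be >= 0")


def project_to_bev(points: np.ndarray, geometry: BeamGeometry) -> np.ndarray:
    """Central projection of phantom points onto the isocenter plane.

    Follows the divergent ray from the source through each point and
    returns its BEV (x, y) in mm.  Points at (or upstream of) the source
    plane raise a geometry error.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u, ex, ey = geometry.axes
    rel = pts - geometry.source_position
    d = rel @ u
    if np.any(d <= 1e-9):
        raise ValueError("point at or upstream of the source; cannot project to BEV")
    scale = geometry.sad / d
    bev = np.stack([(rel @ ex) * scale, (rel @ ey) * scale], axis=1)
    return bev if np.asarray(points).ndim == 2 else bev[0]


def taper_weight(points: np.ndarray, geometry: BeamGeometry, taper: TaperSpec) -> np.ndarray:
    """Correction weight in [0, 1] per point.

    0 on/outside the detector cylinder surface, ramping linearly to 1 at
    ``taper_distance`` of ray path inside; 1 throughout the interior when
    ``taper_distance`` is 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    s = geometry.source_position
    rel = pts - s
    dist = np.linalg.norm(rel, axis=1)
    w_dir = rel / dist[:, None]
    r = taper.cylinder_radius
    # ray-cylinder intersection in the x-z plane (axis along y)
    a = w_dir[:, 0] ** 2 + w_dir[:, 2] ** 2
    b = 2.0 * (s[0] * w_dir[:, 0] + s[2] * w_dir[:, 2])
    c = s[0] ** 2 + s[2] ** 2 - r**2
    disc = b**2 - 4 * a * c
    inside = pts[:, 0] ** 2 + pts[:, 2] ** 2 < r**2
    out = np.zeros(len(pts))
    hit = inside & (disc > 0) & (a > 0)
    if np.any(hit):
        sq = np.sqrt(disc[hit])
        t1 = (-b[hit] - sq) / (2 * a[hit])
        t2 = (-b[hit] + sq) / (2 * a[hit])
        depth = np.minimum(dist[hit] - t1, t2 - dist[hit])
        if taper.taper_distance == 0:
            out[hit] = 1.0
        else:
            out[hit] = np.clip(depth / taper.taper_distance, 0.0, 1.0)
    return out if np.asarray(points).ndim == 2 else out[0]


def apply_mask(subbeam_dose: DoseGrid, mask: CorrectionMask, geometry: BeamGeometry,
               taper: TaperSpec | None = None) -> DoseGrid:
    """Correct one subbeam dose grid with its composite BEV mask.

    Per voxel: ``dose * (1 + w * (m - 1))`` with ``m`` the mask sampled
    bilinearly at the voxel's divergent BEV projection and ``w`` the
    surface-taper weight.  Voxels projecting outside the mask footprint
    are left unchanged (their count is logged).
    """
    if taper is None:
        taper = TaperSpec()
    pts = subbeam_dose.voxel_centers()
    bev = project_to_bev(pts, geometry)
    interp = RegularGridInterpolator((mask.grid.y, mask.grid.x), mask.values,
                                     bounds_error=False, fill_value=np.nan)
    m = interp(bev[:, ::-1])  # (y, x) order
    outside = np.isnan(m)
    n_out = int(outside.sum())
    if n_out:
        logger.info("apply_mask: %d voxels project outside the mask footprint; unchanged", n_out)
        m[outside] = 1.0
    w = taper_weight(pts, geometry, taper)
    factor = 1.0 + w * (m - 1.0)
    out = subbeam_dose.copy()
    out.values = (out.values.ravel() * factor).reshape(subbeam_dose.shape)
    return out


def accumulate(corrected: list[DoseGrid]) -> DoseGrid:
    """Voxelwise sum of subbeam dose grids on an identical lattice."""
    if not corrected:
        raise ValueError("no dose grids to accumulate")
    first = corrected[0]
    total = first.copy()
    for g in corrected[1:]:
        if not first.same_lattice(g):
            raise ValueError("dose grids are on different lattices")
        total.values = total.values + g.values
    return total
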