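"""Beam/imager geometry and CT ray tracing.

Coordinate conventions
----------------------
CT volumes live in a fixed patient coordinate system measured in mm, with
axes ``(x, y, z)``: ``x`` lateral, ``y`` longitudinal (gantry rotation
axis), ``z`` vertical.  The voxel array of a :class:`CtVolume` is indexed
``hu[ix, iy, iz]`` and ``origin`` is the centre of voxel ``(0, 0, 0)``.

The treatment beam rotates about the ``y`` axis.  At gantry angle ``g``
(degrees) the source sits at ``isocenter + sad * (sin g, 0, cos g)`` — at
gantry 0 the source is above the isocenter and the beam travels along
``-z`` toward the imager.  The imager column direction (cross-plane, the
``x`` coordinate of the isocenter plane) and the row direction (in-plane,
``y``) are rotated about the beam axis by the collimator angle.

All lengths exposed by this module are cm except where a parameter is
explicitly documented as mm (CT spacing/origin follow DICOM and stay mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._siddon import trace_rays

__all__ = [
    "BeamGeometry",
    "CtVolume",
    "RadiologicalDepthMaps",
    "DEFAULT_HU_CALIBRATION",
    "project_pixel_to_isocenter",
    "hu_to_red",
    "trace_radiological_depths",
]

#: Placeholder piecewise-linear HU -> relative electron density table
#: (air, water, dense bone).  Clinical use requires the scanner's own curve.
DEFAULT_HU_CALIBRATION = ((-1000.0, 0.0), (0.0, 1.0), (1000.0, 1.6))


@dataclass(frozen=True)
class BeamGeometry:
    """Source/imager geometry of a single beam.

    Defaults model an a-Si portal imager run at 384x512 resolution at a
    source-to-detector distance of 150 cm, whose imaging area projects to
    20.1 x 26.8 cm^2 in the isocenter plane.
    """

    sad: float = 100.0
    sdd: float = 150.0
    gantry_angle: float = 0.0
    collimator_angle: float = 0.0
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, CT coords
    n_rows: int = 384
    n_cols: int = 512
    iso_plane_height: float = 20.1  # cm, in-plane (rows)
    iso_plane_width: float = 26.8  # cm, cross-plane (columns)

    def __post_init__(self) -> None:
        if not (self.sdd > self.sad > 0):
            raise ValueError(f"require sdd > sad > 0, got sad={self.sad}, sdd={self.sdd}")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("imager needs at least 2x2 pixels")
        if self.iso_plane_height <= 0 or self.iso_plane_width <= 0:
            raise ValueError("isocenter-plane extents must be positive")

    # Pixel pitch projected at the isocenter plane, cm.
    @property
    def pitch_y(self) -> float:
        return self.iso_plane_height / self.n_rows

    @property
    def pitch_x(self) -> float:
        return self.iso_plane_width / self.n_cols

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Isocenter-plane coordinates of all pixel centres.

        Returns ``(y, x)`` arrays of shape ``(n_rows, n_cols)`` in cm, with
        the centre of the pixel grid on the central axis.
        """
        y = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.pitch_y
        x = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.pitch_x
        return np.meshgrid(y, x, indexing="ij")

    def beam_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unit vectors ``(x_hat, y_hat, b)`` in CT coordinates.

        ``x_hat`` cross-plane (columns), ``y_hat`` in-plane (rows), ``b``
        the beam direction (source toward imager).
        """
        g = np.deg2rad(self.gantry_angle)
        c = np.deg2rad(self.collimator_angle)
        c0 = np.array([np.cos(g), 0.0, -np.sin(g)])
        r0 = np.array([0.0, 1.0, 0.0])
        b = -np.array([np.sin(g), 0.0, np.cos(g)])
        x_hat = np.cos(c) * c0 + np.sin(c) * r0
        y_hat = -np.sin(c) * c0 + np.cos(c) * r0
        return x_hat, y_hat, b

    def source_position(self) -> np.ndarray:
        """Source position in CT coordinates, mm."""
        g = np.deg2rad(self.gantry_angle)
        u = np.array([np.sin(g), 0.0, np.cos(g)])
        return np.asarray(self.isocenter, float) + 10.0 * self.sad * u


def project_pixel_to_isocenter(row: int, col: int, geom: BeamGeometry) -> tuple[float, float]:
    """Isocenter-plane coordinates ``(y, x)`` in cm of a pixel's ray line.

    Pixel-centre convention; the centre of the pixel grid maps to (0, 0).
    """
    if not (0 <= row < geom.n_rows and 0 <= col < geom.n_cols):
        raise IndexError(f"pixel ({row}, {col}) outside {geom.n_rows}x{geom.n_cols} imager")
    y = (row - (geom.n_rows - 1) / 2.0) * geom.pitch_y
    x = (col - (geom.n_cols - 1) / 2.0) * geom.pitch_x
    return (y, x)


def hu_to_red(hu, calibration: Sequence[tuple[float, float]] = DEFAULT_HU_CALIBRATION):
    """Convert Hounsfield units to relative electron density.

    Piecewise-linear interpolation through the calibration nodes, clamped
    to the end values outside the tabulated HU range.
    """
    cal = np.asarray(calibration, float)
    if cal.ndim != 2 or cal.shape[0] == 0 or cal.shape[1] != 2:
        raise ValueError("calibration must be a non-empty sequence of (HU, RED) pairs")
    h, r = cal[:, 0], cal[:, 1]
    if not np.all(np.diff(h) > 0):
        raise ValueError("calibration HU values must be strictly increasing")
    if np.any(r < 0):
        raise ValueError("relative electron densities must be >= 0")
    return np.interp(hu, h, r)


@dataclass
class CtVolume:
    """A CT voxel grid with its HU -> electron-density calibration.

    ``hu`` is indexed ``[ix, iy, iz]``; ``spacing`` and ``origin`` are mm,
    ``origin`` being the centre of voxel ``(0, 0, 0)``.
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    calibration: Sequence[tuple[float, float]] = DEFAULT_HU_CALIBRATION

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, float)
        if self.hu.ndim != 3 or min(self.hu.shape) < 1:
            raise ValueError("hu must be a non-empty 3D array")
        if min(self.spacing) <= 0:
            raise ValueError("voxel spacing must be positive in all axes")
        hu_to_red(0.0, self.calibration)  # validates the table

    def red(self) -> np.ndarray:
        """Relative electron density volume."""
        return hu_to_red(self.hu, self.calibration)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer corners of the voxel grid, mm."""
        o = np.asarray(self.origin, float)
        sp = np.asarray(self.spacing, float)
        lo = o - sp / 2.0
        hi = lo + sp * np.asarray(self.hu.shape)
        return lo, hi


@dataclass
class RadiologicalDepthMaps:
    """Per-pixel water-equivalent depths split at the isocenter plane.

    ``t_up`` source -> isocenter plane, ``t_down`` isocenter plane ->
    pixel, ``w = t_up + t_down`` the total radiological thickness along
    the ray, and ``d = (t_down - t_up) / 2`` the (signed) midplane offset:
    the radiological depth of the isocenter plane along the ray equals
    ``w/2 - d``.  Positive ``d`` means the material sits displaced toward
    the detector.  All maps are cm, shaped ``(n_rows, n_cols)``.
    """

    t_up: np.ndarray
    t_down: np.ndarray
    geom: BeamGeometry | None = None
    w: np.ndarray = field(init=False)
    d: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.t_up = np.asarray(self.t_up, float)
        self.t_down = np.asarray(self.t_down, float)
        if self.t_up.shape != self.t_down.shape:
            raise ValueError("t_up and t_down must share a shape")
        if np.any(self.t_up < 0) or np.any(self.t_down < 0):
            raise ValueError("radiological depths must be >= 0")
        self.w = self.t_up + self.t_down
        self.d = (self.t_down - self.t_up) / 2.0


def trace_radiological_depths(ct: CtVolume, geom: BeamGeometry) -> RadiologicalDepthMaps:
    """Radiological depths along every pixel ray, split at the isocenter plane.

    Line integrals of relative electron density from the source to each
    imager pixel, computed with exact Siddon voxel traversal and split at
    the plane through the isocenter perpendicular to the central axis.
    """
    if ct.hu.size == 0:
        raise ValueError("empty CT volume")
    lo, hi = ct.bounds()
    if np.any(hi - lo <= 0):
        raise ValueError("zero-extent CT volume")
    p0 = geom.source_position()
    if np.all((p0 >= lo) & (p0 <= hi)):
        raise ValueError("source position lies inside the CT volume")

    x_hat, y_hat, _ = geom.beam_axes()
    yy, xx = geom.pixel_grid()
    iso = np.asarray(geom.isocenter, float)
    # Ray-line crossing with the isocenter plane, mm.
    q = iso[None, :] + 10.0 * (xx.ravel()[:, None] * x_hat[None, :]
                               + yy.ravel()[:, None] * y_hat[None, :])
    # Similar triangles: the pixel sits at sdd/sad times the source->q leg.
    p_det = p0[None, :] + (q - p0[None, :]) * (geom.sdd / geom.sad)
    t_split = geom.sad / geom.sdd

    red = np.ascontiguousarray(ct.red())
    t_up_mm, t_down_mm = trace_rays(
        red,
        np.asarray(ct.origin, float),
        np.asarray(ct.spacing, float),
        p0.astype(float),
        np.ascontiguousarray(p_det, float),
        float(t_split),
    )
    shape = (geom.n_rows, geom.n_cols)
    return RadiologicalDepthMaps(
        t_up=t_up_mm.reshape(shape) / 10.0,
        t_down=t_down_mm.reshape(shape) / 10.0,
        geom=geom,
    )
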