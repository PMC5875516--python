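"""2D dose reconstruction in the isocenter plane from transit portal images.

Two reconstruction paths are provided:

* homogeneous, centered slab:  ``D = S / (F_CAX(w, l) k(x; l) k(y; l))``
* general, CT-based: per-ray radiological thickness ``w_ij`` and midplane
  offset ``d_ij`` enter through the commissioned interpolants and a
  tissue-maximum-ratio (TMR) shift from the ray's radiological half-depth
  to the isocenter-plane depth:

  ``D_ij = TMR(w_ij/2 - d_ij) / TMR(w_ij/2) * f(d_ij, l)
  / (F_CAX(w_ij, l) k(x; l) k(y; l)) * S_ij``

The field edge is defined on the portal image itself: the locus where the
signal equals half of the sum of the CAX signal and the mean background
well outside the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage import measure

from .commissioning import CommissioningTable, DoseMap, EpidImage, cax_signal
from .geometry import BeamGeometry, RadiologicalDepthMaps

__all__ = [
    "FieldMask",
    "TmrTable",
    "EdgeDistanceMaps",
    "detect_field",
    "edge_distances",
    "edge_correction_map",
    "equivalent_square",
    "tmr_ratio",
    "reconstruct_dose_homogeneous",
    "reconstruct_dose",
]

#: Side (pixels) of the corner blocks averaged into the background level.
BACKGROUND_BLOCK = 20

#: Below this equivalent square (cm) the two-edge correction degrades.
MIN_RELIABLE_FIELD = 5.5


@dataclass
class FieldMask:
    """Detected radiation field on a portal image.

    ``row_left``/``row_right`` hold the subpixel half-maximum crossings of
    each row (cm, isocenter-plane cross-plane coordinate; NaN where the
    row does not intersect the field); ``col_top``/``col_bottom`` likewise
    per column along the in-plane direction.
    """

    inside: np.ndarray
    threshold: float
    s_cax: float
    background: float
    row_left: np.ndarray
    row_right: np.ndarray
    col_top: np.ndarray
    col_bottom: np.ndarray
    geom: BeamGeometry


@dataclass
class TmrTable:
    """Tissue-maximum ratios on a depth x field-size grid (CAX values)."""

    depths: np.ndarray  # cm, increasing
    field_sizes: np.ndarray  # cm, increasing
    values: np.ndarray  # (depth, field size)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, float)
        self.field_sizes = np.asarray(self.field_sizes, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.depths) <= 0) or np.any(self.depths < 0):
            raise ValueError("TMR depths must be >= 0 and strictly increasing")
        if np.any(np.diff(self.field_sizes) <= 0):
            raise ValueError("TMR field sizes must be strictly increasing")
        if self.values.shape != (self.depths.size, self.field_sizes.size):
            raise ValueError("TMR grid shape does not match axes")
        if np.any(self.values <= 0):
            raise ValueError("TMR values must be > 0")
        self._interp = RegularGridInterpolator(
            (self.depths, self.field_sizes), self.values,
            method="linear", bounds_error=True,
        )

    def __call__(self, depth, field_size):
        """Bilinear TMR lookup; errors outside the tabulated ranges."""
        depth = np.asarray(depth, float)
        fs = np.broadcast_to(np.asarray(field_size, float), depth.shape)
        pts = np.stack([depth.ravel(), fs.ravel()], axis=-1)
        try:
            out = self._interp(pts)
        except ValueError as exc:
            raise ValueError(
                f"TMR query outside table range (depths {self.depths[0]:g}.."
                f"{self.depths[-1]:g} cm, sizes {self.field_sizes[0]:g}.."
                f"{self.field_sizes[-1]:g} cm): {exc}"
            ) from None
        return out.reshape(depth.shape) if depth.shape else float(out[0])


@dataclass
class EdgeDistanceMaps:
    """Distances (cm) from each in-field pixel to its nearest field edges.

    ``x`` along the pixel's row (cross-plane), ``y`` along its column
    (in-plane); NaN outside the field.
    """

    x: np.ndarray
    y: np.ndarray


def _crossings(profile: np.ndarray, seg: np.ndarray, coords: np.ndarray,
               threshold: float) -> tuple[float, float]:
    """Subpixel threshold crossings bracketing the in-field segment ``seg``."""
    idx = np.flatnonzero(seg)
    lo, hi = idx[0], idx[-1]
    if lo == 0:
        left = coords[0]
    else:
        v0, v1 = profile[lo - 1], profile[lo]
        frac = (threshold - v0) / (v1 - v0) if v1 != v0 else 1.0
        left = coords[lo - 1] + frac * (coords[lo] - coords[lo - 1])
    if hi == len(profile) - 1:
        right = coords[hi]
    else:
        v0, v1 = profile[hi], profile[hi + 1]
        frac = (v0 - threshold) / (v0 - v1) if v1 != v0 else 1.0
        right = coords[hi] + frac * (coords[hi + 1] - coords[hi])
    return left, right


def detect_field(img: EpidImage) -> FieldMask:
    """Detect the radiation field on a portal image.

    The background is the mean over four 20x20 corner blocks; the edge
    threshold is half the sum of the CAX signal and that background. The
    mask is the largest connected component above threshold; subpixel
    half-maximum crossings are stored per row and per column.
    """
    px = img.pixels
    b = BACKGROUND_BLOCK
    background = float(np.mean([
        px[:b, :b].mean(), px[:b, -b:].mean(), px[-b:, :b].mean(), px[-b:, -b:].mean()
    ]))
    s_cax = cax_signal(img)
    threshold = 0.5 * (s_cax + background)
    if threshold - background < 0.05 * abs(s_cax) or s_cax <= 0:
        raise ValueError("no field found: in-field plateau not separable from background")
    above = px >= threshold
    if not above.any():
        raise ValueError("no field found: no pixel above the edge threshold")
    labels, n = ndimage.label(above)
    largest = np.argmax(ndimage.sum_labels(above, labels, index=range(1, n + 1))) + 1
    inside = labels == largest

    geom = img.geom
    yy = (np.arange(geom.n_rows) - (geom.n_rows - 1) / 2.0) * geom.pitch_y
    xx = (np.arange(geom.n_cols) - (geom.n_cols - 1) / 2.0) * geom.pitch_x
    row_left = np.full(geom.n_rows, np.nan)
    row_right = np.full(geom.n_rows, np.nan)
    col_top = np.full(geom.n_cols, np.nan)
    col_bottom = np.full(geom.n_cols, np.nan)
    for r in np.flatnonzero(inside.any(axis=1)):
        row_left[r], row_right[r] = _crossings(px[r], inside[r], xx, threshold)
    for c in np.flatnonzero(inside.any(axis=0)):
        col_top[c], col_bottom[c] = _crossings(px[:, c], inside[:, c], yy, threshold)
    return FieldMask(
        inside=inside, threshold=threshold, s_cax=s_cax, background=background,
        row_left=row_left, row_right=row_right,
        col_top=col_top, col_bottom=col_bottom, geom=geom,
    )


def edge_distances(mask: FieldMask, geom: BeamGeometry) -> EdgeDistanceMaps:
    """Distance from each in-field pixel centre to the nearest field edge
    along its row (``x``) and along its column (``y``)."""
    inside = mask.inside
    yy = (np.arange(geom.n_rows) - (geom.n_rows - 1) / 2.0) * geom.pitch_y
    xx = (np.arange(geom.n_cols) - (geom.n_cols - 1) / 2.0) * geom.pitch_x
    xmap = np.full(inside.shape, np.nan)
    ymap = np.full(inside.shape, np.nan)
    xc = xx[None, :]
    dx = np.minimum(np.abs(xc - mask.row_left[:, None]),
                    np.abs(mask.row_right[:, None] - xc))
    yc = yy[:, None]
    dy = np.minimum(np.abs(yc - mask.col_top[None, :]),
                    np.abs(mask.col_bottom[None, :] - yc))
    xmap[inside] = dx[inside]
    ymap[inside] = dy[inside]
    return EdgeDistanceMaps(x=xmap, y=ymap)


def edge_correction_map(distances: EdgeDistanceMaps, table: CommissioningTable,
                        l: float) -> np.ndarray:
    """Two-edge correction k(x; l) * k(y; l) per pixel; NaN outside the field.

    The correction accounts only for the nearest cross-plane and in-plane
    edges; for equivalent squares below ~5.5 cm the two edges interact
    and a warning is emitted.
    """
    if l <= 0:
        raise ValueError("field size must be positive")
    if l < MIN_RELIABLE_FIELD:
        warnings.warn(
            f"equivalent square {l:.2f} cm < {MIN_RELIABLE_FIELD} cm: the "
            "two-edge correction degrades for small fields", stacklevel=2,
        )
    curve = table.k_curve_for(l)
    out = np.full(distances.x.shape, np.nan)
    valid = np.isfinite(distances.x) & np.isfinite(distances.y)
    if np.any((distances.x[valid] < 0) | (distances.y[valid] < 0)):
        raise ValueError("edge distances must be >= 0")
    out[valid] = curve(distances.x[valid]) * curve(distances.y[valid])
    return out


def equivalent_square(mask: FieldMask, geom: BeamGeometry) -> float:
    """Sterling equivalent square ``l = 4 A / P`` of the detected field.

    Area from the in-field pixel count; perimeter from the smoothed
    marching-squares contour of the mask (smoothing removes the pixel
    staircase so curved apertures are not over-measured).
    """
    inside = mask.inside
    area_px = int(inside.sum())
    if area_px == 0:
        raise ValueError("degenerate field mask: zero area")
    area = area_px * geom.pitch_y * geom.pitch_x
    contours = measure.find_contours(inside.astype(float), 0.5)
    if not contours:
        raise ValueError("degenerate field mask: no contour")
    c = max(contours, key=len)[:-1]
    c_cm = np.stack([c[:, 0] * geom.pitch_y, c[:, 1] * geom.pitch_x], axis=1)
    win = 5
    if len(c_cm) > win:
        pad = np.concatenate([c_cm[-(win // 2):], c_cm, c_cm[: win // 2]])
        kern = np.ones(win) / win
        c_cm = np.stack(
            [np.convolve(pad[:, a], kern, mode="valid") for a in (0, 1)], axis=1
        )
    seg = np.diff(np.vstack([c_cm, c_cm[:1]]), axis=0)
    perimeter = float(np.sqrt((seg ** 2).sum(axis=1)).sum())
    if perimeter <= 0:
        raise ValueError("degenerate field mask: zero perimeter")
    return 4.0 * area / perimeter


def tmr_ratio(w, d, l, tmr: TmrTable):
    """TMR(w/2 - d; l) / TMR(w/2; l).

    Shifts the dose-calculation point from the radiological half-depth of
    the ray to the depth of the isocenter plane.  ``w``, ``d`` may be
    scalars or arrays (broadcast together).
    """
    w = np.asarray(w, float)
    d = np.broadcast_to(np.asarray(d, float), w.shape) if w.shape else np.asarray(d, float)
    return tmr(w / 2.0 - d, l) / tmr(w / 2.0, l)


def reconstruct_dose_homogeneous(
    img: EpidImage, table: CommissioningTable, w: float, l: float,
) -> tuple[DoseMap, FieldMask]:
    """Dose in the isocenter plane for a homogeneous slab centered at isocenter.

    ``D = S / (F_CAX(w, l) k(x; l) k(y; l))`` inside the detected field;
    zero outside.  Returns the dose map and the detected field mask.
    """
    mask = detect_field(img)
    dist = edge_distances(mask, img.geom)
    kmap = edge_correction_map(dist, table, l)
    fcax = table.fcax(w, l)
    dose = np.zeros_like(img.pixels)
    inside = mask.inside
    dose[inside] = img.pixels[inside] / (fcax * kmap[inside])
    return DoseMap(dose=dose, geom=img.geom), mask


def reconstruct_dose(
    img: EpidImage,
    depths: RadiologicalDepthMaps,
    table: CommissioningTable,
    tmr: TmrTable,
    l: float,
) -> tuple[DoseMap, FieldMask]:
    """General CT-based dose reconstruction in the isocenter plane.

    Per-pixel radiological thickness ``w_ij`` and midplane offset ``d_ij``
    enter through the commissioned interpolants and the TMR shift; the
    field-edge correction uses the curve of the nearest commissioned
    field size.  Raises if any in-field ``w_ij`` (or ``d_ij``) falls
    outside the commissioned range.
    """
    mask = detect_field(img)
    inside = mask.inside
    w_in = depths.w[inside]
    d_in = depths.d[inside]
    wlo, whi = table.w_nodes[0], table.w_nodes[-1]
    if np.any(w_in < wlo) or np.any(w_in > whi):
        raise ValueError(
            f"in-field radiological thickness {w_in.min():.2f}..{w_in.max():.2f} cm "
            f"outside the commissioned range [{wlo:g}, {whi:g}] cm"
        )
    dist = edge_distances(mask, img.geom)
    kmap = edge_correction_map(dist, table, l)
    ratio = tmr_ratio(w_in, d_in, l, tmr)
    f_vals = table.f(d_in, np.full_like(d_in, l))
    fcax_vals = table.fcax(w_in, np.full_like(w_in, l))
    dose = np.zeros_like(img.pixels)
    dose[inside] = ratio * f_vals * img.pixels[inside] / (fcax_vals * kmap[inside])
    return DoseMap(dose=dose, geom=img.geom), mask
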