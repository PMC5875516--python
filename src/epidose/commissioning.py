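"""Commissioning of EPID signal-to-dose correlation ratios.

From paired transit portal images and planning-system dose maps acquired
on water-equivalent slab phantoms, this module builds:

* ``F_CAX(w, l)`` — central-axis signal-to-dose ratio versus slab
  thickness ``w`` and square field size ``l``;
* ``f(d, l)`` — displacement factor, the CAX signal ratio of a centered
  slab to the same slab displaced by ``d`` along the beam axis;
* ``k(x; l)`` — field-edge correction curves: the normalized
  signal-to-dose ratio versus distance ``x`` from the field edge,
  averaged over cross-plane subprofiles near the central-right edge.

The correlation ratio rises approaching a field edge because the dose
falls off faster than the imager signal (loss of lateral electronic
equilibrium in the phantom); ``k`` captures that rise so reconstruction
can divide it out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .geometry import BeamGeometry

__all__ = [
    "EpidImage",
    "DoseMap",
    "FMap",
    "EdgeCurve",
    "CommissioningTable",
    "cax_signal",
    "cax_dose",
    "compute_fcax",
    "compute_f",
    "compute_f_map",
    "normalize_k_map",
    "extract_edge_curve",
    "build_commissioning_table",
    "commission_from_fixtures",
]

#: Side of the central pixel block used for CAX signal/dose averages.
CAX_BLOCK = 20

#: Distance from the field edge (cm, isocenter plane) beyond which the
#: edge correction is taken as exactly 1 (>99% of the variability of the
#: correlation ratio is contained within this span).
EDGE_SPAN_CM = 2.76

#: Number of in-field pixels per subprofile used for edge-curve
#: extraction (spans EDGE_SPAN_CM at the default imager resolution).
EDGE_SAMPLES = 53

#: Number of central rows averaged into one edge-correction curve.
EDGE_ROWS = 20


@dataclass
class EpidImage:
    """An integrated (cine-summed), flood- and dark-field corrected portal image."""

    pixels: np.ndarray
    geom: BeamGeometry
    n_frames: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, float)
        if self.pixels.shape != (self.geom.n_rows, self.geom.n_cols):
            raise ValueError(
                f"image shape {self.pixels.shape} != imager "
                f"({self.geom.n_rows}, {self.geom.n_cols})"
            )
        if np.any(self.pixels < 0):
            raise ValueError("EPID pixel values must be >= 0")


@dataclass
class DoseMap:
    """Planar dose (cGy) on the isocenter-plane ray-line grid.

    One dose point per imager pixel: the dose at the point where the
    pixel's ray line crosses the isocenter plane.
    """

    dose: np.ndarray
    geom: BeamGeometry

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, float)
        if self.dose.shape != (self.geom.n_rows, self.geom.n_cols):
            raise ValueError(
                f"dose shape {self.dose.shape} != imager grid "
                f"({self.geom.n_rows}, {self.geom.n_cols})"
            )
        if np.any(self.dose < 0):
            raise ValueError("dose must be >= 0")


@dataclass
class FMap:
    """Per-pixel signal-to-dose ratio F_ij (a.u./cGy); NaN outside the field."""

    values: np.ndarray
    mask: "object"  # FieldMask; kept loose to avoid a circular import


def _cax_block(shape: tuple[int, int]) -> tuple[slice, slice]:
    """Central CAX_BLOCK x CAX_BLOCK slice, lower-index bias on ties.

    For the default 384x512 grid this is rows 182-201, cols 246-265.
    """
    n_rows, n_cols = shape
    if n_rows < CAX_BLOCK or n_cols < CAX_BLOCK:
        raise ValueError(f"image must be at least {CAX_BLOCK}x{CAX_BLOCK}, got {shape}")
    r0 = (n_rows - CAX_BLOCK) // 2
    c0 = (n_cols - CAX_BLOCK) // 2
    return slice(r0, r0 + CAX_BLOCK), slice(c0, c0 + CAX_BLOCK)


def cax_signal(img: EpidImage) -> float:
    """Mean signal over the imager's central 20x20 pixel block (S_CAX)."""
    rs, cs = _cax_block(img.pixels.shape)
    return float(img.pixels[rs, cs].mean())


def cax_dose(dose: DoseMap) -> float:
    """Mean dose over the central 20x20 block of the planar dose map (D_CAX)."""
    rs, cs = _cax_block(dose.dose.shape)
    return float(dose.dose[rs, cs].mean())


def compute_fcax(s_cax: float, d_cax: float) -> float:
    """Central-axis correlation ratio F_CAX = S_CAX / D_CAX (a.u./cGy)."""
    if d_cax <= 0:
        raise ValueError(f"D_CAX must be > 0, got {d_cax}")
    return s_cax / d_cax


def compute_f(s_centered: float, s_displaced: float) -> float:
    """Displacement factor f = S(centered) / S(displaced)."""
    if s_displaced <= 0:
        raise ValueError(f"displaced signal must be > 0, got {s_displaced}")
    return s_centered / s_displaced


def compute_f_map(img: EpidImage, dose: DoseMap, mask) -> FMap:
    """Per-pixel ratio F_ij = S_ij / D_ij inside the field mask."""
    if img.pixels.shape != dose.dose.shape:
        raise ValueError("image and dose map must share a grid")
    inside = mask.inside
    bad = inside & (dose.dose <= 0)
    if np.any(bad):
        idx = np.argwhere(bad)[:5]
        raise ValueError(f"zero dose inside the field at pixels {idx.tolist()} ...")
    values = np.full(img.pixels.shape, np.nan)
    values[inside] = img.pixels[inside] / dose.dose[inside]
    return FMap(values=values, mask=mask)


def normalize_k_map(fmap: FMap, fcax: float) -> np.ndarray:
    """Unitless K_ij = F_ij / F_CAX; NaN outside the field."""
    if fcax <= 0:
        raise ValueError(f"F_CAX must be > 0, got {fcax}")
    return fmap.values / fcax


@dataclass
class EdgeCurve:
    """An edge-correction curve: k sampled at distances x from the field edge."""

    x: np.ndarray  # cm from the edge, increasing, ~[0, EDGE_SPAN_CM]
    k: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.k = np.asarray(self.k, float)
        if self.x.shape != self.k.shape or self.x.ndim != 1:
            raise ValueError("x and k must be 1D arrays of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("edge-curve distances must be strictly increasing")
        if np.any(self.k < 0):
            raise ValueError("k must be >= 0")
        if abs(self.k[-1] - 1.0) > 0.01:
            raise ValueError(
                f"edge curve must settle to 1 at its far end (got {self.k[-1]:.4f})"
            )

    def __call__(self, x) -> np.ndarray:
        """Linear interpolation over the samples; exactly 1 beyond the span."""
        x = np.asarray(x, float)
        if np.any(x < 0):
            raise ValueError("distances to the field edge must be >= 0")
        out = np.interp(x, self.x, self.k, left=self.k[0], right=1.0)
        return np.where(x >= EDGE_SPAN_CM, 1.0, out)


def extract_edge_curve(kmap: np.ndarray, mask, geom: BeamGeometry,
                       n_samples: int = EDGE_SAMPLES, n_rows: int = EDGE_ROWS) -> EdgeCurve:
    """Edge-correction curve from a K map.

    Averages ``n_rows`` cross-plane subprofiles centred on the CAX row,
    each consisting of the ``n_samples`` in-field pixels closest to that
    row's right field edge, indexed by distance to the (subpixel) edge
    crossing, ordered from the edge inward.
    """
    inside = mask.inside
    nr, nc = inside.shape
    r0 = (nr - n_rows) // 2
    rows = range(r0, r0 + n_rows)
    x_pix = (np.arange(nc) - (nc - 1) / 2.0) * geom.pitch_x

    dist = np.empty((n_rows, n_samples))
    kval = np.empty((n_rows, n_samples))
    for i, r in enumerate(rows):
        cols = np.flatnonzero(inside[r])
        x_edge = mask.row_right[r]
        if cols.size < n_samples or not np.isfinite(x_edge):
            raise ValueError(
                f"field too small for edge-curve extraction on row {r}: "
                f"{cols.size} in-field pixels, need {n_samples}"
            )
        take = cols[-n_samples:]  # nearest the right edge
        d = x_edge - x_pix[take]
        order = np.argsort(d)
        dist[i] = d[order]
        kval[i] = kmap[r, take][order]
    if np.any(~np.isfinite(kval)):
        raise ValueError("K map undefined inside the field on a subprofile")
    return EdgeCurve(x=dist.mean(axis=0), k=kval.mean(axis=0))


class _Spline2D:
    """Cubic tensor spline through grid nodes with strict range checks."""

    def __init__(self, u: np.ndarray, v: np.ndarray, grid: np.ndarray,
                 names: tuple[str, str]):
        self.u = np.asarray(u, float)
        self.v = np.asarray(v, float)
        self.grid = np.asarray(grid, float)
        self.names = names
        for nodes, name in ((self.u, names[0]), (self.v, names[1])):
            if nodes.size < 4:
                raise ValueError(f"need at least 4 {name} nodes, got {nodes.size}")
            if np.any(np.diff(nodes) <= 0):
                raise ValueError(f"duplicate or unsorted {name} nodes")
        if self.grid.shape != (self.u.size, self.v.size):
            raise ValueError("grid shape does not match node vectors")
        self._spl = RectBivariateSpline(self.u, self.v, self.grid, kx=3, ky=3, s=0)

    def _check(self, val, nodes, name):
        val = np.asarray(val, float)
        if np.any(val < nodes[0]) or np.any(val > nodes[-1]):
            raise ValueError(
                f"{name}={np.min(val):g}..{np.max(val):g} outside the commissioned "
                f"range [{nodes[0]:g}, {nodes[-1]:g}]; no extrapolation"
            )
        return val

    def __call__(self, u, v):
        u = self._check(u, self.u, self.names[0])
        v = self._check(v, self.v, self.names[1])
        out = self._spl.ev(u, v)
        return float(out) if out.ndim == 0 else out


@dataclass
class CommissioningTable:
    """Commissioned correlation ratios with their interpolants.

    ``F_CAX`` and ``f`` are interpolated with cubic tensor splines through
    the measurement nodes (queries at nodes reproduce the measured values);
    edge curves are linearly interpolated over their samples and selected
    by the nearest commissioned field size, ties toward the smaller field.
    No extrapolation outside the commissioned ranges.
    """

    w_nodes: np.ndarray
    l_nodes: np.ndarray
    fcax_grid: np.ndarray  # (w, l)
    d_nodes: np.ndarray
    fl_nodes: np.ndarray
    f_grid: np.ndarray  # (d, l)
    k_curves: dict[float, EdgeCurve]
    _fcax: _Spline2D = field(init=False, repr=False)
    _f: _Spline2D = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.w_nodes = np.asarray(self.w_nodes, float)
        self.l_nodes = np.asarray(self.l_nodes, float)
        self.fcax_grid = np.asarray(self.fcax_grid, float)
        self.d_nodes = np.asarray(self.d_nodes, float)
        self.fl_nodes = np.asarray(self.fl_nodes, float)
        self.f_grid = np.asarray(self.f_grid, float)
        if np.any(self.fcax_grid <= 0):
            raise ValueError("F_CAX must be positive everywhere")
        self._fcax = _Spline2D(self.w_nodes, self.l_nodes, self.fcax_grid, ("w", "l"))
        self._f = _Spline2D(self.d_nodes, self.fl_nodes, self.f_grid, ("d", "l"))
        if 0.0 in self.d_nodes:
            row = self.f_grid[np.flatnonzero(self.d_nodes == 0.0)[0]]
            if np.any(np.abs(row - 1.0) > 1e-6):
                raise ValueError("f at d=0 must equal 1")
        if not self.k_curves:
            raise ValueError("at least one edge-correction curve is required")
        self.k_curves = {float(l): c for l, c in self.k_curves.items()}

    def fcax(self, w, l):
        """F_CAX at thickness ``w`` cm and field size ``l`` cm (a.u./cGy)."""
        return self._fcax(w, l)

    def f(self, d, l):
        """Displacement factor at displacement ``d`` cm and field size ``l`` cm."""
        return self._f(d, l)

    def k_curve_for(self, l: float) -> EdgeCurve:
        """Edge curve of the nearest commissioned field size (ties -> smaller)."""
        sizes = sorted(self.k_curves)
        best = min(sizes, key=lambda s: (abs(s - l), s))
        return self.k_curves[best]

    def k(self, x, l: float):
        """Edge correction at distance ``x`` cm from the field edge."""
        return self.k_curve_for(l)(x)

    # -- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "w_nodes": self.w_nodes.tolist(),
            "l_nodes": self.l_nodes.tolist(),
            "fcax_grid": self.fcax_grid.tolist(),
            "d_nodes": self.d_nodes.tolist(),
            "fl_nodes": self.fl_nodes.tolist(),
            "f_grid": self.f_grid.tolist(),
            "k_curves": {
                repr(l): {"x": c.x.tolist(), "k": c.k.tolist()}
                for l, c in self.k_curves.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CommissioningTable":
        return cls(
            w_nodes=data["w_nodes"],
            l_nodes=data["l_nodes"],
            fcax_grid=data["fcax_grid"],
            d_nodes=data["d_nodes"],
            fl_nodes=data["fl_nodes"],
            f_grid=data["f_grid"],
            k_curves={
                float(l): EdgeCurve(x=c["x"], k=c["k"])
                for l, c in data["k_curves"].items()
            },
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "CommissioningTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_commissioning_table(
    fcax_measurements: Sequence[tuple[float, float, float]],
    f_measurements: Sequence[tuple[float, float, float]],
    k_curves: Mapping[float, EdgeCurve],
) -> CommissioningTable:
    """Assemble a :class:`CommissioningTable` from measurement lists.

    ``fcax_measurements`` are ``(w, l, value)`` triples on a complete
    ``w x l`` grid; ``f_measurements`` are ``(d, l, value)`` on a complete
    ``d x l`` grid; ``k_curves`` maps field size to its edge curve.
    """

    def pivot(meas, names):
        us = np.array(sorted({m[0] for m in meas}))
        vs = np.array(sorted({m[1] for m in meas}))
        grid = np.full((us.size, vs.size), np.nan)
        for u, v, val in meas:
            i = np.searchsorted(us, u)
            j = np.searchsorted(vs, v)
            if not np.isnan(grid[i, j]):
                raise ValueError(f"duplicate measurement at {names[0]}={u}, {names[1]}={v}")
            grid[i, j] = val
        if np.any(np.isnan(grid)):
            raise ValueError(f"incomplete {names[0]} x {names[1]} measurement grid")
        return us, vs, grid

    w, l, fcax_grid = pivot(fcax_measurements, ("w", "l"))
    d, fl, f_grid = pivot(f_measurements, ("d", "l"))
    return CommissioningTable(
        w_nodes=w, l_nodes=l, fcax_grid=fcax_grid,
        d_nodes=d, fl_nodes=fl, f_grid=f_grid,
        k_curves=dict(k_curves),
    )


def commission_from_fixtures(
    fcax_pairs: Mapping[tuple[float, float], tuple[EpidImage, DoseMap]],
    f_images: Mapping[tuple[float, float], EpidImage],
    edge_pairs: Mapping[float, tuple[EpidImage, DoseMap]],
) -> CommissioningTable:
    """Run the full commissioning procedure on image/dose pairs.

    ``fcax_pairs`` maps ``(w, l)`` to a centered-slab image/dose pair;
    ``f_images`` maps ``(d, l)`` to a displaced-slab image (the ``d=0``
    entry of each series is the reference); ``edge_pairs`` maps field size
    to the pair used for edge-curve extraction (nominally the 12 cm slab).
    """
    from .reconstruction import detect_field  # deferred: avoids import cycle

    fcax_meas = []
    for (w, l), (img, dose) in fcax_pairs.items():
        fcax_meas.append((w, l, compute_fcax(cax_signal(img), cax_dose(dose))))

    f_meas = []
    sizes = sorted({l for _, l in f_images})
    for l in sizes:
        if (0.0, l) not in f_images:
            raise ValueError(f"f series for l={l} is missing the centered (d=0) image")
        s0 = cax_signal(f_images[(0.0, l)])
        for (d, ll), img in f_images.items():
            if ll == l:
                f_meas.append((d, l, compute_f(s0, cax_signal(img))))

    curves = {}
    for l, (img, dose) in edge_pairs.items():
        mask = detect_field(img)
        fmap = compute_f_map(img, dose, mask)
        fcax = compute_fcax(cax_signal(img), cax_dose(dose))
        kmap = normalize_k_map(fmap, fcax)
        curves[l] = extract_edge_curve(kmap, mask, img.geom)

    return build_commissioning_table(fcax_meas, f_meas, curves)
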