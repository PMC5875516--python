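"""Synthetic phantoms, transit portal images, and planning-system dose maps.

The generator emulates the physical structure the correlation-ratio method
relies on, with closed-form ground truth for every commissioned quantity:

* the EPID signal attenuates exponentially with the radiological
  thickness ``w_ij`` of each ray and carries a displacement-dependent
  scatter response (which defines the true displacement factor ``f``);
* the planar dose follows a parametric tissue-maximum-ratio (TMR) curve
  evaluated at the isocenter-plane radiological depth ``w_ij/2 - d_ij``;
* both share an off-axis "horn" and separable error-function field
  penumbras, with the dose penumbra wider than the signal penumbra
  (``sigma_dose > sigma_signal``) — inside the field the dose therefore
  falls off faster approaching the edge than the signal does, producing
  the near-edge rise of the signal-to-dose ratio that the edge-correction
  curves ``k(x)`` must capture.

An optional lateral-disequilibrium dose deficit in low-density (lung)
tissue lowers the simulated planning dose without touching the signal;
the reconstruction has no knowledge of it and will overestimate dose
there, as a primary-path method does in real lung fields.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.special import erf

from .commissioning import DoseMap, EpidImage
from .geometry import (
    BeamGeometry,
    CtVolume,
    RadiologicalDepthMaps,
    trace_radiological_depths,
)
from .reconstruction import TmrTable

__all__ = [
    "SyntheticBeamModel",
    "PhantomSpec",
    "GroundTruth",
    "make_phantom_ct",
    "slab_radiological_depths",
    "simulate_epid_image",
    "simulate_tps_dose",
    "make_tmr_table",
    "ground_truth",
    "generate_commissioning_fixtures",
    "noise_free",
    "FCAX_W_NODES",
    "FCAX_L_NODES",
    "F_L_NODES",
    "F_D_NODES",
    "EDGE_L_NODES",
    "EDGE_W",
]

# HU values mapped through the default calibration: water -> RED 1.0,
# lung -> 0.25, bone -> 1.5.
HU_WATER = 0.0
HU_LUNG = -750.0
HU_BONE = 833.0
HU_AIR = -1000.0

#: Relative electron density below which a voxel counts as lung for the
#: optional lateral-disequilibrium dose deficit.
LUNG_RED_THRESHOLD = 0.6


@dataclass(frozen=True)
class SyntheticBeamModel:
    """Parameters of the synthetic beam/imager pair.

    ``sigma_dose > sigma_signal`` is required: it creates the in-field
    near-edge rise of signal over dose.  ``scatter_gain`` sets the
    per-cm displacement response of the imager signal, so the true
    displacement factor is ``f(d, l) = 1 / (1 + scatter_gain * (l/10) * d)``
    (about 0.6% at d = 10 cm for a 20 cm field with the default gain).
    """

    s0: float = 10000.0  # a.u., open-beam CAX signal
    d0: float = 100.0  # cGy, dose scale at the TMR peak
    mu_eff: float = 0.05  # 1/cm, effective signal attenuation
    tmr_dmax: float = 1.5  # cm, TMR buildup depth
    tmr_mu: float = 0.045  # 1/cm, TMR exponential slope at l = 10 cm
    tmr_fs_slope: float = 0.004  # relative slope change per cm of field size
    sigma_signal: float = 0.35  # cm, signal penumbra width
    sigma_dose: float = 0.55  # cm, dose penumbra width
    horn: float = 0.03  # off-axis bump amplitude at r = 10 cm
    scatter_gain: float = 3e-4  # per cm displacement, per (l/10)
    noise_sd: float = 0.002  # relative, multiplicative Gaussian
    lung_deficit: float = 0.0  # fractional dose loss in lung tissue

    def __post_init__(self) -> None:
        if not (self.sigma_dose > self.sigma_signal > 0):
            raise ValueError("require sigma_dose > sigma_signal > 0")
        if min(self.s0, self.d0, self.mu_eff, self.tmr_dmax, self.tmr_mu) <= 0:
            raise ValueError("scales must be positive")
        if self.noise_sd < 0 or not (0 <= self.lung_deficit < 1):
            raise ValueError("invalid noise or lung-deficit setting")

    # -- parametric TMR -------------------------------------------------
    def tmr(self, depth, field_size=10.0):
        """TMR(depth, l): quadratic buildup to 1 at d_max, exponential beyond."""
        z = np.asarray(depth, float)
        mu = self.tmr_mu * (1.0 - self.tmr_fs_slope * (np.asarray(field_size, float) - 10.0))
        u = np.clip(z / self.tmr_dmax, 0.0, 1.0)
        buildup = 0.5 + 0.5 * (2.0 * u - u * u)
        tail = np.exp(-mu * np.maximum(z - self.tmr_dmax, 0.0))
        return buildup * tail

    def horn_factor(self, r_cm):
        """Off-axis fluence bump, 1 on the CAX."""
        return 1.0 + self.horn * (np.asarray(r_cm, float) / 10.0) ** 2

    def scatter_factor(self, d_cm, field_size):
        """Displacement response multiplying the signal; 1 for a centered object."""
        gain = self.scatter_gain * (field_size / 10.0)
        return 1.0 + gain * np.asarray(d_cm, float)


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic phantom.

    ``kind`` is ``"slab"``, ``"step"`` (two adjacent thicknesses split at
    the cross-plane midline), ``"head"`` (elliptic cylinder with a bone
    shell) or ``"thorax"`` (elliptic body with two low-density lungs).
    ``displacement`` shifts the phantom along the beam axis, positive
    toward the detector.
    """

    kind: str = "slab"
    thickness: float = 16.0  # cm (slab); ignored for head/thorax
    thickness2: float | None = None  # cm, second thickness for "step"
    displacement: float = 0.0  # cm along the beam axis
    lateral_extent: float = 40.0  # cm, slab size in x and y
    lung_red: float = 0.25  # relative electron density of lung inserts

    def __post_init__(self) -> None:
        if self.kind not in ("slab", "step", "head", "thorax"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind in ("slab", "step") and not (2.0 <= self.thickness <= 40.0):
            raise ValueError("slab thickness must lie in [2, 40] cm")
        if self.kind == "step":
            if self.thickness2 is None or not (2.0 <= self.thickness2 <= 40.0):
                raise ValueError("step phantom needs a second thickness in [2, 40] cm")
        if self.lung_red < 0:
            raise ValueError("densities must be >= 0")


def make_phantom_ct(spec: PhantomSpec, spacing: tuple[float, float, float] = (4.0, 4.0, 2.0),
                    ) -> CtVolume:
    """Voxelize a phantom specification into a CT volume (HU).

    The phantom is centred on the coordinate origin (put the isocenter
    there in the beam geometry, or offset it to displace the phantom);
    ``displacement`` shifts slabs/steps along -z (toward the detector at
    gantry 0).
    """
    sp = np.asarray(spacing, float)
    if spec.kind in ("slab", "step"):
        # Voxel edges are aligned with the slab faces and (for the step)
        # with the x = 0 split, so the digitized thickness is exact
        # whenever spacing divides it.
        half_xy = spec.lateral_extent / 2.0 * 10.0
        wmax = spec.thickness if spec.kind == "slab" else max(spec.thickness, spec.thickness2)
        zc = -spec.displacement * 10.0  # slab centre, mm (toward detector = -z)
        nxy = [2 * int(np.ceil(half_xy / sp[a])) for a in (0, 1)]
        half_z_mm = wmax * 5.0 + abs(spec.displacement) * 10.0 + 10.0
        nz = 2 * int(np.ceil(half_z_mm / sp[2]))
        shape = (nxy[0], nxy[1], nz)
        # centre voxel edges on 0 in every axis
        origin = np.array([-(shape[a] / 2.0 - 0.5) * sp[a] for a in range(3)])
        x = origin[0] + np.arange(shape[0]) * sp[0]
        z = origin[2] + np.arange(shape[2]) * sp[2]
        xx, zz = np.meshgrid(x, z, indexing="ij")
        hu = np.full(shape, HU_AIR)
        if spec.kind == "slab":
            inside = np.abs(zz - zc) < spec.thickness * 5.0  # w/2 cm -> mm
        else:
            w = np.where(xx < 0, spec.thickness, spec.thickness2)
            inside = np.abs(zz - zc) < w * 5.0
        hu[:, :, :] = np.where(inside[:, None, :], HU_WATER, HU_AIR)
        return CtVolume(hu=hu, spacing=tuple(sp), origin=tuple(origin))

    if spec.kind == "head":
        a, c = 80.0, 100.0  # mm, ellipse semi-axes in x and z
        shell = 7.0  # mm bone shell
        half_y = 120.0
        half = np.array([a + 10, half_y, c + 10])
    else:  # thorax
        a, c = 160.0, 110.0
        shell = 5.0
        half_y = 150.0
        half = np.array([a + 10, half_y, c + 10])
    shape = np.ceil(2 * half / sp).astype(int) + 1
    origin = -(shape - 1) / 2.0 * sp
    x = origin[0] + np.arange(shape[0]) * sp[0]
    y = origin[1] + np.arange(shape[1]) * sp[1]
    z = origin[2] + np.arange(shape[2]) * sp[2]
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    body = (xx / a) ** 2 + (zz / c) ** 2 <= 1.0
    inner = (xx / (a - shell)) ** 2 + (zz / (c - shell)) ** 2 <= 1.0
    hu = np.full(tuple(shape), HU_AIR)
    hu[body] = HU_BONE
    hu[body & inner] = HU_WATER
    if spec.kind == "thorax":
        hu_lung = HU_AIR + (spec.lung_red / 1.0) * (HU_WATER - HU_AIR)  # linear segment
        for sx in (-1.0, 1.0):
            lung = ((xx - sx * 75.0) / 55.0) ** 2 + (yy / 90.0) ** 2 + (zz / 70.0) ** 2 <= 1.0
            hu[lung & inner] = hu_lung
    return CtVolume(hu=hu, spacing=tuple(sp), origin=tuple(origin))


def slab_radiological_depths(w: float, displacement: float, geom: BeamGeometry,
                             ) -> RadiologicalDepthMaps:
    """Closed-form depth maps for a laterally infinite water slab.

    The slab of thickness ``w`` cm is perpendicular to the central axis
    and displaced ``displacement`` cm toward the detector; each ray's
    path scales with its obliquity ``1/cos(theta)``.
    """
    if w < 0:
        raise ValueError("thickness must be >= 0")
    if w / 2.0 < abs(displacement) and w > 0:
        raise ValueError("displacement moves the isocenter plane outside the slab")
    yy, xx = geom.pixel_grid()
    inv_cos = np.sqrt(geom.sad ** 2 + xx ** 2 + yy ** 2) / geom.sad
    t_up = (w / 2.0 - displacement) * inv_cos
    t_down = (w / 2.0 + displacement) * inv_cos
    return RadiologicalDepthMaps(t_up=t_up, t_down=t_down, geom=geom)


def _field_halves(field) -> tuple[float, float]:
    if np.isscalar(field):
        return float(field) / 2.0, float(field) / 2.0
    lx, ly = field
    return float(lx) / 2.0, float(ly) / 2.0


def _field_profile(u, half, sigma):
    """Error-function aperture edge profile, ~1 deep inside the field."""
    s = np.sqrt(2.0) * sigma
    return 0.5 * (erf((half - u) / s) + erf((half + u) / s))


def _effective_square(field) -> float:
    hx, hy = _field_halves(field)
    lx, ly = 2 * hx, 2 * hy
    return 2.0 * lx * ly / (lx + ly)


def _resolve_depths(phantom, geom, depths):
    if depths is not None:
        return depths
    if phantom is None:
        raise ValueError("either a phantom CT or precomputed depth maps are required")
    return trace_radiological_depths(phantom, geom)


def simulate_epid_image(phantom: CtVolume | None, geom: BeamGeometry, field,
                        model: SyntheticBeamModel, seed: int | None = None,
                        depths: RadiologicalDepthMaps | None = None) -> EpidImage:
    """Simulate an integrated transit portal image.

    ``field`` is a square side in cm or an ``(lx, ly)`` pair.  ``depths``
    may be passed to skip CT ray tracing (e.g. the closed-form slab
    maps).  Noise is multiplicative Gaussian, seeded and reproducible.
    """
    hx, hy = _field_halves(field)
    if 2 * hx > geom.iso_plane_width or 2 * hy > geom.iso_plane_height:
        raise ValueError("field larger than the imager's projected extent")
    dm = _resolve_depths(phantom, geom, depths)
    yy, xx = geom.pixel_grid()
    l_eff = _effective_square(field)
    s = (model.s0
         * np.exp(-model.mu_eff * dm.w)
         * model.horn_factor(np.hypot(xx, yy))
         * _field_profile(xx, hx, model.sigma_signal)
         * _field_profile(yy, hy, model.sigma_signal)
         * model.scatter_factor(dm.d, l_eff))
    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s * (1.0 + model.noise_sd * rng.standard_normal(s.shape))
    return EpidImage(pixels=np.clip(s, 0.0, None), geom=geom)


def simulate_tps_dose(phantom: CtVolume | None, geom: BeamGeometry, field,
                      model: SyntheticBeamModel,
                      depths: RadiologicalDepthMaps | None = None) -> DoseMap:
    """Simulate the planning-system dose map in the isocenter plane (noiseless).

    With ``model.lung_deficit > 0`` and a phantom CT, dose is reduced by
    that fraction wherever the ray crosses the isocenter plane in
    low-density (lung) tissue — emulating lateral electronic
    disequilibrium, which the signal model deliberately ignores.
    """
    hx, hy = _field_halves(field)
    if 2 * hx > geom.iso_plane_width or 2 * hy > geom.iso_plane_height:
        raise ValueError("field larger than the imager's projected extent")
    dm = _resolve_depths(phantom, geom, depths)
    yy, xx = geom.pixel_grid()
    l_eff = _effective_square(field)
    iso_depth = dm.w / 2.0 - dm.d
    dose = (model.d0
            * model.tmr(iso_depth, l_eff)
            * model.horn_factor(np.hypot(xx, yy))
            * _field_profile(xx, hx, model.sigma_dose)
            * _field_profile(yy, hy, model.sigma_dose))
    if model.lung_deficit > 0 and phantom is not None:
        red = phantom.red()
        x_hat, y_hat, _ = geom.beam_axes()
        iso = np.asarray(geom.isocenter, float)
        q = (iso[None, :]
             + 10.0 * xx.ravel()[:, None] * x_hat[None, :]
             + 10.0 * yy.ravel()[:, None] * y_hat[None, :])
        idx = np.round((q - np.asarray(phantom.origin)) / np.asarray(phantom.spacing)).astype(int)
        valid = np.all((idx >= 0) & (idx < np.array(red.shape)), axis=1)
        local = np.ones(q.shape[0])
        local[valid] = red[idx[valid, 0], idx[valid, 1], idx[valid, 2]]
        in_lung = (local < LUNG_RED_THRESHOLD) & (local > 0.01)
        factor = np.where(in_lung, 1.0 - model.lung_deficit, 1.0).reshape(dose.shape)
        dose = dose * factor
    return DoseMap(dose=dose, geom=geom)


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form commissioning quantities implied by the generator."""

    fcax: Callable  # (w, l) -> a.u./cGy
    f: Callable  # (d, l) -> unitless
    k: Callable  # (x,) -> unitless, single-edge correction


def ground_truth(model: SyntheticBeamModel) -> GroundTruth:
    """True F_CAX, f and k implied by the generator's closed forms."""

    def fcax(w, l):
        return (model.s0 * np.exp(-model.mu_eff * np.asarray(w, float))
                / (model.d0 * model.tmr(np.asarray(w, float) / 2.0, l)))

    def f(d, l):
        return 1.0 / model.scatter_factor(d, l)

    def k(x):
        x = np.asarray(x, float)
        ps = 0.5 * (1.0 + erf(x / (np.sqrt(2.0) * model.sigma_signal)))
        pd = 0.5 * (1.0 + erf(x / (np.sqrt(2.0) * model.sigma_dose)))
        return ps / pd

    return GroundTruth(fcax=fcax, f=f, k=k)


# Commissioning measurement grids: slab thicknesses and square fields for
# F_CAX, field sizes and displacements for f (on the thickest slab), and
# the field sizes whose edge curves are extracted from the 12 cm slab.
FCAX_W_NODES = (6.0, 12.0, 16.0, 20.0, 26.0)
FCAX_L_NODES = (5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0)
F_L_NODES = (5.0, 10.0, 15.0, 20.0)
F_D_NODES = tuple(np.arange(-10.0, 10.0 + 1.25, 2.5))
EDGE_L_NODES = (5.0, 10.0, 15.0)
EDGE_W = 12.0
F_W = 26.0


def generate_commissioning_fixtures(model: SyntheticBeamModel, geom: BeamGeometry,
                                    seed: int = 0):
    """Simulate the full slab commissioning session.

    Returns ``(fcax_pairs, f_images, edge_pairs)`` in the layout
    :func:`epidose.commissioning.commission_from_fixtures` expects.  Each
    irradiation draws its noise from an independent child seed.
    """
    ss = np.random.SeedSequence(seed)

    def child():
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))

    fcax_pairs = {}
    for w in FCAX_W_NODES:
        dmaps = slab_radiological_depths(w, 0.0, geom)
        for l in FCAX_L_NODES:
            img = simulate_epid_image(None, geom, l, model, seed=child(), depths=dmaps)
            dose = simulate_tps_dose(None, geom, l, model, depths=dmaps)
            fcax_pairs[(w, l)] = (img, dose)

    f_images = {}
    for d in F_D_NODES:
        dmaps = slab_radiological_depths(F_W, d, geom)
        for l in F_L_NODES:
            f_images[(float(d), l)] = simulate_epid_image(
                None, geom, l, model, seed=child(), depths=dmaps)

    edge_pairs = {}
    dmaps = slab_radiological_depths(EDGE_W, 0.0, geom)
    for l in EDGE_L_NODES:
        img = simulate_epid_image(None, geom, l, model, seed=child(), depths=dmaps)
        dose = simulate_tps_dose(None, geom, l, model, depths=dmaps)
        edge_pairs[l] = (img, dose)
    return fcax_pairs, f_images, edge_pairs


def make_tmr_table(model: SyntheticBeamModel,
                   depths=None, field_sizes=None) -> TmrTable:
    """Tabulate the generator's TMR model as a lookup table."""
    if depths is None:
        depths = np.arange(0.0, 30.0 + 0.125, 0.25)
    if field_sizes is None:
        field_sizes = np.arange(4.0, 24.0 + 1.0, 2.0)
    depths = np.asarray(depths, float)
    field_sizes = np.asarray(field_sizes, float)
    zz, ll = np.meshgrid(depths, field_sizes, indexing="ij")
    return TmrTable(depths=depths, field_sizes=field_sizes, values=model.tmr(zz, ll))


def noise_free(model: SyntheticBeamModel) -> SyntheticBeamModel:
    """A copy of ``model`` with the imager noise switched off."""
    return replace(model, noise_sd=0.0)
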