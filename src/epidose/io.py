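"""Readers and writers for the formats the pipeline touches.

DICOM CT series, planar DICOM RT Dose, DICOM RT Image, 16-bit TIFF cine
stacks, CSV grids (images, dose maps, TMR tables, HU calibrations), the
YAML commissioning manifest and run configuration, and the JSON
commissioning-table container.  All lengths in configs and CSV outputs
are cm; DICOM's native mm is converted at the boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pydicom
import tifffile
import yaml
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .commissioning import CommissioningTable, DoseMap, EpidImage, commission_from_fixtures
from .geometry import BeamGeometry, CtVolume, DEFAULT_HU_CALIBRATION
from .reconstruction import TmrTable

__all__ = [
    "RunConfig",
    "sum_cine_frames",
    "read_ct_series",
    "write_ct_series",
    "read_planar_dose",
    "write_planar_dose",
    "read_epid",
    "write_epid_tiff",
    "write_rt_image",
    "read_array_csv",
    "write_array_csv",
    "load_tmr",
    "write_tmr",
    "load_hu_calibration",
    "write_hu_calibration",
    "load_config",
    "config_hash",
    "run_commissioning",
]

log = logging.getLogger("epidose")

CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
RTIMAGE_SOP = "1.2.840.10008.5.1.4.1.1.481.1"


def sum_cine_frames(frames: Sequence[np.ndarray], geom: BeamGeometry) -> EpidImage:
    """Sum separately exported cine frames into one integrated image."""
    if len(frames) == 0:
        raise ValueError("no cine frames to sum")
    shapes = {np.asarray(f).shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"cine frames disagree in shape: {sorted(shapes)}")
    total = np.sum([np.asarray(f, float) for f in frames], axis=0)
    return EpidImage(pixels=total, geom=geom, n_frames=len(frames))


# -- CSV grids ----------------------------------------------------------

def write_array_csv(path, arr: np.ndarray) -> None:
    """Plain CSV grid at full float precision (%.17g round-trips float64)."""
    np.savetxt(path, np.asarray(arr, float), delimiter=",", fmt="%.17g")


def read_array_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


# -- DICOM CT -----------------------------------------------------------

def _file_meta(sop_class: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_ct_series(ct: CtVolume, directory) -> list[Path]:
    """Write a CT volume as one axial DICOM slice per z index (HU as int16)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = ct.hu.shape
    sx, sy, sz = ct.spacing
    ox, oy, oz = ct.origin
    series_uid = generate_uid()
    paths = []
    for k in range(nz):
        meta = _file_meta(CT_SOP)
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CT_SOP
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [sy, sx]  # row spacing, column spacing
        ds.SliceThickness = sz
        ds.ImagePositionPatient = [ox, oy, oz + k * sz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        stored = np.round(ct.hu[:, :, k].T + 1024.0).astype(np.uint16)  # (y, x)
        ds.PixelData = stored.tobytes()
        p = directory / f"ct_{k:04d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths


def read_ct_series(directory, calibration=DEFAULT_HU_CALIBRATION) -> CtVolume:
    """Read an axial DICOM CT series, sorted by slice position.

    Applies rescale slope/intercept and checks for missing slices.
    """
    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise ValueError("duplicate slice positions in CT series")
        if np.max(dz) - np.min(dz) > 1e-3 * np.median(dz) + 1e-6:
            gap = int(np.argmax(dz))
            raise ValueError(
                f"missing CT slice between z={zs[gap]:.3f} and z={zs[gap + 1]:.3f} mm "
                f"(spacing jumps from {np.min(dz):.3f} to {np.max(dz):.3f} mm)"
            )
        sz = float(np.median(dz))
    else:
        sz = float(getattr(slices[0], "SliceThickness", 1.0))
    first = slices[0]
    sy, sx = (float(v) for v in first.PixelSpacing)
    hu_slices = []
    for s in slices:
        arr = s.pixel_array.astype(float)
        arr = arr * float(getattr(s, "RescaleSlope", 1.0)) + float(
            getattr(s, "RescaleIntercept", 0.0))
        hu_slices.append(arr)
    stack = np.stack(hu_slices)  # (z, y, x)
    hu = stack.transpose(2, 1, 0)  # (x, y, z)
    ox, oy = (float(v) for v in first.ImagePositionPatient[:2])
    oz = float(zs[0])
    return CtVolume(hu=hu, spacing=(sx, sy, sz), origin=(ox, oy, oz),
                    calibration=calibration)


# -- planar dose --------------------------------------------------------

def write_planar_dose(dose: DoseMap, path) -> None:
    """Planar dose as DICOM RT Dose (``.dcm``) or CSV, chosen by suffix.

    CSV writers add a JSON sidecar (same stem, ``.json``) with the beam
    geometry for provenance.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        meta = _file_meta(RTDOSE_SOP)
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = RTDOSE_SOP
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTDOSE"
        ds.DoseUnits = "CGY"
        ds.DoseSummationType = "PLAN"
        ds.Rows, ds.Columns = dose.dose.shape
        ds.PixelSpacing = [dose.geom.pitch_y * 10.0, dose.geom.pitch_x * 10.0]
        scale = float(dose.dose.max()) / (2 ** 32 - 1) if dose.dose.max() > 0 else 1.0
        ds.DoseGridScaling = scale
        ds.BitsAllocated = 32
        ds.BitsStored = 32
        ds.HighBit = 31
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = np.round(dose.dose / scale).astype(np.uint32).tobytes()
        ds.save_as(path, enforce_file_format=True)
    else:
        write_array_csv(path, dose.dose)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({
            "units": "cGy",
            "grid": "isocenter-plane ray lines, one point per EPID pixel",
            "geometry": _geom_dict(dose.geom),
        }, indent=2))


def read_planar_dose(path, geom: BeamGeometry | None = None) -> DoseMap:
    """Read a planar dose map from DICOM RT Dose or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        ds = pydicom.dcmread(path)
        if ds.SOPClassUID != RTDOSE_SOP:
            raise ValueError(f"{path} is not an RT Dose object")
        arr = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    else:
        arr = read_array_csv(path)
    if geom is None:
        geom = _geom_for_shape(arr.shape)
    return DoseMap(dose=arr, geom=geom)


# -- EPID images --------------------------------------------------------

def write_epid_tiff(frames: Sequence[np.ndarray], path) -> None:
    """Write cine frames as a 16-bit TIFF stack."""
    stack = np.stack([np.asarray(f) for f in frames]).astype(np.uint16)
    tifffile.imwrite(path, stack)


def write_rt_image(img: EpidImage, path) -> None:
    """Write an integrated portal image as DICOM RT Image (uint16 + rescale)."""
    meta = _file_meta(RTIMAGE_SOP)
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTIMAGE_SOP
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIMAGE"
    ds.Rows, ds.Columns = img.pixels.shape
    scale = float(img.pixels.max()) / 65535.0 if img.pixels.max() > 0 else 1.0
    ds.RescaleSlope = scale
    ds.RescaleIntercept = 0.0
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.round(img.pixels / scale).astype(np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_epid(path) -> list[np.ndarray]:
    """Read portal-image frames from DICOM RT Image, TIFF stack, or CSV.

    Returns a list of frame arrays (a single-frame list for integrated
    formats); sum with :func:`sum_cine_frames`.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcm":
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return [arr * slope + intercept]
    if suffix in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            return [stack.astype(float)]
        return [frame.astype(float) for frame in stack]
    if suffix == ".csv":
        return [read_array_csv(path)]
    raise ValueError(f"unknown EPID image format: {path}")


# -- tables -------------------------------------------------------------

def load_tmr(path) -> TmrTable:
    """TMR CSV: first column depth (cm), one column per field size (header)."""
    df = pd.read_csv(path)
    depths = df.iloc[:, 0].to_numpy(float)
    sizes = np.array([float(c) for c in df.columns[1:]])
    values = df.iloc[:, 1:].to_numpy(float)
    return TmrTable(depths=depths, field_sizes=sizes, values=values)


def write_tmr(table: TmrTable, path) -> None:
    df = pd.DataFrame(table.values, columns=[f"{s:g}" for s in table.field_sizes])
    df.insert(0, "depth_cm", table.depths)
    df.to_csv(path, index=False, float_format="%.10g")


def load_hu_calibration(path) -> tuple[tuple[float, float], ...]:
    """Two-column CSV ``HU,RED`` with a header row."""
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValueError("HU calibration CSV must have exactly two columns (HU, RED)")
    pairs = tuple((float(h), float(r)) for h, r in df.to_numpy(float))
    return pairs


def write_hu_calibration(calibration, path) -> None:
    pd.DataFrame(list(calibration), columns=["HU", "RED"]).to_csv(path, index=False)


# -- configuration ------------------------------------------------------

def _geom_dict(geom: BeamGeometry) -> dict:
    return {
        "sad": geom.sad, "sdd": geom.sdd,
        "gantry_angle": geom.gantry_angle, "collimator_angle": geom.collimator_angle,
        "isocenter": list(geom.isocenter),
        "n_rows": geom.n_rows, "n_cols": geom.n_cols,
        "iso_plane_height": geom.iso_plane_height, "iso_plane_width": geom.iso_plane_width,
    }


def geometry_from_dict(data: dict | None) -> BeamGeometry:
    data = dict(data or {})
    if "isocenter" in data:
        data["isocenter"] = tuple(data["isocenter"])
    return BeamGeometry(**data)


def _geom_for_shape(shape) -> BeamGeometry:
    """Default geometry, with the pixel grid adapted to a stored array.

    Non-default shapes keep the default projected pixel pitch.
    """
    default = BeamGeometry()
    if shape == (default.n_rows, default.n_cols):
        return default
    return BeamGeometry(
        n_rows=shape[0], n_cols=shape[1],
        iso_plane_height=shape[0] * default.pitch_y,
        iso_plane_width=shape[1] * default.pitch_x,
    )


@dataclass
class RunConfig:
    """Validated run configuration for the CLI pipeline."""

    geometry: BeamGeometry = field(default_factory=BeamGeometry)
    table_path: str | None = None
    tmr_path: str | None = None
    hu_calibration_path: str | None = None
    dd: float = 3.0
    dta: float = 3.0
    pass_threshold: float = 0.95
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.dd <= 10):
            raise ValueError("dd must lie in (0, 10] percent")
        if not (0 < self.dta <= 10):
            raise ValueError("dta must lie in (0, 10] mm")
        if not (0 < self.pass_threshold <= 1):
            raise ValueError("pass threshold must lie in (0, 1]")
        for p in (self.table_path, self.tmr_path, self.hu_calibration_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured file does not exist: {p}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    geom = geometry_from_dict(raw.get("geometry"))
    gamma = raw.get("gamma", {})
    cfg = RunConfig(
        geometry=geom,
        table_path=raw.get("commissioning_table"),
        tmr_path=raw.get("tmr_table"),
        hu_calibration_path=raw.get("hu_calibration"),
        dd=float(gamma.get("dd", 3.0)),
        dta=float(gamma.get("dta", 3.0)),
        pass_threshold=float(gamma.get("pass_threshold", 0.95)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    log.info("loaded config %s (hash %s)", path, config_hash(raw))
    return cfg


def config_hash(raw: dict) -> str:
    """Stable short hash of a configuration mapping."""
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


# -- commissioning manifest --------------------------------------------

def run_commissioning(manifest_path) -> CommissioningTable:
    """Build a commissioning table from a YAML session manifest.

    Manifest layout::

        geometry: {...}            # optional BeamGeometry overrides
        fcax:                      # centered slabs
          - {image: s.csv, dose: d.csv, w: 6.0, l: 5.0}
        f:                         # displacement series (d=0 included)
          - {image: s.csv, d: 0.0, l: 5.0}
        edges:                     # edge-curve pairs (12 cm slab)
          - {image: s.csv, dose: d.csv, l: 5.0}

    Paths are resolved relative to the manifest file.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    geom = geometry_from_dict(manifest.get("geometry"))

    def load_image(rel):
        frames = read_epid(base / rel)
        return sum_cine_frames(frames, geom)

    def load_dose(rel):
        return read_planar_dose(base / rel, geom=geom)

    fcax_pairs = {
        (float(e["w"]), float(e["l"])): (load_image(e["image"]), load_dose(e["dose"]))
        for e in manifest.get("fcax", [])
    }
    f_images = {
        (float(e["d"]), float(e["l"])): load_image(e["image"])
        for e in manifest.get("f", [])
    }
    edge_pairs = {
        float(e["l"]): (load_image(e["image"]), load_dose(e["dose"]))
        for e in manifest.get("edges", [])
    }
    if not fcax_pairs or not f_images or not edge_pairs:
        raise ValueError("manifest must list fcax, f and edges sections")
    log.info("commissioning from %s: %d F_CAX, %d f, %d edge irradiations",
             manifest_path, len(fcax_pairs), len(f_images), len(edge_pairs))
    return commission_from_fixtures(fcax_pairs, f_images, edge_pairs)
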