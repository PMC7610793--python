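"""Readers and writers: GIFTI/OFF surfaces, NIfTI volumes, HDF5 models.

GIFTI is the canonical surface dialect; plain-text OFF is kept as a
dependency-free fixture format.  Vector (V1-style) volumes follow the
FSL convention of storing components along the voxel axes: they are
rotated into world (mm) axes via the normalised rotation part of the
affine on load, and back on write.

Every artefact written here embeds the package version and, when
supplied, a configuration hash so re-runs can be matched to their
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import trimesh as _trimesh
import yaml

from . import __version__
from .field_model import ChargeSet, DipoleGrid, VectorFieldModel
from .surface_geometry import MaskVolume, ScalarVolume, TriangleMesh, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "read_surface",
    "write_surface",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_vector_volume",
    "write_vector_volume",
    "save_model",
    "load_model",
    "config_hash",
    "load_config",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# surfaces


def read_surface(path) -> TriangleMesh:
    """Read a triangulated surface from GIFTI (.gii) or OFF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".off":
        tm = _trimesh.load(str(path), file_type="off", process=False)
        return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    img = nib.load(str(path))
    if not isinstance(img, nib.gifti.GiftiImage):
        raise ValueError(f"{path}: not a GIFTI surface")
    points = faces = None
    for da in img.darrays:
        code = nib.nifti1.intent_codes.label[da.intent]
        if code == "pointset":
            points = da.data
        elif code == "triangle":
            faces = da.data
    if points is None or faces is None:
        raise ValueError(f"{path}: GIFTI file lacks a pointset or triangle array")
    return TriangleMesh(np.asarray(points, dtype=np.float64), np.asarray(faces))


def write_surface(mesh: TriangleMesh, path, meta: dict | None = None) -> None:
    """Write a surface as GIFTI (.gii) or OFF, by extension."""
    path = Path(path)
    if path.suffix == ".off":
        tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        path.write_text(_trimesh.exchange.off.export_off(tm))
        return
    md = {"package": f"gyralfield {__version__}"}
    md.update({str(k): str(v) for k, v in (meta or {}).items()})
    img = nib.gifti.GiftiImage(meta=nib.gifti.GiftiMetaData(md))
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# volumes


def _descrip(meta: dict | None) -> bytes:
    tag = f"gyralfield {__version__}"
    if meta and "config_hash" in meta:
        tag += f" cfg={meta['config_hash']}"
    return tag.encode()[:79]


def write_volume(volume, path, meta: dict | None = None) -> None:
    """Write a ScalarVolume (float32) or MaskVolume (uint8) as NIfTI-1."""
    if isinstance(volume, MaskVolume):
        data = volume.values.astype(np.uint8)
    elif isinstance(volume, ScalarVolume):
        data = volume.values.astype(np.float32)
    else:
        raise TypeError("expected ScalarVolume or MaskVolume")
    img = nib.Nifti1Image(data, volume.grid.affine)
    img.header["descrip"] = _descrip(meta)
    nib.save(img, str(path))


def read_volume(path) -> ScalarVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = VoxelGrid(img.shape[:3], img.affine)
    return ScalarVolume(grid, np.asarray(img.dataobj, dtype=np.float64))


def read_mask(path) -> MaskVolume:
    vol = read_volume(path)
    vals = vol.values
    uniq = np.unique(vals)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError(f"{path}: mask volume is not binary (values {uniq[:5]})")
    return MaskVolume(vol.grid, vals > 0.5)


def _rotation_unit(affine: np.ndarray) -> np.ndarray:
    r = affine[:3, :3]
    return r / np.linalg.norm(r, axis=0, keepdims=True)


def read_vector_volume(path, mask: MaskVolume | None = None) -> np.ndarray:
    """Load a V1-style 4D vector volume; components stored along voxel
    axes are rotated into world axes.  Within the mask, non-unit vectors
    are renormalised with a warning; zero vectors are rejected."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(f"{path}: vector volume must be 4D with last dimension 3")
    r = _rotation_unit(img.affine)
    world = data @ r.T
    if mask is not None:
        vecs = world[mask.values]
        norms = np.linalg.norm(vecs, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError(f"{path}: zero orientation vectors inside the mask")
        if not np.allclose(norms, 1.0, atol=1e-4):
            warnings.warn(f"{path}: non-unit V1 vectors renormalised", stacklevel=2)
        world[mask.values] = vecs / norms[:, None]
    return world


def write_vector_volume(data: np.ndarray, grid: VoxelGrid, path, meta: dict | None = None) -> None:
    """Write world-axis vectors as an FSL-convention (voxel-axis) 4D NIfTI."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError("vector volume must be 4D with last dimension 3")
    r = _rotation_unit(grid.affine)
    voxel_axes = data @ np.linalg.inv(r).T
    img = nib.Nifti1Image(voxel_axes.astype(np.float32), grid.affine)
    img.header["descrip"] = _descrip(meta)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# model container


def save_model(model: VectorFieldModel, path, meta: dict | None = None, sidecar: bool = True) -> None:
    """Serialise a model to HDF5 (bit-exact round trip) plus a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "gyralfield-model"
        f.attrs["version"] = __version__
        for k, v in (meta or {}).items():
            f.attrs[str(k)] = v
        g = f.create_group("charges")
        g.create_dataset("positions", data=model.charges.positions)
        g.create_dataset("charges", data=model.charges.charges)
        grids = f.create_group("grids")
        for i, grid in enumerate(model.grids):
            gg = grids.create_group(str(i))
            gg.attrs["extent"] = float(grid.extent)
            gg.create_dataset("control_points", data=grid.control_points)
            gg.create_dataset("weights", data=grid.weights)
    if sidecar:
        side = {
            "format": "gyralfield-model",
            "version": __version__,
            "n_charges": int(len(model.charges.charges)),
            "total_flux": model.charges.total_flux,
            "grids": [
                {"extent": float(g.extent), "n_control_points": int(g.n_points)}
                for g in model.grids
            ],
        }
        side.update({str(k): v for k, v in (meta or {}).items()})
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=2))


def load_model(path) -> VectorFieldModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "gyralfield-model":
            raise ValueError(f"{path}: not a gyralfield model container")
        charges = ChargeSet(f["charges/positions"][()], f["charges/charges"][()])
        grids = []
        for key in sorted(f["grids"], key=int):
            gg = f["grids"][key]
            grids.append(
                DipoleGrid(gg["control_points"][()], float(gg.attrs["extent"]), gg["weights"][()])
            )
    return VectorFieldModel(charges, grids)


# ---------------------------------------------------------------------------
# configuration


_CONFIG_KEYS = {
    "threshold", "coarse", "fine", "lambda_radial", "lambda_dti", "lambda_l2",
    "ndir", "max_length", "step", "max_iterations", "seed", "smooth_iterations",
    "smooth_alpha", "total_flux", "mid_surface_weight",
}


def load_config(path) -> dict:
    """YAML run configuration; unknown keys are rejected."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg
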