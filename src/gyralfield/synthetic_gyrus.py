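"""Synthetic folded-cortex phantom with known ground-truth fields.

A single gyral blade at human-like scale: the white/grey boundary is a
sinusoidal sheet ``z = A cos(2 pi x / wavelength)`` extruded along y,
with the crown at x = 0 and the sulcal fundi at the domain edges; the
pial surface is the exact normal offset of the white sheet by the
cortical thickness; white matter is everything below the sheet down to a
configurable depth.  Ground-truth divergence-free fields (charges plus
one seeded dipole grid) and noisy, sign-ambiguous orientation samples
make every stage of the pipeline testable without any data download.

Near the sulcal fundi the exact normal offset can locally fold over
(offset distance exceeding the fold radius) while still remaining
outside the white matter — the same situation as abutting pial banks in
real sulci.  ``make_gyrus`` errors only if the pial actually penetrates
the white matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .field_model import (
    DipoleGrid,
    VectorFieldModel,
    build_surface_charges,
    eval_charge_field,
    eval_field,
    grid_field,
    place_hex_grid,
)
from .surface_geometry import (
    CorticalRibbon,
    MaskVolume,
    TriangleMesh,
    VoxelGrid,
    deep_anchor_point,
)

logger = logging.getLogger(__name__)

__all__ = ["GyrusSpec", "make_gyrus", "make_ground_truth_field", "sample_orientations"]


@dataclass
class GyrusSpec:
    """Parameters of the synthetic gyral blade.

    Defaults give one full human-scale blade: 16 mm fold wavelength,
    8 mm amplitude, 2.5 mm cortical thickness, 12 mm extrusion, 1 mm
    voxels, 0.5 mm mesh spacing.
    """

    wavelength: float = 16.0  # mm, fold wavelength
    amplitude: float = 8.0  # mm, fold amplitude (0 -> flat slab)
    thickness: float = 2.5  # mm, cortical (white-to-pial) thickness
    extrusion: float = 12.0  # mm, extent along the fold axis (y)
    depth: float = 6.0  # mm of deep white matter below the fundus
    voxel_size: float = 1.0  # mm
    mesh_spacing: float = 0.5  # mm, approximate mesh edge length
    margin: float = 3.0  # mm of grid padding around the blade
    seed: int = 0

    def __post_init__(self):
        for name in ("wavelength", "thickness", "extrusion", "depth", "voxel_size", "mesh_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.amplitude > 0:
            if self.amplitude >= self.wavelength:
                raise ValueError("amplitude must be below the wavelength")
            if self.thickness >= self.amplitude:
                raise ValueError("cortical thickness must be below the fold amplitude")


def _white_height(spec: GyrusSpec, x):
    """Height of the white/grey boundary; continues at the fundus level
    (-amplitude) beyond the single-blade domain."""
    x = np.clip(np.asarray(x, dtype=np.float64), -spec.wavelength / 2, spec.wavelength / 2)
    return spec.amplitude * np.cos(2.0 * np.pi * x / spec.wavelength)


def _sheet_normals(spec: GyrusSpec, x):
    """Analytic outward (upward) unit normals of the white sheet."""
    slope = -spec.amplitude * (2.0 * np.pi / spec.wavelength) * np.sin(
        2.0 * np.pi * np.asarray(x, dtype=np.float64) / spec.wavelength
    )
    n = np.column_stack([-slope, np.zeros_like(slope), np.ones_like(slope)])
    return n / np.linalg.norm(n, axis=1)[:, None]


def _sheet_mesh(spec: GyrusSpec) -> TriangleMesh:
    nx = max(int(round(spec.wavelength / spec.mesh_spacing)), 4) + 1
    ny = max(int(round(spec.extrusion / spec.mesh_spacing)), 4) + 1
    x = np.linspace(-spec.wavelength / 2, spec.wavelength / 2, nx)
    y = np.linspace(0.0, spec.extrusion, ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    zz = spec.amplitude * np.cos(2.0 * np.pi * xx / spec.wavelength)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v01 = v00 + 1
            v10 = v00 + ny
            v11 = v10 + 1
            # counter-clockwise seen from +z so normals point out of the WM
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    return TriangleMesh(verts, np.array(faces))


def make_gyrus(spec: GyrusSpec | None = None) -> tuple[CorticalRibbon, VoxelGrid, MaskVolume]:
    """Build the synthetic gyral blade: ribbon, voxel grid and WM mask."""
    spec = spec or GyrusSpec()
    white = _sheet_mesh(spec)
    normals = _sheet_normals(spec, white.vertices[:, 0])
    pial_verts = white.vertices + spec.thickness * normals
    # pial must stay outside the white matter (strictly above the boundary)
    if np.any(pial_verts[:, 2] < _white_height(spec, pial_verts[:, 0]) - 1e-9):
        raise ValueError("pial surface self-intersects the white matter "
                         "(cortical thickness too large for the fold curvature)")
    pial = TriangleMesh(pial_verts, white.faces.copy())
    ribbon = CorticalRibbon(white, pial)

    vx = spec.voxel_size
    lo = np.array([-spec.wavelength / 2 - spec.margin, -spec.margin,
                   -spec.amplitude - spec.depth])
    hi = np.array([spec.wavelength / 2 + spec.margin, spec.extrusion + spec.margin,
                   spec.amplitude + spec.thickness + spec.margin])
    shape = tuple(np.ceil((hi - lo) / vx).astype(int) + 1)
    affine = np.diag([vx, vx, vx, 1.0])
    affine[:3, 3] = lo
    grid = VoxelGrid(shape, affine)
    centres = grid.all_voxel_centres().reshape(-1, 3)
    wm = centres[:, 2] < _white_height(spec, centres[:, 0]) - 1e-9
    wm_mask = MaskVolume(grid, wm.reshape(shape))
    return ribbon, grid, wm_mask


def make_ground_truth_field(
    ribbon: CorticalRibbon,
    gyral_mask: MaskVolume,
    deep_mask: MaskVolume,
    n_dipoles: int = 50,
    seed: int = 0,
    extent: float = 10.0,
) -> VectorFieldModel:
    """Known divergence-free recovery target: pial charges plus one dipole
    grid with seeded random weights, scaled so the median dipole
    contribution stays below the median charge-field magnitude."""
    rng = np.random.default_rng(seed)
    total_flux = ribbon.total_volume
    anchor = deep_anchor_point(deep_mask)
    charges = build_surface_charges(ribbon.pial, ribbon.triangle_volumes, anchor, total_flux)
    cps = place_hex_grid(gyral_mask, extent)
    if n_dipoles and n_dipoles < len(cps):
        keep = rng.choice(len(cps), size=n_dipoles, replace=False)
        cps = cps[np.sort(keep)]
    grid = DipoleGrid(cps, extent, rng.standard_normal((len(cps), 3)))
    pts = gyral_mask.voxel_centres()
    charge_med = float(np.median(np.linalg.norm(eval_charge_field(charges, pts), axis=1)))
    dip = grid_field(pts, grid)
    dip_med = float(np.median(np.linalg.norm(dip, axis=1)))
    if dip_med > 0:
        grid.weights *= 0.5 * charge_med / dip_med
    return VectorFieldModel(charges, [grid])


def sample_orientations(
    model: VectorFieldModel,
    grid: VoxelGrid,
    gyral_mask: MaskVolume,
    angular_noise_deg: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Sign-ambiguous orientation volume emulating a DTI V1 map.

    Per gyral voxel, the field direction is rotated by a folded-normal
    angle (scaled so its *mean* equals ``angular_noise_deg``) about a
    uniformly random perpendicular axis, then multiplied by a random
    sign.  Voxels outside the mask are zero-filled.  Returns a 4D array
    (x, y, z, 3).
    """
    if angular_noise_deg < 0:
        raise ValueError("angular noise must be non-negative")
    rng = np.random.default_rng(seed)
    pts = gyral_mask.voxel_centres()
    f = eval_field(model, pts)
    v = f / np.linalg.norm(f, axis=1)[:, None]
    n = len(pts)
    if angular_noise_deg > 0:
        # folded normal scaled to unit mean: E|N(0,1)| = sqrt(2/pi)
        theta = np.deg2rad(angular_noise_deg) * np.abs(rng.standard_normal(n)) * np.sqrt(np.pi / 2)
        # random unit axis perpendicular to v
        raw = rng.standard_normal((n, 3))
        raw -= np.einsum("ij,ij->i", raw, v)[:, None] * v
        nrm = np.linalg.norm(raw, axis=1)
        small = nrm < 1e-12
        if np.any(small):  # pathological draw: retry deterministically
            raw[small] = np.cross(v[small], [1.0, 0.5, 0.25])
            nrm = np.linalg.norm(raw, axis=1)
        axis = raw / nrm[:, None]
        v = v * np.cos(theta)[:, None] + np.cross(axis, v) * np.sin(theta)[:, None]
    signs = rng.choice([-1.0, 1.0], size=n)
    v = v * signs[:, None]
    out = np.zeros(grid.shape + (3,))
    out[gyral_mask.values] = v
    return out
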