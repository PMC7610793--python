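"""Mesh and voxel geometry for gyral white matter.

All meshes and fields live in world (mm) coordinates; volumes carry a
voxel-index -> mm affine with voxel centres at integer 0-based indices.
Surface normals follow the convention that they point *outward*, i.e.
away from white matter (from white matter into grey matter for the
white/grey boundary).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._raycast import bidirectional_ray_distances

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "CorticalRibbon",
    "VoxelGrid",
    "ScalarVolume",
    "MaskVolume",
    "hemisphere_directions",
    "compute_gyral_thickness",
    "threshold_gyral_mask",
    "deep_mask_from_gyral",
    "triangle_cortical_volumes",
    "mid_surface",
    "triangle_normals_areas",
    "vertex_normals",
    "deep_anchor_point",
]


@dataclass
class TriangleMesh:
    """Triangulated surface in mm coordinates.

    Face winding is consistent so that computed normals point outward
    (away from white matter for cortical surfaces).
    """

    vertices: np.ndarray  # (V, 3) float64
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("faces with repeated vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        return v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]

    def face_centres(self) -> np.ndarray:
        a, b, c = self.face_corners()
        return (a + b + c) / 3.0


@dataclass
class VoxelGrid:
    """Regular voxel grid: shape plus a voxel-index -> mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # (4, 4)

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError("shape must be 3 positive integers")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def all_voxel_centres(self) -> np.ndarray:
        idx = np.stack(np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1)
        return self.voxel_to_world(idx.reshape(-1, 3)).reshape(*self.shape, 3)


@dataclass
class ScalarVolume:
    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")


@dataclass
class MaskVolume:
    grid: VoxelGrid
    values: np.ndarray  # boolean

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def voxel_centres(self) -> np.ndarray:
        """World coordinates of the centres of the masked voxels."""
        ijk = np.argwhere(self.values)
        return self.grid.voxel_to_world(ijk)


@dataclass
class CorticalRibbon:
    """Paired white/pial meshes in 1:1 vertex correspondence.

    The mid surface and per-triangle cortical volumes are derived on
    construction.
    """

    white: TriangleMesh
    pial: TriangleMesh
    mid: TriangleMesh = field(init=False)
    triangle_volumes: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.white.n_vertices != self.pial.n_vertices:
            raise ValueError("white/pial vertex counts differ")
        if not np.array_equal(self.white.faces, self.pial.faces):
            raise ValueError("white/pial face arrays differ")
        self.mid = mid_surface_from_pair(self.white, self.pial)
        self.triangle_volumes = triangle_cortical_volumes(self)

    @property
    def total_volume(self) -> float:
        return float(self.triangle_volumes.sum())


# ---------------------------------------------------------------------------
# gyral thickness


def hemisphere_directions(n: int) -> np.ndarray:
    """Evenly distributed unit directions on the upper hemisphere.

    Golden-angle azimuth combined with a base-2 radical-inverse sequence
    for the z-coordinate.  The sequence is prefix-stable: the first ``n``
    directions of ``hemisphere_directions(2 * n)`` equal
    ``hemisphere_directions(n)``, so refining the sampling can only
    tighten a minimum taken over directions.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    i = np.arange(n, dtype=np.uint64)
    # base-2 radical inverse (van der Corput) in [0, 1)
    z = np.zeros(n)
    denom = 2.0
    val = i.copy()
    while np.any(val):
        z += (val % 2) / denom
        val //= 2
        denom *= 2.0
    z = np.clip(z, 0.0, 1.0 - 1e-12)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n)
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def compute_gyral_thickness(
    white: TriangleMesh,
    grid: VoxelGrid,
    wm_mask: MaskVolume,
    n_directions: int = 64,
    max_length: float = 50.0,
) -> ScalarVolume:
    """Per-voxel gyral thickness within the white-matter mask.

    For each WM voxel, the thickness is the minimum over sampled
    directions of the summed distances to the first white/grey-boundary
    intersection on *both* sides of the voxel along the direction.
    Voxels with no two-sided hit within ``max_length`` in any direction
    are assigned ``max_length`` (treated as deep).  Non-WM voxels are
    NaN.
    """
    if wm_mask.n_voxels == 0:
        raise ValueError("empty white-matter mask")
    if n_directions <= 0 or max_length <= 0:
        raise ValueError("n_directions and max_length must be positive")
    dirs = hemisphere_directions(n_directions)
    origins = wm_mask.voxel_centres()
    a, b, c = white.face_corners()
    t_fwd, t_bwd = bidirectional_ray_distances(origins, dirs, a, b, c, max_length)
    both = (t_fwd <= max_length) & (t_bwd <= max_length)
    total = np.where(both, t_fwd + t_bwd, np.inf)
    thick = total.min(axis=1)
    thick = np.minimum(thick, max_length)
    out = np.full(grid.shape, np.nan)
    out[wm_mask.values] = thick
    return ScalarVolume(grid, out)


def threshold_gyral_mask(
    thickness: ScalarVolume, wm_mask: MaskVolume, threshold: float = 10.0
) -> MaskVolume:
    """WM voxels with gyral thickness below ``threshold`` (the gyral blades)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    vals = np.where(wm_mask.values, thickness.values, np.nan)
    with np.errstate(invalid="ignore"):
        gyral = wm_mask.values & (vals < threshold)
    return MaskVolume(thickness.grid, gyral)


def deep_mask_from_gyral(wm_mask: MaskVolume, gyral: MaskVolume) -> MaskVolume:
    """Complement of the gyral mask within white matter."""
    return MaskVolume(wm_mask.grid, wm_mask.values & ~gyral.values)


# ---------------------------------------------------------------------------
# ribbon geometry


def _tet_volume(a, b, c, d) -> np.ndarray:
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def triangle_cortical_volumes(ribbon: CorticalRibbon) -> np.ndarray:
    """Cortical volume (mm^3) of the wedge spanned by each white/pial triangle pair.

    Each wedge is split into three tetrahedra in a fixed order
    (v0w,v1w,v2w,v0p / v1w,v2w,v0p,v1p / v2w,v0p,v1p,v2p); the volume is
    the sum of the absolute tetrahedron volumes.  Inverted wedges (pial
    locally inside white) therefore still contribute positive volume; a
    warning reports their count.
    """
    w0, w1, w2 = ribbon.white.face_corners()
    p0, p1, p2 = ribbon.pial.face_corners()
    tets = np.stack([
        _tet_volume(w0, w1, w2, p0),
        _tet_volume(w1, w2, p0, p1),
        _tet_volume(w2, p0, p1, p2),
    ])
    # a wedge is inverted when its tetrahedra disagree in sign
    has_pos = np.any(tets > 1e-12, axis=0)
    has_neg = np.any(tets < -1e-12, axis=0)
    inverted = int(np.sum(has_pos & has_neg))
    if inverted:
        warnings.warn(f"{inverted} inverted wedge(s); absolute volumes used", stacklevel=2)
    return np.abs(tets).sum(axis=0)


def mid_surface_from_pair(white: TriangleMesh, pial: TriangleMesh) -> TriangleMesh:
    if white.n_vertices != pial.n_vertices:
        raise ValueError("white/pial vertex counts differ")
    return TriangleMesh((white.vertices + pial.vertices) / 2.0, white.faces.copy())


def mid_surface(ribbon: CorticalRibbon) -> TriangleMesh:
    """Mesh halfway between the white/grey boundary and the pial surface."""
    return mid_surface_from_pair(ribbon.white, ribbon.pial)


def triangle_normals_areas(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Unit face normals (from winding) and face areas (mm^2)."""
    a, b, c = mesh.face_corners()
    cr = np.cross(b - a, c - a)
    nrm = np.linalg.norm(cr, axis=1)
    bad = np.nonzero(nrm < 1e-14)[0]
    if bad.size:
        raise ValueError(f"zero-area face(s): {bad[:10].tolist()}")
    return cr / nrm[:, None], nrm / 2.0


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted unit vertex normals."""
    a, b, c = mesh.face_corners()
    cr = np.cross(b - a, c - a)  # area-weighted face normals
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], cr)
    nrm = np.linalg.norm(vn, axis=1)
    nrm[nrm < 1e-14] = 1.0
    return vn / nrm[:, None]


def deep_anchor_point(deep_mask: MaskVolume) -> np.ndarray:
    """Centre of the deep white matter: centroid of deep voxels, snapped
    to the nearest deep voxel centre if the centroid falls outside the mask."""
    if deep_mask.n_voxels == 0:
        raise ValueError("empty deep mask")
    centres = deep_mask.voxel_centres()
    centroid = centres.mean(axis=0)
    ijk = np.round(deep_mask.grid.world_to_voxel(centroid)).astype(int)[0]
    inside = (
        np.all(ijk >= 0)
        and np.all(ijk < np.array(deep_mask.grid.shape))
        and deep_mask.values[tuple(ijk)]
    )
    if inside:
        return centroid
    d = np.linalg.norm(centres - centroid, axis=1)
    return centres[int(np.argmin(d))]
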