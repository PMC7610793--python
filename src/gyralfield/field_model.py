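"""Continuous divergence-free vector field for gyral white matter.

The field is the superposition of

* an electrostatic-like *charge field*: negative point charges at the
  pial triangle centres (proportional to the cortical volume each
  triangle represents) balanced by a single positive charge in the deep
  white matter, and
* linear combinations of compactly supported, divergence-free
  *dipole-like basis fields* centred on hexagonal close-packing lattices.

Each dipole basis is built from the matrix-valued operator
``(-lap I + grad div)`` applied to a Wendland C4 radial basis function
``g(r) = (1-r)^6 (35 r^2 + 18 r + 3)`` (r = |x-y|/s, zero for r > 1).
Because every column of that operator applied to a smooth scalar is
divergence-free, the modelled field has zero divergence everywhere
except at the point charges, which guarantees streamlines do not
terminate inside white matter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .surface_geometry import MaskVolume, TriangleMesh, triangle_normals_areas

logger = logging.getLogger(__name__)

CHARGE_EXCLUSION_MM = 1e-6  # evaluation closer than this to a charge is an error

__all__ = [
    "ChargeSet",
    "DipoleGrid",
    "SparseBasisMap",
    "VectorFieldModel",
    "build_surface_charges",
    "eval_charge_field",
    "wendland_c4",
    "wendland_c4_derivative",
    "dipole_basis_columns",
    "place_hex_grid",
    "build_sparse_map",
    "grid_field",
    "eval_field",
    "eval_divergence_numeric",
    "surface_flux",
]


# ---------------------------------------------------------------------------
# Wendland C4 radial basis function


def wendland_c4(r):
    """Wendland C4 compactly supported RBF: ``(1-r)^6 (35 r^2 + 18 r + 3)``.

    Zero for r > 1; four times continuously differentiable at r = 0 and
    r = 1 in three dimensions, so fields built from its second
    derivatives are continuous with continuous first derivatives.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    out = (1.0 - r) ** 6 * (35.0 * r**2 + 18.0 * r + 3.0)
    return np.where(r <= 1.0, out, 0.0)


def wendland_c4_derivative(r, order: int = 1):
    """Closed-form radial derivatives of the Wendland C4 function (order 1-4)."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    if order == 1:
        out = -56.0 * r * (1.0 - r) ** 5 * (5.0 * r + 1.0)
    elif order == 2:
        out = -56.0 * (1.0 - r) ** 4 * (1.0 + 4.0 * r - 35.0 * r**2)
    elif order == 3:
        out = -1680.0 * r * (1.0 - r) ** 3 * (7.0 * r - 3.0)
    elif order == 4:
        out = -1680.0 * (1.0 - r) ** 2 * (-35.0 * r**2 + 26.0 * r - 3.0)
    else:
        raise ValueError("order must be 1..4")
    return np.where(r <= 1.0, out, 0.0)


def _wendland_d1_over_r(r):
    """g'(r)/r with its finite r->0 limit (= g''(0) = -56), in closed form."""
    out = -56.0 * (1.0 - r) ** 5 * (5.0 * r + 1.0)
    return np.where(r <= 1.0, out, 0.0)


# ---------------------------------------------------------------------------
# charges


@dataclass
class ChargeSet:
    """Point charges generating the initial field (streamline-count units).

    Exactly one positive charge (deep white matter anchor); negative
    charges sit at pial triangle centres; charges sum to zero.
    """

    positions: np.ndarray  # (C, 3)
    charges: np.ndarray  # (C,)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.charges = np.asarray(self.charges, dtype=np.float64)
        if self.positions.shape != (len(self.charges), 3):
            raise ValueError("positions/charges shape mismatch")
        pos = self.charges > 0
        if pos.sum() != 1:
            raise ValueError("exactly one positive charge required")
        total = float(np.abs(self.charges).sum())
        if total > 0 and abs(float(self.charges.sum())) > 1e-9 * total:
            raise ValueError("charges must sum to zero")

    @property
    def total_flux(self) -> float:
        return float(self.charges[self.charges > 0][0])

    @property
    def anchor(self) -> np.ndarray:
        return self.positions[np.argmax(self.charges)]


def build_surface_charges(
    pial: TriangleMesh,
    triangle_volumes: np.ndarray,
    anchor: np.ndarray,
    total_flux: float,
) -> ChargeSet:
    """Negative charges at pial triangle centres proportional to the cortical
    volume each triangle represents, balanced by ``+total_flux`` at ``anchor``."""
    if total_flux <= 0:
        raise ValueError("total_flux must be positive")
    vols = np.asarray(triangle_volumes, dtype=np.float64)
    if np.any(vols < 0) or vols.sum() <= 0:
        raise ValueError("triangle volumes must be non-negative with positive sum")
    q_neg = -total_flux * vols / vols.sum()
    positions = np.vstack([pial.face_centres(), np.asarray(anchor, dtype=np.float64)])
    charges = np.concatenate([q_neg, [total_flux]])
    return ChargeSet(positions, charges)


def eval_charge_field(charges: ChargeSet, points: np.ndarray) -> np.ndarray:
    """Superposition field sum_i q_i (x - p_i) / (4 pi |x - p_i|^3)."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = np.zeros_like(points)
    # chunk over points to bound the (points x charges) temporary
    chunk = max(1, int(4e6 // max(len(charges.charges), 1)))
    for lo in range(0, len(points), chunk):
        p = points[lo : lo + chunk]
        diff = p[:, None, :] - charges.positions[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        if np.any(d < CHARGE_EXCLUSION_MM):
            i, j = np.argwhere(d < CHARGE_EXCLUSION_MM)[0]
            raise ValueError(
                f"evaluation point {p[i]} coincides with charge at "
                f"{charges.positions[j]}"
            )
        out[lo : lo + chunk] = np.einsum(
            "pc,pci->pi", charges.charges[None, :] / (4.0 * np.pi * d**3), diff
        )
    return out


# ---------------------------------------------------------------------------
# dipole bases


def _dipole_blocks(diff: np.ndarray, s: float) -> np.ndarray:
    """3x3 dipole basis blocks for offsets ``diff = x - y`` (K, 3).

    Rows/columns are the three divergence-free basis fields of the
    control point evaluated at x:
    ``B = [(-g'' - g'/r) I + (g'' - g'/r) u u^T] / s^2`` with u = diff/|diff|.
    Exactly zero outside the support |diff| > s; smooth limit
    ``(112 / s^2) I`` at diff -> 0.
    """
    diff = np.atleast_2d(diff)
    dist = np.linalg.norm(diff, axis=1)
    r = dist / s
    g2 = wendland_c4_derivative(r, 2)
    h = _wendland_d1_over_r(r)
    inside = r <= 1.0
    safe = np.where(dist > 1e-300, dist, 1.0)
    u = diff / safe[:, None]
    iso = np.where(inside, (-g2 - h) / s**2, 0.0)
    aniso = np.where(inside, (g2 - h) / s**2, 0.0)
    blocks = aniso[:, None, None] * u[:, :, None] * u[:, None, :]
    blocks[:, 0, 0] += iso
    blocks[:, 1, 1] += iso
    blocks[:, 2, 2] += iso
    return blocks


def dipole_basis_columns(x: np.ndarray, y: np.ndarray, s: float) -> np.ndarray:
    """The 3x3 matrix whose columns are the three divergence-free basis
    fields of the control point ``y`` (extent ``s``) evaluated at ``x``."""
    if s <= 0:
        raise ValueError("extent s must be positive")
    diff = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    return _dipole_blocks(diff[None, :], s)[0]


@dataclass
class DipoleGrid:
    """Hexagonal-close-packing grid of dipole control points with weights.

    Nearest-neighbour spacing is extent/3; every control point's
    radius-``extent`` support sphere intersects the gyral mask it was
    placed for.  ``weights`` holds 3 scalars per control point (one per
    basis column).
    """

    control_points: np.ndarray  # (N, 3)
    extent: float  # s, mm
    weights: np.ndarray = field(default=None)  # (N, 3)

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=np.float64)
        if self.extent <= 0:
            raise ValueError("extent must be positive")
        if self.weights is None:
            self.weights = np.zeros_like(self.control_points)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != self.control_points.shape:
            raise ValueError("weights must be (N, 3)")

    @property
    def n_points(self) -> int:
        return len(self.control_points)


def place_hex_grid(gyral_mask: MaskVolume, s: float) -> np.ndarray:
    """Hexagonal close-packing lattice (nearest-neighbour spacing s/3),
    axis-aligned with origin at the mask bounding-box corner, clipped to
    control points whose radius-``s`` support sphere intersects the mask."""
    if s <= 0:
        raise ValueError("extent s must be positive")
    if gyral_mask.n_voxels == 0:
        raise ValueError("empty mask")
    if s < 2.0 * float(gyral_mask.grid.voxel_size.max()):
        warnings.warn("dipole extent under-resolved relative to voxel size", stacklevel=2)
    centres = gyral_mask.voxel_centres()
    lo = centres.min(axis=0)
    hi = centres.max(axis=0)
    a = s / 3.0
    nk = int(np.ceil((hi[2] - lo[2] + 2 * s) / (a * np.sqrt(6.0) / 3.0))) + 2
    nj = int(np.ceil((hi[1] - lo[1] + 2 * s) / (a * np.sqrt(3.0) / 2.0))) + 2
    ni = int(np.ceil((hi[0] - lo[0] + 2 * s) / a)) + 2
    k = np.arange(nk)
    j = np.arange(nj)
    i = np.arange(ni)
    kk, jj, ii = np.meshgrid(k, j, i, indexing="ij")
    x = a * (ii + 0.5 * ((jj + kk) % 2))
    y = a * (np.sqrt(3.0) / 2.0) * (jj + ((kk % 2) / 3.0))
    z = a * (np.sqrt(6.0) / 3.0) * kk
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    pts += lo - s  # lattice origin tied to the mask bounding-box corner
    keep = cKDTree(centres).query(pts, k=1)[0] <= s
    return pts[keep]


@dataclass
class SparseBasisMap:
    """Sparse linear map M from 3N dipole weights to field samples (3P)."""

    points: np.ndarray  # (P, 3)
    control_points: np.ndarray  # (N, 3)
    extent: float
    matrix: sparse.csr_matrix  # (3P, 3N)

    def apply(self, weights: np.ndarray) -> np.ndarray:
        """Field contribution M w at the evaluation points, as (P, 3)."""
        w = np.asarray(weights, dtype=np.float64).reshape(-1)
        return (self.matrix @ w).reshape(-1, 3)

    def apply_transpose(self, field_grad: np.ndarray) -> np.ndarray:
        """M^T applied to a per-point gradient (P, 3) -> weight gradient (N, 3)."""
        return (self.matrix.T @ np.asarray(field_grad).reshape(-1)).reshape(-1, 3)


def _support_pairs(points: np.ndarray, cps: np.ndarray, s: float):
    tree = cKDTree(cps)
    lists = tree.query_ball_point(points, r=s)
    pi = np.concatenate([np.full(len(l), i, dtype=np.int64) for i, l in enumerate(lists)]) \
        if len(lists) else np.empty(0, dtype=np.int64)
    ci = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists]) \
        if len(lists) else np.empty(0, dtype=np.int64)
    return pi, ci


def build_sparse_map(
    points: np.ndarray, grid: DipoleGrid, chunk_size: int | None = None
) -> SparseBasisMap:
    """Assemble the sparse map M(x) from dipole weights to field samples.

    ``chunk_size`` streams the assembly over blocks of evaluation points
    under a memory cap; the result is bit-identical to the unchunked
    assembly (same per-block arithmetic).
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    P = len(points)
    N = grid.n_points
    if chunk_size is None:
        chunk_size = P or 1
    rows_all, cols_all, vals_all = [], [], []
    for lo in range(0, P, chunk_size):
        pts = points[lo : lo + chunk_size]
        pi, ci = _support_pairs(pts, grid.control_points, grid.extent)
        if len(pi) == 0:
            continue
        blocks = _dipole_blocks(pts[pi] - grid.control_points[ci], grid.extent)
        k = len(pi)
        rr = (3 * (pi + lo))[:, None, None] + np.arange(3)[None, :, None]
        cc = (3 * ci)[:, None, None] + np.arange(3)[None, None, :]
        rows_all.append(np.broadcast_to(rr, (k, 3, 3)).ravel())
        cols_all.append(np.broadcast_to(cc, (k, 3, 3)).ravel())
        vals_all.append(blocks.ravel())
    if rows_all:
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        vals = np.concatenate(vals_all)
    else:
        rows = cols = np.empty(0, dtype=np.int64)
        vals = np.empty(0)
    m = sparse.coo_matrix((vals, (rows, cols)), shape=(3 * P, 3 * N)).tocsr()
    return SparseBasisMap(points, grid.control_points, grid.extent, m)


def grid_field(points: np.ndarray, grid: DipoleGrid) -> np.ndarray:
    """Direct (on-the-fly) evaluation of one grid's field contribution."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = np.zeros_like(points)
    if grid.n_points == 0 or not np.any(grid.weights):
        return out
    pi, ci = _support_pairs(points, grid.control_points, grid.extent)
    if len(pi):
        blocks = _dipole_blocks(points[pi] - grid.control_points[ci], grid.extent)
        contrib = np.einsum("kij,kj->ki", blocks, grid.weights[ci])
        np.add.at(out, pi, contrib)
    return out


# ---------------------------------------------------------------------------
# full model


@dataclass
class VectorFieldModel:
    """Charge field plus an ordered list of dipole grids (coarse then fine).

    Divergence-free everywhere except at the charge positions.
    """

    charges: ChargeSet
    grids: list[DipoleGrid] = field(default_factory=list)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return eval_field(self, points)


def eval_field(model: VectorFieldModel, points: np.ndarray) -> np.ndarray:
    """Model field: charge field plus all dipole-grid contributions."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = eval_charge_field(model.charges, points)
    for grid in model.grids:
        out += grid_field(points, grid)
    return out


def eval_divergence_numeric(field_fn, points: np.ndarray, h: float) -> np.ndarray:
    """Central-difference divergence of any field callable at the points."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    div = np.zeros(len(points))
    for ax in range(3):
        step = np.zeros(3)
        step[ax] = h
        div += (field_fn(points + step)[:, ax] - field_fn(points - step)[:, ax]) / (2 * h)
    return div


def surface_flux(field_fn, mesh: TriangleMesh) -> float:
    """Flux of a field through a closed triangulated surface (centroid rule)."""
    normals, areas = triangle_normals_areas(mesh)
    f = field_fn(mesh.face_centres())
    return float(np.sum(np.einsum("ij,ij->i", f, normals) * areas))
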