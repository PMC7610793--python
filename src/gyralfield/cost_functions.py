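"""Cost terms constraining the vector field, with analytic gradients.

Four terms are combined into the total cost:

* surface density  ``<(f . n - d)^2>``     (uniform endpoint density per
  cortical volume; area-weighted mean over surface triangles)
* radial           ``-<fhat . n>``         (radial orientation at the
  cortical surfaces; area-weighted)
* DTI alignment    ``-<(fhat . v1)^2>``    (alignment with the principal
  diffusion-tensor eigenvector; sign-invariant; voxel-wise)
* L2 density       ``<|f|^2>``             (smooth volumetric density)

Surface normals point from white matter into grey matter, so a field
flowing out of the white matter towards the pial surface minimises the
radial term.  The DTI and radial terms act on the *normalised* field and
are therefore scale-invariant; samples where |f| falls below an epsilon
floor (1e-12 x median |f|) are excluded and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .field_model import DipoleGrid, SparseBasisMap, VectorFieldModel, build_sparse_map, eval_field, grid_field, eval_charge_field
from .surface_geometry import CorticalRibbon, TriangleMesh, triangle_normals_areas

logger = logging.getLogger(__name__)

__all__ = [
    "CostWeights",
    "SurfaceConstraint",
    "OrientationConstraint",
    "target_surface_density",
    "surface_constraint",
    "cost_dti",
    "cost_l2",
    "cost_surf_density",
    "cost_radial",
    "FitProblem",
    "build_fit_problem",
    "total_cost_and_gradient",
]


@dataclass
class CostWeights:
    """Relative weights of the cost terms (lambda_radial, lambda_DTI, lambda_L2)."""

    lambda_radial: float = 1.0
    lambda_dti: float = 1.0
    lambda_l2: float = 1e-3

    def __post_init__(self):
        for name in ("lambda_radial", "lambda_dti", "lambda_l2"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
            setattr(self, name, v)


@dataclass
class SurfaceConstraint:
    """Density and radiality targets on one cortical surface.

    Samples are triangle centres; means are area-weighted so results are
    stable under re-meshing.  ``targets`` are streamlines per mm^2.
    """

    points: np.ndarray  # (T, 3) triangle centres
    normals: np.ndarray  # (T, 3) unit, white->grey
    targets: np.ndarray  # (T,) target normal flux density d_i
    areas: np.ndarray  # (T,) averaging weights

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.normals = np.asarray(self.normals, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        self.areas = np.asarray(self.areas, dtype=np.float64)
        if not np.allclose(np.linalg.norm(self.normals, axis=1), 1.0, atol=1e-8):
            raise ValueError("normals must be unit vectors")
        if np.any(self.targets < 0):
            raise ValueError("target densities must be non-negative")


@dataclass
class OrientationConstraint:
    """Sign-ambiguous principal fibre orientations at gyral voxel centres."""

    points: np.ndarray  # (V, 3)
    v1: np.ndarray  # (V, 3) unit vectors

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.v1 = np.asarray(self.v1, dtype=np.float64)
        if not np.allclose(np.linalg.norm(self.v1, axis=1), 1.0, atol=1e-6):
            raise ValueError("V1 vectors must be unit length")


def target_surface_density(areas, triangle_volumes, total_flux: float) -> np.ndarray:
    """Per-triangle target density d_i = c V_i / A_i, normalised so that
    sum d_i A_i = total_flux (uniform streamline endpoints per cortical volume)."""
    areas = np.asarray(areas, dtype=np.float64)
    vols = np.asarray(triangle_volumes, dtype=np.float64)
    if np.any(areas <= 0):
        raise ValueError("zero-area triangle in surface-density target")
    return total_flux * vols / (vols.sum() * areas)


def surface_constraint(
    mesh: TriangleMesh, triangle_volumes, total_flux: float
) -> SurfaceConstraint:
    """Build the density/radiality constraint set for one surface."""
    normals, areas = triangle_normals_areas(mesh)
    d = target_surface_density(areas, triangle_volumes, total_flux)
    return SurfaceConstraint(mesh.face_centres(), normals, d, areas)


# ---------------------------------------------------------------------------
# individual terms (value + gradient w.r.t. the field samples)


def _normalise(fv: np.ndarray):
    """Unit field, magnitudes, and the epsilon-floor inclusion mask."""
    fv = np.asarray(fv, dtype=np.float64)
    mag = np.linalg.norm(fv, axis=1)
    eps = 1e-12 * max(float(np.median(mag)), 1e-300)
    ok = mag > eps
    n_excl = int((~ok).sum())
    if n_excl:
        logger.debug("%d sample(s) below field-magnitude floor excluded", n_excl)
    safe = np.where(ok, mag, 1.0)
    return fv / safe[:, None], safe, ok, n_excl


def cost_dti(field_values, v1, with_grad: bool = False):
    """-< (fhat . v1)^2 >, in [-1, 0]; invariant to the sign of v1 and to
    rescaling of f."""
    fhat, mag, ok, _ = _normalise(field_values)
    v1 = np.asarray(v1, dtype=np.float64)
    dot = np.einsum("ij,ij->i", fhat, v1)
    n = max(int(ok.sum()), 1)
    val = -float(np.sum(dot[ok] ** 2)) / n
    if not with_grad:
        return val
    grad = -2.0 * dot[:, None] * (v1 - dot[:, None] * fhat) / mag[:, None] / n
    grad[~ok] = 0.0
    return val, grad


def cost_l2(field_values, with_grad: bool = False):
    """Mean squared field magnitude <|f|^2> (volumetric density penalty)."""
    fv = np.asarray(field_values, dtype=np.float64)
    n = len(fv)
    val = float(np.einsum("ij,ij->", fv, fv)) / n
    if not with_grad:
        return val
    return val, 2.0 * fv / n


def cost_surf_density(field_values, constraint: SurfaceConstraint, with_grad: bool = False):
    """Area-weighted mean of (f . n - d)^2 over the surface samples."""
    fv = np.asarray(field_values, dtype=np.float64)
    w = constraint.areas / constraint.areas.sum()
    resid = np.einsum("ij,ij->i", fv, constraint.normals) - constraint.targets
    val = float(np.sum(w * resid**2))
    if not with_grad:
        return val
    return val, 2.0 * (w * resid)[:, None] * constraint.normals


def cost_radial(field_values, normals, areas=None, with_grad: bool = False):
    """-<fhat . n> (area-weighted): -1 when the field is exactly along the
    outward (white-to-grey) normal everywhere, +1 when exactly opposed."""
    fhat, mag, ok, _ = _normalise(field_values)
    normals = np.asarray(normals, dtype=np.float64)
    if areas is None:
        w = np.full(len(fhat), 1.0 / max(len(fhat), 1))
    else:
        areas = np.asarray(areas, dtype=np.float64)
        w = areas / areas.sum()
    wn = np.where(ok, w, 0.0)
    wn = wn / max(wn.sum(), 1e-300)
    dot = np.einsum("ij,ij->i", fhat, normals)
    val = -float(np.sum(wn * dot))
    if not with_grad:
        return val
    grad = -(wn / mag)[:, None] * (normals - dot[:, None] * fhat)
    grad[~ok] = 0.0
    return val, grad


# ---------------------------------------------------------------------------
# assembled fit problem


@dataclass
class FitProblem:
    """Everything needed to evaluate the total cost as a function of the
    free grid's weights: per-sample-set background fields (charges plus
    frozen grids) and sparse basis maps for the grid being optimised."""

    surfaces: list  # [(SurfaceConstraint, SparseBasisMap, f0 (T,3), weight)]
    voxel_map: SparseBasisMap
    voxel_f0: np.ndarray
    orientation: OrientationConstraint | None = None
    n_weights: int = 0

    def field_at_samples(self, w: np.ndarray):
        w = np.asarray(w, dtype=np.float64).reshape(-1)
        surf = [f0 + m.apply(w) for (_, m, f0, _) in self.surfaces]
        vox = self.voxel_f0 + self.voxel_map.apply(w)
        return surf, vox


def build_fit_problem(
    model: VectorFieldModel,
    free_grid: DipoleGrid,
    constraints: list[SurfaceConstraint],
    voxel_points: np.ndarray,
    orientation: OrientationConstraint | None = None,
    surface_weights: list[float] | None = None,
    chunk_size: int | None = None,
) -> FitProblem:
    """Precompute backgrounds and sparse maps for optimising one grid.

    The background at every sample is the charge field plus all grids in
    the model *except* ``free_grid`` evaluated with their current
    (frozen) weights.
    """
    if surface_weights is None:
        surface_weights = [1.0] * len(constraints)

    def background(points):
        f0 = eval_charge_field(model.charges, points)
        for g in model.grids:
            if g is free_grid:
                continue
            f0 = f0 + grid_field(points, g)
        return f0

    surfaces = []
    for con, sw in zip(constraints, surface_weights):
        m = build_sparse_map(con.points, free_grid, chunk_size=chunk_size)
        surfaces.append((con, m, background(con.points), float(sw)))
    voxel_points = np.atleast_2d(np.asarray(voxel_points, dtype=np.float64))
    vox_map = build_sparse_map(voxel_points, free_grid, chunk_size=chunk_size)
    return FitProblem(
        surfaces, vox_map, background(voxel_points), orientation, 3 * free_grid.n_points
    )


def total_cost_and_gradient(
    w: np.ndarray,
    problem: FitProblem,
    cost_weights: CostWeights,
    include_dti: bool = True,
):
    """Total cost C = C_surf-density + lr C_radial + ld C_DTI + l2 C_L2 and
    its analytic gradient with respect to the free dipole weights.

    Surface terms are summed over the constrained surfaces (white/grey
    boundary and mid surface, by default unweighted).  Returns
    (cost, gradient, per-term breakdown).
    """
    w = np.asarray(w, dtype=np.float64).reshape(-1)
    lw = cost_weights
    total = 0.0
    grad = np.zeros_like(w)
    breakdown = {}

    for idx, (con, m, f0, sw) in enumerate(problem.surfaces):
        fv = f0 + m.apply(w)
        c_sd, g_sd = cost_surf_density(fv, con, with_grad=True)
        c_rad, g_rad = cost_radial(fv, con.normals, con.areas, with_grad=True)
        total += sw * (c_sd + lw.lambda_radial * c_rad)
        gf = sw * (g_sd + lw.lambda_radial * g_rad)
        grad += m.apply_transpose(gf).reshape(-1)
        breakdown[f"surf_density_{idx}"] = c_sd
        breakdown[f"radial_{idx}"] = c_rad

    fvox = problem.voxel_f0 + problem.voxel_map.apply(w)
    c_l2, g_l2 = cost_l2(fvox, with_grad=True)
    total += lw.lambda_l2 * c_l2
    gfv = lw.lambda_l2 * g_l2
    breakdown["l2"] = c_l2
    if include_dti and problem.orientation is not None and lw.lambda_dti > 0:
        c_dti, g_dti = cost_dti(fvox, problem.orientation.v1, with_grad=True)
        total += lw.lambda_dti * c_dti
        gfv = gfv + lw.lambda_dti * g_dti
        breakdown["dti"] = c_dti
    grad += problem.voxel_map.apply_transpose(gfv).reshape(-1)

    if not np.isfinite(total):
        bad = [k for k, v in breakdown.items() if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite cost term(s): {bad}")
    breakdown["total"] = total
    return total, grad, breakdown
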