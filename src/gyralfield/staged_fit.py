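"""Three-stage estimation of the gyral white-matter vector field.

1. *Charges*: negative charges across the pial surface (proportional to
   the cortical volume per triangle) balanced by one positive charge at
   the centre of the deep white matter; the resulting field flows from
   deep white matter out through the cortex.
2. *Coarse dipoles* (extent 20 mm): weights minimising
   ``C_surf-density + lr C_radial + l2 C_L2`` with L-BFGS-B.  Surface
   terms are enforced at both the white/grey boundary and the mid
   surface.  The sign-degenerate DTI term is excluded at this stage.
3. *Fine dipoles* (extent 7 mm): the full cost including the DTI
   alignment term, starting from the stage-2 field (coarse weights
   frozen by default).

The final field is the sum of charges, coarse and fine contributions.
Each stage starts its new grid at zero weights, so its objective starts
from the previous stage's field and can only improve.  The fit itself is
deterministic; randomness only enters through synthetic-data generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import optimize

from .cost_functions import (
    CostWeights,
    FitProblem,
    OrientationConstraint,
    SurfaceConstraint,
    build_fit_problem,
    surface_constraint,
    total_cost_and_gradient,
)
from .field_model import (
    DipoleGrid,
    VectorFieldModel,
    build_surface_charges,
    place_hex_grid,
)
from .surface_geometry import CorticalRibbon, MaskVolume, deep_anchor_point, mid_surface

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "FitReport", "stage1_init", "stage2_coarse", "stage3_fine", "run_staged_fit", "build_constraints"]


@dataclass
class FitConfig:
    """Tunable parameters of the staged fit."""

    coarse_extent: float = 20.0  # mm, stage-2 dipole extent
    fine_extent: float = 7.0  # mm, stage-3 dipole extent
    cost_weights: CostWeights = dc_field(default_factory=CostWeights)
    ftol: float = 1e-8  # relative cost-change stopping criterion
    gtol: float = 1e-10
    max_iterations: int = 500
    joint_refinement: bool = False  # stage 3 also refits coarse weights
    mid_surface_weight: float = 1.0  # weight of the mid-surface constraints
    seed: int = 0

    def __post_init__(self):
        if self.coarse_extent <= 0 or self.fine_extent <= 0:
            raise ValueError("extents must be positive")
        if self.coarse_extent <= self.fine_extent:
            raise ValueError("coarse_extent must exceed fine_extent")


@dataclass
class FitReport:
    """Per-stage optimisation diagnostics."""

    stages: dict = dc_field(default_factory=dict)

    def add_stage(self, name, trajectory, breakdown, n_iter, converged, message, n_weights):
        self.stages[name] = {
            "cost_trajectory": [float(c) for c in trajectory],
            "final_terms": {k: float(v) for k, v in breakdown.items()},
            "iterations": int(n_iter),
            "converged": bool(converged),
            "message": str(message),
            "n_weights": int(n_weights),
        }

    def to_dict(self) -> dict:
        return {"stages": self.stages}


def build_constraints(ribbon: CorticalRibbon, total_flux: float) -> list[SurfaceConstraint]:
    """Density/radiality constraints at the white boundary and mid surface."""
    white_c = surface_constraint(ribbon.white, ribbon.triangle_volumes, total_flux)
    mid_c = surface_constraint(ribbon.mid, ribbon.triangle_volumes, total_flux)
    return [white_c, mid_c]


def stage1_init(
    ribbon: CorticalRibbon,
    gyral_mask: MaskVolume,
    deep_mask: MaskVolume,
    total_flux: float | None = None,
) -> VectorFieldModel:
    """Initial model: volume-proportional pial charges plus the balancing
    positive charge at the deep-white-matter anchor; no dipole grids.

    ``total_flux`` defaults to the total cortical volume (one streamline
    unit per mm^3 of cortex).
    """
    if total_flux is None:
        total_flux = ribbon.total_volume
    anchor = deep_anchor_point(deep_mask)
    charges = build_surface_charges(ribbon.pial, ribbon.triangle_volumes, anchor, total_flux)
    return VectorFieldModel(charges, [])


def _optimise_grid(
    model: VectorFieldModel,
    grid: DipoleGrid,
    problem: FitProblem,
    config: FitConfig,
    include_dti: bool,
    stage_name: str,
    report: FitReport | None,
    w0: np.ndarray | None = None,
) -> None:
    """Minimise the (possibly DTI-free) total cost over one grid's weights."""
    w0 = np.zeros(3 * grid.n_points) if w0 is None else np.asarray(w0, np.float64).reshape(-1)
    trajectory = []

    last = {"cost": np.inf}

    def fun(w):
        c, g, _ = total_cost_and_gradient(w, problem, config.cost_weights, include_dti)
        last["cost"] = c
        return c, g

    def cb(w):
        # cost of the accepted iterate == last line-search evaluation
        trajectory.append(last["cost"])

    c0, _, _ = total_cost_and_gradient(w0, problem, config.cost_weights, include_dti)
    trajectory.append(c0)
    if config.max_iterations > 0:
        res = optimize.minimize(
            fun,
            w0,
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={
                "maxiter": config.max_iterations,
                "ftol": config.ftol,
                "gtol": config.gtol,
            },
        )
        w_fit, n_iter, converged, message = res.x, res.nit, res.success, res.message
        if not converged:
            logger.warning("%s optimiser did not fully converge: %s", stage_name, message)
    else:
        w_fit, n_iter, converged, message = w0, 0, True, "zero-iteration budget"
    grid.weights = w_fit.reshape(-1, 3)
    _, _, breakdown = total_cost_and_gradient(w_fit, problem, config.cost_weights, include_dti)
    if report is not None:
        report.add_stage(
            stage_name, trajectory + [breakdown["total"]], breakdown, n_iter, converged,
            message, 3 * grid.n_points,
        )


def stage2_coarse(
    model: VectorFieldModel,
    constraints: list[SurfaceConstraint],
    gyral_mask: MaskVolume,
    config: FitConfig,
    report: FitReport | None = None,
    init_weights: np.ndarray | None = None,
) -> VectorFieldModel:
    """Fit the coarse dipole grid to the surface-density, radial and L2
    terms (no DTI).  Appends the fitted grid to the model in place."""
    grid = DipoleGrid(place_hex_grid(gyral_mask, config.coarse_extent), config.coarse_extent)
    model.grids.append(grid)
    surface_weights = [1.0, config.mid_surface_weight][: len(constraints)]
    problem = build_fit_problem(
        model, grid, constraints, gyral_mask.voxel_centres(), None, surface_weights
    )
    _optimise_grid(model, grid, problem, config, False, "stage2_coarse", report, init_weights)
    return model


def stage3_fine(
    model: VectorFieldModel,
    constraints: list[SurfaceConstraint],
    orientation: OrientationConstraint,
    gyral_mask: MaskVolume,
    config: FitConfig,
    report: FitReport | None = None,
) -> VectorFieldModel:
    """Fit the fine dipole grid to the full cost including DTI alignment.

    Requires a stage-2 model: the sign-degenerate DTI term needs a decent
    initial field estimate.  Coarse weights stay frozen unless
    ``config.joint_refinement`` is set.
    """
    if not model.grids:
        raise ValueError("stage 3 requires a stage-2 (coarse) fit first")
    grid = DipoleGrid(place_hex_grid(gyral_mask, config.fine_extent), config.fine_extent)
    model.grids.append(grid)
    surface_weights = [1.0, config.mid_surface_weight][: len(constraints)]
    problem = build_fit_problem(
        model, grid, constraints, gyral_mask.voxel_centres(), orientation, surface_weights
    )
    _optimise_grid(model, grid, problem, config, True, "stage3_fine", report)
    if config.joint_refinement:
        coarse = model.grids[-2]
        problem_c = build_fit_problem(
            model, coarse, constraints, gyral_mask.voxel_centres(), orientation, surface_weights
        )
        _optimise_grid(
            model, coarse, problem_c, config, True, "stage3_joint_coarse", report,
            w0=coarse.weights.reshape(-1),
        )
    return model


def run_staged_fit(
    ribbon: CorticalRibbon,
    gyral_mask: MaskVolume,
    deep_mask: MaskVolume,
    orientation: OrientationConstraint | None = None,
    config: FitConfig | None = None,
    total_flux: float | None = None,
) -> tuple[VectorFieldModel, FitReport]:
    """Run the full three-stage fit; returns the model and its report."""
    config = config or FitConfig()
    report = FitReport()
    model = stage1_init(ribbon, gyral_mask, deep_mask, total_flux)
    constraints = build_constraints(ribbon, model.charges.total_flux)
    stage2_coarse(model, constraints, gyral_mask, config, report)
    if orientation is not None:
        stage3_fine(model, constraints, orientation, gyral_mask, config, report)
    return model, report
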