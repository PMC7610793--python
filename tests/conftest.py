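"""Shared fixtures: the default synthetic gyrus pipeline, built once.

The heavyweight objects (thickness volume, masks, ground-truth field,
noisy orientations, three-stage fit) are session-scoped so the staged
fit runs exactly once for the whole suite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import gyralfield as gf
from gyralfield.cost_functions import OrientationConstraint
from gyralfield.field_model import eval_field
from gyralfield.staged_fit import build_constraints

THRESHOLD_MM = 10.0
NOISE_DEG = 10.0


@pytest.fixture(scope="session")
def gyrus():
    """Default synthetic gyral blade: (ribbon, grid, wm_mask)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # fundus wedge inversions
        return gf.make_gyrus()


@pytest.fixture(scope="session")
def thickness(gyrus):
    ribbon, grid, wm = gyrus
    return gf.compute_gyral_thickness(ribbon.white, grid, wm, n_directions=64, max_length=50.0)


@pytest.fixture(scope="session")
def masks(gyrus, thickness):
    """(gyral, deep) white-matter masks at the 10 mm threshold."""
    _, _, wm = gyrus
    gyral = gf.threshold_gyral_mask(thickness, wm, THRESHOLD_MM)
    return gyral, gf.deep_mask_from_gyral(wm, gyral)


@pytest.fixture(scope="session")
def truth_model(gyrus, masks):
    """Seeded ground-truth divergence-free field (charges + one dipole grid)."""
    ribbon, _, _ = gyrus
    gyral, deep = masks
    return gf.make_ground_truth_field(ribbon, gyral, deep, n_dipoles=50, seed=0)


@pytest.fixture(scope="session")
def v1_field(gyrus, masks, truth_model):
    """Noisy sign-ambiguous orientation samples from the ground truth."""
    _, grid, _ = gyrus
    gyral, _ = masks
    return gf.sample_orientations(truth_model, grid, gyral, NOISE_DEG, seed=1)


@pytest.fixture(scope="session")
def fitted(gyrus, masks, v1_field):
    """Full three-stage fit against the noisy orientations, with per-stage
    field snapshots at the white-boundary triangle centres."""
    ribbon, grid, wm = gyrus
    gyral, deep = masks
    orient = OrientationConstraint(gyral.voxel_centres(), v1_field[gyral.values])
    config = gf.FitConfig()
    report = gf.FitReport()
    model = gf.stage1_init(ribbon, gyral, deep)
    constraints = build_constraints(ribbon, model.charges.total_flux)
    white_pts = constraints[0].points
    f_white_stage1 = eval_field(model, white_pts)
    gf.stage2_coarse(model, constraints, gyral, config, report)
    f_white_stage2 = eval_field(model, white_pts)
    gf.stage3_fine(model, constraints, orient, gyral, config, report)
    return {
        "model": model,
        "report": report,
        "constraints": constraints,
        "orient": orient,
        "config": config,
        "f_white_stage1": f_white_stage1,
        "f_white_stage2": f_white_stage2,
    }
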