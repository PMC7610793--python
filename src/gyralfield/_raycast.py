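"""Batched bidirectional line/triangle-mesh intersection distances.

Used by the gyral-thickness measure: for every origin and sampling
direction we need the distance to the first mesh intersection on *both*
sides of the origin along the (undirected) line.  A single
Moller-Trumbore pass over all triangles collects the smallest positive
and smallest negative intersection parameter per line.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

_EPS = 1e-9


@njit(cache=True, parallel=True, fastmath=True)
def _line_mesh_kernel(origins, dirs, v0, e1, e2, max_length, t_fwd, t_bwd):
    n_orig = origins.shape[0]
    n_dir = dirs.shape[0]
    n_tri = v0.shape[0]
    for oi in prange(n_orig):
        ox, oy, oz = origins[oi, 0], origins[oi, 1], origins[oi, 2]
        for di in range(n_dir):
            dx, dy, dz = dirs[di, 0], dirs[di, 1], dirs[di, 2]
            best_f = np.inf
            best_b = np.inf
            for ti in range(n_tri):
                e1x, e1y, e1z = e1[ti, 0], e1[ti, 1], e1[ti, 2]
                e2x, e2y, e2z = e2[ti, 0], e2[ti, 1], e2[ti, 2]
                # p = d x e2
                px = dy * e2z - dz * e2y
                py = dz * e2x - dx * e2z
                pz = dx * e2y - dy * e2x
                det = e1x * px + e1y * py + e1z * pz
                if -_EPS < det < _EPS:
                    continue
                inv = 1.0 / det
                tx = ox - v0[ti, 0]
                ty = oy - v0[ti, 1]
                tz = oz - v0[ti, 2]
                u = (tx * px + ty * py + tz * pz) * inv
                if u < 0.0 or u > 1.0:
                    continue
                # q = t x e1
                qx = ty * e1z - tz * e1y
                qy = tz * e1x - tx * e1z
                qz = tx * e1y - ty * e1x
                v = (dx * qx + dy * qy + dz * qz) * inv
                if v < 0.0 or u + v > 1.0:
                    continue
                t = (e2x * qx + e2y * qy + e2z * qz) * inv
                if t > _EPS:
                    if t < best_f:
                        best_f = t
                elif t < -_EPS:
                    if -t < best_b:
                        best_b = -t
            t_fwd[oi, di] = best_f if best_f <= max_length else np.inf
            t_bwd[oi, di] = best_b if best_b <= max_length else np.inf


def bidirectional_ray_distances(origins, dirs, a, b, c, max_length):
    """Distances from each origin to the first mesh hit along +dir and -dir.

    Returns two (n_origins, n_dirs) arrays; entries are ``inf`` when no
    hit occurs within ``max_length`` on that side.
    """
    origins = np.ascontiguousarray(origins, dtype=np.float64)
    dirs = np.ascontiguousarray(dirs, dtype=np.float64)
    a = np.ascontiguousarray(a, dtype=np.float64)
    e1 = np.ascontiguousarray(np.asarray(b, dtype=np.float64) - a)
    e2 = np.ascontiguousarray(np.asarray(c, dtype=np.float64) - a)
    t_fwd = np.empty((origins.shape[0], dirs.shape[0]))
    t_bwd = np.empty_like(t_fwd)
    _line_mesh_kernel(origins, dirs, a, e1, e2, float(max_length), t_fwd, t_bwd)
    return t_fwd, t_bwd
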