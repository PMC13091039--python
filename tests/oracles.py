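"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: the rigid-fit oracle
searches rotation space on a grid with local refinement, and the motif-PAE
oracle is an explicit double loop.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def _rmsd_for_rotations(rots: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """RMSD of centred mobile P vs centred reference Q for a stack of
    rotation matrices (translation optimal by centroid matching)."""
    moved = np.einsum("rij,nj->rni", rots, P)
    return np.sqrt(((moved - Q[None]) ** 2).sum(axis=(1, 2)) / P.shape[0])


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over rotations by Euler-angle grid search (coarse 10°
    full grid, 1° local grid around the best cell, then simplex refinement
    on the rotation vector)."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)

    deg = np.arange(0, 360, 10.0)
    deg_b = np.arange(0, 180 + 1e-9, 10.0)
    grid = np.array(np.meshgrid(deg, deg_b, deg, indexing="ij")).reshape(3, -1).T
    rots = Rotation.from_euler("zyz", grid, degrees=True).as_matrix()
    rmsds = _rmsd_for_rotations(rots, P, Q)
    best = grid[np.argmin(rmsds)]

    offs = np.arange(-10, 10 + 1e-9, 1.0)
    local = np.array(np.meshgrid(*[c + offs for c in best], indexing="ij")).reshape(3, -1).T
    rots = Rotation.from_euler("zyz", local, degrees=True).as_matrix()
    rmsds = _rmsd_for_rotations(rots, P, Q)
    best_local = local[np.argmin(rmsds)]

    x0 = Rotation.from_euler("zyz", best_local, degrees=True).as_rotvec()

    def objective(rotvec: np.ndarray) -> float:
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(((P @ R.T - Q) ** 2).sum() / P.shape[0]))

    res = minimize(objective, x0, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
    return float(min(res.fun, rmsds.min()))


def motif_pae_double_loop(pae: np.ndarray, rows: list[int], cols: list[int]) -> float:
    terms = []
    for i in rows:
        for j in cols:
            terms.append(float(pae[i, j]))
    return math.fsum(terms) / (len(rows) * len(cols))


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation and a random translation."""
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1))).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return R, t
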