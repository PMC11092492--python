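"""Object-manifold geometry of result representations.

The 380 per-problem mean response vectors of a layer partition into 19
"result manifolds" -- the point clouds of problems sharing a numerical
result (result r has r+1 addition and 19-r subtraction members, 20
points each). Three geometric summaries follow the mean-field theory of
linear classification of manifolds:

* capacity -- how many manifolds per ambient dimension a linear readout
  can separate into random binary categories at margin kappa;
* radius and dimensionality -- anchor-point statistics describing the
  effective extent and number of dimensions of each manifold;
* center correlation -- the mean alignment of manifold centroids.

Two independent capacity estimates are provided: the mean-field
estimator (Gaussian samples, each requiring the projection of a random
direction onto a manifold's feasible cone, solved exactly through the
nonnegative dual of the projection program) and an empirical oracle that
measures the fraction of random balanced dichotomies that are linearly
separable at each ambient dimension and reads off the 50% crossing.
For point-like manifolds both converge to the classical value of 2
(two patterns per synapse).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog, nnls

from .representation import MeanResponseMatrix
from .stimuli import N_RESULTS


@dataclass
class ManifoldSet:
    layer: str
    clouds: list  # one (m_i, U) array per manifold
    labels: list  # result value per manifold

    @property
    def ambient_dim(self) -> int:
        return self.clouds[0].shape[1]


@dataclass
class ManifoldGeometry:
    capacity: float
    radius: float
    dimension: float
    center_correlation: float


def extract_result_manifolds(meanresp: MeanResponseMatrix) -> ManifoldSet:
    """Group the 380 problem means into the 19 result manifolds."""
    if meanresp.values.shape[0] != len(meanresp.problems):
        raise ValueError("row count does not match problem list")
    results = np.array([p.result for p in meanresp.problems])
    clouds = [meanresp.values[results == r] for r in range(N_RESULTS)]
    return ManifoldSet(meanresp.layer, clouds, list(range(N_RESULTS)))


# ---------------------------------------------------------------------------
# mean-field estimator


def _project_cone(S, t, kappa):
    """Projection of t onto {v : S v >= kappa} via the nonnegative dual.

    Returns (lambda, residual Sᵀλ = v - t). At kappa = 0 this is an
    exact NNLS problem; for kappa != 0 a projected coordinate descent on
    the dual quadratic program is used.
    """
    if np.all(S @ t >= kappa):
        return np.zeros(S.shape[0]), np.zeros_like(t)
    if kappa == 0.0:
        lam, _ = nnls(S.T, -t)
    else:
        lam = _dual_cd(S, t, kappa)
    return lam, S.T @ lam


def _dual_cd(S, t, kappa, sweeps=500, tol=1e-10):
    """Projected coordinate descent on 0.5 λᵀSSᵀλ + λᵀ(St - κ1), λ >= 0."""
    Q = S @ S.T
    c = S @ t - kappa
    lam = np.zeros(S.shape[0])
    diag = np.clip(np.diag(Q), 1e-12, None)
    for _ in range(sweeps):
        delta = 0.0
        for i in range(len(lam)):
            new = max(0.0, lam[i] - (Q[i] @ lam + c[i]) / diag[i])
            delta = max(delta, abs(new - lam[i]))
            lam[i] = new
        if delta < tol:
            break
    return lam


def manifold_geometry_mft(ms: ManifoldSet, n_samples: int = 200, kappa: float = 0.0,
                          seed: int = 0, max_ambient: int = 5000) -> ManifoldGeometry:
    """Mean-field capacity, radius and dimensionality of a manifold set.

    Per manifold: subtract the centroid, build an orthonormal basis of
    the within-manifold subspace (SVD), scale coordinates by the
    centroid norm and append a unit center coordinate. For each sampled
    Gaussian direction the anchor point on the convex hull is found by
    projecting onto the feasible cone; capacity is the inverse mean
    squared projection residual (averaged across manifolds as inverses),
    radius and dimensionality are anchor statistics. Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    clouds = ms.clouds
    if any(len(c) < 1 for c in clouds):
        raise ValueError("every manifold needs at least one point")
    if ms.ambient_dim > max_ambient:
        proj = rng.standard_normal((ms.ambient_dim, max_ambient)) / np.sqrt(max_ambient)
        clouds = [c @ proj for c in clouds]

    inv_caps, radii, dims = [], [], []
    for cloud in clouds:
        center = cloud.mean(axis=0)
        cnorm = np.linalg.norm(center)
        centered = cloud - center
        # orthonormal within-manifold basis
        u, sv, vt = np.linalg.svd(centered, full_matrices=False)
        keep = sv > 1e-10 * max(1.0, sv.max(initial=0.0))
        basis = vt[keep]
        d = basis.shape[0]
        coords = centered @ basis.T  # (m, d)
        scale = cnorm if cnorm > 1e-12 else 1.0
        S = np.concatenate([coords / scale, np.ones((len(cloud), 1))], axis=1)  # (m, d+1)

        sq_res, r2s, aligns = [], [], []
        for _ in range(n_samples):
            t = rng.standard_normal(d + 1)
            lam, res = _project_cone(S, t, kappa)
            sq_res.append(res @ res)
            tot = lam.sum()
            if tot > 1e-12 and d > 0:
                anchor = (S.T @ lam) / tot
                a_perp = anchor[:d]
                r2 = a_perp @ a_perp
                r2s.append(r2)
                if r2 > 1e-20:
                    aligns.append((t[:d] @ a_perp) ** 2 / r2)
        inv_caps.append(np.mean(sq_res))
        radii.append(np.sqrt(np.mean(r2s)) if r2s else 0.0)
        dims.append(np.mean(aligns) if aligns else 0.0)

    mean_inv = float(np.mean(inv_caps))
    capacity = float(np.inf) if mean_inv == 0 else 1.0 / mean_inv
    return ManifoldGeometry(
        capacity=capacity,
        radius=float(np.mean(radii)),
        dimension=float(np.mean(dims)),
        center_correlation=center_correlation(ms),
    )


# ---------------------------------------------------------------------------
# empirical oracle


def _separable(X, y, tol=1e-7):
    """Linear separability (no bias) of labelled points via an LP.

    Minimizes total hinge slack subject to y_i (w . x_i) >= 1 - xi_i;
    the assignment is separable iff the optimum is (numerically) zero.
    """
    n, d = X.shape
    a_w = -(y[:, None] * X)
    a_ub = np.concatenate([a_w, -np.eye(n)], axis=1)
    b_ub = -np.ones(n)
    c = np.concatenate([np.zeros(d), np.ones(n)])
    bounds = [(None, None)] * d + [(0, None)] * n
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=bounds, method="highs")
    return res.status == 0 and res.fun < tol


class GridError(ValueError):
    """The subsample grid does not bracket the 50% separability crossing."""


def capacity_empirical(ms: ManifoldSet, feature_grid, n_dichotomies: int | None = 40,
                       seed: int = 0) -> dict:
    """Random-dichotomy capacity: P / N* at the 50% separability crossing.

    For each ambient subsample size N on ``feature_grid`` the manifolds
    are randomly projected to N dimensions and random balanced
    dichotomies are tested for linear separability of all their points
    (``n_dichotomies=None`` enumerates every balanced dichotomy).
    Returns the capacity together with the per-N separable fractions.
    """
    rng = np.random.default_rng(seed)
    p = len(ms.clouds)
    if p < 2:
        raise ValueError("need at least two manifolds")
    sizes = np.array([len(c) for c in ms.clouds])
    X_full = np.concatenate(ms.clouds, axis=0)
    owner = np.repeat(np.arange(p), sizes)

    half = p // 2
    if n_dichotomies is None:
        combos = [c for c in itertools.combinations(range(p), half) if 0 in c]
        assignments = np.array([np.isin(np.arange(p), c) for c in combos])
    else:
        assignments = np.stack([
            rng.permutation(np.arange(p) < half) for _ in range(n_dichotomies)
        ])

    fractions = []
    for n_feat in feature_grid:
        proj = rng.standard_normal((X_full.shape[1], n_feat)) / np.sqrt(n_feat)
        Xp = X_full @ proj
        ok = 0
        for assign in assignments:
            y = np.where(assign[owner], 1.0, -1.0)
            ok += _separable(Xp, y)
        fractions.append(ok / len(assignments))
    fractions = np.array(fractions)
    grid = np.asarray(list(feature_grid), dtype=float)

    above = np.nonzero(fractions >= 0.5)[0]
    below = np.nonzero(fractions < 0.5)[0]
    if len(above) == 0 or len(below) == 0:
        raise GridError(
            f"separable fractions {fractions.tolist()} on grid {grid.tolist()} "
            "do not bracket 0.5; widen the feature grid"
        )
    hi = above[0]  # first N achieving >= 50%
    if hi == 0:
        raise GridError("crossing below the smallest grid size; widen the grid downward")
    lo = hi - 1
    f0, f1 = fractions[lo], fractions[hi]
    n_star = grid[lo] + (0.5 - f0) / (f1 - f0) * (grid[hi] - grid[lo])
    return {"capacity": p / n_star, "n_star": float(n_star),
            "grid": grid, "fractions": fractions}


def center_correlation(ms: ManifoldSet) -> float:
    """Mean absolute cosine similarity of globally centered centroids."""
    if len(ms.clouds) < 2:
        raise ValueError("need at least two manifolds")
    centers = np.stack([c.mean(axis=0) for c in ms.clouds])
    centered = centers - centers.mean(axis=0)
    norms = np.linalg.norm(centered, axis=1)
    keep = norms > 1e-12
    if keep.sum() < len(norms):
        warnings.warn(f"{int((~keep).sum())} zero-norm centered centroids excluded")
    c = centered[keep] / norms[keep][:, None]
    cos = np.abs(c @ c.T)
    iu = np.triu_indices(len(c), k=1)
    return float(cos[iu].mean())
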