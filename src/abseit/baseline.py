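"""Absolute Gauss-Newton reconstruction baseline.

Minimises the regularised data misfit

    Phi(m) = 1/2 ||F(exp(m)) - V_meas||^2 + 1/2 lambda ||L (m - m0)||^2

over log-conductivity m (positivity for free), starting from the best-fit
homogeneous estimate m0.  Regularising *about* the homogeneous start makes
the large-lambda limit return that start, the behaviour expected of a
Tikhonov prior in absolute EIT.  The Jacobian comes from the adjoint
identity for four-probe measurements: with unit injection currents,
dV(k,j)/dsigma_e = -area_e * grad(u_k) . grad(u_j), and both fields are
already available because the adjacent measurement pairs coincide with the
drive patterns.

With the identity prior the normal equations are solved in data space
(Woodbury), so one iteration costs one sparse factorisation plus a 208x208
dense solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .forward import (ElectrodeModel, ForwardSolver, N_ELECTRODES,
                      VoltageFrame, electrode_voltage_matrix, pack_frame,
                      valid_measurement_pairs)
from .mesh import DiscMesh
from .rotation import disc_mask
from .phantom import _pixel_grid

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GNConfig:
    lam: float = 1e-2
    prior: str = "tikhonov"        # or "laplace" (element-adjacency Laplacian)
    max_iter: int = 10
    step_tol: float = 1e-4         # stop when ||delta||_inf drops below this
    max_halvings: int = 6

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.prior not in ("tikhonov", "laplace"):
            raise ValueError("prior must be 'tikhonov' or 'laplace'")


@dataclass
class GNResult:
    image: np.ndarray              # 64x64 raster of the reconstruction
    sigma: np.ndarray              # per-element conductivity
    sigma0: float                  # homogeneous starting estimate
    objective: list                # objective value per accepted iterate
    converged: bool
    diverged: bool                 # True if no descent step could be found


def _forward_and_fields(solver: ForwardSolver, sigma: np.ndarray,
                        electrodes: ElectrodeModel):
    u, U = solver.solve_fields(sigma, electrodes)
    frame = pack_frame(electrode_voltage_matrix(U))
    return frame.values, u


def _jacobian(mesh: DiscMesh, u: np.ndarray) -> np.ndarray:
    """(208, n_elements) sensitivity of the frame w.r.t. element conductivity."""
    # per-element gradient of each of the 16 fields: (16, M, 2)
    nodal = u[:, mesh.elements]                     # (16, M, 3)
    gu = np.einsum("kma,mad->kmd", nodal, mesh.grads)
    rows = []
    for k in range(N_ELECTRODES):
        inner = np.einsum("md,jmd->jm", gu[k], gu[valid_measurement_pairs(k)])
        rows.append(-inner * mesh.areas[None, :])
    return np.concatenate(rows, axis=0)


@lru_cache(maxsize=4)
def _raster_lookup(mesh_key: tuple, grid_size: int = 64):
    """Nearest element centroid for every in-disc pixel centre."""
    mesh = _MESH_BY_KEY[mesh_key]
    X, Y, _ = _pixel_grid(mesh.radius, grid_size)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    _, idx = cKDTree(mesh.centroids).query(pts)
    return idx.reshape(grid_size, grid_size)


_MESH_BY_KEY: dict = {}


def rasterize_elements(mesh: DiscMesh, values: np.ndarray, fill: float,
                       grid_size: int = 64) -> np.ndarray:
    """Nearest-centroid raster of a per-element field; ``fill`` outside."""
    key = (mesh.radius, mesh.n_rings)
    _MESH_BY_KEY[key] = mesh
    idx = _raster_lookup(key, grid_size)
    img = np.asarray(values, dtype=float)[idx]
    img[~disc_mask(grid_size)] = fill
    return img


def _laplace_prior(mesh: DiscMesh) -> sp.csr_matrix:
    """Element-adjacency graph Laplacian (first-difference smoothing prior)."""
    edges = {}
    for e, tri in enumerate(mesh.elements):
        for a in range(3):
            key = tuple(sorted((tri[a], tri[(a + 1) % 3])))
            if key in edges:
                edges[key] = (edges[key][0], e)
            else:
                edges[key] = (e, None)
    pairs = np.array([v for v in edges.values() if v[1] is not None])
    m = mesh.n_elements
    data = np.concatenate([np.ones(len(pairs)), -np.ones(len(pairs))])
    rows = np.concatenate([np.arange(len(pairs))] * 2)
    cols = np.concatenate([pairs[:, 0], pairs[:, 1]])
    return sp.csr_matrix((data, (rows, cols)), shape=(len(pairs), m))


def homogeneous_fit(solver: ForwardSolver, v_meas: np.ndarray,
                    electrodes: ElectrodeModel) -> float:
    """Best-fit constant conductivity (uses the 1/sigma scaling of the frame)."""
    f1, _ = _forward_and_fields(solver, np.ones(solver.mesh.n_elements),
                                electrodes)
    denom = float(f1 @ v_meas)
    if denom <= 0:
        return 1.0
    return float(np.clip((f1 @ f1) / denom, 1e-6, 1e6))


def gn_reconstruct(frame: VoltageFrame, mesh: DiscMesh,
                   config: GNConfig = GNConfig(),
                   electrodes: ElectrodeModel | None = None,
                   grid_size: int = 64) -> GNResult:
    """Iterative Gauss-Newton reconstruction of one frame onto a 64x64 grid."""
    electrodes = electrodes or ElectrodeModel()
    solver = ForwardSolver(mesh)
    v_meas = frame.values
    sigma0 = homogeneous_fit(solver, v_meas, electrodes)
    m0 = np.full(mesh.n_elements, np.log(sigma0))
    m = m0.copy()
    L = None if config.prior == "tikhonov" else _laplace_prior(mesh)
    lam = config.lam

    def objective(residual, mm):
        reg = (mm - m0) if L is None else L @ (mm - m0)
        return 0.5 * float(residual @ residual) + 0.5 * lam * float(reg @ reg)

    f, u = _forward_and_fields(solver, np.exp(m), electrodes)
    r = v_meas - f
    obj = [objective(r, m)]
    converged = False
    diverged = False
    for it in range(config.max_iter):
        J = _jacobian(mesh, u) * np.exp(m)[None, :]   # log-parameter chain rule
        if L is None:
            b = J.T @ r - lam * (m - m0)
            A = J @ J.T + lam * np.eye(len(r))
            delta = (b - J.T @ np.linalg.solve(A, J @ b)) / lam
        else:
            LtL = (L.T @ L).toarray()
            A = J.T @ J + lam * LtL
            b = J.T @ r - lam * (LtL @ (m - m0))
            delta = np.linalg.solve(A, b)
        step = 1.0
        accepted = False
        for _ in range(config.max_halvings + 1):
            m_try = m + step * delta
            f_try, u_try = _forward_and_fields(solver, np.exp(m_try), electrodes)
            r_try = v_meas - f_try
            o_try = objective(r_try, m_try)
            if o_try < obj[-1]:
                m, f, u, r = m_try, f_try, u_try, r_try
                obj.append(o_try)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            diverged = True
            log.warning("GN: no descent step at iteration %d; returning "
                        "best iterate", it)
            break
        if np.abs(step * delta).max() < config.step_tol:
            converged = True
            break
    sigma = np.exp(m)
    img = rasterize_elements(mesh, sigma, fill=sigma0, grid_size=grid_size)
    return GNResult(image=img, sigma=sigma, sigma0=sigma0, objective=obj,
                    converged=converged, diverged=diverged)


def sweep_lambda(frame: VoltageFrame, mesh: DiscMesh, lambdas,
                 truth_px: tuple, target_sign: str = "below",
                 config: GNConfig = GNConfig(),
                 electrodes: ElectrodeModel | None = None):
    """Reconstruct per lambda, score against the truth, pick argmin-PE.

    Returns ``(table, best_lambda)`` where the table has one row per lambda
    with the three figures of merit.
    """
    from .metrics import evaluate_image
    import pandas as pd

    lambdas = list(lambdas)
    if len(lambdas) < 1:
        raise ValueError("need at least one lambda")
    rows = []
    for lam in lambdas:
        res = gn_reconstruct(frame, mesh,
                             GNConfig(lam=float(lam), prior=config.prior,
                                      max_iter=config.max_iter,
                                      step_tol=config.step_tol),
                             electrodes)
        fom = evaluate_image(res.image, truth_px, target_sign)
        rows.append({"lambda": float(lam), "AR": fom.AR, "PE": fom.PE,
                     "RNG": fom.RNG})
    table = pd.DataFrame(rows)
    pe = table["PE"].to_numpy()
    best = table["lambda"].iloc[int(np.nanargmin(pe))] if np.isfinite(pe).any() \
        else table["lambda"].iloc[0]
    return table, float(best)
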