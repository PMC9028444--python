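"""Complete-electrode-model FEM forward solver for adjacent-drive EIT.

Solves the 2-D conductivity equation on the symmetric disc mesh with the
complete electrode model (finite-width electrodes with contact impedance),
injecting unit current through each of the 16 adjacent electrode pairs and
reading the 13 valid adjacent four-probe voltage differences per injection —
the 208-value frame that one electrical impedance map packs.

The electrode/Lagrange blocks follow the standard CEM weak form: for
electrode l with contact impedance z_l the system gains
``(1/z_l) \\int_{E_l} u v ds`` node-node terms, ``-(1/z_l) \\int_{E_l} v ds``
node-electrode coupling and ``|E_l|/z_l`` on the electrode diagonal, plus a
zero-mean constraint on the electrode potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import DiscMesh, N_ELECTRODES

#: default per-electrode contact impedance (model units, Ohm*m in 2-D).
#: Stand-in for the reference simulator's unstated default constant.
DEFAULT_CONTACT_IMPEDANCE = 1e-2

N_MEAS = 208  # 16 injections x 13 valid adjacent measurement pairs


@dataclass(frozen=True)
class ElectrodeModel:
    """16 equidistant boundary electrodes with per-electrode contact impedance."""

    contact_impedance: np.ndarray = field(
        default_factory=lambda: np.full(N_ELECTRODES, DEFAULT_CONTACT_IMPEDANCE))

    def __post_init__(self):
        z = np.atleast_1d(np.asarray(self.contact_impedance, dtype=float))
        if z.size == 1:
            z = np.full(N_ELECTRODES, z[0])
        if z.size != N_ELECTRODES:
            raise ValueError("need one contact impedance per electrode")
        if not np.all(z > 0):
            raise ValueError("contact impedances must be strictly positive")
        object.__setattr__(self, "contact_impedance", z)


@dataclass
class VoltageFrame:
    """One adjacent-adjacent frame: 208 four-probe voltages in canonical order.

    Ordering: injection pair k = (k, k+1 mod 16) for k = 0..15; within each
    injection the 13 valid measurement pairs j = (j, j+1 mod 16) with
    j not in {k-1, k, k+1} (mod 16), ascending j.
    """

    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != N_MEAS:
            raise ValueError(f"a voltage frame has {N_MEAS} entries, got {v.size}")
        if not np.all(np.isfinite(v)):
            raise ValueError("voltage frame contains non-finite values")
        self.values = v


def valid_measurement_pairs(k: int) -> np.ndarray:
    """Ascending measurement-pair indices j for injection pair k (13 values)."""
    excl = {(k - 1) % 16, k, (k + 1) % 16}
    return np.array([j for j in range(16) if j not in excl])


class ForwardSolver:
    """Factorise-once CEM solver for a fixed mesh; conductivity varies per call."""

    def __init__(self, mesh: DiscMesh):
        self.mesh = mesh
        n = mesh.n_nodes
        ele = mesh.elements
        # conductivity-independent stiffness geometry: per-element 3x3 blocks
        g = mesh.grads                      # (M, 3, 2)
        Ge = np.einsum("mad,mbd->mab", g, g) * mesh.areas[:, None, None]
        rows = np.repeat(ele, 3, axis=1).ravel()          # a index
        cols = np.tile(ele, (1, 3)).ravel()               # b index
        self._stiff_rows = rows
        self._stiff_cols = cols
        self._Ge = Ge.transpose(0, 2, 1).reshape(-1)      # matches rows/cols order
        # electrode boundary mass structures (fixed geometry, scaled by 1/z_l)
        self._elec_mass = []
        self._elec_vec = []
        self._elec_len = []
        for segs in mesh.electrode_segments:
            p0 = mesh.nodes[segs[:, 0]]
            p1 = mesh.nodes[segs[:, 1]]
            d = np.linalg.norm(p1 - p0, axis=1)
            r = np.concatenate([segs[:, 0], segs[:, 0], segs[:, 1], segs[:, 1]])
            c = np.concatenate([segs[:, 0], segs[:, 1], segs[:, 0], segs[:, 1]])
            v = np.concatenate([d / 3, d / 6, d / 6, d / 3])
            self._elec_mass.append(sp.coo_matrix((v, (r, c)), shape=(n, n)).tocsr())
            b = np.zeros(n)
            np.add.at(b, segs[:, 0], d / 2)
            np.add.at(b, segs[:, 1], d / 2)
            self._elec_vec.append(b)
            self._elec_len.append(d.sum())
        self._elec_len = np.asarray(self._elec_len)
        self._n = n

    def _system(self, sigma: np.ndarray, z: np.ndarray) -> sp.csc_matrix:
        n = self.mesh.n_elements
        data = (np.asarray(sigma, dtype=float)[:, None] *
                self._Ge.reshape(n, 9)).ravel()
        K = sp.coo_matrix((data, (self._stiff_rows, self._stiff_cols)),
                          shape=(self._n, self._n)).tocsr()
        for l in range(N_ELECTRODES):
            K = K + self._elec_mass[l] / z[l]
        B = sp.csr_matrix(
            np.column_stack([-b / zl for b, zl in zip(self._elec_vec, z)]))
        D = sp.diags(self._elec_len / z)
        ones = sp.csr_matrix(np.ones((N_ELECTRODES, 1)))
        zcol = sp.csr_matrix((self._n, 1))
        A = sp.bmat([[K, B, zcol],
                     [B.T, D, ones],
                     [zcol.T, ones.T, None]], format="csc")
        return A

    def solve_fields(self, sigma: np.ndarray,
                     electrodes: ElectrodeModel | None = None):
        """Solve the 16 adjacent injections.

        Returns ``(node_potentials (16, n_nodes), electrode_potentials (16, 16))``.
        """
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (self.mesh.n_elements,):
            raise ValueError("sigma must be per-element")
        if not (np.all(np.isfinite(sigma)) and np.all(sigma > 0)):
            raise ValueError("conductivities must be finite and strictly positive")
        electrodes = electrodes or ElectrodeModel()
        A = self._system(sigma, electrodes.contact_impedance)
        try:
            lu = spla.splu(A)
        except RuntimeError as exc:  # pragma: no cover - degenerate input
            raise np.linalg.LinAlgError(f"singular CEM system: {exc}") from exc
        rhs = np.zeros((self._n + N_ELECTRODES + 1, N_ELECTRODES))
        for k in range(N_ELECTRODES):
            rhs[self._n + k, k] = 1.0
            rhs[self._n + (k + 1) % 16, k] = -1.0
        sol = lu.solve(rhs)
        u = sol[:self._n].T
        U = sol[self._n:self._n + N_ELECTRODES].T
        return u, U


def electrode_voltage_matrix(U: np.ndarray) -> np.ndarray:
    """16x16 matrix V[k, j] = adjacent pair-j voltage under injection k."""
    return U - np.roll(U, -1, axis=1)


def pack_frame(V: np.ndarray, meta: dict | None = None) -> VoltageFrame:
    """Extract the 208 valid entries of the 16x16 pair-voltage matrix."""
    vals = np.concatenate(
        [V[k, valid_measurement_pairs(k)] for k in range(N_ELECTRODES)])
    return VoltageFrame(values=vals, meta=meta or {})


def simulate_voltages(mesh: DiscMesh, sigma: np.ndarray,
                      electrodes: ElectrodeModel | None = None,
                      meta: dict | None = None) -> VoltageFrame:
    """Forward-simulate one adjacent-adjacent frame for a conductivity field."""
    solver = _solver_for(mesh)
    _, U = solver.solve_fields(np.asarray(sigma, dtype=float),
                               electrodes)
    return pack_frame(electrode_voltage_matrix(U), meta)


_SOLVER_CACHE: dict = {}


def _solver_for(mesh: DiscMesh) -> ForwardSolver:
    key = id(mesh)
    if key not in _SOLVER_CACHE:
        _SOLVER_CACHE.clear()  # keep at most a couple of meshes alive
        _SOLVER_CACHE[key] = ForwardSolver(mesh)
    return _SOLVER_CACHE[key]


def sample_contact_impedance(rng: np.random.Generator,
                             base: float = DEFAULT_CONTACT_IMPEDANCE,
                             std: float = 1e-3) -> np.ndarray:
    """Per-electrode contact impedances: base times N(1, std), clamped positive."""
    if base <= 0:
        raise ValueError("base contact impedance must be positive")
    if std < 0:
        raise ValueError("std must be non-negative")
    mult = rng.normal(1.0, std, size=N_ELECTRODES)
    return base * np.maximum(mult, 1e-12)


def add_awgn_snr(frame: VoltageFrame, snr_db: float,
                 rng: np.random.Generator) -> VoltageFrame:
    """Add white Gaussian noise at a target amplitude SNR (in dB).

    The noise std is ``||values||_2 / (sqrt(208) * 10**(snr_db/20))`` so that
    the requested SNR is the ratio of RMS signal to noise std.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    v = frame.values
    std = np.linalg.norm(v) / (np.sqrt(v.size) * 10 ** (snr_db / 20.0))
    noisy = v + rng.normal(0.0, std, size=v.size)
    meta = dict(frame.meta)
    meta["snr_db"] = float(snr_db)
    return VoltageFrame(values=noisy, meta=meta)
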