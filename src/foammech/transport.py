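"""Diffusive tortuosity of a binary phase by steady-state diffusion.

The tortuosity factor tau is defined through D_eff = D * eps / tau, where
eps is the phase volume fraction and D_eff/D is obtained by solving the
steady-state Laplace equation on the phase voxels with fixed
concentrations on the inlet and outlet faces of the chosen axis
(Dirichlet:Dirichlet) and either periodic or insulating lateral
boundaries.  The discretization is voxel-centred finite volumes with unit
conductance between adjacent phase voxels and half-cell (conductance 2)
links to the Dirichlet planes, so a fully dense block gives D_eff/D = 1
exactly and straight channels give D_eff/D = eps.

Note the factor is a transport ratio, not a geometric path-length ratio:
a value of tau means diffusive flux is reduced tau-fold relative to free
diffusion through the same volume fraction, which exceeds the squared
centreline elongation for all but idealized channels.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg

from .volume import VoxelVolume

__all__ = [
    "TransportResult",
    "percolation_fraction",
    "tortuosity",
    "field_context",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TransportResult:
    tortuosity_factor: float
    d_eff_ratio: float  # D_eff / D
    volume_fraction: float  # %
    percolation: float  # %
    axis: int
    converged: bool
    residual: float  # relative inlet/outlet flux mismatch
    lateral: str = "periodic"
    n_unknowns: int = 0
    volume_id: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _phase_of(volume: VoxelVolume | np.ndarray) -> np.ndarray:
    grid = volume.grid if isinstance(volume, VoxelVolume) else np.asarray(volume)
    return grid > 0


def _spanning_mask(phase: np.ndarray, axis: int,
                   structure: np.ndarray | None = None) -> np.ndarray:
    """Voxels in connected components touching both end faces of *axis*.

    26-connectivity by default (the percolation convention); the solver
    passes a 6-connected structure since finite-volume flux only crosses
    shared faces.
    """
    labels, n = ndimage.label(phase, structure=structure
                              if structure is not None else _STRUCT26)
    if n == 0:
        return np.zeros_like(phase)
    first = np.take(labels, 0, axis=axis)
    last = np.take(labels, -1, axis=axis)
    spanning = np.intersect1d(np.unique(first), np.unique(last))
    spanning = spanning[spanning > 0]
    return np.isin(labels, spanning)


def percolation_fraction(volume: VoxelVolume | np.ndarray, axis: int = 0) -> float:
    """Percent of phase voxels connected to both inlet and outlet faces."""
    phase = _phase_of(volume)
    total = int(np.count_nonzero(phase))
    if total == 0:
        raise ValueError("empty phase")
    return 100.0 * int(np.count_nonzero(_spanning_mask(phase, axis))) / total


def _build_system(conn: np.ndarray, axis: int, lateral: str,
                  ) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray, np.ndarray]:
    """Sparse SPD system A x = b for unit concentration drop along *axis*.

    ``conn`` is the percolating mask.  Interior faces get conductance 1;
    inlet/outlet Dirichlet planes couple with conductance 2 (half cell).
    Lateral axes wrap around when ``lateral == 'periodic'``.
    """
    conn = np.moveaxis(conn, axis, 0)  # transport along axis 0 internally
    nz, ny, nx = conn.shape
    idx = -np.ones(conn.shape, dtype=np.int64)
    idx[conn] = np.arange(int(conn.sum()))
    n = int(conn.sum())
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    b = np.zeros(n)

    def couple(mask_a, mask_b, g=1.0):
        ia, ib = idx[mask_a], idx[mask_b]
        ok = (ia >= 0) & (ib >= 0)
        ia, ib = ia[ok], ib[ok]
        rows.extend((ia, ib))
        cols.extend((ib, ia))
        vals.extend((np.full(ia.size, -g), np.full(ia.size, -g)))
        np.add.at(diag, ia, g)
        np.add.at(diag, ib, g)

    # transport-axis internal faces
    a_mask = np.zeros(conn.shape, bool)
    b_mask = np.zeros(conn.shape, bool)
    a_mask[:-1], b_mask[1:] = conn[:-1] & conn[1:], conn[:-1] & conn[1:]
    couple(a_mask, b_mask)
    # lateral faces
    for lat in (1, 2):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[lat] = slice(0, -1)
        sl_b[lat] = slice(1, None)
        both = conn[tuple(sl_a)] & conn[tuple(sl_b)]
        a_mask = np.zeros(conn.shape, bool)
        b_mask = np.zeros(conn.shape, bool)
        a_mask[tuple(sl_a)], b_mask[tuple(sl_b)] = both, both
        couple(a_mask, b_mask)
        if lateral == "periodic":
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[lat] = slice(-1, None)
            sl_b[lat] = slice(0, 1)
            both = conn[tuple(sl_a)] & conn[tuple(sl_b)]
            a_mask = np.zeros(conn.shape, bool)
            b_mask = np.zeros(conn.shape, bool)
            a_mask[tuple(sl_a)], b_mask[tuple(sl_b)] = both, both
            couple(a_mask, b_mask)
    # Dirichlet half-cells: inlet c=1 at z=0 face, outlet c=0 at z=nz-1
    inlet = idx[0][conn[0]]
    outlet = idx[-1][conn[-1]]
    np.add.at(diag, inlet, 2.0)
    np.add.at(diag, outlet, 2.0)
    b[inlet] += 2.0  # 2 * c_in with c_in = 1
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n))
    return A, b, idx, conn


def tortuosity(volume: VoxelVolume | np.ndarray, axis: int = 0,
               lateral: str = "periodic", tol: float = 1e-6,
               maxiter: int = 20000, volume_id: str = "") -> TransportResult:
    """Steady-state diffusion solve; tau = eps / (D_eff / D).

    Solves the Laplace equation on the percolating phase by diagonally
    preconditioned conjugate gradients.  ``residual`` is the relative
    mismatch between inlet and outlet fluxes; ``converged`` requires it to
    be below ``tol``.  Raises on a non-percolating phase ("infinite
    tortuosity").
    """
    if lateral not in ("periodic", "insulating"):
        raise ValueError("lateral must be 'periodic' or 'insulating'")
    phase = _phase_of(volume)
    eps = float(np.count_nonzero(phase)) / phase.size
    perc = percolation_fraction(phase, axis)
    conn = _spanning_mask(phase, axis, structure=ndimage.generate_binary_structure(3, 1))
    if not conn.any():
        raise ValueError("phase does not percolate along the axis: "
                         "infinite tortuosity")
    A, b, idx, conn_t = _build_system(conn, axis, lateral)
    n = b.size
    inv_diag = 1.0 / A.diagonal()
    M = sparse.diags(inv_diag)
    x, info = cg(A, b, rtol=min(tol * 1e-2, 1e-8), atol=0.0, maxiter=maxiter, M=M)
    # flux through the Dirichlet half-cells (lattice units, dx = 1)
    c = np.zeros(conn_t.shape)
    c[conn_t] = x
    q_in = float(np.sum(2.0 * (1.0 - c[0][conn_t[0]])))
    q_out = float(np.sum(2.0 * c[-1][conn_t[-1]]))
    q = 0.5 * (q_in + q_out)
    residual = abs(q_in - q_out) / max(abs(q), 1e-300)
    nz = conn_t.shape[0]
    area = conn_t.shape[1] * conn_t.shape[2]
    d_eff = q * nz / area  # (Q L) / (A * delta_c) with delta_c = 1, dx = 1
    tau = eps / d_eff if d_eff > 0 else float("inf")
    return TransportResult(
        tortuosity_factor=float(tau), d_eff_ratio=float(d_eff),
        volume_fraction=100.0 * eps, percolation=perc, axis=axis,
        converged=bool(info == 0 and residual < tol), residual=float(residual),
        lateral=lateral, n_unknowns=n, volume_id=volume_id)


def solve_concentration(volume: VoxelVolume | np.ndarray, axis: int = 0,
                        lateral: str = "periodic") -> np.ndarray:
    """Direct (dense-ready) solve of the same system; oracle for tests."""
    from scipy.sparse.linalg import spsolve

    phase = _phase_of(volume)
    conn = _spanning_mask(phase, axis, structure=ndimage.generate_binary_structure(3, 1))
    A, b, idx, conn_t = _build_system(conn, axis, lateral)
    x = spsolve(A.tocsc(), b)
    c = np.zeros(conn_t.shape)
    c[conn_t] = x
    return c


def field_context(result: TransportResult) -> dict:
    """Provenance bundle for effective-field estimation.

    Refuses an unconverged transport result; the returned record is plain
    JSON-serializable data.
    """
    if not result.converged:
        raise ValueError("refusing to build field context from an "
                         "unconverged transport result")
    return {
        "tortuosity_factor": result.tortuosity_factor,
        "volume_id": result.volume_id,
        "axis": result.axis,
        "bc": "dirichlet_dirichlet",
        "lateral": result.lateral,
        "volume_fraction": result.volume_fraction,
        "percolation": result.percolation,
    }
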