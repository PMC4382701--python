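"""Vertex mechanics: potential energy, forces, and RK4 time integration.

Vertices are embedded in a viscous medium and carry no mass, so positions
follow the overdamped gradient flow ``eta * dx_j/dt = F_j = -dU/dx_j``.
The potential has three terms::

    U = K_S/2 * sum_i (S_i - s_i)^2            cell-area elasticity
      + sum_j (K_B * L_j + K_R / L_j)          edge tension + repulsion
      + K_E/2 * sum_k (L_k - L_E)^2            outer-edge (cuticle) elasticity

where ``i`` runs over cells, ``j`` over all edges and ``k`` over outermost
edges only.  The target area ``s_i`` of an ``N``-gon is the area of the
regular ``N``-gon relative to the regular hexagon of equal edge length, so
cells relax towards unit (hexagon-equivalent) size.  The edge term is
minimal at ``L* = sqrt(K_R/K_B)`` and diverges as ``L -> 0``, which keeps
neighbouring vertices apart; vertex reconnection is never performed.

Each term's functional form lives in its own small function so alternative
forms are one-line swaps.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .errors import GeometryError, StabilityError
from .mesh import CellStates, TissueMesh
from .params import MechanicsParams


def target_area(N_i: int) -> float:
    """Target area of an ``N_i``-sided cell.

    ``s_i = N_i * tan(pi/6) / (6 * tan(pi/N_i))`` — the area of the regular
    ``N_i``-gon relative to the regular hexagon with the same edge length.
    Strictly increasing in ``N_i`` and exactly 1 for a hexagon.
    """
    if N_i < 3:
        raise ValueError(f"a polygon needs >= 3 edges, got {N_i}")
    return N_i * np.tan(np.pi / 6) / (6 * np.tan(np.pi / N_i))


def _area_term(S: np.ndarray, s: np.ndarray, K_S: float) -> float:
    return 0.5 * K_S * float(np.sum((S - s) ** 2))


def _edge_term(L: np.ndarray, K_B: float, K_R: float) -> float:
    return float(np.sum(K_B * L + K_R / L))


def _outer_term(L: np.ndarray, K_E: float, L_E: float) -> float:
    return 0.5 * K_E * float(np.sum((L - L_E) ** 2))


def _edge_lengths(mesh: TissueMesh) -> np.ndarray:
    e = mesh.edges()
    d = mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]]
    return np.linalg.norm(d, axis=1)


def potential_energy(mesh: TissueMesh, states: CellStates | None = None,
                     params: MechanicsParams | None = None) -> float:
    """Total potential energy of the mesh (plain NumPy reference path)."""
    p = params or MechanicsParams()
    S = mesh.cell_areas()
    s = np.array([target_area(len(c)) for c in mesh.cells])
    L = _edge_lengths(mesh)
    if np.any(L == 0):
        raise GeometryError("zero-length edge: repulsive term undefined")
    outer = mesh.edge_outer_flags()
    return (_area_term(S, s, p.K_S) + _edge_term(L, p.K_B, p.K_R)
            + _outer_term(L[outer], p.K_E, p.L_E))


def vertex_forces(mesh: TissueMesh, states: CellStates | None = None,
                  params: MechanicsParams | None = None) -> np.ndarray:
    """Analytic force ``F_j = -dU/dx_j`` per vertex, shape (V, 2)."""
    p = params or MechanicsParams()
    L = _edge_lengths(mesh)
    if np.any(L == 0):
        raise GeometryError("zero-length edge: repulsive term undefined")
    counts = np.array([len(c) for c in mesh.cells], dtype=np.int64)
    cell_ptr = np.zeros(mesh.n_cells + 1, dtype=np.int64)
    cell_ptr[1:] = np.cumsum(counts)
    cell_verts = np.concatenate(mesh.cells)
    s_target = np.array([target_area(n) for n in counts])
    F = np.zeros_like(mesh.vertices)
    _kernels.accumulate_forces(
        mesh.vertices, cell_ptr, cell_verts, s_target,
        mesh.edges(), mesh.edge_outer_flags(),
        p.K_S, p.K_B, p.K_R, p.K_E, p.L_E, F,
    )
    return F


def integrate_step(mesh: TissueMesh, states: CellStates | None = None,
                   params: MechanicsParams | None = None) -> None:
    """Advance vertex positions by one RK4 step of the gradient flow.

    If the step flips a cell (non-positive area), the step size is halved
    and retried, up to 5 times; ``StabilityError`` is raised if the step
    never succeeds.  Positions are updated in place.
    """
    p = params or MechanicsParams()
    counts = np.array([len(c) for c in mesh.cells], dtype=np.int64)
    cell_ptr = np.zeros(mesh.n_cells + 1, dtype=np.int64)
    cell_ptr[1:] = np.cumsum(counts)
    cell_verts = np.concatenate(mesh.cells)
    s_target = np.array([target_area(n) for n in counts])
    ok = _kernels.rk4_step(
        mesh.vertices, cell_ptr, cell_verts, s_target,
        mesh.edges(), mesh.edge_outer_flags(),
        p.K_S, p.K_B, p.K_R, p.K_E, p.L_E, p.eta, p.dt,
    )
    if not ok:
        raise StabilityError(
            "RK4 step produced a flipped cell even after 5 dt halvings"
        )


def relax(mesh: TissueMesh, params: MechanicsParams | None = None,
          steps: int = 1000) -> None:
    """Run `steps` RK4 steps towards mechanical equilibrium (in place)."""
    p = params or MechanicsParams()
    for _ in range(steps):
        integrate_step(mesh, None, p)
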