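"""Reaction-diffusion of morphogens u, v, w on the cell-adjacency graph.

Each species obeys, per cell ``i`` with neighbour set ``nbr(i)``::

    dz_i/dt = A_z * 1[i in sources(z)] - B_z * z_i
              + D_z * sum_{j in nbr(i)} (z_j - z_i)

i.e. constant synthesis in the source cells, linear degradation everywhere
and unweighted graph diffusion (no degree normalisation, no edge-length
weighting).  Sources: ``u`` — the L1 cells flanking the adaxial-abaxial
identity junctions; ``v`` — all L1 cells; ``w`` — adaxial L1 cells.
Time integration is explicit Euler with the shared model time step.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _kernels
from .errors import StabilityError
from .mesh import (IDENTITY_ADAXIAL, LAYER_L1, CellStates, TissueMesh,
                   boundary_source_cells, classify_layers)
from .params import MorphogenParams


def source_mask(mesh: TissueMesh, states: CellStates, species: str) -> np.ndarray:
    """Boolean synthesis-source mask for one species."""
    if states.layer is None or not (states.layer == LAYER_L1).any():
        classify_layers(mesh, states)
    n = mesh.n_cells
    mask = np.zeros(n, dtype=bool)
    if species == "u":
        mask[boundary_source_cells(mesh, states)] = True
    elif species == "v":
        mask[states.layer == LAYER_L1] = True
    elif species == "w":
        mask[(states.layer == LAYER_L1) & (states.identity == IDENTITY_ADAXIAL)] = True
    else:
        raise ValueError(f"unknown species {species!r}")
    return mask


def morphogen_step(mesh: TissueMesh, states: CellStates,
                   params: MorphogenParams | None = None,
                   dt: float = 0.005) -> None:
    """One explicit-Euler step for all three species, in place.

    Raises ``StabilityError`` if any concentration leaves [0, inf) — for a
    valid dt the scheme cannot go negative, so a negative value means
    ``dt * (B_z + D_z * max_degree)`` exceeded the stability bound.
    """
    p = params or MorphogenParams()
    adj_ptr, adj_idx = mesh.adjacency()
    for species, z in (("u", states.u), ("v", states.v), ("w", states.w)):
        A, B, D = p.species(species)
        src = source_mask(mesh, states, species)
        _kernels.morphogen_euler(z, adj_ptr, adj_idx, src, A, B, D, dt)
        if not np.all(np.isfinite(z)) or np.any(z < 0):
            max_deg = int(np.max(np.diff(adj_ptr)))
            raise StabilityError(
                f"Euler step unstable for {species}: "
                f"dt*(B + D*max_degree) = {dt * (B + D * max_deg):.3f}"
            )


def graph_laplacian(mesh: TissueMesh) -> sp.csr_matrix:
    """Unnormalised Laplacian (degree - adjacency) of the cell graph."""
    adj_ptr, adj_idx = mesh.adjacency()
    n = mesh.n_cells
    data = np.ones(len(adj_idx))
    A = sp.csr_matrix((data, adj_idx, adj_ptr), shape=(n, n))
    deg = sp.diags(np.asarray(A.sum(axis=1)).ravel())
    return (deg - A).tocsr()


def steady_state(mesh: TissueMesh, states: CellStates,
                 params: MorphogenParams | None = None,
                 species: str = "u") -> np.ndarray:
    """Exact steady state by direct linear solve.

    Solves ``(B*I + D*Lap) z = A * source`` on the fixed cell graph; the
    Euler trajectory of :func:`morphogen_step` converges to this solution.
    Used as the oracle for the time-stepped path.
    """
    p = params or MorphogenParams()
    A_z, B_z, D_z = p.species(species)
    n = mesh.n_cells
    src = source_mask(mesh, states, species).astype(float)
    M = (B_z * sp.identity(n, format="csr") + D_z * graph_laplacian(mesh)).tocsc()
    if B_z == 0:
        # pure diffusion: singular whenever the graph is disconnected
        lap = graph_laplacian(mesh)
        ncomp = sp.csgraph.connected_components(lap, directed=False)[0]
        if ncomp > 1:
            raise np.linalg.LinAlgError(
                "B=0 with a disconnected graph: steady state undefined"
            )
    return spla.spsolve(M, A_z * src)
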