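"""Flattened array view of a mesh + states for the compiled kernels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import (IDENTITY_ADAXIAL, LAYER_L1, CellStates, TissueMesh,
                   boundary_source_cells, classify_layers)
from .mechanics import target_area


@dataclass
class FlatTopo:
    """CSR arrays mirroring the topology of one ``TissueMesh``; rebuilt
    after every division, shared across RK4/morphogen/clock kernels."""

    cell_ptr: np.ndarray
    cell_verts: np.ndarray
    s_target: np.ndarray
    edges: np.ndarray
    edge_outer: np.ndarray
    adj_ptr: np.ndarray
    adj_idx: np.ndarray
    src_u: np.ndarray
    src_v: np.ndarray
    src_w: np.ndarray
    epidermal: np.ndarray


def build_flat(mesh: TissueMesh, states: CellStates) -> FlatTopo:
    classify_layers(mesh, states)
    counts = np.array([len(c) for c in mesh.cells], dtype=np.int64)
    cell_ptr = np.zeros(mesh.n_cells + 1, dtype=np.int64)
    cell_ptr[1:] = np.cumsum(counts)
    cell_verts = np.concatenate(mesh.cells) if mesh.cells else np.empty(0, np.int64)
    s_target = np.array([target_area(n) for n in counts])
    edges = mesh.edges()
    edge_outer = mesh.edge_outer_flags()
    adj_ptr, adj_idx = mesh.adjacency()
    l1 = states.layer == LAYER_L1
    src_u = np.zeros(mesh.n_cells, dtype=np.bool_)
    src_u[boundary_source_cells(mesh, states)] = True
    src_v = l1.copy()
    src_w = l1 & (states.identity == IDENTITY_ADAXIAL)
    return FlatTopo(cell_ptr, cell_verts, s_target, edges, edge_outer,
                    adj_ptr, adj_idx, src_u, src_v, src_w, l1.copy())
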