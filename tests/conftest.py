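"""Shared fixtures: hand-built meshes and (session-scoped) simulation runs."""

from __future__ import annotations

import numpy as np
import pytest

from pitchersim.mesh import (IDENTITY_ABAXIAL, IDENTITY_ADAXIAL, CellStates,
                             TissueMesh, classify_layers)


def make_wheel_mesh(n_sectors: int = 10, radius: float = 1.0):
    """Pie of `n_sectors` triangular cells around a shared hub vertex.

    Every cell touches the boundary (all L1) and cell i neighbours cells
    i-1 and i+1 through the radial spokes: a ring adjacency of L1 cells.
    """
    phi = np.linspace(0, 2 * np.pi, n_sectors, endpoint=False)
    rim = np.column_stack([radius * np.cos(phi), radius * np.sin(phi)])
    vertices = np.vstack([[0.0, 0.0], rim])
    cells = [[0, 1 + i, 1 + (i + 1) % n_sectors] for i in range(n_sectors)]
    return TissueMesh(vertices, cells)


def make_onion_mesh(n_rings: int = 5, n_sectors: int = 8):
    """Concentric rings of quadrilateral cells around a central n-gon.

    Ring r (1-based, from the centre outwards) sits between radii r and
    r+1; classification from outside in runs L1, L2, L3, inner, ...
    """
    vertices = []
    ring_ids = []
    for r in range(1, n_rings + 1):
        phi = np.linspace(0, 2 * np.pi, n_sectors, endpoint=False)
        ids = []
        for p in phi:
            ids.append(len(vertices))
            vertices.append((r * np.cos(p), r * np.sin(p)))
        ring_ids.append(ids)
    cells = [ring_ids[0]]  # central cell (vertex angles increase: CCW)
    for r in range(n_rings - 1):
        inner, outer = ring_ids[r], ring_ids[r + 1]
        for i in range(n_sectors):
            j = (i + 1) % n_sectors
            cells.append([inner[i], outer[i], outer[j], inner[j]])
    return TissueMesh(np.array(vertices, dtype=float), cells)


def states_for(mesh: TissueMesh, adaxial: list[int] | None = None,
               abaxial_rest: bool = True) -> CellStates:
    """Fresh states with identities painted on the L1 cells."""
    states = CellStates.zeros(mesh.n_cells)
    classify_layers(mesh, states)
    l1 = states.layer == 1
    if abaxial_rest:
        states.identity[l1] = IDENTITY_ABAXIAL
    if adaxial:
        states.identity[adaxial] = IDENTITY_ADAXIAL
    classify_layers(mesh, states)
    return states


@pytest.fixture
def wheel_mesh():
    return make_wheel_mesh()


@pytest.fixture
def onion_mesh():
    return make_onion_mesh()


@pytest.fixture(scope="session")
def default_tissue():
    """The default ~100-cell depression-shaped initial tissue."""
    from pitchersim import build_initial_mesh

    return build_initial_mesh()


#: stop criterion of the desk-scale phenotype runs (see docs/methods.md)
PHENOTYPE_MAX_CELLS = 250


@pytest.fixture(scope="session")
def phenotype_runs():
    """Desk-scale hollow and ridge simulations, three seeds each, at the
    default model constants."""
    from pitchersim import RunConfig, run_simulation

    runs = {}
    for mode in ("hollow", "ridge"):
        for seed in (1, 2, 3):
            cfg = RunConfig(mode=mode, max_cells=PHENOTYPE_MAX_CELLS,
                            seed=seed)
            runs[(mode, seed)] = run_simulation(cfg)
    return runs


@pytest.fixture(scope="session")
def short_run_pair():
    """One short simulation executed twice with the same config and seed,
    shared by the driver tests and the reproducibility checks."""
    from pitchersim import RunConfig, run_simulation

    cfg = RunConfig(max_cells=118, seed=7)
    return cfg, run_simulation(cfg), run_simulation(cfg)
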