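"""Polygonal tissue mesh: shared-vertex cell aggregate and per-cell state.

A tissue cross-section is a planar aggregate of simple polygons that share
vertices and edges.  Interior edges are shared by exactly two cells; the
outermost edges (the tissue surface) belong to exactly one cell.  Vertices
are never reconnected between cells: the cell wall fixes relative cell
positions, so topology changes only through cell division.

Coordinate convention: the abaxial side points towards +y and the adaxial
side (with the initial depression) towards -y; renderers flip the axis for
display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TopologyError

# identity codes (epidermal differentiation state)
IDENTITY_NONE = 0
IDENTITY_ADAXIAL = 1
IDENTITY_ABAXIAL = 2

# layer codes
LAYER_L1 = 1
LAYER_L2 = 2
LAYER_L3 = 3
LAYER_INNER = 4

# sub-label codes for L2/L3 (side of the tissue the layer descends from)
SUB_NONE = 0
SUB_ADAXIAL = 1
SUB_ABAXIAL = 2

IDENTITY_NAMES = {IDENTITY_NONE: "none", IDENTITY_ADAXIAL: "adaxial", IDENTITY_ABAXIAL: "abaxial"}
LAYER_NAMES = {LAYER_L1: "L1", LAYER_L2: "L2", LAYER_L3: "L3", LAYER_INNER: "inner"}


def polygon_signed_area(pts: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given as an (N,2) array.

    Positive for counter-clockwise orientation.
    """
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _polygon_is_simple(pts: np.ndarray) -> bool:
    # Lazy import keeps shapely off the hot path; this runs only in audits.
    from shapely.geometry import Polygon

    return Polygon(pts).is_valid


class TissueMesh:
    """Shared-vertex polygonal cell aggregate.

    Parameters
    ----------
    vertices : (V, 2) float array
        Vertex positions in model units.
    cells : sequence of int sequences
        One counter-clockwise vertex-index cycle per cell.

    Derived edge/adjacency structures are cached and invalidated whenever
    the topology changes (`invalidate()`); vertex *positions* may move
    freely without invalidating them.
    """

    def __init__(self, vertices: np.ndarray, cells: list) -> None:
        self.vertices = np.asarray(vertices, dtype=float).copy()
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (V, 2) array")
        self.cells: list[np.ndarray] = [np.asarray(c, dtype=np.int64) for c in cells]
        for c in self.cells:
            if len(c) < 3:
                raise TopologyError("every cell needs >= 3 vertices")
        self._cache: dict = {}

    # ------------------------------------------------------------------ #
    # derived topology                                                    #
    # ------------------------------------------------------------------ #
    def invalidate(self) -> None:
        """Drop cached derived structures after a topology change."""
        self._cache.clear()

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def _edge_map(self) -> dict[tuple[int, int], list[int]]:
        """Map from undirected edge (min,max vertex ids) to owning cell ids."""
        if "edge_map" not in self._cache:
            em: dict[tuple[int, int], list[int]] = {}
            for ci, cyc in enumerate(self.cells):
                for k in range(len(cyc)):
                    a, b = int(cyc[k]), int(cyc[(k + 1) % len(cyc)])
                    key = (a, b) if a < b else (b, a)
                    em.setdefault(key, []).append(ci)
            self._cache["edge_map"] = em
        return self._cache["edge_map"]

    def edges(self) -> np.ndarray:
        """(E, 2) array of undirected edges (vertex id pairs, min first)."""
        if "edges" not in self._cache:
            em = self._edge_map()
            keys = sorted(em)
            self._cache["edges"] = np.array(keys, dtype=np.int64).reshape(-1, 2)
            self._cache["edge_outer"] = np.array(
                [len(em[k]) == 1 for k in keys], dtype=bool
            )
        return self._cache["edges"]

    def edge_outer_flags(self) -> np.ndarray:
        """Boolean flag per edge: True if the edge lies on the tissue surface."""
        self.edges()
        return self._cache["edge_outer"]

    def cell_neighbors(self, cell_id: int) -> list[int]:
        """Cells sharing an edge with `cell_id`, in cycle order."""
        em = self._edge_map()
        cyc = self.cells[cell_id]
        out = []
        for k in range(len(cyc)):
            a, b = int(cyc[k]), int(cyc[(k + 1) % len(cyc)])
            key = (a, b) if a < b else (b, a)
            for other in em[key]:
                if other != cell_id:
                    out.append(other)
        return out

    def adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR neighbour lists over cells: (indptr, indices)."""
        if "adj" not in self._cache:
            nbrs = [self.cell_neighbors(ci) for ci in range(self.n_cells)]
            indptr = np.zeros(self.n_cells + 1, dtype=np.int64)
            indptr[1:] = np.cumsum([len(n) for n in nbrs])
            indices = np.array(
                [j for n in nbrs for j in n] or [], dtype=np.int64
            )
            self._cache["adj"] = (indptr, indices)
        return self._cache["adj"]

    def cell_outer_edge_counts(self) -> np.ndarray:
        """Number of outermost (surface) edges owned by each cell."""
        if "outer_counts" not in self._cache:
            em = self._edge_map()
            counts = np.zeros(self.n_cells, dtype=np.int64)
            for key, owners in em.items():
                if len(owners) == 1:
                    counts[owners[0]] += 1
            self._cache["outer_counts"] = counts
        return self._cache["outer_counts"]

    def boundary_cycle(self) -> np.ndarray:
        """Ordered vertex ids of the outer boundary, counter-clockwise.

        Raises ``TopologyError`` if the boundary is not a single closed loop.
        """
        if "boundary" in self._cache:
            return self._cache["boundary"]
        em = self._edge_map()
        # directed outer edges as they appear in their owning cell's CCW
        # cycle: interior on the left, so chaining them walks CCW.
        succ: dict[int, int] = {}
        for ci, cyc in enumerate(self.cells):
            for k in range(len(cyc)):
                a, b = int(cyc[k]), int(cyc[(k + 1) % len(cyc)])
                key = (a, b) if a < b else (b, a)
                if len(em[key]) == 1:
                    if a in succ:
                        raise TopologyError("outer boundary branches at vertex %d" % a)
                    succ[a] = b
        if not succ:
            raise TopologyError("mesh has no outer boundary")
        start = next(iter(succ))
        loop = [start]
        v = succ[start]
        while v != start:
            loop.append(v)
            if v not in succ or len(loop) > len(succ):
                raise TopologyError("outer boundary is not a single closed loop")
            v = succ[v]
        if len(loop) != len(succ):
            raise TopologyError("mesh boundary has more than one loop (holes?)")
        self._cache["boundary"] = np.array(loop, dtype=np.int64)
        return self._cache["boundary"]

    # ------------------------------------------------------------------ #
    # geometry                                                            #
    # ------------------------------------------------------------------ #
    def cell_polygon(self, cell_id: int) -> np.ndarray:
        return self.vertices[self.cells[cell_id]]

    def cell_areas(self) -> np.ndarray:
        return np.array(
            [polygon_signed_area(self.cell_polygon(i)) for i in range(self.n_cells)]
        )

    def cell_centres(self) -> np.ndarray:
        """Per-cell centre: unweighted mean of the cell's vertex positions."""
        return np.array(
            [self.vertices[cyc].mean(axis=0) for cyc in self.cells]
        )

    def copy(self) -> "TissueMesh":
        return TissueMesh(self.vertices.copy(), [c.copy() for c in self.cells])


def compute_cell_geometry(mesh: TissueMesh, cell_id: int):
    """Area, centre and edge lengths of one cell.

    Returns
    -------
    S : float
        Shoelace area (cells are CCW, so positive for a valid cell).
    x_c : (2,) array
        Unweighted mean of the cell's vertex positions.
    L : (N,) array
        Euclidean edge lengths, edge ``k`` running from vertex ``k`` to
        ``k+1`` of the cycle.

    Raises ``TopologyError`` for degenerate polygons (area <= 0 or fewer
    than 3 vertices).
    """
    if cell_id < 0 or cell_id >= mesh.n_cells:
        raise KeyError(f"no cell {cell_id}")
    pts = mesh.cell_polygon(cell_id)
    if len(pts) < 3:
        raise TopologyError(f"cell {cell_id} has fewer than 3 vertices")
    S = polygon_signed_area(pts)
    if S <= 0:
        raise TopologyError(f"cell {cell_id} has non-positive area {S}")
    x_c = pts.mean(axis=0)
    L = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    return S, x_c, L


@dataclass
class CellStates:
    """Per-cell state arrays, index-aligned with ``TissueMesh.cells``.

    ``identity`` is the fixed epidermal differentiation state (adaxial /
    abaxial / none); ``layer`` and ``sub`` are derived positional labels
    refreshed by :func:`classify_layers`.
    """

    identity: np.ndarray  # int8 identity codes
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    clock: np.ndarray
    threshold: np.ndarray
    layer: np.ndarray = field(default=None)  # type: ignore[assignment]
    sub: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.identity)
        if self.layer is None:
            self.layer = np.zeros(n, dtype=np.int8)
        if self.sub is None:
            self.sub = np.zeros(n, dtype=np.int8)
        for name in ("u", "v", "w", "clock", "threshold"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")

    @classmethod
    def zeros(cls, n: int, rng: np.random.Generator | None = None,
              C: float = 10_000.0, fluct: float = 0.10) -> "CellStates":
        """Fresh states: all concentrations and clocks 0, thresholds drawn
        uniformly on ``[(1-fluct)C, (1+fluct)C]`` (or exactly C without rng)."""
        if rng is None:
            thr = np.full(n, C)
        else:
            thr = rng.uniform((1 - fluct) * C, (1 + fluct) * C, size=n)
        return cls(
            identity=np.zeros(n, dtype=np.int8),
            u=np.zeros(n), v=np.zeros(n), w=np.zeros(n),
            clock=np.zeros(n), threshold=thr,
        )

    @property
    def n_cells(self) -> int:
        return len(self.identity)

    def copy(self) -> "CellStates":
        return CellStates(*(getattr(self, f).copy() for f in
                            ("identity", "u", "v", "w", "clock", "threshold",
                             "layer", "sub")))


def classify_layers(mesh: TissueMesh, states: CellStates) -> None:
    """Assign positional layer labels (L1/L2/L3/inner) and the adaxial /
    abaxial sub-label of L2 and L3 cells, in place.

    L1 are the cells owning at least one outermost edge; L2 the remaining
    cells sharing an edge with L1; L3 those sharing an edge with L2; the
    rest are inner.  Adaxial L2 are the L2 cells connected with adaxial L1,
    adaxial L3 those connected with adaxial L2 (and analogously abaxial);
    a cell touching both sides is labelled adaxial.
    """
    n = mesh.n_cells
    layer = np.full(n, LAYER_INNER, dtype=np.int8)
    outer_counts = mesh.cell_outer_edge_counts()
    l1 = outer_counts > 0
    layer[l1] = LAYER_L1

    indptr, indices = mesh.adjacency()

    def touches(mask: np.ndarray) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        for ci in range(n):
            nb = indices[indptr[ci]:indptr[ci + 1]]
            if mask[nb].any():
                out[ci] = True
        return out

    l2 = touches(l1) & ~l1
    layer[l2] = LAYER_L2
    l3 = touches(l2) & ~l1 & ~l2
    layer[l3] = LAYER_L3

    sub = np.zeros(n, dtype=np.int8)
    ada_prev = l1 & (states.identity == IDENTITY_ADAXIAL)
    aba_prev = l1 & (states.identity == IDENTITY_ABAXIAL)
    for lab, mask in ((LAYER_L2, l2), (LAYER_L3, l3)):
        t_ada = touches(ada_prev) & mask
        t_aba = touches(aba_prev) & mask
        sub[t_aba] = SUB_ABAXIAL
        sub[t_ada] = SUB_ADAXIAL  # adaxial wins a tie
        ada_prev, aba_prev = mask & (sub == SUB_ADAXIAL), mask & (sub == SUB_ABAXIAL)

    states.layer = layer
    states.sub = sub


def boundary_source_cells(mesh: TissueMesh, states: CellStates) -> np.ndarray:
    """L1 cells flanking an adaxial-abaxial identity junction.

    Every L1 cell sharing an edge with an L1 cell of the opposite identity
    is a source of the division-promoting morphogen u.  Raises
    ``ConfigurationError`` when either identity is absent (no junction).
    """
    if states.layer is None or not (states.layer == LAYER_L1).any():
        classify_layers(mesh, states)
    l1 = states.layer == LAYER_L1
    ident = states.identity
    if not (l1 & (ident == IDENTITY_ADAXIAL)).any() or not (
        l1 & (ident == IDENTITY_ABAXIAL)
    ).any():
        raise ConfigurationError("need both adaxial and abaxial L1 cells")
    indptr, indices = mesh.adjacency()
    out = []
    for ci in np.flatnonzero(l1):
        nb = indices[indptr[ci]:indptr[ci + 1]]
        nb = nb[l1[nb]]
        opposite = (
            IDENTITY_ABAXIAL if ident[ci] == IDENTITY_ADAXIAL else IDENTITY_ADAXIAL
        )
        if (ident[nb] == opposite).any():
            out.append(ci)
    return np.array(sorted(out), dtype=np.int64)


def audit_topology(mesh: TissueMesh, check_simple: bool = True,
                   tol: float = 1e-9) -> None:
    """Full topological/geometric audit; raises ``TopologyError`` on failure.

    Checks: >=3 vertices and positive (CCW) shoelace area per cell, simple
    polygons, interior edges shared by exactly 2 cells and outer edges by
    exactly 1, a single closed outer boundary whose shoelace area equals
    the sum of cell areas (no gaps or overlaps) within `tol` relative.
    """
    total = 0.0
    for ci in range(mesh.n_cells):
        pts = mesh.cell_polygon(ci)
        if len(pts) < 3:
            raise TopologyError(f"cell {ci}: fewer than 3 vertices")
        S = polygon_signed_area(pts)
        if S <= 0:
            raise TopologyError(f"cell {ci}: non-positive area {S}")
        if len(np.unique(mesh.cells[ci])) != len(mesh.cells[ci]):
            raise TopologyError(f"cell {ci}: repeated vertex in cycle")
        if check_simple and not _polygon_is_simple(pts):
            raise TopologyError(f"cell {ci}: self-intersecting polygon")
        total += S
    em = mesh._edge_map()
    for key, owners in em.items():
        if len(owners) > 2:
            raise TopologyError(f"edge {key} shared by {len(owners)} cells")
    loop = mesh.boundary_cycle()
    outer_area = polygon_signed_area(mesh.vertices[loop])
    if abs(outer_area - total) > tol * max(1.0, abs(total)):
        raise TopologyError(
            f"cell areas sum to {total} but boundary encloses {outer_area}"
        )


# ---------------------------------------------------------------------- #
# serialization (CSV pair, round-trippable)                               #
# ---------------------------------------------------------------------- #
def save_mesh(mesh: TissueMesh, states: CellStates, out_dir) -> None:
    """Write ``vertices.csv`` and ``cells.csv`` into `out_dir`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"id": np.arange(mesh.n_vertices),
         "x": mesh.vertices[:, 0], "y": mesh.vertices[:, 1]}
    ).to_csv(out / "vertices.csv", index=False)
    pd.DataFrame(
        {
            "id": np.arange(mesh.n_cells),
            "vertex_cycle": [" ".join(map(str, c)) for c in mesh.cells],
            "identity": [IDENTITY_NAMES[int(i)] for i in states.identity],
            "u": states.u, "v": states.v, "w": states.w,
            "clock": states.clock, "threshold": states.threshold,
        }
    ).to_csv(out / "cells.csv", index=False)


def load_mesh(in_dir) -> tuple[TissueMesh, CellStates]:
    """Read the CSV pair written by :func:`save_mesh`."""
    src = Path(in_dir)
    vdf = pd.read_csv(src / "vertices.csv").sort_values("id")
    cdf = pd.read_csv(src / "cells.csv").sort_values("id")
    vertices = vdf[["x", "y"]].to_numpy()
    cells = [np.fromstring(s, dtype=np.int64, sep=" ") for s in cdf["vertex_cycle"]]
    mesh = TissueMesh(vertices, cells)
    name_to_code = {v: k for k, v in IDENTITY_NAMES.items()}
    states = CellStates(
        identity=np.array([name_to_code[s] for s in cdf["identity"]], dtype=np.int8),
        u=cdf["u"].to_numpy(), v=cdf["v"].to_numpy(), w=cdf["w"].to_numpy(),
        clock=cdf["clock"].to_numpy(), threshold=cdf["threshold"].to_numpy(),
    )
    classify_layers(mesh, states)
    return mesh, states
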