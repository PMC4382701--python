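"""Procedural generation of the initial primordium cross-section.

The starting tissue is a round aggregate of roughly one hundred polygonal
cells with a small depression on the adaxial side (or a plain disc for the
round control).  Construction: jittered hexagonal seed points inside the
notched disc, a few rounds of centroidal (Lloyd) relaxation of the clipped
Voronoi diagram, conversion to a shared-vertex mesh with one outer chord
per boundary cell, then mechanical relaxation.  A contiguous string of
boundary cells centred on the depression receives the adaxial epidermal
identity; all other boundary cells are abaxial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from . import _kernels
from .errors import GenerationError
from .mesh import (IDENTITY_ABAXIAL, IDENTITY_ADAXIAL, LAYER_L1, CellStates,
                   TissueMesh, audit_topology, classify_layers,
                   polygon_signed_area)
from .mechanics import target_area
from .params import ClockParams, MechanicsParams


@dataclass
class InitialShapeSpec:
    """Geometry and bookkeeping of the initial cell aggregate.

    Depression depth and width are fractions of the disc diameter; the
    depression profile is a raised-cosine notch.  Cell areas are in model
    units with the regular hexagon of unit area as the reference, so a
    target of ~100 cells means a disc of area ~100.
    """

    n_cells: int = 100
    shape: str = "depression"  # or "round"
    depression_depth: float = 0.15
    depression_width: float = 0.35
    adaxial_count: int = 6
    relax_steps: int = 1500
    lloyd_iterations: int = 4
    jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 20:
            raise ValueError("n_cells must be >= 20")
        if self.shape not in ("depression", "round"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.adaxial_count < 2:
            raise ValueError("adaxial_count must be >= 2")


def _domain_polygon(spec: InitialShapeSpec, n_arc: int = 720) -> Polygon:
    """Notched-disc domain boundary (adaxial side towards -y)."""
    R = np.sqrt(spec.n_cells / np.pi)
    phi = np.linspace(0, 2 * np.pi, n_arc, endpoint=False)
    r = np.full(n_arc, R)
    if spec.shape == "depression":
        depth = spec.depression_depth * 2 * R
        width = spec.depression_width * 2 * R
        half_angle = width / (2 * R)
        dphi = np.angle(np.exp(1j * (phi - (-np.pi / 2))))
        in_notch = np.abs(dphi) < half_angle
        r[in_notch] -= depth * 0.5 * (1 + np.cos(np.pi * dphi[in_notch] / half_angle))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    return Polygon(pts)


def _hex_seeds(domain: Polygon, n_target: int,
               rng: np.random.Generator, jitter: float) -> np.ndarray:
    """Jittered hexagonal lattice points inside the domain, with the
    lattice constant set so the point count approximates `n_target`."""
    a = np.sqrt(2 * domain.area / (np.sqrt(3) * n_target))
    minx, miny, maxx, maxy = domain.bounds
    rows = int(np.ceil((maxy - miny) / (a * np.sqrt(3) / 2))) + 2
    cols = int(np.ceil((maxx - minx) / a)) + 2
    pts = []
    for i in range(rows):
        y = miny + (i - 0.5) * a * np.sqrt(3) / 2
        off = 0.5 * a if i % 2 else 0.0
        for j in range(cols):
            x = minx + (j - 0.5) * a + off
            pts.append((x, y))
    pts = np.array(pts)
    pts = pts + rng.uniform(-jitter * a, jitter * a, size=pts.shape)
    from shapely import contains_xy

    keep = contains_xy(domain, pts[:, 0], pts[:, 1])
    return pts[keep]


def _clipped_voronoi(seeds: np.ndarray, domain: Polygon) -> list[Polygon]:
    """Bounded Voronoi cell polygons of `seeds`, clipped to `domain`."""
    R_far = 20.0 * max(abs(b) for b in domain.bounds)
    ghost_phi = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    ghosts = np.column_stack([R_far * np.cos(ghost_phi), R_far * np.sin(ghost_phi)])
    vor = Voronoi(np.vstack([seeds, ghosts]))
    polys = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise GenerationError("unbounded Voronoi region despite ghosts")
        cell = Polygon(vor.vertices[region]).intersection(domain)
        if cell.geom_type == "MultiPolygon":
            cell = max(cell.geoms, key=lambda g: g.area)
        if cell.is_empty or cell.area <= 0:
            raise GenerationError("empty clipped Voronoi cell")
        polys.append(cell)
    return polys


def _polygons_to_mesh(polys: list[Polygon], snap: float = 1e-7) -> TissueMesh:
    """Shared-vertex mesh from clipped cell polygons via coordinate snapping,
    with each cell's run(s) of outer-boundary vertices collapsed to chords."""
    key_to_id: dict[tuple[int, int], int] = {}
    vertices: list[tuple[float, float]] = []
    cells = []
    for poly in polys:
        ring = np.asarray(poly.exterior.coords)[:-1]
        if polygon_signed_area(ring) < 0:
            ring = ring[::-1]
        cyc = []
        for x, y in ring:
            key = (round(x / snap), round(y / snap))
            if key not in key_to_id:
                key_to_id[key] = len(vertices)
                vertices.append((x, y))
            vid = key_to_id[key]
            if not cyc or cyc[-1] != vid:
                cyc.append(vid)
        if cyc and cyc[0] == cyc[-1]:
            cyc.pop()
        if len(cyc) < 3:
            raise GenerationError("degenerate cell after snapping")
        cells.append(cyc)
    mesh = TissueMesh(np.array(vertices), cells)
    _collapse_boundary_arcs(mesh)
    return mesh


def _collapse_boundary_arcs(mesh: TissueMesh) -> None:
    """Replace each cell's chain of consecutive outer edges by one chord.

    Arc-interior vertices belong to a single cell, so removing them keeps
    the mesh watertight; afterwards every boundary cell owns exactly one
    outermost edge per boundary run.
    """
    em = mesh._edge_map()
    # vertices used by >1 cell must be kept
    use_count = np.zeros(mesh.n_vertices, dtype=int)
    for cyc in mesh.cells:
        use_count[cyc] += 1

    def edge_outer(a: int, b: int) -> bool:
        key = (a, b) if a < b else (b, a)
        return len(em[key]) == 1

    new_cells = []
    for cyc in mesh.cells:
        m = len(cyc)
        droppable = []
        for k in range(m):
            v = int(cyc[k])
            prv = int(cyc[(k - 1) % m])
            nxt = int(cyc[(k + 1) % m])
            # v is interior to an outer arc and private to this cell
            if edge_outer(prv, v) and edge_outer(v, nxt) and use_count[v] == 1:
                droppable.append(k)
        # keep >= 4 vertices per cell: retain middle arc vertices if needed
        while droppable and m - len(droppable) < 4:
            droppable.pop(len(droppable) // 2)
        keep = [int(cyc[k]) for k in range(m) if k not in set(droppable)]
        new_cells.append(np.array(keep, dtype=np.int64))
    mesh.cells = new_cells
    mesh.invalidate()
    # drop now-unreferenced vertices and reindex
    used = np.zeros(mesh.n_vertices, dtype=bool)
    for cyc in mesh.cells:
        used[cyc] = True
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(int(used.sum()))
    mesh.vertices = mesh.vertices[used]
    mesh.cells = [remap[cyc] for cyc in mesh.cells]
    mesh.invalidate()


def _boundary_cell_sequence(mesh: TissueMesh) -> list[int]:
    """Boundary cells in the order their outer edges appear along the
    outer boundary loop (counter-clockwise, deduplicated)."""
    em = mesh._edge_map()
    loop = mesh.boundary_cycle()
    nb = len(loop)
    seq: list[int] = []
    for k in range(nb):
        a, b = int(loop[k]), int(loop[(k + 1) % nb])
        key = (a, b) if a < b else (b, a)
        owner = em[key][0]
        if not seq or seq[-1] != owner:
            seq.append(owner)
    if len(seq) > 1 and seq[0] == seq[-1]:
        seq.pop()
    return seq


def _relax(mesh: TissueMesh, params: MechanicsParams, steps: int) -> None:
    counts = np.array([len(c) for c in mesh.cells], dtype=np.int64)
    cell_ptr = np.zeros(mesh.n_cells + 1, dtype=np.int64)
    cell_ptr[1:] = np.cumsum(counts)
    cell_verts = np.concatenate(mesh.cells)
    s_target = np.array([target_area(n) for n in counts])
    edges = mesh.edges()
    outer = mesh.edge_outer_flags()
    for _ in range(steps):
        ok = _kernels.rk4_step(mesh.vertices, cell_ptr, cell_verts, s_target,
                               edges, outer, params.K_S, params.K_B,
                               params.K_R, params.K_E, params.L_E,
                               params.eta, params.dt)
        if not ok:
            raise GenerationError("mechanical relaxation flipped a cell")


def build_initial_mesh(spec: InitialShapeSpec | None = None,
                       mech: MechanicsParams | None = None,
                       clock: ClockParams | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[TissueMesh, CellStates]:
    """Generate the initial tissue: mesh plus fresh cell states.

    Morphogens and clocks start at zero; thresholds are drawn from `rng`
    (derived from ``spec.seed`` when not given).  Raises
    ``GenerationError`` when the tessellation misses the target cell count
    by more than 10%.
    """
    spec = spec or InitialShapeSpec()
    mech = mech or MechanicsParams()
    clock = clock or ClockParams()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    domain = _domain_polygon(spec)
    seeds = _hex_seeds(domain, spec.n_cells, rng, spec.jitter)
    for _ in range(spec.lloyd_iterations):
        polys = _clipped_voronoi(seeds, domain)
        seeds = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    polys = _clipped_voronoi(seeds, domain)
    if abs(len(polys) - spec.n_cells) > 0.1 * spec.n_cells:
        raise GenerationError(
            f"tessellation produced {len(polys)} cells, "
            f"target {spec.n_cells} +- 10%"
        )
    mesh = _polygons_to_mesh(polys)
    audit_topology(mesh)
    _relax(mesh, mech, spec.relax_steps)
    audit_topology(mesh)

    states = CellStates.zeros(mesh.n_cells, rng=rng, C=clock.C,
                              fluct=clock.threshold_fluctuation)
    seq = _boundary_cell_sequence(mesh)
    if spec.adaxial_count >= len(seq) / 2:
        raise GenerationError("adaxial_count must be < half the boundary cells")
    centres = mesh.cell_centres()
    R = np.sqrt(spec.n_cells / np.pi)
    notch_tip = np.array([0.0, -R])  # deepest point of the adaxial side
    d = np.linalg.norm(centres[seq] - notch_tip, axis=1)
    k0 = int(np.argmin(d))
    nsel = spec.adaxial_count
    picks = [(k0 - nsel // 2 + i) % len(seq) for i in range(nsel)]
    states.identity[:] = 0
    for ci in seq:
        states.identity[ci] = IDENTITY_ABAXIAL
    for k in picks:
        states.identity[seq[k]] = IDENTITY_ADAXIAL
    classify_layers(mesh, states)
    return mesh, states


def audit_initial(mesh: TissueMesh, states: CellStates) -> dict:
    """Sanity report of a generated tissue; raises on invariant violations."""
    if mesh.n_cells == 0:
        raise GenerationError("empty mesh")
    audit_topology(mesh)
    classify_layers(mesh, states)
    areas = mesh.cell_areas()
    loop = mesh.boundary_cycle()
    bpts = mesh.vertices[loop]
    blen = float(np.sum(np.linalg.norm(np.roll(bpts, -1, axis=0) - bpts, axis=1)))
    from .mesh import LAYER_NAMES, IDENTITY_NAMES

    report = {
        "n_cells": mesh.n_cells,
        "mean_area": float(areas.mean()),
        "boundary_length": blen,
        "layer_counts": {name: int((states.layer == code).sum())
                         for code, name in LAYER_NAMES.items()},
        "identity_counts": {name: int((states.identity == code).sum())
                            for code, name in IDENTITY_NAMES.items()},
    }
    ada = np.flatnonzero((states.layer == LAYER_L1)
                         & (states.identity == IDENTITY_ADAXIAL))
    seq = _boundary_cell_sequence(mesh)
    pos = {seq.index(int(c)) for c in ada if int(c) in seq}
    L = len(seq)
    # contiguous iff some rotation lines the string up without gaps
    contiguous = bool(pos) and any(
        all(((s + i) % L) in pos for i in range(len(pos))) for s in pos
    )
    report["adaxial_L1_contiguous"] = bool(contiguous)
    return report
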