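"""Cell division: clock dynamics, triggers, orientation rules, splitting.

Non-epidermal cells carry a division clock advanced at rate
``P0 + P * Hill(u; u0, n) * Hill(S; S0, m)`` — division is promoted by the
morphogen u and by cell area — and divide when the clock exceeds their
per-cell threshold, after which daughters restart at clock 0 with freshly
drawn thresholds.  Epidermal (L1) cells instead divide topologically: a
cell that reaches five neighbouring cells (six edges) is split
longitudinally through the midpoints of its outermost and innermost edges,
returning daughters with four neighbours.

Orientation rules by position:

* L1 — the epidermal midpoint rule above (always longitudinal).
* L2/L3 — longitudinal: division line through the cell centre parallel to
  the morphogen-v axis ``L_v``; in ridge mode, adaxial L2/L3 divide
  periclinally instead: line perpendicular to the morphogen-w axis ``L_w``.
* deeper cells — perpendicular to the cell's long axis ``L_0`` through the
  cell centre (shortest-wall-like rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DivisionError
from .mesh import (LAYER_L1, LAYER_L2, LAYER_L3, SUB_ADAXIAL, CellStates,
                   TissueMesh, compute_cell_geometry, polygon_signed_area)
from .params import ClockParams

#: relative eigenvalue gap below which the second-moment axis is a tie
AXIS_TIE_TOL = 1e-12


def division_rate(u, S, params: ClockParams | None = None):
    """Clock advancement rate ``P0 + P * Hill(u) * Hill(S)`` (vectorised)."""
    p = params or ClockParams()
    u = np.asarray(u, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(u < 0) or np.any(S < 0):
        raise ValueError("u and S must be non-negative")
    hu = u ** p.n / (p.u0 ** p.n + u ** p.n)
    hs = S ** p.m / (p.S0 ** p.m + S ** p.m)
    return p.P0 + p.P * hu * hs


def clock_step(mesh: TissueMesh, states: CellStates,
               params: ClockParams | None = None, dt: float = 0.005) -> None:
    """One Euler step of the division clock for all non-epidermal cells.

    Epidermal clocks are left untouched — the epidermis divides by the
    neighbour-count rule, so its clocks are inert.
    """
    p = params or ClockParams()
    S = mesh.cell_areas()
    non_epi = states.layer != LAYER_L1
    states.clock[non_epi] += dt * division_rate(states.u[non_epi], S[non_epi], p)


def check_divisions(mesh: TissueMesh, states: CellStates,
                    params: ClockParams | None = None) -> list[int]:
    """Cells due to divide this step, in ascending id order.

    Non-epidermal cells whose clock strictly exceeds their threshold, plus
    epidermal cells that have reached six edges (five neighbours).
    """
    non_epi = states.layer != LAYER_L1
    due = set(np.flatnonzero(non_epi & (states.clock > states.threshold)).tolist())
    n_edges = np.array([len(c) for c in mesh.cells])
    due |= set(np.flatnonzero((states.layer == LAYER_L1) & (n_edges >= 6)).tolist())
    return sorted(due)


# ---------------------------------------------------------------------- #
# axes                                                                    #
# ---------------------------------------------------------------------- #
def long_axis(points: np.ndarray, centre: np.ndarray | None = None):
    """Long axis of a point set: angle in [0, pi) of the line through
    `centre` minimising the sum of squared point-to-line distances.

    For the line at angle theta with normal ``n = (-sin t, cos t)`` the
    residual is ``R(t) = Sxx sin^2 t - 2 Sxy sin t cos t + Syy cos^2 t``
    (second moments about the centre), minimised in closed form at
    ``t0 = atan2(2 Sxy, Sxx - Syy) / 2``.

    Returns ``(theta0, degenerate)`` where `degenerate` flags an isotropic
    point cloud (moment eigenvalue gap below tolerance); theta0 is then 0.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need >= 3 points")
    c = pts.mean(axis=0) if centre is None else np.asarray(centre, dtype=float)
    d = pts - c
    Sxx = float(np.sum(d[:, 0] ** 2))
    Syy = float(np.sum(d[:, 1] ** 2))
    Sxy = float(np.sum(d[:, 0] * d[:, 1]))
    gap = np.hypot(Sxx - Syy, 2 * Sxy)  # eigenvalue spread of the 2x2 moment
    if gap < AXIS_TIE_TOL * max(Sxx + Syy, 1.0):
        return 0.0, True
    theta = 0.5 * np.arctan2(2 * Sxy, Sxx - Syy)
    return float(theta % np.pi), False


def morphogen_axis(x_c: np.ndarray, z_k: np.ndarray, r_k: np.ndarray):
    """Axis ``L_z`` from neighbour morphogen concentrations.

    Each neighbour ``k`` contributes a vector ``s_k`` pointing from the
    cell centre towards the midpoint ``r_k`` of the shared edge, with
    magnitude equal to the neighbour's concentration ``z_k``.  The polygon
    of the ``s_k`` elongates towards higher concentrations; its long axis
    (about the mean of the ``s_k``) is returned as ``(theta, degenerate)``.

    Raises ``DivisionError`` when every ``z_k`` is zero (no orientation
    information; callers fall back to the long-axis rule).
    """
    z_k = np.asarray(z_k, dtype=float)
    r_k = np.asarray(r_k, dtype=float)
    if len(z_k) < 2:
        raise DivisionError("need >= 2 neighbours for a morphogen axis")
    if np.all(z_k == 0):
        raise DivisionError("all neighbour concentrations are zero")
    d = r_k - np.asarray(x_c, dtype=float)
    norm = np.linalg.norm(d, axis=1)
    if np.any(norm == 0):
        raise DivisionError("edge midpoint coincides with the cell centre")
    s = (z_k / norm)[:, None] * d
    if len(s) == 2:
        # two points: the axis is simply the direction between them
        v = s[1] - s[0]
        if np.hypot(*v) == 0:
            return 0.0, True
        return float(np.arctan2(v[1], v[0]) % np.pi), False
    return long_axis(s)


# ---------------------------------------------------------------------- #
# geometric splitting                                                     #
# ---------------------------------------------------------------------- #
@dataclass
class DivisionEvent:
    """Record of one executed division."""

    parent: int
    mode: str  # epidermal | longitudinal | periclinal | long-axis
    p1: np.ndarray  # division-line endpoints on the parent boundary
    p2: np.ndarray
    daughters: tuple[int, int]
    time: float = np.nan
    angle_deg: float = np.nan  # vs local tissue surface, [0, 90]
    layer: int = 0
    sub: int = 0
    identity: int = 0


def _line_polygon_intersections(pts: np.ndarray, p: np.ndarray, d: np.ndarray,
                                eps: float):
    """Transversal intersections of the infinite line (p, d) with polygon edges.

    Returns a list of (edge index, intersection point).  Raises
    ``DivisionError`` if the line grazes a vertex or does not cross exactly
    two distinct edges.
    """
    nl = np.array([-d[1], d[0]])
    nl = nl / np.linalg.norm(nl)
    sigma = (pts - p) @ nl
    scale = max(1.0, float(np.max(np.abs(pts - p))))
    if np.any(np.abs(sigma) < eps * scale):
        raise DivisionError("division line grazes a vertex")
    hits = []
    m = len(pts)
    for k in range(m):
        sa, sb = sigma[k], sigma[(k + 1) % m]
        if (sa > 0) != (sb > 0):
            t = sa / (sa - sb)
            hits.append((k, pts[k] + t * (pts[(k + 1) % m] - pts[k])))
    if len(hits) != 2:
        raise DivisionError(f"line crosses {len(hits)} edges, need exactly 2")
    return hits


def split_cell(mesh: TissueMesh, states: CellStates, cell_id: int,
               line_point: np.ndarray, line_dir: np.ndarray,
               rng: np.random.Generator,
               params: ClockParams | None = None,
               grazing_eps: float = 0.01,
               min_area_frac: float = 0.01) -> DivisionEvent:
    """Split `cell_id` along the infinite line (`line_point`, `line_dir`).

    Two new vertices are inserted at the boundary intersections (and into
    the neighbouring cells' cycles, so the mesh stays shared-vertex); the
    parent cycle is replaced by one daughter and the other appended.  Both
    daughters inherit the parent's identity and morphogen concentrations;
    clocks reset to 0 and thresholds are redrawn from `rng`.

    Total area is conserved exactly up to round-off.  Raises
    ``DivisionError`` on grazing/missed lines or sliver daughters
    (< `min_area_frac` of the parent area); callers may retry with a
    perturbed line.
    """
    p = params or ClockParams()
    cyc = mesh.cells[cell_id]
    pts = mesh.vertices[cyc]
    parent_area = polygon_signed_area(pts)
    hits = _line_polygon_intersections(pts, np.asarray(line_point, float),
                                       np.asarray(line_dir, float), grazing_eps)
    (k1, P1), (k2, P2) = hits
    m = len(cyc)

    i1 = mesh.n_vertices
    i2 = i1 + 1
    new_vertices = np.vstack([mesh.vertices, P1[None, :], P2[None, :]])

    # daughter cycles (indices into the parent cycle, then global ids)
    def seg(a: int, b: int) -> list[int]:
        """parent-cycle vertex ids from position a+1 .. b inclusive, wrapped."""
        out = []
        k = (a + 1) % m
        while True:
            out.append(int(cyc[k]))
            if k == b:
                break
            k = (k + 1) % m
        return out

    d1 = [i1] + seg(k1, k2) + [i2]
    d2 = [i2] + seg(k2, k1) + [i1]

    a1 = polygon_signed_area(new_vertices[np.array(d1)])
    a2 = polygon_signed_area(new_vertices[np.array(d2)])
    if a1 < min_area_frac * parent_area or a2 < min_area_frac * parent_area:
        raise DivisionError("division produces a sliver daughter")

    # insert the new vertices into the neighbours sharing the two cut edges
    em = mesh._edge_map()
    for k, new_id in ((k1, i1), (k2, i2)):
        a, b = int(cyc[k]), int(cyc[(k + 1) % m])
        key = (a, b) if a < b else (b, a)
        for other in em[key]:
            if other == cell_id:
                continue
            oc = mesh.cells[other].tolist()
            # in the neighbour's CCW cycle the edge runs b -> a
            pos_b = oc.index(b)
            oc.insert(pos_b + 1, new_id)
            mesh.cells[other] = np.array(oc, dtype=np.int64)

    mesh.vertices = new_vertices
    mesh.cells[cell_id] = np.array(d1, dtype=np.int64)
    mesh.cells.append(np.array(d2, dtype=np.int64))
    new_id = mesh.n_cells - 1
    mesh.invalidate()

    # states: daughter 1 reuses the parent slot, daughter 2 is appended
    lo = (1 - p.threshold_fluctuation) * p.C
    hi = (1 + p.threshold_fluctuation) * p.C
    states.identity = np.append(states.identity, states.identity[cell_id])
    states.u = np.append(states.u, states.u[cell_id])
    states.v = np.append(states.v, states.v[cell_id])
    states.w = np.append(states.w, states.w[cell_id])
    states.clock[cell_id] = 0.0
    states.clock = np.append(states.clock, 0.0)
    states.threshold[cell_id] = rng.uniform(lo, hi)
    states.threshold = np.append(states.threshold, rng.uniform(lo, hi))
    states.layer = np.append(states.layer, states.layer[cell_id])
    states.sub = np.append(states.sub, states.sub[cell_id])

    return DivisionEvent(parent=cell_id, mode="", p1=P1, p2=P2,
                         daughters=(cell_id, new_id),
                         layer=int(states.layer[cell_id]),
                         sub=int(states.sub[cell_id]),
                         identity=int(states.identity[cell_id]))


# ---------------------------------------------------------------------- #
# orientation policy                                                      #
# ---------------------------------------------------------------------- #
def _epidermal_line(mesh: TissueMesh, cell_id: int):
    """Line through the midpoints of the outermost and innermost edges.

    The innermost edge is the edge cyclically opposite the outermost one
    (so the split leaves both daughters with four neighbours, which is the
    point of the epidermal rule); among equally opposite candidates the
    one whose midpoint lies farthest from the outer tissue boundary wins.
    """
    from shapely.geometry import LineString, Point

    cyc = mesh.cells[cell_id]
    pts = mesh.vertices[cyc]
    m = len(cyc)
    em = mesh._edge_map()
    mids, outer = [], []
    for k in range(m):
        a, b = int(cyc[k]), int(cyc[(k + 1) % m])
        key = (a, b) if a < b else (b, a)
        mids.append(0.5 * (mesh.vertices[a] + mesh.vertices[b]))
        outer.append(len(em[key]) == 1)
    outer = np.array(outer)
    if not outer.any():
        raise DivisionError(f"cell {cell_id} has no outermost edge")
    loop = mesh.boundary_cycle()
    boundary = LineString(np.vstack([mesh.vertices[loop], mesh.vertices[loop[:1]]]))
    # outermost edge: if several, the one with the longest length
    oidx = [k for k in range(m) if outer[k]]
    if len(oidx) > 1:
        lens = [np.linalg.norm(pts[(k + 1) % m] - pts[k]) for k in oidx]
        k_out = oidx[int(np.argmax(lens))]
    else:
        k_out = oidx[0]
    inner = [k for k in range(m) if not outer[k]]
    # primary criterion: cyclic offset from the outer edge as close to m/2
    # as possible (balanced daughters); tie-break: farthest from the surface
    def balance(k: int) -> float:
        off = (k - k_out) % m
        return abs(off - m / 2.0)

    best = min(balance(k) for k in inner)
    candidates = [k for k in inner if balance(k) == best]
    if len(candidates) > 1:
        dists = [boundary.distance(Point(mids[k])) for k in candidates]
        k_in = candidates[int(np.argmax(dists))]
    else:
        k_in = candidates[0]
    p1, p2 = mids[k_out], mids[k_in]
    return p1, p2 - p1


def division_line_for_cell(mesh: TissueMesh, cell_id: int, states: CellStates,
                           mode: str = "hollow"):
    """Division line (point, direction) and mode label for one cell.

    `mode` selects the forced-orientation preset: in ``hollow`` mode all
    L2/L3 cells divide longitudinally; in ``ridge`` mode adaxial L2/L3
    divide periclinally instead.  Inner cells always divide perpendicular
    to their long axis; L1 uses the epidermal midpoint rule.
    """
    if mode not in ("hollow", "ridge"):
        raise ValueError(f"unknown mode {mode!r}")
    layer = int(states.layer[cell_id])
    S, x_c, _ = compute_cell_geometry(mesh, cell_id)

    if layer == LAYER_L1:
        p, d = _epidermal_line(mesh, cell_id)
        return p, d, "epidermal"

    if layer in (LAYER_L2, LAYER_L3):
        periclinal = mode == "ridge" and int(states.sub[cell_id]) == SUB_ADAXIAL
        species = states.w if periclinal else states.v
        cyc = mesh.cells[cell_id]
        m = len(cyc)
        em = mesh._edge_map()
        z_k, r_k = [], []
        for k in range(m):
            a, b = int(cyc[k]), int(cyc[(k + 1) % m])
            key = (a, b) if a < b else (b, a)
            for other in em[key]:
                if other != cell_id:
                    z_k.append(species[other])
                    r_k.append(0.5 * (mesh.vertices[a] + mesh.vertices[b]))
        try:
            theta, degenerate = morphogen_axis(x_c, np.array(z_k), np.array(r_k))
        except DivisionError:
            theta, degenerate = long_axis(mesh.cell_polygon(cell_id), x_c)
            theta = _resolve_tie(mesh, x_c, theta, degenerate)
            return x_c, _unit(theta + np.pi / 2), "long-axis"
        theta = _resolve_tie(mesh, x_c, theta, degenerate)
        if periclinal:
            return x_c, _unit(theta + np.pi / 2), "periclinal"
        return x_c, _unit(theta), "longitudinal"

    theta, degenerate = long_axis(mesh.cell_polygon(cell_id), x_c)
    theta = _resolve_tie(mesh, x_c, theta, degenerate, interior=True)
    return x_c, _unit(theta + np.pi / 2), "long-axis"


def _unit(theta: float) -> np.ndarray:
    return np.array([np.cos(theta), np.sin(theta)])


def _resolve_tie(mesh: TissueMesh, x_c: np.ndarray, theta: float,
                 degenerate: bool, interior: bool = False) -> float:
    """Tie-break a degenerate axis: align with the local surface tangent;
    fully interior cells fall back to theta = 0."""
    if not degenerate:
        return theta
    if interior:
        return 0.0
    from .morphometrics import local_surface_tangent

    try:
        t = local_surface_tangent(mesh, x_c)
        return float(np.arctan2(t[1], t[0]) % np.pi)
    except Exception:
        return 0.0


def execute_division(mesh: TissueMesh, states: CellStates, cell_id: int,
                     mode: str, rng: np.random.Generator,
                     params: ClockParams | None = None,
                     time: float = np.nan) -> DivisionEvent | None:
    """Orient and execute one division; returns the event, or None if the
    division had to be deferred.

    Degenerate lines (vertex grazing, sliver daughters, wrong crossing
    count) are retried with the line rotated by +-0.01 rad; after three
    failed attempts the division is deferred to a later step.
    """
    p, d, label = division_line_for_cell(mesh, cell_id, states, mode)
    for dtheta in (0.0, 0.01, -0.01):
        c, s = np.cos(dtheta), np.sin(dtheta)
        d_try = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
        try:
            ev = split_cell(mesh, states, cell_id, p, d_try, rng, params)
        except DivisionError:
            continue
        ev.mode = label
        ev.time = time
        from .morphometrics import division_angle_from_line

        try:
            ev.angle_deg = division_angle_from_line(mesh, ev.p1, ev.p2)
        except Exception:
            ev.angle_deg = np.nan
        return ev
    return None
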