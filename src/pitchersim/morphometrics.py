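"""Quantification procedures for simulated tissues.

* Division-plane angles relative to the local tissue surface, on the
  folded axis [0, 90] degrees where 0 is periclinal (parallel to the
  surface) and 90 longitudinal (perpendicular), with rank-based group
  comparison (Mann-Whitney U, Bonferroni correction) and circular
  summaries.
* Whole-tissue morphometrics separating bifacial growth from an adaxial
  protrusion.
* Expression-boundary detection on 1-D intensity profiles: smoothing
  B-spline fit followed by extrema of the backward difference (steepest
  rise/fall).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.interpolate import make_smoothing_spline

from .division import long_axis
from .errors import ConfigurationError
from .mesh import (IDENTITY_ABAXIAL, IDENTITY_ADAXIAL, CellStates, TissueMesh,
                   classify_layers)

#: cut separating periclinal-dominated from longitudinal-dominated angles
ANGLE_CUT_DEG = 45.0
#: protrusion height (in mean cell diameters) above which a tissue is
#: classified as carrying an adaxial protrusion rather than growing bifacially
PROTRUSION_CUTOFF = 2.0


# ---------------------------------------------------------------------- #
# division angles                                                         #
# ---------------------------------------------------------------------- #
def _point_segment_distance(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-300), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def local_surface_tangent(mesh: TissueMesh, point: np.ndarray,
                          window: int = 2) -> np.ndarray:
    """Unit tangent of the tissue surface nearest `point`.

    Finds the boundary segment closest to `point` (nearest-by-distance,
    with the segment-midpoint distance as the deterministic tie-break),
    gathers the chain of +-`window` neighbouring boundary segments and
    returns the least-squares direction of the chain's vertices.
    """
    loop = mesh.boundary_cycle()
    pts = mesh.vertices[loop]
    nb = len(loop)
    point = np.asarray(point, dtype=float)
    dists = np.array([
        _point_segment_distance(point, pts[k], pts[(k + 1) % nb])
        for k in range(nb)
    ])
    k0 = int(np.argmin(dists))
    idx = [(k0 + off) % nb for off in range(-window, window + 2)]
    chain = pts[idx]
    theta, degenerate = long_axis(chain)
    if degenerate:  # straight chain never degenerates; safeguard only
        d = chain[-1] - chain[0]
        theta = float(np.arctan2(d[1], d[0]))
    return np.array([np.cos(theta), np.sin(theta)])


def fold_angle_deg(angle_deg: float) -> float:
    """Fold an axial angle difference into [0, 90] degrees."""
    a = abs(angle_deg) % 180.0
    return min(a, 180.0 - a)


def division_angle_from_line(mesh: TissueMesh, p1: np.ndarray,
                             p2: np.ndarray, window: int = 2) -> float:
    """Angle (degrees, [0, 90]) between a division line and the local
    tissue surface; 0 = periclinal, 90 = longitudinal."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    mid = 0.5 * (p1 + p2)
    t = local_surface_tangent(mesh, mid, window=window)
    d = p2 - p1
    ang = np.degrees(np.arctan2(d[1], d[0]) - np.arctan2(t[1], t[0]))
    return fold_angle_deg(float(ang))


def division_angle(event, mesh: TissueMesh, window: int = 2) -> float:
    """Angle of a recorded division event vs the local tissue surface."""
    return division_angle_from_line(mesh, event.p1, event.p2, window=window)


# ---------------------------------------------------------------------- #
# rank statistics                                                         #
# ---------------------------------------------------------------------- #
@dataclass
class MannWhitneyResult:
    U: float            # U statistic of the first group
    p: float            # two-sided p-value
    p_adjusted: float   # Bonferroni-adjusted across the comparison family
    method: str         # "exact" (full enumeration) or "asymptotic"
    median_a: float
    median_b: float
    quartiles_a: tuple[float, float]
    quartiles_b: tuple[float, float]


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group a: #(a > b) pairs + half the ties."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney test by full enumeration.

    Enumerates every assignment of the pooled observations to the two
    groups (a permutation test on U), which handles ties exactly.  The
    two-sided p-value is the probability of a U at least as far from its
    null mean n*m/2 as the observed one.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    u_obs = _u_statistic(a, b)
    centre = 0.5 * n * m
    count = total = 0
    idx = np.arange(n + m)
    for comb in itertools.combinations(idx, n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - centre) >= abs(u_obs - centre) - 1e-12:
            count += 1
    return u_obs, count / total


def compare_angle_distributions(samples_a, samples_b, n_family: int = 1,
                                exact_max_n: int = 8) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U comparison of two angle samples.

    Uses full enumeration when both groups have at most `exact_max_n`
    observations, otherwise the normal approximation with tie correction
    and continuity correction.  `n_family` is the number of comparisons in
    the family for the Bonferroni adjustment.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 samples")
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        u, p = mann_whitney_exact(a, b)
        method = "exact"
    else:
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    qa = tuple(np.percentile(a, [25, 75]))
    qb = tuple(np.percentile(b, [25, 75]))
    return MannWhitneyResult(
        U=u, p=p, p_adjusted=min(1.0, p * n_family), method=method,
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        quartiles_a=qa, quartiles_b=qb,
    )


def circular_summary(angles_deg, axial: bool = True) -> dict:
    """Mean direction (degrees) and resultant length of angular data.

    Axial data (period 180 degrees, the division-plane case) are doubled
    before averaging and the mean is halved back, the standard treatment
    for undirected axes.
    """
    ang = np.radians(np.asarray(angles_deg, float))
    if axial:
        ang = 2.0 * ang
    C, S = np.mean(np.cos(ang)), np.mean(np.sin(ang))
    R = float(np.hypot(C, S))
    mean = np.arctan2(S, C)
    if axial:
        mean = mean / 2.0
    return {"mean_deg": float(np.degrees(mean) % (180.0 if axial else 360.0)),
            "resultant_length": R}


# ---------------------------------------------------------------------- #
# tissue morphometrics                                                    #
# ---------------------------------------------------------------------- #
def _adaxial_boundary_arc(mesh: TissueMesh, states: CellStates) -> np.ndarray:
    """Positions of the outer-boundary vertices of the adaxial epidermis,
    as one contiguous arc in boundary-loop order."""
    em = mesh._edge_map()
    ada = states.identity == IDENTITY_ADAXIAL
    loop = mesh.boundary_cycle()
    nb = len(loop)
    on_arc = np.zeros(nb, dtype=bool)
    for k in range(nb):
        a, b = int(loop[k]), int(loop[(k + 1) % nb])
        key = (a, b) if a < b else (b, a)
        if ada[em[key][0]]:
            on_arc[k] = True
            on_arc[(k + 1) % nb] = True
    if not on_arc.any():
        raise ConfigurationError("no adaxial boundary found")
    # rotate so the arc does not wrap the array seam
    if on_arc.all():
        idx = np.arange(nb)
    else:
        start = int(np.flatnonzero(~on_arc)[0])
        order = (start + 1 + np.arange(nb)) % nb
        idx = order[on_arc[order]]
    return mesh.vertices[loop[idx]]


@dataclass
class ProtrusionIndex:
    height: float        # outward excursion of the adaxial epidermis beyond
                         # the tissue's typical boundary radius, in mean cell
                         # diameters (negative when invaginated)
    aspect_ratio: float  # tissue extent perpendicular to the junction chord
                         # over the extent along it (bifacial elongation)
    classification: str  # "bifacial" or "protrusion"


def protrusion_index(mesh: TissueMesh, states: CellStates,
                     cutoff: float = PROTRUSION_CUTOFF) -> ProtrusionIndex:
    """Quantify the tissue phenotype: bifacial blade vs adaxial protrusion.

    The protrusion height measures how far the adaxial epidermis sticks
    out of the tissue body: the mean distance of the adaxial boundary
    vertices from the tissue centroid minus the median distance of all
    boundary vertices, in mean cell diameters.  An adaxial outgrowth
    carries its epidermis well beyond the typical boundary radius
    (strongly positive); bifacial growth invaginates the adaxial surface
    into a pit whose lining stays at or inside the typical radius (near
    zero or negative).  The aspect ratio is the tissue extent
    perpendicular to the adaxial junction-to-junction chord over the
    extent along it, a measure of bifacial elongation.  Classification
    uses a fixed cutoff on the height (default 2 cell diameters).  Rigid
    motions leave the result unchanged.
    """
    classify_layers(mesh, states)
    if not (states.identity == IDENTITY_ADAXIAL).any() or not (
        states.identity == IDENTITY_ABAXIAL
    ).any():
        raise ConfigurationError("both epidermal identities are required")
    arc = _adaxial_boundary_arc(mesh, states)
    centroid = mesh.vertices.mean(axis=0)
    boundary = mesh.vertices[mesh.boundary_cycle()]
    mean_diam = float(np.mean(2.0 * np.sqrt(mesh.cell_areas() / np.pi)))
    arc_dist = float(np.mean(np.linalg.norm(arc - centroid, axis=1)))
    typical = float(np.median(np.linalg.norm(boundary - centroid, axis=1)))
    height = (arc_dist - typical) / mean_diam

    chord = arc[-1] - arc[0]
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        raise ConfigurationError("degenerate adaxial boundary arc")
    axis = chord / norm
    perp = np.array([-axis[1], axis[0]])
    along = float(np.ptp(boundary @ axis))
    across = float(np.ptp(boundary @ perp))
    aspect = across / along if along > 0 else np.inf
    label = "protrusion" if height > cutoff else "bifacial"
    return ProtrusionIndex(height=height, aspect_ratio=aspect,
                           classification=label)


# ---------------------------------------------------------------------- #
# expression-boundary detection                                           #
# ---------------------------------------------------------------------- #
@dataclass
class IntensityProfile:
    """Ordered grey values along an epidermal path."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.values = np.asarray(self.values, float)
        if len(self.positions) < 5:
            raise ValueError("profile needs >= 5 points")
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must match in length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")


def make_step_profile(levels, widths, noise_sd: float = 0.0,
                      rng: np.random.Generator | None = None) -> IntensityProfile:
    """Synthetic piecewise-constant profile: `levels[i]` repeated
    `widths[i]` cells, plus optional Gaussian noise.  Positions are the
    cell indices 0, 1, 2, ..."""
    values = np.concatenate([np.full(w, lv, dtype=float)
                             for lv, w in zip(levels, widths)])
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return IntensityProfile(np.arange(len(values), dtype=float), values)


def expression_boundary(profile: IntensityProfile,
                        lam: float | None = None,
                        noise_floor: float | None = None) -> pd.DataFrame:
    """Locate expression boundaries on an intensity profile.

    A cubic smoothing B-spline (generalised cross-validation penalty by
    default) is fitted to the profile and evaluated on the position grid;
    boundaries are the strict local maxima (rise) and minima (fall) of the
    backward difference of the fitted values, i.e. the steepest signal
    transitions.  Extrema whose magnitude falls below `noise_floor`
    (default: 20% of the largest fitted difference, with a tiny absolute
    guard) are discarded, so a flat profile yields an empty result.

    Returns a DataFrame with columns ``position`` and ``kind``
    ("rise"/"fall"), ordered by position.
    """
    x, y = profile.positions, profile.values
    spl = make_smoothing_spline(x, y, lam=lam)
    f = spl(x)
    df = np.diff(f)  # backward difference of fitted values, at x[1:]
    if noise_floor is None:
        noise_floor = max(0.2 * float(np.max(np.abs(df))),
                          1e-9 * (float(np.ptp(y)) + 1.0))
    rows = []
    for i in range(1, len(df) - 1):
        if df[i] > df[i - 1] and df[i] > df[i + 1] and df[i] > noise_floor:
            rows.append((x[i + 1], "rise"))
        elif df[i] < df[i - 1] and df[i] < df[i + 1] and df[i] < -noise_floor:
            rows.append((x[i + 1], "fall"))
    out = pd.DataFrame(rows, columns=["position", "kind"])
    return out.sort_values("position").reset_index(drop=True)
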