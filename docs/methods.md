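# Methods

## Model overview

`pitchersim` simulates a transverse section of a young leaf primordium as
a 2-D vertex model coupled to chemical dynamics.  The state is a
shared-vertex polygonal mesh (`TissueMesh`) plus per-cell scalars
(`CellStates`): a fixed epidermal identity (adaxial / abaxial / none),
three morphogen concentrations (u, v, w), a division clock and a division
threshold.  Layers (L1/L2/L3/inner) are positional labels recomputed from
the topology after every division: L1 owns an outer edge, L2 touches L1,
L3 touches L2; adaxial L2 are the L2 cells in contact with adaxial L1,
adaxial L3 those in contact with adaxial L2 (a cell touching both sides is
labelled adaxial — the deterministic tie-break matters because periclinal
division is the adaxial-specific behaviour).

Within each time step Δt the update order is fixed: morphogen Euler step →
clock Euler step → division check and execution → RK4 mechanics step.
The order lives in one place (the compiled `advance` kernel plus the
driver's division branch) and the bit-reproducibility test pins the
resulting trajectories; changing the order is a visible code change, never
silent behaviour.

## Mechanics

Potential energy (all units dimensionless, hexagon of unit area as the
reference cell):

U = K_S/2 Σ_i (S_i − s_i)² + Σ_j (K_B·L_j + K_R/L_j) + K_E/2 Σ_k (L_k − L_E)²

* Area term: target area s_i = N_i·tan(π/6)/(6·tan(π/N_i)) — the regular
  N-gon's area relative to the regular hexagon at equal edge length, so
  s_6 = 1 exactly.  Keeps cell sizes roughly constant; daughters regrow
  towards their own target after division, which is the only "growth" in
  the model.
* Edge term: tension K_B·L plus repulsion K_R/L; minimal at
  L* = √(K_R/K_B) = 0.1, divergent as L→0, so adjacent vertices can never
  collapse and vertex reconnection (disallowed for walled plant cells)
  is never needed.
* Outer term: quadratic about L_E = 1.3 on surface edges only — the
  cuticle-stiffened outer wall.

The equations of motion are overdamped, η·dx_j/dt = −∂U/∂x_j, integrated
with classical RK4 at Δt = 0.005.  Forces are assembled analytically
(the area gradient of a CCW polygon vertex is ((y_next−y_prev)/2,
(x_prev−x_next)/2)); a finite-difference oracle pins the assembly at 1e-4
relative in the tests.  If a step flips a cell (non-positive signed area)
the step is retried at half the step size, up to five halvings, then the
run aborts with the last valid state flushed.

Defaults: η=1.0, K_S=1.0, K_B=0.1, K_R=0.001, K_E=0.005, L_E=1.3.

## Morphogens

Per species z ∈ {u, v, w} on the cell-adjacency graph:

dz_i/dt = A_z·1[i ∈ sources] − B_z·z_i + D_z·Σ_{j∈nbr(i)} (z_j − z_i)

Diffusion is per-neighbour and unweighted (no degree normalisation, no
edge-length weighting) — the simplest graph Laplacian reading.  Sources:
u in the L1 cells flanking the two adaxial–abaxial identity junctions
(both cells of each junction); v in all L1; w in adaxial L1.  Euler
integration shares the mechanics Δt; a direct sparse solve of
(B·I + D·Lap)z = A·src serves as the steady-state oracle, and the tests
require the Euler trajectory to land on it within 1e-6 along with exact
synthesis–degradation balance.  Daughters inherit the parent's
concentrations (concentration, not mass, is the state variable of the
per-cell ODE).  Defaults: A_u=2, A_v=A_w=1, B=1 for all, D_u=1,
D_v=D_w=0.2.

## Division

Non-epidermal cells integrate a clock at rate

P0 + P · u_iⁿ/(u0ⁿ+u_iⁿ) · S_iᵐ/(S0ᵐ+S_iᵐ)

(P0=1, P=20, u0=0.03, n=2, S0=1.2, m=8) and divide when clock_i strictly
exceeds a threshold drawn per cell at birth, uniformly on [0.9C, 1.1C]
with C=10000.  The Hill-product form is the minimal rate law using all six
constants in which both the boundary morphogen and cell size promote
division; it is isolated in one function (`division_rate`) so alternative
forms are one-line swaps.  Epidermal clocks are inert: the epidermis
divides topologically, when a cell reaches five neighbours (six edges),
through the midpoints of its outermost and innermost edges, returning
daughters with four neighbours.  "Innermost" is the edge most cyclically
opposite the outer edge (tie-break: midpoint farthest from the surface);
choosing by distance alone can pick an edge adjacent to the outer wall,
which splits off a sliver and leaves a six-edge daughter that re-triggers
indefinitely — the opposite-edge rule is what makes the four-neighbour
outcome hold.

Division planes:

* L2/L3 longitudinal — through the cell centre, parallel to the axis L_v
  of the neighbour-concentration polygon s_k = v_k·(r_k−x_c)/|r_k−x_c|
  (r_k = shared-edge midpoints).  The polygon elongates towards higher
  concentration, i.e. towards the epidermis-facing side, so its long axis
  runs perpendicular to the surface.
* Adaxial L2/L3 in ridge mode, periclinal — perpendicular to the analogous
  axis L_w of morphogen w.
* Inner cells — perpendicular to the cell's long axis L_0, the
  minimiser of Σ r_j² over lines through the vertex-mean centre, computed
  in closed form from the second moments (θ0 = ½·atan2(2Σxy, Σx²−Σy²))
  and cross-checked against a 1e-4-rad grid scan.

Degenerate cases: an isotropic moment matrix (relative eigenvalue gap
below 1e-12) falls back to the local surface tangent, or θ=0 for deep
cells; a zero morphogen field falls back to the long-axis rule.  A
division line that grazes a vertex (any vertex within 1% of the cell
scale), misses two distinct edges, or cuts off a daughter below 1% of the
parent's area is retried rotated ±0.01 rad and otherwise deferred; after
a fully deferred batch the driver advances 200 steps (one time unit)
before re-checking, because at one-step granularity a stuck line would be
re-tested against essentially unchanged geometry every step.  The grazing
tolerance doubles as a minimum-new-edge guard: edges shorter than ~0.007
would make the K_R/L repulsion stiff beyond what five step-halvings can
integrate.

Geometric splitting inserts the two intersection vertices into the parent
and into each neighbour sharing a cut edge, so the mesh stays watertight;
area conservation at every division is asserted to 1e-9 and a full
topology audit (simple polygons, CCW orientation, edge-sharing counts,
boundary closure) runs after each one.

## Initial tissue

The generator emulates the youngest primordium stage at which the two
prospective regions still look alike: ~100 polygonal cells in a disc
(radius √(100/π)) with a raised-cosine notch on the adaxial (−y) side,
depth 0.15 and width 0.35 of the disc diameter by default — the reference
geometry only says "small depression", so both are exposed.  Construction:
jittered hexagonal seeds, four Lloyd iterations of the domain-clipped
Voronoi diagram, conversion to a shared-vertex mesh with each cell's outer
arc collapsed to a chord (keeping ≥4 vertices per cell so no triangle
slivers arise), then 1500 RK4 relaxation steps.  The six boundary cells
nearest the notch tip become the contiguous adaxial-L1 string; all other
boundary cells are abaxial.  Morphogens and clocks start at zero; a
2000-step morphogen-only burn-in precedes any division so early
orientation decisions never see an all-zero field.

What the generator does not emulate: real cell-size heterogeneity and
wall curvature, pre-existing morphogen patterns, and any out-of-plane
(3-D) structure.  Passing phenotype tests therefore show that the division
rules are sufficient to produce the two growth modes from this idealised
start — not that the model quantitatively matches any measured tissue.

## Driver and experiments

`run_simulation` loops the update order above until a stop criterion
(default 400 cells, the reference scale of the published end-point
figures; all desk experiments are configurable below that).  The two
presets mirror the headline in-silico experiments: **hollow** forces
longitudinal division in L1/L2/L3 of both identities (L1 through its own
midpoint rule); **ridge** additionally forces periclinal division in
adaxial L2/L3.  All randomness (Voronoi jitter, threshold draws) comes
from one generator seeded by the config, so any (config, seed) pair is
bit-reproducible, which the tests assert on the full event log.

Desk-scale choices: the test suite and the acceptance script run the
phenotype experiments to 250 cells (tests: 3 seeds per mode; script: 2),
always at the default model constants.  250 cells is the smallest scale
at which the ridge outgrowth clearly crosses the fixed 2-cell-diameter
cutoff; the hollow/ridge contrast only widens in longer runs.  The
round-start control is compared on the invagination (protrusion height):
round starts fail to form the adaxial pit that depression starts produce,
which is the geometric signature of suppressed bifacial growth.

## Morphometrics

* Division angle: acute angle between the division line and the local
  surface tangent (least-squares direction of the ±2 boundary edges
  nearest the line's midpoint), folded to [0°, 90°]; 0° is periclinal,
  90° longitudinal.  The same convention as the violin-plot quantification
  of sectioned primordia, applied here to simulated events.
* Group comparison: two-sided Mann–Whitney U — full enumeration of all
  C(n+m, n) group assignments for groups of ≤8 (exact under ties), normal
  approximation with tie and continuity corrections otherwise; Bonferroni
  adjustment across a stated comparison family.  At n=8 the normal
  approximation agrees with enumeration to ~0.01 in p (its intrinsic
  accuracy; asserted at 0.015).  Axial circular summaries (mean direction,
  resultant length on doubled angles) are also reported.
* Phenotype: `protrusion_index` reports how far the adaxial epidermis
  sticks out of the tissue body — the mean centroid-distance of the
  adaxial boundary vertices minus the median centroid-distance of all
  boundary vertices, in mean cell diameters.  A ridge carries its (few)
  adaxial cells at the tip of an outgrowth several cell diameters beyond
  the typical boundary radius; bifacial growth invaginates the adaxial
  surface into a pit whose lining stays at or inside that radius, so the
  height goes negative.  This body-relative measure is used rather than a
  circle fitted to the abaxial boundary (the elongating blade is nowhere
  near circular, so a circle fit misclassifies it) or a deviation from
  the adaxial arc's own chord (the ridge outgrowth is flanked by abaxial
  epidermis, so the short adaxial arc barely deviates from its own
  chord).  Fixed cutoff: height > 2 cell diameters ⇒ "protrusion", else
  "bifacial"; at the desk scale of 250 cells the acceptance runs measure
  heights ≈ −1.5 (hollow) vs ≈ +2.3 to +3.1 (ridge), on opposite sides
  of the cutoff, and the gap keeps widening with tissue size.  The
  bifacial aspect ratio is the tissue extent perpendicular to the adaxial
  junction-to-junction chord over the extent along it.
* Expression boundaries: a cubic smoothing B-spline (GCV-selected penalty
  by default) is fitted to the 1-D intensity profile; boundaries are the
  strict local maxima/minima of the backward difference of the fitted
  values — the steepest rise/fall.  Extrema below a noise floor (default
  20% of the largest fitted difference, with a tiny absolute guard) are
  discarded, so flat profiles return an empty result.  Synthetic step
  profiles with step:noise ratio 5 are recovered within ±1 cell in all of
  100 seeded replicates.

## Known limitations

Strictly 2-D; no cell rearrangement, death, or growth-rate heterogeneity
beyond the clock; morphogen transport ignores wall length and
mechanotransduction; the initial geometry is idealised.  The phenotype
contrast is a qualitative reproduction — simulated durations and final
cell counts are not calibrated to measured primordia.
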