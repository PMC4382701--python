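"""Numba-compiled inner loops over a flattened mesh representation.

The driver converts the object mesh into flat CSR-style arrays (see
``_flat.py``); topology is constant between divisions, so these kernels
only ever move vertex positions and per-cell scalar fields.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# advance() status codes
STATUS_DONE = 0          # completed the requested number of steps
STATUS_CLOCK_TRIGGER = 1  # a clock crossed its threshold (mechanics pending)
STATUS_MECH_FAIL = 2     # RK4 step kept producing flipped cells
STATUS_MORPH_FAIL = 3    # non-finite / negative morphogen (Euler unstable)


@njit(cache=True)
def cell_areas(pos, cell_ptr, cell_verts, out):
    n = cell_ptr.shape[0] - 1
    for c in range(n):
        i0, i1 = cell_ptr[c], cell_ptr[c + 1]
        s = 0.0
        for t in range(i0, i1):
            a = cell_verts[t]
            b = cell_verts[i0 + (t - i0 + 1) % (i1 - i0)]
            s += pos[a, 0] * pos[b, 1] - pos[b, 0] * pos[a, 1]
        out[c] = 0.5 * s


@njit(cache=True)
def accumulate_forces(pos, cell_ptr, cell_verts, s_target,
                      edges, edge_outer, K_S, K_B, K_R, K_E, L_E, F):
    """F_j = -dU/dx_j for the area + edge + outer-edge energy terms."""
    F[:] = 0.0
    n = cell_ptr.shape[0] - 1
    # area elasticity: dS/dx_j = ((y_next - y_prev)/2, (x_prev - x_next)/2)
    for c in range(n):
        i0, i1 = cell_ptr[c], cell_ptr[c + 1]
        m = i1 - i0
        s = 0.0
        for t in range(i0, i1):
            a = cell_verts[t]
            b = cell_verts[i0 + (t - i0 + 1) % m]
            s += pos[a, 0] * pos[b, 1] - pos[b, 0] * pos[a, 1]
        coef = K_S * (0.5 * s - s_target[c])
        for t in range(i0, i1):
            v = cell_verts[t]
            nxt = cell_verts[i0 + (t - i0 + 1) % m]
            prv = cell_verts[i0 + (t - i0 - 1) % m]
            F[v, 0] -= coef * 0.5 * (pos[nxt, 1] - pos[prv, 1])
            F[v, 1] -= coef * 0.5 * (pos[prv, 0] - pos[nxt, 0])
    # edge tension/repulsion (+ outer-edge elasticity)
    for e in range(edges.shape[0]):
        a, b = edges[e, 0], edges[e, 1]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        L = np.sqrt(dx * dx + dy * dy)
        g = K_B - K_R / (L * L)
        if edge_outer[e]:
            g += K_E * (L - L_E)
        gx = g * dx / L
        gy = g * dy / L
        F[a, 0] -= gx
        F[a, 1] -= gy
        F[b, 0] += gx
        F[b, 1] += gy


@njit(cache=True)
def rk4_step(pos, cell_ptr, cell_verts, s_target, edges, edge_outer,
             K_S, K_B, K_R, K_E, L_E, eta, dt):
    """One RK4 step of eta*dx/dt = F(x); halves dt on cell flips (max 5).

    Returns True on success.  Sub-stepping completes the full dt so the
    caller's clock stays aligned.
    """
    nv = pos.shape[0]
    nc = cell_ptr.shape[0] - 1
    k1 = np.empty((nv, 2))
    k2 = np.empty((nv, 2))
    k3 = np.empty((nv, 2))
    k4 = np.empty((nv, 2))
    areas = np.empty(nc)
    saved = pos.copy()
    h = dt
    remaining = dt
    tries = 0
    while remaining > 1e-15:
        step = h if h <= remaining else remaining
        accumulate_forces(pos, cell_ptr, cell_verts, s_target, edges,
                          edge_outer, K_S, K_B, K_R, K_E, L_E, k1)
        trial = pos + (0.5 * step / eta) * k1
        accumulate_forces(trial, cell_ptr, cell_verts, s_target, edges,
                          edge_outer, K_S, K_B, K_R, K_E, L_E, k2)
        trial = pos + (0.5 * step / eta) * k2
        accumulate_forces(trial, cell_ptr, cell_verts, s_target, edges,
                          edge_outer, K_S, K_B, K_R, K_E, L_E, k3)
        trial = pos + (step / eta) * k3
        accumulate_forces(trial, cell_ptr, cell_verts, s_target, edges,
                          edge_outer, K_S, K_B, K_R, K_E, L_E, k4)
        trial = pos + (step / (6.0 * eta)) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        cell_areas(trial, cell_ptr, cell_verts, areas)
        ok = True
        for c in range(nc):
            if not areas[c] > 0.0 or not np.isfinite(areas[c]):
                ok = False
                break
        if ok:
            pos[:] = trial
            remaining -= step
        else:
            tries += 1
            if tries > 5:
                pos[:] = saved
                return False
            h = 0.5 * step
    return True


@njit(cache=True)
def _ipow(x, e):
    """x**e with a fast path for small integral exponents."""
    ei = int(e)
    if ei == e and 0 <= ei <= 16:
        out = 1.0
        base = x
        n = ei
        while n > 0:
            if n & 1:
                out *= base
            base *= base
            n >>= 1
        return out
    return x ** e


@njit(cache=True)
def _rk4_into(pos, cell_ptr, cell_verts, s_target, edges, edge_outer,
              K_S, K_B, K_R, K_E, L_E, eta, dt,
              k1, k2, k3, k4, trial, saved, areas):
    """rk4_step with caller-provided workspace (hot-loop variant)."""
    nc = cell_ptr.shape[0] - 1
    saved[:] = pos
    h = dt
    remaining = dt
    tries = 0
    while remaining > 1e-15:
        step = h if h <= remaining else remaining
        accumulate_forces(pos, cell_ptr, cell_verts, s_target, edges,
                          edge_outer, K_S, K_B, K_R, K_E, L_E, k1)
        trial[:] = pos + (0.5 * step / eta) * k1
        accumulate_forces(trial, cell_ptr, cell_verts, s_target, edges,
                          edge_outer, K_S, K_B, K_R, K_E, L_E, k2)
        trial[:] = pos + (0.5 * step / eta) * k2
        accumulate_forces(trial, cell_ptr, cell_verts, s_target, edges,
                          edge_outer, K_S, K_B, K_R, K_E, L_E, k3)
        trial[:] = pos + (step / eta) * k3
        accumulate_forces(trial, cell_ptr, cell_verts, s_target, edges,
                          edge_outer, K_S, K_B, K_R, K_E, L_E, k4)
        trial[:] = pos + (step / (6.0 * eta)) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        cell_areas(trial, cell_ptr, cell_verts, areas)
        ok = True
        for c in range(nc):
            if not areas[c] > 0.0 or not np.isfinite(areas[c]):
                ok = False
                break
        if ok:
            pos[:] = trial
            remaining -= step
        else:
            tries += 1
            if tries > 5:
                pos[:] = saved
                return False
            h = 0.5 * step
    return True


@njit(cache=True)
def morphogen_euler(z, adj_ptr, adj_idx, source, A, B, D, dt):
    """One explicit-Euler step of dz_i/dt = A*1[src] - B*z_i + D*sum(z_j - z_i)."""
    n = z.shape[0]
    dz = np.empty(n)
    for i in range(n):
        acc = -B * z[i]
        if source[i]:
            acc += A
        for t in range(adj_ptr[i], adj_ptr[i + 1]):
            acc += D * (z[adj_idx[t]] - z[i])
        dz[i] = acc
    for i in range(n):
        z[i] += dt * dz[i]


@njit(cache=True)
def advance(pos, cell_ptr, cell_verts, s_target, edges, edge_outer,
            adj_ptr, adj_idx, src_u, src_v, src_w, epidermal,
            u, v, w, clock, threshold,
            K_S, K_B, K_R, K_E, L_E, eta, dt,
            A_u, B_u, D_u, A_v, B_v, D_v, A_w, B_w, D_w,
            P0, P, u0, S0, nH, mH,
            max_steps, do_clock, do_mech, min_steps=0):
    """Run up to `max_steps` time steps at fixed topology.

    Per-step order: morphogen Euler -> clock Euler -> division trigger
    check -> RK4 mechanics.  On a clock trigger the kernel returns before
    the mechanics sub-step so the caller can execute divisions first and
    then complete the step.  Triggers are ignored for the first
    `min_steps` steps (used to let geometry relax after a deferred
    division instead of re-checking a stuck trigger every step).

    Returns (steps_fully_completed, status).
    """
    nc = cell_ptr.shape[0] - 1
    nv = pos.shape[0]
    areas = np.empty(nc)
    k1 = np.empty((nv, 2))
    k2 = np.empty((nv, 2))
    k3 = np.empty((nv, 2))
    k4 = np.empty((nv, 2))
    trial = np.empty((nv, 2))
    saved = np.empty((nv, 2))
    u0n = _ipow(u0, nH)
    S0m = _ipow(S0, mH)
    for step in range(max_steps):
        morphogen_euler(u, adj_ptr, adj_idx, src_u, A_u, B_u, D_u, dt)
        morphogen_euler(v, adj_ptr, adj_idx, src_v, A_v, B_v, D_v, dt)
        morphogen_euler(w, adj_ptr, adj_idx, src_w, A_w, B_w, D_w, dt)
        for i in range(nc):
            if not np.isfinite(u[i]) or u[i] < 0.0 or not np.isfinite(v[i]) \
                    or v[i] < 0.0 or not np.isfinite(w[i]) or w[i] < 0.0:
                return step, STATUS_MORPH_FAIL
        if do_clock:
            cell_areas(pos, cell_ptr, cell_verts, areas)
            trigger = False
            for i in range(nc):
                if not epidermal[i]:
                    un = _ipow(u[i], nH)
                    Sm = _ipow(areas[i], mH)
                    rate = P0 + P * (un / (u0n + un)) * (Sm / (S0m + Sm))
                    clock[i] += dt * rate
                    if clock[i] > threshold[i]:
                        trigger = True
            if trigger and step >= min_steps:
                return step, STATUS_CLOCK_TRIGGER
        if do_mech:
            ok = _rk4_into(pos, cell_ptr, cell_verts, s_target, edges,
                           edge_outer, K_S, K_B, K_R, K_E, L_E, eta, dt,
                           k1, k2, k3, k4, trial, saved, areas)
            if not ok:
                return step, STATUS_MECH_FAIL
    return max_steps, STATUS_DONE
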