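"""Simulation driver: the full morphogen -> clock -> division -> mechanics
loop, snapshots, event logging and parameter sweeps.

Within every time step the update order is fixed: morphogen Euler step,
clock Euler step, division check and execution, RK4 mechanics step.  All
randomness (threshold draws, initial jitter) comes from a single generator
seeded by the run config, so a (config, seed) pair reproduces snapshots
and the division-event log bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from ._flat import build_flat
from .division import DivisionEvent, check_divisions, execute_division
from .errors import StabilityError
from .initializer import InitialShapeSpec, build_initial_mesh
from .mesh import (LAYER_NAMES, CellStates, TissueMesh, classify_layers,
                   save_mesh)
from .morphometrics import protrusion_index
from .params import ClockParams, MechanicsParams, MorphogenParams
from .render import render_svg


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    morphogens: MorphogenParams = field(default_factory=MorphogenParams)
    clock: ClockParams = field(default_factory=ClockParams)
    shape: InitialShapeSpec = field(default_factory=InitialShapeSpec)
    mode: str = "hollow"  # forced-orientation preset: hollow | ridge
    max_cells: int = 400
    max_steps: int = 50_000_000
    burn_in_steps: int = 2000  # morphogen-only steps before divisions begin
    snapshot_interval: int = 0  # in steps; 0 = final snapshot only
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("hollow", "ridge"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_cells <= 0 or self.max_steps <= 0:
            raise ValueError("stop criterion must be positive")


@dataclass
class RunResult:
    mesh: TissueMesh
    states: CellStates
    events: list[DivisionEvent]
    summary: dict
    log: pd.DataFrame


def _divide_due(mesh, states, cfg, rng, time, events) -> int:
    """Execute all currently due divisions in ascending cell-id order,
    cascading the epidermal six-edge rule until it is quiescent.
    Returns the number of divisions executed."""
    executed = 0
    for _round in range(100):
        due = check_divisions(mesh, states, cfg.clock)
        if not due or mesh.n_cells >= cfg.max_cells:
            break
        progressed = False
        for cid in due:
            if mesh.n_cells >= cfg.max_cells:
                break
            ev = execute_division(mesh, states, cid, cfg.mode, rng,
                                  cfg.clock, time=time)
            if ev is not None:
                events.append(ev)
                executed += 1
                progressed = True
                classify_layers(mesh, states)
        if not progressed:
            break
    return executed


def events_to_frame(events: list[DivisionEvent]) -> pd.DataFrame:
    rows = [
        {
            "parent": e.parent, "mode": e.mode, "time": e.time,
            "daughter_a": e.daughters[0], "daughter_b": e.daughters[1],
            "x1": e.p1[0], "y1": e.p1[1], "x2": e.p2[0], "y2": e.p2[1],
            "angle_deg": e.angle_deg,
            "layer": LAYER_NAMES.get(e.layer, "?"),
            "sub": {0: "none", 1: "adaxial", 2: "abaxial"}[e.sub],
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=[
        "parent", "mode", "time", "daughter_a", "daughter_b",
        "x1", "y1", "x2", "y2", "angle_deg", "layer", "sub",
    ])


def _snapshot(mesh, states, cfg, step, out: Path | None) -> None:
    if out is None:
        return
    d = out / f"snapshot_{step:09d}"
    save_mesh(mesh, states, d)
    render_svg(mesh, states, d / "tissue.svg")


def run_simulation(config: RunConfig | None = None) -> RunResult:
    """Run one simulation to its stop criterion.

    Returns the final mesh/states, the division-event log, a morphometric
    summary and a per-interval log of energy and cell counts.  When
    ``config.out_dir`` is set, snapshots (CSV pair + SVG), ``events.csv``
    and ``summary.json`` are written there.  On an integration failure the
    last valid state is flushed before the error propagates.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.seed)
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    spec = dataclasses.replace(cfg.shape, seed=cfg.seed)
    mesh, states = build_initial_mesh(spec, cfg.mechanics, cfg.clock, rng=rng)

    events: list[DivisionEvent] = []
    log_rows: list[dict] = []
    m, mo, ck = cfg.mechanics, cfg.morphogens, cfg.clock
    step = 0
    chunk = 50_000

    def call_advance(flat, n, do_clock=True, do_mech=True, min_steps=0):
        return _kernels.advance(
            mesh.vertices, flat.cell_ptr, flat.cell_verts, flat.s_target,
            flat.edges, flat.edge_outer, flat.adj_ptr, flat.adj_idx,
            flat.src_u, flat.src_v, flat.src_w, flat.epidermal,
            states.u, states.v, states.w, states.clock, states.threshold,
            m.K_S, m.K_B, m.K_R, m.K_E, m.L_E, m.eta, m.dt,
            mo.A_u, mo.B_u, mo.D_u, mo.A_v, mo.B_v, mo.D_v,
            mo.A_w, mo.B_w, mo.D_w,
            ck.P0, ck.P, ck.u0, ck.S0, ck.n, ck.m,
            n, do_clock, do_mech, min_steps,
        )

    def log_state():
        counts = {f"n_{name}": int((states.layer == code).sum())
                  for code, name in LAYER_NAMES.items()}
        log_rows.append({"step": step, "time": step * m.dt,
                         "n_cells": mesh.n_cells, **counts})

    flat = build_flat(mesh, states)
    # burn-in: morphogen relaxation before any division or movement
    done, status = call_advance(flat, cfg.burn_in_steps,
                                do_clock=False, do_mech=False)
    if status != _kernels.STATUS_DONE:
        raise StabilityError("morphogen burn-in became unstable")
    # the generated tissue may already contain six-edge epidermal cells
    if _divide_due(mesh, states, cfg, rng, 0.0, events):
        flat = build_flat(mesh, states)
    log_state()
    _snapshot(mesh, states, cfg, step, out)

    next_snap = cfg.snapshot_interval or None
    defer_grace = 0  # steps to run before re-checking a deferred trigger
    try:
        while mesh.n_cells < cfg.max_cells and step < cfg.max_steps:
            n = min(chunk, cfg.max_steps - step)
            if next_snap is not None:
                n = min(n, max(1, next_snap - step))
            done, status = call_advance(flat, n, min_steps=defer_grace)
            step += done
            defer_grace = 0
            if status == _kernels.STATUS_CLOCK_TRIGGER:
                executed = _divide_due(mesh, states, cfg, rng, step * m.dt,
                                       events)
                if executed:
                    flat = build_flat(mesh, states)
                else:
                    # every due division was deferred: let the geometry
                    # relax before re-checking the trigger
                    defer_grace = 200
                # finish the interrupted step with its mechanics sub-step
                _, mstat = call_advance(flat, 1, do_clock=False, do_mech=True)
                step += 1
                if mstat != _kernels.STATUS_DONE:
                    raise StabilityError("mechanics step failed after division")
            elif status == _kernels.STATUS_MECH_FAIL:
                raise StabilityError("RK4 step failed after 5 dt halvings")
            elif status == _kernels.STATUS_MORPH_FAIL:
                raise StabilityError("morphogen Euler step became unstable")
            if next_snap is not None and step >= next_snap:
                log_state()
                _snapshot(mesh, states, cfg, step, out)
                next_snap += cfg.snapshot_interval
    except StabilityError:
        _snapshot(mesh, states, cfg, step, out)
        if out:
            events_to_frame(events).to_csv(out / "events.csv", index=False)
        raise

    classify_layers(mesh, states)
    log_state()
    pi = protrusion_index(mesh, states)
    summary = {
        "seed": cfg.seed, "mode": cfg.mode, "steps": step,
        "time": step * m.dt, "n_cells": mesh.n_cells,
        "n_divisions": len(events),
        "protrusion_height": pi.height,
        "aspect_ratio": pi.aspect_ratio,
        "classification": pi.classification,
        "layer_counts": {name: int((states.layer == code).sum())
                         for code, name in LAYER_NAMES.items()},
    }
    if out:
        _snapshot(mesh, states, cfg, step, out)
        events_to_frame(events).to_csv(out / "events.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return RunResult(mesh=mesh, states=states, events=events,
                     summary=summary, log=pd.DataFrame(log_rows))


def sweep(configs: list[RunConfig]) -> pd.DataFrame:
    """Run each config and tabulate (config, phenotype) rows.

    Individual run failures are recorded in the ``error`` column and the
    sweep continues.
    """
    rows = []
    for cfg in configs:
        row = {
            "mode": cfg.mode, "seed": cfg.seed, "shape": cfg.shape.shape,
            "D_u": cfg.morphogens.D_u, "A_u": cfg.morphogens.A_u,
            "P": cfg.clock.P, "max_cells": cfg.max_cells, "error": "",
        }
        try:
            res = run_simulation(cfg)
            row.update({
                "n_cells": res.summary["n_cells"],
                "protrusion_height": res.summary["protrusion_height"],
                "aspect_ratio": res.summary["aspect_ratio"],
                "classification": res.summary["classification"],
            })
            row.update({f"n_{k}": v
                        for k, v in res.summary["layer_counts"].items()})
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# config files                                                            #
# ---------------------------------------------------------------------- #
_MECH_KEYS = {"eta": "eta", "K_S": "K_S", "K_B": "K_B", "K_R": "K_R",
              "K_E": "K_E", "L_E": "L_E", "dt": "dt"}
_MORPH_KEYS = {k: k for k in ("A_u", "B_u", "D_u", "A_v", "B_v", "D_v",
                              "A_w", "B_w", "D_w")}
_CLOCK_KEYS = {"P0": "P0", "P": "P", "u0": "u0", "S0": "S0", "n": "n",
               "m": "m", "C": "C",
               "threshold_fluctuation": "threshold_fluctuation"}
_SHAPE_KEYS = {"cells": "n_cells", "shape": "shape",
               "depression_depth": "depression_depth",
               "depression_width": "depression_width",
               "adaxial": "adaxial_count", "relax_steps": "relax_steps"}
_RUN_KEYS = {"mode": "mode", "max_cells": "max_cells",
             "max_steps": "max_steps", "burn_in_steps": "burn_in_steps",
             "snapshot_interval": "snapshot_interval", "seed": "seed",
             "out_dir": "out_dir"}


def config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a flat key=value mapping (TOML-style)."""
    def pick(keymap):
        return {dst: d[src] for src, dst in keymap.items() if src in d}

    known = set(_MECH_KEYS) | set(_MORPH_KEYS) | set(_CLOCK_KEYS) \
        | set(_SHAPE_KEYS) | set(_RUN_KEYS)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(
        mechanics=MechanicsParams(**pick(_MECH_KEYS)),
        morphogens=MorphogenParams(**pick(_MORPH_KEYS)),
        clock=ClockParams(**pick(_CLOCK_KEYS)),
        shape=InitialShapeSpec(**pick(_SHAPE_KEYS)),
        **pick(_RUN_KEYS),
    )


def load_config(path) -> RunConfig:
    """Load a flat TOML config file."""
    with open(path, "rb") as fh:
        return config_from_dict(tomllib.load(fh))
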