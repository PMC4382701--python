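"""Minimal SVG renderer for tissue snapshots.

Writes plain SVG text (polygons only).  The model's abaxial side points
towards +y; snapshots are drawn with the abaxial side up, matching the
usual presentation of transverse sections.
"""

from __future__ import annotations

from pathlib import Path

from .mesh import (IDENTITY_ABAXIAL, IDENTITY_ADAXIAL, LAYER_L1, LAYER_L2,
                   LAYER_L3, CellStates, TissueMesh)

_FILL = {
    ("L1", "adaxial"): "#4a6fd4",
    ("L1", "abaxial"): "#e8c544",
    ("L2", None): "#bfe3bf",
    ("L3", None): "#e3d2ef",
    ("inner", None): "#f2f2f2",
}


def _cell_fill(states: CellStates, ci: int) -> str:
    layer = int(states.layer[ci])
    if layer == LAYER_L1:
        ident = ("adaxial" if states.identity[ci] == IDENTITY_ADAXIAL
                 else "abaxial" if states.identity[ci] == IDENTITY_ABAXIAL
                 else "abaxial")
        return _FILL[("L1", ident)]
    if layer == LAYER_L2:
        return _FILL[("L2", None)]
    if layer == LAYER_L3:
        return _FILL[("L3", None)]
    return _FILL[("inner", None)]


def render_svg(mesh: TissueMesh, states: CellStates, path,
               scale: float = 20.0, margin: float = 1.0) -> None:
    """Render the tissue to an SVG file, cells coloured by layer/identity."""
    # re-centre for display only; svg y grows downward so model +y (abaxial)
    # ends up at the top of the image
    centre = mesh.vertices.mean(axis=0)
    pts = mesh.vertices - centre
    xs, ys = pts[:, 0], -pts[:, 1]
    minx, maxx = xs.min() - margin, xs.max() + margin
    miny, maxy = ys.min() - margin, ys.max() + margin
    w = (maxx - minx) * scale
    h = (maxy - miny) * scale
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" '
        f'height="{h:.0f}" viewBox="{minx * scale:.2f} {miny * scale:.2f} '
        f'{w:.2f} {h:.2f}">'
    ]
    for ci in range(mesh.n_cells):
        cyc = mesh.cells[ci]
        coords = " ".join(
            f"{pts[j, 0] * scale:.2f},{-pts[j, 1] * scale:.2f}" for j in cyc
        )
        lines.append(
            f'<polygon points="{coords}" fill="{_cell_fill(states, ci)}" '
            f'stroke="#333" stroke-width="0.6"/>'
        )
    lines.append("</svg>")
    Path(path).write_text("\n".join(lines))
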