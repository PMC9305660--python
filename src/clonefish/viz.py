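"""Fishplot export and rendering of clone trees.

A reconstruction is exported as the classic fishplot input pair --
a clones x time-points fraction matrix in percent plus a parent vector
(0 = root) -- and rendered as a stream graph of nested clone bodies:
each clone occupies a vertical band proportional to its cell fraction,
children are drawn inside their parent, and fractions are interpolated
between analysis time points with a monotone cubic (PCHIP) so bands
never overshoot. Black triangles mark analyzed time points, white
triangles stem-cell transplantations. Rendering is pure: identical
inputs produce byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import matplotlib
import numpy as np
from matplotlib.figure import Figure
from scipy.interpolate import PchipInterpolator

from .reconstruct import CloneTree, _violated

__all__ = ["FishplotExport", "export_fishplot", "render_fishplot",
           "write_fishplot_csv"]

INTERIOR_FLOOR = 0.1  # percent; keeps render topology valid across gaps


@dataclass
class FishplotExport:
    clone_ids: List[str]
    fraction_matrix: np.ndarray          # clones x time points, percent
    parent_vector: List[int]             # per clone; 0 = root, else 1-based
    timepoint_positions: List[float]
    annotations: List[Tuple[float, str]]  # (position, 'analysis'|'transplant')
    floored: List[Tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        m, parents = self.fraction_matrix, self.parent_vector
        if np.any(m < 0) or np.any(m > 100):
            raise ValueError("fractions must lie in [0, 100] percent")
        n, n_tp = m.shape
        for t in range(n_tp):
            roots = sum(m[i, t] for i in range(n) if parents[i] == 0)
            if roots > 100 + 5 + n * INTERIOR_FLOOR:
                raise ValueError(f"root fractions exceed 100% at t={t}")
            for i in range(n):
                kids = sum(m[j, t] for j in range(n) if parents[j] == i + 1)
                if kids > m[i, t] + 5 + n * INTERIOR_FLOOR:
                    raise ValueError(
                        f"children exceed parent {self.clone_ids[i]} at t={t}")


def export_fishplot(tree: CloneTree, n_timepoints: Optional[int] = None,
                    timepoint_positions: Optional[Sequence[float]] = None,
                    transplant_positions: Sequence[float] = (),
                    delta: float = 0.05,
                    interior_floor: float = INTERIOR_FLOOR) -> FishplotExport:
    """Convert an admissible clone tree to fishplot tables (percent).

    A clone present both before and after an intermediate zero is floored
    at ``interior_floor`` percent at the interior points (recorded in
    ``floored``) so the rendered body stays topologically connected.
    """
    reason = _violated(tree.clones, tree.parent, delta, ())
    if reason is not None:
        raise ValueError(f"inadmissible tree: {reason}")
    ids = [c.id for c in tree.clones]
    if n_timepoints is None:
        n_timepoints = max(len(c.ccf_by_timepoint) for c in tree.clones)
    m = np.zeros((len(ids), n_timepoints))
    for i, c in enumerate(tree.clones):
        for t in range(n_timepoints):
            m[i, t] = 100.0 * c.ccf(t)
    parents = [0 if tree.parent[cid] is None else ids.index(tree.parent[cid]) + 1
               for cid in ids]

    floored = []
    for i in range(len(ids)):
        present = np.flatnonzero(m[i] > 0)
        if present.size >= 2:
            for t in range(present[0] + 1, present[-1]):
                if m[i, t] < interior_floor:
                    m[i, t] = interior_floor
                    floored.append((i, t))
    # re-floor ancestors so the nesting survives flooring
    for i, t in list(floored):
        p = parents[i]
        while p != 0:
            kids = sum(m[j, t] for j in range(len(ids)) if parents[j] == p)
            if m[p - 1, t] < kids:
                m[p - 1, t] = kids
                floored.append((p - 1, t))
            p = parents[p - 1]

    positions = list(timepoint_positions) if timepoint_positions is not None \
        else [float(t) for t in range(n_timepoints)]
    annotations = [(p, "analysis") for p in positions]
    annotations += [(float(p), "transplant") for p in transplant_positions]
    export = FishplotExport(clone_ids=ids, fraction_matrix=m,
                            parent_vector=parents,
                            timepoint_positions=positions,
                            annotations=annotations, floored=floored)
    export.validate()
    return export


def write_fishplot_csv(export: FishplotExport, fractions_path,
                       parents_path) -> None:
    """CSV pair consumable by the R fishplot package (cross-validation)."""
    import pandas as pd
    pd.DataFrame(export.fraction_matrix, index=export.clone_ids,
                 columns=[f"t{p:g}" for p in export.timepoint_positions]
                 ).to_csv(fractions_path)
    pd.DataFrame({"clone": export.clone_ids,
                  "parent": export.parent_vector}).to_csv(
        parents_path, index=False)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _layout(export: FishplotExport) -> Tuple[np.ndarray, np.ndarray]:
    """Per clone and time point: (bottom, height) in percent, children
    nested inside parents with even padding."""
    m = export.fraction_matrix
    n, n_tp = m.shape
    parents = export.parent_vector
    bottom = np.zeros_like(m)
    height = m.copy()

    children: Dict[int, List[int]] = {}
    for i, p in enumerate(parents):
        children.setdefault(p, []).append(i)

    def place(group: List[int], lo: float, span: float, t: int) -> None:
        total = sum(height[i, t] for i in group)
        free = max(0.0, span - total)
        pad = free / (len(group) + 1)
        pos = lo + pad
        for i in group:
            h = min(height[i, t], span)
            bottom[i, t] = pos
            if i + 1 in children:
                place(children[i + 1], pos, h, t)
            pos += h + pad

    for t in range(n_tp):
        place(children.get(0, []), 0.0, 100.0, t)
    return bottom, height


def render_fishplot(export: FishplotExport, out_path, title: str = "",
                    cmap: str = "tab20", dpi: int = 150,
                    samples_per_segment: int = 40) -> None:
    """Render a fishplot to SVG/PNG (format from the file suffix).

    Clone bodies are PCHIP-interpolated between time points; monotone
    cubic interpolation cannot overshoot the data, so heights stay
    non-negative and bodies never self-intersect.
    """
    export.validate()
    x = np.asarray(export.timepoint_positions, dtype=float)
    bottom, height = _layout(export)
    n = len(export.clone_ids)

    if x.size > 1:
        dense = np.concatenate([
            np.linspace(x[i], x[i + 1], samples_per_segment, endpoint=False)
            for i in range(x.size - 1)] + [x[-1:]])
    else:
        dense = x

    colors = matplotlib.colormaps[cmap](np.linspace(0, 1, max(n, 1) * 2)[:n])
    with matplotlib.rc_context({"svg.hashsalt": "clonefish"}):
        fig = Figure(figsize=(8, 4), dpi=dpi)
        ax = fig.add_subplot(111)
        order = _draw_order(export.parent_vector)
        for i in order:
            if x.size > 1:
                b = PchipInterpolator(x, bottom[i])(dense)
                h = PchipInterpolator(x, height[i])(dense)
            else:
                b, h = bottom[i], height[i]
            h = np.clip(h, 0.0, None)
            ax.fill_between(dense, b, b + h, lw=0.8,
                            facecolor=colors[i], edgecolor="black",
                            alpha=0.9, zorder=2 + order.index(i))
        for pos, marker in export.annotations:
            if marker == "analysis":
                ax.plot([pos], [104], marker="v", color="black",
                        markersize=7, clip_on=False)
            else:
                ax.plot([pos], [104], marker="v", color="white",
                        markeredgecolor="black", markersize=7, clip_on=False)
        ax.set_ylim(0, 100)
        if x.size > 1:
            ax.set_xlim(x[0], x[-1])
        ax.set_ylabel("clone size (%)")
        ax.set_xlabel("time point of analysis")
        ax.set_xticks(x)
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(out_path, metadata=_metadata_for(str(out_path)))


def _draw_order(parents: List[int]) -> List[int]:
    """Parents before children so fills nest visually."""
    order: List[int] = []

    def visit(p: int) -> None:
        for i, par in enumerate(parents):
            if par == p:
                order.append(i)
                visit(i + 1)

    visit(0)
    return order


def _metadata_for(path: str) -> Optional[dict]:
    if path.endswith(".svg"):
        return {"Date": None}  # drop the timestamp: byte-identical output
    if path.endswith(".png"):
        return {"Software": None}
    return None
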