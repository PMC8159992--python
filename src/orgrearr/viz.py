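"""Circular genome map of detected rearrangements (circmap-style).

Concentric tracks, inside out: rearrangement-point circles (filled =
forward/clockwise end, empty = reverse) joined by inward arcs whose
thickness is log-scaled read support; GC content; gene arcs (blue = +
strand / clockwise, red = -); mapping depth; and the expected depth-change
track (blue inward bars where depth should rise clockwise, red outward
where it should fall), inside an outer position scale.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .depth import DepthTrack
from .refio import Reference

_R_POINTS = 0.42
_R_GC = 0.55
_R_GENES = 0.68
_R_DEPTH = 0.80
_R_CHANGE = 0.95
_TRACK_H = 0.10


def _theta(pos: int, n: int) -> float:
    # clockwise from 12 o'clock, like a genome dial
    return math.pi / 2 - 2 * math.pi * (pos - 1) / n


def _ring(ax, values: np.ndarray, r0: float, height: float, n: int,
          color: str) -> None:
    """Radial bar ring: each finite window value drawn from r0 outward,
    scaled to the ring height by the track maximum."""
    vals = np.asarray(values, dtype=float)
    if not np.isfinite(vals).any():
        return
    vmax = np.nanmax(np.abs(vals))
    if vmax == 0:
        vmax = 1.0
    nwin = len(vals)
    for i, v in enumerate(vals):
        if not np.isfinite(v):
            continue
        t0 = _theta(int(i * n / nwin) + 1, n)
        t1 = _theta(int((i + 1) * n / nwin) + 1, n)
        h = height * abs(v) / vmax
        ts = np.linspace(t0, t1, 4)
        xs = np.concatenate([np.cos(ts) * r0, (np.cos(ts) * (r0 + h))[::-1]])
        ys = np.concatenate([np.sin(ts) * r0, (np.sin(ts) * (r0 + h))[::-1]])
        ax.fill(xs, ys, color=color, linewidth=0)


def render_circular_map(
    ref: Reference,
    tracks: dict[str, DepthTrack],
    rearrs: Sequence,
    out_path: str | Path,
) -> Path:
    """Render the figure to ``out_path`` (SVG for vector arcs; PNG works too)."""
    if len(ref.seq) == 0:
        raise ValueError("empty reference")
    n = len(ref.seq)
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.set_aspect("equal")
    ax.axis("off")

    # outer scale
    circle = np.linspace(0, 2 * math.pi, 720)
    ax.plot(np.cos(circle) * 1.02, np.sin(circle) * 1.02, color="black", lw=0.8)
    tick = 10 ** max(3, int(math.log10(max(n, 10)) - 1))
    for pos in range(0, n, tick):
        t = _theta(pos + 1, n)
        ax.plot([math.cos(t) * 1.02, math.cos(t) * 1.05],
                [math.sin(t) * 1.02, math.sin(t) * 1.05], color="black", lw=0.8)
        ax.text(math.cos(t) * 1.12, math.sin(t) * 1.12, f"{pos // 1000}k",
                ha="center", va="center", fontsize=7)

    # rearrangement points and arcs
    for r in rearrs:
        (pa, da), (pb, db) = r.end_a, r.end_b
        lw = 0.5 + math.log10(max(r.n_reads, 1))
        ta, tb = _theta(pa, n), _theta(pb, n)
        ax0 = np.array([math.cos(ta), math.sin(ta)]) * _R_POINTS
        bx0 = np.array([math.cos(tb), math.sin(tb)]) * _R_POINTS
        ctrl = (ax0 + bx0) / 4  # pull the chord toward the centre
        ts = np.linspace(0, 1, 40)[:, None]
        curve = ((1 - ts) ** 2) * ax0 + 2 * ts * (1 - ts) * ctrl + ts**2 * bx0
        ax.plot(curve[:, 0], curve[:, 1], color="purple", lw=lw, alpha=0.7)
        for (p, d) in ((pa, da), (pb, db)):
            t = _theta(p, n)
            filled = d == "forward"
            ax.plot(math.cos(t) * _R_POINTS, math.sin(t) * _R_POINTS,
                    marker="o", ms=4, mfc=("black" if filled else "white"),
                    mec="black")

    if "gc" in tracks:
        _ring(ax, tracks["gc"].values, _R_GC, _TRACK_H, n, "grey")
    for ann in ref.annotations:
        if ann.kind != "gene":
            continue
        t0, t1 = _theta(ann.start, n), _theta(ann.end, n)
        ts = np.linspace(t0, t1, max(int(abs(t1 - t0) * 60), 2))
        color = "blue" if ann.strand == "+" else "red"
        ax.plot(np.cos(ts) * _R_GENES, np.sin(ts) * _R_GENES, color=color, lw=3)
    if "depth" in tracks:
        _ring(ax, tracks["depth"].values, _R_DEPTH, _TRACK_H, n, "darkgreen")
    if "expected_change" in tracks:
        # positive (expected increase clockwise): blue inward; negative: red outward
        vals = tracks["expected_change"].values
        _ring(ax, np.where(vals > 0, vals, np.nan), _R_CHANGE - _TRACK_H, _TRACK_H,
              n, "blue")
        _ring(ax, np.where(vals < 0, -vals, np.nan), _R_CHANGE, _TRACK_H, n, "red")

    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.set_title(ref.name, fontsize=10)
    out_path = Path(out_path)
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
    return out_path
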