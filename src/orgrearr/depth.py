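"""Windowed depth, GC and copy-number ratio tracks.

Depth is the per-window mean base coverage (sum of read bases overlapping
the window divided by the window's true width; the last partial window is
normalized by its own width).  Mutant copy number relative to wild type is
the per-window depth ratio rescaled by the two samples' mapped-read
totals, so library size cancels and a flat genome gives 1.0 everywhere.
Windows falling inside the kept copy of a collapsed inverted repeat are
flagged: their observed depth carries the reads of both copies.
The expected-depth-change track summarizes accepted rearrangement ends:
an end oriented forward (clockwise) drains replication downstream of the
junction, so its reads count negative; reverse ends count positive.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .mapper import MappingTable
from .refio import Reference


@dataclasses.dataclass
class DepthTrack:
    window: int
    values: np.ndarray
    kind: str  # 'depth' | 'gc' | 'ratio' | 'expected_change'
    ref_len: int
    doubled: np.ndarray | None = None  # True where the window is in the kept IR

    def __post_init__(self) -> None:
        expect = math.ceil(self.ref_len / self.window)
        if len(self.values) != expect:
            raise ValueError(f"track needs {expect} windows, got {len(self.values)}")

    def __len__(self) -> int:
        return len(self.values)

    def window_widths(self) -> np.ndarray:
        w = np.full(len(self.values), self.window, dtype=float)
        rem = self.ref_len - (len(self.values) - 1) * self.window
        w[-1] = rem
        return w

    def copy_number_adjusted(self) -> np.ndarray:
        """Depth with the doubled (kept-IR) windows halved to single copy."""
        vals = self.values.astype(float).copy()
        if self.doubled is not None:
            vals[self.doubled] /= 2.0
        return vals


def fold_coverage(mapped_bases: float, genome_length: int) -> float:
    """Average fold coverage: total mapped bases over genome length."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    return mapped_bases / genome_length


def depth_track(
    table: MappingTable, ref: Reference, window: int = 100
) -> DepthTrack:
    """Mean base coverage per window from mapped reads (circular wrap aware)."""
    n = len(ref.seq)
    per_base = np.zeros(n + 1)
    for row in table.rows:
        if not row["mapped"]:
            continue
        start = row["pos"] - 1
        end = start + row["length"]
        if end <= n:
            per_base[start] += 1
            per_base[end] -= 1
        else:  # wraps the origin
            per_base[start] += 1
            per_base[n] -= 1
            per_base[0] += 1
            per_base[end - n] -= 1
    cov = np.cumsum(per_base[:-1])
    nwin = math.ceil(n / window)
    sums = np.add.reduceat(cov, np.arange(0, n, window))
    widths = np.full(nwin, window, dtype=float)
    widths[-1] = n - (nwin - 1) * window
    values = sums / widths
    doubled = None
    if ref.collapsed is not None:
        ks, ke = ref.collapsed[0]
        centers = np.arange(nwin) * window + widths / 2
        doubled = (centers >= ks - 1) & (centers <= ke)
    return DepthTrack(window, values, "depth", n, doubled)


def gc_track(ref: Reference, window: int = 100) -> DepthTrack:
    """Per-window GC fraction over non-N bases (all-N windows are NaN)."""
    arr = np.frombuffer(ref.seq.encode(), dtype=np.uint8)
    isgc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
    notn = (arr != ord("N")).astype(float)
    n = len(arr)
    idx = np.arange(0, n, window)
    gc = np.add.reduceat(isgc, idx)
    denom = np.add.reduceat(notn, idx)
    with np.errstate(invalid="ignore"):
        values = np.where(denom > 0, gc / np.maximum(denom, 1), np.nan)
    return DepthTrack(window, values, "gc", n)


def normalize_against_wt(
    mut: DepthTrack, wt: DepthTrack, mut_total_reads: int, wt_total_reads: int
) -> DepthTrack:
    """(mutant depth / WT depth) per window, rescaled by mapped-read totals.

    Windows where the WT has zero depth are NaN (excluded from summaries).
    """
    if mut.window != wt.window or mut.ref_len != wt.ref_len:
        raise ValueError("track geometry mismatch")
    if mut_total_reads <= 0 or wt_total_reads <= 0:
        raise ValueError("read totals must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (mut.values / wt.values) * (wt_total_reads / mut_total_reads)
    ratio = np.where(wt.values > 0, ratio, np.nan)
    return DepthTrack(mut.window, ratio, "ratio", mut.ref_len, mut.doubled)


def expected_change_track(
    rearrs: Sequence, ref_len: int, window: int = 100
) -> DepthTrack:
    """Signed read support of rearrangement ends per window.

    Forward (clockwise) ends are expected to decrease depth downstream and
    count negative; reverse ends count positive.  Both ends of every
    rearrangement contribute.
    """
    nwin = math.ceil(ref_len / window)
    values = np.zeros(nwin)
    for r in rearrs:
        for pos, direction in (r.end_a, r.end_b):
            w = min((pos - 1) // window, nwin - 1)
            values[w] += -r.n_reads if direction == "forward" else r.n_reads
    return DepthTrack(window, values, "expected_change", ref_len)


def write_track_tsv(track: DepthTrack, path: str | Path) -> Path:
    path = Path(path)
    widths = track.window_widths()
    with open(path, "w") as fh:
        fh.write("start\tend\tvalue\n")
        pos = 1
        for i, v in enumerate(track.values):
            fh.write(f"{pos}\t{pos + int(widths[i]) - 1}\t{v:.6g}\n")
            pos += int(widths[i])
    return path


def write_bedgraph(track: DepthTrack, ref_name: str, path: str | Path) -> Path:
    """bedGraph export (0-based half-open, converted from 1-based internal)."""
    path = Path(path)
    widths = track.window_widths()
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.kind}"\n')
        start = 0
        for i, v in enumerate(track.values):
            end = start + int(widths[i])
            if not np.isnan(v):
                fh.write(f"{ref_name}\t{start}\t{end}\t{v:.6g}\n")
            start = end
    return path
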