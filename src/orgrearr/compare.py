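"""Cross-sample comparison of rearrangement calls and summary statistics.

Calls from several strains are merged on their breakpoint coordinates
(events sharing both ends and the category are the same event) into a
matrix of read counts per sample, written as CSV both raw (.out) and
scaled to reads per million mapped reads (.out2).  Two statistics from the
analysis are provided: the gene/CDS outside-vs-inside density ratio of
rearrangement ends (values above 1 mean breakpoints accumulate outside
genes), and the Morisita overlap between two binned positional
distributions (1 for proportional distributions, 0 for disjoint ones),
used to compare link distributions with repeat distributions.  The
default Morisita variant is Morisita-Horn, which remains valid for
non-integer (scaled) counts; the classical index is available for raw
counts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .junctions import Rearrangement
from .refio import Annotation


def _event_key(r: Rearrangement) -> tuple:
    ends = sorted([tuple(r.end_a), tuple(r.end_b)])
    return (*ends[0], *ends[1], r.category)


def merge_across_samples(
    calls: dict[str, Sequence[Rearrangement]], tolerance: int = 0
) -> pd.DataFrame:
    """Read-count matrix: rows = distinct events, columns = samples.

    Events match when both ends agree within ``tolerance`` bp (same
    directions and category).  The row order is by coordinates, so the
    result is independent of sample order.
    """
    samples = list(calls)
    keys: list[tuple] = []

    def find_key(k: tuple) -> tuple:
        # k = (pos_a, dir_a, pos_b, dir_b, category)
        if tolerance == 0:
            return k
        for existing in keys:
            if existing[4] != k[4] or existing[1] != k[1] or existing[3] != k[3]:
                continue
            if abs(existing[0] - k[0]) <= tolerance and abs(existing[2] - k[2]) <= tolerance:
                return existing
        return k

    counts: dict[tuple, dict[str, int]] = {}
    for sample, rearrs in calls.items():
        for r in rearrs:
            k = find_key(_event_key(r))
            if k not in counts:
                counts[k] = {}
                keys.append(k)
            counts[k][sample] = counts[k].get(sample, 0) + r.n_reads
    rows = sorted(counts)
    data = {s: [counts[k].get(s, 0) for k in rows] for s in samples}
    idx = (
        pd.MultiIndex.from_tuples(
            rows, names=["pos_a", "dir_a", "pos_b", "dir_b", "category"]
        )
        if rows
        else None
    )
    return pd.DataFrame(data, index=idx)


def scale_per_million(df: pd.DataFrame, mapped_reads: dict[str, int]) -> pd.DataFrame:
    """.out2 scaling: count x 1e6 / sample mapped reads."""
    out = df.astype(float).copy()
    for s in df.columns:
        if mapped_reads.get(s, 0) <= 0:
            raise ValueError(f"no mapped-read total for sample {s!r}")
        out[s] = out[s] * 1e6 / mapped_reads[s]
    return out


def write_out_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path)
    return path


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, last_end = 0, 0
    for s, e in sorted(intervals):
        s = max(s, last_end + 1)
        if e >= s:
            total += e - s + 1
            last_end = max(last_end, e)
    return total


def outside_gene_ratio(
    rearrs: Sequence[Rearrangement],
    annotations: Sequence[Annotation],
    ref_len: int,
    feature: str = "gene",
) -> dict[str, float | None]:
    """Length-normalized outside/inside breakpoint density per category.

    Each rearrangement end counts once.  ratio =
    (n_outside / L_outside) / (n_inside / L_inside); > 1 means breakpoints
    are enriched outside the feature.  ``None`` stands in for the
    undefined ratio when no end falls inside (rendered as a dash).
    """
    feats = [(a.start, a.end) for a in annotations if a.kind == feature]
    l_in = _union_length(feats)
    l_out = ref_len - l_in
    if l_in == 0 or l_out == 0:
        raise ValueError("feature span must leave both inside and outside room")

    def inside(pos: int) -> bool:
        return any(s <= pos <= e for s, e in feats)

    out: dict[str, float | None] = {}
    by_cat: dict[str, list[int]] = {}
    for r in rearrs:
        by_cat.setdefault(r.category, []).extend([r.end_a[0], r.end_b[0]])
    for cat, ends in by_cat.items():
        n_in = sum(1 for p in ends if inside(p))
        n_out = len(ends) - n_in
        out[cat] = None if n_in == 0 else (n_out / l_out) / (n_in / l_in)
    return out


def morisita_overlap(
    x: Iterable[float], y: Iterable[float], variant: str = "horn"
) -> float:
    """Overlap between two binned count distributions.

    ``horn`` (default): C = 2 sum(x_i y_i) /
    ((sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) X Y); valid for scaled counts.
    ``classical``: Morisita's original index for integer counts, with
    lambda = sum(x_i (x_i - 1)) / (X (X - 1)).
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("bin counts must align")
    X, Y = xa.sum(), ya.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("zero-total vector")
    cross = float((xa * ya).sum())
    if variant == "horn":
        d = (xa @ xa) / X**2 + (ya @ ya) / Y**2
        return 2 * cross / (d * X * Y)
    if variant == "classical":
        lx = (xa * (xa - 1)).sum() / (X * (X - 1))
        ly = (ya * (ya - 1)).sum() / (Y * (Y - 1))
        return 2 * cross / ((lx + ly) * X * Y)
    raise ValueError(f"unknown variant {variant!r}")
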