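"""Discordant paired-end detection and seed clustering.

Independent support for the junction-read caller: read pairs from the
truncated mapping condition (first 100 bp of each mate) are flagged when
their mapped positions are more than 600 bp apart or when both mates point
the same way, and flagged pairs are greedily clustered against cluster
*seeds* (the first pair seen starts a cluster; a pair joins the first
cluster whose seed it matches within a 500 bp position-difference budget).
The method sees the presence and approximate position of a rearrangement
but cannot resolve short indels.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

from .mapper import MappingTable


@dataclasses.dataclass
class PairAnomaly:
    read_id: str
    pos1: int
    pos2: int
    dir1: str
    dir2: str
    kind: str  # 'far' | 'same_direction'


@dataclasses.dataclass
class PairCluster:
    seed: PairAnomaly
    members: list[PairAnomaly]

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def sd_pos(self) -> float:
        """Pooled standard deviation of member positions around their means
        (both mate coordinates contribute)."""
        if self.n == 0:
            return 0.0
        m1 = sum(m.pos1 for m in self.members) / self.n
        m2 = sum(m.pos2 for m in self.members) / self.n
        ss = sum((m.pos1 - m1) ** 2 + (m.pos2 - m2) ** 2 for m in self.members)
        return math.sqrt(ss / (2 * self.n))


def find_unusual_pairs(
    table: MappingTable, min_sep: int = 600
) -> list[PairAnomaly]:
    """Pairs separated by more than ``min_sep`` bp or pointing the same way.

    Positions are each mate's 1-based leftmost mapped base; pairs with an
    unmapped mate are ignored.  Separation exactly ``min_sep`` is not
    anomalous (strict inequality).
    """
    out: list[PairAnomaly] = []
    pending: dict[str, dict] = {}
    for row in table.rows:
        if not row["mapped"]:
            continue
        other = pending.pop(row["read_id"], None)
        if other is None:
            pending[row["read_id"]] = row
            continue
        r1, r2 = (other, row) if other["mate"] == 1 else (row, other)
        far = abs(r1["pos"] - r2["pos"]) > min_sep
        same = r1["strand"] == r2["strand"]
        if far or same:
            out.append(PairAnomaly(
                r1["read_id"], r1["pos"], r2["pos"], r1["strand"], r2["strand"],
                "far" if far else "same_direction",
            ))
    return out


def cluster_pairs(
    anoms: Sequence[PairAnomaly], max_sum: int = 500
) -> list[PairCluster]:
    """Greedy single-pass clustering against cluster seeds, in input order.

    A pair joins the first existing cluster whose *seed* satisfies
    |dpos1| + |dpos2| < ``max_sum``; otherwise it seeds a new cluster.
    This is deliberately seed-relative (not centroid-relative): it
    reproduces the published greedy behaviour, and for events more than
    2 x ``max_sum`` apart the result is order-independent.
    """
    clusters: list[PairCluster] = []
    for a in anoms:
        for cl in clusters:
            if (abs(a.pos1 - cl.seed.pos1) + abs(a.pos2 - cl.seed.pos2)) < max_sum:
                cl.members.append(a)
                break
        else:
            clusters.append(PairCluster(a, [a]))
    return clusters


def write_pdist(anoms: Sequence[PairAnomaly], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("read_id\tpos1\tpos2\tdir1\tdir2\tkind\n")
        for a in anoms:
            fh.write(f"{a.read_id}\t{a.pos1}\t{a.pos2}\t{a.dir1}\t{a.dir2}\t{a.kind}\n")
    return path


def write_pe(clusters: Sequence[PairCluster], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("seed_pos1\tseed_pos2\tdir1\tdir2\tn\tsd\n")
        for cl in clusters:
            s = cl.seed
            fh.write(f"{s.pos1}\t{s.pos2}\t{s.dir1}\t{s.dir2}\t{cl.n}\t{cl.sd_pos:.2f}\n")
    return path
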