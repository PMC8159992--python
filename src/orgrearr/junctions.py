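"""Junction-read clustering: the split-read rearrangement caller.

A junction read spans a rearrangement breakpoint: one side matches the
reference where the read was anchored, the other side belongs to the
partner locus and shows up as a dense block of mismatches.  From
mismatch-tolerant mappings we collect reads with more than three
mismatches, all confined to one half of the read; the first mismatch
traced from the mismatch-free end marks the junction point.  Reads sharing
a junction point (and direction) form a junction cluster; the mismatch
tails are aligned from the junction point into a two-stage consensus
(plurality with A>T>G>C tie-break, support thresholds 3 then 4), the
consensus is located on the reference to find the partner locus, the
cluster is validated (consensus > 15 bp, surviving members > 3 and > half,
unique partner, per-read re-check, mate consistency) and the accepted
junction is classified into one of five categories:

``del``/``ins``  same-direction ends < 50 bp apart (short deletion or
                 tandem-repeat insertion; arbitrary-sequence insertions are
                 invisible to this method),
``pal``          opposite-direction ends < 70 bp apart (U-turn fold-back
                 at a palindrome/quasi-palindrome),
``mhr``          distant ends whose flanks share an identical sequence of
                 at least ``min_homology`` bases spanning the junction
                 (microhomology/homology-mediated; orientation same or
                 opposite),
``unk``          distant ends with no such shared sequence.

mhr entries caused by one repeat pair (two reciprocal products x two
clusters each) are unified into .mhmr records so the asymmetry of the
reciprocal products can be read off directly.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .mapper import MappingTable
from .refio import Reference, RepeatPair, revcomp

PREFERENCE = "ATGC"  # consensus tie-break order


@dataclasses.dataclass
class JunctionParams:
    min_mismatch: int = 3          # candidates need strictly more
    min_support: int = 3           # temporary-consensus truncation
    final_min: int = 4             # final-consensus truncation
    min_consensus_len: int = 15    # accepted clusters need strictly more
    min_members: int = 3           # survivors needed, strictly more
    indel_max: int = 50            # strict upper bound for del/ins
    pal_max: int = 70              # strict upper bound for pal separation
    min_homology: int = 3          # mhr needs a shared flank >= this
    tail_recheck_max: int = 1      # mismatches tolerated in the short side
    insert_k_sd: float = 3.0       # mate window = mean + k*sd


@dataclasses.dataclass
class JunctionCandidate:
    read_id: str
    mate: int
    map_pos: int
    strand: str
    length: int
    n_mismatch: int
    junction_point: int
    direction: str        # 'forward': matched side at lower coordinates
    matched_len: int
    tail_seq: str         # mismatch-prone side, 5'->3' away from the junction


@dataclasses.dataclass
class Rearrangement:
    category: str
    end_a: tuple[int, str]
    end_b: tuple[int, str]
    homology_len: int = 0
    homology_seq: str = ""
    repeat_orientation: str | None = None
    n_reads: int = 0
    source: str = "junction"
    event_length: int | None = None  # deleted bases / tandem-unit length
    tract_a: tuple[int, int] | None = None  # homology tract at each end
    tract_b: tuple[int, int] | None = None


@dataclasses.dataclass
class JunctionCluster:
    junction_point: int
    direction: str
    members: list[JunctionCandidate]
    consensus: str = ""
    retained: list[JunctionCandidate] = dataclasses.field(default_factory=list)
    final_members: list[JunctionCandidate] = dataclasses.field(default_factory=list)
    partner: tuple[int, str] | None = None
    status: str = "raw"
    reject_reason: str | None = None
    n_reads: int = 0
    rearrangement: Rearrangement | None = None


# ---------------------------------------------------------------------------
# candidate extraction


def find_junction_candidates(
    table: MappingTable, ref: Reference, params: JunctionParams | None = None
) -> list[JunctionCandidate]:
    """Reads with > ``min_mismatch`` mismatches confined to one read half.

    Offsets are taken in reference orientation; the junction point is the
    reference position of the last matching base on the clean side and the
    tail is returned 5'->3' walking away from the junction along the
    rearranged molecule.
    """
    params = params or JunctionParams()
    out: list[JunctionCandidate] = []
    for row in table.rows:
        if not row["mapped"] or row["n_mismatch"] <= params.min_mismatch:
            continue
        L = row["length"]
        offs = row["offsets"]
        if row["strand"] == "-":
            offr = tuple(sorted(L - 1 - o for o in offs))
        else:
            offr = tuple(offs)
        lo, hi = offr[0], offr[-1]
        readref = row["seq"] if row["strand"] == "+" else revcomp(row["seq"])
        if lo >= (L + 1) // 2:  # clean left half
            junction = ref.wrap(row["pos"] + lo - 1)
            out.append(JunctionCandidate(
                row["read_id"], row["mate"], row["pos"], row["strand"], L,
                row["n_mismatch"], junction, "forward", lo, readref[lo:],
            ))
        elif hi <= L // 2 - 1:  # clean right half
            junction = ref.wrap(row["pos"] + hi + 1)
            out.append(JunctionCandidate(
                row["read_id"], row["mate"], row["pos"], row["strand"], L,
                row["n_mismatch"], junction, "reverse", L - 1 - hi,
                revcomp(readref[: hi + 1]),
            ))
    return out


def cluster_by_junction(cands: Sequence[JunctionCandidate]) -> list[JunctionCluster]:
    """Exact grouping by (junction_point, direction)."""
    groups: dict[tuple[int, str], list[JunctionCandidate]] = defaultdict(list)
    for c in cands:
        groups[(c.junction_point, c.direction)].append(c)
    return [
        JunctionCluster(jp, d, members)
        for (jp, d), members in sorted(groups.items())
    ]


# ---------------------------------------------------------------------------
# consensus


def _consensus_pass(tails: Sequence[str], min_sup: int) -> str:
    """Plurality consensus aligned from the junction, tie-break A>T>G>C,
    truncated where the number of reads whose prefix matches drops below
    ``min_sup``."""
    alive = list(tails)
    out: list[str] = []
    i = 0
    while True:
        covering = [t for t in alive if len(t) > i]
        if not covering:
            break
        counts = {b: 0 for b in PREFERENCE}
        for t in covering:
            if t[i] in counts:
                counts[t[i]] += 1
        base = max(PREFERENCE, key=lambda b: (counts[b], -PREFERENCE.index(b)))
        matching = [t for t in covering if t[i] == base]
        if len(matching) < min_sup:
            break
        out.append(base)
        alive = matching + [t for t in alive if len(t) <= i]
        i += 1
    return "".join(out)


def build_consensus(
    cluster: JunctionCluster, min_support: int = 3, final_min: int = 4
) -> tuple[str, list[JunctionCandidate]]:
    """Two-stage consensus over the cluster's mismatch tails.

    Stage one builds a temporary consensus and removes members that
    disagree with it anywhere over their overlap; stage two rebuilds from
    the survivors with the stricter truncation threshold.  Sets
    ``cluster.consensus`` and ``cluster.retained`` and returns both.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    tails = [m.tail_seq for m in cluster.members]
    temp = _consensus_pass(tails, min_support)
    retained = [
        m for m in cluster.members
        if m.tail_seq[: len(temp)] == temp[: len(m.tail_seq)]
    ]
    final = _consensus_pass([m.tail_seq for m in retained], final_min) if retained else ""
    cluster.consensus = final
    cluster.retained = retained
    return final, retained


def locate_partner(consensus: str, ref: Reference) -> tuple[int, str] | None:
    """Exact search of the consensus on both strands; ``None`` unless unique.

    A forward hit means the rearranged molecule enters the partner locus at
    the hit's first base and continues toward higher coordinates; a
    reverse-complement hit enters at the hit's last base and continues
    toward lower coordinates.
    """
    if not consensus:
        return None
    k = len(consensus)
    n = len(ref.seq)
    hay = ref.seq + (ref.seq[: k - 1] if ref.circular else "")

    def all_hits(needle: str) -> list[int]:
        hits, start = [], 0
        while True:
            s = hay.find(needle, start)
            if s < 0 or s >= n:
                return hits
            hits.append(s)
            start = s + 1

    f = all_hits(consensus)
    r = all_hits(revcomp(consensus))
    if len(f) + len(r) != 1:
        return None
    if f:
        return f[0] + 1, "forward"
    return ref.wrap(r[0] + k), "reverse"


# ---------------------------------------------------------------------------
# validation


def estimate_insert_stats(
    table: MappingTable, max_span: int = 2000
) -> tuple[float, float]:
    """Mean and sd of the insert span over concordant (facing) pairs."""
    spans = []
    seen: dict[str, dict] = {}
    for row in table.rows:
        if not row["mapped"]:
            continue
        other = seen.pop(row["read_id"], None)
        if other is None:
            seen[row["read_id"]] = row
            continue
        if row["strand"] == other["strand"]:
            continue
        plus, minus = (row, other) if row["strand"] == "+" else (other, row)
        span = minus["pos"] + minus["length"] - plus["pos"]
        if 0 < span <= max_span:
            spans.append(span)
    if len(spans) < 10:
        return 300.0, 30.0
    arr = np.asarray(spans, dtype=float)
    return float(arr.mean()), float(arr.std())


def _in_window(pos: int, lo: int, hi: int, ref: Reference) -> bool:
    if not ref.circular:
        return lo <= pos <= hi
    n = len(ref.seq)
    return (pos - lo) % n <= (hi - lo)


def _mate_consistent(
    member: JunctionCandidate,
    mate_row: dict | None,
    partner: tuple[int, str],
    ref: Reference,
    insert_stats: tuple[float, float],
    k_sd: float,
) -> bool:
    """Is the paired read where the junction geometry says it should be?

    The fragment continues past the junction read's 3' end: into the
    partner locus when the 3' end lies in the mismatch tail, or along the
    reference when it lies in the matched segment.  The mate must map on
    the same reference, on the strand that continuation implies, within
    insert_mean + k*sd (one read length of slack on both bounds, since the
    mate may itself overlap the junction).
    """
    if mate_row is None or not mate_row["mapped"]:
        return False
    mean, sd = insert_stats
    maxins = int(mean + k_sd * sd)
    L = member.length
    P, pd = partner
    tail_right = member.direction == "forward"
    three_prime_right = member.strand == "+"
    if tail_right == three_prime_right:
        if pd == "forward":
            want, lo, hi = "-", P - L, P + maxins
        else:
            want, lo, hi = "+", P - maxins - L, P + L
    else:
        if member.strand == "+":
            want, lo, hi = "-", member.map_pos - L, member.map_pos + maxins
        else:
            end = member.map_pos + L - 1
            want, lo, hi = "+", end - maxins, end + L
    if mate_row["strand"] != want:
        return False
    return _in_window(mate_row["pos"], lo, hi, ref)


def validate_cluster(
    cluster: JunctionCluster,
    ref: Reference,
    table: MappingTable | None = None,
    params: JunctionParams | None = None,
    insert_stats: tuple[float, float] | None = None,
) -> JunctionCluster:
    """Apply the acceptance cascade; sets status/partner/n_reads in place.

    Order: final consensus longer than ``min_consensus_len``; survivors
    more than ``min_members`` and more than half the original cluster;
    unique partner locus; per-read re-check against the partner (no
    mismatch allowed in the longer segment, at most one in the shorter);
    mate-consistency filter (skipped when no table is supplied).
    """
    params = params or JunctionParams()
    if cluster.consensus == "" and cluster.members:
        build_consensus(cluster, params.min_support, params.final_min)

    def reject(reason: str) -> JunctionCluster:
        cluster.status = "rejected"
        cluster.reject_reason = reason
        return cluster

    if len(cluster.consensus) <= params.min_consensus_len:
        return reject("consensus too short")
    n_orig = len(cluster.members)
    n_surv = len(cluster.retained)
    if n_surv <= params.min_members:
        return reject("insufficient support")
    if n_surv * 2 <= n_orig:
        return reject("not majority")
    partner = locate_partner(cluster.consensus, ref)
    if partner is None:
        return reject("partner not unique")
    cluster.partner = partner
    P, pd = partner
    remaining = []
    for m in cluster.retained:
        expect = ref.segment(P, len(m.tail_seq), pd)
        mism = sum(1 for a, b in zip(m.tail_seq, expect) if a != b)
        mism += len(m.tail_seq) - len(expect)  # ran off a linear reference
        allowed = 0 if len(m.tail_seq) > m.matched_len else params.tail_recheck_max
        if mism <= allowed:
            remaining.append(m)
    if table is not None:
        if insert_stats is None:
            insert_stats = estimate_insert_stats(table)
        remaining = [
            m for m in remaining
            if _mate_consistent(m, table.mate_of(m.read_id, m.mate), partner,
                                ref, insert_stats, params.insert_k_sd)
        ]
    if not remaining:
        return reject("no members after re-check")
    cluster.final_members = remaining
    cluster.n_reads = len(remaining)
    cluster.status = "accepted"
    return cluster


# ---------------------------------------------------------------------------
# classification


def _walk_dir(end_dir: str, is_junction: bool) -> str:
    """Reference walk direction of the retained sequence through an end.

    Junction ends labelled 'forward' retain the lower-coordinate side (the
    molecule walks + into the junction); partner ends labelled 'forward'
    continue toward higher coordinates (the molecule walks + out of the
    junction).  Both map to a '+' walk; 'reverse' ends map to '-'.
    """
    return "+" if end_dir == "forward" else "-"


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def homology_at_junction(
    ref: Reference,
    junction_end: tuple[int, str],
    partner_end: tuple[int, str],
    cap: int = 100,
) -> tuple[int, int, str]:
    """Maximal shared flank (left-extension, right-extension, sequence).

    The junction placement is ambiguous wherever the bases on one side
    could equally have come from either locus; the returned extensions
    count those positions on each side of the reported junction, so
    left + right is the homology length.
    """
    (J, dj), (P, dp) = junction_end, partner_end
    w1, w2 = _walk_dir(dj, True), _walk_dir(dp, False)
    # outward (anti-molecule) bases at/behind the junction from each locus
    a_in = ref.segment(J, cap, "reverse" if w1 == "+" else "forward")
    b_pre = ref.segment(
        ref.wrap(P - 1) if w2 == "+" else ref.wrap(P + 1),
        cap, "reverse" if w2 == "+" else "forward",
    )
    left = _lcp(a_in, b_pre)
    # molecule-forward bases past the junction from each locus
    a_post = ref.segment(
        ref.wrap(J + 1) if w1 == "+" else ref.wrap(J - 1),
        cap, "forward" if w1 == "+" else "reverse",
    )
    b_in = ref.segment(P, cap, "forward" if w2 == "+" else "reverse")
    right = _lcp(a_post, b_in)
    if w1 == "+":
        seq = ref.segment(ref.wrap(J - left + 1), left + right, "forward")
    else:
        seq = ref.segment(ref.wrap(J + left - 1), left + right, "reverse")
    return left, right, seq


def _tracts(
    junction_end: tuple[int, str], partner_end: tuple[int, str], left: int, right: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    """1-based homology tract intervals at the two loci."""
    (J, dj), (P, dp) = junction_end, partner_end
    if dj == "forward":
        ta = (J - left + 1, J + right)
    else:
        ta = (J - right, J + left - 1)
    if dp == "forward":
        tb = (P - left, P + right - 1)
    else:
        tb = (P - right + 1, P + left)
    return tuple(sorted(ta)), tuple(sorted(tb))


def classify(
    junction_end: tuple[int, str],
    partner_end: tuple[int, str],
    ref: Reference,
    min_homology: int = 3,
    indel_max: int = 50,
    pal_max: int = 70,
    n_reads: int = 0,
) -> Rearrangement:
    """Assign one of the five categories to an accepted junction.

    Same-direction ends whose implied event is shorter than ``indel_max``
    are del (downstream skip) or ins (upstream jump = tandem duplication);
    opposite-direction ends closer than ``pal_max`` are pal; everything
    else is mhr when the flanks share >= ``min_homology`` identical bases
    across the junction, otherwise unk.  All comparisons are strict.
    """
    (J, dj), (P, dp) = junction_end, partner_end
    n = len(ref.seq)
    d = P - J
    if ref.circular:
        d = (d + n // 2) % n - n // 2  # signed minimal circular difference
    same_dir = dj == dp
    if same_dir:
        ahead = d if dj == "forward" else -d
        if 2 <= ahead < indel_max + 1:
            length = ahead - 1
            if length < indel_max:
                return Rearrangement("del", junction_end, partner_end,
                                     event_length=length, n_reads=n_reads)
        elif ahead <= 0:
            length = -ahead + 1
            if length < indel_max:
                left, right, seq = homology_at_junction(ref, junction_end, partner_end)
                return Rearrangement("ins", junction_end, partner_end,
                                     homology_len=left + right, homology_seq=seq,
                                     event_length=length, n_reads=n_reads)
    left, right, seq = homology_at_junction(ref, junction_end, partner_end)
    hom = left + right
    if not same_dir and abs(d) < pal_max:
        ta, tb = _tracts(junction_end, partner_end, left, right)
        return Rearrangement("pal", junction_end, partner_end, hom, seq,
                             "opposite", n_reads=n_reads, tract_a=ta, tract_b=tb)
    if hom >= min_homology:
        ta, tb = _tracts(junction_end, partner_end, left, right)
        return Rearrangement(
            "mhr", junction_end, partner_end, hom, seq,
            "same" if same_dir else "opposite", n_reads=n_reads,
            tract_a=ta, tract_b=tb,
        )
    return Rearrangement("unk", junction_end, partner_end, 0, "",
                         n_reads=n_reads)


# ---------------------------------------------------------------------------
# end-to-end driver


def detect_junctions(
    table: MappingTable,
    ref: Reference,
    params: JunctionParams | None = None,
    mate_filter: bool = True,
) -> tuple[list[JunctionCluster], list[Rearrangement]]:
    """Candidates -> clusters -> consensus -> validation -> classification."""
    params = params or JunctionParams()
    cands = find_junction_candidates(table, ref, params)
    clusters = cluster_by_junction(cands)
    insert_stats = estimate_insert_stats(table) if mate_filter else None
    rearrs: list[Rearrangement] = []
    for cl in clusters:
        build_consensus(cl, params.min_support, params.final_min)
        validate_cluster(cl, ref, table if mate_filter else None, params,
                         insert_stats)
        if cl.status == "accepted":
            r = classify(
                (cl.junction_point, cl.direction), cl.partner, ref,
                params.min_homology, params.indel_max, params.pal_max,
                n_reads=cl.n_reads,
            )
            cl.rearrangement = r
            rearrs.append(r)
    return clusters, rearrs


# ---------------------------------------------------------------------------
# mhmr unification


@dataclasses.dataclass
class MhmrRecord:
    repeat: RepeatPair
    slot_reads: dict[str, int]  # keys '1a','1b','2a','2b'
    rearrangement_1_reads: int
    rearrangement_2_reads: int
    total_reads: int
    asymmetry_ratio: float


def _tract_close(a: tuple[int, int], b: tuple[int, int], tol: int) -> bool:
    return abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol


def unify_mhmr(
    mhr_list: Sequence[Rearrangement],
    all_candidates: Sequence[JunctionCandidate] = (),
    ref: Reference | None = None,
    tol: int = 5,
) -> list[MhmrRecord]:
    """Merge mhr entries caused by one repeat pair into a single record.

    A repeat pair supports two reciprocal rearrangements, each observable
    as two junction clusters (anchored on either side), so up to four mhr
    entries collapse into one record.  All junction-read candidates are
    then re-examined against the unified junctions, which can only add
    support, so ``total_reads`` is at least the sum of the constituent
    entries' counts.  The asymmetry ratio is max/min of the two reciprocal
    read counts with the minimum clamped to 1.
    """
    entries = [r for r in mhr_list if r.category == "mhr" and r.tract_a and r.tract_b]
    groups: list[list[Rearrangement]] = []
    for e in entries:
        pair_e = sorted([e.tract_a, e.tract_b])
        for g in groups:
            pair_g = sorted([g[0].tract_a, g[0].tract_b])
            if (_tract_close(pair_e[0], pair_g[0], tol)
                    and _tract_close(pair_e[1], pair_g[1], tol)):
                g.append(e)
                break
        else:
            groups.append([e])

    records: list[MhmrRecord] = []
    for g in groups:
        loci = sorted([g[0].tract_a, g[0].tract_b])
        orientation = g[0].repeat_orientation or "same"
        seq = ""
        if ref is not None:
            seq = ref.segment(loci[0][0], loci[0][1] - loci[0][0] + 1, "forward")
        repeat = RepeatPair(tuple(loci[0]), tuple(loci[1]),
                            loci[0][1] - loci[0][0] + 1, orientation, seq)
        slots: dict[str, int] = {"1a": 0, "1b": 0, "2a": 0, "2b": 0}
        slot_keys: dict[str, tuple[tuple[int, str], tuple[int, str]]] = {}
        for e in g:
            J, dj = e.end_a
            fj = J if dj == "forward" else e.end_b[0]
            in_first = loci[0][0] - tol <= fj <= loci[0][1] + tol
            rnum = "1" if in_first else "2"
            side = "a" if dj == "forward" else "b"
            slots[rnum + side] += e.n_reads
            slot_keys[rnum + side] = (e.end_a, e.end_b)
        if all_candidates:
            recount: dict[str, int] = {k: 0 for k in slots}
            for key, (ea, eb) in slot_keys.items():
                (J, dj), (P, pd) = ea, eb
                cnt = 0
                for c in all_candidates:
                    if c.direction != dj or abs(c.junction_point - J) > tol:
                        continue
                    if ref is not None:
                        shift = c.junction_point - J
                        p_shift = P + shift if pd == "forward" else P - shift
                        expect = ref.segment(ref.wrap(p_shift), len(c.tail_seq), pd)
                        mism = sum(1 for a, b in zip(c.tail_seq, expect) if a != b)
                        mism += len(c.tail_seq) - len(expect)
                        if mism > 1:
                            continue
                    cnt += 1
                recount[key] = cnt
            for k in slots:
                slots[k] = max(slots[k], recount[k])
        r1 = slots["1a"] + slots["1b"]
        r2 = slots["2a"] + slots["2b"]
        ratio = max(r1, r2) / max(min(r1, r2), 1)
        records.append(MhmrRecord(repeat, slots, r1, r2, r1 + r2, ratio))
    records.sort(key=lambda r: r.repeat.locus_a)
    return records


# ---------------------------------------------------------------------------
# writers

CATEGORY_SUFFIXES = ("ins", "del", "mhr", "unk", "pal")
_COLUMNS = ("junction_pos", "junction_dir", "partner_pos", "partner_dir",
            "category", "homology_len", "homology_seq", "n_reads",
            "consensus", "status")


def write_category_files(
    clusters: Sequence[JunctionCluster], out_prefix: str | Path
) -> dict[str, Path]:
    """One TSV per category (suffixes .ins/.del/.mhr/.unk/.pal)."""
    out_prefix = Path(out_prefix)
    paths = {}
    by_cat: dict[str, list[JunctionCluster]] = {c: [] for c in CATEGORY_SUFFIXES}
    for cl in clusters:
        if cl.status == "accepted" and cl.rearrangement is not None:
            by_cat[cl.rearrangement.category].append(cl)
    for cat in CATEGORY_SUFFIXES:
        path = out_prefix.with_name(out_prefix.name + f".{cat}")
        with open(path, "w") as fh:
            fh.write("\t".join(_COLUMNS) + "\n")
            for cl in by_cat[cat]:
                r = cl.rearrangement
                fh.write("\t".join(map(str, (
                    cl.junction_point, cl.direction, r.end_b[0], r.end_b[1],
                    r.category, r.homology_len, r.homology_seq, cl.n_reads,
                    cl.consensus, cl.status,
                ))) + "\n")
        paths[cat] = path
    return paths


def write_mhmr_file(records: Sequence[MhmrRecord], path: str | Path) -> Path:
    path = Path(path)
    cols = ("locus_a_start", "locus_a_end", "locus_b_start", "locus_b_end",
            "orientation", "repeat_len", "reads_1a", "reads_1b", "reads_2a",
            "reads_2b", "rearrangement_1_reads", "rearrangement_2_reads",
            "total_reads", "asymmetry_ratio")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join(map(str, (
                r.repeat.locus_a[0], r.repeat.locus_a[1],
                r.repeat.locus_b[0], r.repeat.locus_b[1],
                r.repeat.orientation, r.repeat.length,
                r.slot_reads["1a"], r.slot_reads["1b"],
                r.slot_reads["2a"], r.slot_reads["2b"],
                r.rearrangement_1_reads, r.rearrangement_2_reads,
                r.total_reads, f"{r.asymmetry_ratio:.3f}",
            ))) + "\n")
    return path
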