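"""Synthetic organelle genomes with planted rearrangements, sequenced in silico.

The generator emulates what matters to the detection stack: a 50-120 kb
circular genome with short dispersed repeats (the substrate of
microhomology-mediated rearrangement), A/T homopolymer clusters, and a
population of molecules in which a controllable fraction carries a planted
event - deletion, tandem insertion, microhomology-mediated rearrangement
(same or opposite repeat orientation, optionally with asymmetric reciprocal
products), or a U-turn fold-back at a quasi-palindrome.  Reads are 150 bp
pairs from ~300 bp inserts with substitution-only errors (the detection
stack is ungapped; indel errors would conflate sequencing error with
biology).  Quality strings are constant; the pipeline never reads them.

Every derived molecule is described as a walk over reference segments, and
the truth table's junction coordinates are computed from the emitted
sequences by maximal extension against the reference - the same convention
the detector's first-mismatch rule produces - so planted events can be
scored at exact 1-based coordinates.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .refio import Reference, RepeatPair, complement, revcomp

#: default half-width of the read-placement window that yields a usable
#: junction read: the partner-side overhang must reach the minimum final
#: consensus length (>15 bp), so tails of 16..read_len/2 bases support a
#: cluster.  Used only for the truth table's expected-support bookkeeping.
MIN_INFORMATIVE_TAIL = 16


@dataclasses.dataclass
class Molecule:
    name: str
    seq: str
    circular: bool
    fraction: float
    #: (start, end, strand) walks over the source reference, 1-based inclusive
    segments: list[tuple[int, int, str]] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class EventSpec:
    """One planted rearrangement.

    category:
      ``del``           deletion of ``span`` (< 50 bp for INDEL-class events)
      ``ins``           tandem duplication of ``span``
      ``mhr_same``      crossover between a direct repeat pair (``repeat``);
                        emits both reciprocal products at
                        ``product_fraction`` and ``product_fraction/asymmetry``
      ``mhr_opposite``  inversion between an inverted repeat pair
      ``pal``           U-turn fold-back at a closely spaced inverted pair
    """

    category: str
    product_fraction: float
    span: tuple[int, int] | None = None
    repeat: RepeatPair | None = None
    asymmetry: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.product_fraction <= 1):
            raise ValueError("product_fraction must be in (0, 1]")
        if self.category in ("del", "ins") and self.span is None:
            raise ValueError(f"{self.category} event needs a span")
        if self.category in ("mhr_same", "mhr_opposite", "pal") and self.repeat is None:
            raise ValueError(f"{self.category} event needs a repeat pair")
        if self.repeat is not None and self.repeat.length > 79:
            raise ValueError("planted homology longer than 79 bp")


class TruthTable:
    """Planted-event ledger: one row per expected junction cluster."""

    COLUMNS = (
        "event_id", "category", "molecule", "product", "fraction",
        "junction_pos", "junction_dir", "partner_pos", "partner_dir",
        "homology_len", "expected_support",
    )

    def __init__(self, rows: list[dict]):
        self.df = pd.DataFrame(rows, columns=list(self.COLUMNS)) if rows else \
            pd.DataFrame(columns=list(self.COLUMNS))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        t = cls([])
        t.df = pd.read_csv(path, sep="\t")
        return t

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# genome synthesis


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def simulate_genome(
    length: int = 100_000,
    gc: float = 0.35,
    repeat_spec: Sequence[tuple[int, str, int]] = (),
    at_cluster_spec: Sequence[tuple[int, int]] = (),
    palindrome_spec: Sequence[tuple[int, int, int]] = (),
    seed: int = 0,
) -> tuple[Reference, list[RepeatPair]]:
    """Random circular genome with planted features; deterministic under seed.

    ``repeat_spec``: (length, orientation, n) dispersed pairs placed at
    well-separated loci (orientation ``same`` or ``inverted``).
    ``at_cluster_spec``: (run_length, n) A/T homopolymer clusters.
    ``palindrome_spec``: (arm_length, spacer, n) closely spaced inverted
    pairs (quasi-palindromes), the substrate of U-turn rearrangements.
    Returns the reference and the list of planted repeat pairs.
    """
    rng = np.random.default_rng(seed)
    arr = _random_seq(rng, length, gc)
    used: list[tuple[int, int]] = []  # 0-based [start, end) blocks, padded

    def reserve(span: int, pad: int = 60) -> int:
        for _ in range(10_000):
            s = int(rng.integers(0, length - span))
            if all(s + span + pad <= us or s >= ue + pad for us, ue in used):
                used.append((s, s + span))
                return s
        raise ValueError("could not place feature without overlap")

    for run_len, n in at_cluster_spec:
        for _ in range(n):
            s = reserve(run_len)
            base = ord("A") if rng.random() < 0.5 else ord("T")
            arr[s : s + run_len] = base

    planted: list[RepeatPair] = []
    for rep_len, orientation, n in repeat_spec:
        for _ in range(n):
            sa = reserve(rep_len)
            sb = reserve(rep_len)
            if sa > sb:
                sa, sb = sb, sa
            src = arr[sa : sa + rep_len].tobytes().decode()
            dst = src if orientation == "same" else revcomp(src)
            arr[sb : sb + rep_len] = np.frombuffer(dst.encode(), dtype=np.uint8)
            planted.append(
                RepeatPair((sa + 1, sa + rep_len), (sb + 1, sb + rep_len),
                           rep_len, orientation, src)
            )
    for arm_len, spacer, n in palindrome_spec:
        for _ in range(n):
            s = reserve(2 * arm_len + spacer)
            arm = arr[s : s + arm_len].tobytes().decode()
            sb = s + arm_len + spacer
            arr[sb : sb + arm_len] = np.frombuffer(revcomp(arm).encode(), dtype=np.uint8)
            planted.append(
                RepeatPair((s + 1, s + arm_len), (sb + 1, sb + arm_len),
                           arm_len, "inverted", arm)
            )
    ref = Reference(name=f"sim_{length}bp", seq=arr.tobytes().decode(), circular=True)
    return ref, planted


# ---------------------------------------------------------------------------
# derived molecules and truth coordinates


def _walk(ref: Reference, start: int, end: int, strand: str) -> str:
    if strand == "+":
        return ref.segment(start, end - start + 1, "forward")
    return ref.segment(start, start - end + 1, "reverse")


def molecule_from_segments(
    ref: Reference, name: str, segments: list[tuple[int, int, str]],
    circular: bool, fraction: float,
) -> Molecule:
    seq = "".join(_walk(ref, s, e, st) for s, e, st in segments)
    return Molecule(name, seq, circular, fraction, list(segments))


def _advance(pos: int, steps: int, strand: str) -> int:
    return pos + steps if strand == "+" else pos - steps


def _continuation(ref: Reference, pos: int, strand: str, length: int) -> str:
    """Reference bases continuing a walk beyond ``pos`` (exclusive)."""
    nxt = _advance(pos, 1, strand)
    if strand == "+":
        return ref.segment(ref.wrap(nxt) if ref.circular else nxt, length, "forward")
    return ref.segment(ref.wrap(nxt) if ref.circular else nxt, length, "reverse")


def _back_continuation(ref: Reference, pos: int, strand: str, length: int) -> str:
    """Reference bases extending a walk backwards before ``pos`` (exclusive),
    listed outward (nearest first), in molecule orientation.

    A '+' walk read backwards stays on the plus strand (plain bases,
    descending coordinates); a '-' walk read backwards keeps its complement
    (ascending coordinates, complemented).
    """
    prv = _advance(pos, -1, strand)
    wrapped = ref.wrap(prv) if ref.circular else prv
    if strand == "+":
        return complement(ref.segment(wrapped, length, "reverse"))
    return complement(ref.segment(wrapped, length, "forward"))


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def expected_clusters(
    ref: Reference, mol: Molecule, cap: int = 150
) -> list[dict]:
    """Expected junction clusters for every novel boundary of a molecule.

    For each boundary between consecutive segments (including the wrap of a
    circular molecule) the matched side is extended while the molecule
    continues to agree with the reference by chance, exactly as a mapped
    junction read's first-mismatch rule would; boundaries that remain
    reference-contiguous for ``cap`` bases are not junctions and are
    skipped.  Returns one row per cluster (two per junction: one anchored
    on each side).
    """
    segs = mol.segments
    boundaries = list(range(1, len(segs))) + ([0] if mol.circular else [])
    rows: list[dict] = []
    mol_ext = mol.seq + (mol.seq[:cap] if mol.circular else "")
    # molecule offset where each segment starts
    seg_starts = np.cumsum([0] + [abs(e - s) + 1 for s, e, _ in segs])
    for b in boundaries:
        i = (b - 1) % len(segs)
        j = b % len(segs)
        p_end, s1 = segs[i][1], segs[i][2]
        q_start, s2 = segs[j][0], segs[j][2]
        if s1 == s2 and ref.wrap(_advance(p_end, 1, s1)) == q_start:
            continue  # reference-contiguous boundary, not a junction
        off = int(seg_starts[b]) if b > 0 else len(mol.seq)
        after = mol_ext[off : off + cap]
        if off >= cap:
            before = mol.seq[off - cap : off][::-1]
        elif mol.circular:
            before = (mol.seq[off - cap :] + mol.seq[:off])[-cap:][::-1]
        else:
            before = mol.seq[:off][::-1]
        # side a: anchored on the earlier segment
        e_a = _lcp(after, _continuation(ref, p_end, s1, cap))
        # side b: anchored on the later segment
        e_b = _lcp(before, _back_continuation(ref, q_start, s2, cap))
        if e_a >= cap or e_b >= cap:
            continue  # reference-contiguous: not a junction
        ja = ref.wrap(_advance(p_end, e_a, s1))
        pa = ref.wrap(_advance(q_start, e_a, s2))
        jb = ref.wrap(_advance(q_start, -e_b, s2))
        pb = ref.wrap(_advance(p_end, -e_b, s1))
        rows.append({
            "junction_pos": ja,
            "junction_dir": "forward" if s1 == "+" else "reverse",
            "partner_pos": pa,
            "partner_dir": "forward" if s2 == "+" else "reverse",
            "side": "a",
        })
        rows.append({
            "junction_pos": jb,
            "junction_dir": "reverse" if s2 == "+" else "forward",
            "partner_pos": pb,
            "partner_dir": "reverse" if s1 == "+" else "forward",
            "side": "b",
        })
    return rows


def apply_events(
    ref: Reference, events: Sequence[EventSpec], seed: int = 0
) -> tuple[list[Molecule], TruthTable]:
    """Build the molecule population and its truth table.

    The intact genome receives whatever fraction the planted products leave
    over; a total planted fraction >= 1 is an error.  mhr events are
    validated against the reference: the repeat pair's two loci must carry
    the claimed (same/inverted) copies, since those are the homology the
    breakpoints rely on.
    """
    n = len(ref.seq)
    molecules: list[Molecule] = []
    truth_rows: list[dict] = []

    def check_repeat(rp: RepeatPair, want: str) -> None:
        a = ref.seq[rp.locus_a[0] - 1 : rp.locus_a[1]]
        b = ref.seq[rp.locus_b[0] - 1 : rp.locus_b[1]]
        ok = (b == a) if want == "same" else (b == revcomp(a))
        if not ok or rp.orientation != want:
            raise ValueError(f"breakpoint without required {want} homology: {rp}")

    for ei, ev in enumerate(events):
        products: list[tuple[str, list[tuple[int, int, str]], bool, float]] = []
        if ev.category == "del":
            d1, d2 = ev.span
            if not (1 < d1 <= d2 < n):
                raise ValueError("deletion span out of range")
            products.append(("P1", [(1, d1 - 1, "+"), (d2 + 1, n, "+")], True,
                             ev.product_fraction))
        elif ev.category == "ins":
            u1, u2 = ev.span
            if not (1 <= u1 <= u2 < n):
                raise ValueError("insertion unit out of range")
            products.append(("P1", [(1, u2, "+"), (u1, n, "+")], True,
                             ev.product_fraction))
        elif ev.category == "mhr_same":
            check_repeat(ev.repeat, "same")
            (a1, a2), (b1, b2) = ev.repeat.locus_a, ev.repeat.locus_b
            products.append(("P1", [(1, a2, "+"), (b2 + 1, n, "+")], True,
                             ev.product_fraction))
            products.append(("P2", [(a2 + 1, b2, "+")], True,
                             ev.product_fraction / ev.asymmetry))
        elif ev.category == "mhr_opposite":
            check_repeat(ev.repeat, "inverted")
            (a1, a2), (b1, b2) = ev.repeat.locus_a, ev.repeat.locus_b
            products.append(
                ("P1", [(1, a2, "+"), (b1 - 1, a2 + 1, "-"), (b1, n, "+")],
                 True, ev.product_fraction)
            )
        elif ev.category == "pal":
            check_repeat(ev.repeat, "inverted")
            (a1, a2), (b1, b2) = ev.repeat.locus_a, ev.repeat.locus_b
            arm = min(3000, a2 - 1, b1 - 2)
            products.append(
                ("P1", [(a2 - arm + 1, a2, "+"), (b1 - 1, b1 - arm, "-")],
                 False, ev.product_fraction)
            )
        else:
            raise ValueError(f"unknown event category {ev.category!r}")

        for pname, segments, circ, frac in products:
            mol = molecule_from_segments(
                ref, f"ev{ei}_{ev.category}_{pname}", segments, circ, frac
            )
            molecules.append(mol)
            for cl in expected_clusters(ref, mol):
                truth_rows.append({
                    "event_id": ei,
                    "category": {"mhr_same": "mhr", "mhr_opposite": "mhr"}.get(
                        ev.category, ev.category),
                    "molecule": mol.name,
                    "product": pname + cl["side"],
                    "fraction": frac,
                    "junction_pos": cl["junction_pos"],
                    "junction_dir": cl["junction_dir"],
                    "partner_pos": cl["partner_pos"],
                    "partner_dir": cl["partner_dir"],
                    "homology_len": ev.repeat.length if ev.repeat else 0,
                    "expected_support": np.nan,  # filled by simulate_reads
                })

    total = sum(m.fraction for m in molecules)
    if total >= 1:
        raise ValueError(f"planted product fractions sum to {total:.3f} >= 1")
    molecules.insert(0, Molecule("intact", ref.seq, True, 1 - total,
                                 [(1, n, "+")]))
    return molecules, TruthTable(truth_rows)


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    molecules: Sequence[Molecule],
    n_pairs: int,
    read_len: int = 150,
    insert_mean: int = 300,
    insert_sd: float = 30.0,
    error_rate: float = 0.001,
    seed: int = 0,
    truth: TruthTable | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], TruthTable | None]:
    """Paired-end reads from a molecule mixture; deterministic under seed.

    Fragments are drawn from molecules proportionally to fraction x length,
    uniformly along each molecule (circular molecules wrap across the
    origin).  R1 is the fragment 5' end, R2 the reverse complement of its
    3' end; errors are substitutions only.  When a truth table is given its
    ``expected_support`` column is filled in: the expected number of reads
    whose placement yields a partner-side tail of
    [``MIN_INFORMATIVE_TAIL``, read_len/2] bases for each cluster.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if insert_mean < read_len:
        raise ValueError("insert_mean must be >= read_len")
    rng = np.random.default_rng(seed)
    weights = np.array([m.fraction * len(m.seq) for m in molecules], dtype=float)
    weights /= weights.sum()
    mol_idx = rng.choice(len(molecules), size=n_pairs, p=weights)
    inserts = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int),
        read_len, None,
    )
    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    exts = {}
    for mi, mol in enumerate(molecules):
        pad = min(2 * insert_mean + int(8 * insert_sd), len(mol.seq))
        exts[mi] = mol.seq + (mol.seq[:pad] if mol.circular else "")
    starts = np.empty(n_pairs, dtype=int)
    for mi, mol in enumerate(molecules):
        mask = mol_idx == mi
        k = int(mask.sum())
        if k == 0:
            continue
        if mol.circular:
            inserts[mask] = np.minimum(inserts[mask], len(mol.seq))
            starts[mask] = rng.integers(0, len(mol.seq), size=k)
        else:
            ins = np.minimum(inserts[mask], len(mol.seq))
            inserts[mask] = ins
            starts[mask] = (rng.random(k) * (len(mol.seq) - ins + 1)).astype(int)

    n_err = rng.binomial(read_len, error_rate, size=2 * n_pairs)
    shift = rng.integers(1, 4, size=int(n_err.sum()) or 1)
    err_cursor = 0
    code = "ACGT"

    def mutate(seq: str, which: int) -> str:
        nonlocal err_cursor
        k = int(n_err[which])
        if k == 0:
            return seq
        pos = rng.choice(len(seq), size=k, replace=False)
        s = list(seq)
        for p in pos:
            base = code.find(s[p])
            if base >= 0:
                s[p] = code[(base + shift[err_cursor]) % 4]
            err_cursor += 1
        return "".join(s)

    for i in range(n_pairs):
        ext = exts[mol_idx[i]]
        frag = ext[starts[i] : starts[i] + inserts[i]]
        name = f"sim{i:07d}"
        r1.append((name, mutate(frag[:read_len], 2 * i)))
        r2.append((name, mutate(revcomp(frag[-read_len:]), 2 * i + 1)))

    if truth is not None and len(truth):
        w = truth.df["molecule"].map(
            {m.name: m.fraction * len(m.seq) for m in molecules}
        )
        total_w = sum(m.fraction * len(m.seq) for m in molecules)
        mol_len = truth.df["molecule"].map({m.name: len(m.seq) for m in molecules})
        density = 2 * n_pairs * (w / total_w) / mol_len  # read starts per bp
        window = read_len // 2 - MIN_INFORMATIVE_TAIL + 1
        truth.df["expected_support"] = density * window
    return r1, r2, truth


def write_fastq(records: Sequence[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> None:
    """Write (id, seq) records as FASTQ; gzip when the path ends in .gz."""
    path = Path(path)
    op = gzip.open if path.suffix == ".gz" else open
    with op(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_config_sidecar(params: dict, path: str | Path) -> None:
    """Echo generator parameters as a flat key = value file for reproducibility."""
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"{k} = {v!r}\n" if isinstance(v, str) else f"{k} = {v}\n")


# ---------------------------------------------------------------------------
# standard planted-event panel (the end-to-end test substrate)


def standard_panel(
    length: int = 100_000,
    seed: int = 0,
    abundant_fraction: float = 0.15,
    rare_fraction: float = 0.004,
) -> tuple[Reference, list[RepeatPair], list[EventSpec]]:
    """A 20-event panel over a 100 kb genome: 4 events per category.

    One event per category is abundant (molecule fraction
    ``abundant_fraction``, ~9 expected well-placed junction reads per
    cluster at 150x) and three are rare (``rare_fraction``, below the
    4-read recovery threshold).  Microhomologies span 4-20 bp.  The
    abundant same-orientation mhr event is strongly asymmetric (25:1), as
    observed for microhomology-mediated products in destabilized organelle
    genomes; its minor product stays below detection thresholds.
    """
    repeat_spec = [
        # direct pairs for mhr_same events (abundant first) + decoys
        (12, "same", 1), (8, "same", 1), (16, "same", 1), (6, "same", 1),
        # inverted pairs for mhr_opposite events
        (14, "inverted", 1), (9, "inverted", 1), (18, "inverted", 1), (5, "inverted", 1),
        (7, "same", 2), (11, "inverted", 1),
    ]
    palindrome_spec = [(12, 24, 1), (8, 36, 1), (16, 20, 1), (10, 44, 1)]
    for attempt in range(8):
        genome_seed = (seed + 99991 * attempt) % (2**31)
        ref, repeats = simulate_genome(
            length=length, gc=0.35,
            repeat_spec=repeat_spec,
            at_cluster_spec=[(10, 20), (14, 10)],
            palindrome_spec=palindrome_spec,
            seed=genome_seed,
        )
        same = [r for r in repeats if r.orientation == "same"
                and r.locus_b[0] - r.locus_a[1] > 500][:4]
        inv_far = [r for r in repeats if r.orientation == "inverted"
                   and r.locus_b[0] - r.locus_a[1] > 500][:4]
        pals = [r for r in repeats if r.orientation == "inverted"
                and 0 < r.locus_b[0] - r.locus_a[1] - 1 <= 60][:4]
        if len(inv_far) >= 4 and len(pals) >= 4 and len(same) >= 4:
            break
    else:
        raise ValueError("panel placement failed")
    rng = np.random.default_rng(genome_seed + 1)

    occupied = [r.locus_a for r in repeats] + [r.locus_b for r in repeats]

    def spans(lengths: list[int]) -> list[tuple[int, int]]:
        out = []
        for L in lengths:
            for _ in range(5000):
                s = int(rng.integers(1000, length - 1000))
                if all(s + L + 300 < a or s > b + 300 for a, b in occupied):
                    out.append((s, s + L - 1))
                    occupied.append((s, s + L - 1))
                    break
            else:
                raise ValueError("could not place event span")
        return out

    del_spans = spans([20, 30, 25, 35])
    ins_spans = spans([10, 15, 24, 30])
    fr = [abundant_fraction] + [rare_fraction] * 3
    events: list[EventSpec] = []
    for i in range(4):
        events.append(EventSpec("del", fr[i], span=del_spans[i]))
        events.append(EventSpec("ins", fr[i], span=ins_spans[i]))
        events.append(EventSpec("mhr_same", fr[i], repeat=same[i],
                                asymmetry=25.0 if i == 0 else 1.0))
        events.append(EventSpec("mhr_opposite", fr[i], repeat=inv_far[i]))
        events.append(EventSpec("pal", fr[i], repeat=pals[i]))
    return ref, repeats, events
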