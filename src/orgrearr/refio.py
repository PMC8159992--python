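"""Reference sequences, annotations, inverted-repeat bookkeeping and repeat discovery.

Chloroplast genomes carry a large inverted repeat (IR) present in two
identical (or reverse-complement-identical) copies.  Reads from the two
copies cannot be told apart, so one copy is excised from the mapping
reference and the depth over the kept copy is interpreted as doubled.
All coordinates at this module's interfaces are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: numeric encoding used throughout the package (A,C,G,T,N -> 0..4)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DECODE = np.array(list("ACGTN"))


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    """Base-wise complement without reversing."""
    return seq.translate(_COMPLEMENT)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array (A=0, C=1, G=2, T=3, N=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


class Annotation(NamedTuple):
    kind: str  # "gene" or "CDS"
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"


class RepeatPair(NamedTuple):
    """A maximal exact repeat: ``locus_b`` carries ``seq`` (same orientation)
    or its reverse complement (inverted)."""

    locus_a: tuple[int, int]
    locus_b: tuple[int, int]
    length: int
    orientation: str  # "same" | "inverted"
    seq: str


@dataclasses.dataclass
class Reference:
    name: str
    seq: str
    circular: bool = True
    #: (kept_interval, dropped_interval) once a duplicate region is collapsed
    collapsed: tuple[tuple[int, int], tuple[int, int]] | None = None
    annotations: list[Annotation] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.annotations:
            if not (1 <= ann.start <= ann.end <= len(self.seq)):
                raise ValueError(f"annotation outside reference: {ann}")

    def __len__(self) -> int:
        return len(self.seq)

    def segment(self, start: int, length: int, direction: str = "forward") -> str:
        """Sequence of ``length`` bases walking from 1-based ``start``.

        ``direction='forward'`` walks toward higher coordinates on the plus
        strand; ``'reverse'`` walks toward lower coordinates on the minus
        strand (i.e. bases are complemented).  Circular references wrap; on
        linear references the walk stops at the ends.
        """
        n = len(self.seq)
        if length <= 0:
            return ""
        out = []
        pos = start - 1
        step = 1 if direction == "forward" else -1
        for _ in range(length):
            if self.circular:
                out.append(self.seq[pos % n])
            else:
                if pos < 0 or pos >= n:
                    break
                out.append(self.seq[pos])
            pos += step
        s = "".join(out)
        return s if direction == "forward" else s.translate(_COMPLEMENT)

    def wrap(self, pos: int) -> int:
        """Map a possibly out-of-range 1-based position into [1, len]."""
        return (pos - 1) % len(self.seq) + 1


def load_fasta(path: str | Path, circular: bool = True) -> Reference:
    """Load a single-record FASTA as a :class:`Reference`.

    The sequence is uppercased; characters outside A/C/G/T/N are rejected
    with the 1-based position of the first offender.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ValueError(f"{path}: multiple records ({len(records)}); expected one")
    rec = records[0]
    seq = str(rec.seq).upper()
    for i, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise ValueError(f"{path}: invalid character {ch!r} at position {i + 1}")
    return Reference(name=rec.id, seq=seq, circular=circular)


def write_fasta(ref: Reference, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, len(ref.seq), width):
            fh.write(ref.seq[i : i + width] + "\n")


def load_annotations(path: str | Path, fmt: str | None = None) -> list[Annotation]:
    """Read gene/CDS intervals from GFF3 or GenBank.

    ``fmt`` is inferred from the suffix when not given (.gff/.gff3 vs
    .gb/.gbk/.genbank).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "genbank" if suffix in {".gb", ".gbk", ".genbank"} else "gff3"
    anns: list[Annotation] = []
    if fmt == "gff3":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 8:
                    continue
                kind = fields[2]
                if kind not in ("gene", "CDS"):
                    continue
                anns.append(
                    Annotation(kind, int(fields[3]), int(fields[4]), fields[6])
                )
    elif fmt == "genbank":
        for rec in SeqIO.parse(str(path), "genbank"):
            for feat in rec.features:
                if feat.type not in ("gene", "CDS"):
                    continue
                strand = "-" if feat.location.strand == -1 else "+"
                anns.append(
                    Annotation(
                        feat.type,
                        int(feat.location.start) + 1,
                        int(feat.location.end),
                        strand,
                    )
                )
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return anns


def collapse_duplicate_region(
    ref: Reference,
    keep: tuple[int, int],
    drop: tuple[int, int],
    identity: str = "revcomp",
) -> Reference:
    """Excise ``drop`` from the reference, recording the kept duplicate.

    ``identity`` controls the duplicate check: ``"revcomp"`` (default,
    inverted-repeat dialect) requires the dropped sequence to equal the
    reverse complement of the kept one, ``"identical"`` requires byte
    identity, ``"any"`` accepts either, ``"none"`` skips the check.
    Annotations inside ``drop`` are removed; those beyond it are shifted.
    """
    n = len(ref.seq)
    ks, ke = keep
    ds, de = drop
    if ds > de or ks > ke:
        raise ValueError("empty interval (start > end)")
    if not (1 <= ks <= ke <= n and 1 <= ds <= de <= n):
        raise ValueError("interval out of range")
    if not (ke < ds or de < ks):
        raise ValueError("keep and drop intervals overlap")
    kept_seq = ref.seq[ks - 1 : ke]
    drop_seq = ref.seq[ds - 1 : de]
    if identity == "identical":
        ok = drop_seq == kept_seq
    elif identity == "revcomp":
        ok = drop_seq == revcomp(kept_seq)
    elif identity == "any":
        ok = drop_seq in (kept_seq, revcomp(kept_seq))
    elif identity == "none":
        ok = True
    else:
        raise ValueError(f"unknown identity mode {identity!r}")
    if not ok:
        raise ValueError("dropped region is not a copy of the kept region "
                         f"under identity={identity!r}")
    new_seq = ref.seq[: ds - 1] + ref.seq[de:]
    shift = de - ds + 1
    new_anns = []
    for ann in ref.annotations:
        if ann.start >= ds and ann.end <= de:
            continue  # fully inside the dropped copy
        if ann.end < ds:
            new_anns.append(ann)
        elif ann.start > de:
            new_anns.append(ann._replace(start=ann.start - shift, end=ann.end - shift))
        # features straddling the cut are dropped: they no longer exist as a unit
    new_keep = keep if ke < ds else (ks - shift, ke - shift)
    return Reference(
        name=ref.name,
        seq=new_seq,
        circular=ref.circular,
        collapsed=(new_keep, drop),
        annotations=new_anns,
    )


def restore_duplicate_region(ref: Reference, identity: str = "revcomp") -> Reference:
    """Reinsert the dropped duplicate, reconstructing the pre-collapse sequence."""
    if ref.collapsed is None:
        raise ValueError("reference has no collapsed region")
    (ks, ke), (ds, de) = ref.collapsed
    kept_seq = ref.seq[ks - 1 : ke]
    insert = revcomp(kept_seq) if identity == "revcomp" else kept_seq
    if len(insert) != de - ds + 1:
        raise ValueError("collapsed interval lengths are inconsistent")
    seq = ref.seq[: ds - 1] + insert + ref.seq[ds - 1 :]
    anns = []
    shift = de - ds + 1
    for ann in ref.annotations:
        if ann.start >= ds:
            anns.append(ann._replace(start=ann.start + shift, end=ann.end + shift))
        else:
            anns.append(ann)
    return Reference(ref.name, seq, ref.circular, None, anns)


def _intersects(start: int, end: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(start <= e and end >= s for s, e in intervals)


def find_dispersed_repeats(
    ref: Reference,
    min_len: int,
    exclude: Sequence[tuple[int, int]] = (),
) -> list[RepeatPair]:
    """All maximal exact repeat pairs of length >= ``min_len``, both orientations.

    Pairs are found by seeding on shared ``min_len``-mers and extending to
    maximal length; contained sub-repeats are suppressed by reporting each
    pair only at full extension.  Pairs touching an ``exclude`` interval
    (e.g. the large IR) are omitted.  Tandem (self-overlapping) duplications
    are reported with orientation ``same``.
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    seq = ref.seq
    n = len(seq)
    k = min_len
    if n < k:
        return []

    kmers: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        kmers.setdefault(w, []).append(i)

    found: set[tuple[int, int, int, int, str]] = set()

    def extend_same(i: int, j: int) -> tuple[int, int, int]:
        # i < j, seq[i:i+k] == seq[j:j+k]; extend to maximal run
        left = 0
        while i - left - 1 >= 0 and seq[i - left - 1] == seq[j - left - 1]:
            left += 1
        right = k
        while j + right < n and seq[i + right] == seq[j + right]:
            right += 1
        return i - left, j - left, right + left

    def extend_inv(i: int, j: int, length: int) -> tuple[int, int, int]:
        # seq[i:i+length] == revcomp(seq[j:j+length]); grow both maximal ways
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        # grow left of a / right of b
        while i - 1 >= 0 and j + length < n and seq[i - 1] == comp[seq[j + length]]:
            i -= 1
            length += 1
        # grow right of a / left of b
        while i + length < n and j - 1 >= 0 and seq[i + length] == comp[seq[j - 1]]:
            j -= 1
            length += 1
        return i, j, length

    for w, positions in kmers.items():
        if len(positions) > 1:
            for ai in range(len(positions)):
                for bi in range(ai + 1, len(positions)):
                    i, j, length = extend_same(positions[ai], positions[bi])
                    found.add((i, j, length, length, "same"))
        rc = revcomp(w)
        if rc in kmers and rc >= w:  # visit each (w, rc) pair once
            for i in positions:
                for j in kmers[rc]:
                    if rc == w and j <= i:
                        continue
                    a, b, length = extend_inv(i, j, k)
                    lo, hi = (a, b) if a <= b else (b, a)
                    if lo == hi:
                        continue  # a self-palindrome, not a dispersed pair
                    found.add((lo, hi, length, length, "inverted"))

    pairs: list[RepeatPair] = []
    seen: set[tuple[int, int, int, int, str]] = set()
    for i, j, la, lb, orient in found:
        key = (i, j, la, orient)
        if key in seen:
            continue
        seen.add(key)
        a = (i + 1, i + la)
        b = (j + 1, j + la)
        if _intersects(a[0], a[1], exclude) or _intersects(b[0], b[1], exclude):
            continue
        pairs.append(RepeatPair(a, b, la, orient, seq[i : i + la]))
    pairs.sort(key=lambda p: (p.locus_a, p.locus_b, p.orientation))
    return pairs


def write_repeats_tsv(pairs: Sequence[RepeatPair], path: str | Path) -> None:
    cols = ("locus_a_start", "locus_a_end", "locus_b_start", "locus_b_end",
            "orientation", "length", "seq")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in pairs:
            fh.write(
                f"{p.locus_a[0]}\t{p.locus_a[1]}\t{p.locus_b[0]}\t{p.locus_b[1]}\t"
                f"{p.orientation}\t{p.length}\t{p.seq}\n"
            )
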