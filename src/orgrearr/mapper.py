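"""Ungapped, fixed-length-index read mapping with minimum-mismatch placement.

The mapper indexes every k-mer of the reference (default k = 14) and maps a
read by exact lookup of a few index windows spaced across the read.  Each
candidate placement is scored by whole-read Hamming distance (no gaps,
ever); the placement with the fewest mismatches wins, provided it does not
exceed the mismatch budget.  Retrying with shifted index windows rescues
reads whose mismatches are concentrated at one end - the signature of a
junction (split) read, which is exactly what the downstream rearrangement
caller feeds on.

Three named presets mirror the analysis conditions used throughout the
package:

=============  ==============  =======  ============
preset         max mismatches  windows  truncate_to
=============  ==============  =======  ============
``h2r3``       2               3        -
``h75r10``     75              10       -
``chp100_h2r3``2               3        100 bp
=============  ==============  =======  ============

The guarantee is conditional: the reported placement is the global
minimum-mismatch placement whenever at least one tried index window of that
placement is mismatch-free.  With mismatches scattered across the read
(possible under ``h75r10``) the heuristic may miss the optimum; this is
inherent to the seeded design and documented rather than patched.
"""

from __future__ import annotations

import dataclasses
import gzip
import itertools
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .refio import Reference, encode, revcomp


@dataclasses.dataclass(frozen=True)
class MapParams:
    index_len: int = 14
    max_mismatch: int = 2
    retries: int = 3
    truncate_to: int | None = None

    def __post_init__(self) -> None:
        if self.index_len < 8:
            raise ValueError("index_len must be >= 8")
        if self.retries < 1:
            raise ValueError("retries must be >= 1")


PRESETS: dict[str, MapParams] = {
    "h2r3": MapParams(14, 2, 3),
    "h75r10": MapParams(14, 75, 10),
    "chp100_h2r3": MapParams(14, 2, 3, truncate_to=100),
}


@dataclasses.dataclass
class Mapping:
    read_id: str
    pos: int  # 1-based leftmost base on the forward strand
    strand: str  # "+" | "-"
    n_mismatch: int
    mismatch_positions: tuple[int, ...]  # 0-based offsets, read as sequenced
    length: int
    mate_id: str | None = None


class Index:
    """Exact-lookup k-mer index over the forward strand of a reference.

    For circular references the sequence is padded with its own first
    ``circular_pad`` bases so origin-spanning placements are discoverable;
    reported positions are canonicalized back into [1, len(ref)].
    """

    def __init__(self, ref: Reference, index_len: int = 14, circular_pad: int | None = None):
        if len(ref.seq) < index_len:
            raise ValueError("reference shorter than index length")
        self.ref = ref
        self.k = index_len
        self.ref_len = len(ref.seq)
        if circular_pad is None:
            circular_pad = 149 if ref.circular else 0
        circular_pad = min(circular_pad, self.ref_len)
        self.pad = circular_pad if ref.circular else 0
        self.codes = encode(ref.seq + ref.seq[: self.pad])
        kmer_vals = self._kmer_values(self.codes)
        valid = ~self._window_has_n(self.codes)
        positions = np.nonzero(valid)[0].astype(np.int64)
        vals = kmer_vals[positions]
        order = np.argsort(vals, kind="stable")
        self._kmer_sorted = vals[order]
        self._pos_sorted = positions[order].astype(np.int64)

    def _kmer_values(self, codes: np.ndarray) -> np.ndarray:
        k = self.k
        n = len(codes) - k + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        weights = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        return win.astype(np.int64) @ weights

    def _window_has_n(self, codes: np.ndarray) -> np.ndarray:
        k = self.k
        isn = (codes == 4).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(isn)])
        return (cs[k:] - cs[:-k]) > 0

    def n_positions(self) -> int:
        """Number of indexed k-mer start positions."""
        return len(self._pos_sorted)

    def lookup(self, kmer: str) -> list[int]:
        """1-based forward-strand start positions of an exact k-mer match."""
        if len(kmer) != self.k:
            raise ValueError(f"need a {self.k}-mer")
        val = self._kmer_values(encode(kmer.upper()))
        lo, hi = np.searchsorted(self._kmer_sorted, val[0], side="left"), np.searchsorted(
            self._kmer_sorted, val[0], side="right"
        )
        return sorted({int(p) % self.ref_len + 1 for p in self._pos_sorted[lo:hi]})


def build_index(ref: Reference, index_len: int = 14, circular_pad: int | None = None) -> Index:
    return Index(ref, index_len, circular_pad)


def _window_offsets(read_len: int, k: int, retries: int) -> np.ndarray:
    """``retries`` evenly spaced window start offsets spanning the read."""
    last = read_len - k
    if retries == 1:
        return np.array([0])
    offs = np.unique(np.round(np.linspace(0, last, retries)).astype(np.int64))
    return offs


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand [lo_i, hi_i) ranges into (owner_index, flat_offset) arrays."""
    counts = hi - lo
    total = int(counts.sum())
    owner = np.repeat(np.arange(len(lo)), counts)
    if total == 0:
        return owner, np.empty(0, dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    flat = np.arange(total) - np.repeat(starts, counts) + np.repeat(lo, counts)
    return owner, flat


def map_batch(
    reads: Sequence[str], index: Index, params: MapParams
) -> list[Mapping | None]:
    """Map equal-length reads in one vectorized pass; order preserved.

    Reads shorter than the index length raise; reads of mixed length are
    grouped internally by length.
    """
    results: list[Mapping | None] = [None] * len(reads)
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        L = len(r) if params.truncate_to is None else min(len(r), params.truncate_to)
        if L < index.k:
            raise ValueError("read shorter than index length")
        by_len.setdefault(L, []).append(i)
    for L, idxs in by_len.items():
        chunk = [
            (reads[i][:L] if params.truncate_to is not None else reads[i]).upper()
            for i in idxs
        ]
        for i, m in zip(idxs, _map_equal_len(chunk, L, index, params)):
            if m is not None:
                m.read_id = str(i)
            results[i] = m
    return results


def _map_equal_len(
    reads: list[str], L: int, index: Index, params: MapParams
) -> list[Mapping | None]:
    n = len(reads)
    k = index.k
    h = params.max_mismatch
    ref_len = index.ref_len
    max_start = len(index.codes) - L  # inclusive upper bound, 0-based

    fwd = np.stack([encode(r) for r in reads])
    rev = np.stack([encode(revcomp(r)) for r in reads])
    offsets = _window_offsets(L, k, params.retries)
    weights = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)

    cand_read: list[np.ndarray] = []
    cand_start: list[np.ndarray] = []
    cand_strand: list[np.ndarray] = []
    for strand_code, mat in ((0, fwd), (1, rev)):
        for off in offsets:
            window = mat[:, off : off + k]
            vals = window.astype(np.int64) @ weights
            has_n = (window == 4).any(axis=1)
            vals[has_n] = -1
            lo = np.searchsorted(index._kmer_sorted, vals, side="left")
            hi = np.searchsorted(index._kmer_sorted, vals, side="right")
            owner, flat = _expand_ranges(lo, hi)
            if len(owner) == 0:
                continue
            starts = index._pos_sorted[flat] - off
            ok = (starts >= 0) & (starts <= max_start)
            owner, starts = owner[ok], starts[ok]
            starts = np.where(starts >= ref_len, starts - ref_len, starts)
            # canonical starts may fall past the pad for linear refs
            ok = starts <= max_start
            cand_read.append(owner[ok])
            cand_start.append(starts[ok])
            cand_strand.append(np.full(ok.sum(), strand_code, dtype=np.int64))

    if not cand_read:
        return [None] * n
    read_i = np.concatenate(cand_read)
    start = np.concatenate(cand_start)
    strand = np.concatenate(cand_strand)
    key = (read_i * 2 + strand) * np.int64(ref_len + 1) + start
    _, uniq = np.unique(key, return_index=True)
    read_i, start, strand = read_i[uniq], start[uniq], strand[uniq]

    nm = np.empty(len(read_i), dtype=np.int64)
    span = np.arange(L)
    chunksz = max(1, 30_000_000 // max(L, 1))
    for c0 in range(0, len(read_i), chunksz):
        c1 = min(c0 + chunksz, len(read_i))
        refmat = index.codes[start[c0:c1, None] + span]
        readmat = np.where(
            strand[c0:c1, None] == 0, fwd[read_i[c0:c1]], rev[read_i[c0:c1]]
        )
        nm[c0:c1] = (refmat != readmat).sum(axis=1)

    keep = nm <= h
    results: list[Mapping | None] = [None] * n
    if not keep.any():
        return results
    read_i, start, strand, nm = read_i[keep], start[keep], strand[keep], nm[keep]
    # minimum mismatch first; ties: smaller forward position, then + strand
    order = np.lexsort((strand, start, nm, read_i))
    read_i, start, strand, nm = read_i[order], start[order], strand[order], nm[order]
    first = np.ones(len(read_i), dtype=bool)
    first[1:] = read_i[1:] != read_i[:-1]
    for ri, st, sd, mm in zip(read_i[first], start[first], strand[first], nm[first]):
        seq_codes = fwd[ri] if sd == 0 else rev[ri]
        diff = np.nonzero(index.codes[st : st + L] != seq_codes)[0]
        if sd == 1:
            diff = L - 1 - diff[::-1]
        results[ri] = Mapping(
            read_id="",
            pos=int(st) + 1,
            strand="+" if sd == 0 else "-",
            n_mismatch=int(mm),
            mismatch_positions=tuple(int(d) for d in diff),
            length=L,
        )
    return results


def map_read(read: str, index: Index, params: MapParams) -> Mapping | None:
    """Map a single read; ``None`` when no placement is within budget."""
    return map_batch([read], index, params)[0]


# ---------------------------------------------------------------------------
# FASTQ / paired-end plumbing


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from plain or gzipped FASTQ."""
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip()
            fh.readline()
            fh.readline()
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ header {header!r}")
            yield header[1:].split()[0], seq


def _strip_mate_suffix(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


class MappingTable:
    """Per-read mapping results for a paired-end run.

    Thin container over parallel lists; exposes pandas export, TSV and SAM
    writers.  ``rows`` hold dicts with keys: read_id, mate (1|2), mapped,
    pos, strand, n_mismatch, offsets, length, seq.
    """

    def __init__(self, rows: list[dict]):
        self.rows = rows
        self._by_id: dict[tuple[str, int], dict] | None = None

    def __len__(self) -> int:
        return len(self.rows)

    def mate_of(self, read_id: str, mate: int) -> dict | None:
        if self._by_id is None:
            self._by_id = {(r["read_id"], r["mate"]): r for r in self.rows}
        return self._by_id.get((read_id, 3 - mate))

    def mapped_rows(self) -> list[dict]:
        return [r for r in self.rows if r["mapped"]]

    def n_mapped(self) -> int:
        return sum(1 for r in self.rows if r["mapped"])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {k: (",".join(map(str, v)) if k == "offsets" else v)
                 for k, v in row.items() if k != "seq"}
                for row in self.rows
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        cols = ("read_id", "mate", "pos", "strand", "n_mismatch",
                "mismatch_offsets", "mate_id")
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.rows:
                if not r["mapped"]:
                    continue
                mate = self.mate_of(r["read_id"], r["mate"])
                mate_id = r["read_id"] if mate is not None and mate["mapped"] else ""
                fh.write(
                    f"{r['read_id']}/{r['mate']}\t{r['mate']}\t{r['pos']}\t{r['strand']}\t"
                    f"{r['n_mismatch']}\t{','.join(map(str, r['offsets']))}\t{mate_id}\n"
                )

    def to_sam(self, path: str | Path, ref: Reference) -> None:
        """Ungapped SAM export (CIGAR is always <len>M) for inspection."""
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            fh.write(f"@SQ\tSN:{ref.name}\tLN:{len(ref.seq)}\n")
            fh.write("@PG\tID:orgrearr\tPN:orgrearr\n")
            for r in self.rows:
                mate = self.mate_of(r["read_id"], r["mate"])
                flag = 0x1  # paired
                flag |= 0x40 if r["mate"] == 1 else 0x80
                if not r["mapped"]:
                    flag |= 0x4
                elif r["strand"] == "-":
                    flag |= 0x10
                if mate is None or not mate["mapped"]:
                    flag |= 0x8
                elif mate["strand"] == "-":
                    flag |= 0x20
                pos = r["pos"] if r["mapped"] else 0
                mpos = mate["pos"] if (mate and mate["mapped"]) else 0
                cigar = f"{r['length']}M" if r["mapped"] else "*"
                seq = r["seq"]
                fh.write(
                    f"{r['read_id']}\t{flag}\t{ref.name if r['mapped'] else '*'}\t{pos}\t"
                    f"{255 if r['mapped'] else 0}\t{cigar}\t"
                    f"{'=' if (mate and mate['mapped'] and r['mapped']) else '*'}\t{mpos}\t0\t"
                    f"{seq}\t{'I' * len(seq)}\n"
                )


def map_pairs(
    r1: str | Path | Iterable[tuple[str, str]],
    r2: str | Path | Iterable[tuple[str, str]],
    index: Index,
    params: MapParams,
    batch_size: int = 100_000,
) -> MappingTable:
    """Map both mates of a paired-end run independently.

    ``r1``/``r2`` are FASTQ paths or (id, seq) iterables in lockstep order;
    an id mismatch between the streams is an error.  When
    ``params.truncate_to`` is set each read is cut to that length from the
    5' end before mapping (tail-trimming).
    """
    it1 = read_fastq(r1) if isinstance(r1, (str, Path)) else iter(r1)
    it2 = read_fastq(r2) if isinstance(r2, (str, Path)) else iter(r2)
    rows: list[dict] = []
    while True:
        batch = list(itertools.islice(zip(it1, it2), batch_size))
        if not batch:
            # detect ragged streams
            leftover = next(it1, None) or next(it2, None)
            if leftover is not None:
                raise ValueError("R1/R2 streams have different lengths")
            break
        for (id1, _), (id2, _) in batch:
            if _strip_mate_suffix(id1) != _strip_mate_suffix(id2):
                raise ValueError(f"read id mismatch: {id1!r} vs {id2!r}")
        seqs = [s.upper() for (_, s), _ in batch] + [s.upper() for _, (_, s) in batch]
        mappings = map_batch(seqs, index, params)
        nb = len(batch)
        for i, ((id1, s1), (id2, s2)) in enumerate(batch):
            base = _strip_mate_suffix(id1)
            for mate, m, seq in ((1, mappings[i], s1), (2, mappings[nb + i], s2)):
                L = len(seq) if params.truncate_to is None else min(len(seq), params.truncate_to)
                row = {
                    "read_id": base,
                    "mate": mate,
                    "mapped": m is not None,
                    "pos": m.pos if m else 0,
                    "strand": m.strand if m else ".",
                    "n_mismatch": m.n_mismatch if m else -1,
                    "offsets": m.mismatch_positions if m else (),
                    "length": L,
                    "seq": seq[:L],
                }
                rows.append(row)
    return MappingTable(rows)


def brute_force_map(read: str, ref: Reference, max_mismatch: int | None = None,
                    circular_pad: int | None = None) -> Mapping | None:
    """Exhaustive minimum-mismatch scan over all placements and both strands.

    Independent oracle for the seeded mapper: O(ref x read), no index.  Tie
    break matches the mapper (smaller position, then + strand).
    """
    read = read.upper()
    L = len(read)
    n = len(ref.seq)
    pad = (min(L - 1, n) if circular_pad is None else circular_pad) if ref.circular else 0
    codes = encode(ref.seq + ref.seq[: pad])
    if len(codes) < L:
        return None
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    keep = min(len(win), n)  # placements past n duplicate canonical ones
    nm_f = (win[:keep] != encode(read)).sum(axis=1)
    nm_r = (win[:keep] != encode(revcomp(read))).sum(axis=1)
    nm_all = np.concatenate([nm_f, nm_r])
    pos_all = np.concatenate([np.arange(keep)] * 2)
    strand_all = np.concatenate([np.zeros(keep, int), np.ones(keep, int)])
    i = np.lexsort((strand_all, pos_all, nm_all))[0]
    nm_v, pos0, strand_code = int(nm_all[i]), int(pos_all[i]), int(strand_all[i])
    if max_mismatch is not None and nm_v > max_mismatch:
        return None
    seq = read if strand_code == 0 else revcomp(read)
    diff = np.nonzero(codes[pos0 : pos0 + L] != encode(seq))[0]
    if strand_code == 1:
        diff = L - 1 - diff[::-1]
    return Mapping("", pos0 + 1, "+" if strand_code == 0 else "-", nm_v,
                   tuple(int(d) for d in diff), L)
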