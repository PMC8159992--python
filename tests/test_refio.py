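"""Reference I/O, IR collapsing and dispersed-repeat discovery."""

import numpy as np
import pytest

import orgrearr as og
from orgrearr.refio import (
    Annotation,
    Reference,
    collapse_duplicate_region,
    find_dispersed_repeats,
    load_annotations,
    load_fasta,
    restore_duplicate_region,
    revcomp,
    write_fasta,
)


class TestLoadFasta:
    def test_identity_and_case_folding(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nacGT\n")
        ref = load_fasta(p)
        assert ref.seq == "ACGT" and len(ref) == 4 and ref.name == "x"

    def test_multi_record_rejected(self, tmp_path):
        p = tmp_path / "two.fa"
        p.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError, match="multiple records"):
            load_fasta(p)

    def test_empty_and_bad_characters(self, tmp_path):
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        with pytest.raises(ValueError):
            load_fasta(empty)
        bad = tmp_path / "bad.fa"
        bad.write_text(">x\nACGQ\n")
        with pytest.raises(ValueError, match="position 4"):
            load_fasta(bad)

    def test_roundtrip(self, tmp_path):
        ref = Reference("r", "ACGTN" * 30, circular=False)
        write_fasta(ref, tmp_path / "r.fa")
        back = load_fasta(tmp_path / "r.fa", circular=False)
        assert back.seq == ref.seq


class TestAnnotations:
    def test_gff3(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr\tsrc\tgene\t10\t90\t.\t+\t.\tID=g1\n"
            "chr\tsrc\tCDS\t20\t80\t.\t-\t.\tID=c1\n"
            "chr\tsrc\texon\t20\t80\t.\t-\t.\tID=e1\n"
        )
        anns = load_annotations(p)
        assert anns == [Annotation("gene", 10, 90, "+"), Annotation("CDS", 20, 80, "-")]


class TestCollapse:
    def _ir_reference(self, n=2000, keep=(801, 900), drop=(1801, 1900), seed=0):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=n))
        ir = seq[keep[0] - 1 : keep[1]]
        seq = seq[: drop[0] - 1] + revcomp(ir) + seq[drop[1] :]
        return Reference("toy", seq), keep, drop

    def test_ir_arithmetic_and_collapse(self):
        # chloroplast-style bookkeeping: both IR copies are 9,589 bp and
        # removing one from a 122,890 bp genome leaves 113,301 bp
        keep = (85_212, 94_800)
        drop = (113_302, 122_890)
        assert keep[1] - keep[0] + 1 == 9_589
        assert drop[1] - drop[0] + 1 == 9_589
        assert 122_890 - 9_589 == 113_301
        ref, keep_t, drop_t = self._ir_reference()
        collapsed = collapse_duplicate_region(ref, keep_t, drop_t)
        assert len(collapsed.seq) == 2000 - 100
        assert collapsed.collapsed == (keep_t, drop_t)

    def test_toy_drop_at_end(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), size=900))
        ref = Reference("t", seq + revcomp(seq[800:900]))
        out = collapse_duplicate_region(ref, (801, 900), (901, 1000))
        assert len(out.seq) == 900
        assert out.collapsed[0] == (801, 900)

    def test_identity_modes(self):
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), size=300))
        ref_ident = Reference("i", seq + seq[:50])
        with pytest.raises(ValueError):
            collapse_duplicate_region(ref_ident, (1, 50), (301, 350), "revcomp")
        out = collapse_duplicate_region(ref_ident, (1, 50), (301, 350), "identical")
        assert len(out.seq) == 300
        out2 = collapse_duplicate_region(ref_ident, (1, 50), (301, 350), "any")
        assert out2.seq == out.seq

    def test_precondition_errors(self):
        ref = Reference("t", "ACGT" * 100)
        with pytest.raises(ValueError, match="empty interval"):
            collapse_duplicate_region(ref, (1, 10), (50, 40))
        with pytest.raises(ValueError, match="overlap"):
            collapse_duplicate_region(ref, (1, 100), (50, 150), "none")
        with pytest.raises(ValueError, match="out of range"):
            collapse_duplicate_region(ref, (1, 10), (390, 410))

    def test_collapse_restore_roundtrip(self):
        ref, keep, drop = self._ir_reference(seed=5)
        collapsed = collapse_duplicate_region(ref, keep, drop)
        restored = restore_duplicate_region(collapsed)
        assert restored.seq == ref.seq

    def test_annotation_shifting(self):
        ref, keep, drop = self._ir_reference(seed=6)
        ref.annotations = [Annotation("gene", 10, 50, "+"),
                           Annotation("gene", 1850, 1880, "+"),
                           Annotation("gene", 1950, 1990, "-")]
        out = collapse_duplicate_region(ref, keep, drop)
        assert out.annotations == [Annotation("gene", 10, 50, "+"),
                                   Annotation("gene", 1850, 1890, "-")]


def _repeat_oracle(seq: str, min_len: int):
    """Exhaustive diagonal-scan oracle for maximal exact repeat pairs."""
    a = np.frombuffer(seq.encode(), np.uint8)
    comp = np.zeros(256, np.uint8)
    for x, y in zip(b"ACGTN", b"TGCAN"):
        comp[x] = y
    b = comp[a]
    n = len(a)
    out = set()

    def runs(mask):
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
        return zip(edges[::2], edges[1::2])

    for d in range(1, n):
        for s, e in runs(a[: n - d] == a[d:]):
            if e - s >= min_len:
                out.add(((s + 1, e), (s + d + 1, e + d), "same"))
    for c in range(1, 2 * n - 1):
        i0 = max(0, c - n + 1)
        idx = np.arange(i0, min(n - 1, c) + 1)
        for s, e in runs(a[idx] == b[c - idx]):
            s, e = s + i0, e + i0
            if e - s < min_len:
                continue
            la = (s + 1, e)
            lb = (c - e + 2, c - s + 1)
            if la == lb:
                continue
            out.add((min(la, lb), max(la, lb), "inverted"))
    return out


class TestDispersedRepeats:
    def test_planted_pair_detected_and_threshold(self):
        ref, repeats = og.simulate_genome(2000, 0.4, [(30, "same", 1)], seed=9)
        found = find_dispersed_repeats(ref, 30)
        planted = repeats[0]
        hits = [p for p in found
                if p.locus_a[0] <= planted.locus_a[0] <= p.locus_a[1]
                and p.length >= 30]
        assert hits, "planted 30 bp duplicate not recovered"
        longest = max(p.length for p in found)
        assert find_dispersed_repeats(ref, longest + 1) == []

    def test_min_len_validation(self):
        ref = Reference("r", "ACGT" * 100)
        with pytest.raises(ValueError):
            find_dispersed_repeats(ref, 2)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_diagonal_oracle(self, seed):
        ref, _ = og.simulate_genome(
            2000, 0.45, [(15, "same", 1), (18, "inverted", 1)], seed=seed
        )
        got = {(p.locus_a, p.locus_b, p.orientation)
               for p in find_dispersed_repeats(ref, 10)}
        assert got == _repeat_oracle(ref.seq, 10)

    def test_reported_pairs_pass_recomparison_and_are_unique(self, small_genome):
        ref, _ = small_genome
        pairs = find_dispersed_repeats(ref, 11)
        assert pairs
        keys = set()
        for p in pairs:
            a = ref.seq[p.locus_a[0] - 1 : p.locus_a[1]]
            b = ref.seq[p.locus_b[0] - 1 : p.locus_b[1]]
            assert p.seq == a
            assert b == (a if p.orientation == "same" else revcomp(a))
            assert p.length == p.locus_a[1] - p.locus_a[0] + 1
            assert p.locus_a <= p.locus_b
            keys.add((p.locus_a, p.locus_b, p.orientation))
        assert len(keys) == len(pairs)

    def test_exclude_intervals(self):
        ref, repeats = og.simulate_genome(3000, 0.4, [(20, "same", 1)], seed=4)
        planted = repeats[0]
        without = find_dispersed_repeats(ref, 20, exclude=[planted.locus_a])
        assert all(
            p.locus_a[1] < planted.locus_a[0] or p.locus_a[0] > planted.locus_a[1]
            for p in without
        )


class TestSegment:
    def test_circular_wrap_and_reverse(self):
        ref = Reference("r", "ACGTAA", circular=True)
        assert ref.segment(5, 4, "forward") == "AAAC"
        # reverse walk from 2: positions 2, 1, 6 complemented
        assert ref.segment(2, 3, "reverse") == "GTT"

    def test_linear_truncation(self):
        ref = Reference("r", "ACGTAA", circular=False)
        assert ref.segment(5, 4, "forward") == "AA"
        assert ref.segment(2, 5, "reverse") == "GT"
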