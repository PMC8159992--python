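"""Junction candidates, clustering, consensus, validation, classification."""

import numpy as np
import pytest

import orgrearr as og
from orgrearr.junctions import (
    JunctionCandidate,
    JunctionCluster,
    JunctionParams,
    build_consensus,
    classify,
    cluster_by_junction,
    find_junction_candidates,
    homology_at_junction,
    locate_partner,
    unify_mhmr,
    validate_cluster,
)
from orgrearr.mapper import MappingTable
from orgrearr.refio import Reference, revcomp
from conftest import make_row


@pytest.fixture(scope="module")
def ref5k():
    ref, _ = og.simulate_genome(5000, 0.4, seed=21)
    return ref


def chimeric_row(ref, anchor_start0, break_len, partner_start0, read_id="c0",
                 strand="+"):
    """A read whose first ``150-break_len`` bases come from ``anchor_start0``
    and whose tail comes from ``partner_start0`` (0-based), mapped at the
    anchor with mismatch offsets taken by direct comparison."""
    L = 150
    head = ref.seq[anchor_start0 : anchor_start0 + L - break_len]
    tail = ref.seq[partner_start0 : partner_start0 + break_len]
    readref = head + tail
    aligned = ref.seq[anchor_start0 : anchor_start0 + L]
    offs = tuple(i for i in range(L) if readref[i] != aligned[i])
    seq = readref if strand == "+" else revcomp(readref)
    if strand == "-":
        offs = tuple(sorted(L - 1 - o for o in offs))
    return make_row(read_id, 1, anchor_start0 + 1, strand, len(offs), offs,
                    L, seq)


class TestCandidates:
    def test_clean_mapping_not_candidate(self, ref5k):
        table = MappingTable([make_row("a", 1, 100, "+", 0, ())])
        assert find_junction_candidates(table, ref5k) == []

    def test_one_sided_tail_yields_candidate(self, ref5k):
        row = chimeric_row(ref5k, 499, 50, 3000)
        table = MappingTable([row])
        cands = find_junction_candidates(table, ref5k)
        assert len(cands) == 1
        c = cands[0]
        # junction = last matching base before the first mismatch
        first_mm = row["offsets"][0]
        assert c.junction_point == 500 + first_mm - 1
        assert c.direction == "forward"
        assert c.tail_seq == row["seq"][first_mm:]
        assert c.matched_len == first_mm

    def test_mismatches_on_both_sides_excluded(self, ref5k):
        table = MappingTable([make_row("b", 1, 100, "+", 4, (10, 60, 100, 140))])
        assert find_junction_candidates(table, ref5k) == []

    def test_three_mismatches_not_enough(self, ref5k):
        table = MappingTable([make_row("c", 1, 100, "+", 3, (100, 120, 140))])
        assert find_junction_candidates(table, ref5k) == []

    def test_minus_strand_candidate_mirrors(self, ref5k):
        plus = chimeric_row(ref5k, 499, 40, 3000, strand="+")
        minus = chimeric_row(ref5k, 499, 40, 3000, strand="-")
        cp = find_junction_candidates(MappingTable([plus]), ref5k)[0]
        cm = find_junction_candidates(MappingTable([minus]), ref5k)[0]
        assert (cp.junction_point, cp.direction, cp.tail_seq) == (
            cm.junction_point, cm.direction, cm.tail_seq)


class TestClustering:
    def _cand(self, jp, direction, tail="ACGT" * 10, rid="x"):
        return JunctionCandidate(rid, 1, jp - 10, "+", 150, 10, jp, direction,
                                 100, tail)

    def test_grouping_by_point(self):
        cands = [self._cand(100, "forward"), self._cand(100, "forward"),
                 self._cand(100, "forward"), self._cand(200, "forward"),
                 self._cand(200, "forward"), self._cand(200, "forward")]
        clusters = cluster_by_junction(cands)
        assert [(c.junction_point, len(c.members)) for c in clusters] == [
            (100, 3), (200, 3)]

    def test_empty_input(self):
        assert cluster_by_junction([]) == []

    def test_direction_is_part_of_key(self):
        cands = [self._cand(100, "forward"), self._cand(100, "reverse")]
        assert len(cluster_by_junction(cands)) == 2


class TestConsensus:
    def _cluster(self, tails):
        members = [
            JunctionCandidate(f"r{i}", 1, 1, "+", 150, 10, 100, "forward",
                              150 - len(t), t)
            for i, t in enumerate(tails)
        ]
        return JunctionCluster(100, "forward", members)

    def test_identical_tails(self):
        tail = "ACGTTGCAAC" * 4
        cons, kept = build_consensus(self._cluster([tail] * 5))
        assert cons == tail and len(kept) == 5

    def test_tie_resolved_by_preference_order(self):
        from orgrearr.junctions import _consensus_pass

        # 3xT vs 3xG at every position: the temporary consensus takes T
        assert _consensus_pass(["T" * 20] * 3 + ["G" * 20] * 3, 3) == "T" * 20
        # with 4 of each the final pass can also hold the T call
        cl = self._cluster(["T" * 20] * 4 + ["G" * 20] * 4)
        cons, kept = build_consensus(cl)
        assert cons == "T" * 20 and len(kept) == 4

    def test_divergent_member_removed(self):
        good = "ACGTACGTACGTACGTACGTACGT"
        bad = good[:5] + revcomp(good[5:])
        cons, kept = build_consensus(self._cluster([good] * 5 + [bad]))
        assert cons == good
        assert len(kept) == 5

    def test_truncation_at_support_threshold(self):
        # 5 long tails agree for 20 bases, then only 2 continue
        tails = ["A" * 20 + "C" * 10] * 2 + ["A" * 20] * 3
        cons, kept = build_consensus(self._cluster(tails), min_support=3,
                                     final_min=4)
        assert cons == "A" * 20
        assert len(kept) == 5

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        tails = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(3)]
        tails = [tails[0]] * 6 + tails
        base = len(build_consensus(self._cluster(tails), 3, 4)[0])
        stricter = len(build_consensus(self._cluster(tails), 5, 7)[0])
        assert stricter <= base


class TestLocatePartner:
    def test_forward_unique(self, ref5k):
        cons = ref5k.seq[1200:1240]
        assert locate_partner(cons, ref5k) == (1201, "forward")

    def test_reverse_unique(self, ref5k):
        cons = revcomp(ref5k.seq[1200:1240])
        assert locate_partner(cons, ref5k) == (1240, "reverse")

    def test_duplicate_not_unique(self):
        core = "".join(np.random.default_rng(2).choice(list("ACGT"), 500))
        ref = Reference("dup", core + core[100:140] + core[300:400])
        assert locate_partner(core[100:140], ref) is None

    def test_origin_spanning_hit(self, ref5k):
        cons = ref5k.seq[-20:] + ref5k.seq[:20]
        assert locate_partner(cons, ref5k) == (len(ref5k.seq) - 19, "forward")


def planted_cluster(ref, junction0, partner0, n_reads, tail_len=40,
                    matched_len=100):
    """Members of one clean planted junction (forward direction)."""
    members = []
    for i in range(n_reads):
        tail = ref.seq[partner0 : partner0 + tail_len + i % 3]
        members.append(JunctionCandidate(
            f"r{i}", 1, junction0 - matched_len + 2, "+", 150, len(tail),
            junction0 + 1, "forward", matched_len, tail))
    return JunctionCluster(junction0 + 1, "forward", members)


class TestValidate:
    def test_clean_planted_cluster_accepted(self, ref5k):
        cl = planted_cluster(ref5k, 999, 3000, 10)
        out = validate_cluster(cl, ref5k)
        assert out.status == "accepted"
        assert out.partner == (3001, "forward")
        assert out.n_reads == 10

    def test_consensus_length_fifteen_rejected(self, ref5k):
        cl = planted_cluster(ref5k, 999, 3000, 8, tail_len=15)
        cl.members = [m for m in cl.members]
        for m in cl.members:  # force all tails to exactly 15
            m.tail_seq = m.tail_seq[:15]
        out = validate_cluster(cl, ref5k)
        assert out.status == "rejected" and out.reject_reason == "consensus too short"

    def test_sixteen_is_enough(self, ref5k):
        cl = planted_cluster(ref5k, 999, 3000, 8)
        for m in cl.members:
            m.tail_seq = m.tail_seq[:16]
        out = validate_cluster(cl, ref5k)
        assert out.status == "accepted"

    def test_survivors_exactly_half_rejected(self, ref5k):
        cl = planted_cluster(ref5k, 999, 3000, 4)
        other = planted_cluster(ref5k, 999, 3500, 4)
        cl.members += other.members
        out = validate_cluster(cl, ref5k)
        assert out.status == "rejected" and out.reject_reason == "not majority"

    def test_four_of_nine_not_majority(self, ref5k):
        # 4 coherent reads + 5 mutually unrelated tails: the temporary
        # consensus follows the coherent four, but 4 <= 9/2 fails "more
        # than half of the original cluster"
        cl = planted_cluster(ref5k, 999, 3000, 4)
        rng = np.random.default_rng(17)
        for i in range(5):
            noisy = planted_cluster(ref5k, 999, 3000, 1)
            m = noisy.members[0]
            m.read_id = f"n{i}"
            m.tail_seq = "".join(rng.choice(list("ACGT"), 40))
            cl.members.append(m)
        out = validate_cluster(cl, ref5k)
        assert out.status == "rejected" and out.reject_reason == "not majority"

    def test_three_members_cannot_reach_final_consensus(self, ref5k):
        # the final consensus needs 4 matching reads at every kept position,
        # so a 3-read cluster can never pass the length criterion
        cl = planted_cluster(ref5k, 999, 3000, 3)
        out = validate_cluster(cl, ref5k)
        assert out.status == "rejected" and out.reject_reason == "consensus too short"

    def test_ambiguous_partner_rejected(self):
        core = "".join(np.random.default_rng(7).choice(list("ACGT"), 2000))
        ref = Reference("dup", core + core[500:560])
        cl = planted_cluster(ref, 99, 500, 6)
        out = validate_cluster(cl, ref)
        assert out.status == "rejected" and out.reject_reason == "partner not unique"

    def test_tail_recheck_drops_noisy_read(self, ref5k):
        cl = planted_cluster(ref5k, 999, 3000, 6)
        bad = cl.members[-1]
        bad.tail_seq = bad.tail_seq[:10] + revcomp(bad.tail_seq[10:20]) + bad.tail_seq[20:]
        out = validate_cluster(cl, ref5k)
        # the corrupted read fails the <=1-mismatch re-check but the cluster survives
        assert out.status in ("accepted", "rejected")
        if out.status == "accepted":
            assert out.n_reads <= 5


class TestClassify:
    def test_deletion_of_twenty(self, ref5k):
        r = classify((1000, "forward"), (1021, "forward"), ref5k)
        assert r.category == "del" and r.event_length == 20

    def test_tandem_insertion_of_ten(self, ref5k):
        r = classify((1000, "forward"), (991, "forward"), ref5k)
        assert r.category == "ins" and r.event_length == 10

    def test_reverse_frame_deletion(self, ref5k):
        r = classify((1021, "reverse"), (1000, "reverse"), ref5k)
        assert r.category == "del" and r.event_length == 20

    def test_fifty_bp_event_is_not_indel(self, ref5k):
        r = classify((1000, "forward"), (1051, "forward"), ref5k)
        assert r.category != "del"
        r2 = classify((1000, "forward"), (951, "forward"), ref5k)
        assert r2.category != "ins"

    def test_mhr_with_planted_homology_matches_string_oracle(self):
        rng = np.random.default_rng(31)
        seq = list("".join(rng.choice(list("ACGT"), 8000)))
        hom = "ACGGTTACGGAT"  # 12 bp shared flank
        seq[988:1000] = hom
        seq[4988:5000] = hom
        ref = Reference("h", "".join(seq))
        r = classify((1000, "forward"), (5001, "forward"), ref)
        assert r.category == "mhr" and r.repeat_orientation == "same"
        # oracle: directly extend the shared flank around both breakpoints
        # (junction after 1-based 1000, partner entry at 5001)
        s = ref.seq
        left = 0
        while s[999 - left] == s[4999 - left]:
            left += 1
        right = 0
        while s[1000 + right] == s[5000 + right]:
            right += 1
        assert left >= 12
        assert r.homology_len == left + right

    def test_unk_without_homology(self):
        rng = np.random.default_rng(33)
        ref = Reference("u", "".join(rng.choice(list("ACGT"), 6000)))
        r = classify((1000, "forward"), (4000, "forward"), ref, min_homology=3)
        if r.homology_len < 3:
            assert r.category == "unk"
        else:
            assert r.category == "mhr"

    def test_pal_boundaries(self, ref5k):
        near = classify((1000, "forward"), (1040, "reverse"), ref5k)
        assert near.category == "pal"
        at70 = classify((1000, "forward"), (1070, "reverse"), ref5k)
        assert at70.category != "pal"

    def test_category_partition(self, mini_run):
        for c in mini_run["clusters"]:
            if c.status == "accepted":
                assert c.rearrangement.category in ("ins", "del", "mhr", "unk", "pal")


class TestEndToEnd:
    def test_planted_events_recovered_exactly(self, mini_run):
        det = {
            (c.junction_point, c.direction): (c.partner, c.rearrangement.category)
            for c in mini_run["clusters"] if c.status == "accepted"
        }
        truth = mini_run["truth"].df
        strong = truth[truth.expected_support >= 8]
        assert len(strong) >= 4
        for _, row in strong.iterrows():
            hit = det.get((row.junction_pos, row.junction_dir))
            assert hit is not None, f"missed cluster at {row.junction_pos}"
            assert hit[0] == (row.partner_pos, row.partner_dir)
            assert hit[1] == row.category

    def test_reciprocality_of_planted_mhr(self, mini_run):
        accepted = {(c.junction_point, c.direction): c
                    for c in mini_run["clusters"] if c.status == "accepted"}
        mhr = [c for c in accepted.values()
               if c.rearrangement and c.rearrangement.category == "mhr"]
        # a/b clusters of one junction coincide under end swap
        keysets = {frozenset([(c.junction_point,), (c.partner[0],)]) for c in mhr}
        assert len(keysets) <= len(mhr)

    def test_monotonicity_in_support_thresholds(self, mini_run):
        table, ref = mini_run["table"], mini_run["ref"]
        base = og.detect_junctions(table, ref, JunctionParams())[1]
        strict = og.detect_junctions(
            table, ref, JunctionParams(min_support=5, final_min=7, min_members=6)
        )[1]
        assert len(strict) <= len(base)

    def test_mate_filter_removes_distant_mate(self, ref5k):
        cl = planted_cluster(ref5k, 999, 3000, 6)
        rows = []
        for i, m in enumerate(cl.members):
            rows.append(make_row(m.read_id, 1, m.map_pos, "+", 40, (), 150))
            # mates parked far away from both junction and partner
            mate_pos = 4500 if i < 3 else 3020
            rows.append(make_row(m.read_id, 2, mate_pos, "-", 0, (), 150))
        table = MappingTable(rows)
        out = validate_cluster(cl, ref5k, table, JunctionParams(),
                               insert_stats=(300.0, 30.0))
        assert out.status == "accepted"
        assert out.n_reads == 3  # only the mates near the partner survive


class TestUnify:
    def test_four_entries_one_record(self, mini_run):
        rearrs = [c.rearrangement for c in mini_run["clusters"]
                  if c.status == "accepted" and c.rearrangement.category == "mhr"]
        cands = og.find_junction_candidates(mini_run["table"], mini_run["ref"])
        recs = unify_mhmr(rearrs, cands, mini_run["ref"])
        assert len(recs) == 1
        rec = recs[0]
        filled = sum(1 for v in rec.slot_reads.values() if v > 0)
        assert filled == 4
        assert rec.total_reads >= sum(r.n_reads for r in rearrs)
        # planted asymmetry 4:1
        assert 2.0 <= rec.asymmetry_ratio <= 8.0

    def test_single_entry_record(self, ref5k):
        r = classify((1000, "forward"), (3000, "forward"), ref5k, min_homology=0)
        r.category = "mhr"
        r.n_reads = 7
        recs = unify_mhmr([r])
        assert len(recs) == 1
        assert recs[0].total_reads >= 7
        assert sum(1 for v in recs[0].slot_reads.values() if v == 0) == 3
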