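import numpy as np
import pytest

import orgrearr as og


@pytest.fixture(scope="session")
def small_genome():
    """20 kb circular genome with one direct repeat, one distant inverted
    pair and one quasi-palindrome planted."""
    ref, repeats = og.simulate_genome(
        20_000, 0.35,
        repeat_spec=[(12, "same", 1), (14, "inverted", 1)],
        at_cluster_spec=[(10, 4)],
        palindrome_spec=[(12, 24, 1)],
        seed=3,
    )
    return ref, repeats


@pytest.fixture(scope="session")
def mini_run(small_genome):
    """A small but complete planted-event run shared across test modules:
    deletion + asymmetric direct-repeat mhr, 15k read pairs (~220x)."""
    ref, repeats = small_genome
    direct = [r for r in repeats if r.orientation == "same"][0]
    events = [
        og.EventSpec("del", 0.3, span=(5001, 5030)),
        og.EventSpec("mhr_same", 0.2, repeat=direct, asymmetry=4.0),
    ]
    molecules, truth = og.apply_events(ref, events, seed=3)
    r1, r2, truth = og.simulate_reads(molecules, 15_000, seed=3, truth=truth)
    index = og.build_index(ref)
    table = og.map_pairs(r1, r2, index, og.PRESETS["h75r10"])
    clusters, rearrs = og.detect_junctions(table, ref)
    return {
        "ref": ref, "repeats": repeats, "events": events,
        "molecules": molecules, "truth": truth, "r1": r1, "r2": r2,
        "index": index, "table": table, "clusters": clusters,
        "rearrs": rearrs,
    }


def make_row(read_id, mate, pos, strand, n_mismatch=0, offsets=(),
             length=150, seq=None, mapped=True):
    """Hand-built MappingTable row for unit tests."""
    return {
        "read_id": read_id, "mate": mate, "mapped": mapped, "pos": pos,
        "strand": strand, "n_mismatch": n_mismatch, "offsets": tuple(offsets),
        "length": length, "seq": seq if seq is not None else "A" * length,
    }
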