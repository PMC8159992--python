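"""Render the circular genome map of a rearranged sample.

Runs simulation, mapping, junction calling and depth tracks, then draws
the circmap-style figure: junction points (filled = clockwise, empty =
counter-clockwise) joined by arcs with log-scaled thickness, GC and depth
rings, and the expected depth-change track.  Output: circular_map.svg in
the working directory.
"""

from pathlib import Path

import orgrearr as og
from orgrearr.depth import depth_track, expected_change_track, gc_track
from orgrearr.viz import render_circular_map

ref, repeats = og.simulate_genome(20_000, gc=0.35,
                                  repeat_spec=[(12, "same", 1)], seed=3)
direct = [r for r in repeats if r.orientation == "same"][0]
events = [og.EventSpec("del", 0.3, span=(5001, 5030)),
          og.EventSpec("mhr_same", 0.2, repeat=direct, asymmetry=4.0)]
molecules, _ = og.apply_events(ref, events, seed=3)
r1, r2, _ = og.simulate_reads(molecules, 15_000, seed=3)

index = og.build_index(ref)
table = og.map_pairs(r1, r2, index, og.PRESETS["h75r10"])
clusters, rearrs = og.detect_junctions(table, ref)

tracks = {
    "depth": depth_track(table, ref),
    "gc": gc_track(ref),
    "expected_change": expected_change_track(rearrs, len(ref.seq)),
}
out = render_circular_map(ref, tracks, rearrs, Path("circular_map.svg"))
print(f"wrote {out} with {len(rearrs)} rearrangement arcs")
for r in rearrs:
    print(f"  {r.category}: {r.end_a[0]} ({r.end_a[1]}) <-> "
          f"{r.end_b[0]} ({r.end_b[1]}), {r.n_reads} reads")
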