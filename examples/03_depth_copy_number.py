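"""Copy-number ratio track: a subgenomic deletion seen as a depth dip.

A mutant population in which half the molecules carry a 2 kb deletion is
compared against wild type.  After dividing per-window depth and
rescaling by mapped-read totals, the ratio over the deleted span sits at
half the flanking level - the molecule fraction of the deletion-carrying
subgenome is read directly off the track.
"""

import numpy as np

import orgrearr as og
from orgrearr.depth import depth_track, normalize_against_wt

ref, _ = og.simulate_genome(10_000, gc=0.4, seed=43)
index = og.build_index(ref)

wt_mol = og.Molecule("wt", ref.seq, True, 1.0, [(1, 10_000, "+")])
mut_mols, _ = og.apply_events(
    ref, [og.EventSpec("del", 0.5, span=(4001, 6000))], seed=43
)

r1, r2, _ = og.simulate_reads([wt_mol], 30_000, seed=7)
wt_table = og.map_pairs(r1, r2, index, og.PRESETS["h2r3"])
m1, m2, _ = og.simulate_reads(mut_mols, 30_000, seed=8)
mut_table = og.map_pairs(m1, m2, index, og.PRESETS["h2r3"])

wt = depth_track(wt_table, ref, window=100)
mut = depth_track(mut_table, ref, window=100)
ratio = normalize_against_wt(mut, wt, mut_table.n_mapped(), wt_table.n_mapped())

inside = np.nanmean(ratio.values[41:59])
outside = np.nanmean(np.concatenate([ratio.values[2:38], ratio.values[62:98]]))
print(f"mean WT depth            : {wt.values.mean():7.1f}x")
print(f"ratio over deleted span  : {inside:7.3f}")
print(f"ratio over flanks        : {outside:7.3f}")
print(f"span / flank             : {inside / outside:7.3f}  "
      "(= 1 - deletion fraction = 0.5)")

self_ratio = normalize_against_wt(wt, wt, wt_table.n_mapped(), wt_table.n_mapped())
print(f"self-normalization error : {np.nanmax(np.abs(self_ratio.values - 1)):.2e}")
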