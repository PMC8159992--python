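# orgrearr

Detection and classification of rearrangements in small circular
(organelle) genomes from Illumina paired-end reads, plus a planted-event
simulator so the whole stack can be validated without real sequencing
data.

## The problem

Plastid and mitochondrial genomes of plants are unstable when homologous
recombination surveillance is lost: short dispersed repeats (3–79 bp)
recombine ectopically, producing deletions, duplications, inversions and
U-turn (fold-back) junctions, and the resulting subgenomes shift the
copy number of whole genome segments. These events are invisible to
conventional gapped aligners at low product fractions; they are best seen
as *junction reads* — single reads whose two halves map to different
loci — and as discordant read pairs. `orgrearr` implements that analysis
end to end for references in the 50–120 kb range:

- **Ungapped indexed mapping** (`orgrearr.mapper`): every 14-mer of the
  reference is indexed; a read is placed by exact lookup of *r* index
  windows spaced across it and scored by whole-read Hamming distance.
  The placement with minimum mismatch wins, with strict (`h2r3`: ≤2
  mismatches, 3 windows), tolerant (`h75r10`: ≤75 mismatches, 10
  windows) and tail-truncated (`chp100_h2r3`: first 100 bp) presets.
  With ≤2 mismatches and 3 windows, one window is always clean, so the
  strict mode provably returns the global minimum-mismatch placement.
- **Junction-read calling** (`orgrearr.junctions`): mapped reads with
  more than 3 mismatches, all confined to one half of the read, define a
  junction point (last matching base from the clean end). Reads sharing
  a junction point and direction form a cluster; their mismatch tails
  are collapsed into a two-stage consensus (plurality per position, ties
  A>T>G>C, support ≥3 then ≥4), which is located on the reference to
  find the partner locus. Clusters survive only if the consensus exceeds
  15 bp, more than 3 and more than half of the members match it, the
  partner is unique, each read re-checks against the partner (≤1
  mismatch on the short side, 0 on the long side) and the mate maps
  where the junction geometry demands. Accepted junctions are classified
  as `del` / `ins` (same-direction ends, event < 50 bp; insertions are
  tandem-repeat only), `pal` (opposite-direction ends < 70 bp apart),
  `mhr` (flanks share ≥3 identical bases across the junction, same or
  opposite orientation) or `unk`. The four clusters generated by one
  repeat pair's two reciprocal products are unified into `.mhmr` records
  that expose the asymmetry between reciprocal products.
- **Discordant pairs** (`orgrearr.pairs`): with 100 bp-truncated strict
  mappings, pairs separated by >600 bp or pointing the same way are
  flagged and greedily clustered against seeds (join when
  |Δpos1|+|Δpos2| < 500).
- **Depth / copy number** (`orgrearr.depth`): 100 bp windowed depth and
  GC tracks, mutant÷wild-type ratio rescaled by mapped-read totals, the
  expected depth-change track implied by junction directions, and
  bookkeeping for a collapsed inverted-repeat copy (the kept copy's
  depth is doubled).
- **Comparison & statistics** (`orgrearr.compare`): merging calls across
  strains into read-count matrices (`.out` raw / `.out2` per million
  mapped reads), the outside/inside-gene breakpoint density ratio, and
  the Morisita overlap (Morisita–Horn by default) between binned
  distributions.
- **Simulation** (`orgrearr.simulate`): circular genomes with planted
  dispersed repeats, A/T clusters and quasi-palindromes; molecule
  populations carrying deletions, tandem insertions, same/opposite
  repeat-mediated rearrangements with asymmetric reciprocal products,
  and fold-backs; error-bearing 150 bp read pairs from ~300 bp inserts;
  and a truth table with exact expected junction coordinates.
- **Visualization & pipeline** (`orgrearr.viz`, `orgrearr.pipeline`,
  `orgrearr` CLI): a circular map with junction points, log-thickness
  arcs, GC/gene/depth/expected-change rings, and a one-command pipeline
  that writes every category file plus a machine-readable summary.

## Worked example

`examples/01_simulate_and_detect.py` plants a 30 bp deletion (30% of
molecules) and an asymmetric direct-repeat rearrangement (20% / 5%
reciprocal products) in a 20 kb genome, sequences 15,000 pairs and calls
junctions:

```
genome: 20,000 bp, direct repeat at (2380, 2391)/(18027, 18038) (TTGTACCGAAAG)

30,000 of 30,000 reads mapped (h75r10)
accepted junction clusters:
  junction   2380 reverse  -> partner  18026 reverse  mhr  n=5
  junction   2392 forward  -> partner  18040 forward  mhr  n=13
  junction   5000 forward  -> partner   5031 forward  del  n=32
  junction   5031 reverse  -> partner   5000 reverse  del  n=40
  junction  18027 reverse  -> partner   2379 reverse  mhr  n=14
  junction  18039 forward  -> partner   2393 forward  mhr  n=7

unified repeat (2380, 2392)/(18027, 18039) (same): reciprocal products
27 vs 12 reads (asymmetry 2.2:1, planted 4:1)
```

Each planted junction is recovered twice (once anchored on either side)
at the exact 1-based breakpoints recorded in the simulator's truth
table: the deletion of 5001–5030 appears as same-direction ends 5000→5031
(`del`, event length 30 bp), and the repeat-mediated event as
distant `mhr` ends whose homology tract is the planted 12 bp repeat. The
unified record compares the two reciprocal products; at this modest
coverage the 4:1 planted asymmetry is estimated at 2.2:1 from 27 vs 12
reads. The other examples cover mapping (`02`), copy-number ratios
(`03`, a 50% deletion subgenome reads out as span/flank = 0.500),
discordant pairs (`04`) and the circular map (`05`).

## Output file formats

Per-category junction files (`.ins`, `.del`, `.mhr`, `.unk`, `.pal`) are
TSVs with columns, in this order: `junction_pos`, `junction_dir`,
`partner_pos`, `partner_dir`, `category`, `homology_len`,
`homology_seq`, `n_reads`, `consensus`, `status`. `.mhmr` holds the
repeat loci, per-slot (1a/1b/2a/2b) read counts, reciprocal totals and
the asymmetry ratio. Pair files: `.pdist` (read_id, pos1, pos2, dir1,
dir2, kind) and `.pe` (seed_pos1, seed_pos2, dir1, dir2, n, sd). Depth
tracks export as TSV (1-based inclusive) and bedGraph (0-based
half-open). Cross-sample matrices are CSV with sample-name headers.

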