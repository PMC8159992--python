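"""End-to-end orchestration: map -> junctions, map(truncated) -> pairs ->
depth -> visualization, with every threshold exposed as a config key.

The pipeline mirrors the analysis flow chart of the method: the same read
pair is mapped twice, once mismatch-tolerantly at full length (h75r10) to
feed the junction-read caller, and once truncated to 100 bp under strict
mismatch limits (chp100_h2r3) to feed the discordant-pair caller.  All
category files (.ins/.del/.mhr/.unk/.pal/.mhmr), the pair files
(.pdist/.pe), depth tracks, a circular map, a machine-readable summary and
an echo of the configuration are written into the result directory.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from pathlib import Path

from . import depth as depth_mod
from . import junctions as junc_mod
from . import pairs as pairs_mod
from .mapper import PRESETS, MapParams, build_index, map_pairs
from .refio import collapse_duplicate_region, load_annotations, load_fasta
from .viz import render_circular_map

DEFAULT_CONFIG = {
    "circular": True,
    "index_len": 14,
    "strict_max_mismatch": 2,
    "strict_retries": 3,
    "loose_max_mismatch": 75,
    "loose_retries": 10,
    "truncate_to": 100,
    "pair_min_sep": 600,
    "pair_max_sum": 500,
    "min_support": 3,
    "final_min": 4,
    "min_consensus_len": 15,
    "min_members": 3,
    "indel_max": 50,
    "pal_max": 70,
    "min_homology": 3,
    "window": 100,
    "mate_filter": True,
    "seed": 0,
}


def load_config(path: str | Path) -> dict:
    """Flat TOML-style key = value config."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _echo_config(cfg: dict, path: Path) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.items():
            if isinstance(v, bool):
                fh.write(f"{k} = {str(v).lower()}\n")
            elif isinstance(v, (int, float)):
                fh.write(f"{k} = {v}\n")
            else:
                fh.write(f'{k} = "{v}"\n')


def run_pipeline(config: dict | str | Path) -> Path:
    """Run every stage; returns the result directory.

    Required config keys: ``reference`` (FASTA), ``r1``/``r2`` (FASTQ),
    ``out_dir``.  Optional: ``annotations`` (GFF3/GenBank),
    ``collapse_keep``/``collapse_drop`` ("start-end" strings for IR
    removal), plus every threshold in ``DEFAULT_CONFIG``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("orgrearr.pipeline")
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()

    current_stage = "init"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        log.info("stage %s", name)

    try:
        stage("reference")
        ref = load_fasta(cfg["reference"], circular=cfg["circular"])
        if cfg.get("annotations"):
            ref.annotations = load_annotations(cfg["annotations"])
        if cfg.get("collapse_keep") and cfg.get("collapse_drop"):
            keep = tuple(int(x) for x in str(cfg["collapse_keep"]).split("-"))
            drop = tuple(int(x) for x in str(cfg["collapse_drop"]).split("-"))
            ref = collapse_duplicate_region(ref, keep, drop,
                                            cfg.get("ir_identity", "revcomp"))

        stage("map-loose")
        loose = MapParams(cfg["index_len"], cfg["loose_max_mismatch"],
                          cfg["loose_retries"])
        index = build_index(ref, cfg["index_len"])
        table_loose = map_pairs(cfg["r1"], cfg["r2"], index, loose)
        table_loose.to_tsv(out / "mappings_h75.tsv")

        stage("junctions")
        jp = junc_mod.JunctionParams(
            min_support=cfg["min_support"], final_min=cfg["final_min"],
            min_consensus_len=cfg["min_consensus_len"],
            min_members=cfg["min_members"], indel_max=cfg["indel_max"],
            pal_max=cfg["pal_max"], min_homology=cfg["min_homology"],
        )
        clusters, rearrs = junc_mod.detect_junctions(
            table_loose, ref, jp, mate_filter=cfg["mate_filter"]
        )
        junc_mod.write_category_files(clusters, out / "rearrangements")
        cands = junc_mod.find_junction_candidates(table_loose, ref, jp)
        mhmr = junc_mod.unify_mhmr(rearrs, cands, ref)
        junc_mod.write_mhmr_file(mhmr, out / "rearrangements.mhmr")

        stage("map-truncated")
        strict_tr = MapParams(cfg["index_len"], cfg["strict_max_mismatch"],
                              cfg["strict_retries"], truncate_to=cfg["truncate_to"])
        table_tr = map_pairs(cfg["r1"], cfg["r2"], index, strict_tr)

        stage("pairs")
        anoms = pairs_mod.find_unusual_pairs(table_tr, cfg["pair_min_sep"])
        pclusters = pairs_mod.cluster_pairs(anoms, cfg["pair_max_sum"])
        pairs_mod.write_pdist(anoms, out / "pairs.pdist")
        pairs_mod.write_pe(pclusters, out / "pairs.pe")

        stage("depth")
        window = cfg["window"]
        dtrack = depth_mod.depth_track(table_loose, ref, window)
        gtrack = depth_mod.gc_track(ref, window)
        ctrack = depth_mod.expected_change_track(rearrs, len(ref.seq), window)
        for name, tr in (("depth", dtrack), ("gc", gtrack),
                         ("expected_change", ctrack)):
            depth_mod.write_track_tsv(tr, out / f"{name}.tsv")
            depth_mod.write_bedgraph(tr, ref.name, out / f"{name}.bedgraph")

        stage("viz")
        render_circular_map(
            ref, {"depth": dtrack, "gc": gtrack, "expected_change": ctrack},
            rearrs, out / "circular_map.svg",
        )

        stage("summary")
        counts = {c: 0 for c in junc_mod.CATEGORY_SUFFIXES}
        for r in rearrs:
            counts[r.category] += 1
        summary = {
            "reference": ref.name,
            "reference_length": len(ref.seq),
            "reads_mapped_loose": table_loose.n_mapped(),
            "reads_mapped_truncated": table_tr.n_mapped(),
            "junction_candidates": len(cands),
            "junction_clusters": len(clusters),
            "accepted_clusters": len(rearrs),
            "category_counts": counts,
            "mhmr_records": len(mhmr),
            "pair_anomalies": len(anoms),
            "pair_clusters": len(pclusters),
            "runtime_s": round(time.time() - t0, 2),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        _echo_config(cfg, out / "config.echo.toml")
        log.info("done in %.1fs", time.time() - t0)
    except Exception as exc:
        log.error("stage %s failed: %s", current_stage, exc)
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
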