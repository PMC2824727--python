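"""End-to-end orchestration: simulate -> anchor -> stats -> synteny ->
distance, with strict config validation and a consolidated JSON report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from .anchor import Thresholds, call_clones, calls_to_frame, parse_blast_tab, summarize_anchors
from .libstats import LibraryStats, chrom_uniformity_test, gc_fraction, observed_depth
from .rearrange import classify_scenario, genomic_distance, optimize_ambiguous_signs, sorting_scenario
from .simulate import (SimConfig, apply_events, emit_alignments,
                       emit_bes_fasta, emit_marker_table, make_ancestor,
                       sample_clones, simulate_screening, write_blast_tab)
from .syntenymap import (blocks_to_frame, call_blocks,
                         chromosome_correspondence, condense,
                         load_marker_table, write_grimm)

log = logging.getLogger("bacomap")

_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_THRESH_KEYS = {f.name for f in dataclasses.fields(Thresholds)}
_TOP_KEYS = {"mode", "seed", "log_level", "sim", "thresholds", "inputs",
             "n_events", "kind_weights", "screening"}
_INPUT_KEYS = {"alignments", "marker_table", "fasta", "screening"}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str = "synthetic"
    seed: int = 0
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    inputs: Dict[str, str] = field(default_factory=dict)
    n_events: int = 0
    kind_weights: Optional[Dict[str, float]] = None
    screening: Dict[str, float] = field(
        default_factory=lambda: {"n_probes": 54, "depth": 10.2})

    def config_hash(self) -> str:
        blob = json.dumps({
            "mode": self.mode, "seed": self.seed,
            "sim": dataclasses.asdict(self.sim),
            "thresholds": dataclasses.asdict(self.thresholds),
            "inputs": self.inputs, "n_events": self.n_events,
            "kind_weights": self.kind_weights, "screening": self.screening,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(source) -> RunConfig:
    """Parse and validate a YAML config (path, text, or dict).

    Unknown keys are rejected by name; referenced input files must
    exist in real-input mode.
    """
    if isinstance(source, dict):
        raw = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    mode = raw.get("mode", "synthetic")
    if mode not in ("synthetic", "real-input"):
        raise ConfigError(f"mode must be synthetic or real-input, got {mode!r}")
    sim_raw = dict(raw.get("sim") or {})
    unknown = set(sim_raw) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"unknown sim key(s): {sorted(unknown)}")
    thr_raw = dict(raw.get("thresholds") or {})
    unknown = set(thr_raw) - _THRESH_KEYS
    if unknown:
        raise ConfigError(f"unknown thresholds key(s): {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    sim_raw.setdefault("seed", seed)
    try:
        sim = SimConfig(**sim_raw)
        thresholds = Thresholds(**thr_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from None
    inputs = dict(raw.get("inputs") or {})
    unknown = set(inputs) - _INPUT_KEYS
    if unknown:
        raise ConfigError(f"unknown inputs key(s): {sorted(unknown)}")
    if mode == "real-input":
        for key, path in inputs.items():
            if not Path(path).exists():
                raise ConfigError(f"inputs.{key}: no such file {path!r}")
    cfg = RunConfig(
        mode=mode, seed=seed, log_level=str(raw.get("log_level", "INFO")),
        sim=sim, thresholds=thresholds, inputs=inputs,
        n_events=int(raw.get("n_events", 0)),
        kind_weights=raw.get("kind_weights"),
        screening=dict(raw.get("screening")
                       or {"n_probes": 54, "depth": 10.2}),
    )
    return cfg


def _distance_stage(markers, report: dict, outdir: Path) -> None:
    seg = condense(markers)
    write_grimm({"query": seg.genome_query, "target": seg.genome_target},
                outdir / "genomes.grimm.txt")
    genome_q, d, exact = optimize_ambiguous_signs(
        seg.genome_query, seg.ambiguous_segments, seg.genome_target)
    scenario = sorting_scenario(genome_q, seg.genome_target)
    dist = classify_scenario(scenario)
    steps = pd.DataFrame(
        [(i + 1, op.kind, " ".join(map(str, op.params)))
         for i, op in enumerate(scenario.operations)],
        columns=["step", "kind", "params"],
    )
    steps.to_csv(outdir / "scenario.tsv", sep="\t", index=False)
    report["distance"] = dict(dist.to_dict(),
                              sign_optimization_exact=exact,
                              n_segments=seg.n_segments,
                              n_ambiguous=len(seg.ambiguous_segments))


def run_full(config: RunConfig, outdir) -> dict:
    """Execute the staged pipeline; returns (and writes) the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "tool_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "mode": config.mode,
        }
    }
    stage = "setup"
    try:
        if config.mode == "synthetic":
            stage = "simulate"
            sim = config.sim
            ancestor = make_ancestor(sim)
            derived, ev_log = apply_events(
                ancestor, k=config.n_events, rng=sim.stream("events"),
                kind_weights=config.kind_weights)
            clones = sample_clones(derived, sim, log=ev_log)
            aln, truth = emit_alignments(clones, derived, sim)
            fasta_text = emit_bes_fasta(clones, sim)
            markers_df = emit_marker_table(derived, sim)
            screening = simulate_screening(
                int(config.screening["n_probes"]),
                float(config.screening["depth"]),
                rng=sim.stream("screening"))
            aln_path = outdir / "alignments.tsv"
            write_blast_tab(aln, aln_path)
            truth.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
            (outdir / "bes.fasta").write_text(fasta_text)
            markers_df.to_csv(outdir / "markers.tsv", sep="\t", index=False)
            screening.to_csv(outdir / "screening.tsv", sep="\t", index=False)
            (outdir / "events.json").write_text(ev_log.to_json())
            report["simulate"] = {
                "n_markers": ancestor.n_markers,
                "n_clones": len(clones),
                "n_events": len(ev_log.events),
                "n_alignments": len(aln),
            }
            inputs = {
                "alignments": aln_path, "fasta": outdir / "bes.fasta",
                "marker_table": outdir / "markers.tsv",
                "screening": outdir / "screening.tsv",
            }
        else:
            inputs = {k: Path(v) for k, v in config.inputs.items()}

        if "alignments" in inputs:
            stage = "anchor"
            alignments = parse_blast_tab(inputs["alignments"])
            calls, _anchors = call_clones(alignments, config.thresholds)
            calls_to_frame(calls).to_csv(outdir / "clone_calls.tsv",
                                         sep="\t", index=False)
            summary = summarize_anchors(calls.values())
            summary.to_csv(outdir / "anchor_summary.tsv", sep="\t", index=False)
            report["anchor"] = dict(zip(summary["category"],
                                        summary["count"].astype(int)))
            if config.mode == "synthetic":
                truth_map = {cid: rec for cid, rec
                             in ev_log.clone_truth.items()}
                agree = sum(
                    1 for cid, c in calls.items()
                    if not truth_map.get(cid, (0, 0, 0, True))[3]
                    and c.klass == "concordant")
                report["anchor"]["concordant_among_nonstraddling"] = agree
        else:
            log.info("anchor stage skipped (no alignments input)")

        stage = "stats"
        stats: dict = {}
        if "fasta" in inputs:
            stats["gc_fraction"] = gc_fraction(inputs["fasta"])
        if "screening" in inputs:
            scr = pd.read_csv(inputs["screening"], sep="\t",
                              dtype=str, keep_default_na=False)
            stats["observed_depth"] = observed_depth(scr)
        if config.mode == "synthetic":
            ls = LibraryStats(
                n_clones=config.sim.n_clones,
                mean_insert=config.sim.insert_mean,
                genome_size=sum(config.sim.chrom_lengths))
            stats["fold_coverage"] = ls.fold_coverage
        if stats:
            report["stats"] = stats

        if "marker_table" in inputs:
            stage = "synteny"
            markers = load_marker_table(inputs["marker_table"])
            blocks = call_blocks(markers)
            blocks_to_frame(blocks).to_csv(outdir / "blocks.tsv",
                                           sep="\t", index=False)
            t2q, q2t = chromosome_correspondence(blocks)
            report["synteny"] = {
                "n_markers": len(markers),
                "n_blocks": len(blocks),
                "target_to_query": t2q,
                "query_to_target": q2t,
            }
            stage = "distance"
            _distance_stage(markers, report, outdir)
        else:
            log.info("synteny/distance stages skipped (no marker table)")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report
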