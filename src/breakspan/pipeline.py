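"""Run orchestration: simulate -> sites -> profile -> span -> correlate.

A single structured config drives the stages; every output table is
written atomically and a manifest JSON records package version, stage
parameters, derived seeds and input checksums, so a run is reproducible
from its run directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage_signal import (
    compute_coverage,
    depth_normalize,
    metaprofile,
    profile_halfwidth,
    site_enrichment,
    top_n_sites,
)
from .correlation_cluster import build_matrix, cluster_factors, correlation_table, rank_transform
from .formats_io import (
    read_bedgraph,
    read_intervals,
    write_bedgraph,
    write_fasta,
    write_intervals_bed,
)
from .genome_sites import read_sites_bed, scan_motif, write_sites_bed
from .span_ratio import bootstrap_ks_test, span_ratio_vector
from .synthetic_data import (
    SimulationConfig,
    make_genome,
    simulate_chip_reads,
    write_truth,
)

log = logging.getLogger("breakspan")

STAGE_ORDER = ["simulate", "sites", "profile", "span", "correlate"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(STAGE_ORDER))
    log_level: str = "INFO"
    simulate: Dict[str, Any] = field(default_factory=dict)
    sites: Dict[str, Any] = field(default_factory=dict)
    profile: Dict[str, Any] = field(default_factory=dict)
    span: Dict[str, Any] = field(default_factory=dict)
    correlate: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.out_dir:
            raise PipelineError("out_dir is required")
        if not isinstance(self.seed, int):
            raise PipelineError("seed must be an integer")
        for stage in self.stages:
            if stage not in STAGE_ORDER:
                raise PipelineError(f"unknown stage {stage!r}")
        # referenced input paths must exist before any stage runs
        for stage, keys in (
            ("sites", ["fasta"]),
            ("profile", ["reads", "sites"]),
            ("span", ["reads_a", "reads_b", "sites"]),
            ("correlate", ["sites"]),
        ):
            section = getattr(self, stage)
            for key in keys:
                path = section.get(key)
                if path is not None and not os.path.exists(path):
                    raise PipelineError(f"{stage}.{key}: missing input {path!r}")
        for name, path in (self.correlate.get("tracks") or {}).items():
            if not os.path.exists(path):
                raise PipelineError(f"correlate.tracks.{name}: missing input {path!r}")

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed; below 2**31."""
        return (self.seed ^ zlib.crc32(stage.encode())) % (2**31)


def _atomic_write(path: str, text: str) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _atomic(path: str, writer) -> str:
    tmp = path + ".tmp"
    writer(tmp)
    os.replace(tmp, path)
    return path


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Execute the configured stages in dependency order.

    Returns the manifest dict; on stage failure the manifest is still
    written with a failure marker and the exception re-raised.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: Dict[str, Any] = {
        "package": "breakspan",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "status": "running",
    }
    outputs: Dict[str, Any] = {}
    try:
        for stage in STAGE_ORDER:
            if stage not in config.stages:
                continue
            log.info("stage %s", stage)
            runner = globals()[f"_stage_{stage}"]
            stage_out = runner(config, outputs)
            manifest["stages"][stage] = {
                "seed": config.stage_seed(stage),
                "params": getattr(config, stage),
                "outputs": stage_out,
            }
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(config, manifest)
        raise
    for stage_info in manifest["stages"].values():
        for path in stage_info["outputs"].values():
            if isinstance(path, str) and os.path.exists(path):
                manifest["inputs"][path] = _sha256(path)
    _write_manifest(config, manifest)
    return manifest


def _write_manifest(config: RunConfig, manifest: Dict[str, Any]) -> None:
    _atomic_write(
        os.path.join(config.out_dir, "manifest.json"),
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
    )


def _out(config: RunConfig, name: str) -> str:
    return os.path.join(config.out_dir, name)


def _stage_simulate(config: RunConfig, outputs: Dict[str, Any]) -> Dict[str, str]:
    params = dict(config.simulate)
    params.setdefault("seed", config.stage_seed("simulate"))
    sim = SimulationConfig.from_dict(params)
    ref, sites = make_genome(sim)
    reads, truth = simulate_chip_reads(ref, sites, sim)
    paths = {
        "fasta": _atomic(_out(config, "genome.fa"), lambda p: write_fasta(ref, p)),
        "sites_bed": _atomic(_out(config, "sites.bed"), lambda p: write_sites_bed(sites, p)),
        "reads_bed": _atomic(_out(config, "reads.bed"), lambda p: write_intervals_bed(reads, p)),
        "truth_tsv": _atomic(_out(config, "truth.tsv"), lambda p: write_truth(truth, p)),
    }
    outputs.update(ref=ref, sites=sites, reads=reads, truth=truth, sim=sim)
    return paths


def _stage_sites(config: RunConfig, outputs: Dict[str, Any]) -> Dict[str, str]:
    from .formats_io import read_fasta

    params = config.sites
    motif = params.get("motif", "GCGATCGC")
    if params.get("fasta"):
        ref = read_fasta(params["fasta"])
    elif "ref" in outputs:
        ref = outputs["ref"]
    else:
        raise PipelineError("sites stage needs a fasta input or a prior simulate stage")
    sites = scan_motif(ref, motif)
    path = _atomic(_out(config, "scanned_sites.bed"), lambda p: write_sites_bed(sites, p))
    outputs.setdefault("ref", ref)
    outputs["sites"] = sites
    return {"sites_bed": path}


def _load_reads(path_or_none, outputs, dialect="bed"):
    if path_or_none:
        return list(read_intervals(path_or_none, dialect))
    if "reads" in outputs:
        return outputs["reads"]
    raise PipelineError("no reads available: give a path or run simulate first")


def _load_sites(path_or_none, outputs):
    if path_or_none:
        return read_sites_bed(path_or_none)
    if "sites" in outputs:
        return outputs["sites"]
    raise PipelineError("no sites available: give a path or run simulate/sites first")


def _stage_profile(config: RunConfig, outputs: Dict[str, Any]) -> Dict[str, str]:
    params = config.profile
    flank = int(params.get("flank", 1000))
    bin_size = int(params.get("bin_size", 10))
    top_n = int(params.get("top_n", 300))
    reads = _load_reads(params.get("reads"), outputs, params.get("dialect", "bed"))
    sites = _load_sites(params.get("sites"), outputs)
    if "ref" in outputs:
        lengths = outputs["ref"].lengths
    else:
        lengths = {}
        for r in reads:
            lengths[r.contig] = max(lengths.get(r.contig, 0), r.end)
    track = compute_coverage(reads, lengths, bin_size)
    if params.get("target_total"):
        track = depth_normalize([track], float(params["target_total"]))[0]
    enr = site_enrichment(track, sites, flank)
    top = top_n_sites(enr, sites, top_n)
    prof = metaprofile(track, top, flank, bin_size)
    left, right = profile_halfwidth(prof)

    enr_df = pd.DataFrame(
        {"site_id": list(enr), "enrichment": list(enr.values())}
    ).sort_values("enrichment", ascending=False)
    prof_df = pd.DataFrame({"offset": prof.offsets, "mean_signal": prof.values})
    summary = {
        "n_sites": prof.n_sites,
        "n_dropped": prof.n_dropped,
        "left_halfwidth_bp": left,
        "right_halfwidth_bp": right,
        "flank": flank,
        "bin_size": bin_size,
        "top_n": top_n,
    }
    paths = {
        "coverage_bedgraph": _atomic(
            _out(config, "coverage.bedgraph"), lambda p: write_bedgraph(track, p)
        ),
        "enrichment_tsv": _atomic(
            _out(config, "enrichment.tsv"),
            lambda p: enr_df.to_csv(p, sep="\t", index=False),
        ),
        "metaprofile_tsv": _atomic(
            _out(config, "metaprofile.tsv"),
            lambda p: prof_df.to_csv(p, sep="\t", index=False),
        ),
        "profile_summary_json": _out(config, "profile_summary.json"),
    }
    _atomic_write(paths["profile_summary_json"], json.dumps(summary, indent=2) + "\n")
    outputs.update(track=track, enrichment=enr)
    return paths


def _simulate_second_experiment(config: RunConfig, outputs: Dict[str, Any]):
    """Experiment B for the span comparison, from config overrides."""
    base = outputs["sim"].to_dict()
    base.update(config.span.get("config_b", {}))
    base["seed"] = config.stage_seed("span") % (2**31)
    sim_b = SimulationConfig.from_dict(base)
    reads_b, _ = simulate_chip_reads(outputs["ref"], outputs["sites"], sim_b)
    return reads_b


def _stage_span(config: RunConfig, outputs: Dict[str, Any]) -> Dict[str, str]:
    params = config.span
    sites = _load_sites(params.get("sites"), outputs)
    reads_a = _load_reads(params.get("reads_a"), outputs)
    if params.get("reads_b"):
        reads_b = list(read_intervals(params["reads_b"]))
    elif "sim" in outputs:
        reads_b = _simulate_second_experiment(config, outputs)
    else:
        raise PipelineError("span stage needs reads_b or a prior simulate stage")

    top_sites = int(params.get("top_sites", 50))
    max_dist = float(params.get("max_dist", 5))
    n_bins = int(params.get("n_bins", 20))
    B = int(params.get("bootstraps", 1000))
    min_reads = int(params.get("min_reads", 1))
    flank = int(params.get("flank", 1000))

    enr = outputs.get("enrichment")
    if enr is None:
        lengths = outputs["ref"].lengths if "ref" in outputs else None
        if lengths is None:
            lengths = {}
            for r in reads_a:
                lengths[r.contig] = max(lengths.get(r.contig, 0), r.end)
        track = compute_coverage(reads_a, lengths, 10)
        enr = site_enrichment(track, sites, flank)

    vec_a, class_a = span_ratio_vector(reads_a, sites, enr, top_sites, max_dist, min_reads)
    vec_b, class_b = span_ratio_vector(reads_b, sites, enr, top_sites, max_dist, min_reads)
    result = bootstrap_ks_test(vec_a, vec_b, B, n_bins, seed=config.stage_seed("span"))

    span_df = pd.DataFrame(
        [
            {"experiment": label, "site_id": c.site_id, "n_span": c.n_span,
             "n_nospan": c.n_nospan, "ratio": c.ratio}
            for label, classes in (("a", class_a), ("b", class_b))
            for c in classes
        ]
    )
    paths = {
        "span_tsv": _atomic(
            _out(config, "span_ratios.tsv"),
            lambda p: span_df.to_csv(p, sep="\t", index=False),
        ),
        "span_result_json": _out(config, "span_result.json"),
    }
    _atomic_write(paths["span_result_json"], json.dumps(result.to_dict(), indent=2) + "\n")
    return paths


def _stage_correlate(config: RunConfig, outputs: Dict[str, Any]) -> Dict[str, str]:
    params = config.correlate
    sites = _load_sites(params.get("sites"), outputs)
    flank = int(params.get("flank", 1000))
    top_n = params.get("top_n")
    tracks: Dict[str, Any] = {}
    for name, path in (params.get("tracks") or {}).items():
        tracks[name] = read_bedgraph(path)
    if not tracks and "track" in outputs:
        tracks = {"self": outputs["track"]}
    if len(tracks) < 2:
        raise PipelineError("correlate stage needs at least 2 tracks")
    if top_n and "enrichment" in outputs:
        sites = top_n_sites(outputs["enrichment"], sites, int(top_n))
    matrix = build_matrix(tracks, sites, flank)
    corr = correlation_table(matrix)
    dend = cluster_factors(rank_transform(matrix))
    paths = {
        "matrix_tsv": _atomic(
            _out(config, "enrichment_matrix.tsv"), lambda p: matrix.to_csv(p, sep="\t")
        ),
        "correlations_tsv": _atomic(
            _out(config, "correlations.tsv"), lambda p: corr.to_csv(p, sep="\t", index=False)
        ),
        "dendrogram_newick": _out(config, "factors.nwk"),
    }
    _atomic_write(paths["dendrogram_newick"], dend.to_newick() + "\n")
    return paths
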