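"""Run configuration, input validation and pipeline orchestration.

A run is described by a single YAML/dict config (grid axes, thresholds,
replicate counts, master seed, stage selection) and produces a manifest
recording the package version, a hash of the semantically meaningful config
fields, the seeds used and every output file written — so a run is fully
self-describing and re-running the same config reproduces byte-identical
stochastic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import concordance, de, enrichment, io, power, resample, simulate

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_config"]

log = logging.getLogger("powerdeg")

STAGES = ("simulate", "power_grid", "de_test", "subsample_size", "subsample_depth", "permute_null", "enrich")


@dataclass
class RunConfig:
    """Structured configuration for a pipeline run."""

    out_dir: str = "powerdeg_run"
    seed: int | None = None
    stages: list = field(default_factory=lambda: list(STAGES))
    # inputs (optional; the simulate stage can provide counts/metadata)
    counts: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    bias: str | None = None
    # simulate stage
    simulate_params: dict = field(default_factory=dict)
    # power grid stage
    grid_axes: dict | None = None
    grid_alpha: float = 3.3e-6
    grid_w: float = 1.0
    # DE / calling thresholds
    adj_p_threshold: float = 0.05
    fc_threshold: float = 1.0
    # resampling design
    subsample_N: list = field(default_factory=lambda: list(range(3, 11)))
    thinning_ratios: list = field(default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 10)])
    n_reps: int = 1000
    # enrichment
    enrich_method: str = "hypergeometric"

    def semantic_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def validate_inputs(counts=None, metadata=None, gmt=None, bias=None):
    """Check input files for consistency; diagnostics, not exceptions.

    Returns ``{"ok": bool, "diagnostics": [str, ...]}``.
    """
    diags = []
    cm = None
    if counts is not None:
        try:
            cm = io.read_counts(counts, metadata)
        except (io.FormatError, FileNotFoundError, KeyError) as exc:
            diags.append(f"counts/metadata: {exc}")
    elif metadata is not None:
        try:
            io.read_metadata(metadata)
        except Exception as exc:  # noqa: BLE001
            diags.append(f"metadata: {exc}")
    if gmt is not None:
        try:
            ann = io.read_gmt(gmt)
            if not ann.terms:
                diags.append(f"gmt: {gmt} defines no terms")
        except (io.FormatError, FileNotFoundError) as exc:
            diags.append(f"gmt: {exc}")
    if bias is not None:
        try:
            io.read_bias_tsv(bias)
        except (io.FormatError, FileNotFoundError) as exc:
            diags.append(f"bias: {exc}")
    if cm is not None and not cm.samples_of("KO"):
        diags.append("counts/metadata: no KO samples")
    return {"ok": not diags, "diagnostics": diags}


def _write_report(reports, path, comments=()):
    frame = resample.report_frame(reports)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; return the manifest."""
    stochastic = {"simulate", "subsample_size", "subsample_depth", "permute_null"}
    if config.seed is None and stochastic & set(config.stages):
        raise ValueError("a master seed is required for stochastic stages")
    os.makedirs(config.out_dir, exist_ok=True)
    from importlib.metadata import version

    try:
        pkg_version = version("powerdeg")
    except Exception:  # noqa: BLE001
        pkg_version = "unknown"
    manifest = {
        "version": pkg_version,
        "config_hash": config.semantic_hash(),
        "config": asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    provenance = [f"config_hash={config.semantic_hash()}", f"seed={config.seed}"]

    def out(name):
        path = os.path.join(config.out_dir, name)
        return path

    def done(stage, outputs):
        manifest["stages"][stage] = {"outputs": outputs}
        log.info("stage %s complete: %s", stage, outputs)

    cm = None
    if config.counts:
        cm = io.read_counts(config.counts, config.metadata)

    try:
        if "simulate" in config.stages:
            params = dict(config.simulate_params)
            cm, truth = simulate.generate(seed=config.seed, **params)
            cpath, mpath, tpath = out("counts.tsv"), out("metadata.tsv"), out("truth.tsv")
            io.write_counts(cm, cpath, mpath, comments=provenance)
            with open(tpath, "w") as fh:
                for line in provenance:
                    fh.write(f"# {line}\n")
                truth.rename_axis("gene_id").to_csv(fh, sep="\t")
            done("simulate", [cpath, mpath, tpath])

        if "power_grid" in config.stages:
            grid = power.traverse_grid(config.grid_axes, config.grid_alpha, config.grid_w)
            gpath = out("power_grid.tsv")
            with open(gpath, "w") as fh:
                for line in provenance + [
                    f"axes={json.dumps(grid.axes)}",
                    f"alpha={grid.alpha}",
                    f"w={grid.w}",
                ]:
                    fh.write(f"# {line}\n")
                grid.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            done("power_grid", [gpath])

        needs_counts = {"de_test", "subsample_size", "subsample_depth", "permute_null", "enrich"}
        if needs_counts & set(config.stages) and cm is None:
            raise RuntimeError(
                "stage requires counts: provide input paths or enable the simulate stage"
            )

        de_result = None
        if "de_test" in config.stages:
            de_result = de.de_test(cm)
            dpath, degpath = out("de.tsv"), out("degs.tsv")
            with open(dpath, "w") as fh:
                for line in provenance:
                    fh.write(f"# {line}\n")
                de_result.rename_axis("gene_id").to_csv(fh, sep="\t")
            degs = de.call_degs(
                de_result, config.adj_p_threshold, config.fc_threshold, analysis_id="full"
            )
            io.write_degs(degs, degpath, comments=provenance)
            done("de_test", [dpath, degpath])

        if "subsample_size" in config.stages:
            reports = []
            for N in config.subsample_N:
                log.info("subsample_size N=%d reps=%d seed=%s", N, config.n_reps, config.seed)
                reports += resample.subsample_samples(
                    cm, N, config.n_reps, config.seed,
                    config.adj_p_threshold, config.fc_threshold,
                )
            path = out("subsample_size.tsv")
            _write_report(reports, path, comments=provenance)
            done("subsample_size", [path])

        if "subsample_depth" in config.stages:
            reports = []
            for ratio in config.thinning_ratios:
                log.info("subsample_depth r=%s reps=%d seed=%s", ratio, config.n_reps, config.seed)
                reports += resample.thin_depth(
                    cm, ratio, config.n_reps, config.seed,
                    config.adj_p_threshold, config.fc_threshold,
                )
            path = out("subsample_depth.tsv")
            _write_report(reports, path, comments=provenance)
            done("subsample_depth", [path])

        if "permute_null" in config.stages:
            reports, summary = resample.permutation_null(
                cm, config.n_reps, config.seed,
                config.adj_p_threshold, config.fc_threshold,
            )
            rpath, spath = out("permutation.tsv"), out("permutation_summary.json")
            _write_report(reports, rpath, comments=provenance)
            with open(spath, "w") as fh:
                json.dump(summary, fh, indent=2, default=str)
            done("permute_null", [rpath, spath])

        if "enrich" in config.stages:
            if config.gmt is None:
                raise RuntimeError("enrich stage requires a gmt annotation file")
            if de_result is None:
                raise RuntimeError("enrich stage requires the de_test stage")
            ann = io.read_gmt(config.gmt)
            if config.bias:
                ann.bias = io.read_bias_tsv(config.bias)
            elif config.enrich_method == "wallenius":
                ann.bias = dict(zip(de_result.index, np.maximum(de_result["base_mean"], 1e-6)))
            universe = list(de_result.index[de_result["status"] == "tested"])
            degs = de.call_degs(de_result, config.adj_p_threshold, config.fc_threshold)
            enr = enrichment.enrich(degs, universe, ann, method=config.enrich_method)
            epath = out("enrichment.tsv")
            with open(epath, "w") as fh:
                for line in provenance:
                    fh.write(f"# {line}\n")
                enr.table.to_csv(fh, sep="\t")
            done("enrich", [epath])
    finally:
        mpath = os.path.join(config.out_dir, "manifest.json")
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest


def concordance_summary(degs_a: de.DEGSet, degs_b: de.DEGSet, universe_size=None) -> dict:
    """JSON-ready overlap summary of two DEG lists (direction-matched)."""
    shared = concordance.shared_degs(degs_a, degs_b)
    expected = None
    if universe_size:
        dA = sum(1 for _, d in degs_a.members if d == "down")
        uA = len(degs_a) - dA
        dB = sum(1 for _, d in degs_b.members if d == "down")
        uB = len(degs_b) - dB
        expected = concordance.expected_shared(universe_size, dA, uA, dB, uB)
    return {
        "size_a": len(degs_a),
        "size_b": len(degs_b),
        "observed_shared": len(shared),
        "expected_shared": expected,
    }
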