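"""End-to-end orchestration: train -> simulate -> score -> evaluate.

A single YAML config names the input files and the GA knobs; a run writes
trained ensembles, response and synergy tables, an optional benchmark
report and a ``manifest.json`` holding the config snapshot, master seed,
input checksums, package version and per-stage timings — enough to
reproduce any output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
import yaml

from . import __version__
from .evaluation import benchmark
from .evolution import GAConfig, evolve
from .io import (
    read_calibration,
    read_drug_panel,
    read_gold_standard,
    read_output_spec,
    read_perturbations,
    read_sif,
    write_ensemble,
)
from .synergy import (
    Perturbation,
    all_perturbations,
    normalize,
    sample_proliferative_profile,
    score_all_pairs,
    simulate_ensemble,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure, prefixed with the stage name."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    lines = ["\t".join(header)]
    lines.extend("\t".join("" if v is None else str(v) for v in row)
                 for row in rows)
    path.write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    if not isinstance(config, dict):
        raise PipelineError("config: top level must be a mapping")
    for key in ("network", "calibration", "drug_panel", "outputs", "out"):
        if key not in config:
            raise PipelineError(f"config: missing required key {key!r}")
    return config


def run_pipeline(config_path: str | Path) -> Path:
    """Run the whole pipeline from a YAML config; returns the output dir."""
    config_path = Path(config_path)
    config = load_config(config_path)
    base = config_path.parent

    def resolve(key: str) -> Path:
        p = Path(config[key])
        return p if p.is_absolute() else base / p

    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # --- stage: inputs ----------------------------------------------------
    try:
        network = read_sif(resolve("network"))
        profile = read_calibration(resolve("calibration"), network)
        panel = read_drug_panel(resolve("drug_panel"))
        panel.validate_against(network)
        outputs = read_output_spec(resolve("outputs"))
        if "perturbations" in config:
            perts = [Perturbation(p) for p in
                     read_perturbations(resolve("perturbations"))]
        else:
            perts = all_perturbations(panel)
        gold = (read_gold_standard(resolve("gold"))
                if "gold" in config else None)
    except Exception as exc:
        raise PipelineError(f"inputs: {exc}") from exc
    timings["inputs"] = time.perf_counter() - t0

    seed = int(config.get("seed", 0))
    ga_kwargs = dict(config.get("ga", {}))
    ga_kwargs["seed"] = seed
    ga = GAConfig(**ga_kwargs)

    out_dir = Path(config["out"])
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage: training --------------------------------------------------
    t0 = time.perf_counter()
    try:
        calibrated = evolve(network, profile, ga)

        def sampler(e: int):
            import numpy as np
            return sample_proliferative_profile(
                outputs, np.random.default_rng([seed, 1, e])
            )

        baseline = evolve(
            network, sampler, dataclasses.replace(ga, seed=seed + 1)
        )
    except Exception as exc:
        raise PipelineError(f"training: {exc}") from exc
    write_ensemble(calibrated.models, out_dir / "models_calibrated", seed=seed)
    write_ensemble(baseline.models, out_dir / "models_random", seed=seed + 1)
    _write_tsv(
        out_dir / "training_log.tsv",
        ["evolution", "generation", "best_fitness", "mean_fitness",
         "sd_fitness"],
        [[r["evolution"], r["generation"], r["best_fitness"],
          r["mean_fitness"], r["sd_fitness"]] for r in calibrated.training_log],
    )
    timings["training"] = time.perf_counter() - t0

    # --- stage: simulation ------------------------------------------------
    t0 = time.perf_counter()
    try:
        resp_cal = simulate_ensemble(calibrated.models, perts, panel, outputs)
        resp_base = simulate_ensemble(baseline.models, perts, panel, outputs)
    except Exception as exc:
        raise PipelineError(f"simulation: {exc}") from exc
    for name, resp in (("responses_calibrated.tsv", resp_cal),
                       ("responses_random.tsv", resp_base)):
        _write_tsv(
            out_dir / name,
            ["perturbation", "growth", "models_used", "models_excluded"],
            [[p, e.growth, e.models_used, e.models_excluded]
             for p, e in sorted(resp.items())],
        )
    timings["simulation"] = time.perf_counter() - t0

    # --- stage: scoring ---------------------------------------------------
    t0 = time.perf_counter()
    scores_cal = score_all_pairs(resp_cal, perts)
    scores_base = score_all_pairs(resp_base, perts)
    normalized = normalize(scores_cal, scores_base)
    _write_tsv(
        out_dir / "synergies.tsv",
        ["drug_a", "drug_b", "observed", "expected", "excess", "normalized",
         "call"],
        [[a, b, r.observed, r.expected, r.excess,
          normalized[(a, b)].normalized if (a, b) in normalized else None,
          r.call]
         for (a, b), r in sorted(scores_cal.items())],
    )
    timings["scoring"] = time.perf_counter() - t0

    # --- stage: evaluation (optional) ------------------------------------
    report = None
    if gold is not None:
        t0 = time.perf_counter()
        try:
            ranked = {p: r.normalized for p, r in normalized.items()}
            result = benchmark(ranked, gold)
        except Exception as exc:
            raise PipelineError(f"evaluation: {exc}") from exc
        _write_tsv(
            out_dir / "aucs.tsv",
            ["metric", "auc", "n_pos", "n_neg"],
            [["roc", result.roc_auc, result.n_pos, result.n_neg],
             ["pr", result.pr_auc, result.n_pos, result.n_neg]],
        )
        _write_tsv(
            out_dir / "curves.tsv",
            ["curve", "x", "y"],
            [["roc", x, y] for x, y in result.roc_points]
            + [["pr", x, y] for x, y in result.pr_points],
        )
        report = {"roc_auc": result.roc_auc, "pr_auc": result.pr_auc}
        timings["evaluation"] = time.perf_counter() - t0

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {
            key: _sha256(resolve(key))
            for key in ("network", "calibration", "drug_panel", "outputs",
                        "perturbations", "gold")
            if key in config
        },
        "counts": {
            "models_calibrated": len(calibrated.models),
            "models_random": len(baseline.models),
            "perturbations": len(perts),
            "pairs_scored": len(scores_cal),
            "pairs_ranked": len(normalized),
        },
        "benchmark": report,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out_dir
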