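"""End-to-end analysis pipeline driven by one YAML config.

Stages run in a fixed order -- input (read or simulate), QC filters,
population frequencies and blocks, D-statistic batteries, admixture-graph
scenario comparison, and geographic interpolation of the regional test
scores -- each writing its outputs before the next begins.  A manifest
records the seed, per-stage row counts and SHA-256 checksums of every
output file, so a rerun with the same config is verifiably identical.

The global seed is expanded per stage by fixed offsets, making every
stage individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .batteries import REGIONAL_TESTS, australasian_battery, regional_battery
from .genotype_io import read_genotypes, read_panel, write_table
from .geo_idw import idw_interpolate, panel_points
from .popfreq import assign_blocks, population_counts
from .qc_filters import (
    FilterConfig,
    filter_samples_by_ancestry,
    filter_variants,
    read_ancestry_table,
)
from .admixgraph import compare_scenarios
from .synthdata import default_scenario_config, scenario_spec, simulate_dataset

log = logging.getLogger("admixkit.pipeline")

# per-stage offsets applied to the global seed
_STAGE_SEEDS = {"simulate": 0, "scenarios": 1}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: str | Path | dict[str, Any]) -> dict[str, Any]:
    """Run the configured stages; returns the manifest (also written as JSON).

    See ``examples/run_pipeline.py`` for a complete config. Top-level keys:
    ``seed``, ``output_dir``, ``input`` (either ``simulate: {scenario, ...}``
    or ``genotypes``/``format``/``panel``/``ancestry`` paths), ``filters``,
    ``block_size``, ``battery`` (``australasian`` and/or ``regional``
    sections), ``scenarios`` (list of ids), and ``idw``.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("output_dir", "admixkit_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.get("log_level", "INFO"))
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "stages": [],
        "counts": {},
        "outputs": {},
    }
    manifest_path = out_dir / "manifest.json"

    def record(stage: str, **counts: Any) -> None:
        manifest["stages"].append(stage)
        manifest["counts"].update({f"{stage}.{k}": v for k, v in counts.items()})
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        write_table(frame, path)
        manifest["outputs"][name] = _sha256(path)

    stage = "input"
    try:
        spec = config["input"]
        if "simulate" in spec:
            sim = dict(spec["simulate"])
            scenario = int(sim.pop("scenario", 1))
            cfg = default_scenario_config(
                scenario, seed=seed + _STAGE_SEEDS["simulate"], **sim
            )
            g, panel, _ = simulate_dataset(cfg)
        else:
            panel = read_panel(spec["panel"])
            haploid = [
                s for s in panel.samples
                if panel.table.at[s, "age_class"] == "ancient"
            ] if spec.get("format") == "eigenstrat" else ()
            g = read_genotypes(
                spec["genotypes"], spec.get("format", "vcf"), haploid_samples=haploid
            )
        log.info("input: %d samples x %d variants", g.n_samples, g.n_variants)
        record(stage, samples=g.n_samples, variants=g.n_variants)

        stage = "qc"
        fspec = dict(config.get("filters", {}))
        apply_maf = bool(fspec.pop("apply_maf", False))
        ancestry_path = config.get("input", {}).get("ancestry")
        fcfg = FilterConfig(**fspec)
        n0 = g.n_variants
        g = filter_variants(g, fcfg, apply_maf=apply_maf)
        s0 = g.n_samples
        if ancestry_path:
            anc = read_ancestry_table(ancestry_path)
            g = filter_samples_by_ancestry(g, panel, anc, fcfg)
        log.info(
            "qc: %d -> %d variants, %d -> %d samples",
            n0, g.n_variants, s0, g.n_samples,
        )
        record(
            stage,
            variants_in=n0, variants_out=g.n_variants,
            samples_in=s0, samples_out=g.n_samples,
        )

        stage = "frequencies"
        freq = population_counts(g, panel)
        blocks = assign_blocks(g.variants, int(config.get("block_size", 100)))
        record(stage, populations=len(freq.populations), blocks=blocks.n_blocks)

        stage = "batteries"
        battery_cfg = config.get("battery", {})
        regional_summaries: dict[str, pd.DataFrame] = {}
        if "australasian" in battery_cfg:
            a = battery_cfg["australasian"]
            rows = australasian_battery(
                freq, blocks, panel,
                test_pops=a["test_pops"],
                aus_pops=a.get("aus_pops"),
                outgroup=a.get("outgroup", "Mbuti"),
                anchor=a.get("anchor", "Mixe"),
            )
            emit("battery_australasian.tsv", pd.DataFrame([r.to_row() for r in rows]))
        if "regional" in battery_cfg:
            r = battery_cfg["regional"]
            for label in r.get("tests", ["A", "B", "C"]):
                tspec = REGIONAL_TESTS[label]
                results, summary = regional_battery(
                    freq, blocks, panel, tspec, r["test_pops"],
                    outgroup=r.get("outgroup"),
                )
                emit(
                    f"battery_regional_{label}.tsv",
                    pd.DataFrame([x.to_row() for x in results]),
                )
                emit(f"battery_regional_{label}_summary.tsv", summary)
                regional_summaries[label] = summary
        record(stage, tests=len(battery_cfg))

        stage = "scenarios"
        if "scenarios" in config:
            sc = config["scenarios"]
            specs = [
                scenario_spec(i, sc.get("candidates")) for i in sc.get("ids", [1, 2, 3])
            ]
            table, summary = compare_scenarios(
                specs, freq, blocks,
                seed=seed + _STAGE_SEEDS["scenarios"],
                n_restarts=int(sc.get("n_restarts", 10)),
            )
            emit("scenario_fits.tsv", table)
            emit("scenario_summary.tsv", summary)
            record(stage, fits=len(table))
        else:
            record(stage, fits=0)

        stage = "idw"
        if regional_summaries and "idw" in config:
            icfg = config["idw"]
            for label, summary in regional_summaries.items():
                scores = dict(
                    zip(summary["test_population"], summary["median_z"])
                )
                pts = panel_points(panel, scores)
                if not pts:
                    continue
                grid = idw_interpolate(
                    pts,
                    spacing=float(icfg.get("spacing", 0.5)),
                    power=float(icfg.get("power", 2.0)),
                    padding=float(icfg.get("padding", 2.0)),
                )
                emit(f"idw_test_{label}.tsv", grid.to_frame())
        record(stage, grids=len(regional_summaries))
    except PipelineError:
        raise
    except Exception as exc:  # partial manifest stays on disk for diagnosis
        manifest["failed_stage"] = stage
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise PipelineError(stage, exc) from exc

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
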