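"""Reproducible end-to-end pipeline with configuration and manifest.

A run either simulates a study (``simulate`` block in the config) or
loads measurement tables, then executes interactions → traits →
decomposition → report, writing every stage table with a provenance
header and a JSON manifest of input checksums, config echo, package
version and per-stage row counts.  Identical config + seed reproduce
identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, design, partition, report, simulate, supernatant, workflows
from ._io import config_hash, file_sha256, read_csv, write_csv

log = logging.getLogger("commfun")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "commfun_out"
    seed: int = 0
    simulate: dict | None = None  # GeneratorConfig fields; None = load inputs
    strains_csv: str | None = None
    supernatant_csv: str | None = None
    competitions_csv: str | None = None
    alpha: float = supernatant.DEFAULT_ALPHA
    aggregate: str = "median"
    transform: str = "none"
    responses: tuple[str, ...] = ("productivity", "pyoverdine")
    variants: tuple[str, ...] = partition.VARIANTS
    replicate_level: bool = True
    endpoint_timepoint_h: float = 24.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown keys {sorted(unknown)}")
        for key in ("responses", "variants"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "simulate": self.simulate,
            "strains_csv": self.strains_csv,
            "supernatant_csv": self.supernatant_csv,
            "competitions_csv": self.competitions_csv,
            "alpha": self.alpha,
            "aggregate": self.aggregate,
            "transform": self.transform,
            "responses": list(self.responses),
            "variants": list(self.variants),
            "replicate_level": self.replicate_level,
            "endpoint_timepoint_h": self.endpoint_timepoint_h,
        }


def _load_inputs(config: PipelineConfig):
    for name in ("strains_csv", "supernatant_csv", "competitions_csv"):
        path = getattr(config, name)
        if path is None:
            raise PipelineError("load", f"{name} not set and no simulate block given")
        if not Path(path).exists():
            raise PipelineError("load", f"missing input file {path}")
    strains = read_csv(config.strains_csv)
    strain_objs = design.strains_from_frame(strains, strict=True)
    combos = []
    for cid in sorted({s.community_id for s in strain_objs}):
        comm = [s for s in strain_objs if s.community_id == cid]
        combos.extend(design.enumerate_combinations(comm, 1, len(comm)))
    return (
        strains,
        read_csv(config.supernatant_csv),
        read_csv(config.competitions_csv),
        combos,
        {
            name: file_sha256(getattr(config, name))
            for name in ("strains_csv", "supernatant_csv", "competitions_csv")
        },
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash the analysis-relevant config only: where outputs land must not
    # change what they contain
    hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    cfg_hash = config_hash(hashed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "stages": {},
        "inputs": {},
    }

    def _write(df: pd.DataFrame, name: str, stage: str) -> None:
        write_csv(df, out / name, seed=config.seed, cfg_hash=cfg_hash)
        manifest["stages"].setdefault(stage, {})[name] = len(df)

    # --- simulate or load ---------------------------------------------------
    if config.simulate is not None:
        gen_fields = dict(config.simulate)
        gen_fields.setdefault("seed", config.seed)
        try:
            gen_cfg = simulate.GeneratorConfig.from_dict(gen_fields)
            study = simulate.generate_study(gen_cfg)
        except (TypeError, simulate.ConfigError) as err:
            raise PipelineError("simulate", str(err)) from err
        strains, sn_meas, comp_meas = study.strains, study.supernatant, study.competitions
        combos = design.combinations_from_frame(study.combinations)
        _write(strains, "strains.csv", "simulate")
        _write(study.combinations, "combinations.csv", "simulate")
        _write(sn_meas, "supernatant.csv", "simulate")
        _write(comp_meas, "competitions.csv", "simulate")
        study.truth.to_json(out / "truth.json")
        log.info("simulate: %d strains, %d combinations", len(strains), len(combos))
    else:
        strains, sn_meas, comp_meas, combos, checksums = _load_inputs(config)
        manifest["inputs"] = checksums
        _write(design.combinations_to_frame(combos), "combinations.csv", "load")
        log.info("load: %d strains, %d combinations", len(strains), len(combos))

    # --- interactions + traits ---------------------------------------------
    try:
        analysis = workflows.analyze_measurements(
            sn_meas,
            comp_meas,
            combos,
            alpha=config.alpha,
            aggregate=config.aggregate,
            endpoint_timepoint_h=config.endpoint_timepoint_h,
        )
    except supernatant.SupernatantError as err:
        raise PipelineError("interactions", str(err)) from err
    _write(analysis.effects, "interactions.csv", "interactions")
    _write(analysis.summaries, "summaries.csv", "interactions")
    _write(analysis.traits.aggregated, "traits.csv", "traits")
    _write(analysis.traits.replicates, "traits_replicates.csv", "traits")
    log.info(
        "interactions: %d directed effects; traits: %d combinations",
        len(analysis.effects),
        len(analysis.traits.aggregated),
    )

    # --- decomposition -------------------------------------------------------
    results = []
    for response in config.responses:
        try:
            results.extend(
                workflows.decompose_all(
                    analysis,
                    response=response,
                    variants=tuple(config.variants),
                    replicate_level=config.replicate_level,
                    transform=config.transform,
                )
            )
        except partition.PartitionError as err:
            raise PipelineError("decompose", f"response {response!r}: {err}") from err
    _write(partition.decomposition_frame(results), "decomposition.csv", "decompose")
    _write(partition.coefficients_frame(results), "coefficients.csv", "decompose")

    # --- report --------------------------------------------------------------
    prod_results = [r for r in results if r.response == "productivity"]
    tables = report.report_summary(
        prod_results or results,
        analysis.traits.aggregated,
        analysis.summaries,
        strains,
        out_dir=out / "figures",
    )
    _write(tables.mean_square_summary, "mean_square_summary.csv", "report")
    _write(tables.type_coefficients, "type_coefficients.csv", "report")
    if tables.dev_regression is not None:
        manifest["stages"]["report"]["dev_regression"] = {
            "slope": tables.dev_regression.slope,
            "stderr": tables.dev_regression.stderr,
            "t": tables.dev_regression.tvalue,
            "p": tables.dev_regression.pvalue,
            "n": tables.dev_regression.n,
        }

    manifest["outputs"] = {
        p.name: file_sha256(p) for p in sorted(out.glob("*.csv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
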