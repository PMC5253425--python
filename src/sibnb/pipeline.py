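"""Configuration, validation and the simulate -> reconstruct -> estimate ->
evaluate pipeline with a reproducibility manifest.

A single TOML file drives a run; every source of randomness is derived from
one top-level seed through stage-keyed substreams, so reruns with the same
config and seed are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .data import MATING_SYSTEMS
from .estimators import estimates_record, write_best_cluster
from .evaluate import SubsampleDesign, sa_pwop_concordance, subsample_experiment
from .io import (
    jsonable,
    write_colony_genotypes,
    write_genotypes,
    write_pedigree,
    write_truth_json,
)
from .recon import ReconConfig, reconstruct
from .sim import SimConfig, simulate_genotypes, simulate_pedigree
from .truth import truth_summary


class ConfigError(ValueError):
    pass


_SIM_KEYS = {
    "n_females", "n_males", "total_offspring", "male_reuse_rate",
    "contamination_rate", "fecundity_dispersion", "n_loci", "maf_low",
    "maf_high", "error_rate", "missing_rate", "seed",
}
_RECON_KEYS = {
    "mating_system", "error_rate", "seed", "restarts", "sweeps", "cooling",
    "initial_temperature", "max_component_parents", "allow_approximate",
}
_EST_KEYS = {"method"}
_EVAL_KEYS = {"mode", "fractions", "replicates", "method"}
_RUN_KEYS = {"stages", "seed"}
_SECTIONS = {
    "simulate": _SIM_KEYS,
    "reconstruct": _RECON_KEYS,
    "estimate": _EST_KEYS,
    "evaluate": _EVAL_KEYS,
    "run": _RUN_KEYS,
}
_ALIASES = {"mono": "monogamy", "mpfm": "male_polygamy_female_monogamy", "poly": "polygamy"}


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def validate_config(config: dict | str | Path) -> list[dict]:
    """Schema / range checks. Unknown keys are errors; deliberate crossings
    (assumed vs simulated error rate) are warnings. Returns the issue list."""
    if not isinstance(config, dict):
        config = load_config(config)
    issues: list[dict] = []
    unknown_sections = set(config) - set(_SECTIONS)
    if unknown_sections:
        raise ConfigError(f"unknown config sections: {sorted(unknown_sections)}")
    for section, keys in _SECTIONS.items():
        present = config.get(section, {})
        unknown = set(present) - keys
        if unknown:
            raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
    sim = config.get("simulate", {})
    if sim:
        try:
            _sim_config(sim, seed=0).validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
    rec = config.get("reconstruct", {})
    if rec:
        try:
            _recon_config(rec, seed=0).validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
    if sim and rec:
        e_sim = sim.get("error_rate", SimConfig(2, 2, 2).error_rate)
        e_rec = rec.get("error_rate", ReconConfig().error_rate)
        if e_sim != e_rec:
            issues.append(
                {
                    "level": "warning",
                    "message": f"assumed error rate {e_rec} differs from simulated {e_sim} "
                    "(intentional crossings are part of the evaluation design)",
                }
            )
    return issues


def _sim_config(section: dict, seed: int | None) -> SimConfig:
    kwargs = dict(section)
    kwargs.setdefault("seed", seed)
    if "fecundity_dispersion" in kwargs and kwargs["fecundity_dispersion"] == "inf":
        kwargs["fecundity_dispersion"] = float("inf")
    return SimConfig(**kwargs)


def _recon_config(section: dict, seed: int | None) -> ReconConfig:
    kwargs = dict(section)
    kwargs.setdefault("seed", seed)
    if "mating_system" in kwargs:
        kwargs["mating_system"] = _ALIASES.get(kwargs["mating_system"], kwargs["mating_system"])
        if kwargs["mating_system"] not in MATING_SYSTEMS:
            raise ConfigError(f"unknown mating system {kwargs['mating_system']!r}")
    return ReconConfig(**kwargs)


def _stage_seed(seed: int | None, stage: int) -> int | None:
    if seed is None:
        return None
    state = np.random.SeedSequence([int(seed), stage]).generate_state(1)
    return int(state[0]) % 2**31


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, digests, timings."""

    config: dict
    seed: int | None
    version: str = __version__
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(jsonable(self.__dict__), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: dict | str | Path,
    out_dir,
    seed: int | None = None,
    stages: list[str] | None = None,
) -> RunManifest:
    """Execute the configured stages in order, writing outputs and a manifest.

    Stage randomness comes from stage-keyed substreams of the single
    top-level seed (CLI/argument seed overrides the config's [run] seed).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_section = config.get("run", {})
    if seed is None:
        seed = run_section.get("seed")
    if stages is None:
        stages = run_section.get("stages", ["simulate", "reconstruct", "estimate", "evaluate"])
    manifest = RunManifest(config=config, seed=seed)

    state: dict = {}
    try:
        for stage in stages:
            t0 = time.perf_counter()
            _STAGES[stage](config, out, seed, state, manifest)
            manifest.timings[stage] = time.perf_counter() - t0
            manifest.stages.append(stage)
    except Exception as exc:  # record partial state, then re-raise
        manifest.failed_stage = stage
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(out / "manifest.json")
        raise
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.outputs[p.name] = _digest(p)
    manifest.write(out / "manifest.json")
    return manifest


def _stage_simulate(config, out, seed, state, manifest):
    sim = _sim_config(config.get("simulate", {}), seed=_stage_seed(seed, 0))
    ped = simulate_pedigree(sim)
    gt = simulate_genotypes(ped, sim)
    state["pedigree"], state["genotypes"] = ped, gt
    state["true_nb"] = truth_summary(ped)["true_nb"]
    write_pedigree(ped, out / "pedigree.csv", out / "roster.csv")
    write_genotypes(gt, out / "genotypes.csv")
    write_colony_genotypes(gt, out / "genotypes.colony.txt")
    write_truth_json(jsonable(truth_summary(ped)), out / "truth.json")


def _stage_reconstruct(config, out, seed, state, manifest):
    if "genotypes" not in state:
        raise ConfigError("reconstruct stage requires a simulate stage (or explicit genotypes)")
    rc = _recon_config(config.get("reconstruct", {}), seed=_stage_seed(seed, 1))
    part = reconstruct(state["genotypes"], rc)
    state["partition"] = part
    write_best_cluster(part, out / "partition.bestcluster.txt")


def _stage_estimate(config, out, seed, state, manifest):
    if "partition" not in state:
        raise ConfigError("estimate stage requires a reconstruct stage")
    method = config.get("estimate", {}).get("method", "both")
    record = estimates_record(state["partition"], state.get("genotypes"), method=method)
    if "true_nb" in state:
        record["true_nb"] = state["true_nb"]
    with open(out / "estimates.json", "w") as fh:
        json.dump(jsonable(record), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage_evaluate(config, out, seed, state, manifest):
    section = config.get("evaluate", {})
    mode = section.get("mode", "none")
    if mode == "none":
        return
    if "genotypes" not in state:
        raise ConfigError("evaluate stage requires a simulate stage")
    rc = _recon_config(config.get("reconstruct", {}), seed=_stage_seed(seed, 2))
    if mode == "subsample":
        design = SubsampleDesign(
            fractions=tuple(section.get("fractions", SubsampleDesign().fractions)),
            replicates=section.get("replicates", 10),
            seed=_stage_seed(seed, 3),
        )
        true_nb = state["true_nb"]
        if not isinstance(true_nb, (int, float)):
            raise ConfigError("true Nb is infinite; subsample evaluation undefined")
        table = subsample_experiment(
            state["genotypes"], float(true_nb), design, rc,
            method=section.get("method", "sa"),
        )
        table.to_csv(out / "subsample.csv", index=False)
    elif mode == "concordance":
        if "partition" not in state:
            raise ConfigError("concordance evaluation requires a reconstruct stage")
        result = sa_pwop_concordance([(state["partition"], state["genotypes"])])
        result.table.to_csv(out / "concordance.csv", index=False)
    else:
        raise ConfigError(f"unknown evaluate mode {mode!r}")


_STAGES = {
    "simulate": _stage_simulate,
    "reconstruct": _stage_reconstruct,
    "estimate": _stage_estimate,
    "evaluate": _stage_evaluate,
}
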