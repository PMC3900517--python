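"""Declarative configuration, result serialization, and the run manifest.

A run is fully determined by a flat YAML config (generator parameters,
decoder choices, the analysis to run, and one master seed); outputs are
tidy CSV tables plus a JSON summary, written next to a manifest recording
the config hash, package/library versions and the master seed so any
result file can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import popdecode
from popdecode.classifiers import DecoderSpec
from popdecode.experiments import (
    DEFAULT_IMBALANCE_GRID,
    DEFAULT_SIZE_GRID,
    DEFAULT_SWEEP_KINDS,
    DEFAULT_TRIAL_GRID,
    compare_decoders,
    memory_analysis,
    sweep_imbalance,
    sweep_joint,
    sweep_population_size,
    sweep_trial_number,
)
from popdecode.synth import GeneratorConfig, generate_dataset

REQUIRED_KEYS = ("seed", "out_dir")
_FLOAT_FORMAT = "%.17g"  # full float64 round-trip precision


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    for key in REQUIRED_KEYS:
        if key not in config:
            raise ValueError(f"config is missing required key: {key!r}")


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> Path:
    """One CSV per table plus a summary.json; values round-trip bit-exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, list] = {}
    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.csv", index=False, float_format=_FLOAT_FORMAT)
        summary[name] = json.loads(table.to_json(orient="records"))
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return out_dir


def read_results(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    out_dir = Path(out_dir)
    return {p.stem: pd.read_csv(p) for p in sorted(out_dir.glob("*.csv"))}


def _manifest(config: dict) -> dict:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config": config,
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "seed": config["seed"],
        "versions": {
            "popdecode": popdecode.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }


def _decoder_specs(config: dict) -> list[DecoderSpec]:
    entries = config.get("decoders", list(DEFAULT_SWEEP_KINDS))
    specs = []
    for entry in entries:
        if isinstance(entry, str):
            specs.append(DecoderSpec(entry, rng_seed=config["seed"]))
        else:
            specs.append(
                DecoderSpec(
                    entry["kind"],
                    params=entry.get("params", {}),
                    rng_seed=entry.get("rng_seed", config["seed"]),
                )
            )
    return specs


def run_from_config(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the configured analysis; outputs are a pure function of the
    config.  Returns the results directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    out_dir = Path(out_dir or config["out_dir"])
    seed = int(config["seed"])
    gen_kwargs = dict(config.get("generator", {}))
    variable = config.get("variable", "endogenous")
    gen_kwargs.setdefault("rng_seed", seed)
    if "variable_preset" in gen_kwargs:
        preset = gen_kwargs.pop("variable_preset")
        gcfg = GeneratorConfig.for_variable(preset, **gen_kwargs)
    else:
        gcfg = GeneratorConfig(**gen_kwargs)
    dataset = generate_dataset(gcfg)
    specs = _decoder_specs(config)
    n_seeds = int(config.get("n_seeds", 20))
    n_perm = int(config.get("n_perm", 50))
    analysis = config.get("analysis", "none")

    tables: dict[str, pd.DataFrame] = {}
    tables["compare"] = compare_decoders(
        dataset, specs, variable, cell_subset=config.get("cell_subset", "all"),
        master_seed=seed, n_seeds=n_seeds, n_perm=n_perm,
    )
    if analysis == "size":
        tables["size_sweep"] = sweep_population_size(
            dataset, specs[0], sizes=tuple(config.get("size_grid", DEFAULT_SIZE_GRID)),
            master_seed=seed, n_draws=int(config.get("n_draws", 20)),
            n_seeds=n_seeds, n_perm=min(n_perm, 10), variable=variable,
        )
    elif analysis == "trials":
        tables["trial_sweep"] = sweep_trial_number(
            dataset, specs[0],
            train_sizes=tuple(config.get("trial_grid", DEFAULT_TRIAL_GRID)),
            master_seed=seed, n_seeds=n_seeds, variable=variable,
        )
    elif analysis == "joint":
        joint = sweep_joint(
            dataset, specs[0],
            size_grid=tuple(config.get("size_grid", DEFAULT_SIZE_GRID)),
            trial_grid=tuple(config.get("trial_grid", DEFAULT_TRIAL_GRID)),
            master_seed=seed, n_seeds=min(n_seeds, 10), n_perm=min(n_perm, 5),
            variable=variable,
        )
        tables["joint_sweep"] = joint["table"]
    elif analysis == "imbalance":
        tables["imbalance_sweep"] = sweep_imbalance(
            dataset, specs,
            imbalance_grid=tuple(config.get("imbalance_grid", DEFAULT_IMBALANCE_GRID)),
            master_seed=seed, n_seeds=n_seeds, variable=variable,
        )
    elif analysis == "memory":
        tables["memory"] = memory_analysis(
            dataset, master_seed=seed, n_seeds=n_seeds,
            n_perm=min(n_perm, 5),
        )
    elif analysis != "none":
        raise ValueError(f"unknown analysis {analysis!r}")

    write_results(tables, out_dir)
    (out_dir / "manifest.json").write_text(json.dumps(_manifest(config), indent=1))
    return out_dir
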