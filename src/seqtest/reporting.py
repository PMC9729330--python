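"""Study configuration files and reproducible simulation grids.

A study config lists sequential designs and a grid of true effect sizes;
running it produces one tidy CSV row per design x truth cell with decision
rates, sample-size summaries and Monte-Carlo standard errors.  Every row
carries the seed, replicate count and software version needed to
regenerate it, and cell seeds are derived from stable spawn keys so that
partially completed runs can be resumed without changing any result.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .priors import PriorSpec, point
from .simulate import simulate_design
from .stopping import DesignSpec, HypothesisSpec, ThresholdPair, wald_thresholds

__all__ = ["StudyConfig", "load_config", "save_config", "reproduce_grid"]


class ConfigError(ValueError):
    """Raised when a study config violates the schema."""


_PRIOR_KEYS = {"family", "location", "scale", "df", "truncation"}
_DESIGN_KEYS = {"label", "test", "sided", "delta1", "delta0", "prior", "null_prior",
                "alpha", "beta", "log_lower", "log_upper", "n_start", "n_step", "n_max"}
_TOP_KEYS = {"replicates", "seed", "delta_true", "designs", "output"}


@dataclass(frozen=True)
class StudyConfig:
    """A validated design x delta_true simulation grid."""

    designs: list  # list[(label, DesignSpec)]
    delta_true: list
    replicates: int
    seed: int
    output: str | None = None


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {', '.join(unknown)}")


def _parse_prior(raw, where: str) -> PriorSpec:
    if not isinstance(raw, dict):
        raise ConfigError(f"{where} must be a mapping")
    _reject_unknown(raw, _PRIOR_KEYS, where)
    try:
        return PriorSpec(
            family=raw.get("family", "normal"),
            location=float(raw.get("location", 0.0)),
            scale=float(raw.get("scale", 0.0)),
            df=raw.get("df"),
            truncation=raw.get("truncation", "none"),
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _parse_design(raw: dict, index: int) -> tuple[str, DesignSpec]:
    where = f"designs[{index}]"
    if not isinstance(raw, dict):
        raise ConfigError(f"{where} must be a mapping")
    _reject_unknown(raw, _DESIGN_KEYS, where)
    test = raw.get("test")
    if test not in ("sprt", "sbft"):
        raise ConfigError(f"{where}.test must be 'sprt' or 'sbft'")

    if "log_lower" in raw or "log_upper" in raw:
        if not ("log_lower" in raw and "log_upper" in raw):
            raise ConfigError(f"{where}: log_lower and log_upper must be given together")
        thresholds = ThresholdPair(float(raw["log_lower"]), float(raw["log_upper"]))
    else:
        alpha, beta = raw.get("alpha"), raw.get("beta")
        if alpha is None or beta is None:
            raise ConfigError(f"{where}: give alpha and beta (Wald) or explicit log thresholds")
        if not (0 < float(alpha) < 1 and 0 < float(beta) < 1):
            raise ConfigError(f"{where}: alpha and beta must lie strictly between 0 and 1")
        thresholds = wald_thresholds(float(alpha), float(beta))

    sided = int(raw.get("sided", 1))
    if test == "sprt":
        if "delta1" not in raw:
            raise ConfigError(f"{where}: SPRT requires delta1")
        alt = HypothesisSpec(point(float(raw["delta1"])))
    else:
        if "prior" not in raw:
            raise ConfigError(f"{where}: SBFT requires a prior mapping")
        alt = HypothesisSpec(_parse_prior(raw["prior"], f"{where}.prior"))
    if "null_prior" in raw:
        null = HypothesisSpec(_parse_prior(raw["null_prior"], f"{where}.null_prior"))
    else:
        null = HypothesisSpec(point(float(raw.get("delta0", 0.0))))

    try:
        design = DesignSpec(
            test_type=test, sided=sided, alt=alt, null=null, thresholds=thresholds,
            n_start=int(raw.get("n_start", 2)), n_step=int(raw.get("n_step", 1)),
            n_max=int(raw.get("n_max", 10_000)),
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc
    label = str(raw.get("label", f"{test}-{index}"))
    return label, design


def load_config(path) -> StudyConfig:
    """Parse and validate a YAML study config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")
    if "designs" not in raw or not raw["designs"]:
        raise ConfigError("config requires a nonempty 'designs' list")
    if "delta_true" not in raw or raw["delta_true"] is None:
        raise ConfigError("config requires a 'delta_true' list")
    designs = [_parse_design(d, i) for i, d in enumerate(raw["designs"])]
    labels = [lab for lab, _ in designs]
    if len(set(labels)) != len(labels):
        raise ConfigError("design labels must be unique")
    delta_true = [float(d) for d in np.atleast_1d(raw["delta_true"])]
    replicates = int(raw.get("replicates", 10_000))
    if replicates < 1:
        raise ConfigError("replicates must be positive")
    return StudyConfig(
        designs=designs,
        delta_true=delta_true,
        replicates=replicates,
        seed=int(raw.get("seed", 0)),
        output=raw.get("output"),
    )


def _config_document(config: StudyConfig) -> dict:
    """Plain-data document describing a StudyConfig (YAML/JSON friendly)."""
    designs = []
    for label, d in config.designs:
        entry = {
            "label": label, "test": d.test_type, "sided": d.sided,
            "log_lower": d.thresholds.log_lower, "log_upper": d.thresholds.log_upper,
            "n_start": d.n_start, "n_step": d.n_step, "n_max": d.n_max,
        }
        if d.test_type == "sprt":
            entry["delta1"] = d.alt.prior.location
        else:
            p = d.alt.prior
            entry["prior"] = {"family": p.family, "location": p.location,
                              "scale": p.scale, "truncation": p.truncation}
            if p.df is not None:
                entry["prior"]["df"] = p.df
        if not (d.null.prior.is_point and d.null.prior.location == 0.0):
            if d.null.prior.is_point:
                entry["delta0"] = d.null.prior.location
            else:
                p = d.null.prior
                entry["null_prior"] = {"family": p.family, "location": p.location,
                                       "scale": p.scale, "truncation": p.truncation}
        designs.append(entry)
    doc = {"replicates": config.replicates, "seed": config.seed,
           "delta_true": list(config.delta_true), "designs": designs}
    if config.output is not None:
        doc["output"] = config.output
    return doc


def save_config(config: StudyConfig, path) -> None:
    """Write a StudyConfig back to YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(_config_document(config), sort_keys=True))


def _cell_seed(master_seed: int, i_design: int, j_delta: int) -> np.random.SeedSequence:
    # spawn keys make cell seeds independent of iteration order and resumption
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(i_design, j_delta))


_ROW_COLUMNS = ["label", "test", "sided", "delta_true", "log_lower", "log_upper",
                "rate_accept_alt", "rate_accept_null", "rate_undecided",
                "mean_n", "se_mean_n", "median_n", "n_q25", "n_q75", "n_q90",
                "n_replicates", "mc_se_rates", "seed", "version"]


def reproduce_grid(config: StudyConfig, out_path=None, resume: bool = False,
                   progress=None, **sim_kwargs) -> pd.DataFrame:
    """Run the full design x delta_true grid of a study config.

    Writes (when ``out_path`` is given) one CSV row per cell, flushing
    after every cell together with a ``<out>.resume.json`` marker so an
    interrupted run can be resumed with ``resume=True``; completed cells
    are then skipped and their rows reloaded, giving a byte-identical
    final CSV.
    """
    out_path = Path(out_path) if out_path is not None else None
    marker = out_path.with_suffix(out_path.suffix + ".resume.json") if out_path else None
    if out_path is not None:
        # JSON sidecar with the full configuration that produced the CSV
        sidecar = out_path.with_suffix(out_path.suffix + ".config.json")
        sidecar.write_text(json.dumps(_config_document(config), indent=2, sort_keys=True))
    done: dict[str, dict] = {}
    if resume and marker is not None and marker.exists():
        done = {entry["key"]: entry["row"] for entry in json.loads(marker.read_text())}

    rows = []
    for i, (label, design) in enumerate(config.designs):
        for j, d_true in enumerate(config.delta_true):
            key = f"{label}@{d_true!r}"
            if key in done:
                rows.append(done[key])
                continue
            oc = simulate_design(design, d_true, config.replicates,
                                 _cell_seed(config.seed, i, j), **sim_kwargs)
            row = {
                "label": label, "test": design.test_type, "sided": design.sided,
                "delta_true": d_true,
                "log_lower": design.thresholds.log_lower,
                "log_upper": design.thresholds.log_upper,
                "rate_accept_alt": oc.rate_accept_alt,
                "rate_accept_null": oc.rate_accept_null,
                "rate_undecided": oc.rate_undecided,
                "mean_n": oc.mean_n, "se_mean_n": oc.se_mean_n, "median_n": oc.median_n,
                "n_q25": oc.n_quantiles[0.25], "n_q75": oc.n_quantiles[0.75],
                "n_q90": oc.n_quantiles[0.9],
                "n_replicates": oc.n_replicates, "mc_se_rates": oc.mc_se_rates,
                "seed": config.seed, "version": __version__,
            }
            rows.append(row)
            done[key] = row
            if out_path is not None:
                pd.DataFrame(rows, columns=_ROW_COLUMNS).to_csv(out_path, index=False)
                marker.write_text(json.dumps(
                    [{"key": k, "row": r} for k, r in done.items()]))
            if progress is not None:
                progress(label, d_true, oc)
    table = pd.DataFrame(rows, columns=_ROW_COLUMNS)
    if out_path is not None:
        table.to_csv(out_path, index=False)
        if marker.exists():
            marker.unlink()
    return table
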