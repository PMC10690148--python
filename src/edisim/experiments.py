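"""Orchestration of the package's in-silico experiments.

Each experiment reproduces one family of simulation panels as CSV tables:

* ``priming_panels`` — DC / activated-DC / T / Tfh time courses for bolus,
  2-ED and 7-ED dosing;
* ``gc_panels`` — GC size, native-binding GC cells, titers and antigen pools
  over time, plus day-21 summaries, for the same regimens;
* ``release_sweep`` — day-21 metrics as a function of the second-dose
  release duration;
* ``mismatch_check`` — peak Tfh for matched escalating dosing vs bolus
  adjuvant with escalating antigen (the co-administration requirement);
* ``fit_demo`` — synthetic cohort generation followed by the two-parameter
  fit, reporting recovered vs generating values.

Outputs are plain CSV plus a JSON metadata file; a manifest records every
file with its row count and checksum so a run is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .gc import GCParams, native_gc_fraction, native_ic_fraction, simulate_gc
from .priming import PrimingParams, fit_priming_params, simulate_priming
from .regimens import (
    Regimen,
    make_bolus,
    make_exponential_ed,
    make_mismatched,
    make_two_dose,
    parse_regimen,
    with_extended_release,
)
from .synthetic import CohortSpec, gen_cohort

__all__ = ["ExperimentConfig", "run_experiment", "write_tables", "EXPERIMENTS"]

logger = logging.getLogger("edisim")

EXPERIMENTS = (
    "priming_panels",
    "gc_panels",
    "release_sweep",
    "mismatch_check",
    "fit_demo",
)


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    experiment: str
    regimens: Sequence[str] = ("bolus", "2ed", "7ed")
    out_dir: str = "results"
    seed: int = 42
    n_replicates: int = 10
    t_end: float = 21.0
    release_durations: Sequence[float] = (0.0, 2.0, 5.0, 10.0, 21.0)
    priming_params: PrimingParams = field(default_factory=PrimingParams)
    gc_params: GCParams = field(default_factory=GCParams)
    n_animals_per_group: int = 5
    noise_cv: float = 0.3

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; valid: {EXPERIMENTS}"
            )
        if self.experiment != "fit_demo" and len(self.regimens) == 0:
            raise ValueError("regimen set must not be empty")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        if "priming_params" in d and isinstance(d["priming_params"], Mapping):
            d["priming_params"] = PrimingParams.from_dict(d["priming_params"])
        if "gc_params" in d and isinstance(d["gc_params"], Mapping):
            d["gc_params"] = GCParams.from_dict(d["gc_params"])
        return cls(**d)

    def digest(self) -> str:
        payload = {
            "experiment": self.experiment,
            "regimens": list(self.regimens),
            "seed": self.seed,
            "n_replicates": self.n_replicates,
            "t_end": self.t_end,
            "release_durations": list(self.release_durations),
            "priming_params": self.priming_params.to_dict(),
            "gc_params": self.gc_params.to_dict(),
            "n_animals_per_group": self.n_animals_per_group,
            "noise_cv": self.noise_cv,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _resolve(names: Sequence[str]) -> dict[str, Regimen]:
    return {name: parse_regimen(name) for name in names}


def _priming_panels(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    tables = {}
    for name, regimen in _resolve(cfg.regimens).items():
        traj = simulate_priming(cfg.priming_params, regimen, t_end=cfg.t_end)
        tables[f"priming_{name}"] = traj.to_dataframe()
    return tables


def _gc_panels(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    tables = {}
    summary = []
    for name, regimen in _resolve(cfg.regimens).items():
        logger.info("gc_panels: simulating %s (%d replicates)", name, cfg.n_replicates)
        out = simulate_gc(
            cfg.gc_params, regimen, t_end=cfg.t_end,
            n_replicates=cfg.n_replicates, seed=cfg.seed,
        )
        tables[f"gc_{name}"] = out.mean
        day = cfg.t_end
        summary.append({
            "regimen": name,
            "day": day,
            "gc_b": out.at("gc_b", day),
            "gc_b_native": out.at("gc_b_native", day),
            "ic_total": out.at("ic_native", day) + out.at("ic_nonnative", day),
            "native_ic_fraction": native_ic_fraction(out, day),
            "native_gc_fraction": native_gc_fraction(out, day),
        })
    tables["gc_summary"] = pd.DataFrame(summary)
    return tables


def _release_sweep(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    rows = []
    base = make_two_dose(0.2, 7.0)
    for duration in cfg.release_durations:
        regimen = with_extended_release(base, 1, duration) if duration else base
        logger.info("release_sweep: duration %.1f d", duration)
        out = simulate_gc(
            cfg.gc_params, regimen, t_end=cfg.t_end,
            n_replicates=cfg.n_replicates, seed=cfg.seed,
        )
        day = cfg.t_end
        rows.append({
            "release_days": duration,
            "native_ic_fraction": native_ic_fraction(out, day),
            "native_gc_fraction": native_gc_fraction(out, day),
            "gc_b": out.at("gc_b", day),
            "ic_total": out.at("ic_native", day) + out.at("ic_nonnative", day),
        })
    return {"release_sweep": pd.DataFrame(rows)}


def _mismatch_check(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    matched = make_exponential_ed(7, 2.0)
    mismatched = make_mismatched(
        antigen=make_exponential_ed(7, 2.0), adjuvant=make_bolus()
    )
    rows = []
    for name, regimen in (("matched_7ed", matched), ("bolus_adj_7ed_ag", mismatched)):
        traj = simulate_priming(cfg.priming_params, regimen, t_end=cfg.t_end)
        rows.append({"schedule": name, "peak_tfh": traj.peak("tfh")})
    return {"mismatch_check": pd.DataFrame(rows)}


def _fit_demo(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    regimens = _resolve(cfg.regimens)
    spec = CohortSpec(
        regimens=list(regimens.values()),
        n_animals_per_group=cfg.n_animals_per_group,
        readouts=("tfh_day14",),
        noise_cv=cfg.noise_cv,
        seed=cfg.seed,
    )
    cohort = gen_cohort(spec, cfg.priming_params)
    observed = cohort.by_regimen("tfh_day14")
    result = fit_priming_params(
        observed, {r.label: r for r in regimens.values()}, cfg.priming_params,
        seed=cfg.seed,
    )
    fit_table = pd.DataFrame([
        {
            "parameter": "k_dc",
            "generating": cfg.priming_params.k_dc,
            "fitted": result.k_dc,
        },
        {
            "parameter": "T_baseline",
            "generating": cfg.priming_params.T_baseline,
            "fitted": result.T_baseline,
        },
    ])
    pred = pd.DataFrame(
        [{"regimen": lab, "predicted_tfh_day14": v}
         for lab, v in result.predictions.items()]
    )
    return {"fit_parameters": fit_table, "fit_predictions": pred,
            "cohort": cohort.table}


_RUNNERS = {
    "priming_panels": _priming_panels,
    "gc_panels": _gc_panels,
    "release_sweep": _release_sweep,
    "mismatch_check": _mismatch_check,
    "fit_demo": _fit_demo,
}


def write_tables(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict:
    """Write one CSV per table and return a manifest with counts and checksums."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    entries = []
    for name, df in results.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        entries.append({"file": path.name, "rows": int(len(df)), "sha256": digest})
        logger.info("wrote %s (%d rows)", path, len(df))
    manifest = {"n_files": len(entries), "files": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one experiment end to end; returns the manifest plus metadata."""
    logger.info(
        "experiment %s starting (seed=%d, hash=%s)",
        config.experiment, config.seed, config.digest(),
    )
    t0 = time.time()
    tables = _RUNNERS[config.experiment](config)
    manifest = write_tables(tables, config.out_dir)
    metadata = {
        "experiment": config.experiment,
        "config_hash": config.digest(),
        "package_version": __version__,
        "seed": config.seed,
        "n_replicates": config.n_replicates,
        "regimens": list(config.regimens),
        "runtime_s": round(time.time() - t0, 2),
        "manifest": manifest,
        "priming_params": config.priming_params.to_dict(),
        "gc_params": config.gc_params.to_dict(),
    }
    meta_path = Path(config.out_dir) / "run_metadata.json"
    meta_path.write_text(json.dumps(metadata, indent=2))
    logger.info("experiment %s finished in %.1f s", config.experiment,
                metadata["runtime_s"])
    return metadata
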