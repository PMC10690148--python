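"""Synthetic cohort generator.

Emulates per-animal flow-cytometry readouts (e.g. day-14 Tfh counts for
n = 5 animals per dosing group) by multiplying the model-predicted group mean
with lognormal animal-to-animal noise.  The noise is mean-preserving: with
``sigma**2 = ln(1 + cv**2)`` and ``mu = -sigma**2/2`` the multiplicative
factor has expectation 1 and coefficient of variation ``cv`` exactly.

The generated cohorts feed the two-parameter fit
(:func:`edisim.priming.fit_priming_params`), making the whole
fit-and-compare pipeline testable without any experimental data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gc import GCParams, simulate_gc
from .priming import PrimingParams, simulate_priming, tfh_at
from .regimens import Regimen

__all__ = ["CohortSpec", "CohortData", "gen_cohort", "READOUTS"]

READOUTS = ("tfh_day14", "gcb_day14", "native_gcb_day14")


@dataclass
class CohortSpec:
    """What to generate: regimens, group size, readouts, noise level, seed."""

    regimens: Sequence[Regimen]
    n_animals_per_group: int = 5
    readouts: Sequence[str] = ("tfh_day14",)
    noise_cv: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 1:
            raise ValueError("n_animals_per_group must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        unknown = set(self.readouts) - set(READOUTS)
        if unknown:
            raise ValueError(f"unknown readouts {sorted(unknown)}; valid: {READOUTS}")


@dataclass
class CohortData:
    """Per-animal values plus an echo of the generating configuration."""

    table: pd.DataFrame  # columns: regimen_label, readout, animal_index, value
    spec: CohortSpec
    model_means: dict = field(default_factory=dict)

    def values(self, regimen_label: str, readout: str) -> np.ndarray:
        mask = (self.table["regimen_label"] == regimen_label) & (
            self.table["readout"] == readout
        )
        return self.table.loc[mask, "value"].to_numpy()

    def by_regimen(self, readout: str) -> dict[str, np.ndarray]:
        labels = self.table["regimen_label"].unique()
        return {lab: self.values(lab, readout) for lab in labels}

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def _model_means(
    regimen: Regimen,
    readouts: Sequence[str],
    priming_params: PrimingParams,
    gc_params: GCParams | None,
    gc_replicates: int,
    seed: int,
) -> dict[str, float]:
    means: dict[str, float] = {}
    if "tfh_day14" in readouts:
        traj = simulate_priming(priming_params, regimen, t_end=14.0)
        means["tfh_day14"] = tfh_at(traj, 14.0)
    gc_readouts = [r for r in readouts if r != "tfh_day14"]
    if gc_readouts:
        if gc_params is None:
            raise ValueError(
                "GC readouts requested but no GC parameters supplied"
            )
        out = simulate_gc(
            gc_params, regimen, t_end=14.0, n_replicates=gc_replicates, seed=seed
        )
        if "gcb_day14" in gc_readouts:
            means["gcb_day14"] = out.at("gc_b", 14.0)
        if "native_gcb_day14" in gc_readouts:
            means["native_gcb_day14"] = out.at("gc_b_native", 14.0)
    return means


def gen_cohort(
    spec: CohortSpec,
    priming_params: PrimingParams,
    gc_params: GCParams | None = None,
    gc_replicates: int = 3,
) -> CohortData:
    """Generate a pseudo-experimental cohort.

    Each animal's value is ``model_mean * exp(N(-sigma^2/2, sigma))`` with
    ``sigma = sqrt(ln(1 + noise_cv^2))``, so the expectation over animals
    equals the model mean.  Deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log1p(spec.noise_cv**2))
    rows = []
    model_means: dict[tuple[str, str], float] = {}
    for regimen in spec.regimens:
        means = _model_means(
            regimen, spec.readouts, priming_params, gc_params,
            gc_replicates, spec.seed,
        )
        for readout in spec.readouts:
            mean = means[readout]
            model_means[(regimen.label, readout)] = mean
            if spec.noise_cv == 0:
                factors = np.ones(spec.n_animals_per_group)
            else:
                factors = np.exp(
                    rng.normal(-0.5 * sigma**2, sigma, size=spec.n_animals_per_group)
                )
            for i, f in enumerate(factors):
                rows.append((regimen.label, readout, i, mean * f))
    table = pd.DataFrame(
        rows, columns=["regimen_label", "readout", "animal_index", "value"]
    )
    return CohortData(table=table, spec=spec, model_means=model_means)
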