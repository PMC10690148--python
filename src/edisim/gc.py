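"""Stochastic germinal-center model with antigen degradation and FDC capture.

The model couples, within one simulated lymph node:

* **deterministic antigen kinetics** — soluble *native* (intact) antigen
  enters with each dose, is converted to *non-native* (partially degraded)
  antigen with a 6.2-hour half-life, and both species are cleared; antibody
  of the matching specificity deposits soluble antigen onto follicular
  dendritic cells (FDCs) as immune complexes (ICs), where it is protected
  from further degradation and decays only slowly through consumption;
* **deterministic antibody kinetics** — plasma cells exported by the GCs
  secrete antibody; the *titer* is the antibody concentration weighted by
  affinity (weight ``10**(affinity - a_ref)``), and the per-epitope titer
  drives IC deposition of the corresponding antigen species;
* **stochastic agent-based GC dynamics** — B cells targeting either the
  native or the non-native epitope are seeded into a fixed number of GCs at
  a rate proportional to available antigen, capture FDC antigen according to
  their affinity, compete for T-cell help, divide (with mutation), die, and
  exit as antibody-secreting cells.  The non-native epitope is
  immunodominant: it has both a higher precursor frequency and a higher mean
  germline affinity.

All antigen amounts are normalized to the total dose (cumulative input = 1
for a standard regimen), so pool sizes read directly as dose fractions.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .regimens import Regimen

__all__ = [
    "NATIVE",
    "NONNATIVE",
    "AntigenState",
    "AntibodyState",
    "PlasmaPool",
    "MassAudit",
    "GCParams",
    "GCPopulation",
    "GCOutput",
    "UndefinedFractionError",
    "ConfigurationError",
    "step_antigen",
    "update_antibodies",
    "gc_step",
    "simulate_gc",
    "native_ic_fraction",
    "native_gc_fraction",
]

NATIVE = 0
NONNATIVE = 1


class UndefinedFractionError(ValueError):
    """Requested a fraction whose denominator is zero."""


class ConfigurationError(ValueError):
    """Parameters incompatible with the configured time step."""


@dataclass
class AntigenState:
    """Antigen pools, as fractions of the total administered dose."""

    sol_native: float = 0.0
    sol_nonnative: float = 0.0
    ic_native: float = 0.0
    ic_nonnative: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sol_native", "sol_nonnative", "ic_native", "ic_nonnative"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_soluble(self) -> float:
        return self.sol_native + self.sol_nonnative

    @property
    def total_ic(self) -> float:
        return self.ic_native + self.ic_nonnative

    @property
    def total(self) -> float:
        return self.total_soluble + self.total_ic


@dataclass
class AntibodyState:
    """Per-epitope antibody concentration and affinity-weighted titer.

    ``titer`` is concentration weighted by ``10**(affinity - a_ref)``; the
    mean affinity is recoverable as ``a_ref + log10(titer/conc)``.
    """

    conc_native: float = 0.0
    conc_nonnative: float = 0.0
    titer_native: float = 0.0
    titer_nonnative: float = 0.0

    def titer(self, epitope: int) -> float:
        return self.titer_native if epitope == NATIVE else self.titer_nonnative

    def mean_affinity(self, epitope: int, a_ref: float = 8.0) -> float:
        conc = self.conc_native if epitope == NATIVE else self.conc_nonnative
        titer = self.titer(epitope)
        if conc <= 0:
            return float("nan")
        return a_ref + math.log10(titer / conc)


@dataclass
class PlasmaPool:
    """Accumulated antibody-secreting cells, per epitope.

    ``n_*`` counts cells; ``w_*`` is the affinity-weighted count
    (``sum 10**(affinity - a_ref)``), which sets titer production.
    """

    n_native: float = 0.0
    w_native: float = 0.0
    n_nonnative: float = 0.0
    w_nonnative: float = 0.0

    def add(
        self,
        epitopes: np.ndarray,
        affinities: np.ndarray,
        p_plasma: float,
        a_ref: float,
    ) -> None:
        """Register exported GC cells; a fraction ``p_plasma`` secrete antibody."""
        if len(epitopes) == 0:
            return
        w = 10.0 ** (np.asarray(affinities, dtype=float) - a_ref)
        nat = np.asarray(epitopes) == NATIVE
        self.n_native += p_plasma * float(nat.sum())
        self.w_native += p_plasma * float(w[nat].sum())
        self.n_nonnative += p_plasma * float((~nat).sum())
        self.w_nonnative += p_plasma * float(w[~nat].sum())

    def as_clones(self) -> list[tuple[int, float, float]]:
        """Aggregate view as (epitope, effective affinity, count) entries."""
        out = []
        if self.n_native > 0:
            out.append((NATIVE, 8.0 + math.log10(self.w_native / self.n_native),
                        self.n_native))
        if self.n_nonnative > 0:
            out.append((NONNATIVE,
                        8.0 + math.log10(self.w_nonnative / self.n_nonnative),
                        self.n_nonnative))
        return out


@dataclass
class MassAudit:
    """Running antigen mass balance: input = pools + cleared + consumed."""

    input: float = 0.0
    cleared_soluble: float = 0.0
    decayed_ic: float = 0.0

    def residual(self, state: AntigenState) -> float:
        return self.input - (state.total + self.cleared_soluble + self.decayed_ic)


_HALF_LIFE_NATIVE_H = 6.2  # intact antigen half-life in the lymph node, hours


@dataclass
class GCParams:
    """Parameters of the lymph-node GC model.

    Rates are per day.  The native->non-native conversion rate ``k_deg`` is
    fixed by the measured ~6.2 h half-life of intact antigen in the node.
    Affinities are on a -log10 Kd scale; ``a_ref`` is the reference affinity
    at which an antibody carries unit weight in the titer.
    """

    # antigen kinetics
    k_deg: float = math.log(2.0) / (_HALF_LIFE_NATIVE_H / 24.0)
    delta_sol: float = 1.5
    k_dep: float = 10.0         # max IC deposition coefficient (1/day scale)
    K_dep_half: float = 8.0     # titer half-saturation of deposition
    delta_ic: float = 0.22
    # lymph node / GC geometry
    n_gc: int = 20
    gc_capacity: int = 2000
    # naive B cell influx
    seeding_rate: float = 40.0  # cells/GC/day at saturating antigen
    K_seed: float = 1e-4
    K_recruit: float = 1e-3     # per-epitope antigen half-saturation of recruitment
    precursor_freq_native: float = 0.2
    precursor_freq_nonnative: float = 0.8
    germline_aff_native: float = 5.7
    germline_sd_native: float = 0.15
    germline_aff_nonnative: float = 5.9
    germline_sd_nonnative: float = 0.15
    aff_min: float = 4.0
    aff_cap: float = 10.0
    # birth / death / mutation
    beta_max: float = 3.2
    mu_death: float = 0.45
    p_silent: float = 0.5
    p_lethal: float = 0.3
    p_affect: float = 0.2
    mut_shift: float = 1.0      # affinity change = mut_shift - LogNormal(mut_mu, mut_sigma)
    mut_mu: float = 0.5
    mut_sigma: float = 0.3
    # export and antibody production
    p_exit: float = 0.2         # 1/day differentiation (export) rate
    p_plasma: float = 0.5       # fraction of exports that secrete antibody
    k_ab: float = 4.5           # concentration produced per plasma cell per day
    delta_ab: float = 0.6
    a_ref: float = 8.0
    # antigen capture and T-cell help competition
    aff_capture_ref: float = 6.0
    K_ic: float = 0.15
    help_threshold: float = 0.2
    # time stepping
    dt: float = 0.01

    def __post_init__(self) -> None:
        probs = (self.p_silent, self.p_lethal, self.p_affect)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("mutation outcome probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("mutation outcome probabilities must sum to 1")
        freq = self.precursor_freq_native + self.precursor_freq_nonnative
        if abs(freq - 1.0) > 1e-9:
            raise ValueError("precursor frequencies must sum to 1")
        if self.k_deg < 0:
            raise ValueError("k_deg must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        per_step = (self.mu_death + self.p_exit + self.beta_max) * self.dt
        if per_step > 1.0:
            raise ConfigurationError(
                f"per-step event probability {per_step:.3f} exceeds 1 at dt={self.dt}"
            )

    def replace(self, **kw) -> "GCParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d) -> "GCParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown GC parameters: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "GCParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


# -- deterministic kinetics -------------------------------------------------


def _deposition_coeff(titer: float, p: "GCParams") -> float:
    """Per-day IC deposition coefficient: cooperative (quadratic) at low titer.

    ``k_dep * titer**2 / (K_dep_half + titer)`` — antigen transport to FDCs
    requires decoration by several antibodies (and complement), so deposition
    is weak until antibody is plentiful, then scales linearly with titer.
    """
    return p.k_dep * titer * titer / (p.K_dep_half + titer)


def step_antigen(
    state: AntigenState,
    ab: AntibodyState,
    input_rate: float,
    dt: float,
    params: GCParams,
    audit: MassAudit | None = None,
) -> AntigenState:
    """Advance the antigen pools by ``dt`` with titers held fixed.

    Operator-split sub-steps: each pool's total outflow over a sub-step uses
    the exact exponential decay factor (so pure decay is solved exactly) and
    is then apportioned among conversion, clearance and deposition in
    proportion to their rates; inflows (dose release, conversion, deposition)
    are applied after.  Sub-steps are sized so no pool turns over more than
    ~10% per sub-step, keeping the splitting error far below the integrator
    tolerance elsewhere.  Every flow is accounted, so the discrete mass
    balance (input = pools + cleared + consumed) holds to float round-off.
    ``input_rate`` is the constant-rate release of *native* antigen over the
    step; impulses should be added to ``sol_native`` by the caller before
    stepping.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params
    sn, snn = state.sol_native, state.sol_nonnative
    icn, icnn = state.ic_native, state.ic_nonnative
    tn, tnn = ab.titer_native, ab.titer_nonnative
    u = input_rate

    if u == 0.0 and sn < 1e-18 and snn < 1e-18:
        # soluble phase exhausted: only slow IC consumption remains
        f = math.exp(-p.delta_ic * dt)
        if audit is not None:
            audit.cleared_soluble += sn + snn
            audit.decayed_ic += (icn + icnn) * (1.0 - f)
        return AntigenState(0.0, 0.0, icn * f, icnn * f)

    dep_n = _deposition_coeff(tn, p)
    dep_nn = _deposition_coeff(tnn, p)
    r_n = p.k_deg + p.delta_sol + dep_n
    r_nn = p.delta_sol + dep_nn
    rmax = max(r_n, r_nn, p.delta_ic)
    n_sub = max(1, math.ceil(rmax * dt / 0.1))
    if n_sub > 200000:
        raise RuntimeError(
            f"antigen step requires {n_sub} sub-steps (rate {rmax:.3g}/day); "
            "reduce dt or titers are diverging"
        )
    h = dt / n_sub
    loss_n = 1.0 - math.exp(-r_n * h)
    loss_nn = 1.0 - math.exp(-r_nn * h)
    loss_ic = 1.0 - math.exp(-p.delta_ic * h)
    inp = clr = dec = 0.0
    for _ in range(n_sub):
        out_n = sn * loss_n
        conv = out_n * (p.k_deg / r_n) if r_n > 0 else 0.0
        clr_n = out_n * (p.delta_sol / r_n) if r_n > 0 else 0.0
        cap_n = out_n * (dep_n / r_n) if r_n > 0 else 0.0
        out_nn = snn * loss_nn
        clr_nn = out_nn * (p.delta_sol / r_nn) if r_nn > 0 else 0.0
        cap_nn = out_nn * (dep_nn / r_nn) if r_nn > 0 else 0.0
        dec_n = icn * loss_ic
        dec_nn = icnn * loss_ic
        sn += u * h - out_n
        snn += conv - out_nn
        icn += cap_n - dec_n
        icnn += cap_nn - dec_nn
        inp += u * h
        clr += clr_n + clr_nn
        dec += dec_n + dec_nn
    if min(sn, snn, icn, icnn) < 0:
        raise RuntimeError(
            "negative antigen pool after update; step size too large"
        )
    if audit is not None:
        audit.input += inp
        audit.cleared_soluble += clr
        audit.decayed_ic += dec
    return AntigenState(sn, snn, icn, icnn)


def _plasma_weights(
    plasma: PlasmaPool | Iterable[tuple[int, float, float]], a_ref: float
) -> tuple[float, float, float, float]:
    """(N_native, W_native, N_nonnative, W_nonnative) from either pool form."""
    if isinstance(plasma, PlasmaPool):
        return plasma.n_native, plasma.w_native, plasma.n_nonnative, plasma.w_nonnative
    n = [0.0, 0.0]
    w = [0.0, 0.0]
    for epitope, affinity, count in plasma:
        n[epitope] += count
        w[epitope] += count * 10.0 ** (affinity - a_ref)
    return n[NATIVE], w[NATIVE], n[NONNATIVE], w[NONNATIVE]


def update_antibodies(
    ab: AntibodyState,
    plasma_pool: PlasmaPool | Iterable[tuple[int, float, float]],
    dt: float,
    params: GCParams,
) -> AntibodyState:
    """Advance antibody concentration and affinity-weighted titer by ``dt``.

    Each plasma cell secretes concentration at rate ``k_ab``; its titer
    contribution is weighted by ``10**(affinity - a_ref)``.  Decay at
    ``delta_ab`` applies to both.  The linear ODE is solved exactly over the
    step (plasma counts held fixed).
    """
    p = params
    n_nat, w_nat, n_nn, w_nn = _plasma_weights(plasma_pool, p.a_ref)
    if p.delta_ab > 0:
        f = math.exp(-p.delta_ab * dt)
        g = (1.0 - f) / p.delta_ab
    else:
        f, g = 1.0, dt

    def step(value: float, production: float) -> float:
        return value * f + p.k_ab * production * g

    return AntibodyState(
        conc_native=step(ab.conc_native, n_nat),
        conc_nonnative=step(ab.conc_nonnative, n_nn),
        titer_native=step(ab.titer_native, w_nat),
        titer_nonnative=step(ab.titer_nonnative, w_nn),
    )


# -- agent-based GC dynamics ------------------------------------------------


@dataclass
class GCPopulation:
    """B cells of every GC in the node, stored as flat arrays.

    ``gc_id`` assigns each cell to one of ``n_gc`` germinal centers;
    selection competition and the capacity cap act per GC.
    """

    epitope: np.ndarray
    affinity: np.ndarray
    lineage: np.ndarray
    n_mutations: np.ndarray
    gc_id: np.ndarray
    n_gc: int = 1

    @classmethod
    def empty(cls, n_gc: int = 1) -> "GCPopulation":
        return cls(
            epitope=np.empty(0, dtype=np.int8),
            affinity=np.empty(0, dtype=float),
            lineage=np.empty(0, dtype=np.int64),
            n_mutations=np.empty(0, dtype=np.int32),
            gc_id=np.empty(0, dtype=np.int32),
            n_gc=n_gc,
        )

    @property
    def size(self) -> int:
        return len(self.affinity)

    def counts(self) -> np.ndarray:
        return np.bincount(self.gc_id, minlength=self.n_gc)

    def select(self, mask: np.ndarray) -> "GCPopulation":
        return GCPopulation(
            self.epitope[mask], self.affinity[mask], self.lineage[mask],
            self.n_mutations[mask], self.gc_id[mask], self.n_gc,
        )

    @staticmethod
    def concatenate(a: "GCPopulation", b: "GCPopulation") -> "GCPopulation":
        return GCPopulation(
            np.concatenate([a.epitope, b.epitope]),
            np.concatenate([a.affinity, b.affinity]),
            np.concatenate([a.lineage, b.lineage]),
            np.concatenate([a.n_mutations, b.n_mutations]),
            np.concatenate([a.gc_id, b.gc_id]),
            a.n_gc,
        )


def _capture_signal(pop: GCPopulation, antigen: AntigenState, p: GCParams) -> np.ndarray:
    """Saturating amount of FDC antigen captured by each cell, in [0, 1)."""
    ic = np.where(pop.epitope == NATIVE, antigen.ic_native, antigen.ic_nonnative)
    s = 10.0 ** (pop.affinity - p.aff_capture_ref) * ic / p.K_ic
    return s / (1.0 + s)


def _limit_per_gc(
    gc_ids: np.ndarray, allowed: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Boolean keep-mask so that at most ``allowed[g]`` entries remain per GC."""
    n = len(gc_ids)
    keep = np.ones(n, dtype=bool)
    counts = np.bincount(gc_ids, minlength=len(allowed))
    over = np.nonzero(counts > allowed)[0]
    for g in over:
        idx = np.nonzero(gc_ids == g)[0]
        drop = rng.choice(idx, size=len(idx) - int(allowed[g]), replace=False)
        keep[drop] = False
    return keep


def gc_step(
    pop: GCPopulation,
    antigen: AntigenState,
    params: GCParams,
    rng: np.random.Generator,
) -> tuple[GCPopulation, tuple[np.ndarray, np.ndarray]]:
    """One time step of birth/death/mutation/export for every GC.

    Per cell and step (probabilities are rate * dt):

    * capture: ``c = s/(1+s)`` with ``s = 10**(affinity - aff_capture_ref)
      * ic_epitope / K_ic`` — zero if the cell's epitope has no FDC antigen;
    * T-cell help: ``help = min(1, c / (<c>_GC + help_threshold))`` — the
      competitive share of help within the cell's GC, damped by a constant
      threshold so that a uniformly starved GC receives little help;
    * events (mutually exclusive draws): death ``mu_death*dt``, export
      ``p_exit*dt``, division ``beta_max*c*help*dt`` — the product of the
      absolute amount of antigen captured and the competitive help share, so
      GCs expand near ``beta_max`` only while their antigen is abundant and
      contract as it wanes;
    * each division yields one daughter whose receptor is unchanged
      (``p_silent``), lethally mutated (``p_lethal``, daughter discarded) or
      affinity-changing (``p_affect``, affinity shifted by ``mut_shift -
      LogNormal(mut_mu, mut_sigma)``: mostly deleterious with a ~5%
      beneficial tail, clipped to [aff_min, aff_cap]);
    * daughters exceeding ``gc_capacity`` are rejected uniformly at random.

    Returns the updated population and the (epitope, affinity) arrays of the
    exported cells.  Bit-reproducible for a given rng state.
    """
    p = params
    dt = p.dt
    empty_exit = (np.empty(0, dtype=np.int8), np.empty(0, dtype=float))
    if pop.size == 0:
        return pop, empty_exit

    p_death = p.mu_death * dt
    p_exit = p.p_exit * dt
    p_div_max = p.beta_max * dt
    if p_death + p_exit + p_div_max > 1.0:
        raise ConfigurationError(
            "per-step probabilities exceed 1; decrease dt"
        )

    c = _capture_signal(pop, antigen, p)
    counts = np.bincount(pop.gc_id, minlength=pop.n_gc)
    sums = np.bincount(pop.gc_id, weights=c, minlength=pop.n_gc)
    mean_c = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    help_prob = np.minimum(1.0, c / (mean_c[pop.gc_id] + p.help_threshold))
    p_div = p_div_max * c * help_prob

    u = rng.random(pop.size)
    dead = u < p_death
    exited = (~dead) & (u < p_death + p_exit)
    divide = (~dead) & (~exited) & (u < p_death + p_exit + p_div)

    exports = (pop.epitope[exited].copy(), pop.affinity[exited].copy())

    survivors = pop.select(~dead & ~exited)

    div_idx = np.nonzero(divide)[0]
    if len(div_idx):
        outcome = rng.random(len(div_idx))
        lethal = (outcome >= p.p_silent) & (outcome < p.p_silent + p.p_lethal)
        affect = outcome >= p.p_silent + p.p_lethal
        d_aff = pop.affinity[div_idx].copy()
        n_aff = int(affect.sum())
        if n_aff:
            delta = p.mut_shift - np.exp(rng.normal(p.mut_mu, p.mut_sigma, size=n_aff))
            d_aff[affect] = np.clip(d_aff[affect] + delta, p.aff_min, p.aff_cap)
        viable = ~lethal
        daughters = GCPopulation(
            epitope=pop.epitope[div_idx][viable],
            affinity=d_aff[viable],
            lineage=pop.lineage[div_idx][viable],
            n_mutations=(pop.n_mutations[div_idx] + 1)[viable],
            gc_id=pop.gc_id[div_idx][viable],
            n_gc=pop.n_gc,
        )
        allowed = np.maximum(0, p.gc_capacity - survivors.counts())
        keep = _limit_per_gc(daughters.gc_id, allowed, rng)
        daughters = daughters.select(keep)
        survivors = GCPopulation.concatenate(survivors, daughters)

    return survivors, exports


def _seed_cells(
    pop: GCPopulation,
    antigen: AntigenState,
    params: GCParams,
    rng: np.random.Generator,
    lineage_counter: list[int],
) -> GCPopulation:
    """Poisson influx of naive precursors, proportional to available antigen.

    The total influx saturates in total antigen (soluble + FDC-bound); the
    epitope of each recruit is drawn with probability proportional to
    precursor frequency times a saturating function of that epitope's antigen
    availability, so native-specific B cells stop entering once intact
    antigen is exhausted but are recruited at full strength whenever a
    meaningful amount of it is present.
    """
    p = params
    avail = antigen.total
    if avail <= 0:
        return pop
    lam = p.seeding_rate * avail / (avail + p.K_seed) * p.dt
    n_new = rng.poisson(lam, size=p.n_gc)
    room = np.maximum(0, p.gc_capacity - pop.counts())
    n_new = np.minimum(n_new, room)
    total = int(n_new.sum())
    if total == 0:
        return pop
    gc_ids = np.repeat(np.arange(p.n_gc, dtype=np.int32), n_new)
    a_nat = antigen.sol_native + antigen.ic_native
    a_nn = antigen.sol_nonnative + antigen.ic_nonnative
    w_nat = p.precursor_freq_native * a_nat / (a_nat + p.K_recruit)
    w_nn = p.precursor_freq_nonnative * a_nn / (a_nn + p.K_recruit)
    if w_nat + w_nn <= 0:
        return pop
    p_native = w_nat / (w_nat + w_nn)
    native = rng.random(total) < p_native
    aff = np.where(
        native,
        rng.normal(p.germline_aff_native, p.germline_sd_native, size=total),
        rng.normal(p.germline_aff_nonnative, p.germline_sd_nonnative, size=total),
    )
    aff = np.clip(aff, p.aff_min, p.aff_cap)
    lineages = np.arange(lineage_counter[0], lineage_counter[0] + total, dtype=np.int64)
    lineage_counter[0] += total
    seeded = GCPopulation(
        epitope=np.where(native, NATIVE, NONNATIVE).astype(np.int8),
        affinity=aff,
        lineage=lineages,
        n_mutations=np.zeros(total, dtype=np.int32),
        gc_id=gc_ids,
        n_gc=p.n_gc,
    )
    return GCPopulation.concatenate(pop, seeded)


# -- whole-node simulation --------------------------------------------------

_RECORD_COLUMNS = [
    "time_day", "gc_b", "gc_b_native", "aff_native_mean", "aff_nonnative_mean",
    "titer_native", "titer_nonnative", "conc_native", "conc_nonnative",
    "sol_native", "sol_nonnative", "ic_native", "ic_nonnative",
    "plasma_native", "plasma_nonnative",
]


@dataclass
class GCOutput:
    """Replicate-averaged lymph-node output plus per-replicate detail."""

    times: np.ndarray
    mean: pd.DataFrame
    replicates: list[pd.DataFrame]
    audits: list[MassAudit]
    n_replicates: int
    seeds: list[list[int]]
    regimen_label: str
    params_digest: str

    def at(self, column: str, day: float) -> float:
        """Replicate-mean value of ``column`` at ``day`` (linear interpolation)."""
        t = self.mean["time_day"].to_numpy()
        if not (t[0] <= day <= t[-1]):
            raise ValueError(f"day {day} outside simulated range [{t[0]}, {t[-1]}]")
        return float(np.interp(day, t, self.mean[column].to_numpy()))


def _simulate_one(
    params: GCParams,
    impulse_steps: Sequence[tuple[int, float]],
    rates: np.ndarray,
    n_steps: int,
    record_steps: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, MassAudit]:
    p = params
    state = AntigenState()
    ab = AntibodyState()
    plasma = PlasmaPool()
    pop = GCPopulation.empty(p.n_gc)
    audit = MassAudit()
    lineage_counter = [0]
    impulses = dict()
    for k, amount in impulse_steps:
        impulses[k] = impulses.get(k, 0.0) + amount
    rows = []
    record_set = set(int(k) for k in record_steps)

    def record(t: float) -> None:
        nat = pop.epitope == NATIVE
        n_nat = int(nat.sum())
        n_tot = pop.size
        rows.append((
            t, n_tot, n_nat,
            float(pop.affinity[nat].mean()) if n_nat else np.nan,
            float(pop.affinity[~nat].mean()) if n_tot - n_nat else np.nan,
            ab.titer_native, ab.titer_nonnative,
            ab.conc_native, ab.conc_nonnative,
            state.sol_native, state.sol_nonnative,
            state.ic_native, state.ic_nonnative,
            plasma.n_native, plasma.n_nonnative,
        ))

    record(0.0)
    for k in range(n_steps):
        if k in impulses:
            state = replace(state, sol_native=state.sol_native + impulses[k])
            audit.input += impulses[k]
        state = step_antigen(state, ab, float(rates[k]), p.dt, p, audit)
        ab = update_antibodies(ab, plasma, p.dt, p)
        pop = _seed_cells(pop, state, p, rng, lineage_counter)
        pop, (exit_epi, exit_aff) = gc_step(pop, state, p, rng)
        plasma.add(exit_epi, exit_aff, p.p_plasma, p.a_ref)
        if (k + 1) in record_set:
            record((k + 1) * p.dt)
    df = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    return df, audit


def simulate_gc(
    params: GCParams,
    regimen: Regimen,
    t_end: float = 21.0,
    n_replicates: int = 10,
    seed: int = 0,
    record_every: float = 0.25,
) -> GCOutput:
    """Simulate ``n_replicates`` independent lymph nodes under a regimen.

    Antigen/antibody kinetics are deterministic per node; the coupled GCs are
    stochastic, so replicates differ through the B-cell dynamics and the
    antibody they feed back.  Replicate seeds are derived deterministically
    from ``seed``; the same seed yields identical output.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    p = params
    n_steps = int(round(t_end / p.dt))
    impulse_steps = []
    for e in regimen.impulses("antigen"):
        k = int(round(e.start_time / p.dt))
        if k <= n_steps:
            impulse_steps.append((min(k, n_steps - 1), e.amount))
    mid = (np.arange(n_steps) + 0.5) * p.dt
    rates = np.zeros(n_steps)
    for e in regimen.releases("antigen"):
        rates += np.where((mid >= e.start_time) & (mid < e.end_time), e.rate, 0.0)
    every = max(1, int(round(record_every / p.dt)))
    record_steps = np.arange(every, n_steps + 1, every)
    if len(record_steps) == 0 or record_steps[-1] != n_steps:
        record_steps = np.append(record_steps, n_steps)

    reps: list[pd.DataFrame] = []
    audits: list[MassAudit] = []
    seeds = [[int(seed), r] for r in range(n_replicates)]
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seeds[r]))
        try:
            df, audit = _simulate_one(
                p, impulse_steps, rates, n_steps, record_steps, rng
            )
        except Exception as exc:
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc
        reps.append(df)
        audits.append(audit)
    mean = reps[0][["time_day"]].copy()
    for col in _RECORD_COLUMNS[1:]:
        stacked = np.stack([df[col].to_numpy(dtype=float) for df in reps])
        if col.startswith("aff_"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean[col] = np.nanmean(stacked, axis=0)
        else:
            mean[col] = stacked.mean(axis=0)
    return GCOutput(
        times=mean["time_day"].to_numpy(),
        mean=mean,
        replicates=reps,
        audits=audits,
        n_replicates=n_replicates,
        seeds=seeds,
        regimen_label=regimen.label,
        params_digest=p.digest(),
    )


def native_ic_fraction(output: GCOutput, day: float) -> float:
    """Share of FDC-bound immune-complexed antigen that is native at ``day``."""
    ic_n = output.at("ic_native", day)
    ic_nn = output.at("ic_nonnative", day)
    denom = ic_n + ic_nn
    if denom <= 0:
        raise UndefinedFractionError(f"no FDC-bound antigen at day {day}")
    return ic_n / denom


def native_gc_fraction(output: GCOutput, day: float) -> float:
    """Fraction of GC B cells targeting the native epitope at ``day``."""
    total = output.at("gc_b", day)
    if total <= 0:
        raise UndefinedFractionError(f"no GC B cells at day {day}")
    return output.at("gc_b_native", day) / total
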