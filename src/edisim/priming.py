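"""Kinetic model of innate activation, DC recruitment and Tfh priming.

A deterministic compartment model of the events between vaccine injection and
T follicular helper (Tfh) cell expansion in the draining lymph node:

* adjuvant (``adj``) and antigen (``ag``) appear with each dose and clear at
  constant rates;
* adjuvant activates innate/tissue cells (``innate``), a single proxy
  compartment for the cytokine/chemokine response at the injection site and
  draining node;
* activated innate cells recruit dendritic cells (``dc``), which otherwise
  relax back to their baseline number;
* DCs become activated and antigen-loaded (``adc``) at a rate that saturates
  in both adjuvant and antigen concentration — both must be present, so
  co-administration of the two components matters;
* activated antigen-loaded DCs drive saturating proliferation of
  antigen-specific T cells (``t_cells``), which differentiate into Tfh cells
  (``tfh``) at a constant per-capita rate.

Governing equations (state order adj, ag, innate, dc, adc, t_cells, tfh)::

    adj'     = u_adj(t) - delta_adj * adj
    ag'      = u_ag(t)  - delta_ag  * ag
    innate'  = k_innate * adj - delta_innate * innate
    dc'      = k_dc * innate - delta_dc * (dc - dc_baseline)
    adc'     = k_uptake * [adj/(adj+K_adj)] * [ag/(ag+K_ag)] * dc
               - delta_adc * adc
    t_cells' = rho * [adc/(adc+K_T)] * t_cells - delta_T * (t_cells - T_baseline)
    tfh'     = k_tfh * t_cells - delta_tfh * tfh

Impulse doses are additive jumps in ``adj``/``ag``; the stiff integrator is
restarted at every dose boundary.  Two parameters — the DC recruitment rate
``k_dc`` and the baseline T-cell count ``T_baseline`` — are fitted to observed
day-14 Tfh counts across regimens (:func:`fit_priming_params`); everything
else is an order-of-magnitude default.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .regimens import Regimen

__all__ = [
    "PrimingParams",
    "PrimingTrajectory",
    "IntegrationError",
    "IdentifiabilityError",
    "simulate_priming",
    "tfh_at",
    "fit_priming_params",
    "FitResult",
]

STATE_NAMES = ("adj", "ag", "innate", "dc", "adc", "t_cells", "tfh")


class IntegrationError(RuntimeError):
    """Raised when the ODE solution becomes non-finite."""


class IdentifiabilityError(ValueError):
    """Raised when the fit is requested with too few distinct regimens."""


@dataclass
class PrimingParams:
    """Rate constants of the priming model (units: 1/day unless noted).

    ``k_dc`` (DC recruitment per activated-innate unit per day) and
    ``T_baseline`` (cells) are the two fitted parameters; their defaults are
    the values recovered by the shipped fit demo.  ``dc_baseline``, ``K_T``
    and ``T_baseline`` are in cells; ``K_adj``/``K_ag`` are in dose-fraction
    units (the dose is normalized to 1).
    """

    delta_adj: float = 1.5
    delta_ag: float = 1.5
    k_innate: float = 1.0
    delta_innate: float = 1.0
    k_dc: float = 2000.0          # FITTED
    dc_baseline: float = 200.0
    delta_dc: float = 0.8
    k_uptake: float = 1.0
    K_adj: float = 0.1
    K_ag: float = 0.1
    delta_adc: float = 1.0
    rho: float = 0.9
    K_T: float = 5.0
    delta_T: float = 0.1
    T_baseline: float = 10.0      # FITTED
    k_tfh: float = 0.3
    delta_tfh: float = 0.2
    tfh_depletes_tcells: bool = False

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name == "tfh_depletes_tcells":
                continue
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.dc_baseline <= 0 or self.T_baseline <= 0:
            raise ValueError("dc_baseline and T_baseline must be > 0")

    def replace(self, **kw) -> "PrimingParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PrimingParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown priming parameters: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "PrimingParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def tfh_fixed_point(self) -> float:
        """Resting Tfh level with no vaccine: k_tfh * T_baseline / delta_tfh."""
        if self.delta_tfh == 0:
            return 0.0
        return self.k_tfh * self.T_baseline / self.delta_tfh


@dataclass
class PrimingTrajectory:
    """Time course of all priming-model compartments on a uniform day grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 7), columns STATE_NAMES
    regimen_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states must be finite")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def tfh(self) -> np.ndarray:
        return self["tfh"]

    def peak(self, name: str) -> float:
        return float(self[name].max())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_day", self.times)
        return df


def _segment_rates(regimen: Regimen, t0: float, t1: float) -> tuple[float, float]:
    """Constant (u_adj, u_ag) release rates on a segment containing no boundaries."""
    tm = 0.5 * (t0 + t1)
    u_adj = u_ag = 0.0
    for e in regimen.events:
        if not e.is_impulse and e.start_time <= tm < e.end_time:
            if e.covers("antigen"):
                u_ag += e.rate
            if e.covers("adjuvant"):
                u_adj += e.rate
    return u_adj, u_ag


def _rhs_factory(p: PrimingParams, u_adj: float, u_ag: float):
    def rhs(t, y):
        adj, ag, innate, dc, adc, tc, tfh = y
        sat = (adj / (adj + p.K_adj)) * (ag / (ag + p.K_ag)) if adj > 0 and ag > 0 else 0.0
        d_adj = u_adj - p.delta_adj * adj
        d_ag = u_ag - p.delta_ag * ag
        d_innate = p.k_innate * adj - p.delta_innate * innate
        d_dc = p.k_dc * innate - p.delta_dc * (dc - p.dc_baseline)
        d_adc = p.k_uptake * sat * dc - p.delta_adc * adc
        prolif = p.rho * (adc / (adc + p.K_T)) * tc if adc > 0 else 0.0
        d_tc = prolif - p.delta_T * (tc - p.T_baseline)
        d_tfh = p.k_tfh * tc - p.delta_tfh * tfh
        if p.tfh_depletes_tcells:
            d_tc -= p.k_tfh * tc
        return (d_adj, d_ag, d_innate, d_dc, d_adc, d_tc, d_tfh)

    return rhs


def _initial_state(p: PrimingParams) -> np.ndarray:
    return np.array([0.0, 0.0, 0.0, p.dc_baseline, 0.0, p.T_baseline,
                     p.tfh_fixed_point])


def _boundaries(regimen: Regimen, t_end: float) -> list[float]:
    pts = {0.0, t_end}
    for e in regimen.events:
        if e.start_time < t_end:
            pts.add(e.start_time)
        if not e.is_impulse and e.end_time < t_end:
            pts.add(e.end_time)
    return sorted(pts)


def _apply_impulses(regimen: Regimen, t: float, y: np.ndarray) -> None:
    for e in regimen.events:
        if e.is_impulse and e.start_time == t:
            if e.covers("adjuvant"):
                y[0] += e.amount
            if e.covers("antigen"):
                y[1] += e.amount


def simulate_priming(
    params: PrimingParams,
    regimen: Regimen,
    t_end: float = 21.0,
    dt_out: float = 0.05,
    rtol: float = 1e-7,
    atol: float = 1e-10,
) -> PrimingTrajectory:
    """Integrate the priming ODEs over ``[0, t_end]``.

    Impulse doses are applied as additive state jumps and the integrator is
    restarted at every dose boundary, so each segment has smooth right-hand
    sides.  Output is reported on a uniform grid with spacing ``dt_out``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    grid[-1] = min(grid[-1], t_end)
    y = _initial_state(params)
    bounds = _boundaries(regimen, t_end)
    out_t: list[float] = []
    out_y: list[np.ndarray] = []
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        _apply_impulses(regimen, t0, y)
        eval_mask = (grid >= t0) & (grid < t1)
        t_eval = grid[eval_mask]
        if len(out_t) == 0 and (len(t_eval) == 0 or t_eval[0] > t0):
            t_eval = np.insert(t_eval, 0, t0)
        u_adj, u_ag = _segment_rates(regimen, t0, t1)
        sol = solve_ivp(
            _rhs_factory(params, u_adj, u_ag),
            (t0, t1),
            y,
            method="LSODA",
            t_eval=np.unique(np.append(t_eval, t1)),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            bad = np.argwhere(~np.isfinite(sol.y))
            if len(bad):
                var, idx = bad[0]
                raise IntegrationError(
                    f"non-finite {STATE_NAMES[var]} at t={sol.t[idx]:.4g}"
                )
            raise IntegrationError(f"integration failed on [{t0}, {t1}]: {sol.message}")
        keep = sol.t < t1 if t1 < t_end else np.ones_like(sol.t, dtype=bool)
        for ti, yi in zip(sol.t[keep], sol.y[:, keep].T):
            out_t.append(float(ti))
            out_y.append(yi)
        y = sol.y[:, -1].copy()
    # dedupe/sort (segment ends coincide with next segment starts only at t_end)
    out = {}
    for ti, yi in zip(out_t, out_y):
        out[round(ti, 12)] = yi
    times = np.array(sorted(out))
    states = np.array([out[t] for t in times])
    states = np.maximum(states, 0.0)  # clip integrator noise at the origin
    return PrimingTrajectory(times, states, regimen_label=regimen.label)


def tfh_at(trajectory: PrimingTrajectory, day: float) -> float:
    """Tfh count at ``day`` by linear interpolation on the output grid."""
    t = trajectory.times
    if not (t[0] <= day <= t[-1]):
        raise ValueError(f"day {day} outside simulated range [{t[0]}, {t[-1]}]")
    return float(np.interp(day, t, trajectory.tfh))


def _tfh_at_day(params: PrimingParams, regimen: Regimen, day: float) -> float:
    """Fast path: integrate only as far as ``day`` and return tfh(day)."""
    y = _initial_state(params)
    bounds = _boundaries(regimen, day)
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        _apply_impulses(regimen, t0, y)
        u_adj, u_ag = _segment_rates(regimen, t0, t1)
        sol = solve_ivp(
            _rhs_factory(params, u_adj, u_ag),
            (t0, t1),
            y,
            method="LSODA",
            rtol=1e-7,
            atol=1e-10,
        )
        if not sol.success:
            raise IntegrationError(sol.message)
        y = sol.y[:, -1].copy()
    return float(max(y[6], 1e-300))


@dataclass
class FitResult:
    """Outcome of the two-parameter fit."""

    k_dc: float
    T_baseline: float
    objective: float
    predictions: dict[str, float] = field(default_factory=dict)
    observed_log_means: dict[str, float] = field(default_factory=dict)
    n_starts: int = 1
    success: bool = True
    message: str = ""


def fit_priming_params(
    observed: Mapping[str, Sequence[float]],
    regimens: Mapping[str, Regimen],
    base_params: PrimingParams,
    day: float = 14.0,
    n_starts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Fit (k_dc, T_baseline) to per-regimen day-``day`` Tfh counts.

    Minimizes the sum over regimens of
    ``(log model_tfh(day) - mean(log observed))**2`` — a log-scale least
    squares, appropriate because counts span orders of magnitude.  The search
    runs in log-parameter space with ``n_starts`` multiplicatively perturbed
    starting points (seeded); the best local optimum is returned.

    Raises :class:`IdentifiabilityError` if fewer than two distinct regimens
    carry observations (two unknowns need at least two constraints).
    """
    labels = [lab for lab in observed if len(observed[lab]) > 0]
    if len(labels) < 2:
        raise IdentifiabilityError(
            "fitting k_dc and T_baseline requires observations from >= 2 regimens"
        )
    missing = [lab for lab in labels if lab not in regimens]
    if missing:
        raise ValueError(f"no regimen definition for observed groups: {missing}")
    log_means = {
        lab: float(np.mean(np.log(np.asarray(observed[lab], dtype=float))))
        for lab in labels
    }

    def residuals(x: np.ndarray) -> np.ndarray:
        p = base_params.replace(k_dc=math.exp(x[0]), T_baseline=math.exp(x[1]))
        return np.array(
            [math.log(_tfh_at_day(p, regimens[lab], day)) - log_means[lab]
             for lab in labels]
        )

    x0 = np.array([math.log(base_params.k_dc), math.log(base_params.T_baseline)])
    rng = np.random.default_rng(seed)
    best = None
    message = ""
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, 1.0, size=2)
        try:
            res = least_squares(residuals, xs, method="lm", xtol=1e-12, ftol=1e-12)
        except Exception as exc:  # pragma: no cover - optimizer failure path
            message = str(exc)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"optimizer failed to converge from any start: {message}")
    k_dc = math.exp(best.x[0])
    t_base = math.exp(best.x[1])
    fitted = base_params.replace(k_dc=k_dc, T_baseline=t_base)
    predictions = {
        lab: _tfh_at_day(fitted, regimens[lab], day) for lab in labels
    }
    return FitResult(
        k_dc=k_dc,
        T_baseline=t_base,
        objective=float(2 * best.cost),
        predictions=predictions,
        observed_log_means=log_means,
        n_starts=max(1, n_starts),
        success=bool(best.success),
        message=str(best.message),
    )
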