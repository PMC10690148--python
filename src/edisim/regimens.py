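"""Vaccine dosing regimens.

A regimen is an ordered sequence of dose events, each delivering a fraction of
the total antigen and/or adjuvant dose either as an instantaneous impulse or as
a constant-rate release over a window.  Regimens are the shared input to both
the T-cell priming model and the germinal-center model.

Built-in constructors cover the regimens studied experimentally:

* :func:`make_bolus` — the whole dose at day 0;
* :func:`make_exponential_ed` — *n* injections with exponentially escalating
  amounts (amount of injection ``k`` proportional to ``e**k``), the classic
  7-dose escalating-dose immunization when ``n=7, interval=2``;
* :func:`make_two_dose` — a two-shot extended prime (e.g. 20% at day 0, 80% at
  day 7);
* :func:`with_extended_release` — convert one event into a zero-order release
  of the same amount over a chosen duration (slow-release second dose);
* :func:`make_mismatched` — independent antigen and adjuvant schedules, used to
  probe the requirement that the two be co-administered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import yaml

__all__ = [
    "DoseEvent",
    "Regimen",
    "make_bolus",
    "make_exponential_ed",
    "make_dose_number_series",
    "make_two_dose",
    "make_mismatched",
    "with_extended_release",
    "input_rate",
    "parse_regimen",
]

COMPONENTS = ("antigen", "adjuvant", "both")


@dataclass(frozen=True)
class DoseEvent:
    """One administration event.

    Parameters
    ----------
    start_time:
        Day of administration (>= 0).
    amount:
        Fraction of the total dose delivered by this event (> 0).
    duration:
        0 for an instantaneous impulse; > 0 for a constant-rate release over
        ``[start_time, start_time + duration]`` days.
    component:
        Which vaccine component the event delivers: ``"antigen"``,
        ``"adjuvant"`` or ``"both"``.
    """

    start_time: float
    amount: float
    duration: float = 0.0
    component: str = "both"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"amount must be > 0, got {self.amount}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if self.start_time < 0:
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")
        if self.component not in COMPONENTS:
            raise ValueError(
                f"component must be one of {COMPONENTS}, got {self.component!r}"
            )

    @property
    def is_impulse(self) -> bool:
        return self.duration == 0.0

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def rate(self) -> float:
        """Constant release rate (amount/day); 0 for impulses."""
        return 0.0 if self.is_impulse else self.amount / self.duration

    def covers(self, component: str) -> bool:
        """True if this event delivers the given component."""
        if component == "both":
            return True
        return self.component in ("both", component)


@dataclass(frozen=True)
class Regimen:
    """An ordered dosing schedule with a human-readable label."""

    events: tuple[DoseEvent, ...]
    label: str = ""

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.start_time))
        object.__setattr__(self, "events", events)

    def events_for(self, component: str) -> tuple[DoseEvent, ...]:
        return tuple(e for e in self.events if e.covers(component))

    def total(self, component: str = "antigen") -> float:
        return sum(e.amount for e in self.events_for(component))

    def impulses(self, component: str = "antigen") -> tuple[DoseEvent, ...]:
        return tuple(e for e in self.events_for(component) if e.is_impulse)

    def releases(self, component: str = "antigen") -> tuple[DoseEvent, ...]:
        return tuple(e for e in self.events_for(component) if not e.is_impulse)

    @property
    def end_time(self) -> float:
        return max((e.end_time for e in self.events), default=0.0)

    def validate_normalized(self, total: float = 1.0, tol: float = 1e-9) -> None:
        """Check that antigen and adjuvant amounts each sum to ``total``."""
        for component in ("antigen", "adjuvant"):
            s = self.total(component)
            if abs(s - total) > tol:
                raise ValueError(
                    f"{component} amounts sum to {s}, expected {total}"
                    f" (regimen {self.label!r})"
                )

    def scaled(self, factor: float) -> "Regimen":
        """Same schedule with every amount multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("factor must be > 0")
        events = tuple(replace(e, amount=e.amount * factor) for e in self.events)
        return Regimen(events, label=f"{self.label}x{factor:g}")

    # -- serialization ------------------------------------------------------

    def to_config(self) -> list[dict]:
        return [
            {
                "day": e.start_time,
                "fraction": e.amount,
                "duration_days": e.duration,
                "component": e.component,
            }
            for e in self.events
        ]

    @classmethod
    def from_config(cls, entries: Iterable[dict], label: str = "") -> "Regimen":
        events = tuple(
            DoseEvent(
                start_time=float(d["day"]),
                amount=float(d["fraction"]),
                duration=float(d.get("duration_days", 0.0)),
                component=str(d.get("component", "both")),
            )
            for d in entries
        )
        return cls(events, label=label)

    def to_yaml(self) -> str:
        return yaml.safe_dump({"label": self.label, "events": self.to_config()})

    @classmethod
    def from_file(cls, path: str) -> "Regimen":
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text) if not path.endswith(".json") else json.loads(text)
        if isinstance(data, list):
            return cls.from_config(data)
        return cls.from_config(data["events"], label=data.get("label", ""))


# -- constructors -----------------------------------------------------------


def make_bolus(total: float = 1.0, component: str = "both") -> Regimen:
    """Traditional single-shot immunization: the whole dose at day 0."""
    return Regimen((DoseEvent(0.0, total, 0.0, component),), label="bolus")


def make_exponential_ed(
    n_doses: int,
    interval: float = 2.0,
    total: float = 1.0,
    component: str = "both",
) -> Regimen:
    """Escalating-dose immunization with exponentially increasing amounts.

    Injection ``k`` (k = 0..n_doses-1) is given on day ``k*interval`` with an
    amount proportional to ``e**k``, normalized so the amounts sum to
    ``total``.  With ``n_doses=7, interval=2`` this is the 7-shot escalating
    regimen whose final injection on day 12 carries 63% of the dose.
    """
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    if n_doses > 1 and interval <= 0:
        raise ValueError("interval must be > 0 when n_doses > 1")
    weights = [math.exp(k) for k in range(n_doses)]
    norm = sum(weights)
    events = tuple(
        DoseEvent(k * interval if n_doses > 1 else 0.0, total * w / norm, 0.0, component)
        for k, w in enumerate(weights)
    )
    return Regimen(events, label=f"{n_doses}ed")


def make_dose_number_series(
    n_doses: int, span: float = 12.0, total: float = 1.0
) -> Regimen:
    """Escalating regimen with ``n_doses`` injections spread over ``span`` days.

    Keeps the exponential escalation pattern and the total time window fixed
    while varying the number of injections (interval = span/(n-1)).
    """
    if n_doses == 1:
        return make_bolus(total)
    return make_exponential_ed(n_doses, interval=span / (n_doses - 1), total=total)


def make_two_dose(
    first_fraction: float,
    interval: float = 7.0,
    total: float = 1.0,
    component: str = "both",
) -> Regimen:
    """Two-shot extended prime: ``first_fraction`` at day 0, the rest at ``interval``.

    ``make_two_dose(0.2, 7)`` is the optimized 2-ED regimen (20% day 0,
    80% day 7).  ``first_fraction=1`` degenerates to a bolus.
    """
    if not 0 < first_fraction <= 1:
        raise ValueError(f"first_fraction must be in (0, 1], got {first_fraction}")
    events = [DoseEvent(0.0, total * first_fraction, 0.0, component)]
    if first_fraction < 1.0:
        events.append(DoseEvent(interval, total * (1.0 - first_fraction), 0.0, component))
    label = "2ed" if abs(first_fraction - 0.2) < 1e-12 and interval == 7.0 else (
        f"2dose:{first_fraction:g}:{interval:g}"
    )
    return Regimen(tuple(events), label=label)


def make_mismatched(antigen: Regimen, adjuvant: Regimen, label: str = "") -> Regimen:
    """Combine an antigen schedule with an independent adjuvant schedule.

    Used for the co-administration check: e.g. bolus adjuvant with escalating
    antigen, which desynchronizes DC recruitment from antigen availability.
    """
    events = tuple(
        replace(e, component="antigen") for e in antigen.events_for("antigen")
    ) + tuple(replace(e, component="adjuvant") for e in adjuvant.events_for("adjuvant"))
    if not label:
        label = f"ag[{antigen.label}]+adj[{adjuvant.label}]"
    return Regimen(events, label=label)


def with_extended_release(
    regimen: Regimen, event_index: int, duration: float
) -> Regimen:
    """Turn one event into a constant-rate release of the same total amount.

    The event at ``event_index`` releases its amount uniformly over
    ``[start, start + duration]``.  ``duration=0`` leaves the event unchanged.
    If the event delivers both components, only the antigen is extended; the
    adjuvant is still given as an impulse at the event's start (extended
    release models slow antigen efflux from the injection-site depot).
    """
    if not 0 <= event_index < len(regimen.events):
        raise ValueError(
            f"event_index {event_index} out of range for {len(regimen.events)} events"
        )
    if duration < 0:
        raise ValueError("duration must be >= 0")
    target = regimen.events[event_index]
    if duration == 0:
        return regimen
    new_events = list(regimen.events)
    if target.component == "both":
        new_events[event_index] = replace(target, component="antigen", duration=duration)
        new_events.append(replace(target, component="adjuvant"))
    else:
        new_events[event_index] = replace(target, duration=duration)
    label = f"{regimen.label}-ext{duration:g}"
    return Regimen(tuple(new_events), label=label)


# -- querying ---------------------------------------------------------------


def input_rate(
    regimen: Regimen, t: float, component: str = "antigen"
) -> tuple[float, list[DoseEvent]]:
    """Continuous input rate at time ``t`` plus any impulses occurring at ``t``.

    Returns ``(rate, impulses)`` where ``rate`` (amount/day) sums the active
    constant-rate releases and ``impulses`` lists impulse events whose
    start_time equals ``t`` exactly.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    rate = 0.0
    impulses: list[DoseEvent] = []
    for e in regimen.events_for(component):
        if e.is_impulse:
            if e.start_time == t:
                impulses.append(e)
        elif e.start_time <= t < e.end_time:
            rate += e.rate
    return rate, impulses


# -- shorthand parsing ------------------------------------------------------

_SHORTHAND_HELP = (
    "bolus | 7ed | 2ed | 2ed-ext:<days> | ned:<n> | 2dose:<frac>:<interval>"
)


def parse_regimen(name: str) -> Regimen:
    """Build a regimen from a CLI shorthand name.

    Recognized forms: ``bolus``, ``7ed``, ``2ed``, ``2ed-ext:<days>``,
    ``ned:<n>`` (n escalating doses over 12 days), and
    ``2dose:<frac>:<interval>``.
    """
    name = name.strip().lower()
    if name == "bolus":
        return make_bolus()
    if name == "7ed":
        return make_exponential_ed(7, 2.0)
    if name == "2ed":
        return make_two_dose(0.2, 7.0)
    if name.startswith("2ed-ext:"):
        days = float(name.split(":", 1)[1])
        base = make_two_dose(0.2, 7.0)
        return with_extended_release(base, 1, days)
    if name.startswith("ned:"):
        n = int(name.split(":", 1)[1])
        return make_dose_number_series(n)
    if name.startswith("2dose:"):
        _, frac, interval = name.split(":")
        return make_two_dose(float(frac), float(interval))
    raise ValueError(f"unknown regimen {name!r}; expected one of: {_SHORTHAND_HELP}")


def shipped_regimens() -> dict[str, Regimen]:
    """The named regimens exercised throughout the package's experiments."""
    return {
        "bolus": make_bolus(),
        "2ed": make_two_dose(0.2, 7.0),
        "7ed": make_exponential_ed(7, 2.0),
        "2ed-ext10": parse_regimen("2ed-ext:10"),
    }
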