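"""Binding-cooperativity bookkeeping: ddG and fold-changes between states.

Comparing the dissociation constant of the same ligand against two
differently liganded states of the enzyme measures cooperativity as a
free-energy difference,

    ddG = RT ln(Kd_a / Kd_b),

negative when state *a* binds tighter.  Fold-changes are the same ratio
presented the way binding papers quote them (one significant figure,
"20-fold increase" / "10-fold drop").
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import DomainError, ValidationError

__all__ = [
    "R_GAS",
    "NO_BINDING",
    "Direction",
    "BindingState",
    "ThermoComparison",
    "delta_delta_g",
    "fold_change",
    "cooperativity_report",
]

R_GAS = 8.314  # J mol^-1 K^-1


class _NoBinding:
    """Sentinel for ligand/state pairs with no detectable binding."""

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NO_BINDING"


NO_BINDING = _NoBinding()


class Direction(str, enum.Enum):
    TIGHTER = "tighter"  # state a binds tighter (kd_a < kd_b)
    WEAKER = "weaker"
    EQUAL = "equal"


@dataclass(frozen=True)
class BindingState:
    """A (label, Kd, temperature) row of a state-comparison table."""

    label: str
    kd: float | _NoBinding  # uM
    temperature: float  # K

    def __post_init__(self) -> None:
        if self.kd is not NO_BINDING and not (self.kd > 0):
            raise DomainError(f"state {self.label!r}: kd must be > 0 or NO_BINDING")


@dataclass
class ThermoComparison:
    state_a: BindingState
    state_b: BindingState
    ddg: float  # kJ/mol, RT ln(kd_a/kd_b)
    fold: float  # exact ratio >= 1
    fold_presented: str  # e.g. "10-fold"
    direction: Direction


def _check_kd(name: str, kd) -> float:
    if kd is NO_BINDING:
        raise DomainError(f"{name} is the no-binding sentinel; cannot enter ddG math")
    kd = float(kd)
    if not (kd > 0 and math.isfinite(kd)):
        raise DomainError(f"{name} must be a positive finite Kd, got {kd!r}")
    return kd


def delta_delta_g(
    kd_a: float,
    kd_b: float,
    temperature: float,
    temperature_b: float | None = None,
    allow_temperature_mismatch: bool = False,
) -> float:
    """ddG = RT ln(Kd_a/Kd_b) in kJ/mol; antisymmetric in (a, b).

    Both states must share the temperature; pass
    ``allow_temperature_mismatch=True`` to override explicitly (the shared
    ``temperature`` is then used).
    """
    a = _check_kd("kd_a", kd_a)
    b = _check_kd("kd_b", kd_b)
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    if temperature_b is not None and temperature_b != temperature:
        if not allow_temperature_mismatch:
            raise ValidationError(
                f"states were measured at different temperatures "
                f"({temperature} K vs {temperature_b} K); comparing Kd values "
                f"across temperatures needs allow_temperature_mismatch=True"
            )
    return R_GAS * temperature * math.log(a / b) / 1000.0


def fold_change(kd_a: float, kd_b: float) -> tuple[float, str, Direction]:
    """Affinity ratio >= 1 with direction, plus the one-significant-figure
    presentation string ("10-fold").  Direction refers to state a: "tighter"
    means kd_a < kd_b."""
    a = _check_kd("kd_a", kd_a)
    b = _check_kd("kd_b", kd_b)
    if a == b:
        return 1.0, "1-fold", Direction.EQUAL
    ratio = max(a, b) / min(a, b)
    exponent = math.floor(math.log10(ratio))
    lead = round(ratio / 10**exponent)
    if lead == 10:
        lead, exponent = 1, exponent + 1
    presented = f"{lead * 10**exponent:g}-fold"
    return ratio, presented, Direction.TIGHTER if a < b else Direction.WEAKER


def cooperativity_report(
    table: dict[str, tuple[float | _NoBinding, float]],
    pairs: list[tuple[str, str]] | None = None,
) -> list[ThermoComparison]:
    """Pairwise ddG/fold-change comparisons across liganded states.

    ``table`` maps state label -> (Kd uM, temperature K); ``pairs`` selects
    the comparisons (default: all pairs sharing a temperature).  States with
    the NO_BINDING sentinel are accepted in the table but excluded from the
    free-energy arithmetic.
    """
    if len(table) < 2:
        return []
    states = {label: BindingState(label, kd, t) for label, (kd, t) in table.items()}
    if pairs is None:
        labels = list(states)
        pairs = [
            (a, b)
            for i, a in enumerate(labels)
            for b in labels[i + 1:]
            if states[a].temperature == states[b].temperature
        ]
    report = []
    for la, lb in pairs:
        if la not in states or lb not in states:
            raise ValidationError(f"unknown state label in pair ({la!r}, {lb!r})")
        sa, sb = states[la], states[lb]
        if sa.kd is NO_BINDING or sb.kd is NO_BINDING:
            continue
        ddg = delta_delta_g(sa.kd, sb.kd, sa.temperature, sb.temperature)
        ratio, presented, direction = fold_change(sa.kd, sb.kd)
        report.append(ThermoComparison(sa, sb, ddg, ratio, presented, direction))
    return report
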