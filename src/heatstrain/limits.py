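"""Occupational WBGT exposure-limit engine.

Screening reference limits in the ISO 7243 style: one WBGT threshold (°C)
per combination of acclimatization status and metabolic-rate class. A case
"exceeds" its limit when its maximum estimated WBGT is equal to or greater
than the limit for its (acclimatization, workload) cell — the boundary is
inclusive.

The packaged default table (°C WBGT)::

                    rest  low  moderate  high  very_high
    acclimatized      33   30        28    25         23
    unacclimatized    32   29        26    22         18

The table is data, not code: it can be replaced from a YAML/JSON file whose
values are validated for completeness and monotonicity (limits never increase
with workload; unacclimatized limits never exceed acclimatized ones).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError, DomainError

__all__ = [
    "MetabolicClass",
    "ExposureLimitTable",
    "DEFAULT_LIMIT_TABLE",
    "get_limit",
    "exceeds_limit",
    "load_limit_table",
    "workload_class",
]


class MetabolicClass(enum.Enum):
    """ISO metabolic-rate (workload) class ordering light to heavy work.

    "Heavy physical work" — intense arm and trunk work, carrying heavy
    material, pushing or pulling heavily loaded carts — is class ``HIGH``.
    """

    REST = "rest"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    VERY_HIGH = "very_high"

    @property
    def rank(self) -> int:
        return _CLASS_ORDER.index(self)


_CLASS_ORDER = [
    MetabolicClass.REST,
    MetabolicClass.LOW,
    MetabolicClass.MODERATE,
    MetabolicClass.HIGH,
    MetabolicClass.VERY_HIGH,
]


@dataclass(frozen=True)
class ExposureLimitTable:
    """WBGT limit (°C) per (acclimatized, MetabolicClass) cell.

    Validated on construction: all 10 cells present; within each
    acclimatization status limits strictly decrease with workload; for every
    class the unacclimatized limit does not exceed the acclimatized one.
    """

    limits: Mapping[tuple[bool, MetabolicClass], float]

    def __post_init__(self) -> None:
        limits = dict(self.limits)
        object.__setattr__(self, "limits", limits)
        missing = [
            (acc, mc)
            for acc in (True, False)
            for mc in MetabolicClass
            if (acc, mc) not in limits
        ]
        if missing:
            raise ConfigError(f"limit table missing cells: {missing}")
        for acc in (True, False):
            row = [limits[(acc, mc)] for mc in _CLASS_ORDER]
            if any(b >= a for a, b in zip(row, row[1:])):
                raise ConfigError(
                    "limits must strictly decrease with workload class "
                    f"(acclimatized={acc}: {row})"
                )
        for mc in MetabolicClass:
            if limits[(False, mc)] > limits[(True, mc)]:
                raise ConfigError(
                    f"unacclimatized limit exceeds acclimatized for {mc.value}"
                )

    def limit(self, acclimatized: bool, mclass: MetabolicClass) -> float:
        return self.limits[(bool(acclimatized), mclass)]


DEFAULT_LIMIT_TABLE = ExposureLimitTable(
    {
        (True, MetabolicClass.REST): 33.0,
        (True, MetabolicClass.LOW): 30.0,
        (True, MetabolicClass.MODERATE): 28.0,
        (True, MetabolicClass.HIGH): 25.0,
        (True, MetabolicClass.VERY_HIGH): 23.0,
        (False, MetabolicClass.REST): 32.0,
        (False, MetabolicClass.LOW): 29.0,
        (False, MetabolicClass.MODERATE): 26.0,
        (False, MetabolicClass.HIGH): 22.0,
        (False, MetabolicClass.VERY_HIGH): 18.0,
    }
)


def get_limit(
    table: ExposureLimitTable, acclimatized: bool, mclass: MetabolicClass
) -> float:
    """Look up the WBGT limit (°C) for one cell."""
    try:
        return table.limit(acclimatized, mclass)
    except KeyError as exc:  # table validation makes this unreachable
        raise ConfigError(f"limit table missing {(acclimatized, mclass)}") from exc


def exceeds_limit(
    wbgt_max: float,
    acclimatized: bool,
    mclass: MetabolicClass,
    table: ExposureLimitTable = DEFAULT_LIMIT_TABLE,
) -> bool:
    """True iff ``wbgt_max`` is equal to or greater than the cell's limit."""
    import math

    if not math.isfinite(wbgt_max):
        raise DomainError(f"wbgt_max must be finite, got {wbgt_max}")
    return wbgt_max >= get_limit(table, acclimatized, mclass)


def workload_class(heavy_exertion: bool) -> MetabolicClass:
    """Map the case table's heavy-exertion flag to a metabolic-rate class.

    Heavy physical work maps to ``HIGH``; all other outdoor manual work is
    treated as at least ``MODERATE``.
    """
    return MetabolicClass.HIGH if heavy_exertion else MetabolicClass.MODERATE


def load_limit_table(source: str | Path | Mapping) -> ExposureLimitTable:
    """Load and validate a limit table from YAML/JSON or a mapping.

    Expected shape::

        limits:
          acclimatized:   {rest: 33, low: 30, moderate: 28, high: 25, very_high: 23}
          unacclimatized: {rest: 32, low: 29, moderate: 26, high: 22, very_high: 18}
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if "limits" in data:
        data = data["limits"]
    if not isinstance(data, Mapping):
        raise ConfigError("limit table file must map acclimatization to classes")
    limits: dict[tuple[bool, MetabolicClass], float] = {}
    for key, acc in (("acclimatized", True), ("unacclimatized", False)):
        row = data.get(key)
        if not isinstance(row, Mapping):
            raise ConfigError(f"limit table missing {key!r} section")
        for name, value in row.items():
            try:
                mc = MetabolicClass(name)
            except ValueError as exc:
                raise ConfigError(f"unknown metabolic class {name!r}") from exc
            try:
                limits[(acc, mc)] = float(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"non-numeric limit for {key}.{name}") from exc
    return ExposureLimitTable(limits)
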