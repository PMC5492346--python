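"""Worker-case data model, flag derivation from weather, and cohort summaries.

A :class:`WorkerCase` is one compensated occupational heat-related illness:
age, whether the work was heavy physical work, whether the worker was
unacclimatized (less than one week since first outdoor placement), the onset
date, the event flags (tropical night the night before onset; onset day
inside a heat wave), and the maximum estimated WBGT around onset.

The package ships a reference cohort of the 47 compensated cases among
Korean outdoor workers (2010–2014) used to validate the pipeline; see
:func:`load_reference_cohort`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from datetime import date, timedelta
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import AnalysisConfig
from .errors import (
    CoverageError,
    DomainError,
    EmptyInputError,
    IncompleteCaseError,
    IntegrityError,
    SchemaError,
)
from .events import daily_summaries, detect_heat_waves, heat_wave_days, is_tropical_night
from .limits import (
    DEFAULT_LIMIT_TABLE,
    ExposureLimitTable,
    MetabolicClass,
    exceeds_limit,
    get_limit,
    workload_class,
)
from .wbgt import MeteoSeries

__all__ = [
    "WorkerCase",
    "CaseClassification",
    "CohortSummary",
    "load_cases",
    "save_cases",
    "load_reference_cohort",
    "derive_flags",
    "classify",
    "summarize",
    "round_percent",
]

CASE_COLUMNS = [
    "case_id",
    "age",
    "heavy_exertion",
    "unacclimatized",
    "onset_date",
    "tropical_night",
    "heat_wave",
    "wbgt_max",
]

#: SHA-256 of the packaged reference cohort CSV (integrity check).
_REFERENCE_SHA256 = "0e56833931c14da8edcf6a9328a7b78f009d747cba7a72edbc955d22a001ec6a"
_REFERENCE_RESOURCE = "table1_cases.csv"


@dataclass(frozen=True)
class WorkerCase:
    case_id: str
    age: int
    heavy_exertion: bool
    unacclimatized: bool
    onset_date: Optional[date] = None
    tropical_night: Optional[bool] = None
    heat_wave: Optional[bool] = None
    wbgt_max: Optional[float] = None

    def __post_init__(self) -> None:
        if not 15 <= self.age <= 100:
            raise DomainError(f"case {self.case_id}: age {self.age} outside [15, 100]")
        if self.wbgt_max is not None and not pd.notna(self.wbgt_max):
            raise DomainError(f"case {self.case_id}: wbgt_max must be finite")


@dataclass(frozen=True)
class CaseClassification:
    """A case joined with its exposure-limit verdict."""

    case: WorkerCase
    mclass: MetabolicClass
    limit_c: float
    exceeds: bool


@dataclass(frozen=True)
class CohortSummary:
    """Counts and half-up 1-decimal percentages over a case set.

    Indeterminate flags count as ``False`` in the proportions and are
    reported separately in ``indeterminate``.
    """

    n_total: int
    counts: dict[str, int]
    proportions: dict[str, float]
    indeterminate: dict[str, int]
    age_decade_counts: dict[int, int]
    age_decade_proportions: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "counts": dict(self.counts),
            "proportions_pct": dict(self.proportions),
            "indeterminate": dict(self.indeterminate),
            "age_decades": {
                str(k): {
                    "count": self.age_decade_counts[k],
                    "pct": self.age_decade_proportions[k],
                }
                for k in sorted(self.age_decade_counts)
            },
        }


def round_percent(count: int, total: int) -> float:
    """100·count/total rounded half-up to one decimal (62.65 -> 62.7)."""
    if total <= 0:
        raise EmptyInputError("total must be positive")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_TRUE = {"1", "true", "o", "yes", "y"}
_FALSE = {"0", "false", "x", "no", "n"}


def _parse_flag(raw, column: str, row_label) -> Optional[bool]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    text = str(raw).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise SchemaError(f"row {row_label}: cannot parse flag {column}={raw!r}")


def load_cases(path: str | Path) -> list[WorkerCase]:
    """Read worker cases from CSV.

    The header must contain the eight schema columns; flags accept ``o``/``x``
    as well as ``1``/``0``. ``onset_date`` may be empty. Raises
    :class:`SchemaError` naming the offending row on any parse failure.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: no header row") from exc
    missing = [c for c in CASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    cases: list[WorkerCase] = []
    for idx, row in df.iterrows():
        label = row["case_id"] or f"#{idx + 1}"
        try:
            age = int(row["age"])
        except ValueError as exc:
            raise SchemaError(f"row {label}: unparsable age {row['age']!r}") from exc
        raw_wbgt = row["wbgt_max"].strip()
        try:
            wbgt_max = float(raw_wbgt) if raw_wbgt else None
        except ValueError as exc:
            raise SchemaError(f"row {label}: unparsable wbgt_max {raw_wbgt!r}") from exc
        raw_onset = row["onset_date"].strip()
        onset = date.fromisoformat(raw_onset) if raw_onset else None
        heavy = _parse_flag(row["heavy_exertion"], "heavy_exertion", label)
        unacc = _parse_flag(row["unacclimatized"], "unacclimatized", label)
        if heavy is None or unacc is None:
            raise SchemaError(f"row {label}: heavy_exertion/unacclimatized required")
        cases.append(
            WorkerCase(
                case_id=str(row["case_id"]),
                age=age,
                heavy_exertion=heavy,
                unacclimatized=unacc,
                onset_date=onset,
                tropical_night=_parse_flag(row["tropical_night"], "tropical_night", label),
                heat_wave=_parse_flag(row["heat_wave"], "heat_wave", label),
                wbgt_max=wbgt_max,
            )
        )
    return cases


def save_cases(cases: Sequence[WorkerCase], path: str | Path) -> None:
    """Write cases to CSV with flags as 0/1 (round-trips with load_cases)."""

    def flag(value: Optional[bool]) -> str:
        return "" if value is None else str(int(value))

    rows = [
        {
            "case_id": c.case_id,
            "age": c.age,
            "heavy_exertion": flag(c.heavy_exertion),
            "unacclimatized": flag(c.unacclimatized),
            "onset_date": c.onset_date.isoformat() if c.onset_date else "",
            "tropical_night": flag(c.tropical_night),
            "heat_wave": flag(c.heat_wave),
            "wbgt_max": "" if c.wbgt_max is None else repr(c.wbgt_max),
        }
        for c in cases
    ]
    pd.DataFrame(rows, columns=CASE_COLUMNS).to_csv(path, index=False)


def reference_cohort_path() -> Path:
    """Filesystem path of the packaged 47-case reference cohort."""
    return Path(resources.files("heatstrain.data") / _REFERENCE_RESOURCE)


def load_reference_cohort(verify: bool = True) -> list[WorkerCase]:
    """Load the packaged 47-case reference cohort.

    With ``verify=True`` (default) the file's SHA-256 is checked and an
    :class:`IntegrityError` raised on mismatch.
    """
    path = reference_cohort_path()
    if verify:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        if digest != _REFERENCE_SHA256:
            raise IntegrityError(
                f"reference cohort checksum mismatch: {digest} != {_REFERENCE_SHA256}"
            )
    return load_cases(path)


def derive_flags(
    case: WorkerCase,
    weather: MeteoSeries,
    config: AnalysisConfig | None = None,
) -> WorkerCase:
    """Fill a case's event flags and WBGT maximum from station weather.

    Requires weather coverage of the onset day and the three prior days
    (raises :class:`CoverageError` listing missing days). The tropical-night
    flag is the night immediately preceding onset; the heat-wave flag is
    true iff the onset day lies inside a detected episode; ``wbgt_max`` is
    the maximum estimated WBGT over the ``config.wbgt_window_days`` calendar
    days ending at onset. Idempotent for fixed weather and config.
    """
    config = config or AnalysisConfig()
    if case.onset_date is None:
        raise IncompleteCaseError(f"case {case.case_id}: onset_date required")
    summaries = daily_summaries(weather, config)
    have = {s.date for s in summaries}
    required = [case.onset_date - timedelta(days=k) for k in range(0, 4)]
    missing = sorted(d for d in required if d not in have)
    if missing:
        raise CoverageError(
            f"case {case.case_id}: weather missing days {[d.isoformat() for d in missing]}"
        )
    by_date = {s.date: s for s in summaries}
    episodes = detect_heat_waves(
        summaries,
        threshold=config.heat_wave_threshold_c,
        min_run=config.heat_wave_min_run_days,
    )
    window = [
        case.onset_date - timedelta(days=k)
        for k in range(config.wbgt_window_days)
    ]
    wbgts = [
        by_date[d].wbgt_max for d in window if d in by_date and by_date[d].wbgt_max is not None
    ]
    return replace(
        case,
        tropical_night=is_tropical_night(
            by_date[case.onset_date], threshold=config.tropical_night_threshold_c
        ),
        heat_wave=case.onset_date in heat_wave_days(episodes),
        wbgt_max=max(wbgts) if wbgts else None,
    )


def classify(
    case: WorkerCase, table: ExposureLimitTable = DEFAULT_LIMIT_TABLE
) -> CaseClassification:
    """Classify one case against the exposure-limit table.

    Workload class comes from the heavy-exertion flag; the applicable limit
    from the worker's acclimatization status; ``exceeds`` is inclusive
    (WBGTmax equal to the limit counts as exceeding).
    """
    if case.wbgt_max is None:
        raise IncompleteCaseError(f"case {case.case_id}: wbgt_max required")
    mclass = workload_class(case.heavy_exertion)
    acclimatized = not case.unacclimatized
    limit = get_limit(table, acclimatized, mclass)
    return CaseClassification(
        case=case,
        mclass=mclass,
        limit_c=limit,
        exceeds=exceeds_limit(case.wbgt_max, acclimatized, mclass, table),
    )


def summarize(
    cases: Sequence[WorkerCase],
    classifications: Optional[Sequence[CaseClassification]] = None,
) -> CohortSummary:
    """Tally cohort counts and percentages.

    If ``classifications`` is omitted, each case with a WBGT maximum is
    classified against the default limit table. Indeterminate flags count as
    ``False`` and are tallied separately. Permutation-invariant in case
    order.
    """
    if not cases:
        raise EmptyInputError("empty cohort")
    if classifications is None:
        classifications = [
            classify(c) for c in cases if c.wbgt_max is not None
        ]
        if len(classifications) != len(cases):
            raise IncompleteCaseError(
                "cannot classify: some cases lack wbgt_max; pass classifications"
            )
    if len(classifications) != len(cases):
        raise SchemaError(
            f"{len(classifications)} classifications for {len(cases)} cases"
        )
    if {id(cl.case) for cl in classifications} != {id(c) for c in cases}:
        if {cl.case.case_id for cl in classifications} != {c.case_id for c in cases}:
            raise SchemaError("classifications not aligned with cases")

    n = len(cases)
    counts = {
        "heat_wave": sum(bool(c.heat_wave) for c in cases),
        "tropical_night": sum(bool(c.tropical_night) for c in cases),
        "unacclimatized": sum(c.unacclimatized for c in cases),
        "heavy_exertion": sum(c.heavy_exertion for c in cases),
        "exceeds_limit": sum(cl.exceeds for cl in classifications),
    }
    indeterminate = {
        "heat_wave": sum(c.heat_wave is None for c in cases),
        "tropical_night": sum(c.tropical_night is None for c in cases),
    }
    decades: dict[int, int] = {}
    for c in cases:
        decades[c.age // 10 * 10] = decades.get(c.age // 10 * 10, 0) + 1
    return CohortSummary(
        n_total=n,
        counts=counts,
        proportions={k: round_percent(v, n) for k, v in counts.items()},
        indeterminate=indeterminate,
        age_decade_counts=dict(sorted(decades.items())),
        age_decade_proportions={
            k: round_percent(v, n) for k, v in sorted(decades.items())
        },
    )
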