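"""Rule-based detection of heat waves and tropical nights.

A heat wave is a run of at least ``min_run`` consecutive calendar days whose
daily maximum dry-bulb temperature reaches the threshold (default 33 °C,
inclusive — "33 °C or higher"). A tropical night keeps its minimum strictly
above the threshold (default 25 °C — "above 25 °C") over the configured night
window. Missing calendar days break heat-wave runs rather than being
interpolated; a night window with insufficient coverage yields an
*indeterminate* tropical-night flag (``None``), which is distinct from
``False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional, Sequence

from .config import AnalysisConfig, NightWindow
from .errors import EmptyInputError, OrderingError
from .wbgt import MeteoSeries, series_wbgt

__all__ = [
    "DailySummary",
    "HeatWaveEpisode",
    "daily_summaries",
    "detect_heat_waves",
    "is_tropical_night",
    "heat_wave_days",
]


@dataclass(frozen=True)
class DailySummary:
    """Per-calendar-day aggregates used by the event rules.

    ``night_tmin`` is the minimum temperature over the night window *ending*
    on this date's morning; it is ``None`` when fewer than the required
    fraction of night-window hours were observed. ``wbgt_max`` is the maximum
    estimated WBGT over this date's in-envelope hours (``None`` if none).
    ``tmax >= night_tmin`` is *not* an invariant: the two windows differ.
    """

    date: date
    tmax: float
    night_tmin: Optional[float] = None
    wbgt_max: Optional[float] = None


@dataclass(frozen=True)
class HeatWaveEpisode:
    """A maximal run of qualifying days, inclusive of both endpoints."""

    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise OrderingError(
                f"episode end {self.end_date} before start {self.start_date}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def __contains__(self, day: date) -> bool:
        return self.start_date <= day <= self.end_date


def _night_hours(window: NightWindow, day: date):
    """Yield (date, hour) pairs of the night window labelled ``day``."""
    prev = day - timedelta(days=1)
    for h in range(window.start_hour, 24):
        yield prev, h
    for h in range(0, window.end_hour):
        yield day, h


def daily_summaries(
    series: MeteoSeries, config: AnalysisConfig | None = None
) -> list[DailySummary]:
    """Aggregate an hourly series into one :class:`DailySummary` per day.

    A day appears as soon as it has at least one observation; its ``tmax``
    uses whatever hours exist (the daily max is robust to gaps). The night
    minimum requires ``config.night_min_coverage`` of the window's hours.
    """
    config = config or AnalysisConfig()
    if len(series) == 0:  # MeteoSeries forbids this, but guard for duck types
        raise EmptyInputError("empty meteorological series")

    by_day: dict[date, list] = {}
    # (date, hour) -> min ta in that hour, for night-window lookups
    hour_min: dict[tuple[date, int], float] = {}
    for obs in series:
        d = obs.timestamp.date()
        by_day.setdefault(d, []).append(obs)
        key = (d, obs.timestamp.hour)
        hour_min[key] = min(hour_min.get(key, obs.ta), obs.ta)

    wbgt_by_day: dict[date, list[float]] = {}
    for ts, est in series_wbgt(series):
        if est.valid:
            wbgt_by_day.setdefault(ts.date(), []).append(est.wbgt)

    window = config.night_window
    need = config.night_min_coverage * window.n_hours
    summaries = []
    for d in sorted(by_day):
        night_vals = [
            hour_min[key] for key in _night_hours(window, d) if key in hour_min
        ]
        night_tmin = min(night_vals) if len(night_vals) >= need else None
        wbgts = wbgt_by_day.get(d)
        summaries.append(
            DailySummary(
                date=d,
                tmax=max(o.ta for o in by_day[d]),
                night_tmin=night_tmin,
                wbgt_max=max(wbgts) if wbgts else None,
            )
        )
    return summaries


def detect_heat_waves(
    summaries: Sequence[DailySummary],
    threshold: float = 33.0,
    min_run: int = 2,
) -> list[HeatWaveEpisode]:
    """Find maximal runs of >= ``min_run`` consecutive days with
    ``tmax >= threshold``. A missing calendar day breaks a run.

    Raises :class:`OrderingError` if summaries are not date-sorted.
    """
    dates = [s.date for s in summaries]
    for prev, cur in zip(dates, dates[1:]):
        if cur <= prev:
            raise OrderingError(f"summaries not date-sorted at {cur}")

    episodes: list[HeatWaveEpisode] = []
    run_start: Optional[date] = None
    run_end: Optional[date] = None

    def flush() -> None:
        nonlocal run_start, run_end
        if run_start is not None and (run_end - run_start).days + 1 >= min_run:
            episodes.append(HeatWaveEpisode(run_start, run_end))
        run_start = run_end = None

    for s in summaries:
        hot = s.tmax >= threshold
        contiguous = run_end is not None and s.date == run_end + timedelta(days=1)
        if hot and contiguous:
            run_end = s.date
        else:
            flush()
            if hot:
                run_start = run_end = s.date
    flush()
    return episodes


def is_tropical_night(
    summary: DailySummary, threshold: float = 25.0
) -> Optional[bool]:
    """Strictly-above test on the night minimum; ``None`` if indeterminate."""
    if summary.night_tmin is None:
        return None
    return summary.night_tmin > threshold


def heat_wave_days(episodes: Sequence[HeatWaveEpisode]) -> set[date]:
    """The set of calendar days covered by any episode."""
    days: set[date] = set()
    for ep in episodes:
        d = ep.start_date
        while d <= ep.end_date:
            days.add(d)
            d += timedelta(days=1)
    return days
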