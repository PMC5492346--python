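"""Analysis configuration: event thresholds, night window, WBGT-max window.

Defaults follow the Korean heat-advisory conventions used throughout the
package: a heat wave is >=2 consecutive days with daily maximum temperature
>=33 °C, a tropical night keeps its minimum strictly above 25 °C over the
18:00–09:00 window, and the per-case WBGT maximum is taken over the onset
calendar day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

__all__ = ["NightWindow", "AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class NightWindow:
    """Half-open night window: ``start_hour`` on the previous calendar day
    (inclusive) to ``end_hour`` on the morning of the labelled day
    (exclusive). The tropical-night flag attaches to the morning's date, so
    "after a tropical night" means the night immediately preceding onset."""

    start_hour: int = 18
    end_hour: int = 9

    def __post_init__(self) -> None:
        for h in (self.start_hour, self.end_hour):
            if not 0 <= h <= 23:
                raise ConfigError(f"night window hour {h} outside [0, 23]")
        if self.start_hour <= self.end_hour:
            raise ConfigError(
                "night window must wrap midnight (start_hour > end_hour); "
                f"got start={self.start_hour}, end={self.end_hour}"
            )

    @property
    def n_hours(self) -> int:
        return (24 - self.start_hour) + self.end_hour


@dataclass(frozen=True)
class AnalysisConfig:
    heat_wave_threshold_c: float = 33.0
    heat_wave_min_run_days: int = 2
    tropical_night_threshold_c: float = 25.0
    night_window: NightWindow = field(default_factory=NightWindow)
    #: Fraction of night-window hours required to compute night_tmin at all.
    night_min_coverage: float = 0.75
    #: Number of calendar days (ending at onset) over which WBGTmax is taken.
    wbgt_window_days: int = 1

    def __post_init__(self) -> None:
        if self.heat_wave_threshold_c <= 0 or self.tropical_night_threshold_c <= 0:
            raise ConfigError("thresholds must be positive")
        if self.heat_wave_min_run_days < 1:
            raise ConfigError("heat_wave.min_run_days must be >= 1")
        if not 0.0 < self.night_min_coverage <= 1.0:
            raise ConfigError("night_min_coverage must be in (0, 1]")
        if self.wbgt_window_days < 1:
            raise ConfigError("wbgt_window_days must be >= 1")


def load_config(source: str | Path | Mapping[str, Any] | None) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML/JSON file or mapping.

    Recognised keys (all optional)::

        heat_wave:       {threshold_c, min_run_days}
        tropical_night:  {threshold_c}
        night_window:    {start_hour, end_hour}
        wbgt_window_days: int
    """
    if source is None:
        return AnalysisConfig()
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")

    def section(name: str) -> Mapping[str, Any]:
        sec = data.get(name, {})
        if not isinstance(sec, Mapping):
            raise ConfigError(f"config section {name!r} must be a mapping")
        return sec

    hw = section("heat_wave")
    tn = section("tropical_night")
    nw = section("night_window")
    defaults = AnalysisConfig()
    try:
        return AnalysisConfig(
            heat_wave_threshold_c=float(
                hw.get("threshold_c", defaults.heat_wave_threshold_c)
            ),
            heat_wave_min_run_days=int(
                hw.get("min_run_days", defaults.heat_wave_min_run_days)
            ),
            tropical_night_threshold_c=float(
                tn.get("threshold_c", defaults.tropical_night_threshold_c)
            ),
            night_window=NightWindow(
                start_hour=int(nw.get("start_hour", defaults.night_window.start_hour)),
                end_hour=int(nw.get("end_hour", defaults.night_window.end_hour)),
            ),
            wbgt_window_days=int(
                data.get("wbgt_window_days", defaults.wbgt_window_days)
            ),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid config value: {exc}") from exc
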