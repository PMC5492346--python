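"""Seeded generators for synthetic weather series and worker cohorts.

These emulate the statistical structure the analysis assumes so that every
pipeline stage is testable without external data:

* hourly summer urban weather with a sinusoidal diurnal cycle (minimum near
  06:00, maximum near 15:00), declared heat-wave episodes that lift the
  daily maximum to a target peak, declared tropical nights whose minima are
  floored above 25 °C, relative humidity anti-phased with temperature, and
  optional Gaussian noise;
* worker cohorts with independent Bernoulli risk flags at configured
  prevalences, uniform integer ages, and truncated-Gaussian WBGT maxima.

Default cohort prevalences and WBGT moments match the packaged 47-case
reference cohort (heavy 41/47, unacclimatized 22/47, heat wave 29/47,
tropical night 37/47; WBGT mean 29.9 °C, SD 2.1 °C). A fixed seed gives a
byte-identical series; distinct seeds give independent streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .cases import WorkerCase
from .wbgt import MeteoObservation, MeteoSeries

__all__ = [
    "WeatherGenConfig",
    "CohortGenConfig",
    "generate_weather",
    "generate_cohort",
]

#: Arbitrary but fixed series start (a Korean mid-summer date); day index 0.
DEFAULT_START = date(2013, 7, 15)

#: Floor applied to declared tropical-night windows, safely above the 25 °C rule.
TROPICAL_NIGHT_FLOOR_C = 26.0

_DIURNAL_MIN_HOUR = 6
_DIURNAL_MAX_HOUR = 15


@dataclass(frozen=True)
class WeatherGenConfig:
    n_days: int = 10
    base_tmean: float = 26.0
    diurnal_amplitude: float = 4.0
    #: (start_day, length_days, peak_tmax °C) triples; day indices from 0.
    heatwave_episodes: tuple[tuple[int, int, float], ...] = ()
    #: Day indices whose *preceding* night is made tropical (min > 25 °C).
    tropical_night_nights: tuple[int, ...] = ()
    rh_base: float = 70.0
    rh_diurnal_amplitude: float = 20.0
    noise_sd: float = 0.3
    seed: int = 0
    start_date: date = DEFAULT_START

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "heatwave_episodes",
            tuple(tuple(e) for e in self.heatwave_episodes),
        )
        object.__setattr__(
            self, "tropical_night_nights", tuple(self.tropical_night_nights)
        )
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.diurnal_amplitude < 0 or self.rh_diurnal_amplitude < 0:
            raise ConfigError("amplitudes must be >= 0")
        if not 5.0 <= self.rh_base <= 99.0:
            raise ConfigError("rh_base must lie in [5, 99] %")
        for start, length, peak in self.heatwave_episodes:
            if length < 2:
                raise ConfigError(f"episode at day {start}: length {length} < 2")
            if peak < 33.0:
                raise ConfigError(f"episode at day {start}: peak {peak} < 33 °C")
            if start < 0 or start + length > self.n_days:
                raise ConfigError(f"episode [{start}, {start + length}) outside series")
            if peak < self.base_tmean + self.diurnal_amplitude:
                raise ConfigError(
                    f"episode peak {peak} below the background daily maximum"
                )
        for d in self.tropical_night_nights:
            if not 1 <= d < self.n_days:
                raise ConfigError(
                    f"tropical night day index {d} outside [1, n_days); the "
                    "preceding evening must exist in the series"
                )


def _diurnal_anomaly(hour: int, amplitude: float) -> float:
    """Asymmetric sinusoid: −amplitude at 06:00, +amplitude at 15:00."""
    if _DIURNAL_MIN_HOUR <= hour <= _DIURNAL_MAX_HOUR:
        phase = (hour - _DIURNAL_MIN_HOUR) / (_DIURNAL_MAX_HOUR - _DIURNAL_MIN_HOUR)
        return -amplitude * math.cos(math.pi * phase)
    fall = (hour - _DIURNAL_MAX_HOUR) % 24 / (24 - (_DIURNAL_MAX_HOUR - _DIURNAL_MIN_HOUR))
    return amplitude * math.cos(math.pi * fall)


def generate_weather(config: WeatherGenConfig) -> MeteoSeries:
    """Generate an hourly :class:`MeteoSeries` of ``config.n_days`` days.

    With ``noise_sd == 0`` the series is closed-form: every background day
    has ``tmax == base_tmean + diurnal_amplitude`` at 15:00 and nightly
    minimum ``base_tmean − diurnal_amplitude`` at 06:00; declared episode
    days reach exactly ``peak_tmax``; declared tropical nights are floored
    at 26 °C while all other nights stay at the background minimum.
    """
    rng = np.random.default_rng(config.seed)
    amp = config.diurnal_amplitude
    episode_days: dict[int, float] = {}
    for start, length, peak in config.heatwave_episodes:
        for d in range(start, start + length):
            # strongest elevation wins where episodes overlap
            elev = peak - (config.base_tmean + amp)
            episode_days[d] = max(episode_days.get(d, 0.0), elev)
    tropical = set(config.tropical_night_nights)

    observations = []
    for day in range(config.n_days):
        for hour in range(24):
            anomaly = _diurnal_anomaly(hour, amp)
            # daytime weight: 0 at the 06:00 minimum, 1 at the 15:00 peak
            weight = (anomaly + amp) / (2 * amp) if amp > 0 else 1.0
            ta = config.base_tmean + anomaly + episode_days.get(day, 0.0) * weight
            # the night window labelled d covers 18:00 (d−1) .. 08:00 (d)
            night_of = day + 1 if hour >= 18 else day
            if night_of in tropical and (hour >= 18 or hour < 9):
                ta = max(ta, TROPICAL_NIGHT_FLOOR_C)
            if config.noise_sd > 0:
                ta += rng.normal(0.0, config.noise_sd)
            norm = anomaly / amp if amp > 0 else 0.0
            rh = float(np.clip(config.rh_base - config.rh_diurnal_amplitude * norm, 5.0, 99.0))
            observations.append(
                MeteoObservation(
                    timestamp=datetime.combine(
                        config.start_date + timedelta(days=day),
                        datetime.min.time(),
                    )
                    + timedelta(hours=hour),
                    ta=round(ta, 4),
                    rh=round(rh, 4),
                )
            )
    return MeteoSeries(station_id=f"SYN-{config.seed}", observations=tuple(observations))


@dataclass(frozen=True)
class CohortGenConfig:
    """Cohort generator; defaults mirror the reference cohort's margins."""

    n_cases: int = 47
    p_heavy: float = 41 / 47
    p_unacclimatized: float = 22 / 47
    p_heat_wave: float = 29 / 47
    p_tropical_night: float = 37 / 47
    wbgt_mean: float = 29.9
    wbgt_sd: float = 2.1
    age_range: tuple[int, int] = (29, 77)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigError("n_cases must be >= 1")
        for name in ("p_heavy", "p_unacclimatized", "p_heat_wave", "p_tropical_night"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        lo, hi = self.age_range
        if not (15 <= lo <= hi <= 100):
            raise ConfigError(f"age_range {self.age_range} outside [15, 100]")
        if self.wbgt_sd < 0:
            raise ConfigError("wbgt_sd must be >= 0")


#: Truncation bounds for generated WBGT maxima (°C).
WBGT_TRUNC = (18.0, 38.0)


def generate_cohort(config: CohortGenConfig) -> list[WorkerCase]:
    """Draw ``n_cases`` independent synthetic worker cases.

    Flags are independent Bernoulli draws at the configured prevalences,
    ages integer-uniform over ``age_range`` (inclusive), and WBGT maxima
    Gaussian truncated to [18, 38] °C by rejection.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    heavy = rng.random(n) < config.p_heavy
    unacc = rng.random(n) < config.p_unacclimatized
    hw = rng.random(n) < config.p_heat_wave
    tn = rng.random(n) < config.p_tropical_night
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    lo, hi = WBGT_TRUNC
    if config.wbgt_sd == 0:
        wbgt = np.full(n, float(np.clip(config.wbgt_mean, lo, hi)))
    else:
        wbgt = np.empty(n)
        remaining = np.arange(n)
        while remaining.size:
            draw = rng.normal(config.wbgt_mean, config.wbgt_sd, remaining.size)
            ok = (draw >= lo) & (draw <= hi)
            wbgt[remaining[ok]] = draw[ok]
            remaining = remaining[~ok]
    return [
        WorkerCase(
            case_id=f"S{i + 1:04d}",
            age=int(ages[i]),
            heavy_exertion=bool(heavy[i]),
            unacclimatized=bool(unacc[i]),
            tropical_night=bool(tn[i]),
            heat_wave=bool(hw[i]),
            wbgt_max=float(round(wbgt[i], 2)),
        )
        for i in range(n)
    ]
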