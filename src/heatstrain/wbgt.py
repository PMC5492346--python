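"""Closed-form WBGT estimation from dry-bulb temperature and relative humidity.

The natural wet-bulb temperature ``Tw`` is approximated by Stull's empirical
inverse-psychrometric fit (all ``atan`` terms in radians, Ta in °C, RH in %):

    Tw = Ta·atan(0.151977·(RH + 8.313659)^1/2)
         + atan(Ta + RH) − atan(RH − 1.676331)
         + 0.00391838·RH^(3/2)·atan(0.023101·RH)
         − 4.686035

and the wet-bulb globe temperature is then estimated with Park's regression
for Korean outdoor conditions:

    WBGT = −0.24418 + 0.553991·Tw + 0.455346·Ta − 0.00217·Tw² + 0.002782·Tw·Ta

The ``atan(Ta + RH)`` term sums °C and % as printed in the source regression;
it is implemented literally, not "corrected".  Both fits are regressions, so a
validity envelope is tracked (RH ∈ [5, 99] %, Ta ∈ [−20, 50] °C): outside it
the value is still computed but flagged invalid, never silently clamped or
dropped — downstream daily maxima must see every hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, EmptyInputError, OrderingError

__all__ = [
    "RH_VALID_RANGE",
    "TA_VALID_RANGE",
    "MeteoObservation",
    "MeteoSeries",
    "WbgtEstimate",
    "stull_wet_bulb",
    "park_wbgt",
    "series_wbgt",
    "in_validity_envelope",
]

#: Validity envelope of the regression fits (flagging only, never clamping).
RH_VALID_RANGE = (5.0, 99.0)
TA_VALID_RANGE = (-20.0, 50.0)


@dataclass(frozen=True)
class MeteoObservation:
    """One timestamped hourly observation from a surface weather station.

    Attributes
    ----------
    timestamp : datetime
        Local civil time, minute resolution.
    ta : float
        Dry-bulb air temperature in °C.
    rh : float
        Relative humidity in %.
    """

    timestamp: datetime
    ta: float
    rh: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ta) and np.isfinite(self.rh)):
            raise DomainError(
                f"non-finite observation at {self.timestamp}: ta={self.ta}, rh={self.rh}"
            )
        if not 0.0 <= self.rh <= 100.0:
            raise DomainError(f"rh={self.rh} outside [0, 100] at {self.timestamp}")
        if not -50.0 <= self.ta <= 60.0:
            raise DomainError(f"ta={self.ta} outside [-50, 60] at {self.timestamp}")


@dataclass(frozen=True)
class MeteoSeries:
    """An ordered hourly (or finer) series for one station.

    Timestamps must be strictly increasing; the series must be non-empty.
    """

    station_id: str
    observations: tuple[MeteoObservation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        if not self.observations:
            raise EmptyInputError(f"station {self.station_id!r}: empty series")
        times = [o.timestamp for o in self.observations]
        for prev, cur in zip(times, times[1:]):
            if cur <= prev:
                raise OrderingError(
                    f"station {self.station_id!r}: timestamps not strictly "
                    f"increasing at {cur} (previous {prev})"
                )

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterable[MeteoObservation]:
        return iter(self.observations)


@dataclass(frozen=True)
class WbgtEstimate:
    """Estimated natural wet-bulb temperature and WBGT for one observation."""

    tw: float
    wbgt: float
    valid: bool = field(default=True)


def _check_finite(ta, rh) -> None:
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if not (np.all(np.isfinite(ta)) and np.all(np.isfinite(rh))):
        raise DomainError("ta and rh must be finite")
    if np.any(rh < 0.0):
        raise DomainError("rh must be >= 0 %")


def in_validity_envelope(ta, rh):
    """True where (ta, rh) lies inside the regression validity envelope."""
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    return (
        (rh >= RH_VALID_RANGE[0])
        & (rh <= RH_VALID_RANGE[1])
        & (ta >= TA_VALID_RANGE[0])
        & (ta <= TA_VALID_RANGE[1])
    )


def stull_wet_bulb(ta, rh):
    """Estimate the natural wet-bulb temperature in °C.

    Parameters
    ----------
    ta : float or array-like
        Dry-bulb air temperature, °C.
    rh : float or array-like
        Relative humidity, %. Must be >= 0.

    Returns
    -------
    float or ndarray
        Wet-bulb temperature estimate in °C (scalar in, scalar out).

    Raises
    ------
    DomainError
        If any input is non-finite or rh is negative. Values outside the
        validity envelope are computed anyway; use
        :func:`in_validity_envelope` to flag them.
    """
    _check_finite(ta, rh)
    scalar = np.isscalar(ta) and np.isscalar(rh)
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    tw = (
        ta * np.arctan(0.151977 * np.sqrt(rh + 8.313659))
        + np.arctan(ta + rh)
        - np.arctan(rh - 1.676331)
        + 0.00391838 * rh ** 1.5 * np.arctan(0.023101 * rh)
        - 4.686035
    )
    return float(tw) if scalar else tw


def park_wbgt(ta: float, rh: float) -> WbgtEstimate:
    """Estimate WBGT from one (ta, rh) pair.

    Returns a :class:`WbgtEstimate` whose ``tw`` equals
    ``stull_wet_bulb(ta, rh)`` exactly and whose ``valid`` flag reports the
    envelope check.
    """
    tw = stull_wet_bulb(ta, rh)
    wbgt = _park_quadratic(tw, ta)
    return WbgtEstimate(
        tw=float(tw), wbgt=float(wbgt), valid=bool(in_validity_envelope(ta, rh))
    )


def _park_quadratic(tw, ta):
    return (
        -0.24418
        + 0.553991 * tw
        + 0.455346 * np.asarray(ta, dtype=float)
        - 0.00217 * np.asarray(tw, dtype=float) ** 2
        + 0.002782 * np.asarray(tw, dtype=float) * np.asarray(ta, dtype=float)
    )


def series_wbgt(
    series: MeteoSeries,
) -> list[tuple[datetime, WbgtEstimate]]:
    """Estimate WBGT for every observation of a series, order preserved."""
    ta = np.array([o.ta for o in series.observations])
    rh = np.array([o.rh for o in series.observations])
    tw = stull_wet_bulb(ta, rh)
    wbgt = _park_quadratic(tw, ta)
    valid = in_validity_envelope(ta, rh)
    return [
        (obs.timestamp, WbgtEstimate(tw=float(t), wbgt=float(w), valid=bool(v)))
        for obs, t, w, v in zip(series.observations, tw, wbgt, valid)
    ]


def series_from_arrays(
    station_id: str,
    timestamps: Sequence[datetime],
    ta: Sequence[float],
    rh: Sequence[float],
) -> MeteoSeries:
    """Build a :class:`MeteoSeries` from parallel sequences."""
    obs = tuple(
        MeteoObservation(timestamp=t, ta=float(a), rh=float(r))
        for t, a, r in zip(timestamps, ta, rh)
    )
    return MeteoSeries(station_id=station_id, observations=obs)
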