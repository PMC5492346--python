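"""Weather CSV I/O.

Schema: ``station_id, timestamp, ta_c, rh_pct`` with a mandatory header,
ISO 8601 local timestamps without UTC offset, UTF-8. One station per file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .wbgt import MeteoObservation, MeteoSeries, series_wbgt

__all__ = ["read_weather_csv", "write_weather_csv", "write_wbgt_csv"]

WEATHER_COLUMNS = ["station_id", "timestamp", "ta_c", "rh_pct"]


def read_weather_csv(path: str | Path) -> MeteoSeries:
    """Read one station's hourly series from CSV."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: no header row") from exc
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    stations = df["station_id"].astype(str).unique()
    if len(stations) != 1:
        raise SchemaError(f"{path}: expected one station, found {list(stations)}")
    try:
        times = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: unparsable timestamp ({exc})") from exc
    obs = tuple(
        MeteoObservation(timestamp=t.to_pydatetime(), ta=float(a), rh=float(r))
        for t, a, r in zip(times, df["ta_c"], df["rh_pct"])
    )
    return MeteoSeries(station_id=str(stations[0]), observations=obs)


def _frame(series: MeteoSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "station_id": series.station_id,
            "timestamp": [o.timestamp.isoformat() for o in series],
            "ta_c": [o.ta for o in series],
            "rh_pct": [o.rh for o in series],
        }
    )


def write_weather_csv(series: MeteoSeries, path: str | Path) -> None:
    _frame(series).to_csv(path, index=False)


def write_wbgt_csv(series: MeteoSeries, path: str | Path) -> None:
    """Write the weather table with appended ``tw_c, wbgt_c, valid`` columns."""
    df = _frame(series)
    estimates = [est for _, est in series_wbgt(series)]
    df["tw_c"] = [e.tw for e in estimates]
    df["wbgt_c"] = [e.wbgt for e in estimates]
    df["valid"] = [int(e.valid) for e in estimates]
    df.to_csv(path, index=False)
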