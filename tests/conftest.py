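from datetime import date, datetime, timedelta

import pytest

from heatstrain.events import DailySummary
from heatstrain.wbgt import MeteoObservation, MeteoSeries


def hourly_series(
    hours_ta, start=datetime(2013, 8, 1), rh=60.0, station="T1"
) -> MeteoSeries:
    """Build an hourly series from a flat list of temperatures."""
    obs = tuple(
        MeteoObservation(
            timestamp=start + timedelta(hours=i),
            ta=float(t),
            rh=float(rh[i]) if hasattr(rh, "__len__") else float(rh),
        )
        for i, t in enumerate(hours_ta)
    )
    return MeteoSeries(station_id=station, observations=obs)


def summaries_from_tmax(tmaxes, start=date(2013, 8, 1), skip_days=()):
    """DailySummary list with the given daily maxima; optional missing days."""
    out = []
    for i, t in enumerate(tmaxes):
        if i in skip_days:
            continue
        out.append(DailySummary(date=start + timedelta(days=i), tmax=float(t)))
    return out


@pytest.fixture(scope="session")
def reference_cohort():
    from heatstrain.cases import load_reference_cohort

    return load_reference_cohort()
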