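from datetime import date, datetime, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
import pytest

from luxdose.solar import GeoSite
from luxdose.timeseries import DayRecord, LightTimeseries


@pytest.fixture(scope="session")
def basel_site() -> GeoSite:
    return GeoSite("CH", 47.5585, 7.5839, "Europe/Zurich")


@pytest.fixture(scope="session")
def kl_site() -> GeoSite:
    return GeoSite("MY", 3.0650, 101.6009, "Asia/Kuala_Lumpur")


def make_series(
    values,
    start="2023-07-10 00:00",
    tz="Europe/Zurich",
    epoch_s=60,
    photopic=None,
    participant_id="p1",
    site_id="CH",
) -> LightTimeseries:
    """Build a LightTimeseries from a plain value list."""
    idx = pd.date_range(
        pd.Timestamp(start).tz_localize(ZoneInfo(tz)),
        periods=len(values),
        freq=f"{epoch_s}s",
    )
    data = pd.DataFrame({"mel_edi": np.asarray(values, dtype=float)}, index=idx)
    if photopic is not None:
        data["photopic"] = np.asarray(photopic, dtype=float)
    return LightTimeseries(
        participant_id=participant_id, site_id=site_id, epoch_s=epoch_s, data=data
    )


def make_day(
    values, start="2023-07-10 00:00", tz="Europe/Zurich", epoch_s=60, valid=True
) -> DayRecord:
    """Wrap a value list into a DayRecord (one local day's slice)."""
    ts = make_series(values, start=start, tz=tz, epoch_s=epoch_s)
    start_ts = pd.Timestamp(start, tz=tz)
    return DayRecord(
        participant_id="p1",
        local_date=start_ts.date(),
        data=ts.data,
        epoch_s=epoch_s,
        expected_epochs=int(24 * 3600 / epoch_s),
        missing_fraction=0.0,
        valid=valid,
    )


def full_day_values(fill=0.0, epoch_s=60):
    return np.full(int(24 * 3600 / epoch_s), fill, dtype=float)
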