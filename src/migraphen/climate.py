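"""Winter climate summaries from daily station records.

For each spring year y the winter window runs from November 1 of y-1 through
January 1 of y (both endpoints inclusive — 62 days). Temperature is the mean
over all station-days in the window; precipitation is each station's window
total, averaged across stations, in cm. Missing daily values are excluded,
never imputed as zero.
"""
from __future__ import annotations

from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

#: (month, day) endpoints of the default winter window, endpoint-inclusive.
DEFAULT_WINDOW = ((11, 1), (1, 1))


def _window_bounds(year: int, window) -> Tuple[pd.Timestamp, pd.Timestamp]:
    (m0, d0), (m1, d1) = window
    start = pd.Timestamp(year=year - 1, month=m0, day=d0)
    end = pd.Timestamp(year=year if (m1, d1) < (m0, d0) else year - 1, month=m1, day=d1)
    if end <= start:
        raise ValueError(f"empty winter window {window} for year {year}")
    return start, end


def winter_summary(records: pd.DataFrame, years: Iterable[int],
                   stations: Optional[Iterable[str]] = None,
                   window=DEFAULT_WINDOW) -> pd.DataFrame:
    """Per-year winter climate summary.

    ``records`` has columns station_id, date, tmean_c, prcp_cm; ``stations``
    optionally restricts to stations inside the winter range. The year label
    is the spring year the winter precedes.
    """
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    if stations is not None:
        df = df[df["station_id"].isin(set(stations))]
    # exact duplicate station-day records (e.g. a station file ingested twice)
    # must not change any summary
    df = df.drop_duplicates(subset=["station_id", "date"], keep="first")
    rows = []
    for year in years:
        start, end = _window_bounds(int(year), window)
        win = df[(df["date"] >= start) & (df["date"] <= end)]
        temps = win["tmean_c"].dropna()
        if len(win) == 0 or len(temps) == 0:
            raise ValueError(f"no station-days in winter window for year {year}")
        per_station_prcp = win.dropna(subset=["prcp_cm"]).groupby("station_id")["prcp_cm"].sum()
        rows.append(dict(year=int(year),
                         tmean_c=float(temps.mean()),
                         prcp_cm=float(per_station_prcp.mean()) if len(per_station_prcp) else np.nan,
                         n_station_days=int(len(temps))))
    return pd.DataFrame(rows)
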