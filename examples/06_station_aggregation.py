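"""Aggregating hourly station records to seasonal city means.

Two stations map to one city; hourly values are rolled up to daily,
monthly and seasonal means under a 75% completeness rule. Winter groups
December with the January and February that follow it.
"""

import numpy as np
import pandas as pd

from geodrivers import StationSeries, aggregate_series

rng = np.random.default_rng(0)
ts = pd.date_range("2015-03-01", "2016-03-01", freq="h", inclusive="left")
frames = []
for sid in ("s1", "s2"):
    base = 45 + 15 * np.cos(2 * np.pi * (ts.dayofyear - 15) / 365)
    frames.append(pd.DataFrame({
        "station_id": sid, "unit_id": "cityA", "timestamp": ts,
        "value": base + rng.normal(0, 3, len(ts)),
    }))
series = StationSeries(pd.concat(frames, ignore_index=True))

seasonal = aggregate_series(series, level="seasonal", completeness=0.75)
print(seasonal.to_string(index=False))
print("-> each row is the unweighted mean of station means; winter pollution")
print("   peaks, and the '2016-winter' row covers Dec 2015 + Jan/Feb 2016.")
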