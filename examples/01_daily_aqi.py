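"""Compute a daily air-quality index and aggregate a month of values.

The daily index is the worst pollutant's concentration relative to its
NSW regulatory standard, scaled to 100 at the standard.
"""

import datetime as dt

import gtwrkit as g

standards = g.default_standards()

# a winter day with elevated fine particulates
day = g.PollutantDay(
    station_id="SYD-EAST",
    date=dt.date(2016, 7, 12),
    concentrations={"PM2.5": 31.0, "PM10": 42.0, "NO2": 0.05, "CO": 2.1},
)
result = g.compute_daily_aqi(day, standards)
print(f"daily AQI = {result.value:.1f}  ({result.status}, driven by {result.dominant_pollutant})")
# 124.0 means PM2.5 sits 24% above its 25 ug/m3 standard -> "Poor" band

# monthly covariate value = arithmetic mean of the daily indices
dailies = [(dt.date(2016, 7, d), v) for d, v in [(1, 38.0), (2, 55.0), (12, 124.0)]]
monthly = g.monthly_aqi(dailies)
print(f"monthly mean AQI for 2016-07 = {monthly.iloc[0]:.1f}")
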