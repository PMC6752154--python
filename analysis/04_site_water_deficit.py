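#!/usr/bin/env python
"""Site water balance: daily Hargreaves ET0, climatic moisture deficit, and
anomaly integrals around the two drought events.

Builds a 1961-1990 day-of-year climatology of the daily deficit and
integrates departures from it over each drought window — the integral
captures both how intense and how long an anomaly was.
"""

from pathlib import Path

import pandas as pd

from sprucegarden.climate import (
    anomaly_integral, daily_deficit, day_of_year_climatology,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
LATITUDE = 55.28

WINDOWS = {
    "drought_1998_1999": ("1998-09-01", "1999-08-31"),
    "drought_2002": ("2002-04-01", "2002-09-30"),
    "normal_1995": ("1995-04-01", "1995-09-30"),
}


def main():
    weather = pd.read_csv(ROOT / "data" / "weather.csv")
    deficit = daily_deficit(weather, LATITUDE)
    deficit.daily.to_csv(ROOT / "deficit_daily.csv", index=False,
                         float_format="%.3f")
    deficit.annual.to_csv(ROOT / "deficit_annual.csv", index=False,
                          float_format="%.1f")

    annual = deficit.annual.set_index("year")["cmd"]
    normal = annual.loc[1961:1990].mean()
    print(f"annual CMD, daily scale: 1961-1990 normal {normal:.0f} mm; "
          f"1999: {annual[1999]:.0f} mm; 2002: {annual[2002]:.0f} mm")

    clim = day_of_year_climatology(
        deficit.daily["date"], deficit.daily["deficit"].to_numpy(),
        reference_years=(1961, 1990),
    )
    rows = []
    for name, window in WINDOWS.items():
        integral = anomaly_integral(
            deficit.daily["date"], deficit.daily["deficit"].to_numpy(),
            clim, window=window,
        )
        rows.append({"window": name, "start": window[0], "end": window[1],
                     "deficit_anomaly_mm": round(integral, 1)})
        print(f"  {name}: deficit anomaly integral {integral:+.0f} mm "
              f"({'drier' if integral > 0 else 'wetter'} than normal)")
    pd.DataFrame(rows).to_csv(ROOT / "anomaly_integrals.csv", index=False)


if __name__ == "__main__":
    main()
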