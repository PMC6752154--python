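"""Hargreaves ET0, moisture deficits, anomaly integrals, bioclimatic normals."""

import numpy as np
import pandas as pd
import pytest

from sprucegarden.climate import (
    anomaly_integral,
    daily_deficit,
    day_of_year_climatology,
    derived_normals,
    extraterrestrial_radiation,
    hargreaves_et0,
    read_climate_normals,
)


class TestHargreaves:
    def test_zero_diurnal_range_gives_zero(self):
        assert hargreaves_et0(15.0, 15.0, 15.0, 55.0, 182) == pytest.approx(0.0)

    def test_cold_pivot_temperature_gives_zero(self):
        # (Tmean + 17.8) factor vanishes; negatives are clamped
        assert hargreaves_et0(-20.0, -15.6, -17.8, 55.0, 15) == pytest.approx(0.0)
        assert hargreaves_et0(-30.0, -20.0, -25.0, 55.0, 15) == 0.0

    def test_worked_day_against_solar_geometry_oracle(self):
        """1 July at 55.28 N, Tmin 10 / Tmax 25 / Tmean 17.5.

        Expected value from an independent line-by-line computation of the
        standard solar-geometry chain (inverse Earth-Sun distance 0.96700,
        declination 0.402952 rad, sunset hour angle 2.233389 rad,
        Ra = 41.17729 MJ m-2 day-1 = 16.80033 mm/day), giving
        ET0 = 0.0023 * 16.80033 * (17.5 + 17.8) * sqrt(15) = 5.28282 mm.
        """
        assert hargreaves_et0(10.0, 25.0, 17.5, 55.28, 182) == pytest.approx(
            5.2828, abs=1e-4
        )
        assert extraterrestrial_radiation(55.28, 182) == pytest.approx(
            16.8003, abs=1e-4
        )

    def test_tmax_below_tmin_rejected(self):
        with pytest.raises(ValueError):
            hargreaves_et0(10.0, 5.0, 7.5, 55.0, 100)

    def test_et0_increases_with_diurnal_range(self):
        vals = [hargreaves_et0(15.0 - d / 2, 15.0 + d / 2, 15.0, 55.0, 182)
                for d in (2.0, 6.0, 12.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_polar_night_radiation_zero(self):
        assert extraterrestrial_radiation(80.0, 355) == pytest.approx(0.0, abs=1e-9)

    def test_radiation_nearly_symmetric_about_solstice(self):
        # near-symmetry about day 172; the Earth-Sun distance term breaks
        # exact symmetry by ~1% over +-60 days
        for k in (10, 30, 45):
            a = extraterrestrial_radiation(55.0, 172 - k)
            b = extraterrestrial_radiation(55.0, 172 + k)
            assert a == pytest.approx(b, rel=0.01)
        assert extraterrestrial_radiation(55.0, 112) == pytest.approx(
            extraterrestrial_radiation(55.0, 232), rel=0.012
        )


def _weather(year, precip, tmin=5.0, tmax=20.0):
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    n = len(dates)
    return pd.DataFrame(
        {"date": dates.strftime("%Y-%m-%d"), "tmin": tmin, "tmax": tmax,
         "tmean": (tmin + tmax) / 2.0,
         "precip": np.broadcast_to(precip, n).astype(float)}
    )


class TestDeficit:
    def test_abundant_precipitation_gives_zero_cmd(self):
        d = daily_deficit(_weather(2001, 50.0), 55.0)
        assert d.annual["cmd"].iloc[0] == pytest.approx(0.0)

    def test_zero_precipitation_cmd_is_sum_of_et0(self):
        d = daily_deficit(_weather(2001, 0.0), 55.0)
        assert d.annual["cmd"].iloc[0] == pytest.approx(
            float(np.nansum(d.daily["et0"])), rel=1e-12
        )

    def test_cmd_monotone_in_precip_scaling(self):
        rng = np.random.default_rng(1)
        base = rng.gamma(0.7, 2.2, 365)
        cmds = []
        for scale in (1.0, 0.5, 0.25):
            d = daily_deficit(_weather(2001, base * scale), 55.0)
            cmds.append(float(d.annual["cmd"].iloc[0]))
        assert cmds[0] < cmds[1] < cmds[2]

    def test_missing_days_counted_not_imputed(self):
        w = _weather(2001, 1.0)
        w.loc[10:19, "tmax"] = np.nan
        d = daily_deficit(w, 55.0)
        assert int(d.annual["n_missing"].iloc[0]) == 10
        full = daily_deficit(_weather(2001, 1.0), 55.0)
        assert d.annual["cmd"].iloc[0] < full.annual["cmd"].iloc[0] + 1e-9

    def test_monthly_sums_equal_daily_sum(self):
        d = daily_deficit(_weather(2001, 0.5), 55.0).daily
        monthly = d.assign(m=pd.to_datetime(d["date"]).dt.month).groupby("m")[
            "deficit"
        ].sum()
        assert monthly.sum() == pytest.approx(d["deficit"].sum(), rel=1e-12)


class TestAnomalies:
    def _clim_series(self):
        dates = pd.date_range("1961-01-01", "1995-12-31", freq="D")
        vals = 3.0 + 2.0 * np.sin(2 * np.pi * dates.dayofyear / 365.25)
        return dates, vals

    def test_series_equal_to_climatology_integrates_to_zero(self):
        dates, vals = self._clim_series()
        clim = day_of_year_climatology(pd.Series(dates), vals,
                                       reference_years=(1961, 1990), smooth_days=1)
        integral = anomaly_integral(
            pd.Series(dates), vals, clim, window=("1992-03-01", "1992-03-31")
        )
        assert integral == pytest.approx(0.0, abs=0.05)

    def test_uniform_anomaly_rectangle(self):
        dates, vals = self._clim_series()
        clim = day_of_year_climatology(pd.Series(dates), vals,
                                       reference_years=(1961, 1990), smooth_days=1)
        shifted = vals.copy()
        sel = (dates >= "1992-06-01") & (dates <= "1992-06-30")
        shifted = np.where(sel, vals + 1.0, vals)
        integral = anomaly_integral(
            pd.Series(dates), shifted, clim, window=("1992-06-01", "1992-06-30")
        )
        assert integral == pytest.approx(30.0, abs=0.1)

    def test_missing_climatology_day_rejected(self):
        dates = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        clim = pd.Series(1.0, index=range(1, 100))
        with pytest.raises(ValueError, match="climatology"):
            anomaly_integral(pd.Series(dates), np.ones(len(dates)), clim)

    def test_generator_drought_mass_recovered(self):
        """Precipitation scaled in a window -> anomaly integral matches the
        suppressed precipitation mass (law-of-large-numbers check)."""
        from sprucegarden.synthetic import DroughtWindow, GeneratorConfig, simulate_weather
        win = ("1999-05-01", "1999-08-31")
        cfg = GeneratorConfig(
            weather_years=(1961, 2000), tmean_noise_sd=0.0,
            drought_windows=(DroughtWindow(*win, precip_scale=0.4, temp_shift=0.0),),
        )
        rng = np.random.default_rng(21)
        w = simulate_weather(cfg, rng)
        dates = pd.to_datetime(w["date"])
        clim = day_of_year_climatology(dates, w["precip"].to_numpy(),
                                       reference_years=(1961, 1990))
        integral = anomaly_integral(dates, w["precip"].to_numpy(), clim, window=win)
        sel = (dates >= win[0]) & (dates <= win[1])
        suppressed = w.loc[sel.to_numpy(), "precip"].sum() * (1 / 0.4 - 1)
        assert integral < 0
        assert -integral == pytest.approx(suppressed, rel=0.25)


class TestNormals:
    def test_constant_climate_closed_form(self):
        out = derived_normals([10.0] * 12, [100.0] * 12)
        assert out["MAT"] == 10.0
        assert out["TD"] == 0.0
        assert out["MAP"] == 1200.0
        assert out["MSP"] == 500.0
        assert out["AHM"] == pytest.approx(20.0 / 1.2)

    def test_continentality_from_monthly_extremes(self):
        # a site with MWMT 15.6 and MCMT -18.0 has TD 33.6
        t = [-18.0, -14.0, -8.0, 2.0, 9.0, 13.5, 15.6, 14.0, 8.5, 2.0, -8.0, -15.0]
        p = [20, 18, 20, 25, 45, 80, 90, 70, 50, 30, 25, 20]
        out = derived_normals(t, p)
        assert out["MWMT"] == 15.6
        assert out["MCMT"] == -18.0
        assert out["TD"] == pytest.approx(33.6)

    def test_td_shift_invariance(self):
        t = np.linspace(-15.0, 15.0, 12).tolist()
        p = [50.0] * 12
        a = derived_normals(t, p)
        b = derived_normals([x + 7.3 for x in t], p)
        assert a["TD"] == pytest.approx(b["TD"])

    def test_missing_month_rejected(self):
        with pytest.raises(ValueError):
            derived_normals([1.0] * 11, [50.0] * 12)
        with pytest.raises(ValueError, match="missing"):
            derived_normals([1.0] * 11 + [np.nan], [50.0] * 12)

    def test_normals_table_invariants_checked(self, tmp_path, paper_scale_trial):
        path = tmp_path / "clim.csv"
        paper_scale_trial.provenance_climate.to_csv(path, index=False)
        df = read_climate_normals(path)
        assert len(df) == 33
        bad = df.copy()
        bad.loc[0, "TD"] = bad.loc[0, "TD"] + 5.0
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="TD"):
            read_climate_normals(path)
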