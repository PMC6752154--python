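"""Synthetic provenance-trial generator with known ground truth.

Emulates a 40-year white-spruce common garden at a boreal test site:
33 provenances from 6 regions in a randomized complete block design with
5 blocks of 5-tree row plots (25 trees per provenance for height/DBH and
survival), a core subsample of one tree per provenance per block
(165 trees, two cores each), and a daily weather record with drought
anomalies in two event years.

Ring widths follow a multiplicative model on a shared age trend:

    width_i(t) = [A exp(-(t - t0)/tau) + c] * G_region * b_block
                 * eps_i(t) * prod_e m_{r,e} ** d_e(t)

where m_{r,e} in (0, 1] is the region's drought multiplier for event e and
d_e(t) = decay**(t - e) for t >= e switches the shock on in the event year
and lets it fade geometrically (growth does not rebound instantly).
Noise is multiplicative lognormal — growth is positive and right-skewed —
so the injected multiplier m is, by construction, the true resistance of
the region and variance arithmetic is exact on the log scale.

Every random draw goes through one ``numpy.random.default_rng`` stream
(PCG64), so a fixed seed reproduces the trial bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ringio import RingSeries, TrialDesign

#: Region order, provenance counts and regional truths used as defaults.
#: Growth, survival and drought multipliers are realistic for a range-wide
#: boreal spruce trial: western sources slow-growing but drought-hardy,
#: southeastern sources fast-growing but drought-sensitive.
REGION_DEFAULTS = pd.DataFrame(
    {
        "region": [
            "Boreal Cordillera", "Montane Cordillera", "Maritime Mixedwood",
            "Boreal Plains", "Boreal Shield", "Temperate Mixedwood",
        ],
        "n_provenances": [4, 4, 3, 9, 9, 4],
        "height_cm": [546.0, 700.0, 767.0, 908.0, 957.0, 966.0],
        "dbh_mm": [63.0, 84.0, 79.0, 116.0, 117.0, 122.0],
        "survival": [0.97, 0.84, 0.78, 0.97, 0.95, 0.89],
        "growth_multiplier": [0.75, 0.90, 0.95, 1.10, 1.15, 1.15],
        "m_1999": [0.69, 0.60, 0.60, 0.50, 0.44, 0.44],
        "m_2002": [0.64, 0.53, 0.69, 0.63, 0.55, 0.67],
    }
).set_index("region")

#: Regional 1961-1990 climate-normal means and SDs (MAT/MWMT/MCMT deg C,
#: MAP/MSP/CMD mm) used to draw provenance origin climates.
REGION_CLIMATE = pd.DataFrame(
    {
        "region": [
            "Boreal Cordillera", "Montane Cordillera", "Maritime Mixedwood",
            "Boreal Plains", "Boreal Shield", "Temperate Mixedwood",
        ],
        "MAT": [-3.3, 1.2, 5.0, -0.6, 0.7, 5.5],
        "MAT_sd": [1.3, 1.6, 0.5, 1.6, 1.0, 0.6],
        "MWMT": [13.7, 13.4, 17.4, 17.0, 16.5, 20.1],
        "MWMT_sd": [1.2, 0.7, 0.7, 1.4, 0.8, 0.3],
        "MCMT": [-22.6, -12.2, -6.2, -21.7, -16.9, -10.9],
        "MCMT_sd": [3.3, 3.5, 0.8, 2.5, 2.5, 1.6],
        "MAP": [310.0, 702.0, 1246.0, 450.0, 922.0, 832.0],
        "MAP_sd": [46.0, 250.0, 146.0, 66.0, 179.0, 11.0],
        "MSP": [193.0, 290.0, 463.0, 291.0, 468.0, 384.0],
        "MSP_sd": [19.6, 77.1, 31.1, 51.3, 66.8, 19.2],
        "CMD": [201.0, 174.0, 52.0, 177.0, 66.0, 192.0],
        "CMD_sd": [43.5, 66.0, 16.0, 30.4, 52.6, 10.7],
    }
).set_index("region")


@dataclass
class DroughtWindow:
    """A weather anomaly window: precipitation scaled, temperature shifted."""

    start: str
    end: str
    precip_scale: float = 0.5
    temp_shift: float = 0.0


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic trial; defaults are the study conditions."""

    # design
    n_blocks: int = 5
    trees_per_plot: int = 5
    region_table: pd.DataFrame = field(default_factory=lambda: REGION_DEFAULTS.copy())
    years: tuple[int, int] = (1988, 2017)

    # ring-width model
    trend_initial_mm: float = 2.5  # A
    trend_decay_years: float = 12.0  # tau
    trend_asymptote_mm: float = 0.8  # c
    tree_noise_sd: float = 0.15  # lognormal sigma, tree-year
    core_noise_sd: float = 0.10  # lognormal sigma, core-year
    block_sd: float = 0.05  # lognormal sigma of block multipliers
    event_years: tuple[int, ...] = (1999, 2002)
    recovery_decay: float = 0.3  # geometric fade of the shock after the event

    # trait model (height in cm; DBH scaled by dbh_scale)
    height_var_prov: float = 3600.0
    height_var_block: float = 900.0
    height_var_plot: float = 1600.0
    height_var_resid: float = 14400.0
    dbh_scale: float = 0.13  # DBH variances = height variances * dbh_scale**2
    survival_prov_logit_sd: float = 0.3

    # weather model
    latitude_deg: float = 55.28
    weather_years: tuple[int, int] = (1961, 2017)
    tmean_annual_c: float = 0.6
    tmean_amplitude_c: float = 16.8
    tmean_noise_sd: float = 3.0
    diurnal_range_c: float = 10.0
    diurnal_range_sd: float = 2.0
    precip_wet_prob: float = 0.4
    precip_mean_base: float = 1.35  # mm/day annual mean rate
    precip_mean_amplitude: float = 1.16  # summer-peaking seasonal swing
    precip_gamma_shape: float = 0.7
    drought_windows: tuple[DroughtWindow, ...] = (
        DroughtWindow("1997-11-01", "1999-08-31", precip_scale=0.45, temp_shift=1.5),
        DroughtWindow("2002-04-01", "2002-09-30", precip_scale=0.55, temp_shift=-1.0),
    )

    def __post_init__(self):
        t = self.region_table
        if (t["n_provenances"] < 1).any() or self.n_blocks < 1:
            raise ValueError("design sizes must be >= 1")
        if not ((t["m_1999"] > 0) & (t["m_1999"] <= 1)).all():
            raise ValueError("drought multipliers must be in (0, 1]")
        if not ((t["m_2002"] > 0) & (t["m_2002"] <= 1)).all():
            raise ValueError("drought multipliers must be in (0, 1]")
        for v in (
            self.height_var_prov, self.height_var_block,
            self.height_var_plot, self.height_var_resid,
        ):
            if v < 0:
                raise ValueError("variances must be >= 0")

    @property
    def regions(self) -> list[str]:
        return list(self.region_table.index)

    def provenance_ids(self) -> pd.DataFrame:
        rows = []
        i = 0
        for region in self.regions:
            for _ in range(int(self.region_table.loc[region, "n_provenances"])):
                i += 1
                rows.append((f"P{i:02d}", region))
        return pd.DataFrame(rows, columns=["provenance_id", "region"])


@dataclass
class SyntheticTrial:
    """A fully generated trial plus the ground truth that produced it."""

    design: TrialDesign
    series: list[RingSeries]
    weather: pd.DataFrame
    provenance_climate: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# traits + design
# ---------------------------------------------------------------------------

def simulate_traits(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[TrialDesign, dict]:
    """Trial design with height/DBH/survival for every planted tree.

    Heights and DBH follow the nested generative model
    region mean + prov(R) + block + plot(B) + residual with the configured
    variance components; survival is Bernoulli with a region probability
    perturbed per provenance on the logit scale.
    """
    provs = cfg.provenance_ids()
    t = cfg.region_table
    sd = np.sqrt
    prov_eff_h = rng.normal(0.0, sd(cfg.height_var_prov), len(provs))
    prov_eff_d = rng.normal(0.0, sd(cfg.height_var_prov) * cfg.dbh_scale, len(provs))
    block_eff_h = rng.normal(0.0, sd(cfg.height_var_block), cfg.n_blocks)
    block_eff_d = rng.normal(0.0, sd(cfg.height_var_block) * cfg.dbh_scale, cfg.n_blocks)
    prov_logit = rng.normal(0.0, cfg.survival_prov_logit_sd, len(provs))

    rows = []
    truth_plots = {}
    for pi, (prov, region) in enumerate(provs.itertuples(index=False)):
        for b in range(1, cfg.n_blocks + 1):
            plot = f"{prov}-B{b}"
            plot_h = rng.normal(0.0, sd(cfg.height_var_plot))
            plot_d = rng.normal(0.0, sd(cfg.height_var_plot) * cfg.dbh_scale)
            truth_plots[plot] = plot_h
            p_region = float(t.loc[region, "survival"])
            logit = np.log(p_region / (1 - p_region)) if 0 < p_region < 1 else np.inf
            p_tree = 1.0 / (1.0 + np.exp(-(logit + prov_logit[pi]))) if np.isfinite(logit) else p_region
            for k in range(1, cfg.trees_per_plot + 1):
                h = (
                    t.loc[region, "height_cm"] + prov_eff_h[pi]
                    + block_eff_h[b - 1] + plot_h
                    + rng.normal(0.0, sd(cfg.height_var_resid))
                )
                d = (
                    t.loc[region, "dbh_mm"] + prov_eff_d[pi]
                    + block_eff_d[b - 1] + plot_d
                    + rng.normal(0.0, sd(cfg.height_var_resid) * cfg.dbh_scale)
                )
                surv = int(rng.random() < p_tree)
                rows.append(
                    (f"{prov}-B{b}-T{k}", prov, region, b, plot, h, d, surv)
                )
    design = TrialDesign(
        pd.DataFrame(
            rows,
            columns=[
                "tree_id", "provenance_id", "region", "block", "plot",
                "height_cm", "dbh_mm", "survival",
            ],
        )
    )
    truth = {
        "region_height_cm": t["height_cm"].to_dict(),
        "region_dbh_mm": t["dbh_mm"].to_dict(),
        "region_survival": t["survival"].to_dict(),
        "variance_components_height": {
            "provenance": cfg.height_var_prov,
            "block": cfg.height_var_block,
            "plot": cfg.height_var_plot,
            "residual": cfg.height_var_resid,
        },
    }
    return design, truth


# ---------------------------------------------------------------------------
# chronologies
# ---------------------------------------------------------------------------

def age_trend(cfg: GeneratorConfig, years: np.ndarray) -> np.ndarray:
    """Shared negative-exponential age trend, mm."""
    t0 = cfg.years[0]
    return (
        cfg.trend_initial_mm * np.exp(-(years - t0) / cfg.trend_decay_years)
        + cfg.trend_asymptote_mm
    )


def drought_exponent(cfg: GeneratorConfig, years: np.ndarray, event: int) -> np.ndarray:
    """d_e(t): 1 in the event year, geometric fade afterwards, 0 before."""
    d = np.zeros(len(years))
    after = years >= event
    d[after] = cfg.recovery_decay ** (years[after] - event)
    return d


def simulate_chronologies(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    design: TrialDesign,
    cores_per_tree: int = 2,
) -> tuple[list[RingSeries], dict]:
    """Two cores for one sampled tree per provenance per block.

    The sampled tree is the first tree of each plot. Returns the core
    series and a truth record with every multiplier involved.
    """
    years = np.arange(cfg.years[0], cfg.years[1] + 1)
    trend = age_trend(cfg, years)
    t = cfg.region_table
    block_mult = np.exp(rng.normal(0.0, cfg.block_sd, cfg.n_blocks))
    shock = {}
    for region in cfg.regions:
        s = np.ones(len(years))
        for e in cfg.event_years:
            m = float(t.loc[region, f"m_{e}"])
            s = s * m ** drought_exponent(cfg, years, e)
        shock[region] = s

    sampled = (
        design.table.sort_values(["provenance_id", "block", "tree_id"])
        .groupby(["provenance_id", "block"], sort=True)
        .head(1)
    )
    series: list[RingSeries] = []
    for row in sampled.itertuples(index=False):
        g = float(t.loc[row.region, "growth_multiplier"])
        eps = np.exp(rng.normal(0.0, cfg.tree_noise_sd, len(years)))
        tree_width = trend * g * block_mult[row.block - 1] * eps * shock[row.region]
        for ci in range(cores_per_tree):
            core_eps = np.exp(rng.normal(0.0, cfg.core_noise_sd, len(years)))
            series.append(
                RingSeries(
                    core_id=f"{row.tree_id}{'NSEW'[ci]}",
                    tree_id=row.tree_id,
                    years=years.copy(),
                    widths=tree_width * core_eps,
                )
            )
    truth = {
        "block_multipliers": {b + 1: float(v) for b, v in enumerate(block_mult)},
        "region_growth_multipliers": t["growth_multiplier"].to_dict(),
        "resistance": {
            str(e): t[f"m_{e}"].to_dict() for e in cfg.event_years
        },
        "recovery_decay": cfg.recovery_decay,
        "age_trend": {
            "initial_mm": cfg.trend_initial_mm,
            "decay_years": cfg.trend_decay_years,
            "asymptote_mm": cfg.trend_asymptote_mm,
        },
        "sampled_trees": sampled["tree_id"].tolist(),
    }
    return series, truth


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def simulate_weather(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Daily weather: sinusoidal temperature, thinned-gamma precipitation.

    Within each configured drought window precipitation is scaled down and
    temperature shifted by the window's anomaly.
    """
    dates = pd.date_range(
        f"{cfg.weather_years[0]}-01-01", f"{cfg.weather_years[1]}-12-31", freq="D"
    )
    doy = dates.dayofyear.to_numpy()
    n = len(dates)
    # coldest around mid-January (doy 15), warmest mid-July
    seasonal = cfg.tmean_annual_c - cfg.tmean_amplitude_c * np.cos(
        2.0 * np.pi * (doy - 15) / 365.25
    )
    tmean = seasonal + rng.normal(0.0, cfg.tmean_noise_sd, n)
    half_range = np.abs(rng.normal(cfg.diurnal_range_c, cfg.diurnal_range_sd, n)) / 2.0
    half_range = np.maximum(half_range, 0.5)

    rate = cfg.precip_mean_base - cfg.precip_mean_amplitude * np.cos(
        2.0 * np.pi * (doy - 196) / 365.25
    )
    rate = np.maximum(rate, 0.05)
    wet = rng.random(n) < cfg.precip_wet_prob
    intensity = rng.gamma(
        cfg.precip_gamma_shape,
        rate / (cfg.precip_wet_prob * cfg.precip_gamma_shape),
        n,
    )
    precip = np.where(wet, intensity, 0.0)

    for w in cfg.drought_windows:
        sel = np.asarray((dates >= pd.Timestamp(w.start)) & (dates <= pd.Timestamp(w.end)))
        precip[sel] *= w.precip_scale
        tmean[sel] += w.temp_shift

    return pd.DataFrame(
        {
            "date": dates.strftime("%Y-%m-%d"),
            "tmin": np.round(tmean - half_range, 2),
            "tmax": np.round(tmean + half_range, 2),
            "tmean": np.round(tmean, 2),
            "precip": np.round(precip, 2),
        }
    )


# ---------------------------------------------------------------------------
# provenance climate normals
# ---------------------------------------------------------------------------

def simulate_provenance_climate(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Origin climate-normal table (13 variables) for each provenance.

    The seven core variables are drawn around the regional means with the
    regional SDs; the remaining six (PAS, DD5, DD_0, FFP, AHM, SHM) are
    derived deterministically with standard bioclimatic relationships so
    the table is internally consistent.
    """
    provs = cfg.provenance_ids()
    rows = []
    for prov, region in provs.itertuples(index=False):
        c = REGION_CLIMATE.loc[region]
        mat = rng.normal(c["MAT"], c["MAT_sd"])
        mwmt = rng.normal(c["MWMT"], c["MWMT_sd"])
        mcmt = rng.normal(c["MCMT"], c["MCMT_sd"])
        if mwmt < mat + 5:
            mwmt = mat + 5.0
        if mcmt > mat - 5:
            mcmt = mat - 5.0
        map_ = max(rng.normal(c["MAP"], c["MAP_sd"]), 150.0)
        msp = np.clip(rng.normal(c["MSP"], c["MSP_sd"]), 80.0, 0.75 * map_)
        cmd = max(rng.normal(c["CMD"], c["CMD_sd"]), 0.0)
        td = mwmt - mcmt
        # deterministic companions (simple degree-day / snow approximations)
        dd5 = max(0.0, 500.0 + 180.0 * mat + 30.0 * (mwmt - 15.0))
        dd0 = max(0.0, -120.0 * mcmt + 300.0 - 40.0 * mat)
        ffp = max(30.0, 90.0 + 9.0 * mat + 2.0 * mcmt / 2.0)
        pas = map_ * np.clip(0.35 - 0.018 * mat, 0.05, 0.7)
        rows.append(
            {
                "provenance_id": prov, "region": region,
                "MAT": round(mat, 1), "MWMT": round(mwmt, 1),
                "MCMT": round(mcmt, 1), "TD": round(td, 1),
                "MAP": round(map_, 0), "MSP": round(msp, 0),
                "PAS": round(pas, 0), "DD5": round(dd5, 0),
                "DD_0": round(dd0, 0), "FFP": round(ffp, 0),
                "AHM": round((mat + 10.0) / (map_ / 1000.0), 1),
                "SHM": round(mwmt / (msp / 1000.0), 1),
                "CMD": round(cmd, 0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full trial
# ---------------------------------------------------------------------------

def simulate_trial(cfg: GeneratorConfig | None = None, seed: int = 0) -> SyntheticTrial:
    """Generate design, cores, weather and origin climate in one call."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    design, truth_traits = simulate_traits(cfg, rng)
    series, truth_rings = simulate_chronologies(cfg, rng, design)
    weather = simulate_weather(cfg, rng)
    climate = simulate_provenance_climate(cfg, rng)
    truth = {"seed": seed, "traits": truth_traits, "rings": truth_rings}
    return SyntheticTrial(
        design=design,
        series=series,
        weather=weather,
        provenance_climate=climate,
        truth=truth,
    )
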