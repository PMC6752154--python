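"""Config-driven orchestration of the full analysis pipeline.

Reads rings, design, weather and climate-normal inputs, runs cross-dating
-> detrending -> resilience -> water deficits -> regional mixed models ->
associations -> PCA, and writes every table plus a run manifest into one
output directory. Each stage is an importable function so the command-line
subcommands and the end-to-end run produce identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chronology import detrend_chronologies, interseries_correlations
from .climate import anomaly_integral, daily_deficit, day_of_year_climatology
from .inference import climate_pca, fit_glmm_survival, fit_lmm_blues, spearman_holm
from .resilience import EventScheme, compute_resilience, regional_resilience_table, resilience_frame
from .ringio import (
    DEFAULT_WINDOW,
    build_tree_chronologies,
    chronologies_to_frame,
    read_design_csv,
    read_rings_csv,
    read_rwl,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    rings: str | None = None  # .rwl or .csv
    design: str | None = None
    weather: str | None = None
    climate_normals: str | None = None
    latitude_deg: float = 55.28
    window: tuple[int, int] = DEFAULT_WINDOW
    stiffness: float = 0.7
    event_years: tuple[int, ...] = (1999, 2002)
    pre_window: tuple[int, int] = (1993, 1997)
    post_window: tuple[int, int] = (2003, 2007)
    climatology_reference: tuple[int, int] = (1961, 1990)
    holm_family: str = "matrix"
    outdir: str = "results/pipeline"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window", "event_years", "pre_window", "post_window",
                    "climatology_reference"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self, need: tuple[str, ...]) -> None:
        if not (0.0 < self.stiffness <= 1.0):
            raise ConfigError(f"stiffness must be in (0, 1], got {self.stiffness}")
        for key in need:
            path = getattr(self, key)
            if path is None:
                raise ConfigError(f"config key {key!r} is required for this stage")
            if not Path(path).exists():
                raise ConfigError(f"{key} file not found: {path}")

    def scheme(self) -> EventScheme:
        return EventScheme(
            event_years=self.event_years,
            pre_window=self.pre_window,
            post_window=self.post_window,
        )

    def resolved(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }


def _read_rings(path: str):
    if str(path).endswith((".rwl", ".txt")):
        return read_rwl(path)
    return read_rings_csv(path)


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write outputs; returns the output index."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def stage(name):
        logger.info("stage: %s", name)

    # --- rings -> chronologies -----------------------------------------
    cfg.validate(("rings", "design"))
    stage("ringio")
    series = _read_rings(cfg.rings)
    design = read_design_csv(cfg.design)
    chronos = build_tree_chronologies(series, design, window=cfg.window)
    logger.info("read %d cores -> %d tree chronologies", len(series), len(chronos))

    stage("crossdate")
    report = interseries_correlations(chronos)
    pd.DataFrame(
        {"tree_id": list(report.r_by_tree), "r": list(report.r_by_tree.values())}
    ).to_csv(out / "crossdating_r.csv", index=False)
    (out / "crossdating.json").write_text(json.dumps(report.summary(), indent=2))
    outputs["crossdating"] = str(out / "crossdating.json")

    stage("detrend")
    chronos, spline = detrend_chronologies(chronos, stiffness=cfg.stiffness)
    frame = chronologies_to_frame(chronos)
    _float_csv(frame, out / "chronologies_detrended.csv")
    outputs["chronologies"] = str(out / "chronologies_detrended.csv")

    stage("resilience")
    scheme = cfg.scheme()
    sets = [compute_resilience(c, scheme) for c in chronos]
    tree_table = resilience_frame(sets, design)
    _float_csv(tree_table, out / "resilience_trees.csv")
    regional = regional_resilience_table(sets, design)
    _float_csv(regional, out / "resilience_regional.csv")
    outputs["resilience"] = str(out / "resilience_regional.csv")

    # --- weather --------------------------------------------------------
    if cfg.weather is not None:
        cfg.validate(("weather",))
        stage("deficit")
        weather = pd.read_csv(cfg.weather)
        deficit = daily_deficit(weather, cfg.latitude_deg)
        _float_csv(deficit.daily, out / "deficit_daily.csv")
        _float_csv(deficit.annual, out / "deficit_annual.csv")
        outputs["deficit"] = str(out / "deficit_annual.csv")

        clim = day_of_year_climatology(
            deficit.daily["date"], deficit.daily["deficit"].to_numpy(),
            reference_years=cfg.climatology_reference,
        )
        integrals = []
        for e in cfg.event_years:
            integrals.append(
                {
                    "window": f"{e}-04-01..{e}-09-30",
                    "deficit_anomaly_mm": anomaly_integral(
                        deficit.daily["date"], deficit.daily["deficit"].to_numpy(),
                        clim, window=(f"{e}-04-01", f"{e}-09-30"),
                    ),
                }
            )
        _float_csv(pd.DataFrame(integrals), out / "anomaly_integrals.csv")
        outputs["anomalies"] = str(out / "anomaly_integrals.csv")

    # --- regional trait models -----------------------------------------
    stage("blues")
    trait_tables = []
    for trait, preset in (("height_cm", "plots"), ("dbh_mm", "plots")):
        est = fit_lmm_blues(design.table, response=trait, preset=preset)
        t = est.table.copy()
        t.insert(0, "trait", trait)
        trait_tables.append(t)
    surv = fit_glmm_survival(design.table, preset="plots")
    t = surv.table.copy()
    t.insert(0, "trait", "survival")
    trait_tables.append(t)
    _float_csv(pd.concat(trait_tables, ignore_index=True), out / "traits_regional.csv")
    outputs["traits"] = str(out / "traits_regional.csv")

    # --- associations + PCA --------------------------------------------
    if cfg.climate_normals is not None:
        cfg.validate(("climate_normals",))
        stage("associate")
        climate = pd.read_csv(cfg.climate_normals, dtype={"provenance_id": str})
        climate = climate.set_index("provenance_id")
        climate_vars = climate.select_dtypes(include=[np.number])

        prov_traits = design.table.groupby("provenance_id")[
            ["height_cm", "dbh_mm", "survival"]
        ].mean()
        prov_res = tree_table.groupby("provenance_id")[
            [c for c in tree_table.columns
             if c.startswith(("resistance_", "recovery_")) or c == "resilience"]
        ].mean()
        traits = prov_traits.join(prov_res, how="inner")
        assoc = spearman_holm(traits, climate_vars, family=cfg.holm_family)
        _float_csv(assoc.tidy(), out / "associations.csv")
        outputs["associations"] = str(out / "associations.csv")

        stage("pca")
        pca = climate_pca(climate_vars)
        _float_csv(pca.scores.reset_index(), out / "pca_scores.csv")
        _float_csv(pca.loadings.reset_index(names="variable"), out / "pca_loadings.csv")
        _float_csv(
            pd.DataFrame(
                {
                    "pc": [f"PC{i+1}" for i in range(len(pca.variance_fraction))],
                    "variance_fraction": pca.variance_fraction,
                }
            ),
            out / "pca_variance.csv",
        )
        outputs["pca"] = str(out / "pca_variance.csv")

    # --- manifest -------------------------------------------------------
    resolved = cfg.resolved()
    manifest = {
        "config": resolved,
        "config_sha256": hashlib.sha256(
            json.dumps(resolved, sort_keys=True).encode()
        ).hexdigest(),
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "counts": {
            "cores_read": len(series),
            "trees": len(chronos),
            "eps": report.eps,
        },
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    outputs["manifest"] = str(out / "manifest.json")
    return outputs
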