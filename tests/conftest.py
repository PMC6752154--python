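import logging

import numpy as np
import pandas as pd
import pytest

import sprucegarden as sg
from sprucegarden.synthetic import GeneratorConfig, simulate_trial

logging.getLogger("sprucegarden").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """A reduced trial (2 provenances per region, 3 blocks) for fast tests."""
    table = GeneratorConfig().region_table.copy()
    table["n_provenances"] = 2
    return GeneratorConfig(n_blocks=3, trees_per_plot=2, region_table=table,
                           weather_years=(1985, 2008))


@pytest.fixture(scope="session")
def small_trial(small_cfg):
    return simulate_trial(small_cfg, seed=11)


@pytest.fixture(scope="session")
def paper_scale_trial():
    """One full-size trial: 33 provenances x 6 regions x 5 blocks."""
    return simulate_trial(GeneratorConfig(), seed=42)


@pytest.fixture(scope="session")
def detrended_paper_trial(paper_scale_trial):
    trial = paper_scale_trial
    chronos = sg.build_tree_chronologies(trial.series, trial.design)
    chronos, spline = sg.detrend_chronologies(chronos)
    return trial, chronos, spline


def make_design(tree_ids, region="R1", block=1):
    rows = [
        {
            "tree_id": t, "provenance_id": "P1", "region": region,
            "block": block, "plot": "P1-B1", "height_cm": 900.0,
            "dbh_mm": 100.0, "survival": 1,
        }
        for t in tree_ids
    ]
    return sg.TrialDesign(pd.DataFrame(rows))


@pytest.fixture
def simple_design():
    return make_design


@pytest.fixture
def chrono_factory():
    """Build a TreeChronology directly from a width vector."""

    def make(widths, years=None, tree_id="T1", region="R1", block=1):
        widths = np.asarray(widths, dtype=float)
        if years is None:
            years = np.arange(1988, 1988 + len(widths))
        return sg.TreeChronology(
            tree_id=tree_id,
            provenance_id="P1",
            region=region,
            block=block,
            years=np.asarray(years, dtype=int),
            width_mm=widths,
            n_cores=np.full(len(widths), 2, dtype=int),
            raw_mean=float(np.mean(widths)),
            raw_sd=float(np.std(widths, ddof=1)),
        )

    return make
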