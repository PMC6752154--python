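#!/usr/bin/env python
"""Generate the synthetic provenance trial used by the downstream analyses.

Writes ring-width cores (RWL and long CSV), the trial design with traits,
daily site weather 1961-2017 with the two drought anomalies, provenance
origin climate normals, and the ground-truth record, under results/data/.
"""

import json
from pathlib import Path

from sprucegarden.ringio import write_design_csv, write_rings_csv, write_rwl
from sprucegarden.synthetic import GeneratorConfig, simulate_trial

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig()
    trial = simulate_trial(cfg, seed=SEED)

    write_rwl(trial.series, OUT / "rings.rwl")
    write_rings_csv(trial.series, OUT / "rings.csv")
    write_design_csv(trial.design, OUT / "design.csv")
    trial.weather.to_csv(OUT / "weather.csv", index=False)
    trial.provenance_climate.to_csv(OUT / "climate_normals.csv", index=False)
    (OUT / "truth.json").write_text(
        json.dumps(trial.truth, indent=2, default=float)
    )

    n_trees = trial.design.table["tree_id"].nunique()
    n_cored = len({s.tree_id for s in trial.series})
    print(f"trial: {n_trees} trees planted, {n_cored} cored "
          f"({len(trial.series)} cores), "
          f"{len(trial.weather)} weather days -> {OUT}")


if __name__ == "__main__":
    main()
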