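#!/usr/bin/env python
"""Trait-climate associations and the provenance climate ordination.

Provenance means of the garden traits and drought indices are correlated
(Spearman) with the 13 origin climate normals; p-values are adjusted over
the whole matrix with Holm's step-down. A correlation-matrix PCA of the
climate table gives the ordination used to group provenances into regions.
"""

from pathlib import Path

import pandas as pd

import sprucegarden as sg
from sprucegarden.inference import climate_pca, spearman_holm
from sprucegarden.resilience import compute_resilience, resilience_frame
from sprucegarden.ringio import read_design_csv, read_rings_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    design = read_design_csv(ROOT / "data" / "design.csv")
    climate = pd.read_csv(ROOT / "data" / "climate_normals.csv",
                          dtype={"provenance_id": str}).set_index("provenance_id")
    climate_vars = climate.select_dtypes("number")

    series = read_rings_csv(ROOT / "data" / "rings.csv")
    chronos = sg.build_tree_chronologies(series, design)
    chronos, _ = sg.detrend_chronologies(chronos)
    res = resilience_frame([compute_resilience(c) for c in chronos], design)

    prov_traits = design.table.groupby("provenance_id")[
        ["height_cm", "dbh_mm", "survival"]
    ].mean()
    idx_cols = [c for c in res.columns
                if c.startswith(("resistance_", "recovery_")) or c == "resilience"]
    traits = prov_traits.join(res.groupby("provenance_id")[idx_cols].mean())

    assoc = spearman_holm(traits, climate_vars, family="matrix")
    assoc.tidy().to_csv(ROOT / "associations.csv", index=False,
                        float_format="%.4g")
    sig = assoc.tidy().query("significant")
    print(f"{len(sig)} of {assoc.rho.size} trait-climate pairs significant "
          "after Holm adjustment; strongest:")
    print(sig.reindex(sig.rho.abs().sort_values(ascending=False).index)
          .head(8)[["trait", "climate", "rho", "p_holm"]]
          .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    pca = climate_pca(climate_vars)
    pca.scores.reset_index().to_csv(ROOT / "pca_scores.csv", index=False,
                                    float_format="%.4f")
    pca.loadings.reset_index(names="variable").to_csv(
        ROOT / "pca_loadings.csv", index=False, float_format="%.4f")
    print(f"\nclimate PCA: PC1 {100 * pca.variance_fraction[0]:.1f}% and "
          f"PC2 {100 * pca.variance_fraction[1]:.1f}% of variance "
          f"(together {100 * pca.variance_fraction[:2].sum():.1f}%)")


if __name__ == "__main__":
    main()
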