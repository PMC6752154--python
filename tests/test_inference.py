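"""Mixed models, Tukey letters, Spearman/Holm, climate PCA."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sprucegarden.inference import (
    climate_pca,
    fit_glmm_survival,
    fit_lmm,
    fit_lmm_blues,
    holm_adjust,
    spearman_holm,
    spearman_with_p,
    tukey_letters,
)
from sprucegarden.synthetic import GeneratorConfig, simulate_traits


def balanced_table(region_means, n_prov=2, n_blocks=3, n_trees=2, noise=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for region, mu in region_means.items():
        for p in range(n_prov):
            prov = f"{region[:3]}{p}"
            for b in range(1, n_blocks + 1):
                for k in range(n_trees):
                    y = mu + (rng.normal(0, noise) if noise else 0.0)
                    rows.append(
                        {"region": region, "provenance_id": prov, "block": b,
                         "plot": f"{prov}-B{b}", "height_cm": y,
                         "dbh_mm": y / 10, "survival": 1,
                         "tree_id": f"{prov}-B{b}-T{k}"}
                    )
    return pd.DataFrame(rows)


class TestLmm:
    def test_balanced_noiseless_blues_equal_group_means(self):
        means = {"A": 500.0, "B": 700.0, "C": 900.0}
        df = balanced_table(means)
        est = fit_lmm_blues(df, "height_cm", preset="plots")
        t = est.table.set_index("region")
        for r, mu in means.items():
            assert t.loc[r, "estimate"] == pytest.approx(mu, abs=1e-6)
        for name, v in est.vcomp.items():
            if name != "residual":
                assert v == pytest.approx(0.0, abs=1e-6)

    def test_single_level_factor_clamped_to_zero(self):
        df = balanced_table({"A": 1.0, "B": 2.0}, n_blocks=1, noise=0.1)
        est = fit_lmm_blues(df, "height_cm", preset="cores")
        assert est.vcomp["block"] == 0.0

    def test_rank_deficient_fixed_design_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_lmm(np.arange(10.0), X, {})

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_reml_matches_lme4(self, tmp_path):
        """Variance components, BLUEs and SEs agree with lme4 on one trial."""
        rng = np.random.default_rng(7)
        design, _ = simulate_traits(GeneratorConfig(), rng)
        df = design.table
        df.to_csv(tmp_path / "d.csv", index=False)
        script = tmp_path / "ref.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f'd <- read.csv("{tmp_path}/d.csv")\n'
            "f <- lmer(height_cm ~ 0 + region + (1|provenance_id) + (1|block)"
            " + (1|plot), data=d, REML=TRUE)\n"
            "vc <- as.data.frame(VarCorr(f))\n"
            "fe <- fixef(f); se <- sqrt(diag(as.matrix(vcov(f))))\n"
            "out <- data.frame(term=sub('region', '', names(fe)), est=fe, se=se)\n"
            f'write.csv(out, "{tmp_path}/fe.csv", row.names=FALSE)\n'
            f'write.csv(vc[,c("grp","vcov")], "{tmp_path}/vc.csv", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                       capture_output=True)
        mine = fit_lmm_blues(df, "height_cm", preset="plots")
        fe = pd.read_csv(tmp_path / "fe.csv").set_index("term")
        t = mine.table.set_index("region")
        assert np.allclose(t["estimate"], fe.loc[t.index, "est"], atol=1e-4)
        assert np.allclose(t["se"], fe.loc[t.index, "se"], atol=5e-3)
        vc = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["vcov"]
        assert mine.vcomp["residual"] == pytest.approx(vc["Residual"], rel=1e-3)
        assert mine.vcomp["provenance"] == pytest.approx(vc["provenance_id"], rel=1e-2)
        assert mine.vcomp["block"] == pytest.approx(vc["block"], rel=1e-2)
        assert mine.vcomp["plot"] == pytest.approx(vc["plot"], rel=1e-2)


class TestGlmm:
    def test_all_survive_flags_separation(self):
        df = balanced_table({"A": 1.0, "B": 2.0}, noise=0.1)
        df["survival"] = 1
        est = fit_glmm_survival(df, preset="plots")
        assert set(est.separation) == {"A", "B"}
        t = est.table.set_index("region")
        assert (t["estimate"] == 1.0).all()
        assert np.isinf(t["se"]).all()

    def test_mixed_rates_recovered_on_probability_scale(self):
        rng = np.random.default_rng(12)
        cfg = GeneratorConfig()
        design, _ = simulate_traits(cfg, rng)
        est = fit_glmm_survival(design.table, preset="plots")
        t = est.table.set_index("region")
        truth = cfg.region_table["survival"]
        for r in t.index:
            assert abs(t.loc[r, "estimate"] - truth[r]) < 0.08
            assert 0.0 < t.loc[r, "se"] < 0.15

    def test_null_survival_rarely_separates_letters(self):
        """Type-I control: no region effect -> shared letters in >= 90%."""
        table = GeneratorConfig().region_table.copy()
        table["survival"] = 0.9
        table["n_provenances"] = 3
        cfg = GeneratorConfig(region_table=table)
        shared = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            design, _ = simulate_traits(cfg, rng)
            est = fit_glmm_survival(design.table, preset="plots")
            letters = [s for s in est.table["letters"] if s]
            if letters and set.intersection(*(set(s) for s in letters)):
                shared += 1
        assert shared / n_rep >= 0.9


class TestTukeyLetters:
    def test_identical_means_share_a_letter(self):
        letters = tukey_letters(np.array([5.0, 5.0, 5.0]), np.eye(3), 100.0)
        assert letters == ["a", "a", "a"]

    def test_distant_means_distinct(self):
        letters = tukey_letters(np.array([0.0, 10.0]), np.eye(2) * 0.5, 100.0)
        assert letters[0] != letters[1]

    def test_three_cluster_height_pattern(self):
        """Regional height means separate into low / mid / high clusters."""
        rng = np.random.default_rng(5)
        design, _ = simulate_traits(GeneratorConfig(), rng)
        est = fit_lmm_blues(design.table, "height_cm", preset="plots")
        t = est.table.set_index("region")
        low = t.loc["Boreal Cordillera", "letters"]
        mid = {t.loc["Montane Cordillera", "letters"],
               t.loc["Maritime Mixedwood", "letters"]}
        high = {t.loc[r, "letters"] for r in
                ("Boreal Plains", "Boreal Shield", "Temperate Mixedwood")}
        # the slowest region shares no letter with the fastest cluster
        assert not set(low) & set("".join(high))
        assert len({t.loc[r, "letters"] for r in t.index}) >= 3

    def test_letters_define_nonsignificant_groups(self):
        est = np.array([0.0, 1.0, 2.0, 10.0])
        cov = np.eye(4) * 0.8
        letters = tukey_letters(est, cov, 50.0)
        from scipy.stats import studentized_range
        qc = studentized_range.ppf(0.95, 4, 50.0) / np.sqrt(2)
        for i, j in itertools.combinations(range(4), 2):
            sig = abs(est[i] - est[j]) / np.sqrt(1.6) > qc
            share = bool(set(letters[i]) & set(letters[j]))
            assert share != sig

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError):
            tukey_letters(np.array([0.0, 1.0]), np.full((2, 2), np.nan), 10.0)


class TestSpearmanHolm:
    def test_holm_step_down_by_hand(self):
        # brute force: sorted p (0.01, 0.02, 0.03), m = 3:
        # 0.01*3=0.03; max(0.03, 0.02*2)=0.04; max(0.04, 0.03*1)=0.04
        adj = holm_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_holm_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 20)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    @pytest.mark.parametrize(
        "n,rho,expected_p",
        [
            # frozen from the reference rank-correlation test (untied data)
            (33, 0.259024, 0.145219),
            (33, 0.351939, 0.045239),
            (33, -0.187166, 0.295675),
            (50, -0.310444, 0.028647),
        ],
    )
    def test_untied_null_matches_reference_test(self, n, rho, expected_p):
        from sprucegarden.inference import _spearman_mc_p
        # tolerance covers Monte-Carlo resolution plus the reference
        # routine's own series approximation error
        assert _spearman_mc_p(n, rho) == pytest.approx(expected_p, abs=4e-3)

    def test_monotone_pair_exact_p(self):
        # strictly monotone, n = 5: only 2 of 120 permutations reach |rho| = 1
        rho, p = spearman_with_p(np.arange(5.0), np.arange(5.0) ** 3)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2.0 / 120.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_rho_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1, _ = spearman_with_p(x, y)
        r2, _ = spearman_with_p(np.exp(x), y ** 3)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_matrix_constant_column_flagged(self):
        idx = [f"P{i}" for i in range(8)]
        traits = pd.DataFrame({"h": np.arange(8.0), "flat": 1.0}, index=idx)
        climate = pd.DataFrame({"MAT": np.arange(8.0) ** 2}, index=idx)
        out = spearman_holm(traits, climate)
        assert np.isnan(out.rho.loc["flat", "MAT"])
        assert out.rho.loc["h", "MAT"] == pytest.approx(1.0)
        assert bool(out.significant.loc["h", "MAT"])

    def test_family_scope_changes_adjustment(self):
        rng = np.random.default_rng(3)
        idx = [f"P{i}" for i in range(20)]
        traits = pd.DataFrame(rng.normal(size=(20, 3)), index=idx,
                              columns=["a", "b", "c"])
        climate = pd.DataFrame(rng.normal(size=(20, 4)), index=idx,
                               columns=list("wxyz"))
        full = spearman_holm(traits, climate, family="matrix")
        per = spearman_holm(traits, climate, family="per_trait")
        assert (full.p_holm.to_numpy() >= per.p_holm.to_numpy() - 1e-12).all()


class TestClimatePca:
    def test_variance_fractions_sum_to_one(self, paper_scale_trial):
        clim = paper_scale_trial.provenance_climate.set_index("provenance_id")
        res = climate_pca(clim.select_dtypes("number"))
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_two_perfectly_correlated_variables(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 3.0 * x + 1.0})
        res = climate_pca(df)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_affine_rescaling_invariance(self, paper_scale_trial):
        clim = paper_scale_trial.provenance_climate.set_index("provenance_id")
        clim = clim.select_dtypes("number")
        res1 = climate_pca(clim)
        scaled = clim.copy()
        scaled["MAP"] = scaled["MAP"] * 0.03937 + 2.0
        res2 = climate_pca(scaled)
        assert np.allclose(res1.variance_fraction, res2.variance_fraction, atol=1e-10)
        assert np.allclose(np.abs(res1.scores), np.abs(res2.scores), atol=1e-8)

    def test_constant_variable_named_in_error(self):
        df = pd.DataFrame({"a": np.arange(6.0), "flat": 2.0, "b": np.arange(6.0)[::-1]})
        with pytest.raises(ValueError, match="flat"):
            climate_pca(df)

    def test_loadings_are_variable_pc_correlations(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        res = climate_pca(df)
        for var in df.columns:
            r = np.corrcoef(df[var], res.scores["PC1"])[0, 1]
            assert res.loadings.loc[var, "PC1"] == pytest.approx(r, abs=1e-6)
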