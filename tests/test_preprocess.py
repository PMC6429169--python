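import numpy as np
import pandas as pd
import pytest
from scipy import stats

import neurosem as ns
from neurosem.preprocess import DataError


class TestResidualize:
    def covariates(self, rng, n=80):
        return pd.DataFrame({
            "age": rng.uniform(55, 90, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "wbv": rng.normal(1200, 100, size=n),
        })

    def test_residuals_orthogonal_to_covariates(self, rng):
        cov = self.covariates(rng)
        regions = pd.DataFrame(rng.normal(size=(80, 4)),
                               columns=list("abcd"))
        regions["a"] += 0.01 * cov["age"].values
        out = ns.residualize_covariates(regions, cov)
        assert np.abs(out.mean()).max() < 1e-10
        for c in cov:
            for r in out:
                assert abs(np.corrcoef(out[r], cov[c])[0, 1]) < 1e-10

    def test_idempotent(self, rng):
        cov = self.covariates(rng)
        regions = pd.DataFrame(rng.normal(size=(80, 3)))
        once = ns.residualize_covariates(regions, cov)
        twice = ns.residualize_covariates(once, cov)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_region_equal_to_covariate_vanishes(self, rng):
        cov = self.covariates(rng)
        regions = pd.DataFrame({"copy_of_age": cov["age"].values})
        out = ns.residualize_covariates(regions, cov)
        assert np.abs(out.values).max() < 1e-9

    def test_collinear_covariates_rejected(self, rng):
        cov = self.covariates(rng)
        cov["age2"] = 2 * cov["age"]
        with pytest.raises(DataError, match="collinear"):
            ns.residualize_covariates(pd.DataFrame(rng.normal(size=(80, 2))), cov)


class TestStandardize:
    def test_unit_scale_and_zero_mean(self):
        g = np.array([[0.0], [1.0], [2.0]])
        x = np.array([[1.0], [2.0], [3.0]])
        g_c, x_s = ns.standardize(g, x)
        assert g_c.mean() == pytest.approx(0.0)
        assert x_s.mean() == pytest.approx(0.0)
        assert x_s.std(axis=0)[0] == pytest.approx(1.0)

    def test_genotypes_centred_but_not_scaled(self):
        g = np.array([[0.0], [0.0], [2.0]])
        g_c, _ = ns.standardize(g, np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(np.asarray(g_c).ravel(),
                                   [-2 / 3, -2 / 3, 4 / 3])

    def test_constant_column_named_in_error(self):
        g = np.ones((5, 1))
        x = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(DataError, match="snp1"):
            ns.standardize(g, x)

    def test_scale_regions_switch(self, rng):
        x = rng.normal(scale=3.0, size=(50, 2))
        _, x_c = ns.standardize(rng.normal(size=(50, 1)), x, scale_regions=False)
        assert np.asarray(x_c).std(axis=0)[0] > 1.5


class TestBonferroni:
    def test_test_count_multiplier(self):
        p = np.full((9, 35), 0.001)  # 315 tests
        adjusted, flags = ns.bonferroni_adjust(p)
        assert adjusted[0, 0] == pytest.approx(0.315)
        assert not flags.any()

    def test_capped_at_one(self):
        adjusted, _ = ns.bonferroni_adjust(np.array([[0.9] * 315]))
        assert np.all(adjusted == 1.0)

    def test_significance_flags(self):
        p = np.full((9, 35), 1e-6)
        _, flags = ns.bonferroni_adjust(p, alpha=0.05)
        assert flags.all()


class TestAnova:
    def test_hand_computed_f_statistic(self):
        scores = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float)[:, None]
        labels = np.repeat(["g1", "g2", "g3"], 3)
        out = ns.anova_by_group(scores, labels)
        assert out["F"].iloc[0] == pytest.approx(3.0)
        assert out["p"].iloc[0] == pytest.approx(stats.f(2, 6).sf(3.0))

    def test_two_groups_equals_squared_t(self, rng):
        scores = rng.normal(size=(40, 1))
        labels = np.repeat(["a", "b"], 20)
        out = ns.anova_by_group(scores, labels)
        t = stats.ttest_ind(scores[:20, 0], scores[20:, 0]).statistic
        assert out["F"].iloc[0] == pytest.approx(t**2)

    def test_equal_means_give_near_zero_f(self):
        scores = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])[:, None]
        labels = np.repeat(["a", "b", "c"], 2)
        out = ns.anova_by_group(scores, labels)
        assert out["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_groups_with_two_samples(self):
        with pytest.raises(ValueError):
            ns.anova_by_group(np.zeros((4, 1)), ["a"] * 4)
        with pytest.raises(ValueError):
            ns.anova_by_group(np.zeros((3, 1)), ["a", "a", "b"])


class TestLoadStudy:
    def write_dataset(self, tmp_path, config=None, seed=0):
        ds = ns.simulate_dataset(config or ns.SimulationConfig(
            n_individuals=40, n_snps=4, group_sizes=(3, 2), n_nonzero_a=2),
            seed=seed)
        return ds, ds.write_tables(tmp_path)

    def test_round_trip_preserves_values(self, tmp_path):
        ds, paths = self.write_dataset(tmp_path)
        tables = ns.load_study(paths["genotypes"], paths["regions"],
                               paths["grouping"])
        np.testing.assert_array_equal(tables.genotypes.values, ds.g)
        np.testing.assert_allclose(tables.regions.values, ds.x)
        assert list(tables.grouping.index) == list(ds.spec.region_ids)

    def test_ungrouped_regions_dropped(self, tmp_path):
        ds, paths = self.write_dataset(tmp_path)
        grouping = pd.read_csv(paths["grouping"], sep="\t")
        grouping = grouping.iloc[:-2]  # drop the mapping for two regions
        grouping.to_csv(paths["grouping"], sep="\t", index=False)
        tables = ns.load_study(paths["genotypes"], paths["regions"],
                               paths["grouping"])
        assert tables.regions.shape[1] == ds.x.shape[1] - 2
        assert len(tables.dropped_regions) == 2

    def test_disjoint_sample_ids_rejected(self, tmp_path):
        _, paths = self.write_dataset(tmp_path)
        g = pd.read_csv(paths["genotypes"], index_col=0)
        g.index = ["X" + str(i) for i in range(len(g))]
        g.to_csv(paths["genotypes"])
        with pytest.raises(DataError, match="overlapping"):
            ns.load_study(paths["genotypes"], paths["regions"], paths["grouping"])

    def test_non_numeric_cell_located(self, tmp_path):
        _, paths = self.write_dataset(tmp_path)
        g = pd.read_csv(paths["genotypes"], index_col=0)
        g.iloc[3, 1] = "NA?"
        g.to_csv(paths["genotypes"])
        with pytest.raises(DataError, match="row"):
            ns.load_study(paths["genotypes"], paths["regions"], paths["grouping"])


class TestSplitAndPipeline:
    def test_split_halves_disjoint_and_reproducible(self):
        ids = np.array([f"S{i}" for i in range(101)])
        tr1, va1 = ns.train_validation_split(ids, seed=3)
        tr2, va2 = ns.train_validation_split(ids, seed=3)
        assert set(tr1) & set(va1) == set()
        assert len(tr1) == 51 and len(va1) == 50
        assert np.array_equal(tr1, tr2) and np.array_equal(va1, va2)

    def test_full_pipeline_on_synthetic_cohort(self, tmp_path, rng):
        """End-to-end: tables -> residualize -> standardize -> fit ->
        robust -> scores -> Bonferroni -> ANOVA, with no external data."""
        cfg = ns.SimulationConfig(n_individuals=240, n_snps=5,
                                  group_sizes=(4, 3), n_nonzero_a=3,
                                  n_phenotype_latents=1)
        ds = ns.simulate_dataset(cfg, seed=8)
        paths = ds.write_tables(tmp_path)
        n = cfg.n_individuals
        samples = pd.read_csv(paths["regions"], index_col=0).index
        pd.DataFrame({
            "age": rng.uniform(55, 90, size=n),
            "sex": rng.integers(0, 2, size=n),
            "wbv": rng.normal(1200, 100, size=n),
        }, index=samples).to_csv(tmp_path / "covariates.csv", index_label="sample_id")
        pd.DataFrame(
            {"diagnosis": np.where(ds.y == 1, "case", "control")}, index=samples
        ).to_csv(tmp_path / "diagnosis.csv", index_label="sample_id")

        tables = ns.load_study(paths["genotypes"], paths["regions"],
                               paths["grouping"],
                               covariates=tmp_path / "covariates.csv",
                               diagnosis=tmp_path / "diagnosis.csv")
        corrected = ns.residualize_covariates(tables.regions, tables.covariates)
        g_c, x_s = ns.standardize(tables.genotypes, corrected)
        spec = ns.build_spec(tables.grouping, snp_ids=list(g_c.columns),
                             region_order=list(x_s.columns))
        fit = ns.fit_sem(g_c.values, x_s.values, spec, seed=0)
        fit = ns.robust_adjust(fit, g_c.values, x_s.values)
        scores = ns.bartlett_scores(fit, x_s.values)
        adjusted, flags = ns.bonferroni_adjust(fit.snp_weight_pvalues())
        assert adjusted.shape == (2, 5)
        anova = ns.anova_by_group(scores, tables.diagnosis.values)
        assert len(anova) == 2
        assert np.isfinite(anova["F"]).all()
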