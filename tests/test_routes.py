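"""Registry enumeration, filtration/selection/reduction behavior, leakage audit."""

import numpy as np
import pytest

from ensembletx.routes import (FeatureRoute, MethodRegistry, RegistryError,
                               SelectionMethod, apply_filtration,
                               apply_selection, default_registry,
                               default_selection_methods, enumerate_routes,
                               enumerate_specs, filtration_mask,
                               make_reduction, reduced_registry)


class TestEnumeration:
    def test_default_grid_counts(self):
        reg = default_registry()
        assert len(reg.filtration) == 5
        assert len(reg.selection) == 102
        assert len(reg.reduction) == 7
        assert len(reg.classifiers) == 12
        assert len(enumerate_specs(reg)) == 5 * 102 * 7 * 12
        assert len(enumerate_routes(reg)) == 3570

    def test_no_duplicate_specs(self):
        specs = enumerate_specs(reduced_registry())
        assert len(specs) == len(set(specs))

    def test_single_method_registry_yields_one_spec(self):
        reg = MethodRegistry(filtration=["no"],
                             selection=[SelectionMethod("no", "no")],
                             reduction=["no"], classifiers=["lda"])
        assert len(enumerate_specs(reg)) == 1

    def test_empty_category_is_configuration_error(self):
        reg = MethodRegistry(filtration=[])
        with pytest.raises(RegistryError):
            enumerate_specs(reg)

    def test_product_size_matches_any_registry(self):
        reg = default_registry().subset(filtration=["no", "var"],
                                        reduction=["no", "pcr", "sis"],
                                        classifiers=["lda"])
        assert len(enumerate_specs(reg)) == 2 * 102 * 3 * 1


class TestFiltration:
    def test_var_keeps_high_variance_half(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, np.linspace(0.1, 5, 100), size=(30, 100))
        out = apply_filtration(x, "var")
        assert out.shape[1] == 50
        variances = x.var(axis=0, ddof=1)
        kept = filtration_mask(x, "var")
        assert variances[kept].min() >= np.median(variances) - 1e-12

    def test_cov_var_retains_quarter(self):
        rng = np.random.default_rng(1)
        x = np.abs(rng.normal(5, 2, size=(20, 100)))
        assert apply_filtration(x, "cov_var").shape[1] == 25

    def test_var_importance_retains_quarter(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 80))
        assert apply_filtration(x, "varImportance").shape[1] == 20

    def test_no_is_identity(self):
        x = np.random.default_rng(3).normal(size=(10, 8))
        assert np.array_equal(apply_filtration(x, "no"), x)

    def test_unknown_method_errors(self):
        with pytest.raises(RegistryError):
            apply_filtration(np.zeros((5, 5)), "bogus")


@pytest.fixture(scope="module")
def shifted():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(60, 50))
    y = np.repeat([0, 1], 30)
    x[y == 1, :10] += 5.0  # overwhelming signal in the first 10 features
    return x, y


class TestSelection:
    def test_zscore_family_finds_dominant_signal(self, shifted):
        x, y = shifted
        method = SelectionMethod("zscore:welch_t:k10", "zscore",
                                 {"stat": "welch_t", "k": 10})
        assert set(apply_selection(x, y, method)) == set(range(10))

    def test_no_action_returns_all(self, shifted):
        x, y = shifted
        idx = apply_selection(x, y, SelectionMethod("no", "no"))
        assert np.array_equal(idx, np.arange(50))

    def test_k_clamped_to_available_features(self, shifted):
        x, y = shifted
        method = SelectionMethod("zscore:welch_t:k500", "zscore",
                                 {"stat": "welch_t", "k": 500})
        assert len(apply_selection(x, y, method)) == 50

    def test_single_class_errors(self, shifted):
        x, _ = shifted
        method = SelectionMethod("zscore:welch_t:k10", "zscore",
                                 {"stat": "welch_t", "k": 10})
        with pytest.raises(ValueError):
            apply_selection(x, np.ones(60, dtype=int), method)

    @pytest.mark.parametrize("method", [
        m for m in default_selection_methods()
        if m.params.get("k", 10) <= 25 and m.params.get("m", 5) <= 10
        and m.params.get("stat") != "mutual_info"])
    def test_each_family_member_runs_and_returns_valid_indices(self, method, shifted):
        x, y = shifted
        idx = apply_selection(x, y, method, seed=0)
        assert len(idx) >= 1
        assert len(np.unique(idx)) == len(idx)
        assert idx.min() >= 0 and idx.max() < 50

    def test_de_selection_recovers_truth_genes(self, small_gene_data):
        """Moderated-t top-k overlaps the generator's truth DE list."""
        x = small_gene_data["x_train"]
        y = small_gene_data["y_train"]
        genes = small_gene_data["gene_names"]
        truth = set(small_gene_data["truth"]["de_genes"])
        k = len(truth)
        method = SelectionMethod(f"de:moderated:k{k}", "de",
                                 {"variant": "moderated", "k": k})
        idx = apply_selection(x, y, method)
        hit = len(set(genes[idx]) & truth) / k
        assert hit >= 0.8


class TestReduction:
    def test_no_action_identity(self):
        x = np.random.default_rng(0).normal(size=(12, 6))
        red = make_reduction("no").fit(x, np.tile([0, 1], 6))
        assert np.array_equal(red.transform(x), x)

    def test_wgcna_two_correlated_blocks_give_two_eigengenes(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        # two blocks of perfectly correlated features
        x = np.column_stack([a, 2 * a, -a, b, 3 * b, -0.5 * b])
        red = make_reduction("wgcna").fit(x, np.tile([0, 1], 10))
        out = red.transform(x)
        assert out.shape[1] == 2
        for j in range(2):
            corrs = [abs(np.corrcoef(out[:, j], x[:, i])[0, 1]) for i in range(6)]
            assert max(corrs) > 0.999

    def test_pcr_single_component_captures_rank_one_data(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=15)
        v = rng.normal(size=8)
        x = np.outer(u, v)
        red = make_reduction("pcr", n_components=1).fit(x, (u > 0).astype(int))
        scores = red.transform(x)
        # reconstruction via the single component leaves ~zero residual
        recon = red._pca.inverse_transform(scores)
        assert np.abs(x - recon).max() < 1e-8

    def test_sis_keeps_n_over_log_n_features(self):
        rng = np.random.default_rng(6)
        n = 50
        x = rng.normal(size=(n, 200))
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        red = make_reduction("sis").fit(x, y)
        assert red.transform(x).shape[1] == int(n / np.log(n))

    @pytest.mark.parametrize("method_id", ["plsr", "cppls", "logisticFwd"])
    def test_fitted_transform_applies_to_held_out(self, method_id):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(40, 30))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        x[y == 1, :3] += 2.0
        red = make_reduction(method_id).fit(x, y)
        held_out = rng.normal(size=(9, 30))
        out = red.transform(held_out)
        assert out.shape[0] == 9
        assert np.isfinite(out).all()


class TestLeakageAudit:
    def test_fitted_state_independent_of_held_out_data(self, small_gene_data):
        """Fitting twice on the same training fold yields identical state no
        matter what the held-out fold contains (poisoned fold audit)."""
        x = small_gene_data["x_train"]
        y = small_gene_data["y_train"]
        route_a = FeatureRoute("var", "zscore:welch_t:k25", "pcr").fit(x, y, seed=1)
        route_b = FeatureRoute("var", "zscore:welch_t:k25", "pcr").fit(x, y, seed=1)
        poisoned = np.full((5, x.shape[1]), 1e6)
        _ = route_b.transform(poisoned)
        assert np.array_equal(route_a.selected_features_, route_b.selected_features_)
        clean = small_gene_data["x_test"]
        assert np.allclose(route_a.transform(clean), route_b.transform(clean))
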