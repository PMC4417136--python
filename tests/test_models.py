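"""OLS fits, eigenvector retention, LRT, stepwise AIC and VIF diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhizopart.eigen import phylo_eigenvectors, spatial_eigenvectors
from rhizopart.io import CHEMISTRY_COLUMNS
from rhizopart.models import (
    ModelError,
    class_models,
    fit_ols,
    format_results_table,
    lrt_drop_class,
    results_table,
    retain_significant_phylo,
    step_aic_chemistry,
    vif,
)


def brute_force_ols(y, X):
    """Normal-equations oracle via pseudo-inverse."""
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    beta = np.linalg.pinv(A) @ y
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - rss / tss
    p = X.shape[1]
    adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    llf = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    return beta, r2, adj, llf


def _df(arr, prefix="x"):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestFitOls:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        X = _df(rng.standard_normal((30, 3)))
        y = 2 + X.to_numpy() @ np.array([1.0, -2.0, 0.5])
        fit = fit_ols(y, X)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_matches_pinv_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n, p = rng.integers(15, 40), rng.integers(1, 6)
            X = _df(rng.standard_normal((n, p)))
            y = rng.standard_normal(n)
            fit = fit_ols(y, X)
            beta, r2, adj, llf = brute_force_ols(y, X.to_numpy())
            np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)
            assert fit.adj_r2 == pytest.approx(adj, abs=1e-10)
            assert fit.llf == pytest.approx(llf, abs=1e-8)

    def test_pure_noise_adjusted_r2_centred_on_zero(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(200):
            X = _df(rng.standard_normal((60, 4)))
            vals.append(fit_ols(rng.standard_normal(60), X).adj_r2)
        assert abs(np.mean(vals)) < 0.02

    def test_binary_predictor_equals_t_test(self):
        rng = np.random.default_rng(3)
        g = np.repeat([0.0, 1.0], 20)
        y = rng.standard_normal(40) + 0.8 * g
        fit = fit_ols(y, _df(g[:, None]))
        t = stats.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
        assert fit.f_pvalue == pytest.approx(t.pvalue, rel=1e-10)

    def test_rank_deficiency_lists_aliased_columns(self):
        rng = np.random.default_rng(4)
        X = _df(rng.standard_normal((20, 2)))
        X["x2"] = X["x0"] + X["x1"]
        with pytest.raises(ModelError, match="aliased"):
            fit_ols(rng.standard_normal(20), X)


class TestVif:
    def test_orthogonal_centred_columns_unit_vif(self):
        x = np.random.default_rng(5).standard_normal((30, 3))
        q, _ = np.linalg.qr(x - x.mean(axis=0))
        out = vif(_df(q))
        np.testing.assert_allclose(out.to_numpy(), 1.0, atol=1e-8)

    def test_duplicated_column_infinite(self):
        x = np.random.default_rng(6).standard_normal(25)
        out = vif(_df(np.column_stack([x, x])))
        assert np.isinf(out).all()

    def test_closed_form_for_two_correlated_columns(self):
        # exact sample correlation r via orthogonal construction
        rng = np.random.default_rng(7)
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= (b @ a) / (a @ a) * a
        b /= b.std()
        r = 0.6
        x2 = r * a + np.sqrt(1 - r * r) * b
        out = vif(_df(np.column_stack([a, x2])))
        np.testing.assert_allclose(out.to_numpy(), 1 / (1 - r**2), rtol=1e-10)
        assert out.iloc[0] == pytest.approx(1.5625)


class TestLrt:
    def test_identical_designs_give_p_one(self):
        rng = np.random.default_rng(8)
        X = _df(rng.standard_normal((30, 2)))
        fit = fit_ols(rng.standard_normal(30), X)
        assert lrt_drop_class(fit, fit) == 1.0

    def test_non_nested_designs_rejected(self):
        rng = np.random.default_rng(9)
        full = fit_ols(rng.standard_normal(30), _df(rng.standard_normal((30, 2))))
        other = fit_ols(rng.standard_normal(30),
                        _df(rng.standard_normal((30, 1)), prefix="z"))
        with pytest.raises(ModelError, match="subset"):
            lrt_drop_class(full, other)

    def test_null_statistic_is_chi_square_df2(self):
        """Distributional check: LR stats under H0 against chi2(2) by KS."""
        rng = np.random.default_rng(10)
        n = 84
        stats_ = []
        for _ in range(2000):
            y = rng.standard_normal(n)
            X = _df(rng.standard_normal((n, 2)))
            full = fit_ols(y, X)
            reduced = fit_ols(y, X.iloc[:, :0])
            p = lrt_drop_class(full, reduced)
            stats_.append(stats.chi2.isf(p, 2))
        ks = stats.kstest(stats_, "chi2", args=(2,))
        assert ks.pvalue > 0.01

    def test_strong_dropped_effect_detected(self):
        rng = np.random.default_rng(11)
        X = _df(rng.standard_normal((84, 3)))
        y = X["x0"].to_numpy() * 0.8 + rng.standard_normal(84)
        full = fit_ols(y, X)
        reduced = fit_ols(y, X[["x1", "x2"]])
        assert lrt_drop_class(full, reduced) < 0.001


@pytest.fixture(scope="module")
def predictor_sets(default_tree, default_frame):
    phylo = phylo_eigenvectors(default_tree, default_frame, 7)
    spatial = spatial_eigenvectors(default_frame, 2)
    return (
        phylo,
        spatial,
        phylo.vectors.add_prefix("phylo_"),
        spatial.vectors.add_prefix("space_"),
    )


class TestRetainSignificantPhylo:
    def test_recovers_single_active_eigenvector(self, predictor_sets):
        _, _, phylo_X, spatial_X = predictor_sets
        rng = np.random.default_rng(12)
        ev2 = phylo_X.iloc[:, 1].to_numpy()
        ev2 = ev2 / ev2.std()
        hits, sizes = 0, []
        for _ in range(100):
            y = 0.8 * ev2 + rng.standard_normal(84)
            retained = retain_significant_phylo(y, phylo_X, spatial_X)
            hits += phylo_X.columns[1] in retained
            sizes.append(len(retained))
        # the active eigenvector is almost always kept; spurious additions
        # stay at the alpha level, so the retained set stays small
        assert hits >= 90
        assert np.median(sizes) == 1

    def test_null_retention_matches_alpha(self, predictor_sets):
        _, _, phylo_X, spatial_X = predictor_sets
        rng = np.random.default_rng(13)
        counts = [
            len(retain_significant_phylo(rng.standard_normal(84),
                                         phylo_X, spatial_X))
            for _ in range(500)
        ]
        # expected 7 * 0.05 = 0.35 retained per replicate
        assert 0.25 <= np.mean(counts) <= 0.45

    def test_exact_eigenvector_response(self, predictor_sets):
        _, _, phylo_X, spatial_X = predictor_sets
        y = phylo_X.iloc[:, 2].to_numpy()
        joint = pd.concat([phylo_X, spatial_X], axis=1)
        fit = fit_ols(y, joint)
        assert fit.pvalues[phylo_X.columns[2]] < 1e-10
        assert phylo_X.columns[2] in retain_significant_phylo(y, phylo_X, spatial_X)


class TestStepAicChemistry:
    def test_recovers_ph_only_dependence(self, default_frame):
        chem = default_frame.chemistry_zscores()
        rng = np.random.default_rng(14)
        hits, sizes = 0, []
        for _ in range(100):
            y = 0.7 * chem["pH"].to_numpy() + rng.standard_normal(84)
            selected = step_aic_chemistry(y, chem)
            hits += "pH" in selected
            sizes.append(len(selected))
        assert hits >= 90
        assert np.median(sizes) == 1

    def test_null_selection_is_small(self, default_frame):
        chem = default_frame.chemistry_zscores()
        rng = np.random.default_rng(15)
        sizes = [len(step_aic_chemistry(rng.standard_normal(84), chem))
                 for _ in range(200)]
        assert np.median(sizes) <= 1

    def test_aliased_chemistry_rejected(self, default_frame):
        chem = default_frame.chemistry_zscores().copy()
        for c in chem.columns[1:]:
            chem[c] = chem.iloc[:, 0]
        with pytest.raises(ModelError):
            step_aic_chemistry(np.random.default_rng(16).standard_normal(84), chem)


class TestClassModels:
    def test_species_signal_lands_in_species_cell(
        self, default_frame, predictor_sets
    ):
        phylo, spatial, phylo_X, _ = predictor_sets
        rng = np.random.default_rng(17)
        # species pattern orthogonal to the phylogenetic eigenvectors
        offsets = rng.standard_normal(14)
        sp = pd.get_dummies(default_frame.species, dtype=float)
        pattern = sp.to_numpy() @ offsets
        nuis = np.column_stack([np.ones(84), phylo_X.to_numpy()])
        q, _ = np.linalg.qr(nuis)
        pattern = pattern - q @ (q.T @ pattern)
        y = pattern / pattern.std() + 0.7 * rng.standard_normal(84)
        cells = class_models(y, default_frame, phylo, spatial)
        assert cells["species"].p_value < 0.01
        assert cells["species"].adj_r2 > cells["phylogeny"].adj_r2

    def test_phylogeny_and_chemistry_never_share_a_design(
        self, default_frame, predictor_sets
    ):
        phylo, spatial, _, _ = predictor_sets
        rng = np.random.default_rng(18)
        cells = class_models(rng.standard_normal(84), default_frame, phylo, spatial)
        for cell in cells.values():
            labels = set(cell.fit.design_labels)
            has_phylo = any(l.startswith("phylo_") for l in labels)
            has_chem = any(l in CHEMISTRY_COLUMNS for l in labels)
            assert not (has_phylo and has_chem)

    def test_results_table_shape_and_formatting(
        self, default_frame, predictor_sets
    ):
        phylo, spatial, _, _ = predictor_sets
        rng = np.random.default_rng(19)
        axes = pd.DataFrame(
            rng.standard_normal((84, 2)),
            index=default_frame.data.index, columns=["MDS1", "MDS2"],
        )
        table = results_table(axes, default_frame, phylo, spatial,
                              community="bacterial")
        assert len(table) == 2 * 5
        assert set(table["predictor_class"]) == {
            "species", "chemistry", "space", "phylogeny", "genus"
        }
        text = format_results_table(table)
        assert "bacterial" in text
        # noise axes routinely produce small/negative adjusted R^2 cells
        assert "<0.01" in text
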