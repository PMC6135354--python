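"""Sparse direction, sPLS-DA fitting, and cross-validated tuning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cross_decomposition import PLSRegression

from pepdiff import (
    SPLSDAClassifier,
    SPLSDACV,
    SplsdaConfig,
    fit_splsda,
    scores_plot_data,
    spls_direction,
    tune_splsda,
)
from pepdiff.exceptions import (
    ConfigError,
    DegenerateResponseError,
    FoldError,
    RankError,
)
from pepdiff.io import ProteinQuantTable

from conftest import make_design


def _random_xy(rng, n=8, p=6):
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    y = rng.normal(size=n)
    y -= y.mean()
    return X, y


def _protein_table(X, samples):
    """Samples-by-variables matrix to a ProteinQuantTable (variables as proteins)."""
    ab = pd.DataFrame(
        X.T, index=[f"P{j:03d}" for j in range(X.shape[1])], columns=samples
    )
    return ProteinQuantTable(abundances=ab, n_peptides=pd.Series(2, index=ab.index))


class TestSplsDirection:
    def test_eta_zero_is_proportional_to_cross_covariance(self, rng):
        X, y = _random_xy(rng)
        w = spls_direction(X, y, 0.0)
        Z = X.T @ y
        np.testing.assert_allclose(w, Z / np.linalg.norm(Z), atol=1e-12)

    def test_eta_near_one_keeps_single_argmax(self, rng):
        X, y = _random_xy(rng)
        w = spls_direction(X, y, 0.999)
        Z = X.T @ y
        assert np.count_nonzero(w) == 1
        assert np.flatnonzero(w)[0] == np.argmax(np.abs(Z))

    @pytest.mark.parametrize("eta", np.round(np.arange(0.0, 1.0, 0.1), 1).tolist())
    def test_matches_bruteforce_threshold_formula(self, rng, eta):
        X, y = _random_xy(rng)
        Z = X.T @ y
        thr = eta * np.max(np.abs(Z))
        raw = np.array([np.sign(z) * max(abs(z) - thr, 0.0) for z in Z])
        expected = raw / np.linalg.norm(raw)
        np.testing.assert_allclose(spls_direction(X, y, eta), expected, atol=1e-12)

    def test_sparsity_monotone_in_eta(self, rng):
        X, y = _random_xy(rng, n=10, p=15)
        support_prev = None
        for eta in (0.1, 0.3, 0.5, 0.7, 0.9):
            support = set(np.flatnonzero(spls_direction(X, y, eta)))
            if support_prev is not None:
                assert support <= support_prev
            support_prev = support

    def test_constant_response_raises(self, rng):
        X, _ = _random_xy(rng)
        with pytest.raises(DegenerateResponseError):
            spls_direction(X, np.ones(8), 0.5)

    def test_eta_out_of_range_raises(self, rng):
        X, y = _random_xy(rng)
        with pytest.raises(ConfigError):
            spls_direction(X, y, 1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        eta=st.floats(0.0, 0.99),
        n=st.integers(3, 12),
        p=st.integers(2, 20),
    )
    def test_direction_properties_hold_generally(self, seed, eta, n, p):
        # unit norm, argmax coordinate always survives, sign agreement with Z
        rng = np.random.default_rng(seed)
        X, y = _random_xy(rng, n=n, p=p)
        w = spls_direction(X, y, eta)
        Z = X.T @ y
        if np.max(np.abs(Z)) == 0:
            assert not w.any()
            return
        assert np.linalg.norm(w) == pytest.approx(1.0)
        assert w[np.argmax(np.abs(Z))] != 0
        nz = w != 0
        np.testing.assert_array_equal(np.sign(w[nz]), np.sign(Z[nz]))


class TestSPLSDAClassifier:
    def _binary_instance(self, rng, n=10, p=20):
        X = rng.normal(size=(n, p))
        y = np.array([0.0] * (n // 2) + [1.0] * (n - n // 2))
        return X, y

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_eta_zero_equals_plain_pls1(self, rng, k):
        X, y = self._binary_instance(rng)
        clf = SPLSDAClassifier(eta=0.0, n_components=k, scale=True).fit(X, y)
        pls = PLSRegression(n_components=k, scale=True).fit(X, y)
        np.testing.assert_allclose(clf.coef_, pls.coef_.ravel(), atol=1e-8)

    def test_separable_single_informative_variable(self, rng):
        X = rng.normal(scale=0.3, size=(10, 8))
        y = np.repeat([0.0, 1.0], 5)
        X[:, 3] += y * 10  # one variable carries the classes far apart
        clf = SPLSDAClassifier(eta=0.9, n_components=1).fit(X, y)
        assert clf.selected_[3]
        assert np.array_equal(clf.predict(X), y)

    def test_sample_order_invariance(self, rng):
        X, y = self._binary_instance(rng)
        clf = SPLSDAClassifier(eta=0.5, n_components=2).fit(X, y)
        perm = rng.permutation(len(y))
        clf2 = SPLSDAClassifier(eta=0.5, n_components=2).fit(X[perm], y[perm])
        np.testing.assert_allclose(clf.coef_, clf2.coef_, atol=1e-10)

    def test_scale_equivariance(self, rng):
        X, y = self._binary_instance(rng)
        clf = SPLSDAClassifier(eta=0.4, n_components=2, scale=True).fit(X, y)
        X2 = X.copy()
        X2[:, 5] *= 7.5
        clf2 = SPLSDAClassifier(eta=0.4, n_components=2, scale=True).fit(X2, y)
        assert np.array_equal(clf.selected_, clf2.selected_)
        np.testing.assert_allclose(
            clf.decision_function(X), clf2.decision_function(X2), atol=1e-8
        )

    def test_beta_zero_outside_active_set(self, rng):
        X, y = self._binary_instance(rng)
        clf = SPLSDAClassifier(eta=0.8, n_components=1).fit(X, y)
        assert np.all(clf.coef_[~clf.selected_] == 0.0)
        assert clf.selected_.sum() < X.shape[1]

    def test_k_exceeding_rank_raises(self, rng):
        X, y = self._binary_instance(rng, n=6, p=4)
        with pytest.raises(RankError):
            SPLSDAClassifier(eta=0.1, n_components=6).fit(X, y)

    def test_nonbinary_response_rejected(self, rng):
        X, _ = self._binary_instance(rng)
        with pytest.raises(DegenerateResponseError):
            SPLSDAClassifier().fit(X, np.arange(10.0))

    def test_sklearn_params_round_trip(self):
        clf = SPLSDAClassifier(eta=0.3, n_components=2, scale=False)
        params = clf.get_params()
        assert params == {"eta": 0.3, "n_components": 2, "scale": False}
        clf.set_params(eta=0.7)
        assert clf.eta == 0.7


class TestTuning:
    def test_single_point_grid_is_identity(self, rng):
        design = make_design(5)
        X = rng.normal(size=(10, 12))
        prot = _protein_table(X, design.samples)
        cfg = SplsdaConfig(eta_grid=(0.5,), k_grid=(2,), fold_seed=0)
        eta, K, grid = tune_splsda(prot, design, cfg)
        assert (eta, K) == (0.5, 2)
        assert grid.shape == (1, 1)

    def test_large_effect_reaches_zero_cv_error(self, rng):
        design = make_design(5)
        X = rng.normal(scale=1.0, size=(10, 12))
        X[:, 0] += np.repeat([0.0, 5.0], 5)  # shift = 5 x noise sd
        prot = _protein_table(X, design.samples)
        eta, K, grid = tune_splsda(prot, design, SplsdaConfig(fold_seed=3))
        assert grid.to_numpy().min() == 0.0
        assert grid.loc[eta, K] == 0.0

    def test_pure_noise_cv_error_near_half(self):
        # mean CV error over seeds hovers around the chance level
        design = make_design(5)
        errs = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(10, 15))
            prot = _protein_table(X, design.samples)
            cfg = SplsdaConfig(eta_grid=(0.5,), k_grid=(1,), fold_seed=seed)
            _, _, grid = tune_splsda(prot, design, cfg)
            errs.append(grid.to_numpy().min())
        assert 0.4 <= np.mean(errs) <= 0.6

    def test_grid_deterministic_given_fold_seed(self, rng):
        design = make_design(5)
        X = rng.normal(size=(10, 10))
        prot = _protein_table(X, design.samples)
        cfg = SplsdaConfig(eta_grid=(0.1, 0.5), k_grid=(1, 2), fold_seed=11)
        _, _, g1 = tune_splsda(prot, design, cfg)
        _, _, g2 = tune_splsda(prot, design, cfg)
        assert g1.equals(g2)
        assert ((g1 >= 0) & (g1 <= 1)).all().all()

    def test_tie_break_prefers_larger_eta_then_smaller_k(self, rng):
        # constant grid (pure noise often ties): the chosen point must be
        # the sparsest/simplest among the minimizers
        design = make_design(5)
        X = rng.normal(scale=0.1, size=(10, 6))
        X[:, 2] += np.repeat([0.0, 8.0], 5)  # all grid points reach zero error
        prot = _protein_table(X, design.samples)
        cfg = SplsdaConfig(eta_grid=(0.1, 0.5, 0.9), k_grid=(1, 2), fold_seed=0)
        eta, K, grid = tune_splsda(prot, design, cfg)
        assert grid.to_numpy().min() == 0.0
        best = grid.to_numpy().min()
        etas_at_best = [e for e in grid.index for k in grid.columns if grid.loc[e, k] == best]
        assert eta == max(etas_at_best)
        assert K == min(k for k in grid.columns if grid.loc[eta, k] == best)

    def test_too_few_samples_per_class_raises(self):
        design = make_design(3)
        X = np.random.default_rng(0).normal(size=(6, 5))
        prot = _protein_table(X, design.samples)
        with pytest.raises(FoldError):
            tune_splsda(prot, design, SplsdaConfig(n_folds=4))


class TestScoresPlotData:
    def test_coordinates_and_separation(self, rng):
        design = make_design(5)
        X = rng.normal(scale=0.3, size=(10, 8))
        X[:, 1] += np.repeat([0.0, 6.0], 5)
        prot = _protein_table(X, design.samples)
        clf, _ = fit_splsda(prot, design, eta=0.5, K=2)
        df = scores_plot_data(clf, prot, design)
        assert len(df) == 10
        assert set(df["group_name"]) == {"group0", "group1"}
        c1_by_group = df.groupby("group")["component_1"].mean()
        # groups separate in sign along component 1
        assert np.sign(c1_by_group[0]) != np.sign(c1_by_group[1])
        assert not df["single_component"].any()

    def test_single_component_zero_fills_second(self, rng):
        design = make_design(5)
        prot = _protein_table(rng.normal(size=(10, 6)), design.samples)
        clf, _ = fit_splsda(prot, design, eta=0.5, K=1)
        df = scores_plot_data(clf, prot, design)
        assert (df["component_2"] == 0).all()
        assert df["single_component"].all()


class TestMissingHandling:
    def test_proteins_with_missing_cells_excluded_from_fit(self, rng):
        design = make_design(5)
        X = rng.normal(size=(10, 5))
        prot = _protein_table(X, design.samples)
        prot.abundances.iloc[2, 3] = np.nan
        clf, fitted = fit_splsda(prot, design, eta=0.1, K=1)
        assert "P002" not in fitted
        assert len(fitted) == 4
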