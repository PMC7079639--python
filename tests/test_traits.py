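"""Derived traits, trend estimation, partial-R2 decomposition, biplot."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metgain import (
    biplot_decomposition,
    derive_traits,
    sequential_r2,
    trait_trend,
)

from oracles import prefix_r2_oracle


class TestDeriveTraits:
    def test_unit_identities(self):
        df = pd.DataFrame({"dh": [60.0], "dm": [100.0],
                           "gy_g_m2": [450.0], "gw_mg": [45.0]})
        out = derive_traits(df)
        assert out.loc[0, "dhm"] == 40.0
        assert out.loc[0, "gn"] == pytest.approx(10_000.0)
        assert out.loc[0, "gy_t_ha"] == pytest.approx(4.5)

    def test_missing_component_keeps_row(self):
        df = pd.DataFrame({"dh": [60.0, 61.0], "dm": [100.0, np.nan],
                           "gy_g_m2": [450.0, 400.0], "gw_mg": [45.0, 40.0]})
        out = derive_traits(df)
        assert np.isnan(out.loc[1, "dhm"])
        assert out.loc[1, "gn"] == pytest.approx(10_000.0)

    def test_invalid_components_flagged(self):
        df = pd.DataFrame({"dh": [60.0, 50.0], "dm": [55.0, 100.0],
                           "gy_g_m2": [450.0, 450.0], "gw_mg": [-1.0, 45.0]})
        out = derive_traits(df)
        assert np.isnan(out.loc[0, "dhm"]) and np.isnan(out.loc[0, "gn"])
        assert "dhm_invalid" in out.loc[0, "derived_flags"]
        assert "gn_missing" in out.loc[0, "derived_flags"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        dh=st.floats(40.0, 90.0), dhm=st.floats(1.0, 80.0),
        gy=st.floats(10.0, 1500.0), gw=st.floats(5.0, 80.0),
    )
    def test_identities_hold_for_every_valid_row(self, dh, dhm, gy, gw):
        out = derive_traits(pd.DataFrame(
            {"dh": [dh], "dm": [dh + dhm], "gy_g_m2": [gy], "gw_mg": [gw]}))
        assert out.loc[0, "dhm"] == pytest.approx(dhm, rel=1e-12, abs=1e-9)
        assert out.loc[0, "gn"] == pytest.approx(gy / (gw / 1000.0), rel=1e-12)
        assert out.loc[0, "gy_t_ha"] == pytest.approx(0.01 * gy, rel=1e-12)


class TestTrend:
    def test_exact_linear_series(self):
        pts = [(y, 30.0 + 1.08 * (y - 15)) for y in range(15, 25)]
        tt = trait_trend(pts, "gw_mg")
        assert tt["slope"] == pytest.approx(1.08, abs=1e-12)
        assert tt["p_value"] < 1e-10

    def test_constant_series(self):
        tt = trait_trend([(y, 85.0) for y in range(15, 22)], "ph_cm")
        assert tt["slope"] == pytest.approx(0.0, abs=1e-12)
        assert tt["p_value"] == pytest.approx(1.0)

    def test_two_years_gives_slope_without_p(self):
        with pytest.warns(UserWarning, match="3 years"):
            tt = trait_trend([(15, 30.0), (16, 31.0)], "gw_mg")
        assert tt["slope"] == pytest.approx(1.0)
        assert tt["p_value"] is None and tt["flags"]


class TestSequentialR2:
    def _data(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=["gw", "dm", "dh", "ph"])
        y = 1 + 2 * X["gw"] + 0.8 * X["dm"] + rng.normal(0, 0.7, n)
        return y.to_numpy(), X

    def test_single_predictor_contribution_is_total(self):
        y, X = self._data()
        out = sequential_r2(y, X[["gw"]], order=["gw"])
        assert out.table.loc[0, "partial_r2"] == pytest.approx(out.total_r2, abs=1e-12)
        assert out.table.loc[0, "contribution_pct"] == pytest.approx(100.0)

    def test_orthogonal_predictors_partial_equals_marginal(self):
        n = 32
        t = np.arange(n)
        X = pd.DataFrame({
            "a": np.where(t % 2 == 0, 1.0, -1.0),
            "b": np.where((t // 2) % 2 == 0, 1.0, -1.0),
        })
        rng = np.random.default_rng(3)
        y = 1 + 0.9 * X["a"].to_numpy() + 0.4 * X["b"].to_numpy() + rng.normal(0, 0.5, n)
        marg_a = sequential_r2(y, X[["a"]], order=["a"]).total_r2
        marg_b = sequential_r2(y, X[["b"]], order=["b"]).total_r2
        for order in (["a", "b"], ["b", "a"]):
            out = sequential_r2(y, X, order=order)
            partials = out.table.set_index("trait")["partial_r2"]
            assert partials["a"] == pytest.approx(marg_a, abs=1e-10)
            assert partials["b"] == pytest.approx(marg_b, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_refit_oracle_and_telescopes(self, seed):
        y, X = self._data(seed)
        rng = np.random.default_rng(seed + 100)
        order = list(rng.permutation(X.columns))
        out = sequential_r2(y, X, order=order)
        partials_o, total_o = prefix_r2_oracle(y, X, order)
        np.testing.assert_allclose(out.table["partial_r2"], partials_o, atol=1e-10)
        assert out.total_r2 == pytest.approx(total_o, abs=1e-10)
        assert out.table["partial_r2"].sum() == pytest.approx(out.total_r2, abs=1e-10)

    def test_auto_order_invariant_to_column_order(self):
        y, X = self._data(7)
        out1 = sequential_r2(y, X, order="auto")
        out2 = sequential_r2(y, X[list(reversed(X.columns))], order="auto")
        assert out1.order == out2.order
        assert out1.order[0] == "gw"   # strongest predictor enters first

    def test_exact_collinearity_detected(self):
        y, X = self._data(1)
        X = X.copy()
        X["dhm"] = X["dm"] - X["dh"]
        with pytest.warns(UserWarning, match="collinear"):
            out = sequential_r2(y, X, order="auto")
        assert out.collinear
        assert out.table["partial_r2"].sum() == pytest.approx(out.total_r2, abs=1e-10)

    def test_constant_predictor_rejected(self):
        y, X = self._data(2)
        X = X.assign(const=1.0)
        with pytest.raises(ValueError, match="constant"):
            sequential_r2(y, X, order="auto")


class TestBiplot:
    def test_rank_two_matrix_fully_explained(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(30, 2))
        M = pd.DataFrame(
            base @ rng.normal(size=(2, 5)),
            columns=list("abcde"),
        )
        out = biplot_decomposition(M)
        assert out.cumulative == pytest.approx(1.0, abs=1e-10)
        assert out.all_fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(out.all_fractions) <= 1e-12)

    def test_duplicated_trait_columns_coincide(self):
        rng = np.random.default_rng(6)
        M = pd.DataFrame(rng.normal(size=(25, 3)), columns=["a", "b", "c"])
        M["a2"] = 2.0 * M["a"] + 1.0   # same trait in different units
        out = biplot_decomposition(M)
        ia, ia2 = out.trait_names.index("a"), out.trait_names.index("a2")
        np.testing.assert_allclose(out.loadings[ia], out.loadings[ia2], atol=1e-8)

    def test_rank2_reconstruction_recovers_known_correlations(self):
        """Loadings reproduce trait correlations up to rank-2 truncation."""
        rng = np.random.default_rng(8)
        f = rng.normal(size=(600, 2))
        load = np.array([[1.0, 0.0], [0.9, 0.3], [0.0, 1.0], [-0.8, 0.4]])
        M = pd.DataFrame(f @ load.T + rng.normal(0, 0.15, (600, 4)),
                         columns=list("wxyz"))
        out = biplot_decomposition(M)
        n = len(M)
        # rank-2 reconstruction of the correlation matrix from the biplot
        recon = out.scores @ out.loadings.T
        Z = (M - M.mean()) / M.std(ddof=1)
        corr_emp = np.corrcoef(Z.to_numpy().T)
        corr_recon = (recon.T @ recon) / (n - 1)
        scale = np.sqrt(np.diag(corr_recon))
        corr_recon = corr_recon / np.outer(scale, scale)
        np.testing.assert_allclose(corr_recon, corr_emp, atol=0.1)

    def test_shape_preconditions(self):
        with pytest.raises(ValueError):
            biplot_decomposition(pd.DataFrame({"a": [1.0, 2.0]}))
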