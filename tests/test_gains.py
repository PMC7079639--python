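"""Gain regressions, top-line selection and yearly distributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metgain import (
    compute_gylc,
    estimate_gylc_gain,
    estimate_gyp_gain,
    hyl_overlap,
    select_top_lines,
    yearly_yield_distribution,
)
from metgain.gains import _ols

from oracles import ols_oracle


def _table(names, means, lc=None):
    lc = lc or []
    return pd.DataFrame(
        {
            "genotype_name": names,
            "across_site_mean": means,
            "is_local_check": [n in lc for n in names],
        }
    )


class TestSelection:
    def test_top_five_of_distinct_means(self):
        tbl = _table([f"G{i}" for i in range(10)], np.arange(10, dtype=float))
        sel = select_top_lines(tbl, year=15, n=5)
        assert sel.genotype_names == ["G9", "G8", "G7", "G6", "G5"]

    def test_local_check_is_skipped_and_next_line_promoted(self):
        tbl = _table(["LC", "A", "B", "C", "D", "E", "F"],
                     [9.0, 8, 7, 6, 5, 4, 3], lc=["LC"])
        sel = select_top_lines(tbl, year=15, n=5)
        assert "LC" not in sel.genotype_names
        assert sel.genotype_names == ["A", "B", "C", "D", "E"]

    def test_rank_five_tie_broken_lexicographically(self):
        tbl = _table(["A", "B", "C", "D", "Zed", "Ann"],
                     [9.0, 8, 7, 6, 5.0, 5.0])
        sel1 = select_top_lines(tbl, year=15, n=5)
        sel2 = select_top_lines(tbl.iloc[::-1].reset_index(drop=True), year=15, n=5)
        assert sel1.genotype_names[-1] == "Ann"
        assert sel1.genotype_names == sel2.genotype_names

    def test_fewer_candidates_than_requested_flagged(self):
        tbl = _table(["A", "B"], [5.0, 4.0])
        with pytest.warns(UserWarning):
            sel = select_top_lines(tbl, year=15, n=5)
        assert len(sel.genotype_names) == 2 and sel.flags


class TestGYP:
    def test_exact_line(self):
        pts = [(y, 4.0 + 0.1 * (y - 1)) for y in range(1, 11)]
        est = estimate_gyp_gain(pts)
        assert est.slope == pytest.approx(0.1, abs=1e-12)
        assert est.slope_kg_per_ha_yr == pytest.approx(100.0, abs=1e-9)
        assert est.percent_rate == pytest.approx(0.1 / 4.45 * 100, abs=1e-9)
        assert est.r_squared == pytest.approx(1.0)

    def test_constant_series(self):
        est = estimate_gyp_gain([(y, 4.2) for y in range(1, 6)])
        assert est.slope == pytest.approx(0.0, abs=1e-12)
        assert est.percent_rate == pytest.approx(0.0, abs=1e-12)
        assert est.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_single_year_errors(self):
        with pytest.raises(ValueError):
            estimate_gyp_gain([(1, 4.0)])

    def test_percent_rate_invariant_to_units(self):
        pts = [(y, 4.0 + 0.1 * y) for y in range(1, 8)]
        est_t = estimate_gyp_gain(pts)
        est_kg = estimate_gyp_gain([(y, 1000 * v) for y, v in pts])
        assert est_t.percent_rate == pytest.approx(est_kg.percent_rate, rel=1e-12)

    def test_grand_mean_denominator(self):
        pts = [(y, 4.0 + 0.1 * y) for y in range(1, 8)]
        est = estimate_gyp_gain(pts, denominator="grand_mean", grand_means=[4.0] * 7)
        assert est.percent_rate == pytest.approx(100 * 0.1 / 4.0)


class TestGYLC:
    def test_formula(self):
        assert compute_gylc(5.0, 4.0) == pytest.approx(25.0)
        assert compute_gylc(4.0, 4.0) == 0.0
        with pytest.raises(ValueError):
            compute_gylc(5.0, 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        h=st.floats(0.1, 20.0),
        lc=st.floats(0.1, 20.0),
        c=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, h, lc, c):
        assert compute_gylc(c * h, c * lc) == pytest.approx(
            compute_gylc(h, lc), rel=1e-9, abs=1e-9
        )

    def test_constant_margin_gives_zero_slopes(self):
        est = estimate_gylc_gain([(y, 4.5, 4.0) for y in range(1, 8)])
        assert est.slope == pytest.approx(0.0, abs=1e-10)
        assert est.slope_kg_per_ha_yr == pytest.approx(0.0, abs=1e-9)

    def test_constructed_absolute_slope(self):
        pts = [(y, 4.0 + 0.0651 * y + 0.5, 4.0 + 0.0) for y in range(1, 11)]
        # lc constant, hyl grows 0.0651/yr -> absolute slope 65.1 kg/ha/yr
        est = estimate_gylc_gain(pts)
        assert est.slope_kg_per_ha_yr == pytest.approx(65.1, abs=1e-9)


def test_ols_matches_closed_form_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = np.arange(15, 25, dtype=float)
        y = rng.normal(4 + 0.1 * x, 0.3)
        slope, intercept, r2, p = _ols(x, y)
        so, io_, r2o, po = ols_oracle(x, y)
        assert slope == pytest.approx(so, abs=1e-10)
        assert r2 == pytest.approx(r2o, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)


class TestDistribution:
    def test_density_normalizes_and_mean_shift_equivariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"year": np.repeat([15, 16], 40),
                           "value": rng.normal(4, 0.5, 80)})
        out = yearly_yield_distribution(df)
        for _, row in out.iterrows():
            area = np.trapezoid(row["density_values"], row["density_grid"])
            assert area == pytest.approx(1.0, abs=1e-3)
        shifted = yearly_yield_distribution(df.assign(value=df["value"] + 1.0))
        np.testing.assert_allclose(shifted["mean"], out["mean"] + 1.0, atol=1e-12)

    def test_degenerate_year_flagged(self):
        df = pd.DataFrame({"year": [15] * 6, "value": [4.0] * 6})
        out = yearly_yield_distribution(df)
        assert out.loc[0, "degenerate"]
        assert out.loc[0, "sd"] == 0.0


def test_hyl_overlap_bounds(small_program):
    from metgain.gains import HYLSelection

    a = HYLSelection(15, "high", ["A", "B", "C", "D", "E"], np.ones(5))
    b = HYLSelection(15, "low", ["C", "D", "E", "F", "G"], np.ones(5))
    assert hyl_overlap(a, b) == pytest.approx(0.6)
    assert 0.0 <= hyl_overlap(a, b) <= 1.0
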