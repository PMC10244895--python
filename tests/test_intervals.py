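"""The intervals method: filtering, threshold, area proportions, PCA and
interval-count selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import antfea as af
from antfea.intervals import (IntervalScheme, IntervalsError, _r_squared,
                              combine_stress_area, validate_element_table)


def _table(model, stresses, areas=None):
    stresses = np.asarray(stresses, float)
    areas = np.ones_like(stresses) if areas is None else np.asarray(areas, float)
    return pd.DataFrame({"model": model,
                         "element_id": np.arange(1, len(stresses) + 1),
                         "tresca": stresses, "area_mm2": areas})


class TestFilter:
    def test_hundred_elements_keep_98(self):
        t = _table("a", np.linspace(0.1, 1.0, 100))
        assert len(af.filter_top_percent(t)) == 98

    def test_fifty_elements_ceil_rule(self):
        t = _table("a", np.linspace(0.1, 1.0, 50))
        assert len(af.filter_top_percent(t)) == 49

    def test_removed_are_the_highest(self):
        rng = np.random.default_rng(8)
        t = _table("a", rng.lognormal(0, 1, 500))
        kept = af.filter_top_percent(t)
        removed = t[~t["element_id"].isin(kept["element_id"])]
        assert kept["tresca"].max() < removed["tresca"].min()

    def test_per_model_independent(self):
        t = pd.concat([_table("a", np.linspace(0.1, 1.0, 100)),
                       _table("b", np.linspace(5.0, 6.0, 50))], ignore_index=True)
        f = af.filter_top_percent(t)
        assert (f["model"] == "a").sum() == 98
        assert (f["model"] == "b").sum() == 49

    def test_empty_table_errors(self):
        with pytest.raises(IntervalsError):
            af.filter_top_percent(_table("a", []))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100.0), min_size=5, max_size=60, unique=True))
    def test_order_statistics_property(self, stresses):
        """max kept < min removed, for any strictly-unique stress sample."""
        t = _table("a", stresses)
        kept = af.filter_top_percent(t, percent=10.0)
        removed = t[~t["element_id"].isin(kept["element_id"])]
        if len(removed) and len(kept):
            assert kept["tresca"].max() < removed["tresca"].min()


class TestThreshold:
    def test_uniform_percentile(self):
        # ln(stress) uniform on [0, 1]: 98th percentile of linspace = 0.98
        t = _table("a", np.exp(np.linspace(0.0, 1.0, 10001)))
        assert af.fit_upper_threshold(t) == pytest.approx(0.98, abs=1e-9)

    def test_identical_values(self):
        t = _table("a", np.full(50, 2.5))
        assert af.fit_upper_threshold(t) == pytest.approx(np.log(2.5))


class TestScheme:
    def test_invariants(self):
        s = IntervalScheme(lower=-2.0, upper_threshold=0.69, n_intervals=15)
        edges = s.edges()
        assert len(edges) == 15
        widths = np.diff(edges)
        np.testing.assert_allclose(widths, widths[0])
        assert edges[-1] == 0.69

    def test_lower_must_be_below_upper(self):
        with pytest.raises(IntervalsError):
            IntervalScheme(lower=1.0, upper_threshold=0.5, n_intervals=5)


class TestAreaProportions:
    def test_all_in_one_interval(self):
        s = IntervalScheme(lower=0.0, upper_threshold=2.0, n_intervals=4)
        t = _table("a", np.exp([0.1, 0.2, 0.3]))
        row = af.area_proportions(t, s).to_numpy()[0]
        np.testing.assert_allclose(row, [1.0, 0, 0, 0])

    def test_two_equal_area_elements_split(self):
        s = IntervalScheme(lower=0.0, upper_threshold=2.0, n_intervals=3)
        t = _table("a", np.exp([0.5, 1.5]))
        row = af.area_proportions(t, s).to_numpy()[0]
        np.testing.assert_allclose(row, [0.5, 0.5, 0.0])

    def test_above_threshold_in_last_open_interval(self):
        s = IntervalScheme(lower=0.0, upper_threshold=1.0, n_intervals=3)
        t = _table("a", np.exp([0.1, 5.0]))
        row = af.area_proportions(t, s).to_numpy()[0]
        np.testing.assert_allclose(row, [0.5, 0.0, 0.5])

    def test_area_doubling_leaves_row_unchanged(self, synthetic_tables):
        filt = af.filter_top_percent(synthetic_tables)
        scheme = af.build_scheme(filt, 15)
        m1 = af.area_proportions(filt, scheme)
        doubled = filt.copy()
        doubled.loc[doubled["model"] == "m0", "area_mm2"] *= 2.0
        m2 = af.area_proportions(doubled, scheme)
        np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy())

    def test_rows_sum_to_one(self, synthetic_tables):
        filt = af.filter_top_percent(synthetic_tables)
        mat = af.area_proportions(filt, af.build_scheme(filt, 15))
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-9)
        assert (mat.to_numpy() >= 0).all()

    def test_below_lower_clamped_to_first(self, caplog):
        s = IntervalScheme(lower=0.0, upper_threshold=1.0, n_intervals=3)
        t = _table("a", np.exp([-5.0, 0.5]))
        row = af.area_proportions(t, s).to_numpy()[0]
        np.testing.assert_allclose(row, [0.5, 0.5, 0.0])

    def test_bit_identical_rerun(self, synthetic_tables):
        filt = af.filter_top_percent(synthetic_tables)
        scheme = af.build_scheme(filt, 25)
        a = af.area_proportions(filt, scheme)
        b = af.area_proportions(filt, scheme)
        assert a.equals(b)


class TestPca:
    def test_identical_rows_degenerate(self):
        mat = pd.DataFrame(np.ones((3, 5)))
        with pytest.warns(UserWarning, match="zero-variance"):
            res = af.pca_profiles(mat)
        assert len(res.explained_variance_pct) == 0

    def test_rank_one_matrix(self):
        base = np.linspace(0, 1, 6)
        mat = pd.DataFrame(np.outer([1.0, 2.0, 3.0, 4.0], base))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = af.pca_profiles(mat)
        assert res.explained_variance_pct[0] == pytest.approx(100.0)

    def test_matches_correlation_eigendecomposition(self):
        """Brute-force oracle: variance percentages from the eigenvalues of
        the correlation matrix."""
        rng = np.random.default_rng(17)
        mat = pd.DataFrame(rng.uniform(size=(10, 15)))
        res = af.pca_profiles(mat, standardize=True)
        corr = np.corrcoef(mat.to_numpy(), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        expected = 100.0 * eig / eig.sum()
        np.testing.assert_allclose(res.explained_variance_pct,
                                   expected[:len(res.explained_variance_pct)],
                                   atol=1e-9)

    def test_needs_two_models(self):
        with pytest.raises(IntervalsError):
            af.pca_profiles(pd.DataFrame(np.ones((1, 5))))


class TestSelection:
    def test_r_squared_sign_invariant(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert _r_squared(a, b) == pytest.approx(_r_squared(-a, b))
        assert _r_squared(a, b) == pytest.approx(_r_squared(a, -b))

    def test_point_mass_profiles_select_first_candidate(self):
        """Stress mass at three well-separated points occupies one bin per
        point at every candidate count, so all area-proportion matrices are
        equal up to column placement: R^2 = 1 at the first pair and N* = 5."""
        rng = np.random.default_rng(5)
        frames = []
        locations = np.exp([0.1, 0.5, 2.0])  # last one above the threshold
        for j in range(6):
            weights = rng.dirichlet(np.ones(3))
            frames.append(_table(f"m{j}", locations, areas=weights))
        table = pd.concat(frames, ignore_index=True)
        sel = af.select_interval_count(table, upper_threshold=1.0)
        assert sel.n_intervals == 5
        assert sel.r2_per_pair[0]["r2_pc1"] == pytest.approx(1.0, abs=1e-9)
        assert sel.r2_per_pair[0]["r2_pc2"] == pytest.approx(1.0, abs=1e-9)

    def test_needs_three_candidates(self, synthetic_tables):
        filt = af.filter_top_percent(synthetic_tables)
        with pytest.raises(IntervalsError):
            af.select_interval_count(filt, candidates=(5, 15))

    def test_selection_on_synthetic_cohort(self, synthetic_tables):
        filt = af.filter_top_percent(synthetic_tables)
        sel = af.select_interval_count(filt)
        assert sel.n_intervals in (5, 15, 25, 50, 75)
        assert len(sel.r2_per_pair) == 4
        for rec in sel.r2_per_pair:
            assert 0.0 <= rec["r2_pc1"] <= 1.0 + 1e-12


class TestChainAndIO:
    def test_full_chain_consistency(self, synthetic_tables):
        chain = af.run_intervals_chain(synthetic_tables)
        mat = chain["matrix"]
        assert mat.shape[1] == chain["selection"].n_intervals
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-9)
        assert chain["upper_threshold"] == pytest.approx(
            chain["fitted_threshold"])
        pct = chain["pca"].explained_variance_pct
        assert (pct >= 0).all() and pct.sum() <= 100.0 + 1e-6

    def test_csv_round_trip(self, synthetic_tables, tmp_path):
        p = tmp_path / "elements.csv"
        synthetic_tables.to_csv(p, index=False)
        back = af.read_element_table(str(p))
        np.testing.assert_allclose(back["tresca"], synthetic_tables["tresca"])

    def test_combine_stress_area_two_file_input(self):
        stress = pd.DataFrame({"model": ["a", "a"], "element_id": [1, 2],
                               "s_tresca": [0.5, 1.5]})
        area = pd.DataFrame({"model": ["a", "a"], "element_id": [1, 2],
                             "elem_area": [1e-4, 2e-4]})
        merged = combine_stress_area(stress, area)
        validate_element_table(merged)
        assert merged["tresca"].tolist() == [0.5, 1.5]
        assert merged["area_mm2"].tolist() == [1e-4, 2e-4]

    def test_validation_rejects_bad_tables(self):
        bad = _table("a", [1.0, -2.0])
        with pytest.raises(IntervalsError, match="positive"):
            validate_element_table(bad)
        dup = _table("a", [1.0, 2.0])
        dup.loc[1, "element_id"] = 1
        with pytest.raises(IntervalsError, match="unique"):
            validate_element_table(dup)
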