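"""Correlation, path decomposition and population ANOVA."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from popgrowth import (
    PathAnalysis,
    path_decomposition,
    pearson,
    population_anova,
    windowed_path_analysis,
)
from popgrowth.association import DEFAULT_WINDOWS
from popgrowth.growth_data import table_from_frame, derive_traits


def _orthonormal_centered(n, k, seed=0):
    """k mean-zero, unit-norm, mutually orthogonal columns of length n."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k))
    z -= z.mean(axis=0)
    q, _ = np.linalg.qr(z)
    q -= q.mean(axis=0)  # re-centre (QR can shift means)
    q, _ = np.linalg.qr(q)
    return q


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == 0.0
        assert res.stars == "**"

    def test_matches_direct_formula_and_scipy(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=10)
        y = x + rng.normal(size=10)
        res = pearson(x, y)
        cov = np.cov(x, y, ddof=1)
        assert res.r == pytest.approx(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]), abs=1e-12)
        r_sp, p_sp = st.pearsonr(x, y)
        assert res.r == pytest.approx(r_sp, abs=1e-12)
        assert res.p_value == pytest.approx(p_sp, rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson(x, y).r == pearson(y, x).r

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2, np.nan, 4, 5, 6])
        y = np.array([2.0, 4, 6, np.nan, 10, 12])
        res = pearson(x, y)
        assert res.n == 4
        assert res.r == pytest.approx(1.0)

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson([1.0, 2.0], [3.0, 4.0])


class TestPathDecomposition:
    def test_orthogonal_predictors_have_zero_indirect_effect(self):
        q = _orthonormal_centered(40, 3)
        X = pd.DataFrame(q[:, :2], columns=["a", "b"])
        y = 0.7 * q[:, 0] + 0.2 * q[:, 1] + 0.4 * q[:, 2]
        res = path_decomposition(X, y)
        for name in ("a", "b"):
            assert res.ipc[name] == pytest.approx(0.0, abs=1e-10)
            assert res.dpc[name] == pytest.approx(res.r_with_response[name], abs=1e-10)

    def test_hand_solved_two_predictor_normal_equations(self):
        # sample correlations built exactly: r12=0.5, r1y=0.8, r2y=0.6
        # normal equations give dpc1 = 2/3, dpc2 = 4/15;
        # ipc1 = 0.5 * 4/15 = 2/15, and dpc1 + ipc1 = 0.8.
        q = _orthonormal_centered(60, 3, seed=1)
        x1 = q[:, 0]
        x2 = 0.5 * q[:, 0] + np.sqrt(0.75) * q[:, 1]
        b1, b2 = 2 / 3, 4 / 15
        resid_var = 1 - (b1 * 0.8 + b2 * 0.6)
        y = b1 * x1 + b2 * x2 + np.sqrt(resid_var) * q[:, 2]
        res = path_decomposition(pd.DataFrame({"x1": x1, "x2": x2}), y)
        assert res.dpc["x1"] == pytest.approx(2 / 3, abs=1e-9)
        assert res.dpc["x2"] == pytest.approx(4 / 15, abs=1e-9)
        assert res.ipc["x1"] == pytest.approx(2 / 15, abs=1e-9)
        assert res.dpc["x1"] + res.ipc["x1"] == pytest.approx(0.8, abs=1e-9)

    def test_path_identity_on_random_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(10, 60)
            X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
            y = X @ rng.normal(size=3) + rng.normal(size=n)
            res = path_decomposition(X, y)
            for name in "abc":
                assert res.dpc[name] + res.ipc[name] == pytest.approx(
                    res.r_with_response[name], abs=1e-10
                )

    def test_collinear_predictors_named_in_error(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": 2 * x1})
        with pytest.raises(ValueError, match="singular.*x1~x3"):
            path_decomposition(X, x1 + x2)

    def test_too_small_sample_raises(self):
        X = pd.DataFrame(np.eye(4)[:, :3], columns=list("abc"))
        with pytest.raises(ValueError, match="need n >"):
            path_decomposition(X, np.arange(4.0))

    def test_estimator_interface(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["d", "h", "s"])
        y = X["d"] * 2 + rng.normal(size=30)
        pa = PathAnalysis().fit(X, y)
        assert pa.get_params() == {}
        assert set(pa.dpc_) == {"d", "h", "s"}
        assert pa.stars_["d"] == "**"


class TestWindowedPathAnalysis:
    def test_cardinality_six_windows_two_crosses(self, traits1):
        out = windowed_path_analysis(traits1)
        assert set(out["window"]) == {f"{lo}-{hi}" for lo, hi in DEFAULT_WINDOWS}
        assert len(out) == 6 * 2 * 3  # windows x cross types x predictors

    def test_single_age_window_equals_plain_decomposition(self, traits1):
        out = windowed_path_analysis(traits1, windows=((5, 5),))
        d = traits1.data
        sub = d[(d["age"] == 5) & (d["cross_type"] == "DxM")]
        direct = path_decomposition(
            sub[["dbh_cm", "height_m", "hdr"]], sub["volume_m3"]
        )
        row = out[(out["cross_type"] == "DxM") & (out["trait"] == "dbh_cm")].iloc[0]
        assert row["dpc"] == pytest.approx(direct.dpc["dbh_cm"], rel=1e-12)

    def test_pooled_window_equals_concatenation_oracle(self, traits1):
        out = windowed_path_analysis(traits1, windows=((4, 6),))
        d = traits1.data
        pieces = [d[(d["age"] == a) & (d["cross_type"] == "MxD")] for a in (4, 5, 6)]
        pooled = pd.concat(pieces)
        direct = path_decomposition(
            pooled[["dbh_cm", "height_m", "hdr"]], pooled["volume_m3"]
        )
        for trait in ("dbh_cm", "height_m", "hdr"):
            row = out[(out["cross_type"] == "MxD") & (out["trait"] == trait)].iloc[0]
            assert row["dpc"] == pytest.approx(direct.dpc[trait], rel=1e-12)
            assert row["ipc"] == pytest.approx(direct.ipc[trait], rel=1e-12)

    def test_empty_window_skipped_with_warning(self, traits1):
        with pytest.warns(UserWarning, match="empty window"):
            out = windowed_path_analysis(traits1, windows=((30, 31), (2, 3)))
        assert set(out["window"]) == {"2-3"}

    def test_dbh_dominates_volume_paths_on_simulated_trial(self, traits1):
        """DBH's direct path on volume exceeds height's and HDR's in
        every window of both populations (the pattern the method is
        meant to expose: DBH is the best volume predictor)."""
        out = windowed_path_analysis(traits1)
        for (_, _), sub in out.groupby(["cross_type", "window"]):
            s = sub.set_index("trait")["dpc"]
            assert s["dbh_cm"] > abs(s["height_m"])
            assert s["dbh_cm"] > abs(s["hdr"])


class TestPopulationAnova:
    @staticmethod
    def _table(values_a, values_b, age=5):
        rows = []
        for i, v in enumerate(values_a):
            rows.append([f"A{i}", "DxM", 1, "t1", age, v, v])
        for i, v in enumerate(values_b):
            rows.append([f"B{i}", "MxD", 1, "t1", age, v, v])
        df = pd.DataFrame(
            rows,
            columns=["clone_id", "cross_type", "block", "tree_id", "age", "dbh_cm", "height_m"],
        )
        return derive_traits(table_from_frame(df))

    def test_identical_means_give_zero_f(self):
        t = self._table([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        res = population_anova(t, "dbh_cm", 5)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.stars == "ns"

    def test_degenerate_zero_within_variance(self):
        t = self._table([1.0, 1.0], [3.0, 3.0])
        res = population_anova(t, "dbh_cm", 5)
        assert np.isinf(res.f_stat)
        assert res.p_value == 0.0
        assert res.flag == "DEGENERATE"

    def test_matches_brute_force_sum_of_squares(self):
        a = [4.1, 5.2, 3.9, 4.8, 5.0, 4.4]
        b = [6.0, 5.5, 6.3, 5.9, 6.1, 5.7]
        t = self._table(a, b)
        res = population_anova(t, "dbh_cm", 5)
        grand = np.mean(a + b)
        ss_between = 6 * (np.mean(a) - grand) ** 2 + 6 * (np.mean(b) - grand) ** 2
        ss_within = np.var(a, ddof=0) * 6 + np.var(b, ddof=0) * 6
        f_oracle = (ss_between / 1) / (ss_within / 10)
        assert res.f_stat == pytest.approx(f_oracle, abs=1e-12)

    def test_f_equals_t_squared_for_two_groups(self, traits1):
        for age in (4, 9, 15):
            res = population_anova(traits1, "dbh_cm", age)
            d = traits1.data[traits1.data["age"] == age]
            groups = [g["dbh_cm"].to_numpy() for _, g in d.groupby("cross_type")]
            t_stat, _ = st.ttest_ind(*groups, equal_var=True)
            assert res.f_stat == pytest.approx(t_stat**2, abs=1e-10 * max(1, t_stat**2))

    def test_missing_group_raises(self, traits1):
        solo = traits1.copy()
        solo.data = solo.data[solo.data["cross_type"] == "DxM"]
        with pytest.raises(ValueError, match="group missing"):
            population_anova(solo, "dbh_cm", 5)
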