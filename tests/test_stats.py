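"""Repeated-measures ANOVA, Holm adjustment and the exploratory regression.

The ANOVA implementation is checked against three independent routes: the
paired-t equivalence (F = t^2 for a 2-level factor), a brute-force
projection-matrix GLM decomposition built here from design matrices, and
pingouin's rm_anova.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ocupred import (
    RepeatedMeasuresANOVA,
    holm_adjust,
    pairwise_contrasts,
    rt_ttc_regression,
)
from ocupred.stats import bonferroni_adjust


def _long(Y, factors):
    """Long-format frame from an (n_subjects, a[, b]) cell-mean array."""
    n = Y.shape[0]
    rows = []
    if Y.ndim == 2:
        for s in range(n):
            for i, ai in enumerate(factors[0]):
                rows.append({"subj": s, "A": ai, "y": Y[s, i]})
    else:
        for s in range(n):
            for i, ai in enumerate(factors[0]):
                for j, bj in enumerate(factors[1]):
                    rows.append({"subj": s, "A": ai, "B": bj, "y": Y[s, i, j]})
    return pd.DataFrame(rows)


def _glm_two_way_ss(Y):
    """Independent oracle: sums of squares via nested least-squares fits.

    Builds explicit dummy design matrices for subject, A, B and their
    interactions and computes each effect's SS as the drop in residual SS
    when the effect's columns are added last to its error stratum's model.
    """
    n, a, b = Y.shape
    y = Y.reshape(-1)
    subj = np.repeat(np.arange(n), a * b)
    A = np.tile(np.repeat(np.arange(a), b), n)
    B = np.tile(np.arange(b), n * a)

    def dummies(v, k):
        return np.eye(k)[v]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    S = dummies(subj, n)
    XA = dummies(A, a)
    XB = dummies(B, b)
    XAB = np.einsum("ni,nj->nij", XA, XB).reshape(len(y), a * b)
    XSA = np.einsum("ni,nj->nij", S, XA).reshape(len(y), n * a)
    XSB = np.einsum("ni,nj->nij", S, XB).reshape(len(y), n * b)

    full_wo_A = np.hstack([S, XB])
    ss_a = rss(full_wo_A) - rss(np.hstack([full_wo_A, XA]))
    full_wo_B = np.hstack([S, XA])
    ss_b = rss(full_wo_B) - rss(np.hstack([full_wo_B, XB]))
    main = np.hstack([S, XA, XB])
    ss_ab = rss(main) - rss(np.hstack([main, XAB]))
    ss_sa = rss(np.hstack([S, XA, XB, XAB])) - rss(np.hstack([XSA, XB, XAB]))
    ss_sb = rss(np.hstack([S, XA, XB, XAB])) - rss(np.hstack([XSB, XA, XAB]))
    grand = np.ones((len(y), 1))
    ss_total = rss(grand)
    ss_s = rss(grand) - rss(S)
    ss_sab = ss_total - ss_s - ss_a - ss_b - ss_ab - ss_sa - ss_sb
    return ss_a, ss_b, ss_ab, ss_sa, ss_sb, ss_sab


class TestRmAnova:
    def test_two_level_factor_equals_paired_t(self, rng):
        """One-way, 2 levels: F equals the squared paired-t statistic."""
        Y = rng.normal(size=(10, 2)) + np.array([0.0, 0.4])
        res = RepeatedMeasuresANOVA(_long(Y, [[0, 1]]), "y", "A", "subj").fit()
        t, p = sps.ttest_rel(Y[:, 0], Y[:, 1])
        row = res.anova_table.loc["A"]
        assert row["F"] == pytest.approx(t**2, abs=1e-10)
        assert row["p_unc"] == pytest.approx(p, abs=1e-12)
        assert row["eps_gg"] == 1.0  # 2 levels cannot violate sphericity
        assert row["df_num"] == 1 and row["df_den"] == 9

    def test_zero_between_condition_variance_gives_zero_F(self):
        Y = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))  # subject offsets only
        res = RepeatedMeasuresANOVA(_long(Y, [[0, 1, 2]]), "y", "A", "subj").fit()
        assert res.anova_table.loc["A", "F"] == 0.0
        assert res.anova_table.loc["A", "p_unc"] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_way_matches_glm_decomposition(self, seed):
        """Agrees with the projection-matrix GLM oracle to 1e-10."""
        rng = np.random.default_rng(seed)
        n, a, b = 5, 3, 4
        Y = rng.normal(size=(n, a, b))
        res = RepeatedMeasuresANOVA(
            _long(Y, [list("xyz"), list("pqrs")]), "y", ["A", "B"], "subj"
        ).fit()
        ss_a, ss_b, ss_ab, ss_sa, ss_sb, ss_sab = _glm_two_way_ss(Y)
        tab = res.anova_table
        assert tab.loc["A", "ss_effect"] == pytest.approx(ss_a, abs=1e-10)
        assert tab.loc["B", "ss_effect"] == pytest.approx(ss_b, abs=1e-10)
        assert tab.loc["A:B", "ss_effect"] == pytest.approx(ss_ab, abs=1e-10)
        assert tab.loc["A", "ss_error"] == pytest.approx(ss_sa, abs=1e-10)
        assert tab.loc["B", "ss_error"] == pytest.approx(ss_sb, abs=1e-10)
        assert tab.loc["A:B", "ss_error"] == pytest.approx(ss_sab, abs=1e-8)
        # partial eta squared identity
        assert tab.loc["A", "partial_eta_sq"] == pytest.approx(
            ss_a / (ss_a + ss_sa), abs=1e-12
        )

    def test_matches_pingouin(self, rng):
        """Cross-check F, p, and GG epsilon against pingouin's rm_anova."""
        pingouin = pytest.importorskip("pingouin")
        Y = rng.normal(size=(8, 3, 2)) + rng.normal(size=(1, 3, 2))
        df = _long(Y, [[3, 4, 5], [1.0, 1.5]])
        res = RepeatedMeasuresANOVA(df, "y", ["A", "B"], "subj").fit()
        pg = pingouin.rm_anova(
            data=df, dv="y", within=["A", "B"], subject="subj", correction=True
        ).set_index("Source")
        for ours, theirs in [("A", "A"), ("B", "B"), ("A:B", "A * B")]:
            assert res.anova_table.loc[ours, "F"] == pytest.approx(
                pg.loc[theirs, "F"], rel=1e-9
            )
            assert res.anova_table.loc[ours, "p_unc"] == pytest.approx(
                pg.loc[theirs, "p_unc"], rel=1e-9
            )
            assert res.anova_table.loc[ours, "eps_gg"] == pytest.approx(
                pg.loc[theirs, "eps"], rel=1e-6
            )

    def test_permutation_invariance(self, rng):
        Y = rng.normal(size=(7, 3, 2))
        df = _long(Y, [[0, 1, 2], [0, 1]])
        base = RepeatedMeasuresANOVA(df, "y", ["A", "B"], "subj").fit().anova_table
        relabel = {0: 6, 1: 2, 2: 5, 3: 0, 4: 4, 5: 1, 6: 3}
        df2 = df.assign(subj=df["subj"].map(relabel))
        perm = RepeatedMeasuresANOVA(df2, "y", ["A", "B"], "subj").fit().anova_table
        pd.testing.assert_frame_equal(base, perm)

    def test_missing_cell_reported(self, rng):
        df = _long(rng.normal(size=(5, 3)), [[0, 1, 2]])
        df = df[~((df.subj == 2) & (df.A == 1))]
        with pytest.raises(ValueError, match="missing cells"):
            RepeatedMeasuresANOVA(df, "y", "A", "subj").fit()

    def test_epsilon_bounds(self, rng):
        Y = rng.normal(size=(12, 4)) * np.array([1.0, 1.0, 1.0, 6.0])
        res = RepeatedMeasuresANOVA(_long(Y, [[0, 1, 2, 3]]), "y", "A", "subj").fit()
        eps = res.anova_table.loc["A", "eps_gg"]
        assert 1.0 / 3.0 <= eps < 1.0  # heterogeneity pushes eps below 1

    def test_type_i_error_calibrated(self):
        """Null simulation: uncorrected test rejects at ~alpha (binomial CI)."""
        rng = np.random.default_rng(99)
        alpha, reps = 0.05, 1000
        rejections = 0
        for _ in range(reps):
            Y = rng.normal(size=(6, 3, 2)) + rng.normal(size=(6, 1, 1))
            df = _long(Y, [[0, 1, 2], [0, 1]])
            res = RepeatedMeasuresANOVA(df, "y", ["A", "B"], "subj").fit(gg="never")
            rejections += res.anova_table.loc["A", "p_unc"] < alpha
        rate = rejections / reps
        ci = 3 * np.sqrt(alpha * (1 - alpha) / reps)  # ~0.021
        assert abs(rate - alpha) <= ci

    def test_summary_mentions_design(self, rng):
        df = _long(rng.normal(size=(5, 2)), [[0, 1]])
        s = RepeatedMeasuresANOVA(df, "y", "A", "subj").fit().summary()
        assert "Repeated-measures ANOVA" in s and "n = 5" in s


class TestHolm:
    def test_hand_computed_step_down(self):
        """(0.01, 0.02, 0.03) -> (0.03, 0.04, 0.04) by the step-down rule."""
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04], atol=1e-15
        )

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.uniform(size=20)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_bonferroni_dominates_holm(self, rng):
        p = rng.uniform(size=8)
        assert np.all(bonferroni_adjust(p) >= holm_adjust(p) - 1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestContrasts:
    def test_pairwise_against_scipy(self, rng):
        Y = rng.normal(size=(9, 3)) + np.array([0.0, 0.3, 0.6])
        df = _long(Y, [[3, 4, 5]])
        out = pairwise_contrasts(df, "y", "A", "subj")
        assert len(out) == 3
        t, p = sps.ttest_rel(Y[:, 0], Y[:, 1])
        row = out[out["pair"] == "3 vs 4"].iloc[0]
        assert row["t"] == pytest.approx(t)
        assert row["p_raw"] == pytest.approx(p)
        np.testing.assert_allclose(
            out["p_adjusted"], holm_adjust(out["p_raw"]), atol=1e-15
        )


class TestRegression:
    def test_collinear_points(self):
        df = pd.DataFrame({"speed": [3.0] * 3, "saccadic_rt": [0.0, 1.0, 2.0],
                           "relative_ttc": [0.0, 1.0, 2.0]})
        out = rt_ttc_regression(df)
        assert out.iloc[0]["slope"] == pytest.approx(1.0)
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_null_coupling_slope_near_zero(self, rng):
        n = 400
        df = pd.DataFrame({
            "speed": np.repeat(5.0, n),
            "saccadic_rt": rng.normal(0.3, 0.05, n),
            "relative_ttc": rng.normal(100.0, 5.0, n),
        })
        out = rt_ttc_regression(df)
        # 95% CI on the slope contains zero
        se = out.iloc[0]["slope"] / max(abs(out.iloc[0]["r"]) * np.sqrt(n - 2) /
                                        np.sqrt(1 - out.iloc[0]["r"] ** 2), 1e-9)
        assert abs(out.iloc[0]["slope"]) <= 2.5 * abs(se) + 1e-9 or out.iloc[0]["p"] > 0.01

    def test_constructed_coupling_signs(self, rng):
        """Early saccades extrapolate the old 4 deg/s speed: for a slow-down
        (3 deg/s) early responders press too early (relative < 100, rising
        with RT -> positive slope); for a speed-up the sign flips."""
        n = 300
        rt = rng.uniform(0.15, 0.6, n)
        frames = []
        for v, sign in ((3.0, +1), (5.0, -1)):
            # perceived speed blends old (4) and new (v) with weight ~ RT
            w = np.clip(rt / 0.6, 0, 1)
            perceived = 4.0 + (v - 4.0) * w
            rel = 100.0 * v / perceived + rng.normal(0, 1.0, n)
            frames.append(pd.DataFrame({
                "speed": v, "saccadic_rt": rt, "relative_ttc": rel,
            }))
        out = rt_ttc_regression(pd.concat(frames)).set_index("speed")
        assert out.loc[3.0, "slope"] > 0
        assert out.loc[5.0, "slope"] < 0

    def test_degenerate_x_variance_rejected(self):
        df = pd.DataFrame({"speed": [3.0] * 5, "saccadic_rt": [0.3] * 5,
                           "relative_ttc": [90.0, 95, 100, 105, 110]})
        with pytest.raises(ValueError, match="degenerate"):
            rt_ttc_regression(df)

    def test_too_few_points_rejected(self):
        df = pd.DataFrame({"speed": [3.0, 3.0], "saccadic_rt": [0.2, 0.4],
                           "relative_ttc": [90.0, 95.0]})
        with pytest.raises(ValueError, match=">= 3"):
            rt_ttc_regression(df)
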