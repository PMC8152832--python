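"""Pooled t, BH-FDR, Pearson screen, regression and variance partitioning."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ssmrs import behavior, mrs, stats as sstats, synthetic as syn


class TestPooledT:
    def test_summary_route_matches_scipy_from_stats(self, rng):
        m1, s1, n1, m2, s2, n2 = 10.0, 2.0, 14, 11.5, 3.0, 17
        ours = sstats.pooled_t_from_summary(m1, s1, n1, m2, s2, n2)
        ref = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-12)
        assert ours.df == n1 + n2 - 2

    def test_raw_and_summary_routes_identical(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=25)
        raw = sstats.pooled_t_from_raw(x, y)
        summ = sstats.pooled_t_from_summary(
            x.mean(), x.std(ddof=1), 20, y.mean(), y.std(ddof=1), 25
        )
        assert raw.t == pytest.approx(summ.t, abs=1e-12)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert raw.t == pytest.approx(ref.statistic, rel=1e-12)

    def test_equal_means_give_zero_t_unit_p(self):
        res = sstats.pooled_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert res.t == 0.0 and res.p == 1.0
        x = np.arange(6.0)
        same = sstats.pooled_t_from_raw(x, x)
        assert same.t == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_unequal_means_is_signed_infinite(self):
        with pytest.warns(UserWarning):
            res = sstats.pooled_t_from_raw([1.0, 1.0], [2.0, 2.0])
        assert res.t == -math.inf and res.p == 0.0

    def test_type_i_error_calibrated_under_the_null(self):
        rng = np.random.default_rng(99)
        reps, n = 10_000, 15
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        hits = sum(
            sstats.pooled_t_from_raw(x[i], y[i]).p < 0.05 for i in range(reps)
        )
        assert 0.04 <= hits / reps <= 0.06

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            sstats.pooled_t_from_raw([1.0], [2.0, 3.0])


def bh_oracle(pvals, q):
    """Largest rejection set {p <= c} whose cutoff c satisfies c <= |set|*q/m."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    best = None
    for c in sorted(p):
        k = int((p <= c).sum())
        if c <= k * q / m:
            best = c
    if best is None:
        return np.zeros(m, dtype=bool)
    return p <= best


class TestBHFDR:
    def test_single_pvalue(self):
        critical, flags = sstats.bh_fdr([0.04])
        assert critical == 0.04 and flags.tolist() == [True]

    def test_hand_evaluated_thresholds(self):
        # thresholds i*q/m = .0167, .0333, .05: reject .01 and .02, not .30
        critical, flags = sstats.bh_fdr([0.01, 0.02, 0.30], q=0.05)
        assert flags.tolist() == [True, True, False]
        assert critical == 0.02

    def test_matches_bruteforce_oracle_on_short_lists(self):
        rng = np.random.default_rng(5)
        for m in range(1, 13):
            for _ in range(30):
                p = np.round(rng.uniform(size=m), 3)
                _, flags = sstats.bh_fdr(p, q=0.05)
                assert flags.tolist() == bh_oracle(p, 0.05).tolist()

    def test_sandwiched_between_bonferroni_and_unadjusted(self, rng):
        p = rng.uniform(size=40)
        _, flags = sstats.bh_fdr(p, q=0.05)
        bonf = p <= 0.05 / p.size
        assert (flags | ~bonf).all()  # rejects everything Bonferroni rejects
        assert (~flags | (p <= 0.05)).all()  # never rejects beyond raw alpha

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            sstats.bh_fdr([])


class TestFisherRZ:
    def test_published_group_contrast(self):
        res = sstats.fisher_rz_compare(-0.486, 25, 0.480, 26)
        assert round(res.z, 2) == -3.53
        assert res.p < 0.001

    def test_equal_correlations_give_zero(self):
        assert sstats.fisher_rz_compare(0.3, 30, 0.3, 40).z == 0.0

    def test_matches_independent_closed_form(self):
        r1, n1, r2, n2 = 0.62, 28, 0.15, 33
        res = sstats.fisher_rz_compare(r1, n1, r2, n2)
        # separate hand route: atanh via log form
        zt = lambda r: 0.5 * math.log((1 + r) / (1 - r))
        expected = (zt(r1) - zt(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
        assert res.z == pytest.approx(expected, rel=1e-12)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            sstats.fisher_rz_compare(1.0, 25, 0.2, 26)
        with pytest.raises(ValueError):
            sstats.fisher_rz_compare(0.5, 3, 0.2, 26)


class TestRegression:
    def test_noiseless_line_fully_explained(self):
        x = pd.DataFrame({"x": np.linspace(0, 10, 30)})
        y = 2.0 * x["x"] + 1.0
        res = sstats.fit_regression(y, x)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.predictors[0].b == pytest.approx(2.0, rel=1e-10)
        assert res.predictors[0].beta == pytest.approx(1.0, rel=1e-10)
        assert res.intercept == pytest.approx(1.0, rel=1e-9)

    def test_coefficients_match_normal_equations(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = 1.5 * X["a"] - 0.5 * X["c"] + rng.normal(size=40)
        res = sstats.fit_regression(y, X)
        design = np.column_stack([np.ones(40), X.to_numpy()])
        coefs = np.linalg.solve(design.T @ design, design.T @ y.to_numpy())
        got = [res.intercept] + [p.b for p in res.predictors]
        assert np.allclose(got, coefs, atol=1e-10)
        resid = y.to_numpy() - design @ coefs
        r2 = 1.0 - resid.var() / y.to_numpy().var()
        assert res.r2 == pytest.approx(r2, abs=1e-10)

    def test_standardized_beta_relation(self, rng):
        X = pd.DataFrame(rng.normal(scale=[1.0, 5.0], size=(50, 2)), columns=["a", "b"])
        y = pd.Series(X["a"] - 0.2 * X["b"] + rng.normal(size=50))
        res = sstats.fit_regression(y, X)
        for p in res.predictors:
            expected = p.b * X[p.name].std(ddof=1) / y.std(ddof=1)
            assert p.beta == pytest.approx(expected, rel=1e-9)

    def test_exact_collinearity_names_offender(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["twice_a"] = 2.0 * X["a"]
        with pytest.raises(ValueError, match="collinear"):
            sstats.fit_regression(rng.normal(size=20), X)

    def test_too_few_rows_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError, match="n > p"):
            sstats.fit_regression(rng.normal(size=4), X)

    def test_null_predictor_p_uniform_over_replicates(self):
        # two real predictors plus one pure-noise predictor: the noise
        # predictor's p-value should be uniform under the null
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(400):
            X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "null"])
            y = X["a"] + 0.5 * X["b"] + rng.normal(size=30)
            res = sstats.fit_regression(y, X)
            pvals.append({p.name: p.p for p in res.predictors}["null"])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


def semipartial_oracle(y, X, j):
    """Squared correlation of y with x_j residualized on the other predictors."""
    others = np.column_stack([np.ones(len(X))] + [X[c] for c in X.columns if c != j])
    beta, *_ = np.linalg.lstsq(others, X[j].to_numpy(), rcond=None)
    resid = X[j].to_numpy() - others @ beta
    return float(np.corrcoef(resid, np.asarray(y, dtype=float))[0, 1] ** 2)


class TestR2Change:
    def test_orthogonal_predictors_decompose_exactly(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {"s": np.sin(2 * np.pi * t / n), "c": np.cos(2 * np.pi * t / n)}
        )
        rng = np.random.default_rng(2)
        y = 1.0 * X["s"] - 2.0 * X["c"] + rng.normal(size=n)
        for j in X.columns:
            change = sstats.r2_change(y, X, j)
            r = np.corrcoef(X[j], y)[0, 1]
            assert change == pytest.approx(r**2, abs=1e-10)

    def test_equals_squared_semipartial_on_correlated_designs(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            base = rng.normal(size=(30, 3))
            mix = base @ rng.normal(size=(3, 3)) + 0.5 * rng.normal(size=(30, 3))
            X = pd.DataFrame(mix, columns=["a", "b", "c"])
            y = pd.Series(mix @ rng.normal(size=3) + rng.normal(size=30))
            res = sstats.fit_regression(y, X)
            for p in res.predictors:
                assert p.r2_change == pytest.approx(
                    semipartial_oracle(y, X, p.name), abs=1e-10
                )
                # each predictor's unique share is bounded by the model fit
                assert -1e-12 <= p.r2_change <= res.r2 + 1e-12

    def test_two_step_refit_drops_negligible_predictors(self):
        rng = np.random.default_rng(31)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["strong", "weak", "noise"])
        y = 2.0 * X["strong"] + 0.01 * X["noise"] + rng.normal(size=60)
        full, reduced, dropped = sstats.refit_dropping_negligible(y, X, 0.01)
        assert "strong" in [p.name for p in reduced.predictors]
        assert set(dropped) <= {"weak", "noise"} and dropped


class TestScreen:
    def test_count_covers_all_regions_metabolites_ratios_and_measures(
        self, default_cohort
    ):
        trials, panel = default_cohort
        perf = behavior.performance_table(trials)
        feats = sstats.build_feature_matrix(mrs.correct_panel(panel))
        screen = sstats.pearson_screen(feats, perf)
        per_group = (7 * 5 + 7) * 3
        assert screen.groupby("group").size().eq(per_group).all()

    def test_perfect_linear_relation_reported_as_unit_r(self, default_cohort):
        trials, panel = default_cohort
        perf = behavior.performance_table(trials)
        feats = sstats.build_feature_matrix(mrs.correct_panel(panel))
        # overwrite one feature with an exact copy of the measure
        feats["LSM1 NAA"] = perf.set_index("subject_id")["ssrt"].reindex(feats.index)
        screen = sstats.pearson_screen(feats, perf)
        row = screen.query(
            "feature == 'LSM1 NAA' and measure == 'ssrt' and group == 'young'"
        ).iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-12) and row["candidate"]

    def test_zero_variance_feature_reported_missing(self, default_cohort):
        trials, panel = default_cohort
        perf = behavior.performance_table(trials)
        feats = sstats.build_feature_matrix(mrs.correct_panel(panel))
        feats["OCC Cr"] = 1.0
        screen = sstats.pearson_screen(feats, perf)
        rows = screen[screen["feature"] == "OCC Cr"]
        assert rows["r"].isna().all() and not rows["candidate"].any()

    def test_planted_effect_flagged_with_high_power(self):
        # within-group screen flags the study-sized LSTR Glx vs GoRT effect
        # (|r| ~ 0.57 at n = 25) in nearly every replicate
        hits = 0
        reps = 50
        for rep in range(reps):
            spec = syn.CohortSpec(
                seed=40_000 + rep,
                n_older=0,
                effects=(syn.PlantedEffect("young", "LSTR", "Glx", "go_rt", -0.572),),
            )
            trials, panel = syn.simulate_cohort(spec)
            perf = behavior.performance_table(trials)
            feats = sstats.build_feature_matrix(mrs.correct_panel(panel))
            screen = sstats.pearson_screen(feats, perf)
            row = screen.query("feature == 'LSTR Glx' and measure == 'go_rt'").iloc[0]
            if row["candidate"] and row["r"] < 0:
                hits += 1
        assert hits >= 0.9 * reps
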