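"""Statistical chain: group contrasts, FDR, correlation screening, regression.

Implements the analysis sequence applied to the joined behavioral and MRS
tables: pooled-variance Student's t-tests for group differences (with
Benjamini-Hochberg FDR control over the metabolite family), Pearson
correlation screening of region x metabolite measures against the three
principal performance measures within each age group, candidate-based
ordinary least squares regression with R²-change variance partitioning
(the amount by which R² drops when one predictor is removed — the squared
semipartial correlation), and Fisher r-to-z contrasts of correlations
between groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "PredictorStats",
    "RegressionSummary",
    "FisherZResult",
    "pooled_t_from_summary",
    "pooled_t_from_raw",
    "bh_fdr",
    "build_feature_matrix",
    "pearson_screen",
    "fisher_rz_compare",
    "fit_regression",
    "r2_change",
    "refit_dropping_negligible",
]

SCREEN_MEASURES = ("go_rt", "proactive_slowing", "ssrt")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int
    n2: int


@dataclass(frozen=True)
class CorrelationResult:
    group: str
    region: str
    metabolite: str
    measure: str
    r: float
    n: int
    p: float

    @property
    def candidate(self) -> bool:
        return math.isfinite(self.p) and self.p < 0.05


@dataclass(frozen=True)
class PredictorStats:
    name: str
    b: float
    b_se: float
    beta: float
    beta_se: float
    p: float
    r2_change: float


@dataclass(frozen=True)
class RegressionSummary:
    r2: float
    r2_adjusted: float
    f: float
    f_p: float
    n: int
    intercept: float
    intercept_se: float
    intercept_p: float
    predictors: tuple[PredictorStats, ...] = ()

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "predictor": "Intercept",
                "r2_change": np.nan,
                "beta": np.nan,
                "beta_se": np.nan,
                "B": self.intercept,
                "B_se": self.intercept_se,
                "p": self.intercept_p,
            }
        ]
        rows += [
            {
                "predictor": pr.name,
                "r2_change": pr.r2_change,
                "beta": pr.beta,
                "beta_se": pr.beta_se,
                "B": pr.b,
                "B_se": pr.b_se,
                "p": pr.p,
            }
            for pr in self.predictors
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FisherZResult:
    z: float
    p: float


def pooled_t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
) -> TTestResult:
    """Two-sample pooled-variance Student's t from group summaries.

    df = n1 + n2 - 2; two-tailed p.  Sign convention: positive t when
    ``mean1 > mean2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        if mean1 == mean2:
            t = 0.0
        else:
            warnings.warn("zero pooled variance with unequal means: infinite t")
            t = math.copysign(math.inf, mean1 - mean2)
    else:
        t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df) if math.isfinite(t) else 0.0
    return TTestResult(t, df, p, mean1, mean2, sd1, sd2, n1, n2)


def pooled_t_from_raw(
    x, y, *, equal_var: bool = True
) -> TTestResult:
    """Two-sample t-test from raw observations (pooled by default, Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if equal_var:
        return pooled_t_from_summary(
            float(x.mean()), float(x.std(ddof=1)), x.size,
            float(y.mean()), float(y.std(ddof=1)), y.size,
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return TTestResult(
        float(res.statistic),
        int(round(res.df)),
        float(res.pvalue),
        float(x.mean()),
        float(y.mean()),
        float(x.std(ddof=1)),
        float(y.std(ddof=1)),
        x.size,
        y.size,
    )


def bh_fdr(pvalues, q: float = 0.05) -> tuple[float | None, np.ndarray]:
    """Benjamini-Hochberg step-up at level q.

    Returns ``(critical_p, reject_flags)`` where ``critical_p`` is the
    largest p-value passing its step-up threshold (None when nothing is
    rejected); all p-values at or below it are rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr needs at least one p-value")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    critical = float(p[reject].max()) if reject.any() else None
    return critical, reject


def build_feature_matrix(corrected_panel: pd.DataFrame) -> pd.DataFrame:
    """Wide per-subject matrix of corrected concentrations plus NAA/mIns ratios.

    Columns are ``"<region> <metabolite>"``; QC-failed entries are NaN.
    Expects the output of :func:`ssmrs.mrs.correct_panel`; the ratio rows are
    added here via :func:`ssmrs.mrs.ratio_table`.
    """
    from . import mrs as _mrs

    ratios = _mrs.ratio_table(corrected_panel)
    long = pd.concat(
        [
            corrected_panel[
                ["subject_id", "group", "region", "metabolite", "corrected_concentration"]
            ],
            ratios,
        ],
        ignore_index=True,
    )
    long["feature"] = long["region"] + " " + long["metabolite"]
    wide = long.pivot_table(
        index="subject_id", columns="feature", values="corrected_concentration",
        dropna=False,
    )
    wide.columns.name = None
    groups = long.drop_duplicates("subject_id").set_index("subject_id")["group"]
    wide.insert(0, "group", groups.reindex(wide.index))
    return wide


def pearson_screen(
    features: pd.DataFrame,
    performance: pd.DataFrame,
    measures: tuple[str, ...] = SCREEN_MEASURES,
    alpha: float = 0.05,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Correlate every metabolite feature with each performance measure per group.

    ``features`` is the wide matrix from :func:`build_feature_matrix`;
    ``performance`` the per-subject table from
    :func:`ssmrs.behavior.performance_table`.  Pairwise deletion handles
    QC-missing values; correlations with fewer than ``min_pairs`` complete
    pairs or zero variance are reported with NaN r and p.  The ``candidate``
    flag marks two-tailed p < alpha (uncorrected, by design — the screen
    only selects regression candidates).
    """
    perf = performance.set_index("subject_id")
    rows = []
    for group in perf["group"].unique():
        sids = perf.index[perf["group"] == group]
        feats = features.loc[features.index.intersection(sids)]
        feat_cols = [c for c in feats.columns if c != "group"]
        for col in feat_cols:
            region, metabolite = col.split(" ", 1)
            x_all = feats[col]
            for measure in measures:
                y_all = perf.loc[feats.index, measure]
                mask = x_all.notna() & y_all.notna()
                n = int(mask.sum())
                r = p = np.nan
                if n >= min_pairs:
                    x = x_all[mask].to_numpy()
                    y = y_all[mask].to_numpy()
                    if x.std() > 0 and y.std() > 0:
                        res = sps.pearsonr(x, y)
                        r, p = float(res.statistic), float(res.pvalue)
                rows.append(
                    {
                        "group": group,
                        "region": region,
                        "metabolite": metabolite,
                        "feature": col,
                        "measure": measure,
                        "r": r,
                        "n": n,
                        "p": p,
                        "candidate": bool(np.isfinite(p) and p < alpha),
                    }
                )
    return pd.DataFrame(rows)


def fisher_rz_compare(r1: float, n1: int, r2: float, n2: int) -> FisherZResult:
    """Compare two independent correlations via the Fisher r-to-z transform.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-tailed normal p.  By convention the first-named group is the first
    argument.
    """
    for r in (r1, r2):
        if not abs(r) < 1.0:
            raise ValueError(f"|r| must be < 1 for the z transform, got {r}")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("each correlation needs n > 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return FisherZResult(z, 2.0 * sps.norm.sf(abs(z)))


def _clean_xy(y: pd.Series, X: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    data = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    return data["__y__"].to_numpy(dtype=float), data[X.columns].astype(float)


def fit_regression(y, X: pd.DataFrame) -> RegressionSummary:
    """OLS of a performance measure on candidate predictors.

    Reports R², adjusted R², the overall F, and per predictor the raw
    coefficient B (SE), the standardized coefficient β (SE; both sides
    z-scored), the two-tailed p, and the R²-change on removal.  Rows with
    any missing value are dropped listwise.  Exact collinearity raises with
    the offending predictors named.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    yv, Xc = _clean_xy(y, X)
    n, k = Xc.shape
    if n <= k + 1:
        raise ValueError(f"need n > p + 1 observations ({n} rows, {k} predictors)")
    design = sm.add_constant(Xc.to_numpy())
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = [
            c
            for j, c in enumerate(Xc.columns)
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1))
            == np.linalg.matrix_rank(design)
        ]
        raise ValueError(f"rank-deficient design; collinear predictors: {bad}")
    fit = sm.OLS(yv, design).fit()

    zy = (yv - yv.mean()) / yv.std(ddof=1)
    zX = (Xc - Xc.mean()) / Xc.std(ddof=1)
    zfit = sm.OLS(zy, sm.add_constant(zX.to_numpy())).fit()

    predictors = []
    for j, name in enumerate(Xc.columns):
        reduced_r2 = 0.0
        if k > 1:
            sub = sm.add_constant(Xc.drop(columns=[name]).to_numpy())
            reduced_r2 = sm.OLS(yv, sub).fit().rsquared
        predictors.append(
            PredictorStats(
                name=str(name),
                b=float(fit.params[j + 1]),
                b_se=float(fit.bse[j + 1]),
                beta=float(zfit.params[j + 1]),
                beta_se=float(zfit.bse[j + 1]),
                p=float(fit.pvalues[j + 1]),
                r2_change=float(fit.rsquared - reduced_r2),
            )
        )
    return RegressionSummary(
        r2=float(fit.rsquared),
        r2_adjusted=float(fit.rsquared_adj),
        f=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        n=n,
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        intercept_p=float(fit.pvalues[0]),
        predictors=tuple(predictors),
    )


def r2_change(y, X: pd.DataFrame, predictor: str) -> float:
    """R²(full) - R²(without ``predictor``): the squared semipartial correlation."""
    summary = fit_regression(y, X)
    for pr in summary.predictors:
        if pr.name == str(predictor):
            return pr.r2_change
    raise KeyError(f"predictor {predictor!r} not in design")


def refit_dropping_negligible(
    y, X: pd.DataFrame, min_r2_change: float = 0.01
) -> tuple[RegressionSummary, RegressionSummary, list[str]]:
    """Two-step refit: drop predictors whose unique variance is negligible.

    Fits the full candidate model, removes every predictor whose R²-change
    is below ``min_r2_change`` (default 1%), and refits once on the
    survivors.  Returns (full, reduced, dropped names); with nothing to
    drop — or nothing to keep — the reduced model is the full model.
    """
    full = fit_regression(y, X)
    dropped = [p.name for p in full.predictors if p.r2_change < min_r2_change]
    if not dropped or len(dropped) == len(full.predictors):
        return full, full, []
    reduced = fit_regression(y, X.drop(columns=dropped))
    return full, reduced, dropped
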