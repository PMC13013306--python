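"""Univariate and multivariate cohort statistics.

Group comparisons for a binary-outcome cohort table: 2x2 contingency
analysis (Pearson chi-square with optional Yates continuity correction,
Fisher's exact test, Woolf-interval odds ratios), continuous comparisons
(pooled-variance t test, Mann-Whitney U reported as a normal-approximation
Z), logistic regression with Wald intervals, variance inflation factors,
and intraclass correlation for rater agreement.

Contingency convention
----------------------
A :class:`ContingencyTable2x2` stores ``(a, b, c, d)`` with

* ``a`` feature present and outcome positive,
* ``b`` feature absent  and outcome positive,
* ``c`` feature present and outcome negative,
* ``d`` feature absent  and outcome negative,

so the cross-product odds ratio is ``ad / bc``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "Chi2Result",
    "OddsRatioResult",
    "LogisticFit",
    "SeparationError",
    "crosstab",
    "pearson_chi2",
    "chi2_auto",
    "fisher_exact",
    "odds_ratio_woolf",
    "group_compare_continuous",
    "logistic_fit",
    "vif",
    "icc_agreement",
    "table1_report",
    "table2_report",
    "validate_cohort",
]

#: minimum expected cell count below which the Yates-corrected chi-square is
#: used by default (see docs/methods.md for the calibration of this bound)
YATES_EXPECTED_THRESHOLD = 8.0

#: normal quantile used for all Wald-type 95% intervals
Z95 = 1.96

BINARY_COLUMNS = [
    "stas", "sex", "smoking", "location", "interface", "morph_irregularity",
    "spiculation", "lobulation", "pleural_indentation", "vascular_convergence",
    "vacuole", "air_bronchogram",
]
CONTINUOUS_COLUMNS = ["age", "ctr", "fd2d", "fd3d"]


class SeparationError(RuntimeError):
    """Raised when logistic regression data are (quasi-)completely separated."""


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("contingency table must contain at least one observation")
        self.a, self.b, self.c, self.d = (int(x) for x in cells)

    def as_array(self) -> np.ndarray:
        """Rows = feature present/absent, columns = outcome +/-."""
        return np.array([[self.a, self.c], [self.b, self.d]], dtype=float)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    continuity_corrected: bool


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("confidence bounds must bracket the odds ratio")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression result with Wald summaries."""

    feature_names: list[str]
    coef: np.ndarray          # includes intercept as first entry
    se: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_iter: int
    llf: float
    n_obs: int

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef[1:])

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef[1:] - Z95 * self.se[1:])

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef[1:] + Z95 * self.se[1:])

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.coef[0] + X @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "coef": self.coef[1:],
            "se": self.se[1:],
            "odds_ratio": self.odds_ratios,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_values[1:],
        })


def _check_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(int)


def crosstab(feature, label) -> ContingencyTable2x2:
    """2x2 table of a binary feature against a binary outcome label."""
    f = _check_binary(feature, "feature")
    y = _check_binary(label, "label")
    if len(f) != len(y):
        raise ValueError("feature and label must have the same length")
    return ContingencyTable2x2(
        a=int(((f == 1) & (y == 1)).sum()),
        b=int(((f == 0) & (y == 1)).sum()),
        c=int(((f == 1) & (y == 0)).sum()),
        d=int(((f == 0) & (y == 0)).sum()),
    )


def _expected(table: ContingencyTable2x2) -> np.ndarray:
    obs = table.as_array()
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()


def pearson_chi2(table: ContingencyTable2x2, yates: bool = False) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, optionally Yates-corrected.

    The Yates statistic subtracts 0.5 from each absolute deviation, clamped
    at zero, and is never larger than the uncorrected statistic.
    """
    obs = table.as_array()
    exp = _expected(table)
    if (exp <= 0).any():
        raise ValueError("zero marginal total; use fisher_exact instead")
    dev = np.abs(obs - exp)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / exp).sum())
    return Chi2Result(stat, df=1, p_value=float(sps.chi2.sf(stat, 1)), continuity_corrected=yates)


def chi2_auto(table: ContingencyTable2x2, expected_threshold: float = YATES_EXPECTED_THRESHOLD) -> Chi2Result:
    """Chi-square with the package's correction policy.

    Uncorrected by default; Yates continuity correction when any expected
    cell falls below ``expected_threshold``.
    """
    yates = bool(_expected(table).min() < expected_threshold)
    return pearson_chi2(table, yates=yates)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (hypergeometric tail summation)."""
    obs = table.as_array()
    if obs.sum(axis=0).min() == 0 and obs.sum(axis=1).min() == 0:
        raise ValueError("degenerate table")
    return float(sps.fisher_exact(obs, alternative="two-sided")[1])


def odds_ratio_woolf(table: ContingencyTable2x2) -> OddsRatioResult:
    """Cross-product odds ratio with the Woolf (log) confidence interval.

    The Haldane-Anscombe 0.5 correction is added to every cell if and only
    if any cell is zero.  The p-value is the two-sided Wald test of
    ``log OR = 0``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and c == 0) or (b == 0 and d == 0) or (a == 0 and b == 0) or (c == 0 and d == 0):
        raise ValueError("odds ratio undefined: an entire row or column is zero")
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(orr)
    p = 2.0 * sps.norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        odds_ratio=float(orr),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p_value=float(min(p, 1.0)),
    )


def group_compare_continuous(x_pos, x_neg, method: str = "t", welch: bool = False):
    """Compare a continuous feature between outcome groups.

    ``method='t'`` runs the independent-sample t test (pooled variance by
    default, Welch via ``welch=True``); ``method='mann_whitney'`` runs the
    Mann-Whitney U test with tie-corrected normal approximation, reported as
    a signed Z for the first (positive) group.  Returns ``(statistic,
    p_value)``.
    """
    x1 = np.asarray(x_pos, dtype=float)
    x2 = np.asarray(x_neg, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs at least two observations")
    if np.ptp(np.concatenate([x1, x2])) == 0:
        warnings.warn("all values identical across both groups", stacklevel=2)
        return 0.0, 1.0
    if method == "t":
        stat, p = sps.ttest_ind(x1, x2, equal_var=not welch)
        return float(stat), float(p)
    if method == "mann_whitney":
        n1, n2 = len(x1), len(x2)
        combined = np.concatenate([x1, x2])
        ranks = sps.rankdata(combined)
        r1 = ranks[:n1].sum()
        u1 = r1 - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            warnings.warn("zero rank variance", stacklevel=2)
            return 0.0, 1.0
        z = (u1 - mu) / np.sqrt(sigma2)
        p = 2.0 * sps.norm.sf(abs(z))
        return float(z), float(min(p, 1.0))
    raise ValueError(f"unknown method {method!r}")


def mann_whitney_u(x_pos, x_neg) -> float:
    """The U statistic of the first sample (count of winning pairs + half ties)."""
    x1 = np.asarray(x_pos, dtype=float)
    x2 = np.asarray(x_neg, dtype=float)
    ranks = sps.rankdata(np.concatenate([x1, x2]))
    return float(ranks[: len(x1)].sum() - len(x1) * (len(x1) + 1) / 2.0)


def logistic_fit(X, y, feature_names=None, max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald 95% intervals.

    Newton-type iteratively reweighted least squares (via statsmodels) with
    an intercept added automatically (``X=None`` fits the intercept-only
    model).  Complete or quasi-complete separation raises
    :class:`SeparationError` with a diagnostic instead of returning a
    meaningless diverged fit.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = _check_binary(y, "label")
    if X is None:
        X = np.empty((len(y), 0))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(y) == X.shape[1]:
        X = X.T
    if X.shape[0] != len(y):
        raise ValueError("X and y must have the same number of rows")
    k = X.shape[1]
    if len(y) <= k + 1:
        raise ValueError("need more observations than predictors")
    if k and (X.std(axis=0) == 0).any():
        raise ValueError("constant predictor column in design matrix")
    if feature_names is None:
        feature_names = [f"x{i + 1}" for i in range(k)]
    design = np.ones((len(y), 1)) if k == 0 else sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, design).fit(method="newton", maxiter=max_iter, tol=tol, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning) as exc:
        raise SeparationError(
            f"logistic fit failed, data are likely completely separated: {exc}"
        ) from exc
    coef = np.asarray(res.params, dtype=float)
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge within max_iter")
    if np.abs(coef).max() > 50:
        raise SeparationError(
            "diverging coefficients (|beta| > 50): quasi-complete separation"
        )
    return LogisticFit(
        feature_names=list(feature_names),
        coef=coef,
        se=np.asarray(res.bse, dtype=float),
        p_values=np.asarray(res.pvalues, dtype=float),
        converged=True,
        n_iter=int(res.mle_retvals.get("iterations", -1)),
        llf=float(res.llf),
        n_obs=len(y),
    )


def vif(X, feature_names=None) -> pd.DataFrame:
    """Variance inflation factors: VIF_i = 1 / (1 - R_i^2).

    ``R_i^2`` comes from the OLS regression (with intercept) of predictor i
    on the remaining predictors.  Exact collinearity yields ``inf`` with the
    ``collinear`` flag set.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two predictor columns")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    if feature_names is None:
        feature_names = [f"x{i + 1}" for i in range(X.shape[1])]
    rows = []
    for i in range(X.shape[1]):
        others = np.delete(X, i, axis=1)
        res = sm.OLS(X[:, i], sm.add_constant(others)).fit()
        r2 = min(float(res.rsquared), 1.0)
        if 1.0 - r2 < 1e-12:
            rows.append((feature_names[i], np.inf, True))
        else:
            rows.append((feature_names[i], 1.0 / (1.0 - r2), False))
    return pd.DataFrame(rows, columns=["feature", "vif", "collinear"])


def icc_agreement(ratings, form: str = "agreement") -> float:
    """Single-measure intraclass correlation from a subjects x raters matrix.

    ``form='agreement'`` is the two-way random-effects absolute-agreement
    single-measure ICC(2,1); ``form='consistency'`` is ICC(3,1), which is
    blind to systematic rater offsets.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2:
        raise ValueError("ratings must be an n_subjects x n_raters matrix")
    n, k = R.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    gm = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    ssr = k * ((row_means - gm) ** 2).sum()
    ssc = n * ((col_means - gm) ** 2).sum()
    sse = ((R - row_means[:, None] - col_means[None, :] + gm) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if ssr < 1e-12 * max(sse, 1.0) or (msr == 0 and mse == 0):
        raise ValueError("zero between-subject variance: ICC undefined")
    if form == "agreement":
        denom = msr + (k - 1) * mse + k / n * (msc - mse)
        return float((msr - mse) / denom)
    if form == "consistency":
        return float((msr - mse) / (msr + (k - 1) * mse))
    raise ValueError(f"unknown ICC form {form!r}")


# ---------------------------------------------------------------------------
# table-level reports

def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table; raises with every violation listed."""
    problems = []
    required = set(BINARY_COLUMNS) | set(CONTINUOUS_COLUMNS)
    missing = sorted(required - set(df.columns))
    for col in missing:
        problems.append(f"missing column: {col}")
    if "patient_id" in df.columns and df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        problems.append(f"duplicate patient id(s): {dups}")
    present = [c for c in required if c in df.columns]
    if df[present].isna().any().any():
        bad = [c for c in present if df[c].isna().any()]
        problems.append(f"missing values in columns: {bad}")
    for col in BINARY_COLUMNS:
        if col in df.columns and df[col].notna().all():
            if not df[col].isin([0, 1]).all():
                problems.append(f"non-binary values in column: {col}")
    if "ctr" in df.columns and df["ctr"].notna().all():
        if ((df["ctr"] < 0) | (df["ctr"] > 100)).any():
            problems.append("ctr outside [0, 100]")
    if problems:
        raise ValueError("invalid cohort table:\n  " + "\n  ".join(problems))
    return df


#: continuous features summarized as mean +/- sd and compared by t test;
#: the remaining continuous features use median (IQR) and Mann-Whitney U.
_T_TEST_FEATURES = ("age", "fd2d")


def table1_report(df: pd.DataFrame) -> pd.DataFrame:
    """Baseline group-comparison table (counts/percentages, statistics, p)."""
    validate_cohort(df)
    y = df["stas"].to_numpy()
    pos, neg = df[y == 1], df[y == 0]
    rows = []
    for colname in BINARY_COLUMNS[1:]:
        t = crosstab(df[colname], y)
        res = chi2_auto(t)
        rows.append({
            "feature": colname, "kind": "binary",
            "pos_summary": f"{t.a} ({100 * t.a / len(pos):.2f})",
            "neg_summary": f"{t.c} ({100 * t.c / len(neg):.2f})",
            "statistic": res.statistic, "p_value": res.p_value,
            "test": "chi2_yates" if res.continuity_corrected else "chi2",
        })
    for colname in CONTINUOUS_COLUMNS:
        xp, xn = pos[colname].to_numpy(), neg[colname].to_numpy()
        if colname in _T_TEST_FEATURES:
            stat, p = group_compare_continuous(xp, xn, method="t")
            rows.append({
                "feature": colname, "kind": "continuous",
                "pos_summary": f"{xp.mean():.2f} +/- {xp.std(ddof=1):.2f}",
                "neg_summary": f"{xn.mean():.2f} +/- {xn.std(ddof=1):.2f}",
                "statistic": stat, "p_value": p, "test": "t",
            })
        else:
            z, p = group_compare_continuous(xp, xn, method="mann_whitney")
            q = lambda v: np.percentile(v, [25, 50, 75])
            qp, qn = q(xp), q(xn)
            rows.append({
                "feature": colname, "kind": "continuous",
                "pos_summary": f"{qp[1]:.2f} ({qp[0]:.2f},{qp[2]:.2f})",
                "neg_summary": f"{qn[1]:.2f} ({qn[0]:.2f},{qn[2]:.2f})",
                "statistic": z, "p_value": p, "test": "mann_whitney_z",
            })
    return pd.DataFrame(rows)


def table2_report(df: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Univariate and multivariate logistic regression summaries.

    Univariate: one logistic fit per feature.  Features significant at
    ``alpha`` enter the multivariate model; VIFs of the multivariate design
    are reported alongside.
    """
    validate_cohort(df)
    y = df["stas"].to_numpy()
    features = BINARY_COLUMNS[1:] + CONTINUOUS_COLUMNS
    uni_rows = []
    for colname in features:
        x = df[colname].to_numpy(dtype=float)[:, None]
        try:
            fit = logistic_fit(x, y, feature_names=[colname])
            s = fit.summary_frame().iloc[0]
            uni_rows.append({
                "feature": colname, "odds_ratio": s.odds_ratio,
                "ci_low": s.ci_low, "ci_high": s.ci_high, "p_value": s.p_value,
            })
        except SeparationError:
            uni_rows.append({
                "feature": colname, "odds_ratio": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
            })
    uni = pd.DataFrame(uni_rows)
    selected = uni.loc[uni["p_value"] < alpha, "feature"].tolist()
    multi = pd.DataFrame(columns=["feature", "odds_ratio", "ci_low", "ci_high", "p_value"])
    vifs = pd.DataFrame(columns=["feature", "vif", "collinear"])
    fit = None
    if len(selected) >= 1:
        Xm = df[selected].to_numpy(dtype=float)
        fit = logistic_fit(Xm, y, feature_names=selected)
        multi = fit.summary_frame()[["feature", "odds_ratio", "ci_low", "ci_high", "p_value"]]
        if len(selected) >= 2:
            vifs = vif(Xm, feature_names=selected)
    return {"univariate": uni, "multivariate": multi, "vif": vifs, "multivariate_fit": fit, "selected": selected}
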