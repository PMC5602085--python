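"""Group statistics for the structure-function analysis.

* one-way ANOVA with Bonferroni-adjusted pairwise post-hoc comparisons;
* linear mixed-effects structure-function regressions (function feature ~
  structure feature + age + gender, subject random intercept; collapses to
  OLS when every subject contributes one eye);
* Benjamini-Hochberg FDR adjustment;
* covariate-adjusted ROC: logistic regression disease ~ age + gender +
  marker, then the nonparametric (Mann-Whitney/Wilcoxon) AUC of the
  predicted probabilities with the DeLong standard error;
* the DeLong paired test for comparing correlated AUCs.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .errors import DataError, DegenerateInputError, PairingError, RangeError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelFit:
    """A structure-function regression slope with its uncertainty."""

    response: str
    predictor: str
    slope: float
    ci95: tuple
    p_value: float
    p_fdr: float | None = None
    covariates: tuple = ("age", "gender")
    mixed: bool = False  # True when a subject random intercept was fitted
    n: int = 0

    def __post_init__(self):
        lo, hi = self.ci95
        if not lo - 1e-12 <= self.slope <= hi + 1e-12:
            raise DataError("confidence interval must contain the slope")
        if not 0 < self.p_value <= 1:
            raise DataError("p-value must be in (0, 1]")


@dataclass(frozen=True)
class ROCResult:
    """AUC of one marker's covariate-adjusted logistic score."""

    marker: str
    auc: float
    se_auc: float
    n_cases: int
    n_controls: int
    covariates: tuple
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)
    logistic_score: bool = True

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise DataError("AUC must be in [0, 1]")
        if self.se_auc < 0:
            raise DataError("SE(AUC) must be >= 0")


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def anova_oneway(values_by_group: dict[str, np.ndarray],
                 posthoc: str = "bonferroni") -> dict:
    """Classical one-way ANOVA with Bonferroni pairwise post-hoc tests.

    Returns ``{"F": ..., "p": ..., "pairwise": {(a, b): p_adj}}``; pairwise
    p-values are two-sample t-tests multiplied by the number of pairs,
    capped at 1.
    """
    groups = {k: np.asarray(v, float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise DegenerateInputError("need at least 2 groups")
    for name, v in groups.items():
        if len(v) < 2:
            raise DegenerateInputError(f"group {name!r} has n < 2")
    names = list(groups)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) < 1e-300:
        F, p = 0.0, 1.0  # all observations identical
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = sstats.f_oneway(*groups.values())
        if not np.isfinite(F):
            F, p = 0.0, 1.0
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        if np.ptp(groups[a]) < 1e-300 and np.ptp(groups[b]) < 1e-300:
            praw = 1.0 if np.mean(groups[a]) == np.mean(groups[b]) else 0.0
        else:
            praw = sstats.ttest_ind(groups[a], groups[b]).pvalue
        pairwise[(a, b)] = min(1.0, float(praw) * n_pairs)
    return {"F": float(F), "p": float(p), "pairwise": pairwise}


# ---------------------------------------------------------------------------
# Structure-function regression
# ---------------------------------------------------------------------------

def _design_matrix(df, predictor, covariates):
    X = pd.DataFrame({predictor: df[predictor].astype(float)})
    if "age" in covariates:
        X["age"] = df["age"].astype(float)
    if "gender" in covariates:
        X["gender_male"] = (df["gender"].astype(str).str.upper()
                            .str.startswith("M")).astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_structure_function(table: pd.DataFrame, response: str, predictor: str,
                           subject_col: str = "subject_id",
                           covariates: tuple = ("age", "gender")) -> ModelFit:
    """Fit ``response ~ predictor + age + gender`` with a subject random
    intercept.

    When every subject contributes a single eye the random intercept is
    unidentifiable and the model collapses to ordinary least squares.
    Returns the predictor's slope, 95% CI and p-value.
    """
    cols = [response, predictor, *(
        c for c in ("age", "gender") if c in covariates), subject_col]
    df = table.dropna(subset=[c for c in cols if c in table.columns])
    if len(df) < 10:
        raise DataError(f"need >= 10 complete cases, got {len(df)}")
    if np.ptp(df[predictor].astype(float)) < 1e-12:
        raise DegenerateInputError(f"predictor {predictor!r} is constant")

    y = df[response].astype(float).to_numpy()
    X = _design_matrix(df, predictor, covariates)
    singletons = df[subject_col].value_counts().max() == 1

    if singletons:
        fit = sm.OLS(y, X).fit()
        mixed = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM(y, X, groups=df[subject_col].to_numpy()).fit(reml=True)
        mixed = True
    slope = float(fit.params[predictor])
    ci = fit.conf_int()
    lo, hi = float(ci.loc[predictor, 0]), float(ci.loc[predictor, 1])
    p = float(fit.pvalues[predictor])
    return ModelFit(response=response, predictor=predictor, slope=slope,
                    ci95=(lo, hi), p_value=max(min(p, 1.0), np.nextafter(0, 1)),
                    covariates=tuple(covariates), mixed=mixed, n=len(df))


def fit_structure_function_by_group(table: pd.DataFrame, response: str,
                                    predictor: str, group_col: str = "group",
                                    subject_col: str = "subject_id",
                                    covariates: tuple = ("age", "gender")
                                    ) -> dict[str, ModelFit]:
    """Per-group slopes via a group x predictor interaction (OLS).

    The pooled model from :func:`fit_structure_function` is the headline;
    this reports how the association differs by diagnostic group.
    """
    df = table.dropna(subset=[response, predictor]).copy()
    out = {}
    for g, sub in df.groupby(group_col):
        if len(sub) < 10 or np.ptp(sub[predictor].astype(float)) < 1e-12:
            continue
        out[g] = fit_structure_function(sub, response, predictor,
                                        subject_col=subject_col,
                                        covariates=covariates)
    return out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise RangeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

def mann_whitney_auc(scores, labels) -> float:
    """Nonparametric AUC: the probability a random case outscores a random
    control, ties counted 1/2 (Wilcoxon statistic)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("both classes must be present")
    ranks = sstats.rankdata(scores)
    return float((ranks[labels].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def _delong_components(scores, labels):
    """Per-observation structural components of the AUC (DeLong).

    Returns (auc, v10, v01): v10[i] over cases, v01[j] over controls.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    # psi matrix via broadcasting; ties get 1/2
    psi = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_variance(scores, labels) -> float:
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def adjusted_roc(marker, labels, age=None, gender=None,
                 marker_name: str = "marker") -> ROCResult:
    """Covariate-adjusted ROC of one marker.

    Fits logistic regression ``disease ~ age + gender + marker``, scores each
    eye by its predicted probability, and computes the nonparametric AUC of
    the scores with the DeLong standard error.  With constant covariates the
    logistic score is monotone in the marker, so the AUC equals the
    unadjusted marker AUC.  Under perfect separation the scores are still
    usable (a warning is logged).
    """
    marker = np.asarray(marker, float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise DataError("both classes must be present")
    cols, names = [marker], ["marker"]
    if age is not None:
        cols.append(np.asarray(age, float))
        names.append("age")
    if gender is not None:
        g = np.asarray([1.0 if str(x).upper().startswith("M") else 0.0
                        for x in np.asarray(gender)])
        cols.append(g)
        names.append("gender")
    X = np.column_stack(cols)
    if np.any(~np.isfinite(X)):
        raise DataError("missing covariate or marker values")
    keep = np.ptp(X, axis=0) > 1e-12  # drop constant columns
    Xf = X[:, keep] if keep.any() else marker[:, None]

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        lr = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
        lr.fit(Xf, labels)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            log.warning("logistic fit for %s did not converge "
                        "(possible perfect separation); AUC computed from "
                        "the fitted scores anyway", marker_name)
    scores = lr.predict_proba(Xf)[:, 1]

    auc = mann_whitney_auc(scores, labels)
    se = float(np.sqrt(delong_variance(scores, labels)))
    return ROCResult(marker=marker_name, auc=auc, se_auc=se,
                     n_cases=int(labels.sum()),
                     n_controls=int((1 - labels).sum()),
                     covariates=tuple(n for n in names if n != "marker"),
                     scores=scores, labels=labels.astype(bool))


def delong_compare(roc_a: ROCResult, roc_b: ROCResult) -> dict:
    """DeLong paired z-test on two correlated AUCs.

    Both ROCs must have been computed on the same eyes in the same order.
    Symmetric: swapping the arguments negates z and keeps p.
    """
    if roc_a.scores is None or roc_b.scores is None:
        raise PairingError("ROC results must retain their scores")
    if len(roc_a.scores) != len(roc_b.scores) \
            or not np.array_equal(roc_a.labels, roc_b.labels):
        raise PairingError("ROCs are not paired (different eyes or labels)")

    auc_a, v10_a, v01_a = _delong_components(roc_a.scores, roc_a.labels)
    auc_b, v10_b, v01_b = _delong_components(roc_b.scores, roc_b.labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 1e-300:
        z = 0.0
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = 2 * sstats.norm.sf(abs(z))
    return {"z": float(z), "p": float(min(p, 1.0)),
            "auc_a": auc_a, "auc_b": auc_b}
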