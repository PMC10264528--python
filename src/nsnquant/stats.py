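"""The statistical chain for cohort-level analysis.

Reliability of repeated measurements (intraclass correlation), feature-vs-
doubling-time correlations (Spearman), growing-vs-nongrowing contrasts
(Mann-Whitney U), univariate and backward-stepwise multivariable logistic
regression for growth prediction, and ROC analysis with Youden-index
optimal cutoffs.

Implementation notes
--------------------
* The ICC is the single-measurement, absolute-agreement, two-way form
  (ICC(A,1)), computed from the two-way ANOVA mean squares.
* Mann-Whitney U uses average ranks with tie correction; the p-value is by
  exact enumeration of all group assignments when n_a + n_b <= 12 (valid
  with ties), otherwise by normal approximation with continuity correction.
* Logistic regression is maximum likelihood via iteratively reweighted
  least squares with Wald z tests; complete separation is detected and
  flagged rather than reported as huge odds ratios.
* AUC is computed from the tie-corrected rank statistic, which equals the
  trapezoidal area under the empirical ROC exactly, including ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MW_LIMIT = 12  # pooled-size bound for exact U enumeration


# --------------------------------------------------------------------------
# reliability

def icc_single_absolute(set1: np.ndarray, set2: np.ndarray) -> float:
    """ICC(A,1): two-way, absolute-agreement, single-measurement ICC.

    ``set1``/``set2`` are the two measurement sets over the same n subjects
    (here: nodules).  Computed from the two-way ANOVA decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-subject, MSC the between-measurement and MSE the
    residual mean square, k = 2 raters.  Returns NaN (degenerate) when the
    between-subject variance is zero.
    """
    x = np.column_stack([np.asarray(set1, float), np.asarray(set2, float)])
    n, k = x.shape
    if n < 5:
        raise ValueError("need >= 5 subjects for a meaningful ICC")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(msr, 0.0) and np.isclose(mse, 0.0):
        return float("nan")
    return float((msr - mse) / denom)


def icc_reliability(set1: pd.DataFrame, set2: pd.DataFrame) -> pd.Series:
    """Per-feature ICC(A,1) between two measurement sets.

    Input frames must share columns (features) and index (nodules).
    Features with zero between-nodule variance are reported as NaN.
    """
    if list(set1.columns) != list(set2.columns):
        raise ValueError("measurement sets have different feature columns")
    if len(set1) != len(set2):
        raise ValueError("measurement sets have different lengths")
    out = {}
    for col in set1.columns:
        a, b = set1[col].to_numpy(float), set2[col].to_numpy(float)
        if np.allclose(a, a[0]) and np.allclose(b, b[0]):
            out[col] = float("nan")  # degenerate: no between-nodule variance
        else:
            out[col] = icc_single_absolute(a, b)
    return pd.Series(out, name="icc")


# --------------------------------------------------------------------------
# correlations and contrasts

class CorrelationResult(NamedTuple):
    rho: float
    p: float


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties; p by the
    t approximation on n - 2 degrees of freedom."""
    res = sps.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return CorrelationResult(float(res.statistic), float(res.pvalue))


class MannWhitneyResult(NamedTuple):
    u: float          # U statistic of the first sample
    p: float          # two-sided
    method: str       # "exact" or "asymptotic"


def _u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is computed from average ranks (tie-corrected).  For pooled sizes
    <= 12 the null distribution of U is enumerated exhaustively over all
    C(n, n_a) group assignments of the observed pooled values (exact even
    under ties); two-sided p = min(1, 2 min(P(U <= u), P(U >= u))).
    Larger samples use the normal approximation with tie-corrected variance
    and continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = _u_from_ranks(ranks[:n_a], n_a)
    n = n_a + n_b
    if n <= EXACT_MW_LIMIT:
        us = np.array([_u_from_ranks(ranks[list(idx)], n_a)
                       for idx in combinations(range(n), n_a)])
        p_low = np.mean(us <= u + 1e-12)
        p_high = np.mean(us >= u - 1e-12)
        p = min(1.0, 2.0 * min(p_low, p_high))
        return MannWhitneyResult(u, float(p), "exact")
    mean_u = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return MannWhitneyResult(u, 1.0, "asymptotic")
    # continuity correction shrinks |U - mean| by 0.5
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return MannWhitneyResult(u, float(p), "asymptotic")


@dataclass(frozen=True)
class AssociationResult:
    """Per-variable association summary against the growth outcome."""

    variable: str
    spearman_rho: float
    spearman_p: float
    u_statistic: float
    mann_whitney_p: float
    median_growing: float
    iqr_growing: tuple[float, float]
    median_nongrowing: float
    iqr_nongrowing: tuple[float, float]


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    return float(np.median(x)), (float(np.percentile(x, 25)),
                                 float(np.percentile(x, 75)))


def associate_features(table: pd.DataFrame, feature_names: Sequence[str],
                       dt_col: str = "doubling_time",
                       outcome_col: str = "growing") -> list[AssociationResult]:
    """Correlation with doubling time plus growing/nongrowing contrast for
    each feature.  Infinite doubling times participate in the Spearman rank
    correlation as the largest ranks (stable nodules grow slowest)."""
    results = []
    growing = table[outcome_col].to_numpy() == 1
    dt = table[dt_col].to_numpy(float)
    for name in feature_names:
        x = table[name].to_numpy(float)
        rho, p_rho = spearman(x, dt)
        mw = mann_whitney(x[growing], x[~growing])
        med_g, iqr_g = _median_iqr(x[growing])
        med_n, iqr_n = _median_iqr(x[~growing])
        results.append(AssociationResult(
            variable=name, spearman_rho=rho, spearman_p=p_rho,
            u_statistic=mw.u, mann_whitney_p=mw.p,
            median_growing=med_g, iqr_growing=iqr_g,
            median_nongrowing=med_n, iqr_nongrowing=iqr_n))
    return results


# --------------------------------------------------------------------------
# logistic regression

@dataclass(frozen=True)
class LogisticModel:
    """A fitted logistic regression model.

    ``beta``/``se``/``wald_p`` are indexed like ``predictors`` with the
    intercept first.  ``odds_ratios`` = exp(beta) for the non-intercept
    terms.  ``separation`` flags (quasi-)complete separation: coefficient
    estimates diverge and Wald statistics are meaningless.
    """

    predictors: tuple[str, ...]         # without intercept
    beta: np.ndarray                    # intercept first, then predictors
    se: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    converged: bool
    separation: bool
    n_iter: int
    log_likelihood: float
    elimination_trace: tuple[str, ...] = field(default=())

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def odds_ratios(self) -> dict[str, float]:
        return {name: float(np.exp(b))
                for name, b in zip(self.predictors, self.beta[1:])}

    def coefficient(self, name: str) -> float:
        return float(self.beta[1 + self.predictors.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.wald_p[1 + self.predictors.index(name)])

    def predict_proba(self, design: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = _design_matrix(design, self.predictors)
        return _sigmoid(x @ self.beta)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(eta / 2.0))  # numerically stable logistic


def _design_matrix(design, predictors: Sequence[str]) -> np.ndarray:
    if isinstance(design, pd.DataFrame):
        x = design[list(predictors)].to_numpy(float)
    else:
        x = np.asarray(design, float)
        if x.ndim == 1:
            x = x[:, None]
    return np.column_stack([np.ones(len(x)), x])


def logistic_fit(design: pd.DataFrame | np.ndarray,
                 outcome: Sequence[int],
                 predictors: Sequence[str] | None = None,
                 max_iter: int = 50, score_tol: float = 1e-8) -> LogisticModel:
    """Maximum-likelihood logistic regression via IRLS (Newton-Raphson).

    Convergence when the maximal absolute score component drops below
    ``score_tol`` (or after ``max_iter`` iterations).  Complete or
    quasi-complete separation is detected (all fitted probabilities pinned
    to their outcomes, or diverging coefficients) and reported through the
    ``separation`` flag instead of silently huge odds ratios.
    """
    if isinstance(design, pd.DataFrame):
        predictors = tuple(predictors or design.columns)
    else:
        arr = np.atleast_2d(np.asarray(design, float))
        n_pred = arr.shape[1] if arr.shape[0] != 1 else arr.shape[0]
        predictors = tuple(predictors or (f"x{i}" for i in range(
            np.asarray(design, float).reshape(len(outcome), -1).shape[1])))
    y = np.asarray(outcome, float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    x = _design_matrix(design, predictors)
    if x.shape[1] > 1 and np.any(np.ptp(x[:, 1:], axis=0) == 0):
        raise ValueError("design contains a constant column besides the intercept")
    beta = np.zeros(x.shape[1])
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        p = _sigmoid(x @ beta)
        w = p * (1.0 - p)
        score = x.T @ (y - p)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        # dampen absurd steps to keep the iteration stable
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if np.max(np.abs(beta)) > 1e3:
            separation = True
            break
    p = _sigmoid(x @ beta)
    eps = 1e-10
    ll = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    margins = np.where(y == 1, p, 1.0 - p)
    if not converged and np.all(margins > 1.0 - 1e-4):
        separation = True
    if np.max(np.abs(beta)) > 30.0 and np.all(margins > 0.5):
        separation = True
    w = p * (1.0 - p)
    hess = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(x.shape[1], np.nan)
        separation = True
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    return LogisticModel(
        predictors=tuple(predictors), beta=beta, se=se, wald_z=z,
        wald_p=pvals, converged=converged, separation=separation,
        n_iter=it, log_likelihood=ll)


def backward_stepwise(design: pd.DataFrame, outcome: Sequence[int],
                      p_enter: float = 0.05,
                      p_remove: float = 0.10) -> LogisticModel:
    """Univariate screening followed by backward elimination.

    Candidates significant in a univariate logistic fit (Wald p <
    ``p_enter``) seed the multivariable model; the predictor with the
    largest Wald p is dropped while it exceeds ``p_remove``, refitting each
    time.  The elimination trace lists the dropped variables in order.  An
    all-noise design yields the intercept-only model.
    """
    y = np.asarray(outcome, float)
    candidates = []
    for name in design.columns:
        model = logistic_fit(design[[name]], y)
        if not model.separation and model.p_value(name) < p_enter:
            candidates.append(name)
    trace: list[str] = []
    while True:
        if not candidates:
            null_model = logistic_fit(pd.DataFrame(index=design.index), y,
                                      predictors=())
            return LogisticModel(
                predictors=(), beta=null_model.beta, se=null_model.se,
                wald_z=null_model.wald_z, wald_p=null_model.wald_p,
                converged=null_model.converged, separation=False,
                n_iter=null_model.n_iter,
                log_likelihood=null_model.log_likelihood,
                elimination_trace=tuple(trace))
        model = logistic_fit(design[candidates], y)
        pvals = {name: model.p_value(name) for name in candidates}
        worst = max(pvals, key=pvals.get)
        if model.separation:
            # drop the most collinear/degenerate predictor and continue
            candidates.remove(worst)
            trace.append(f"{worst} (separation)")
            continue
        if pvals[worst] > p_remove:
            candidates.remove(worst)
            trace.append(worst)
            continue
        return LogisticModel(
            predictors=model.predictors, beta=model.beta, se=model.se,
            wald_z=model.wald_z, wald_p=model.wald_p,
            converged=model.converged, separation=model.separation,
            n_iter=model.n_iter, log_likelihood=model.log_likelihood,
            elimination_trace=tuple(trace))


# --------------------------------------------------------------------------
# ROC

@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve, AUC and the Youden-optimal operating cutoff.

    ``thresholds`` are the distinct score values in decreasing order; a
    case is called positive when its score >= threshold.  ``auc`` is the
    trapezoidal area, computed through the tie-corrected rank (Mann-
    Whitney) statistic.  The optimal cutoff maximizes the Youden index
    J = sensitivity + specificity - 1; ties resolve to the lowest cutoff.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    youden_j: float

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")


def roc_analysis(score: Sequence[float], outcome: Sequence[int]) -> ROCResult:
    """Empirical ROC analysis of a continuous score against a binary outcome."""
    score = np.asarray(score, float)
    y = np.asarray(outcome, int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need both positive and negative cases")
    ranks = sps.rankdata(score)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    thresholds = np.unique(score)[::-1]
    sens = np.array([(score[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(score[y == 0] < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best_j = j.max()
    # ties toward the lowest cutoff: thresholds are descending, take last argmax
    best_idx = np.where(np.isclose(j, best_j))[0][-1]
    return ROCResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=float(auc), optimal_cutoff=float(thresholds[best_idx]),
        youden_j=float(best_j))
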