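"""Binary-response GLM machinery.

Self-contained logistic-regression engine used by every modelling stage:
iteratively reweighted least squares (IRLS) fitting, likelihood-ratio
testing, Benjamini-Hochberg FDR screening, forward-backward stepwise
selection, variance inflation factors, and the discrimination /
calibration metrics reported for favourability models (sensitivity,
specificity, CCR, AUC, Nagelkerke's R-squared, AIC).

The fitter is written here rather than delegated to a library because the
selection machinery needs tight control over convergence, separation and
rank-deficiency handling; statsmodels is used as an independent
cross-check in the test-suite, never as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

INTERCEPT = "(Intercept)"

#: IRLS convergence: stop when max absolute coefficient change drops below this.
IRLS_TOL = 1e-8
#: IRLS iteration cap.
IRLS_MAX_ITER = 50
#: |beta| beyond this, with the likelihood still improving, flags (quasi-)separation.
SEPARATION_BETA = 15.0
#: Default stepwise thresholds (entry must not exceed removal, else cycling).
P_ENTER_DEFAULT = 0.05
P_REMOVE_DEFAULT = 0.10


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; ``columns`` names the offending terms."""

    def __init__(self, columns: list[str]):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; linearly dependent columns: "
            + ", ".join(self.columns)
        )


class SingleClassError(ValueError):
    """Response contains only one class."""


class StepwiseCyclingError(RuntimeError):
    """Stepwise selection failed to terminate within its iteration budget."""


@dataclass
class FittedLogisticModel:
    """A maximum-likelihood logistic fit with its bookkeeping.

    ``terms`` always starts with the intercept.  ``entry_order`` maps each
    non-intercept term to the rank (1-based) at which it entered during
    selection; for direct fits it is the input order.
    """

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    log_lik: float
    null_log_lik: float
    n: int
    n1: int
    n0: int
    entry_order: dict[str, int] = field(default_factory=dict)
    converged: bool = True
    separation: bool = False

    def __post_init__(self) -> None:
        if self.n != self.n1 + self.n0 or self.n1 < 1 or self.n0 < 1:
            raise ValueError("need n = n1 + n0 with at least one case per class")
        if self.log_lik < self.null_log_lik - 1e-8:
            raise ValueError("fitted log-likelihood below the null log-likelihood")

    @property
    def k(self) -> int:
        """Number of estimated parameters, intercept included."""
        return len(self.terms)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        """Evaluate eta = X beta on new rows; columns looked up by term name."""
        eta = np.full(len(table), self.coef(INTERCEPT))
        for t in self.terms:
            if t != INTERCEPT:
                eta += self.coef(t) * table[t].to_numpy(dtype=float)
        return eta

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(table))


@dataclass
class EvaluationReport:
    """Discrimination and fit metrics for one model."""

    sensitivity: float
    specificity: float
    ccr: float
    auc: float
    deviance_explained: float
    aic: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "ccr", "auc", "deviance_explained"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _as_response(response) -> np.ndarray:
    y = np.asarray(response, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1 with no missing values")
    if y.min() == y.max():
        raise SingleClassError("response contains a single class")
    return y


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Reject rank-deficient designs, naming the dependent columns via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise RankDeficiencyError(bad)


def _log_lik(y: np.ndarray, eta: np.ndarray) -> float:
    # Numerically safe Bernoulli log-likelihood: sum y*eta - log(1 + e^eta).
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def null_log_likelihood(n1: int, n0: int) -> float:
    """Closed-form intercept-only log-likelihood."""
    n = n1 + n0
    p = n1 / n
    return n1 * np.log(p) + n0 * np.log(1.0 - p)


def fit_logistic(design: pd.DataFrame, response) -> FittedLogisticModel:
    """Fit a logistic regression by IRLS.

    ``design`` holds one column per term and must include the intercept
    column ``(Intercept)`` (a column of ones).  Non-convergence and
    (quasi-)separation are flagged on the returned model, not raised;
    rank deficiency and single-class responses are rejected.
    """
    y = _as_response(response)
    names = list(design.columns)
    if INTERCEPT not in names:
        raise ValueError(f"design must include an intercept column named {INTERCEPT!r}")
    X = design.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("design contains non-finite values")
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if min(n1, n0) < 2:
        raise ValueError("need at least 2 observations in each class")
    _check_rank(X, names)

    beta = np.zeros(X.shape[1])
    ll_prev = _log_lik(y, X @ beta)
    converged = False
    separation = False
    cov = None
    for _ in range(IRLS_MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        xtwx = X.T @ Xw
        try:
            beta_new = np.linalg.solve(xtwx, Xw.T @ z)
        except np.linalg.LinAlgError:
            separation = True
            break
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        ll = _log_lik(y, X @ beta)
        if np.max(np.abs(beta)) > SEPARATION_BETA and ll > ll_prev:
            separation = True
        ll_prev = ll
        if step < IRLS_TOL:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf)
    p = 2.0 * norm.sf(np.abs(zstat))

    ll_null = null_log_likelihood(n1, n0)
    order = {t: i + 1 for i, t in enumerate(t for t in names if t != INTERCEPT)}
    return FittedLogisticModel(
        terms=names,
        beta=beta,
        se=se,
        p_value=p,
        log_lik=max(_log_lik(y, eta), ll_null),
        null_log_lik=ll_null,
        n=n1 + n0,
        n1=n1,
        n0=n0,
        entry_order=order,
        converged=converged,
        separation=separation,
    )


def lr_test(full: FittedLogisticModel, reduced: FittedLogisticModel) -> float:
    """Likelihood-ratio p-value for nested logistic models on the same data."""
    if (full.n, full.n1, full.n0) != (reduced.n, reduced.n1, reduced.n0):
        raise ValueError("models were fitted on different data")
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested")
    df = full.k - reduced.k
    if df == 0:
        return 1.0
    stat = max(0.0, 2.0 * (full.log_lik - reduced.log_lik))
    return float(chi2.sf(stat, df))


def bh_fdr(p_values, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up acceptance flags at FDR rate ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if not ((p >= 0) & (p <= 1)).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) * q / m)
    if not below.any():
        return np.zeros(m, dtype=bool)
    cutoff = sorted_p[np.nonzero(below)[0][-1]]
    return p <= cutoff


def _design(table: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    out = pd.DataFrame({INTERCEPT: np.ones(len(table))}, index=table.index)
    for t in terms:
        out[t] = table[t].to_numpy(dtype=float)
    return out


def fit_terms(table: pd.DataFrame, terms: list[str], response) -> FittedLogisticModel:
    """Fit the logistic model containing exactly ``terms`` plus an intercept."""
    return fit_logistic(_design(table, list(terms)), response)


def stepwise(
    candidates: pd.DataFrame,
    response,
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
    log: list | None = None,
) -> FittedLogisticModel:
    """Forward-backward stepwise logistic selection with LR tests.

    Forward: admit the candidate with the smallest likelihood-ratio p-value
    if it is below ``p_enter`` (ties broken by larger deviance reduction,
    then by declared candidate order).  Backward: drop the included term
    with the largest removal p-value if it exceeds ``p_remove``.  Candidates
    that would make the design rank deficient are skipped.  Every decision
    is appended to ``log`` when given.
    """
    if p_enter > p_remove:
        raise ValueError("p_enter must not exceed p_remove (prevents cycling)")
    y = _as_response(response)
    names = list(candidates.columns)
    included: list[str] = []
    entry_seq: dict[str, int] = {}
    next_rank = 1
    current = fit_terms(candidates, [], y)
    budget = max(2 * len(names), 4)
    for _ in range(budget + 1):
        acted = False
        # -- forward step
        best = None  # (p, -deviance_reduction, input_order, term, model)
        for j, t in enumerate(names):
            if t in included:
                continue
            try:
                trial = fit_terms(candidates, included + [t], y)
            except RankDeficiencyError:
                continue
            p = lr_test(trial, current)
            drop = trial.log_lik - current.log_lik
            key = (p, -drop, j)
            if best is None or key < best[0]:
                best = (key, t, trial)
        if best is not None and best[0][0] < p_enter:
            _, term, model = best
            included.append(term)
            entry_seq[term] = next_rank
            next_rank += 1
            if log is not None:
                log.append(("enter", term, best[0][0]))
            current = model
            acted = True
        # -- backward step
        worst = None  # (p, term)
        for t in included:
            rest = [u for u in included if u != t]
            p = lr_test(current, fit_terms(candidates, rest, y))
            if worst is None or p > worst[0]:
                worst = (p, t)
        if worst is not None and worst[0] > p_remove:
            p, term = worst
            included.remove(term)
            entry_seq.pop(term)
            if log is not None:
                log.append(("remove", term, p))
            current = fit_terms(candidates, included, y)
            acted = True
        if not acted:
            ranks = {t: r for r, (t, _) in enumerate(sorted(entry_seq.items(), key=lambda kv: kv[1]), start=1)}
            current.entry_order = ranks
            return current
    raise StepwiseCyclingError(f"no convergence within {budget} stepwise iterations")


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: VIF_j = 1 / (1 - R^2_j)."""
    X = design.to_numpy(dtype=float)
    names = list(design.columns)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    if (X.std(axis=0) == 0).any():
        bad = [n for n, s in zip(names, X.std(axis=0)) if s == 0]
        raise ValueError(f"constant columns have no VIF: {', '.join(bad)}")
    out = {}
    ones = np.ones((X.shape[0], 1))
    for j, name in enumerate(names):
        yj = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def nagelkerke_r2(model: FittedLogisticModel) -> float:
    """Nagelkerke's pseudo R-squared ('deviance explained')."""
    if model.n == 0:
        raise ValueError("empty model")
    n = model.n
    cox_snell = 1.0 - np.exp(2.0 * (model.null_log_lik - model.log_lik) / n)
    ceiling = 1.0 - np.exp(2.0 * model.null_log_lik / n)
    return float(cox_snell / ceiling)


def aic(model: FittedLogisticModel) -> float:
    """Akaike information criterion, 2k - 2 logL, k counting the intercept."""
    return 2.0 * model.k - 2.0 * model.log_lik


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_presence > score_absence), ties count half."""
    s = np.asarray(scores, dtype=float)
    y = _as_response(labels)
    from scipy.stats import rankdata

    ranks = rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def confusion_metrics(scores, labels, threshold: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, CCR) classifying positive at score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = _as_response(labels)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    n1 = int(y.sum())
    n0 = len(y) - n1
    return tp / n1, tn / n0, (tp + tn) / len(y)
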