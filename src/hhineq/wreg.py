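"""Probability-weighted logistic and linear-probability regression.

Both fitters treat weights as sampling probability weights
(pseudo-maximum-likelihood): point estimates maximize the weighted
objective and the variance is the robust sandwich, optionally cluster-summed.
The module also carries the model-checking toolkit used around such fits:
perfect-prediction/collinearity screening, odds-ratio tables, average
marginal effects, Hosmer–Lemeshow calibration, weighted ROC AUC, variance
inflation factors and the link (specification) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .survey_core import (
    CATEGORICAL_LEVELS,
    OUTCOME,
    REFERENCE_LEVELS,
    WEIGHT,
    SurveyTable,
    _coerce_frame,
)

__all__ = [
    "Design",
    "FitResult",
    "MarginalEffects",
    "DropReport",
    "build_design",
    "drop_perfect_predictors",
    "fit_weighted_logit",
    "fit_weighted_lpm",
    "odds_ratio_table",
    "average_marginal_effects",
    "hosmer_lemeshow",
    "roc_auc",
    "vif",
    "link_test",
]

_IRLS_TOL = 1e-8
_IRLS_MAXIT = 100


@dataclass
class Design:
    """Expanded design matrix with bookkeeping for term groups."""

    y: np.ndarray
    X: np.ndarray
    w: np.ndarray
    columns: list[str]
    term_of_column: list[str]  # parent term per column ("Intercept" first)
    kind_of_column: list[str]  # "intercept" | "dummy" | "continuous"
    index: pd.Index  # rows of the source frame actually used
    formula: str


@dataclass
class DropReport:
    """Columns removed before fitting, with the reason per column."""

    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.dropped)

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.dropped]


@dataclass
class FitResult:
    coefficients: pd.Series
    vcov: pd.DataFrame
    link: str  # "logit" | "identity"
    n_used: int
    dropped_terms: list[tuple[str, str]]
    converged: bool
    fitted_probabilities: np.ndarray
    design: Design

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.vcov.to_numpy())), index=self.coefficients.index
        )

    def loglik(self) -> float:
        """Weighted Bernoulli log-likelihood at the fit (logit link only)."""
        if self.link != "logit":
            raise ValueError("loglik defined for logit link")
        p = np.clip(self.fitted_probabilities, 1e-12, 1 - 1e-12)
        y, w = self.design.y, self.design.w
        return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


@dataclass
class MarginalEffects:
    ame: pd.Series
    se: pd.Series


def _parse_formula(formula: str) -> tuple[str, list[tuple[str, bool]]]:
    """Return (outcome, [(term, force_categorical), ...])."""
    if "~" not in formula:
        raise ValueError("formula must be of the form 'outcome ~ term + term'")
    lhs, rhs = formula.split("~", 1)
    terms = []
    for tok in rhs.split("+"):
        tok = tok.strip()
        if not tok:
            continue
        if tok.startswith("C(") and tok.endswith(")"):
            terms.append((tok[2:-1].strip(), True))
        else:
            terms.append((tok, False))
    return lhs.strip(), terms


def build_design(
    data,
    formula: str,
    reference_levels: dict | None = None,
    weight_col: str = WEIGHT,
) -> Design:
    """Expand a ``y ~ a + C(b) + x`` formula into a numeric design matrix.

    Categorical terms (object/category dtype, or wrapped in ``C()``) expand
    into one 0/1 dummy per non-reference level named ``term[level]``; the
    reference levels default to :data:`~hhineq.survey_core.REFERENCE_LEVELS`.
    Rows with a missing value in the outcome, the weight or any term are
    dropped (complete case).
    """
    df = _coerce_frame(data)
    refs = dict(REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)
    yname, terms = _parse_formula(formula)
    for name in [yname, weight_col] + [t for t, _ in terms]:
        if name not in df.columns:
            raise ValueError(f"column {name!r} not found")

    used = df[[yname, weight_col] + [t for t, _ in terms]].dropna()
    y = used[yname].to_numpy(dtype=float)
    w = used[weight_col].to_numpy(dtype=float)

    cols: list[np.ndarray] = [np.ones(len(used))]
    names = ["Intercept"]
    owners = ["Intercept"]
    kinds = ["intercept"]
    for term, force_cat in terms:
        col = used[term]
        is_cat = force_cat or col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype
        ) or col.dtype == bool
        if is_cat:
            known = CATEGORICAL_LEVELS.get(term)
            levels = known if known is not None else sorted(col.dropna().unique())
            ref = refs.get(term, levels[0])
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
                owners.append(term)
                kinds.append("dummy")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
            owners.append(term)
            kinds.append("dummy" if set(np.unique(col)) <= {0.0, 1.0} else "continuous")
    X = np.column_stack(cols)
    return Design(
        y=y, X=X, w=w, columns=names, term_of_column=owners,
        kind_of_column=kinds, index=used.index, formula=formula,
    )


def _screen_design(
    design: Design, check_perfect: bool = True
) -> tuple[Design, DropReport]:
    """Drop perfect-prediction dummies, then exactly collinear columns."""
    report = DropReport()
    keep = np.ones(design.X.shape[1], dtype=bool)
    y = design.y
    if check_perfect:
        for j in range(1, design.X.shape[1]):
            if design.kind_of_column[j] != "dummy":
                continue
            cell = design.X[:, j] == 1.0
            if cell.any() and (y[cell].min() == y[cell].max()):
                keep[j] = False
                report.dropped.append((design.columns[j], "perfect prediction"))
    # greedy Gram–Schmidt scan for exact collinearity among the survivors
    basis: list[np.ndarray] = []
    for j in np.flatnonzero(keep):
        c = design.X[:, j].astype(float)
        r = c.copy()
        for q in basis:
            r -= (q @ r) * q
        nr, nc = np.linalg.norm(r), np.linalg.norm(c)
        if nr <= 1e-8 * max(nc, 1.0):
            keep[j] = False
            report.dropped.append((design.columns[j], "collinearity"))
        else:
            basis.append(r / nr)
    sub = np.flatnonzero(keep)
    reduced = Design(
        y=design.y, X=design.X[:, sub], w=design.w,
        columns=[design.columns[j] for j in sub],
        term_of_column=[design.term_of_column[j] for j in sub],
        kind_of_column=[design.kind_of_column[j] for j in sub],
        index=design.index, formula=design.formula,
    )
    return reduced, report


def drop_perfect_predictors(
    data, formula: str, reference_levels: dict | None = None
) -> tuple[Design, DropReport]:
    """Screen a design for perfectly predictive cells and aliased columns.

    Returns the reduced design plus a report listing each dropped column with
    its reason (``"perfect prediction"`` or ``"collinearity"``); the report is
    empty when the design is well conditioned.
    """
    design = build_design(data, formula, reference_levels)
    return _screen_design(design)


def _sandwich(bread_inv: np.ndarray, scores: np.ndarray, cluster=None) -> np.ndarray:
    if cluster is None:
        meat = scores.T @ scores
    else:
        cl = pd.Series(np.asarray(cluster))
        summed = pd.DataFrame(scores).groupby(cl.to_numpy()).sum().to_numpy()
        meat = summed.T @ summed
    V = bread_inv @ meat @ bread_inv
    return (V + V.T) / 2.0


def fit_weighted_logit(
    data,
    formula: str,
    reference_levels: dict | None = None,
    cluster=None,
    screen: bool = True,
) -> FitResult:
    """Probability-weighted logistic regression via IRLS.

    Maximizes the weighted Bernoulli log-likelihood starting from beta = 0,
    with tolerance 1e-8 on the largest coefficient change and at most 100
    iterations.  The variance is the robust sandwich built from the weighted
    scores, optionally summed within ``cluster`` ids.  Perfect-prediction and
    exactly collinear columns are dropped beforehand (``screen=True``).
    """
    design = build_design(data, formula, reference_levels)
    if screen:
        design, report = _screen_design(design)
    else:
        design, report = design, DropReport()
        _, check = _screen_design(design)
        aliased = [c for c, r in check.dropped if r == "collinearity"]
        if aliased:
            raise ValueError(f"design is rank deficient; aliased terms: {aliased}")
    y, X, w = design.y, design.X, design.w
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")

    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(_IRLS_MAXIT):
        p = expit(X @ beta)
        mu_var = np.clip(p * (1 - p), 1e-10, None)
        grad = X.T @ (w * (y - p))
        H = X.T @ (X * (w * mu_var)[:, None])
        delta = np.linalg.solve(H, grad)
        beta = beta + delta
        if np.max(np.abs(delta)) < _IRLS_TOL:
            converged = True
            break
    if not converged:
        warnings.warn("IRLS did not converge within 100 iterations")

    p = expit(X @ beta)
    H = X.T @ (X * (w * np.clip(p * (1 - p), 1e-10, None))[:, None])
    bread_inv = np.linalg.inv(H)
    scores = X * (w * (y - p))[:, None]
    V = _sandwich(bread_inv, scores, cluster)
    return FitResult(
        coefficients=pd.Series(beta, index=design.columns),
        vcov=pd.DataFrame(V, index=design.columns, columns=design.columns),
        link="logit", n_used=len(y), dropped_terms=report.dropped,
        converged=converged, fitted_probabilities=p, design=design,
    )


def fit_weighted_lpm(
    data,
    formula: str,
    reference_levels: dict | None = None,
    cluster=None,
    screen: bool = True,
) -> FitResult:
    """Weighted least squares of the binary outcome (linear probability model)."""
    design = build_design(data, formula, reference_levels)
    if screen:
        # only aliasing matters for least squares; perfectly predictive
        # cells are a logit-specific (likelihood) problem
        design, report = _screen_design(design, check_perfect=False)
    else:
        report = DropReport()
    y, X, w = design.y, design.X, design.w
    A = X.T @ (X * w[:, None])
    beta = np.linalg.solve(A, X.T @ (w * y))
    fitted = X @ beta
    bread_inv = np.linalg.inv(A)
    scores = X * (w * (y - fitted))[:, None]
    V = _sandwich(bread_inv, scores, cluster)
    return FitResult(
        coefficients=pd.Series(beta, index=design.columns),
        vcov=pd.DataFrame(V, index=design.columns, columns=design.columns),
        link="identity", n_used=len(y), dropped_terms=report.dropped,
        converged=True, fitted_probabilities=fitted, design=design,
    )


def significance_mark(p: float) -> str:
    """Three-tier marks: a (<0.01), b (<0.05), c (<0.1)."""
    if p < 0.01:
        return "a"
    if p < 0.05:
        return "b"
    if p < 0.1:
        return "c"
    return ""


def odds_ratio_table(fit: FitResult) -> pd.DataFrame:
    """Adjusted odds ratios with 95% CIs and a/b/c significance marks."""
    if fit.link != "logit":
        raise ValueError("odds ratios are defined for logit fits only")
    beta = fit.coefficients
    se = fit.se
    z = beta / se.replace(0.0, np.nan)
    p = pd.Series(2 * norm.sf(np.abs(z.fillna(np.inf))), index=beta.index)
    tab = pd.DataFrame(
        {
            "term": beta.index,
            "estimate": beta.to_numpy(),
            "se": se.to_numpy(),
            "aOR": np.exp(beta.to_numpy()),
            "ci_low": np.exp(beta.to_numpy() - 1.96 * se.to_numpy()),
            "ci_high": np.exp(beta.to_numpy() + 1.96 * se.to_numpy()),
            "p": p.to_numpy(),
            "mark": [significance_mark(v) for v in p.to_numpy()],
        }
    ).set_index("term")
    return tab


def _ame_vector(fit: FitResult, beta: np.ndarray) -> np.ndarray:
    """AMEs for a given coefficient vector on the fit's design."""
    d = fit.design
    X, w = d.X, d.w
    W = w.sum()
    if fit.link == "identity":
        return beta[1:].copy()
    p = expit(X @ beta)
    out = np.empty(X.shape[1] - 1)
    for j in range(1, X.shape[1]):
        if d.kind_of_column[j] == "continuous":
            out[j - 1] = np.sum(w * beta[j] * p * (1 - p)) / W
        else:
            group = [
                k
                for k in range(1, X.shape[1])
                if d.term_of_column[k] == d.term_of_column[j]
            ]
            X1 = X.copy()
            X1[:, group] = 0.0
            X0 = X1.copy()
            X1[:, j] = 1.0
            diff = expit(X1 @ beta) - expit(X0 @ beta)
            out[j - 1] = np.sum(w * diff) / W
    return out


def average_marginal_effects(fit: FitResult, data=None) -> MarginalEffects:
    """Average marginal effects on the probability scale.

    Continuous terms use the weighted mean of ``beta * p * (1 - p)``; dummy
    terms use the discrete difference in predicted probability between the
    level and its reference (other dummies of the same term zeroed).  For an
    identity-link fit the AMEs are the coefficients themselves.  Standard
    errors come from the delta method with a numerically differentiated
    Jacobian.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    beta = fit.coefficients.to_numpy()
    names = fit.coefficients.index[1:]
    ame = _ame_vector(fit, beta)
    if fit.link == "identity":
        se = fit.se.iloc[1:].to_numpy()
    else:
        eps = 1e-6
        J = np.empty((len(ame), len(beta)))
        for k in range(len(beta)):
            bp, bm = beta.copy(), beta.copy()
            bp[k] += eps
            bm[k] -= eps
            J[:, k] = (_ame_vector(fit, bp) - _ame_vector(fit, bm)) / (2 * eps)
        V = J @ fit.vcov.to_numpy() @ J.T
        se = np.sqrt(np.clip(np.diag(V), 0.0, None))
    return MarginalEffects(
        ame=pd.Series(ame, index=names), se=pd.Series(se, index=names)
    )


def hosmer_lemeshow(fit: FitResult, data=None, groups: int = 10):
    """Hosmer–Lemeshow calibration test on deciles of fitted risk.

    Observed and expected event counts are compared per group with a
    chi-square statistic on ``groups - 2`` degrees of freedom (unweighted
    counts, as the test is conventionally run on the unweighted model fit).
    """
    p = np.asarray(fit.fitted_probabilities, dtype=float)
    y = fit.design.y
    n_distinct = len(np.unique(p))
    if n_distinct < groups:
        warnings.warn(
            f"only {n_distinct} distinct fitted probabilities; "
            f"reducing groups from {groups}"
        )
        groups = max(n_distinct, 3)
    order = np.argsort(p, kind="mergesort")
    stat = 0.0
    for chunk in np.array_split(order, groups):
        e1 = p[chunk].sum()
        o1 = y[chunk].sum()
        e0 = len(chunk) - e1
        o0 = len(chunk) - o1
        if e1 > 0:
            stat += (o1 - e1) ** 2 / e1
        if e0 > 0:
            stat += (o0 - e0) ** 2 / e0
    df = groups - 2
    return float(stat), float(chi2.sf(stat, df))


def roc_auc(fit_or_scores, data=None) -> float:
    """Weighted ROC AUC via the Mann–Whitney formulation (ties count 1/2)."""
    if isinstance(fit_or_scores, FitResult):
        s = np.asarray(fit_or_scores.fitted_probabilities, dtype=float)
        y = fit_or_scores.design.y
        w = fit_or_scores.design.w
    else:
        s, y, w = (np.asarray(a, dtype=float) for a in fit_or_scores)
    pos, neg = y == 1, y == 0
    Wp, Wn = w[pos].sum(), w[neg].sum()
    if Wp == 0 or Wn == 0:
        raise ValueError("both outcome classes must be present")
    order = np.argsort(s, kind="mergesort")
    s_, y_, w_ = s[order], y[order], w[order]
    total = 0.0
    cum_neg = 0.0
    i = 0
    n = len(s_)
    while i < n:
        j = i
        while j < n and s_[j] == s_[i]:
            j += 1
        wn_tie = w_[i:j][y_[i:j] == 0].sum()
        wp_tie = w_[i:j][y_[i:j] == 1].sum()
        total += wp_tie * (cum_neg + 0.5 * wn_tie)
        cum_neg += wn_tie
        i = j
    return float(total / (Wp * Wn))


@dataclass
class VifResult:
    per_term: pd.Series
    mean: float


def vif(data, formula: str, reference_levels: dict | None = None) -> VifResult:
    """Variance inflation factors from weighted auxiliary regressions.

    ``VIF_k = 1 / (1 - R^2_k)`` where ``R^2_k`` is the weighted R-squared of
    design column *k* on all the others (intercept included).  Aliased
    columns are reported as ``inf``; the mean VIF skips them.
    """
    design = build_design(data, formula, reference_levels)
    X, w = design.X, design.w
    vals = {}
    for j in range(1, X.shape[1]):
        xk = X[:, j]
        others = np.delete(X, j, axis=1)
        A = others.T @ (others * w[:, None])
        try:
            b = np.linalg.solve(A, others.T @ (w * xk))
        except np.linalg.LinAlgError:
            b = np.linalg.lstsq(others * np.sqrt(w)[:, None],
                                xk * np.sqrt(w), rcond=None)[0]
        resid = xk - others @ b
        mbar = np.sum(w * xk) / w.sum()
        sst = np.sum(w * (xk - mbar) ** 2)
        ssr = np.sum(w * resid**2)
        if sst <= 0:
            vals[design.columns[j]] = np.inf
            continue
        r2 = 1.0 - ssr / sst
        vals[design.columns[j]] = np.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    per = pd.Series(vals)
    finite = per[np.isfinite(per)]
    return VifResult(per_term=per, mean=float(finite.mean()))


def link_test(fit: FitResult, data=None):
    """Specification check: refit on the linear predictor and its square.

    Returns ``(coef_hat, coef_hatsq, p_hatsq)``; a small ``p_hatsq`` flags
    functional-form misspecification.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    d = fit.design
    xb = d.X @ fit.coefficients.to_numpy()
    if np.ptp(xb) < 1e-12:
        raise ValueError("linear predictor is constant; link test undefined")
    aux = pd.DataFrame(
        {OUTCOME: d.y, "hat": xb, "hatsq": xb**2, WEIGHT: d.w}
    )
    refit = fit_weighted_logit(aux, f"{OUTCOME} ~ hat + hatsq", screen=False)
    b = refit.coefficients
    se = refit.se
    p_hatsq = float(2 * norm.sf(abs(b["hatsq"] / se["hatsq"])))
    return float(b["hat"]), float(b["hatsq"]), p_hatsq
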