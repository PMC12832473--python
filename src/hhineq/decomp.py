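"""Regression-based decomposition of the concentration index.

Step 1 fits a weighted model of the binary outcome on the explanatory
factors (linear probability model by default, or a logit whose average
marginal effects are used).  Step 2 writes the outcome's concentration index
as a sum over factors of ``(beta_k xbar_k / mu) CI_k`` (standard index; the
Erreygers version scales by ``4 mu / (b - a)``) plus an unexplained residual
defined as total minus explained.  Percent shares divide each contribution
by the total index and may legitimately exceed 100 or turn negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cindex import IndexEstimate, standard_ci, weighted_cov, _POINT
from .survey_core import (
    OUTCOME,
    WEIGHT,
    RankVector,
    SurveyTable,
    _coerce_frame,
    weighted_fractional_rank,
)
from .wreg import (
    FitResult,
    average_marginal_effects,
    build_design,
    fit_weighted_logit,
    fit_weighted_lpm,
)

__all__ = [
    "DecompositionTable",
    "decompose_index",
    "percent_contributions",
    "ses_sensitivity",
    "default_ranks",
]


@dataclass
class DecompositionTable:
    """Per-factor contributions to a concentration index.

    ``detail`` has one row per design column (beta/AME, weighted mean,
    factor concentration index, absolute contribution, percent share);
    ``groups`` aggregates dummy levels back to their parent variable by
    summing contributions and mean-weight-averaging the factor indices.
    """

    detail: pd.DataFrame
    groups: pd.DataFrame
    total_index: float
    residual: float
    residual_percent: float
    index_type: str
    model: str
    fit: FitResult

    @property
    def explained(self) -> float:
        return float(self.detail["contribution"].sum())


def default_ranks(data, index: pd.Index | None = None) -> RankVector:
    """Fractional ranks from ``ses_score`` if present, else ``ses_quintile``."""
    df = _coerce_frame(data)
    if index is not None:
        df = df.loc[index]
    col = "ses_score" if "ses_score" in df.columns and df["ses_score"].notna().all() \
        else "ses_quintile"
    return weighted_fractional_rank(
        df[col].to_numpy(dtype=float), df[WEIGHT].to_numpy(dtype=float)
    )


def decompose_index(
    data,
    formula: str,
    ranks: RankVector | None = None,
    index_type: str = "erreygers",
    model: str = "lpm",
    bounds=(0.0, 1.0),
    reference_levels: dict | None = None,
) -> DecompositionTable:
    """Decompose the outcome's concentration index into factor contributions.

    ``ranks``, when given, must align row-by-row with ``data``; rows dropped
    by the complete-case design keep their rank values.  When omitted, ranks
    are computed on the analysis rows from the SES columns.  ``model`` is
    ``"lpm"`` (coefficients used directly) or ``"logit_ame"`` (average
    marginal effects of a weighted logit).
    """
    df = _coerce_frame(data)
    if model == "lpm":
        fit = fit_weighted_lpm(df, formula, reference_levels)
        betas = fit.coefficients.iloc[1:]
    elif model == "logit_ame":
        fit = fit_weighted_logit(df, formula, reference_levels)
        if not fit.converged:
            raise ValueError("logit model did not converge")
        betas = average_marginal_effects(fit).ame
    else:
        raise ValueError(f"unknown decomposition model {model!r}")

    d = fit.design
    if ranks is None:
        r = default_ranks(df, d.index).rank
    else:
        pos = df.index.get_indexer(d.index)
        r = np.asarray(ranks.rank, dtype=float)[pos]
    w = d.w
    y = d.y
    mu = float(np.sum(w * y) / w.sum())
    if mu == 0:
        raise ValueError("mean outcome is zero; index undefined")

    a, b = float(bounds[0]), float(bounds[1])
    if index_type == "standard":
        scale = 2.0 / mu
        total = standard_ci(y, r, w).value
    elif index_type == "erreygers":
        scale = 8.0 / (b - a)
        total = _POINT["erreygers"](y, r, w, bounds).value
    elif index_type == "wagstaff":
        wag = _POINT["wagstaff"](y, r, w, bounds)
        scale = (2.0 / mu) * mu * (b - a) / ((b - mu) * (mu - a))
        total = wag.value
    else:
        raise ValueError(f"unknown index type {index_type!r}")

    rows = []
    for j, name in enumerate(d.columns[1:], start=1):
        xk = d.X[:, j]
        cov_k = weighted_cov(xk, r, w)
        xbar = float(np.sum(w * xk) / w.sum())
        ci_k = 2.0 * cov_k / xbar if abs(xbar) > 1e-300 else np.nan
        contribution = scale * float(betas.iloc[j - 1]) * cov_k
        rows.append(
            {
                "factor": name,
                "group": d.term_of_column[j],
                "beta": float(betas.iloc[j - 1]),
                "mean": xbar,
                "factor_ci": ci_k,
                "contribution": contribution,
            }
        )
    detail = pd.DataFrame(rows).set_index("factor")
    explained = float(detail["contribution"].sum())
    residual = total - explained

    if total != 0:
        detail["percent"] = 100.0 * detail["contribution"] / total
        residual_percent = 100.0 * residual / total
    else:
        detail["percent"] = np.nan
        residual_percent = np.nan

    def _agg(g: pd.DataFrame) -> pd.Series:
        msum = g["mean"].sum()
        ci = float((g["mean"] * g["factor_ci"]).sum() / msum) if msum > 0 else np.nan
        return pd.Series(
            {
                "factor_ci": ci,
                "contribution": g["contribution"].sum(),
                "percent": g["percent"].sum(),
            }
        )

    order = list(dict.fromkeys(detail["group"]))
    groups = (
        detail.groupby("group", sort=False).apply(_agg, include_groups=False)
        .loc[order]
    )
    return DecompositionTable(
        detail=detail, groups=groups, total_index=total, residual=residual,
        residual_percent=float(residual_percent), index_type=index_type,
        model=model, fit=fit,
    )


def percent_contributions(t: DecompositionTable) -> pd.DataFrame:
    """Percent shares per variable group (plus the residual row).

    Shares are ``100 * contribution / total_index``; they can exceed 100 or
    be negative, with the residual absorbing the difference so the column
    sums to 100.
    """
    if t.total_index == 0:
        raise ValueError(
            "total index is zero: report absolute contributions instead"
        )
    out = t.groups[["contribution", "percent"]].copy()
    out.loc["residual"] = [t.residual, t.residual_percent]
    return out


@dataclass
class SesSensitivityReport:
    wald_stat: float
    wald_df: int
    wald_p: float
    pseudo_r2_categorical: float
    pseudo_r2_ordinal: float
    ses_share_categorical: float
    ses_share_ordinal: float

    @property
    def pseudo_r2_delta(self) -> float:
        return abs(self.pseudo_r2_categorical - self.pseudo_r2_ordinal)


def _pseudo_r2(fit: FitResult) -> float:
    """Weighted McFadden pseudo R-squared."""
    df0 = pd.DataFrame({OUTCOME: fit.design.y, WEIGHT: fit.design.w})
    null = fit_weighted_logit(df0, f"{OUTCOME} ~ ", screen=False)
    return 1.0 - fit.loglik() / null.loglik()


def ses_sensitivity(
    data,
    formula_base: str,
    ranks: RankVector | None = None,
    reference_levels: dict | None = None,
) -> SesSensitivityReport:
    """Compare SES-as-categories with SES-as-ordinal specifications.

    ``formula_base`` must contain a ``C(ses_quintile)`` term; the ordinal
    variant replaces it with the numeric 1-5 quintile.  Reports the joint
    Wald test of the SES dummies, the two McFadden pseudo R-squared values
    and both decompositions' SES percent shares.
    """
    if "C(ses_quintile)" not in formula_base:
        raise ValueError("formula_base must include C(ses_quintile)")
    formula_ord = formula_base.replace("C(ses_quintile)", "ses_quintile")
    df = _coerce_frame(data)

    fit_cat = fit_weighted_logit(df, formula_base, reference_levels)
    fit_ord = fit_weighted_logit(df, formula_ord, reference_levels)

    ses_cols = [
        c for c, t in zip(fit_cat.design.columns, fit_cat.design.term_of_column)
        if t == "ses_quintile"
    ]
    beta = fit_cat.coefficients.loc[ses_cols].to_numpy()
    V = fit_cat.vcov.loc[ses_cols, ses_cols].to_numpy()
    stat = float(beta @ np.linalg.solve(V, beta))
    dof = len(ses_cols)
    pval = float(chi2.sf(stat, dof))

    dec_cat = decompose_index(df, formula_base, ranks, model="logit_ame",
                              reference_levels=reference_levels)
    dec_ord = decompose_index(df, formula_ord, ranks, model="logit_ame",
                              reference_levels=reference_levels)
    return SesSensitivityReport(
        wald_stat=stat, wald_df=dof, wald_p=pval,
        pseudo_r2_categorical=_pseudo_r2(fit_cat),
        pseudo_r2_ordinal=_pseudo_r2(fit_ord),
        ses_share_categorical=float(dec_cat.groups.loc["ses_quintile", "percent"]),
        ses_share_ordinal=float(dec_ord.groups.loc["ses_quintile", "percent"]),
    )
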