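"""Survey data model, outcome harmonization and weighted descriptive statistics.

The central object is :class:`SurveyTable`, a thin validated wrapper around a
:class:`pandas.DataFrame` holding one row per household/respondent with a
binary "no hunger" outcome, a socio-economic ranking variable, covariates and
a positive probability weight.  On top of it this module provides

* :func:`harmonize_no_hunger` — recode raw 7-day hunger items from either
  survey convention into a common ``1 = no household hunger`` indicator,
* :func:`weighted_fractional_rank` — weighted fractional (midpoint) ranks of
  the SES distribution, with tie-group averaging,
* :func:`weighted_quintiles` — weighted SES quintiles (1 = poorest),
* :func:`prevalence_table` — weighted prevalence estimates with
  effective-sample-size logit confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SurveyTable",
    "RankVector",
    "PrevalenceEstimate",
    "CATEGORICAL_LEVELS",
    "REFERENCE_LEVELS",
    "MISSING_CODES",
    "load_survey",
    "harmonize_no_hunger",
    "weighted_fractional_rank",
    "weighted_quintiles",
    "prevalence_table",
    "prevalence_to_frame",
]

#: Values interpreted as missing when reading CSV input.
MISSING_CODES = ["", "NA", "-9"]

#: Closed level sets for the categorical covariates.
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "sex": ["male", "female"],
    "employment": ["not_economically_active", "unemployed", "employed"],
    "race": ["black_african", "people_of_colour", "asian_indian", "white"],
    "education": ["none", "primary", "secondary", "tertiary"],
    "dwelling": ["formal", "traditional", "informal"],
    "electricity": ["no", "yes"],
    "piped_water": ["no", "yes"],
}

#: Default reference level per categorical covariate (regression baselines).
REFERENCE_LEVELS: dict[str, object] = {
    "sex": "male",
    "employment": "not_economically_active",
    "race": "black_african",
    "education": "none",
    "dwelling": "formal",
    "electricity": "no",
    "piped_water": "no",
    "ses_quintile": 1,
}

#: Canonical column names.
OUTCOME = "outcome_no_hunger"
WEIGHT = "weight"
MANDATORY = (OUTCOME, WEIGHT)


@dataclass
class SurveyTable:
    """One row per household/respondent plus load-time quality flags.

    ``data`` uses the canonical column names: ``outcome_no_hunger``,
    ``ses_score`` (optional), ``ses_quintile``, ``weight``, the covariates in
    :data:`CATEGORICAL_LEVELS` plus ``age``, ``household_size``, ``province``
    and ``wave_id``.  ``flagged`` marks rows whose categorical values fell
    outside the declared level sets (the value is set to missing).
    """

    data: pd.DataFrame
    flagged: pd.Series | None = None
    messages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = pd.Series(False, index=self.data.index)
        self.validate()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def validate(self) -> None:
        df = self.data
        for col in MANDATORY:
            if col not in df.columns:
                raise ValueError(f"mandatory column {col!r} is missing")
        w = pd.to_numeric(df[WEIGHT], errors="coerce")
        bad = df.index[~(w > 0)]
        if len(bad):
            raise ValueError(
                f"non-positive or missing weight in row(s) {list(bad[:5])}"
            )
        y = df[OUTCOME]
        ok = y.isna() | y.isin([0, 1])
        if not ok.all():
            raise ValueError("outcome_no_hunger must be 0, 1 or missing")
        if "ses_quintile" in df.columns:
            q = df["ses_quintile"].dropna()
            if not q.isin([1, 2, 3, 4, 5]).all():
                raise ValueError("ses_quintile must lie in 1..5")

    def copy(self) -> "SurveyTable":
        return SurveyTable(
            self.data.copy(), self.flagged.copy(), list(self.messages)
        )


@dataclass
class RankVector:
    """Weighted fractional ranks aligned to the rows of a SurveyTable.

    ``rank`` holds midpoint ranks in (0, 1) whose weighted mean is exactly
    0.5; rows tied on the ranking variable share the weight-averaged rank of
    their tie group (``tie_group`` is a per-row group id).
    """

    rank: np.ndarray
    tie_group: np.ndarray

    def __len__(self) -> int:
        return len(self.rank)


@dataclass
class PrevalenceEstimate:
    """Weighted prevalence for one group, on the percent scale."""

    group: object
    n: int
    proportion: float
    std_err: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def _coerce_frame(data) -> pd.DataFrame:
    return data.data if isinstance(data, SurveyTable) else data


def load_survey(path, schema: dict[str, str] | None = None) -> SurveyTable:
    """Read a survey CSV into a validated :class:`SurveyTable`.

    Parameters
    ----------
    path:
        CSV file with a header row; missing values coded as empty string,
        ``NA`` or ``-9``.
    schema:
        Optional map from canonical column names to the file's column names;
        identity by default.

    Rows with categorical values outside the declared level sets are flagged
    (value set to missing) and counted in ``messages``; a missing mandatory
    column or a non-positive weight is a hard error.
    """
    raw = pd.read_csv(path, na_values=MISSING_CODES, keep_default_na=False)
    if schema:
        missing = [src for src in schema.values() if src not in raw.columns]
        if missing:
            raise ValueError(f"mapped column(s) not found in file: {missing}")
        raw = raw.rename(columns={src: dst for dst, src in schema.items()})
    for col in MANDATORY:
        if col not in raw.columns:
            raise ValueError(f"mandatory column {col!r} is missing")

    w = pd.to_numeric(raw[WEIGHT], errors="coerce")
    bad = np.flatnonzero(~(w.to_numpy() > 0))
    if len(bad):
        raise ValueError(
            f"non-positive or missing weight in row {bad[0]}"
            + (f" (and {len(bad) - 1} more)" if len(bad) > 1 else "")
        )
    raw[WEIGHT] = w

    flagged = pd.Series(False, index=raw.index)
    messages: list[str] = []
    for col, levels in CATEGORICAL_LEVELS.items():
        if col not in raw.columns:
            continue
        vals = raw[col]
        out = vals.notna() & ~vals.isin(levels)
        if out.any():
            n_out = int(out.sum())
            messages.append(
                f"{n_out} row(s) with out-of-set level in {col!r} flagged"
            )
            warnings.warn(messages[-1])
            flagged |= out
            raw.loc[out, col] = np.nan
    for col in (OUTCOME, "ses_score", "ses_quintile", "age", "household_size"):
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    return SurveyTable(raw, flagged, messages)


def harmonize_no_hunger(raw, convention: str):
    """Recode a raw 7-day hunger item into the binary no-hunger outcome.

    ``nids_hunger``: raw 1 means someone went hungry, so no_hunger = 1 - raw.
    ``nfnss_reversed``: raw is already coded 1 = no hunger episode, returned
    unchanged.  Missing values propagate.
    """
    arr = np.asarray(pd.to_numeric(pd.Series(raw), errors="coerce"), dtype=float)
    valid = np.isnan(arr) | np.isin(arr, (0.0, 1.0))
    if not valid.all():
        raise ValueError("raw hunger indicator must be 0, 1 or missing")
    if convention == "nids_hunger":
        out = 1.0 - arr
    elif convention == "nfnss_reversed":
        out = arr.copy()
    else:
        raise ValueError(f"unknown harmonization convention {convention!r}")
    if isinstance(raw, pd.Series):
        return pd.Series(out, index=raw.index, name=OUTCOME)
    return out


def weighted_fractional_rank(ses, weight) -> RankVector:
    """Weighted fractional (midpoint) ranks of ``ses``.

    Rows are sorted by ``ses``; the untied rank of row *i* is
    ``(cum_weight_before_i + w_i/2) / W``.  Rows tied on ``ses`` all receive
    the weight-averaged rank of their tie group.  The weighted mean of the
    returned ranks is 0.5 to within floating error.
    """
    s = np.asarray(ses, dtype=float)
    w = np.asarray(weight, dtype=float)
    if s.shape != w.shape or s.ndim != 1:
        raise ValueError("ses and weight must be 1-d and aligned")
    if len(s) < 2:
        raise ValueError("need at least 2 rows to rank")
    if not np.all(w > 0):
        raise ValueError("weights must be positive")
    if np.isnan(s).any():
        raise ValueError("ses contains missing values")

    order = np.argsort(s, kind="mergesort")
    ws = w[order]
    W = ws.sum()
    mid = (np.cumsum(ws) - ws / 2.0) / W

    # tie groups by ses value
    uniq, inverse = np.unique(s, return_inverse=True)
    if len(uniq) == 1:
        warnings.warn("all ses values identical: single tie group, ranks 0.5")
    g_sorted = inverse[order]
    num = np.bincount(g_sorted, weights=ws * mid, minlength=len(uniq))
    den = np.bincount(g_sorted, weights=ws, minlength=len(uniq))
    group_rank = num / den
    return RankVector(rank=group_rank[inverse], tie_group=inverse)


def _weighted_quantile_cuts(s: np.ndarray, w: np.ndarray, probs) -> np.ndarray:
    """Lowest value whose cumulative weight share reaches each prob."""
    order = np.argsort(s, kind="mergesort")
    sv, wv = s[order], w[order]
    uniq, start = np.unique(sv, return_index=True)
    cum = np.cumsum(wv)
    # cumulative weight at the END of each distinct-value block
    end = np.r_[start[1:], len(sv)] - 1
    F = cum[end] / cum[-1]
    cuts = []
    for p in probs:
        idx = np.searchsorted(F, p - 1e-12, side="left")
        cuts.append(uniq[min(idx, len(uniq) - 1)])
    return np.asarray(cuts)


def weighted_quintiles(ses, weight):
    """Weighted SES quintiles 1..5 (1 = poorest).

    Cut points are the weighted 20/40/60/80th percentiles; a value equal to a
    cut point stays in the lower quintile, so a mass point spanning several
    cut points is assigned the lowest quintile it touches (with a warning).
    """
    s = np.asarray(ses, dtype=float)
    w = np.asarray(weight, dtype=float)
    if not np.all(w > 0):
        raise ValueError("weights must be positive")
    if len(np.unique(s)) < 5:
        warnings.warn(
            "fewer than 5 distinct ses values: quintiles will be unbalanced"
        )
    cuts = _weighted_quantile_cuts(s, w, (0.2, 0.4, 0.6, 0.8))
    q = 1 + (s[:, None] > cuts[None, :]).sum(axis=1)
    if len(np.unique(cuts)) < 4:
        warnings.warn(
            "a single ses value spans multiple quintile cut points; "
            "assigned to the lower quintile"
        )
    return q.astype(int)


def prevalence_table(data, by: str | None = None) -> list[PrevalenceEstimate]:
    """Weighted prevalence of the no-hunger outcome, optionally by group.

    Proportion is ``100 * sum(w*y) / sum(w)`` over rows with a non-missing
    outcome.  The standard error uses the weighted binomial variance with
    Kish effective sample size ``(sum w)^2 / sum(w^2)``; the 95% interval is
    computed on the logit scale and back-transformed so it stays in
    [0, 100].  Groups whose outcome is entirely missing are omitted with a
    warning; a group at 0% or 100% gets a degenerate interval and is flagged.
    """
    df = _coerce_frame(data)
    sub = df[df[OUTCOME].notna()]
    if by is None:
        groups = [("all", sub)]
    else:
        omitted = set(df[by].dropna().unique()) - set(sub[by].dropna().unique())
        for g in sorted(omitted, key=str):
            warnings.warn(f"group {g!r} omitted: outcome entirely missing")
        groups = sorted(sub.groupby(by, observed=True), key=lambda kv: str(kv[0]))

    out: list[PrevalenceEstimate] = []
    z = 1.959963984540054
    for name, g in groups:
        if len(g) == 0:
            continue
        y = g[OUTCOME].to_numpy(dtype=float)
        w = g[WEIGHT].to_numpy(dtype=float)
        p = float(np.sum(w * y) / np.sum(w))
        n_eff = float(np.sum(w) ** 2 / np.sum(w**2))
        if p <= 0.0 or p >= 1.0:
            out.append(
                PrevalenceEstimate(
                    group=name, n=len(g), proportion=100 * p, std_err=0.0,
                    ci_low=100 * p, ci_high=100 * p, degenerate=True,
                )
            )
            warnings.warn(f"group {name!r}: proportion at boundary, degenerate CI")
            continue
        se_p = np.sqrt(p * (1 - p) / n_eff)
        se_l = se_p / (p * (1 - p))
        lo = float(expit(logit(p) - z * se_l))
        hi = float(expit(logit(p) + z * se_l))
        out.append(
            PrevalenceEstimate(
                group=name, n=len(g), proportion=100 * p,
                std_err=float(se_p), ci_low=100 * lo, ci_high=100 * hi,
            )
        )
    return out


def prevalence_to_frame(estimates: list[PrevalenceEstimate]) -> pd.DataFrame:
    """Serialize prevalence estimates as a tidy frame (CSV-ready)."""
    return pd.DataFrame(
        {
            "group": [e.group for e in estimates],
            "n": [e.n for e in estimates],
            "proportion": [e.proportion for e in estimates],
            "std_err": [e.std_err for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
        }
    )
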