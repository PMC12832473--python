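"""Rank-dependent socio-economic inequality indices.

Three functionals of a health variable ``h`` and weighted fractional ranks
``r`` of the socio-economic distribution:

* standard concentration index  ``C = 2 cov_w(h, r) / mu``,
* Erreygers bounded-variable correction ``E = 4 mu C / (b - a)``
  (for a binary outcome ``E = 8 cov_w(h, r)`` and lies in [-1, 1]),
* Wagstaff normalization ``W = C mu (b - a) / ((b - mu)(mu - a))``
  (binary: ``W = C / (1 - mu)``).

Positive values mean the (desirable) outcome is concentrated among the
higher-ranked (richer) units.  Standard errors come from the "convenient
regression" whose slope reproduces the index, with a heteroskedasticity-
robust slope variance, or from a seeded household bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .survey_core import RankVector, weighted_fractional_rank

__all__ = [
    "IndexEstimate",
    "weighted_cov",
    "standard_ci",
    "erreygers_index",
    "wagstaff_index",
    "index_se",
    "interpret_index",
]


@dataclass
class IndexEstimate:
    index_type: str  # "standard" | "erreygers" | "wagstaff"
    value: float
    std_err: float | None
    p_value: float | None
    mean_outcome: float
    n: int
    bounds: tuple[float, float] | None = None


def _as_rank(ranks) -> np.ndarray:
    if isinstance(ranks, RankVector):
        return ranks.rank
    return np.asarray(ranks, dtype=float)


def weighted_cov(a, b, w) -> float:
    """Population-style weighted covariance sum(w (a-am)(b-bm)) / sum(w)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w = np.asarray(w, dtype=float)
    W = w.sum()
    am = np.sum(w * a) / W
    bm = np.sum(w * b) / W
    return float(np.sum(w * (a - am) * (b - bm)) / W)


def standard_ci(h, ranks, weight) -> IndexEstimate:
    """Standard concentration index ``C = 2 cov_w(h, r) / mu``."""
    h = np.asarray(h, dtype=float)
    r = _as_rank(ranks)
    w = np.asarray(weight, dtype=float)
    W = w.sum()
    mu = float(np.sum(w * h) / W)
    if abs(mu) < 1e-300:
        raise ValueError("mean outcome is zero: standard index undefined")
    C = 2.0 * weighted_cov(h, r, w) / mu
    return IndexEstimate(
        index_type="standard", value=C, std_err=None, p_value=None,
        mean_outcome=mu, n=len(h),
    )


def _check_bounds(h: np.ndarray, bounds) -> tuple[float, float]:
    a, b = float(bounds[0]), float(bounds[1])
    if not a < b:
        raise ValueError("bounds must satisfy a < b")
    if h.min() < a or h.max() > b:
        raise ValueError("outcome values fall outside the stated bounds")
    return a, b


def erreygers_index(h, ranks, weight, bounds=(0.0, 1.0)) -> IndexEstimate:
    """Erreygers index ``E = 4 mu C / (b - a) = 8 cov_w(h, r) / (b - a)``."""
    h = np.asarray(h, dtype=float)
    r = _as_rank(ranks)
    w = np.asarray(weight, dtype=float)
    a, b = _check_bounds(h, bounds)
    mu = float(np.sum(w * h) / w.sum())
    E = 8.0 * weighted_cov(h, r, w) / (b - a)
    return IndexEstimate(
        index_type="erreygers", value=E, std_err=None, p_value=None,
        mean_outcome=mu, n=len(h), bounds=(a, b),
    )


def wagstaff_index(h, ranks, weight, bounds=(0.0, 1.0)) -> IndexEstimate:
    """Wagstaff index ``W = C mu (b - a) / ((b - mu)(mu - a))``."""
    h = np.asarray(h, dtype=float)
    r = _as_rank(ranks)
    w = np.asarray(weight, dtype=float)
    a, b = _check_bounds(h, bounds)
    mu = float(np.sum(w * h) / w.sum())
    if not (a < mu < b):
        raise ValueError("mean outcome at a bound: Wagstaff index undefined")
    C = 2.0 * weighted_cov(h, r, w) / mu
    Wv = C * mu * (b - a) / ((b - mu) * (mu - a))
    return IndexEstimate(
        index_type="wagstaff", value=Wv, std_err=None, p_value=None,
        mean_outcome=mu, n=len(h), bounds=(a, b),
    )


_POINT = {
    "standard": standard_ci,
    "erreygers": erreygers_index,
    "wagstaff": wagstaff_index,
}


def _convenient_regression_se(h, r, w, index_type, bounds) -> float:
    """Robust SE of the WLS slope that reproduces the index.

    The outcome transform is ``2 sigma_r^2 h / mu`` for the standard index
    and ``8 sigma_r^2 h / (b - a)`` for Erreygers; the Wagstaff SE rescales
    the standard one by its mu-dependent factor (mu treated as fixed).
    """
    W = w.sum()
    rm = np.sum(w * r) / W
    var_r = np.sum(w * (r - rm) ** 2) / W
    mu = np.sum(w * h) / W
    a, b = float(bounds[0]), float(bounds[1])
    if index_type == "erreygers":
        t = 8.0 * var_r * h / (b - a)
        scale = 1.0
    else:
        t = 2.0 * var_r * h / mu
        scale = 1.0
        if index_type == "wagstaff":
            scale = mu * (b - a) / ((b - mu) * (mu - a))
    X = np.column_stack([np.ones_like(r), r])
    A = X.T @ (X * w[:, None])
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (X.T @ (w * t))
    resid = t - X @ beta
    S = X * (w * resid)[:, None]
    V = Ainv @ (S.T @ S) @ Ainv
    return float(scale * np.sqrt(V[1, 1]))


def index_se(
    h,
    ranks,
    weight,
    index_type: str = "erreygers",
    method: str = "convenient_regression",
    bounds=(0.0, 1.0),
    n_boot: int = 1000,
    seed: int | None = None,
) -> IndexEstimate:
    """Index point estimate with a standard error and two-sided p-value.

    ``convenient_regression`` (default) uses the robust slope SE of the
    transformed-outcome regression on rank; ``bootstrap`` resamples
    households with replacement (re-ranking each resample), B = ``n_boot``,
    seeded.  The p-value is two-sided normal on value / SE.
    """
    h = np.asarray(h, dtype=float)
    r = _as_rank(ranks)
    w = np.asarray(weight, dtype=float)
    if len(h) < 10:
        raise ValueError("need at least 10 observations for a standard error")
    if index_type not in _POINT:
        raise ValueError(f"unknown index type {index_type!r}")
    est = _POINT[index_type](h, r, w, bounds) if index_type != "standard" \
        else standard_ci(h, r, w)

    if method == "convenient_regression":
        se = _convenient_regression_se(h, r, w, index_type, bounds)
    elif method == "bootstrap":
        if n_boot < 100:
            warnings.warn("bootstrap with fewer than 100 replicates")
        rng = np.random.default_rng(seed)
        n = len(h)
        vals = np.empty(n_boot)
        for bidx in range(n_boot):
            take = rng.integers(0, n, size=n)
            rb = weighted_fractional_rank(r[take], w[take]).rank
            if index_type == "standard":
                vals[bidx] = standard_ci(h[take], rb, w[take]).value
            else:
                vals[bidx] = _POINT[index_type](h[take], rb, w[take], bounds).value
        se = float(np.std(vals, ddof=1))
    else:
        raise ValueError(f"unknown SE method {method!r}")

    p = float(2 * norm.sf(abs(est.value) / se)) if se > 0 else 0.0
    est.std_err = se
    est.p_value = p
    return est


def interpret_index(e) -> str:
    """Human-readable label: direction of inequality plus magnitude in %."""
    value = float(getattr(e, "value", e))
    if value > 0:
        return f"Pro-rich inequality ({abs(value) * 100:.1f}%)"
    if value < 0:
        return f"Pro-poor inequality ({abs(value) * 100:.1f}%)"
    return "No socio-economic inequality (0.0%)"
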