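"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's computational paths: the
concentration index comes from the trapezoid area under the concentration
curve, quantile cuts from an O(n) cumulative-sum scan, and the AUC from
exhaustive pair counting.
"""

import numpy as np


def concentration_index_trapezoid(h, ses, w) -> float:
    """Standard concentration index as 1 - 2 * area under the curve.

    Points of the concentration curve are (cumulative weight share,
    cumulative outcome share) ordered by ses; tied ses values are merged
    into one step.  Equivalent to the trapezoid rule 1 - sum f_i (L_i +
    L_{i-1}).
    """
    h = np.asarray(h, float)
    ses = np.asarray(ses, float)
    w = np.asarray(w, float)
    order = np.argsort(ses, kind="mergesort")
    sv, hv, wv = ses[order], h[order], w[order]
    # merge tied ses values into single steps
    uniq, idx = np.unique(sv, return_inverse=True)
    wsum = np.bincount(idx, weights=wv)
    hsum = np.bincount(idx, weights=wv * hv)
    f = wsum / wsum.sum()
    L = np.cumsum(hsum) / hsum.sum()
    L_prev = np.r_[0.0, L[:-1]]
    return float(1.0 - np.sum(f * (L + L_prev)))


def weighted_quantile_scan(ses, w, p) -> float:
    """Lowest ses value whose cumulative weight share reaches p (O(n) scan)."""
    order = np.argsort(ses, kind="mergesort")
    sv = np.asarray(ses, float)[order]
    wv = np.asarray(w, float)[order]
    W = wv.sum()
    acc = 0.0
    i = 0
    while i < len(sv):
        j = i
        while j < len(sv) and sv[j] == sv[i]:
            acc += wv[j]
            j += 1
        if acc / W >= p - 1e-12:
            return float(sv[i])
        i = j
    return float(sv[-1])


def quintiles_bruteforce(ses, w) -> np.ndarray:
    """Quintiles via the scan oracle: count cut values strictly below ses."""
    cuts = [weighted_quantile_scan(ses, w, p) for p in (0.2, 0.4, 0.6, 0.8)]
    s = np.asarray(ses, float)
    return 1 + np.sum(s[:, None] > np.asarray(cuts)[None, :], axis=1)


def auc_all_pairs(scores, y, w) -> float:
    """Weighted AUC by exhaustive positive/negative pair enumeration."""
    s = np.asarray(scores, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    num = 0.0
    den = 0.0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            pair = w[i] * w[j]
            den += pair
            if s[i] > s[j]:
                num += pair
            elif s[i] == s[j]:
                num += 0.5 * pair
    return num / den
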