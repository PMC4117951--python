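"""Independent brute-force oracles used to cross-check the implementation.

Each function here is deliberately naive — direct enumeration or textbook
formulas — and shares no code with the package paths it validates.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def bh_qvalues_bruteforce(p_values) -> np.ndarray:
    """BH step-up by explicit sort / scale / cumulative-min from the top rank."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        running = min(running, ranked[i] * n / (i + 1))
        q[i] = running
    out = np.empty(n)
    out[order] = q
    return out


def posterior_probability_enumeration(k: int, n: int, p0: float, p1: float, prior: float) -> float:
    """Bayes' rule on the two-state model via direct binomial pmf evaluation."""
    like_m = stats.binom.pmf(k, n, p1)
    like_nm = stats.binom.pmf(k, n, p0)
    num = prior * like_m
    den = num + (1.0 - prior) * like_nm
    return num / den


def auc_trapezoid(scores, truth) -> float:
    """Trapezoidal integration of the tie-aware ROC curve."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    thresholds = np.unique(scores)[::-1]
    n_pos = truth.sum()
    n_neg = (~truth).sum()
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = scores >= t
        tpr.append(np.sum(pred & truth) / n_pos)
        fpr.append(np.sum(pred & ~truth) / n_neg)
    return float(np.trapezoid(tpr, fpr))
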