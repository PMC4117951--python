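"""Binomial baseline caller with FDR correction.

The widely used baseline tests, per covered site, the null hypothesis "this
cytosine is not methylated": the number of C reads ``k`` out of ``n`` is
compared to Binomial(n, p0) where ``p0`` is the non-conversion rate, with
p = P(X >= k) as the upper-tail p-value.  P-values are corrected across all
covered sites by the Benjamini-Hochberg step-up procedure, and sites with
q < alpha are called methylated.

Because p-values are bounded below by ``p0^n``, low-coverage sites in
sparsely methylated genomes can never reach significance after FDR
correction: a site covered by a single C read is only callable when the
genome-wide fraction of significant sites exceeds ``p0 / alpha`` (4% at the
usual p0 = 0.002, alpha = 0.05).  :func:`min_calling_percentile` quantifies
this power pathology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CALL_METHYLATED, CALL_NO_DATA, CALL_UNMETHYLATED

__all__ = [
    "BinomialResult",
    "binomial_pvalue",
    "bh_qvalues",
    "binomial_test",
    "binomial_classify",
    "min_calling_percentile",
]


def binomial_pvalue(k, n, p0):
    """Upper-tail binomial p-value P(X >= k) for X ~ Binomial(n, p0).

    Sites with ``n == 0`` have no test and return NaN (distinct from p = 1,
    which is the legitimate p-value of a covered site with k = 0).
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie strictly inside (0, 1), got {p0}")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    with np.errstate(invalid="ignore"):
        p = stats.binom.sf(k - 1, n, p0)
    p = np.where(n >= 1, p, np.nan)
    if p.ndim == 0:
        return float(p)
    return p


def bh_qvalues(p_values):
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * N / j`` capped at 1, with ties sharing the
    standard min-rank convention.  An empty input yields an empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite and lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class BinomialResult:
    """Per-site binomial test results over the covered sites of one family."""

    p_values: np.ndarray
    q_values: np.ndarray
    alpha: float = 0.05

    @property
    def methylated(self) -> np.ndarray:
        return self.q_values < self.alpha


def binomial_test(k, n, p0, alpha: float = 0.05) -> BinomialResult:
    """Run the binomial test plus BH correction on covered-site count arrays."""
    p = np.atleast_1d(binomial_pvalue(k, n, p0))
    if np.any(np.isnan(p)):
        raise ValueError("binomial_test requires n >= 1 everywhere; filter uncovered sites")
    return BinomialResult(p_values=p, q_values=bh_qvalues(p), alpha=alpha)


def binomial_classify(sites: pd.DataFrame, p0: float, alpha: float = 0.05) -> pd.DataFrame:
    """Classify a count table with the binomial method.

    ``sites`` is a frame with ``n_meth``/``n_total`` columns.  Sites with no
    reads are excluded from the FDR family and called ``no_data``; the output
    is row-aligned with the input and adds ``p_value``, ``q_value`` and
    ``call`` columns.
    """
    out = sites.copy()
    n = out["n_total"].to_numpy()
    k = out["n_meth"].to_numpy()
    covered = n > 0
    p_value = np.full(len(out), np.nan)
    q_value = np.full(len(out), np.nan)
    call = np.full(len(out), CALL_NO_DATA, dtype=object)
    if covered.any():
        res = binomial_test(k[covered], n[covered], p0, alpha=alpha)
        p_value[covered] = res.p_values
        q_value[covered] = res.q_values
        call[covered] = np.where(res.methylated, CALL_METHYLATED, CALL_UNMETHYLATED)
    out["p_value"] = p_value
    out["q_value"] = q_value
    out["call"] = call
    return out


def min_calling_percentile(k, n, p0, alpha: float = 0.05):
    """Smallest p-value percentile at which BH can call this site methylated.

    Under BH, a site with p-value ``p`` and rank ``r`` among ``N`` tests is
    significant when ``p * N / r <= alpha``; the most favourable case is when
    a fraction ``r / N`` of the genome has smaller p-values, so the site
    becomes callable once that fraction reaches ``p / alpha``.  Because the
    p-value percentile tracks the genome-wide methylation level, the returned
    fraction is the minimum genome methylation level at which the site can be
    called; values above 1 mean the site can never be called.
    """
    return binomial_pvalue(k, n, p0) / alpha
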