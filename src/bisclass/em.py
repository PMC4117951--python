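"""EM estimation of conversion error rates and the global methylation level.

The count data are modelled as a two-component binomial mixture: each
covered site is methylated with probability ``pi`` and its C-read count is
Binomial(n, p1) if methylated, Binomial(n, p0) otherwise.  Expectation-
Maximization on this mixture yields maximum-likelihood estimates of the
non-conversion rate ``p0``, the retention rate ``p1`` and the global
methylation level ``pi`` directly from the data, without spike-in controls.

E-step (responsibility of the methylated component for site i):

    gamma_i = pi * B(k_i; n_i, p1) / [pi * B(k_i; n_i, p1) + (1 - pi) * B(k_i; n_i, p0)]

M-step:

    pi = mean(gamma),  p1 = sum(gamma * k) / sum(gamma * n),
    p0 = sum((1 - gamma) * k) / sum((1 - gamma) * n)

A moment-based alternative for the global level alone inverts
``E[F] = pi * p1 + (1 - pi) * p0`` given known error rates
(:func:`estimate_global_level`); on model-generated data the two estimators
agree to Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EMResult", "em_fit", "estimate_global_level"]

_PROB_EPS = 1e-12


def _counts(sites) -> tuple[np.ndarray, np.ndarray]:
    """Extract (n_meth, n_total) arrays from a frame or an array pair."""
    if isinstance(sites, pd.DataFrame):
        return sites["n_meth"].to_numpy(), sites["n_total"].to_numpy()
    k, n = sites
    return np.asarray(k), np.asarray(n)


@dataclass
class EMResult:
    """Fitted two-component binomial mixture."""

    p0: float
    p1: float
    pi: float
    responsibilities: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool

    def summary(self) -> dict:
        return {
            "p0": self.p0,
            "p1": self.p1,
            "pi": self.pi,
            "loglik": float(self.loglik_trace[-1]) if len(self.loglik_trace) else float("nan"),
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def em_fit(
    sites,
    init: tuple[float, float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> EMResult:
    """Fit (p0, p1, pi) by EM on the two-component binomial mixture.

    Parameters
    ----------
    sites
        Count table (frame with ``n_meth``/``n_total``) or an ``(k, n)``
        array pair.  Sites with no reads are excluded from the fit.
    init
        Optional ``(p0, p1, pi)`` starting point with ``p0 < p1``.  The
        default (p0 = 0.005, p1 = 0.5, pi = overall C-read fraction) sits
        well inside the basin of attraction for sparse methylomes.
    tol
        Convergence threshold on the absolute log-likelihood change.
    max_iter
        Iteration cap; hitting it leaves ``converged = False``.

    Returns
    -------
    EMResult
        Estimates with per-site responsibilities (NaN for uncovered sites)
        and the log-likelihood trace, which is non-decreasing by EM
        monotonicity.  Component labels are swapped on exit if needed so
        that ``p0 < p1`` always holds.
    """
    k_all, n_all = _counts(sites)
    covered = n_all > 0
    k = k_all[covered].astype(float)
    n = n_all[covered].astype(float)
    if k.size == 0:
        raise ValueError("em_fit requires at least one site with n_total >= 1")

    f_tot = k.sum() / n.sum()
    if init is None:
        init = (0.005, 0.5, float(np.clip(f_tot, 1e-4, 0.5)))
    p0, p1, pi = init
    if not 0.0 <= p0 < p1 <= 1.0:
        raise ValueError(f"init must satisfy p0 < p1, got {init}")
    if not 0.0 < pi < 1.0:
        raise ValueError(f"init pi must lie in (0, 1), got {pi}")

    def _expand(resp_covered: np.ndarray) -> np.ndarray:
        full = np.full(len(k_all), np.nan)
        full[covered] = resp_covered
        return full

    if k.sum() == 0:
        # No methylation signal at all: p1 is unidentifiable.
        return EMResult(
            p0=0.0,
            p1=p1,
            pi=_PROB_EPS,
            responsibilities=_expand(np.zeros_like(k)),
            loglik_trace=np.empty(0),
            n_iter=0,
            converged=False,
        )

    # Collapse to unique (k, n) pairs; the likelihood only depends on counts.
    pairs, inverse, weights = np.unique(
        np.column_stack([k, n]), axis=0, return_inverse=True, return_counts=True
    )
    ku, nu = pairs[:, 0], pairs[:, 1]
    w = weights.astype(float)

    trace: list[float] = []
    gamma_u = np.full(ku.shape, np.nan)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p0c = float(np.clip(p0, _PROB_EPS, 1 - _PROB_EPS))
        p1c = float(np.clip(p1, _PROB_EPS, 1 - _PROB_EPS))
        log_m = np.log(pi) + stats.binom.logpmf(ku, nu, p1c)
        log_nm = np.log1p(-pi) + stats.binom.logpmf(ku, nu, p0c)
        log_norm = np.logaddexp(log_m, log_nm)
        loglik = float(np.sum(w * log_norm))
        if not np.isfinite(loglik):
            raise FloatingPointError("non-finite likelihood in EM")
        trace.append(loglik)
        gamma_u = np.exp(log_m - log_norm)

        pi = float(np.sum(w * gamma_u) / np.sum(w))
        denom1 = np.sum(w * gamma_u * nu)
        denom0 = np.sum(w * (1.0 - gamma_u) * nu)
        if denom1 > 0:
            p1 = float(np.sum(w * gamma_u * ku) / denom1)
        if denom0 > 0:
            p0 = float(np.sum(w * (1.0 - gamma_u) * ku) / denom0)
        pi = float(np.clip(pi, _PROB_EPS, 1 - _PROB_EPS))

        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    if p0 > p1:  # label swap to restore identifiability convention
        p0, p1 = p1, p0
        pi = 1.0 - pi
        gamma_u = 1.0 - gamma_u

    return EMResult(
        p0=p0,
        p1=p1,
        pi=pi,
        responsibilities=_expand(gamma_u[inverse]),
        loglik_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
    )


def estimate_global_level(sites, p0: float, p1: float, floor: float = 1e-6) -> float:
    """Moment estimate of the global methylation level given error rates.

    The pooled C-read fraction has expectation ``pi * p1 + (1 - pi) * p0``;
    inverting gives ``pi = (F_tot - p0) / (p1 - p0)``, clipped into
    ``[floor, 1 - floor]``.  This generalizes the raw fractional methylation
    level, which it equals when p0 = 0, p1 = 1; with ``p1 < 1`` and
    ``p0 > 0`` the corrected level sits below the raw fraction for sparse
    methylomes.
    """
    if p1 <= p0:
        raise ValueError(f"require p0 < p1, got p0={p0}, p1={p1}")
    k, n = _counts(sites)
    total = n.sum()
    if total <= 0:
        raise ValueError("estimate_global_level requires at least one read")
    f_tot = k.sum() / total
    return float(np.clip((f_tot - p0) / (p1 - p0), floor, 1.0 - floor))
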