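"""Core probability model for binary methylation calling.

Bisulfite sequencing reduces each cytosine to a pair of counts: ``n_meth``
reads that retained a C (the methylation signal) out of ``n_total`` reads
covering the site.  Because bisulfite conversion is imperfect, a
non-methylated cytosine still yields a C read with probability ``p0`` (the
non-conversion rate), while a methylated cytosine yields a C read only with
probability ``p1`` (one minus the over-conversion rate).  Under this
two-state model the read counts at a site are binomial with success rate
``p0`` or ``p1`` depending on the latent methylation status, and the
posterior odds of methylation are

    odds = [pi / (1 - pi)] * [p1^k (1-p1)^(n-k)] / [p0^k (1-p0)^(n-k)]

for a prior methylation probability ``pi``.  A site is called methylated
when the odds reach a cutoff; a cutoff of 19 bounds the posterior
probability of a false methylated call by 0.05.

All numerical routines here accept scalars or numpy arrays and do the
likelihood arithmetic in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CALL_METHYLATED",
    "CALL_UNMETHYLATED",
    "CALL_NO_DATA",
    "DEFAULT_ODDS_CUTOFF",
    "MethSite",
    "ErrorModel",
    "SiteCall",
    "effective_error_rates",
    "site_log_likelihood",
    "log_likelihood_ratio",
    "posterior_odds",
    "posterior_probability",
    "classify_site",
    "cutoff_for_posterior_error",
]

CALL_METHYLATED = "methylated"
CALL_UNMETHYLATED = "unmethylated"
CALL_NO_DATA = "no_data"

#: Posterior odds at which the probability of a false methylated call is 0.05.
DEFAULT_ODDS_CUTOFF = 19.0

#: Column order of the canonical per-cytosine count table.
COUNT_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]


def effective_error_rates(p0: float, p1: float, eps: float = 0.0) -> tuple[float, float]:
    """Fold a symmetric per-read sequencing error ``eps`` into the conversion rates.

    A C read is observed either because the underlying base signal was C and
    was read correctly, or because it was T and was misread:

        p_eff = p * (1 - eps) + (1 - p) * eps

    With ``eps < 0.5`` the ordering ``p0_eff < p1_eff`` is preserved, so the
    effective rates can simply replace ``p0``/``p1`` everywhere downstream.
    """
    if not 0.0 <= p0 < p1 <= 1.0:
        raise ValueError(f"require 0 <= p0 < p1 <= 1, got p0={p0}, p1={p1}")
    if not 0.0 <= eps < 0.5:
        raise ValueError(f"sequencing error must satisfy 0 <= eps < 0.5, got {eps}")
    p0_eff = p0 * (1.0 - eps) + (1.0 - p0) * eps
    p1_eff = p1 * (1.0 - eps) + (1.0 - p1) * eps
    return p0_eff, p1_eff


@dataclass(frozen=True)
class ErrorModel:
    """Conversion/sequencing error rates of a bisulfite experiment.

    Parameters
    ----------
    p0
        Non-conversion rate: probability that a non-methylated C survives
        conversion and is read as C.
    p1
        Retention rate: probability that a methylated C is read as C
        (one minus the over-conversion rate).
    eps
        Per-read sequencing miscall probability.  In practice sequencing
        errors are confounded with ``p0``/``p1`` when the rates are estimated
        from data, so the default is 0 and ``eps`` matters only for forward
        simulation.
    """

    p0: float
    p1: float
    eps: float = 0.0

    def __post_init__(self) -> None:
        effective_error_rates(self.p0, self.p1, self.eps)  # validates

    @property
    def p0_eff(self) -> float:
        return effective_error_rates(self.p0, self.p1, self.eps)[0]

    @property
    def p1_eff(self) -> float:
        return effective_error_rates(self.p0, self.p1, self.eps)[1]


@dataclass(frozen=True)
class MethSite:
    """A single cytosine with its mapped read counts."""

    chrom: str
    pos: int
    strand: str = "."
    context: str = "CpG"
    n_meth: int = 0
    n_total: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.n_total < 0 or not 0 <= self.n_meth <= self.n_total:
            raise ValueError(
                f"require 0 <= n_meth <= n_total, got ({self.n_meth}, {self.n_total})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    @property
    def fraction(self) -> float:
        """Fractional methylation ``n_meth / n_total`` (NaN when uncovered)."""
        if self.n_total == 0:
            return float("nan")
        return self.n_meth / self.n_total


@dataclass(frozen=True)
class SiteCall:
    """Per-site classification result."""

    site: MethSite
    call: str
    odds: float = float("nan")
    prior_used: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")


def site_log_likelihood(k, n, rate):
    """Log-likelihood of ``k`` C reads out of ``n`` under C-read probability ``rate``.

    Returns ``k*log(rate) + (n-k)*log(1-rate)``, the binomial kernel without
    the combinatorial constant (the constant cancels in any odds ratio).
    Degenerate rates 0 and 1 yield ``-inf`` when the counts are incompatible
    and 0 otherwise, by the usual ``0*log(0) = 0`` convention.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    if np.any(rate < 0) or np.any(rate > 1):
        raise ValueError("rate must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        term_c = np.where(k > 0, k * np.log(rate), 0.0)
        term_t = np.where(n - k > 0, (n - k) * np.log1p(-rate), 0.0)
    out = term_c + term_t
    if out.ndim == 0:
        return float(out)
    return out


def log_likelihood_ratio(k, n, p0_eff, p1_eff):
    """Log of P(counts | methylated) / P(counts | non-methylated)."""
    return site_log_likelihood(k, n, p1_eff) - site_log_likelihood(k, n, p0_eff)


def posterior_odds(k, n, p0_eff, p1_eff, prior):
    """Posterior odds of methylation given ``k`` C reads out of ``n``.

    ``prior`` is the prior probability that the site is methylated, strictly
    inside (0, 1).  Computed in log space; a site with no reads returns the
    bare prior odds ``prior / (1 - prior)``.
    """
    prior = np.asarray(prior, dtype=float)
    if np.any(prior <= 0.0) or np.any(prior >= 1.0):
        raise ValueError("prior must lie strictly inside (0, 1)")
    log_prior_odds = np.log(prior) - np.log1p(-prior)
    log_odds = log_prior_odds + log_likelihood_ratio(k, n, p0_eff, p1_eff)
    with np.errstate(over="ignore"):
        odds = np.exp(log_odds)
    if np.ndim(odds) == 0:
        return float(odds)
    return odds


def posterior_probability(odds):
    """Posterior methylation probability ``odds / (1 + odds)`` (1 for infinite odds)."""
    odds = np.asarray(odds, dtype=float)
    with np.errstate(invalid="ignore"):
        prob = np.where(np.isinf(odds), 1.0, odds / (1.0 + odds))
    if prob.ndim == 0:
        return float(prob)
    return prob


def classify_site(odds, cutoff: float = DEFAULT_ODDS_CUTOFF):
    """Binary call from posterior odds: methylated iff ``odds >= cutoff``.

    A tie at the cutoff is called methylated.  The default cutoff of 19
    corresponds to a posterior methylation probability of 0.95.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    odds = np.asarray(odds, dtype=float)
    if np.any(odds < 0):
        raise ValueError("odds must be non-negative")
    call = np.where(odds >= cutoff, CALL_METHYLATED, CALL_UNMETHYLATED)
    if call.ndim == 0:
        return str(call)
    return call


def cutoff_for_posterior_error(max_error: float = 0.05) -> float:
    """Smallest odds cutoff bounding the false-methylated posterior probability.

    At posterior odds ``o`` the probability that the site is actually
    non-methylated is ``1 / (1 + o)``; requiring this to be at most
    ``max_error`` gives ``o >= (1 - max_error) / max_error`` — 19 for the
    conventional 0.05 bound.
    """
    if not 0.0 < max_error < 1.0:
        raise ValueError(f"max_error must lie in (0, 1), got {max_error}")
    return (1.0 - max_error) / max_error
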