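"""Spatial autocorrelation of methylation levels and bandwidth selection.

Methylation levels of nearby cytosines co-vary; the decay of the pairwise
Pearson correlation of fractional methylation with genomic distance both
justifies the use of a local prior and fixes its kernel bandwidth.  The
bandwidth rule picks the distance at which the correlation first drops
(and stays) below a threshold, 0.2 by convention — about 1.5 kb in
honey-bee methylomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CorrelationCurve", "correlation_curve", "select_bandwidth"]


@dataclass
class CorrelationCurve:
    """Binned distance-vs-correlation curve.

    ``correlations`` holds NaN for bins with fewer than two pairs or with
    degenerate (zero-variance) methylation values.
    """

    bin_edges: np.ndarray
    correlations: np.ndarray
    n_pairs: np.ndarray
    min_coverage: int

    @property
    def bin_mids(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_mid": self.bin_mids, "correlation": self.correlations, "n_pairs": self.n_pairs}
        )


def correlation_curve(
    sites: pd.DataFrame,
    max_dist: float = 5000,
    bin_width: float = 50,
    min_coverage: int = 4,
) -> CorrelationCurve:
    """Pearson correlation of fractional methylation versus pair distance.

    All same-chromosome pairs of sites with coverage at least
    ``min_coverage`` and separation at most ``max_dist`` contribute, binned
    by distance.  The coverage filter stabilizes the per-site fraction F;
    pair moments are accumulated per bin so memory stays linear in the
    number of sites.
    """
    if max_dist <= 0 or bin_width <= 0:
        raise ValueError("max_dist and bin_width must be positive")
    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    # Accumulated pair moments per bin: n, sum x, sum y, sum xy, sum x^2, sum y^2.
    moments = np.zeros((6, n_bins))

    for _, grp in sites.groupby("chrom", sort=False):
        n_tot = grp["n_total"].to_numpy()
        keep = n_tot >= min_coverage
        if keep.sum() < 2:
            continue
        pos = grp["pos"].to_numpy().astype(float)[keep]
        if np.any(np.diff(pos) < 0):
            raise ValueError("sites must be sorted by (chrom, pos)")
        f = (grp["n_meth"].to_numpy()[keep] / n_tot[keep]).astype(float)
        m = len(pos)
        for lag in range(1, m):
            d = pos[lag:] - pos[:-lag]
            within = d <= max_dist
            if not within.any():
                break
            b = np.minimum((d[within] / bin_width).astype(int), n_bins - 1)
            x = f[: m - lag][within]
            y = f[lag:][within]
            moments[0] += np.bincount(b, minlength=n_bins)
            moments[1] += np.bincount(b, weights=x, minlength=n_bins)
            moments[2] += np.bincount(b, weights=y, minlength=n_bins)
            moments[3] += np.bincount(b, weights=x * y, minlength=n_bins)
            moments[4] += np.bincount(b, weights=x * x, minlength=n_bins)
            moments[5] += np.bincount(b, weights=y * y, minlength=n_bins)

    n, sx, sy, sxy, sxx, syy = moments
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        corr = cov / np.sqrt(varx * vary)
    corr[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    return CorrelationCurve(
        bin_edges=edges,
        correlations=corr,
        n_pairs=n.astype(np.int64),
        min_coverage=min_coverage,
    )


def select_bandwidth(curve: CorrelationCurve, threshold: float = 0.2) -> float:
    """Kernel bandwidth from the correlation decay.

    Returns the smallest bin midpoint at which the correlation first drops
    below ``threshold`` and stays below it in the following bin (bins with
    no estimate are skipped).  If the curve never crosses, the largest bin
    edge is returned with a warning.
    """
    valid = ~np.isnan(curve.correlations)
    if not valid.any():
        raise ValueError("correlation curve has no estimated bins")
    mids = curve.bin_mids[valid]
    corr = curve.correlations[valid]
    below = corr < threshold
    for i in range(len(corr)):
        if below[i] and (i + 1 >= len(corr) or below[i + 1]):
            return float(mids[i])
    warnings.warn(
        f"spatial correlation never drops below {threshold}; "
        "returning the maximum distance examined",
        stacklevel=2,
    )
    return float(curve.bin_edges[-1])
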