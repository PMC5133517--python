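"""Marker-by-marker Haseman-Elston-type regression of trait similarity on IBD sharing.

At each marker, two simple linear regressions are run across all unordered
pairs of individuals: the squared residual difference D on the binary sharing
indicator pi, and the squared residual sum S on pi.  With a binary predictor
each slope is the difference of group means,

    beta_D = mean(D | pi=1) - mean(D | pi=0),   beta_S likewise,

and the residual error variances sigma2_D, sigma2_S are RSS/(n_pairs - 2).
The two slopes are pooled by inverse-variance weighting,

    beta_hat = [sigma2_D / (sigma2_S + sigma2_D)] * beta_S
             + [sigma2_S / (sigma2_S + sigma2_D)] * beta_D,

with standard error

    SE(beta_hat) = sqrt( 1 / ( [1/sigma2_D + 1/sigma2_S] * sum(pi) ) ),

and linkage is tested one-sided via t = beta_hat / SE against the lower tail
of a t distribution with n_pairs - 2 degrees of freedom (alternative: slope
negative, i.e. sharing pairs are more alike than non-sharing pairs).

Under linkage the D slope is expected negative but the S slope positive
(sharing inflates trait sums' spread), so pooling the slopes with their own
signs can attenuate or cancel a true signal.  The formula is nevertheless the
default here; ``sign_corrected=True`` negates beta_S before pooling so both
regressions point the same way, and is intended for sensitivity analysis.

Because pairs built from the same individuals are dependent, the nominal
t-based p-values are calibrated chromosome-wide by permutation (see
:mod:`ibdqt.permutation`).

Markers where pi is constant (no pair shares, or every pair shares) carry no
slope information and are flagged undefined; they are excluded from minimum-p
summaries and peak-region reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .errors import IbdqtError, PairAlignmentError
from .ibd import IbdMatrix

__all__ = [
    "marker_regression",
    "combine_slopes",
    "standard_error",
    "linkage_test",
    "scan",
    "ScanResult",
]


def marker_regression(y, pi) -> tuple[float, float]:
    """OLS of y on intercept + binary pi: (slope, residual error variance).

    slope = mean(y | pi=1) - mean(y | pi=0); the residual variance is
    RSS/(n-2).  If pi is constant the statistic is undefined and
    ``(nan, nan)`` is returned (a flag, not an exception).
    """
    y = np.asarray(y, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if y.shape != pi.shape:
        raise IbdqtError("y and pi must have equal length")
    n = y.size
    n1 = pi.sum()
    if n1 == 0 or n1 == n or n <= 2:
        return (np.nan, np.nan)
    mean1 = y[pi == 1].mean()
    mean0 = y[pi == 0].mean()
    rss = ((y[pi == 1] - mean1) ** 2).sum() + ((y[pi == 0] - mean0) ** 2).sum()
    return (float(mean1 - mean0), float(rss / (n - 2)))


def combine_slopes(beta_S: float, beta_D: float, sigma2_S: float, sigma2_D: float) -> float:
    """Inverse-variance-weighted pooled slope of the S and D regressions.

    beta_hat = (sigma2_D * beta_S + sigma2_S * beta_D) / (sigma2_S + sigma2_D);
    nan (undefined) if both variances are zero.
    """
    total = sigma2_S + sigma2_D
    if not total > 0:
        return np.nan
    return (sigma2_D * beta_S + sigma2_S * beta_D) / total


def standard_error(sigma2_S: float, sigma2_D: float, pi_sum: float) -> float:
    """SE of the pooled slope: sqrt(1 / ([1/sigma2_D + 1/sigma2_S] * sum(pi))).

    Undefined (nan) unless both variances and the sharing count are positive.
    """
    if not (sigma2_S > 0 and sigma2_D > 0 and pi_sum > 0):
        return np.nan
    return float(np.sqrt(1.0 / ((1.0 / sigma2_D + 1.0 / sigma2_S) * pi_sum)))


def linkage_test(beta_hat: float, se: float, df: int) -> tuple[float, float]:
    """One-sided t test of the pooled slope against the negative alternative.

    t = beta_hat / se; p is the lower-tail probability under t(df).
    """
    if not se > 0:
        raise IbdqtError("standard error must be positive")
    t = beta_hat / se
    p = float(stats.t.cdf(t, df))
    return (float(t), p)


@dataclass
class ScanResult:
    """Per-marker scan table plus the peak region.

    ``table`` columns: marker, position_bp, pi_sum, beta_D, beta_S, sigma2_D,
    sigma2_S, beta_hat, se, t, p, defined.  Undefined markers carry NaN
    statistics and ``defined == False``.
    """

    table: pd.DataFrame
    n_pairs: int
    peak_threshold: float
    sign_corrected: bool = False

    def min_p_marker(self) -> int | None:
        """Index (into the table) of the smallest defined p, or None."""
        defined = self.table.loc[self.table["defined"], "p"]
        if defined.empty:
            return None
        return int(defined.idxmin())

    def peak_region(self) -> tuple[int, int] | None:
        """Maximal run of markers with p < threshold containing the min-p marker.

        Returns inclusive (first, last) marker indices, or None when no
        defined marker falls below the reporting threshold.
        """
        imin = self.min_p_marker()
        if imin is None or not self.table.loc[imin, "p"] < self.peak_threshold:
            return None
        below = (self.table["p"] < self.peak_threshold) & self.table["defined"]
        lo = imin
        while lo > 0 and below.iloc[lo - 1]:
            lo -= 1
        hi = imin
        while hi + 1 < len(below) and below.iloc[hi + 1]:
            hi += 1
        return (lo, hi)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _scan_core(
    indicator: sp.spmatrix, D: np.ndarray, S: np.ndarray, sign_corrected: bool = False
):
    """Vectorised per-marker statistics for a sparse pairs x markers indicator.

    Group means and within-group sums of squares are obtained from four
    sparse matrix-vector products, so the whole scan is O(nnz + markers);
    no per-marker solver is involved.  Returns a dict of column arrays.
    """
    X = indicator.tocsc()
    if X.dtype != np.float64:
        X = X.astype(np.float64)
    n, m = X.shape
    pi_sum = np.asarray(X.sum(axis=0)).ravel()
    n0 = n - pi_sum

    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, y in (("D", D), ("S", S)):
            y = np.asarray(y, dtype=float)
            s1 = X.T @ y
            q1 = X.T @ (y * y)
            mean1 = s1 / pi_sum
            mean0 = (y.sum() - s1) / n0
            rss = (y * y).sum() - pi_sum * mean1**2 - n0 * mean0**2
            rss = np.maximum(rss, 0.0)  # guard tiny negative round-off
            out[f"beta_{name}"] = mean1 - mean0
            out[f"sigma2_{name}"] = rss / (n - 2)

        s2D, s2S = out["sigma2_D"], out["sigma2_S"]
        beta_S_eff = -out["beta_S"] if sign_corrected else out["beta_S"]
        beta_hat = (s2D * beta_S_eff + s2S * out["beta_D"]) / (s2S + s2D)
        se = np.sqrt(1.0 / ((1.0 / s2D + 1.0 / s2S) * pi_sum))
        t = beta_hat / se

    defined = (pi_sum > 0) & (pi_sum < n) & (s2D > 0) & (s2S > 0)
    p = np.full(m, np.nan)
    if defined.any():
        p[defined] = stats.t.cdf(t[defined], df=n - 2)
    for key in ("beta_D", "beta_S", "sigma2_D", "sigma2_S"):
        out[key][~defined] = np.nan
    beta_hat[~defined] = np.nan
    se[~defined] = np.nan
    t[~defined] = np.nan
    out.update(pi_sum=pi_sum, beta_hat=beta_hat, se=se, t=t, p=p, defined=defined)
    return out


def _align_pair_values(matrix: IbdMatrix, pair_stats: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Reorder the D/S columns of ``pair_stats`` to the matrix pair order."""
    keys = [
        (a, b) if a <= b else (b, a)
        for a, b in zip(pair_stats["id1"], pair_stats["id2"])
    ]
    stat_index = {k: i for i, k in enumerate(keys)}
    matrix_pairs = set(matrix.pairs)
    missing_in_stats = matrix_pairs - stat_index.keys()
    missing_in_matrix = stat_index.keys() - matrix_pairs
    if missing_in_stats or missing_in_matrix:
        raise PairAlignmentError(missing_in_stats, missing_in_matrix)
    order = np.array([stat_index[p] for p in matrix.pairs])
    D = pair_stats["D"].to_numpy(dtype=float)[order]
    S = pair_stats["S"].to_numpy(dtype=float)[order]
    return D, S


def scan(
    matrix: IbdMatrix,
    pair_stats: pd.DataFrame,
    sign_corrected: bool = False,
    peak_threshold: float = 0.01,
) -> ScanResult:
    """Run the dual-regression statistic at every marker of an IBD matrix.

    ``pair_stats`` must cover exactly the matrix's pairs (columns id1, id2,
    D, S); a mismatch raises :class:`PairAlignmentError` listing the missing
    pairs.  Markers with constant sharing are flagged undefined.
    """
    D, S = _align_pair_values(matrix, pair_stats)
    cols = _scan_core(matrix.indicator, D, S, sign_corrected=sign_corrected)
    table = pd.DataFrame(
        {
            "marker": np.arange(matrix.n_markers),
            "position_bp": matrix.marker_positions_bp,
            "pi_sum": cols["pi_sum"].astype(int),
            "beta_D": cols["beta_D"],
            "beta_S": cols["beta_S"],
            "sigma2_D": cols["sigma2_D"],
            "sigma2_S": cols["sigma2_S"],
            "beta_hat": cols["beta_hat"],
            "se": cols["se"],
            "t": cols["t"],
            "p": cols["p"],
            "defined": cols["defined"],
        }
    )
    return ScanResult(
        table=table,
        n_pairs=matrix.n_pairs,
        peak_threshold=peak_threshold,
        sign_corrected=sign_corrected,
    )
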