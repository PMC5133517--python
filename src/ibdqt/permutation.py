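"""Chromosome-wide significance by individual-level permutation.

The pairs entering the marker scan are not independent: every individual
appears in n-1 pairs, so the nominal t-based p-values cannot be referred to
their asymptotic distribution family-wise.  The familywise chromosome-wide
threshold is instead calibrated empirically: the residual-to-individual
assignment is shuffled (a Fisher-Yates permutation of the residual vector
over individuals), D and S are recomputed for all pairs, the full scan is
re-run against the untouched IBD matrix, and the minimum defined p-value is
recorded.  Permuting individuals rather than pairs preserves exactly the
pairwise dependence structure of D and S under the null of no linkage.

The alpha-level threshold is the k-th smallest null minimum p with
k = floor(alpha * n_perm), a conservative (under-shooting) convention; an
observed minimum p strictly below the threshold is chromosome-wide
significant at level alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import IbdqtError
from .ibd import IbdMatrix
from .scan import _scan_core

__all__ = ["permute_scan", "PermutationResult", "pair_member_indices"]


@dataclass
class PermutationResult:
    """Null minimum-p distribution and the derived familywise threshold."""

    n_perm: int
    alpha: float
    threshold: float
    null_min_p: np.ndarray
    seed: int | None
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "threshold": None if math.isnan(self.threshold) else self.threshold,
            "seed": self.seed,
            "degenerate": self.degenerate,
            **self.meta,
        }


def pair_member_indices(matrix: IbdMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Index arrays (i, j) mapping each matrix pair row to its two individuals.

    Individuals are the sorted sample roster; the returned arrays index into
    a residual vector ordered the same way.
    """
    individuals = matrix.individuals()
    idx = {s: k for k, s in enumerate(individuals)}
    ii = np.array([idx[a] for a, _ in matrix.pairs])
    jj = np.array([idx[b] for _, b in matrix.pairs])
    return ii, jj, individuals


def _threshold_from_null(null_min_p: np.ndarray, alpha: float) -> float:
    finite = np.sort(null_min_p[np.isfinite(null_min_p)])
    if finite.size == 0:
        return np.nan
    k = int(np.floor(alpha * finite.size))
    if k < 1:
        warnings.warn(
            f"alpha * n_perm = {alpha * finite.size:.3g} < 1; "
            "threshold set to the smallest null minimum p",
            stacklevel=3,
        )
        k = 1
    return float(finite[k - 1])


def permute_scan(
    residuals,
    matrix: IbdMatrix,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    sign_corrected: bool = False,
) -> PermutationResult:
    """Estimate the chromosome-wide minimum-p threshold by permutation.

    ``residuals`` is a pandas Series indexed by individual id (or a mapping);
    it must cover every individual in the matrix.  Each permutation shuffles
    the residual values over individuals, recomputes D and S for all pairs,
    re-runs the scan, and records the minimum p over defined markers.
    Reproducible given ``seed``.
    """
    if not 0 < alpha < 1:
        raise IbdqtError(f"alpha must be in (0, 1), got {alpha}")
    if n_perm < 1:
        raise IbdqtError("n_perm must be positive")
    if n_perm * alpha < 20:
        warnings.warn(
            f"n_perm={n_perm} is small for alpha={alpha}; "
            f"recommend n_perm >= {math.ceil(20 / alpha)}",
            stacklevel=2,
        )

    ii, jj, individuals = pair_member_indices(matrix)
    try:
        r = np.array([float(residuals[s]) for s in individuals])
    except KeyError as exc:
        raise IbdqtError(f"residuals missing individual {exc}") from None

    if np.allclose(r, r[0]):
        warnings.warn(
            "all residuals are identical: the null scan is degenerate and "
            "no threshold can be estimated",
            stacklevel=2,
        )
        return PermutationResult(
            n_perm=n_perm, alpha=alpha, threshold=np.nan,
            null_min_p=np.full(n_perm, np.nan), seed=seed, degenerate=True,
        )

    rng = np.random.default_rng(seed)
    X = matrix.indicator.tocsc().astype(np.float64)
    null_min_p = np.full(n_perm, np.nan)
    for b in range(n_perm):
        perm = rng.permutation(r)
        D = (perm[ii] - perm[jj]) ** 2
        S = (perm[ii] + perm[jj]) ** 2
        cols = _scan_core(X, D, S, sign_corrected=sign_corrected)
        p_defined = cols["p"][cols["defined"]]
        if p_defined.size:
            null_min_p[b] = p_defined.min()

    threshold = _threshold_from_null(null_min_p, alpha)
    return PermutationResult(
        n_perm=n_perm,
        alpha=alpha,
        threshold=threshold,
        null_min_p=null_min_p,
        seed=seed,
        meta={"n_pairs": matrix.n_pairs, "n_markers": matrix.n_markers},
    )
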