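"""Phenotype preparation for IBD mapping of a quantitative trait.

The trait analysed here is diastolic blood pressure (DBP, mm Hg) in a cohort
of unrelated individuals.  Three steps turn the raw phenotype table into the
per-pair quantities the marker scan consumes:

1. treatment adjustment — individuals on antihypertensive medication have
   5 mm Hg added back to their observed DBP, the standard correction for
   treated blood pressure;
2. residualization — ordinary least squares of adjusted DBP on an intercept,
   gender, age, smoking status and the principal-component scores that stand
   in for ethnicity/population structure; the residuals carry the trait
   variation the covariates cannot explain;
3. pair statistics — for every unordered pair (i, j) the squared residual
   difference D = (r_i - r_j)^2 and squared residual sum S = (r_i + r_j)^2,
   the two responses of the Haseman-Elston-type regressions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, IbdqtError

TREATMENT_ADJUSTMENT_MMHG = 5.0

#: columns every phenotype table must provide (pc* columns are discovered)
REQUIRED_COLUMNS = ("id", "dbp", "treated", "gender", "age", "smoking")


def pc_columns(table: pd.DataFrame) -> list[str]:
    """Return the principal-component score columns (``pc1``, ``pc2``, ...) in order."""
    cols = [c for c in table.columns if c.startswith("pc") and c[2:].isdigit()]
    return sorted(cols, key=lambda c: int(c[2:]))


def load_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV (named header) and validate it.

    Expected columns: id, dbp, treated, gender, age, smoking, pc1..pcK.
    Boolean columns may be coded 0/1.
    """
    table = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise IbdqtError(f"phenotype table missing columns: {missing}")
    for col in ("treated", "gender", "smoking"):
        table[col] = table[col].astype(bool)
    validate_phenotypes(table)
    return table


def validate_phenotypes(table: pd.DataFrame) -> None:
    """Check the phenotype-table invariants: unique ids, finite positive DBP."""
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise IbdqtError(f"duplicate individual ids: {dupes}")
    dbp = table["dbp"].to_numpy(dtype=float)
    finite = np.isfinite(dbp)
    if not (dbp[finite] > 0).all():
        raise IbdqtError("dbp values must be positive")


def adjust_dbp(dbp, treated):
    """Apply the antihypertensive-treatment correction: DBP + 5 mm Hg if treated.

    Accepts scalars or aligned array-likes and returns the same shape.
    """
    dbp_arr = np.asarray(dbp, dtype=float)
    treated_arr = np.asarray(treated, dtype=bool)
    out = dbp_arr + TREATMENT_ADJUSTMENT_MMHG * treated_arr
    if np.isscalar(dbp) or out.ndim == 0:
        return float(out)
    return out


def residualize(table: pd.DataFrame) -> pd.Series:
    """OLS residuals of adjusted DBP on intercept + gender + age + smoking + PCs.

    All principal-component columns present in the table are used.  Rows with
    any missing trait or covariate value are dropped with a warning.  Returns
    a float Series indexed by individual id; residuals sum to ~0 because an
    intercept is always fitted.

    Raises
    ------
    CollinearityError
        If the design matrix is rank deficient (names the collinear columns).
    """
    validate_phenotypes(table)
    covariate_cols = ["gender", "age", "smoking", *pc_columns(table)]
    y = pd.Series(
        adjust_dbp(table["dbp"].to_numpy(), table["treated"].to_numpy()),
        index=table["id"], name="adjusted_dbp",
    )
    X = table[covariate_cols].astype(float)
    X.index = table["id"]

    keep = y.notna() & np.isfinite(y) & X.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} individual(s) with missing phenotype or covariates",
            stacklevel=2,
        )
        y, X = y[keep], X[keep]

    design = sm.add_constant(X, has_constant="add")
    if len(y) <= design.shape[1]:
        raise IbdqtError(
            f"need more individuals ({len(y)}) than model parameters ({design.shape[1]})"
        )
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        culprits = [
            col for col in design.columns
            if col != "const"
            and np.linalg.matrix_rank(design.drop(columns=col).to_numpy()) == rank
        ]
        raise CollinearityError(culprits)

    fit = sm.OLS(y, design).fit()
    resid = fit.resid
    resid.name = "residual"
    return resid


def pair_statistics(residuals: pd.Series) -> pd.DataFrame:
    """Squared difference D and squared sum S for every unordered pair.

    Pairs are ordered lexicographically by (id1, id2) with id1 < id2; the
    result has exactly n(n-1)/2 rows.  The identity D + S = 2(r_i^2 + r_j^2)
    holds for every pair.
    """
    if residuals.index.duplicated().any():
        raise IbdqtError("duplicate ids in residual vector")
    if len(residuals) < 2:
        raise IbdqtError("need at least 2 individuals to form pairs")
    r = residuals.sort_index()
    ids = r.index.to_numpy()
    vals = r.to_numpy(dtype=float)
    ii, jj = np.triu_indices(len(vals), k=1)
    return pd.DataFrame(
        {
            "id1": ids[ii],
            "id2": ids[jj],
            "D": (vals[ii] - vals[jj]) ** 2,
            "S": (vals[ii] + vals[jj]) ** 2,
        }
    )


def pair_count(n: int) -> int:
    """Number of unordered pairs among n individuals: n(n-1)/2."""
    return n * (n - 1) // 2
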