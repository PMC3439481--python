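"""Derivation of analysis-ready traits.

Raw ocular and MRI measurements become analysis traits in four steps:
worse-eye selection, ordinal grading of cortical opacity (0-4, capped at 4
wedges), annual change of longitudinal volumes, then per-trait adjustment —
least-squares residuals on age and sex followed by a rank-based inverse
normal transform (INT) of the residuals using the empirical quantile
(rank - 1/3) / (n + 1/3). The INT forces an approximately standard normal
marginal, which the downstream familial-correlation and regression stages
assume.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateError, InsufficientDataError, MissingError, RangeError, SingularityError

__all__ = [
    "grade_cortical_cataract",
    "worse_eye",
    "annual_change",
    "residualize",
    "inverse_normal_transform",
    "apply_exclusions",
    "prepare_trait",
]

logger = logging.getLogger(__name__)

MAX_WEDGES = 8  # lens cortex graded in one-eighth wedges
GRADE_CAP = 4


def grade_cortical_cataract(wedges):
    """Ordinal 0-4 cortical cataract grade from the count of opaque wedges.

    Four or more positive one-eighth wedges are assigned the top grade 4.
    Accepts a scalar or array; NaN propagates.
    """
    w = np.asarray(wedges, dtype=float)
    if np.any(w[~np.isnan(w)] < 0) or np.any(w[~np.isnan(w)] > MAX_WEDGES):
        raise RangeError(f"wedge count outside [0, {MAX_WEDGES}]")
    out = np.minimum(w, GRADE_CAP)
    return float(out) if np.isscalar(wedges) else out


def worse_eye(left, right, higher_is_worse: bool = True):
    """Per-subject worse measurement over the two eyes.

    Missing eyes are ignored; both missing raises :class:`MissingError` for
    scalars and yields NaN for array input.
    """
    l = np.asarray(left, dtype=float)
    r = np.asarray(right, dtype=float)
    scalar = l.ndim == 0
    l, r = np.atleast_1d(l), np.atleast_1d(r)
    pick = np.fmax if higher_is_worse else np.fmin  # fmax/fmin ignore NaN
    out = pick(l, r)
    if scalar:
        if np.isnan(out[0]):
            raise MissingError("both eyes missing")
        return float(out[0])
    return out


def annual_change(baseline, followup, years):
    """Per-year change between two exams: (followup - baseline) / years."""
    y = np.asarray(years, dtype=float)
    if np.any(y[~np.isnan(y)] <= 0):
        raise RangeError("years between examinations must be > 0")
    out = (np.asarray(followup, dtype=float) - np.asarray(baseline, dtype=float)) / y
    return float(out) if np.isscalar(years) else out


def residualize(trait, covariates) -> np.ndarray:
    """Least-squares residuals of a trait on intercept + covariate columns.

    ``covariates`` is a DataFrame or 2-D array (typically age and sex).
    Rows with any missing value get a missing residual. Requires >= 10
    complete cases and a full-rank design.
    """
    y = np.asarray(trait, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    keep = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    if keep.sum() < 10:
        raise InsufficientDataError(f"only {int(keep.sum())} complete cases (need >= 10)")
    Xc = np.column_stack([np.ones(keep.sum()), X[keep]])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise SingularityError("covariate design is rank deficient")
    beta, *_ = np.linalg.lstsq(Xc, y[keep], rcond=None)
    resid = np.full_like(y, np.nan)
    resid[keep] = y[keep] - Xc @ beta
    return resid


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform of a column.

    Maps value i to Phi^-1((rank_i - 1/3) / (n + 1/3)) with average ranks for
    ties; missing values are preserved. Requires >= 3 non-missing values that
    are not all identical.
    """
    v = np.asarray(values, dtype=float)
    keep = ~np.isnan(v)
    n = int(keep.sum())
    if n < 3:
        raise InsufficientDataError(f"INT needs >= 3 non-missing values, got {n}")
    obs = v[keep]
    if np.all(obs == obs[0]):
        raise DegenerateError("all values identical; INT undefined")
    n_ties = n - len(np.unique(obs))
    if n_ties > 0.5 * n:
        logger.warning("inverse_normal_transform: heavily tied input (%d/%d tied)", n_ties, n)
    ranks = stats.rankdata(obs, method="average")
    out = np.full_like(v, np.nan)
    out[keep] = stats.norm.ppf((ranks - 1.0 / 3.0) / (n + 1.0 / 3.0))
    return out


def apply_exclusions(table: pd.DataFrame, flags) -> pd.DataFrame:
    """Drop flagged subjects (missing exam data, prior cataract surgery...)."""
    flags = np.asarray(flags, dtype=bool)
    if flags.shape[0] != len(table):
        raise RangeError("exclusion flags not aligned to table rows")
    n_out = int(flags.sum())
    logger.info("apply_exclusions: removed %d of %d subjects", n_out, len(table))
    return table.loc[~flags].reset_index(drop=True)


def prepare_trait(table: pd.DataFrame, trait: str,
                  covariates: tuple[str, ...] = ("age", "sex")) -> pd.DataFrame:
    """Attach ``<trait>.resid`` and ``<trait>.int`` columns for one trait."""
    out = table.copy()
    resid = residualize(out[trait], out[list(covariates)])
    out[f"{trait}.resid"] = resid
    out[f"{trait}.int"] = inverse_normal_transform(resid)
    return out
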