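"""Library-size normalization and expression transforms.

Implements trimmed-mean-of-M-values (TMM) scaling factors, log2
counts-per-million with a library-size-adjusted prior count, and per-feature
z-scoring. TMM estimates, for every sample against a reference sample, a
weighted mean of per-gene log-ratios (M-values) after trimming the most
extreme 30% of M-values and 5% of absolute-expression A-values, with
inverse-asymptotic-variance weights; the resulting factors are rescaled so
their geometric mean is one. Effective library size = raw library size x
factor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["tmm_factors", "effective_library_sizes", "log_cpm", "standardize_features"]


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, sum_trim: float) -> float:
    """Log2 TMM factor of one sample against the reference sample."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return np.nan
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)

    log_r = np.log2((obs / n_obs) / (ref / n_ref))          # M-values
    abs_e = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))    # A-values
    # delta-method variance of the M-value for weighting
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.max(np.abs(log_r)) < 1e-6:
        return 0.0

    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    trimmed = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not trimmed.any():
        return np.nan
    f = np.sum(log_r[trimmed] / v[trimmed]) / np.sum(1.0 / v[trimmed])
    return f if np.isfinite(f) else 0.0


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                sum_trim: float = 0.05, ref_sample: str | None = None) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean one).

    Parameters
    ----------
    counts
        Features x samples non-negative integer matrix.
    logratio_trim, sum_trim
        Two-sided trim fractions applied to M-values and A-values.
    ref_sample
        Reference sample id; by default the sample whose 75th-percentile
        count fraction is closest to the mean of those fractions.

    Returns
    -------
    pandas.Series of positive factors indexed by sample id.
    """
    values = counts.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        bad = list(counts.columns[lib <= 0])
        raise ValueError(f"samples with zero total count: {bad}")

    if ref_sample is None:
        f75 = np.quantile(values / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)

    log_factors = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        if j == ref_idx:
            continue
        f = _tmm_pair(values[:, j], values[:, ref_idx], lib[j], lib[ref_idx],
                      logratio_trim, sum_trim)
        if np.isnan(f):
            warnings.warn(
                f"sample {counts.columns[j]!r} shares no co-expressed genes "
                "with the reference; factor set to 1"
            )
            f = 0.0
        log_factors[j] = f

    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def effective_library_sizes(counts: pd.DataFrame, factors: pd.Series) -> pd.Series:
    """Raw library size times TMM factor, aligned to the count matrix."""
    if not counts.columns.equals(factors.index):
        raise ValueError("normalization factors not aligned to count matrix samples")
    return counts.sum(axis=0).astype(float) * factors


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None,
            prior_count: float = 0.5) -> pd.DataFrame:
    """Log2 counts-per-million on effective library sizes.

    The prior count is expressed in CPM units and adjusted per sample in
    proportion to its effective library size (``prior * eff_lib / 1e6``
    counts), so the value equals ``log2(CPM + prior)``: doubling all counts
    and library sizes leaves values unchanged exactly, and zero counts stay
    finite. With ``prior_count=0`` the CPM columns sum to exactly 1e6.
    """
    if prior_count < 0:
        raise ValueError("prior_count must be >= 0")
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    eff = effective_library_sizes(counts, factors).to_numpy()
    values = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        out = np.log2(values / eff * 1e6 + prior_count)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def standardize_features(expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Z-score each feature row across all samples (sample SD, ddof=1).

    Constant rows cannot be standardized; they are set to all-zero and
    returned in the second element. Z-scoring is idempotent on
    already-standardized rows.
    """
    if expr.shape[1] < 3:
        raise ValueError("standardization needs at least three samples")
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[constant] = 1.0
    z = (values - mean) / sd
    z[constant] = 0.0
    out = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    return out, expr.index[constant]
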