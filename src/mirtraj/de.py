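"""Two-group differential expression for count data at fixed NB dispersion.

The test mirrors the classic exact test for negative-binomial counts with a
known common dispersion (variance = mu + dispersion * mu^2). Counts are first
scaled to a common effective library size (the geometric mean of the
contrast's effective library sizes, rounded half-to-even) — a deliberate,
documented approximation to quantile-adjusted pseudo-counts. Conditional on a
feature's total count t, the group-A sum then follows a beta-binomial
distribution BB(t, n_A/phi, n_B/phi), and the two-sided p-value doubles the
smaller of the two tails (tie mass at the observed value included, capped at
one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .normalize import effective_library_sizes

__all__ = ["Contrast", "DECall", "nb_exact_test", "call_de", "venn_partition",
           "VennPartition"]

#: thresholds from the upstream study design: raw p < 0.05, |log2FC| > 0.75,
#: average log2CPM > 0
DEFAULT_P_MAX = 0.05
DEFAULT_LFC_MIN = 0.75
DEFAULT_LOGCPM_MIN = 0.0
DEFAULT_DISPERSION = 0.1


@dataclass(frozen=True)
class Contrast:
    """Two disjoint, non-empty sample groups; fold changes are B versus A."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self):
        a, b = set(self.group_a), set(self.group_b)
        if not a or not b:
            raise ValueError(f"contrast {self.name!r}: both groups must be non-empty")
        if a & b:
            raise ValueError(f"contrast {self.name!r}: groups overlap: {sorted(a & b)}")

    @staticmethod
    def from_design(design: pd.DataFrame, name: str,
                    a: dict, b: dict) -> "Contrast":
        """Build a contrast by selecting design rows matching column=value dicts."""
        def select(cond):
            mask = np.ones(len(design), dtype=bool)
            for col, val in cond.items():
                mask &= design[col].to_numpy() == val
            return tuple(design.loc[mask, "sample_id"])
        ga, gb = select(a), select(b)
        if not ga or not gb:
            raise ValueError(f"contrast {name!r}: empty group for {a} / {b}")
        return Contrast(name, ga, gb)


def _betabinom_two_sided_p(a_sum: int, total: int, r_a: float, r_b: float) -> float:
    """Exact conditional two-sided p for a group-A sum given the total.

    Enumerates the beta-binomial conditional distribution over all splits
    (k, total-k); the p-value is twice the smaller tail including the
    observed value, capped at one.
    """
    if total == 0:
        return 1.0
    k = np.arange(total + 1)
    logw = (gammaln(k + r_a) - gammaln(k + 1)
            + gammaln(total - k + r_b) - gammaln(total - k + 1))
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    lower = w[: a_sum + 1].sum()
    upper = w[a_sum:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def equalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Scale every sample to the geometric mean effective library size.

    Rounds half-to-even to integer pseudo-counts so the conditional exact
    test applies.
    """
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    eff = effective_library_sizes(counts, factors).to_numpy()
    common = np.exp(np.mean(np.log(eff)))
    scaled = counts.to_numpy(dtype=float) * (common / eff)
    return pd.DataFrame(np.round(scaled).astype(np.int64),
                        index=counts.index, columns=counts.columns)


def nb_exact_test(counts: pd.DataFrame, contrast: Contrast,
                  dispersion: float = DEFAULT_DISPERSION,
                  factors: pd.Series | None = None,
                  prior_count: float = 0.5) -> pd.DataFrame:
    """Per-feature NB exact test for the given contrast.

    Parameters
    ----------
    counts
        Features x samples raw counts covering both contrast groups.
    contrast
        Sample groups; log2 fold change is group B over group A.
    dispersion
        Fixed NB dispersion (variance = mu + dispersion * mu^2); must be > 0.
    factors
        Optional TMM factors for the full matrix; library sizes are equalized
        on the contrast samples before testing.
    prior_count
        Prior added to each group-mean count when computing log2FC and the
        average log2CPM, so both stay finite.

    Returns
    -------
    DataFrame indexed by feature with columns logFC, logCPM, pvalue, fdr.
    A feature with zero total count gets p = 1 and logFC = 0.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    for group in (contrast.group_a, contrast.group_b):
        if len(group) < 2:
            raise ValueError(f"contrast {contrast.name!r}: each group needs >=2 samples")
        missing = set(group) - set(counts.columns)
        if missing:
            raise ValueError(f"samples not in count matrix: {sorted(missing)}")

    sub = counts.loc[:, list(contrast.group_a) + list(contrast.group_b)]
    if factors is not None:
        factors = factors.loc[sub.columns]
    pseudo = equalize_counts(sub, factors)
    common = float(np.exp(np.mean(np.log(
        effective_library_sizes(sub, factors if factors is not None
                                else pd.Series(1.0, index=sub.columns)).to_numpy()))))

    n_a, n_b = len(contrast.group_a), len(contrast.group_b)
    a_sums = pseudo.loc[:, list(contrast.group_a)].sum(axis=1).to_numpy()
    b_sums = pseudo.loc[:, list(contrast.group_b)].sum(axis=1).to_numpy()
    totals = a_sums + b_sums
    r_a, r_b = n_a / dispersion, n_b / dispersion

    pvals = np.ones(len(pseudo))
    for i in range(len(pseudo)):
        if totals[i] > 0:
            pvals[i] = _betabinom_two_sided_p(int(a_sums[i]), int(totals[i]), r_a, r_b)

    mean_a = a_sums / n_a
    mean_b = b_sums / n_b
    logfc = np.log2((mean_b + prior_count) / (mean_a + prior_count))
    logfc[totals == 0] = 0.0
    overall_mean = totals / (n_a + n_b)
    logcpm = np.log2((overall_mean + prior_count) / common * 1e6)

    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"logFC": logfc, "logCPM": logcpm, "pvalue": pvals, "fdr": fdr},
        index=pseudo.index,
    )


@dataclass(frozen=True)
class DECall:
    """Thresholded up/down calls over a feature universe."""

    up: frozenset
    down: frozenset
    universe: frozenset
    p_max: float = DEFAULT_P_MAX
    lfc_min: float = DEFAULT_LFC_MIN
    logcpm_min: float = DEFAULT_LOGCPM_MIN

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


def call_de(table: pd.DataFrame, p_max: float = DEFAULT_P_MAX,
            lfc_min: float = DEFAULT_LFC_MIN,
            logcpm_min: float = DEFAULT_LOGCPM_MIN,
            use_fdr: bool = False) -> DECall:
    """Call up/down features by raw p, |log2FC| and average log2CPM thresholds.

    The raw p-value is thresholded by default; ``use_fdr=True`` switches the
    significance column to the BH-adjusted p (both are always present in the
    table).
    """
    if not 0 < p_max <= 1:
        raise ValueError("p_max must be in (0, 1]")
    p = table["fdr"] if use_fdr else table["pvalue"]
    sig = (p < p_max) & (table["logCPM"] > logcpm_min)
    up = table.index[sig & (table["logFC"] > lfc_min)]
    down = table.index[sig & (table["logFC"] < -lfc_min)]
    return DECall(up=frozenset(up), down=frozenset(down),
                  universe=frozenset(table.index),
                  p_max=p_max, lfc_min=lfc_min, logcpm_min=logcpm_min)


@dataclass(frozen=True)
class VennPartition:
    """Shared / A-specific / B-specific DE sets between two contrasts."""

    shared_up: frozenset
    shared_down: frozenset
    a_only_up: frozenset
    a_only_down: frozenset
    b_only_up: frozenset
    b_only_down: frozenset
    shared_fraction: float = field(default=float("nan"))


def venn_partition(call_a: DECall, call_b: DECall) -> VennPartition:
    """Partition two DE calls into shared and contrast-specific sets.

    The shared fraction is |shared| / |A union B| over up and down combined
    (direction-matched sharing).
    """
    if call_a.universe != call_b.universe:
        raise ValueError("DE calls cover different feature universes")
    shared_up = call_a.up & call_b.up
    shared_down = call_a.down & call_b.down
    union = (call_a.up | call_a.down) | (call_b.up | call_b.down)
    shared = shared_up | shared_down
    frac = len(shared) / len(union) if union else float("nan")
    return VennPartition(
        shared_up=frozenset(shared_up),
        shared_down=frozenset(shared_down),
        a_only_up=frozenset(call_a.up - call_b.up),
        a_only_down=frozenset(call_a.down - call_b.down),
        b_only_up=frozenset(call_b.up - call_a.up),
        b_only_down=frozenset(call_b.down - call_a.down),
        shared_fraction=frac,
    )
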