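"""miRNA regulator nomination by target anti-correlation.

For every annotated miRNA -> target edge whose endpoints are expressed, a
Pearson correlation is computed across all samples from standardized
expression. Each miRNA with enough tested targets gets a one-sample,
one-sided Wilcoxon signed-rank test of its target correlations against zero
(alternative: median < 0) — the "negative shift" test. A miRNA is nominated
as a candidate regulator when it falls in a down-regulated trajectory class
(down_down or down_up, i.e. opposite to its up-class targets) and its shift
p-value clears the threshold. Candidates are ranked by ascending p-value,
ties broken by more negative mean correlation then id; each carries its
anti-correlated targets (tested targets with r < 0 belonging to an up
class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon

from .classify import CLASSES
from .enrichment import GeneSetCollection, enrich_collection

__all__ = ["pair_correlations", "regulator_shift_test", "nominate_regulators",
           "anticorrelated_target_enrichment"]

logger = logging.getLogger(__name__)

DOWN_CLASSES = ("down_down", "down_up")
UP_CLASSES = ("up_up", "up_down")
#: S4-file style labels for the two candidate flavors
FLAVOR = {"down_down": "down_enhanced", "down_up": "down_counteracted"}


def _row_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between paired rows of two equally shaped matrices."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc * yc).sum(axis=1) / denom


def pair_correlations(mirna_expr: pd.DataFrame, mrna_expr: pd.DataFrame,
                      target_map: pd.DataFrame) -> pd.DataFrame:
    """Pearson and Spearman correlation for every usable target-map edge.

    Both expression matrices must cover the identical samples in the same
    order (an error otherwise — no silent intersection) with at least three
    samples. Edges whose miRNA or gene is absent or constant are dropped and
    the drop count logged.

    Returns a DataFrame with columns (mirna_id, target_gene_id, r, rho, n).
    """
    if not mirna_expr.columns.equals(mrna_expr.columns):
        raise ValueError("miRNA and mRNA expression matrices cover different samples")
    n = mirna_expr.shape[1]
    if n < 3:
        raise ValueError("need at least three shared samples for correlations")

    edges = target_map[["mirna_id", "target_gene_id"]].drop_duplicates()
    present = (edges["mirna_id"].isin(mirna_expr.index)
               & edges["target_gene_id"].isin(mrna_expr.index))
    constant_mirnas = mirna_expr.index[mirna_expr.std(axis=1, ddof=1) == 0]
    constant_genes = mrna_expr.index[mrna_expr.std(axis=1, ddof=1) == 0]
    usable = (present
              & ~edges["mirna_id"].isin(constant_mirnas)
              & ~edges["target_gene_id"].isin(constant_genes))
    dropped = int((~usable).sum())
    if dropped:
        logger.info("pair_correlations: dropped %d edges with absent or constant endpoints",
                    dropped)
    edges = edges[usable]
    if edges.empty:
        return pd.DataFrame(columns=["mirna_id", "target_gene_id", "r", "rho", "n"])

    x = mirna_expr.loc[edges["mirna_id"]].to_numpy(dtype=float)
    y = mrna_expr.loc[edges["target_gene_id"]].to_numpy(dtype=float)
    r = _row_correlations(x, y)
    xr = np.apply_along_axis(rankdata, 1, x)
    yr = np.apply_along_axis(rankdata, 1, y)
    rho = _row_correlations(xr, yr)

    out = edges.reset_index(drop=True).copy()
    out["r"] = r
    out["rho"] = rho
    out["n"] = n
    return out.sort_values(["mirna_id", "target_gene_id"], ignore_index=True)


def _shift_p(r_values: np.ndarray) -> float:
    """One-sample one-sided Wilcoxon signed-rank p for median(r) < 0.

    Exact null distribution when n <= 25 with no zeros and no tied
    magnitudes; otherwise a normal approximation with continuity and tie
    corrections (zeros dropped).
    """
    r = np.asarray(r_values, dtype=float)
    nonzero = r[r != 0]
    if nonzero.size == 0:
        return 1.0
    ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    if nonzero.size <= 25 and nonzero.size == r.size and not ties:
        method = "exact"
    else:
        method = "approx"
    res = wilcoxon(nonzero, alternative="less", method=method,
                   correction=(method == "approx"))
    return float(res.pvalue)


def regulator_shift_test(pairs: pd.DataFrame, min_targets: int = 5) -> pd.DataFrame:
    """Per-miRNA negative-shift test over its target correlations.

    miRNAs with fewer than ``min_targets`` tested edges are omitted (their
    ids and reason are logged). Returns a DataFrame indexed by mirna_id with
    columns (n_targets, mean_r, mean_rho, p_shift).
    """
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    rows = []
    for mirna, grp in pairs.groupby("mirna_id", sort=True):
        if len(grp) < min_targets:
            logger.info("regulator_shift_test: %s omitted (%d < %d targets)",
                        mirna, len(grp), min_targets)
            continue
        r = grp["r"].to_numpy()
        rows.append({"mirna_id": mirna, "n_targets": len(grp),
                     "mean_r": float(r.mean()),
                     "mean_rho": float(grp["rho"].mean()),
                     "p_shift": _shift_p(r)})
    return pd.DataFrame(rows).set_index("mirna_id") if rows else pd.DataFrame(
        columns=["n_targets", "mean_r", "mean_rho", "p_shift"]).rename_axis("mirna_id")


def nominate_regulators(shift: pd.DataFrame, mirna_classes: pd.Series,
                        mrna_classes: pd.Series, pairs: pd.DataFrame,
                        p_threshold: float = 0.05) -> pd.DataFrame:
    """Flag and rank candidate miRNA regulators.

    A candidate has trajectory class down_down or down_up and shift
    p < ``p_threshold``. Candidates are ranked 1..k by ascending p, ties
    broken by more negative mean r then lexicographic id; non-candidates get
    no rank. Each row lists the miRNA's anti-correlated targets: tested
    targets with r < 0 whose mRNA class is up_up or up_down, semicolon-joined
    in ascending-r order.
    """
    table = shift.copy()
    table["trajectory_class"] = mirna_classes.reindex(table.index).fillna("unclassified")
    table["flavor"] = table["trajectory_class"].map(FLAVOR).fillna("")
    table["candidate"] = (table["trajectory_class"].isin(DOWN_CLASSES)
                          & (table["p_shift"] < p_threshold))

    up_genes = set(mrna_classes.index[mrna_classes.isin(UP_CLASSES)])
    anti = pairs[(pairs["r"] < 0) & pairs["target_gene_id"].isin(up_genes)]
    anti = anti.sort_values(["r", "target_gene_id"])
    anti_by_mirna = anti.groupby("mirna_id")["target_gene_id"].apply(
        lambda ids: ";".join(ids))
    table["anticorrelated_targets"] = anti_by_mirna.reindex(table.index).fillna("")
    table["n_anticorrelated"] = table["anticorrelated_targets"].map(
        lambda s: len(s.split(";")) if s else 0)

    cand = table[table["candidate"]].reset_index()
    cand = cand.sort_values(["p_shift", "mean_r", "mirna_id"], kind="mergesort")
    ranks = pd.Series(np.arange(1, len(cand) + 1, dtype=float),
                      index=pd.Index(cand["mirna_id"]))
    table["rank"] = ranks.reindex(table.index)
    return table.sort_values(["rank", "p_shift"], na_position="last",
                             kind="mergesort")


def anticorrelated_target_enrichment(regulators: pd.DataFrame,
                                     mrna_classes: pd.Series,
                                     collection: GeneSetCollection,
                                     universe) -> pd.DataFrame:
    """Enrichment of pooled anti-correlated targets, split by target class.

    The anti-correlated targets of all candidate regulators are pooled, then
    partitioned into an up_up pool and an up_down pool (the trajectory
    classes are exclusive, so the pools are disjoint), and each pool is
    tested against the collection. With no candidates (or empty pools) an
    empty table is returned.
    """
    candidates = regulators[regulators["candidate"]] if "candidate" in regulators else regulators
    pooled: set = set()
    for joined in candidates["anticorrelated_targets"]:
        if joined:
            pooled.update(joined.split(";"))
    queries = {}
    for cls in UP_CLASSES:
        pool = pooled & set(mrna_classes.index[mrna_classes == cls])
        if pool:
            queries[f"{cls}_targets"] = pool
    if not queries:
        logging.getLogger(__name__).warning(
            "anticorrelated_target_enrichment: no candidate targets to pool")
        return enrich_collection({}, collection, universe)
    return enrich_collection(queries, collection, universe)
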