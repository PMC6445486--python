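"""Four-class differentiation x genotype trajectory assignment.

A feature is classified only when it is significantly changed in *both* the
differentiation contrast (RA-differentiated vs stem cells, in wild type) and
the genotype contrast (null vs wild type, in differentiated cells):

    up_up    : up with differentiation, up in the null genotype
    up_down  : up with differentiation, down in the null genotype
    down_up  : down with differentiation, up in the null genotype
    down_down: down with differentiation, down in the null genotype

The first token is always the differentiation direction, the second the
genotype-effect direction. Everything else is ``unclassified``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .de import DECall

__all__ = ["CLASSES", "classify_features", "class_trajectories"]

CLASSES = ("up_up", "up_down", "down_up", "down_down")
UNCLASSIFIED = "unclassified"


def classify_features(diff_call: DECall, geno_call: DECall) -> pd.Series:
    """Assign each feature in the shared universe to one of the four classes.

    Returns a Series indexed by feature id with values in
    ``{"up_up", "up_down", "down_up", "down_down", "unclassified"}``.
    """
    if diff_call.universe != geno_call.universe:
        raise ValueError("DE calls cover different feature universes")
    index = pd.Index(sorted(diff_call.universe))
    out = pd.Series(UNCLASSIFIED, index=index, name="trajectory_class")
    out[out.index.isin(diff_call.up & geno_call.up)] = "up_up"
    out[out.index.isin(diff_call.up & geno_call.down)] = "up_down"
    out[out.index.isin(diff_call.down & geno_call.up)] = "down_up"
    out[out.index.isin(diff_call.down & geno_call.down)] = "down_down"
    return out


def class_trajectories(expr: pd.DataFrame, design: pd.DataFrame,
                       assignment: pd.Series) -> pd.DataFrame:
    """Per-class mean +/- SD expression in each genotype x stage cell.

    ``expr`` should be standardized expression (features x samples) so class
    averages are comparable across features. Returns a long-format table with
    columns (trajectory_class, genotype, stage, mean, sd, n_features,
    n_samples), ordered for trajectory plotting (ESC before RA). Empty
    classes are emitted with null summaries and a warning.
    """
    missing = set(design["sample_id"]) - set(expr.columns)
    if missing:
        raise ValueError(f"design samples absent from expression matrix: {sorted(missing)}")
    rows = []
    cells = design.groupby(["genotype", "stage"], sort=True)["sample_id"].apply(list)
    for cls in CLASSES:
        members = assignment.index[assignment == cls]
        members = members.intersection(expr.index)
        if len(members) == 0:
            warnings.warn(f"trajectory class {cls!r} is empty")
        for (genotype, stage), samples in cells.items():
            if len(members) == 0:
                mean = sd = np.nan
            else:
                block = expr.loc[members, samples].to_numpy()
                per_feature = block.mean(axis=1)
                mean = float(per_feature.mean())
                sd = float(per_feature.std(ddof=1)) if len(members) > 1 else 0.0
            rows.append({"trajectory_class": cls, "genotype": genotype,
                         "stage": stage, "mean": mean, "sd": sd,
                         "n_features": len(members), "n_samples": len(samples)})
    out = pd.DataFrame(rows)
    stage_order = pd.CategoricalDtype(["ESC", "RA"], ordered=True)
    out["stage"] = out["stage"].astype(stage_order)
    return out.sort_values(["trajectory_class", "genotype", "stage"],
                           ignore_index=True)
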