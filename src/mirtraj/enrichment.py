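"""One-sided Fisher-exact over-representation of feature sets.

The significance of an overlap between a query set and an annotated set,
within a stated universe, is the hypergeometric upper tail
P(X >= overlap) — equivalently a one-sided Fisher exact test on the 2x2
table. Collections are read from GMT or two-column TSV files, tested pair
by pair, and BH-adjusted across the whole result table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "fisher_enrichment", "enrich_collection",
           "read_gene_sets"]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named, non-empty feature sets with an optional collection universe."""

    sets: dict
    universe: frozenset | None = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def items(self):
        return self.sets.items()


def fisher_enrichment(query, target_set, universe, query_name: str = "query",
                      set_name: str = "set") -> dict:
    """One-sided over-representation test of ``query`` in ``target_set``.

    Both sets must be subsets of ``universe``. Returns a record with the 2x2
    table (overlap, query_only, set_only, neither), the hypergeometric upper
    tail p = P(X >= overlap), an odds ratio (0.5 added to every cell when any
    cell is zero), and the overlapping ids.
    """
    query, target_set, universe = set(query), set(target_set), set(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain at least two features")
    stray = query - universe
    if stray:
        raise ValueError(f"query ids outside the universe: {sorted(stray)[:10]}")
    stray = target_set - universe
    if stray:
        raise ValueError(f"set ids outside the universe: {sorted(stray)[:10]}")

    overlap = query & target_set
    a = len(overlap)
    b = len(query) - a                # query only
    c = len(target_set) - a           # set only
    d = len(universe) - a - b - c     # neither
    # upper tail including the observed table: P(X >= a)
    p = float(hypergeom.sf(a - 1, len(universe), len(target_set), len(query)))
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return {"query": query_name, "set": set_name, "overlap": a,
            "query_only": b, "set_only": c, "neither": d,
            "odds_ratio": float(odds), "pvalue": min(p, 1.0),
            "overlap_ids": ";".join(sorted(overlap))}


def enrich_collection(queries: dict, collection: GeneSetCollection,
                      universe) -> pd.DataFrame:
    """Test every query x set pair; BH FDR across the full table.

    Sets with no member inside the universe are skipped with a warning.
    Rows are sorted by (fdr, pvalue, query, set).
    """
    universe = set(universe)
    if len(set(collection.sets)) != len(collection.sets):
        raise ValueError("duplicate set names in collection")
    records = []
    for qname, query in queries.items():
        for sname, members in collection.items():
            inside = set(members) & universe
            if not inside:
                warnings.warn(f"set {sname!r} has no members in the universe; skipped")
                continue
            records.append(fisher_enrichment(query, inside, universe,
                                             query_name=qname, set_name=sname))
    table = pd.DataFrame(records)
    if table.empty:
        return pd.DataFrame(columns=["query", "set", "overlap", "query_only",
                                     "set_only", "neither", "odds_ratio",
                                     "pvalue", "fdr", "overlap_ids"])
    table["fdr"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    table = table.sort_values(["fdr", "pvalue", "query", "set"], ignore_index=True)
    return table[["query", "set", "overlap", "query_only", "set_only", "neither",
                  "odds_ratio", "pvalue", "fdr", "overlap_ids"]]


def read_gene_sets(path, fmt: str = "gmt") -> GeneSetCollection:
    """Read a gene-set collection from GMT or two-column TSV.

    GMT lines are ``name<TAB>description<TAB>member...``; the TSV format is
    (set_name, feature_id) pairs aggregated by name. Duplicate members are
    deduplicated with a warning; a duplicate set name is an error; an empty
    file yields an empty collection with a warning.
    """
    sets: dict = {}
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if not lines:
        warnings.warn(f"{path}: empty gene-set file")
        return GeneSetCollection(sets={})
    if fmt == "gmt":
        for lineno, line in enumerate(lines, start=1):
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line "
                                 "(need name, description, >=1 member)")
            name, members = fields[0], fields[2:]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = set(members)
            if len(unique) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in {name!r} deduplicated")
            sets[name] = frozenset(unique)
    elif fmt == "tsv":
        seen_pairs = set()
        for lineno, line in enumerate(lines, start=1):
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: malformed TSV line "
                                 "(need set_name<TAB>feature_id)")
            name, member = fields
            if (name, member) in seen_pairs:
                warnings.warn(f"{path}:{lineno}: duplicate pair ({name}, {member})")
                continue
            seen_pairs.add((name, member))
            sets.setdefault(name, set()).add(member)
        sets = {name: frozenset(members) for name, members in sets.items()}
    else:
        raise ValueError(f"unknown gene-set format {fmt!r} (expected 'gmt' or 'tsv')")
    return GeneSetCollection(sets=sets)
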