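"""Pathway enrichment of DEG and exon-variant gene lists.

One-sided hypergeometric enrichment against a GMT pathway collection.
With N the number of genes in the union of all pathways, n the size of
the pathway of interest, M the number of query genes inside that
universe and k the overlap, the p-value is the upper tail
P(X >= k | N, n, M).  Following the study's reporting rule, a pathway is
flagged significant only when p < 0.05 *and* it contains at least 5
query genes; p-values are raw (no multiple-testing correction).

Six query categories mirror the study: up- and down-regulated DEGs and
genes owning at least one exon variant, for each of the two hypertrophy
contrasts (PAH_up, PAH_down, PAH_AS, PHH_up, PHH_down, PHH_AS).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("PAH_up", "PAH_down", "PAH_AS", "PHH_up", "PHH_down", "PHH_AS")

ENRICHMENT_COLUMNS = ["pathway_id", "category", "N", "n", "M", "k",
                      "p", "neg_log10_p", "significant"]


class PathwayDB:
    """A named collection of gene sets with their union as universe."""

    def __init__(self, pathways: Mapping[str, Iterable[str]],
                 descriptions: Mapping[str, str] | None = None):
        self.pathways: dict[str, frozenset[str]] = {}
        for pid, genes in pathways.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"pathway {pid!r} is empty")
            self.pathways[pid] = genes
        self.descriptions = dict(descriptions or {})
        self.universe: frozenset[str] = frozenset().union(*self.pathways.values())

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pid: str) -> frozenset[str]:
        return self.pathways[pid]

    @classmethod
    def from_gmt(cls, path: str | Path) -> "PathwayDB":
        pathways, desc = {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line: {line!r}")
                pathways[fields[0]] = [g for g in fields[2:] if g]
                desc[fields[0]] = fields[1]
        return cls(pathways, desc)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for pid, genes in self.pathways.items():
                fh.write("\t".join([pid, self.descriptions.get(pid, pid),
                                    *sorted(genes)]) + "\n")


def hypergeom_upper(N: int, n: int, M: int, k: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for k of n pathway genes among
    M query genes drawn from a universe of N."""
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, M, n)))


def enrich(query_genes: Iterable[str], pathways: PathwayDB,
           alpha: float = 0.05, min_k: int = 5,
           category: str | None = None) -> pd.DataFrame:
    """Test every pathway for over-representation of the query genes.

    Query genes outside the pathway universe are dropped before M is
    computed.  Rows are sorted by ascending p.
    """
    if not pathways.universe:
        raise ValueError("empty pathway universe")
    query = frozenset(query_genes) & pathways.universe
    N = len(pathways.universe)
    M = len(query)
    rows = []
    for pid, genes in pathways.pathways.items():
        n = len(genes)
        k = len(query & genes)
        p = hypergeom_upper(N, n, M, k)
        rows.append({
            "pathway_id": pid, "category": category, "N": N, "n": n,
            "M": M, "k": k, "p": p,
            "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
            "significant": bool(p < alpha and k >= min_k),
        })
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    return df.sort_values(["p", "pathway_id"], kind="mergesort").reset_index(drop=True)


def enrich_categories(queries: Mapping[str, Iterable[str]], pathways: PathwayDB,
                      alpha: float = 0.05, min_k: int = 5) -> pd.DataFrame:
    """Run :func:`enrich` for each named query category and concatenate."""
    frames = [enrich(genes, pathways, alpha=alpha, min_k=min_k, category=cat)
              for cat, genes in queries.items()]
    if not frames:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def heat_matrix(records: pd.DataFrame,
                pathway_order: Iterable[str] | None = None,
                groups: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Pathway x category matrix of -log10 p, zero where not significant.

    ``pathway_order`` fixes row order (e.g. the study's biological
    pathway groups); ``groups`` adds a leading ``group`` column of
    user-supplied labels.
    """
    df = records.copy()
    df["cell"] = np.where(df["significant"], df["neg_log10_p"], 0.0)
    wide = df.pivot_table(index="pathway_id", columns="category",
                          values="cell", fill_value=0.0, aggfunc="max")
    cats = [c for c in CATEGORIES if c in wide.columns]
    cats += [c for c in wide.columns if c not in cats]
    wide = wide[cats]
    if pathway_order is not None:
        order = [p for p in pathway_order if p in wide.index]
        order += [p for p in wide.index if p not in order]
        wide = wide.loc[order]
    if groups is not None:
        wide.insert(0, "group", [groups.get(p, "") for p in wide.index])
    wide.columns.name = None
    return wide
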