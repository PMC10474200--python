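"""Hypergeometric over-representation analysis and direct-interaction subnetworks.

Given a query gene list and a gene-set database over a background
universe of N genes, a set of size K overlapping the size-n query in k
genes is scored with the upper-tail hypergeometric probability
P(X >= k); Benjamini-Hochberg FDR is computed across all sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import io
from .signatures import normalize_symbol


@dataclass
class GeneSetDB:
    """Named gene sets over a background universe.

    Sets are clipped to the universe on construction; the default
    universe is the union of all sets.
    """

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.sets = {
            name: {normalize_symbol(g) for g in genes}
            for name, genes in self.sets.items()
        }
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        else:
            self.universe = {normalize_symbol(g) for g in self.universe}
            self.sets = {n: s & self.universe for n, s in self.sets.items()}

    @classmethod
    def from_gmt(cls, path: str | Path, universe: set[str] | None = None):
        return cls(io.read_gmt(path), universe or set())

    def to_gmt(self, path: str | Path) -> None:
        io.write_gmt(self.sets, path)


def hypergeom_enrich(
    query: set[str],
    db: GeneSetDB,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every set of ``db``.

    Returns one row per set with K (set size), k (overlap), N (universe
    size), n (query size in universe), the hypergeometric tail p-value
    P(X >= k), BH FDR and a significance flag at ``alpha`` on the raw p
    (raw-p ranking is what threshold-at-0.05 workflows consume).
    """
    if not db.universe:
        raise ValueError("empty background universe")
    query = {normalize_symbol(g) for g in query}
    if not query:
        raise ValueError("empty query gene list")
    outside = query - db.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
        query = query & db.universe
    if not query:
        raise ValueError("no query gene lies in the background universe")

    N, n = len(db.universe), len(query)
    rows = []
    for name in sorted(db.sets):
        members = db.sets[name]
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "K": K, "k": k, "N": N, "n": n,
                     "p_value": min(p, 1.0)})
    result = pd.DataFrame(rows)
    result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result["significant"] = result["p_value"] <= alpha
    result = result.sort_values(
        ["p_value", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
    return result


def direct_interaction_network(
    query: set[str],
    interactions: pd.DataFrame,
    high_cut: float = 0.70,
    low_cut: float = 0.50,
) -> nx.Graph:
    """Induced subnetwork of weighted interactions among query genes.

    Edges with confidence >= high_cut are labeled ``high`` (drawn thick),
    edges <= low_cut are labeled ``low`` (thin); weights strictly between
    the cuts are dropped.
    """
    if high_cut < low_cut:
        raise ValueError("high_cut must be >= low_cut")
    for col in ("geneA", "geneB", "weight"):
        if col not in interactions.columns:
            raise ValueError(f"interaction table missing column {col!r}")
    weights = interactions["weight"].to_numpy(dtype=float)
    if ((weights < 0) | (weights > 1)).any():
        raise ValueError("interaction weights must lie in [0, 1]")

    query = {normalize_symbol(g) for g in query}
    g = nx.Graph()
    g.add_nodes_from(sorted(query))
    for _, row in interactions.iterrows():
        a = normalize_symbol(row["geneA"])
        b = normalize_symbol(row["geneB"])
        if a not in query or b not in query or a == b:
            continue
        w = float(row["weight"])
        if w >= high_cut:
            g.add_edge(a, b, weight=w, tier="high")
        elif w <= low_cut:
            g.add_edge(a, b, weight=w, tier="low")
    return g
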