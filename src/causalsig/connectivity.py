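"""Connectivity-map scoring of query signatures against reference rank profiles.

A query is the top/bottom slice of a DEG table ranked by log2 fold
change.  Each half is located within a reference signature's full gene
ranking with a Kolmogorov-Smirnov-style enrichment statistic; a
perturbation whose up-half sinks and down-half rises is a *reverser* of
the query.  Raw scores are set to zero when both halves enrich the same
way and otherwise normalized per sign block to [-100, 100] (the classic
connectivity-map build-02 convention; strongest reversers score -100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .signatures import normalize_symbol, validate_deg_table


@dataclass(frozen=True)
class QuerySignature:
    """Ordered up/down gene lists forming a connectivity query."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    n_per_side: int

    def __post_init__(self):
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"genes on both query sides: {overlap}")

    def swapped(self) -> "QuerySignature":
        return QuerySignature(self.down, self.up, self.n_per_side)

    def to_gmt_lines(self, name: str = "QUERY") -> list[str]:
        return [
            f"{name}_UP\tna\t" + "\t".join(self.up),
            f"{name}_DN\tna\t" + "\t".join(self.down),
        ]


@dataclass
class ReferenceSignatureDB:
    """Gene-by-signature rank matrix; rank 1 = most up-regulated."""

    ranks: pd.DataFrame
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.ranks)
        expected = np.arange(1, n + 1)
        for col in self.ranks.columns:
            if not np.array_equal(np.sort(self.ranks[col].to_numpy()), expected):
                raise ValueError(
                    f"column {col!r} is not a permutation of 1..{n}"
                )

    @property
    def signature_ids(self) -> list[str]:
        return list(self.ranks.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, metadata: dict[str, str] | None = None):
        return cls(io.read_rank_matrix(path), metadata or {})

    def to_tsv(self, path: str | Path) -> None:
        io.write_rank_matrix(self.ranks, path)


@dataclass(frozen=True)
class ConnectivityResult:
    signature_id: str
    ks_up: float
    ks_down: float
    raw: float
    score: float  # normalized to [-100, 100]
    description: str = ""


def build_query(deg_table: pd.DataFrame, n_per_side: int = 50) -> QuerySignature:
    """Top up-regulated and top down-regulated genes by log2FC.

    Takes the ``n_per_side`` largest positive and most-negative fold
    changes (ties broken lexicographically); short sides are taken whole
    with a warning.
    """
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    table = validate_deg_table(deg_table)
    if len(table) == 0:
        raise ValueError("empty DEG table")
    pos = table[table["log2fc"] > 0].sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    )
    neg = table[table["log2fc"] < 0].sort_values(
        ["log2fc", "gene"], ascending=[True, True], kind="mergesort"
    )
    if len(pos) < n_per_side or len(neg) < n_per_side:
        warnings.warn(
            f"query sides truncated to {len(pos)} up / {len(neg)} down "
            f"(requested {n_per_side})",
            stacklevel=2,
        )
    up = tuple(pos["gene"].head(n_per_side))
    down = tuple(neg["gene"].head(n_per_side))
    return QuerySignature(up, down, n_per_side)


def ks_enrichment(gene_list, rank_vector: pd.Series) -> float:
    """Signed KS enrichment of a gene list within one reference ranking.

    With t query genes at sorted positions V(1) <= ... <= V(t) among n
    ranked genes, a = max_j [j/t - V(j)/n] and b = max_j [V(j)/n -
    (j-1)/t]; the statistic is a if a > b else -b.  Positive values mean
    the list concentrates at the top of the ranking.
    """
    genes = [normalize_symbol(g) for g in gene_list]
    if not genes:
        raise ValueError("empty gene list")
    lookup = dict(
        zip((normalize_symbol(g) for g in rank_vector.index), rank_vector)
    )
    missing = [g for g in genes if g not in lookup]
    if missing:
        raise KeyError(f"query genes absent from the ranking: {missing[:5]}")
    n = len(rank_vector)
    v = np.sort(np.array([lookup[g] for g in genes], dtype=float))
    t = len(v)
    j = np.arange(1, t + 1)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


def connectivity_score(
    query: QuerySignature,
    db: ReferenceSignatureDB,
) -> list[ConnectivityResult]:
    """Score the query against every reference signature.

    raw = ks_up - ks_down when the halves disagree in direction, else 0;
    scores are normalized to +/-100 within the positive and negative
    blocks separately and sorted ascending, so the strongest reversers
    (mimic-down, oppose-up) come first.
    """
    if not db.signature_ids:
        raise ValueError("reference database holds no signatures")
    if not query.up and not query.down:
        raise ValueError("query has no genes on either side")

    raws: dict[str, tuple[float, float, float]] = {}
    for sig_id in db.signature_ids:
        ranks = db.ranks[sig_id]
        ks_up = ks_enrichment(query.up, ranks) if query.up else 0.0
        ks_down = ks_enrichment(query.down, ranks) if query.down else 0.0
        if ks_up * ks_down > 0:
            raw = 0.0
        else:
            raw = ks_up - ks_down
        raws[sig_id] = (ks_up, ks_down, raw)

    pos_max = max((r for *_, r in raws.values() if r > 0), default=0.0)
    neg_max = max((-r for *_, r in raws.values() if r < 0), default=0.0)

    results = []
    for sig_id, (ks_up, ks_down, raw) in raws.items():
        if raw > 0:
            score = 100.0 * raw / pos_max
        elif raw < 0:
            score = -100.0 * (-raw) / neg_max
        else:
            score = 0.0
        results.append(
            ConnectivityResult(
                signature_id=sig_id,
                ks_up=ks_up,
                ks_down=ks_down,
                raw=raw,
                score=score,
                description=db.metadata.get(sig_id, ""),
            )
        )
    results.sort(key=lambda r: (r.score, r.signature_id))
    return results


def results_to_frame(results: list[ConnectivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "signature": [r.signature_id for r in results],
            "score": [round(r.score, 2) for r in results],
            "ks_up": [r.ks_up for r in results],
            "ks_down": [r.ks_down for r in results],
            "description": [r.description for r in results],
        }
    )
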