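"""Biomarker-overlap confidence scoring and Venn region counts.

Candidate regulators and DEGs gain confidence when they recur across
independent evidence lists: a disease-biomarker set, the DEG list, and
the causal-hub lists derived from two signatures.  Each biomarker gene
is scored by how many of the four lists contain it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .causal import CausalHypothesis
from .signatures import normalize_symbol


@dataclass
class EvidenceLists:
    """The four gene sets compared: biomarkers, DEGs and two hub lists."""

    biomarkers: set[str]
    degs: set[str]
    hubs_gs1: set[str]
    hubs_gs2: set[str]
    labels: tuple[str, str, str, str] = (
        "biomarkers", "degs", "hubs_gs1", "hubs_gs2"
    )

    def __post_init__(self):
        self.biomarkers = {normalize_symbol(g) for g in self.biomarkers}
        self.degs = {normalize_symbol(g) for g in self.degs}
        self.hubs_gs1 = {normalize_symbol(g) for g in self.hubs_gs1}
        self.hubs_gs2 = {normalize_symbol(g) for g in self.hubs_gs2}

    def as_dict(self) -> dict[str, set[str]]:
        return dict(zip(self.labels,
                        (self.biomarkers, self.degs,
                         self.hubs_gs1, self.hubs_gs2)))


@dataclass(frozen=True)
class OverlapRecord:
    gene: str
    confidence_score: int
    in_biomarkers: bool
    is_deg: bool
    in_hubs_gs1: bool
    in_hubs_gs2: bool
    sign: str = ""
    p_gs1: float | None = None
    p_gs2: float | None = None


def _hyp_maps(hyps: list[CausalHypothesis] | None):
    if not hyps:
        return {}, {}
    return (
        {h.node: h.p_value for h in hyps},
        {h.node: h.activity_label for h in hyps},
    )


def score_overlaps(
    lists: EvidenceLists,
    hyps_gs1: list[CausalHypothesis] | None = None,
    hyps_gs2: list[CausalHypothesis] | None = None,
    convention: str = "membership",
) -> list[OverlapRecord]:
    """Score each biomarker gene by its recurrence across evidence lists.

    ``convention='membership'`` (default): the score is the number of the
    four lists containing the gene (1..4).  ``convention='printed'``
    follows the published table layout instead, where a biomarker that is
    only a DEG is reported with score 1; the two conventions otherwise
    agree.  Records are sorted by score (descending) then by the smaller
    hypothesis p-value.
    """
    if convention not in ("membership", "printed"):
        raise ValueError(f"unknown convention: {convention!r}")
    if not lists.biomarkers:
        raise ValueError("empty biomarker set")
    p1, s1 = _hyp_maps(hyps_gs1)
    p2, s2 = _hyp_maps(hyps_gs2)

    records = []
    for gene in sorted(lists.biomarkers):
        flags = (
            True,
            gene in lists.degs,
            gene in lists.hubs_gs1,
            gene in lists.hubs_gs2,
        )
        score = sum(flags)
        if convention == "printed" and flags[1] and not (flags[2] or flags[3]):
            score = 1
        sign = s1.get(gene) or s2.get(gene) or ""
        records.append(
            OverlapRecord(
                gene=gene,
                confidence_score=score,
                in_biomarkers=True,
                is_deg=flags[1],
                in_hubs_gs1=flags[2],
                in_hubs_gs2=flags[3],
                sign=sign,
                p_gs1=p1.get(gene),
                p_gs2=p2.get(gene),
            )
        )

    def sort_key(r: OverlapRecord):
        ps = [p for p in (r.p_gs1, r.p_gs2) if p is not None]
        return (-r.confidence_score, min(ps) if ps else 2.0, r.gene)

    records.sort(key=sort_key)
    return records


def overlaps_to_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "confidence_score": [r.confidence_score for r in records],
            "sign": [r.sign for r in records],
            "p_gs1": [r.p_gs1 for r in records],
            "p_gs2": [r.p_gs2 for r in records],
            "is_deg": ["Yes" if r.is_deg else "No" for r in records],
        }
    )


def venn_counts(lists: EvidenceLists) -> dict[frozenset[str], int]:
    """Exclusive region counts for all 2^4 - 1 nonempty label combinations."""
    sets = lists.as_dict()
    labels = list(sets)
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set().union(
                *(sets[l] for l in labels if l not in combo)
            ) if len(combo) < len(labels) else set()
            counts[frozenset(combo)] = len(inside - outside)
    return counts


def venn_counts_to_tsv(counts: dict[frozenset[str], int], path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tcount\n")
        for region in sorted(counts, key=lambda r: (len(r), sorted(r))):
            fh.write("+".join(sorted(region)) + f"\t{counts[region]}\n")
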