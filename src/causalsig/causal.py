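"""Causal reasoning on signed regulatory networks.

Every network node is treated as a candidate upstream regulator in one of
two activity states (activated ``+`` or inhibited ``-``).  A hypothesis is
scored against an observed gene signature by propagating the hypothesised
activity sign along shortest paths (product of activation/inhibition edge
signs) and counting how many differentially expressed genes it explains.
Under the null that each sign prediction is a coin flip, the number of
correct predictions k out of n scored genes follows Binomial(n, 1/2); the
hypothesis p-value is the upper tail P(X >= k).

Genes reachable only through shortest paths whose sign products disagree
are *ambiguous* and excluded from n by default; genes farther than the
calculation distance are unreachable and never scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

from .network import NODE_FUNCTIONS, RegulatoryNetwork
from .signatures import GeneSignature

AMBIGUOUS = "ambiguous"
UNREACHABLE = "unreachable"


@dataclass(frozen=True)
class CausalHypothesis:
    """One (regulator, activity-sign) hypothesis and its score.

    ``k_correct`` of ``n_scored`` sign predictions match the observed
    signature; ``n_ambiguous`` reachable genes had conflicting
    shortest-path signs and were excluded. ``p_value`` is the upper-tail
    binomial probability of k or more correct predictions by chance.
    """

    node: str
    function: str
    predicted_activity: int  # +1 activated, -1 inhibited
    distance: int
    k_correct: int
    n_scored: int
    n_ambiguous: int
    p_value: float
    sign_tie: bool = False

    @property
    def activity_label(self) -> str:
        return "+" if self.predicted_activity > 0 else "-"


def binomial_tail_p(k: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, 1/2), computed exactly.

    Integer arithmetic keeps the tail exact well below double-precision
    underflow of naive products (n up to several hundred is routine).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if k < 0 or k > n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    return sum(comb(n, i) for i in range(k, n + 1)) / (1 << n)


def _propagate_all(
    net: RegulatoryNetwork,
    regulator: str,
    max_distance: int,
    mechanism: str | None = None,
) -> dict[str, tuple[int, frozenset[int]]]:
    """BFS sign propagation from ``regulator`` out to ``max_distance``.

    Returns ``{gene: (distance, sign_products)}`` where ``sign_products``
    is the set of edge-sign products over all shortest paths. When
    ``mechanism`` is given, only edges with that mechanism label are
    traversed (used for the direct-transcription filter at distance 1).
    """
    G = net.graph
    if regulator not in G:
        raise KeyError(f"unknown node: {regulator!r}")

    def edge_ok(u: str, v: str) -> bool:
        return mechanism is None or G[u][v]["mechanism"] == mechanism

    dist: dict[str, int] = {regulator: 0}
    layers: list[list[str]] = [[regulator]]
    for d in range(1, max_distance + 1):
        frontier: list[str] = []
        for u in layers[d - 1]:
            for v in G.successors(u):
                if v not in dist and edge_ok(u, v):
                    dist[v] = d
                    frontier.append(v)
        if not frontier:
            break
        layers.append(frontier)

    signs: dict[str, set[int]] = {regulator: {1}}
    for d in range(1, len(layers)):
        for v in layers[d]:
            acc: set[int] = set()
            for u in G.predecessors(v):
                if dist.get(u) == d - 1 and u in signs and edge_ok(u, v):
                    es = G[u][v]["sign"]
                    acc.update(s * es for s in signs[u])
            signs[v] = acc
    return {
        g: (d, frozenset(signs[g])) for g, d in dist.items() if d > 0
    }


def propagate_sign(
    net: RegulatoryNetwork,
    regulator: str,
    gene: str,
    max_distance: int = 3,
):
    """Predicted sign of ``gene`` under an activated ``regulator``.

    Returns +1 or -1 when all shortest paths within ``max_distance``
    agree, :data:`AMBIGUOUS` when they conflict, and :data:`UNREACHABLE`
    when no such path exists (including ``gene == regulator``).
    """
    if gene not in net.graph:
        raise KeyError(f"unknown node: {gene!r}")
    reach = _propagate_all(net, regulator, max_distance)
    if gene not in reach:
        return UNREACHABLE
    _, signset = reach[gene]
    if len(signset) == 1:
        return next(iter(signset))
    return AMBIGUOUS


def _score_node(
    net: RegulatoryNetwork,
    node: str,
    observed: dict[str, int],
    max_distance: int,
    mechanism: str | None,
    ambiguous_incorrect: bool,
) -> tuple[int, int, int]:
    """Count (k for the ``+`` hypothesis, n scored, n ambiguous)."""
    reach = _propagate_all(net, node, max_distance, mechanism)
    k_plus = n = n_amb = 0
    for gene, obs in observed.items():
        if gene == node or gene not in reach:
            continue
        _, signset = reach[gene]
        if len(signset) != 1:
            n_amb += 1
            continue
        n += 1
        if next(iter(signset)) == obs:
            k_plus += 1
    if ambiguous_incorrect:
        n += n_amb
    return k_plus, n, n_amb


def score_hypotheses(
    net: RegulatoryNetwork,
    sig: GeneSignature,
    max_distance: int = 3,
    alpha: float = 0.05,
    min_n: int = 3,
    ambiguous_incorrect: bool = False,
    _function: str | None = None,
    _mechanism: str | None = None,
) -> list[CausalHypothesis]:
    """Score every network node as an upstream-regulator hypothesis.

    For each node the better of the two activity signs is reported (ties
    broken toward ``+`` and flagged); hypotheses with fewer than
    ``min_n`` scored genes or p-value above ``alpha`` are dropped.
    Regulators need not themselves be differentially expressed.
    """
    observed = sig.observed_signs()
    if not observed:
        raise ValueError("empty signature: nothing to score")
    if max_distance not in (1, 2, 3):
        raise ValueError(f"max_distance must be 1, 2 or 3, got {max_distance}")

    if _function is None:
        candidates = sorted(net.graph.nodes)
    else:
        candidates = net.nodes_with_function(_function)

    out: list[CausalHypothesis] = []
    for node in candidates:
        k_plus, n, n_amb = _score_node(
            net, node, observed, max_distance, _mechanism, ambiguous_incorrect
        )
        if n < min_n:
            continue
        p_plus = binomial_tail_p(k_plus, n)
        p_minus = binomial_tail_p(n - k_plus, n)
        if p_plus <= p_minus:
            sign, k, p = 1, k_plus, p_plus
        else:
            sign, k, p = -1, n - k_plus, p_minus
        if p > alpha:
            continue
        out.append(
            CausalHypothesis(
                node=node,
                function=net.function_of(node),
                predicted_activity=sign,
                distance=max_distance,
                k_correct=k,
                n_scored=n,
                n_ambiguous=n_amb,
                p_value=p,
                sign_tie=(p_plus == p_minus),
            )
        )
    out.sort(key=lambda h: (h.p_value, h.node))
    return out


def filter_hypotheses(
    net: RegulatoryNetwork,
    sig: GeneSignature,
    function: str,
    distance: int,
    alpha: float = 0.05,
    min_n: int = 3,
    require_transcription_mechanism: bool | None = None,
) -> list[CausalHypothesis]:
    """Re-score hypotheses restricted to one molecular function and a
    tighter calculation distance.

    A distance of 1 means the regulator acts one step from the
    transcriptional event; for transcription factors the final edge is
    additionally required to be a transcription-regulation mechanism
    (on by default for ``function='TF'`` at distance 1).
    """
    if function not in NODE_FUNCTIONS:
        raise ValueError(f"unknown molecular function: {function!r}")
    if require_transcription_mechanism is None:
        require_transcription_mechanism = function == "TF" and distance == 1
    mechanism = (
        "transcription-regulation"
        if require_transcription_mechanism and distance == 1
        else None
    )
    return score_hypotheses(
        net,
        sig,
        max_distance=distance,
        alpha=alpha,
        min_n=min_n,
        _function=function,
        _mechanism=mechanism,
    )


def intersect_hypotheses(
    hyps_a: list[CausalHypothesis],
    hyps_b: list[CausalHypothesis],
) -> list[tuple[str, int, float, float]]:
    """(node, sign) hypotheses present in both lists, with both p-values.

    Ordered by the smaller of the two p-values; these are the
    higher-confidence regulators surviving two independent signatures.
    """
    index_b = {(h.node, h.predicted_activity): h.p_value for h in hyps_b}
    out = []
    for h in hyps_a:
        key = (h.node, h.predicted_activity)
        if key in index_b:
            out.append((h.node, h.predicted_activity, h.p_value, index_b[key]))
    out.sort(key=lambda r: (min(r[2], r[3]), r[0]))
    return out


def hypotheses_to_records(hyps: list[CausalHypothesis]) -> list[dict]:
    """Table-shaped dicts (node, function, sign, k, n, ambiguous, distance, p)."""
    return [
        {
            "node": h.node,
            "function": h.function,
            "sign": h.activity_label,
            "k_correct": h.k_correct,
            "n_scored": h.n_scored,
            "n_ambiguous": h.n_ambiguous,
            "distance": h.distance,
            "p_value": h.p_value,
        }
        for h in hyps
    ]
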