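"""Signaling pathway impact analysis (SPIA).

Combines two independent lines of evidence per pathway: over-representation
of the query genes among pathway members (pNDE, hypergeometric tail) and
the net accumulated topological perturbation (pPERT, bootstrap).  Gene-level
perturbation factors solve the linear system

    PF(g) = dE(g) + sum_j beta_{jg} / N_ds(j) * PF(j)

where beta_{jg} is the signed interaction weight of upstream gene j on g
and N_ds(j) the number of genes j regulates in the pathway.  The net
accumulation Acc(g) = PF(g) - dE(g) sums to the pathway statistic tA.
pPERT is the bootstrap probability of |tA| at least as large when the same
evidence values land on random pathway members; pG combines pNDE and
pPERT with Fisher's product rule (chi-square with 4 df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats

_DAMPING = 0.99
_SINGULAR_COND = 1e10


@dataclass
class PathwayTopology:
    """A pathway's member genes plus signed regulatory adjacency.

    ``beta`` maps (source, target) pairs, both members, to +1 (activation)
    or -1 (inhibition).
    """

    name: str
    genes: list[str]
    beta: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has no member genes")
        members = set(self.genes)
        for (src, tgt) in self.beta:
            if src not in members or tgt not in members:
                raise ValueError(
                    f"beta entry ({src}, {tgt}) outside pathway {self.name!r}"
                )

    def n_downstream(self) -> dict[str, int]:
        out: dict[str, int] = {g: 0 for g in self.genes}
        for (src, _tgt) in self.beta:
            out[src] += 1
        return out

    def system_matrix(self) -> np.ndarray:
        """I - B with B[target, source] = beta/N_ds(source)."""
        idx = {g: i for i, g in enumerate(self.genes)}
        m = len(self.genes)
        B = np.zeros((m, m))
        nds = self.n_downstream()
        for (src, tgt), b in self.beta.items():
            B[idx[tgt], idx[src]] += b / nds[src]
        return np.eye(m) - B


def perturbation_factors(
    topology: PathwayTopology,
    delta_e: dict[str, float],
) -> tuple[dict[str, float], dict[str, float], float, bool]:
    """Solve the pathway perturbation system for one evidence vector.

    Returns (PF, Acc, tA, damped): per-gene perturbation factors, net
    accumulations Acc = PF - dE, their sum tA, and whether damping was
    applied because I - B was singular (unit-gain cycles).
    """
    A = topology.system_matrix()
    de = np.array([delta_e.get(g, 0.0) for g in topology.genes], dtype=float)
    damped = False
    if np.linalg.cond(A) > _SINGULAR_COND:
        damped = True
        B = np.eye(len(topology.genes)) - A
        A = np.eye(len(topology.genes)) - _DAMPING * B
    pf = np.linalg.solve(A, de)
    acc = pf - de
    return (
        dict(zip(topology.genes, pf)),
        dict(zip(topology.genes, acc)),
        float(acc.sum()),
        damped,
    )


def hub_pseudo_evidence(
    deg_evidence: dict[str, float],
    hubs: list[tuple[str, int]],
) -> dict[str, float]:
    """Extend DEG evidence with causal hubs absent from the DEG table.

    Hubs carry no measured fold change, so each receives its predicted
    activity sign times the median |log2FC| of the DEG evidence.
    """
    evidence = dict(deg_evidence)
    if deg_evidence:
        med = float(np.median(np.abs(list(deg_evidence.values()))))
    else:
        med = 1.0
    for gene, sign in hubs:
        if gene not in evidence:
            evidence[gene] = float(sign) * med
    return evidence


def spia_run(
    topologies: list[PathwayTopology],
    deg_table: pd.DataFrame,
    hubs: list[tuple[str, int]] | None = None,
    n_boot: int = 500,
    seed: int = 0,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Run SPIA for every pathway against the DEG + hub evidence.

    ``deg_table`` supplies per-gene log2FC evidence; ``hubs`` are
    (gene, sign) causal-regulator calls folded in as pseudo-evidence.
    Returns one row per pathway with tA, pNDE, pPERT, pG and flags,
    ranked by pG ascending.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    deg_evidence = dict(
        zip(deg_table["gene"], deg_table["log2fc"].astype(float))
    )
    evidence = hub_pseudo_evidence(deg_evidence, hubs or [])

    if universe is None:
        universe = set(evidence)
        for top in topologies:
            universe |= set(top.genes)
    N = len(universe)
    query = set(evidence) & universe
    n = len(query)

    rows = []
    for top in topologies:
        members = set(top.genes) & universe
        K = len(members)
        k = len(members & query)
        pnde = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0

        if k == 0:
            rows.append(
                {"pathway": top.name, "tA": 0.0, "pNDE": min(pnde, 1.0),
                 "pPERT": 1.0, "pG": np.nan, "k": k, "K": K,
                 "damped": False, "no_evidence": True}
            )
            continue

        A = top.system_matrix()
        damped = False
        if np.linalg.cond(A) > _SINGULAR_COND:
            damped = True
            B = np.eye(len(top.genes)) - A
            A = np.eye(len(top.genes)) - _DAMPING * B
        lu, piv = linalg.lu_factor(A)

        member_idx = {g: i for i, g in enumerate(top.genes)}
        de = np.zeros(len(top.genes))
        values = []
        for g in sorted(members & query):
            de[member_idx[g]] = evidence[g]
            values.append(evidence[g])
        ta = float(linalg.lu_solve((lu, piv), de).sum() - de.sum())

        # bootstrap: same evidence values on random member positions
        values = np.asarray(values)
        boot_de = np.zeros((len(top.genes), n_boot))
        for b in range(n_boot):
            pos = rng.choice(len(top.genes), size=len(values), replace=False)
            boot_de[pos, b] = rng.permutation(values)
        ta_boot = (
            linalg.lu_solve((lu, piv), boot_de).sum(axis=0) - boot_de.sum(axis=0)
        )
        r = int(np.sum(np.abs(ta_boot) >= abs(ta)))
        ppert = (r + 1) / (n_boot + 1)

        rows.append(
            {"pathway": top.name, "tA": ta, "pNDE": min(pnde, 1.0),
             "pPERT": ppert, "pG": np.nan, "k": k, "K": K,
             "damped": damped, "no_evidence": False}
        )

    result = pd.DataFrame(rows)
    chi = -2.0 * (np.log(result["pNDE"]) + np.log(result["pPERT"]))
    result["pG"] = stats.chi2.sf(chi, df=4)
    result = result.sort_values(
        ["pG", "pathway"], kind="mergesort"
    ).reset_index(drop=True)
    return result


def read_topologies(path: str | Path) -> list[PathwayTopology]:
    """Edge-list TSV (pathway, source, target, beta) -> topologies.

    Isolated member genes can be declared with an empty target and beta 0.
    """
    df = pd.read_csv(path, sep="\t")
    tops = []
    for name, grp in df.groupby("pathway", sort=True):
        genes: list[str] = []
        beta: dict[tuple[str, str], float] = {}
        for _, row in grp.iterrows():
            src = str(row["source"])
            if src not in genes:
                genes.append(src)
            tgt = row["target"]
            if pd.isna(tgt) or tgt == "":
                continue
            tgt = str(tgt)
            if tgt not in genes:
                genes.append(tgt)
            b = float(row["beta"])
            if b != 0:
                beta[(src, tgt)] = b
        tops.append(PathwayTopology(str(name), genes, beta))
    return tops


def write_topologies(tops: list[PathwayTopology], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\tsource\ttarget\tbeta\n")
        for top in tops:
            covered = set()
            for (src, tgt), b in sorted(top.beta.items()):
                fh.write(f"{top.name}\t{src}\t{tgt}\t{b:g}\n")
                covered.update((src, tgt))
            for g in top.genes:
                if g not in covered:
                    fh.write(f"{top.name}\t{g}\t\t0\n")
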