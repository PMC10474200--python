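"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator plants a small set of active/inhibited regulators in a
hub-dominated signed network and lets their activity propagate (sign
products along shortest paths, truncated at distance 3) to produce a DEG
table: downstream genes show the propagated sign except for a noise
fraction epsilon that flips, signal genes draw large |log2FC| and small
p-values, null genes draw near-zero fold changes and uniform p-values.
Pathway sets (one spiked with signal genes), partially overlapping
biomarker lists and a reference rank database containing an exact
reverser of the query complete the inputs, so every downstream stage of
the pipeline is testable without any external download.

All generators derive child RNG streams deterministically from the one
config seed, so equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .causal import _propagate_all
from .connectivity import ReferenceSignatureDB
from .enrichment import GeneSetDB
from .network import RegulatoryNetwork
from .spia import PathwayTopology

# child-stream tags, fixed so each generator is independently reproducible
_STAGE = {"network": 1, "deg": 2, "genesets": 3, "refdb": 4, "biomarkers": 5}

_FUNCTIONS = ("TF", "kinase", "phosphatase", "RNA", "other")
_FUNCTION_P = (0.15, 0.12, 0.05, 0.08, 0.60)

PROPAGATION_DISTANCE = 3  # planted effects truncated at distance 3


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate a single-contrast
    vaccine-response experiment at desk scale."""

    n_genes: int = 800
    n_regulators: int = 2
    network_size: int = 500
    out_degree_mean: float = 3.0
    edge_sign_neg_frac: float = 0.3
    noise_rate: float = 0.05
    effect_mu: float = 2.5  # median |log2FC| of signal genes
    effect_sigma: float = 0.6  # log-scale spread (heavy upper tail)
    null_frac: float = 0.5
    signal_p_beta: tuple[float, float] = (0.5, 200.0)
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 50)
    n_biomarker_lists: int = 2
    biomarker_overlap_frac: float = 0.3
    biomarker_list_size: int = 100
    n_reference_sigs: int = 20
    seed: int = 0

    def validate(self) -> None:
        for name in ("edge_sign_neg_frac", "noise_rate", "null_frac",
                     "biomarker_overlap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes", "n_regulators", "network_size",
                     "n_pathways", "n_biomarker_lists", "biomarker_list_size",
                     "n_reference_sigs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.out_degree_mean <= 0:
            raise ValueError("out_degree_mean must be positive")
        if self.effect_sigma < 0:
            raise ValueError("effect_sigma must be non-negative")
        lo, hi = self.pathway_size_range
        if lo < 2 or hi < lo:
            raise ValueError("pathway sizes must be >= 2 and ordered")
        if min(self.signal_p_beta) <= 0:
            raise ValueError("signal_p_beta parameters must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence((self.seed, _STAGE[stage]))
        )


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    planted_regulators: list[tuple[str, int]]
    true_signal_genes: set[str]
    reverser_signature_id: str | None = None
    mimic_signature_id: str | None = None
    propagated_signs: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_regulators": [[n, s] for n, s in self.planted_regulators],
            "true_signal_genes": sorted(self.true_signal_genes),
            "reverser_signature_id": self.reverser_signature_id,
            "mimic_signature_id": self.mimic_signature_id,
            "propagated_signs": dict(sorted(self.propagated_signs.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_regulators=[(n, int(s)) for n, s in d["planted_regulators"]],
            true_signal_genes=set(d["true_signal_genes"]),
            reverser_signature_id=d.get("reverser_signature_id"),
            mimic_signature_id=d.get("mimic_signature_id"),
            propagated_signs={g: int(s) for g, s in d["propagated_signs"].items()},
        )


def _mechanism_for(rng: np.random.Generator, function: str) -> str:
    if function == "TF":
        return "transcription-regulation" if rng.random() < 0.85 else "binding"
    if function in ("kinase", "phosphatase"):
        return "phosphorylation" if rng.random() < 0.85 else "binding"
    return "binding" if rng.random() < 0.6 else "other"


def generate_network(cfg: SimulationConfig) -> RegulatoryNetwork:
    """Hub-dominated signed directed network.

    Each node emits Poisson(out_degree_mean) edges whose targets are
    chosen preferentially by current in-degree, reproducing the
    heavy-tailed degree structure of curated regulatory databases.
    Expected edge count is network_size * out_degree_mean.
    """
    cfg.validate()
    rng = cfg.rng("network")
    n = cfg.network_size
    names = [f"G{i:04d}" for i in range(n)]
    functions = rng.choice(len(_FUNCTIONS), size=n, p=_FUNCTION_P)

    net = RegulatoryNetwork()
    for name, fi in zip(names, functions):
        net.add_node(name, _FUNCTIONS[fi])
    if n == 1:
        return net

    in_deg = np.ones(n)  # +1 smoothing for preferential attachment
    for i in range(n):
        d = min(int(rng.poisson(cfg.out_degree_mean)), n - 1)
        if d == 0:
            continue
        w = in_deg.copy()
        w[i] = 0.0
        targets = rng.choice(n, size=d, replace=False, p=w / w.sum())
        src_fn = _FUNCTIONS[functions[i]]
        for t in targets:
            sign = -1 if rng.random() < cfg.edge_sign_neg_frac else 1
            net.add_edge(names[i], names[t], sign, _mechanism_for(rng, src_fn))
            in_deg[t] += 1.0
    return net


def _downstream_reach(net: RegulatoryNetwork, node: str) -> dict[str, int]:
    """Unambiguous propagated signs within the planting distance."""
    reach = _propagate_all(net, node, PROPAGATION_DISTANCE)
    return {
        g: next(iter(signs))
        for g, (_d, signs) in reach.items()
        if len(signs) == 1
    }


def pick_planted_regulators(
    net: RegulatoryNetwork, cfg: SimulationConfig
) -> list[str]:
    """The n_regulators nodes with the widest unambiguous downstream
    reach, preferring transcription factors (deterministic given the
    network)."""
    scored = []
    for node in sorted(net.graph.nodes):
        reach = len(_downstream_reach(net, node))
        if reach > 0:
            is_tf = net.function_of(node) == "TF"
            scored.append((-int(is_tf), -reach, node))
    if len(scored) < cfg.n_regulators:
        raise ValueError(
            "network has too few nodes with downstream targets; "
            "increase network_size or out_degree_mean"
        )
    scored.sort()
    return [node for *_, node in scored[: cfg.n_regulators]]


def generate_deg_table(
    net: RegulatoryNetwork, cfg: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Observed DEG table implied by the planted regulators.

    Signal genes take the propagated sign (flipped with probability
    noise_rate), a heavy-tailed magnitude |log2FC| ~ Lognormal with
    median effect_mu and log-sd effect_sigma, and p ~ Beta(signal_p_beta);
    null genes take log2FC ~ Normal(0, 0.3) and p ~ Uniform(0, 1).
    FDR is Benjamini-Hochberg across the table.
    """
    cfg.validate()
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    rng = cfg.rng("deg")

    regulators = pick_planted_regulators(net, cfg)
    reg_signs = [1 if i % 2 == 0 else -1 for i in range(len(regulators))]
    planted = list(zip(regulators, reg_signs))

    # consensus propagated sign per gene; cross-regulator conflicts dropped
    propagated: dict[str, int] = {}
    conflicted: set[str] = set()
    for reg, rsign in planted:
        for gene, psign in _downstream_reach(net, reg).items():
            s = rsign * psign
            if gene in propagated and propagated[gene] != s:
                conflicted.add(gene)
            propagated.setdefault(gene, s)
    for gene in conflicted:
        propagated.pop(gene, None)
    for reg, _ in planted:
        propagated.pop(reg, None)

    n_signal = min(
        len(propagated), int(round((1.0 - cfg.null_frac) * cfg.n_genes))
    )
    signal_genes = sorted(propagated)[:n_signal]
    truth_signs = {g: propagated[g] for g in signal_genes}

    other_nodes = sorted(set(net.graph.nodes) - set(signal_genes))
    n_null = cfg.n_genes - n_signal
    null_genes = other_nodes[:n_null]
    n_fill = n_null - len(null_genes)
    null_genes += [f"X{i:04d}" for i in range(n_fill)]

    rows = []
    for g in signal_genes:
        sign = truth_signs[g]
        if rng.random() < cfg.noise_rate:
            sign = -sign
        mag = rng.lognormal(np.log(cfg.effect_mu), cfg.effect_sigma)
        rows.append((g, sign * mag, float(rng.beta(*cfg.signal_p_beta))))
    for g in null_genes:
        rows.append((g, float(rng.normal(0.0, 0.3)), float(rng.uniform())))

    table = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue"])
    table["fdr"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    table = table.sort_values("gene", kind="mergesort").reset_index(drop=True)

    truth = GroundTruth(
        planted_regulators=planted,
        true_signal_genes=set(signal_genes),
        propagated_signs=truth_signs,
    )
    return table, truth


def generate_genesets(
    net: RegulatoryNetwork,
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> tuple[GeneSetDB, list[PathwayTopology]]:
    """Pathway database over the network's genes.

    The first pathway is *spiked*: ~70% of its members are drawn from
    the true signal genes, the rest at random; remaining pathways are
    uniform draws.  Each pathway carries a sparse signed topology among
    its members.
    """
    cfg.validate()
    rng = cfg.rng("genesets")
    universe = sorted(net.graph.nodes)
    if not universe:
        raise ValueError("empty gene universe")
    lo, hi = cfg.pathway_size_range
    if hi > len(universe):
        raise ValueError("pathway size exceeds the gene universe")

    sets: dict[str, set[str]] = {}
    tops: list[PathwayTopology] = []
    signal = sorted(truth.true_signal_genes & set(universe))
    for i in range(cfg.n_pathways):
        name = f"PW{i:03d}" + ("_SPIKED" if i == 0 else "")
        size = int(rng.integers(lo, hi + 1))
        if i == 0 and signal:
            n_sig = min(len(signal), max(1, int(round(0.7 * size))))
            members = set(
                rng.choice(signal, size=n_sig, replace=False).tolist()
            )
            rest = [g for g in universe if g not in members]
            extra = size - len(members)
            if extra > 0:
                members |= set(
                    rng.choice(rest, size=extra, replace=False).tolist()
                )
        else:
            members = set(
                rng.choice(universe, size=size, replace=False).tolist()
            )
        sets[name] = members

        genes = sorted(members)
        beta: dict[tuple[str, str], float] = {}
        p_edge = min(1.0, 2.0 / max(len(genes) - 1, 1))
        for src in genes:
            for tgt in genes:
                if src != tgt and rng.random() < p_edge:
                    beta[(src, tgt)] = (
                        -1.0 if rng.random() < cfg.edge_sign_neg_frac else 1.0
                    )
        tops.append(PathwayTopology(name, genes, beta))

    return GeneSetDB(sets, set(universe)), tops


def query_ordering(deg_table: pd.DataFrame) -> list[str]:
    """Genes ordered most-upregulated first (rank 1), ties lexicographic."""
    ordered = deg_table.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    )
    return list(ordered["gene"])


def generate_reference_db(
    deg_table: pd.DataFrame,
    cfg: SimulationConfig,
    truth: GroundTruth | None = None,
) -> ReferenceSignatureDB:
    """Reference rank database: random permutations plus an exact
    reverser (query order inverted) and an exact mimic of the query."""
    cfg.validate()
    if len(deg_table) == 0:
        raise ValueError("empty DEG table")
    rng = cfg.rng("refdb")
    genes = query_ordering(deg_table)
    n = len(genes)
    query_rank = pd.Series(np.arange(1, n + 1), index=genes)

    cols: dict[str, np.ndarray] = {}
    meta: dict[str, str] = {}
    for i in range(cfg.n_reference_sigs):
        sig = f"SIG{i:03d}"
        cols[sig] = rng.permutation(n) + 1
        meta[sig] = "random perturbation"
    cols["REVERSER"] = (n + 1 - query_rank.to_numpy()).astype(int)
    meta["REVERSER"] = "exact reverser of the query ordering"
    cols["MIMIC"] = query_rank.to_numpy().astype(int)
    meta["MIMIC"] = "exact mimic of the query ordering"

    ranks = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    if truth is not None:
        truth.reverser_signature_id = "REVERSER"
        truth.mimic_signature_id = "MIMIC"
    return ReferenceSignatureDB(ranks, meta)


def generate_biomarker_lists(
    deg_table: pd.DataFrame,
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> list[set[str]]:
    """Biomarker gene lists partially overlapping the signal genes.

    A biomarker_overlap_frac share of each list is drawn from the true
    signal genes (and planted regulators); the remainder are bystander
    symbols absent from the study."""
    cfg.validate()
    rng = cfg.rng("biomarkers")
    pool = sorted(
        truth.true_signal_genes | {n for n, _ in truth.planted_regulators}
    )
    lists = []
    for i in range(cfg.n_biomarker_lists):
        size = cfg.biomarker_list_size
        n_overlap = min(len(pool), int(round(cfg.biomarker_overlap_frac * size)))
        chosen = set(rng.choice(pool, size=n_overlap, replace=False).tolist())
        n_fill = size - len(chosen)
        chosen |= {f"BM{i}_{j:03d}" for j in range(n_fill)}
        lists.append(chosen)
    return lists
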