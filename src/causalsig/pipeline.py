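"""End-to-end orchestration of the signature -> causal -> pathway workflow.

Stages: derive GS1/GS2 signatures from the DEG table, trim the larger
one to the causal engine's preferred query size, score upstream-regulator
hypotheses for both signatures, filter to direct-acting transcription
factors (and RNA regulators), intersect across signatures, score
biomarker overlaps, run over-representation and SPIA on the DEG+hub
union, and score the query against the reference perturbation database.
All intermediate tables are written under the run directory; a JSON
report summarizes counts, top hits and warnings.  Reruns with the same
config and inputs are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .causal import (
    filter_hypotheses,
    hypotheses_to_records,
    intersect_hypotheses,
    score_hypotheses,
)
from .connectivity import (
    ReferenceSignatureDB,
    build_query,
    connectivity_score,
    results_to_frame,
)
from .enrichment import GeneSetDB, hypergeom_enrich
from .network import RegulatoryNetwork
from .overlap import EvidenceLists, overlaps_to_frame, score_overlaps, venn_counts, venn_counts_to_tsv
from .signatures import build_signature, read_deg_table, trim_signature, write_deg_table
from .spia import read_topologies, spia_run, write_topologies
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    generate_biomarker_lists,
    generate_deg_table,
    generate_genesets,
    generate_network,
    generate_reference_db,
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name as a machine-readable code."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    outdir: str = "causalsig_run"
    seed: int = 1
    synthetic: bool = True
    sim: dict = field(default_factory=dict)

    # file inputs, used when synthetic=False
    deg_table: str | None = None
    network_edges: str | None = None
    network_nodes: str | None = None
    genesets_gmt: str | None = None
    topologies: str | None = None
    biomarkers: str | None = None
    reference_db: str | None = None

    gs1_log2fc: float = 2.00
    gs2_log2fc: float = 5.00
    fdr_cut: float = 0.05
    trim_target: int = 1100
    max_distance: int = 3
    alpha: float = 0.05
    tf_distance: int = 1
    min_n: int = 3
    n_per_side: int = 50
    n_boot: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.synthetic:
        sim = SimulationConfig(**{**cfg.sim, "seed": cfg.seed})
        net = generate_network(sim)
        table, truth = generate_deg_table(net, sim)
        db, tops = generate_genesets(net, truth, sim)
        refdb = generate_reference_db(table, sim, truth)
        biomarkers = generate_biomarker_lists(table, truth, sim)[0]
        net.write_sif(outdir / "network_edges.sif", outdir / "network_nodes.tsv")
        write_deg_table(table, outdir / "deg_table.tsv")
        db.to_gmt(outdir / "genesets.gmt")
        write_topologies(tops, outdir / "topologies.tsv")
        refdb.to_tsv(outdir / "reference_db.tsv")
        io.write_gene_list(biomarkers, outdir / "biomarkers.txt")
        truth.to_json(outdir / "ground_truth.json")
        return net, table, db, tops, biomarkers, refdb, truth

    for name in ("deg_table", "network_edges", "genesets_gmt",
                 "topologies", "biomarkers", "reference_db"):
        path = getattr(cfg, name)
        if path is None:
            raise PipelineError("config", f"missing input path: {name}")
        if not Path(path).exists():
            raise PipelineError("config", f"input file not found: {name}={path}")
    net = RegulatoryNetwork.read_sif(cfg.network_edges, cfg.network_nodes)
    table = read_deg_table(cfg.deg_table)
    db = GeneSetDB.from_gmt(cfg.genesets_gmt)
    tops = read_topologies(cfg.topologies)
    biomarkers = io.read_gene_list(cfg.biomarkers)
    refdb = ReferenceSignatureDB.from_tsv(cfg.reference_db)
    return net, table, db, tops, biomarkers, refdb, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": asdict(cfg),
        "counts": {},
        "top": {},
        "warnings": [],
    }

    def _stage(name: str, fn, *args, **kwargs):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                result = fn(*args, **kwargs)
            report["warnings"].extend(f"{name}: {w.message}" for w in caught)
            return result
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise PipelineError(name, str(exc)) from exc

    net, table, db, tops, biomarkers, refdb, truth = _stage(
        "inputs", _load_inputs, cfg, outdir
    )
    report["counts"]["deg_table"] = len(table)

    gs1 = _stage("signatures", build_signature, table, cfg.gs1_log2fc, cfg.fdr_cut, "GS1")
    gs2 = _stage("signatures", build_signature, table, cfg.gs2_log2fc, cfg.fdr_cut, "GS2")
    gs1 = _stage("trim", trim_signature, gs1, table, cfg.trim_target)
    gs1.write_tsv(outdir / "gs1.tsv")
    gs2.write_tsv(outdir / "gs2.tsv")
    report["counts"]["gs1"] = len(gs1)
    report["counts"]["gs2"] = len(gs2)
    if len(gs2) == 0:
        raise PipelineError("signatures", "GS2 selected no genes; lower gs2_log2fc")

    hyps1 = _stage("causal", score_hypotheses, net, gs1,
                   cfg.max_distance, cfg.alpha, cfg.min_n)
    hyps2 = _stage("causal", score_hypotheses, net, gs2,
                   cfg.max_distance, cfg.alpha, cfg.min_n)
    for name, hyps in (("hypotheses_gs1", hyps1), ("hypotheses_gs2", hyps2)):
        pd.DataFrame(hypotheses_to_records(hyps)).to_csv(
            outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        report["counts"][name] = len(hyps)

    tf1 = _stage("filter", filter_hypotheses, net, gs1, "TF", cfg.tf_distance,
                 cfg.alpha, cfg.min_n)
    tf2 = _stage("filter", filter_hypotheses, net, gs2, "TF", cfg.tf_distance,
                 cfg.alpha, cfg.min_n)
    rna1 = _stage("filter", filter_hypotheses, net, gs1, "RNA", cfg.max_distance,
                  cfg.alpha, cfg.min_n)
    for name, hyps in (("tf_gs1", tf1), ("tf_gs2", tf2), ("rna_gs1", rna1)):
        pd.DataFrame(hypotheses_to_records(hyps)).to_csv(
            outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        report["counts"][name] = len(hyps)

    common = _stage("intersect", intersect_hypotheses, hyps1, hyps2)
    pd.DataFrame(
        common, columns=["node", "sign", "p_gs1", "p_gs2"]
    ).to_csv(outdir / "intersection.tsv", sep="\t", index=False,
             float_format="%.6g")
    report["counts"]["intersection"] = len(common)
    report["top"]["intersection"] = [
        {"node": n, "sign": s, "p_gs1": pa, "p_gs2": pb}
        for n, s, pa, pb in common[:5]
    ]

    lists = EvidenceLists(
        biomarkers=biomarkers,
        degs=gs1.genes() | gs2.genes(),
        hubs_gs1={h.node for h in hyps1},
        hubs_gs2={h.node for h in hyps2},
    )
    records = _stage("overlap", score_overlaps, lists, hyps1, hyps2)
    overlaps_to_frame(records).to_csv(
        outdir / "overlap_scores.tsv", sep="\t", index=False,
        float_format="%.6g")
    venn_counts_to_tsv(venn_counts(lists), outdir / "venn_counts.tsv")
    report["counts"]["overlap_records"] = len(records)

    hub_query = {n for n, *_ in common} or {h.node for h in hyps1[:10]}
    enr = _stage("enrichment", hypergeom_enrich, hub_query, db, cfg.alpha)
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
               float_format="%.6g")
    report["counts"]["enrichment_sets"] = len(enr)
    report["top"]["enrichment"] = enr.head(3)[
        ["set_name", "p_value"]].to_dict("records")

    hubs = [(h.node, h.predicted_activity) for h in hyps1]
    spia = _stage("spia", spia_run, tops,
                  table[table["gene"].isin(gs1.genes())],
                  hubs, cfg.n_boot, cfg.seed)
    spia.to_csv(outdir / "spia.tsv", sep="\t", index=False,
                float_format="%.6g")
    report["counts"]["spia_pathways"] = len(spia)
    report["top"]["spia"] = spia.head(3)[
        ["pathway", "tA", "pG"]].to_dict("records")

    query = _stage("connectivity", build_query, table, cfg.n_per_side)
    conn = _stage("connectivity", connectivity_score, query, refdb)
    results_to_frame(conn).to_csv(
        outdir / "connectivity.tsv", sep="\t", index=False,
        float_format="%.6g")
    report["counts"]["connectivity_sigs"] = len(conn)
    report["top"]["connectivity"] = [
        {"signature": r.signature_id, "score": round(r.score, 2)}
        for r in conn[:3]
    ]
    if truth is not None:
        report["ground_truth_planted"] = [
            [n, s] for n, s in truth.planted_regulators
        ]

    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
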