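"""Generator contracts: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from causalsig import (
    SimulationConfig,
    generate_biomarker_lists,
    generate_deg_table,
    generate_genesets,
    generate_network,
    generate_reference_db,
)
from causalsig.causal import _propagate_all
from causalsig.synthetic import PROPAGATION_DISTANCE, query_ordering


def _edges(net):
    return sorted(net.graph.edges(data=True), key=lambda e: e[:2])


class TestGenerateNetwork:
    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            generate_network(SimulationConfig(network_size=0))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_rate=1.5).validate()

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=7, network_size=120)
        assert _edges(generate_network(cfg)) == _edges(generate_network(cfg))

    def test_different_seeds_differ(self):
        a = generate_network(SimulationConfig(seed=1, network_size=120))
        b = generate_network(SimulationConfig(seed=2, network_size=120))
        assert _edges(a) != _edges(b)

    def test_edge_count_follows_degree_law(self):
        # E[edges] = network_size * out_degree_mean (Poisson sum)
        counts = [
            generate_network(
                SimulationConfig(seed=s, network_size=50, out_degree_mean=3.0)
            ).number_of_edges()
            for s in range(30)
        ]
        assert abs(np.mean(counts) - 150) < 3 * np.sqrt(150) / np.sqrt(30) + 5
        for c in counts:
            assert abs(c - 150) < 6 * np.sqrt(150)

    def test_annotations_complete(self):
        net = generate_network(SimulationConfig(seed=3, network_size=80))
        for _n, d in net.graph.nodes(data=True):
            assert d["function"] in {"TF", "kinase", "phosphatase", "RNA", "other"}
        for _u, _v, d in net.graph.edges(data=True):
            assert d["sign"] in (1, -1)
            assert d["mechanism"] in {
                "transcription-regulation", "phosphorylation", "binding", "other"
            }
        assert all(u != v for u, v in net.graph.edges())


class TestGenerateDegTable:
    def test_noiseless_signs_match_propagation(self):
        cfg = SimulationConfig(seed=5, network_size=200, n_genes=300,
                               noise_rate=0.0)
        net = generate_network(cfg)
        table, truth = generate_deg_table(net, cfg)
        observed = dict(zip(table["gene"], np.sign(table["log2fc"])))
        # every signal gene carries its propagated sign exactly
        for gene, sign in truth.propagated_signs.items():
            assert observed[gene] == sign
        # and that sign is re-derivable from some planted regulator
        for gene in truth.true_signal_genes:
            explained = False
            for reg, rsign in truth.planted_regulators:
                reach = _propagate_all(net, reg, PROPAGATION_DISTANCE)
                if gene in reach and len(reach[gene][1]) == 1:
                    explained |= (
                        rsign * next(iter(reach[gene][1])) == observed[gene]
                    )
            assert explained

    def test_half_noise_halves_concordance(self):
        cfg = SimulationConfig(seed=9, network_size=300, n_genes=500,
                               noise_rate=0.5)
        net = generate_network(cfg)
        table, truth = generate_deg_table(net, cfg)
        sig = table[table["gene"].isin(truth.true_signal_genes)]
        obs = dict(zip(sig["gene"], np.sign(sig["log2fc"])))
        agree = [obs[g] == s for g, s in truth.propagated_signs.items()]
        n = len(agree)
        assert abs(np.mean(agree) - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_pure_null_selects_nothing(self):
        cfg = SimulationConfig(seed=2, network_size=100, n_genes=300,
                               null_frac=1.0)
        net = generate_network(cfg)
        table, truth = generate_deg_table(net, cfg)
        assert truth.true_signal_genes == set()
        assert (table["fdr"] <= 0.05).sum() == 0

    def test_bh_null_calibration_across_seeds(self):
        # BH on pure-null p-vectors: P(any rejection) <= alpha, so the
        # mean rejection indicator over seeds stays within 2 SE of 0.05
        rng = np.random.default_rng(123)
        alpha, n_seeds = 0.05, 200
        any_rej = [
            (multipletests(rng.uniform(size=150), method="fdr_bh")[1] <= alpha).any()
            for _ in range(n_seeds)
        ]
        se = np.sqrt(alpha * (1 - alpha) / n_seeds)
        assert np.mean(any_rej) <= alpha + 2 * se

    def test_table_determinism(self):
        cfg = SimulationConfig(seed=4, network_size=150, n_genes=200)
        net = generate_network(cfg)
        t1, _ = generate_deg_table(net, cfg)
        t2, _ = generate_deg_table(net, cfg)
        pd.testing.assert_frame_equal(t1, t2)


class TestGenesetsAndReferences:
    def test_spiked_pathway_enriched_for_signal(self, sim_bundle):
        cfg, net, _table, truth = sim_bundle
        db, tops = generate_genesets(net, truth, cfg)
        spiked = next(s for s in db.sets if "SPIKED" in s)
        frac_spiked = len(db.sets[spiked] & truth.true_signal_genes) / len(
            db.sets[spiked]
        )
        background = len(truth.true_signal_genes) / len(db.universe)
        assert frac_spiked > 2 * background
        assert len(db.sets) == cfg.n_pathways
        for top in tops:
            members = set(top.genes)
            assert all(s in members and t in members for s, t in top.beta)

    def test_pathway_size_exceeding_universe_errors(self, sim_bundle):
        cfg, net, _table, truth = sim_bundle
        big = SimulationConfig(seed=cfg.seed, network_size=cfg.network_size,
                               pathway_size_range=(2, 10_000))
        with pytest.raises(ValueError):
            generate_genesets(net, truth, big)

    def test_reference_columns_are_permutations(self, sim_bundle):
        cfg, _net, table, truth = sim_bundle
        db = generate_reference_db(table, cfg, truth)
        n = len(db.ranks)
        for col in db.ranks.columns:
            assert sorted(db.ranks[col]) == list(range(1, n + 1))
            assert db.ranks[col].sum() == n * (n + 1) // 2

    def test_reverser_is_exact_reverse_of_query_order(self, sim_bundle):
        cfg, _net, table, truth = sim_bundle
        db = generate_reference_db(table, cfg, truth)
        order = query_ordering(table)
        n = len(order)
        rev = db.ranks[truth.reverser_signature_id]
        assert all(rev[g] == n - i for i, g in enumerate(order))
        assert truth.reverser_signature_id in db.signature_ids

    def test_biomarker_lists_partially_overlap(self, sim_bundle):
        cfg, _net, table, truth = sim_bundle
        lists = generate_biomarker_lists(table, truth, cfg)
        assert len(lists) == cfg.n_biomarker_lists
        pool = truth.true_signal_genes | {n for n, _ in truth.planted_regulators}
        for lst in lists:
            assert len(lst) == cfg.biomarker_list_size
            overlap = len(lst & pool)
            assert 0 < overlap < len(lst)
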