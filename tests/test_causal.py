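"""Sign propagation, binomial hypothesis scoring and filtering."""

from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalsig import (
    GeneSignature,
    RegulatoryNetwork,
    binomial_tail_p,
    filter_hypotheses,
    intersect_hypotheses,
    propagate_sign,
    score_hypotheses,
)
from causalsig.causal import AMBIGUOUS, UNREACHABLE


def _two_path_net(signs_ab: tuple[int, int], signs_cd: tuple[int, int]):
    """A reaches B via C (signs_ab) and via D (signs_cd)."""
    net = RegulatoryNetwork()
    for n in "ABCD":
        net.add_node(n)
    net.add_edge("A", "C", signs_ab[0])
    net.add_edge("C", "B", signs_ab[1])
    net.add_edge("A", "D", signs_cd[0])
    net.add_edge("D", "B", signs_cd[1])
    return net


class TestPropagateSign:
    def test_single_inhibition_edge(self):
        net = RegulatoryNetwork()
        net.add_edge("A", "B", -1)
        assert propagate_sign(net, "A", "B", 1) == -1

    def test_agreeing_two_step_paths(self):
        net = _two_path_net((1, -1), (-1, 1))
        assert propagate_sign(net, "A", "B", 2) == -1

    def test_conflicting_two_step_paths(self):
        net = _two_path_net((1, 1), (1, -1))
        assert propagate_sign(net, "A", "B", 2) is AMBIGUOUS

    def test_distance_cutoff_makes_unreachable(self):
        net = RegulatoryNetwork()
        net.add_edge("A", "B", 1)
        net.add_edge("B", "C", 1)
        assert propagate_sign(net, "A", "C", 1) is UNREACHABLE
        assert propagate_sign(net, "A", "C", 2) == 1

    def test_only_shortest_paths_count(self):
        # direct negative edge beats a longer positive detour
        net = RegulatoryNetwork()
        net.add_edge("A", "B", -1)
        net.add_edge("A", "C", 1)
        net.add_edge("C", "B", 1)
        assert propagate_sign(net, "A", "B", 3) == -1

    def test_unknown_node_errors(self):
        net = RegulatoryNetwork()
        net.add_edge("A", "B", 1)
        with pytest.raises(KeyError):
            propagate_sign(net, "A", "Z", 2)


class TestBinomialTail:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (17, 17, 7.63e-06),
            (60, 62, 4.24e-16),
            (15, 16, 2.59e-04),
            (0, 5, 1.0),
        ],
    )
    def test_reference_values(self, k, n, expected):
        assert binomial_tail_p(k, n) == pytest.approx(expected, rel=5e-3)

    def test_matches_exhaustive_enumeration(self):
        # oracle: count sign-outcome vectors with >= k successes
        for n in range(1, 13):
            outcomes = list(product([0, 1], repeat=n))
            for k in range(n + 1):
                frac = sum(sum(o) >= k for o in outcomes) / 2**n
                assert binomial_tail_p(k, n) == pytest.approx(frac, abs=1e-12)

    def test_certainty_and_errors(self):
        assert binomial_tail_p(10, 10) == 0.5**10
        with pytest.raises(ValueError):
            binomial_tail_p(5, 4)
        with pytest.raises(ValueError):
            binomial_tail_p(0, 0)

    @given(st.integers(1, 30).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, n - 1))))
    @settings(derandomize=True, max_examples=60)
    def test_strictly_decreasing_in_k(self, nk):
        # n bounded so the point mass C(n,k)/2^n stays above double epsilon
        n, k = nk
        assert binomial_tail_p(k + 1, n) < binomial_tail_p(k, n)


class TestScoreHypotheses:
    def test_fully_concordant_star(self, star_net):
        sig = GeneSignature("S", tuple(f"D{i}" for i in range(10)), (), 2.0, 0.05)
        hyps = score_hypotheses(star_net, sig, max_distance=1)
        assert len(hyps) == 1
        h = hyps[0]
        assert (h.node, h.predicted_activity) == ("T", 1)
        assert (h.k_correct, h.n_scored) == (10, 10)
        assert h.p_value == pytest.approx(0.5**10)

    def test_half_discordant_star_filtered_at_alpha(self, star_net):
        sig = GeneSignature(
            "S",
            tuple(f"D{i}" for i in range(5)),
            tuple(f"D{i}" for i in range(5, 10)),
            2.0,
            0.05,
        )
        assert score_hypotheses(star_net, sig, max_distance=1, alpha=0.05) == []
        hyps = score_hypotheses(star_net, sig, max_distance=1, alpha=1.0)
        (h,) = [h for h in hyps if h.node == "T"]
        assert (h.k_correct, h.n_scored) == (5, 10)
        assert h.p_value == pytest.approx(0.6230468750)
        assert h.sign_tie

    def test_sign_flip_maps_k_to_n_minus_k(self, star_net):
        # all observed down: the inhibited hypothesis explains everything
        sig = GeneSignature("S", (), tuple(f"D{i}" for i in range(10)), 2.0, 0.05)
        (h,) = score_hypotheses(star_net, sig, max_distance=1)
        assert h.predicted_activity == -1
        assert (h.k_correct, h.n_scored) == (10, 10)

    def test_ambiguous_genes_excluded_from_n(self):
        net = _two_path_net((1, 1), (1, -1))  # B ambiguous from A
        for i in range(3):
            net.add_edge("A", f"E{i}", 1)
        sig = GeneSignature("S", ("B", "E0", "E1", "E2"), (), 2.0, 0.05)
        hyps = score_hypotheses(net, sig, max_distance=2, alpha=1.0, min_n=1)
        (h,) = [h for h in hyps if h.node == "A"]
        assert h.n_scored == 3  # E0..E2; ambiguous B excluded
        assert h.n_ambiguous == 1
        assert h.k_correct == 3

    def test_ambiguous_as_incorrect_flag(self):
        net = _two_path_net((1, 1), (1, -1))
        sig = GeneSignature("S", ("B", "C", "D"), (), 2.0, 0.05)
        hyps = score_hypotheses(
            net, sig, max_distance=2, alpha=1.0, min_n=1,
            ambiguous_incorrect=True,
        )
        (h,) = [h for h in hyps if h.node == "A"]
        assert h.n_scored == 3 and h.k_correct == 2

    def test_empty_signature_errors(self, star_net):
        with pytest.raises(ValueError):
            score_hypotheses(star_net, GeneSignature("S", (), (), 2.0, 0.05))


class TestFilterAndIntersect:
    def test_tf_distance1_mechanism_filter(self):
        net = RegulatoryNetwork()
        net.add_node("T", "TF")
        net.add_node("K", "kinase")
        for i in range(8):
            net.add_edge("T", f"D{i}", 1, "transcription-regulation")
            net.add_edge("K", f"D{i}", 1, "phosphorylation")
        sig = GeneSignature("S", tuple(f"D{i}" for i in range(8)), (), 2.0, 0.05)
        hyps = filter_hypotheses(net, sig, "TF", 1)
        assert [h.node for h in hyps] == ["T"]
        assert hyps[0].p_value == pytest.approx(0.5**8)
        # the kinase would match at distance 1 without the function filter
        assert filter_hypotheses(net, sig, "kinase", 1) != []

    def test_mechanism_excludes_non_transcription_edges(self):
        net = RegulatoryNetwork()
        net.add_node("T", "TF")
        for i in range(6):
            net.add_edge("T", f"D{i}", 1, "binding")
        sig = GeneSignature("S", tuple(f"D{i}" for i in range(6)), (), 2.0, 0.05)
        assert filter_hypotheses(net, sig, "TF", 1) == []
        assert filter_hypotheses(
            net, sig, "TF", 1, require_transcription_mechanism=False
        ) != []

    def test_unknown_function_errors(self, star_net):
        sig = GeneSignature("S", ("D0", "D1", "D2"), (), 2.0, 0.05)
        with pytest.raises(ValueError):
            filter_hypotheses(star_net, sig, "chaperone", 1)

    def test_intersection_on_node_and_sign(self, star_net):
        up = tuple(f"D{i}" for i in range(10))
        sig_up = GeneSignature("U", up, (), 2.0, 0.05)
        sig_dn = GeneSignature("D", (), up, 2.0, 0.05)
        h_up = score_hypotheses(star_net, sig_up, 1)
        h_dn = score_hypotheses(star_net, sig_dn, 1)
        assert intersect_hypotheses(h_up, h_up)[0][:2] == ("T", 1)
        assert intersect_hypotheses(h_up, h_dn) == []  # opposite signs
        assert len(intersect_hypotheses(h_up, h_up)) == len(h_up)
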