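import math

import numpy as np
import pytest

from egdelim.io_formats import Alignment
from egdelim.ktheta import (
    KThetaConfig,
    clade_diversity,
    between_clade_K,
    ktheta_test,
    reciprocal_monophyly_prob,
    run_ktheta,
    select_comparison_pairs,
    _ancestral_rm_prob,
)
from egdelim.phylo_trees import Clade, parse_newick
from egdelim.subst_models import SubstitutionModel


def jc_distance(p):
    return -0.75 * math.log(1 - 4 * p / 3)


def find_node(tree, labels):
    want = frozenset(labels)
    for node in tree.preorder_node_iter():
        if frozenset(l.taxon.label for l in node.leaf_iter()) == want:
            return node
    raise AssertionError(f"no node with leafset {labels}")


class TestCladeDiversity:
    def test_all_identical_uses_floor(self):
        seq = "ACGT" * 96 + "A"  # L = 385
        aln = Alignment.from_records([(f"s{i}", seq) for i in range(5)])
        cd = clade_diversity(aln, [f"s{i}" for i in range(5)])
        assert cd.all_identical
        assert cd.d == pytest.approx(2 / (385 * 5), abs=1e-9)
        assert cd.pi == pytest.approx(0.0012987, abs=1e-6)

    def test_hand_arithmetic(self):
        # two sequences differing at 4/400 sites: d = 0.01
        a = "A" * 400
        b = "C" * 4 + "A" * 396
        aln = Alignment.from_records([("a", a), ("b", b)])
        cd = clade_diversity(aln, ["a", "b"])
        assert cd.d == pytest.approx(0.01)
        assert cd.pi == pytest.approx(0.02)
        assert cd.theta == pytest.approx(0.0205479, abs=1e-6)

    def test_singleton_is_null_not_error(self):
        aln = Alignment.from_records([("a", "ACGT")])
        cd = clade_diversity(aln, ["a"])
        assert cd.n == 1 and cd.d is None and cd.theta is None

    def test_theta_pi_d_ordering(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        c = "G" * 5 + "A" * 95
        aln = Alignment.from_records([("a", a), ("b", b), ("c", c)])
        cd = clade_diversity(aln, "abc")
        assert cd.theta >= cd.pi >= cd.d


class TestBetweenCladeK:
    def test_identical_cross_sequences(self, jc_model):
        aln = Alignment.from_records(
            [("a1", "ACGT" * 10), ("a2", "ACGT" * 10), ("b1", "ACGT" * 10)]
        )
        assert between_clade_K(aln, ["a1", "a2"], ["b1"], jc_model) == 0.0

    def test_jc_closed_form(self, jc_model):
        L = 1200
        x = "A" * L
        y = "C" * 300 + "A" * 900  # p = 0.25 to x
        aln = Alignment.from_records([("x1", x), ("x2", x), ("y1", y)])
        K = between_clade_K(aln, ["x1", "x2"], ["y1"], jc_model)
        assert K == pytest.approx(0.30410, abs=1e-4)

    def test_overlap_rejected(self, jc_model):
        aln = Alignment.from_records([("a", "ACGT"), ("b", "ACGA")])
        with pytest.raises(ValueError, match="overlap"):
            between_clade_K(aln, ["a", "b"], ["b"], jc_model)


class TestReciprocalMonophyly:
    def test_ancestral_recursion_spot_values(self):
        assert _ancestral_rm_prob(1, 1) == 1.0
        assert _ancestral_rm_prob(2, 1) == pytest.approx(1 / 3)
        assert _ancestral_rm_prob(2, 2) == pytest.approx(1 / 9)

    def test_closed_form_examples(self):
        assert reciprocal_monophyly_prob(2, 1, 0.0, mode="closed") == pytest.approx(1 / 3)
        assert reciprocal_monophyly_prob(2, 1, 50.0, mode="closed") == pytest.approx(1.0, abs=1e-12)
        tau = 2.02
        assert reciprocal_monophyly_prob(2, 1, tau, mode="closed") == pytest.approx(
            1 - (2 / 3) * math.exp(-tau)
        )

    def test_closed_outside_domain(self):
        with pytest.raises(ValueError, match="mc"):
            reciprocal_monophyly_prob(3, 1, 1.0, mode="closed")

    @pytest.mark.parametrize("n1,n2", [(2, 1), (2, 2)])
    def test_mc_matches_closed_form(self, n1, n2):
        for tau in (0.0, 0.5, 1.0, 2.0, 4.0):
            closed = reciprocal_monophyly_prob(n1, n2, tau, mode="closed")
            mc, se = reciprocal_monophyly_prob(
                n1, n2, tau, mode="mc", mc_reps=20000, seed=11, with_se=True
            )
            assert abs(mc - closed) <= 3 * max(se, 1e-9)

    def test_mc_monotone_in_tau_at_matched_seed(self):
        values = [
            reciprocal_monophyly_prob(5, 3, tau, mode="mc", mc_reps=4000, seed=2)
            for tau in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            reciprocal_monophyly_prob(0, 1, 1.0)
        with pytest.raises(ValueError):
            reciprocal_monophyly_prob(2, 1, -0.5)


def scenario_alignment(L=60):
    """Two cherries (x, y) plus a distant singleton z."""
    x = "A" * L
    y = "C" * 6 + "A" * (L - 6)
    z = "G" * 30 + "A" * (L - 30)
    return Alignment.from_records(
        [("x1", x), ("x2", x), ("y1", y), ("y2", y), ("z", z)]
    )


class TestSelectComparisonPairs:
    def test_sister_pair(self, jc_model):
        aln = scenario_alignment()
        tree = parse_newick("((x1:0.01,x2:0.01):0.2,(y1:0.01,y2:0.01):0.2);")
        clades = [
            Clade(frozenset(["x1", "x2"]), 0.95, find_node(tree, ["x1", "x2"])),
            Clade(frozenset(["y1", "y2"]), 0.97, find_node(tree, ["y1", "y2"])),
        ]
        pairs = select_comparison_pairs(tree, clades, aln.subset(["x1", "x2", "y1", "y2"]), jc_model)
        assert len(pairs) == 1
        a, b, is_sister = pairs[0]
        assert is_sister and {a.labels, b.labels} == {frozenset(["x1", "x2"]), frozenset(["y1", "y2"])}

    def test_unsupported_sister_falls_back_to_lowest_K(self, jc_model):
        aln = scenario_alignment()
        tree = parse_newick(
            "((x1:0.01,x2:0.01):0.2,((y1:0.01,y2:0.01):0.1,z:0.11):0.1);"
        )
        clades = [
            Clade(frozenset(["x1", "x2"]), 0.95, find_node(tree, ["x1", "x2"])),
            Clade(frozenset(["y1", "y2"]), 0.97, find_node(tree, ["y1", "y2"])),
        ]
        pairs = {frozenset([a.labels, b.labels]): s for a, b, s in select_comparison_pairs(tree, clades, aln, jc_model)}
        # x's sister {y1,y2,z} is unsupported: x pairs with the closer clade y
        key = frozenset([frozenset(["x1", "x2"]), frozenset(["y1", "y2"])])
        assert key in pairs and pairs[key] is False
        # y's sister is the singleton z (trivially supported)
        key_z = frozenset([frozenset(["y1", "y2"]), frozenset(["z"])])
        assert key_z in pairs and pairs[key_z] is True

    def test_nested_clades_paired_at_their_own_level(self, jc_model):
        aln = scenario_alignment()
        tree = parse_newick(
            "((x1:0.01,x2:0.01):0.2,((y1:0.01,y2:0.01):0.1,z:0.11):0.1);"
        )
        clades = [
            Clade(frozenset(["x1", "x2"]), 0.95, find_node(tree, ["x1", "x2"])),
            Clade(frozenset(["y1", "y2"]), 0.97, find_node(tree, ["y1", "y2"])),
            Clade(frozenset(["y1", "y2", "z"]), 0.99, find_node(tree, ["y1", "y2", "z"])),
        ]
        pairs = {frozenset([a.labels, b.labels]) for a, b, _ in select_comparison_pairs(tree, clades, aln, jc_model)}
        assert pairs == {
            frozenset([frozenset(["x1", "x2"]), frozenset(["y1", "y2", "z"])]),
            frozenset([frozenset(["y1", "y2"]), frozenset(["z"])]),
        }

    def test_fewer_than_two_candidates(self, jc_model):
        aln = scenario_alignment()
        tree = parse_newick("((x1:0.01,x2:0.01):0.2,(y1:0.01,y2:0.01):0.2);")
        assert select_comparison_pairs(tree, [], aln.subset(["x1", "x2", "y1", "y2"]), jc_model) == []


def two_clade_case(k_diffs, jc_model, L=400):
    """Clade A: 2 sequences differing at 4 sites; clade B: 1 sequence k_diffs away."""
    a1 = "A" * L
    a2 = "C" * 4 + "A" * (L - 4)
    # b's G-block covers a2's C-block, so b differs from both at exactly k sites
    b = "G" * k_diffs + "A" * (L - k_diffs)
    aln = Alignment.from_records([("a1", a1), ("a2", a2), ("b", b)])
    tree = parse_newick("((a1:0.01,a2:0.01):0.1,b:0.11);")
    pair = (
        Clade(frozenset(["a1", "a2"]), 0.95, find_node(tree, ["a1", "a2"])),
        Clade(frozenset(["b"]), 1.0, None),
        True,
    )
    return aln, tree, pair


class TestKThetaTest:
    def test_hand_computed_ratio(self, jc_model):
        aln, tree, pair = two_clade_case(40, jc_model)
        res = ktheta_test(aln, tree, pair, jc_model)
        theta = 0.02 / (1 - 4 * 0.02 / 3)  # d=0.01, n=2
        K = jc_distance(40 / 400)
        assert res.theta_used == pytest.approx(theta)
        assert res.K == pytest.approx(K, abs=1e-6)
        assert res.ratio == pytest.approx(K / theta, rel=1e-6)
        assert (res.n1, res.n2) == (2, 1)
        assert res.decision == "species"

    def test_ratio_below_threshold_is_hard_fail(self, jc_model):
        # K = 3.98 * theta: not a species regardless of p
        aln, tree, pair = two_clade_case(31, jc_model)
        res = ktheta_test(aln, tree, pair, jc_model)
        assert res.ratio < 4.0
        assert res.p_2clades > 0.95
        assert res.decision == "not-species"

    def test_narrow_p_miss_is_flagged(self, jc_model):
        aln, tree, pair = two_clade_case(40, jc_model)
        config = KThetaConfig(p_threshold=0.9999)
        res = ktheta_test(aln, tree, pair, jc_model, config)
        assert res.ratio >= 4.0
        assert 0.9999 * 0.95 <= res.p_2clades < 0.9999
        assert res.decision == "flagged" and res.flags

    def test_both_singletons_rejected(self, jc_model):
        aln = Alignment.from_records([("a", "A" * 40), ("b", "C" * 40)])
        tree = parse_newick("(a:1,b:1);")
        pair = (Clade(frozenset(["a"]), 1.0, None), Clade(frozenset(["b"]), 1.0, None), True)
        with pytest.raises(ValueError, match="n = 1"):
            ktheta_test(aln, tree, pair, jc_model)

    def test_ratio_invariant_to_labels_and_order(self, jc_model):
        aln, tree, pair = two_clade_case(40, jc_model)
        res = ktheta_test(aln, tree, pair, jc_model)
        swapped = ktheta_test(aln, tree, (pair[1], pair[0], pair[2]), jc_model)
        assert swapped.ratio == pytest.approx(res.ratio)
        # rename tips consistently
        mapping = {"a1": "q", "a2": "r", "b": "s"}
        aln2 = Alignment.from_records(
            [(mapping[l], s) for l, s in aln.records]
        )
        tree2 = parse_newick("((q:0.01,r:0.01):0.1,s:0.11);")
        pair2 = (
            Clade(frozenset(["q", "r"]), 0.95, find_node(tree2, ["q", "r"])),
            Clade(frozenset(["s"]), 1.0, None),
            True,
        )
        assert ktheta_test(aln2, tree2, pair2, jc_model).ratio == pytest.approx(res.ratio)

    def test_smaller_on_n2_rule(self, jc_model):
        # both clades have theta; the larger theta comes from an n=2 clade
        L = 400
        a1, a2 = "A" * L, "C" * 8 + "A" * (L - 8)        # d = 0.02
        b = "G" * 40 + "A" * (L - 40)
        b1, b2, b3 = b, b[:4] + "T" + b[5:], b[:8] + "T" + b[9:]  # d small
        aln = Alignment.from_records(
            [("a1", a1), ("a2", a2), ("b1", b1), ("b2", b2), ("b3", b3)]
        )
        tree = parse_newick("((a1:0.01,a2:0.01):0.2,(b1:0.01,(b2:0.005,b3:0.005):0.005):0.2);")
        pair = (
            Clade(frozenset(["a1", "a2"]), 0.95, find_node(tree, ["a1", "a2"])),
            Clade(frozenset(["b1", "b2", "b3"]), 0.95, find_node(tree, ["b1", "b2", "b3"])),
            True,
        )
        larger = ktheta_test(aln, tree, pair, jc_model, KThetaConfig(theta_rule="larger"))
        footnote = ktheta_test(aln, tree, pair, jc_model, KThetaConfig(theta_rule="smaller_on_n2"))
        assert larger.theta_used > footnote.theta_used
        assert footnote.theta_used == clade_diversity(aln, ["b1", "b2", "b3"]).theta


class TestRunKTheta:
    def test_deterministic_under_fixed_seed(self, its2_fixture, its2_model):
        config = KThetaConfig(bootstrap_replicates=50, mc_reps=2000, seed=9)
        t1 = run_ktheta(its2_fixture.alignment, its2_model, config).table()
        t2 = run_ktheta(its2_fixture.alignment, its2_model, config).table()
        assert t1.to_csv() == t2.to_csv()

    def test_two_species_dataset_detected(self, coi_model):
        from egdelim.synthetic_data import SimulationConfig, SpeciesSpec, simulate_genealogy, simulate_sequences

        Ne, mu = 2.5e5, 2e-8
        cfg = SimulationConfig(
            species=(SpeciesSpec("P1", 6, Ne), SpeciesSpec("P2", 6, Ne)),
            species_tree=f"(P1:{10 * Ne},P2:{10 * Ne});",
            mu=mu, L=385, model=coi_model, seed=20,
        )
        aln = simulate_sequences(simulate_genealogy(cfg), cfg)
        rep = run_ktheta(aln, coi_model, KThetaConfig(bootstrap_replicates=100, mc_reps=5000, seed=4))
        assert any(r.decision == "species" for r in rep.results)

    def test_unreachable_support_threshold_warns_empty(self, its2_fixture, its2_model):
        config = KThetaConfig(support_threshold=1.0 - 1e-12, bootstrap_replicates=20, seed=1)
        # a threshold above every achievable support empties the report
        config.support_threshold = 1.0
        import warnings as w

        with w.catch_warnings(record=True) as caught:
            w.simplefilter("always")
            rep = run_ktheta(
                its2_fixture.alignment.subset(its2_fixture.alignment.labels[:8]),
                its2_model,
                config,
            )
        if not rep.clades:
            assert rep.results == []
            assert any("support" in str(c.message) for c in caught)

    def test_too_few_sequences(self, jc_model):
        aln = Alignment.from_records([("a", "ACGT"), ("b", "ACGA"), ("c", "AAGA")])
        with pytest.raises(ValueError):
            run_ktheta(aln, jc_model)
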