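import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from biopotency.errors import DomainError, NotComputableError, TreeStructureError
from biopotency.ledger import (
    InteractionClass,
    MaterialNode,
    PurificationTree,
    RoundingPolicy,
    TBAResult,
    campaign_report,
    classify_interaction,
    compute_tba,
    recovery,
    sum_tba,
    tba_per_gram,
)
from biopotency.potency import Censoring, PotencyEstimate

from conftest import FRACTION_IDS, SEQUENTIAL_IDS, exact_tba_l


def _node(ic50_ug_ml=None, weight_g=None, node_id="n", **kwargs):
    potency = PotencyEstimate.from_value(ic50_ug_ml, "µg/mL") if ic50_ug_ml else None
    return MaterialNode(id=node_id, weight_g=weight_g, potency=potency, **kwargs)


class TestComputeTBA:
    def test_worked_example_1000_l(self):
        # EDV50 of 1 L/mg = 1000 L/g, i.e. IC50 = 1 mg/L; 1 g of solids
        node = MaterialNode(id="x", weight_g=1.0,
                            potency=PotencyEstimate.from_value(1, "mg/L"))
        assert compute_tba(node).tba == pytest.approx(1000.0, rel=1e-12)

    def test_table2_single_ethanolic(self):
        assert round(compute_tba(_node(10.02, 3.0)).tba, 2) == 299.40

    def test_table3_f17(self):
        assert round(compute_tba(_node(6.7, 0.006)).tba, 3) == 0.896

    def test_zero_weight(self):
        assert compute_tba(_node(10.0, 0.0)).tba == 0.0

    def test_missing_potency_not_computable(self):
        r = compute_tba(_node(weight_g=1.0))
        assert r.tba is None and "potency" in r.reason

    def test_censored_excluded_unless_override(self):
        node = MaterialNode(id="c", weight_g=1.0,
                            potency=PotencyEstimate(ic50=0.5, censored=Censoring.RIGHT))
        assert compute_tba(node).tba is None
        assert compute_tba(node, allow_censored=True).tba == pytest.approx(2.0)

    def test_sd_propagates_linearly_with_weight(self):
        node = MaterialNode(id="s", weight_g=2.0,
                            potency=PotencyEstimate(ic50=0.01002, ic50_sd=0.00313))
        r = compute_tba(node)
        assert r.tba_sd == pytest.approx(2.0 * 0.00313 / 0.01002**2, rel=1e-12)

    def test_provenance_recorded(self):
        r = compute_tba(_node(10.02, 3.0))
        assert r.provenance["weight_g"] == 3.0
        assert r.provenance["ic50_g_per_l"] == pytest.approx(0.01002)

    @given(w=st.floats(min_value=1e-6, max_value=1e3), k=st.floats(min_value=1e-3, max_value=1e3))
    def test_linearity_in_weight(self, w, k):
        p = PotencyEstimate(ic50=0.02)
        a = compute_tba(MaterialNode(id="a", weight_g=w, potency=p)).tba
        b = compute_tba(MaterialNode(id="b", weight_g=k * w, potency=p)).tba
        assert b == pytest.approx(k * a, rel=1e-9)

    def test_unit_invariance(self):
        via_ug = _node(14.09, 6.0).potency
        via_gl = PotencyEstimate(ic50=0.01409)
        a = compute_tba(MaterialNode(id="a", weight_g=6.0, potency=via_ug)).tba
        b = compute_tba(MaterialNode(id="b", weight_g=6.0, potency=via_gl)).tba
        # weight entered as 6000 mg at the io boundary is stored as 6.0 g
        assert a == pytest.approx(b, rel=1e-12)


class TestPerGram:
    def test_single_extract(self):
        r = compute_tba(_node(10.02, 3.0))
        assert round(tba_per_gram(r, 75.0), 2) == 3.99

    def test_sequential_total(self, extracts_tree):
        total = sum_tba([compute_tba(extracts_tree[i]) for i in SEQUENTIAL_IDS])
        assert round(total / 230.0, 2) == 3.72

    def test_identity_denominator(self):
        r = compute_tba(_node(10.0, 2.0))
        assert tba_per_gram(r, 1.0) == r.tba

    def test_nonpositive_mass(self):
        with pytest.raises(DomainError):
            tba_per_gram(compute_tba(_node(10.0, 1.0)), 0.0)

    def test_not_computable_raises(self):
        with pytest.raises(NotComputableError):
            tba_per_gram(compute_tba(_node(weight_g=1.0)), 10.0)


class TestSumTBA:
    def test_six_sequential_extracts(self, extracts_tree):
        total = sum_tba([compute_tba(extracts_tree[i]) for i in SEQUENTIAL_IDS])
        assert round(total, 2) == 856.60

    def test_table3_rounded_addends(self, fractions_tree):
        results = [compute_tba(fractions_tree[i]) for i in FRACTION_IDS]
        assert sum_tba(results, rounding=3) == pytest.approx(5.963, abs=1e-12)
        # unrounded sum differs in the third decimal
        assert sum_tba(results) == pytest.approx(5.960, abs=5e-4)

    def test_empty(self):
        assert sum_tba([]) == 0.0

    @given(perm=st.permutations(list(range(6))))
    def test_order_invariance(self, perm):
        results = [
            TBAResult(node_id=str(i), tba=t)
            for i, t in enumerate([38.354, 425.834, 158.904, 99.639, 64.090, 69.782])
        ]
        base = sum_tba(results)
        assert sum_tba([results[i] for i in perm]) == pytest.approx(base, rel=1e-12)


class TestRecovery:
    def test_table3_recoveries(self, fractions_tree):
        parent = fractions_tree["dcm"]
        children = [fractions_tree[i] for i in FRACTION_IDS]
        rep = recovery(parent, children, tba_addend_decimals=3)
        assert round(rep.mass_recovery_pct, 2) == 2.61
        assert round(rep.tba_recovery_pct, 1) == 2.1
        assert rep.interaction_class is InteractionClass.EQUIVALENT

    def test_single_identical_child(self):
        p = _node(10.0, 2.0, node_id="p")
        c = MaterialNode(id="c", weight_g=2.0, potency=p.potency, parent_id="p")
        rep = recovery(p, [c])
        assert rep.mass_recovery_pct == pytest.approx(100.0, rel=1e-12)
        assert rep.tba_recovery_pct == pytest.approx(100.0, rel=1e-12)

    def test_two_halves_linearity(self):
        p = _node(10.0, 2.0, node_id="p")
        halves = [MaterialNode(id=f"h{i}", weight_g=1.0, potency=p.potency, parent_id="p")
                  for i in (1, 2)]
        rep = recovery(p, halves)
        assert rep.mass_recovery_pct == pytest.approx(100.0, rel=1e-9)
        assert rep.tba_recovery_pct == pytest.approx(100.0, rel=1e-9)

    def test_additive_conservation_any_partition(self):
        # children carry the parent's own potency, weights partition the parent's
        p = _node(23.7, 5.0, node_id="p")
        weights = [0.5, 1.25, 3.25]
        children = [MaterialNode(id=f"c{i}", weight_g=w, potency=p.potency, parent_id="p")
                    for i, w in enumerate(weights)]
        rep = recovery(p, children)
        assert rep.tba_recovery_pct == pytest.approx(100.0, abs=1e-9)

    def test_censored_children_contribute_zero(self):
        p = _node(10.0, 2.0, node_id="p")
        good = MaterialNode(id="g", weight_g=1.0, potency=p.potency, parent_id="p")
        cens = MaterialNode(id="c", weight_g=1.0, parent_id="p",
                            potency=PotencyEstimate(ic50=0.01, censored=Censoring.RIGHT))
        rep = recovery(p, [good, cens])
        assert rep.tba_recovery_pct == pytest.approx(50.0, rel=1e-9)
        assert rep.censored_child_ids == ("c",)

    def test_parent_without_weight_errors(self):
        with pytest.raises(DomainError):
            recovery(_node(10.0, None, node_id="p"), [_node(10.0, 1.0, node_id="c")])


class TestClassifyInteraction:
    def test_paper_case_equivalent(self):
        call = classify_interaction(3.99, 3.72, tolerance_pct=10.0)
        assert call.interaction_class is InteractionClass.EQUIVALENT
        assert round(call.ratio_pct, 1) == 93.2

    def test_reduced(self):
        call = classify_interaction(100.0, 50.0, tolerance_pct=10.0)
        assert call.interaction_class is InteractionClass.REDUCED
        joined = " ".join(call.interpretations)
        assert "degradation" in joined and "synergistic" in joined

    def test_increased(self):
        call = classify_interaction(50.0, 100.0, tolerance_pct=10.0)
        assert call.interaction_class is InteractionClass.INCREASED
        assert "antagonistic" in " ".join(call.interpretations)

    def test_tighter_tolerance_flips_paper_case(self):
        call = classify_interaction(3.99, 3.72, tolerance_pct=5.0)
        assert call.interaction_class is InteractionClass.REDUCED

    def test_zero_reference_errors(self):
        with pytest.raises(DomainError):
            classify_interaction(0.0, 1.0)


class TestPurificationTree:
    def test_duplicate_id(self):
        t = PurificationTree([_node(10, 1, node_id="a")])
        with pytest.raises(TreeStructureError):
            t.add(_node(10, 1, node_id="a"))

    def test_two_roots(self):
        with pytest.raises(TreeStructureError, match="exactly one root"):
            PurificationTree([_node(10, 1, node_id="a"), _node(10, 1, node_id="b")])

    def test_dangling_parent(self):
        with pytest.raises(TreeStructureError, match="unknown parent"):
            PurificationTree([
                _node(10, 1, node_id="a"),
                _node(10, 1, node_id="b", parent_id="ghost"),
            ])

    def test_cycle(self):
        with pytest.raises(TreeStructureError):
            PurificationTree([
                _node(10, 1, node_id="a", parent_id="b"),
                _node(10, 1, node_id="b", parent_id="a"),
            ])

    def test_depth_first_order(self, fractions_tree):
        order = [n.id for n in fractions_tree.depth_first()]
        assert order[0] == "dcm"
        assert order[1:] == FRACTION_IDS


class TestCampaignReport:
    def test_single_node_tree(self):
        rep = campaign_report(PurificationTree([_node(10.0, 1.0, node_id="only")]))
        assert len(rep.rows) == 1
        assert rep.groups == ()

    def test_fraction_table_total_and_parent(self, fractions_tree):
        pol = RoundingPolicy.fraction_table()
        rep = campaign_report(fractions_tree, policy=pol)
        group = rep.groups[0]
        assert group.total_tba_l == pytest.approx(5.963, abs=1e-12)
        assert pol.table_tba(fractions_tree["dcm"]) == 283.88
        assert round(group.recovery.mass_recovery_pct, 2) == 2.61
        assert round(group.recovery.tba_recovery_pct, 1) == 2.1

    def test_extract_table_rows(self, extracts_tree):
        rep = campaign_report(extracts_tree, policy=RoundingPolicy.extract_table())
        rows = {r.node_id: r for r in rep.rows}
        r = rows["etoh_single"]
        assert (r.edv50_l_per_g, r.tba_l, r.tba_per_gram) == (99.80, 299.40, 3.99)
        assert rows["leaves"].reason is not None  # plant node has no potency

    def test_oracle_equivalence_random_trees(self):
        # brute-force oracle: exact rational arithmetic over a naive loop
        from biopotency.synthetic import random_compounds, simulate_fractionation

        for seed in range(20):
            compounds = random_compounds(6, seed=seed)
            tree = simulate_fractionation(compounds, n_fractions=4, seed=seed)
            rep = campaign_report(tree)
            group = rep.groups[0]
            oracle = sum(
                (exact_tba_l(n) for n in tree if n.parent_id and n.potency),
                Fraction(0),
            )
            assert group.total_tba_l == pytest.approx(float(oracle), rel=1e-9)
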