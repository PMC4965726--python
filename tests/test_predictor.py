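import random

import pytest

from bruteforce import brute_force_classes, random_instance
from conftest import make_arch
from scafpred.model import (
    ComplexCatalog,
    DDINetwork,
    build_interactome,
)
from scafpred.predictor import (
    PredictorConfig,
    classify,
    criterion1,
    criterion2_witnesses,
    criterion3_witnesses,
    mediating_regions,
    predict_all,
)


class TestCriterion1:
    def test_path_graph(self):
        net = build_interactome([("A", "B"), ("B", "C")])
        assert criterion1(net) == {"B"}

    def test_triangle(self):
        net = build_interactome([("A", "B"), ("B", "C"), ("A", "C")])
        assert criterion1(net) == {"A", "B", "C"}

    def test_self_loop_does_not_count(self):
        net = build_interactome([("A", "B"), ("A", "A")])
        assert criterion1(net) == set()

    def test_matches_degree_filter_on_random_graph(self):
        rng = random.Random(11)
        net, *_ = random_instance(rng, max_proteins=50)
        expected = {
            p
            for p in net.proteins
            if len(set(net.graph.neighbors(p)) - {p}) >= 2
        }
        assert criterion1(net) == expected


class TestMediatingRegions:
    def test_single_matching_family(self):
        net = build_interactome([("S", "P")])
        arch = {"S": make_arch("S", "D1", "D2"), "P": make_arch("P", "D3")}
        ddi = DDINetwork.from_pairs([("D1", "D3")])
        regions = mediating_regions("S", "P", arch, ddi)
        assert {r.family for r in regions} == {"D1"}

    def test_partner_without_domains_yields_nothing(self):
        arch = {"S": make_arch("S", "D1")}
        ddi = DDINetwork.from_pairs([("D1", "D3")])
        assert mediating_regions("S", "P", arch, ddi) == set()

    def test_homotypic_ddi(self):
        arch = {"S": make_arch("S", "D5", "D5"), "P": make_arch("P", "D5")}
        ddi = DDINetwork.from_pairs([("D5", "D5")])
        regions = mediating_regions("S", "P", arch, ddi)
        assert {(r.family, r.copy_index) for r in regions} == {("D5", 1), ("D5", 2)}

    def test_lenient_mode_uses_ddi_active_families(self):
        arch = {"S": make_arch("S", "D1", "D9")}
        ddi = DDINetwork.from_pairs([("D1", "D3")])
        config = PredictorConfig(require_partner_domain_known=False)
        regions = mediating_regions("S", "P", arch, ddi, config)
        assert {r.family for r in regions} == {"D1"}


class TestCriterion2:
    def test_two_partners_via_different_regions(self):
        net = build_interactome([("S", "A"), ("S", "B")])
        arch = {
            "S": make_arch("S", "D1", "D2"),
            "A": make_arch("A", "D3"),
            "B": make_arch("B", "D4"),
        }
        ddi = DDINetwork.from_pairs([("D1", "D3"), ("D2", "D4")])
        witnesses = criterion2_witnesses("S", net, arch, ddi)
        assert {w.pair for w in witnesses} == {("A", "B")}
        (w,) = witnesses
        assert w.region1.family == "D1" and w.region2.family == "D2"

    def test_hub_with_competitive_partners_rejected(self):
        net = build_interactome([("H", f"P{i}") for i in range(1, 5)])
        arch = {"H": make_arch("H", "D5")}
        arch.update({f"P{i}": make_arch(f"P{i}", "D6") for i in range(1, 5)})
        ddi = DDINetwork.from_pairs([("D5", "D6")])
        assert criterion2_witnesses("H", net, arch, ddi) == set()

    def test_region_semantics_switch_on_duplicated_family(self):
        net = build_interactome([("H", "P1"), ("H", "P2")])
        arch = {
            "H": make_arch("H", "D5", "D5"),
            "P1": make_arch("P1", "D6"),
            "P2": make_arch("P2", "D6"),
        }
        ddi = DDINetwork.from_pairs([("D5", "D6")])
        instance_w = criterion2_witnesses("H", net, arch, ddi, PredictorConfig())
        family_w = criterion2_witnesses(
            "H", net, arch, ddi, PredictorConfig(region_semantics="family")
        )
        assert {w.pair for w in instance_w} == {("P1", "P2")}
        assert family_w == set()

    def test_representative_assignment_is_deterministic(self):
        net = build_interactome([("S", "A"), ("S", "B")])
        arch = {
            "S": make_arch("S", "D2", "D1", "D1"),
            "A": make_arch("A", "D3"),
            "B": make_arch("B", "D4"),
        }
        ddi = DDINetwork.from_pairs([("D1", "D3"), ("D2", "D3"), ("D1", "D4"), ("D2", "D4")])
        (w,) = criterion2_witnesses("S", net, arch, ddi)
        # lowest copy index first, family as tie-break
        assert (w.region1.family, w.region1.copy_index) == ("D1", 1)
        assert (w.region2.family, w.region2.copy_index) == ("D2", 1)


class TestCriterion3:
    NET = build_interactome([("S", "A"), ("S", "B"), ("S", "C")])

    def test_triad_complex(self):
        catalog = ComplexCatalog({"X": frozenset({"S", "A", "B"})})
        witnesses = criterion3_witnesses("S", self.NET, catalog)
        assert {w.pair for w in witnesses} == {("A", "B")}
        assert next(iter(witnesses)).complex_id == "X"

    def test_complex_member_must_also_interact(self):
        net = build_interactome([("S", "A"), ("S", "Z")])
        catalog = ComplexCatalog({"X": frozenset({"S", "A", "B"})})
        assert criterion3_witnesses("S", net, catalog) == set()

    def test_four_member_complex_gives_all_pairs(self):
        catalog = ComplexCatalog({"X": frozenset({"S", "A", "B", "C"})})
        witnesses = criterion3_witnesses("S", self.NET, catalog)
        assert {w.pair for w in witnesses} == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_smallest_complex_id_recorded(self):
        catalog = ComplexCatalog(
            {"Z9": frozenset({"S", "A", "B"}), "A1": frozenset({"S", "A", "B"})}
        )
        (w,) = criterion3_witnesses("S", build_interactome([("S", "A"), ("S", "B")]), catalog)
        assert w.complex_id == "A1"


class TestClassify:
    def _witnesses(self, s, net, arch, ddi, catalog, config=None):
        config = config or PredictorConfig()
        return (
            criterion2_witnesses(s, net, arch, ddi, config),
            criterion3_witnesses(s, net, catalog),
        )

    def test_joint_pair_is_type1(self, toy_problem):
        net, arch, ddi, catalog = toy_problem
        c2, c3 = self._witnesses("S", net, arch, ddi, catalog)
        pred = classify("S", c2, c3)
        assert pred.type_class == "I"
        (w,) = pred.witnesses
        assert w.has_regions and w.complex_id == "CPX1"

    def test_domain_only_is_type2(self, toy_problem):
        net, arch, ddi, _ = toy_problem
        empty = ComplexCatalog({})
        c2, c3 = self._witnesses("S", net, arch, ddi, empty)
        assert classify("S", c2, c3).type_class == "II"

    def test_complex_only_is_type3(self, toy_problem):
        net, arch, _, catalog = toy_problem
        no_ddi = DDINetwork()
        c2, c3 = self._witnesses("S", net, arch, no_ddi, catalog)
        assert classify("S", c2, c3).type_class == "III"

    def test_no_evidence_is_none(self, toy_problem):
        net, arch, *_ = toy_problem
        assert classify("S", set(), set()) is None

    def test_witness_policies_disagree_on_disjoint_pairs(self):
        # criterion 2 holds for (A,B), criterion 3 only for (A,C)
        net = build_interactome([("S", "A"), ("S", "B"), ("S", "C")])
        arch = {
            "S": make_arch("S", "D1", "D2"),
            "A": make_arch("A", "D3"),
            "B": make_arch("B", "D4"),
        }
        ddi = DDINetwork.from_pairs([("D1", "D3"), ("D2", "D4")])
        catalog = ComplexCatalog({"X": frozenset({"S", "A", "C"})})
        c2 = criterion2_witnesses("S", net, arch, ddi)
        c3 = criterion3_witnesses("S", net, catalog)
        assert classify("S", c2, c3, PredictorConfig(joint_witness=True)).type_class == "II"
        assert classify("S", c2, c3, PredictorConfig(joint_witness=False)).type_class == "I"


class TestPredictAll:
    def test_toy_problem_single_prediction(self, toy_problem):
        preds = predict_all(*toy_problem)
        assert [(p.scaffold, p.type_class) for p in preds] == [("S", "I")]

    def test_no_evidence_sources_no_predictions(self, toy_problem):
        net, arch, *_ = toy_problem
        assert predict_all(net, arch, DDINetwork(), ComplexCatalog({})) == []

    def test_planted_counts_recovered(self):
        from scafpred.simulate import SimConfig, generate

        ds = generate(SimConfig(n_type1=5, n_type2=7, n_type3=3, n_hub_decoys=4, seed=42))
        preds = predict_all(ds.interactome, ds.architectures, ds.ddi, ds.complexes)
        got = {p.scaffold: p.type_class for p in preds}
        want = {s: l for s, l in ds.truth.labels.items() if l in ("I", "II", "III")}
        assert got == want


@pytest.mark.parametrize("region_semantics", ["instance", "family"])
@pytest.mark.parametrize("joint_witness", [True, False])
def test_oracle_equivalence_random_instances(region_semantics, joint_witness):
    """predict_all agrees with exhaustive triple/assignment enumeration."""
    seed = {"instance": 0, "family": 1}[region_semantics] * 2 + int(joint_witness)
    rng = random.Random(100 + seed)
    config = PredictorConfig(joint_witness=joint_witness, region_semantics=region_semantics)
    for _ in range(40):
        net, arch, ddi, catalog = random_instance(rng)
        expected = brute_force_classes(
            net, arch, ddi, catalog,
            region_semantics=region_semantics, joint_witness=joint_witness,
        )
        got = {p.scaffold: p.type_class for p in predict_all(net, arch, ddi, catalog, config)}
        assert got == expected


def test_monotonicity_in_evidence():
    """Adding a DDI pair or a complex never removes or demotes a candidate."""
    rank = {"none": 0, "III": 1, "II": 1, "I": 2}
    rng = random.Random(5)
    for _ in range(15):
        net, arch, ddi, catalog = random_instance(rng, max_proteins=15)
        base = {p.scaffold: p.type_class for p in predict_all(net, arch, ddi, catalog)}
        families = sorted({f for a in arch.values() for f in a.families}) or ["D0"]
        extra_pair = frozenset((rng.choice(families), rng.choice(families)))
        bigger_ddi = DDINetwork(ddi.pairs | {extra_pair})
        proteins = sorted(net.proteins)
        extra_complex = frozenset(rng.sample(proteins, min(3, len(proteins))))
        bigger_catalog = ComplexCatalog({**catalog.complexes, "EXTRA": extra_complex})
        for ddi2, cat2 in ((bigger_ddi, catalog), (ddi, bigger_catalog)):
            new = {p.scaffold: p.type_class for p in predict_all(net, arch, ddi2, cat2)}
            for s in set(base) | set(new):
                assert rank[new.get(s, "none")] >= rank[base.get(s, "none")], s


def test_single_instance_protein_never_type1_or_type2():
    """A one-domain protein cannot recruit two partners through different
    regions, under either region semantics."""
    rng = random.Random(9)
    for _ in range(20):
        net, arch, ddi, catalog = random_instance(rng, max_proteins=20)
        for semantics in ("instance", "family"):
            preds = predict_all(
                net, arch, ddi, catalog, PredictorConfig(region_semantics=semantics)
            )
            for p in preds:
                if len(arch.get(p.scaffold, ())) <= 1:
                    assert p.type_class == "III"


def test_type_partition_is_disjoint_and_exact():
    """Each scaffold gets exactly one class; under the independent-witness
    policy no Type II scaffold can have any criterion-3 witness."""
    rng = random.Random(13)
    for _ in range(15):
        net, arch, ddi, catalog = random_instance(rng, max_proteins=20)
        for joint in (True, False):
            config = PredictorConfig(joint_witness=joint)
            preds = predict_all(net, arch, ddi, catalog, config)
            scaffolds = [p.scaffold for p in preds]
            assert len(scaffolds) == len(set(scaffolds))
            for p in preds:
                c3 = criterion3_witnesses(p.scaffold, net, catalog)
                c2 = criterion2_witnesses(p.scaffold, net, arch, ddi, config)
                if p.type_class == "II":
                    if joint:
                        # only non-overlapping pairs may carry complex evidence
                        assert not ({w.pair for w in c2} & {w.pair for w in c3})
                    else:
                        assert not c3
                if p.type_class == "III":
                    assert not c2
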