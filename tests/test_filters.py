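"""MOI filters: worked examples, brute-force oracle equivalence, and
monotonicity in the control cohort."""

import numpy as np
import pytest

from mendelscope.filters import (
    ClassificationEvidence,
    ConsensusConfig,
    FilterScenario,
    assess_de_novo,
    classify_variant,
    consensus_deleterious,
    filter_compound_het,
    filter_dominant_private,
    filter_recessive_hom,
)

from conftest import (
    call,
    make_variant,
    oracle_compound_het,
    oracle_dominant,
    oracle_recessive,
    random_toy_cohort,
)


def trio_scenario(moi, controls=("c1", "c2"), design="trio"):
    return FilterScenario(
        moi_hypothesis=moi,
        design=design,
        case_ids=("case",),
        control_ids=tuple(controls),
        parent_map={"case": ("sire", "dam")},
    )


class TestRecessive:
    def test_classic_trio_retained(self):
        v = make_variant(calls={"case": call(2), "sire": call(1), "dam": call(1),
                                "c1": call(1), "c2": call(0)})
        res = filter_recessive_hom([v], trio_scenario("recessive_hom"))
        assert res.retained == [v]

    def test_hom_alt_control_removes(self):
        v = make_variant(calls={"case": call(2), "sire": call(1), "dam": call(1),
                                "c1": call(2), "c2": call(0)})
        res = filter_recessive_hom([v], trio_scenario("recessive_hom"))
        assert res.retained == []
        failed = [r for r in res.audit if not r["passed"]]
        assert failed and failed[0]["check"] == "control_not_hom_alt"

    def test_het_case_fails(self):
        v = make_variant(calls={"case": call(1), "sire": call(1), "dam": call(1)})
        assert filter_recessive_hom([v], trio_scenario("recessive_hom", ())).retained == []

    def test_multi_case_requires_all_hom(self):
        sc = FilterScenario("recessive_hom", "multiple_cases",
                            ("k1", "k2", "k3"), ("c1",), {})
        v = make_variant(calls={"k1": call(2), "k2": call(2), "k3": call(1), "c1": call(0)})
        assert filter_recessive_hom([v], sc).retained == []

    def test_no_cases_errors(self):
        sc = FilterScenario("recessive_hom", "single_case", (), (), {})
        with pytest.raises(ValueError, match="no cases"):
            filter_recessive_hom([], sc)


class TestDominant:
    def test_de_novo_trio_retained(self):
        v = make_variant(calls={"case": call(1), "sire": call(0), "dam": call(0),
                                "c1": call(0), "c2": call(0)})
        res = filter_dominant_private([v], trio_scenario("dominant_private"))
        assert res.retained == [v]

    def test_any_control_carrier_removes(self):
        v = make_variant(calls={"case": call(1), "sire": call(0), "dam": call(0),
                                "c1": call(1), "c2": call(0)})
        assert filter_dominant_private([v], trio_scenario("dominant_private")).retained == []

    def test_half_sib_design_requires_both_cases_het(self):
        sc = FilterScenario("dominant_private", "half_sibs",
                            ("k1", "k2"), ("c1",), {"k1": ("sire", None), "k2": ("sire", None)})
        both = make_variant(pos=1, calls={"k1": call(1), "k2": call(1), "sire": call(0), "c1": call(0)})
        one = make_variant(pos=2, calls={"k1": call(1), "k2": call(0), "sire": call(0), "c1": call(0)})
        res = filter_dominant_private([both, one], sc)
        assert [v.pos for v in res.retained] == [1]

    def test_hemizygous_male_x_case_passes_x_linked(self):
        sc = FilterScenario("x_linked", "single_case", ("case",), ("c1",), {})
        v = make_variant("ChrX", 100, calls={"case": call(1, hemizygous=True), "c1": call(0)})
        assert filter_dominant_private([v], sc).retained == [v]


class TestCompoundHet:
    def _gene_pair(self, ctl1_extra=None, ctl2_extra=None, sire_v2=0, dam_v1=0):
        v1 = make_variant(pos=100, gene="LRP4",
                          calls={"case": call(1), "sire": call(1), "dam": call(dam_v1),
                                 **(ctl1_extra or {})})
        v2 = make_variant(pos=200, gene="LRP4",
                          calls={"case": call(1), "sire": call(sire_v2), "dam": call(1),
                                 **(ctl2_extra or {})})
        return v1, v2

    def test_trans_pair_with_single_carriers_retained(self):
        # controls carry each allele singly, none carries both
        ctl1 = {f"c{i}": call(1 if i < 5 else 0) for i in range(20)}
        ctl2 = {f"c{i}": call(1 if i >= 15 else 0) for i in range(20)}
        v1, v2 = self._gene_pair(ctl1, ctl2)
        sc = trio_scenario("recessive_compound_het", tuple(f"c{i}" for i in range(20)))
        res = filter_compound_het([v1, v2], sc)
        assert "LRP4" in res.gene_pairs
        assert res.gene_pairs["LRP4"] == [(v1, v2)]

    def test_cis_pair_removed(self):
        # both alleles from the sire, dam carries neither
        v1 = make_variant(pos=100, gene="LRP4",
                          calls={"case": call(1), "sire": call(1), "dam": call(0)})
        v2 = make_variant(pos=200, gene="LRP4",
                          calls={"case": call(1), "sire": call(1), "dam": call(0)})
        res = filter_compound_het([v1, v2], trio_scenario("recessive_compound_het", ()))
        assert res.gene_pairs == {}

    def test_control_carrying_both_removes(self):
        ctl_both_1 = {"c1": call(1)}
        ctl_both_2 = {"c1": call(1)}
        v1, v2 = self._gene_pair(ctl_both_1, ctl_both_2)
        sc = trio_scenario("recessive_compound_het", ("c1",))
        assert filter_compound_het([v1, v2], sc).gene_pairs == {}

    def test_unlabeled_variants_skipped_with_warning(self):
        v = make_variant(calls={"case": call(1)})
        with pytest.warns(UserWarning, match="gene label"):
            res = filter_compound_het([v], trio_scenario("recessive_compound_het", ()))
        assert res.retained == []


class TestDeNovo:
    def _trio_variant(self, sire_call, dam_call):
        return make_variant(calls={"case": call(1, ref_depth=10, alt_depth=11),
                                   "sire": sire_call, "dam": dam_call})

    def test_clean_parents_give_de_novo(self):
        v = self._trio_variant(call(0, ref_depth=15, alt_depth=0),
                               call(0, ref_depth=12, alt_depth=0))
        assert assess_de_novo(v, "case", "sire", "dam") == "de_novo"

    def test_missing_sire_is_undetermined(self):
        v = self._trio_variant(call(None), call(0, ref_depth=12, alt_depth=0))
        assert assess_de_novo(v, "case", "sire", "dam") == "undetermined"
        v2 = make_variant(calls={"case": call(1, ref_depth=10, alt_depth=9),
                                 "dam": call(0, ref_depth=12, alt_depth=0)})
        assert assess_de_novo(v2, "case", None, "dam") == "undetermined"

    def test_sire_with_excess_alt_reads_flags_mosaic(self):
        # 3 alt reads of 30 at error rate 0.005: binomial tail ~4e-4 < 0.05
        v = self._trio_variant(call(0, ref_depth=27, alt_depth=3),
                               call(0, ref_depth=12, alt_depth=0))
        assert assess_de_novo(v, "case", "sire", "dam") == "mosaic_parent_suspected"

    def test_carrier_parent_means_inherited(self):
        v = self._trio_variant(call(1, ref_depth=10, alt_depth=9),
                               call(0, ref_depth=12, alt_depth=0))
        assert assess_de_novo(v, "case", "sire", "dam") == "inherited"

    def test_variant_absent_in_case_errors(self):
        v = make_variant(calls={"case": call(0), "sire": call(0), "dam": call(0)})
        with pytest.raises(ValueError):
            assess_de_novo(v, "case", "sire", "dam")


class TestConsensusAndClassification:
    def test_consensus_threshold(self):
        assert consensus_deleterious({"SIFT": "deleterious", "PolyPhen2": "deleterious",
                                      "MAPP": "tolerated"})
        assert not consensus_deleterious({})
        assert not consensus_deleterious({"SIFT": "deleterious"})
        assert consensus_deleterious({"SIFT": "deleterious", "MAPP": "deleterious"})

    def test_unrecognized_tools_do_not_count(self):
        assert not consensus_deleterious({"MyTool": "deleterious", "Other": "deleterious"})
        config = ConsensusConfig(min_deleterious_tools=1, predictors=("MyTool",))
        assert consensus_deleterious({"MyTool": "deleterious"}, config)

    def test_classification_ladder(self):
        pathogenic = ClassificationEvidence(
            consequence="truncating", private=True, segregation_consistent=True,
            de_novo_or_mosaic_support=True)
        assert classify_variant(pathogenic) == "pathogenic"
        likely = ClassificationEvidence(
            consequence="missense", private=True, segregation_consistent=True,
            predictor_consensus=True, gene_plausible=False)
        assert classify_variant(likely) == "likely_pathogenic"
        vus = ClassificationEvidence(consequence="intronic", private=True)
        assert classify_variant(vus) == "uncertain"
        assert classify_variant(ClassificationEvidence()) == "uncertain"


class TestOracleEquivalence:
    """Each filter equals an exhaustive re-check of its textual
    definition on random toy cohorts."""

    N_COHORTS = 250  # the acceptance suite runs the full 1000

    def _scenarios(self, cases, controls, parent_map):
        design = "single_case" if not any(
            p for ps in parent_map.values() for p in ps
        ) else "single_parent"
        mk = lambda moi: FilterScenario(moi, design, tuple(cases), tuple(controls), parent_map)
        return mk

    def test_filters_match_brute_force(self):
        rng = np.random.default_rng(20250929)
        for _ in range(self.N_COHORTS):
            variants, cases, controls, parent_map = random_toy_cohort(rng)
            mk = self._scenarios(cases, controls, parent_map)

            got = filter_recessive_hom(variants, mk("recessive_hom"))
            want = oracle_recessive(variants, cases, controls, parent_map)
            assert [v.key for v in got.retained] == [v.key for v in want]

            got_d = filter_dominant_private(variants, mk("dominant_private"))
            want_d = oracle_dominant(variants, cases, controls, parent_map, True)
            assert [v.key for v in got_d.retained] == [v.key for v in want_d]

            got_c = filter_compound_het(variants, mk("recessive_compound_het"))
            want_c = oracle_compound_het(variants, cases, controls, parent_map)
            got_pairs = {
                g: [(a.key, b.key) for a, b in ps] for g, ps in got_c.gene_pairs.items()
            }
            want_pairs = {
                g: [(a.key, b.key) for a, b in ps] for g, ps in want_c.items()
            }
            assert got_pairs == want_pairs

    def test_adding_a_control_only_shrinks_retained_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            variants, cases, controls, parent_map = random_toy_cohort(rng)
            if not controls:
                continue
            mk_full = self._scenarios(cases, controls, parent_map)
            mk_less = self._scenarios(cases, controls[:-1], parent_map)
            for fn, moi in (
                (filter_recessive_hom, "recessive_hom"),
                (filter_dominant_private, "dominant_private"),
            ):
                full = {v.key for v in fn(variants, mk_full(moi)).retained}
                less = {v.key for v in fn(variants, mk_less(moi)).retained}
                assert full <= less
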