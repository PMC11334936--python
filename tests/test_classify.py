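"""Subcomposition grouping and category assignment."""

import itertools
from collections import Counter

import pytest

from gemmannot import (
    Category,
    Inducer,
    categorize,
    group_subcompositions,
    parse_composition,
)
from gemmannot.classify import COOPERATIVE, INDEPENDENT
from gemmannot.generator import GeneratorConfig, generate_random_composition

from oracle import oracle_categories


class TestGrouping:
    def test_cre_plus_floxed_is_one_event(self, kb):
        comp = parse_composition(
            "Agrp<tm1(cre)Lowl>/Agrp<+> Lepr<tm1.1Chua>/Lepr<tm1.1Chua>"
        )
        subs = group_subcompositions(comp, kb)
        assert len(subs) == 1
        assert subs[0].target_gene == "Lepr"
        assert len(subs[0].shared_drivers) == 1

    def test_tet_on_cre_shares_two_drivers(self, kb):
        comp = parse_composition(
            "Pkd1<tm2Ggg>/Pkd1<+> Tg(Pax8-rtTA2S*M2)1Koes/0 Tg(tetO-cre)1Jaw/0"
        )
        subs = group_subcompositions(comp, kb)
        assert len(subs) == 1
        assert subs[0].target_gene == "Pkd1"
        assert len(subs[0].shared_drivers) == 2
        assert subs[0].category == Category.C6

    def test_independent_mutation(self, kb):
        subs = group_subcompositions(
            parse_composition("Zfp541<em1Osb>/Zfp541<em1Osb>"), kb
        )
        assert len(subs) == 1
        assert subs[0].category == Category.I1
        assert not subs[0].shared_drivers

    def test_wildtype_pair_produces_no_event(self, kb):
        assert group_subcompositions(parse_composition("Trp53<+>/Trp53<+>"), kb) == []

    def test_dangling_driver_kept_for_manual_queue(self, kb):
        subs = group_subcompositions(parse_composition("Tg(tetO-cre)1Jaw/0"), kb)
        assert len(subs) == 1
        assert subs[0].category == Category.UNCLASSIFIED

    def test_unknown_promoter_yields_unclassified_not_crash(self, kb):
        comp = parse_composition(
            "Tg(Nphs2-cre)1A/0 Lepr<tm1.1Chua>/Lepr<tm1.1Chua>"
        )
        subs = group_subcompositions(comp, kb)
        assert [s.category for s in subs] == [Category.UNCLASSIFIED]

    def test_heuristic_floxed_alongside_cre_driver(self, kb):
        # Mybl2<tm9Zzz> is not in the attribute table; with a cre driver
        # present it is presumed floxed and flagged
        comp = parse_composition(
            "Agrp<tm1(cre)Lowl>/Agrp<+> Mybl2<tm9Zzz>/Mybl2<tm9Zzz>"
        )
        subs = group_subcompositions(comp, kb)
        assert [s.category for s in subs] == [Category.C1]
        assert subs[0].heuristic

    def test_one_subcomposition_per_floxed_target(self, kb):
        comp = parse_composition(
            "Agrp<tm1(cre)Lowl>/Agrp<+> Lepr<tm1.1Chua>/Lepr<tm1.1Chua> "
            "Mcl1<tm1Ywh>/Mcl1<tm1Ywh>"
        )
        subs = group_subcompositions(comp, kb)
        assert [s.target_gene for s in subs] == ["Lepr", "Mcl1"]
        assert all(s.category == Category.C1 for s in subs)

    def test_multi_driver_flag(self, kb):
        comp = parse_composition(
            "Agrp<tm1(cre)Lowl>/Agrp<+> Tg(Mx1-cre)1Cgn/0 "
            "Lepr<tm1.1Chua>/Lepr<tm1.1Chua>"
        )
        subs = group_subcompositions(comp, kb)
        assert len(subs) == 2
        assert all(s.multi_driver for s in subs)


class TestCategorize:
    @pytest.mark.parametrize(
        "text,expected,inducer",
        [
            ("Gt(ROSA)26Sor<tm1(cre/ERT2)Thl>/Gt(ROSA)26Sor<+> "
             "Mcl1<tm1Ywh>/Mcl1<tm1Ywh>", Category.C2, Inducer.TAMOXIFEN),
            ("Tg(Scgb1a1-rtTA)1Jaw/0 Tg(tetO-Aimp1)29872Mcla/0",
             Category.C3, Inducer.TET_ON),
            ("Tg(Mx1-tTA)1Cgn/0 Tg(tetO-Aimp1)29872Mcla/0",
             Category.C4, Inducer.TET_OFF),
            ("Hnf4a<tm1Sad>/Hnf4a<tm1Sad> Six2<tm1(tTA,tetO-EGFP/cre)Amc>/Six2<+>",
             Category.C5, Inducer.TET_OFF),
        ],
    )
    def test_categories_and_inducers(self, kb, text, expected, inducer):
        subs = group_subcompositions(parse_composition(text), kb)
        assert len(subs) == 1
        assert subs[0].category == expected
        assert subs[0].inducer == inducer
        assert categorize(subs[0], kb) == expected

    def test_triple_beats_pair_rule(self, kb):
        # with rtTA + tetO-cre + floxed, the Tet-on knockout triple must win
        # even though the tetO-cre allele alone also contains the cre keyword
        comp = parse_composition(
            "Tg(Pax8-rtTA2S*M2)1Koes/0 Tg(tetO-cre)1Jaw/0 Pkd1<tm2Ggg>/Pkd1<+>"
        )
        subs = group_subcompositions(comp, kb)
        assert [s.category for s in subs] == [Category.C6]

    def test_category_system_is_two_plus_six(self):
        assert len(INDEPENDENT) == 2
        assert len(COOPERATIVE) == 6
        assert INDEPENDENT | COOPERATIVE | {Category.UNCLASSIFIED} == set(Category)


@pytest.fixture(scope="module")
def generated(kb):
    cfg = GeneratorConfig(seed=77, n=1000)
    return generate_random_composition(cfg, kb)


class TestTotalityAndPartition:

    def test_classifier_total_over_generator(self, kb, generated):
        for s in generated:
            subs = group_subcompositions(parse_composition(s), kb)
            for sub in subs:
                assert sub.category in set(Category)

    def test_partition_of_non_driver_pairs(self, kb, generated):
        from gemmannot.knowledge import driver_roles

        for s in generated:
            comp = parse_composition(s)
            expected = Counter()
            for pair in comp.pairs:
                fa = pair.functional_allele()
                if fa is None or driver_roles(fa):
                    continue
                expected[pair.raw] += 1
            got = Counter()
            for sub in group_subcompositions(comp, kb):
                for m in sub.members:
                    fa = m.functional_allele()
                    if fa is not None and not driver_roles(fa):
                        got[m.raw] += 1
            # one sub per (driver system, target): targets may legitimately
            # repeat, so compare the supports and minimum counts
            assert set(got) == set(expected)
            for key, n in expected.items():
                assert got[key] >= n


class TestBruteForceOracle:
    def test_rule_engine_matches_enumeration(self, kb, oracle_pool):
        """All compositions of <=4 double alleles from the fixture pool."""
        checked = 0
        for size in (1, 2, 3, 4):
            for combo in itertools.combinations(oracle_pool, size):
                comp = parse_composition(" ".join(combo))
                subs = group_subcompositions(comp, kb)
                engine = Counter(s.category.value for s in subs)
                expected = oracle_categories(list(combo), kb.attribute_map)
                assert engine == expected, f"mismatch on {combo}"
                checked += 1
        assert checked > 2000
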