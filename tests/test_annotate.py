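"""Rendering of biological descriptions from subcompositions."""

import pytest

from gemmannot import (
    Category,
    Provenance,
    annotate_composition,
    detect_marker,
    parse_allele,
    parse_composition,
    render_subcomposition,
)
from gemmannot.classify import Subcomposition
from gemmannot.errors import TemplateSlotError
from gemmannot.generator import GeneratorConfig, generate_random_composition


class TestWorkedExamples:
    def test_examples_render_byte_identically(self, kb, worked_examples):
        """Curated genotype -> description pairs must reproduce exactly."""
        assert len(worked_examples) == 7
        for row in worked_examples:
            ann = annotate_composition(
                parse_composition(row["allele_composition"]), kb
            )
            assert ann.text == row["annotation"]
            assert [c.value for c, _ in ann.per_subcomposition] == [row["category"]]


class TestTemplates:
    def test_c4_tet_off_overexpression(self, kb):
        ann = annotate_composition(
            parse_composition("Tg(Mx1-tTA)1Cgn/0 Tg(tetO-Aimp1)29872Mcla/0"), kb
        )
        assert ann.per_subcomposition[0][0] == Category.C4
        assert ann.text == (
            "Overexpressing Aimp1 in interferon-responsive cells, including "
            "liver and hematopoietic cells; tetracycline/doxycycline "
            "treatment shuts off the overexpression."
        )
        assert ann.template_invented

    def test_i1_point_mutation_wording(self, kb):
        ann = annotate_composition(
            parse_composition("Kras<tm4Tyj>/Kras<tm4Tyj>"), kb
        )
        assert ann.text == "Kras carrying a targeted point mutation (global)"
        assert ann.template_invented

    def test_c5_without_marker_drops_marker_clause(self, kb):
        ann = annotate_composition(
            parse_composition(
                "Hnf4a<tm1Sad>/Hnf4a<tm1Sad> Tg(Six2-tTA)1Jaw/0 Tg(tetO-cre)1Jaw/0"
            ),
            kb,
        )
        assert ann.per_subcomposition[0][0] == Category.C5
        assert "marked by" not in ann.text
        assert "restore the expression of Hnf4a" in ann.text

    def test_unclassified_routed_to_manual(self, kb):
        ann = annotate_composition(parse_composition("Tg(tetO-cre)1Jaw/0"), kb)
        assert ann.text.startswith("Manual annotation required for:")
        assert ann.provenance == Provenance.NEEDS_MANUAL
        assert ann.needs_manual

    def test_wildtype_annotates_to_nothing(self, kb):
        ann = annotate_composition(parse_composition("Trp53<+>/Trp53<+>"), kb)
        assert ann.per_subcomposition == []
        assert ann.text == ""
        assert ann.provenance == Provenance.MACHINE

    def test_missing_slot_raises(self):
        sub = Subcomposition(category=Category.C1, target_gene="Lepr", pattern=None)
        with pytest.raises(TemplateSlotError):
            render_subcomposition(sub)

    def test_heuristic_provenance_propagates(self, kb):
        ann = annotate_composition(
            parse_composition(
                "Agrp<tm1(cre)Lowl>/Agrp<+> Mybl2<tm9Zzz>/Mybl2<tm9Zzz>"
            ),
            kb,
        )
        assert ann.provenance == Provenance.HEURISTIC

    def test_tissues_mentioned_subset_of_table(self, kb):
        ann = annotate_composition(
            parse_composition(
                "Agrp<tm1(cre)Lowl>/Agrp<+> Lepr<tm1.1Chua>/Lepr<tm1.1Chua>"
            ),
            kb,
        )
        table_phrases = {p.tissue_phrase for p in kb.driver_map.values()}
        assert ann.tissues_mentioned == ["neurons"]
        assert set(ann.tissues_mentioned) <= table_phrases


class TestDetectMarker:
    def test_egfp_in_combined_cassette(self):
        assert detect_marker(parse_allele("Six2<tm1(tTA,tetO-EGFP/cre)Amc>")) == "EGFP"

    def test_plain_teto_cre_has_no_marker(self):
        assert detect_marker(parse_allele("Tg(tetO-cre)1Jaw")) is None

    def test_plain_cre_has_no_marker(self):
        assert detect_marker(parse_allele("Agrp<tm1(cre)Lowl>")) is None


class TestInducerPhraseCoupling:
    """Inducible categories must mention their inducer; others must not."""

    def test_over_generator_output(self, kb):
        cfg = GeneratorConfig(seed=4242, n=400)
        for s in generate_random_composition(cfg, kb):
            ann = annotate_composition(parse_composition(s), kb)
            for cat, text in ann.per_subcomposition:
                if cat == Category.C2:
                    assert "tamoxifen" in text
                    assert "tetracycline" not in text
                elif cat in (Category.C3, Category.C4, Category.C5, Category.C6):
                    assert "tetracycline" in text
                elif cat in (Category.I1, Category.I2, Category.C1):
                    assert "tamoxifen" not in text
                    assert "tetracycline" not in text

    def test_determinism(self, kb):
        s = ("Pkd1<tm2Ggg>/Pkd1<+> Tg(Pax8-rtTA2S*M2)1Koes/0 "
             "Tg(tetO-cre)1Jaw/0")
        first = annotate_composition(parse_composition(s), kb)
        second = annotate_composition(parse_composition(s), kb)
        assert first.text == second.text
        assert first.per_subcomposition == second.per_subcomposition
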