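"""Render subcompositions into human-readable biological descriptions.

Each category has a fixed sentence template; slots are the target gene, the
tissue phrase of the driving promoter, the zygosity qualifier and (for
tetO-cre cassettes) a co-driven reporter. Punctuation is deliberately
uneven across templates — each is kept byte-exact to the curated wording it
reproduces, so downstream text matching stays stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Tuple

from .classify import Category, Subcomposition, group_subcompositions
from .errors import TemplateSlotError
from .knowledge import KnowledgeTable, find_co_driven_reporter
from .nomenclature import Allele, AlleleComposition, ZygosityClass

__all__ = [
    "Provenance",
    "Annotation",
    "detect_marker",
    "render_subcomposition",
    "annotate_composition",
]

# templates with no verbatim curated example; flagged in structured output
INVENTED_TEMPLATES = frozenset({Category.C4})


class Provenance(str, Enum):
    MACHINE = "machine"
    HEURISTIC = "heuristic"
    NEEDS_MANUAL = "needs_manual"


@dataclass
class Annotation:
    """Composition-level annotation: joined text plus per-event detail."""

    text: str
    per_subcomposition: List[Tuple[Category, str]] = field(default_factory=list)
    provenance: Provenance = Provenance.MACHINE
    tissues_mentioned: List[str] = field(default_factory=list)
    subcompositions: List[Subcomposition] = field(default_factory=list)
    template_invented: bool = False

    @property
    def needs_manual(self) -> bool:
        return self.provenance == Provenance.NEEDS_MANUAL


def detect_marker(driver: Allele) -> Optional[str]:
    """Reporter co-driven with cre in a tetO cassette (e.g. EGFP), or None."""
    return find_co_driven_reporter(driver)


# ---------------------------------------------------------------------------

def _require(sub: Subcomposition, *slots: str) -> None:
    for slot in slots:
        if not getattr(sub, slot):
            raise TemplateSlotError(
                f"category {sub.category.value} needs slot {slot!r}"
            )


def _het(sub: Subcomposition) -> str:
    return " heterozygously" if sub.zygosity_qualifier == ZygosityClass.HETEROZYGOUS else ""


def _place(sub: Subcomposition, knockout: bool) -> str:
    """Adverbial phrase: 'ubiquitously', 'specifically in <tissue>' for
    knockouts, plain 'in <tissue>' otherwise."""
    _require(sub, "pattern")
    if sub.pattern.ubiquitous:
        return "ubiquitously"
    if knockout:
        return f"specifically in {sub.pattern.tissue_phrase}"
    return f"in {sub.pattern.tissue_phrase}"


def _in_place(sub: Subcomposition) -> str:
    _require(sub, "pattern")
    if sub.pattern.ubiquitous:
        return "ubiquitously"
    return f"in {sub.pattern.tissue_phrase}"


def render_subcomposition(sub: Subcomposition) -> str:
    """One sentence (or two) describing one biological event."""
    cat = sub.category
    if cat == Category.UNCLASSIFIED:
        return f"Manual annotation required for: {sub.raw_alleles()}"

    _require(sub, "target_gene")
    gene = sub.target_gene

    if cat == Category.I1:
        if sub.attribute == "null":
            return f"{gene} conventional knockout (global knockout)"
        if sub.attribute == "point_mutation":
            return f"{gene} carrying a targeted point mutation (global)"
        return f"{gene} mutant allele"
    if cat == Category.I2:
        return f"Overexpressing {gene} {_in_place(sub)}"
    if cat == Category.C1:
        return f"Knockout {gene}{_het(sub)} {_place(sub, knockout=True)}"
    if cat == Category.C2:
        return (
            f"Knockout {gene}{_het(sub)} {_place(sub, knockout=True)}"
            " in a tamoxifen-inducible manner."
        )
    if cat == Category.C3:
        return (
            "tetracycline/doxycycline treatment induced overexpression of "
            f"{gene} {_in_place(sub)}."
        )
    if cat == Category.C4:
        return (
            f"Overexpressing {gene} {_in_place(sub)}; tetracycline/doxycycline "
            "treatment shuts off the overexpression."
        )
    if cat == Category.C5:
        marker_clause = (
            f"Inactivation is marked by {sub.marker}, " if sub.marker else ""
        )
        return (
            f"Inactivating {gene}{_het(sub)} {_in_place(sub)}. "
            f"{marker_clause}tetracycline/doxycycline treatment restore "
            f"the expression of {gene}."
        )
    if cat == Category.C6:
        return (
            f"Inactivating {gene}{_het(sub)} {_in_place(sub)}. The inactivation "
            "is induced by tetracycline(or doxycycline) treatment."
        )
    raise TemplateSlotError(f"no template for category {cat!r}")


def annotate_composition(
    comp: AlleleComposition, kb: KnowledgeTable
) -> Annotation:
    """Full pipeline: group → categorize → render → join.

    Per-event texts are joined with ``"; "`` in input order. Provenance is
    needs_manual when any event is UNCLASSIFIED, heuristic when any floxed
    status was presumed rather than curated, machine otherwise.
    """
    subs = group_subcompositions(comp, kb)
    rendered: List[Tuple[Category, str]] = []
    tissues: List[str] = []
    any_unclassified = False
    any_heuristic = False
    any_invented = False
    for sub in subs:
        text = render_subcomposition(sub)
        rendered.append((sub.category, text))
        if sub.category == Category.UNCLASSIFIED:
            any_unclassified = True
        if sub.heuristic:
            any_heuristic = True
        if sub.category in INVENTED_TEMPLATES or (
            sub.category == Category.I1 and sub.attribute != "null"
        ):
            any_invented = True
        if sub.pattern is not None and not sub.pattern.ubiquitous:
            if sub.pattern.tissue_phrase not in tissues:
                tissues.append(sub.pattern.tissue_phrase)

    if any_unclassified:
        provenance = Provenance.NEEDS_MANUAL
    elif any_heuristic:
        provenance = Provenance.HEURISTIC
    else:
        provenance = Provenance.MACHINE

    return Annotation(
        text="; ".join(t for _, t in rendered),
        per_subcomposition=rendered,
        provenance=provenance,
        tissues_mentioned=tissues,
        subcompositions=subs,
        template_invented=any_invented,
    )
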