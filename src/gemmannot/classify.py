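"""Split an allele composition into subcompositions and assign categories.

A *subcomposition* is the subset of double alleles producing one biological
event. Two independent categories and six cooperative categories are
recognized:

=========  ==================================================================
I1         mutation of a gene or its regulatory elements (global)
I2         transgene overexpression (tissue depends on the construct promoter)
C1         tissue-specific knockout: Cre driver + floxed allele
C2         tamoxifen-inducible knockout: CreERT2 driver + floxed allele
C3         Tet-on overexpression: rtTA driver + tetO-driven gene
C4         Tet-off overexpression: tTA driver + tetO-driven gene
C5         knockout-and-restore: tTA + tetO-cre + floxed (Tet-off cre)
C6         inducible knockout: rtTA + tetO-cre + floxed (Tet-on cre)
=========  ==================================================================

Anything that fits no category is UNCLASSIFIED and queued for manual
annotation; the classifier is total and never raises on a parsed composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional

from .knowledge import (
    AlleleRole,
    ExpressionPattern,
    KnowledgeTable,
    driver_roles,
    expression_pattern,
    find_co_driven_reporter,
    role_of,
)
from .nomenclature import (
    Allele,
    AlleleComposition,
    AlleleKind,
    DoubleAllele,
    ZygosityClass,
    split_top_level,
    zygosity,
)

__all__ = ["Category", "Inducer", "Subcomposition", "group_subcompositions", "categorize"]


class Category(str, Enum):
    I1 = "I1"
    I2 = "I2"
    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    C4 = "C4"
    C5 = "C5"
    C6 = "C6"
    UNCLASSIFIED = "UNCLASSIFIED"


COOPERATIVE = frozenset({Category.C1, Category.C2, Category.C3,
                         Category.C4, Category.C5, Category.C6})
INDEPENDENT = frozenset({Category.I1, Category.I2})


class Inducer(str, Enum):
    NONE = "none"
    TAMOXIFEN = "tamoxifen"
    TET_ON = "tet_on"
    TET_OFF = "tet_off"


_INDUCER_FOR = {
    Category.C2: Inducer.TAMOXIFEN,
    Category.C3: Inducer.TET_ON,
    Category.C6: Inducer.TET_ON,
    Category.C4: Inducer.TET_OFF,
    Category.C5: Inducer.TET_OFF,
}

TARGET_ROLES = frozenset(
    {
        AlleleRole.FLOXED,
        AlleleRole.TETO_TARGET,
        AlleleRole.MUTANT,
        AlleleRole.TRANSGENE_OVEREXPRESSION,
    }
)


@dataclass
class Subcomposition:
    """One biological event: target double allele(s) plus enabling drivers."""

    members: List[DoubleAllele] = field(default_factory=list)
    shared_drivers: List[DoubleAllele] = field(default_factory=list)
    category: Category = Category.UNCLASSIFIED
    target_gene: str = ""
    pattern: Optional[ExpressionPattern] = None
    zygosity_qualifier: Optional[ZygosityClass] = None
    inducer: Inducer = Inducer.NONE
    marker: Optional[str] = None
    attribute: Optional[str] = None      # allele attribute for I1 wording
    heuristic: bool = False              # floxed status presumed, not curated
    multi_driver: bool = False           # >1 compatible driver system
    anchor: int = 0                      # input position used for ordering

    def raw_alleles(self) -> str:
        return " ".join(p.raw for p in self.members + self.shared_drivers)


# ---------------------------------------------------------------------------

def _target_gene_of(pair: DoubleAllele, role: AlleleRole) -> str:
    a = pair.functional_allele()
    if a is None:
        return ""
    if a.kind == AlleleKind.TARGETED:
        return a.gene_symbol
    # transgene: the expressed gene follows the promoter prefix
    segments = split_top_level(a.construct, "-")
    if role == AlleleRole.TETO_TARGET:
        return segments[1] if len(segments) > 1 else segments[0]
    return segments[-1] if len(segments) > 1 else segments[0]


@dataclass(frozen=True)
class _DriverSystem:
    """A driver unit that can act on a target: one cre-type driver, one
    transactivator, or a transactivator + tetO-cre pair."""

    flox_category: Optional[Category]   # category produced on a floxed target
    teto_category: Optional[Category]   # category produced on a tetO target
    drivers: tuple                      # (index, pair) tuples, input order
    tissue_allele: Optional[Allele]     # allele whose promoter sets the tissue
    marker_allele: Optional[Allele] = None

    @property
    def min_index(self) -> int:
        return min(i for i, _ in self.drivers)


def _build_systems(driver_pairs: list[tuple[int, DoubleAllele, frozenset]]) -> list[_DriverSystem]:
    systems: list[_DriverSystem] = []
    for i, pair, roles in driver_pairs:
        fa = pair.functional_allele()
        if AlleleRole.CRE_DRIVER in roles:
            systems.append(_DriverSystem(Category.C1, None, ((i, pair),), fa))
        if AlleleRole.CREERT2_DRIVER in roles:
            systems.append(_DriverSystem(Category.C2, None, ((i, pair),), fa))
        if AlleleRole.RTTA_DRIVER in roles:
            systems.append(_DriverSystem(None, Category.C3, ((i, pair),), fa))
        if AlleleRole.TTA_DRIVER in roles:
            systems.append(_DriverSystem(None, Category.C4, ((i, pair),), fa))
    # tetO-cre pairs combine with a transactivator into a knockout system;
    # the transactivator's promoter sets the tissue, the tetO cassette may
    # carry a co-driven reporter.
    for i, pair, roles in driver_pairs:
        if AlleleRole.TETO_CRE not in roles:
            continue
        tc_allele = pair.functional_allele()
        for j, other, oroles in driver_pairs:
            shared = (j == i)
            if AlleleRole.TTA_DRIVER in oroles:
                drivers = ((i, pair),) if shared else tuple(sorted([(i, pair), (j, other)]))
                systems.append(
                    _DriverSystem(Category.C5, None, drivers,
                                  other.functional_allele(), tc_allele)
                )
            if AlleleRole.RTTA_DRIVER in oroles:
                drivers = ((i, pair),) if shared else tuple(sorted([(i, pair), (j, other)]))
                systems.append(
                    _DriverSystem(Category.C6, None, drivers,
                                  other.functional_allele(), tc_allele)
                )
    systems.sort(key=lambda s: s.min_index)
    return systems


def group_subcompositions(
    comp: AlleleComposition, kb: KnowledgeTable
) -> List[Subcomposition]:
    """Partition a composition's double alleles into subcompositions.

    Every non-driver, non-wild-type double allele lands in exactly one
    subcomposition (or one per enabling driver system when several apply);
    drivers are attached as ``shared_drivers`` and are emitted as their own
    UNCLASSIFIED subcomposition only when they enable nothing.
    """
    info = []
    for i, pair in enumerate(comp.pairs):
        fa = pair.functional_allele()
        if fa is None:
            continue  # wild-type-only pair: no biological event
        info.append((i, pair, role_of(fa, kb), driver_roles(fa)))

    driver_pairs = [(i, p, dr) for i, p, _, dr in info if dr]
    target_pairs = [(i, p, r) for i, p, r, dr in info if not dr]
    systems = _build_systems(driver_pairs)
    flox_systems = [s for s in systems if s.flox_category is not None]
    teto_systems = [s for s in systems if s.teto_category is not None]

    used_driver_idx: set[int] = set()
    subs: List[Subcomposition] = []

    def emit_target(i: int, pair: DoubleAllele, role: AlleleRole,
                    heuristic: bool = False) -> None:
        zyg = zygosity(pair)
        if role == AlleleRole.FLOXED:
            matched = flox_systems
        elif role == AlleleRole.TETO_TARGET:
            matched = teto_systems
        else:
            matched = []

        if role in (AlleleRole.FLOXED, AlleleRole.TETO_TARGET):
            if not matched:
                subs.append(Subcomposition(
                    members=[pair], category=Category.UNCLASSIFIED,
                    target_gene=_target_gene_of(pair, role),
                    zygosity_qualifier=zyg, heuristic=heuristic, anchor=i,
                ))
                return
            multi = len(matched) > 1
            for sys_ in matched:
                cat = sys_.flox_category if role == AlleleRole.FLOXED else sys_.teto_category
                sub = Subcomposition(
                    members=[pair],
                    shared_drivers=[p for _, p in sys_.drivers],
                    category=cat,
                    target_gene=_target_gene_of(pair, role),
                    zygosity_qualifier=zyg,
                    inducer=_INDUCER_FOR.get(cat, Inducer.NONE),
                    heuristic=heuristic,
                    multi_driver=multi,
                    anchor=i,
                )
                try:
                    sub.pattern = expression_pattern(sys_.tissue_allele, kb)
                except Exception:
                    sub.category = Category.UNCLASSIFIED
                    sub.inducer = Inducer.NONE
                if sys_.marker_allele is not None:
                    sub.marker = find_co_driven_reporter(sys_.marker_allele)
                used_driver_idx.update(j for j, _ in sys_.drivers)
                subs.append(sub)
            return

        if role == AlleleRole.MUTANT:
            fa = pair.functional_allele()
            subs.append(Subcomposition(
                members=[pair], category=Category.I1,
                target_gene=_target_gene_of(pair, role),
                zygosity_qualifier=zyg,
                attribute=kb.attribute_map.get((fa.gene_symbol, fa.designation)),
                anchor=i,
            ))
            return

        if role == AlleleRole.TRANSGENE_OVEREXPRESSION:
            sub = Subcomposition(
                members=[pair], category=Category.I2,
                target_gene=_target_gene_of(pair, role),
                zygosity_qualifier=zyg, anchor=i,
            )
            try:
                sub.pattern = expression_pattern(pair.functional_allele(), kb)
            except Exception:
                sub.category = Category.UNCLASSIFIED
            subs.append(sub)
            return

        subs.append(Subcomposition(
            members=[pair], category=Category.UNCLASSIFIED,
            target_gene=_target_gene_of(pair, role),
            zygosity_qualifier=zyg, anchor=i,
        ))

    for i, pair, role in target_pairs:
        if role == AlleleRole.UNKNOWN and flox_systems:
            # curation gap: a targeted allele of unknown attribute alongside
            # a compatible cre-type driver is presumed floxed (flagged)
            fa = pair.functional_allele()
            if fa is not None and fa.kind == AlleleKind.TARGETED:
                emit_target(i, pair, AlleleRole.FLOXED, heuristic=True)
                continue
        emit_target(i, pair, role)

    for i, pair, _dr in driver_pairs:
        if i not in used_driver_idx:
            subs.append(Subcomposition(
                members=[pair], category=Category.UNCLASSIFIED, anchor=i,
            ))

    subs.sort(key=lambda s: s.anchor)
    return subs


# ---------------------------------------------------------------------------

def categorize(sub: Subcomposition, kb: KnowledgeTable) -> Category:
    """Category of a grouped subcomposition from its role multiset.

    Rule precedence: the three-component Tet systems (C5, C6) win over the
    two-component rules (C2, C1, C3, C4); independent singletons (I1, I2)
    apply only without drivers; anything else is UNCLASSIFIED.
    """
    droles: set[AlleleRole] = set()
    for pair in sub.shared_drivers:
        fa = pair.functional_allele()
        if fa is not None:
            droles |= driver_roles(fa)

    trole: Optional[AlleleRole] = None
    if sub.members:
        fa = sub.members[0].functional_allele()
        if fa is not None:
            trole = role_of(fa, kb)
            if trole == AlleleRole.UNKNOWN and sub.heuristic:
                trole = AlleleRole.FLOXED

    if trole == AlleleRole.FLOXED:
        if {AlleleRole.TTA_DRIVER, AlleleRole.TETO_CRE} <= droles:
            return Category.C5
        if {AlleleRole.RTTA_DRIVER, AlleleRole.TETO_CRE} <= droles:
            return Category.C6
        if AlleleRole.CREERT2_DRIVER in droles:
            return Category.C2
        if AlleleRole.CRE_DRIVER in droles:
            return Category.C1
        return Category.UNCLASSIFIED
    if trole == AlleleRole.TETO_TARGET:
        if AlleleRole.RTTA_DRIVER in droles:
            return Category.C3
        if AlleleRole.TTA_DRIVER in droles:
            return Category.C4
        return Category.UNCLASSIFIED
    if trole == AlleleRole.MUTANT and not droles:
        return Category.I1
    if trole == AlleleRole.TRANSGENE_OVEREXPRESSION and not droles:
        return Category.I2
    return Category.UNCLASSIFIED
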