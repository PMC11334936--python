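"""Parsing and canonical formatting of MGI-dialect allele-composition strings.

An allele composition is the full genotype of a genetically engineered mouse
model (GEMM), written as whitespace-separated *double alleles* — the pair of
alleles at one locus or transgene insertion, joined by ``/``::

    Pkd1<tm2Ggg>/Pkd1<+> Tg(Pax8-rtTA2S*M2)1Koes/0 Tg(tetO-cre)1Jaw/0

Four allele forms are recognized:

* ``Gene<designation>`` — a targeted (knock-in/knock-out/point-mutant) allele
  at the named endogenous locus;
* ``Gene<+>`` — the wild-type allele of that locus;
* ``Tg(construct)LineLab`` — a random-insertion transgene;
* ``0`` — the empty homologous position of a hemizygous transgene.

The pair separator ``/`` and the token separator (whitespace) are recognized
only at the top nesting level: ``/`` inside ``<...>`` or ``(...)`` (as in
``Six2<tm1(tTA,tetO-EGFP/cre)Amc>``) never splits a pair.

Only the angle-bracket dialect is accepted here; the caret/superscript dialect
(``Mybl2^tm1.1Epr^``) is normalized by :mod:`gemmannot.io` before parsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List

from .errors import EmptyCompositionError, NomenclatureSyntaxError

__all__ = [
    "AlleleKind",
    "Allele",
    "DoubleAllele",
    "AlleleComposition",
    "ZygosityClass",
    "parse_allele",
    "parse_double_allele",
    "parse_composition",
    "zygosity",
    "format_allele",
    "format_double_allele",
    "format_composition",
]


class AlleleKind(str, Enum):
    TARGETED = "targeted"
    TRANSGENE = "transgene"
    WILDTYPE = "wildtype"
    HEMIZYGOUS_NULL_PARTNER = "hemizygous_null_partner"


class ZygosityClass(str, Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    HEMIZYGOUS = "hemizygous"
    COMPOUND_HETEROZYGOUS = "compound_heterozygous"


@dataclass(frozen=True)
class Allele:
    """One allele: an engineered allele, a wild-type allele, or ``0``."""

    kind: AlleleKind
    gene_symbol: str = ""   # host gene for TARGETED/WILDTYPE, empty for TRANSGENE
    designation: str = ""   # content of <...> for TARGETED ("+" for WILDTYPE)
    construct: str = ""     # content of Tg(...) for TRANSGENE
    line_lab: str = ""      # suffix after Tg(...), e.g. "1Koes"
    raw: str = ""

    @property
    def is_engineered(self) -> bool:
        return self.kind in (AlleleKind.TARGETED, AlleleKind.TRANSGENE)


@dataclass(frozen=True)
class DoubleAllele:
    """The pair of alleles at one locus / transgene position."""

    first: Allele
    second: Allele
    raw: str = ""

    def functional_allele(self) -> Allele | None:
        """The engineered allele that determines the pair's role; None when
        the pair is wild-type only (``Gene<+>/Gene<+>``)."""
        for a in (self.first, self.second):
            if a.is_engineered:
                return a
        return None


@dataclass(frozen=True)
class AlleleComposition:
    """Ordered list of double alleles parsed from one genotype string."""

    pairs: List[DoubleAllele] = field(default_factory=list)
    raw: str = ""


# ---------------------------------------------------------------------------
# low-level scanning

_OPEN = {"<": ">", "(": ")"}
_CLOSE = {">": "<", ")": "("}


def _check_balanced(token: str) -> None:
    stack: list[str] = []
    for ch in token:
        if ch in _OPEN:
            stack.append(ch)
        elif ch in _CLOSE:
            if not stack or stack[-1] != _CLOSE[ch]:
                raise NomenclatureSyntaxError(
                    f"unbalanced brackets in token {token!r}", token=token
                )
            stack.pop()
    if stack:
        raise NomenclatureSyntaxError(
            f"unbalanced brackets in token {token!r}", token=token
        )


def split_top_level(text: str, sep: str) -> List[str]:
    """Split *text* at occurrences of *sep* outside ``<>`` / ``()`` nesting."""
    parts: List[str] = []
    depth = 0
    current: list[str] = []
    for ch in text:
        if ch in _OPEN:
            depth += 1
        elif ch in _CLOSE:
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(current))
            current = []
        else:
            current.append(ch)
    parts.append("".join(current))
    return parts


# ---------------------------------------------------------------------------
# parsing

def parse_allele(token: str) -> Allele:
    """Parse one side of a double allele."""
    if token == "0":
        return Allele(kind=AlleleKind.HEMIZYGOUS_NULL_PARTNER, raw="0")
    _check_balanced(token)

    if token.startswith("Tg("):
        depth = 0
        close = -1
        for i, ch in enumerate(token[2:], start=2):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0:
                    close = i
                    break
        construct = token[3:close]
        line_lab = token[close + 1:]
        if not construct:
            raise NomenclatureSyntaxError(
                f"empty transgene construct in {token!r}", token=token
            )
        if "<" in line_lab or "(" in line_lab:
            raise NomenclatureSyntaxError(
                f"unexpected brackets in transgene line/lab suffix of {token!r}",
                token=token,
            )
        return Allele(
            kind=AlleleKind.TRANSGENE,
            construct=construct,
            line_lab=line_lab,
            raw=token,
        )

    # targeted / wild-type: Gene<designation>; the first '<' at paren depth 0
    # separates gene symbol from designation (gene symbols such as
    # Gt(ROSA)26Sor legitimately contain parentheses).
    depth = 0
    lt = -1
    for i, ch in enumerate(token):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "<" and depth == 0:
            lt = i
            break
    if lt <= 0 or not token.endswith(">"):
        raise NomenclatureSyntaxError(
            f"unrecognized allele token {token!r}", token=token
        )
    gene = token[:lt]
    designation = token[lt + 1:-1]
    if not designation:
        raise NomenclatureSyntaxError(
            f"empty designation in {token!r}", token=token
        )
    kind = AlleleKind.WILDTYPE if designation == "+" else AlleleKind.TARGETED
    return Allele(kind=kind, gene_symbol=gene, designation=designation, raw=token)


def parse_double_allele(token: str) -> DoubleAllele:
    """Parse one whitespace-free ``A/B`` token into a :class:`DoubleAllele`."""
    _check_balanced(token)
    sides = split_top_level(token, "/")
    if len(sides) != 2 or not sides[0] or not sides[1]:
        raise NomenclatureSyntaxError(
            f"expected exactly one top-level '/' in {token!r}", token=token
        )
    first = parse_allele(sides[0])
    second = parse_allele(sides[1])
    _validate_pairing(first, second, token)
    return DoubleAllele(first=first, second=second, raw=token)


def _validate_pairing(a: Allele, b: Allele, token: str) -> None:
    kinds = {a.kind, b.kind}
    locus_kinds = {AlleleKind.TARGETED, AlleleKind.WILDTYPE}
    if kinds <= locus_kinds:
        if a.gene_symbol != b.gene_symbol:
            raise NomenclatureSyntaxError(
                f"pair {token!r} mixes two loci "
                f"({a.gene_symbol!r} vs {b.gene_symbol!r})",
                token=token,
            )
        return
    if AlleleKind.TRANSGENE in kinds:
        other = b if a.kind == AlleleKind.TRANSGENE else a
        tg = a if a.kind == AlleleKind.TRANSGENE else b
        if other.kind == AlleleKind.HEMIZYGOUS_NULL_PARTNER:
            return
        if (
            other.kind == AlleleKind.TRANSGENE
            and other.construct == tg.construct
            and other.line_lab == tg.line_lab
        ):
            return
        raise NomenclatureSyntaxError(
            f"transgene in {token!r} must pair with '0' or an identical copy",
            token=token,
        )
    raise NomenclatureSyntaxError(
        f"invalid allele pairing in {token!r}", token=token
    )


def parse_composition(raw: str) -> AlleleComposition:
    """Parse a whole genotype string into an :class:`AlleleComposition`."""
    text = raw.strip()
    if not text:
        raise EmptyCompositionError("empty allele-composition string")
    pairs = [parse_double_allele(tok) for tok in text.split()]
    return AlleleComposition(pairs=pairs, raw=raw)


# ---------------------------------------------------------------------------
# zygosity

def zygosity(pair: DoubleAllele) -> ZygosityClass:
    """Classify the zygosity of a double allele; symmetric in pair order."""
    a, b = pair.first, pair.second
    kinds = {a.kind, b.kind}
    if AlleleKind.HEMIZYGOUS_NULL_PARTNER in kinds:
        return ZygosityClass.HEMIZYGOUS
    if kinds == {AlleleKind.WILDTYPE}:
        return ZygosityClass.HOMOZYGOUS
    if AlleleKind.WILDTYPE in kinds:
        return ZygosityClass.HETEROZYGOUS
    if a.kind == AlleleKind.TRANSGENE:
        return ZygosityClass.HOMOZYGOUS  # identical copies enforced at parse
    if a.designation == b.designation:
        return ZygosityClass.HOMOZYGOUS
    return ZygosityClass.COMPOUND_HETEROZYGOUS


# ---------------------------------------------------------------------------
# formatting

def format_allele(a: Allele) -> str:
    if a.kind == AlleleKind.HEMIZYGOUS_NULL_PARTNER:
        return "0"
    if a.kind == AlleleKind.TRANSGENE:
        return f"Tg({a.construct}){a.line_lab}"
    return f"{a.gene_symbol}<{a.designation}>"


def format_double_allele(pair: DoubleAllele) -> str:
    return f"{format_allele(pair.first)}/{format_allele(pair.second)}"


def format_composition(comp: AlleleComposition) -> str:
    """Canonical serialization: single-space-joined pairs, original order."""
    return " ".join(format_double_allele(p) for p in comp.pairs)
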