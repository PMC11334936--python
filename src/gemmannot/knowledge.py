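"""Knowledge tables: allele functional roles and promoter expression patterns.

The meaning of an engineered allele depends on information the nomenclature
string alone cannot carry. Two external facts are needed:

* which promoter drives a recombinase/transactivator and where that promoter
  is active (the *driver table*, curated from public mouse-genome resources);
* whether a targeted allele is floxed, null, a point mutation, etc. (the
  *attribute table* — e.g. ``Lepr<tm1.1Chua>`` is floxed but the string looks
  like any other ``tm`` allele).

Both ship as editable TSV files so users can extend the catalog without
touching code. Functional-role keywords (cre, CreERT2, rtTA, tTA, tetO) are
detected directly from the allele designation/construct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Tuple

import pandas as pd

from .errors import FileMissingError, KnowledgeConflictError, UnknownDriverError
from .nomenclature import Allele, AlleleKind, split_top_level

__all__ = [
    "AlleleRole",
    "ExpressionPattern",
    "KnowledgeTable",
    "load_knowledge",
    "default_knowledge",
    "role_of",
    "driver_roles",
    "expression_pattern",
    "promoter_of",
]

ATTRIBUTE_VALUES = {"floxed", "null", "point_mutation", "reporter", "other"}


class AlleleRole(str, Enum):
    CRE_DRIVER = "cre_driver"
    CREERT2_DRIVER = "creert2_driver"
    RTTA_DRIVER = "rtta_driver"
    TTA_DRIVER = "tta_driver"
    TETO_TARGET = "teto_target"
    TETO_CRE = "teto_cre"
    FLOXED = "floxed"
    MUTANT = "mutant"
    TRANSGENE_OVEREXPRESSION = "transgene_overexpression"
    WILDTYPE_ROLE = "wildtype"
    UNKNOWN = "unknown"


DRIVER_ROLES = frozenset(
    {
        AlleleRole.CRE_DRIVER,
        AlleleRole.CREERT2_DRIVER,
        AlleleRole.RTTA_DRIVER,
        AlleleRole.TTA_DRIVER,
        AlleleRole.TETO_CRE,
    }
)


@dataclass(frozen=True)
class ExpressionPattern:
    """Where a promoter is active, phrased exactly as used in annotations."""

    tissue_phrase: str
    ubiquitous: bool = False

    def __post_init__(self):
        if self.ubiquitous and self.tissue_phrase != "ubiquitously":
            raise ValueError("ubiquitous patterns must use phrase 'ubiquitously'")


@dataclass
class KnowledgeTable:
    driver_map: Dict[str, ExpressionPattern] = field(default_factory=dict)
    attribute_map: Dict[Tuple[str, str], str] = field(default_factory=dict)
    constants: Dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# loading

def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    if not Path(path).is_file():
        raise FileMissingError(f"knowledge table not found: {path}")
    # keep_default_na: the literal attribute value "null" must stay a string
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KnowledgeConflictError(
            f"{path}: missing required column(s) {missing}"
        )
    return df


def load_knowledge(
    driver_table: str | Path,
    attribute_table: str | Path,
    constants_table: str | Path,
) -> KnowledgeTable:
    """Load the three TSV knowledge tables into a :class:`KnowledgeTable`.

    Duplicate keys are rejected with :class:`KnowledgeConflictError`.
    """
    kb = KnowledgeTable()

    drivers = _read_tsv(Path(driver_table), ["promoter", "tissue_phrase", "ubiquitous"])
    for _, row in drivers.iterrows():
        promoter = row["promoter"].strip()
        if promoter in kb.driver_map:
            raise KnowledgeConflictError(f"duplicate driver promoter {promoter!r}")
        kb.driver_map[promoter] = ExpressionPattern(
            tissue_phrase=row["tissue_phrase"].strip(),
            ubiquitous=row["ubiquitous"].strip() == "1",
        )

    attrs = _read_tsv(Path(attribute_table), ["gene", "designation", "attribute"])
    for _, row in attrs.iterrows():
        key = (row["gene"].strip(), row["designation"].strip())
        value = row["attribute"].strip()
        if value not in ATTRIBUTE_VALUES:
            raise KnowledgeConflictError(
                f"unknown attribute {value!r} for allele {key}"
            )
        if key in kb.attribute_map:
            raise KnowledgeConflictError(f"duplicate attribute key {key}")
        kb.attribute_map[key] = value

    consts = _read_tsv(Path(constants_table), ["name", "value"])
    for _, row in consts.iterrows():
        name = row["name"].strip()
        if name in kb.constants:
            raise KnowledgeConflictError(f"duplicate constant {name!r}")
        kb.constants[name] = float(row["value"])

    return kb


def default_knowledge() -> KnowledgeTable:
    """The knowledge tables bundled with the package."""
    data = resources.files("gemmannot") / "data"
    return load_knowledge(
        str(data / "drivers.tsv"),
        str(data / "attributes.tsv"),
        str(data / "constants.tsv"),
    )


# ---------------------------------------------------------------------------
# role detection

def _payload(a: Allele) -> str:
    return a.designation if a.kind == AlleleKind.TARGETED else a.construct


def _tokens(a: Allele) -> list[str]:
    """Designation/construct tokens, delimited by ``( ) - / ,``."""
    return [t for t in re.split(r"[()\-/,]+", _payload(a)) if t]


def _keyword_flags(a: Allele) -> dict[str, bool]:
    toks = [t.lower() for t in _tokens(a)]
    has_cre = any(t in ("cre", "icre") for t in toks)
    has_ert = any(t in ("ert", "ert2") for t in toks)
    return {
        "creert2": any(t.startswith("creer") for t in toks) or (has_cre and has_ert),
        "cre": has_cre,
        "teto": "teto" in toks,
        "rtta": any(t.startswith("rtta") for t in toks),
        # rtTA tokens start with 'r', so the tTA prefix test cannot fire on them
        "tta": any(t.startswith("tta") for t in toks),
    }


def driver_roles(a: Allele) -> FrozenSet[AlleleRole]:
    """All driver roles carried by one allele.

    A single knock-in cassette can combine a transactivator with a
    tetO-driven cre (e.g. ``tm1(tTA,tetO-EGFP/cre)``); classification needs
    the full set, while :func:`role_of` reports the precedence-first role.
    """
    if not a.is_engineered:
        return frozenset()
    f = _keyword_flags(a)
    roles: set[AlleleRole] = set()
    if f["creert2"]:
        roles.add(AlleleRole.CREERT2_DRIVER)
    elif f["teto"] and f["cre"]:
        roles.add(AlleleRole.TETO_CRE)
    elif f["cre"]:
        roles.add(AlleleRole.CRE_DRIVER)
    if f["rtta"]:
        roles.add(AlleleRole.RTTA_DRIVER)
    elif f["tta"]:
        roles.add(AlleleRole.TTA_DRIVER)
    return frozenset(roles)


def role_of(a: Allele, kb: KnowledgeTable) -> AlleleRole:
    """The functional role of one allele (total: never raises).

    Keyword precedence: CreERT2 before plain cre; tetO-cre before tetO
    targets; rtTA before tTA. Non-driver targeted alleles fall back to the
    attribute table.
    """
    if a.kind == AlleleKind.WILDTYPE or a.kind == AlleleKind.HEMIZYGOUS_NULL_PARTNER:
        return AlleleRole.WILDTYPE_ROLE
    f = _keyword_flags(a)
    if f["creert2"]:
        return AlleleRole.CREERT2_DRIVER
    if f["teto"]:
        return AlleleRole.TETO_CRE if f["cre"] else AlleleRole.TETO_TARGET
    if f["rtta"]:
        return AlleleRole.RTTA_DRIVER
    if f["tta"]:
        return AlleleRole.TTA_DRIVER
    if f["cre"]:
        return AlleleRole.CRE_DRIVER
    if a.kind == AlleleKind.TARGETED:
        attr = kb.attribute_map.get((a.gene_symbol, a.designation))
        if attr == "floxed":
            return AlleleRole.FLOXED
        if attr in ("null", "point_mutation", "reporter", "other"):
            return AlleleRole.MUTANT
        return AlleleRole.UNKNOWN
    if a.kind == AlleleKind.TRANSGENE:
        return AlleleRole.TRANSGENE_OVEREXPRESSION
    return AlleleRole.UNKNOWN


# ---------------------------------------------------------------------------
# expression patterns

def promoter_of(driver: Allele) -> str:
    """Promoter symbol of a driver allele.

    Knock-in drivers are expressed from the host locus, so the promoter is
    the host gene symbol; transgenic drivers carry the promoter as the
    construct prefix before the first top-level ``-``.
    """
    if driver.kind == AlleleKind.TARGETED:
        return driver.gene_symbol
    return split_top_level(driver.construct, "-")[0]


def expression_pattern(driver: Allele, kb: KnowledgeTable) -> ExpressionPattern:
    """Resolve where a driver allele is expressed.

    Raises :class:`UnknownDriverError` when the promoter is not in the
    driver table; callers treat that as UNCLASSIFIED, not a crash.
    """
    promoter = promoter_of(driver)
    try:
        return kb.driver_map[promoter]
    except KeyError:
        raise UnknownDriverError(
            f"promoter {promoter!r} not in driver table"
        ) from None


# ---------------------------------------------------------------------------
# reporters

REPORTERS = (
    "EGFP", "GFP", "EYFP", "YFP", "ECFP", "CFP",
    "tdTomato", "mCherry", "DsRed", "RFP", "lacZ", "luc",
)
_REPORTERS_LOWER = {r.lower() for r in REPORTERS}


def find_co_driven_reporter(driver: Allele) -> str | None:
    """A fluorophore/reporter co-driven with cre in a tetO cassette, if any.

    In cassettes like ``tm1(tTA,tetO-EGFP/cre)`` the reporter and cre share
    the tetO promoter, so the reporter marks where cre acts.
    """
    f = _keyword_flags(driver)
    if not (f["teto"] and f["cre"]):
        return None
    for tok in _tokens(driver):
        if tok.lower() in _REPORTERS_LOWER:
            return tok
    return None
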