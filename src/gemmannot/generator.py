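"""Seeded grammar-based generator of valid allele compositions.

Each draw picks a category from the configured mix and emits an allele set
that the classifier must map back to exactly that category — a closed-loop
self-consistency oracle used throughout the property tests. Gene pools come
from the knowledge table (floxed/mutant alleles from the attribute table,
driver promoters from the driver table) so generated strings always resolve.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List

from .classify import Category
from .errors import GeneratorConfigError
from .knowledge import KnowledgeTable

__all__ = ["GeneratorConfig", "generate_random_composition"]

_LINE_LABS = ["1Jaw", "1Koes", "2Abc", "3Jesc", "1Cgn"]
_TETO_GENES = ["Aimp1", "Bdnf", "Igf1", "Myc", "Kras"]
_RTTA_VARIANTS = ["rtTA", "rtTA2S*M2", "rtTA3"]


@dataclass
class GeneratorConfig:
    seed: int = 0
    n: int = 100
    mix: Dict[str, float] = field(
        default_factory=lambda: {c.value: 1.0 for c in Category}
    )


def _floxed_genes(kb: KnowledgeTable) -> List[tuple]:
    return sorted(k for k, v in kb.attribute_map.items() if v == "floxed")


def _mutant_genes(kb: KnowledgeTable) -> List[tuple]:
    return sorted(
        k for k, v in kb.attribute_map.items()
        if v in ("null", "point_mutation", "other")
    )


def _promoters(kb: KnowledgeTable) -> List[str]:
    return sorted(kb.driver_map)


def _tg_promoters(kb: KnowledgeTable) -> List[str]:
    # transgene constructs use '-' as an internal separator, so promoters
    # containing parentheses (e.g. Gt(ROSA)26Sor) are knock-in only here
    return [p for p in sorted(kb.driver_map) if "(" not in p]


def _check_pools(cfg: GeneratorConfig, kb: KnowledgeTable) -> None:
    needs_flox = {"C1", "C2", "C5", "C6"}
    needs_driver = {"C1", "C2", "C3", "C4", "C5", "C6", "I2"}
    for cat, weight in cfg.mix.items():
        if weight <= 0:
            continue
        if cat in needs_flox and not _floxed_genes(kb):
            raise GeneratorConfigError(f"category {cat}: no floxed alleles in table")
        if cat == "I1" and not _mutant_genes(kb):
            raise GeneratorConfigError("category I1: no mutant alleles in table")
        if cat in needs_driver and not _tg_promoters(kb):
            raise GeneratorConfigError(f"category {cat}: no driver promoters in table")


def _floxed_pair(rng: random.Random, kb: KnowledgeTable) -> str:
    gene, designation = rng.choice(_floxed_genes(kb))
    zyg = rng.choice(["hom", "het"])
    partner = f"{gene}<+>" if zyg == "het" else f"{gene}<{designation}>"
    return f"{gene}<{designation}>/{partner}"


def _tg(rng: random.Random, construct: str) -> str:
    lab = rng.choice(_LINE_LABS)
    return f"Tg({construct}){lab}/0"


def _driver_cre(rng: random.Random, kb: KnowledgeTable, kind: str) -> str:
    """kind: 'cre' or 'cre/ERT2'; knock-in or transgenic form."""
    if rng.random() < 0.5:
        promoter = rng.choice(_promoters(kb))
        return f"{promoter}<tm1({kind})Lowl>/{promoter}<+>"
    promoter = rng.choice(_tg_promoters(kb))
    suffix = "cre" if kind == "cre" else "cre/ERT2"
    return _tg(rng, f"{promoter}-{suffix}")


def _emit(rng: random.Random, category: str, kb: KnowledgeTable) -> List[str]:
    if category == "I1":
        gene, designation = rng.choice(_mutant_genes(kb))
        return [f"{gene}<{designation}>/{gene}<{designation}>"]
    if category == "I2":
        promoter = rng.choice(_tg_promoters(kb))
        gene = rng.choice(_TETO_GENES)
        return [_tg(rng, f"{promoter}-{gene}")]
    if category == "C1":
        return [_driver_cre(rng, kb, "cre"), _floxed_pair(rng, kb)]
    if category == "C2":
        return [_driver_cre(rng, kb, "cre/ERT2"), _floxed_pair(rng, kb)]
    if category in ("C3", "C4"):
        promoter = rng.choice(_tg_promoters(kb))
        ta = rng.choice(_RTTA_VARIANTS) if category == "C3" else "tTA"
        gene = rng.choice(_TETO_GENES)
        return [_tg(rng, f"{promoter}-{ta}"), _tg(rng, f"tetO-{gene}")]
    if category in ("C5", "C6"):
        flox = _floxed_pair(rng, kb)
        if category == "C5" and rng.random() < 0.5:
            # combined knock-in cassette: transactivator plus tetO-driven
            # reporter/cre in one allele
            promoter = rng.choice(_promoters(kb))
            return [f"{promoter}<tm1(tTA,tetO-EGFP/cre)Amc>/{promoter}<+>", flox]
        promoter = rng.choice(_tg_promoters(kb))
        ta = rng.choice(_RTTA_VARIANTS) if category == "C6" else "tTA"
        return [_tg(rng, f"{promoter}-{ta}"), _tg(rng, "tetO-cre"), flox]
    if category == "UNCLASSIFIED":
        return [_tg(rng, "tetO-cre")]
    raise GeneratorConfigError(f"unknown category {category!r}")


def generate_random_composition(
    cfg: GeneratorConfig, kb: KnowledgeTable
) -> List[str]:
    """Generate ``cfg.n`` composition strings per the category mix.

    Deterministic: the same seed and config yield byte-identical output.
    """
    active = sorted((c, w) for c, w in cfg.mix.items() if w > 0)
    if not active:
        raise GeneratorConfigError("category mix has no positive weight")
    _check_pools(cfg, kb)
    rng = random.Random(cfg.seed)
    categories = [c for c, _ in active]
    weights = [w for _, w in active]
    out: List[str] = []
    for _ in range(cfg.n):
        category = rng.choices(categories, weights=weights, k=1)[0]
        pairs = _emit(rng, category, kb)
        rng.shuffle(pairs)
        out.append(" ".join(pairs))
    return out
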