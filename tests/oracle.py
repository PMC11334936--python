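"""Independent brute-force classification oracle.

Re-derives the category multiset of a composition from first principles:
its own tokenizer and keyword flags, explicit enumeration of driver subsets
per target, and a literal transcription of the category definitions. Shares
no code path with gemmannot.classify beyond the attribute table contents.
"""

from collections import Counter
import re

_WILD = re.compile(r"^[^<]*<\+>$")


def _sides(pair_token):
    depth, parts, cur = 0, [], []
    for ch in pair_token:
        if ch in "<(":
            depth += 1
        elif ch in ">)":
            depth -= 1
        if ch == "/" and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def _functional(pair_token):
    for side in _sides(pair_token):
        if side != "0" and not _WILD.match(side):
            return side
    return None


def _flags(side):
    if side.startswith("Tg("):
        payload = side[3:side.rindex(")")]
    else:
        payload = side[side.index("<") + 1:-1]
    toks = [t.lower() for t in re.split(r"[()\-/,]+", payload) if t]
    cre = any(t in ("cre", "icre") for t in toks)
    ert = any(t in ("ert", "ert2") for t in toks) or any(
        t.startswith("creer") for t in toks
    )
    return {
        "creert2": cre and ert or any(t.startswith("creer") for t in toks),
        "cre": cre,
        "teto": "teto" in toks,
        "rtta": any(t.startswith("rtta") for t in toks),
        "tta": any(t.startswith("tta") for t in toks),
    }


def _host_gene(side):
    return side[: side.index("<")]


def _designation(side):
    return side[side.index("<") + 1:-1]


def oracle_categories(pair_tokens, attribute_map):
    """Category multiset for a list of double-allele tokens."""
    drivers = []   # (idx, flags)
    targets = []   # (idx, kind) kind in {floxed, teto_target, mutant, tg, unknown}
    for i, tok in enumerate(pair_tokens):
        side = _functional(tok)
        if side is None:
            continue
        f = _flags(side)
        if f["creert2"] or f["cre"] or f["rtta"] or f["tta"]:
            drivers.append((i, f))
        elif f["teto"]:
            targets.append((i, "teto_target"))
        elif side.startswith("Tg("):
            targets.append((i, "tg"))
        else:
            attr = attribute_map.get((_host_gene(side), _designation(side)))
            if attr == "floxed":
                targets.append((i, "floxed"))
            elif attr in ("null", "point_mutation", "reporter", "other"):
                targets.append((i, "mutant"))
            else:
                targets.append((i, "unknown"))

    # enumerate driver systems: singles and transactivator+tetO-cre subsets
    flox_systems = []   # (category, driver index set)
    teto_systems = []
    for i, f in drivers:
        if f["creert2"]:
            flox_systems.append(("C2", {i}))
        elif f["teto"] and f["cre"]:
            pass  # tetO-cre alone acts only with a transactivator
        elif f["cre"]:
            flox_systems.append(("C1", {i}))
        if f["rtta"]:
            teto_systems.append(("C3", {i}))
        elif f["tta"]:
            teto_systems.append(("C4", {i}))
    for i, f in drivers:
        if not (f["teto"] and f["cre"]) or f["creert2"]:
            continue
        for j, g in drivers:
            if g["tta"] and not g["rtta"]:
                flox_systems.append(("C5", {i, j}))
            if g["rtta"]:
                flox_systems.append(("C6", {i, j}))

    counts = Counter()
    used = set()
    any_flox_system = bool(flox_systems)
    for i, kind in targets:
        if kind == "unknown" and any_flox_system:
            kind = "floxed"  # presumed floxed alongside a cre-type driver
        if kind == "floxed":
            if flox_systems:
                for cat, idxs in flox_systems:
                    counts[cat] += 1
                    used |= idxs
            else:
                counts["UNCLASSIFIED"] += 1
        elif kind == "teto_target":
            if teto_systems:
                for cat, idxs in teto_systems:
                    counts[cat] += 1
                    used |= idxs
            else:
                counts["UNCLASSIFIED"] += 1
        elif kind == "mutant":
            counts["I1"] += 1
        elif kind == "tg":
            counts["I2"] += 1
        else:
            counts["UNCLASSIFIED"] += 1
    for i, _ in drivers:
        if i not in used:
            counts["UNCLASSIFIED"] += 1
    return counts
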