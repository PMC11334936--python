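import csv
from importlib import resources

import pytest

from gemmannot import default_knowledge


@pytest.fixture(scope="session")
def kb():
    return default_knowledge()


@pytest.fixture(scope="session")
def worked_examples():
    """The bundled curated examples: composition, category, annotation."""
    path = resources.files("gemmannot") / "data" / "examples.tsv"
    with open(str(path), encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


# distinct double-allele tokens drawn from the bundled examples, plus a tTA
# driver (Tet-off overexpression has no curated example), a lone tetO-cre,
# an uncurated targeted allele and a wild-type pair — the pool for the
# brute-force classification oracle
ORACLE_POOL = [
    "Zfp541<em1Osb>/Zfp541<em1Osb>",
    "Tg(Myh6-Acsl1)J3Jesc/0",
    "Agrp<tm1(cre)Lowl>/Agrp<+>",
    "Lepr<tm1.1Chua>/Lepr<tm1.1Chua>",
    "Gt(ROSA)26Sor<tm1(cre/ERT2)Thl>/Gt(ROSA)26Sor<+>",
    "Mcl1<tm1Ywh>/Mcl1<tm1Ywh>",
    "Tg(Scgb1a1-rtTA)1Jaw/0",
    "Tg(tetO-Aimp1)29872Mcla/0",
    "Hnf4a<tm1Sad>/Hnf4a<tm1Sad>",
    "Six2<tm1(tTA,tetO-EGFP/cre)Amc>/Six2<+>",
    "Pkd1<tm2Ggg>/Pkd1<+>",
    "Tg(Pax8-rtTA2S*M2)1Koes/0",
    "Tg(tetO-cre)1Jaw/0",
    "Tg(Mx1-tTA)1Cgn/0",
    "Mybl2<tm9Zzz>/Mybl2<tm9Zzz>",
    "Trp53<+>/Trp53<+>",
]


@pytest.fixture(scope="session")
def oracle_pool():
    return list(ORACLE_POOL)
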