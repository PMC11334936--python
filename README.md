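# gemmannot

Genotype strings of genetically engineered mouse models (GEMMs) are written
in a compact registry nomenclature — `Pkd1<tm2Ggg>/Pkd1<+>
Tg(Pax8-rtTA2S*M2)1Koes/0 Tg(tetO-cre)1Jaw/0` — that is opaque to anyone
outside mouse genetics. What that line actually means is: *Pkd1 is
inactivated heterozygously in the kidney, and only after
tetracycline/doxycycline treatment*. `gemmannot` turns the former into the
latter automatically.

The package is aimed at interdisciplinary researchers and database curators
who need plain-language descriptions of mouse genotypes at scale: it parses
allele-composition strings, recognizes the engineered-genetics systems in
play (Cre-loxP, tamoxifen-dependent CreERT2, and the Tet-on/Tet-off
rtTA/tTA–tetO systems), classifies each biological event, and renders a
one-sentence description. It also provides the companion fuzzy phenotype
search used to look such models up by free-text phenotype keywords.

## The model

A genotype (*allele composition*) is an ordered list of *double alleles*,
the two alleles at one locus or transgene insertion. The engine splits a
composition into *subcompositions* — minimal sets of double alleles
producing one biological event — and assigns each to one of eight
categories:

| Category | System | Event |
|---|---|---|
| I1 | — | mutation of a gene or its regulatory elements (global) |
| I2 | — | transgene overexpression, tissue set by the construct promoter |
| C1 | Cre-loxP | tissue-specific knockout (Cre driver + floxed allele) |
| C2 | CreERT2-loxP | tamoxifen-inducible knockout |
| C3 | rtTA + tetO (Tet-on) | doxycycline-induced overexpression |
| C4 | tTA + tetO (Tet-off) | overexpression shut off by doxycycline |
| C5 | tTA + tetO-cre + loxP | knockout-and-restore (Tet-off cre) |
| C6 | rtTA + tetO-cre + loxP | doxycycline-induced knockout (Tet-on cre) |

Anything that fits no category is reported as UNCLASSIFIED and flagged for
manual annotation rather than guessed. The tissue wording comes from an
editable TSV knowledge table mapping driver promoters to expression
patterns; a second table records curated allele attributes (floxed, null,
point mutation), since floxed status cannot be read off the allele symbol.

Phenotype search is plain keyword cosine similarity: records and queries
are tokenized to term-frequency vectors *u*, *v* and ranked by
*u·v / (‖u‖‖v‖)*, returning the top 10 non-zero-scoring hits.

## Worked example

```python
from gemmannot import default_knowledge, parse_composition, annotate_composition

kb = default_knowledge()
comp = parse_composition(
    "Pkd1<tm2Ggg>/Pkd1<+> Tg(Pax8-rtTA2S*M2)1Koes/0 Tg(tetO-cre)1Jaw/0"
)
ann = annotate_composition(comp, kb)
print(ann.per_subcomposition[0][0].value)
print(ann.text)
```

prints

```
C6
Inactivating Pkd1 heterozygously in the kidney. The inactivation is induced by tetracycline(or doxycycline) treatment.
```

i.e. the three double alleles were recognized as one cooperative Tet-on
knockout event: the *Pax8*-driven rtTA (kidney) activates the tetO-driven
Cre only under doxycycline, which then excises the floxed *Pkd1* allele;
the `/Pkd1<+>` wild-type partner makes the knockout heterozygous.

The same pipeline is available from the shell:

```bash
gemmannot annotate --input genotypes.tsv --out annotations.tsv --format tsv
gemmannot classify --input genotypes.tsv
gemmannot search --corpus phenotypes.tsv --query "abnormal heart" --top 10
gemmannot generate --seed 1 --n 20 --mix "C1=0.5,C6=0.5"
```

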