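# Methods

## Nomenclature model

A genotype string is parsed as whitespace-separated double-allele tokens,
each split at its unique top-level `/`. "Top-level" is decided by a single
scan tracking `<>`/`()` nesting depth, which is required for cassette
designations such as `tm1(tTA,tetO-EGFP/cre)Amc` where `/` appears inside
the brackets. Only the angle-bracket dialect is held internally; the
caret-superscript rendering common in running text (`Mybl2^tm1.1Epr^`) is
rewritten to angle brackets by the readers before parsing, so there is one
canonical form and `format(parse(s))` is idempotent.

Gene symbols are matched case-sensitively and may themselves contain
parentheses (`Gt(ROSA)26Sor`): the parser takes the first `<` at
parenthesis depth zero as the gene/designation boundary. This is a dialect
assumption; registry symbols with `<` inside the gene name do not occur.

Pairing rules are enforced at parse time: two targeted/wild-type alleles
must name the same locus; a transgene pairs only with `0` (hemizygous) or
an identical copy. Two *distinct* mutant designations at one locus are
accepted and classed COMPOUND_HETEROZYGOUS — the compound case never
appears in the curated examples but exists in real registry data, and the
zygosity classifier must be total. Zygosity is symmetric in pair order by
construction.

## Knowledge tables

Three TSV tables (UTF-8, tab-delimited, header row, `#` comments) ship in
`src/gemmannot/data/` and are deliberately data, not code:

* `drivers.tsv` — promoter → expression pattern. The phrase is used
  verbatim in rendered text; `ubiquitous=1` rows must carry the phrase
  `ubiquitously`. The bundled rows cover the promoters exercised by the
  curated examples (Agrp, Myh6, Scgb1a1, Six2, Pax8, Gt(ROSA)26Sor, Mx1);
  users extend the file for their own colonies. The Mx1 phrase is our own
  curation choice, as is any entry — editing the TSV changes wording, not
  behavior.
* `attributes.tsv` — (gene, designation) → {floxed, null, point_mutation,
  reporter, other}. Floxed status is *not* inferable from the symbol
  (`tm1Ywh` the floxed allele and a null `tm` allele look identical), so
  the curated table is the primary source. Fallback heuristic: a targeted
  allele of unknown attribute co-occurring with a compatible cre-type
  driver is presumed floxed and the whole annotation is flagged
  `provenance=heuristic`.
* `constants.tsv` — documented molecular facts (loxP site = 34 bp, Cre =
  343 aa). They are part of the machine-checkable knowledge surface and are
  not consulted during classification.

Functional roles are detected by keyword scan over designation/construct
tokens (delimiters `( ) - / ,`), case-insensitive except gene symbols, with
precedence CreERT2 > tetO-cre > tetO target > rtTA > tTA > cre. Two
precedence rules matter in practice: any allele carrying both `cre` and
`ERT2` tokens is never a plain Cre driver, and rtTA variant tokens
(`rtTA2S*M2`, `rtTA3`) are recognized by prefix so they never classify as
tTA. A single cassette can carry several driver functions (the
knockout-and-restore knock-in combines tTA with a tetO-driven EGFP/cre);
`role_of` reports the precedence-first role while `driver_roles` exposes
the full set, which the classifier consumes.

## Classification

Each non-driver engineered double allele (floxed, tetO target, mutant,
overexpression transgene) anchors one subcomposition. Driver alleles are
organized into *driver systems*: a Cre or CreERT2 allele alone, a
transactivator alone (for tetO targets), or a transactivator + tetO-cre
combination (for floxed targets). Rule precedence is triples before pairs:
{tTA, tetO-cre, floxed} → C5 and {rtTA, tetO-cre, floxed} → C6 win over
the two-component rules {CreERT2, floxed} → C2, {Cre, floxed} → C1,
{rtTA, tetO} → C3, {tTA, tetO} → C4; driverless mutants → I1 and
transgene overexpression → I2; everything else is UNCLASSIFIED.

Design choices where the rules were genuinely open:

* One subcomposition per (driver system, target) pair, in deterministic
  input order; several floxed targets sharing one driver give one event
  each ("one target gene per biological event"), and several compatible
  drivers for one target are all emitted, flagged `multi_driver`.
* Drivers that enable nothing become UNCLASSIFIED subcompositions instead
  of being dropped, so the manual-annotation queue sees them; wild-type
  only pairs produce no event at all.
* A composition containing any UNCLASSIFIED event is flagged
  `needs_manual`, but machine annotations for its classifiable events are
  still emitted.
* An unknown driver promoter makes that event UNCLASSIFIED rather than
  raising: classification is total over parseable input.
* Trans-arranged loxP chromosome-engineering alleles have no category and
  fall through to UNCLASSIFIED by design.

## Rendering

Each category has a fixed template; slots are the target gene, the tissue
phrase, a zygosity adverb and an optional reporter. The adverbial is
`ubiquitously` for ubiquitous drivers, `specifically in <tissue>` for
Cre/CreERT2 knockouts and plain `in <tissue>` otherwise; `heterozygously`
is inserted after the gene for heterozygous knockout targets in all
knockout templates (the curated examples only show it for the Tet-on
knockout, so this generalization is a package choice). Reporters co-driven
with cre in a tetO cassette (EGFP and kin, from a configurable list) are
mentioned as marking the excision pattern. Trailing punctuation is
intentionally uneven across templates: each is byte-exact to the curated
wording it reproduces, and normalizing it would break exact-match
consumers. The Tet-off overexpression (C4) template and the non-null I1
wordings have no curated exemplar; they are our own and are flagged
`template_invented` in structured output. Event texts join with `"; "`.

## Fuzzy phenotype search

Tokenization is lowercase split on non-alphanumeric runs; vectors are raw
term frequencies over the corpus vocabulary — no idf, stemming or synonym
expansion, the simplest faithful reading of "keyword cosine similarity".
Scores are clamped to [0, 1] (rounding can push identical vectors one ulp
above 1). Zero-scoring records are suppressed; ties break
lexicographically by record text, making rankings independent of corpus
order; `k` defaults to 10.

## Synthetic composition generator

The generator is first-class, seeded (`random.Random(seed)`) and
grammar-driven: for a requested category it emits an allele set that the
classifier must map back to exactly that category, drawing floxed/mutant
alleles from the attribute table and driver promoters from the driver
table so every generated string resolves. Knock-in and transgenic driver
forms, homo-/heterozygous floxed targets, rtTA variant spellings and the
combined tTA/tetO-cre cassette are all sampled. It emulates structural
variety of genotypes, not registry realism: allele designations and line
labels come from small fixed pools, genetic backgrounds are absent, and
category frequencies follow the configured mix rather than any census.
Passing the closed-loop and round-trip suites therefore demonstrates
grammatical and logical self-consistency, not coverage of every string in
a live registry — curation gaps in the TSVs remain the dominant failure
mode on real data, and they surface as UNCLASSIFIED, not as wrong text.

## Verification sizes and numerics

Property suites run on 1000 generated compositions (round-trip, zygosity
symmetry, totality), 50 per category for the closed loop, and all 1470
compositions of ≤4 double alleles drawn from the 14-token fixture pool for
the brute-force oracle comparison — sizes chosen so the whole suite runs
in seconds while exhausting the rule interactions the pool can express.
The oracle (tests/oracle.py and its mirror in scripts/acceptance.py)
re-derives the category multiset with its own tokenizer and an explicit
enumeration of driver subsets per target, sharing no code with the engine.
All annotation output is deterministic: no floating point enters parsing,
classification or rendering; search is the only numeric component.

## Known limitations

* The attribute and driver tables ship only the rows the bundled examples
  need; real-registry coverage is the user's curation task.
* Compound-heterozygous and multi-driver genotypes render with the same
  templates as their simple counterparts; no combined wording exists.
* `Gene<designation>/0` (sex-chromosome hemizygous knock-ins) is outside
  the accepted dialect and is routed to the rejects list.
* Search is purely lexical; "semantic" matching beyond shared keywords is
  out of scope.
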