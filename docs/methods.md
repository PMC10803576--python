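# Methods

## Pipeline overview

`mirlit` turns one MEDLINE citation file per disease corpus into article
counts. For every record the *mining text* is the title and abstract joined
by a single space; records without an abstract are mined on the title
alone (the retrieval queries match on title *or* abstract, so a title-only
record is still evidence). The pipeline steps are:

1. drop records carrying a "Review" publication type (any of a record's
   publication types equal to "Review", case-insensitively, excludes it —
   mirroring the `NOT (Review[Publication Type])` clause of the retrieval
   query);
2. extract miRNA family mentions and concept-term matches from each
   record's mining text;
3. count articles per family, per term, and per (family, term) pair, each
   at most once per article;
4. rank the top-k families per corpus, build the co-occurrence matrix
   restricted to those families, tabulate the yearly trend;
5. across corpora: sum family counts and score breadth of top-k
   membership.

## Mention grammar

The grammar accepts an optional three-letter species prefix (`hsa-`,
`mmu-`, ...), one of the spellings *microRNA / micro RNA / miRNA / miR* in
any case, an optional hyphen or single space, one or more digits, then
optional suffixes: a single paralog letter, a `-digit` paralog index, and
a `-3p`/`-5p` arm. Matches must start and end at word boundaries; a hyphen
*before* the mention is allowed so `anti-miR-21` is found. Normalization
keeps only the first integer: family identity deliberately collapses
paralogs (`miR-146a`, `miR-146b`), arms and species forms, because the
literature counts of interest are family-level.

Decisions worth knowing:

* **Clusters.** `miR-17-92` is consumed as one token and normalizes to
  `miR-17`; the trailing `-92` is indistinguishable from a paralog index
  inside a single-token grammar, and splitting cluster names would require
  a curated cluster list.
* **Slash lists.** `miR-146a/b` yields only `miR-146` — correct here by
  the coincidence that both arms share the family.
* **No whitelist.** Any integer is accepted (families above 1000 occur in
  real corpora, e.g. miR-1207), so unusual indices are counted rather than
  silently dropped.
* **Blind spot.** Non-`miR`-prefixed names (`let-7`) are not extracted.
  This mirrors the mining rule the package implements; `mirna.EXTRA_PATTERNS`
  is the extension hook.
* **Space-separated mentions.** `miR 146` is accepted. Whether originally
  intended is unknowable; accepting it is the more sensitive choice and is
  isolated in one grammar constant for sensitivity analysis.

## Concept matching

Matching is case-insensitive substring search. Pure substring matching
conflates the printed cytokine list (`IL-1` is a substring of `IL-10`,
`IL-17`, `IL-18`), so two guards are applied:

* variants ending in a digit require the next character to be a non-digit
  — `IL-1β` and `IL-1b` still count as IL-1;
* variants marked `^` in the config require a word boundary before the
  match; the defaults mark the single-letter-prefixed cell names
  (`T-cell`, `T-reg`, `Treg`, `B-cell`). The sigil is explicit in the
  config rather than auto-detected because `Treg` would escape any
  "single letter then separator" heuristic.

Built-in variants cover hyphen/space interchange (`T cell` ⇔ `T-cell`),
`Treg`/`regulatory T`, `tumor necrosis factor` for TNF, and
`interleukin-n`/`interleukin n` for each `IL-n`. Plurals come free with
substring semantics. The generic term `interleukin` is its own canonical
entry and co-counts with specific `IL-n` hits — the curated list names it
separately, so the two are counted independently; users who want exclusive
counting can drop the entry from their config.

Not done, deliberately: stemming, negation detection, ontology grounding.
These change the counting model and belong upstream of a tool whose
contract is transparent substring semantics.

## Counting

All counts are per-article-deduplicated: sets of families and terms are
taken per record before any aggregation, so mention multiplicity never
matters and every result is invariant under record permutation. A matrix
cell is bounded by the minimum of its row and column marginals (set
intersection), a property-tested invariant. Rankings sort by count
descending with ties broken by ascending family integer index — ties must
break *somehow* deterministic, and the numeric index is stable across
runs and implementations. Cross-corpus aggregation sums per-corpus counts
without PMID deduplication (one retrieval file per disease is the unit of
analysis); a diagnostic lists PMIDs occurring in several corpora so users
can judge the overlap.

Records whose date field yields no 4-digit year are excluded from trend
series only — never from the other counts — and their number is logged.

## MEDLINE I/O

Fields are `TAG - value` lines (tag left-padded to four characters),
continuations are exactly six leading spaces and re-join with a single
space, records separate on blank lines. The parser is deliberately
lenient: a block without a PMID is skipped with a warning; a malformed
line inside a record is treated as a continuation of the previous field.
Input is read as UTF-8 with replacement on undecodable bytes — Greek
letters must survive because cytokine matching depends on them. Only
PMID/TI/AB/DP/PT/JT have dedicated semantics; all fields are kept verbatim
in an ordered multimap so writing re-produces the record. The writer wraps
long values at ~86 columns on spaces, which the continuation-join rule
inverts exactly for single-spaced text.

## Synthetic corpora and what they show

The generator samples, per record, a set of families and a set of terms by
independent Bernoulli draws, a Review flag, and a publication year, then
renders them into filler sentences through random surface forms (species
prefixes, spellings, case changes, paralog and arm suffixes, plural and
Greek-suffixed term forms). Ground truth is recorded **at sampling time**,
so engine-versus-truth comparison independently checks the whole
extraction → matching → counting path. Two constructions keep the truth
exact:

* the filler vocabulary contains no digits, no miR-like token, and no
  substring of any dictionary variant;
* terms are only rendered through surface forms that match exactly their
  own canonical term under the full default dictionaries (IL-6 is never
  rendered as `interleukin-6`, which would also hit the independent
  `interleukin` entry).

With surface noise enabled the generator also emits duplicated mentions
(counts must not change) and drops the date field on ~5% of records
(trend series must shrink accordingly).

The packaged nine-corpus fixture uses the nine rheumatic-disease labels
with sizes equal to realistic per-disease retrieval counts scaled down
roughly tenfold (floor 15; 342 records total — large enough for stable
rankings, small enough that the full suite runs in seconds), a skewed
family distribution, and two families (`miR-146`, `miR-155`) included
with probability 1 everywhere, which forces both to breadth 9 in any
correct analysis.

What passing these tests does **not** show: performance on real abstracts.
The generator's filler is not natural prose — real text contains gene
symbols with embedded digits, novel term spellings, and negations, none of
which the synthetic corpora produce. The synthetic oracle validates the
counting machinery exactly; validity of the dictionaries against real
corpora is a curation question, not a software one.

## Reporting

Every figure writes a companion CSV of exactly the plotted numbers, and
all checks assert on those tables, never on pixels. Trend lines zero-fill
the full year range between the earliest and latest observed year.
Heatmap columns are grouped cell types → cytokines → processes in
dictionary order; the color scale is anchored at zero and normalized per
panel (per-panel keeps small corpora readable; a shared scale is one flag
away since the tables carry raw counts). Donut wedges are top-k counts
normalized by the in-ranking total.

## Numerical/degenerate-input choices

* Empty corpora, empty rankings, empty aggregates: all legal, producing
  empty (but schema-complete) tables.
* `top_k` with k < 1, mixed-k breadth input, duplicate corpus labels,
  malformed family names in generator specs: `ValueError`.
* The run manifest records tool version, k, review handling, a content
  hash of the dictionaries and per-corpus record censuses; replaying the
  same inputs reproduces every table byte-identically.
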