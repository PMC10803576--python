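# mirlit

Dictionary-based miRNA literature-relevance mining over PubMed/MEDLINE
citation exports.

## The problem

Thousands of primary research articles mention microRNAs in connection with
rheumatic diseases (rheumatoid arthritis, osteoarthritis, lupus, ...), far
too many to read. A practical way to find the *most relevant* miRNAs for a
disease is bibliometric: download the PubMed citations for a disease query,
find every miRNA mentioned in a title or abstract, and count in how many
articles each miRNA family appears — then cross those mentions with curated
lists of immune cell types, cytokines and pathological processes to see
*what* each miRNA is studied with.

`mirlit` implements that pipeline as a reusable toolkit for anyone running
a computer-guided literature review: parse the MEDLINE files PubMed's
*save citations to file* option produces (one file per disease corpus),
normalize miRNA mentions to family identifiers, count per-article
deduplicated co-occurrences, rank the top-k families per corpus, score
cross-disease breadth, tabulate yearly publication trends, and render the
standard report figures.

A typical corpus is retrieved with a query of the form

```
((((miR[Title/Abstract]) OR (miRNA[Title/Abstract])) OR (microRNA[Title/Abstract]))
 AND (Disease name[Title/Abstract])) NOT (Review[Publication Type])
```

saved in PubMed format. `mirlit` does not query PubMed itself; it consumes
the saved files.

## The counting model

* **Mention grammar.** A miRNA mention is *miR / miRNA / microRNA / micro
  RNA* (any case, optional `hsa-`/`mmu-`/... species prefix, optional
  hyphen or space) followed by a number, with optional lettered paralog
  (`a`, `b`), numeric paralog index (`-1`, `-2`) and arm (`-5p`/`-3p`)
  suffixes. Every mention normalizes to the family `miR-N` by its first
  integer, so `hsa-miR-125b-1`, `miR-125a-5p` and `MicroRNA-125` all count
  as `miR-125`.
* **Concept dictionaries.** Three curated term lists — 14 cell types, 11
  cytokines, 15 pathological processes — matched case-insensitively as
  substrings with two guards: a term ending in a digit must not be followed
  by another digit (`IL-1` never fires inside `IL-10`/`IL-17`/`IL-18`,
  while `IL-1β` still counts), and single-letter-prefixed terms need a word
  boundary (`T-cell` does not fire inside `NKT-cell`). Dictionaries are
  overridable via a YAML config; the packaged default is authoritative.
* **Once-per-article dedup.** A family, a term, or a (family, term) pair
  contributes at most one count per article, regardless of how often it is
  mentioned. All counts are therefore article counts, invariant under
  record order.
* **Ranking and breadth.** Per corpus the top-k (default k = 7) families
  are ranked by article count, ties broken by ascending family index.
  A family's *breadth* is the number of corpora in whose top-k it appears.

## Worked example

```python
from mirlit import parse_medline, count_mirna_articles, top_k
from mirlit.medline import Corpus

text = """PMID- 101
TI  - miR-146a constrains IL-1β signaling in synovial fibroblasts.
AB  - We show that hsa-miR-146a-5p and miR-146b lower IL-1 driven inflammation.
DP  - 2021 Mar
PT  - Journal Article

PMID- 102
TI  - miR-155 and miR-146 in Treg homeostasis.
AB  - Both microRNA-155 and miR-146 shape regulatory T cell function.
DP  - 2022 Jan
PT  - Journal Article
"""
corpus = Corpus(label="demo", records=parse_medline(text))
counts = count_mirna_articles(corpus)
print(counts)                              # {'miR-146': 2, 'miR-155': 1}
print(top_k(counts, k=2, label="demo").entries)
# [('miR-146', 2), ('miR-155', 1)]
```

`miR-146` counts 2 because each article contributes at most once per
family: article 101 mentions `miR-146a`, `hsa-miR-146a-5p` and `miR-146b`,
but they are all the `miR-146` family.

The packaged nine-disease synthetic corpus set exercises the whole
pipeline (the two families embedded in every corpus must reach breadth 9):

```python
from mirlit import run_pipeline
from mirlit.fixtures import paper_shaped_fixture

corpora, truths = paper_shaped_fixture(seed=20230829)
bundle = run_pipeline(corpora)
print(bundle.rankings["rheumatoid arthritis"].entries)
# [('miR-146', 65), ('miR-155', 65), ('miR-21', 28), ('miR-125', 19),
#  ('miR-223', 19), ('miR-124', 15), ('miR-34', 8)]
print(bundle.breadth_map["miR-146"], bundle.breadth_map["miR-155"])  # 9 9
```

Here 65 means: 65 of the 82-record rheumatoid-arthritis fixture articles
(after dropping Review-tagged records) mention the miR-146 family. Note the
deterministic tie-break: miR-125 and miR-223 both have 19 articles and
miR-125 ranks first because 125 < 223.

## Command line

```
mirlit simulate -o fixture/            # write the nine synthetic corpora + truth tables
mirlit mine -o out/ fixture/*.medline.txt   # full pipeline: tables, manifest, figures
mirlit validate fixture/gout.medline.txt fixture/gout.truth_records.csv
mirlit dicts                           # print the effective dictionaries
```

`mine` writes per-corpus ranking/co-occurrence/trend tables, an aggregate
table, a breadth table, a run manifest, and the report figures (trend
lines, top-25 bar chart, breadth chart, per-corpus donuts, annotated
co-occurrence heatmaps), each figure with a companion CSV of exactly the
numbers plotted.

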