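"""Per-article-deduplicated counting: miRNA publication counts,
miRNA × concept co-occurrence matrices, top-k rankings, cross-corpus
breadth and yearly trends.

Every count in this module is an *article* count: a record contributes at
most 1 to each family, each term, and each (family, term) pair, regardless
of mention multiplicity inside its title/abstract.  All results are
invariant under permutation of the records in a corpus.
"""

from __future__ import annotations

import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from mirlit.dictionaries import (
    ConceptDictionary,
    all_columns,
    default_dictionaries,
    dictionary_hash,
    match_all,
)
from mirlit.medline import Corpus, filter_reviews
from mirlit.mirna import extract_mirnas, family_index

logger = logging.getLogger(__name__)

DEFAULT_K = 7  # rank depth: the "top seven" most-published families


@dataclass
class CooccurrenceMatrix:
    """miRNA-family × concept-term article-count matrix for one corpus.

    Rows are families, columns are (category, canonical_term) pairs in the
    fixed layout cell types → cytokines → processes.  Zero rows/columns
    are retained so every corpus shares the column layout.
    """

    corpus_label: str
    row_families: list[str]
    col_terms: list[tuple[str, str]]
    counts: pd.DataFrame  # index = families, columns = MultiIndex (category, term)

    def cell(self, family: str, category: str, term: str) -> int:
        return int(self.counts.loc[family, (category, term)])

    def to_long(self) -> pd.DataFrame:
        """Long-form table: family, category, term, count."""
        rows = [
            (f, cat, term, int(self.counts.loc[f, (cat, term)]))
            for f in self.row_families
            for cat, term in self.col_terms
        ]
        return pd.DataFrame(rows, columns=["family", "category", "term", "count"])


@dataclass
class Ranking:
    """Top-k most-published families in one corpus, deterministically ordered:
    article count descending, ties by ascending family integer index."""

    corpus_label: str
    k: int
    entries: list[tuple[str, int]]

    @property
    def families(self) -> list[str]:
        return [f for f, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["family", "count"])


@dataclass
class TrendSeries:
    """Article counts per publication year for one corpus (or an aggregate)."""

    label: str
    year_counts: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        years = sorted(self.year_counts)
        return pd.DataFrame(
            {"year": years, "count": [self.year_counts[y] for y in years]}
        )


def _rank_key(item: tuple[str, int]) -> tuple[int, int]:
    family, count = item
    return (-count, family_index(family))


def count_mirna_articles(corpus: Corpus) -> dict[str, int]:
    """Number of articles mentioning each miRNA family at least once."""
    counts: Counter[str] = Counter()
    for rec in corpus:
        counts.update(extract_mirnas(rec.mining_text()))
    return dict(counts)


def count_cooccurrence(
    corpus: Corpus,
    dicts: dict[str, ConceptDictionary] | None = None,
    families: list[str] | None = None,
) -> CooccurrenceMatrix:
    """Articles mentioning both a family and a concept term, per pair.

    ``families`` restricts (and orders) the rows — e.g. to a corpus's
    top-7; by default rows are every family in the corpus, ordered by the
    ranking rule.
    """
    if dicts is None:
        dicts = default_dictionaries()
    cols = all_columns(dicts)

    pair_counts: Counter[tuple[str, tuple[str, str]]] = Counter()
    seen_families: Counter[str] = Counter()
    for rec in corpus:
        text = rec.mining_text()
        fams = extract_mirnas(text)
        if families is not None:
            fams &= set(families)
        if not fams:
            continue
        seen_families.update(fams)
        hits = match_all(text, dicts)
        for f in fams:
            for col in hits:
                pair_counts[(f, col)] += 1

    if families is not None:
        rows = list(families)
    else:
        rows = sorted(seen_families.items(), key=_rank_key)
        rows = [f for f, _ in rows]

    data = [[pair_counts.get((f, col), 0) for col in cols] for f in rows]
    frame = pd.DataFrame(
        data, index=pd.Index(rows, name="family"),
        columns=pd.MultiIndex.from_tuples(cols, names=["category", "term"]),
        dtype=int,
    )
    return CooccurrenceMatrix(
        corpus_label=corpus.label, row_families=rows, col_terms=cols, counts=frame
    )


def top_k(counts: dict[str, int], k: int = DEFAULT_K, label: str = "") -> Ranking:
    """The k most-published families, count descending, ties broken by
    ascending family integer index; zero-count families never appear."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ordered = sorted(
        ((f, c) for f, c in counts.items() if c >= 1), key=_rank_key
    )
    return Ranking(corpus_label=label, k=k, entries=ordered[:k])


def breadth(rankings: list[Ranking]) -> dict[str, int]:
    """For each family, the number of corpora in whose top-k it appears."""
    ks = {r.k for r in rankings}
    if len(ks) > 1:
        raise ValueError(f"rankings have mixed k values: {sorted(ks)}")
    out: Counter[str] = Counter()
    for r in rankings:
        out.update(r.families)
    return dict(out)


def aggregate_counts(per_corpus_counts: list[dict[str, int]]) -> dict[str, int]:
    """Elementwise sum of per-corpus family counts.

    An article present in two disease corpora contributes once per corpus,
    matching the one-file-per-disease design; see the shared-PMID
    diagnostic in :func:`run_pipeline`.
    """
    total: Counter[str] = Counter()
    for counts in per_corpus_counts:
        total.update(counts)
    return dict(total)


def yearly_trend(corpus: Corpus) -> TrendSeries:
    """Article counts per parsed publication year; records without a
    parseable year are excluded (their number is logged, never dropped
    from the other counts)."""
    missing = sum(1 for rec in corpus if rec.year is None)
    if missing:
        logger.info("corpus %r: %d records without a parseable year excluded from trend",
                    corpus.label, missing)
    year_counts = Counter(rec.year for rec in corpus if rec.year is not None)
    return TrendSeries(label=corpus.label, year_counts=dict(year_counts))


@dataclass
class ResultBundle:
    """Everything one pipeline run computes, plus the manifest that makes
    the run reproducible."""

    k: int
    corpus_labels: list[str]
    counts: dict[str, dict[str, int]]               # label -> family -> articles
    rankings: dict[str, Ranking]                    # label -> top-k
    matrices: dict[str, CooccurrenceMatrix]         # label -> top-k co-occurrence
    trends: dict[str, TrendSeries]                  # label -> yearly series
    aggregate: dict[str, int]                       # family -> summed articles
    breadth_map: dict[str, int]                     # family -> corpora in top-k
    shared_pmids: dict[str, int] = field(default_factory=dict)  # pmid -> #corpora (>1)
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str) -> list[str]:
        """Serialize every table (CSV, UTF-8, header row) plus manifest.json;
        returns the paths written, deterministically ordered."""
        os.makedirs(outdir, exist_ok=True)
        written: list[str] = []

        def save(frame: pd.DataFrame, name: str) -> None:
            path = os.path.join(outdir, name)
            frame.to_csv(path, index=False)
            written.append(path)

        for label in self.corpus_labels:
            slug = _slug(label)
            save(self.rankings[label].to_frame(), f"ranking_{slug}.csv")
            save(self.matrices[label].to_long(), f"cooccurrence_{slug}.csv")
            save(self.trends[label].to_frame(), f"trend_{slug}.csv")

        agg = sorted(self.aggregate.items(), key=_rank_key)
        save(pd.DataFrame(agg, columns=["family", "count"]), "aggregate_counts.csv")

        br = sorted(self.breadth_map.items(), key=lambda it: (-it[1], family_index(it[0])))
        save(pd.DataFrame(br, columns=["family", "n_corpora_top_k"]), "breadth.csv")

        manifest_path = os.path.join(outdir, "manifest.json")
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(manifest_path)
        return written


def _slug(label: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in label.lower()).strip("_")


def run_pipeline(
    corpora: list[Corpus],
    dicts: dict[str, ConceptDictionary] | None = None,
    k: int = DEFAULT_K,
    keep_reviews: bool = False,
) -> ResultBundle:
    """The full screening pipeline over one or more disease corpora.

    Per corpus: drop Review-tagged records (unless ``keep_reviews``),
    count family articles, rank the top-k, build the co-occurrence matrix
    restricted to those top-k families, and tabulate the yearly trend.
    Across corpora: aggregate family counts, breadth of top-k membership,
    and a diagnostic of PMIDs shared between corpora.  Deterministic given
    its inputs.
    """
    if not corpora:
        raise ValueError("run_pipeline requires at least one corpus")
    labels = [c.label for c in corpora]
    if len(set(labels)) != len(labels):
        raise ValueError(f"corpus labels are not unique: {labels}")
    if dicts is None:
        dicts = default_dictionaries()

    working = corpora if keep_reviews else [filter_reviews(c) for c in corpora]

    counts: dict[str, dict[str, int]] = {}
    rankings: dict[str, Ranking] = {}
    matrices: dict[str, CooccurrenceMatrix] = {}
    trends: dict[str, TrendSeries] = {}
    for corpus in working:
        c = count_mirna_articles(corpus)
        counts[corpus.label] = c
        ranking = top_k(c, k=k, label=corpus.label)
        rankings[corpus.label] = ranking
        matrices[corpus.label] = count_cooccurrence(corpus, dicts, families=ranking.families)
        trends[corpus.label] = yearly_trend(corpus)

    pmid_presence: Counter[str] = Counter()
    for corpus in working:
        for pmid in {rec.pmid for rec in corpus}:
            pmid_presence[pmid] += 1
    shared = {pmid: n for pmid, n in pmid_presence.items() if n > 1}
    if shared:
        logger.info("%d PMIDs appear in more than one corpus; aggregate counts "
                    "count them once per corpus", len(shared))

    manifest = {
        "tool": "mirlit",
        "version": _version(),
        "k": k,
        "keep_reviews": keep_reviews,
        "dictionary_hash": dictionary_hash(dicts),
        "corpora": [
            {"label": c.label, "source_path": c.source_path,
             "n_records_input": len(orig), "n_records_counted": len(c)}
            for c, orig in zip(working, corpora)
        ],
    }

    return ResultBundle(
        k=k,
        corpus_labels=labels,
        counts=counts,
        rankings=rankings,
        matrices=matrices,
        trends=trends,
        aggregate=aggregate_counts([counts[l] for l in labels]),
        breadth_map=breadth([rankings[l] for l in labels]),
        shared_pmids=shared,
        manifest=manifest,
    )


def _version() -> str:
    from mirlit import __version__

    return __version__
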