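"""Synthetic MEDLINE corpora with exact ground truth.

The generator samples, per record, which miRNA families and which concept
terms the record mentions (independent Bernoulli draws), then renders each
sampled mention into natural-looking filler sentences through a random
surface form (species prefixes, spelling variants, lettered paralogs, arm
suffixes, plural terms, case changes).  Ground truth is recorded *at
sampling time*, before any text exists, so comparing engine output against
it is a genuine independent check of the whole extraction → matching →
counting path.

Two safety properties make the truth exact rather than approximate:

* the filler vocabulary contains no digits, no miR-like token and no
  substring of any dictionary variant, so filler never creates a mention;
* a term is only ever rendered through a surface form that matches exactly
  its own canonical term under the full default dictionaries (e.g. IL-6 is
  never rendered as "interleukin-6", which would also hit the separate
  "interleukin" entry).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pandas as pd

from mirlit.dictionaries import ConceptDictionary, default_dictionaries, match_all
from mirlit.medline import CitationRecord, Corpus, write_medline
from mirlit.mirna import extract_mirnas, family_index

__all__ = [
    "FixtureSpec",
    "TruthRecord",
    "FixtureTruth",
    "generate_corpus",
    "paper_shaped_fixture",
    "FILLER_WORDS",
    "DISEASES",
]

# Free of digits, of "mir", and of every dictionary variant (as substring,
# case-insensitive); verified by test and by _check_filler at import.
FILLER_WORDS = (
    "we", "report", "that", "the", "observed", "levels", "in", "of", "were",
    "a", "cohort", "with", "samples", "from", "patients", "and", "show",
    "expression", "was", "altered", "compared", "to", "controls", "these",
    "data", "suggest", "roles", "for", "this", "candidate", "during",
    "disease", "onset", "our", "results", "support", "further", "work",
    "on", "its", "function", "clinical", "relevance", "remains", "under",
    "study", "serum", "plasma", "assays", "confirmed", "findings",
)

_TITLE_ENDINGS = (".", "")


def _check_filler(dicts: dict[str, ConceptDictionary]) -> None:
    text = " ".join(FILLER_WORDS)
    if extract_mirnas(text):
        raise AssertionError("filler vocabulary contains a miRNA-like token")
    if match_all(text, dicts):
        raise AssertionError("filler vocabulary collides with a dictionary variant")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic corpus.

    ``family_probs`` maps canonical families ("miR-146") to per-record
    inclusion probabilities; ``term_probs`` maps (category, canonical_term)
    pairs likewise.  ``surface_noise`` additionally enables missing
    publication dates on a small fraction of records and duplicated
    mentions (which must not change any count).  The same seed always
    yields byte-identical output.
    """

    seed: int
    n_records: int
    family_probs: dict[str, float] = field(default_factory=dict)
    term_probs: dict[tuple[str, str], float] = field(default_factory=dict)
    review_prob: float = 0.0
    year_range: tuple[int, int] = (1994, 2022)
    surface_noise: bool = True
    label: str = "fixture"
    pmid_start: int = 100001  # lets multi-corpus fixtures use disjoint PMID ranges

    def validate(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")
        for fam, p in self.family_probs.items():
            family_index(fam)  # raises on malformed family names
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range for {fam}: {p}")
        for (cat, term), p in self.term_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range for {(cat, term)}: {p}")
        if not 0.0 <= self.review_prob <= 1.0:
            raise ValueError("review_prob out of range")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be ordered (lo, hi)")


@dataclass(frozen=True)
class TruthRecord:
    """Sampled ground truth for one record."""

    pmid: str
    families: frozenset[str]
    terms: frozenset[tuple[str, str]]
    year: int | None
    is_review: bool


@dataclass
class FixtureTruth:
    """Per-record sampled truth plus brute-force derived count tables."""

    records: list[TruthRecord]

    def _subset(self, include_reviews: bool) -> list[TruthRecord]:
        if include_reviews:
            return self.records
        return [r for r in self.records if not r.is_review]

    def family_counts(self, include_reviews: bool = True) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self._subset(include_reviews):
            for fam in rec.families:
                out[fam] = out.get(fam, 0) + 1
        return out

    def cooccurrence_counts(
        self, include_reviews: bool = True
    ) -> dict[tuple[str, str, str], int]:
        """(family, category, term) -> article count, by brute force."""
        out: dict[tuple[str, str, str], int] = {}
        for rec in self._subset(include_reviews):
            for fam in rec.families:
                for cat, term in rec.terms:
                    key = (fam, cat, term)
                    out[key] = out.get(key, 0) + 1
        return out

    def year_counts(self, include_reviews: bool = True) -> dict[int, int]:
        out: dict[int, int] = {}
        for rec in self._subset(include_reviews):
            if rec.year is not None:
                out[rec.year] = out.get(rec.year, 0) + 1
        return out

    def n_reviews(self) -> int:
        return sum(1 for r in self.records if r.is_review)

    def to_records_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "pmid": rec.pmid,
                    "year": "" if rec.year is None else rec.year,
                    "is_review": int(rec.is_review),
                    "families": "|".join(sorted(rec.families, key=family_index)),
                    "terms": "|".join(f"{c}:{t}" for c, t in sorted(rec.terms)),
                }
            )
        return pd.DataFrame(
            rows, columns=["pmid", "year", "is_review", "families", "terms"]
        )

    @classmethod
    def from_records_frame(cls, frame: pd.DataFrame) -> "FixtureTruth":
        records = []
        for _, row in frame.iterrows():
            fams = frozenset(str(row["families"]).split("|")) if str(row["families"]) else frozenset()
            terms = frozenset(
                tuple(item.split(":", 1)) for item in str(row["terms"]).split("|") if item
            )
            year_cell = row["year"]
            year = None if (pd.isna(year_cell) or str(year_cell) == "") else int(year_cell)
            records.append(
                TruthRecord(
                    pmid=str(row["pmid"]),
                    families=fams,
                    terms=terms,
                    year=year,
                    is_review=bool(int(row["is_review"])),
                )
            )
        return cls(records=records)


# ---------------------------------------------------------------------------
# surface rendering

_SPELLINGS = ("miR", "mir", "MiR", "miRNA", "microRNA", "micro RNA")
_SPECIES = ("", "", "", "hsa-", "mmu-", "rno-")
_SEPARATORS = ("-", "-", "-", "", " ")
_LETTER_SUFFIXES = ("", "", "", "a", "b")
_PARALOGS = ("", "", "", "-1", "-2")
_ARMS = ("", "", "", "-5p", "-3p")


def _render_family(family: str, rng: random.Random, noise: bool) -> str:
    idx = family_index(family)
    if not noise:
        return f"miR-{idx}"
    species = rng.choice(_SPECIES)
    spelling = rng.choice(_SPELLINGS)
    if species and " " in spelling:
        spelling = "miR"  # "hsa-micro RNA" is not a surface form seen in print
    token = f"{species}{spelling}{rng.choice(_SEPARATORS)}{idx}{rng.choice(_LETTER_SUFFIXES)}"
    token += rng.choice(_PARALOGS)
    token += rng.choice(_ARMS)
    return token


_GREEK = ("β", "α", "b")


def _self_identifying_forms(
    dicts: dict[str, ConceptDictionary]
) -> dict[tuple[str, str], list[str]]:
    """For each (category, term): surface forms that match exactly that term
    and nothing else under the full dictionary set."""
    forms: dict[tuple[str, str], list[str]] = {}
    for category, d in dicts.items():
        for canonical, variants in d.entries:
            candidates: list[str] = []
            for v in variants:
                candidates.append(v.text)
                if v.text[-1].isdigit():
                    candidates.extend(v.text + g for g in _GREEK)
                elif v.text[-1].isalpha():
                    candidates.append(v.text + "s")  # substring plural
            good = [
                c for c in candidates
                if match_all(f"margin {c} margin", dicts) == {(category, canonical)}
            ]
            if not good:
                raise AssertionError(
                    f"term {canonical!r} has no self-identifying surface form"
                )
            forms[(category, canonical)] = good
    return forms


def _render_term(
    col: tuple[str, str],
    forms: dict[tuple[str, str], list[str]],
    rng: random.Random,
    noise: bool,
) -> str:
    options = forms[col]
    if not noise:
        return options[0]
    text = rng.choice(options)
    roll = rng.random()
    if roll < 0.15:
        return text.upper()
    if roll < 0.30:
        return text.capitalize()
    return text


def _sentence(rng: random.Random, tokens: list[str], n_filler: int) -> str:
    words = [rng.choice(FILLER_WORDS) for _ in range(n_filler)]
    slots = sorted(rng.randrange(len(words) + 1) for _ in tokens)
    for offset, (slot, token) in enumerate(zip(slots, tokens)):
        words.insert(slot + offset, token)
    return " ".join(words)


# ---------------------------------------------------------------------------
# generation

def generate_corpus(
    spec: FixtureSpec,
    dicts: dict[str, ConceptDictionary] | None = None,
) -> tuple[str, FixtureTruth]:
    """Render one synthetic corpus as MEDLINE text with its exact truth.

    Deterministic: equal specs yield byte-identical text and equal truth.
    """
    spec.validate()
    if dicts is None:
        dicts = default_dictionaries()
    _check_filler(dicts)
    forms = _self_identifying_forms(dicts)
    for col in spec.term_probs:
        if col not in forms:
            raise ValueError(f"term {col} not present in the dictionaries")

    rng = random.Random(spec.seed)
    family_order = sorted(spec.family_probs, key=family_index)
    term_order = sorted(spec.term_probs)

    records: list[CitationRecord] = []
    truth_rows: list[TruthRecord] = []
    for i in range(spec.n_records):
        pmid = str(spec.pmid_start + i)
        families = [f for f in family_order if rng.random() < spec.family_probs[f]]
        terms = [t for t in term_order if rng.random() < spec.term_probs[t]]
        is_review = rng.random() < spec.review_prob
        year: int | None = rng.randint(*spec.year_range)
        if spec.surface_noise and rng.random() < 0.05:
            year = None

        tokens = [_render_family(f, rng, spec.surface_noise) for f in families]
        tokens += [_render_term(t, forms, rng, spec.surface_noise) for t in terms]
        if spec.surface_noise and tokens and rng.random() < 0.25:
            # duplicated mention: must not change any count
            tokens.append(rng.choice(tokens))
        rng.shuffle(tokens)

        n_title = rng.randint(0, min(2, len(tokens)))
        title_tokens, abstract_tokens = tokens[:n_title], tokens[n_title:]
        title = _sentence(rng, title_tokens, rng.randint(4, 7)) + "."
        title = title[0].upper() + title[1:]
        abstract = (
            _sentence(rng, abstract_tokens, rng.randint(10, 18)) + ". "
            + _sentence(rng, [], rng.randint(6, 10)) + "."
        )

        pub_types = ["Journal Article"]
        if is_review:
            pub_types.append("Review")

        raw: list[tuple[str, str]] = [("PMID", pmid)]
        if year is not None:
            month = rng.choice(("Jan", "Apr", "Jul", "Oct"))
            raw.append(("DP", f"{year} {month}"))
        raw.append(("TI", title))
        raw.append(("AB", abstract))
        raw.extend(("PT", pt) for pt in pub_types)

        records.append(
            CitationRecord(
                pmid=pmid, title=title, abstract=abstract,
                pub_types=pub_types, year=year, raw_fields=raw,
            )
        )
        truth_rows.append(
            TruthRecord(
                pmid=pmid,
                families=frozenset(families),
                terms=frozenset(terms),
                year=year,
                is_review=is_review,
            )
        )

    text = write_medline(records)
    return text, FixtureTruth(records=truth_rows)


def generate_corpus_object(
    spec: FixtureSpec,
    dicts: dict[str, ConceptDictionary] | None = None,
) -> tuple[Corpus, FixtureTruth]:
    """Generate and immediately re-parse, returning a Corpus object.

    Going through the MEDLINE text (rather than the in-memory records)
    means every downstream count also exercises the parser.
    """
    from mirlit.medline import parse_medline

    text, truth = generate_corpus(spec, dicts)
    return Corpus(label=spec.label, records=parse_medline(text)), truth


# ---------------------------------------------------------------------------
# the packaged nine-disease demonstration fixture

#: The nine rheumatic diseases and their fixture corpus sizes.  Sizes are
#: the real per-disease PubMed snapshot counts scaled down roughly tenfold
#: (floor 15), keeping the strong skew toward osteoarthritis, rheumatoid
#: arthritis and lupus while staying desk-sized.
DISEASES: dict[str, int] = {
    "ankylosing spondylitis": 15,
    "gout": 15,
    "juvenile idiopathic arthritis": 15,
    "osteoarthritis": 128,
    "psoriatic arthritis": 15,
    "rheumatoid arthritis": 82,
    "Sjogren syndrome": 15,
    "systemic lupus erythematosus": 42,
    "systemic sclerosis": 15,
}

_COMMON_FAMILIES: dict[str, float] = {
    "miR-146": 1.0,   # forced into every corpus: breadth must reach 9
    "miR-155": 1.0,   # ditto
    "miR-21": 0.45,
    "miR-223": 0.30,
    "miR-125": 0.25,
    "miR-124": 0.20,
    "miR-26": 0.18,
    "miR-34": 0.15,
    "miR-29": 0.15,
}

_DISEASE_FAMILIES: dict[str, dict[str, float]] = {
    "osteoarthritis": {"miR-140": 0.50, "miR-145": 0.20},
    "psoriatic arthritis": {"miR-151": 0.40, "miR-92": 0.35},
    "Sjogren syndrome": {"miR-1207": 0.30, "miR-150": 0.25},
    "systemic sclerosis": {"miR-196": 0.30},
    "gout": {"miR-20": 0.25},
}

_COMMON_TERMS: dict[tuple[str, str], float] = {
    ("cell_type", "fibroblast"): 0.30,
    ("cell_type", "macrophage"): 0.20,
    ("cell_type", "monocyte"): 0.15,
    ("cell_type", "T-cell"): 0.15,
    ("cell_type", "osteoclast"): 0.10,
    ("cytokine", "IL-1"): 0.20,
    ("cytokine", "IL-6"): 0.25,
    ("cytokine", "IL-17"): 0.15,
    ("cytokine", "TNF"): 0.25,
    ("cytokine", "interleukin"): 0.10,
    ("process", "inflammation"): 0.35,
    ("process", "apoptosis"): 0.20,
    ("process", "proliferation"): 0.20,
    ("process", "biomarker"): 0.15,
    ("process", "therapy"): 0.15,
}

_DISEASE_TERMS: dict[str, dict[tuple[str, str], float]] = {
    "osteoarthritis": {
        ("cell_type", "chondrocyte"): 0.50,
        ("process", "degeneration"): 0.30,
    },
    "systemic lupus erythematosus": {("process", "autoantibody"): 0.25},
    "systemic sclerosis": {("process", "fibrosis"): 0.40},
    "ankylosing spondylitis": {("cell_type", "osteoblast"): 0.25},
}


def paper_shaped_fixture(
    seed: int = 20230829,
    dicts: dict[str, ConceptDictionary] | None = None,
) -> tuple[list[Corpus], dict[str, FixtureTruth]]:
    """Nine disease-labeled corpora with skewed family distributions.

    miR-146 and miR-155 are included with probability 1 in every corpus,
    so both must reach breadth 9 (top-7 membership in all nine corpora)
    in any correct analysis of the fixture.
    """
    master = random.Random(seed)
    corpora: list[Corpus] = []
    truths: dict[str, FixtureTruth] = {}
    for idx, (label, n) in enumerate(DISEASES.items()):
        family_probs = dict(_COMMON_FAMILIES)
        family_probs.update(_DISEASE_FAMILIES.get(label, {}))
        term_probs = dict(_COMMON_TERMS)
        term_probs.update(_DISEASE_TERMS.get(label, {}))
        spec = FixtureSpec(
            seed=master.randrange(2**31),
            n_records=n,
            family_probs=family_probs,
            term_probs=term_probs,
            review_prob=0.15,
            year_range=(1994, 2022),
            surface_noise=True,
            label=label,
            pmid_start=1_000_001 + idx * 100_000,
        )
        corpus, truth = generate_corpus_object(spec, dicts)
        corpora.append(corpus)
        truths[label] = truth
    return corpora, truths


# ---------------------------------------------------------------------------
# truth serialization and engine-vs-truth comparison

def truth_tables(truth: FixtureTruth) -> dict[str, pd.DataFrame]:
    """Derived truth tables over the raw corpus (reviews included),
    mirroring the engine's output schema."""
    fam = sorted(truth.family_counts().items(), key=lambda it: (-it[1], family_index(it[0])))
    co = truth.cooccurrence_counts()
    co_rows = sorted(
        ((f, c, t, n) for (f, c, t), n in co.items()),
        key=lambda r: (family_index(r[0]), r[1], r[2]),
    )
    years = sorted(truth.year_counts().items())
    return {
        "records": truth.to_records_frame(),
        "family_counts": pd.DataFrame(fam, columns=["family", "count"]),
        "cooccurrence": pd.DataFrame(co_rows, columns=["family", "category", "term", "count"]),
        "year_counts": pd.DataFrame(years, columns=["year", "count"]),
    }


def compare_with_truth(
    corpus: Corpus,
    truth: FixtureTruth,
    dicts: dict[str, ConceptDictionary] | None = None,
) -> list[str]:
    """Differences between engine output on ``corpus`` and the sampled truth.

    Empty list means exact agreement on: family counts (raw and
    review-filtered), every co-occurrence cell, yearly trend, and the
    review-filter census.
    """
    from mirlit.engine import count_cooccurrence, count_mirna_articles, yearly_trend
    from mirlit.medline import filter_reviews

    if dicts is None:
        dicts = default_dictionaries()
    diffs: list[str] = []

    got = count_mirna_articles(corpus)
    want = truth.family_counts(include_reviews=True)
    if got != want:
        diffs.extend(_dict_diff("family_counts", want, got))

    filtered = filter_reviews(corpus)
    got_f = count_mirna_articles(filtered)
    want_f = truth.family_counts(include_reviews=False)
    if got_f != want_f:
        diffs.extend(_dict_diff("family_counts_no_reviews", want_f, got_f))

    if len(corpus) - len(filtered) != truth.n_reviews():
        diffs.append(
            f"review filter removed {len(corpus) - len(filtered)} records, "
            f"truth says {truth.n_reviews()}"
        )

    matrix = count_cooccurrence(corpus, dicts)
    want_co = truth.cooccurrence_counts(include_reviews=True)
    got_co = {
        (f, cat, term): int(matrix.counts.loc[f, (cat, term)])
        for f in matrix.row_families
        for cat, term in matrix.col_terms
        if int(matrix.counts.loc[f, (cat, term)])
    }
    if got_co != want_co:
        diffs.extend(_dict_diff("cooccurrence", want_co, got_co))

    got_years = yearly_trend(corpus).year_counts
    want_years = truth.year_counts(include_reviews=True)
    if got_years != want_years:
        diffs.extend(_dict_diff("year_counts", want_years, got_years))

    return diffs


def _dict_diff(name: str, want: dict, got: dict) -> list[str]:
    out = []
    for key in sorted(set(want) | set(got), key=str):
        w, g = want.get(key, 0), got.get(key, 0)
        if w != g:
            out.append(f"{name}[{key}]: truth {w} != engine {g}")
    return out
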