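import re

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")

from mirlit.dictionaries import default_dictionaries
from mirlit.fixtures import FixtureSpec, generate_corpus_object, paper_shaped_fixture


@pytest.fixture(scope="session")
def dicts():
    return default_dictionaries()


@pytest.fixture(scope="session")
def nine_corpora():
    """The packaged nine-disease fixture, generated once per session."""
    return paper_shaped_fixture(seed=20230829)


@pytest.fixture()
def small_corpus():
    """A 200-record mixed-noise corpus with its sampled truth."""
    spec = FixtureSpec(
        seed=11,
        n_records=200,
        family_probs={"miR-146": 0.5, "miR-155": 0.35, "miR-21": 0.3,
                      "miR-125": 0.2, "miR-1207": 0.1, "miR-2": 0.15},
        term_probs={("cytokine", "IL-1"): 0.25, ("cytokine", "IL-17"): 0.25,
                    ("cytokine", "TNF"): 0.2, ("cytokine", "interleukin"): 0.15,
                    ("cell_type", "fibroblast"): 0.3, ("cell_type", "T-reg"): 0.15,
                    ("process", "inflammation"): 0.3, ("process", "pain"): 0.15},
        review_prob=0.2,
        surface_noise=True,
        label="small",
    )
    return generate_corpus_object(spec)


# ---------------------------------------------------------------------------
# Brute-force miRNA mention oracle: a character-level walker, written
# independently of the regex grammar in mirlit.mirna.  It enumerates every
# position where a mention could start, applies the stated rules by hand
# (species prefix, spelling, separator, digits, suffixes, boundaries), and
# collects the normalized families.

_SPELLINGS = ("micro rna", "microrna", "mirna", "mir")


def _digits_at(low: str, i: int) -> int:
    j = i
    while j < len(low) and low[j].isdigit():
        j += 1
    return j


def _tail_ok(low: str, i: int) -> bool:
    """From position i (end of digits), can some combination of optional
    letter suffix, -digit paralog and -3p/-5p arm reach a word boundary?"""
    n = len(low)
    ends = {i}
    # letter suffix
    for e in list(ends):
        if e < n and low[e].isalpha():
            ends.add(e + 1)
    # paralog index
    for e in list(ends):
        if e < n and low[e] == "-":
            d = _digits_at(low, e + 1)
            if d > e + 1:
                ends.add(d)
    # arm
    for e in list(ends):
        if e + 2 < n + 1 and low[e:e + 3] in ("-3p", "-5p"):
            ends.add(e + 3)
    return any(e == n or not low[e].isalnum() for e in ends)


def brute_force_families(text: str) -> set[str]:
    low = text.lower()
    n = len(low)
    found: set[str] = set()
    for s in range(n):
        starts_ok = False
        if s == 0 or not low[s - 1].isalnum():
            starts_ok = True  # plain start at a word boundary
        if (s >= 4 and low[s - 1] == "-" and low[s - 4:s - 1].isalpha()
                and (s == 4 or not low[s - 5].isalnum())):
            starts_ok = True  # species-prefixed start
        if not starts_ok:
            continue
        for spelling in _SPELLINGS:
            if not low.startswith(spelling, s):
                continue
            after = s + len(spelling)
            for sep in ("-", " ", ""):
                p = after
                if sep:
                    if not low.startswith(sep, p):
                        continue
                    p += 1
                d = _digits_at(low, p)
                if d == p:
                    continue
                if _tail_ok(low, d):
                    found.add(f"miR-{int(low[p:d])}")
    return found


# Brute-force concept matcher: plain lowercase substring scan with the two
# guards applied by hand, independent of the compiled per-variant regexes.

def brute_force_terms(text: str, dictionary) -> set[str]:
    low = text.lower()
    hits = set()
    for canonical, variants in dictionary.entries:
        for v in variants:
            needle = v.text.lower()
            start = 0
            matched = False
            while True:
                i = low.find(needle, start)
                if i < 0:
                    break
                end = i + len(needle)
                ok = True
                if v.word_start and i > 0 and low[i - 1].isalnum():
                    ok = False
                if needle[-1].isdigit() and end < len(low) and low[end].isdigit():
                    ok = False
                if ok:
                    matched = True
                    break
                start = i + 1
            if matched:
                hits.add(canonical)
                break
    return hits


@pytest.fixture(scope="session")
def mirna_oracle():
    return brute_force_families


@pytest.fixture(scope="session")
def term_oracle():
    return brute_force_terms
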