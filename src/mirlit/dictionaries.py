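"""Curated concept dictionaries (cell types, cytokines, processes) and
their matcher.

Matching is case-insensitive substring search with two guards that the
printed term lists make necessary:

* **digit guard** — a variant ending in a digit requires the next character
  to be a non-digit, so "IL-1" never fires inside "IL-10"/"IL-17"/"IL-18"
  while "IL-1β"/"IL-1b" still count as IL-1;
* **word-start guard** — variants marked with a leading ``^`` in the config
  (the single-letter-prefixed cell names: T-cell, T-reg, Treg, B-cell)
  require a word boundary before the match, so "T-cell" does not fire
  inside "NKT-cell".

Plurals need no special handling: "fibroblast" is a substring of
"fibroblasts".  The packaged default file reproduces the built-in
dictionaries exactly; users may point the tools at their own file with the
same schema.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml

CATEGORIES = ("cell_type", "cytokine", "process")


@dataclass(frozen=True)
class Variant:
    """One matchable surface form of a canonical term."""

    text: str
    word_start: bool = False  # require a word boundary before the match

    def pattern(self) -> re.Pattern[str]:
        body = re.escape(self.text)
        prefix = r"(?<![A-Za-z0-9])" if self.word_start else ""
        suffix = r"(?!\d)" if self.text[-1].isdigit() else ""
        return re.compile(prefix + body + suffix, re.IGNORECASE)


@dataclass
class ConceptDictionary:
    """A category of curated terms with their matching variants."""

    category: str
    entries: list[tuple[str, list[Variant]]]
    _compiled: dict[str, list[re.Pattern[str]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        seen: set[str] = set()
        for canonical, variants in self.entries:
            if canonical in seen:
                raise ValueError(f"duplicate canonical term {canonical!r}")
            seen.add(canonical)
            if not variants or any(not v.text for v in variants):
                raise ValueError(f"term {canonical!r} has an empty variant list or variant")

    @property
    def canonical_terms(self) -> list[str]:
        return [canonical for canonical, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def compiled(self) -> dict[str, list[re.Pattern[str]]]:
        if not self._compiled:
            self._compiled = {
                canonical: [v.pattern() for v in variants]
                for canonical, variants in self.entries
            }
        return self._compiled


def match_terms(text: str, dictionary: ConceptDictionary) -> set[str]:
    """Canonical terms of ``dictionary`` whose variants occur in ``text``.

    Set semantics: a term is reported once no matter how many of its
    variants match or how often.  Matching is monotone in the text —
    appending text can only add terms.
    """
    hits: set[str] = set()
    for canonical, patterns in dictionary.compiled().items():
        if any(p.search(text) for p in patterns):
            hits.add(canonical)
    return hits


def _parse_variant(spec: str) -> Variant:
    if spec.startswith("^"):
        return Variant(text=spec[1:], word_start=True)
    return Variant(text=spec)


def _parse_entry(entry) -> tuple[str, list[Variant]]:
    if isinstance(entry, str):
        return entry, [_parse_variant(entry)]
    canonical = entry["canonical"]
    variants = [_parse_variant(v) for v in entry.get("variants", [canonical])]
    return canonical, variants


def dictionaries_from_mapping(data: dict) -> dict[str, ConceptDictionary]:
    """Build the category → dictionary map from a parsed config mapping."""
    out: dict[str, ConceptDictionary] = {}
    for category in CATEGORIES:
        entries = [_parse_entry(e) for e in data.get(category, [])]
        out[category] = ConceptDictionary(category=category, entries=entries)
    unknown = set(data) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown dictionary categories in config: {sorted(unknown)}")
    return out


def load_dictionaries(path: str) -> dict[str, ConceptDictionary]:
    """Load a dictionary config file (YAML; see the packaged default)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return dictionaries_from_mapping(data)


def default_dictionaries() -> dict[str, ConceptDictionary]:
    """The built-in dictionaries: 14 cell types, 11 cytokines, 15 processes."""
    text = resources.files("mirlit.data").joinpath("default_dictionaries.yaml").read_text("utf-8")
    return dictionaries_from_mapping(yaml.safe_load(text))


def dictionary_hash(dicts: dict[str, ConceptDictionary]) -> str:
    """Stable content hash of a dictionary set, recorded in run manifests."""
    h = hashlib.sha256()
    for category in CATEGORIES:
        d = dicts.get(category)
        if d is None:
            continue
        for canonical, variants in d.entries:
            h.update(category.encode())
            h.update(canonical.encode())
            for v in variants:
                h.update(("^" if v.word_start else "") .encode() + v.text.encode())
    return h.hexdigest()[:16]


def all_columns(dicts: dict[str, ConceptDictionary]) -> list[tuple[str, str]]:
    """Fixed (category, canonical_term) column layout: cell types, cytokines,
    processes, each in dictionary order."""
    cols: list[tuple[str, str]] = []
    for category in CATEGORIES:
        if category in dicts:
            cols.extend((category, t) for t in dicts[category].canonical_terms)
    return cols


def match_all(text: str, dicts: dict[str, ConceptDictionary]) -> set[tuple[str, str]]:
    """Match every category at once; returns (category, canonical) pairs."""
    hits: set[tuple[str, str]] = set()
    for category, d in dicts.items():
        hits.update((category, t) for t in match_terms(text, d))
    return hits


def format_dictionaries(dicts: dict[str, ConceptDictionary]) -> str:
    """Human-readable dump used by the CLI ``dicts`` subcommand."""
    lines: list[str] = []
    for category in CATEGORIES:
        d = dicts.get(category)
        if d is None:
            continue
        lines.append(f"[{category}] ({len(d)} terms)")
        for canonical, variants in d.entries:
            shown = ", ".join(("^" if v.word_start else "") + v.text for v in variants)
            lines.append(f"  {canonical}: {shown}")
    return "\n".join(lines)
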