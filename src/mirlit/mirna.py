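"""miRNA mention detection and family-level normalization.

Mentions are mined with a single grammar: an optional three-letter species
prefix (``hsa-``, ``mmu-``, ...), one of the spellings *microRNA* /
*micro RNA* / *miRNA* / *miR* in any case, an optional hyphen or single
space, then the family integer, optionally followed by a lettered paralog
suffix (``a``, ``b``...), a numeric paralog index (``-1``, ``-2``) and an
arm suffix (``-3p``/``-5p``).  Every match normalizes to the family
identifier ``miR-N`` where N is the first integer after the prefix, so
``hsa-miR-125b-1``, ``MicroRNA-125`` and ``mir125a-5p`` all collapse to
``miR-125``.

A bare "miR"/"miRNA"/"microRNA" with no number is not a mention.  Names
without the miR prefix (let-7 and friends) are deliberately outside the
grammar; extend via EXTRA_PATTERNS if a corpus needs them.
"""

from __future__ import annotations

import re

__all__ = ["normalize_mirna", "extract_mirnas", "MIRNA_PATTERN", "family_index", "EXTRA_PATTERNS"]

# The mention grammar.  The capture group is the family integer.  Cluster
# notations ("miR-17-92") are consumed as one token and normalize to the
# first integer; slash paralog lists ("miR-146a/b") match up to the first
# arm only, which lands on the same family.
MIRNA_PATTERN = re.compile(
    r"""
    (?<![A-Za-z0-9])           # left boundary: not inside a word
                               # (hyphen allowed: anti-miR-21 is a mention)
    (?:[a-z]{3}-)?             # optional species prefix (hsa-, mmu-, rno-)
    (?:micro\ ?rna|mirna|mir)  # prefix spellings, collapsed on output
    [-\ ]?                     # optional separator
    (\d+)                      # family integer  -> canonical miR-N
    [a-z]?                     # lettered paralog suffix
    (?:-\d+)?                  # numeric paralog index or cluster tail
    (?:-[35]p)?                # arm suffix
    (?![A-Za-z0-9])            # right boundary
    """,
    re.IGNORECASE | re.VERBOSE,
)

#: Hook for corpora that need non-"miR"-prefixed names (e.g. let-7): each
#: pattern must expose the family integer as group 1 and is normalized to
#: the same "miR-N" space only if that is meaningful for the analysis.
EXTRA_PATTERNS: list[re.Pattern[str]] = []


def normalize_mirna(token: str) -> str:
    """Normalize one mined token to its canonical family string ``miR-N``.

    Species prefixes, spelling variants, case, lettered/numeric paralog
    suffixes and arm suffixes are all stripped; the first integer after
    the prefix names the family.  Idempotent: a canonical string maps to
    itself.

    Raises ``ValueError`` for a token the grammar cannot anchor (no digits
    after a miR-like prefix).
    """
    m = MIRNA_PATTERN.search(token)
    if m is None:
        raise ValueError(f"not a miRNA mention: {token!r}")
    return f"miR-{int(m.group(1))}"


def extract_mirnas(text: str) -> set[str]:
    """All miRNA families mentioned in free text, as a set.

    Set semantics implement the once-per-article rule: repeating a mention,
    or mentioning two members of one family (miR-146a and miR-146b), yields
    a single family entry.
    """
    families = {f"miR-{int(num)}" for num in MIRNA_PATTERN.findall(text)}
    for pat in EXTRA_PATTERNS:
        families.update(f"miR-{int(num)}" for num in pat.findall(text))
    return families


def family_index(family: str) -> int:
    """Integer index of a canonical family string (miR-21 -> 21).

    Used as the deterministic tie-breaker in rankings.
    """
    if not family.startswith("miR-"):
        raise ValueError(f"not a canonical family: {family!r}")
    return int(family[4:])
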