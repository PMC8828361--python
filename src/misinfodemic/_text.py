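"""Shared text utilities: tokenization and the pinned English stop-word list.

The same tokenizer backs narrative keyword tagging, bigram extraction and
topic modelling so that all three stages agree on what a "token" is:
case-folded alphanumeric runs, with hash signs (and all other punctuation)
acting as separators.
"""

from __future__ import annotations

import re

_TOKEN_RE = re.compile(r"[a-z0-9]+")

# Pinned stop-word list (versioned with the package so token streams are
# reproducible across environments). Standard high-frequency English function
# words; deliberately small — domain words are never stop words.
STOPWORDS: frozenset[str] = frozenset(
    """
    a about above after again against all am an and any are aren as at be
    because been before being below between both but by can cannot could
    couldn did didn do does doesn doing don down during each few for from
    further had hadn has hasn have haven having he her here hers herself him
    himself his how i if in into is isn it its itself just me more most
    mustn my myself no nor not now of off on once only or other our ours
    ourselves out over own re s same shan she should shouldn so some such t
    than that the their theirs them themselves then there these they this
    those through to too under until up very was wasn we were weren what
    when where which while who whom why will with won would wouldn you your
    yours yourself yourselves
    """.split()
)


def tokenize(text: str) -> list[str]:
    """Case-fold and split on non-alphanumeric characters (incl. '#')."""
    return _TOKEN_RE.findall(text.lower())


def tokenize_content(text: str) -> list[str]:
    """Tokenize and drop stop words (the bigram/topic-model preprocessing)."""
    return [t for t in tokenize(text) if t not in STOPWORDS]
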