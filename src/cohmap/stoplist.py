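"""Packaged function-word stoplist.

Content-word filtering keeps nouns, verbs, adjectives and adverbs; everything
grammatical — articles, prepositions, pronouns, auxiliaries, conjunctions —
plus interjections/fillers ("um", "uh") is removed before a response vector
is composed. The list is deliberately closed-class only; it can be replaced
wholesale via the ``stoplist`` argument of the scoring functions, and its
SHA-256 hash is logged for reproducibility.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

_DEFAULT_STOPLIST = """
a an the
this that these those
i you he she it we they me him her us them
my your his its our their mine yours hers ours theirs
myself yourself himself herself itself ourselves yourselves themselves
who whom whose which what
someone anyone everyone no-one somebody anybody everybody nobody
something anything everything nothing
be am is are was were been being
have has had having
do does did doing done
will would shall should can could may might must
ought need dare
in on at by for with about against between into through during before after
above below to from up down out off over under again further of
and but or nor so yet both either neither whether because although though
while if unless until since as than
not no nor n't
there here when where why how
all each every some any few more most other such only own same
just also too very quite rather really
oh ah um uh er erm hmm mm mhm well okay ok yeah yes right
"""

DEFAULT_STOPLIST: frozenset[str] = frozenset(_DEFAULT_STOPLIST.split())


def load_stoplist(path: str | Path) -> frozenset[str]:
    """Read a whitespace-separated stoplist file (lowercased)."""
    text = Path(path).read_text(encoding="utf-8")
    return frozenset(w.lower() for w in text.split())


def stoplist_hash(stoplist: frozenset[str]) -> str:
    """SHA-256 of the sorted stoplist — logged with every scoring run."""
    blob = "\n".join(sorted(stoplist)).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()
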