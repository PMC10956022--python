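"""Lexicons, tokenization and matching for count-based language features.

Three matching modes are supported:

* ``token`` — exact equality against lowercase word tokens;
* ``wildcard`` — entries ending in ``*`` match any token with that prefix
  (the LIWC word-stem convention);
* ``phrase`` — multiword entries matched against consecutive tokens by a
  greedy non-overlapping left-to-right scan, longest entry first.

The full LIWC dictionary and the full NRC emotion lexicon are proprietary /
externally licensed and are loaded from user-supplied files
(:func:`load_liwc_dic`, :func:`load_lexicon_tsv`).  :func:`builtin_lexicons`
ships small stand-in lexicons — explicitly non-exhaustive — whose entries are
the published example terms for each feature, so the whole pipeline runs and
is testable without any proprietary data.  Feature values computed with the
stand-ins are NOT comparable in magnitude to values computed with the real
dictionaries.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "Lexicon",
    "TokenSequence",
    "tokenize",
    "count_matches",
    "load_liwc_dic",
    "load_lexicon_tsv",
    "builtin_lexicons",
]


class LexiconFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Lexicon:
    """A named set of lowercase terms with a matching mode."""

    name: str
    mode: str  # "token" | "wildcard" | "phrase"
    entries: frozenset[str]

    def __post_init__(self):
        if self.mode not in ("token", "wildcard", "phrase"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.entries:
            raise ValueError(f"lexicon {self.name!r} has no entries")
        for e in self.entries:
            if "*" in e[:-1]:
                raise ValueError(f"{self.name!r}: '*' only allowed terminally ({e!r})")


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[str, ...]

    @property
    def word_count(self) -> int:
        return len(self.tokens)


_WORDISH = re.compile(r"[\w']+", re.UNICODE)


def tokenize(text: str) -> TokenSequence:
    """Lowercase word tokens; edge punctuation stripped, contractions kept.

    Any run of word characters and apostrophes is a token candidate; leading
    and trailing apostrophes/underscores are then stripped so ``"'tis'"`` →
    ``tis`` but ``i'll`` survives intact.  Unicode is NFC-normalized and the
    typographic apostrophe is folded onto ``'``.
    """
    text = unicodedata.normalize("NFC", text or "").replace("’", "'").lower()
    tokens = tuple(
        stripped
        for raw in _WORDISH.findall(text)
        if (stripped := raw.strip("'_"))
    )
    return TokenSequence(tokens)


def count_matches(tokens: TokenSequence, lex: Lexicon) -> int:
    """Number of lexicon matches in a token sequence.

    Token and wildcard modes count matching tokens (so the count never
    exceeds the word count).  Phrase mode counts non-overlapping phrase
    occurrences in a greedy left-to-right scan, trying the longest entry at
    each position first (ties broken lexicographically); each occurrence
    counts once regardless of its length.
    """
    if lex.mode == "token":
        entries = lex.entries
        return sum(1 for t in tokens.tokens if t in entries)
    if lex.mode == "wildcard":
        exact = frozenset(e for e in lex.entries if not e.endswith("*"))
        prefixes = tuple(e[:-1] for e in lex.entries if e.endswith("*"))
        n = 0
        for t in tokens.tokens:
            if t in exact or any(t.startswith(p) for p in prefixes):
                n += 1
        return n
    # phrase mode
    phrases = sorted(
        (tuple(e.split()) for e in lex.entries),
        key=lambda p: (-len(p), p),
    )
    seq = tokens.tokens
    n = 0
    i = 0
    while i < len(seq):
        for ph in phrases:
            if seq[i : i + len(ph)] == ph:
                n += 1
                i += len(ph)
                break
        else:
            i += 1
    return n


# ---------------------------------------------------------------------------
# loaders


def load_liwc_dic(
    path: str | Path, categories: Iterable[str] | None = None
) -> dict[str, Lexicon]:
    """Load a LIWC-dialect ``.dic`` file into one Lexicon per category.

    The dialect is a ``%``-delimited header mapping numeric (or symbolic)
    category ids to category names, followed by ``term<TAB>id[,id...]``
    lines; terms may end in ``*`` for stem matching.  A category's lexicon
    uses wildcard mode when any of its entries is starred, token mode
    otherwise.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    it = iter(enumerate(lines, 1))
    for lineno, line in it:
        if line.strip() == "%":
            break
        if line.strip():
            raise LexiconFormatError(
                f"line {lineno}: expected '%' header before categories"
            )
    else:
        raise LexiconFormatError("missing '%' header")
    id_to_name: dict[str, str] = {}
    for lineno, line in it:
        if line.strip() == "%":
            break
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise LexiconFormatError(f"line {lineno}: malformed category {line!r}")
        id_to_name[parts[0]] = " ".join(parts[1:])
    else:
        raise LexiconFormatError("missing closing '%' of header")
    entries: dict[str, set[str]] = {name: set() for name in id_to_name.values()}
    for lineno, line in it:
        if not line.strip():
            continue
        parts = re.split(r"[\t ]+", line.strip())
        term = parts[0].lower()
        for cid in (c for chunk in parts[1:] for c in chunk.split(",") if c):
            if cid not in id_to_name:
                raise LexiconFormatError(
                    f"line {lineno}: term {term!r} references unknown category "
                    f"id {cid!r}"
                )
            entries[id_to_name[cid]].add(term)
    wanted = set(categories) if categories is not None else set(entries)
    out = {}
    for name, terms in entries.items():
        if name not in wanted or not terms:
            continue
        mode = "wildcard" if any(t.endswith("*") for t in terms) else "token"
        out[name] = Lexicon(name=name, mode=mode, entries=frozenset(terms))
    return out


def load_lexicon_tsv(path: str | Path) -> dict[str, Lexicon]:
    """Load a simple ``term<TAB>feature_name`` TSV into Lexicons.

    Multiword terms get phrase mode for their feature; trailing ``*`` marks a
    stem and forces wildcard mode.  This is also the dialect used for the NRC
    emotion lexicon's polarity categories (term → Positive / Negative).
    """
    grouped: dict[str, set[str]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), 1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        if "\t" not in line:
            raise LexiconFormatError(f"line {lineno}: expected term<TAB>feature")
        term, feat = line.split("\t", 1)
        grouped.setdefault(feat.strip(), set()).add(term.strip().lower())
    out = {}
    for feat, terms in grouped.items():
        if any(" " in t for t in terms):
            mode = "phrase"
        elif any(t.endswith("*") for t in terms):
            mode = "wildcard"
        else:
            mode = "token"
        out[feat] = Lexicon(name=feat, mode=mode, entries=frozenset(terms))
    return out


# ---------------------------------------------------------------------------
# built-in stand-ins

_YOU = ("you", "yours", "you'll", "y'all")
_THEY = ("they", "their", "themselves", "they'll")
_I = ("i", "i'll", "mine", "my", "myself")
_WE = ("we", "us", "ours", "let's")
_THIRD_SINGULAR = ("he", "she", "it")

# Example terms published for each feature; deliberately non-exhaustive.
_BUILTIN: dict[str, tuple[str, tuple[str, ...]]] = {
    '"You" Pronouns': ("token", _YOU),
    '"They" Pronouns': ("token", _THEY),
    "Personal Pronouns": ("token", _YOU + _THEY + _I + _WE + _THIRD_SINGULAR),
    '"I" Pronouns': ("token", _I),
    '"We" Pronouns': ("token", _WE),
    "Past-Oriented": ("token", ("ago", "yesterday", "remember")),
    "Present-Oriented": ("token", ("now", "current", "is")),
    "Future-Oriented": ("token", ("we'll", "upcoming", "eventual")),
    "Negative": ("token", ("frustrated", "scream", "hurt", "loathe")),
    "Positive": ("token", ("calm", "peace", "love", "enjoy", "satisfied")),
    "Checking for Understanding": (
        "phrase",
        (
            "it sounds like",
            "that seems",
            "heard you correctly",
            "you sound",
            "let me make sure",
        ),
    ),
    "Demonstrating Understanding": ("phrase", ("i hear you", "i see", "i understand")),
    "Hedging": ("phrase", ("maybe", "from my perspective", "apparently")),
    "Absolutist": (
        "token",
        ("absolutely", "always", "completely", "everyone", "must", "never", "nothing"),
    ),
}


def builtin_lexicons() -> dict[str, Lexicon]:
    """Stand-in lexicons for the 14 count-based language features.

    Entries are only the published example terms per feature — small,
    non-exhaustive stand-ins that keep the pipeline runnable without the
    proprietary LIWC and full NRC emotion lexicons.  The four paralinguistic
    features need no lexicon and are absent here.
    """
    return {
        name: Lexicon(name=name, mode=mode, entries=frozenset(terms))
        for name, (mode, terms) in _BUILTIN.items()
    }
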