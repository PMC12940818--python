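"""Text cleaning, sentence segmentation and offset-preserving tokenization.

Every downstream object (entity mention, pattern hit, candidate association)
is traceable to a character span in a cleaned document, so the contract here
is strict: sentences are exact slices of the document, and token offsets
reconstruct each sentence exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "Sentence",
    "Token",
    "clean_text",
    "split_sentences",
    "tokenize",
    "load_abbreviations",
    "DEFAULT_ABBREVIATIONS",
]

_CONTROL_RE = re.compile(r"[\x00-\x08\x0b\x0c\x0e-\x1f\x7f]")
_WS_RE = re.compile(r"\s+")

# A word token: unicode letters/digits, hyphens only word-internal ("MMP-2",
# "α-blocker" stay atomic). Everything else non-space is a 1-char token.
_WORD_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*|[^\s]", re.UNICODE)

_TERMINAL = (".", "?", "!")


@dataclass(frozen=True)
class Sentence:
    """One sentence of a cleaned document.

    ``text`` equals the slice ``document[start:end]`` of the cleaned
    title+abstract the sentence came from.
    """

    pmid: str
    index: int
    text: str
    start: int
    end: int

    @property
    def source_span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Token:
    """One token of a sentence; offsets are within the sentence text."""

    text: str
    start: int
    end: int
    index: int


def clean_text(title: str, abstract: str) -> str:
    """Join title and abstract into one cleaned document.

    Control characters are removed, whitespace runs collapse to single
    spaces, and a period is appended to the title when it lacks terminal
    punctuation so that segmentation sees a sentence boundary between title
    and abstract. Empty inputs yield an empty document.
    """
    parts = []
    t = _normalize_ws(title)
    if t:
        if not t.endswith(_TERMINAL):
            t += "."
        parts.append(t)
    a = _normalize_ws(abstract)
    if a:
        parts.append(a)
    return " ".join(parts)


def _normalize_ws(text: str) -> str:
    return _WS_RE.sub(" ", _CONTROL_RE.sub("", text)).strip()


#: Guard list used when no config file is given: a period ending one of
#: these strings does not terminate a sentence.
DEFAULT_ABBREVIATIONS = (
    "e.g.", "i.e.", "vs.", "et al.", "al.", "Fig.", "Figs.", "Tab.",
    "Ref.", "No.", "approx.", "ca.", "cf.", "Dr.", "Prof.", "St.",
    "spp.", "sp.", "subsp.", "wt.", "vol.", "resp.",
)


def load_abbreviations(path) -> tuple[str, ...]:
    """Read a guard list, one abbreviation per line; '#' lines are comments."""
    with open(path, encoding="utf-8") as fh:
        return tuple(
            line.strip() for line in fh
            if line.strip() and not line.startswith("#")
        )


def _ends_with_abbreviation(document: str, pos: int, guards: Iterable[str]) -> bool:
    # pos is the index of the candidate terminal "."; check the text up to
    # and including it against the guard list and single capital initials.
    head = document[: pos + 1]
    for abbr in guards:
        if head.endswith(abbr):
            return True
    # single capital initial: " J."
    if pos >= 1 and head[-2].isupper() and (pos == 1 or not head[-3].isalnum()):
        return True
    return False


def split_sentences(
    document: str,
    pmid: str = "",
    abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS,
) -> list[Sentence]:
    """Rule-based sentence boundary detection.

    Splits after '.', '?' or '!' followed by a space and an uppercase letter
    or digit, unless the period terminates a guarded abbreviation or a
    single capital initial. Unsplittable text yields one sentence; the empty
    document yields none.
    """
    if not document:
        return []
    boundaries: list[int] = []
    for m in re.finditer(r"[.?!] ", document):
        pos = m.start()
        nxt = document[pos + 2] if pos + 2 < len(document) else ""
        if not (nxt.isupper() or nxt.isdigit()):
            continue
        if document[pos] == "." and _ends_with_abbreviation(document, pos, abbreviations):
            continue
        boundaries.append(pos + 1)  # split point: just after the terminal char

    sentences: list[Sentence] = []
    start = 0
    for b in boundaries + [len(document)]:
        text = document[start:b]
        lead = len(text) - len(text.lstrip(" "))
        s0 = start + lead
        text = document[s0:b].rstrip(" ")
        if text:
            sentences.append(
                Sentence(pmid=pmid, index=len(sentences), text=text,
                         start=s0, end=s0 + len(text))
            )
        start = b
    return sentences


def tokenize(text: str | Sentence) -> list[Token]:
    """Tokenize a sentence, keeping exact character offsets.

    Maximal runs of letters/digits with internal hyphens form word tokens;
    every other non-space character is a single-character token. The
    concatenation of token texts with the inter-token gaps reproduces the
    input exactly.
    """
    s = text.text if isinstance(text, Sentence) else text
    return [
        Token(text=m.group(0), start=m.start(), end=m.end(), index=i)
        for i, m in enumerate(_WORD_RE.finditer(s))
    ]
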