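"""Sentence-scoped extraction of e-resource mentions and descriptor hits.

Raw text is split into sentences; within each sentence, named bioinformatics
e-resources are recognised through their terminological head word (the final
noun that assigns one of four semantic classes: Algorithm, Application, Data,
Data resource), and descriptor terms are tagged by case-insensitive
longest-match against a flat dictionary.

The recogniser is deliberately simple: a mention is a maximal run of
"name tokens" (capitalised words, acronyms, tokens with digits, hyphenated
tokens) immediately preceding and including a head word.  No part-of-speech
tagging or noun-phrase chunking is attempted.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

ALGORITHM = "Algorithm"
APPLICATION = "Application"
DATA = "Data"
DATA_RESOURCE = "Data resource"

SEMANTIC_CLASSES = (ALGORITHM, APPLICATION, DATA, DATA_RESOURCE)

#: accepted spellings in lexicon files, normalised to the canonical form
_CLASS_ALIASES = {
    "algorithm": ALGORITHM,
    "application": APPLICATION,
    "data": DATA,
    "data resource": DATA_RESOURCE,
    "dataresource": DATA_RESOURCE,
    "data_resource": DATA_RESOURCE,
}


def normalize_class(name: str) -> str:
    try:
        return _CLASS_ALIASES[name.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown semantic class: {name!r}") from None


# --------------------------------------------------------------------------
# lexicons

@dataclass(frozen=True)
class HeadLexicon:
    """Maps terminological head words to their semantic class.

    Head words are single lowercase tokens ("algorithm", "database", ...);
    the class of a resource mention is the class of its head word.
    """

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for head, cls in self.entries.items():
            if not head or head != head.lower():
                raise ValueError(f"head word must be lowercase: {head!r}")
            if cls not in SEMANTIC_CLASSES:
                raise ValueError(f"unknown class {cls!r} for head {head!r}")

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.entries

    def class_of(self, token: str) -> str:
        return self.entries[token.lower()]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HeadLexicon":
        """Read a 2-column TSV (head_word <TAB> class); '#' starts a comment."""
        entries: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            head, klass = line.split("\t")
            entries[head.strip().lower()] = normalize_class(klass)
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{h}\t{c}" for h, c in sorted(self.entries.items())]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class DescriptorDictionary:
    """Flat list of lowercase descriptor terms with a per-term source tag.

    Terms may be multi-word ("gene expression data"); matching is by exact
    token sequence, case-insensitively, with no stemming.
    """

    terms: frozenset[str]
    source_tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.terms:
            if not t.strip():
                raise ValueError("empty descriptor term")
            if t != t.lower():
                raise ValueError(f"descriptor term must be lowercase: {t!r}")

    @classmethod
    def from_terms(cls, terms: Iterable[str], source: str = "extracted") -> "DescriptorDictionary":
        lowered = frozenset(t.strip().lower() for t in terms if t.strip())
        return cls(lowered, {t: source for t in lowered})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DescriptorDictionary":
        """Read a 1- or 2-column TSV (term [<TAB> source]); '#' comments."""
        terms: set[str] = set()
        tags: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            term = parts[0].strip().lower()
            terms.add(term)
            tags[term] = parts[1].strip() if len(parts) > 1 else "extracted"
        return cls(frozenset(terms), tags)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{t}\t{self.source_tags.get(t, 'extracted')}" for t in sorted(self.terms)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term.lower() in self.terms


# --------------------------------------------------------------------------
# records

@dataclass(frozen=True)
class ResourceMention:
    surface: str
    canonical_key: str
    semantic_class: str
    char_span: tuple[int, int]  # half-open, sentence-relative


@dataclass(frozen=True)
class DescriptorHit:
    term: str
    char_span: tuple[int, int]  # half-open, sentence-relative


@dataclass
class SentenceRecord:
    doc_id: str
    sent_index: int
    text: str
    mentions: list[ResourceMention] = field(default_factory=list)
    descriptor_hits: list[DescriptorHit] = field(default_factory=list)


def canonical_key(surface: str) -> str:
    """Lowercase, whitespace-normalised resource key (no disambiguation)."""
    return " ".join(surface.lower().split())


# --------------------------------------------------------------------------
# sentence splitting

#: tokens (sans terminal period) that do not end a sentence
_ABBREVIATIONS = {
    "e.g", "i.e", "cf", "fig", "figs", "eq", "eqs", "etc", "et al", "al",
    "vs", "ref", "refs", "no", "approx", "ca",
}

_BOUNDARY = re.compile(r"[.!?]+(?=\s)")


def split_sentences(document_text: str, doc_id: str = "doc") -> list[SentenceRecord]:
    """Split text into sentences on [.!?] + whitespace + capital/digit.

    A small abbreviation stop-list ("e.g.", "Fig.", ...) suppresses false
    boundaries.  Deterministic; empty input yields an empty list.
    """
    text = document_text
    if not text.strip():
        return []
    boundaries: list[int] = []
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        # next non-space character must open a new sentence
        rest = text[end:].lstrip()
        if not rest or not (rest[0].isupper() or rest[0].isdigit() or rest[0] == "("):
            continue
        prev = text[: m.start()].rstrip()
        last_word = prev.split()[-1] if prev.split() else ""
        last_word = last_word.lstrip("([\"'").lower()
        if last_word in _ABBREVIATIONS or last_word.rstrip(".") in _ABBREVIATIONS:
            continue
        boundaries.append(end)
    records: list[SentenceRecord] = []
    start = 0
    for end in boundaries + [len(text)]:
        chunk = text[start:end].strip()
        if chunk:
            records.append(SentenceRecord(doc_id, len(records), chunk))
        start = end
    return records


# --------------------------------------------------------------------------
# mention recognition

_WORD = re.compile(r"[A-Za-z0-9][A-Za-z0-9'\-]*")

#: capitalised function words (typically sentence-initial) that are never
#: part of a resource name
_NAME_STOPWORDS = {
    "the", "a", "an", "this", "that", "these", "those", "we", "our", "its",
    "it", "in", "on", "of", "for", "with", "and", "or", "to", "by", "using",
    "is", "are", "was", "were", "here", "both", "all", "each",
}


def _tokens_with_spans(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(), m.start(), m.end()) for m in _WORD.finditer(text)]


def _is_name_token(token: str) -> bool:
    """Capitalised word, acronym, token containing a digit, or hyphenated."""
    if token.lower() in _NAME_STOPWORDS:
        return False
    if any(ch.isdigit() for ch in token):
        return True
    if "-" in token:
        return True
    if token[0].isupper():
        return True
    return False


def find_resource_mentions(sentence: SentenceRecord, lexicon: HeadLexicon) -> list[ResourceMention]:
    """Recognise resource mentions: a name-token run ending in a head word.

    The run must contain at least one name token before the head word (a bare
    head word like "the algorithm" is a generic noun, not a resource name).
    Mentions are non-overlapping, assigned left-to-right.
    """
    toks = _tokens_with_spans(sentence.text)
    mentions: list[ResourceMention] = []
    consumed_until = -1  # token index consumed by a previous mention
    for i, (tok, start, end) in enumerate(toks):
        if tok.lower() not in lexicon.entries:
            continue
        # walk backwards over contiguous name tokens
        j = i - 1
        while j > consumed_until and _is_name_token(toks[j][0]):
            j -= 1
        first = j + 1
        if first == i:  # no name token precedes the head word
            continue
        span = (toks[first][1], end)
        surface = sentence.text[span[0]: span[1]]
        mentions.append(
            ResourceMention(
                surface=surface,
                canonical_key=canonical_key(surface),
                semantic_class=lexicon.class_of(tok),
                char_span=span,
            )
        )
        consumed_until = i
    return mentions


# --------------------------------------------------------------------------
# descriptor matching

def find_descriptors(sentence: SentenceRecord, dictionary: DescriptorDictionary) -> list[DescriptorHit]:
    """Tag descriptor terms: case-insensitive longest match, left-to-right.

    Hits never overlap one another, and a hit overlapping a resource-mention
    span is discarded — a resource's own name is not its descriptor.
    """
    if not dictionary.terms:
        return []
    term_seqs = {tuple(t.split()): t for t in dictionary.terms}
    max_len = max(len(s) for s in term_seqs)
    toks = _tokens_with_spans(sentence.text)
    lowered = [t.lower() for t, _, _ in toks]
    mention_spans = [m.char_span for m in sentence.mentions]

    def overlaps_mention(start: int, end: int) -> bool:
        return any(start < me and ms < end for ms, me in mention_spans)

    hits: list[DescriptorHit] = []
    i = 0
    while i < len(toks):
        matched = False
        for n in range(min(max_len, len(toks) - i), 0, -1):
            seq = tuple(lowered[i: i + n])
            if seq in term_seqs:
                start, end = toks[i][1], toks[i + n - 1][2]
                if not overlaps_mention(start, end):
                    hits.append(DescriptorHit(term_seqs[seq], (start, end)))
                    i += n
                    matched = True
                break  # longest match decided, even if it overlapped a mention
        if not matched:
            i += 1
    return hits


def annotate(sentence: SentenceRecord, lexicon: HeadLexicon, dictionary: DescriptorDictionary) -> SentenceRecord:
    """Fill a sentence's mentions then descriptor hits, in place."""
    sentence.mentions = find_resource_mentions(sentence, lexicon)
    sentence.descriptor_hits = find_descriptors(sentence, dictionary)
    return sentence


# --------------------------------------------------------------------------
# corpus-level driver and serialization

def read_corpus(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (doc_id, text) from a directory of .txt files, sorted by name."""
    root = Path(path)
    for f in sorted(root.glob("*.txt")):
        yield f.stem, f.read_text(encoding="utf-8")


def read_sentences_jsonl(path: str | Path) -> list[SentenceRecord]:
    """Read pre-sentencised input: one JSON record per line."""
    records = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        records.append(SentenceRecord(str(obj["doc_id"]), int(obj["sent_index"]), obj["text"]))
    return records


def extract_corpus(
    corpus: str | Path | Iterable[tuple[str, str]],
    lexicon: HeadLexicon,
    dictionary: DescriptorDictionary,
) -> list[SentenceRecord]:
    """Split, annotate and return every sentence of a corpus."""
    docs = read_corpus(corpus) if isinstance(corpus, (str, Path)) else corpus
    out: list[SentenceRecord] = []
    for doc_id, text in docs:
        for rec in split_sentences(text, doc_id=doc_id):
            out.append(annotate(rec, lexicon, dictionary))
    return out


_TSV_HEADER = "doc_id\tsent_index\tkind\tsurface\tclass\tstart\tend"


def write_extraction_tsv(records: Sequence[SentenceRecord], path: str | Path) -> None:
    """Serialise mentions and descriptor hits to TSV.

    Columns: doc_id, sent_index, kind (mention|descriptor), surface
    (mention surface text, or the dictionary term for descriptor rows),
    class (empty for descriptors), start, end — 0-based half-open
    sentence-relative character offsets.
    """
    lines = [_TSV_HEADER]
    for rec in records:
        for m in rec.mentions:
            lines.append(
                f"{rec.doc_id}\t{rec.sent_index}\tmention\t{m.surface}"
                f"\t{m.semantic_class}\t{m.char_span[0]}\t{m.char_span[1]}"
            )
        for h in rec.descriptor_hits:
            lines.append(
                f"{rec.doc_id}\t{rec.sent_index}\tdescriptor\t{h.term}"
                f"\t\t{h.char_span[0]}\t{h.char_span[1]}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_extraction_tsv(path: str | Path) -> list[SentenceRecord]:
    """Read extraction TSV back into SentenceRecords (text not recoverable)."""
    by_sentence: dict[tuple[str, int], SentenceRecord] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if lines and lines[0] == _TSV_HEADER:
        lines = lines[1:]
    for line in lines:
        if not line.strip():
            continue
        doc_id, sent_index, kind, surface, klass, start, end = line.split("\t")
        key = (doc_id, int(sent_index))
        rec = by_sentence.setdefault(key, SentenceRecord(doc_id, int(sent_index), ""))
        span = (int(start), int(end))
        if kind == "mention":
            rec.mentions.append(
                ResourceMention(surface, canonical_key(surface), normalize_class(klass), span)
            )
        elif kind == "descriptor":
            rec.descriptor_hits.append(DescriptorHit(surface, span))
        else:
            raise ValueError(f"unknown record kind: {kind!r}")
    return [by_sentence[k] for k in sorted(by_sentence)]
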