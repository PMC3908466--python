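"""Annotated-corpus data model and CoNLL-style BIO readers/writers.

A corpus is a list of documents; each document is a list of tokenized
sentences plus a list of typed, non-overlapping concept spans addressed by
(sentence index, token start, token end) with 0-based, half-open token
coordinates.

The exchange format is token-per-line BIO: ``token<TAB>label`` with a blank
line between sentences and a ``#doc <id>`` comment line opening each
document.  Labels are ``O`` or ``B_<type>`` / ``I_<type>``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "ConceptSpan",
    "AnnotatedDocument",
    "Corpus",
    "BioParseError",
    "read_bio",
    "write_bio",
    "tokenize",
    "corpus_stats",
]

_LABEL_RE = re.compile(r"^(O|[BI]_\S+)$")


class BioParseError(ValueError):
    """Malformed BIO input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class Token:
    """A single token with its position in the document."""

    text: str
    sent_index: int = 0
    tok_index: int = 0

    def __post_init__(self):
        if not self.text or re.search(r"\s", self.text):
            raise ValueError(f"token text must be non-empty, whitespace-free: {self.text!r}")
        if self.sent_index < 0 or self.tok_index < 0:
            raise ValueError("token indices must be >= 0")


@dataclass(frozen=True, order=True)
class ConceptSpan:
    """A typed concept mention: tokens [start, end) of one sentence."""

    sent_index: int
    start: int
    end: int
    ctype: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    def overlaps(self, other: "ConceptSpan") -> bool:
        return (
            self.sent_index == other.sent_index
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AnnotatedDocument:
    doc_id: str
    sentences: list[list[str]]
    spans: list[ConceptSpan] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for sp in self.spans:
            if not (0 <= sp.sent_index < len(self.sentences)):
                raise ValueError(f"span {sp} references missing sentence in {self.doc_id!r}")
            if sp.end > len(self.sentences[sp.sent_index]):
                raise ValueError(f"span {sp} exceeds sentence length in {self.doc_id!r}")
        ordered = sorted(self.spans)
        for a, b in zip(ordered, ordered[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping spans {a} and {b} in {self.doc_id!r}")

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def spans_in_sentence(self, sent_index: int) -> list[ConceptSpan]:
        return sorted(sp for sp in self.spans if sp.sent_index == sent_index)


@dataclass
class Corpus:
    documents: list[AnnotatedDocument]
    type_inventory: list[str]

    def __post_init__(self):
        known = set(self.type_inventory)
        if len(known) != len(self.type_inventory):
            raise ValueError("type_inventory has duplicates")
        for doc in self.documents:
            for sp in doc.spans:
                if sp.ctype not in known:
                    raise ValueError(f"span type {sp.ctype!r} not in inventory {known}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[AnnotatedDocument]:
        return iter(self.documents)

    @property
    def n_sentences(self) -> int:
        return sum(len(d.sentences) for d in self.documents)

    @property
    def n_spans(self) -> int:
        return sum(len(d.spans) for d in self.documents)

    def subset(self, doc_indices: Iterable[int]) -> "Corpus":
        """New corpus holding the given documents (same inventory)."""
        docs = [self.documents[i] for i in doc_indices]
        return Corpus(documents=docs, type_inventory=list(self.type_inventory))


def _decode_bio_labels(labels: list[str], sent_index: int, line_numbers: list[int]) -> list[ConceptSpan]:
    """Decode one sentence's BIO labels into spans.

    Repair policy: an I_<t> that does not continue an open chunk of type t is
    treated as B_<t> (lenient CoNLL convention); a warning is logged.
    """
    spans: list[ConceptSpan] = []
    open_start = None
    open_type = None

    def close(upto: int):
        nonlocal open_start, open_type
        if open_type is not None:
            spans.append(ConceptSpan(sent_index, open_start, upto, open_type))
            open_start = open_type = None

    for i, lab in enumerate(labels):
        if lab == "O":
            close(i)
        else:
            kind, ctype = lab.split("_", 1)
            if kind == "B":
                close(i)
                open_start, open_type = i, ctype
            else:  # I
                if open_type != ctype:
                    logger.warning(
                        "line %d: dangling I_%s repaired to B_%s", line_numbers[i], ctype, ctype
                    )
                    close(i)
                    open_start, open_type = i, ctype
    close(len(labels))
    return spans


def read_bio(stream: IO[str] | Iterable[str]) -> Corpus:
    """Parse token-per-line BIO text into a :class:`Corpus`.

    ``#doc <id>`` lines delimit documents; a blank line ends a sentence.
    The type inventory lists concept types in first-seen order.  Overlap
    cannot arise from BIO decoding, but document validation still enforces it.
    """
    documents: list[AnnotatedDocument] = []
    inventory: list[str] = []
    seen: set[str] = set()

    cur_id: str | None = None
    cur_sents: list[list[str]] = []
    cur_spans: list[ConceptSpan] = []
    toks: list[str] = []
    labs: list[str] = []
    lnos: list[int] = []
    n_anonymous = 0

    def end_sentence():
        nonlocal toks, labs, lnos
        if toks:
            for sp in _decode_bio_labels(labs, len(cur_sents), lnos):
                cur_spans.append(sp)
                if sp.ctype not in seen:
                    seen.add(sp.ctype)
                    inventory.append(sp.ctype)
            cur_sents.append(toks)
            toks, labs, lnos = [], [], []

    def end_document():
        nonlocal cur_id, cur_sents, cur_spans, n_anonymous
        end_sentence()
        if cur_sents or cur_id is not None:
            doc_id = cur_id
            if doc_id is None:
                doc_id = f"doc{n_anonymous}"
                n_anonymous += 1
            documents.append(AnnotatedDocument(doc_id, cur_sents, cur_spans))
        cur_id, cur_sents, cur_spans = None, [], []

    for lno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("#doc"):
            end_document()
            cur_id = line[len("#doc"):].strip() or None
            if cur_id is None:
                cur_id = ""
            continue
        if not line.strip():
            end_sentence()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise BioParseError(f"expected 'token<TAB>label', got {line!r}", lno)
        tok, lab = parts
        if not tok.strip():
            raise BioParseError("empty token", lno)
        if not _LABEL_RE.match(lab):
            raise BioParseError(f"bad label {lab!r}", lno)
        toks.append(tok)
        labs.append(lab)
        lnos.append(lno)
    end_document()

    return Corpus(documents=documents, type_inventory=inventory)


def write_bio(corpus: Corpus, stream: IO[str] | None = None) -> str | None:
    """Serialize a corpus to BIO text; the inverse of :func:`read_bio`.

    Returns the text if ``stream`` is None, else writes to ``stream``.
    """
    out: list[str] = []
    for doc in corpus.documents:
        out.append(f"#doc {doc.doc_id}")
        for si, sent in enumerate(doc.sentences):
            labels = ["O"] * len(sent)
            for sp in doc.spans_in_sentence(si):
                labels[sp.start] = f"B_{sp.ctype}"
                for i in range(sp.start + 1, sp.end):
                    labels[i] = f"I_{sp.ctype}"
            for tok, lab in zip(sent, labels):
                out.append(f"{tok}\t{lab}")
            out.append("")
    text = "\n".join(out) + ("\n" if out else "")
    if stream is None:
        return text
    stream.write(text)
    return None


_PUNCT = set(".,;:!?()[]{}\"'%/")
_SENT_END = re.compile(r"[.!?]$")


def tokenize(text: str) -> list[list[Token]]:
    """Deterministic whitespace + punctuation tokenizer with sentence splits.

    Punctuation characters become single-character tokens.  A sentence break
    is placed after a ``.``, ``!`` or ``?`` token when followed by a
    capitalized word, or at a newline.
    """
    sentences: list[list[Token]] = []
    cur: list[str] = []

    def flush():
        nonlocal cur
        if cur:
            si = len(sentences)
            sentences.append([Token(t, si, i) for i, t in enumerate(cur)])
            cur = []

    for line in text.split("\n"):
        words = line.split()
        pieces: list[str] = []
        for w in words:
            buf = ""
            for ch in w:
                if ch in _PUNCT:
                    if buf:
                        pieces.append(buf)
                        buf = ""
                    pieces.append(ch)
                else:
                    buf += ch
            if buf:
                pieces.append(buf)
        for j, p in enumerate(pieces):
            cur.append(p)
            if p in ".!?":
                nxt = pieces[j + 1] if j + 1 < len(pieces) else None
                if nxt is not None and nxt[:1].isupper():
                    flush()
        flush()  # newline ends a sentence
    return sentences


def corpus_stats(corpus: Corpus) -> pd.DataFrame:
    """Document/token/span counts, one row per concept type plus totals.

    The shape mirrors a descriptive-statistics table: overall document and
    token counts with the number of concept phrases per type.
    """
    per_type = {t: 0 for t in corpus.type_inventory}
    for doc in corpus.documents:
        for sp in doc.spans:
            per_type[sp.ctype] += 1
    rows = [
        {"statistic": "documents", "ctype": "", "count": len(corpus.documents)},
        {"statistic": "tokens", "ctype": "", "count": sum(d.n_tokens for d in corpus.documents)},
    ]
    for t in corpus.type_inventory:
        rows.append({"statistic": "concept_phrases", "ctype": t, "count": per_type[t]})
    return pd.DataFrame(rows)
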