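"""Tag-scheme machinery: spans <-> BIO <-> enriched BMEWO+ labels.

BIO marks each token as Beginning/Inside a typed chunk or Outside.  The
tagger's internal BMEWO+ scheme refines this: B is split into W (single-word
chunk) and B (first word of a multi-word chunk), I into M and E (middle /
end), and O into {B, M, E, W}_O positional variants, where B_O, E_O and W_O
additionally carry the type of the neighbouring chunk.  Sentence boundaries
contribute the pseudo-types BOS and EOS so that every outside position gets
a well-defined label.

Outside-run convention (fixed here and relied on by the transition model):
for a maximal run of outside tokens, the first token is ``B_O_<left>`` where
``<left>`` is the type of the chunk ending just before the run (BOS at the
sentence start), the last token is ``E_O_<right>`` for the chunk starting
just after (EOS at the sentence end), and interior tokens are the untyped
``M_O``.  A run of length one collapses these roles: between two chunks it
becomes ``W_O_<right>`` (conditioned on the *following* chunk), after a
final chunk ``B_O_<left>``, before an initial chunk ``E_O_<right>``, and in
a chunkless one-token sentence ``W_O_EOS``.

All label spellings are plain strings (``B_Problem``, ``E_O_Problem``,
``M_O``) and are stable across model serialization.

Strategy projection (`project_types`) erases the spans of non-target types,
producing the corpus a one-type- or a-few-types-at-a-time model trains on.
"""

from __future__ import annotations

from .corpus_io import AnnotatedDocument, ConceptSpan, Corpus

__all__ = [
    "BOS",
    "EOS",
    "OUTSIDE_KINDS",
    "spans_to_bio",
    "bio_to_spans",
    "bio_to_bmewo_plus",
    "bmewo_plus_to_bio",
    "project_types",
    "label_inventory",
]

BOS = "BOS"
EOS = "EOS"
OUTSIDE_KINDS = ("B_O", "M_O", "E_O", "W_O")


def spans_to_bio(sentence_length: int, spans: list[ConceptSpan]) -> list[str]:
    """Encode non-overlapping spans of one sentence as BIO labels."""
    labels = ["O"] * sentence_length
    ordered = sorted(spans)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping spans {a} and {b}")
    for sp in ordered:
        if sp.end > sentence_length:
            raise ValueError(f"span {sp} exceeds sentence length {sentence_length}")
        labels[sp.start] = f"B_{sp.ctype}"
        for i in range(sp.start + 1, sp.end):
            labels[i] = f"I_{sp.ctype}"
    return labels


def bio_to_spans(labels: list[str], sent_index: int = 0) -> list[ConceptSpan]:
    """Chunk-decode a BIO label sequence (lenient: orphan I starts a chunk)."""
    spans: list[ConceptSpan] = []
    start = None
    ctype = None
    for i, lab in enumerate(labels):
        if lab == "O":
            if ctype is not None:
                spans.append(ConceptSpan(sent_index, start, i, ctype))
                start = ctype = None
        else:
            kind, t = lab.split("_", 1)
            if kind == "B" or ctype != t:
                if ctype is not None:
                    spans.append(ConceptSpan(sent_index, start, i, ctype))
                start, ctype = i, t
    if ctype is not None:
        spans.append(ConceptSpan(sent_index, start, len(labels), ctype))
    return spans


def _chunk_runs(labels: list[str], sent_index: int = 0):
    """Split a sentence labeling into alternating chunk / outside runs.

    Yields ("chunk", start, end, ctype) and ("out", start, end, None).
    """
    spans = bio_to_spans(labels, sent_index)
    pos = 0
    for sp in spans:
        if pos < sp.start:
            yield ("out", pos, sp.start, None)
        yield ("chunk", sp.start, sp.end, sp.ctype)
        pos = sp.end
    if pos < len(labels):
        yield ("out", pos, len(labels), None)


def bio_to_bmewo_plus(labels: list[str]) -> list[str]:
    """Convert a valid BIO sequence to the enriched BMEWO+ representation."""
    for lab in labels:
        if lab != "O" and not lab.startswith(("B_", "I_")):
            raise ValueError(f"not a BIO label: {lab!r}")
    out = [""] * len(labels)
    runs = list(_chunk_runs(labels))
    for k, (kind, start, end, ctype) in enumerate(runs):
        if kind == "chunk":
            if end - start == 1:
                out[start] = f"W_{ctype}"
            else:
                out[start] = f"B_{ctype}"
                for i in range(start + 1, end - 1):
                    out[i] = f"M_{ctype}"
                out[end - 1] = f"E_{ctype}"
        else:
            left = runs[k - 1][3] if k > 0 else BOS
            right = runs[k + 1][3] if k + 1 < len(runs) else EOS
            n = end - start
            if n == 1:
                if left != BOS and right != EOS:
                    out[start] = f"W_O_{right}"
                elif left != BOS:  # run trails the sentence-final chunk
                    out[start] = f"B_O_{left}"
                elif right != EOS:  # run precedes the sentence-initial chunk
                    out[start] = f"E_O_{right}"
                else:  # chunkless one-token sentence
                    out[start] = f"W_O_{EOS}"
            else:
                out[start] = f"B_O_{left}"
                for i in range(start + 1, end - 1):
                    out[i] = "M_O"
                out[end - 1] = f"E_O_{right}"
    return out


def bmewo_plus_to_bio(labels: list[str]) -> list[str]:
    """Total map back to BIO; tolerates inconsistent decoder output.

    B_<t> -> B_<t>, W_<t> -> B_<t>, M_<t> -> I_<t>, E_<t> -> I_<t>,
    every outside kind -> O.
    """
    out = []
    for lab in labels:
        if lab == "M_O" or lab.startswith(("B_O_", "M_O_", "E_O_", "W_O_")):
            out.append("O")
            continue
        kind, t = lab.split("_", 1)
        if kind in ("B", "W"):
            out.append(f"B_{t}")
        elif kind in ("M", "E"):
            out.append(f"I_{t}")
        else:
            raise ValueError(f"not a BMEWO+ label: {lab!r}")
    return out


def project_types(corpus: Corpus, target_types: list[str] | set[str]) -> Corpus:
    """Corpus restricted to the given concept types (strategy projection).

    Tokens are untouched; spans of other types are erased and the inventory
    becomes exactly ``target_types`` (in original inventory order).
    """
    targets = list(dict.fromkeys(target_types))
    if not targets:
        raise ValueError("target_types must be non-empty")
    unknown = set(targets) - set(corpus.type_inventory)
    if unknown:
        raise ValueError(f"unknown concept types: {sorted(unknown)}")
    keep = set(targets)
    docs = [
        AnnotatedDocument(
            d.doc_id, d.sentences, [sp for sp in d.spans if sp.ctype in keep]
        )
        for d in corpus.documents
    ]
    inventory = [t for t in corpus.type_inventory if t in keep]
    return Corpus(documents=docs, type_inventory=inventory)


def label_inventory(type_inventory: list[str], scheme: str = "bio") -> list[str]:
    """Ordered label set for k concept types under a tagging scheme.

    BIO yields 2k+1 labels; BMEWO+ yields the enriched set: 4 in-chunk labels
    per type, M_O, B_O conditioned on each type or BOS, and E_O / W_O
    conditioned on each type or EOS (7k+4 labels in total).
    """
    if not type_inventory:
        raise ValueError("empty type inventory")
    types = list(type_inventory)
    scheme = scheme.lower()
    if scheme == "bio":
        labels = [f"{k}_{t}" for t in types for k in ("B", "I")]
        return labels + ["O"]
    if scheme in ("bmewo+", "bmewo_plus", "bmewoplus"):
        labels = [f"{k}_{t}" for t in types for k in ("B", "M", "E", "W")]
        labels.append("M_O")
        labels += [f"B_O_{x}" for x in types + [BOS]]
        labels += [f"E_O_{x}" for x in types + [EOS]]
        labels += [f"W_O_{x}" for x in types + [EOS]]
        return labels
    raise ValueError(f"unknown scheme {scheme!r}")
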