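"""First-order HMM chunker with character-LM emissions and n-best rescoring.

The tagger follows a two-stage design.  A first-order hidden Markov model
over enriched BMEWO+ labels proposes candidate labelings of each sentence:
transition probabilities come from a smoothed label-bigram model and the
emission probability of a token given a label comes from a per-label
character n-gram language model.  The n best candidates under the HMM are
then rescored by a second layer of character language models -- one model
per concept type over whole chunk surface strings, plus one model over
outside text segments framed with markers encoding the neighbouring chunk
types -- and the best rescored candidate is returned.

Training splits the available sentences 80/20: the HMM is estimated on the
80% part and the rescoring models on the held-out 20% part.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import IO, Sequence

import numpy as np

from .char_lm import CharNGramLM, train_char_lm
from .corpus_io import AnnotatedDocument, ConceptSpan, Corpus, tokenize
from .tag_schemes import (
    BOS,
    EOS,
    bio_to_bmewo_plus,
    bio_to_spans,
    bmewo_plus_to_bio,
    label_inventory,
    spans_to_bio,
)

__all__ = [
    "TaggerConfig",
    "HmmModel",
    "RescoringModel",
    "TaggerModel",
    "Candidate",
    "legal_successors",
    "legal_start",
    "train_hmm",
    "train_rescorer",
    "train_full",
    "viterbi_decode",
    "nbest_decode",
    "rescore",
    "tag",
    "save_model",
    "load_model",
]

START = "<START>"
STOP = "<STOP>"

_NEG_INF = float("-inf")
_FORMAT = "charhmm-tagger"
_FORMAT_VERSION = 1

# Private-use marker characters framing outside segments in the rescorer.
_MARKER_BASE = 0xE000
_MARKER_BOS = chr(0xE0FE)  # ""
_MARKER_EOS = chr(0xE0FF)  # ""


@dataclass
class TaggerConfig:
    """Tunable knobs for training and decoding.

    max_n is the character n-gram order of every language model (token
    emissions and rescoring); nbest_size the number of HMM candidates passed
    to the rescorer; alpha interpolates the HMM base score into the final
    rescored score (0 = pure rescoring, base score breaks ties only);
    trans_smoothing is the add-lambda mass spread over structurally legal
    label bigrams; train_fraction the share of sentences used for the HMM
    (the rest trains the rescorer); seed drives the deterministic split.
    """

    max_n: int = 50
    nbest_size: int = 64
    alpha: float = 0.0
    trans_smoothing: float = 0.01
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.nbest_size < 1:
            raise ValueError("nbest_size must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# structural transition legality


def legal_start(types: Sequence[str]) -> set[str]:
    """Labels that may open a sentence under the BMEWO+ conventions."""
    out = {f"B_{t}" for t in types} | {f"W_{t}" for t in types}
    out.add(f"B_O_{BOS}")  # outside run of length >= 2 at sentence start
    out |= {f"E_O_{t}" for t in types}  # lone outside token before first chunk
    out.add(f"W_O_{EOS}")  # chunkless one-token sentence
    return out


def legal_successors(label: str, types: Sequence[str]) -> set[str]:
    """Labels (or STOP) that may follow ``label`` in a well-formed sentence."""
    chunk_starts = {f"B_{t}" for t in types} | {f"W_{t}" for t in types}
    if label.startswith("B_O_") or label == "M_O" or label.startswith(("E_O_", "W_O_")):
        # outside kinds
        if label == "M_O":
            return {"M_O"} | {f"E_O_{x}" for x in list(types) + [EOS]}
        kind, x = label.split("_O_", 1)
        if kind == "B":
            out = {"M_O"} | {f"E_O_{y}" for y in list(types) + [EOS]}
            if x != BOS:  # lone trailing outside token after a final chunk
                out.add(STOP)
            return out
        if kind == "E":
            return {STOP} if x == EOS else {f"B_{x}", f"W_{x}"}
        # W_O
        return {STOP} if x == EOS else {f"B_{x}", f"W_{x}"}
    kind, t = label.split("_", 1)
    if kind in ("B", "M"):
        return {f"M_{t}", f"E_{t}"}
    if kind in ("E", "W"):
        # a chunk just closed: next chunk, trailing outside run, lone W_O, or end
        out = set(chunk_starts)
        out.add(f"B_O_{t}")
        out |= {f"W_O_{s}" for s in types}
        out.add(STOP)
        return out
    raise ValueError(f"not a BMEWO+ label: {label!r}")


# ---------------------------------------------------------------------------
# models


@dataclass
class HmmModel:
    """HMM over BMEWO+ labels with char-LM emissions."""

    labels: list[str]
    type_inventory: list[str]
    max_n: int
    start_logp: np.ndarray  # (L,)
    trans_logp: np.ndarray  # (L, L)
    stop_logp: np.ndarray  # (L,)
    emission_lms: dict[str, CharNGramLM]
    _emission_cache: dict = field(default_factory=dict, repr=False)

    @property
    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def emission_logp(self, label: str, token: str) -> float:
        key = (label, token)
        cached = self._emission_cache.get(key)
        if cached is None:
            cached = self.emission_lms[label].log_prob(token)
            self._emission_cache[key] = cached
        return cached

    def emission_matrix(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array(
            [[self.emission_logp(lab, tok) for lab in self.labels] for tok in tokens]
        )


@dataclass
class RescoringModel:
    """Second-stage character LMs over chunk strings and outside segments."""

    type_inventory: list[str]
    max_n: int
    chunk_lms: dict[str, CharNGramLM]
    outside_lm: CharNGramLM

    def _marker(self, neighbor: str) -> str:
        if neighbor == BOS:
            return _MARKER_BOS
        if neighbor == EOS:
            return _MARKER_EOS
        return chr(_MARKER_BASE + self.type_inventory.index(neighbor))

    def outside_string(self, segment_tokens: Sequence[str], left: str, right: str) -> str:
        """Outside segment framed with neighbour-type context markers."""
        return self._marker(left) + " ".join(segment_tokens) + self._marker(right)

    def score_labeling(self, tokens: Sequence[str], bmewo_labels: Sequence[str]) -> float:
        """Log score of one candidate labeling of a sentence."""
        bio = bmewo_plus_to_bio(list(bmewo_labels))
        spans = bio_to_spans(bio)
        score = 0.0
        boundaries = []  # (start, end, ctype)
        for sp in spans:
            chunk = " ".join(tokens[sp.start : sp.end])
            score += self.chunk_lms[sp.ctype].log_prob(chunk)
            boundaries.append(sp)
        pos = 0
        prev_type = BOS
        for sp in boundaries:
            if pos < sp.start:
                score += self.outside_lm.log_prob(
                    self.outside_string(tokens[pos : sp.start], prev_type, sp.ctype)
                )
            pos = sp.end
            prev_type = sp.ctype
        if pos < len(tokens):
            score += self.outside_lm.log_prob(
                self.outside_string(tokens[pos:], prev_type, EOS)
            )
        return score


@dataclass
class Candidate:
    """One n-best hypothesis: a BMEWO+ labeling with its scores."""

    labels: list[str]
    base_score: float
    rescored_score: float | None = None


@dataclass
class TaggerModel:
    """Trained two-stage tagger: HMM proposer plus rescorer."""

    base: HmmModel
    rescorer: RescoringModel
    config: TaggerConfig

    @property
    def type_inventory(self) -> list[str]:
        return self.base.type_inventory


# ---------------------------------------------------------------------------
# training


def _labeled_sentences(corpus: Corpus):
    """Yield (tokens, bmewo_labels) for every non-empty sentence."""
    for doc in corpus.documents:
        for si, sent in enumerate(doc.sentences):
            if not sent:
                continue
            bio = spans_to_bio(len(sent), doc.spans_in_sentence(si))
            yield sent, bio_to_bmewo_plus(bio)


def train_hmm(corpus: Corpus, type_inventory: list[str] | None = None, max_n: int = 50,
              trans_smoothing: float = 0.01) -> HmmModel:
    """Estimate transition and emission models from a labeled corpus.

    Transitions are add-lambda smoothed label bigram MLEs restricted to
    structurally legal successors (the union of the BMEWO+ well-formedness
    rules and any bigram actually observed); illegal transitions keep
    probability zero so decoded sequences always map to valid chunkings.
    Emission LMs are per-label character models over the token strings
    carrying that label; a label never observed falls back to a uniform
    ground model over the corpus alphabet.
    """
    types = list(type_inventory) if type_inventory is not None else list(corpus.type_inventory)
    labels = label_inventory(types, "bmewo+")
    idx = {lab: i for i, lab in enumerate(labels)}
    L = len(labels)

    sentences = list(_labeled_sentences(corpus))
    if not sentences:
        raise ValueError("cannot train on an empty corpus")

    start_counts = np.zeros(L)
    trans_counts = np.zeros((L, L))
    stop_counts = np.zeros(L)
    per_label_tokens: dict[str, list[str]] = {lab: [] for lab in labels}
    alphabet: set[str] = set()

    legal_next = {lab: legal_successors(lab, types) for lab in labels}
    start_mask = np.zeros(L, dtype=bool)
    for lab in legal_start(types):
        start_mask[idx[lab]] = True
    trans_mask = np.zeros((L, L), dtype=bool)
    stop_mask = np.zeros(L, dtype=bool)
    for lab in labels:
        for nxt in legal_next[lab]:
            if nxt == STOP:
                stop_mask[idx[lab]] = True
            else:
                trans_mask[idx[lab], idx[nxt]] = True

    for tokens, labs in sentences:
        ids = [idx[l] for l in labs]
        start_counts[ids[0]] += 1
        start_mask[ids[0]] = True
        for a, b in zip(ids, ids[1:]):
            trans_counts[a, b] += 1
            trans_mask[a, b] = True
        stop_counts[ids[-1]] += 1
        stop_mask[ids[-1]] = True
        for tok, lab in zip(tokens, labs):
            per_label_tokens[lab].append(tok)
            alphabet.update(tok)

    lam = trans_smoothing

    def smooth_row(counts: np.ndarray, mask: np.ndarray) -> np.ndarray:
        out = np.full(counts.shape, _NEG_INF)
        sm = counts[mask] + lam
        out[mask] = np.log(sm / sm.sum())
        return out

    # rows: START -> labels; label -> labels+STOP (joint normalization)
    start_logp = smooth_row(start_counts, start_mask)
    trans_logp = np.full((L, L), _NEG_INF)
    stop_logp = np.full(L, _NEG_INF)
    for a in range(L):
        row_mask = np.concatenate([trans_mask[a], [stop_mask[a]]])
        row_counts = np.concatenate([trans_counts[a], [stop_counts[a]]])
        if not row_mask.any():
            # label unreachable under these rules; make STOP legal so rows stay total
            row_mask[-1] = True
        row = smooth_row(row_counts, row_mask)
        trans_logp[a] = row[:L]
        stop_logp[a] = row[L]

    emission_lms = {}
    for lab in labels:
        lm = train_char_lm(per_label_tokens[lab], max_n=max_n)
        if not per_label_tokens[lab]:
            lm.alphabet = set(alphabet)  # uniform ground over the corpus alphabet
        emission_lms[lab] = lm

    return HmmModel(
        labels=labels,
        type_inventory=types,
        max_n=max_n,
        start_logp=start_logp,
        trans_logp=trans_logp,
        stop_logp=stop_logp,
        emission_lms=emission_lms,
    )


def train_rescorer(corpus: Corpus, type_inventory: list[str] | None = None,
                   max_n: int = 50) -> RescoringModel:
    """Train per-type chunk LMs and the context-framed outside-segment LM."""
    types = list(type_inventory) if type_inventory is not None else list(corpus.type_inventory)
    if not list(_labeled_sentences(corpus)):
        raise ValueError("cannot train a rescorer on an empty corpus")
    chunk_strings: dict[str, list[str]] = {t: [] for t in types}
    alphabet: set[str] = set()

    rescorer = RescoringModel(
        type_inventory=types,
        max_n=max_n,
        chunk_lms={},
        outside_lm=CharNGramLM(max_n=max_n),
    )
    outside_strings: list[str] = []
    for doc in corpus.documents:
        for si, sent in enumerate(doc.sentences):
            for tok in sent:
                alphabet.update(tok)
            spans = doc.spans_in_sentence(si)
            pos = 0
            prev_type = BOS
            for sp in spans:
                chunk_strings[sp.ctype].append(" ".join(sent[sp.start : sp.end]))
                if pos < sp.start:
                    outside_strings.append(
                        rescorer.outside_string(sent[pos : sp.start], prev_type, sp.ctype)
                    )
                pos = sp.end
                prev_type = sp.ctype
            if pos < len(sent):
                outside_strings.append(rescorer.outside_string(sent[pos:], prev_type, EOS))

    for t in types:
        lm = train_char_lm(chunk_strings[t], max_n=max_n)
        if not chunk_strings[t]:
            lm.alphabet = set(alphabet)
        rescorer.chunk_lms[t] = lm
    rescorer.outside_lm = train_char_lm(outside_strings, max_n=max_n)
    if not outside_strings:
        rescorer.outside_lm.alphabet = set(alphabet)
    return rescorer


def split_sentences_80_20(corpus: Corpus, config: TaggerConfig) -> tuple[Corpus, Corpus]:
    """Deterministic per-document 80/20 sentence split.

    Within each document, a seeded permutation assigns ceil(0.8 * n) of its
    sentences to the HMM part and the remainder to the rescorer part
    (stratified by document so both parts see every document's style).
    Returns two corpora whose documents contain the selected sentences with
    re-indexed spans.
    """
    rng = np.random.default_rng(config.seed)
    base_docs, res_docs = [], []
    for doc in corpus.documents:
        n = len(doc.sentences)
        order = rng.permutation(n)
        n_base = max(1, math.ceil(config.train_fraction * n)) if n > 1 else 1
        base_set = set(order[:n_base].tolist())

        def build(indices: list[int], suffix: str) -> AnnotatedDocument | None:
            if not indices:
                return None
            remap = {old: new for new, old in enumerate(indices)}
            sents = [doc.sentences[i] for i in indices]
            spans = [
                ConceptSpan(remap[sp.sent_index], sp.start, sp.end, sp.ctype)
                for sp in doc.spans
                if sp.sent_index in remap
            ]
            return AnnotatedDocument(f"{doc.doc_id}{suffix}", sents, spans)

        keep = sorted(base_set)
        rest = sorted(set(range(n)) - base_set)
        d1 = build(keep, "")
        d2 = build(rest, "")
        if d1:
            base_docs.append(d1)
        if d2:
            res_docs.append(d2)
    inv = list(corpus.type_inventory)
    return Corpus(base_docs, inv), Corpus(res_docs, inv)


def train_full(corpus: Corpus, strategy_types: list[str] | None = None,
               config: TaggerConfig | None = None) -> TaggerModel:
    """Train the full two-stage tagger on a (possibly projected) corpus.

    If ``strategy_types`` is given the corpus is first projected onto those
    types (the one-/a-few-types-at-a-time strategies); otherwise the full
    inventory is used (all-types-at-once).
    """
    from .tag_schemes import project_types

    config = config or TaggerConfig()
    if strategy_types is not None:
        corpus = project_types(corpus, strategy_types)
    if corpus.n_sentences < 5:
        raise ValueError("corpus too small for the 80/20 split (need >= 5 sentences)")
    base_part, rescore_part = split_sentences_80_20(corpus, config)
    base = train_hmm(
        base_part,
        corpus.type_inventory,
        max_n=config.max_n,
        trans_smoothing=config.trans_smoothing,
    )
    rescorer = train_rescorer(rescore_part, corpus.type_inventory, max_n=config.max_n)
    return TaggerModel(base=base, rescorer=rescorer, config=config)


# ---------------------------------------------------------------------------
# decoding


def viterbi_decode(model: HmmModel, tokens: Sequence[str]) -> tuple[list[str], float]:
    """Best BMEWO+ labeling of one sentence with its log score.

    Ties break toward the earlier label in the inventory at each argmax.
    """
    if not tokens:
        raise ValueError("empty token sequence")
    E = model.emission_matrix(tokens)
    T, L = E.shape
    delta = model.start_logp + E[0]
    back = np.zeros((T, L), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + model.trans_logp  # (from, to)
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(L)] + E[t]
    final = delta + model.stop_logp
    last = int(np.argmax(final))
    seq = [last]
    for t in range(T - 1, 0, -1):
        seq.append(int(back[t, seq[-1]]))
    seq.reverse()
    return [model.labels[i] for i in seq], float(final[last])


def nbest_decode(model: HmmModel, tokens: Sequence[str], n: int) -> list[Candidate]:
    """Top-n distinct labelings by HMM score, non-increasing; [0] is Viterbi."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not tokens:
        raise ValueError("empty token sequence")
    E = model.emission_matrix(tokens)
    T, L = E.shape
    # scores[l] : up to n best partial scores ending in label l, descending
    scores = np.full((L, n), _NEG_INF)
    scores[:, 0] = model.start_logp + E[0]
    backs: list[np.ndarray] = []  # per t: (L, n, 2) -> (prev label, prev rank)
    for t in range(1, T):
        new_scores = np.full((L, n), _NEG_INF)
        back = np.full((L, n, 2), -1, dtype=int)
        flat = (scores[:, :, None] + model.trans_logp[:, None, :]).reshape(L * n, L)
        for l2 in range(L):
            col = flat[:, l2]
            k = min(n, L * n)
            top = np.argpartition(col, -k)[-k:]
            top = top[np.argsort(col[top])[::-1]]
            vals = col[top]
            keep = vals > _NEG_INF
            top, vals = top[keep], vals[keep]
            m = len(top)
            new_scores[l2, :m] = vals + E[t, l2]
            back[l2, :m, 0] = top // n
            back[l2, :m, 1] = top % n
        scores = new_scores
        backs.append(back)
    final = (scores + model.stop_logp[:, None]).ravel()
    order = np.argsort(final)[::-1][:n]
    out: list[Candidate] = []
    for pos in order:
        sc = float(final[pos])
        if sc == _NEG_INF:
            break
        l, r = int(pos // n), int(pos % n)
        seq = [l]
        for back in reversed(backs):
            l, r = int(back[l, r, 0]), int(back[l, r, 1])
            seq.append(l)
        seq.reverse()
        out.append(Candidate(labels=[model.labels[i] for i in seq], base_score=sc))
    return out


def rescore(candidates: list[Candidate], rescorer: RescoringModel,
            tokens: Sequence[str], alpha: float = 0.0) -> Candidate:
    """Pick the best candidate under the second-stage LM score.

    The active score is rescored + alpha * base; ties go to the earlier
    candidate in the (base-score-ordered) input list, i.e. the higher base
    score.  Candidate order in the input does not otherwise matter.
    """
    if not candidates:
        raise ValueError("no candidates to rescore")
    ordered = sorted(
        range(len(candidates)), key=lambda i: candidates[i].base_score, reverse=True
    )
    best_i, best_key = None, None
    for rank, i in enumerate(ordered):
        cand = candidates[i]
        cand.rescored_score = rescorer.score_labeling(tokens, cand.labels)
        key = (cand.rescored_score + alpha * cand.base_score, -rank)
        if best_key is None or key > best_key:
            best_i, best_key = i, key
    return candidates[best_i]


def tag(model: TaggerModel, text_or_tokens) -> list[ConceptSpan]:
    """Tag raw text, a token matrix, or a document; returns concept spans.

    Per sentence: n-best HMM decoding, rescoring, then BMEWO+ -> BIO -> span
    decoding (so output spans are always valid and non-overlapping).
    """
    if isinstance(text_or_tokens, str):
        sentences = [[t.text for t in sent] for sent in tokenize(text_or_tokens)]
    elif isinstance(text_or_tokens, AnnotatedDocument):
        sentences = text_or_tokens.sentences
    else:
        sentences = list(text_or_tokens)
    spans: list[ConceptSpan] = []
    for si, sent in enumerate(sentences):
        if not sent:
            continue
        cands = nbest_decode(model.base, sent, model.config.nbest_size)
        best = rescore(cands, model.rescorer, sent, alpha=model.config.alpha)
        bio = bmewo_plus_to_bio(best.labels)
        spans.extend(bio_to_spans(bio, si))
    return spans


# ---------------------------------------------------------------------------
# serialization


def save_model(model: TaggerModel, stream: IO[str]) -> None:
    """Write the tagger to a versioned JSON container."""
    payload = {
        "format": _FORMAT,
        "version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "type_inventory": model.base.type_inventory,
        "labels": model.base.labels,
        "start_logp": model.base.start_logp.tolist(),
        "trans_logp": model.base.trans_logp.tolist(),
        "stop_logp": model.base.stop_logp.tolist(),
        "emission_lms": {l: lm.to_dict() for l, lm in model.base.emission_lms.items()},
        "chunk_lms": {t: lm.to_dict() for t, lm in model.rescorer.chunk_lms.items()},
        "outside_lm": model.rescorer.outside_lm.to_dict(),
    }
    json.dump(payload, stream)


def load_model(stream: IO[str]) -> TaggerModel:
    d = json.load(stream)
    if d.get("format") != _FORMAT:
        raise ValueError(f"not a {_FORMAT} container")
    if d.get("version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported version {d.get('version')}")
    config = TaggerConfig(**d["config"])
    base = HmmModel(
        labels=d["labels"],
        type_inventory=d["type_inventory"],
        max_n=config.max_n,
        start_logp=np.array(d["start_logp"]),
        trans_logp=np.array(d["trans_logp"]),
        stop_logp=np.array(d["stop_logp"]),
        emission_lms={l: CharNGramLM.from_dict(x) for l, x in d["emission_lms"].items()},
    )
    rescorer = RescoringModel(
        type_inventory=d["type_inventory"],
        max_n=config.max_n,
        chunk_lms={t: CharNGramLM.from_dict(x) for t, x in d["chunk_lms"].items()},
        outside_lm=CharNGramLM.from_dict(d["outside_lm"]),
    )
    return TaggerModel(base=base, rescorer=rescorer, config=config)
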