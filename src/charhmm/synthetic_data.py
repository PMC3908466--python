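"""Seeded generator of annotated corpora with tagger-exploitable structure.

The generator emulates the statistical shape of annotated concept-mention
corpora (clinical notes with Problem/Test/Treatment phrases; biology
abstracts with Protein/DNA/Cell Type/Cell Line/RNA phrases) at desk scale:
documents of tokenized sentences, 3-5 non-overlapping concept types whose
surface forms carry type-specific character morphology (suffix pools), 1-4
token phrases, and per-type context cue words placed immediately before a
phrase.  Character morphology is the signal the tagger's emission LMs can
learn; cue words are the cross-type context signal that distinguishes the
all-types-at-once strategy from single-type models.

``ambiguity_rate`` injects surface forms shared between the first two
concept types; such forms are only disambiguated by their cue context,
which is the mechanism behind type-confusion errors of single-type models.

All randomness flows from one ``numpy`` generator seeded by the config; the
same config yields byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import AnnotatedDocument, ConceptSpan, Corpus

__all__ = [
    "TypeSpec",
    "GeneratorConfig",
    "GenerationLedger",
    "generate_corpus",
    "ambiguity_scenario",
    "i2b2_like",
    "jnlpba_like",
]

_FILLER_POOL = "aeiounrst"
_FILLER_SIZE = 60


@dataclass(frozen=True)
class TypeSpec:
    """Morphology and abundance of one concept type.

    ``weight`` is the relative abundance of the type among generated spans;
    ``char_pool`` feeds the word stems and ``length_probs`` is the
    phrase-length distribution over 1..4 tokens.  Phrases have a
    modifier+head shape mirroring real concept mentions ("acute
    appendicitis"): the final token of every phrase is a head word ending
    in one of ``suffixes`` and any preceding tokens are modifier words
    ending in one of ``mod_suffixes`` -- both type-specific, which is the
    character signature the emission LMs can learn, including the
    distinction between one multi-token phrase and adjacent single-token
    phrases.  ``cues`` are outside context words placed directly before a
    phrase of this type.
    """

    name: str
    weight: float = 1.0
    vocab_size: int = 40
    suffixes: tuple[str, ...] = ("in",)
    mod_suffixes: tuple[str, ...] = ("ic",)
    char_pool: str = "bcdfgklmnprst"
    length_probs: tuple[float, ...] = (0.45, 0.3, 0.15, 0.1)
    cues: tuple[str, ...] = ()

    def __post_init__(self):
        if self.weight <= 0 or self.vocab_size < 1:
            raise ValueError("weight and vocab_size must be positive")
        if abs(sum(self.length_probs) - 1.0) > 1e-9:
            raise ValueError("length_probs must sum to 1")


@dataclass(frozen=True)
class GeneratorConfig:
    n_docs: int = 50
    sentences_per_doc: tuple[int, int] = (3, 6)
    tokens_per_sentence: tuple[int, int] = (8, 14)
    types: tuple[TypeSpec, ...] = ()
    phrase_rate: float = 1.2  # expected spans per sentence
    ambiguity_rate: float = 0.0
    cue_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not self.types:
            raise ValueError("need at least one concept type")
        if not (0.0 <= self.ambiguity_rate <= 1.0 and 0.0 <= self.cue_prob <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.sentences_per_doc
        if not (1 <= lo <= hi):
            raise ValueError("bad sentences_per_doc range")
        lo, hi = self.tokens_per_sentence
        if not (1 <= lo <= hi):
            raise ValueError("bad tokens_per_sentence range")
        max_phrase = max(len(t.length_probs) for t in self.types)
        if max_phrase + 1 > lo:  # phrase plus a cue must fit the shortest sentence
            raise ValueError(
                f"tokens_per_sentence lower bound {lo} cannot hold a "
                f"{max_phrase}-token phrase with its cue"
            )


@dataclass
class GenerationLedger:
    """Ground-truth bookkeeping emitted alongside a generated corpus."""

    config: GeneratorConfig
    vocabularies: dict[str, list[str]]  # head words per type
    modifier_vocabularies: dict[str, list[str]]
    shared_forms: set[str]
    span_counts: dict[str, int]
    n_tokens: int = 0

    @property
    def shared_fraction(self) -> float:
        all_words = set().union(*self.vocabularies.values())
        return len(self.shared_forms) / len(all_words) if all_words else 0.0


def _make_word(rng: np.random.Generator, pool: str, lo: int = 2, hi: int = 5,
               suffix: str = "") -> str:
    stem = "".join(rng.choice(list(pool), size=int(rng.integers(lo, hi + 1))))
    return stem + suffix


def _build_vocabularies(config: GeneratorConfig, rng: np.random.Generator):
    heads: dict[str, list[str]] = {}
    mods: dict[str, list[str]] = {}
    used: set[str] = set()

    def draw(n: int, pool: str, suffixes: tuple[str, ...]) -> list[str]:
        words: list[str] = []
        while len(words) < n:
            w = _make_word(rng, pool, suffix=str(rng.choice(list(suffixes))))
            if w not in used:
                used.add(w)
                words.append(w)
        return words

    for spec in config.types:
        heads[spec.name] = draw(spec.vocab_size, spec.char_pool, spec.suffixes)
        mods[spec.name] = draw(
            max(4, spec.vocab_size // 2), spec.char_pool, spec.mod_suffixes
        )
    filler: list[str] = []
    while len(filler) < _FILLER_SIZE:
        w = _make_word(rng, _FILLER_POOL, lo=2, hi=6)
        if w not in used:
            used.add(w)
            filler.append(w)
    shared: set[str] = set()
    if config.ambiguity_rate > 0.0 and len(config.types) >= 2:
        # Directional sharing: the second type borrows surface forms that
        # carry the first type's morphology.  This is the shape of real
        # type ambiguity (a non-target phrase that *looks like* the target
        # type), and the setting in which single-type models misdetect
        # non-target phrases while an all-types model can assign them to
        # their true type from context.
        a, b = config.types[0].name, config.types[1].name
        for w in heads[a]:
            if w not in heads[b] and rng.random() < config.ambiguity_rate:
                heads[b].append(w)
                shared.add(w)
    return heads, mods, filler, shared


def _sample_phrase(rng: np.random.Generator, spec: TypeSpec,
                   heads: list[str], mods: list[str]) -> list[str]:
    n = int(rng.choice(np.arange(1, len(spec.length_probs) + 1), p=spec.length_probs))
    return [str(rng.choice(mods)) for _ in range(n - 1)] + [str(rng.choice(heads))]


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GenerationLedger]:
    """Generate a deterministic annotated corpus plus its ledger."""
    rng = np.random.default_rng(config.seed)
    heads, mods, filler, shared = _build_vocabularies(config, rng)
    type_weights = np.array([t.weight for t in config.types], dtype=float)
    type_weights /= type_weights.sum()
    specs = list(config.types)

    ledger = GenerationLedger(
        config=config,
        vocabularies={k: list(v) for k, v in heads.items()},
        modifier_vocabularies={k: list(v) for k, v in mods.items()},
        shared_forms=shared,
        span_counts={t.name: 0 for t in config.types},
    )

    tok_lo, tok_hi = config.tokens_per_sentence
    documents = []
    for d in range(config.n_docs):
        n_sents = int(rng.integers(config.sentences_per_doc[0], config.sentences_per_doc[1] + 1))
        sentences: list[list[str]] = []
        spans: list[ConceptSpan] = []
        for si in range(n_sents):
            target_len = int(rng.integers(tok_lo, tok_hi + 1))
            n_spans = int(min(rng.poisson(config.phrase_rate), 3))
            # sample phrases (with optional cue) until they fit the sentence
            while True:
                picks = []
                budget = 0
                for _ in range(n_spans):
                    spec = specs[int(rng.choice(len(specs), p=type_weights))]
                    phrase = _sample_phrase(rng, spec, heads[spec.name], mods[spec.name])
                    cue = None
                    if spec.cues and rng.random() < config.cue_prob:
                        cue = str(rng.choice(list(spec.cues)))
                    picks.append((spec, cue, phrase))
                    budget += len(phrase) + (1 if cue else 0)
                # leave room for a one-token gap between consecutive spans
                if budget + max(0, n_spans - 1) <= target_len:
                    break
                n_spans -= 1
            n_gaps = n_spans + 1
            spare = target_len - budget
            # inner gaps need >= 1 filler token unless a cue already separates
            gap_min = [0] * n_gaps
            for g in range(1, n_spans):
                if picks[g][1] is None:
                    gap_min[g] = 1
            spare -= sum(gap_min)
            extra = rng.multinomial(max(0, spare), np.ones(n_gaps) / n_gaps)
            tokens: list[str] = []
            for g in range(n_gaps):
                for _ in range(gap_min[g] + int(extra[g])):
                    tokens.append(str(rng.choice(filler)))
                if g < n_spans:
                    spec, cue, phrase = picks[g]
                    if cue:
                        tokens.append(cue)
                    start = len(tokens)
                    tokens.extend(phrase)
                    spans.append(ConceptSpan(si, start, start + len(phrase), spec.name))
                    ledger.span_counts[spec.name] += 1
            sentences.append(tokens)
            ledger.n_tokens += len(tokens)
        documents.append(AnnotatedDocument(f"synth-{config.seed}-{d:04d}", sentences, spans))

    corpus = Corpus(documents=documents, type_inventory=[t.name for t in config.types])
    return corpus, ledger


# ---------------------------------------------------------------------------
# presets


def i2b2_like(seed: int = 0) -> GeneratorConfig:
    """Clinical-note-like preset: 3 concept types with 12 : 7.4 : 8.5 abundance.

    The abundance ratios follow the relative frequency of Problem, Test and
    Treatment phrases in clinical challenge corpora, scaled to ~50 documents.
    """
    return GeneratorConfig(
        n_docs=50,
        types=(
            TypeSpec(
                "Problem", weight=11.968, suffixes=("oma", "itis", "algia"),
                char_pool="bdgmnpr", cues=("reports", "denies"),
            ),
            TypeSpec(
                "Test", weight=7.369, suffixes=("gram", "scopy", "assay"),
                char_pool="cfklst", cues=("underwent", "ordered"),
            ),
            TypeSpec(
                "Treatment", weight=8.500, suffixes=("cillin", "mycin", "olol"),
                char_pool="hjvwz", cues=("given", "started"),
            ),
        ),
        seed=seed,
    )


def jnlpba_like(seed: int = 0) -> GeneratorConfig:
    """Biology-abstract-like preset: 5 types with a ~30:1 abundance spread.

    Relative abundances mirror Protein >> DNA > Cell Type > Cell Line >> RNA,
    the rarest type about 1/30 of the most frequent, scaled to ~50 documents.
    """
    return GeneratorConfig(
        n_docs=50,
        types=(
            TypeSpec(
                "Protein", weight=30.269, suffixes=("ase", "kin"),
                char_pool="bdgmnpr", cues=("binds", "activates"),
            ),
            TypeSpec(
                "DNA", weight=9.530, suffixes=("mer", "box"),
                char_pool="cfklst", cues=("upstream",),
            ),
            TypeSpec(
                "CellType", weight=6.710, suffixes=("cyte", "blast"),
                char_pool="hjvwz", cues=("cultured",),
            ),
            TypeSpec(
                "CellLine", weight=3.830, suffixes=("cell", "clone"),
                char_pool="qxyz", cues=("derived",),
            ),
            TypeSpec(
                "RNA", weight=0.951, suffixes=("rna", "mir"),
                char_pool="aegu", cues=("spliced",),
            ),
        ),
        phrase_rate=1.4,
        seed=seed,
    )


def ambiguity_scenario(seed: int = 0) -> tuple[Corpus, GenerationLedger]:
    """Two-type corpus where ~1/3 of surface forms are shared between types.

    Shared forms are disambiguated only by cue context (a "revealed"-like
    cue precedes TypeA phrases, a "treated"-like cue precedes TypeB
    phrases), so a model trained on one type at a time lacks the evidence
    the all-types model has; this is the setting in which type-confusion
    errors and the strategy gap become observable.
    """
    config = GeneratorConfig(
        n_docs=48,
        sentences_per_doc=(4, 6),
        tokens_per_sentence=(9, 14),
        types=(
            TypeSpec(
                "TypeA", weight=1.0, suffixes=("oma", "itis"),
                mod_suffixes=("ary",), char_pool="bdgmnpr",
                cues=("revealed", "showed"),
            ),
            # cue morphology deliberately disjoint from TypeA's so that the
            # character models can actually tell the two cue families apart
            TypeSpec(
                "TypeB", weight=1.3, suffixes=("ol", "ine"),
                mod_suffixes=("yl",), char_pool="cfklst",
                cues=("upon", "through"),
            ),
        ),
        phrase_rate=1.6,
        ambiguity_rate=0.5,
        cue_prob=0.85,
        seed=seed,
    )
    return generate_corpus(config)
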