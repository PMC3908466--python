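"""Bounded-order character n-gram language model with Witten–Bell smoothing.

The model assigns a probability to a string as a product of per-character
conditional probabilities, each conditioned on up to ``max_n - 1`` preceding
characters (the string is framed with a BEGIN sentinel and terminated by an
END event).  Conditionals are smoothed by recursive Witten–Bell
interpolation

    P(c | ctx) = lam(ctx) * MLE(c | ctx) + (1 - lam(ctx)) * P(c | ctx[1:])

with lam(ctx) = N(ctx) / (N(ctx) + D(ctx)), where N is the number of events
observed after ``ctx`` and D the number of distinct continuation symbols.
The recursion grounds at the uniform distribution over the observed
alphabet plus the reserved UNK and END symbols, so every string over any
alphabet receives strictly positive probability.

These models serve three roles in the tagger: per-label emission models over
token strings, per-type rescoring models over chunk surface strings, and an
outside-text rescoring model over context-framed outside segments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import IO, Iterable

__all__ = ["BEGIN", "END", "UNK", "CharNGramLM", "train_char_lm"]

# Reserved symbols; chosen from Unicode noncharacters so they cannot collide
# with trainable text.
BEGIN = "﷐"
END = "﷑"
UNK = "﷒"

_FORMAT = "charhmm-charlm"
_FORMAT_VERSION = 1


@dataclass
class CharNGramLM:
    """Smoothed character n-gram model of bounded order ``max_n``."""

    max_n: int = 50
    # context string -> {symbol -> count}; "" is the unigram context
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    alphabet: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.max_n < 1:
            raise ValueError("max_n must be >= 1")

    # -- training ---------------------------------------------------------

    def add(self, string: str) -> None:
        """Accumulate counts for all k-grams (k <= max_n) of one string."""
        self.alphabet.update(string)
        padded = BEGIN + string
        events = list(string) + [END]
        for i, sym in enumerate(events):
            ctx = padded[max(0, i + 1 - (self.max_n - 1)) : i + 1] if self.max_n > 1 else ""
            # count the event under every suffix order, down to the empty context
            for k in range(len(ctx) + 1):
                bucket = self.counts.setdefault(ctx[k:], {})
                bucket[sym] = bucket.get(sym, 0) + 1

    # -- probabilities ----------------------------------------------------

    @property
    def _n_ground(self) -> int:
        return len(self.alphabet) + 2  # + UNK + END

    def conditional_prob(self, char: str, context: str = "") -> float:
        """P(char | context) under recursive Witten–Bell interpolation.

        ``char`` is a single character, or the END / UNK sentinel.  Only the
        final ``max_n - 1`` characters of ``context`` are used.  Characters
        outside the alphabet are mapped to UNK.
        """
        if char not in (END, UNK) and char not in self.alphabet:
            char = UNK
        ctx = context[-(self.max_n - 1) :] if self.max_n > 1 else ""
        p = 1.0 / self._n_ground
        # evaluate from the empty context up to the longest suffix
        for k in range(len(ctx), -1, -1):
            bucket = self.counts.get(ctx[k:])
            if not bucket:
                continue
            total = sum(bucket.values())
            distinct = len(bucket)
            lam = total / (total + distinct)
            p = lam * (bucket.get(char, 0) / total) + (1.0 - lam) * p
        return p

    def log_prob(self, string: str) -> float:
        """Natural-log probability of ``string`` (BEGIN-framed, END-closed)."""
        padded = BEGIN + string
        logp = 0.0
        for i, sym in enumerate(list(string) + [END]):
            logp += math.log(self.conditional_prob(sym, padded[: i + 1]))
        return logp

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": _FORMAT,
            "version": _FORMAT_VERSION,
            "max_n": self.max_n,
            "alphabet": "".join(sorted(self.alphabet)),
            "counts": self.counts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CharNGramLM":
        if d.get("format") != _FORMAT:
            raise ValueError(f"not a {_FORMAT} container")
        if d.get("version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported version {d.get('version')}")
        return cls(
            max_n=d["max_n"],
            counts={c: dict(b) for c, b in d["counts"].items()},
            alphabet=set(d["alphabet"]),
        )

    def save(self, stream: IO[str]) -> None:
        json.dump(self.to_dict(), stream)

    @classmethod
    def load(cls, stream: IO[str]) -> "CharNGramLM":
        return cls.from_dict(json.load(stream))


def train_char_lm(strings: Iterable[str], max_n: int = 50) -> CharNGramLM:
    """Train a character LM on a collection of strings.

    An empty collection yields the ground (uniform-over-UNK/END) model; an
    ``max_n`` below 1 is rejected.
    """
    model = CharNGramLM(max_n=max_n)
    for s in strings:
        model.add(s)
    return model
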