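"""Deterministic FTR-type classification.

Given a sentence already judged to make future time reference, assign it
to tense/modal semantic categories by closed-vocabulary keyword
matching.  The rules, in order:

1. *Exclusions.*  Negated sentences are excluded (negators flip modal
   polarity, so keyword matching cannot recover the intended certainty),
   then "mixed-modal" sentences containing both high- and low-certainty
   keywords (no principled way to pick the class criterion).
2. *Dominance.*  Modal categories dominate tense: if any modal keyword
   is present, the matching modal flags are set and both tense flags are
   zero ("It will possibly rain tomorrow" is other-low-certainty, not
   also future tense).
3. *Tense.*  Otherwise a future-tense keyword sets ``future_tense``;
   failing that the sentence is residual ``present_tense`` ("tomorrow it
   rains").

Modal concord — a low-certainty modal verb together with a low-certainty
modifier ("It could probably rain tomorrow") — legitimately sets both
low-certainty flags.  Every category is a dichotomous 0/1 flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .lexicon import (
    HIGH_CERTAINTY,
    LOW_CERTAINTY,
    MODAL_CATEGORIES,
    TYPE_CATEGORIES,
    ModalLexicon,
    tokenize,
)

EXCLUSION_REASONS = ("none", "negation", "mixed_modal")


@dataclass(frozen=True)
class FTRTypeLabelSet:
    """Dichotomous flags over the tense/modal categories plus exclusion status."""

    flags: Mapping[str, int]
    excluded: int = 0
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if set(self.flags) != set(TYPE_CATEGORIES):
            raise ValueError("flags must cover exactly the type categories")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.excluded:
            if any(self.flags.values()):
                raise ValueError("excluded sentences carry no category flags")
            if self.exclusion_reason == "none":
                raise ValueError("excluded requires a reason")
        else:
            if not any(self.flags.values()):
                raise ValueError("non-excluded sentences must carry >=1 flag")
            if self.flags["future_tense"] and self.flags["present_tense"]:
                raise ValueError("future and present tense are mutually exclusive")
            if any(self.flags[c] for c in MODAL_CATEGORIES) and (
                    self.flags["future_tense"] or self.flags["present_tense"]):
                raise ValueError("modal flags dominate tense flags")

    def __getitem__(self, category: str) -> int:
        return self.flags[category]

    def active(self) -> tuple[str, ...]:
        return tuple(c for c in TYPE_CATEGORIES if self.flags[c])


def detect_negation(sentence_text: str, lexicon: ModalLexicon | None = None) -> int:
    """1 iff any negation keyword is present as a token (after contraction expansion)."""
    lexicon = lexicon or ModalLexicon.default()
    return int(lexicon.has_negation(tokenize(sentence_text)))


def detect_mixed_modal(sentence_text: str, lexicon: ModalLexicon | None = None) -> int:
    """1 iff the sentence carries both a high- and a low-certainty keyword."""
    lexicon = lexicon or ModalLexicon.default()
    tokens = tokenize(sentence_text)
    has_low = any(lexicon.matches(tokens, c) for c in LOW_CERTAINTY)
    has_high = any(lexicon.matches(tokens, c) for c in HIGH_CERTAINTY)
    return int(has_low and has_high)


def _zero_flags() -> dict[str, int]:
    return {c: 0 for c in TYPE_CATEGORIES}


def classify_ftr_type(sentence_text: str,
                      lexicon: ModalLexicon | None = None) -> FTRTypeLabelSet:
    """Classify one future-referring sentence into the tense/modal categories.

    The caller is responsible for having established future time
    reference first; this stage does not re-check it.
    """
    lexicon = lexicon or ModalLexicon.default()
    tokens = tokenize(sentence_text)

    if lexicon.has_negation(tokens):
        return FTRTypeLabelSet(_zero_flags(), excluded=1, exclusion_reason="negation")

    matched = lexicon.matched_categories(tokens)
    if (matched & set(LOW_CERTAINTY)) and (matched & set(HIGH_CERTAINTY)):
        return FTRTypeLabelSet(_zero_flags(), excluded=1, exclusion_reason="mixed_modal")

    flags = _zero_flags()
    modal = matched & set(MODAL_CATEGORIES)
    if modal:
        for cat in modal:
            flags[cat] = 1
    elif "future_tense" in matched:
        flags["future_tense"] = 1
    else:
        flags["present_tense"] = 1
    return FTRTypeLabelSet(flags)


def proportions_by_type(labelsets: Iterable[FTRTypeLabelSet]) -> dict[str, float]:
    """Per-type proportions normalised to sum to 1.

    For each category k the raw value is the mean of its flag over the
    (non-excluded) label sets; the vector of means is then renormalised
    to sum to one.  Excluded label sets must be removed beforehand.
    """
    labelsets = list(labelsets)
    if not labelsets:
        raise ValueError("cannot compute proportions of an empty group")
    if any(ls.excluded for ls in labelsets):
        raise ValueError("excluded label sets must be filtered out first")
    n = len(labelsets)
    means = {c: sum(ls[c] for ls in labelsets) / n for c in TYPE_CATEGORIES}
    total = sum(means.values())
    return {c: v / total for c, v in means.items()}
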