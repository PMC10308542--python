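"""The closed-vocabulary modal/tense lexicon and its tokenizer.

The FTR-type stage classifies future-referring sentences by the presence
of keywords from fixed semantic categories: tense (future/present) and
modal semantics (epistemic certainty, deontic obligation, bouletic
desire, irrealis conditionality).  Matching is case-insensitive on token
boundaries; multi-word keys match as contiguous token sequences, and a
contraction table is expanded first so that negators and modals inside
contractions ("won't" = will + not) are visible to the matcher.

The shipped default lexicon is a documented, versioned superset of the
canonical exemplars for each category and is fully overridable from a
YAML/JSON config.  The ``verbal_high_certainty`` slot exists for
completeness but ships EMPTY: no defensible default trigger set exists
for it, so it never fires unless configured.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import yaml

LEXICON_VERSION = "1.0"

#: Category names in canonical order.  The first two are tense
#: categories; the rest are modal and dominate tense.
TENSE_CATEGORIES = ("future_tense", "present_tense")
MODAL_CATEGORIES = (
    "verbal_low_certainty",
    "other_low_certainty",
    "other_high_certainty",
    "verbal_high_certainty",
    "deontic",
    "bouletic",
    "irrealis",
)
TYPE_CATEGORIES = TENSE_CATEGORIES + MODAL_CATEGORIES

LOW_CERTAINTY = ("verbal_low_certainty", "other_low_certainty")
HIGH_CERTAINTY = ("other_high_certainty", "verbal_high_certainty")

_DEFAULT_KEYWORDS: dict[str, list[str]] = {
    # matched only when no modal keyword is present (dominance)
    "future_tense": [
        "will", "shall",
        "am going to", "is going to", "are going to", "was going to",
        "were going to", "be going to", "been going to", "being going to",
    ],
    # residual: no keywords; fires when nothing else does
    "present_tense": [],
    "verbal_low_certainty": ["could", "may", "might", "should"],
    "other_low_certainty": [
        "possibly", "probably", "potentially", "possible", "probable",
        "possibility", "perhaps", "maybe", "likely",
        "i think", "i guess", "i suppose", "i reckon",
    ],
    "other_high_certainty": [
        "definitely", "certainly", "absolutely", "certain", "definite",
        "surely", "for sure", "undoubtedly", "without a doubt",
    ],
    "verbal_high_certainty": [],  # intentionally empty; see module docstring
    "deontic": [
        "must",
        "have to", "has to", "had to", "having to",
        "need to", "needs to", "needed to", "needing to",
    ],
    "bouletic": [
        "hope", "hopes", "hoped", "hoping",
        "want", "wants", "wanted", "wanting",
        "wish", "wishes", "wished", "wishing",
        "would like to",
    ],
    "irrealis": ["if", "would"],
}

_DEFAULT_NEGATION = [
    "not", "never", "cannot", "none", "nothing", "nobody", "neither", "nor",
]

#: Contractions expanded before matching so the underlying modal/negator
#: is visible.  "'d" is read as *would* (the irrealis/conditional use);
#: perfective "'d" (= had) is rare in future-referring text.
CONTRACTIONS: dict[str, list[str]] = {
    "won't": ["will", "not"],
    "shan't": ["shall", "not"],
    "can't": ["can", "not"],
    "cannot": ["can", "not"],
    "ain't": ["is", "not"],
    "i'll": ["i", "will"], "you'll": ["you", "will"], "he'll": ["he", "will"],
    "she'll": ["she", "will"], "it'll": ["it", "will"], "we'll": ["we", "will"],
    "they'll": ["they", "will"], "that'll": ["that", "will"],
    "there'll": ["there", "will"],
    "i'd": ["i", "would"], "you'd": ["you", "would"], "he'd": ["he", "would"],
    "she'd": ["she", "would"], "it'd": ["it", "would"], "we'd": ["we", "would"],
    "they'd": ["they", "would"],
    "i'm": ["i", "am"], "you're": ["you", "are"], "we're": ["we", "are"],
    "they're": ["they", "are"], "it's": ["it", "is"], "he's": ["he", "is"],
    "she's": ["she", "is"], "that's": ["that", "is"], "there's": ["there", "is"],
    "i've": ["i", "have"], "you've": ["you", "have"], "we've": ["we", "have"],
    "they've": ["they", "have"],
}

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?")


def tokenize(text: str) -> list[str]:
    """Lowercase, NFC-normalize, split on punctuation, expand contractions."""
    text = unicodedata.normalize("NFC", text).lower().replace("’", "'")
    out: list[str] = []
    for tok in _TOKEN_RE.findall(text):
        if tok in CONTRACTIONS:
            out.extend(CONTRACTIONS[tok])
        elif tok.endswith("n't"):
            out.extend([tok[:-3], "not"])
        elif tok.endswith("'ll"):
            out.extend([tok[:-3], "will"])
        elif tok.endswith("'d"):
            out.extend([tok[:-2], "would"])
        elif "'" in tok:
            out.append(tok.split("'")[0])
        else:
            out.append(tok)
    return out


@dataclass(frozen=True)
class ModalLexicon:
    """Keyword lists per category plus the negation list.

    ``keywords`` maps each category in :data:`TYPE_CATEGORIES` to its
    surface forms (multi-word keys are token sequences).  No key may
    appear in two categories.
    """

    keywords: dict[str, tuple[tuple[str, ...], ...]]
    negation: tuple[tuple[str, ...], ...]
    version: str = LEXICON_VERSION

    def __post_init__(self) -> None:
        unknown = set(self.keywords) - set(TYPE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown lexicon categories: {sorted(unknown)}")
        seen: dict[tuple[str, ...], str] = {}
        for cat, keys in self.keywords.items():
            for key in keys:
                if key in seen:
                    raise ValueError(
                        f"keyword {' '.join(key)!r} in both {seen[key]} and {cat}")
                seen[key] = cat

    @classmethod
    def from_lists(cls, keywords: dict[str, list[str]],
                   negation: list[str], version: str = LEXICON_VERSION) -> "ModalLexicon":
        kw = {cat: tuple(tuple(tokenize(k)) for k in keywords.get(cat, []))
              for cat in TYPE_CATEGORIES}
        neg = tuple(tuple(tokenize(k)) for k in negation)
        return cls(keywords=kw, negation=neg, version=version)

    @classmethod
    def default(cls) -> "ModalLexicon":
        return cls.from_lists(_DEFAULT_KEYWORDS, _DEFAULT_NEGATION)

    @classmethod
    def from_config(cls, path: str | Path) -> "ModalLexicon":
        """Load a lexicon override from a YAML or JSON config file.

        The config maps category names to keyword lists and may carry a
        ``negation`` list and a ``version`` string; omitted categories
        fall back to the shipped defaults.
        """
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) if Path(path).suffix in (".yaml", ".yml") \
                else json.load(fh)
        keywords = {cat: data.get(cat, _DEFAULT_KEYWORDS[cat]) for cat in TYPE_CATEGORIES}
        return cls.from_lists(
            keywords,
            data.get("negation", _DEFAULT_NEGATION),
            version=str(data.get("version", LEXICON_VERSION)),
        )

    def matches(self, tokens: list[str], category: str) -> bool:
        return any(_contains(tokens, key) for key in self.keywords[category])

    def matched_categories(self, tokens: list[str]) -> set[str]:
        return {cat for cat in TYPE_CATEGORIES if self.matches(tokens, cat)}

    def has_negation(self, tokens: list[str]) -> bool:
        return any(_contains(tokens, key) for key in self.negation)


def _contains(tokens: list[str], key: tuple[str, ...]) -> bool:
    if not key:
        return False
    k = len(key)
    first = key[0]
    for i, tok in enumerate(tokens):
        if tok == first and tuple(tokens[i:i + k]) == key:
            return True
    return False
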