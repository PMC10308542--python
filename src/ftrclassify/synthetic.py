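"""Seeded synthetic-data generators.

Every input the pipeline needs can be generated with known ground
truth: template sentences whose time-reference and FTR-type labels are
known by construction, posts with temporal expressions planted at known
day offsets, simulated intertemporal choosers with a known discount
rate, and simulated survey participants following a known two-equation
mediation structure.  All generators are pure functions of their
arguments plus a seed.

Template texts deliberately mix in distractor tokens that are absent
from the modal lexicon, so the trainable time-reference stage cannot
succeed by memorising the FTR-type keywords alone.

The ``verbal_high_certainty`` category ships with an empty lexicon, so
no default template can plant it; it is covered only under a custom
lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Post
from .discounting import ChoiceItem, generate_battery
from .lexicon import TYPE_CATEGORIES

# ---------------------------------------------------------------------------
# Labeled sentences

@dataclass(frozen=True)
class LabeledSentence:
    """A generated sentence with its ground-truth labels."""

    text: str
    time_ref: str                      # FTR | PTR | OTHER
    flags: Mapping[str, int] | None    # FTR-type flags; None for non-FTR
    excluded: int = 0
    exclusion_reason: str = "none"
    category: str = ""
    planted_offset_days: int | None = None


_SUBJECTS = ["it", "the show", "the storm", "the game", "the meeting", "our flight"]
_VERBS = ["rain", "snow", "start", "end", "begin", "happen"]
#: (surface form, deterministic day offset or None)
_FUTURE_ADVS = [("tomorrow", 1), ("next week", 7), ("in three days", 3),
                ("in two weeks", 14), ("in five days", 5)]
_PAST_ADVS = [("yesterday", -1), ("last week", -7), ("two days ago", -2),
              ("four days ago", -4), ("in the past", None)]
_DISTRACTORS = ["honestly", "frankly", "anyway", "basically", "apparently", ""]

_VLOW = ["could", "may", "might", "should"]
_OLOW = ["possibly", "probably", "potentially", "perhaps"]
_OHIGH = ["definitely", "certainly", "absolutely", "surely"]
_BOUL = [("i hope", "rains"), ("i want", "to rain"), ("she hopes", "rains"),
         ("they want", "to rain")]
_DEON_OPEN = [("you must", "come"), ("i have to", "travel"),
              ("she needs to", "pack"), ("we need to", "leave")]

GENERATOR_CATEGORIES = (
    "future_tense", "present_tense", "verbal_low_certainty",
    "other_low_certainty", "other_high_certainty", "deontic", "bouletic",
    "irrealis", "concord", "negation_excluded", "mixed_modal_excluded",
    "PTR", "OTHER",
)


def _flags(*active: str) -> dict[str, int]:
    return {c: int(c in active) for c in TYPE_CATEGORIES}


def _render(rng: np.random.Generator, category: str) -> LabeledSentence:
    subj = rng.choice(_SUBJECTS)
    verb = rng.choice(_VERBS)
    adv, offset = _FUTURE_ADVS[rng.integers(len(_FUTURE_ADVS))]
    dist = rng.choice(_DISTRACTORS)
    lead = f"{dist} " if dist else ""

    if category == "future_tense":
        aux = rng.choice(["will", "shall", "is going to"])
        text = f"{lead}{subj} {aux} {verb} {adv}"
        return LabeledSentence(text, "FTR", _flags("future_tense"),
                               category=category, planted_offset_days=offset)
    if category == "present_tense":
        text = f"{lead}{adv} {subj} {verb}s"
        return LabeledSentence(text, "FTR", _flags("present_tense"),
                               category=category, planted_offset_days=offset)
    if category == "verbal_low_certainty":
        text = f"{lead}{subj} {rng.choice(_VLOW)} {verb} {adv}"
        return LabeledSentence(text, "FTR", _flags("verbal_low_certainty"),
                               category=category, planted_offset_days=offset)
    if category == "other_low_certainty":
        text = f"{lead}{subj} will {rng.choice(_OLOW)} {verb} {adv}"
        return LabeledSentence(text, "FTR", _flags("other_low_certainty"),
                               category=category, planted_offset_days=offset)
    if category == "other_high_certainty":
        text = f"{lead}{subj} will {rng.choice(_OHIGH)} {verb} {adv}"
        return LabeledSentence(text, "FTR", _flags("other_high_certainty"),
                               category=category, planted_offset_days=offset)
    if category == "deontic":
        opener, v = _DEON_OPEN[rng.integers(len(_DEON_OPEN))]
        text = f"{lead}{opener} {v} {adv}"
        return LabeledSentence(text, "FTR", _flags("deontic"),
                               category=category, planted_offset_days=offset)
    if category == "bouletic":
        opener, v = _BOUL[rng.integers(len(_BOUL))]
        text = f"{lead}{opener} it {v} {adv}"
        return LabeledSentence(text, "FTR", _flags("bouletic"),
                               category=category, planted_offset_days=offset)
    if category == "irrealis":
        text = f"{lead}if {subj} {verb}s {adv}, that is fine"
        return LabeledSentence(text, "FTR", _flags("irrealis"),
                               category=category, planted_offset_days=offset)
    if category == "concord":
        text = f"{lead}{subj} {rng.choice(_VLOW)} {rng.choice(_OLOW)} {verb} {adv}"
        return LabeledSentence(
            text, "FTR", _flags("verbal_low_certainty", "other_low_certainty"),
            category=category, planted_offset_days=offset)
    if category == "negation_excluded":
        form = rng.choice([f"{subj} will not {verb} {adv}",
                           f"{subj} won't {verb} {adv}",
                           f"{subj} is never going to {verb} {adv}"])
        return LabeledSentence(f"{lead}{form}", "FTR", None, excluded=1,
                               exclusion_reason="negation", category=category,
                               planted_offset_days=offset)
    if category == "mixed_modal_excluded":
        text = (f"{lead}there is {rng.choice(_OHIGH)} a possibility "
                f"of {rng.choice(['rain', 'snow'])} {adv}")
        return LabeledSentence(text, "FTR", None, excluded=1,
                               exclusion_reason="mixed_modal", category=category,
                               planted_offset_days=offset)
    if category == "PTR":
        padv, poffset = _PAST_ADVS[rng.integers(len(_PAST_ADVS))]
        pverb = rng.choice(["rained", "snowed", "started", "ended", "happened",
                            "finished", "closed", "arrived"])
        text = f"{lead}{subj} {pverb} {padv}"
        return LabeledSentence(text, "PTR", None, category=category,
                               planted_offset_days=poffset)
    if category == "OTHER":
        text = rng.choice([
            "the sun is hot", "the office is big", "water is wet",
            "she is at work", "the building is tall", "i like tea",
            "it can rain a lot here", "they are friendly",
            "the coffee tastes bitter", "he lives near the park",
            "the room feels cold", "cats sleep a lot",
        ])
        return LabeledSentence(f"{lead}{text}", "OTHER", None, category=category)
    raise ValueError(f"unknown template category {category!r}")


def generate_labeled_sentences(n_per_category: int, seed: int = 0) -> list[LabeledSentence]:
    """A balanced labeled corpus: ``n_per_category`` sentences for each
    template category (8 FTR-type flags, concord, both exclusion cases,
    PTR and OTHER)."""
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    rng = np.random.default_rng(seed)
    return [_render(rng, cat)
            for cat in GENERATOR_CATEGORIES for _ in range(n_per_category)]


# ---------------------------------------------------------------------------
# Timed posts

@dataclass(frozen=True)
class TimedPost:
    post: Post
    offsets: tuple[int, ...]
    expected_H: float


def _offset_surface(offset: int) -> str:
    if offset == 0:
        return "today"
    if offset == 1:
        return "tomorrow"
    if offset == -1:
        return "yesterday"
    if offset > 1:
        return f"in {offset} days"
    return f"{-offset} days ago"


def generate_timed_posts(n: int, offsets: Sequence[int], seed: int = 0) -> list[TimedPost]:
    """Posts whose single sentence embeds temporal expressions at the
    requested day offsets; the horizon pipeline must recover their mean
    exactly.  Anchors are noon-UTC dates drawn from the seed."""
    offs = tuple(int(o) for o in offsets)
    if not offs:
        raise ValueError("at least one offset required")
    for o in offsets:
        if int(o) != o:
            raise ValueError(f"offset {o!r} not resolvable by the rule inventory")
    rng = np.random.default_rng(seed)
    base = datetime(2020, 1, 1, 12, 0, tzinfo=timezone.utc)
    posts = []
    for i in range(n):
        anchor = base + timedelta(days=int(rng.integers(0, 365)))
        phrases = " and ".join(_offset_surface(o) for o in offs)
        text = f"We meet {phrases}."
        post = Post(post_id=f"tp{i}", author_id=f"a{i}", text=text,
                    posted_at=anchor, condition="unlabeled")
        posts.append(TimedPost(post, offs, float(np.mean(offs))))
    return posts


# ---------------------------------------------------------------------------
# Simulated choosers

def simulate_choices(k_true: float, epsilon: float = 0.0, seed: int = 0,
                     battery: Sequence[ChoiceItem] | None = None) -> np.ndarray:
    """Responses to the 110-item battery from a hyperbolic chooser.

    The deterministic choice is 1 iff LLR/(1 + k_true D) > SSR; each
    response is then flipped independently with probability ``epsilon``
    (stated choice noise, 0 <= eps < 0.5).
    """
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    if not 0 <= epsilon < 0.5:
        raise ValueError("epsilon must lie in [0, 0.5)")
    if battery is None:
        battery = generate_battery()
    D = np.array([it.delay_days for it in battery])
    ssr = np.array([it.ssr for it in battery])
    llr = np.array([it.llr for it in battery])
    choices = (llr / (1.0 + k_true * D) > ssr).astype(np.int8)
    if epsilon > 0:
        rng = np.random.default_rng(seed)
        flips = rng.random(len(battery)) < epsilon
        choices = np.where(flips, 1 - choices, choices).astype(np.int8)
    return choices


# ---------------------------------------------------------------------------
# Simulated survey participants

#: Defaults emulate a realistic online-survey sample: DASS anxiety
#: mean 4.4 / SD 7.07, depression mean 6.86 / SD 9.66; intercepts 28.25
#: and -4.41; path sizes giving an anxiety indirect effect of 0.04 and
#: total effect of 0.08 on the ln(k) scale.
STUDY2_DEFAULTS = dict(
    alpha1=1.0, alpha2=0.0, beta=0.04, tau1=0.04, tau2=0.0,
    lambda1=28.25, lambda2=-4.41, rho=0.5,
    anx_mean=4.4, anx_sd=7.07, dep_mean=6.86, dep_sd=9.66,
    sigma1=14.0, sigma2=2.0,
)


def simulate_study2(n: int, seed: int = 0, **params) -> pd.DataFrame:
    """Simulate survey participants with a planted mediation structure.

    Anxiety and depression are discretized bivariate normals (clipped to
    the 0-42 DASS range, correlation ``rho``); the mediator M and
    outcome Y = ln(k) follow the two planted linear equations with
    Gaussian errors ``sigma1``/``sigma2`` applied to the *observed*
    (discretized) scores — so with zero noise the fitted paths equal the
    planted ones exactly.  The planted parameters are stored in
    ``DataFrame.attrs['params']``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    p = {**STUDY2_DEFAULTS, **params}
    unknown = set(params) - set(STUDY2_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown parameters {sorted(unknown)}")
    if not -1 < p["rho"] < 1:
        raise ValueError("rho must lie in (-1, 1)")

    rng = np.random.default_rng(seed)
    cov = np.array([[p["anx_sd"] ** 2, p["rho"] * p["anx_sd"] * p["dep_sd"]],
                    [p["rho"] * p["anx_sd"] * p["dep_sd"], p["dep_sd"] ** 2]])
    latent = rng.multivariate_normal([p["anx_mean"], p["dep_mean"]], cov, size=n)
    anx = np.clip(np.rint(latent[:, 0]), 0, 42)
    dep = np.clip(np.rint(latent[:, 1]), 0, 42)

    e1 = rng.normal(0, p["sigma1"], n) if p["sigma1"] > 0 else 0.0
    e2 = rng.normal(0, p["sigma2"], n) if p["sigma2"] > 0 else 0.0
    M = p["lambda1"] + p["alpha1"] * anx + p["alpha2"] * dep + e1
    Y = p["lambda2"] + p["tau1"] * anx + p["tau2"] * dep + p["beta"] * M + e2

    df = pd.DataFrame({
        "participant_id": [f"p{i:04d}" for i in range(n)],
        "anxiety": anx, "depression": dep,
        "mean_subj_dist": M, "log_k": Y,
    })
    df.attrs["params"] = p
    return df
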