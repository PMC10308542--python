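"""Trainable sentence-level time-reference classification.

A single three-way model over {FTR, PTR, OTHER}: future time reference,
past time reference, and the residual class (anything that refers to
neither — statements of fact, ability, present states).  Annotation is
semantic, not formal: "It rains tomorrow" is FTR despite its present
tense, and "He could run a 4-minute mile in his 20s" is PTR despite the
modal.

The model is a bag-of-n-grams (1-2) L2-regularized multinomial logistic
regression: contract-equivalent scalar class probabilities, convex
optimisation to tolerance, fully reproducible under a fixed seed.
p_ftr and p_ptr are the softmax masses of the FTR and PTR classes, and
the binary flags split at 0.5:  is_ftr = 1 iff p_ftr >= 0.5 (and
likewise for PTR).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus import Sentence

logger = logging.getLogger(__name__)

LABELS = ("FTR", "PTR", "OTHER")
DECISIONS = ("accept", "reject", "ignore")


@dataclass(frozen=True)
class AnnotatedExample:
    """A labeled training sentence; ``ignore`` examples are excluded."""

    text: str
    target_label: str  # FTR | PTR | OTHER
    decision: str = "accept"

    def __post_init__(self) -> None:
        if self.target_label not in LABELS:
            raise ValueError(f"unknown label {self.target_label!r}")
        if self.decision not in DECISIONS:
            raise ValueError(f"unknown decision {self.decision!r}")

    @property
    def effective_label(self) -> str:
        """Merged three-class label: accept keeps the annotated label,
        reject maps to the residual OTHER class."""
        return self.target_label if self.decision == "accept" else "OTHER"


@dataclass(frozen=True)
class TimeRefPrediction:
    sentence_ref: str
    p_ftr: float
    p_ptr: float

    @property
    def is_ftr(self) -> int:
        return int(self.p_ftr >= 0.5)

    @property
    def is_ptr(self) -> int:
        return int(self.p_ptr >= 0.5)


@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion counts and the four derived proportions.

    accuracy = (tp+tn)/(tp+fp+fn+tn); precision = tp/(tp+fp);
    recall = tp/(tp+fn); F1 = 2rp/(r+p).  A ratio with a zero
    denominator is reported as None (absent), never as 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def accuracy(self) -> float | None:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * r * p / (r + p)


class TimeReferenceModel:
    """Vocabulary + softmax weights; picklable-free JSON persistence."""

    def __init__(self, vectorizer: CountVectorizer, clf: LogisticRegression):
        self.vectorizer = vectorizer
        self.clf = clf

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        """(n, 3) probabilities in LABELS order."""
        X = self.vectorizer.transform(texts)
        proba = self.clf.predict_proba(X)
        classes = list(self.clf.classes_)
        out = np.zeros((proba.shape[0], len(LABELS)))
        for j, lab in enumerate(LABELS):
            if lab in classes:  # absent classes keep probability 0
                out[:, j] = proba[:, classes.index(lab)]
        return out

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "ftrclassify-timeref-v1",
            "ngram_range": list(self.vectorizer.ngram_range),
            "vocabulary": {k: int(v) for k, v in self.vectorizer.vocabulary_.items()},
            "classes": list(self.clf.classes_),
            "coef": self.clf.coef_.tolist(),
            "intercept": self.clf.intercept_.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TimeReferenceModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "ftrclassify-timeref-v1":
            raise ValueError(f"{path}: not a time-reference model file")
        vec = CountVectorizer(ngram_range=tuple(payload["ngram_range"]),
                              vocabulary=payload["vocabulary"])
        # instantiating with a fixed vocabulary skips fitting
        vec._validate_vocabulary()
        clf = LogisticRegression()
        clf.classes_ = np.array(payload["classes"])
        clf.coef_ = np.array(payload["coef"])
        clf.intercept_ = np.array(payload["intercept"])
        return cls(vec, clf)


def _effective_examples(examples: Iterable[AnnotatedExample]) -> list[AnnotatedExample]:
    return [ex for ex in examples if ex.decision != "ignore"]


def train_time_reference_model(
    examples: Sequence[AnnotatedExample],
    split: float = 0.8,
    seed: int = 0,
    class_weight: str | None = None,
) -> tuple[TimeReferenceModel, dict[str, ClassifierMetrics]]:
    """Train on a seeded ``split`` fraction, evaluate on the rest.

    Returns the fitted model and held-out metrics per label.  Requires
    at least two classes in the training data.  ``class_weight`` may be
    set to "balanced" to reweight for class imbalance (off by default).
    """
    usable = _effective_examples(examples)
    labels = {ex.effective_label for ex in usable}
    if len(labels) < 2:
        raise ValueError(f"training data contains a single class {labels}")
    if not 0 < split < 1:
        raise ValueError("split must be a fraction in (0, 1)")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(usable))
    n_train = max(1, int(round(split * len(usable))))
    train_ix, test_ix = order[:n_train], order[n_train:]
    train = [usable[i] for i in train_ix]
    test = [usable[i] for i in test_ix]
    if len({ex.effective_label for ex in train}) < 2:
        raise ValueError("train split collapsed to a single class; reseed or add data")

    vec = CountVectorizer(ngram_range=(1, 2), lowercase=True)
    X = vec.fit_transform([ex.text for ex in train])
    y = [ex.effective_label for ex in train]
    clf = LogisticRegression(C=1.0, max_iter=2000, tol=1e-8,
                             class_weight=class_weight)
    clf.fit(X, y)
    model = TimeReferenceModel(vec, clf)

    metrics = evaluate(model, test) if test else {}
    return model, metrics


def predict_time_reference(model: TimeReferenceModel,
                           sentence: "Sentence | str") -> TimeRefPrediction:
    """Per-sentence probabilities and binary flags.

    An empty sentence yields the OTHER convention p_ftr = p_ptr = 0,
    logged.
    """
    if isinstance(sentence, Sentence):
        text, ref = sentence.text, sentence.sentence_id
    else:
        text, ref = sentence, ""
    if not text.strip():
        logger.info("empty sentence %r: predicting OTHER by convention", ref)
        return TimeRefPrediction(ref, 0.0, 0.0)
    proba = model.predict_proba([text])[0]
    return TimeRefPrediction(ref, float(proba[0]), float(proba[1]))


def evaluate(model: TimeReferenceModel,
             test: Sequence[AnnotatedExample]) -> dict[str, ClassifierMetrics]:
    """Held-out confusion metrics per label.

    FTR and PTR use their thresholded binary flags as the positive
    prediction; OTHER is predicted when neither flag fires.
    """
    usable = _effective_examples(test)
    if not usable:
        raise ValueError("test set is empty")
    preds = [predict_time_reference(model, ex.text) for ex in usable]
    true = [ex.effective_label for ex in usable]

    out: dict[str, ClassifierMetrics] = {}
    for label in LABELS:
        if label == "FTR":
            predicted = [p.is_ftr for p in preds]
        elif label == "PTR":
            predicted = [p.is_ptr for p in preds]
        else:
            predicted = [int(p.is_ftr == 0 and p.is_ptr == 0) for p in preds]
        actual = [int(t == label) for t in true]
        tp = sum(1 for a, p in zip(actual, predicted) if a and p)
        fp = sum(1 for a, p in zip(actual, predicted) if not a and p)
        fn = sum(1 for a, p in zip(actual, predicted) if a and not p)
        tn = sum(1 for a, p in zip(actual, predicted) if not a and not p)
        out[label] = ClassifierMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
    return out
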