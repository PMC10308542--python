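"""Corpus ingestion and sentence segmentation.

Posts are the unit of ingestion (one social-media contribution with a
posting timestamp and a condition label); sentences are the unit of all
downstream classification.  Segmentation is rule-based — terminal
punctuation with an abbreviation guard — so the package runs with zero
model downloads and is bit-reproducible; the backend used is logged per
corpus.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from dateutil import parser as date_parser

logger = logging.getLogger(__name__)

CONDITIONS = ("mental_health", "control", "unlabeled")

SEGMENTER_BACKEND = "rule-based (terminal punctuation + abbreviation list)"


@dataclass(frozen=True)
class Post:
    """A single timestamped contribution by one author."""

    post_id: str
    author_id: str
    text: str
    posted_at: datetime
    condition: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.text.strip():
            raise ValueError("post text empty after whitespace normalization")


@dataclass(frozen=True)
class Sentence:
    """One sentence of a post, with its half-open character span."""

    post_ref: str
    sent_index: int
    text: str
    char_span: tuple[int, int]

    @property
    def sentence_id(self) -> str:
        return f"{self.post_ref}:{self.sent_index}"


def parse_timestamp(value: object) -> datetime:
    """Parse ISO-8601 strings or epoch seconds; naive values are UTC."""
    if isinstance(value, datetime):
        ts = value
    elif isinstance(value, (int, float)):
        ts = datetime.fromtimestamp(float(value), tz=timezone.utc)
    elif isinstance(value, str):
        s = value.strip()
        if re.fullmatch(r"-?\d+(\.\d+)?", s):
            ts = datetime.fromtimestamp(float(s), tz=timezone.utc)
        else:
            ts = date_parser.isoparse(s)
    else:
        raise ValueError(f"cannot parse timestamp from {value!r}")
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts


_REQUIRED_FIELDS = ("post_id", "author_id", "text", "posted_at")


def _record_to_post(rec: dict, lineno: int, strict: bool) -> Post | None:
    missing = [f for f in _REQUIRED_FIELDS if rec.get(f) in (None, "")]
    if missing:
        msg = f"line {lineno}: record missing field(s) {missing}"
        if strict:
            raise ValueError(msg)
        logger.warning("skipping malformed record: %s", msg)
        return None
    try:
        return Post(
            post_id=str(rec["post_id"]),
            author_id=str(rec["author_id"]),
            text=str(rec["text"]),
            posted_at=parse_timestamp(rec["posted_at"]),
            condition=str(rec.get("condition") or "unlabeled"),
        )
    except (ValueError, OverflowError) as exc:
        if strict:
            raise ValueError(f"line {lineno}: {exc}") from exc
        logger.warning("skipping malformed record at line %d: %s", lineno, exc)
        return None


def read_corpus(path: str | Path, format: str | None = None, *, strict: bool = False) -> list[Post]:
    """Read posts from a JSONL or CSV file.

    ``format`` defaults from the file suffix.  In lenient mode (default)
    malformed records are skipped with a warning carrying the line
    number; with ``strict=True`` they raise.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")

    posts: list[Post] = []
    seen: set[str] = set()
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    if strict:
                        raise ValueError(f"line {lineno}: invalid JSON") from exc
                    logger.warning("skipping invalid JSON at line %d", lineno)
                    continue
                post = _record_to_post(rec, lineno, strict)
                if post is not None:
                    posts.append(post)
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            for lineno, rec in enumerate(csv.DictReader(fh), start=2):
                post = _record_to_post(rec, lineno, strict)
                if post is not None:
                    posts.append(post)

    for post in posts:
        if post.post_id in seen:
            raise ValueError(f"duplicate post_id {post.post_id!r}")
        seen.add(post.post_id)
    return posts


def write_sentences_jsonl(sentences: Iterable[Sentence], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(json.dumps({
                "sentence_id": s.sentence_id,
                "post_ref": s.post_ref,
                "sent_index": s.sent_index,
                "text": s.text,
                "char_span": list(s.char_span),
            }) + "\n")


# ---------------------------------------------------------------------------
# Sentence segmentation

#: Tokens after which a period does not end a sentence.
ABBREVIATIONS = frozenset({
    "mr", "mrs", "ms", "dr", "prof", "sr", "jr", "st", "vs", "etc",
    "e.g", "i.e", "cf", "al", "approx", "dept", "est", "fig", "no",
    "p.m", "a.m", "u.s", "u.k", "inc", "ltd", "co",
})

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


def _is_abbreviation(text: str, end: int) -> bool:
    # token preceding the terminal period, lowercased, dots kept except the last
    m = re.search(r"(\S+)$", text[:end])
    if not m:
        return False
    tok = m.group(1).lower().rstrip(".")
    tok = tok.lstrip("(\"'")
    if tok in ABBREVIATIONS:
        return True
    # single letters ("J. Smith") and dotted initialisms
    return len(tok) == 1 and tok.isalpha()


def split_sentences(post: Post) -> list[Sentence]:
    """Deterministically segment a post into ordered sentences.

    Splits at runs of terminal punctuation unless the preceding token is
    a known abbreviation or a single initial.  Sentence spans are
    non-overlapping half-open offsets into the NFC-normalized post text,
    ordered by position; concatenating them in order reproduces the text
    up to the inter-sentence whitespace the splitter consumed.
    """
    text = unicodedata.normalize("NFC", post.text)
    if not text.strip():
        return []

    boundaries: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        if m.group().startswith(".") and _is_abbreviation(text, m.start()):
            continue
        boundaries.append(m.end())
    if not boundaries or boundaries[-1] < len(text):
        boundaries.append(len(text))

    sentences: list[Sentence] = []
    start = 0
    for end in boundaries:
        raw = text[start:end]
        stripped = raw.strip()
        if stripped:
            lead = len(raw) - len(raw.lstrip())
            span = (start + lead, start + lead + len(stripped))
            sentences.append(Sentence(post.post_id, len(sentences), stripped, span))
        start = end
    return sentences


def segment_corpus(posts: Sequence[Post]) -> list[Sentence]:
    """Segment every post; empty/whitespace-only posts are dropped with a logged count."""
    logger.info("segmenting %d posts with backend: %s", len(posts), SEGMENTER_BACKEND)
    out: list[Sentence] = []
    dropped = 0
    for post in posts:
        sents = split_sentences(post)
        if not sents:
            dropped += 1
            continue
        out.extend(sents)
    if dropped:
        logger.info("dropped %d posts with no segmentable text", dropped)
    return out
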