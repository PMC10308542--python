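"""Temporal expression resolution and sentence time horizons.

A sentence's *time horizon* H(s) is the mean signed day-distance between
its resolved temporal references and the posting time:

    H(s) = sum_r D(r) / n

where D(r) is the day-delta of reference r from the posting date and n
is the number of references in the sentence.  Positive H is future
reference, negative is past.

Expressions are found by a deterministic rule inventory (regular
expressions over keywords and date patterns) and resolved against the
posting timestamp.  Deltas are computed on calendar dates — posting time
truncated to its date — so "tomorrow" is always exactly +1 day.  Numeric
dates such as 10-06-2020 are parsed day-first by default (switchable).

Sub-day references ("tonight") resolve to the posting date itself.
Mirroring how clock-time tagging systems anchor such expressions at
00:00, a reference resolving to the posting date with a negative raw
clock delta (e.g. "tonight" posted at 16:00 gives -16 h) is flagged as a
same-day-past artifact and dropped by :func:`filter_horizons`.  Sub-day
*future* references survive with H = 0 and are excluded only from the
log-scale transform, with a logged count.
"""

from __future__ import annotations

import calendar
import logging
import math
import re
from dataclasses import dataclass, replace
from datetime import date, datetime, time, timedelta, timezone
from typing import Iterable, Sequence

from dateutil.relativedelta import relativedelta

from .corpus import Sentence

logger = logging.getLogger(__name__)

DROP_REASONS = ("none", "no_expression", "same_day_past")


@dataclass(frozen=True)
class TemporalExpression:
    """One temporal reference found in a sentence, resolved to a date."""

    surface: str
    span: tuple[int, int]
    kind: str  # absolute | relative | combined
    resolved: date
    anchor: datetime
    #: Clock-time resolution where one exists; date-level expressions
    #: anchor at midnight of the resolved date (used only for the
    #: same-day-past artifact check).
    resolved_time: datetime | None = None

    @property
    def delta_days(self) -> int:
        return (self.resolved - self.anchor.date()).days


@dataclass(frozen=True)
class HorizonRecord:
    """The horizon statistic for one sentence with its filters and transforms."""

    sentence_ref: str
    n_refs: int
    H_days: float
    abs_H: float
    t_ref: int  # 0 = future, 1 = past
    retained: int
    drop_reason: str = "none"
    log_abs_H: float | None = None


# ---------------------------------------------------------------------------
# Rule inventory

_MONTHS = {m.lower(): i for i, m in enumerate(calendar.month_name) if m}
_MONTHS.update({m.lower(): i for i, m in enumerate(calendar.month_abbr) if m})
_WEEKDAYS = {d.lower(): i for i, d in enumerate(calendar.day_name)}

_NUMBER_WORDS = {
    "a": 1, "an": 1, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "twenty": 20, "thirty": 30,
}

_MONTH_ALT = "|".join(sorted(_MONTHS, key=len, reverse=True))
_WEEKDAY_ALT = "|".join(_WEEKDAYS)
_NUM = r"(?:\d+|" + "|".join(_NUMBER_WORDS) + r")"
_UNIT = r"(?:minute|hour|day|week|month|year)"
_AT_TIME = r"(?:\s+at\s+\d{1,2}(?::\d{2})?\s*(?:am|pm)?)?"


def _num(tok: str) -> int:
    return int(tok) if tok.isdigit() else _NUMBER_WORDS[tok]


def _parse_year(tok: str) -> int:
    y = int(tok)
    return y + 2000 if y < 100 else y


_PATTERNS: list[tuple[re.Pattern, str]] = [
    (re.compile(r"\b(\d{4})-(\d{1,2})-(\d{1,2})\b"), "iso"),
    (re.compile(r"\b(\d{1,2})[-/](\d{1,2})[-/](\d{2,4})\b"), "numeric"),
    (re.compile(r"\b(" + _MONTH_ALT + r")\.?\s+(\d{1,2})(?:st|nd|rd|th)?(?:,?\s+(\d{4}))?\b"),
     "month_day"),
    (re.compile(r"\b(\d{1,2})(?:st|nd|rd|th)?\s+(?:of\s+)?(" + _MONTH_ALT + r")\.?(?:,?\s+(\d{4}))?\b"),
     "day_month"),
    (re.compile(r"\bday\s+after\s+tomorrow" + _AT_TIME + r"\b"), "day_after_tomorrow"),
    (re.compile(r"\b(today|tomorrow|yesterday|tonight)" + _AT_TIME + r"\b"), "deictic"),
    (re.compile(r"\bthis\s+(morning|afternoon|evening)\b"), "part_of_day"),
    (re.compile(r"\b(next|last)\s+(week|month|year)\b"), "next_last_unit"),
    (re.compile(r"\b(this|next|last)\s+(" + _WEEKDAY_ALT + r")" + _AT_TIME + r"\b"), "rel_weekday"),
    (re.compile(r"\b(?:on\s+)?(" + _WEEKDAY_ALT + r")" + _AT_TIME + r"\b"), "bare_weekday"),
    (re.compile(r"\bin\s+(" + _NUM + r")\s+(" + _UNIT + r")s?\b"), "in_n_units"),
    (re.compile(r"\b(" + _NUM + r")\s+(" + _UNIT + r")s?\s+ago\b"), "n_units_ago"),
]


def _shift_months(anchor: date, months: int) -> date:
    return anchor + relativedelta(months=months)


def _resolve(rule: str, m: re.Match, anchor: datetime, dayfirst: bool):
    """Return (kind, resolved_date, resolved_time|None) or None to skip."""
    a = anchor.date()
    midnight = datetime.combine(a, time(0), tzinfo=anchor.tzinfo)
    if rule == "iso":
        y, mo, d = (int(g) for g in m.groups())
        return "absolute", date(y, mo, d), None
    if rule == "numeric":
        p, q, ytok = m.groups()
        y = _parse_year(ytok)
        d, mo = (int(p), int(q)) if dayfirst else (int(q), int(p))
        if mo > 12 and d <= 12:  # unambiguous: the other order was meant
            d, mo = mo, d
        return "absolute", date(y, mo, d), None
    if rule == "month_day":
        mo, d, y = _MONTHS[m.group(1).lower()], int(m.group(2)), m.group(3)
        return "absolute", date(int(y) if y else a.year, mo, d), None
    if rule == "day_month":
        d, mo, y = int(m.group(1)), _MONTHS[m.group(2).lower()], m.group(3)
        return "absolute", date(int(y) if y else a.year, mo, d), None
    if rule == "day_after_tomorrow":
        return "relative", a + timedelta(days=2), None
    if rule == "deictic":
        word = m.group(1).lower()
        offset = {"today": 0, "tonight": 0, "tomorrow": 1, "yesterday": -1}[word]
        resolved = a + timedelta(days=offset)
        # midnight-anchored clock resolution for same-day words
        t = midnight if offset == 0 else None
        kind = "combined" if "at" in m.group(0).lower() else "relative"
        return kind, resolved, t
    if rule == "part_of_day":
        return "relative", a, midnight
    if rule == "next_last_unit":
        direction = 1 if m.group(1).lower() == "next" else -1
        unit = m.group(2).lower()
        if unit == "week":
            return "relative", a + timedelta(weeks=direction), None
        if unit == "month":
            return "relative", _shift_months(a, direction), None
        return "relative", a + relativedelta(years=direction), None
    if rule in ("rel_weekday", "bare_weekday"):
        if rule == "rel_weekday":
            qualifier, day_name = m.group(1).lower(), m.group(2).lower()
        else:
            qualifier, day_name = "this", m.group(1).lower()
        target = _WEEKDAYS[day_name]
        diff = (target - a.weekday()) % 7
        if qualifier == "this":
            resolved = a + timedelta(days=diff)           # nearest forward, 0-6
        elif qualifier == "next":
            resolved = a + timedelta(days=diff or 7)      # strictly forward, 1-7
        else:  # last
            back = (a.weekday() - target) % 7
            resolved = a - timedelta(days=back or 7)      # strictly backward
        kind = "combined" if "at" in m.group(0).lower() else "relative"
        return kind, resolved, None
    if rule in ("in_n_units", "n_units_ago"):
        n = _num(m.group(1).lower())
        unit = m.group(2).lower()
        sign = 1 if rule == "in_n_units" else -1
        if unit in ("minute", "hour"):
            delta = timedelta(**{unit + "s": sign * n})
            resolved_dt = anchor + delta
            return "relative", resolved_dt.date(), resolved_dt
        if unit == "day":
            return "relative", a + timedelta(days=sign * n), None
        if unit == "week":
            return "relative", a + timedelta(weeks=sign * n), None
        if unit == "month":
            return "relative", _shift_months(a, sign * n), None
        return "relative", a + relativedelta(years=sign * n), None
    raise AssertionError(rule)


def extract_temporal_expressions(sentence: "Sentence | str", anchor: datetime,
                                 *, dayfirst: bool = True) -> list[TemporalExpression]:
    """Find and resolve all temporal expressions in a sentence.

    Matching is deterministic leftmost-longest: candidate matches from
    every rule are collected and overlaps resolved in favour of the
    earliest, then longest, match.  Unparseable candidates (e.g. an
    impossible calendar date) are skipped with a log entry.
    """
    text = sentence.text if isinstance(sentence, Sentence) else sentence
    lowered = text.lower()
    candidates: list[tuple[int, int, str, re.Match]] = []
    for pattern, rule in _PATTERNS:
        for m in pattern.finditer(lowered):
            candidates.append((m.start(), -(m.end() - m.start()), rule, m))
    candidates.sort(key=lambda c: (c[0], c[1]))

    out: list[TemporalExpression] = []
    taken: list[tuple[int, int]] = []
    for start, neg_len, rule, m in candidates:
        end = start - neg_len
        if any(s < end and start < e for s, e in taken):
            continue
        try:
            resolved = _resolve(rule, m, anchor, dayfirst)
        except (ValueError, KeyError):
            logger.info("skipping unparseable temporal candidate %r", m.group(0))
            continue
        if resolved is None:
            continue
        kind, day, clock = resolved
        taken.append((start, end))
        out.append(TemporalExpression(
            surface=text[start:end], span=(start, end), kind=kind,
            resolved=day, anchor=anchor, resolved_time=clock,
        ))
    out.sort(key=lambda e: e.span)
    return out


# ---------------------------------------------------------------------------
# Horizon statistic

def sentence_horizon(exprs: Sequence[TemporalExpression], anchor: datetime,
                     sentence_ref: str = "") -> HorizonRecord:
    """Compute H(s) = mean day-delta over the sentence's references.

    An empty expression set yields a record marked ``no_expression``.  A
    record whose references all land on the posting date with a negative
    raw clock delta is marked ``same_day_past`` (midnight-anchoring
    artifact); both are dropped by :func:`filter_horizons`.
    """
    if not exprs:
        return HorizonRecord(sentence_ref, 0, math.nan, math.nan, 0,
                             retained=0, drop_reason="no_expression")
    deltas = [e.delta_days for e in exprs]
    H = sum(deltas) / len(deltas)
    t_ref = 1 if H < 0 else 0

    retained, reason = 1, "none"
    if H == 0:
        raw = [((e.resolved_time or datetime.combine(
            e.resolved, time(0), tzinfo=anchor.tzinfo)) - anchor).total_seconds()
            for e in exprs]
        if sum(raw) / len(raw) < 0:
            retained, reason = 0, "same_day_past"
    return HorizonRecord(sentence_ref, len(exprs), float(H), abs(float(H)),
                         t_ref, retained=retained, drop_reason=reason)


def filter_horizons(records: Iterable[HorizonRecord]) -> list[HorizonRecord]:
    """Retain only records with a usable horizon (drops the
    no-expression and same-day-past cases)."""
    return [r for r in records if r.retained == 1]


def log_abs_horizon(record: HorizonRecord) -> HorizonRecord:
    """Attach ln|H| to a retained record; |H| must be positive."""
    if not record.retained:
        raise ValueError("log transform applies only to retained records")
    if record.abs_H == 0:
        raise ValueError(
            f"{record.sentence_ref}: |H| = 0 cannot enter the log-scale "
            "analysis (should have been excluded)")
    return replace(record, log_abs_H=math.log(record.abs_H))


def log_transform(records: Iterable[HorizonRecord]) -> list[HorizonRecord]:
    """Log-transform a retained collection, dropping |H| = 0 rows with a
    logged count (sub-day future references)."""
    out, dropped = [], 0
    for r in records:
        if r.abs_H == 0:
            dropped += 1
            continue
        out.append(log_abs_horizon(r))
    if dropped:
        logger.info("excluded %d zero-horizon records from log-scale analysis", dropped)
    return out
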