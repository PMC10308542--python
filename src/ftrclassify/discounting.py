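"""Hyperbolic delay discounting from an intertemporal-choice battery.

Subjective value follows the hyperbolic form V = A / (1 + kD): A is the
delayed amount, D the delay in days and k the per-day discount rate
(larger k = steeper devaluation of delayed rewards).

The battery fully crosses 10 smaller-sooner amounts (GBP 50-95 in steps
of 5) with 11 delays of a fixed GBP 100 larger-later reward, giving 110
binary items.  Participant-level k is estimated Kirby-style: enumerate
every indifference rate k_i = (LLR/SSR - 1)/D over the battery's
(amount, delay) pairs, predict each participant's choices under every
candidate, and keep the candidate(s) matching the most empirical
choices; ties are resolved by the geometric mean of the tied set.
Choice *stochasticity* is the fraction of a participant's choices that
disagree with their best-fitting k's predictions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

LLR_AMOUNT = 100.0
SSR_AMOUNTS = tuple(float(a) for a in range(50, 100, 5))

#: Delay labels with their day equivalents.  The mapping follows the
#: standard convention for these labels and is configurable.
DELAY_DAYS: dict[str, float] = {
    "later today": 0.0,
    "tomorrow": 1.0,
    "one week": 7.0,
    "one month": 30.0,
    "two months": 61.0,
    "three months": 91.0,
    "six months": 182.0,
    "one year": 365.0,
    "two years": 730.0,
    "five years": 1825.0,
    "ten years": 3650.0,
}


@dataclass(frozen=True)
class ChoiceItem:
    """One binary item: SSR now versus the fixed GBP 100 LLR after a delay."""

    ssr: float
    llr: float
    delay_label: str
    delay_days: float

    def __post_init__(self) -> None:
        if not self.ssr < self.llr:
            raise ValueError("smaller-sooner reward must be below the larger-later")
        if self.delay_days < 0:
            raise ValueError("delay cannot be negative")


@dataclass(frozen=True)
class DiscountEstimate:
    participant_id: str
    k: float
    log_k: float
    match_prop: float
    stochasticity: float
    n_responses: int


def generate_battery(delay_days: Mapping[str, float] | None = None) -> list[ChoiceItem]:
    """The full 10 x 11 = 110 item battery in canonical order."""
    delays = dict(delay_days) if delay_days is not None else DELAY_DAYS
    return [ChoiceItem(ssr, LLR_AMOUNT, label, d)
            for ssr in SSR_AMOUNTS for label, d in delays.items()]


def hyperbolic_value(A: float, k: float, D: float) -> float:
    """V = A / (1 + kD)."""
    if A < 0 or k < 0 or D < 0:
        raise ValueError("amount, rate and delay must be non-negative")
    return A / (1.0 + k * D)


def predict_choice(item: ChoiceItem, k: float) -> int:
    """1 (larger-later) iff the discounted LLR strictly exceeds the SSR.

    Exact indifference predicts the immediate choice — a deterministic
    tie rule on a measure-zero boundary.
    """
    return int(hyperbolic_value(item.llr, k, item.delay_days) > item.ssr)


def candidate_k_grid(battery: Sequence[ChoiceItem]) -> np.ndarray:
    """All indifference rates k_i = (LLR/SSR - 1)/D over the battery.

    Zero-delay items have no finite indifference rate and contribute
    nothing; duplicates are collapsed and the grid sorted ascending.
    """
    ks = {(item.llr / item.ssr - 1.0) / item.delay_days
          for item in battery if item.delay_days > 0}
    return np.array(sorted(ks))


def _prediction_matrix(battery: Sequence[ChoiceItem], grid: np.ndarray) -> np.ndarray:
    """(n_candidates, n_items) binary predictions under each candidate k."""
    D = np.array([it.delay_days for it in battery])
    ssr = np.array([it.ssr for it in battery])
    llr = np.array([it.llr for it in battery])
    V = llr[None, :] / (1.0 + grid[:, None] * D[None, :])
    return (V > ssr[None, :]).astype(np.int8)


def estimate_k(responses: Mapping[int, int] | Sequence[int],
               battery: Sequence[ChoiceItem],
               grid: np.ndarray | None = None,
               participant_id: str = "") -> DiscountEstimate:
    """Kirby-style k for one participant.

    ``responses`` is either a full response vector aligned with the
    battery or a mapping from battery item index to choice (1 =
    larger-later); missing items are allowed and logged.
    """
    if grid is None:
        grid = candidate_k_grid(battery)
    if isinstance(responses, Mapping):
        idx = np.array(sorted(responses), dtype=int)
        chosen = np.array([responses[i] for i in idx], dtype=np.int8)
    else:
        resp = np.asarray(responses)
        idx = np.flatnonzero(resp >= 0)
        chosen = resp[idx].astype(np.int8)
    if idx.size == 0:
        raise ValueError("no responses for participant")
    if idx.size < len(battery):
        logger.info("participant %s: %d of %d battery items answered",
                    participant_id, idx.size, len(battery))

    preds = _prediction_matrix(battery, grid)[:, idx]
    matches = (preds == chosen[None, :]).sum(axis=1)
    best = matches.max()
    tied = grid[matches == best]
    # geometric mean of the argmax set; a singleton is returned exactly
    # (exp(log k) round-trip would perturb indifference boundaries)
    k = float(tied[0]) if tied.size == 1 else float(np.exp(np.mean(np.log(tied))))
    match_prop = best / idx.size
    return DiscountEstimate(
        participant_id=participant_id, k=k, log_k=math.log(k),
        match_prop=float(match_prop), stochasticity=float(1.0 - match_prop),
        n_responses=int(idx.size),
    )


def attention_check(check_choices: Sequence[int | None]) -> str:
    """Pass/fail on the two same-day items of unequal value.

    Each entry is 1 if the larger present-time reward was chosen, 0 if
    the smaller, None if the item is absent.  Choosing the smaller
    reward on either item fails (participants were ejected for this);
    absent items pass with a warning.
    """
    present = [c for c in check_choices if c is not None]
    if len(present) < len(check_choices) or not present:
        logger.warning("attention-check item(s) missing; treating as pass")
    if any(c == 0 for c in present):
        return "fail"
    return "pass"
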