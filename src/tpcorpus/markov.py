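"""Interval-pattern encoding and nth-order Markov transition tables.

A melodic transition of Markov order *n* involves ``n + 1`` consecutive
tones.  Every transition is re-expressed relative to its first pitch
(first element 0, subsequent elements signed semitone offsets), which
makes the statistics transposition-invariant: the analysis operates on
relative pitch, not absolute pitch.  Transitional probabilities are
maximum-likelihood count ratios

    P(outcome | context) = count(context, outcome) / count(context)

with no smoothing; a context that was never observed has no probability
("absent"), never 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

MAX_ORDER = 7

__all__ = [
    "IntervalPattern",
    "TransitionTable",
    "to_interval_pattern",
    "count_ngrams",
    "pool_movements",
    "pattern_probability",
    "MAX_ORDER",
]


@dataclass(frozen=True, order=True)
class IntervalPattern:
    """A transposition-invariant melodic transition.

    ``offsets`` holds ``order + 1`` signed semitone offsets relative to
    the first tone, so ``offsets[0]`` is always 0.  The first ``order``
    elements form the Markov context; the last element is the outcome.
    """

    offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.offsets) < 2:
            raise ValueError("an interval pattern needs at least two tones")
        if self.offsets[0] != 0:
            raise ValueError("interval patterns are relative: first offset must be 0")
        object.__setattr__(self, "offsets", tuple(int(o) for o in self.offsets))

    @property
    def order(self) -> int:
        return len(self.offsets) - 1

    @property
    def context(self) -> tuple[int, ...]:
        """The conditioning part: all offsets except the last."""
        return self.offsets[:-1]

    @property
    def outcome(self) -> int:
        """Offset of the final tone relative to the first tone."""
        return self.offsets[-1]

    @classmethod
    def from_string(cls, text: str) -> "IntervalPattern":
        """Parse the conventional comma-separated form, e.g. ``"0,-2,-3,-5"``."""
        return cls(tuple(int(part) for part in text.split(",")))

    def __str__(self) -> str:
        return ",".join(str(o) for o in self.offsets)


def to_interval_pattern(pitches: Sequence[int]) -> IntervalPattern:
    """Renumber a pitch window so its first pitch is 0.

    ``(65, 63, 62, 60, 58)`` and any transposition of it map to the same
    pattern ``[0, -2, -3, -5, -7]``.
    """
    if len(pitches) < 2:
        raise ValueError("need at least two pitches to form a transition")
    first = pitches[0]
    return IntervalPattern(tuple(int(p) - int(first) for p in pitches))


@dataclass
class TransitionTable:
    """Per-context outcome counts for one Markov order.

    ``counts`` maps a relative context (tuple of offsets, first element 0)
    to a mapping outcome-offset -> count.  Probabilities are derived views
    over the counts, so pooling tables is exact count addition.
    """

    order: int
    counts: dict[tuple[int, ...], dict[int, int]] = field(default_factory=dict)

    def add(self, pattern: IntervalPattern, n: int = 1) -> None:
        if pattern.order != self.order:
            raise ValueError(
                f"pattern order {pattern.order} does not match table order {self.order}"
            )
        outcomes = self.counts.setdefault(pattern.context, {})
        outcomes[pattern.outcome] = outcomes.get(pattern.outcome, 0) + n

    def context_total(self, context: tuple[int, ...]) -> int:
        return sum(self.counts.get(tuple(context), {}).values())

    @property
    def probabilities(self) -> dict[tuple[int, ...], dict[int, float]]:
        """Per-context outcome probabilities (each context sums to 1)."""
        out: dict[tuple[int, ...], dict[int, float]] = {}
        for ctx, outcomes in self.counts.items():
            total = sum(outcomes.values())
            if total > 0:
                out[ctx] = {o: c / total for o, c in outcomes.items()}
        return out

    def patterns(self) -> Iterator[IntervalPattern]:
        """All full patterns (context + outcome) with count >= 1."""
        for ctx, outcomes in self.counts.items():
            for outcome, c in outcomes.items():
                if c >= 1:
                    yield IntervalPattern(ctx + (outcome,))

    def probability(self, pattern: IntervalPattern) -> float | None:
        """P(outcome | context) for a full pattern, or None if the context
        was never observed."""
        if pattern.order != self.order:
            raise ValueError(
                f"pattern order {pattern.order} does not match table order {self.order}"
            )
        outcomes = self.counts.get(pattern.context)
        total = sum(outcomes.values()) if outcomes else 0
        if total == 0:
            return None
        return outcomes.get(pattern.outcome, 0) / total


def count_ngrams(pitches: Sequence[int], order: int) -> TransitionTable:
    """Count all order-(n+1)-tone transitions in one melodic sequence.

    Every window of ``order + 1`` consecutive pitches contributes one
    count; windows never cross sequence (movement) boundaries.  A
    sequence shorter than ``order + 1`` yields an empty table.
    """
    if not 1 <= order <= MAX_ORDER:
        raise ValueError(f"order must be in 1..{MAX_ORDER}, got {order}")
    table = TransitionTable(order=order)
    arr = np.asarray(list(pitches), dtype=np.int64)
    n = order + 1
    if arr.size < n:
        return table
    windows = np.lib.stride_tricks.sliding_window_view(arr, n)
    rel = windows - windows[:, :1]
    uniq, cnt = np.unique(rel, axis=0, return_counts=True)
    for row, c in zip(uniq, cnt):
        offs = tuple(int(v) for v in row)
        table.counts.setdefault(offs[:-1], {})
        table.counts[offs[:-1]][offs[-1]] = (
            table.counts[offs[:-1]].get(offs[-1], 0) + int(c)
        )
    return table


def pool_movements(tables: Iterable[TransitionTable]) -> TransitionTable:
    """Pool per-movement tables into one piece-level table.

    Counts are summed, so pooled probabilities equal a weighted average of
    per-movement probabilities with weights proportional to each
    movement's context occurrence counts.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("cannot pool an empty list of tables")
    orders = {t.order for t in tables}
    if len(orders) != 1:
        raise ValueError(f"cannot pool tables of mixed orders {sorted(orders)}")
    pooled = TransitionTable(order=tables[0].order)
    for t in tables:
        for ctx, outcomes in t.counts.items():
            dest = pooled.counts.setdefault(ctx, {})
            for outcome, c in outcomes.items():
                dest[outcome] = dest.get(outcome, 0) + c
    return pooled


def pattern_probability(
    table: TransitionTable, pattern: IntervalPattern
) -> float | None:
    """Transitional probability of ``pattern`` under ``table`` (None if the
    context is unobserved)."""
    return table.probability(pattern)
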