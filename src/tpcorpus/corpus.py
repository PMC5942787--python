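"""Universal-pattern filtering and the piece x pattern probability matrix.

Only interval patterns that occur at least once in *every* piece of the
corpus ("universal" patterns) enter the trend regression; patterns with a
zero probability in some pieces are excluded by design.  Pieces are kept
in their publication order (serial number 1..N), which serves as the
time-course regressand.

The packaged Beethoven piano-sonata matrices (32 sonatas, highest-pitch
lines pooled over movements, Markov orders 1-5) ship as CSV under
``datasets/beethoven_sonatas`` and load via :func:`load_beethoven_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .markov import IntervalPattern, TransitionTable, pattern_probability

__all__ = [
    "CorpusMatrix",
    "UniversalityError",
    "universal_patterns",
    "build_matrix",
    "load_beethoven_matrix",
    "BEETHOVEN_ORDERS",
]

BEETHOVEN_ORDERS = (1, 2, 3, 4, 5)


class UniversalityError(ValueError):
    """A pattern assumed universal is absent (or zero) in some piece."""


@dataclass
class CorpusMatrix:
    """Pieces (rows, in serial order) x universal patterns (columns) matrix
    of transitional probabilities.

    ``values`` is an N x P float array with every cell defined and > 0;
    ``piece_index`` is strictly increasing.
    """

    order: int
    piece_index: list[int]
    patterns: list[IntervalPattern]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.piece_index), len(self.patterns)):
            raise ValueError("values shape does not match piece_index x patterns")
        if any(b <= a for a, b in zip(self.piece_index, self.piece_index[1:])):
            raise ValueError("piece_index must be strictly increasing")

    @property
    def n_pieces(self) -> int:
        return len(self.piece_index)

    def to_frame(self) -> pd.DataFrame:
        """DataFrame with piece_index as index and pattern strings as columns."""
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.piece_index, name="piece_index"),
            columns=[str(p) for p in self.patterns],
        )

    def to_csv(self, path: str | Path) -> None:
        # default float formatting round-trips exactly (repr precision)
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, order: int | None = None) -> "CorpusMatrix":
        patterns = [IntervalPattern.from_string(c) for c in df.columns]
        orders = {p.order for p in patterns}
        if len(orders) != 1:
            raise ValueError(f"matrix columns mix Markov orders {sorted(orders)}")
        inferred = orders.pop()
        if order is not None and order != inferred:
            raise ValueError(f"columns have order {inferred}, expected {order}")
        return cls(
            order=inferred,
            piece_index=[int(i) for i in df.index],
            patterns=patterns,
            values=df.to_numpy(dtype=float),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "CorpusMatrix":
        # round_trip parsing keeps write/read exact at full precision
        df = pd.read_csv(path, float_precision="round_trip").set_index("piece_index")
        return cls.from_frame(df)


def universal_patterns(
    tables: Sequence[TransitionTable], order: int
) -> list[IntervalPattern]:
    """Patterns (context + outcome) with count >= 1 in every piece's pooled
    table, sorted lexicographically.

    Requires at least two pieces; all tables must share ``order``.
    """
    if len(tables) < 2:
        raise ValueError("universality needs a corpus of at least two pieces")
    for t in tables:
        if t.order != order:
            raise ValueError(f"table of order {t.order} in an order-{order} corpus")
    common = set(tables[0].patterns())
    for t in tables[1:]:
        common &= set(t.patterns())
    return sorted(common)


def build_matrix(
    tables: Sequence[TransitionTable],
    patterns: Sequence[IntervalPattern],
    piece_order: Sequence[int],
) -> CorpusMatrix:
    """Assemble the corpus matrix: cell (i, j) = P(pattern j | piece i).

    Raises :class:`UniversalityError` if any pattern is absent (or has
    zero probability) in some piece.
    """
    if len(tables) != len(piece_order):
        raise ValueError("one table per piece is required")
    orders = {t.order for t in tables}
    if len(orders) != 1:
        raise ValueError("tables mix Markov orders")
    order = orders.pop()
    values = np.empty((len(tables), len(patterns)))
    for i, table in enumerate(tables):
        for j, pat in enumerate(patterns):
            p = pattern_probability(table, pat)
            if p is None or p == 0.0:
                raise UniversalityError(
                    f"pattern {pat} is not universal: "
                    f"absent or zero in piece {piece_order[i]}"
                )
            values[i, j] = p
    idx = np.argsort(piece_order)
    return CorpusMatrix(
        order=order,
        piece_index=[int(piece_order[i]) for i in idx],
        patterns=list(patterns),
        values=values[idx],
    )


def load_beethoven_matrix(order: int) -> CorpusMatrix:
    """Load the packaged 32-sonata transitional-probability matrix.

    Available orders and column counts: 1 -> 20 two-tone patterns,
    2 -> 37, 3 -> 12, 4 -> 3, 5 -> 1.  Values are the published
    3-decimal probabilities; column order follows the source tables.
    """
    if order not in BEETHOVEN_ORDERS:
        raise ValueError(
            f"packaged matrices exist for orders {BEETHOVEN_ORDERS}, got {order}"
        )
    ref = resources.files("tpcorpus").joinpath(
        f"datasets/beethoven_sonatas/order{order}.csv"
    )
    with resources.as_file(ref) as path:
        df = pd.read_csv(path).set_index("piece_index")
    return CorpusMatrix.from_frame(df, order=order)
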