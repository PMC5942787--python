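"""Pipeline orchestration, report writing and diatonic pattern decoding.

Ties the stages together — encode, count, pool, universality filter,
matrix assembly, stepwise regression, report — behind a single
configuration object, and decodes abstract interval patterns into their
diatonic instantiations (the note-name sequences that realize a pattern
entirely inside a given major scale).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import (
    BEETHOVEN_ORDERS,
    CorpusMatrix,
    load_beethoven_matrix,
    universal_patterns,
    build_matrix,
)
from .markov import IntervalPattern, count_ngrams, pool_movements
from .regression import ProbabilityTrendModel, StepwiseSettings, TrendResults
from .score_io import MelodicSequence, extract_highest_line, read_coded_csv, read_musicxml

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "diatonic_instantiations",
    "C_MAJOR",
    "reproduce",
    "run_pipeline",
    "encode_directory",
    "sequences_by_piece",
]

C_MAJOR = (0, 2, 4, 5, 7, 9, 11)
_C_MAJOR_NAMES = ("C", "D", "E", "F", "G", "A", "B")


@dataclass
class PipelineConfig:
    """Settings shared across pipeline stages."""

    orders: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    p_enter: float = 0.05
    p_remove: float = 0.10
    vif_limit: float = 2.0
    ci_limit: float = 20.0
    seed: int = 0
    output_dir: Path = field(default_factory=lambda: Path("tpcorpus_out"))

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        bad = [o for o in self.orders if not 1 <= o <= 7]
        if bad:
            raise ValueError(f"orders outside 1..7: {bad}")
        self.settings = StepwiseSettings(
            p_enter=self.p_enter,
            p_remove=self.p_remove,
            vif_limit=self.vif_limit,
            ci_limit=self.ci_limit,
        )


def diatonic_instantiations(
    pattern: IntervalPattern,
    scale: Sequence[int] = C_MAJOR,
    names: Sequence[str] | None = None,
) -> list[tuple[str, ...]]:
    """Note-name sequences realizing ``pattern`` inside a major scale.

    For each of the 7 scale degrees as starting note, the pattern is
    realized (octave-reduced) and kept iff every realized pitch class
    lies in the scale.  Spelling uses the natural names of the given
    scale; the default is C major, so ``[0, 1]`` decodes to
    ``[("E", "F"), ("B", "C")]``.
    """
    if len(scale) != 7:
        raise ValueError("scale must list exactly 7 pitch classes")
    if names is None:
        if tuple(scale) == C_MAJOR:
            names = _C_MAJOR_NAMES
        else:
            raise ValueError("names must be given for scales other than C major")
    name_of = {pc % 12: name for pc, name in zip(scale, names)}
    out: list[tuple[str, ...]] = []
    for start in scale:
        pcs = [(start + off) % 12 for off in pattern.offsets]
        if all(pc in name_of for pc in pcs):
            out.append(tuple(name_of[pc] for pc in pcs))
    return out


def sequences_by_piece(
    sequences: Sequence[MelodicSequence],
) -> list[tuple[str, list[MelodicSequence]]]:
    """Group sequences by piece, preserving first-appearance order (the
    corpus's serial order)."""
    grouped: dict[str, list[MelodicSequence]] = {}
    for seq in sequences:
        grouped.setdefault(seq.piece_id, []).append(seq)
    return list(grouped.items())


def encode_directory(root: str | Path) -> list[MelodicSequence]:
    """Encode a directory tree of MusicXML movements.

    Each subdirectory of ``root`` is one piece (sorted by name = serial
    order); each ``.xml`` / ``.musicxml`` file inside is one movement.
    A flat directory is treated as a single piece.
    """
    root = Path(root)
    piece_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not piece_dirs:
        piece_dirs = [root]
    sequences = []
    for piece_dir in piece_dirs:
        files = sorted(
            f
            for f in piece_dir.iterdir()
            if f.suffix.lower() in {".xml", ".musicxml"}
        )
        for f in files:
            events = read_musicxml(f)
            sequences.append(
                extract_highest_line(events, piece_id=piece_dir.name, movement_id=f.stem)
            )
    return sequences


def _fit_matrix(matrix: CorpusMatrix, config: PipelineConfig) -> TrendResults:
    model = ProbabilityTrendModel(matrix)
    return model.fit(settings=config.settings)


def _write_reports(
    results: TrendResults, order: int, out_dir: Path
) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"order{order}_model.csv"
    json_path = out_dir / f"order{order}_path.json"
    results.to_report_csv(csv_path)
    results.to_json(json_path)
    return [csv_path, json_path]


def reproduce(order: int, config: PipelineConfig | None = None) -> TrendResults:
    """One-command trend regression on a packaged 32-sonata matrix.

    Loads the packaged matrix for ``order`` (1-5), runs stepwise
    selection with the configured thresholds, writes the model report and
    path JSON into the output directory, and returns the results.  At
    order 5 no predictor enters and the adopted model is intercept-only.
    """
    if order not in BEETHOVEN_ORDERS:
        raise ValueError(f"packaged matrices cover orders {BEETHOVEN_ORDERS}")
    config = config or PipelineConfig()
    matrix = load_beethoven_matrix(order)
    results = _fit_matrix(matrix, config)
    _write_reports(results, order, config.output_dir)
    logger.info(
        "order %d: %d candidate patterns, %d selected",
        order,
        matrix.values.shape[1],
        results.final.k,
    )
    return results


def run_pipeline(
    inputs: str | Path | Sequence[MelodicSequence],
    config: PipelineConfig | None = None,
) -> dict[int, TrendResults | None]:
    """Run encode -> count -> pool -> universal -> matrix -> regress for
    every configured order.

    ``inputs`` may be a coded-sequence CSV path, a MusicXML directory
    tree, or an in-memory list of sequences.  Pieces are ordered by first
    appearance and given serial numbers 1..N.  Orders at which no
    universal pattern exists map to ``None`` in the returned dict (and a
    report noting zero candidates is still written).
    """
    config = config or PipelineConfig()
    if isinstance(inputs, (str, Path)):
        path = Path(inputs)
        if not path.exists():
            raise FileNotFoundError(f"input not found: {path}")
        if path.is_dir():
            sequences = encode_directory(path)
        else:
            sequences = read_coded_csv(path)
    else:
        sequences = list(inputs)
    pieces = sequences_by_piece(sequences)
    if len(pieces) < 2:
        raise ValueError(f"corpus has {len(pieces)} piece(s); at least 2 required")
    logger.info(
        "corpus: %d pieces, %d movements", len(pieces), len(sequences)
    )
    out: dict[int, TrendResults | None] = {}
    config.output_dir.mkdir(parents=True, exist_ok=True)
    for order in config.orders:
        tables = [
            pool_movements(count_ngrams(m.pitches, order) for m in movements)
            for _, movements in pieces
        ]
        patterns = universal_patterns(tables, order)
        logger.info("order %d: %d universal pattern(s)", order, len(patterns))
        if not patterns:
            (config.output_dir / f"order{order}_model.csv").write_text(
                f"order,{order}\nuniversal_patterns,0\n"
                "note,no universal patterns at this order\n"
            )
            out[order] = None
            continue
        matrix = build_matrix(tables, patterns, list(range(1, len(pieces) + 1)))
        matrix.to_csv(config.output_dir / f"order{order}_matrix.csv")
        results = _fit_matrix(matrix, config)
        _write_reports(results, order, config.output_dir)
        out[order] = results
    return out


def export_tp_table(
    sequences: Sequence[MelodicSequence], order: int, path: str | Path
) -> pd.DataFrame:
    """Per-piece transitional probabilities for every pattern observed
    anywhere in the corpus (blank where a piece lacks the context).

    Values are rounded to 3 decimals on output only.
    """
    pieces = sequences_by_piece(sequences)
    tables = [
        pool_movements(count_ngrams(m.pitches, order) for m in movements)
        for _, movements in pieces
    ]
    all_patterns = sorted({p for t in tables for p in t.patterns()})
    data = {
        str(pat): [t.probability(pat) for t in tables] for pat in all_patterns
    }
    df = pd.DataFrame(
        data, index=pd.Index([pid for pid, _ in pieces], name="piece_id")
    )
    df.round(3).to_csv(path)
    return df
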