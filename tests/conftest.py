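"""Shared fixtures: programmatic MusicXML builders and random corpora."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

STEP_OF = {0: "C", 2: "D", 4: "E", 5: "F", 7: "G", 9: "A", 11: "B"}


def note_xml(
    midi: int | None = None,
    duration: int = 1,
    chord: bool = False,
    grace: bool = False,
    tie_start: bool = False,
    tie_stop: bool = False,
    slur: str | None = None,
    voice: int = 1,
) -> str:
    """One <note> element; ``midi=None`` makes a rest."""
    parts = ["<note>"]
    if grace:
        parts.append("<grace/>")
    if chord:
        parts.append("<chord/>")
    if midi is None:
        parts.append("<rest/>")
    else:
        pc = midi % 12
        alter = 0
        if pc not in STEP_OF:
            pc -= 1
            alter = 1
        octave = midi // 12 - 1
        parts.append(
            f"<pitch><step>{STEP_OF[pc]}</step>"
            + (f"<alter>{alter}</alter>" if alter else "")
            + f"<octave>{octave}</octave></pitch>"
        )
    if not grace:
        parts.append(f"<duration>{duration}</duration>")
    parts.append(f"<voice>{voice}</voice>")
    if tie_start:
        parts.append('<tie type="start"/>')
    if tie_stop:
        parts.append('<tie type="stop"/>')
    if slur is not None:
        parts.append(f'<notations><slur type="{slur}" number="1"/></notations>')
    parts.append("</note>")
    return "".join(parts)


def score_xml(measure_bodies: list[str], divisions: int = 1) -> str:
    """A minimal single-part partwise score."""
    measures = []
    for i, body in enumerate(measure_bodies, start=1):
        attrs = (
            f"<attributes><divisions>{divisions}</divisions></attributes>"
            if i == 1
            else ""
        )
        measures.append(f'<measure number="{i}">{attrs}{body}</measure>')
    return (
        '<?xml version="1.0" encoding="UTF-8"?>'
        '<score-partwise version="3.1">'
        "<part-list><score-part id=\"P1\"><part-name>P</part-name></score-part>"
        "</part-list>"
        '<part id="P1">' + "".join(measures) + "</part></score-partwise>"
    )


@pytest.fixture
def write_score(tmp_path: Path):
    """Write a score built from measure bodies to a temp .xml file."""

    def _write(measure_bodies: list[str], name: str = "score.xml", divisions: int = 1):
        path = tmp_path / name
        path.write_text(score_xml(measure_bodies, divisions=divisions))
        return path

    return _write


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_sequence(rng: np.random.Generator, length: int) -> list[int]:
    """A bounded random-walk melody (keeps pitches in MIDI range)."""
    steps = rng.integers(-4, 5, size=length - 1)
    pitches = 60 + np.concatenate([[0], np.cumsum(steps)])
    return list(np.clip(pitches, 20, 100).astype(int))


def brute_force_table(pitches: list[int], order: int) -> dict:
    """Independent window-enumeration oracle for n-gram counting."""
    counts: dict[tuple[int, ...], dict[int, int]] = {}
    for i in range(len(pitches) - order):
        window = pitches[i : i + order + 1]
        rel = tuple(p - window[0] for p in window)
        ctx, out = rel[:-1], rel[-1]
        counts.setdefault(ctx, {})
        counts[ctx][out] = counts[ctx].get(out, 0) + 1
    return counts
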