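"""MusicXML reading, highest-pitch line extraction, and the coded-sequence CSV.

The melodic proxy used throughout the package is the *highest-pitch line*
of a movement: at every onset where a non-grace note begins, the topmost
pitch sounding at that instant.  Grace notes are excluded, tied notes and
slurred repetitions of the same pitch count as one tone.  Slurred notes of
*different* pitches are not merged — merging them would delete melodic
intervals.

Coded sequences travel as plain CSV with columns
``piece_id, movement_id, note_index, pitch`` (one note per row, header
mandatory), which round-trips exactly through :func:`write_coded_csv` and
:func:`read_coded_csv`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "NoteEvent",
    "MelodicSequence",
    "MusicXMLError",
    "EmptyScoreError",
    "SchemaError",
    "read_musicxml",
    "extract_highest_line",
    "read_coded_csv",
    "write_coded_csv",
]

_STEP_TO_SEMITONE = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}


class MusicXMLError(ValueError):
    """Malformed or unusable MusicXML input."""


class EmptyScoreError(MusicXMLError):
    """A score containing no pitched notes."""


class SchemaError(ValueError):
    """A coded-sequence CSV missing required columns."""


@dataclass(frozen=True)
class NoteEvent:
    """One notated pitched note placed on the movement's global timeline.

    ``onset`` and ``duration`` are rational times in whole-note-free
    units (quarter notes); ``pitch`` is an integer semitone number in the
    MIDI convention (C4 = 60).
    """

    onset: Fraction
    duration: Fraction
    pitch: int
    is_grace: bool = False
    tie_to_next: bool = False
    slur_ids: frozenset = frozenset()
    voice_id: str = "1"

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if not self.is_grace and self.duration <= 0:
            raise ValueError("non-grace notes must have positive duration")
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch {self.pitch} outside MIDI range 0..127")

    @property
    def offset_end(self) -> Fraction:
        return self.onset + self.duration


@dataclass
class MelodicSequence:
    """Ordered highest-pitch semitone numbers for one movement of one piece."""

    piece_id: str
    movement_id: str
    pitches: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pitches)


def _pitch_to_midi(pitch_el: etree._Element) -> int:
    step = pitch_el.findtext("step")
    if step is None or step not in _STEP_TO_SEMITONE:
        raise MusicXMLError(f"<pitch> with missing or invalid <step>: {step!r}")
    octave = pitch_el.findtext("octave")
    if octave is None:
        raise MusicXMLError("<pitch> missing <octave>")
    alter = pitch_el.findtext("alter")
    semis = _STEP_TO_SEMITONE[step] + (int(round(float(alter))) if alter else 0)
    return (int(octave) + 1) * 12 + semis


def read_musicxml(path: str | Path) -> list[NoteEvent]:
    """Read an uncompressed partwise MusicXML file into note events.

    Emits one :class:`NoteEvent` per notated pitched note across all
    parts and voices, with onsets on a single global timeline measured in
    quarter notes.  Rests produce no events.  Handles ``<chord/>``,
    ``<grace/>``, ``<tie type="start">``, slur notations, ``<backup>`` /
    ``<forward>`` and mid-part ``<divisions>`` changes.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise MusicXMLError(f"malformed MusicXML in {path.name}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "score-partwise":
        raise MusicXMLError(
            f"unsupported root element <{root.tag}>; expected <score-partwise>"
        )

    events: list[NoteEvent] = []
    slur_counter = 0
    for part_idx, part in enumerate(root.iter("part")):
        divisions = 1
        cursor = Fraction(0)
        last_onset = Fraction(0)
        open_slurs: dict[tuple[str, str], int] = {}
        for measure in part.iter("measure"):
            for el in measure:
                if el.tag == "attributes":
                    div_text = el.findtext("divisions")
                    if div_text is not None:
                        divisions = int(div_text)
                elif el.tag == "backup":
                    cursor -= Fraction(int(el.findtext("duration")), divisions)
                elif el.tag == "forward":
                    cursor += Fraction(int(el.findtext("duration")), divisions)
                elif el.tag == "note":
                    is_grace = el.find("grace") is not None
                    is_chord = el.find("chord") is not None
                    dur_text = el.findtext("duration")
                    duration = (
                        Fraction(int(dur_text), divisions) if dur_text else Fraction(0)
                    )
                    onset = last_onset if is_chord else cursor
                    if not is_chord:
                        last_onset = onset
                        cursor += duration if not is_grace else 0
                    pitch_el = el.find("pitch")
                    if pitch_el is None:  # rest or unpitched: advances time only
                        continue
                    voice = el.findtext("voice") or "1"
                    tie_to_next = any(
                        t.get("type") == "start" for t in el.findall("tie")
                    )
                    # slur bookkeeping: a slur id covers every note from its
                    # <slur type="start"> to its <slur type="stop"> inclusive
                    slurs = [
                        s
                        for notations in el.findall("notations")
                        for s in notations.findall("slur")
                    ]
                    for s in slurs:
                        if s.get("type") == "start":
                            slur_counter += 1
                            open_slurs[(voice, s.get("number", "1"))] = slur_counter
                    note_slurs = frozenset(
                        sid
                        for (v, _), sid in open_slurs.items()
                        if v == voice
                    )
                    for s in slurs:
                        if s.get("type") == "stop":
                            open_slurs.pop((voice, s.get("number", "1")), None)
                    events.append(
                        NoteEvent(
                            onset=onset,
                            duration=duration if not is_grace else Fraction(0),
                            pitch=_pitch_to_midi(pitch_el),
                            is_grace=is_grace,
                            tie_to_next=tie_to_next,
                            slur_ids=note_slurs,
                            voice_id=f"P{part_idx + 1}:{voice}",
                        )
                    )
    if not any(not e.is_grace for e in events) and not events:
        raise EmptyScoreError(f"{path.name} contains no pitched notes")
    events.sort(key=lambda e: (e.onset, -e.pitch))
    return events


def _merge_with_previous(prev: NoteEvent, cur: NoteEvent) -> bool:
    """Whether two consecutive highest-line emissions count as one tone."""
    if prev is cur:  # one sustained note emitted at successive onsets
        return True
    if prev.pitch != cur.pitch:
        return False
    if prev.tie_to_next and cur.onset == prev.offset_end:
        return True
    # slurred immediate repetition of the same pitch
    return bool(prev.slur_ids & cur.slur_ids)


def extract_highest_line(
    events: Sequence[NoteEvent],
    piece_id: str = "",
    movement_id: str = "",
) -> MelodicSequence:
    """Extract the highest-pitch line of one movement.

    At each distinct onset where at least one non-grace note begins, the
    maximum pitch among all non-grace notes *sounding* at that onset
    (started and not yet ended) is emitted; consecutive emissions are
    merged into one element when they arise from a sustained note, a tie,
    or a slurred repetition of the same pitch.  Grace notes are never
    emitted and never trigger an emission.
    """
    sounding = [e for e in events if not e.is_grace]
    if not sounding:
        raise EmptyScoreError("no non-grace events to extract a line from")
    sounding.sort(key=lambda e: e.onset)
    onsets = sorted({e.onset for e in sounding})
    pitches: list[int] = []
    prev_event: NoteEvent | None = None
    for t in onsets:
        active = [e for e in sounding if e.onset <= t < e.offset_end]
        if not active:
            continue
        # prefer the note that actually starts here among equal top pitches
        top = max(active, key=lambda e: (e.pitch, e.onset == t))
        if prev_event is not None and _merge_with_previous(prev_event, top):
            prev_event = top
            continue
        pitches.append(top.pitch)
        prev_event = top
    return MelodicSequence(piece_id=piece_id, movement_id=movement_id, pitches=pitches)


_CODED_COLUMNS = ["piece_id", "movement_id", "note_index", "pitch"]


def write_coded_csv(sequences: Iterable[MelodicSequence], path: str | Path) -> None:
    """Write melodic sequences as a coded-sequence CSV (one note per row)."""
    rows = [
        (seq.piece_id, seq.movement_id, i, p)
        for seq in sequences
        for i, p in enumerate(seq.pitches)
    ]
    df = pd.DataFrame(rows, columns=_CODED_COLUMNS)
    df.to_csv(path, index=False)


def read_coded_csv(path: str | Path) -> list[MelodicSequence]:
    """Read a coded-sequence CSV back into melodic sequences.

    Sequences are returned grouped by (piece_id, movement_id) in file row
    order; a gap in ``note_index`` is preserved (row order wins) but
    logged as a warning.
    """
    df = pd.read_csv(path, dtype={"piece_id": str, "movement_id": str})
    missing = [c for c in _CODED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"coded CSV missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        return []
    if not pd.api.types.is_integer_dtype(df["pitch"]):
        raise ValueError("coded CSV column 'pitch' must contain integers")
    sequences: list[MelodicSequence] = []
    seen: dict[tuple[str, str], MelodicSequence] = {}
    for row in df.itertuples(index=False):
        key = (row.piece_id, row.movement_id)
        if key not in seen:
            seq = MelodicSequence(piece_id=row.piece_id, movement_id=row.movement_id)
            seen[key] = seq
            sequences.append(seq)
        seq = seen[key]
        if int(row.note_index) != len(seq.pitches):
            logger.warning(
                "note_index gap in %s/%s at row index %d; keeping file row order",
                row.piece_id,
                row.movement_id,
                row.note_index,
            )
        seq.pitches.append(int(row.pitch))
    return sequences
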