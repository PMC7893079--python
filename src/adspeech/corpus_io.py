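"""Reading and writing the cohort: CHAT transcripts, segment feature tables, metadata.

The transcript dialect is the minimal CHAT subset needed for rate-type disfluency
features: ``*PAR:``/``*INV:`` main tiers, ``&``-prefixed filled pauses, ``(.)``
``(..)`` ``(...)`` unfilled pauses, ``[/]`` repetitions and ``[//]`` retraces.
All other inline codes are stripped; dependent (``%``) and header (``@``) tiers
are ignored. Punctuation is dropped from the token stream.

Acoustic feature tables are plain CSV, one row per voice-activity-detected
segment in temporal order, with a mandatory ``duration_s`` column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

PARTICIPANT = "participant"
INTERVIEWER = "interviewer"

FILLED_PAUSE = "filled-pause"
UNFILLED_PAUSE = "unfilled-pause"
REPETITION = "repetition"
RETRACE = "retrace"
MARKER_KINDS = (FILLED_PAUSE, UNFILLED_PAUSE, REPETITION, RETRACE)

DURATION_COLUMN = "duration_s"

_TIER_RE = re.compile(r"^\*([A-Z]{3}):\s*(.*)$")
_SPEAKER_CODES = {"PAR": PARTICIPANT, "INV": INTERVIEWER}
_SPEAKER_TO_CODE = {v: k for k, v in _SPEAKER_CODES.items()}
_UNFILLED = {"(.)", "(..)", "(...)"}
_PUNCT = {".", "?", "!", ",", ";", ":", "+...", "+..?", "+/.", "+//."}
_MARKER_CODE = {REPETITION: "[/]", RETRACE: "[//]"}


class ChatParseError(ValueError):
    """Raised for malformed transcript input; message names the offending line."""


@dataclass(frozen=True)
class Marker:
    """A disfluency annotation anchored after ``position`` tokens of its utterance."""

    kind: str
    position: int


@dataclass(frozen=True)
class Utterance:
    speaker: str
    tokens: tuple[str, ...]
    markers: tuple[Marker, ...] = ()

    def __post_init__(self):
        if self.speaker not in (PARTICIPANT, INTERVIEWER):
            raise ValueError(f"unknown speaker role {self.speaker!r}")
        for m in self.markers:
            if m.kind not in MARKER_KINDS:
                raise ValueError(f"unknown marker kind {m.kind!r}")

    def marker_kinds(self) -> tuple[str, ...]:
        return tuple(m.kind for m in self.markers)


@dataclass(frozen=True)
class Transcript:
    participant_id: str
    utterances: tuple[Utterance, ...]

    def participant_tokens(self) -> list[str]:
        return [t for u in self.utterances if u.speaker == PARTICIPANT
                for t in u.tokens]

    def interviewer_utterance_count(self) -> int:
        return sum(1 for u in self.utterances if u.speaker == INTERVIEWER)

    def marker_count(self, kind: str) -> int:
        if kind not in MARKER_KINDS:
            raise ValueError(f"unknown marker kind {kind!r}")
        return sum(1 for u in self.utterances if u.speaker == PARTICIPANT
                   for m in u.markers if m.kind == kind)


@dataclass
class SessionAcoustics:
    participant_id: str
    feature_set_name: str
    matrix: np.ndarray            # segments x features, rows in temporal order
    durations: np.ndarray         # seconds, one per segment
    feature_names: tuple[str, ...]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D (segments x features)")
        if self.matrix.shape[0] != self.durations.shape[0]:
            raise ValueError("segment count and duration count differ")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match matrix columns")
        if not (self.durations > 0).all():
            raise ValueError("segment durations must be strictly positive")

    @property
    def n_segments(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Participant:
    id: str
    label: str                    # "AD" | "non-AD"
    age: float
    gender: str                   # "male" | "female"
    transcript: Transcript
    acoustics: SessionAcoustics

    def __post_init__(self):
        if self.label not in ("AD", "non-AD"):
            raise ValueError(f"label must be AD or non-AD, got {self.label!r}")
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be male or female, got {self.gender!r}")


@dataclass
class Cohort:
    participants: list[Participant]
    split: dict[str, str] = field(default_factory=dict)   # id -> "train" | "test"

    def __post_init__(self):
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate participant id in cohort")
        for pid, s in self.split.items():
            if s not in ("train", "test"):
                raise ValueError(f"split for {pid!r} must be train or test")

    def subset(self, which: str) -> list[Participant]:
        return [p for p in self.participants if self.split.get(p.id) == which]

    @property
    def train(self) -> list[Participant]:
        return self.subset("train")

    @property
    def test(self) -> list[Participant]:
        return self.subset("test")

    def labels(self, participants: list[Participant] | None = None) -> np.ndarray:
        ps = self.participants if participants is None else participants
        return np.array([1 if p.label == "AD" else 0 for p in ps])


# ---------------------------------------------------------------------------
# CHAT parsing / writing
# ---------------------------------------------------------------------------

_OTHER_BRACKET_RE = re.compile(r"\[(?!/{1,2}\])[^\]]*\]")


def _parse_main_line(content: str, lineno: int) -> tuple[tuple[str, ...], tuple[Marker, ...]]:
    content = _OTHER_BRACKET_RE.sub(" ", content)   # strip non-marker codes
    tokens: list[str] = []
    markers: list[Marker] = []
    for raw in content.split():
        if raw in _UNFILLED:
            markers.append(Marker(UNFILLED_PAUSE, len(tokens)))
        elif raw == "[/]":
            markers.append(Marker(REPETITION, len(tokens)))
        elif raw == "[//]":
            markers.append(Marker(RETRACE, len(tokens)))
        elif raw.startswith("&"):
            # &-um (modern) or &um (legacy) filler; never a lexical token
            markers.append(Marker(FILLED_PAUSE, len(tokens)))
        elif raw.startswith("[") and raw.endswith("]"):
            continue                      # other bracketed codes stripped
        elif raw in _PUNCT:
            continue
        else:
            word = raw.strip("<>")
            if word:
                tokens.append(word)
    return tuple(tokens), tuple(markers)


def parse_chat(text: str, participant_id: str = "unknown") -> Transcript:
    """Parse a CHAT-dialect transcript string into a :class:`Transcript`."""
    if not text.strip():
        raise ChatParseError("empty transcript file")
    # join tab-indented continuation lines onto their tier line
    logical: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line[0] in " \t":
            if not logical:
                raise ChatParseError(f"line {lineno}: continuation without a tier line")
            prev_no, prev = logical[-1]
            logical[-1] = (prev_no, prev + " " + line.strip())
        else:
            logical.append((lineno, line.rstrip()))

    utterances: list[Utterance] = []
    for lineno, line in logical:
        if line.startswith("@") or line.startswith("%"):
            continue
        if not line.startswith("*"):
            raise ChatParseError(f"line {lineno}: expected a tier line, got {line[:30]!r}")
        m = _TIER_RE.match(line)
        if m is None:
            raise ChatParseError(f"line {lineno}: malformed speaker tier {line[:30]!r}")
        code = m.group(1)
        if code not in _SPEAKER_CODES:
            raise ChatParseError(f"line {lineno}: unknown speaker code *{code}")
        tokens, markers = _parse_main_line(m.group(2), lineno)
        if not tokens and not markers:
            continue                      # empty main line
        utterances.append(Utterance(_SPEAKER_CODES[code], tokens, markers))
    if not utterances:
        raise ChatParseError("transcript contains no utterances")
    return Transcript(participant_id, tuple(utterances))


def write_chat(transcript: Transcript) -> str:
    """Serialize to the canonical dialect; re-parsing reproduces the Transcript."""
    lines = ["@Begin"]
    for u in transcript.utterances:
        pieces: list[str] = []
        by_pos: dict[int, list[str]] = {}
        for m in u.markers:
            if m.kind == FILLED_PAUSE:
                code = "&-uh"
            elif m.kind == UNFILLED_PAUSE:
                code = "(.)"
            else:
                code = _MARKER_CODE[m.kind]
            by_pos.setdefault(m.position, []).append(code)
        for i, tok in enumerate(u.tokens):
            pieces.extend(by_pos.get(i, []))
            pieces.append(tok)
        pieces.extend(by_pos.get(len(u.tokens), []))
        pieces.append(".")
        lines.append(f"*{_SPEAKER_TO_CODE[u.speaker]}:\t" + " ".join(pieces))
    lines.append("@End")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Feature tables and metadata
# ---------------------------------------------------------------------------

def load_feature_table(path: str | Path, feature_set_name: str,
                       participant_id: str | None = None) -> SessionAcoustics:
    """Load a per-segment acoustic feature CSV (temporal row order preserved)."""
    path = Path(path)
    df = pd.read_csv(path)
    if DURATION_COLUMN not in df.columns:
        raise ValueError(f"{path.name}: missing required column {DURATION_COLUMN!r}")
    if len(df) == 0:
        raise ValueError(f"{path.name}: feature table has zero segments")
    durations = pd.to_numeric(df[DURATION_COLUMN], errors="raise").to_numpy()
    feats = df.drop(columns=[DURATION_COLUMN])
    try:
        matrix = feats.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path.name}: non-numeric feature cell ({exc})") from exc
    return SessionAcoustics(
        participant_id=participant_id or path.stem,
        feature_set_name=feature_set_name,
        matrix=matrix,
        durations=durations,
        feature_names=tuple(feats.columns),
    )


def write_feature_table(acoustics: SessionAcoustics, path: str | Path):
    df = pd.DataFrame(acoustics.matrix, columns=list(acoustics.feature_names))
    df.insert(0, DURATION_COLUMN, acoustics.durations)
    df.to_csv(path, index=False)


def assemble_cohort(transcripts: dict[str, Transcript],
                    acoustics: dict[str, SessionAcoustics],
                    metadata: pd.DataFrame) -> tuple[Cohort, dict[str, list[str]]]:
    """Inner-join the three sources on participant id.

    ``metadata`` needs columns id, label, age, gender and optionally split.
    Returns the cohort plus a report of ids present in some sources only.
    """
    for name, mapping in (("transcripts", transcripts), ("acoustics", acoustics)):
        if len(mapping) != len(set(mapping)):
            raise ValueError(f"duplicate participant id in {name}")
    ids_meta = list(metadata["id"].astype(str))
    if len(ids_meta) != len(set(ids_meta)):
        raise ValueError("duplicate participant id in metadata")
    if metadata["label"].isna().any():
        raise ValueError("participant with missing label in metadata")

    sets = {"transcripts": set(map(str, transcripts)),
            "acoustics": set(map(str, acoustics)),
            "metadata": set(ids_meta)}
    common = sets["transcripts"] & sets["acoustics"] & sets["metadata"]
    unmatched = {name: sorted(s - common) for name, s in sets.items() if s - common}

    meta = metadata.assign(id=metadata["id"].astype(str)).set_index("id")
    participants: list[Participant] = []
    split: dict[str, str] = {}
    for pid in ids_meta:                      # metadata order is canonical
        if pid not in common:
            continue
        row = meta.loc[pid]
        if pd.isna(row.get("age")):
            raise ValueError(f"participant {pid}: missing age")
        participants.append(Participant(
            id=pid, label=str(row["label"]), age=float(row["age"]),
            gender=str(row["gender"]),
            transcript=replace(transcripts[pid], participant_id=pid),
            acoustics=acoustics[pid],
        ))
        if "split" in meta.columns and not pd.isna(row["split"]):
            split[pid] = str(row["split"])
    return Cohort(participants, split), unmatched


# ---------------------------------------------------------------------------
# On-disk cohort manifest
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, out_dir: str | Path):
    """Write a cohort as one metadata CSV plus per-participant .cha/.csv files."""
    out = Path(out_dir)
    (out / "transcripts").mkdir(parents=True, exist_ok=True)
    (out / "acoustics").mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.participants:
        (out / "transcripts" / f"{p.id}.cha").write_text(write_chat(p.transcript))
        write_feature_table(p.acoustics, out / "acoustics" / f"{p.id}.csv")
        rows.append({"id": p.id, "label": p.label, "age": p.age,
                     "gender": p.gender,
                     "split": cohort.split.get(p.id, ""),
                     "feature_set": p.acoustics.feature_set_name})
    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False)


def load_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    meta = pd.read_csv(src / "metadata.csv")
    feature_set = str(meta["feature_set"].iloc[0]) if "feature_set" in meta else "custom"
    transcripts, acoustics = {}, {}
    for pid in meta["id"].astype(str):
        transcripts[pid] = parse_chat(
            (src / "transcripts" / f"{pid}.cha").read_text(), participant_id=pid)
        acoustics[pid] = load_feature_table(
            src / "acoustics" / f"{pid}.csv", feature_set, participant_id=pid)
    cohort, unmatched = assemble_cohort(transcripts, acoustics, meta)
    if unmatched:
        raise ValueError(f"inconsistent cohort directory: unmatched ids {unmatched}")
    return cohort
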