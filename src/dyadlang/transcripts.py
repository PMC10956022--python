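"""Data model and I/O for two-speaker timestamped psychotherapy transcripts.

A session is an ordered list of talk turns — maximal spans of speech by one
speaker, bounded by a change of speaker — each carrying start/end offsets in
seconds from session start and the raw utterance text.  Session metadata links
the transcript to a therapist, a patient, an admitting diagnosis and an
(optional) PHQ-9 depression severity score.

Two on-disk dialects are supported:

* CSV — ``transcripts.csv`` with columns ``session_id, turn_index, speaker,
  start_s, end_s, text`` (speaker coded ``T``/``P``) and ``metadata.csv`` with
  columns ``session_id, therapist_id, patient_id, diagnosis, phq9, sample``.
* JSON — a transcript file holding an array of ``{session_id, turns: [...]}``
  objects and a metadata file holding an array of metadata objects.

Validation never throws on bad content: problems are reported as
:class:`ValidationIssue` records attached to the returned :class:`Corpus`.
"""

from __future__ import annotations

import json
import math
import re
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
import pandas as pd

THERAPIST = "therapist"
PATIENT = "patient"
ROLES = (THERAPIST, PATIENT)
DIAGNOSES = ("depression", "eating_disorder", "unknown")
SAMPLES = ("primary", "secondary")

_SPEAKER_CODES = {"T": THERAPIST, "P": PATIENT, THERAPIST: THERAPIST, PATIENT: PATIENT}
_SPEAKER_OUT = {THERAPIST: "T", PATIENT: "P"}

PHQ9_MAX = 27


class TranscriptFormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


@dataclass(frozen=True)
class TalkTurn:
    """One maximal same-speaker span of speech."""

    turn_index: int
    speaker: str
    start_s: float
    end_s: float
    text: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class SessionMetadata:
    session_id: str
    therapist_id: str
    patient_id: str
    diagnosis: str = "unknown"
    phq9: int | None = None
    sample: str = "primary"


@dataclass
class SessionTranscript:
    metadata: SessionMetadata
    turns: list[TalkTurn]

    @property
    def session_id(self) -> str:
        return self.metadata.session_id

    @property
    def duration_s(self) -> float:
        return max((t.end_s for t in self.turns), default=0.0)

    def turns_for(self, speaker: str) -> list[TalkTurn]:
        return [t for t in self.turns if t.speaker == speaker]


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str
    location: str


@dataclass
class Corpus:
    sessions: list[SessionTranscript]
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def primary_sessions(self) -> list[SessionTranscript]:
        return [s for s in self.sessions if s.metadata.sample == "primary"]

    @property
    def secondary_sessions(self) -> list[SessionTranscript]:
        return [s for s in self.sessions if s.metadata.sample == "secondary"]

    @property
    def primary_count(self) -> int:
        return len(self.primary_sessions)

    @property
    def secondary_count(self) -> int:
        return len(self.secondary_sessions)

    def session(self, session_id: str) -> SessionTranscript:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise KeyError(session_id)


# ---------------------------------------------------------------------------
# validation


def validate_transcript(t: SessionTranscript) -> list[ValidationIssue]:
    """Report every invariant violation in one transcript.

    The validator reports and never throws.  Same-speaker adjacency is
    reported as a "merge candidate" warning (see :func:`merge_same_speaker`);
    everything else is an error.
    """
    issues: list[ValidationIssue] = []
    sid = t.session_id

    def err(msg: str, loc: str) -> None:
        issues.append(ValidationIssue("error", msg, loc))

    def warn(msg: str, loc: str) -> None:
        issues.append(ValidationIssue("warning", msg, loc))

    if len(t.turns) < 2:
        err("transcript has fewer than 2 turns", sid)
    roles = {u.speaker for u in t.turns}
    for r in roles - set(ROLES):
        err(f"unknown speaker role {r!r}", sid)
    if t.turns and not roles.issuperset(ROLES):
        err("both speaker roles must be present", sid)
    if t.turns and t.duration_s <= 0:
        err("session duration must be positive", sid)

    for u in t.turns:
        if u.start_s < 0 or u.end_s < u.start_s:
            err(
                f"turn {u.turn_index}: requires end_s >= start_s >= 0 "
                f"(got start={u.start_s}, end={u.end_s})",
                f"{sid}:turn{u.turn_index}",
            )
    for a, b in zip(t.turns, t.turns[1:]):
        if b.start_s < a.start_s:
            err(
                f"turns {a.turn_index},{b.turn_index}: not sorted by start_s",
                f"{sid}:turn{b.turn_index}",
            )
        elif b.start_s < a.end_s:
            err(
                f"turns {a.turn_index},{b.turn_index}: overlap",
                f"{sid}:turn{a.turn_index},{b.turn_index}",
            )
        if a.speaker == b.speaker:
            warn(
                f"turns {a.turn_index},{b.turn_index}: same-speaker adjacency "
                "(merge candidate)",
                f"{sid}:turn{a.turn_index},{b.turn_index}",
            )

    md = t.metadata
    if md.diagnosis not in DIAGNOSES:
        err(f"unknown diagnosis {md.diagnosis!r}", sid)
    if md.phq9 is not None and not (0 <= md.phq9 <= PHQ9_MAX):
        err(f"phq9 {md.phq9} outside [0, {PHQ9_MAX}]", sid)
    if md.sample not in SAMPLES:
        err(f"unknown sample {md.sample!r}", sid)
    return issues


def merge_same_speaker(t: SessionTranscript) -> SessionTranscript:
    """Merge consecutive same-speaker turns into maximal spans.

    Texts are joined by a single space; the merged turn runs from the first
    start to the last end.  Turn indices are renumbered 0..n-1.  After this
    fix-up every transcript strictly alternates speakers.
    """
    merged: list[TalkTurn] = []
    for u in t.turns:
        if merged and merged[-1].speaker == u.speaker:
            prev = merged[-1]
            merged[-1] = TalkTurn(
                turn_index=prev.turn_index,
                speaker=prev.speaker,
                start_s=prev.start_s,
                end_s=max(prev.end_s, u.end_s),
                text=(prev.text + " " + u.text).strip(),
            )
        else:
            merged.append(u)
    merged = [replace(u, turn_index=i) for i, u in enumerate(merged)]
    return SessionTranscript(metadata=t.metadata, turns=merged)


def validate_corpus(c: Corpus) -> list[ValidationIssue]:
    """Corpus-level invariants on top of per-transcript validation."""
    issues: list[ValidationIssue] = []
    for s in c.sessions:
        issues.extend(validate_transcript(s))
    primary = {
        (s.metadata.therapist_id, s.metadata.patient_id) for s in c.primary_sessions
    }
    seen_pairs: set[tuple[str, str]] = set()
    for s in c.primary_sessions:
        pair = (s.metadata.therapist_id, s.metadata.patient_id)
        if pair in seen_pairs:
            issues.append(
                ValidationIssue(
                    "error",
                    f"duplicate primary dyad {pair}",
                    s.session_id,
                )
            )
        seen_pairs.add(pair)
    primary_therapists = {s.metadata.therapist_id for s in c.primary_sessions}
    for s in c.secondary_sessions:
        tid = s.metadata.therapist_id
        if tid not in primary_therapists:
            issues.append(
                ValidationIssue(
                    "error",
                    f"secondary session therapist {tid!r} absent from primary sample",
                    s.session_id,
                )
            )
        elif (tid, s.metadata.patient_id) in primary:
            issues.append(
                ValidationIssue(
                    "error",
                    f"secondary session repeats primary dyad ({tid}, "
                    f"{s.metadata.patient_id})",
                    s.session_id,
                )
            )
    return issues


# ---------------------------------------------------------------------------
# parsing helpers

_MMSS = re.compile(r"^\s*(\d+):([0-5]?\d(?:\.\d+)?)\s*$")


def parse_time_s(value) -> float:
    """Parse a timestamp: float seconds or a ``mm:ss(.fff)`` string."""
    if isinstance(value, (int, float)):
        v = float(value)
        if math.isnan(v):
            raise ValueError("missing timestamp")
        return v
    s = str(value).strip()
    m = _MMSS.match(s)
    if m:
        return 60.0 * int(m.group(1)) + float(m.group(2))
    return float(s)  # raises ValueError on garbage


def _norm_text(text) -> str:
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return ""
    return unicodedata.normalize("NFC", str(text))


def _parse_phq9(value) -> int | None:
    if value is None or value == "":
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return int(value)


# ---------------------------------------------------------------------------
# readers


_TRANSCRIPT_COLS = ["session_id", "turn_index", "speaker", "start_s", "end_s", "text"]
_METADATA_COLS = ["session_id", "therapist_id", "patient_id", "diagnosis", "phq9", "sample"]


def read_corpus(
    transcript_path: str | Path,
    metadata_path: str | Path,
    format: str = "csv",
    merge: bool = True,
) -> Corpus:
    """Read and validate a corpus from disk.

    Sessions with fatal issues are kept in the corpus with their problems
    listed in ``corpus.issues``; they are never silently dropped.  With
    ``merge=True`` (the default) same-speaker adjacent turns are merged so
    that "talk turn" means a maximal same-speaker span.
    """
    if format == "csv":
        turn_rows, meta_rows = _read_csv(transcript_path, metadata_path)
    elif format == "json":
        turn_rows, meta_rows = _read_json(transcript_path, metadata_path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return _assemble(turn_rows, meta_rows, merge=merge)


def _read_csv(transcript_path, metadata_path):
    tdf = pd.read_csv(transcript_path, dtype={"session_id": str}, keep_default_na=False,
                      na_values=[""])
    mdf = pd.read_csv(metadata_path, dtype=str, keep_default_na=False, na_values=[])
    for col in _TRANSCRIPT_COLS:
        if col not in tdf.columns:
            raise TranscriptFormatError(f"transcript file missing column {col!r}")
    for col in _METADATA_COLS:
        if col not in mdf.columns:
            raise TranscriptFormatError(f"metadata file missing column {col!r}")
    turn_rows = tdf.to_dict("records")
    meta_rows = mdf.to_dict("records")
    return turn_rows, meta_rows


def _read_json(transcript_path, metadata_path):
    with open(transcript_path, encoding="utf-8") as fh:
        sessions = json.load(fh)
    with open(metadata_path, encoding="utf-8") as fh:
        meta_rows = json.load(fh)
    if not isinstance(sessions, list) or not isinstance(meta_rows, list):
        raise TranscriptFormatError("JSON dialect expects top-level arrays")
    turn_rows = []
    for sess in sessions:
        if "session_id" not in sess or "turns" not in sess:
            raise TranscriptFormatError("JSON session object needs session_id and turns")
        for turn in sess["turns"]:
            row = dict(turn)
            row["session_id"] = sess["session_id"]
            turn_rows.append(row)
    return turn_rows, meta_rows


def _assemble(turn_rows, meta_rows, merge: bool) -> Corpus:
    issues: list[ValidationIssue] = []
    meta_by_sid: dict[str, SessionMetadata] = {}
    for i, row in enumerate(meta_rows):
        sid = str(row["session_id"])
        try:
            phq9 = _parse_phq9(row.get("phq9"))
        except (TypeError, ValueError):
            issues.append(
                ValidationIssue("error", f"metadata row {i}: unparseable phq9 "
                                f"{row.get('phq9')!r}", sid)
            )
            phq9 = None
        meta_by_sid[sid] = SessionMetadata(
            session_id=sid,
            therapist_id=str(row["therapist_id"]),
            patient_id=str(row["patient_id"]),
            diagnosis=str(row.get("diagnosis") or "unknown"),
            phq9=phq9,
            sample=str(row.get("sample") or "primary"),
        )

    turns_by_sid: dict[str, list[TalkTurn]] = {}
    for i, row in enumerate(turn_rows):
        sid = str(row["session_id"])
        speaker = _SPEAKER_CODES.get(str(row["speaker"]).strip())
        if speaker is None:
            issues.append(
                ValidationIssue("error", f"row {i}: unknown speaker "
                                f"{row['speaker']!r}", f"{sid}:row{i}")
            )
            continue
        try:
            start_s = parse_time_s(row["start_s"])
            end_s = parse_time_s(row["end_s"])
        except (TypeError, ValueError):
            issues.append(
                ValidationIssue("error", f"row {i}: unparseable timestamp",
                                f"{sid}:row{i}")
            )
            continue
        turns_by_sid.setdefault(sid, []).append(
            TalkTurn(
                turn_index=int(row["turn_index"]),
                speaker=speaker,
                start_s=start_s,
                end_s=end_s,
                text=_norm_text(row.get("text")),
            )
        )

    sessions = []
    for sid, turns in turns_by_sid.items():
        md = meta_by_sid.get(sid)
        if md is None:
            issues.append(
                ValidationIssue("error", "transcript session has no metadata row", sid)
            )
            md = SessionMetadata(session_id=sid, therapist_id="?", patient_id="?")
        turns = sorted(turns, key=lambda u: (u.start_s, u.turn_index))
        sess = SessionTranscript(metadata=md, turns=turns)
        issues.extend(validate_transcript(sess))
        if merge:
            sess = merge_same_speaker(sess)
        sessions.append(sess)
    for sid, md in meta_by_sid.items():
        if sid not in turns_by_sid:
            issues.append(
                ValidationIssue("warning", "metadata row has no transcript turns", sid)
            )
    sessions.sort(key=lambda s: s.session_id)
    corpus = Corpus(sessions=sessions, issues=issues)
    issues.extend(
        i for i in validate_corpus(corpus) if i not in issues
    )
    return corpus


# ---------------------------------------------------------------------------
# writers


def write_corpus(
    c: Corpus, out_path: str | Path, format: str = "csv"
) -> dict[str, Path]:
    """Write a corpus; ``read_corpus`` on the result reproduces it.

    Times are written to millisecond precision; text is UTF-8.
    Returns a mapping ``{"transcripts": path, "metadata": path}``.
    """
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        tpath = out / "transcripts.csv"
        mpath = out / "metadata.csv"
        trows = [
            {
                "session_id": s.session_id,
                "turn_index": u.turn_index,
                "speaker": _SPEAKER_OUT[u.speaker],
                "start_s": f"{u.start_s:.3f}",
                "end_s": f"{u.end_s:.3f}",
                "text": u.text,
            }
            for s in c.sessions
            for u in s.turns
        ]
        pd.DataFrame(trows, columns=_TRANSCRIPT_COLS).to_csv(tpath, index=False)
        pd.DataFrame(
            [_meta_row(s.metadata) for s in c.sessions], columns=_METADATA_COLS
        ).to_csv(mpath, index=False)
    elif format == "json":
        tpath = out / "transcripts.json"
        mpath = out / "metadata.json"
        sessions = [
            {
                "session_id": s.session_id,
                "turns": [
                    {
                        "turn_index": u.turn_index,
                        "speaker": _SPEAKER_OUT[u.speaker],
                        "start_s": round(u.start_s, 3),
                        "end_s": round(u.end_s, 3),
                        "text": u.text,
                    }
                    for u in s.turns
                ],
            }
            for s in c.sessions
        ]
        tpath.write_text(
            json.dumps(sessions, ensure_ascii=False, indent=1), encoding="utf-8"
        )
        mpath.write_text(
            json.dumps(
                [_meta_row(s.metadata) for s in c.sessions],
                ensure_ascii=False,
                indent=1,
            ),
            encoding="utf-8",
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    return {"transcripts": tpath, "metadata": mpath}


def _meta_row(md: SessionMetadata) -> dict:
    return {
        "session_id": md.session_id,
        "therapist_id": md.therapist_id,
        "patient_id": md.patient_id,
        "diagnosis": md.diagnosis,
        "phq9": "" if md.phq9 is None else md.phq9,
        "sample": md.sample,
    }
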