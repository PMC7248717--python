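"""Domain types and tabular I/O for reading-session studies.

A *study* bundles, per participant and session, a 90 Hz gaze stream, a 4 Hz
skin-conductance (EDA) stream, the paragraph presentation schedule with its
text-type / music-type condition labels, per-paragraph questionnaire answers,
and the self-caught mind-wandering button presses.  All times are milliseconds
from session start and every interval is half-open ``[onset, offset)`` so a
sample belongs to at most one paragraph.

Streams are held as :class:`pandas.DataFrame` objects with fixed schemas:

====================  =====================================================
stream                columns
====================  =====================================================
gaze                  ``t, x, y, pupil, valid``
eda                   ``t, sc``
====================  =====================================================

On disk a study is a directory of UTF-8 comma-separated files with header
rows: ``paragraphs.csv``, ``self_reports.csv``, ``mw_reports.csv`` and one
``gaze_<participant>_<session>.csv`` / ``eda_<participant>_<session>.csv``
pair per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GAZE_COLUMNS = ["t", "x", "y", "pupil", "valid"]
EDA_COLUMNS = ["t", "sc"]

TEXT_TYPES = ("ComputerScience", "Psychology", "Random")
MUSIC_TYPES = ("Sad", "Happy", "NoMusic")

PARAGRAPH_COLUMNS = [
    "participant",
    "session",
    "paragraph",
    "onset",
    "offset",
    "text_type",
    "music_type",
]

SELF_REPORT_COLUMNS = [
    "participant",
    "session",
    "paragraph",
    "interest",
    "difficulty",
    "tiredness",
    "happiness",
    "sadness",
    "relevance",
    "attentional_focus",
    "trt",
    "tut",
    "reading_duration",
]

MW_REPORT_COLUMNS = ["participant", "session", "t"]


class StudyLoadError(RuntimeError):
    """A study directory is missing files or contains malformed rows."""


class StudyValidationError(ValueError):
    """A stream violates a structural invariant (e.g. non-monotone time)."""


@dataclass(frozen=True)
class ParagraphEvent:
    """One reading segment with its experimental condition.

    ``music_type`` is the stimulus actually played during this paragraph
    (``NoMusic`` for the within-session control paragraphs); the session it
    belongs to is either a Sad- or a Happy-music session.
    """

    participant: str
    session: str
    paragraph: str
    onset: float
    offset: float
    text_type: str
    music_type: str

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise StudyValidationError(
                f"paragraph {self.paragraph}: onset {self.onset} >= offset {self.offset}"
            )
        if self.text_type not in TEXT_TYPES:
            raise StudyValidationError(f"unknown text_type {self.text_type!r}")
        if self.music_type not in MUSIC_TYPES:
            raise StudyValidationError(f"unknown music_type {self.music_type!r}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class SelfReport:
    """Post-paragraph questionnaire answers.

    Ratings are on the printed 0-100 scale in steps of 20; attentional focus
    is an integer in -5..+5 (-5 = absorbed in own thoughts, +5 = focused on
    the text).  The task-related / task-unrelated thought booleans are only
    collected when attentional focus < +3, otherwise they are ``None``.
    """

    participant: str
    session: str
    paragraph: str
    interest: float
    difficulty: float
    tiredness: float
    happiness: float
    sadness: float
    relevance: float
    attentional_focus: int
    trt: bool | None
    tut: bool | None
    reading_duration: float


@dataclass(frozen=True)
class MWReport:
    """A self-caught mind-wandering button press at session time ``t`` ms."""

    participant: str
    session: str
    t: float


@dataclass
class Study:
    """In-memory study: streams keyed by ``(participant, session)``."""

    participants: list[str]
    sessions: list[tuple[str, str]]
    gaze: dict[tuple[str, str], pd.DataFrame]
    eda: dict[tuple[str, str], pd.DataFrame]
    paragraphs: list[ParagraphEvent]
    self_reports: list[SelfReport]
    mw_reports: list[MWReport]
    ground_truth: "object | None" = None
    pupil_standardized: bool = False
    _by_id: dict[str, ParagraphEvent] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {p.paragraph: p for p in self.paragraphs}

    def paragraph(self, paragraph_id: str) -> ParagraphEvent:
        try:
            return self._by_id[paragraph_id]
        except KeyError:
            raise KeyError(f"unknown paragraph id {paragraph_id!r}") from None

    def session_span(self, key: tuple[str, str]) -> tuple[float, float]:
        """Recording span ``[t_min, t_max]`` across both streams of a session."""
        ts = []
        for streams in (self.gaze, self.eda):
            df = streams.get(key)
            if df is not None and len(df):
                ts.append((float(df["t"].iloc[0]), float(df["t"].iloc[-1])))
        if not ts:
            return (0.0, 0.0)
        return (min(a for a, _ in ts), max(b for _, b in ts))


def slice_paragraph(study: Study, paragraph_id: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return the gaze and EDA samples of one paragraph.

    Samples with ``onset <= t < offset`` are returned in stream order; the
    boundary sample at ``offset`` belongs to the next paragraph.
    """
    ev = study.paragraph(paragraph_id)
    key = (ev.participant, ev.session)
    out = []
    for streams in (study.gaze, study.eda):
        df = streams.get(key)
        if df is None or not len(df):
            out.append(df.iloc[0:0] if df is not None else pd.DataFrame())
            continue
        t = df["t"].to_numpy()
        lo = int(np.searchsorted(t, ev.onset, side="left"))
        hi = int(np.searchsorted(t, ev.offset, side="left"))
        out.append(df.iloc[lo:hi])
    return out[0], out[1]


def validate_study(study: Study) -> list[str]:
    """Check all structural invariants; return a list of violation messages.

    The report is empty iff the study is valid.  Checked: strictly increasing
    timestamps per stream, non-negative gaze times, paragraph intervals valid
    and pairwise disjoint within a session, self reports resolving to known
    paragraphs, TRT/TUT answered only under the focus < +3 gate, and every
    mind-wandering report lying inside its session's recording span.
    """
    report: list[str] = []
    for name, streams in (("gaze", study.gaze), ("eda", study.eda)):
        for key, df in streams.items():
            t = df["t"].to_numpy()
            if len(t) and name == "gaze" and t[0] < 0:
                report.append(f"{name} stream {key}: negative timestamp")
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                report.append(f"{name} stream {key}: timestamps not strictly increasing")
    by_session: dict[tuple[str, str], list[ParagraphEvent]] = {}
    for ev in study.paragraphs:
        by_session.setdefault((ev.participant, ev.session), []).append(ev)
    for key, events in by_session.items():
        events = sorted(events, key=lambda e: e.onset)
        for a, b in zip(events, events[1:]):
            if b.onset < a.offset:
                report.append(
                    f"session {key}: paragraphs {a.paragraph} and {b.paragraph} overlap"
                )
    known = {p.paragraph for p in study.paragraphs}
    for sr in study.self_reports:
        if sr.paragraph not in known:
            report.append(f"self report for unknown paragraph {sr.paragraph!r}")
        if sr.attentional_focus >= 3 and (sr.trt is not None or sr.tut is not None):
            report.append(
                f"paragraph {sr.paragraph}: TRT/TUT answered at focus >= +3"
            )
    for mw in study.mw_reports:
        key = (mw.participant, mw.session)
        if key not in study.gaze and key not in study.eda:
            report.append(f"MW report for unknown session {key}")
            continue
        lo, hi = study.session_span(key)
        if not (lo <= mw.t <= hi):
            report.append(
                f"MW report at t={mw.t} outside recording span of session {key}"
            )
    return report


def _events_frame(study: Study) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant": e.participant,
                "session": e.session,
                "paragraph": e.paragraph,
                "onset": e.onset,
                "offset": e.offset,
                "text_type": e.text_type,
                "music_type": e.music_type,
            }
            for e in study.paragraphs
        ],
        columns=PARAGRAPH_COLUMNS,
    )


def _reports_frame(study: Study) -> pd.DataFrame:
    rows = []
    for r in study.self_reports:
        d = {c: getattr(r, c) for c in SELF_REPORT_COLUMNS}
        d["trt"] = "" if r.trt is None else int(r.trt)
        d["tut"] = "" if r.tut is None else int(r.tut)
        rows.append(d)
    return pd.DataFrame(rows, columns=SELF_REPORT_COLUMNS)


def write_study(study: Study, root: str | Path) -> None:
    """Write a study directory in the documented CSV dialect (lossless)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    _events_frame(study).to_csv(root / "paragraphs.csv", index=False, float_format="%.17g")
    _reports_frame(study).to_csv(root / "self_reports.csv", index=False, float_format="%.17g")
    pd.DataFrame(
        [{"participant": m.participant, "session": m.session, "t": m.t} for m in study.mw_reports],
        columns=MW_REPORT_COLUMNS,
    ).to_csv(root / "mw_reports.csv", index=False, float_format="%.17g")
    for (pid, sid), df in study.gaze.items():
        out = df.copy()
        out["valid"] = out["valid"].astype(int)
        out.to_csv(root / f"gaze_{pid}_{sid}.csv", index=False, float_format="%.17g")
    for (pid, sid), df in study.eda.items():
        df.to_csv(root / f"eda_{pid}_{sid}.csv", index=False, float_format="%.17g")


def _opt_bool(v) -> bool | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return bool(int(v))


def load_study(root: str | Path) -> Study:
    """Load a study directory written by :func:`write_study`.

    Raises :class:`StudyLoadError` for missing files and
    :class:`StudyValidationError` (naming the offending stream) for
    non-monotone timestamps.
    """
    root = Path(root)
    for fname in ("paragraphs.csv", "self_reports.csv", "mw_reports.csv"):
        if not (root / fname).exists():
            raise StudyLoadError(f"missing file {root / fname}")
    pev = pd.read_csv(root / "paragraphs.csv", dtype={"participant": str, "session": str, "paragraph": str}, float_precision="round_trip")
    paragraphs = []
    for i, row in pev.iterrows():
        try:
            paragraphs.append(
                ParagraphEvent(
                    participant=str(row["participant"]),
                    session=str(row["session"]),
                    paragraph=str(row["paragraph"]),
                    onset=float(row["onset"]),
                    offset=float(row["offset"]),
                    text_type=str(row["text_type"]),
                    music_type=str(row["music_type"]),
                )
            )
        except (StudyValidationError, ValueError) as exc:
            raise StudyLoadError(f"paragraphs.csv line {i + 2}: {exc}") from exc
    srf = pd.read_csv(root / "self_reports.csv", dtype={"participant": str, "session": str, "paragraph": str}, float_precision="round_trip")
    self_reports = [
        SelfReport(
            participant=str(r["participant"]),
            session=str(r["session"]),
            paragraph=str(r["paragraph"]),
            interest=float(r["interest"]),
            difficulty=float(r["difficulty"]),
            tiredness=float(r["tiredness"]),
            happiness=float(r["happiness"]),
            sadness=float(r["sadness"]),
            relevance=float(r["relevance"]),
            attentional_focus=int(r["attentional_focus"]),
            trt=_opt_bool(r["trt"]),
            tut=_opt_bool(r["tut"]),
            reading_duration=float(r["reading_duration"]),
        )
        for _, r in srf.iterrows()
    ]
    mwf = pd.read_csv(root / "mw_reports.csv", dtype={"participant": str, "session": str}, float_precision="round_trip")
    mw_reports = [
        MWReport(participant=str(r["participant"]), session=str(r["session"]), t=float(r["t"]))
        for _, r in mwf.iterrows()
    ]
    sessions = sorted({(e.participant, e.session) for e in paragraphs})
    gaze, eda = {}, {}
    for pid, sid in sessions:
        gpath = root / f"gaze_{pid}_{sid}.csv"
        epath = root / f"eda_{pid}_{sid}.csv"
        if not gpath.exists() or not epath.exists():
            raise StudyLoadError(f"missing stream file(s) for session ({pid}, {sid})")
        g = pd.read_csv(gpath, float_precision="round_trip")
        g["valid"] = g["valid"].astype(bool)
        e = pd.read_csv(epath, float_precision="round_trip")
        for name, df in (("gaze", g), ("eda", e)):
            t = df["t"].to_numpy()
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise StudyValidationError(
                    f"{name} stream ({pid}, {sid}): timestamps not strictly increasing"
                )
        gaze[(pid, sid)] = g[GAZE_COLUMNS]
        eda[(pid, sid)] = e[EDA_COLUMNS]
    participants = sorted({p for p, _ in sessions})
    return Study(
        participants=participants,
        sessions=sessions,
        gaze=gaze,
        eda=eda,
        paragraphs=paragraphs,
        self_reports=self_reports,
        mw_reports=mw_reports,
    )


def write_feature_table(records, path: str | Path) -> pd.DataFrame:
    """Write per-paragraph feature rows to a delimited text file.

    ``records`` is a sequence of :class:`~mindwander.dataset_builder.ParagraphRecord`
    that all carry the same feature-name set; columns are the identifying
    fields, the condition labels, the label, then the features in sorted-name
    order.  Returns the frame that was written.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    names = list(records[0].features.keys())
    for r in records[1:]:
        if list(r.features.keys()) != names:
            raise ValueError(
                f"heterogeneous feature sets: record {r.paragraph} does not match {records[0].paragraph}"
            )
    rows = []
    for r in records:
        row = {
            "participant": r.participant,
            "session": r.session,
            "paragraph": r.paragraph,
            "text_type": r.text_type,
            "music_type": r.music_type,
            "label": r.label,
        }
        row.update(r.features)
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format="%.17g")
    return frame
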