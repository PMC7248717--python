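"""Paragraph labeling, exclusions, and modeling-matrix assembly.

Each reading paragraph becomes one row: a binary mind-wandering label (1 iff
a self-caught button press falls inside the paragraph's half-open interval),
the 19 eye features, the 18 EDA features, and four behavioral features
(reading duration, interest, difficulty, tiredness).  Two exclusion rules
are applied before modeling: paragraphs failing the gaze quality screen are
dropped from *all* modalities (a paragraph without trustworthy eye data is
not used for the EDA model either), and participants who never reported mind
wandering are removed entirely, since a user-independent fold for them has
no positive class to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import eda_pipeline, gaze_pipeline
from .session_model import MWReport, ParagraphEvent, Study, slice_paragraph

BEHAVIOR_FEATURE_NAMES = [
    "reading_duration",
    "interest",
    "difficulty",
    "tiredness",
]

FEATURE_GROUPS = {
    "eye": gaze_pipeline.EYE_FEATURE_NAMES,
    "eda": eda_pipeline.EDA_FEATURE_NAMES,
    "behavior": BEHAVIOR_FEATURE_NAMES,
}


@dataclass
class ParagraphRecord:
    participant: str
    session: str
    paragraph: str
    text_type: str
    music_type: str
    label: int
    features: dict[str, float] = field(default_factory=dict)
    excluded: str | None = None


@dataclass
class Dataset:
    """Aligned modeling matrix: rows are retained paragraphs."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray  # participant id per row
    feature_names: list[str]
    provenance: dict = field(default_factory=dict)


def label_paragraph_mw(event: ParagraphEvent, mw_reports: list[MWReport]) -> int:
    """1 iff any button press of the paragraph's session falls in [onset, offset)."""
    for r in mw_reports:
        if (
            r.participant == event.participant
            and r.session == event.session
            and event.onset <= r.t < event.offset
        ):
            return 1
    return 0


def build_paragraph_records(
    study: Study,
    feature_groups: set[str] | None = None,
    idt_dispersion_px: float = gaze_pipeline.DEFAULT_DISPERSION_PX,
    idt_min_duration_ms: float = gaze_pipeline.DEFAULT_MIN_DURATION_MS,
    reading_area: tuple[float, float, float, float] | None = None,
    decomposition_params: eda_pipeline.DecompositionParams | None = None,
    peak_min_amp_us: float = 0.01,
) -> list[ParagraphRecord]:
    """Run the full feature pipeline over every paragraph of a study.

    Records for paragraphs failing the gaze quality screen carry an exclusion
    reason and no features.  ``feature_groups`` limits which (expensive)
    feature families are computed; the gaze quality screen always runs
    because its exclusions apply to every modality.
    """
    groups = set(FEATURE_GROUPS) if feature_groups is None else set(feature_groups)
    unknown = groups - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature groups {sorted(unknown)}")
    if not study.pupil_standardized and "eye" in groups:
        gaze_pipeline.pupil_zscore(study)

    decomps: dict[tuple[str, str], eda_pipeline.EdaDecomposition] = {}
    if "eda" in groups:
        by_participant: dict[str, list[tuple[str, str]]] = {}
        for key in study.eda:
            by_participant.setdefault(key[0], []).append(key)
        for pid, keys in by_participant.items():
            mean, sd = eda_pipeline.subject_scale_factors([study.eda[k] for k in keys])
            for key in keys:
                z = study.eda[key].assign(sc=(study.eda[key]["sc"] - mean) / sd)
                decomps[key] = eda_pipeline.decompose_cvx(
                    z, params=decomposition_params, subject_mean_us=mean, subject_sd_us=sd
                )

    reports_by_session: dict[tuple[str, str], list] = {}
    for r in study.mw_reports:
        reports_by_session.setdefault((r.participant, r.session), []).append(r)
    self_by_paragraph = {r.paragraph: r for r in study.self_reports}

    records: list[ParagraphRecord] = []
    for ev in study.paragraphs:
        key = (ev.participant, ev.session)
        label = label_paragraph_mw(ev, reports_by_session.get(key, []))
        rec = ParagraphRecord(
            participant=ev.participant,
            session=ev.session,
            paragraph=ev.paragraph,
            text_type=ev.text_type,
            music_type=ev.music_type,
            label=label,
        )
        gaze_df, _ = slice_paragraph(study, ev.paragraph)
        eye_feats, decision = gaze_pipeline.paragraph_eye_features(
            gaze_df,
            dispersion_px=idt_dispersion_px,
            min_duration_ms=idt_min_duration_ms,
            reading_area=reading_area,
        )
        if not decision.keep:
            rec.excluded = decision.reason
            records.append(rec)
            continue
        if "eye" in groups:
            rec.features.update(eye_feats)
        if "eda" in groups:
            decomp = decomps[key]
            window = (ev.onset, ev.offset)
            peaks = eda_pipeline.detect_scr_peaks(decomp, window, peak_min_amp_us)
            rec.features.update(eda_pipeline.extract_eda_features(decomp, peaks, window))
        if "behavior" in groups:
            sr = self_by_paragraph.get(ev.paragraph)
            rec.features["reading_duration"] = ev.duration
            rec.features["interest"] = sr.interest if sr else np.nan
            rec.features["difficulty"] = sr.difficulty if sr else np.nan
            rec.features["tiredness"] = sr.tiredness if sr else np.nan
        records.append(rec)
    return records


def apply_exclusions(
    records: list[ParagraphRecord],
) -> tuple[list[ParagraphRecord], pd.DataFrame]:
    """Apply the two study-level exclusion rules.

    Drops (a) paragraphs already flagged by the gaze quality screen and
    (b) every paragraph of participants with zero mind-wandering labels
    across the whole study.  Returns ``(retained, exclusion_log)``; the log
    has one row per dropped paragraph with its reason.  Idempotent.
    """
    mw_by_participant: dict[str, int] = {}
    for r in records:
        mw_by_participant[r.participant] = mw_by_participant.get(r.participant, 0) + r.label
    no_mw = {p for p, n in mw_by_participant.items() if n == 0}
    retained: list[ParagraphRecord] = []
    log_rows = []
    for r in records:
        if r.participant in no_mw:
            log_rows.append((r.participant, r.paragraph, "participant-no-mw"))
        elif r.excluded is not None:
            log_rows.append((r.participant, r.paragraph, r.excluded))
        else:
            retained.append(r)
    log = pd.DataFrame(log_rows, columns=["participant", "paragraph", "reason"])
    return retained, log


def build_dataset(
    records: list[ParagraphRecord],
    feature_groups: set[str] | frozenset[str],
    provenance: dict | None = None,
) -> Dataset:
    """Assemble the modeling matrix from retained records.

    Column order is deterministic: eye, then EDA, then behavioral features,
    each in registry order.  Column count is 19*[eye] + 18*[eda] +
    4*[behavior].
    """
    groups = set(feature_groups)
    if not groups:
        raise ValueError("at least one feature group is required")
    unknown = groups - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature groups {sorted(unknown)}")
    names: list[str] = []
    for g in ("eye", "eda", "behavior"):
        if g in groups:
            names.extend(FEATURE_GROUPS[g])
    rows, y, part = [], [], []
    for r in records:
        if r.excluded is not None:
            continue
        missing = [n for n in names if n not in r.features]
        if missing:
            raise ValueError(
                f"record {r.paragraph} lacks features {missing[:3]}...; "
                "was the pipeline run with these groups?"
            )
        rows.append([r.features[n] for n in names])
        y.append(r.label)
        part.append(r.participant)
    X = pd.DataFrame(rows, columns=names)
    return Dataset(
        X=X,
        y=np.asarray(y, dtype=int),
        groups=np.asarray(part, dtype=object),
        feature_names=names,
        provenance=provenance or {},
    )


def dataset_from_study(
    study: Study, feature_groups: set[str] | None = None, **pipeline_kwargs
) -> tuple[Dataset, pd.DataFrame]:
    """Convenience: records -> exclusions -> matrix in one call."""
    groups = set(FEATURE_GROUPS) if feature_groups is None else set(feature_groups)
    records = build_paragraph_records(study, feature_groups=groups, **pipeline_kwargs)
    retained, log = apply_exclusions(records)
    ds = build_dataset(
        retained,
        groups,
        provenance={"n_paragraphs": len(records), "n_retained": len(retained)},
    )
    return ds, log
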