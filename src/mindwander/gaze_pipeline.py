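"""Fixation detection and eye-movement feature extraction.

Raw 90 Hz gaze samples are clustered into fixations with the
dispersion-threshold identification (I-DT) algorithm: a candidate window is
grown sample by sample while its dispersion ``(max x - min x) + (max y -
min y)`` stays within a threshold, and is emitted as a fixation when it spans
at least a minimum duration.  Defaults are 40 px dispersion (about 1 degree
of visual angle at 60 cm on a 1920 x 1200 desktop monitor) and 100 ms
minimum duration.  Invalid (tracking-loss) samples are dropped beforehand and
a sampling gap longer than ``max_gap_ms`` splits the candidate window so a
fixation never spans a blink.

From consecutive fixation pairs the module derives saccade geometry (length,
transit time, angle, regression status), screens paragraphs for data quality,
z-scores pupil size per participant, and assembles the 19-value eye feature
registry: the mean of all nine base measures plus min and max for fixation
duration, pupil size, saccade length, saccade transit time, and regression
length.  Note that "saccade velocity" is, by the registry's definition, the
transit time between two subsequent fixations in milliseconds, not a px/ms
rate; the conventional rate is available as an optional extra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session_model import Study

DEFAULT_DISPERSION_PX = 40.0
DEFAULT_MIN_DURATION_MS = 100.0
DEFAULT_MAX_GAP_MS = 75.0
DEFAULT_LINE_HEIGHT_PX = 36.0

#: The 19 per-paragraph eye features, in registry order.
EYE_FEATURE_NAMES = [
    "fix_duration_mean",
    "fix_duration_min",
    "fix_duration_max",
    "pupil_mean",
    "pupil_min",
    "pupil_max",
    "saccade_length_mean",
    "saccade_length_min",
    "saccade_length_max",
    "saccade_velocity_mean",
    "saccade_velocity_min",
    "saccade_velocity_max",
    "saccade_angle_mean",
    "regression_length_mean",
    "regression_length_min",
    "regression_length_max",
    "n_regressions",
    "n_fixations",
    "n_saccades",
]


@dataclass(frozen=True)
class Fixation:
    onset: float
    offset: float
    x: float
    y: float
    pupil: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Saccade:
    source: int  # index of the preceding fixation
    target: int
    length: float
    transit_ms: float  # "saccade velocity" in the registry
    angle: float
    is_regression: bool
    regression_length: float


@dataclass(frozen=True)
class QualityDecision:
    keep: bool
    reason: str | None
    valid_fraction: float
    n_fixations: int


def _clean(samples: pd.DataFrame) -> pd.DataFrame:
    return samples[samples["valid"].to_numpy(dtype=bool)]


def detect_fixations_idt(
    samples: pd.DataFrame,
    dispersion_px: float = DEFAULT_DISPERSION_PX,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    max_gap_ms: float | None = DEFAULT_MAX_GAP_MS,
) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    ``samples`` must be time-ordered and contain only valid samples (use
    ``valid`` upstream).  At each start index the window is extended to the
    last sample keeping dispersion <= threshold; it becomes a fixation iff
    its time span reaches ``min_duration_ms``.  The centroid is the mean of
    the window's points; fixations are non-overlapping and ordered.
    """
    n = len(samples)
    if n < 2:
        return []
    t = samples["t"].to_numpy(dtype=float)
    x = samples["x"].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    pupil = samples["pupil"].to_numpy(dtype=float)

    if max_gap_ms is not None:
        breaks = np.nonzero(np.diff(t) > max_gap_ms)[0]
        segments = np.split(np.arange(n), breaks + 1)
    else:
        segments = [np.arange(n)]

    out: list[Fixation] = []
    for seg in segments:
        if len(seg) < 2:
            continue
        st, sx, sy, sp = t[seg], x[seg], y[seg], pupil[seg]
        m = len(seg)
        i = 0
        while i < m - 1:
            xmin = xmax = sx[i]
            ymin = ymax = sy[i]
            j = i
            while j + 1 < m:
                nx, ny = sx[j + 1], sy[j + 1]
                d = (max(xmax, nx) - min(xmin, nx)) + (max(ymax, ny) - min(ymin, ny))
                if d > dispersion_px:
                    break
                j += 1
                xmin, xmax = min(xmin, nx), max(xmax, nx)
                ymin, ymax = min(ymin, ny), max(ymax, ny)
            if st[j] - st[i] >= min_duration_ms:
                sl = slice(i, j + 1)
                out.append(
                    Fixation(
                        onset=float(st[i]),
                        offset=float(st[j]),
                        x=float(np.mean(sx[sl])),
                        y=float(np.mean(sy[sl])),
                        pupil=float(np.mean(sp[sl])),
                    )
                )
                i = j + 1
            else:
                i += 1
    return out


def detect_fixations_reference(
    samples: pd.DataFrame,
    dispersion_px: float = DEFAULT_DISPERSION_PX,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    max_gap_ms: float | None = DEFAULT_MAX_GAP_MS,
) -> list[Fixation]:
    """Exhaustive reference I-DT used to verify the incremental detector.

    Recomputes the dispersion of every candidate window from scratch with a
    full pass over its samples (quadratic cost); intended for verification on
    short streams, not production use.
    """
    n = len(samples)
    if n < 2:
        return []
    t = samples["t"].to_numpy(dtype=float)
    x = samples["x"].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    pupil = samples["pupil"].to_numpy(dtype=float)

    def dispersion(i: int, j: int) -> float:
        xs, ys = x[i : j + 1], y[i : j + 1]
        return (xs.max() - xs.min()) + (ys.max() - ys.min())

    def segment_end(i: int) -> int:
        # last index reachable from i without a gap split
        j = i
        while j + 1 < n and (max_gap_ms is None or t[j + 1] - t[j] <= max_gap_ms):
            j += 1
        return j

    out: list[Fixation] = []
    i = 0
    while i < n - 1:
        end = segment_end(i)
        if end == i:
            i += 1
            continue
        j = i
        for cand in range(i, end + 1):
            if dispersion(i, cand) <= dispersion_px:
                j = cand
            else:
                break
        if j > i and t[j] - t[i] >= min_duration_ms:
            out.append(
                Fixation(
                    onset=float(t[i]),
                    offset=float(t[j]),
                    x=float(np.mean(x[i : j + 1])),
                    y=float(np.mean(y[i : j + 1])),
                    pupil=float(np.mean(pupil[i : j + 1])),
                )
            )
            i = j + 1
        else:
            i += 1
    return out


def filter_reading_area(
    fixations: list[Fixation], area_rect: tuple[float, float, float, float]
) -> list[Fixation]:
    """Keep fixations whose centroid lies in the half-open rect (x0, y0, x1, y1)."""
    x0, y0, x1, y1 = area_rect
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"degenerate reading area {area_rect}")
    return [f for f in fixations if x0 <= f.x < x1 and y0 <= f.y < y1]


def screen_paragraph_quality(
    samples: pd.DataFrame,
    fixations: list[Fixation],
    min_valid_fraction: float = 0.75,
    min_fixations: int = 5,
) -> QualityDecision:
    """Exclude paragraphs with insufficient eye-tracker accuracy.

    A paragraph is kept when at least ``min_valid_fraction`` of its samples
    carry a valid tracking flag and at least ``min_fixations`` fixations
    survived the reading-area filter.
    """
    n = len(samples)
    frac = float(samples["valid"].to_numpy(dtype=bool).mean()) if n else 0.0
    if frac < min_valid_fraction:
        return QualityDecision(False, "low-validity", frac, len(fixations))
    if len(fixations) < min_fixations:
        return QualityDecision(False, "few-fixations", frac, len(fixations))
    return QualityDecision(True, None, frac, len(fixations))


def compute_saccades(
    fixations: list[Fixation], line_height_px: float = DEFAULT_LINE_HEIGHT_PX
) -> list[Saccade]:
    """One saccade per consecutive fixation pair.

    A regression is a leftward movement staying within one line of text
    (``dx < 0`` and ``|dy| < line_height_px``); leftward sweeps to the next
    line are line returns, not regressions.
    """
    out: list[Saccade] = []
    for k in range(len(fixations) - 1):
        a, b = fixations[k], fixations[k + 1]
        dx, dy = b.x - a.x, b.y - a.y
        length = math.hypot(dx, dy)
        is_reg = dx < 0 and abs(dy) < line_height_px
        out.append(
            Saccade(
                source=k,
                target=k + 1,
                length=length,
                transit_ms=b.onset - a.offset,
                angle=math.atan2(dy, dx),
                is_regression=is_reg,
                regression_length=length if is_reg else 0.0,
            )
        )
    return out


def fixations_frame(fixations: list[Fixation]) -> pd.DataFrame:
    """Fixations as a delimited-text-ready table."""
    return pd.DataFrame(
        [
            {"onset": f.onset, "offset": f.offset, "duration": f.duration,
             "x": f.x, "y": f.y, "pupil": f.pupil}
            for f in fixations
        ]
    )


def saccades_frame(saccades: list[Saccade]) -> pd.DataFrame:
    """Saccades as a delimited-text-ready table."""
    return pd.DataFrame(
        [
            {"source": s.source, "target": s.target, "length": s.length,
             "transit_ms": s.transit_ms, "angle": s.angle,
             "is_regression": s.is_regression,
             "regression_length": s.regression_length}
            for s in saccades
        ]
    )


def pupil_zscore(study: Study) -> Study:
    """Replace pupil size with per-participant z-scores, in place.

    Statistics pool all valid samples of a participant across both sessions;
    population standard deviation.  Raises for participants with fewer than
    two valid samples or zero pupil variance.
    """
    by_participant: dict[str, list[tuple[tuple[str, str], pd.DataFrame]]] = {}
    for key, df in study.gaze.items():
        by_participant.setdefault(key[0], []).append((key, df))
    for pid, items in by_participant.items():
        vals = np.concatenate(
            [df.loc[df["valid"].astype(bool), "pupil"].to_numpy(dtype=float) for _, df in items]
        )
        if len(vals) < 2:
            raise ValueError(f"participant {pid}: fewer than 2 valid pupil samples")
        mean, sd = float(np.mean(vals)), float(np.std(vals))
        if sd == 0:
            raise ValueError(f"participant {pid}: zero pupil variance")
        for key, df in items:
            study.gaze[key] = df.assign(pupil=(df["pupil"] - mean) / sd)
    study.pupil_standardized = True
    return study


def extract_eye_features(
    fixations: list[Fixation], saccades: list[Saccade]
) -> dict[str, float]:
    """Compute the 19-value eye feature registry for one paragraph.

    Counts are totals within the paragraph; regression-length statistics are
    taken over regressions only and are zero when the paragraph contains
    none.  Requires a non-empty fixation list (quality screening upstream
    guarantees at least ``min_fixations``).
    """
    if not fixations:
        raise ValueError("no fixations; paragraph should have been excluded upstream")

    def stats(values: np.ndarray) -> tuple[float, float, float]:
        return float(np.mean(values)), float(np.min(values)), float(np.max(values))

    durations = np.array([f.duration for f in fixations])
    pupils = np.array([f.pupil for f in fixations])
    feats: dict[str, float] = {}
    feats["fix_duration_mean"], feats["fix_duration_min"], feats["fix_duration_max"] = stats(durations)
    feats["pupil_mean"], feats["pupil_min"], feats["pupil_max"] = stats(pupils)
    if saccades:
        lengths = np.array([s.length for s in saccades])
        transits = np.array([s.transit_ms for s in saccades])
        angles = np.array([s.angle for s in saccades])
        (
            feats["saccade_length_mean"],
            feats["saccade_length_min"],
            feats["saccade_length_max"],
        ) = stats(lengths)
        (
            feats["saccade_velocity_mean"],
            feats["saccade_velocity_min"],
            feats["saccade_velocity_max"],
        ) = stats(transits)
        feats["saccade_angle_mean"] = float(np.mean(angles))
    else:
        for name in (
            "saccade_length_mean",
            "saccade_length_min",
            "saccade_length_max",
            "saccade_velocity_mean",
            "saccade_velocity_min",
            "saccade_velocity_max",
            "saccade_angle_mean",
        ):
            feats[name] = 0.0
    regressions = [s for s in saccades if s.is_regression]
    if regressions:
        reg_len = np.array([s.regression_length for s in regressions])
        (
            feats["regression_length_mean"],
            feats["regression_length_min"],
            feats["regression_length_max"],
        ) = stats(reg_len)
    else:
        feats["regression_length_mean"] = 0.0
        feats["regression_length_min"] = 0.0
        feats["regression_length_max"] = 0.0
    feats["n_regressions"] = float(len(regressions))
    feats["n_fixations"] = float(len(fixations))
    feats["n_saccades"] = float(len(saccades))
    return {name: feats[name] for name in EYE_FEATURE_NAMES}


def paragraph_eye_features(
    samples: pd.DataFrame,
    dispersion_px: float = DEFAULT_DISPERSION_PX,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    max_gap_ms: float | None = DEFAULT_MAX_GAP_MS,
    reading_area: tuple[float, float, float, float] | None = None,
    line_height_px: float = DEFAULT_LINE_HEIGHT_PX,
    min_valid_fraction: float = 0.75,
    min_fixations: int = 5,
) -> tuple[dict[str, float] | None, QualityDecision]:
    """Full per-paragraph gaze pipeline: detect, filter, screen, extract.

    Returns ``(features, decision)`` with ``features=None`` when the
    paragraph is excluded.
    """
    valid = _clean(samples)
    fixations = detect_fixations_idt(valid, dispersion_px, min_duration_ms, max_gap_ms)
    if reading_area is not None:
        fixations = filter_reading_area(fixations, reading_area)
    decision = screen_paragraph_quality(samples, fixations, min_valid_fraction, min_fixations)
    if not decision.keep:
        return None, decision
    saccades = compute_saccades(fixations, line_height_px)
    return extract_eye_features(fixations, saccades), decision
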