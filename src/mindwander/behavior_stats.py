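"""Repeated-measures behavioral analysis of the 3 x 3 reading design.

Per-paragraph variables (mind-wandering frequency, task-related and
task-unrelated thought indicators, questionnaire ratings) are first averaged
into per-participant condition-cell means, then analyzed with a two-factor
within-subject ANOVA.  Because sphericity rarely holds for within-subject
covariances, F tests are Greenhouse-Geisser corrected: the epsilon of an
effect is estimated from the covariance of its orthonormal contrast
variables and scales both degrees of freedom.  Simple effects within a
factor use Helmert contrasts — the two non-control levels against each
other, then their mean against the control — tested as one-sample t tests on
per-subject contrast scores.  Binary thought indicators are arcsine-square-
root transformed per-cell proportions, the standard variance-stabilizing
device for proportions entering an ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session_model import Study
from .dataset_builder import label_paragraph_mw

TEXT_ORDER = ("ComputerScience", "Psychology", "Random")  # control (Random) last
MUSIC_ORDER = ("Sad", "Happy", "NoMusic")  # control (NoMusic) last


@dataclass(frozen=True)
class ContrastResult:
    name: str
    weights: tuple[float, ...]
    estimate: float
    se: float
    t: float
    F: float
    p: float


def paragraph_table(study: Study) -> pd.DataFrame:
    """One row per paragraph with label, conditions, and behavioral variables.

    ``trt``/``tut`` are 0/1 with unasked (focus >= +3) coded 0 — a focused
    reader reported no off-task thought episode.
    """
    reports = {r.paragraph: r for r in study.self_reports}
    by_session: dict[tuple[str, str], list] = {}
    for m in study.mw_reports:
        by_session.setdefault((m.participant, m.session), []).append(m)
    rows = []
    for ev in study.paragraphs:
        sr = reports.get(ev.paragraph)
        rows.append(
            {
                "participant": ev.participant,
                "session": ev.session,
                "paragraph": ev.paragraph,
                "text_type": ev.text_type,
                "music_type": ev.music_type,
                "mw": label_paragraph_mw(ev, by_session.get((ev.participant, ev.session), [])),
                "trt": int(bool(sr.trt)) if sr else np.nan,
                "tut": int(bool(sr.tut)) if sr else np.nan,
                "par": sr.relevance if sr else np.nan,
                "interest": sr.interest if sr else np.nan,
                "difficulty": sr.difficulty if sr else np.nan,
                "tiredness": sr.tiredness if sr else np.nan,
                "attentional_focus": sr.attentional_focus if sr else np.nan,
                "reading_duration": ev.duration,
            }
        )
    return pd.DataFrame(rows)


def cell_means(study: Study, variable: str, arcsine: bool = False) -> np.ndarray:
    """Per-participant 3 x 3 cell means, shape ``(n, text, music)``.

    Axis order follows ``TEXT_ORDER`` x ``MUSIC_ORDER`` (controls last).
    With ``arcsine=True`` the per-cell mean (a proportion for binary
    variables) is arcsine-square-root transformed.
    """
    tab = paragraph_table(study)
    if variable not in tab.columns:
        raise KeyError(f"unknown paragraph variable {variable!r}")
    participants = sorted(tab["participant"].unique())
    out = np.full((len(participants), 3, 3), np.nan)
    grouped = tab.groupby(["participant", "text_type", "music_type"])[variable].mean()
    for i, pid in enumerate(participants):
        for a, tt in enumerate(TEXT_ORDER):
            for b, mt in enumerate(MUSIC_ORDER):
                key = (pid, tt, mt)
                if key in grouped.index:
                    out[i, a, b] = grouped.loc[key]
    if arcsine:
        out = arcsine_transform(out)
    return out


def summarize_cells(study: Study, variable: str) -> pd.DataFrame:
    """Across-participant mean (sd) per condition cell.

    Cell means are computed per participant first (the design is balanced at
    the participant level), then averaged; missing cells surface as NaN.
    """
    cells = cell_means(study, variable)
    mean = np.nanmean(cells, axis=0)
    sd = np.nanstd(cells, axis=0, ddof=1)
    frame = pd.DataFrame(
        {
            mt: [f"{mean[a, b]:.3f}({sd[a, b]:.3f})" for a in range(3)]
            for b, mt in enumerate(MUSIC_ORDER)
        },
        index=list(TEXT_ORDER),
    )
    frame.attrs["mean"] = mean
    frame.attrs["sd"] = sd
    return frame


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the space orthogonal to the mean."""
    c = np.zeros((k - 1, k))
    for j in range(1, k):
        c[j - 1, :j] = 1.0 / j
        c[j - 1, j] = -1.0
        c[j - 1] /= np.linalg.norm(c[j - 1])
    return c


def _gg_epsilon(profiles: np.ndarray, contrasts: np.ndarray) -> np.ndarray:
    """Greenhouse-Geisser epsilon from per-subject effect profiles.

    ``profiles`` has shape (..., n, m); ``contrasts`` is (q, m) orthonormal.
    Epsilon is (tr M)^2 / (q * tr M^2) for M the contrast-space covariance,
    clipped to [1/q, 1].
    """
    centered = profiles - profiles.mean(axis=-2, keepdims=True)
    n = profiles.shape[-2]
    s = np.einsum("...ni,...nj->...ij", centered, centered) / (n - 1)
    m = contrasts @ s @ contrasts.T
    q = contrasts.shape[0]
    tr = np.trace(m, axis1=-2, axis2=-1)
    tr2 = np.einsum("...ij,...ji->...", m, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = tr**2 / (q * tr2)
    return np.clip(np.nan_to_num(eps, nan=1.0), 1.0 / q, 1.0)


def rm_anova_2way(cells: np.ndarray, as_frame: bool = True):
    """Two-factor within-subject ANOVA with Greenhouse-Geisser correction.

    ``cells`` has shape ``(..., n_subjects, a, b)`` (leading batch axes are
    broadcast, which makes large calibration simulations cheap).  For each
    effect (A, B, A x B) the standard within-subject decomposition gives an
    F against the effect-by-subject interaction; epsilon scales both degrees
    of freedom of the corrected p-value.  Missing cells are not imputed.
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim < 3:
        raise ValueError("cells must have shape (..., n, a, b)")
    if np.isnan(y).any():
        raise ValueError("missing cells; the design must be complete")
    n, a, b = y.shape[-3], y.shape[-2], y.shape[-1]
    grand = y.mean(axis=(-3, -2, -1), keepdims=True)
    subj = y.mean(axis=(-2, -1), keepdims=True)
    amean = y.mean(axis=(-3, -1), keepdims=True)
    bmean = y.mean(axis=(-3, -2), keepdims=True)
    cell = y.mean(axis=-3, keepdims=True)
    sa = y.mean(axis=-1, keepdims=True)  # subject x A
    sb = y.mean(axis=-2, keepdims=True)  # subject x B

    ss_a = (n * b) * ((amean - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_b = (n * a) * ((bmean - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_ab = n * ((cell - amean - bmean + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_as = b * ((sa - subj - amean + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_bs = a * ((sb - subj - bmean + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_total = ((y - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_subj = (a * b) * ((subj - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    profiles_a = y.mean(axis=-1)  # (..., n, a)
    profiles_b = y.mean(axis=-2)
    profiles_ab = y.reshape(*y.shape[:-2], a * b)
    cab = np.kron(ca, cb)

    effects = {}
    for name, ss, ss_err, df1, df2, prof, con in (
        ("A", ss_a, ss_as, a - 1, (a - 1) * (n - 1), profiles_a, ca),
        ("B", ss_b, ss_bs, b - 1, (b - 1) * (n - 1), profiles_b, cb),
        ("AxB", ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), profiles_ab, cab),
    ):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df1) / (ss_err / df2)
        eps = _gg_epsilon(prof, con)
        p_unc = stats.f.sf(f, df1, df2)
        p_gg = stats.f.sf(f, df1 * eps, df2 * eps)
        effects[name] = {
            "ss": ss,
            "ss_error": ss_err,
            "df1": df1,
            "df2": df2,
            "F": f,
            "epsilon": eps,
            "df1_gg": df1 * eps,
            "df2_gg": df2 * eps,
            "p": p_unc,
            "p_gg": p_gg,
        }
    if not as_frame:
        return effects
    rows = []
    for name, e in effects.items():
        rows.append({"effect": name, **{k: np.asarray(v).item() for k, v in e.items()}})
    return pd.DataFrame(rows).set_index("effect")


def helmert_contrasts(
    level_means: np.ndarray, level_names: tuple[str, ...] | None = None
) -> list[ContrastResult]:
    """Helmert simple-effect contrasts on per-subject level means.

    ``level_means`` has shape ``(n_subjects, k)`` with the control level
    LAST.  Contrast 1 compares the first two (non-control) levels; contrast
    ``j`` compares the mean of the first ``j`` levels with level ``j + 1``
    (for k = 3: weights (1, -1, 0) and (1/2, 1/2, -1)).  Each contrast is a
    one-sample t test on per-subject contrast scores.
    """
    m = np.asarray(level_means, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need (n_subjects, k >= 2) level means")
    n, k = m.shape
    names = level_names or tuple(f"L{i + 1}" for i in range(k))
    out = []
    for j in range(1, k):
        w = np.zeros(k)
        w[:j] = 1.0 / j
        w[j] = -1.0
        scores = m @ w
        est = float(scores.mean())
        se = float(scores.std(ddof=1) / np.sqrt(n))
        t = est / se if se > 0 else np.nan
        p = float(2 * stats.t.sf(abs(t), n - 1)) if se > 0 else np.nan
        label = (
            f"{names[0]} vs {names[1]}"
            if j == 1
            else f"mean({', '.join(names[:j])}) vs {names[j]}"
        )
        out.append(
            ContrastResult(
                name=label,
                weights=tuple(w),
                estimate=est,
                se=se,
                t=float(t),
                F=float(t**2) if np.isfinite(t) else np.nan,
                p=p,
            )
        )
    return out


def arcsine_transform(x):
    """Variance-stabilizing arcsine-square-root transform for proportions."""
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1) & ~np.isnan(arr)):
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(arr))


def correlation_screen(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    r_threshold: float = 0.2,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Pearson correlations with the reporting filter.

    Returns one row per variable pair with ``r``, ``p``, and ``reported``
    (|r| >= r_threshold and p < p_threshold).  Constant variables are
    skipped with a note in ``frame.attrs['skipped']``.
    """
    cols = variables or [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows, skipped = [], []
    for i, v1 in enumerate(cols):
        for v2 in cols[i + 1 :]:
            pair = table[[v1, v2]].dropna()
            if len(pair) < 3:
                skipped.append(f"{v1}~{v2}: fewer than 3 complete rows")
                continue
            if pair[v1].nunique() < 2 or pair[v2].nunique() < 2:
                skipped.append(f"{v1}~{v2}: constant variable")
                continue
            r, p = stats.pearsonr(pair[v1], pair[v2])
            rows.append(
                {
                    "var1": v1,
                    "var2": v2,
                    "n": len(pair),
                    "r": float(r),
                    "p": float(p),
                    "reported": bool(abs(r) >= r_threshold and p < p_threshold),
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["skipped"] = skipped
    return frame
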