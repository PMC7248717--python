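"""Synthetic reading-session generator with ground-truth mind wandering.

The generator emulates the 3 x 3 repeated-measures reading study the package
analyzes: every participant completes one Sad-music and one Happy-music
session; a session presents 2 texts x 3 text types x 4 paragraphs = 24
reading segments with music playing on exactly half of them (counterbalanced
within each text type against the No-Music control).

Per paragraph it simulates

* a 90 Hz gaze stream following a line-wise reading scan path — fixations at
  successive word positions with log-normal durations, forward saccades,
  occasional same-line regressions, line-return sweeps, pupil drift and
  measurement noise, and a small fraction of invalid (tracking-loss) samples;
* a 4 Hz skin-conductance stream: a smooth tonic drift plus a sparse train of
  sudomotor impulses convolved with a Bateman kernel
  ``B(t) = exp(-t/tau0) - exp(-t/tau1)`` and Gaussian measurement noise.

Mind wandering is drawn per paragraph from a configurable base rate modulated
by condition-specific multipliers, and expresses itself through effect
multipliers on the generative parameters: longer and fewer fixations, higher
pupil variability, and a higher skin-conductance-response rate.  Every latent
quantity (MW flags, fixation schedules, impulse trains, tonic traces) is kept
as ground truth so downstream stages can be tested by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .session_model import (
    GAZE_COLUMNS,
    MWReport,
    ParagraphEvent,
    SelfReport,
    Study,
)

# Table-2-shaped default MW rate multipliers, normalized so the design-weighted
# mean (No-Music paragraphs are twice as frequent) is 1 and the overall MW
# fraction stays at the configured base rate.
_RAW_CELL_RATES = {
    ("ComputerScience", "Sad"): 0.34,
    ("Psychology", "Sad"): 0.18,
    ("Random", "Sad"): 0.19,
    ("ComputerScience", "Happy"): 0.22,
    ("Psychology", "Happy"): 0.25,
    ("Random", "Happy"): 0.39,
    ("ComputerScience", "NoMusic"): 0.12,
    ("Psychology", "NoMusic"): 0.08,
    ("Random", "NoMusic"): 0.15,
}
_W = sum(v * (2 if k[1] == "NoMusic" else 1) for k, v in _RAW_CELL_RATES.items()) / 12.0
DEFAULT_MW_CONDITION_MULT = {k: v / _W for k, v in _RAW_CELL_RATES.items()}


@dataclass
class GazeParams:
    """Generative parameters of the reading scan path (90 Hz)."""

    fs_hz: float = 90.0
    fix_dur_meanlog: float = math.log(210.0)  # ms
    fix_dur_sdlog: float = 0.30
    saccade_transit_ms: float = 27.0
    word_advance_px: float = 105.0
    word_advance_sd_px: float = 18.0
    regression_prob: float = 0.12
    line_start_x: float = 360.0
    line_end_x: float = 1560.0
    line_height_px: float = 36.0
    first_line_y: float = 400.0
    n_lines: int = 8
    within_fix_jitter_px: float = 2.0
    gaze_noise_px: float = 5.0
    pupil_baseline: float = 60.0
    pupil_slow_amp: float = 1.5
    pupil_slow_period_s: float = 18.0
    pupil_noise_sd: float = 1.0
    invalid_prob: float = 0.02
    # slow attentional/arousal state: per-paragraph log-normal multipliers on
    # the fixation cycle and on pupil variability, independent of MW
    state_sdlog: float = 0.22
    pupil_state_sdlog: float = 0.45
    # mind-wandering effect multipliers
    mw_fix_dur_mult: float = 1.4
    mw_fix_count_mult: float = 0.7
    mw_pupil_sd_mult: float = 1.5


@dataclass
class EdaParams:
    """Generative parameters of the electrodermal stream (4 Hz)."""

    fs_hz: float = 4.0
    tau0_s: float = 2.0  # slow Bateman time constant
    tau1_s: float = 0.7  # fast Bateman time constant
    tonic_drift_amp_us: float = 0.3
    tonic_periods_s: tuple[float, float] = (300.0, 120.0)
    scr_rate_per_min: float = 3.0
    scr_amp_meanlog: float = math.log(0.4)  # peak amplitude, µS
    scr_amp_sdlog: float = 0.7
    noise_sd_us: float = 0.02
    mw_scr_rate_mult: float = 2.5

    def __post_init__(self) -> None:
        if not self.tau0_s > self.tau1_s > 0:
            raise ValueError(f"require tau0 > tau1 > 0, got {self.tau0_s}, {self.tau1_s}")


@dataclass
class ParticipantTraits:
    """Stable individual differences, drawn once per participant.

    These are what makes user-independent (leave-one-participant-out)
    detection genuinely hard: a held-out reader's baseline oculomotor and
    electrodermal statistics differ from everyone in the training folds.
    """

    pupil_baseline: float = 60.0
    eda_baseline_us: float = 5.0
    fix_dur_logshift: float = 0.0  # added to the fixation-duration meanlog
    pupil_noise_mult: float = 1.0
    scr_rate_mult: float = 1.0
    scr_amp_logshift: float = 0.0


@dataclass
class SimConfig:
    """Study-level design and noise configuration."""

    n_participants: int = 20
    paragraphs_per_text: int = 4
    texts_per_type: int = 2
    paragraph_duration_ms: float = 25_000.0
    paragraph_duration_sdlog: float = 0.10
    inter_paragraph_gap_ms: float = 8_000.0
    mw_base_rate: float = 0.158
    mw_condition_mult: dict = field(default_factory=lambda: dict(DEFAULT_MW_CONDITION_MULT))
    # between-participant trait spreads (log scale where multiplicative)
    trait_fix_dur_sdlog: float = 0.18
    trait_pupil_noise_sdlog: float = 0.25
    trait_scr_rate_sdlog: float = 0.20
    trait_scr_amp_sdlog: float = 0.30
    # an episode starts at a uniform fraction of the paragraph in this range
    # and runs to the paragraph end, so effects dilute over the full window
    episode_start_frac: tuple[float, float] = (0.0, 0.6)
    gaze: GazeParams = field(default_factory=GazeParams)
    eda: EdaParams = field(default_factory=EdaParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mw_base_rate < 1:
            raise ValueError("mw_base_rate must lie in [0, 1)")
        if self.paragraph_duration_ms <= 0 or self.inter_paragraph_gap_ms < 0:
            raise ValueError("durations must be positive")


@dataclass
class GroundTruth:
    """Latent quantities recorded during generation, for recovery tests."""

    mw_flags: dict[str, bool]
    episodes: dict[str, tuple[float, float]]
    fixations: dict[str, pd.DataFrame]
    regression_counts: dict[str, int]
    scr_events: dict[tuple[str, str], pd.DataFrame]
    tonic: dict[tuple[str, str], np.ndarray]
    tonic_t: dict[tuple[str, str], np.ndarray]


def bateman_kernel(t_s: np.ndarray, tau0_s: float, tau1_s: float) -> np.ndarray:
    """Biexponential skin-conductance-response shape, zero for t < 0."""
    if not tau0_s > tau1_s > 0:
        raise ValueError(f"require tau0 > tau1 > 0, got {tau0_s}, {tau1_s}")
    t = np.asarray(t_s, dtype=float)
    tp = np.maximum(t, 0.0)
    return np.where(t >= 0, np.exp(-tp / tau0_s) - np.exp(-tp / tau1_s), 0.0)


def bateman_mode_s(tau0_s: float, tau1_s: float) -> float:
    """Time of the kernel maximum: tau0*tau1/(tau0-tau1) * ln(tau0/tau1)."""
    return tau0_s * tau1_s / (tau0_s - tau1_s) * math.log(tau0_s / tau1_s)


def bateman_peak_value(tau0_s: float, tau1_s: float) -> float:
    return float(bateman_kernel(np.array([bateman_mode_s(tau0_s, tau1_s)]), tau0_s, tau1_s)[0])


def mw_rate(config: SimConfig, text_type: str, music_type: str) -> float:
    mult = config.mw_condition_mult.get((text_type, music_type), 1.0)
    return min(config.mw_base_rate * mult, 0.95)


def design_plan(config: SimConfig, seed: int | None = None) -> list[ParagraphEvent]:
    """Draw the full presentation schedule of a study.

    Per participant: two sessions (S1/S2; Sad- and Happy-music condition in
    counterbalanced order), each with a randomized order of 6 texts (2 per
    text type) of 4 paragraphs each, and music on exactly 2 of every text's 4
    paragraphs so each session has 12 music and 12 No-Music paragraphs,
    balanced within text type.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    events: list[ParagraphEvent] = []
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        conditions = ["Sad", "Happy"] if p % 2 == 0 else ["Happy", "Sad"]
        for s, music_cond in enumerate(conditions):
            sid = f"S{s + 1}"
            texts = [
                tt
                for tt in ("ComputerScience", "Psychology", "Random")
                for _ in range(config.texts_per_type)
            ]
            rng.shuffle(texts)
            t_cursor = 0.0
            idx = 0
            for text_type in texts:
                n_par = config.paragraphs_per_text
                with_music = rng.choice(n_par, size=n_par // 2, replace=False)
                for k in range(n_par):
                    dur = config.paragraph_duration_ms * math.exp(
                        rng.normal(0.0, config.paragraph_duration_sdlog)
                    )
                    onset = t_cursor
                    offset = onset + dur
                    t_cursor = offset + config.inter_paragraph_gap_ms
                    events.append(
                        ParagraphEvent(
                            participant=pid,
                            session=sid,
                            paragraph=f"{pid}-{sid}-p{idx:02d}",
                            onset=onset,
                            offset=offset,
                            text_type=text_type,
                            music_type=music_cond if k in with_music else "NoMusic",
                        )
                    )
                    idx += 1
    return events


def simulate_gaze(
    event: ParagraphEvent,
    episode: tuple[float, float] | None,
    params: GazeParams,
    rng: np.random.Generator,
    traits: ParticipantTraits | None = None,
    pupil_phase: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Simulate one paragraph's gaze stream.

    ``episode`` is the absolute mind-wandering window (or None); the effect
    multipliers — longer fixations, fewer fixations, higher pupil
    variability — apply only to fixations and samples inside it.  Returns
    ``(samples, true_fixations, n_regressions)``; sample timestamps are
    absolute session times on the paragraph's 90 Hz grid, the schedule frame
    has columns ``onset, offset, x, y, in_episode``.
    """
    if event.duration <= 0:
        raise ValueError("paragraph duration must be positive")
    traits = traits or ParticipantTraits(pupil_baseline=params.pupil_baseline)
    ep = None
    if episode is not None:
        ep = (episode[0] - event.onset, episode[1] - event.onset)
    dur_mult = params.mw_fix_dur_mult
    # scale transits so the expected fixation count drops by mw_fix_count_mult
    # while durations grow by mw_fix_dur_mult inside the episode
    mean_dur = math.exp(params.fix_dur_meanlog + params.fix_dur_sdlog**2 / 2)
    base_cycle = mean_dur + params.saccade_transit_ms
    target_cycle = base_cycle / params.mw_fix_count_mult
    mw_transit_scale = max(
        (target_cycle - mean_dur * dur_mult) / params.saccade_transit_ms, 0.2
    )
    base_pupil = traits.pupil_baseline
    state = math.exp(rng.normal(0.0, params.state_sdlog))
    pupil_state = math.exp(rng.normal(0.0, params.pupil_state_sdlog))
    meanlog = params.fix_dur_meanlog + traits.fix_dur_logshift + math.log(state)

    # schedule fixations along the reading path
    fix_rows = []
    n_regressions = 0
    t = 0.0
    x = params.line_start_x
    line = 0
    while t < event.duration:
        in_ep = ep is not None and ep[0] <= t < ep[1]
        dur = math.exp(rng.normal(meanlog, params.fix_dur_sdlog)) * (
            dur_mult if in_ep else 1.0
        )
        onset, offset = t, min(t + dur, event.duration)
        y = params.first_line_y + line * params.line_height_px
        fix_rows.append((onset, offset, x, y, in_ep))
        transit_scale = (mw_transit_scale if in_ep else 1.0) * state
        transit = params.saccade_transit_ms * transit_scale * math.exp(rng.normal(0, 0.2))
        t = offset + transit
        if rng.random() < params.regression_prob and len(fix_rows) > 1:
            back = rng.integers(1, 4)
            x = max(x - back * params.word_advance_px, params.line_start_x)
            n_regressions += 1
        else:
            x = x + rng.normal(params.word_advance_px, params.word_advance_sd_px)
            if x > params.line_end_x:
                x = params.line_start_x + rng.normal(0.0, 10.0)
                line = (line + 1) % params.n_lines
                t += params.saccade_transit_ms  # longer return sweep
    schedule = pd.DataFrame(fix_rows, columns=["onset", "offset", "x", "y", "in_episode"])

    # sample the path on the 90 Hz grid
    step = 1000.0 / params.fs_hz
    n = int(event.duration / step)
    tt = np.arange(n) * step
    xs = np.empty(n)
    ys = np.empty(n)
    on = schedule["onset"].to_numpy()
    off = schedule["offset"].to_numpy()
    fx = schedule["x"].to_numpy()
    fy = schedule["y"].to_numpy()
    idx = np.searchsorted(on, tt, side="right") - 1
    idx = np.clip(idx, 0, len(on) - 1)
    in_fix = tt < off[idx]
    xs = fx[idx].copy()
    ys = fy[idx].copy()
    # transit samples: interpolate toward the next fixation
    moving = ~in_fix & (idx < len(on) - 1)
    if np.any(moving):
        j = idx[moving]
        frac = (tt[moving] - off[j]) / np.maximum(on[j + 1] - off[j], 1e-9)
        xs[moving] = fx[j] + frac * (fx[j + 1] - fx[j])
        ys[moving] = fy[j] + frac * (fy[j + 1] - fy[j])
    jitter = np.where(in_fix, params.within_fix_jitter_px, params.gaze_noise_px)
    xs = xs + rng.normal(0.0, 1.0, n) * jitter
    ys = ys + rng.normal(0.0, 1.0, n) * jitter
    sd_mult = np.full(n, pupil_state)
    if ep is not None:
        sd_mult[(tt >= ep[0]) & (tt < ep[1])] *= params.mw_pupil_sd_mult
    pupil = (
        base_pupil
        + params.pupil_slow_amp
        * sd_mult
        * np.sin(2 * np.pi * tt / (params.pupil_slow_period_s * 1000.0) + pupil_phase)
        + rng.normal(0.0, 1.0, n) * params.pupil_noise_sd * traits.pupil_noise_mult * sd_mult
    )
    valid = rng.random(n) >= params.invalid_prob
    xs[~valid] = np.nan
    ys[~valid] = np.nan
    pupil[~valid] = np.nan
    samples = pd.DataFrame(
        {"t": tt + event.onset, "x": xs, "y": ys, "pupil": pupil, "valid": valid},
        columns=GAZE_COLUMNS,
    )
    schedule = schedule.assign(
        onset=schedule["onset"] + event.onset, offset=schedule["offset"] + event.onset
    )
    return samples, schedule, n_regressions


def simulate_eda(
    duration_ms: float,
    events: pd.DataFrame,
    params: EdaParams,
    rng: np.random.Generator | None = None,
    baseline_us: float = 5.0,
    tonic_phases: tuple[float, float] = (0.0, 0.0),
    noise: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Render a skin-conductance stream from a sudomotor impulse train.

    ``events`` has columns ``t`` (ms) and ``amp`` (intended SCR *peak*
    amplitude in µS); each impulse contributes ``amp/B_max * B(t - t_i)`` so
    an isolated response crests at ``amp``.  Returns ``(samples, tonic)``
    where ``tonic`` is the noiseless drift on the same 4 Hz grid.
    """
    rng = np.random.default_rng() if rng is None else rng
    step = 1000.0 / params.fs_hz
    t = np.arange(0.0, duration_ms, step)
    a1, a2 = params.tonic_drift_amp_us, params.tonic_drift_amp_us * 0.6
    p1, p2 = params.tonic_periods_s
    tonic = (
        baseline_us
        + a1 * np.sin(2 * np.pi * t / (p1 * 1000.0) + tonic_phases[0])
        + a2 * np.sin(2 * np.pi * t / (p2 * 1000.0) + tonic_phases[1])
    )
    sc = tonic.copy()
    peak = bateman_peak_value(params.tau0_s, params.tau1_s)
    for _, row in events.iterrows():
        dt_s = (t - float(row["t"])) / 1000.0
        sc = sc + float(row["amp"]) / peak * bateman_kernel(dt_s, params.tau0_s, params.tau1_s)
    if noise and params.noise_sd_us > 0:
        sc = sc + rng.normal(0.0, params.noise_sd_us, len(t))
    return pd.DataFrame({"t": t, "sc": sc}), tonic


def _draw_scr_events(
    config: SimConfig,
    session_events: list[ParagraphEvent],
    episodes: dict[str, tuple[float, float]],
    traits: ParticipantTraits,
    session_end_ms: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Piecewise-constant-rate Poisson impulse train over one session.

    The SCR rate is elevated (by ``mw_scr_rate_mult``) only inside
    mind-wandering episode windows.
    """
    p = config.eda
    base = p.scr_rate_per_min * traits.scr_rate_mult / 60_000.0  # per ms
    intervals: list[tuple[float, float, float]] = [(0.0, session_end_ms, base)]
    for ev in session_events:
        ep = episodes.get(ev.paragraph)
        if ep is not None:
            intervals.append((ep[0], ep[1], base * (p.mw_scr_rate_mult - 1.0)))
    times = []
    for lo, hi, rate in intervals:
        n = rng.poisson(rate * (hi - lo))
        times.extend(rng.uniform(lo, hi, n))
    times = np.sort(np.asarray(times))
    amps = np.exp(
        rng.normal(p.scr_amp_meanlog + traits.scr_amp_logshift, p.scr_amp_sdlog, len(times))
    )
    return pd.DataFrame({"t": times, "amp": amps})


def _quantize_rating(latent: float) -> float:
    return float(np.clip(round(latent / 20.0) * 20.0, 0.0, 100.0))


_RELEVANCE_MEAN = {"ComputerScience": 52.0, "Psychology": 21.0, "Random": 6.0}
_DIFFICULTY_MEAN = {"ComputerScience": 40.0, "Psychology": 40.0, "Random": 55.0}


def _self_report(
    ev: ParagraphEvent, mw: bool, session_frac: float, rng: np.random.Generator
) -> SelfReport:
    relevance = _quantize_rating(rng.normal(_RELEVANCE_MEAN[ev.text_type], 18.0))
    interest = _quantize_rating(
        0.5 * relevance + rng.normal(30.0, 15.0) - (15.0 if mw else 0.0)
    )
    difficulty = _quantize_rating(rng.normal(_DIFFICULTY_MEAN[ev.text_type], 15.0))
    tiredness = _quantize_rating(
        20.0 + 30.0 * session_frac + (15.0 if mw else 0.0) + rng.normal(0.0, 12.0)
    )
    happiness = _quantize_rating(rng.normal(55.0 if ev.music_type == "Happy" else 45.0, 15.0))
    sadness = _quantize_rating(rng.normal(55.0 if ev.music_type == "Sad" else 35.0, 15.0))
    if mw:
        focus = int(np.clip(round(rng.normal(-1.5, 1.8)), -5, 5))
    else:
        focus = int(np.clip(round(rng.normal(3.5, 1.2)), -5, 5))
    trt = tut = None
    if focus < 3:
        p_tut = 0.7 if mw else 0.25
        p_trt = 0.55 if ev.text_type == "Random" else 0.35
        tut = bool(rng.random() < p_tut)
        trt = bool(rng.random() < p_trt)
    return SelfReport(
        participant=ev.participant,
        session=ev.session,
        paragraph=ev.paragraph,
        interest=interest,
        difficulty=difficulty,
        tiredness=tiredness,
        happiness=happiness,
        sadness=sadness,
        relevance=relevance,
        attentional_focus=focus,
        trt=trt,
        tut=tut,
        reading_duration=ev.duration,
    )


def simulate_study(config: SimConfig | None = None, seed: int | None = None) -> Study:
    """Generate a full study with ground truth attached.

    Deterministic given ``(config, seed)``; ``seed`` overrides
    ``config.seed``.
    """
    config = SimConfig() if config is None else config
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    events = design_plan(config, seed=int(rng.integers(2**31)))
    by_session: dict[tuple[str, str], list[ParagraphEvent]] = {}
    for ev in events:
        by_session.setdefault((ev.participant, ev.session), []).append(ev)

    mw_flags: dict[str, bool] = {}
    episodes: dict[str, tuple[float, float]] = {}
    lo_frac, hi_frac = config.episode_start_frac
    for ev in events:
        flag = bool(rng.random() < mw_rate(config, ev.text_type, ev.music_type))
        mw_flags[ev.paragraph] = flag
        if flag:
            lo = ev.onset + rng.uniform(lo_frac, hi_frac) * ev.duration
            episodes[ev.paragraph] = (lo, ev.offset)

    gaze: dict[tuple[str, str], pd.DataFrame] = {}
    eda: dict[tuple[str, str], pd.DataFrame] = {}
    mw_reports: list[MWReport] = []
    self_reports: list[SelfReport] = []
    gt_fix: dict[str, pd.DataFrame] = {}
    gt_regr: dict[str, int] = {}
    gt_scr: dict[tuple[str, str], pd.DataFrame] = {}
    gt_tonic: dict[tuple[str, str], np.ndarray] = {}
    gt_tonic_t: dict[tuple[str, str], np.ndarray] = {}

    participants = sorted({ev.participant for ev in events})
    traits = {
        p: ParticipantTraits(
            pupil_baseline=rng.normal(config.gaze.pupil_baseline, 5.0),
            eda_baseline_us=rng.uniform(2.0, 8.0),
            fix_dur_logshift=rng.normal(0.0, config.trait_fix_dur_sdlog),
            pupil_noise_mult=math.exp(rng.normal(0.0, config.trait_pupil_noise_sdlog)),
            scr_rate_mult=math.exp(rng.normal(0.0, config.trait_scr_rate_sdlog)),
            scr_amp_logshift=rng.normal(0.0, config.trait_scr_amp_sdlog),
        )
        for p in participants
    }

    for key in sorted(by_session):
        pid, _ = key
        tr = traits[pid]
        session_events = sorted(by_session[key], key=lambda e: e.onset)
        blocks = []
        n_session = len(session_events)
        for i, ev in enumerate(session_events):
            mw = mw_flags[ev.paragraph]
            samples, schedule, n_reg = simulate_gaze(
                ev,
                episodes.get(ev.paragraph),
                config.gaze,
                rng,
                traits=tr,
                pupil_phase=rng.uniform(0, 2 * np.pi),
            )
            blocks.append(samples)
            gt_fix[ev.paragraph] = schedule
            gt_regr[ev.paragraph] = n_reg
            if mw:
                lo, hi = episodes[ev.paragraph]
                mw_reports.append(MWReport(pid, ev.session, float(rng.uniform(lo, hi))))
            self_reports.append(_self_report(ev, mw, i / max(n_session - 1, 1), rng))
        gaze[key] = pd.concat(blocks, ignore_index=True)
        session_end = session_events[-1].offset + 10_000.0
        scr_events = _draw_scr_events(config, session_events, episodes, tr, session_end, rng)
        stream, tonic = simulate_eda(
            session_end,
            scr_events,
            config.eda,
            rng,
            baseline_us=tr.eda_baseline_us,
            tonic_phases=(rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
        )
        eda[key] = stream
        gt_scr[key] = scr_events
        gt_tonic[key] = tonic
        gt_tonic_t[key] = stream["t"].to_numpy()

    truth = GroundTruth(
        mw_flags=mw_flags,
        episodes=episodes,
        fixations=gt_fix,
        regression_counts=gt_regr,
        scr_events=gt_scr,
        tonic=gt_tonic,
        tonic_t=gt_tonic_t,
    )
    return Study(
        participants=participants,
        sessions=sorted(by_session),
        gaze=gaze,
        eda=eda,
        paragraphs=events,
        self_reports=self_reports,
        mw_reports=mw_reports,
        ground_truth=truth,
    )


def small_config(n_participants: int = 4, seed: int = 0, **kwargs) -> SimConfig:
    """A reduced study for fast tests: fewer participants, shorter paragraphs."""
    base = SimConfig(n_participants=n_participants, seed=seed, **kwargs)
    return replace(base, paragraph_duration_ms=8_000.0, inter_paragraph_gap_ms=2_000.0)
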