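"""End-to-end reproduction benchmarks.

Each function regenerates its inputs with the synthetic-session simulator,
runs the corresponding pipeline stage from scratch, and returns summary
numbers: structural design counts, fixation-detector/reference agreement,
electrodermal decomposition recovery, the nested leave-one-participant-out
detection benchmark, and the Greenhouse-Geisser type-I calibration.  They
back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import behavior_stats, dataset_builder, detection, eda_pipeline, gaze_pipeline, simulate


def structural_counts() -> dict[str, int]:
    """Design and registry sizes implied by the defaults."""
    events = simulate.design_plan(simulate.SimConfig(n_participants=20), seed=0)
    per_session = pd.DataFrame(
        [(e.participant, e.session) for e in events]
    ).value_counts()
    counts = pd.DataFrame(
        [(e.text_type, e.music_type) for e in events], columns=["text", "music"]
    ).value_counts()
    return {
        "paragraphs_per_session": int(per_session.iloc[0]) if per_session.nunique() == 1 else -1,
        "nomusic_computer_science_paragraphs": int(counts[("ComputerScience", "NoMusic")]),
        "eye_feature_count": len(gaze_pipeline.EYE_FEATURE_NAMES),
        "eda_feature_count": len(eda_pipeline.EDA_FEATURE_NAMES),
    }


def _random_walk_stream(rng: np.random.Generator, n: int) -> pd.DataFrame:
    t = np.cumsum(rng.integers(8, 16, n)).astype(float)
    steps = rng.normal(0, rng.uniform(2, 25), (n, 2))
    jumps = (rng.random(n) < 0.05)[:, None] * rng.normal(0, 300, (n, 2))
    xy = np.cumsum(steps + jumps, axis=0) + 500
    return pd.DataFrame(
        {"t": t, "x": xy[:, 0], "y": xy[:, 1], "pupil": np.ones(n), "valid": np.ones(n, bool)}
    )


def idt_oracle_agreement(n_streams: int = 1000, seed: int = 0) -> float:
    """Fraction of random streams on which incremental I-DT equals the
    exhaustive window-enumeration reference."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_streams):
        s = _random_walk_stream(rng, int(rng.integers(2, 200)))
        disp = float(rng.uniform(10, 80))
        fast = gaze_pipeline.detect_fixations_idt(s, disp, 100)
        slow = gaze_pipeline.detect_fixations_reference(s, disp, 100)
        agree += fast == slow
    return agree / n_streams


def decomposition_recovery(
    n_streams: int = 20,
    duration_ms: float = 300_000.0,
    seed: int = 0,
    amp_threshold_us: float = 0.05,
) -> dict[str, float]:
    """Driver/tonic recovery on simulated streams with known impulse trains.

    Impulses are drawn at the generator's default rate and amplitudes with a
    2 s minimum separation so each ground-truth impulse is attributable to
    one recovered cluster; matching allows +/-2 samples and the reported
    timing error is in 250 ms samples.
    """
    params = simulate.EdaParams()
    rng = np.random.default_rng(seed)
    errs, precisions, recalls, corrs = [], [], [], []
    for _ in range(n_streams):
        n_ev = rng.poisson(params.scr_rate_per_min * duration_ms / 60_000.0)
        times = np.sort(rng.uniform(5_000, duration_ms - 10_000, n_ev))
        times = times[np.concatenate([[True], np.diff(times) > 2_000])]
        amps = np.exp(rng.normal(params.scr_amp_meanlog, params.scr_amp_sdlog, len(times)))
        events = pd.DataFrame({"t": times, "amp": amps})
        stream, tonic = simulate.simulate_eda(
            duration_ms, events, params, rng,
            baseline_us=rng.uniform(2, 8),
            tonic_phases=tuple(rng.uniform(0, 2 * np.pi, 2)),
        )
        z, mean, sd = eda_pipeline.zstandardize_subject(stream)
        decomp = eda_pipeline.decompose_cvx(z, subject_mean_us=mean, subject_sd_us=sd)
        recovered = eda_pipeline.driver_impulses(decomp, min_amp_us=amp_threshold_us)
        truth = events[events["amp"] >= amp_threshold_us]
        used = np.zeros(len(recovered), dtype=bool)
        matched_errs = []
        for t in truth["t"]:
            if not len(recovered):
                continue
            dt = np.abs(recovered["t"].to_numpy() - t)
            j = int(np.argmin(dt))
            if dt[j] <= 500.0 and not used[j]:
                used[j] = True
                matched_errs.append(dt[j] / 250.0)
        recalls.append(len(matched_errs) / max(len(truth), 1))
        precisions.append(used.sum() / max(len(recovered), 1))
        errs.extend(matched_errs)
        corrs.append(np.corrcoef(decomp.tonic, (tonic - mean) / sd)[0, 1])
    return {
        "impulse_time_error_samples": float(np.mean(errs)),
        "driver_support_precision": float(np.mean(precisions)),
        "driver_support_recall": float(np.mean(recalls)),
        "tonic_correlation": float(np.mean(corrs)),
        "n_streams": n_streams,
    }


def detection_benchmark(
    seeds: tuple[int, ...] = (0, 1, 2),
    n_participants: int = 20,
    n_label_permutations: int = 5,
) -> dict[str, float]:
    """Nested-LOPO random forest on full default studies.

    For each seed a complete study is simulated, the full feature pipeline is
    run, and the forest is evaluated on eye+EDA and EDA-only feature sets.
    The chance-level reference re-runs the baseline (logistic) pipeline on
    label-permuted data of the first study.
    """
    f1_both, f1_eda = [], []
    permuted_kappa = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, seed in enumerate(seeds):
            cfg = simulate.SimConfig(n_participants=n_participants)
            study = simulate.simulate_study(cfg, seed=seed)
            records = dataset_builder.build_paragraph_records(study)
            retained, _ = dataset_builder.apply_exclusions(records)
            ds_both = dataset_builder.build_dataset(retained, {"eye", "eda"})
            ds_eda = dataset_builder.build_dataset(retained, {"eda"})
            spec = detection.ModelSpec("random_forest", seed=seed)
            f1_both.append(detection.nested_lopo_cv(ds_both, spec).aggregate["f1"])
            f1_eda.append(detection.nested_lopo_cv(ds_eda, spec).aggregate["f1"])
            if i == 0:
                kappas = detection.permutation_null_kappa(
                    ds_both,
                    detection.ModelSpec("logistic", seed=seed),
                    n_permutations=n_label_permutations,
                    seed=seed,
                )
                permuted_kappa = float(np.mean(kappas))
    return {
        "f1_eye_eda": float(np.mean(f1_both)),
        "f1_eda": float(np.mean(f1_eda)),
        "permuted_kappa": permuted_kappa,
        "n_seeds": len(seeds),
    }


def anova_type1_calibration(
    n_sims: int = 5000, n_subjects: int = 30, seed: int = 0
) -> dict[str, float]:
    """Type-I error of the GG-corrected two-way RM-ANOVA on null data.

    Subjects x 3 x 3 iid normal draws; the rejection rate of the corrected
    test at alpha = 0.05 is reported per effect.
    """
    rng = np.random.default_rng(seed)
    y = rng.normal(size=(n_sims, n_subjects, 3, 3))
    effects = behavior_stats.rm_anova_2way(y, as_frame=False)
    return {
        "type1_text": float((effects["A"]["p_gg"] < 0.05).mean()),
        "type1_music": float((effects["B"]["p_gg"] < 0.05).mean()),
        "type1_interaction": float((effects["AxB"]["p_gg"] < 0.05).mean()),
        "n_sims": n_sims,
    }
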