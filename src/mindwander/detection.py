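"""Imbalance-aware, user-independent mind-wandering classification.

Evaluation is nested leave-one-participant-out (LOPO) cross-validation: the
outer loop holds out all paragraphs of one participant; inside each outer
training set the features are standardized (statistics from training rows
only), the minority class is oversampled with SMOTE (training rows only —
synthetic points never leak into evaluation), and for the tunable model
families the hyperparameters are selected by stratified 3-fold inner
cross-validation maximizing weighted F1.  Logistic regression is the
untuned baseline and skips the inner loop.  Per-fold metrics (accuracy,
Cohen's kappa, AUC, and support-weighted F1/precision/recall) are averaged
over folds.

Feature attribution uses a model-agnostic Monte-Carlo permutation-sampling
estimate of Shapley values on the model's positive-class probability: for
each sampled feature permutation and background row, features are switched
one at a time from the background to the explained instance and the change
in model output is credited to the switched feature.  Per explained
instance the attributions sum exactly to the model output minus the
background expectation (additivity holds per permutation by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset_builder import Dataset

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "logistic": [{}],
    # compact grid spanning tree count and depth; nested LOPO refits every
    # combination 3x per outer fold, so the grid is kept small enough for a
    # single-CPU evaluation of a full study
    "random_forest": [
        {"n_estimators": 100, "max_depth": 5},
        {"n_estimators": 100, "max_depth": 10},
        {"n_estimators": 300, "max_depth": 5},
    ],
    "svm_rbf": [
        {"C": c, "gamma": g} for c in (0.1, 1.0, 10.0) for g in ("scale", 0.01, 0.1)
    ],
}


@dataclass
class ModelSpec:
    """A model family plus its hyperparameter grid.

    ``logistic`` is the untuned baseline; ``svm_rbf`` and ``random_forest``
    require a non-empty grid.
    """

    family: str = "random_forest"
    grid: list[dict] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.grid is None:
            self.grid = [dict(g) for g in DEFAULT_GRIDS[self.family]]
        if self.family != "logistic" and not self.grid:
            raise ValueError(f"{self.family} requires a non-empty grid")


@dataclass
class FoldScaler:
    """Per-feature standardization fitted on training rows only."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask of non-constant features

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.kept] - self.mean) / self.sd


@dataclass
class FoldResult:
    participant: str
    chosen_params: dict
    confusion: np.ndarray
    metrics: dict[str, float]


@dataclass
class CVResult:
    folds: list[FoldResult]
    aggregate: dict[str, float] = field(default_factory=dict)
    aggregate_sd: dict[str, float] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    attributions: pd.Series | None = None

    def summary(self) -> pd.DataFrame:
        rows = [
            {"metric": k, "mean": v, "sd": self.aggregate_sd.get(k, np.nan)}
            for k, v in self.aggregate.items()
        ]
        return pd.DataFrame(rows)


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balance classes 1:1 by synthetic minority oversampling.

    New points are ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)`` and
    ``x_nn`` one of the ``k`` nearest minority neighbors of ``x_i``.
    Returns ``(X_aug, y_aug, synthetic)`` where ``synthetic`` flags the
    appended rows; original rows are preserved first and untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X.copy(), y.copy(), np.zeros(len(y), dtype=bool)
    if n_min < 2:
        raise ValueError("need at least 2 minority samples for SMOTE")
    if k >= n_min:
        warnings.warn(f"k={k} >= minority count {n_min}; reducing to {n_min - 1}")
        k = n_min - 1
    Xm = X[y == minority]
    # k nearest minority neighbors, excluding self
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]
    base = rng.integers(0, n_min, n_new)
    pick = nn[base, rng.integers(0, k, n_new)]
    u = rng.uniform(0.0, 1.0, (n_new, 1))
    X_new = Xm[base] + u * (Xm[pick] - Xm[base])
    X_aug = np.vstack([X, X_new])
    y_aug = np.concatenate([y, np.full(n_new, minority)])
    synthetic = np.concatenate([np.zeros(len(y), dtype=bool), np.ones(n_new, dtype=bool)])
    return X_aug, y_aug, synthetic


def fold_standardize(
    X_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, FoldScaler]:
    """Standardize with training statistics; constant features are dropped."""
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    kept = sd > 0
    if not np.all(kept):
        warnings.warn(f"dropping {int((~kept).sum())} constant feature(s) in fold")
    scaler = FoldScaler(mean=mean[kept], sd=sd[kept], kept=kept)
    return scaler.transform(X_train), scaler.transform(X_test), scaler


def _make_model(family: str, params: dict, seed: int):
    if family == "logistic":
        return LogisticRegression(max_iter=2000, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    raise ValueError(f"unknown model family {family!r}")


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> dict[str, float]:
    """The evaluation battery for one fold.

    Weighted F1/precision/recall use class-support weights; AUC needs
    continuous scores and both classes in the truth, otherwise it is NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "kappa": float(cohen_kappa_score(y_true, y_pred)),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0
        )
    out["precision"] = float(p)
    out["recall"] = float(r)
    out["f1"] = float(f1)
    if scores is not None and len(np.unique(y_true)) == 2:
        out["auc"] = float(roc_auc_score(y_true, scores))
    else:
        out["auc"] = float("nan")
    return out


def _inner_select(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    inner_folds: int,
    rng: np.random.Generator,
) -> dict:
    """Grid search by stratified k-fold on the outer-training rows.

    SMOTE is applied inside each inner training split only, so inner
    validation rows are always real observations.
    """
    if len(spec.grid) == 1:
        return dict(spec.grid[0])
    skf = StratifiedKFold(
        n_splits=inner_folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    splits = list(skf.split(X, y))
    best_score, best_params = -np.inf, dict(spec.grid[0])
    for params in spec.grid:
        scores = []
        for tr_idx, va_idx in splits:
            X_tr, y_tr, _ = smote_oversample(
                X[tr_idx], y[tr_idx], seed=np.random.default_rng(spec.seed)
            )
            model = _make_model(spec.family, params, spec.seed)
            model.fit(X_tr, y_tr)
            pred = model.predict(X[va_idx])
            scores.append(compute_metrics(y[va_idx], pred)["f1"])
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_params = score, dict(params)
    return best_params


def nested_lopo_cv(
    dataset: Dataset,
    model_spec: ModelSpec | None = None,
    inner_folds: int = 3,
    attribution_permutations: int = 0,
) -> CVResult:
    """Nested leave-one-participant-out evaluation.

    One outer fold per participant; standardization, SMOTE, and (for the
    tunable families) inner 3-fold grid search all see only the outer
    training rows.  Folds whose training set is single-class are skipped
    with a warning.  With ``attribution_permutations > 0`` a Shapley
    attribution summary is accumulated over held-out rows.
    """
    spec = ModelSpec() if model_spec is None else model_spec
    participants = sorted(set(dataset.groups))
    if len(participants) < 3:
        raise ValueError("need at least 3 participants for LOPO")
    rng = np.random.default_rng(spec.seed)
    X_all = dataset.X.to_numpy(dtype=float)
    y_all = dataset.y
    folds: list[FoldResult] = []
    attr_sum = np.zeros(X_all.shape[1])
    attr_n = 0
    for pid in participants:
        test_mask = dataset.groups == pid
        X_tr_raw, y_tr = X_all[~test_mask], y_all[~test_mask]
        X_te_raw, y_te = X_all[test_mask], y_all[test_mask]
        if len(np.unique(y_tr)) < 2:
            warnings.warn(f"fold {pid}: single-class training set, skipped")
            continue
        X_tr, X_te, scaler = fold_standardize(X_tr_raw, X_te_raw)
        params = _inner_select(X_tr, y_tr, spec, inner_folds, rng)
        X_fit, y_fit, _ = smote_oversample(
            X_tr, y_tr, seed=np.random.default_rng(spec.seed)
        )
        model = _make_model(spec.family, params, spec.seed)
        model.fit(X_fit, y_fit)
        pred = model.predict(X_te)
        scores = model.predict_proba(X_te)[:, 1]
        metrics = compute_metrics(y_te, pred, scores)
        folds.append(
            FoldResult(
                participant=pid,
                chosen_params=params,
                confusion=confusion_matrix(y_te, pred, labels=[0, 1]),
                metrics=metrics,
            )
        )
        if attribution_permutations > 0:
            n_explain = min(len(X_te), 8)
            idx = rng.choice(len(X_te), size=n_explain, replace=False)
            phi = shapley_importance(
                model,
                X_te[idx],
                X_tr,
                n_permutations=attribution_permutations,
                seed=int(rng.integers(2**31)),
            )
            full = np.zeros(X_all.shape[1])
            full[scaler.kept] = np.abs(phi).mean(axis=0)
            attr_sum += full * n_explain
            attr_n += n_explain
    if not folds:
        raise ValueError("no usable outer folds")
    metric_names = folds[0].metrics.keys()
    aggregate = {
        m: float(np.nanmean([f.metrics[m] for f in folds])) for m in metric_names
    }
    aggregate_sd = {
        m: float(np.nanstd([f.metrics[m] for f in folds])) for m in metric_names
    }
    attributions = None
    if attr_n:
        attributions = pd.Series(
            attr_sum / attr_n, index=dataset.feature_names
        ).sort_values(ascending=False)
    return CVResult(
        folds=folds,
        aggregate=aggregate,
        aggregate_sd=aggregate_sd,
        feature_names=list(dataset.feature_names),
        attributions=attributions,
    )


def shapley_importance(
    model,
    X_explain: np.ndarray,
    X_background: np.ndarray,
    n_permutations: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo permutation-sampling Shapley values.

    For each explained row, each sampled permutation pairs with one
    background row; walking through the permutation, features flip from the
    background value to the explained value and the resulting change in
    ``predict_proba[:, 1]`` is the flipped feature's credit.  Returns an
    ``(n_explain, n_features)`` array; per row the values sum to
    ``f(x) - mean_b f(b)`` over the sampled backgrounds (exact additivity).
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations for a stable estimate")
    rng = np.random.default_rng(seed)
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    n_explain, d = X_explain.shape
    n_pairs = (n_permutations + 1) // 2
    phi = np.zeros((n_explain, d))
    for i in range(n_explain):
        x = X_explain[i]
        for _ in range(n_pairs):
            # antithetic pair: a permutation and its reversal share a background,
            # which removes order-count imbalance (and makes d=2 exact)
            base_order = rng.permutation(d)
            b = X_background[rng.integers(len(X_background))]
            for order in (base_order, base_order[::-1]):
                # hybrid rows: background with the first j features of `order`
                # switched to x
                hybrids = np.tile(b, (d + 1, 1))
                for j, feat in enumerate(order):
                    hybrids[j + 1 :, feat] = x[feat]
                out = model.predict_proba(hybrids)[:, 1]
                phi[i, order] += np.diff(out)
    return phi / (2 * n_pairs)


def permutation_null_kappa(
    dataset: Dataset,
    model_spec: ModelSpec | None = None,
    n_permutations: int = 5,
    seed: int = 0,
) -> list[float]:
    """Aggregate kappa under label permutation (chance-level reference).

    Labels are shuffled within participant groups kept intact, then the full
    nested LOPO pipeline runs; the resulting kappas should scatter around 0.
    """
    rng = np.random.default_rng(seed)
    spec = ModelSpec(family="logistic") if model_spec is None else model_spec
    out = []
    for _ in range(n_permutations):
        y_perm = rng.permutation(dataset.y)
        ds = Dataset(
            X=dataset.X,
            y=y_perm,
            groups=dataset.groups,
            feature_names=dataset.feature_names,
        )
        try:
            res = nested_lopo_cv(ds, spec)
        except ValueError:
            continue
        out.append(res.aggregate["kappa"])
    return out
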