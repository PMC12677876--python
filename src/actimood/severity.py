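"""Leak-safe binary classification of severe mood days.

Targets are mood-only: ``severe_day`` = 1 iff MoodPosMax >= 7 or
MoodNegMax >= 7; ``severe_tomorrow`` shifts the same rule one calendar day
forward within each patient (rows at gaps and each patient's last day carry
a missing next-day label and are excluded from next-day training).

Predictors span four domains -- actigraphy extremes and summaries, sleep
metrics, energy self-ratings, demographics -- and never include any
mood-derived column (asserted, not assumed). All fitting (median
imputation, scaling, SMOTE-style minority oversampling, hyperparameter
selection, decision-threshold tuning) happens strictly inside training
folds of a patient-grouped 5-fold outer / 3-fold inner cross-validation.
Every fit is audited: the returned results carry the per-fold train/test
patient sets so leakage guards can be asserted after the fact.

``SeverityModel(...).fit()`` runs one model through the nested CV and
returns a :class:`SeverityResults`; :func:`run_experiment` runs the whole
menu plus a soft-vote ensemble for both targets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import GroupKFold
from sklearn.neighbors import NearestNeighbors

from .config import ClassifierConfig
from .errors import IntegrityError, SplitError

log = logging.getLogger(__name__)

SEVERE_MAGNITUDE = 7.0

ACTIGRAPHY_BLOCK = (
    [f"max{i}" for i in range(1, 5)]
    + [f"min{i}" for i in range(1, 5)]
    + [f"contrast{i}" for i in range(1, 5)]
    + ["total_ac", "avg_ac_per_min", "avg_ac_per_epoch", "std_ac", "max_ac"]
)
SLEEP_BLOCK = [
    "sleep_duration", "sleep_efficiency", "sleep_waso", "sleep_time",
    "pct_sleep", "sleep_fragmentation",
]
ENERGY_BLOCK = [
    "energy_pos_max", "energy_pos_min", "energy_neg_max", "energy_neg_min",
    "energy_min", "energy_max", "energy_mean", "energy_range",
]
_MOOD_PATTERN = re.compile("mood", re.IGNORECASE)


# ---------------------------------------------------------------------------
# labels and features
# ---------------------------------------------------------------------------

def make_labels(met_daily: pd.DataFrame) -> pd.DataFrame:
    """Per patient-day severe_day and (calendar-shifted) severe_tomorrow.

    ``severe_tomorrow`` on day t equals ``severe_day`` on day t+1 when the
    same patient has an adjacent next day, else missing (NaN).
    """
    df = met_daily[["patient_id", "date", "mood_pos_max", "mood_neg_max"]].copy()
    if not df.equals(df.sort_values(["patient_id", "date"])):
        log.warning("met_daily not sorted; sorting by (patient_id, date)")
        df = df.sort_values(["patient_id", "date"])
    df = df.reset_index(drop=True)
    df["severe_day"] = (
        (df["mood_pos_max"] >= SEVERE_MAGNITUDE)
        | (df["mood_neg_max"] >= SEVERE_MAGNITUDE)
    ).astype(float)
    df.loc[df["mood_pos_max"].isna(), "severe_day"] = np.nan

    dates = pd.to_datetime(df["date"])
    nxt_same = (df["patient_id"].shift(-1) == df["patient_id"]) & (
        (dates.shift(-1) - dates).dt.days == 1
    )
    df["severe_tomorrow"] = np.where(
        nxt_same, df["severe_day"].shift(-1), np.nan
    )
    return df[["patient_id", "date", "severe_day", "severe_tomorrow"]]


def assemble_features(
    daily_features: pd.DataFrame,
    met_daily: pd.DataFrame,
    patients: pd.DataFrame,
) -> pd.DataFrame:
    """Join the four predictor domains on (patient_id, date).

    Numeric features pass through with NaN preserved for in-fold median
    imputation; gender and diagnostic group are indicator-coded. Raises
    :class:`IntegrityError` on duplicated keys or on any mood-derived column
    smuggled into the actigraphy/patient inputs (the label leakage guard).
    """
    for name, df in (("daily_features", daily_features), ("patients", patients)):
        bad = [c for c in df.columns if _MOOD_PATTERN.search(c)]
        if bad:
            raise IntegrityError(f"mood-derived columns in {name}: {bad}")
    for df in (daily_features, met_daily):
        if df.duplicated(["patient_id", "date"]).any():
            raise IntegrityError("duplicated (patient_id, date) keys")

    acti = daily_features[
        ["patient_id", "date"]
        + [c for c in ACTIGRAPHY_BLOCK + SLEEP_BLOCK if c in daily_features.columns]
    ]
    energy = met_daily[
        ["patient_id", "date"]
        + [c for c in ENERGY_BLOCK if c in met_daily.columns]
    ]
    X = acti.merge(energy, on=["patient_id", "date"], how="inner")
    demo = patients[["patient_id", "group", "age_months", "gender"]]
    X = X.merge(demo, on="patient_id", how="left")
    X = pd.get_dummies(X, columns=["group", "gender"], dtype=float)
    assert not any(_MOOD_PATTERN.search(c) for c in X.columns)
    return X


def grouped_splits(groups, k: int, seed: int = 0):
    """Patient-grouped k-fold (train_idx, test_idx) pairs.

    Every patient's rows fall wholly in train or test; the folds partition
    the rows. GroupKFold balances fold sizes by row count as far as the
    grouping allows.
    """
    groups = np.asarray(groups)
    n_patients = len(pd.unique(groups))
    if n_patients < k:
        raise SplitError(f"{n_patients} patients cannot form {k} grouped folds")
    gkf = GroupKFold(n_splits=k)
    return list(gkf.split(np.zeros(len(groups)), groups=groups))


# ---------------------------------------------------------------------------
# minority oversampling (SMOTE-style, training folds only)
# ---------------------------------------------------------------------------

def oversample_minority(
    X: np.ndarray, y: np.ndarray, k_neighbors: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes with convex interpolation between each sampled
    minority row and one of its k nearest minority neighbours (Euclidean,
    in the already imputed and scaled feature space).

    A minority class of size 1 falls back to duplication with a warning;
    balanced input is returned unchanged. Must only ever be called on
    training partitions -- the pipeline enforces this.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if len(Xm) == 1:
        log.warning("minority class of size 1: duplicating instead of SMOTE")
        Xs = np.repeat(Xm, need, axis=0)
    else:
        k = min(k_neighbors, len(Xm) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)  # column 0 is the point itself
        base = rng.integers(0, len(Xm), size=need)
        pick = idx[base, rng.integers(1, k + 1, size=need)]
        lam = rng.random(size=(need, 1))
        Xs = Xm[base] + lam * (Xm[pick] - Xm[base])
    return (
        np.vstack([X, Xs]),
        np.concatenate([y, np.full(need, minority, dtype=y.dtype)]),
    )


# ---------------------------------------------------------------------------
# in-fold preprocessing
# ---------------------------------------------------------------------------

class _FoldPreprocessor:
    """Median imputation + standardisation fit on training rows only."""

    def fit(self, X: np.ndarray) -> "_FoldPreprocessor":
        self.medians_ = np.nanmedian(X, axis=0)
        self.medians_ = np.where(np.isnan(self.medians_), 0.0, self.medians_)
        Xi = self._impute(X)
        self.mean_ = Xi.mean(axis=0)
        sd = Xi.std(axis=0)
        self.sd_ = np.where(sd == 0, 1.0, sd)
        return self

    def _impute(self, X):
        return np.where(np.isnan(X), self.medians_, X)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (self._impute(X) - self.mean_) / self.sd_


def _make_model(name: str, params: dict, seed: int):
    if name == "logistic_regression":
        return LogisticRegression(max_iter=3000, random_state=seed, **params)
    if name == "gradient_boosted_trees":
        return HistGradientBoostingClassifier(random_state=seed, **params)
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=150, random_state=seed, n_jobs=1, **params
        )
    if name == "extra_trees":
        return ExtraTreesClassifier(
            n_estimators=150, random_state=seed, n_jobs=1, **params
        )
    raise ValueError(f"unknown model {name!r}")


#: Small documented hyperparameter grids (none are specified upstream).
HYPER_GRIDS = {
    "logistic_regression": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "gradient_boosted_trees": [
        {"max_leaf_nodes": 15}, {"max_leaf_nodes": 31}
    ],
    "random_forest": [{"max_depth": None}, {"max_depth": 8}],
    "extra_trees": [{"max_depth": None}, {"max_depth": 8}],
}


def sweep_threshold(
    scores: np.ndarray,
    y: np.ndarray,
    grid=(0.05, 0.95, 0.05),
    objective: str = "accuracy",
) -> float:
    """Grid argmax of the objective; ties broken toward 0.5, then lower."""
    start, stop, step = grid
    thresholds = np.round(np.arange(start, stop + step / 2, step), 10)
    best = []
    for t in thresholds:
        pred = (scores >= t).astype(int)
        acc = accuracy_score(y, pred)
        if objective == "accuracy_f1":
            obj = 0.5 * (acc + f1_score(y, pred, zero_division=0))
        else:
            obj = acc
        best.append(obj)
    best = np.asarray(best)
    cand = thresholds[best == best.max()]
    return float(cand[np.lexsort((cand, np.abs(cand - 0.5)))[0]])


@dataclass
class FoldAudit:
    """Leakage instrumentation for one outer fold."""

    fold: int
    train_patients: set
    test_patients: set
    stats_fit_on: str = "train"  # imputation/scaling/SMOTE/threshold provenance


def tune_train(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    gtr: np.ndarray,
    model_name: str,
    config: ClassifierConfig,
    rng: np.random.Generator,
):
    """Inner grouped CV model selection + threshold tuning, training fold only.

    Returns (preprocessor, fitted model, threshold, chosen params). The
    threshold is tuned on one reserved grouped split (~1/(inner_folds) of
    the training patients) and the final model is refit on the whole
    (oversampled) training fold.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    grid = HYPER_GRIDS[model_name]
    if len(pd.unique(gtr)) >= config.inner_folds and len(grid) > 1:
        inner = grouped_splits(gtr, config.inner_folds)
        mean_auc = []
        for params in grid:
            aucs = []
            for itr, iva in inner:
                pp = _FoldPreprocessor().fit(Xtr[itr])
                Xi, yi = oversample_minority(
                    pp.transform(Xtr[itr]), ytr[itr],
                    config.oversampling_neighbors, rng,
                )
                m = _make_model(model_name, params, seed).fit(Xi, yi)
                yv = ytr[iva]
                if len(np.unique(yv)) == 2:
                    aucs.append(
                        roc_auc_score(
                            yv, m.predict_proba(pp.transform(Xtr[iva]))[:, 1]
                        )
                    )
            mean_auc.append(np.mean(aucs) if aucs else -np.inf)
        params = grid[int(np.argmax(mean_auc))]
    else:
        params = grid[0]

    # reserved grouped validation split for the decision threshold
    thr_tr, thr_va = grouped_splits(gtr, config.inner_folds)[0]
    pp = _FoldPreprocessor().fit(Xtr[thr_tr])
    Xi, yi = oversample_minority(
        pp.transform(Xtr[thr_tr]), ytr[thr_tr],
        config.oversampling_neighbors, rng,
    )
    m = _make_model(model_name, params, seed).fit(Xi, yi)
    va_scores = m.predict_proba(pp.transform(Xtr[thr_va]))[:, 1]
    threshold = sweep_threshold(
        va_scores, ytr[thr_va], config.threshold_grid, config.threshold_objective
    )

    pp_full = _FoldPreprocessor().fit(Xtr)
    Xf, yf = oversample_minority(
        pp_full.transform(Xtr), ytr, config.oversampling_neighbors, rng
    )
    final = _make_model(model_name, params, seed).fit(Xf, yf)
    return pp_full, final, threshold, params, (thr_tr, thr_va)


def evaluate(scores: np.ndarray, threshold: float, y: np.ndarray) -> dict:
    """Fold metrics from continuous scores and the tuned threshold.

    ROC-AUC / PR-AUC (average precision) need both classes in the test fold;
    single-class folds record them as missing rather than 0.5.
    """
    pred = (scores >= threshold).astype(int)
    two_class = len(np.unique(y)) == 2
    cm = confusion_matrix(y, pred, labels=[0, 1])
    return {
        "roc_auc": float(roc_auc_score(y, scores)) if two_class else np.nan,
        "pr_auc": float(average_precision_score(y, scores)) if two_class else np.nan,
        "accuracy": float(accuracy_score(y, pred)),
        "f1": float(f1_score(y, pred, zero_division=0)),
        "threshold": float(threshold),
        "tn": int(cm[0, 0]), "fp": int(cm[0, 1]),
        "fn": int(cm[1, 0]), "tp": int(cm[1, 1]),
        "n_test": int(len(y)),
    }


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class SeverityModel:
    """Nested grouped-CV classifier for one target and one estimator family.

    Parameters
    ----------
    features : DataFrame from :func:`assemble_features` (patient_id, date + X).
    labels : DataFrame from :func:`make_labels`.
    target : "severe_day" or "severe_tomorrow".
    model_name : entry of the model menu.
    config : :class:`ClassifierConfig`.
    """

    def __init__(self, features, labels, target="severe_day",
                 model_name="logistic_regression",
                 config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.target = target
        self.model_name = model_name
        data = features.merge(
            labels[["patient_id", "date", target]], on=["patient_id", "date"]
        )
        data = data[data[target].notna()].reset_index(drop=True)
        self.feature_names = [
            c for c in data.columns if c not in ("patient_id", "date", target)
        ]
        self.X = data[self.feature_names].to_numpy(dtype=float)
        self.y = data[target].to_numpy(dtype=int)
        self.groups = data["patient_id"].to_numpy()

    def fit(self) -> "SeverityResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        folds = grouped_splits(self.groups, cfg.outer_folds)
        rows, audits, fold_models = [], [], []
        for i, (tr, te) in enumerate(folds):
            audits.append(FoldAudit(
                fold=i,
                train_patients=set(self.groups[tr]),
                test_patients=set(self.groups[te]),
            ))
            pp, model, thr, params, _ = tune_train(
                self.X[tr], self.y[tr], self.groups[tr],
                self.model_name, cfg, rng,
            )
            scores = model.predict_proba(pp.transform(self.X[te]))[:, 1]
            row = evaluate(scores, thr, self.y[te])
            row.update(fold=i, params=str(params))
            rows.append(row)
            fold_models.append((pp, model, thr, te, scores))
        return SeverityResults(
            model=self, fold_metrics=pd.DataFrame(rows), audits=audits,
            _fold_models=fold_models,
        )


@dataclass
class SeverityResults:
    model: SeverityModel
    fold_metrics: pd.DataFrame
    audits: list
    _fold_models: list = field(repr=False, default_factory=list)

    @property
    def aggregate(self) -> dict:
        """Mean across folds; missing AUCs (single-class folds) excluded."""
        agg = {}
        for m in ("roc_auc", "pr_auc", "accuracy", "f1", "threshold"):
            agg[m] = float(np.nanmean(self.fold_metrics[m]))
        return agg

    def assert_leak_free(self) -> None:
        for a in self.audits:
            overlap = a.train_patients & a.test_patients
            if overlap:
                raise IntegrityError(f"fold {a.fold}: patients in both "
                                     f"partitions: {sorted(overlap)[:5]}")

    def permutation_importance(self, n_repeats: int = 5,
                               rng: np.random.Generator | None = None
                               ) -> pd.DataFrame:
        """Cross-validated permutation importance: mean ROC-AUC drop when a
        feature is shuffled within each frozen test fold, averaged over
        folds and repeats; sorted descending."""
        if n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        rng = rng or np.random.default_rng(self.model.config.seed)
        names = self.model.feature_names
        drops = np.zeros((len(self._fold_models), len(names)))
        for fi, (pp, m, thr, te, base_scores) in enumerate(self._fold_models):
            Xte, yte = self.model.X[te], self.model.y[te]
            if len(np.unique(yte)) < 2:
                drops[fi] = np.nan
                continue
            base = roc_auc_score(yte, base_scores)
            for j in range(len(names)):
                vals = []
                for _ in range(n_repeats):
                    Xp = Xte.copy()
                    Xp[:, j] = rng.permutation(Xp[:, j])
                    vals.append(
                        roc_auc_score(yte, m.predict_proba(pp.transform(Xp))[:, 1])
                    )
                drops[fi, j] = base - np.mean(vals)
        out = pd.DataFrame({
            "feature": names,
            "importance": np.nanmean(drops, axis=0),
        }).sort_values("importance", ascending=False).reset_index(drop=True)
        return out

    def summary(self) -> str:
        a = self.aggregate
        lines = [
            f"SeverityResults: target={self.model.target} "
            f"model={self.model.model_name}",
            f"  folds={len(self.fold_metrics)}  "
            f"ROC-AUC={a['roc_auc']:.3f}  PR-AUC={a['pr_auc']:.3f}  "
            f"accuracy={a['accuracy']:.3f}  F1={a['f1']:.3f}",
            f"  mean tuned threshold={a['threshold']:.2f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# full experiment: model menu + soft-vote ensemble, both targets
# ---------------------------------------------------------------------------

def run_experiment(
    daily_features: pd.DataFrame,
    met_daily: pd.DataFrame,
    patients: pd.DataFrame,
    config: ClassifierConfig | None = None,
    targets=("severe_day", "severe_tomorrow"),
    importance_repeats: int = 3,
) -> dict:
    """Evaluate the model menu plus a soft-vote ensemble for each target.

    Returns a report dict with per-model aggregate metrics, per-fold tables,
    the best model (by mean ROC-AUC), its permutation importance table, and
    class-balance counts for both targets.
    """
    cfg = config or ClassifierConfig()
    features = assemble_features(daily_features, met_daily, patients)
    labels = make_labels(met_daily)
    report = {"targets": {}, "class_balance": {}}
    for target in targets:
        lab = labels[labels[target].notna()]
        counts = lab[target].value_counts().to_dict()
        report["class_balance"][target] = {
            "0": int(counts.get(0.0, 0)), "1": int(counts.get(1.0, 0)),
            "n": int(len(lab)),
        }
        per_model, results_objs = {}, {}
        for name in cfg.model_menu:
            res = SeverityModel(
                features, labels, target, name, cfg
            ).fit()
            res.assert_leak_free()
            per_model[name] = res.aggregate
            results_objs[name] = res
        if cfg.include_ensemble and len(cfg.model_menu) > 1:
            per_model["soft_vote"] = _soft_vote(results_objs, cfg)
        best = max(per_model, key=lambda k: per_model[k]["roc_auc"])
        # importance is always computed on a fitted member (not the ensemble)
        best_member = max(results_objs, key=lambda k: per_model[k]["roc_auc"])
        best_res = results_objs[best_member]
        importance = best_res.permutation_importance(importance_repeats)
        report["targets"][target] = {
            "models": per_model,
            "best_model": best,
            "fold_metrics": {
                name: r.fold_metrics for name, r in results_objs.items()
            },
            "importance": importance,
            "results": results_objs,
        }
    return report


def _soft_vote(results_objs: dict, cfg: ClassifierConfig) -> dict:
    """Unweighted mean of member fold probabilities, evaluated per fold at
    the mean of the member thresholds."""
    members = list(results_objs.values())
    ref = members[0]
    rows = []
    for fi in range(len(ref._fold_models)):
        te = ref._fold_models[fi][3]
        scores = np.mean(
            [m._fold_models[fi][4] for m in members], axis=0
        )
        thr = float(np.mean([m._fold_models[fi][2] for m in members]))
        rows.append(evaluate(scores, thr, ref.model.y[te]))
    df = pd.DataFrame(rows)
    return {m: float(np.nanmean(df[m]))
            for m in ("roc_auc", "pr_auc", "accuracy", "f1", "threshold")}
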