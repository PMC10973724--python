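"""Nested cross-validation harness and the final deployment fit.

Outer stratified 5-fold loop: each fold's training portion drives the inner
multi-objective pipeline search; the selected configuration is refit on the
whole training portion; the held fold is split stratified 60/40 into a
calibration set (Venn-Abers fit) and a test set on which AUC, sensitivity /
specificity at threshold 0.5, ECE and log-loss are reported.  Aggregates
are the mean fold AUC with its standard error and normal 95% CI, plus a
pooled misclassification-by-age audit over all outer test folds.

Synthetic (SMOTE) rows may train and calibrate but are excluded from outer
test metrics by default, so performance is stated on real samples only;
``include_synthetic_in_test=True`` mirrors the alternative convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .calibrate import VennAbersCalibrator, expected_calibration_error
from .cohort import GlycomicsCohort
from .optimize import (Learner, PipelineConfig, auc_roc, default_search_space,
                       inner_fold_splits, log_loss, make_scaler,
                       optimise_pipeline)

Z_95 = 1.96  # normal multiplier on the SE of fold means (t(4) optional)


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def stratified_kfold(labels, k: int, seed: int = 0) -> list:
    """Seeded stratified folds as (train_idx, held_idx) pairs."""
    y = np.asarray(labels).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < k:
        raise ValueError(f"each class needs >= {k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def threshold_metrics(probs, labels, threshold: float = 0.5) -> tuple[float, float, float]:
    """(sensitivity, specificity, false-negative rate) at a decision threshold.

    Predicted positive iff prob >= threshold.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return float(sens), float(spec), float(1.0 - sens)


def mean_ci(values, level: float = 0.95, use_t: bool = False):
    """(mean, SE, lower, upper) of the mean of fold-level values."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    mean = float(v.mean())
    se = float(v.std(ddof=1) / np.sqrt(len(v)))
    from scipy import stats as _st
    if use_t:
        mult = float(_st.t.ppf(0.5 + level / 2, len(v) - 1))
    elif abs(level - 0.95) < 1e-12:
        mult = Z_95
    else:
        mult = float(_st.norm.ppf(0.5 + level / 2))
    return mean, se, mean - mult * se, mean + mult * se


@dataclass
class AgeRangeAudit:
    """Misclassified / total counts in fixed-width age bins."""

    bin_edges: np.ndarray
    misclassified: np.ndarray
    totals: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        lo = self.bin_edges[:-1]
        hi = self.bin_edges[1:] - 1
        return pd.DataFrame({"age_range": [f"{int(a)}-{int(b)}" for a, b in zip(lo, hi)],
                             "misclassified": self.misclassified,
                             "total": self.totals})


def age_range_audit(probs, labels, ages, threshold: float = 0.5,
                    bin_width: int = 5) -> AgeRangeAudit:
    """Bin misclassifications by age, bins of ``bin_width`` years from the
    minimum age present."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    a = np.asarray(ages, dtype=int)
    if not (len(p) == len(y) == len(a)):
        raise ValueError("probs, labels, ages must have equal lengths")
    pred = (p >= threshold).astype(int)
    wrong = pred != y
    a_min = int(a.min())
    n_bins = int((a.max() - a_min) // bin_width) + 1
    edges = a_min + bin_width * np.arange(n_bins + 1)
    idx = (a - a_min) // bin_width
    mis = np.bincount(idx[wrong], minlength=n_bins)
    tot = np.bincount(idx, minlength=n_bins)
    return AgeRangeAudit(edges, mis, tot)


# ---------------------------------------------------------------------------
# NCV
# ---------------------------------------------------------------------------

def _refit(config: PipelineConfig, X, y, seed: int):
    scaler = make_scaler(config.scaler)
    Xs = X if scaler is None else scaler.fit_transform(X)
    learner = Learner(config, seed=seed).fit(Xs, y)

    def score(Xq):
        Xq = np.asarray(Xq, dtype=float)
        return learner.predict_score(Xq if scaler is None else scaler.transform(Xq))

    return score


@dataclass
class FoldResult:
    fold: int
    config: PipelineConfig
    auc: float
    sensitivity: float
    specificity: float
    fnr: float
    ece: float
    logloss: float
    n_test: int
    failed: bool = False
    error: str = ""


@dataclass
class NCVReport:
    folds: list
    mean_auc: float
    se_auc: float
    ci_auc: tuple
    age_audit: AgeRangeAudit
    predictions: pd.DataFrame  # per-test-sample fold, p_pos, label, age
    threshold: float = 0.5

    @property
    def fold_aucs(self) -> np.ndarray:
        return np.array([f.auc for f in self.folds if not f.failed])

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc, "se_auc": self.se_auc,
            "ci_auc": list(self.ci_auc), "threshold": self.threshold,
            "folds": [{
                "fold": f.fold, "auc": f.auc, "sensitivity": f.sensitivity,
                "specificity": f.specificity, "fnr": f.fnr, "ece": f.ece,
                "logloss": f.logloss, "n_test": f.n_test,
                "config": {"scaler": f.config.scaler, "learner": f.config.learner,
                           "params": f.config.param_dict},
                "failed": f.failed, "error": f.error,
            } for f in self.folds],
            "age_audit": self.age_audit.to_frame().to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def run_ncv(cohort: GlycomicsCohort, space: dict | None = None,
            outer_k: int = 5, inner_k: int = 5, n_trials: int = 50,
            calib_frac: float = 0.6, threshold: float = 0.5, seed: int = 0,
            include_synthetic_in_test: bool = False,
            sampler: str = "tpe") -> NCVReport:
    """Nested cross-validation of the full pipeline on a cohort.

    Features entering the models are the 24 GPs plus age and the one-hot
    male flag, so the downstream covariate-effect audit is meaningful.
    Stage seeds derive from ``seed`` by fixed offsets.
    """
    space = space or default_search_space()
    X = cohort.feature_matrix().to_numpy(dtype=float)
    y = cohort.labels
    ages = cohort.age
    synth = cohort.is_synthetic

    folds = stratified_kfold(y, outer_k, seed=seed)
    results: list[FoldResult] = []
    pred_rows = []
    for f, (tr, held) in enumerate(folds):
        fold_seed = (seed * 10007 + 13 * f) % (2 ** 31)
        try:
            _, best, _ = optimise_pipeline(
                X[tr], y[tr], space, n_trials=n_trials,
                inner_folds=inner_fold_splits(y[tr], inner_k, fold_seed),
                seed=fold_seed, sampler=sampler)
            score = _refit(best.config, X[tr], y[tr], seed=fold_seed)
            calib_idx, test_idx = train_test_split(
                held, train_size=calib_frac, stratify=y[held],
                random_state=(fold_seed + 7) % (2 ** 31))
            cal = VennAbersCalibrator().fit(score(X[calib_idx]), y[calib_idx])
            if not include_synthetic_in_test:
                test_idx = test_idx[~synth[test_idx]]
            p_pos = cal.predict_p_pos(score(X[test_idx]))
            yt, at = y[test_idx], ages[test_idx]
            sens, spec, fnr = threshold_metrics(p_pos, yt, threshold)
            results.append(FoldResult(
                fold=f, config=best.config, auc=auc_roc(p_pos, yt),
                sensitivity=sens, specificity=spec, fnr=fnr,
                ece=expected_calibration_error(p_pos, yt),
                logloss=log_loss(p_pos, yt), n_test=len(test_idx)))
            for i, pi in zip(test_idx, p_pos):
                pred_rows.append({"fold": f, "index": int(i), "p_pos": float(pi),
                                  "label": int(y[i]), "age": int(ages[i])})
        except Exception as e:  # noqa: BLE001 - a failed fold is reported, not fatal
            results.append(FoldResult(
                fold=f, config=PipelineConfig.make("none", "LR", {}),
                auc=np.nan, sensitivity=np.nan, specificity=np.nan,
                fnr=np.nan, ece=np.nan, logloss=np.nan, n_test=0,
                failed=True, error=f"{type(e).__name__}: {e}"))

    ok = [r for r in results if not r.failed]
    if len(ok) < 3:
        raise RuntimeError(
            f"only {len(ok)} outer folds succeeded; "
            + "; ".join(r.error for r in results if r.failed))
    aucs = [r.auc for r in ok]
    mean, se, lo, hi = mean_ci(aucs)
    preds = pd.DataFrame(pred_rows)
    audit = age_range_audit(preds["p_pos"], preds["label"], preds["age"],
                            threshold=threshold)
    return NCVReport(folds=results, mean_auc=mean, se_auc=se, ci_auc=(lo, hi),
                     age_audit=audit, predictions=preds, threshold=threshold)


# ---------------------------------------------------------------------------
# final deployment fit
# ---------------------------------------------------------------------------

@dataclass
class CalibratedPipeline:
    """Deployable artefact: selected config, refit scorer, IVAP calibrator."""

    config: PipelineConfig
    _score: object = field(repr=False, default=None)
    calibrator: VennAbersCalibrator = field(repr=False, default=None)
    feature_names: list = field(default_factory=list)

    def raw_score(self, X) -> np.ndarray:
        return self._score(np.asarray(X, dtype=float))

    def predict_interval(self, X) -> pd.DataFrame:
        return self.calibrator.predict(self.raw_score(X))

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) array of [p_neg, p_pos]."""
        p_pos = self.calibrator.predict_p_pos(self.raw_score(X))
        return np.column_stack([1.0 - p_pos, p_pos])


def final_fit(cohort: GlycomicsCohort, space: dict | None = None,
              n_trials: int = 50, inner_k: int = 5, calib_frac: float = 0.1,
              seed: int = 0, sampler: str = "tpe") -> CalibratedPipeline:
    """Deployment protocol: 5-fold CV pipeline search on a stratified 90%
    of the cohort, refit of the winner on that 90%, Venn-Abers calibration
    on the held-out 10%."""
    space = space or default_search_space()
    feats = cohort.feature_matrix()
    X = feats.to_numpy(dtype=float)
    y = cohort.labels
    idx = np.arange(len(y))
    train_idx, calib_idx = train_test_split(
        idx, test_size=calib_frac, stratify=y, random_state=seed % (2 ** 31))
    _, best, _ = optimise_pipeline(
        X[train_idx], y[train_idx], space, n_trials=n_trials,
        inner_folds=inner_fold_splits(y[train_idx], inner_k, seed),
        seed=seed, sampler=sampler)
    score = _refit(best.config, X[train_idx], y[train_idx], seed=seed)
    cal = VennAbersCalibrator().fit(score(X[calib_idx]), y[calib_idx])
    return CalibratedPipeline(config=best.config, _score=score, calibrator=cal,
                              feature_names=list(feats.columns))
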