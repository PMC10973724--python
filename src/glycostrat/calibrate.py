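"""Isotonic regression and inductive Venn-Abers probability calibration.

The Venn-Abers predictor turns raw classifier scores into calibrated
probability *intervals*: for a test score s it fits isotonic regression
twice on the calibration pairs augmented with (s, 0) and with (s, 1), reads
both fits at s to get a lower bound p0 and an upper bound p1, and collapses
the interval with the minimax rule p_pos = p1 / (1 - p0 + p1).  Unlike
plain isotonic calibration it does not overfit small calibration sets, and
being rank-based it is invariant to monotone transformations of the score.

The implementation here is the naive reference: two pool-adjacent-violators
fits per query.  Any fast path must match it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# PAVA
# ---------------------------------------------------------------------------

@dataclass
class IsotonicFit:
    """Weighted least-squares nondecreasing fit.

    ``x`` are the unique sorted abscissae (ties pre-pooled by weighted
    mean), ``y_fit`` the nondecreasing fitted values.  Prediction between
    breakpoints interpolates linearly and clips at the ends.
    """

    x: np.ndarray
    y_fit: np.ndarray

    def predict(self, xq) -> np.ndarray:
        return np.interp(np.asarray(xq, dtype=float), self.x, self.y_fit)


def pava_isotonic(x, y, w=None) -> IsotonicFit:
    """Pool-adjacent-violators solution of the weighted monotone LS problem."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if w is None:
        w = np.ones_like(y)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal lengths")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")

    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], w[order]

    # pre-pool ties in x by weighted mean
    ux, start = np.unique(xs, return_index=True)
    vals = np.empty(len(ux))
    wts = np.empty(len(ux))
    bounds = np.append(start, len(xs))
    for i in range(len(ux)):
        sl = slice(bounds[i], bounds[i + 1])
        wts[i] = ws[sl].sum()
        vals[i] = np.average(ys[sl], weights=ws[sl])

    # stack-based PAVA
    val_st: list[float] = []
    wt_st: list[float] = []
    size_st: list[int] = []
    for v, wt in zip(vals, wts):
        cv, cw, cs = v, wt, 1
        while val_st and val_st[-1] > cv:
            pv, pw, ps = val_st.pop(), wt_st.pop(), size_st.pop()
            cv = (pv * pw + cv * cw) / (pw + cw)
            cw += pw
            cs += ps
        val_st.append(cv)
        wt_st.append(cw)
        size_st.append(cs)

    fitted = np.repeat(val_st, size_st)
    return IsotonicFit(ux, fitted)


# ---------------------------------------------------------------------------
# inductive Venn-Abers
# ---------------------------------------------------------------------------

def minimax_combine(p0: float, p1: float) -> tuple[float, float]:
    """Collapse a Venn-Abers interval: p_pos = p1 / (1 - p0 + p1)."""
    if not (0 <= p0 <= p1 <= 1):
        raise ValueError(f"require 0 <= p0 <= p1 <= 1, got ({p0}, {p1})")
    p_pos = p1 / (1.0 - p0 + p1)
    return float(p_pos), float(1.0 - p_pos)


@dataclass
class VennAbersResult:
    p0: float
    p1: float
    p_pos: float

    @property
    def p_neg(self) -> float:
        return 1.0 - self.p_pos


class VennAbersCalibrator:
    """Inductive Venn-Abers predictor over a held-out calibration set.

    Queries run two isotonic fits on the calibration pairs augmented with
    (s, 0) and (s, 1).  The calibration ties are pre-pooled once at fit
    time and each augmented fit is solved by a C pool-adjacent-violators
    routine; :meth:`predict_interval_naive` is the reference per-query
    :func:`pava_isotonic` refit that any fast path must reproduce.
    """

    def __init__(self) -> None:
        self._scores = None
        self._labels = None
        self._x = None   # pooled unique scores, sorted
        self._y = None   # pooled mean labels
        self._w = None   # pooled weights

    def fit(self, calib_scores, calib_labels) -> "VennAbersCalibrator":
        s = np.asarray(calib_scores, dtype=float)
        y = np.asarray(calib_labels).astype(float)
        if len(s) != len(y) or len(s) == 0:
            raise ValueError("scores and labels must be non-empty and equal length")
        if y.min() == y.max():
            raise ValueError("calibration set must contain both classes")
        self._scores, self._labels = s, y
        order = np.argsort(s, kind="stable")
        xs, ys = s[order], y[order]
        ux, start = np.unique(xs, return_index=True)
        bounds = np.append(start, len(xs))
        self._x = ux
        self._w = np.diff(bounds).astype(float)
        self._y = np.array([ys[bounds[i]:bounds[i + 1]].mean()
                            for i in range(len(ux))])
        return self

    def _check(self) -> None:
        if self._scores is None:
            raise RuntimeError("calibrator queried before fit")

    def _augmented_fit_at(self, s: float, label: float) -> float:
        from sklearn.isotonic import isotonic_regression

        pos = int(np.searchsorted(self._x, s))
        if pos < len(self._x) and self._x[pos] == s:
            w = np.concatenate([self._w[:pos], [self._w[pos] + 1.0],
                                self._w[pos + 1:]])
            y = self._y.copy()
            y[pos] = np.average([self._y[pos], label],
                                weights=[self._w[pos], 1.0])
            at = pos
        else:
            w = np.insert(self._w, pos, 1.0)
            y = np.insert(self._y, pos, label)
            at = pos
        fit = isotonic_regression(y, sample_weight=w, increasing=True)
        return float(fit[at])

    def predict_interval(self, s: float) -> VennAbersResult:
        """[p0, p1] plus the minimax-combined probability for one score."""
        self._check()
        p0 = self._augmented_fit_at(float(s), 0.0)
        p1 = self._augmented_fit_at(float(s), 1.0)
        if 0 < p0 - p1 < 1e-12:  # float round-off on an empty interval
            p0 = p1
        p_pos, _ = minimax_combine(p0, p1)
        return VennAbersResult(p0, p1, p_pos)

    def predict_interval_naive(self, s: float) -> VennAbersResult:
        """Reference implementation: two full :func:`pava_isotonic` refits."""
        self._check()
        xs = np.append(self._scores, s)
        p0 = float(pava_isotonic(xs, np.append(self._labels, 0.0)).predict(s))
        p1 = float(pava_isotonic(xs, np.append(self._labels, 1.0)).predict(s))
        p_pos, _ = minimax_combine(p0, p1)
        return VennAbersResult(p0, p1, p_pos)

    def predict(self, scores) -> pd.DataFrame:
        """Per-sample p0, p1, p_pos for a vector of test scores."""
        self._check()
        rows = [self.predict_interval(float(s)) for s in np.asarray(scores, float)]
        return pd.DataFrame({"p0": [r.p0 for r in rows],
                             "p1": [r.p1 for r in rows],
                             "p_pos": [r.p_pos for r in rows]})

    def predict_p_pos(self, scores) -> np.ndarray:
        return self.predict(scores)["p_pos"].to_numpy()


def ivap_fit(calib_scores, calib_labels) -> VennAbersCalibrator:
    """Functional alias for fitting the calibrator."""
    return VennAbersCalibrator().fit(calib_scores, calib_labels)


def ivap_interval(calibrator: VennAbersCalibrator, s: float) -> VennAbersResult:
    return calibrator.predict_interval(s)


# ---------------------------------------------------------------------------
# calibration diagnostics
# ---------------------------------------------------------------------------

def _bin_index(p: np.ndarray, n_bins: int) -> np.ndarray:
    # right-closed equal-width bins on [0, 1]; bin 0 keeps p = 0
    idx = np.ceil(p * n_bins).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def expected_calibration_error(probs, labels, n_bins: int = 10) -> float:
    """Bin-weighted mean |empirical accuracy - mean confidence|."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(float)
    idx = _bin_index(p, n_bins)
    ece = 0.0
    n = len(p)
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        ece += m.sum() / n * abs(y[m].mean() - p[m].mean())
    return float(ece)


def reliability_bins(probs, labels, n_bins: int = 10) -> pd.DataFrame:
    """Bin table behind a reliability diagram (count, confidence, accuracy)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(float)
    idx = _bin_index(p, n_bins)
    edges = np.linspace(0, 1, n_bins + 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "count": int(m.sum()),
            "confidence": float(p[m].mean()) if m.any() else np.nan,
            "accuracy": float(y[m].mean()) if m.any() else np.nan,
        })
    return pd.DataFrame(rows)
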