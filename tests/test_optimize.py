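"""Objectives, Pareto machinery and the Parzen-estimator search, checked
against pair-counting, transport-LP and brute-force dominance oracles."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

import glycostrat as g
from glycostrat.optimize import (CategoricalDim, PipelineConfig, TrialRecord,
                                 evaluate_config, inner_fold_splits,
                                 nondomination_ranks, random_config)
from glycostrat.synthetic import generate_cohort, strong_signal_spec


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def emd_lp(a, b):
    """Transport linear program between two empirical distributions."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    A_eq, b_eq = [], []
    for i in range(na):
        row = np.zeros(na * nb)
        row[i * nb:(i + 1) * nb] = 1
        A_eq.append(row)
        b_eq.append(1 / na)
    for j in range(nb):
        row = np.zeros(na * nb)
        row[j::nb] = 1
        A_eq.append(row)
        b_eq.append(1 / nb)
    res = linprog(cost, A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return res.fun


def pareto_brute_force(objs):
    keep = []
    for i, (a1, e1) in enumerate(objs):
        dominated = any(
            (a2 >= a1 and e2 <= e1) and (a2 > a1 or e2 < e1)
            for j, (a2, e2) in enumerate(objs) if j != i)
        if not dominated:
            keep.append(i)
    return keep


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_auc_worked_examples():
    assert g.auc_roc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
    assert g.auc_roc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
    assert g.auc_roc([0.3] * 6, [0, 1] * 3) == 0.5
    with pytest.raises(ValueError, match="both classes"):
        g.auc_roc([0.1, 0.2], [1, 1])


def test_auc_equals_pair_counting_and_sklearn(rng):
    from sklearn.metrics import roc_auc_score
    for _ in range(200):
        n = int(rng.integers(4, 25))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        s = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
        assert g.auc_roc(s, y) == pytest.approx(auc_pair_counting(s, y),
                                                abs=1e-12)
        assert g.auc_roc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_emd_worked_examples():
    assert g.emd_1d([0.5, 0.7], [0.5, 0.7]) == 0.0
    assert g.emd_1d([0.9, 0.85, 0.95], [0.8, 0.75, 0.85]) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        g.emd_1d([], [0.5])


def test_emd_equals_transport_lp(rng):
    for _ in range(60):
        a = rng.uniform(size=int(rng.integers(1, 7)))
        b = rng.uniform(size=int(rng.integers(1, 7)))
        assert g.emd_1d(a, b) == pytest.approx(emd_lp(a, b), abs=1e-9)
    # constant shift with non-interleaving supports changes EMD by |c|
    a = rng.uniform(0, 1, 5)
    b = a + 3.0
    assert g.emd_1d(a, b + 0.25) == pytest.approx(g.emd_1d(a, b) + 0.25)


def test_log_loss_values():
    assert g.log_loss([0.5, 0.5], [1, 0]) == pytest.approx(np.log(2))
    assert g.log_loss([0.9, 0.1], [1, 0]) == pytest.approx(-np.log(0.9))
    # clipping keeps a confidently wrong prediction finite near -ln(1e-15)
    assert g.log_loss([1.0], [0]) == pytest.approx(34.5, abs=0.1)


# ---------------------------------------------------------------------------
# Pareto machinery
# ---------------------------------------------------------------------------

def _trial(auc, emd, ll=0.5, name="LR"):
    t = TrialRecord(PipelineConfig.make("none", name, {}),
                    np.array([auc + emd]), np.array([auc]), ll)
    return t


def test_pareto_front_worked_example():
    trials = [_trial(0.8, 0.1), _trial(0.7, 0.2), _trial(0.9, 0.3)]
    front = g.pareto_front(trials)
    got = sorted((round(a, 9), round(e, 9)) for a, e in
                 (t.objective for t in front))
    assert got == [(0.8, 0.1), (0.9, 0.3)]
    assert g.pareto_front([trials[0]]) == [trials[0]]
    dup = [_trial(0.8, 0.1), _trial(0.8, 0.1)]
    assert len(g.pareto_front(dup)) == 2
    with pytest.raises(ValueError):
        g.pareto_front([])


def test_pareto_front_equals_brute_force(rng):
    for _ in range(25):
        n = int(rng.integers(1, 51))
        trials = [_trial(float(rng.uniform(0.4, 1.0)),
                         float(np.round(rng.uniform(0, 0.3), 2)))
                  for _ in range(n)]
        objs = [t.objective for t in trials]
        expect = {id(trials[i]) for i in pareto_brute_force(objs)}
        got = {id(t) for t in g.pareto_front(trials)}
        assert got == expect


def test_select_best_rules():
    front = [_trial(0.8, 0.1, ll=0.50), _trial(0.7, 0.1, ll=0.45),
             _trial(0.9, 0.1, ll=0.60)]
    assert g.select_best(front) is front[1]
    tie = [_trial(0.7, 0.1, ll=0.45), _trial(0.8, 0.1, ll=0.45)]
    assert g.select_best(tie) is tie[1]
    assert g.select_best([front[0]]) is front[0]
    assert g.select_best(front) in front
    with pytest.raises(ValueError):
        g.select_best([])


# ---------------------------------------------------------------------------
# configuration space + proposals
# ---------------------------------------------------------------------------

def test_random_configs_lie_inside_grid(rng):
    space = g.default_search_space()
    for _ in range(100):
        cfg = random_config(space, rng)
        cfg.validate(space)  # raises if outside bounds


def test_config_validation_rejects_bad_values():
    space = g.default_search_space()
    with pytest.raises(ValueError, match="bounds"):
        PipelineConfig.make("none", "LR", {"C": 100.0, "penalty": "l2",
                                           "l1_ratio": 0.0}).validate(space)
    with pytest.raises(ValueError, match="keys"):
        PipelineConfig.make("none", "RF", {"C": 1.0}).validate(space)


def test_proposals_track_good_region(rng):
    """A history whose non-dominated trials all use XGB steers proposals
    towards XGB (binomial tolerance on a seeded run)."""
    space = g.default_search_space()
    history = []
    for i in range(30):
        learner = "XGB" if i < 10 else ["LR", "SVM", "RF"][i % 3]
        params = {d.name: (d.choices[0] if isinstance(d, CategoricalDim)
                           else d.low)
                  for d in space["params"][learner]}
        auc = 0.9 if learner == "XGB" else 0.6
        emd = 0.02 if learner == "XGB" else 0.2
        history.append(_trial(auc, emd, name=learner))
        history[-1] = TrialRecord(PipelineConfig.make("none", learner, params),
                                  np.array([auc + emd]), np.array([auc]), 0.5)
    picks = [g.propose_config(history, space, rng).learner for _ in range(100)]
    assert np.mean([p == "XGB" for p in picks]) >= 0.7


def test_propose_random_during_startup(rng):
    space = g.default_search_space()
    cfg = g.propose_config([], space, rng)
    cfg.validate(space)


# ---------------------------------------------------------------------------
# evaluation + leakage guards
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def signal_data():
    cohort, _ = generate_cohort(strong_signal_spec(100), seed=6)
    return cohort.feature_matrix().to_numpy(float), cohort.labels


def test_constant_learner_objective():
    """A constant-score learner has mean val AUC 0.5 and EMD 0 by the tie
    convention."""
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 60)
    aucs = [g.auc_roc(np.full(30, 0.5), y[:30]) for _ in range(3)]
    assert aucs == [0.5] * 3
    assert g.emd_1d([0.5, 0.5], [0.5, 0.5]) == 0.0


def test_memorising_learner_flagged_by_emd(rng):
    """1-NN-style memorisation on pure noise: train AUC 1, val AUC ~ 0.5,
    so the EMD objective is large."""
    X = rng.normal(size=(80, 5))
    y = rng.integers(0, 2, 80)
    from sklearn.neighbors import KNeighborsClassifier

    folds = inner_fold_splits(y, 4, seed=0)
    train_aucs, val_aucs = [], []
    for tr, va in folds:
        knn = KNeighborsClassifier(n_neighbors=1).fit(X[tr], y[tr])
        train_aucs.append(g.auc_roc(knn.predict_proba(X[tr])[:, 1], y[tr]))
        val_aucs.append(g.auc_roc(knn.predict_proba(X[va])[:, 1], y[va]))
    assert g.emd_1d(train_aucs, val_aucs) > 0.25


def test_scaler_fitted_on_fold_train_only(signal_data):
    """Leakage guard: under minmax the validation rows may fall outside
    [0, 1], which is only possible if the scaler never saw them."""
    X, y = signal_data
    folds = inner_fold_splits(y, 4, seed=1)
    from glycostrat.optimize import make_scaler
    outside = 0
    for tr, va in folds:
        scaler = make_scaler("minmax")
        scaler.fit(X[tr])
        Xva = scaler.transform(X[va])
        outside += int((Xva < 0).any() or (Xva > 1).any())
    assert outside > 0


def test_evaluate_config_shapes_and_failure(signal_data):
    X, y = signal_data
    cfg = PipelineConfig.make("standard", "LR",
                              {"C": 1.0, "penalty": "l2", "l1_ratio": 0.0})
    rec = evaluate_config(cfg, X, y, 4, seed=0)
    assert not rec.failed
    assert len(rec.train_aucs) == len(rec.val_aucs) == 4
    assert ((0 <= rec.val_aucs) & (rec.val_aucs <= 1)).all()
    assert rec.emd >= 0
    bad = PipelineConfig.make("none", "nope", {})
    rec2 = evaluate_config(bad, X, y, 4, seed=0)
    assert rec2.failed and "nope" in rec2.error


def test_optimise_pipeline_determinism_and_signal(signal_data):
    X, y = signal_data
    space = g.small_search_space(learners=("LR", "RF"))
    front1, best1, hist1 = g.optimise_pipeline(X, y, space, n_trials=6,
                                               inner_folds=3, seed=3)
    front2, best2, hist2 = g.optimise_pipeline(X, y, space, n_trials=6,
                                               inner_folds=3, seed=3)
    assert [t.config for t in hist1] == [t.config for t in hist2]
    assert np.allclose([t.mean_val_auc for t in hist1],
                       [t.mean_val_auc for t in hist2])
    assert best1.config == best2.config
    assert best1 in front1
    assert best1.mean_val_auc >= 0.8  # strong planted signal is found
    # n_trials=1: the front is that single trial
    front_single, best_single, _ = g.optimise_pipeline(
        X, y, space, n_trials=1, inner_folds=3, seed=4)
    assert len(front_single) == 1 and best_single is front_single[0]


def test_nondomination_ranks_structure():
    trials = [_trial(0.9, 0.05), _trial(0.8, 0.2), _trial(0.7, 0.3)]
    ranks = nondomination_ranks(trials)
    assert ranks[0] == 0
    assert (ranks >= 0).all()
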