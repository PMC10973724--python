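"""Pipeline search space and multi-objective (AUC vs. overfitting) optimisation.

A pipeline is (scaler, learner, hyperparameters).  Each candidate is scored
on inner stratified folds by its mean validation AUC-ROC (maximised) and the
first Wasserstein distance between its train and validation AUC
distributions (minimised) — the overfitting objective.  Candidates are
proposed by a Pareto-dominance Parzen-estimator sampler: after a random
start-up phase the trial archive is split by non-domination rank into a
"good" and a "bad" set, one-dimensional densities (Laplace-smoothed
frequencies for categoricals, Silverman-bandwidth Gaussian KDEs for
continuous dimensions, log-scaled where declared) are built for each, and
the proposal is the candidate drawn from the good model with the highest
good/bad density ratio.  The final pipeline is the Pareto-front member with
the lowest mean validation log-loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

EPS_LOGLOSS = 1e-15


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc_roc(scores, labels) -> float:
    """AUC-ROC via the midrank Mann-Whitney formulation (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def emd_1d(a, b) -> float:
    """First Wasserstein distance between two empirical distributions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("inputs must be non-empty")
    return float(stats.wasserstein_distance(a, b))


def log_loss(scores, labels, eps: float = EPS_LOGLOSS) -> float:
    """Mean negative Bernoulli log-likelihood with probabilities clipped
    to [eps, 1 - eps]."""
    p = np.clip(np.asarray(scores, dtype=float), eps, 1 - eps)
    y = np.asarray(labels).astype(float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# search space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoricalDim:
    name: str
    choices: tuple

    def contains(self, v) -> bool:
        return v in self.choices


@dataclass(frozen=True)
class FloatDim:
    name: str
    low: float
    high: float
    log: bool = False

    def contains(self, v) -> bool:
        return self.low <= v <= self.high


@dataclass(frozen=True)
class IntDim:
    name: str
    low: int
    high: int
    step: int = 1

    def contains(self, v) -> bool:
        return self.low <= v <= self.high and (v - self.low) % self.step == 0

    @property
    def values(self) -> np.ndarray:
        return np.arange(self.low, self.high + 1, self.step)


SCALERS = ("none", "minmax", "standard")
LEARNERS = ("LR", "SVM", "RF", "XGB")


def default_search_space() -> dict:
    """The declared pipeline grid.

    Every hyperparameter configuration reported by the framework's reference
    runs lies inside these bounds.
    """
    return {
        "scaler": CategoricalDim("scaler", SCALERS),
        "learner": CategoricalDim("learner", LEARNERS),
        "params": {
            "LR": [FloatDim("C", 1e-3, 10.0, log=True),
                   CategoricalDim("penalty", ("l1", "l2", "elasticnet")),
                   FloatDim("l1_ratio", 0.0, 1.0)],
            "SVM": [FloatDim("C", 1e-3, 10.0, log=True),
                    CategoricalDim("kernel", ("linear", "poly", "rbf"))],
            "RF": [IntDim("n_estimators", 20, 400, 20),
                   IntDim("max_depth", 2, 10),
                   CategoricalDim("criterion", ("gini", "entropy"))],
            "XGB": [IntDim("n_estimators", 40, 400, 40),
                    IntDim("max_depth", 2, 8),
                    CategoricalDim("booster", ("gbtree", "dart")),
                    FloatDim("gamma", 0.0, 15.0)],
        },
    }


def small_search_space(learners=("LR",), scalers=("none", "minmax")) -> dict:
    """Reduced grid (subset of the default) for fast experiments."""
    full = default_search_space()
    return {
        "scaler": CategoricalDim("scaler", tuple(scalers)),
        "learner": CategoricalDim("learner", tuple(learners)),
        "params": {k: full["params"][k] for k in learners},
    }


@dataclass(frozen=True)
class PipelineConfig:
    """One point of the search space: scaler, learner and its hyperparameters."""

    scaler: str
    learner: str
    params: tuple  # sorted tuple of (name, value) pairs

    @classmethod
    def make(cls, scaler: str, learner: str, params: dict) -> "PipelineConfig":
        return cls(scaler, learner, tuple(sorted(params.items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def validate(self, space: dict) -> None:
        if not space["scaler"].contains(self.scaler):
            raise ValueError(f"scaler {self.scaler!r} outside the grid")
        if not space["learner"].contains(self.learner):
            raise ValueError(f"learner {self.learner!r} outside the grid")
        dims = {d.name: d for d in space["params"][self.learner]}
        p = self.param_dict
        if set(p) != set(dims):
            raise ValueError(
                f"hyperparameter keys {sorted(p)} do not match learner "
                f"{self.learner} dims {sorted(dims)}")
        for name, v in p.items():
            if not dims[name].contains(v):
                raise ValueError(f"{name}={v!r} outside the declared bounds")

    def sort_key(self) -> tuple:
        return (self.scaler, self.learner, self.params)


# ---------------------------------------------------------------------------
# learners (thin contract over sklearn / xgboost)
# ---------------------------------------------------------------------------

class Learner:
    """fit / predict_score / clone contract around a probabilistic classifier."""

    def __init__(self, config: PipelineConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self._est = None

    def clone(self) -> "Learner":
        return Learner(self.config, self.seed)

    def _build(self):
        p = self.config.param_dict
        kind = self.config.learner
        if kind == "LR":
            l1_ratio = p.get("l1_ratio") if p.get("penalty") == "elasticnet" else None
            return LogisticRegression(
                C=p["C"], penalty=p["penalty"], l1_ratio=l1_ratio,
                solver="saga", max_iter=1000, tol=1e-3, random_state=self.seed)
        if kind == "SVM":
            return SVC(C=p["C"], kernel=p["kernel"], random_state=self.seed)
        if kind == "RF":
            return RandomForestClassifier(
                n_estimators=p["n_estimators"], max_depth=p["max_depth"],
                criterion=p["criterion"], random_state=self.seed, n_jobs=1)
        if kind == "XGB":
            return XGBClassifier(
                n_estimators=p["n_estimators"], max_depth=p["max_depth"],
                booster=p["booster"], gamma=p["gamma"],
                eval_metric="logloss", tree_method="hist",
                random_state=self.seed, n_jobs=1, verbosity=0)
        raise ValueError(f"unknown learner {kind!r}")

    def fit(self, X, y) -> "Learner":
        self._est = self._build()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._est.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int))
        return self

    def predict_score(self, X) -> np.ndarray:
        """Positive-class scores in [0, 1].

        SVM margins are squashed through a logistic so every learner emits
        probabilistic scores; downstream Venn-Abers calibration is invariant
        to this monotone map.
        """
        if self._est is None:
            raise RuntimeError("predict_score called before fit")
        X = np.asarray(X, dtype=float)
        if self.config.learner == "SVM":
            margin = self._est.decision_function(X)
            return 1.0 / (1.0 + np.exp(-margin))
        return self._est.predict_proba(X)[:, 1]


def make_scaler(kind: str):
    if kind == "none":
        return None
    if kind == "minmax":
        return MinMaxScaler(clip=False)
    if kind == "standard":
        return StandardScaler()
    raise ValueError(f"unknown scaler {kind!r}")


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    config: PipelineConfig
    train_aucs: np.ndarray = field(default_factory=lambda: np.array([]))
    val_aucs: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_val_logloss: float = np.inf
    failed: bool = False
    error: str = ""

    @property
    def mean_val_auc(self) -> float:
        return float(np.mean(self.val_aucs))

    @property
    def emd(self) -> float:
        return emd_1d(self.train_aucs, self.val_aucs)

    @property
    def objective(self) -> tuple:
        return (self.mean_val_auc, self.emd)


def inner_fold_splits(y, k: int, seed: int) -> list:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), np.asarray(y).astype(int)))


def evaluate_config(config: PipelineConfig, X, y, inner_folds, seed: int = 0) -> TrialRecord:
    """Score one configuration over the inner folds.

    The scaler is fitted on each fold's training portion only (no leakage);
    train and validation AUCs and the validation log-loss are recorded per
    fold.  A learner failure marks the trial failed rather than raising.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if isinstance(inner_folds, int):
        inner_folds = inner_fold_splits(y, inner_folds, seed)
    train_aucs, val_aucs, val_lls = [], [], []
    try:
        for tr, va in inner_folds:
            Xtr, Xva = X[tr], X[va]
            scaler = make_scaler(config.scaler)
            if scaler is not None:
                Xtr = scaler.fit_transform(Xtr)
                Xva = scaler.transform(Xva)
            learner = Learner(config, seed=seed).fit(Xtr, y[tr])
            train_aucs.append(auc_roc(learner.predict_score(Xtr), y[tr]))
            sva = learner.predict_score(Xva)
            val_aucs.append(auc_roc(sva, y[va]))
            val_lls.append(log_loss(sva, y[va]))
    except Exception as e:  # noqa: BLE001 - failed trials are data, not crashes
        return TrialRecord(config, failed=True, error=f"{type(e).__name__}: {e}")
    return TrialRecord(config, np.array(train_aucs), np.array(val_aucs),
                       float(np.mean(val_lls)))


# ---------------------------------------------------------------------------
# Pareto machinery
# ---------------------------------------------------------------------------

def _dominates(obj_a, obj_b) -> bool:
    """a dominates b: >= on AUC, <= on EMD, strict somewhere."""
    ge = obj_a[0] >= obj_b[0] and obj_a[1] <= obj_b[1]
    strict = obj_a[0] > obj_b[0] or obj_a[1] < obj_b[1]
    return ge and strict


def pareto_front(trials) -> list:
    """Non-dominated trials under (maximise mean val AUC, minimise EMD)."""
    trials = [t for t in trials if not t.failed]
    if not trials:
        raise ValueError("no successful trials")
    objs = [t.objective for t in trials]
    front = []
    for i, t in enumerate(trials):
        if not any(_dominates(objs[j], objs[i]) for j in range(len(trials)) if j != i):
            front.append(t)
    return front


def nondomination_ranks(trials) -> np.ndarray:
    """0-based successive-front ranks of the (non-failed) trials."""
    objs = [t.objective for t in trials]
    n = len(objs)
    ranks = np.full(n, -1)
    remaining = list(range(n))
    r = 0
    while remaining:
        front = [i for i in remaining
                 if not any(_dominates(objs[j], objs[i]) for j in remaining if j != i)]
        for i in front:
            ranks[i] = r
        remaining = [i for i in remaining if i not in front]
        r += 1
    return ranks


def select_best(front) -> TrialRecord:
    """Front member with the lowest mean validation log-loss.

    Ties break towards higher mean validation AUC, then lexicographic
    configuration order.
    """
    if not front:
        raise ValueError("empty Pareto front")
    return min(front, key=lambda t: (t.mean_val_logloss, -t.mean_val_auc,
                                     t.config.sort_key()))


# ---------------------------------------------------------------------------
# Parzen-estimator proposals
# ---------------------------------------------------------------------------

def _sample_dim(dim, rng):
    if isinstance(dim, CategoricalDim):
        return dim.choices[rng.integers(len(dim.choices))]
    if isinstance(dim, FloatDim):
        if dim.log:
            return float(np.exp(rng.uniform(np.log(dim.low), np.log(dim.high))))
        return float(rng.uniform(dim.low, dim.high))
    if isinstance(dim, IntDim):
        return int(rng.choice(dim.values))
    raise TypeError(dim)


def random_config(space: dict, rng) -> PipelineConfig:
    scaler = _sample_dim(space["scaler"], rng)
    learner = _sample_dim(space["learner"], rng)
    params = {d.name: _sample_dim(d, rng) for d in space["params"][learner]}
    return PipelineConfig.make(scaler, learner, params)


class _CatModel:
    def __init__(self, dim, values):
        counts = {c: 1 for c in dim.choices}  # Laplace smoothing
        for v in values:
            counts[v] += 1
        total = sum(counts.values())
        self.choices = dim.choices
        self.probs = np.array([counts[c] / total for c in dim.choices])

    def sample(self, rng):
        return self.choices[rng.choice(len(self.choices), p=self.probs)]

    def density(self, v) -> float:
        return float(self.probs[self.choices.index(v)])


class _NumModel:
    """Gaussian KDE (Silverman bandwidth) on the dim's natural scale."""

    def __init__(self, dim, values):
        self.dim = dim
        self.log = isinstance(dim, FloatDim) and dim.log
        x = np.asarray(values, dtype=float)
        self.x = np.log(x) if self.log else x
        self.lo = np.log(dim.low) if self.log else float(dim.low)
        self.hi = np.log(dim.high) if self.log else float(dim.high)
        sd = self.x.std(ddof=1) if len(self.x) > 1 else 0.0
        if sd <= 0:
            self.bw = max((self.hi - self.lo) / 10.0, 1e-12)
        else:
            self.bw = 1.06 * sd * len(self.x) ** (-0.2)

    def sample(self, rng):
        centre = self.x[rng.integers(len(self.x))]
        v = np.clip(rng.normal(centre, self.bw), self.lo, self.hi)
        v = float(np.exp(v)) if self.log else float(v)
        if isinstance(self.dim, IntDim):
            grid = self.dim.values
            v = int(grid[np.argmin(np.abs(grid - v))])
        return v

    def density(self, v) -> float:
        t = np.log(v) if self.log else float(v)
        z = (t - self.x) / self.bw
        return float(np.mean(np.exp(-0.5 * z * z)) / (self.bw * np.sqrt(2 * np.pi)))


def _uniform_density(dim) -> float:
    if isinstance(dim, CategoricalDim):
        return 1.0 / len(dim.choices)
    if isinstance(dim, IntDim):
        return 1.0 / len(dim.values)
    if dim.log:
        return 1.0 / (np.log(dim.high) - np.log(dim.low))
    return 1.0 / (dim.high - dim.low)


def _group_models(space, trials):
    """Per-dimension models for one (good or bad) trial group."""
    models = {"scaler": _CatModel(space["scaler"], [t.config.scaler for t in trials]),
              "learner": _CatModel(space["learner"], [t.config.learner for t in trials])}
    for learner, dims in space["params"].items():
        sub = [t for t in trials if t.config.learner == learner]
        per = {}
        for d in dims:
            vals = [t.config.param_dict[d.name] for t in sub]
            if isinstance(d, CategoricalDim):
                per[d.name] = _CatModel(d, vals) if vals else None
            else:
                per[d.name] = _NumModel(d, vals) if len(vals) >= 2 else None
        models[learner] = per
    return models


def _config_density(space, models, config: PipelineConfig) -> float:
    dens = models["scaler"].density(config.scaler)
    dens *= models["learner"].density(config.learner)
    dims = {d.name: d for d in space["params"][config.learner]}
    for name, v in config.param_dict.items():
        m = models[config.learner][name]
        dens *= m.density(v) if m is not None else _uniform_density(dims[name])
    return dens


def _config_log_ratio(space, good_m, bad_m, config: PipelineConfig) -> float:
    """log good/bad density ratio, per dimension.

    A hyperparameter dimension where either group has too few observations
    to model contributes ratio 1: crediting a dimension one side knows
    nothing about would let a sharp density in the other group dominate the
    score for arbitrary values.
    """
    ratio = np.log(good_m["scaler"].density(config.scaler)) \
        - np.log(bad_m["scaler"].density(config.scaler))
    ratio += np.log(good_m["learner"].density(config.learner)) \
        - np.log(bad_m["learner"].density(config.learner))
    for name, v in config.param_dict.items():
        gm = good_m[config.learner][name]
        bm = bad_m[config.learner][name]
        if gm is None or bm is None:
            continue
        ratio += np.log(max(gm.density(v), 1e-300)) \
            - np.log(max(bm.density(v), 1e-300))
    return float(ratio)


def propose_config(history, space: dict, rng, n_startup: int = 10,
                   gamma: float = 0.25, n_candidates: int = 24) -> PipelineConfig:
    """Next configuration to try.

    Uniform over the grid during start-up; afterwards the archive is split
    by non-domination rank into good (the ranks covering the best
    ceil(gamma * n) trials) and bad, each modelled per dimension, and the
    best of ``n_candidates`` draws from the good model under the good/bad
    density ratio is returned.
    """
    history = [t for t in history if not t.failed]
    if len(history) < n_startup:
        return random_config(space, rng)

    ranks = nondomination_ranks(history)
    n_good = int(np.ceil(gamma * len(history)))
    order = np.argsort(ranks, kind="stable")
    cut_rank = ranks[order[n_good - 1]]
    good = [history[i] for i in range(len(history)) if ranks[i] <= cut_rank]
    bad = [history[i] for i in range(len(history)) if ranks[i] > cut_rank]

    good_m = _group_models(space, good)
    bad_m = _group_models(space, bad) if bad else None

    best, best_ratio = None, -np.inf
    for _ in range(n_candidates):
        learner = good_m["learner"].sample(rng)
        scaler = good_m["scaler"].sample(rng)
        params = {}
        for d in space["params"][learner]:
            m = good_m[learner][d.name]
            params[d.name] = m.sample(rng) if m is not None else _sample_dim(d, rng)
        cand = PipelineConfig.make(scaler, learner, params)
        if bad_m is None:
            ratio = np.log(max(_config_density(space, good_m, cand), 1e-300))
        else:
            ratio = _config_log_ratio(space, good_m, bad_m, cand)
        if ratio > best_ratio:
            best, best_ratio = cand, ratio
    return best


def optimise_pipeline(X, y, space: dict | None = None, n_trials: int = 50,
                      inner_folds: int = 5, seed: int = 0,
                      n_startup: int = 10, sampler: str = "tpe"):
    """Run the sequential search; return (front, selected trial, archive).

    ``sampler="random"`` disables the Parzen-estimator guidance (grid-random
    fallback); everything is reproducible from ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = space or default_search_space()
    rng = np.random.default_rng(seed)
    y = np.asarray(y).astype(int)
    folds = inner_fold_splits(y, inner_folds, seed) \
        if isinstance(inner_folds, int) else inner_folds
    history: list[TrialRecord] = []
    for t in range(n_trials):
        if sampler == "random":
            config = random_config(space, rng)
        else:
            config = propose_config(history, space, rng, n_startup=n_startup)
        rec = evaluate_config(config, X, y, folds, seed=seed)
        history.append(rec)
    ok = [t for t in history if not t.failed]
    if not ok:
        raise RuntimeError("all optimisation trials failed")
    front = pareto_front(ok)
    return front, select_best(front), history
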