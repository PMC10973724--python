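"""Covariate-matched SMOTE augmentation of the control class.

The cohort this emulates lacks healthy controls above 60 and has none above
74, while cases extend well beyond.  The augmented dataset is built by:

* dropping every sample (both classes) older than 74 — the control upper
  bound defines the usable age range;
* for each age 61-71, synthesising controls until their count matches the
  case count at that exact age;
* for each age 72-74, synthesising controls up to half (floor) of the case
  count — the control base there is too thin to support full matching.

Synthetic controls are SMOTE interpolants (a + lambda*(b - a), b one of the
k = 3 nearest neighbours of a) computed on the 24 GP features only; age is
assigned to the stratum exactly and sex is drawn Bernoulli at the observed
control male proportion, so the covariate matching the strategy exists for
is never undone by the interpolation itself.  Neighbour search runs within
the age stratum, widening +-1 year at a time when a stratum is thinner than
k + 1 controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cohort import GP_COLUMNS, GlycomicsCohort
from .preprocess import balance_report

AGE_UPPER_BOUND = 74
HALF_MATCH_AGES = (72, 73, 74)
EXACT_MATCH_AGES = tuple(range(61, 72))


@dataclass
class SmoteParams:
    """SMOTE controls: neighbour count k (default 3) and the RNG seed."""

    k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class AugmentationPlan:
    """Per-age control targets plus the age-74 drop directive.

    ``targets`` maps age -> total control count wanted at that age
    (>= the existing count; synthesis makes up the deficit).
    """

    targets: dict = field(default_factory=dict)
    age_upper_bound: int = AGE_UPPER_BOUND
    half_match_ages: tuple = HALF_MATCH_AGES
    existing: dict = field(default_factory=dict)

    def deficits(self) -> dict:
        return {a: t - self.existing.get(a, 0) for a, t in self.targets.items()
                if t > self.existing.get(a, 0)}


def smote_sample(minority: np.ndarray, params: SmoteParams, n_new: int,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Generate ``n_new`` synthetic rows from a minority matrix.

    Each row is a + lambda*(b - a) with a drawn uniformly from the minority
    rows, b uniform among a's k nearest Euclidean neighbours (self excluded)
    and lambda ~ Uniform(0, 1).  Returns the rows plus nothing else; use
    :func:`smote_sample_with_provenance` when the generating pairs matter.
    """
    rows, _ = smote_sample_with_provenance(minority, params, n_new, rng)
    return rows


def smote_sample_with_provenance(minority, params: SmoteParams, n_new: int,
                                 rng=None):
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2:
        raise ValueError("minority must be a 2-D matrix")
    n = len(minority)
    if n <= params.k:
        raise ValueError(f"need > k = {params.k} minority rows, got {n}")
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if n_new == 0:
        return minority[:0].copy(), np.empty((0, 3))

    dist = cdist(minority, minority)
    np.fill_diagonal(dist, np.inf)
    # ties broken by index order for determinism
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, : params.k]

    a_idx = rng.integers(0, n, size=n_new)
    b_pick = rng.integers(0, params.k, size=n_new)
    b_idx = neighbours[a_idx, b_pick]
    lam = rng.uniform(0.0, 1.0, size=n_new)
    rows = minority[a_idx] + lam[:, None] * (minority[b_idx] - minority[a_idx])
    prov = np.column_stack([a_idx, b_idx, lam])
    return rows, prov


def build_augmentation_plan(cohort: GlycomicsCohort) -> AugmentationPlan:
    """Derive per-age control targets from the cohort's case/control counts."""
    age = cohort.age
    y = cohort.labels
    targets: dict[int, int] = {}
    existing: dict[int, int] = {}
    for a in EXACT_MATCH_AGES + HALF_MATCH_AGES:
        n_cases = int(((age == a) & (y == 1)).sum())
        n_controls = int(((age == a) & (y == 0)).sum())
        existing[a] = n_controls
        want = n_cases if a in EXACT_MATCH_AGES else n_cases // 2
        targets[a] = max(want, n_controls)
    return AugmentationPlan(targets=targets, existing=existing)


def _stratum_pool(controls: pd.DataFrame, age: int, k: int) -> pd.DataFrame:
    """Controls at ``age``, widened +-1 year at a time until > k are found."""
    width = 0
    ages = controls["age"].to_numpy()
    while True:
        mask = np.abs(ages - age) <= width
        if mask.sum() > k:
            return controls.loc[mask]
        width += 1
        if width > int(np.ptp(ages)) + 1:
            raise ValueError(
                f"insufficient control neighbours for age stratum {age} "
                f"(need > {k} controls)"
            )


def augment_cohort(cohort: GlycomicsCohort, plan: AugmentationPlan | None = None,
                   params: SmoteParams | None = None) -> GlycomicsCohort:
    """Apply the plan: drop over-74 rows, synthesise controls per stratum.

    Original retained rows are flagged ``is_synthetic = False`` and left
    untouched; synthetic rows carry the stratum age, a Bernoulli-drawn sex at
    the observed control male proportion, fresh sample ids and
    ``is_synthetic = True``.  The per-stratum SMOTE provenance (pool row
    positions of a and b, lambda) is attached as ``.augmentation_log``.
    """
    params = params or SmoteParams()
    if plan is None:
        plan = build_augmentation_plan(cohort)
    rng = np.random.default_rng(params.seed)

    tab = cohort.table.copy()
    tab = tab[tab["age"] <= plan.age_upper_bound].reset_index(drop=True)
    if "is_synthetic" not in tab.columns:
        tab["is_synthetic"] = False
    controls = tab[tab["label"] == "control"]
    male_prop = float((controls["sex"] == "male").mean())

    new_rows = []
    log_rows = []
    counter = 0
    for a in sorted(plan.targets):
        deficit = plan.targets[a] - int((controls["age"] == a).sum())
        if deficit <= 0:
            continue
        pool = _stratum_pool(controls, a, params.k)
        X = pool[GP_COLUMNS].to_numpy(dtype=float)
        rows, prov = smote_sample_with_provenance(X, params, deficit, rng)
        pool_ids = pool["sample_id"].to_numpy()
        for r, (ai, bi, lam) in zip(rows, prov):
            counter += 1
            seed_row = pool.iloc[int(ai)]
            rec = {"sample_id": f"SYN{counter:05d}",
                   "age": int(a),
                   "sex": "male" if rng.uniform() < male_prop else "female",
                   "year": seed_row["year"], "plate": seed_row["plate"],
                   "label": "control", "is_synthetic": True}
            rec.update({c: v for c, v in zip(GP_COLUMNS, r)})
            new_rows.append(rec)
            log_rows.append({"sample_id": rec["sample_id"], "age": int(a),
                             "parent_a": pool_ids[int(ai)],
                             "parent_b": pool_ids[int(bi)], "lam": float(lam)})

    if new_rows:
        tab = pd.concat([tab, pd.DataFrame(new_rows)[tab.columns]],
                        ignore_index=True)
    out = GlycomicsCohort(tab, schema_mode=cohort.schema_mode,
                          require_unit_sum=False)
    out.augmentation_log = pd.DataFrame(
        log_rows, columns=["sample_id", "age", "parent_a", "parent_b", "lam"])
    return out


def audit_augmentation(before: GlycomicsCohort, after: GlycomicsCohort,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Paired covariate balance reports before/after augmentation.

    Returns one row per variable with p/q-values from both cohorts and a
    ``newly_significant`` flag marking covariates whose imbalance the
    augmentation itself introduced.
    """
    rep_b = balance_report(before, alpha=alpha).set_index("variable")
    rep_a = balance_report(after, alpha=alpha).set_index("variable")
    out = pd.DataFrame({
        "test": rep_b["test"],
        "p_before": rep_b["p_value"], "q_before": rep_b["q_value"],
        "p_after": rep_a["p_value"], "q_after": rep_a["q_value"],
        "significant_before": rep_b["significant"],
        "significant_after": rep_a["significant"],
    })
    out["newly_significant"] = out["significant_after"] & ~out["significant_before"]
    return out.reset_index()
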