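"""Log-scale empirical-Bayes batch correction and covariate balance testing.

Batch correction follows the classic location/scale empirical-Bayes scheme
for omics matrices: per-feature linear standardisation with the batch factor
and protected biological covariates (class label, age, sex) in the design,
batch-wise additive (gamma) and multiplicative (delta^2) effect estimates on
the standardised residuals, parametric shrinkage of both towards batch-level
priors (normal for gamma, inverse-gamma for delta^2) by fixed-point
iteration, and adjustment (z - gamma*)/delta* followed by de-standardisation.
GP matrices enter on the natural-log scale and leave on the fraction scale.

The balance-testing half implements the covariate audit used before/after
augmentation: Mann-Whitney U for numeric variables (age, GPs), Fisher's
exact test for sex, Benjamini-Hochberg control across the tested set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GP_COLUMNS, N_GP, GlycomicsCohort


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

def log_transform_gps(cohort_or_matrix) -> np.ndarray:
    """Element-wise natural log of GP fractions.

    Accepts a cohort or a raw (n, 24) fraction matrix.  Zeros are a hard
    error: the generator enforces a positivity floor and silent pseudo-counts
    would distort the log-scale EB model.
    """
    if isinstance(cohort_or_matrix, GlycomicsCohort):
        gp = cohort_or_matrix.gp
    else:
        gp = np.asarray(cohort_or_matrix, dtype=float)
    if (gp <= 0).any():
        raise ValueError(
            "GP values must be strictly positive for the log transform; "
            "regenerate the data with a positivity floor instead of adding an epsilon"
        )
    return np.log(gp)


# ---------------------------------------------------------------------------
# empirical-Bayes batch model
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted per-feature linear model + EB-shrunken batch effects.

    gamma_hat / gamma_star and delta2_hat / delta2_star are (n_batch,
    n_feature) arrays in *standardised* units; ``batch_shift_log`` returns
    the additive effect on the log-GP scale.
    """

    batch_levels: np.ndarray
    design_cols: list
    beta: np.ndarray              # (n_design, p) OLS coefficients
    grand_mean: np.ndarray        # (p,) weighted across batches
    sigma2: np.ndarray            # (p,) pooled residual variance
    gamma_hat: np.ndarray
    delta2_hat: np.ndarray
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    gamma_bar: np.ndarray         # (n_batch,) prior means
    tau2_bar: np.ndarray          # (n_batch,) prior variances
    a_prior: np.ndarray           # (n_batch,) inverse-gamma shape
    b_prior: np.ndarray           # (n_batch,) inverse-gamma scale
    n_per_batch: np.ndarray

    @property
    def n_features(self) -> int:
        return self.gamma_hat.shape[1]

    def batch_shift_log(self, level) -> np.ndarray:
        """Shrunken additive batch effect on the log-GP scale, per feature."""
        i = int(np.where(self.batch_levels == level)[0][0])
        return self.gamma_star[i] * np.sqrt(self.sigma2)


def _design_matrix(batch_codes: np.ndarray, n_batch: int, covariates) -> np.ndarray:
    onehot = np.eye(n_batch)[batch_codes]
    if covariates is None or np.size(covariates) == 0:
        return onehot
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != len(batch_codes):
        cov = cov.T
    return np.hstack([onehot, cov])


def fit_batch_model(logX: np.ndarray, batch, covariates=None,
                    tol: float = 1e-6, max_iter: int = 500) -> BatchModel:
    """Fit the per-feature EB batch model on log-scale data.

    Parameters
    ----------
    logX : (n, p) array, natural-log GP values.
    batch : length-n category vector (any hashable labels).
    covariates : optional (n, c) design columns for biological covariates
        (label, age, sex) whose effects are protected by the standardisation
        and restored after adjustment.
    tol, max_iter : fixed-point convergence controls for the parametric
        posterior updates.
    """
    logX = np.asarray(logX, dtype=float)
    if not np.isfinite(logX).all():
        raise ValueError("non-finite values in the input matrix")
    n, p = logX.shape
    batch = np.asarray(batch)
    levels, codes = np.unique(batch, return_inverse=True)
    n_batch = len(levels)
    counts = np.bincount(codes, minlength=n_batch)
    if (counts < 2).any():
        small = levels[counts < 2]
        raise ValueError(f"batch level(s) with < 2 samples: {list(small)}")

    design = _design_matrix(codes, n_batch, covariates)
    beta, *_ = np.linalg.lstsq(design, logX, rcond=None)
    grand_mean = (counts / n) @ beta[:n_batch]
    resid = logX - design @ beta
    sigma2 = (resid ** 2).mean(axis=0)
    sigma2 = np.maximum(sigma2, 1e-12)

    # standardise: remove grand mean + covariate effects, keep batch effects in
    stand_mean = np.tile(grand_mean, (n, 1))
    if design.shape[1] > n_batch:
        stand_mean = stand_mean + design[:, n_batch:] @ beta[n_batch:]
    Z = (logX - stand_mean) / np.sqrt(sigma2)

    gamma_hat = np.vstack([Z[codes == i].mean(axis=0) for i in range(n_batch)])
    # ddof=0 keeps delta2 consistent with the pooled sigma2 denominator, so a
    # single batch (or identical batches) gives gamma_hat = 0, delta2_hat = 1
    # exactly and the adjustment collapses to the identity.
    delta2_hat = np.vstack([Z[codes == i].var(axis=0, ddof=0) for i in range(n_batch)])
    delta2_hat = np.maximum(delta2_hat, 1e-12)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2_bar = gamma_hat.var(axis=1, ddof=1)
    m = delta2_hat.mean(axis=1)
    s2 = delta2_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2 * s2 + m ** 2) / s2
        b_prior = (m * s2 + m ** 3) / s2

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    if n_batch > 1:
        for i in range(n_batch):
            if not np.isfinite(tau2_bar[i]) or tau2_bar[i] <= 0 or not np.isfinite(a_prior[i]):
                continue  # degenerate prior: keep raw estimates
            g, d2 = gamma_hat[i].copy(), delta2_hat[i].copy()
            Zi = Z[codes == i]
            ni = counts[i]
            for _ in range(max_iter):
                g_new = (ni * tau2_bar[i] * gamma_hat[i] + d2 * gamma_bar[i]) / (
                    ni * tau2_bar[i] + d2
                )
                sse = ((Zi - g_new) ** 2).sum(axis=0)
                d2_new = (b_prior[i] + 0.5 * sse) / (ni / 2 + a_prior[i] - 1)
                change = max(
                    np.abs(g_new - g).max() / max(np.abs(g).max(), 1e-12),
                    np.abs(d2_new - d2).max() / max(np.abs(d2).max(), 1e-12),
                )
                g, d2 = g_new, d2_new
                if change < tol:
                    break
            gamma_star[i], delta2_star[i] = g, np.maximum(d2, 1e-12)

    return BatchModel(
        batch_levels=levels, design_cols=list(range(design.shape[1])),
        beta=beta, grand_mean=grand_mean, sigma2=sigma2,
        gamma_hat=gamma_hat, delta2_hat=delta2_hat,
        gamma_star=gamma_star, delta2_star=delta2_star,
        gamma_bar=gamma_bar, tau2_bar=tau2_bar,
        a_prior=a_prior, b_prior=b_prior, n_per_batch=counts,
    )


def apply_batch_correction(logX: np.ndarray, model: BatchModel, batch,
                           covariates=None) -> np.ndarray:
    """Adjust log-scale data with a fitted model; return *fraction-scale* GPs.

    The adjustment is (z - gamma*)/delta* on the standardised scale, then
    de-standardisation (covariate effects restored) and exponentiation.
    Output is strictly positive by construction and is deliberately not
    renormalised to unit sum.
    """
    logX = np.asarray(logX, dtype=float)
    n, p = logX.shape
    if p != model.n_features:
        raise ValueError(f"feature count {p} != fitted {model.n_features}")
    batch = np.asarray(batch)
    lut = {lv: i for i, lv in enumerate(model.batch_levels)}
    try:
        codes = np.array([lut[b] for b in batch])
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"unseen batch level {e.args[0]!r}") from None

    n_batch = len(model.batch_levels)
    design = _design_matrix(codes, n_batch, covariates)
    stand_mean = np.tile(model.grand_mean, (n, 1))
    if design.shape[1] > n_batch:
        stand_mean = stand_mean + design[:, n_batch:] @ model.beta[n_batch:]
    Z = (logX - stand_mean) / np.sqrt(model.sigma2)
    Zadj = (Z - model.gamma_star[codes]) / np.sqrt(model.delta2_star[codes])
    log_corrected = Zadj * np.sqrt(model.sigma2) + stand_mean
    return np.exp(log_corrected)


def correct_cohort(cohort: GlycomicsCohort, batch_cols=("year", "plate"),
                   protect_covariates: bool = True) -> tuple[GlycomicsCohort, BatchModel]:
    """Convenience wrapper: fit + apply on a cohort's combined batch factor."""
    logX = log_transform_gps(cohort)
    batch = cohort.batch_key(tuple(batch_cols))
    cov = None
    if protect_covariates:
        cov = np.column_stack([cohort.labels, cohort.age, cohort.sex_male]).astype(float)
    model = fit_batch_model(logX, batch, cov)
    corrected = apply_batch_correction(logX, model, batch, cov)
    return cohort.with_gp(corrected, require_unit_sum=False), model


# ---------------------------------------------------------------------------
# over-60 exclusion (non-augmented dataset)
# ---------------------------------------------------------------------------

def filter_non_augmented(cohort: GlycomicsCohort, age_cut: int = 60) -> GlycomicsCohort:
    """Drop all samples over ``age_cut`` (boundary inclusive-keep)."""
    keep = cohort.age <= age_cut
    out = cohort.subset(np.where(keep)[0])
    labels = out.labels
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("fewer than 2 samples per class after the age filter")
    return out


# ---------------------------------------------------------------------------
# hypothesis tests + multiplicity
# ---------------------------------------------------------------------------

def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact null distribution when min(n_a, n_b) <= 8 and there are no ties;
    normal approximation with tie and continuity correction otherwise.
    Constant pooled data yields p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("constant pooled data; Mann-Whitney p set to 1", stacklevel=2)
        return float(len(a) * len(b) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    A zero margin makes every table equally (un)informative: p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; Fisher p set to 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up q-values, returned in input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, clipped to 1.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def balance_report(cohort: GlycomicsCohort, include_gps: bool = False,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Covariate (and optionally GP) balance between control and case.

    Mann-Whitney U for numeric variables, Fisher's exact test for sex, BH
    across all tested variables; a variable is flagged at q < ``alpha``.
    """
    y = cohort.labels
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    rows = []
    age = cohort.age
    _, p_age = mann_whitney_u(age[y == 0], age[y == 1])
    rows.append(("age", "mann-whitney-u", p_age))
    male = cohort.sex_male
    tab = [[int(((y == 0) & (male == 1)).sum()), int(((y == 0) & (male == 0)).sum())],
           [int(((y == 1) & (male == 1)).sum()), int(((y == 1) & (male == 0)).sum())]]
    rows.append(("sex", "fisher-exact", fisher_exact(tab)))
    if include_gps:
        gp = cohort.gp
        for j, name in enumerate(GP_COLUMNS):
            _, pj = mann_whitney_u(gp[y == 0, j], gp[y == 1, j])
            rows.append((name, "mann-whitney-u", pj))
    rep = pd.DataFrame(rows, columns=["variable", "test", "p_value"])
    rep["q_value"] = benjamini_hochberg(rep["p_value"].to_numpy())
    rep["significant"] = rep["q_value"] < alpha
    return rep
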