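"""Cohort data model and CSV interchange.

A cohort is one row per plasma sample: 24 UPLC glycan-peak (GP) relative
abundances normalised to total chromatogram area, the demographic covariates
(age in years, sex), the measurement batch labels (year, plate) and the
binary disease status.  GP abundances are held internally as fractions that
sum to 1 per sample; tables stored as percentages are rescaled on read and
the declared mode is remembered so round-trips are faithful.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_GP = 24
GP_COLUMNS = [f"GP{i}" for i in range(1, N_GP + 1)]
META_COLUMNS = ["sample_id", "age", "sex", "year", "plate", "label"]
SEX_LEVELS = ("female", "male")
LABEL_LEVELS = ("control", "case")

#: per-sample GP sum tolerance, fraction mode (float round-off from
#: total-area normalisation); percent mode uses 1e-4 on the 0-100 scale.
FRACTION_SUM_TOL = 1e-6
PERCENT_SUM_TOL = 1e-4

AGE_MIN, AGE_MAX = 18, 100


class CohortSchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class CohortValidationError(ValueError):
    """A sample violates a cohort invariant; offending sample_ids are named."""


@dataclass
class GlycomicsCohort:
    """Validated case-control glycomics table.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``sample_id``, ``GP1``..``GP24`` (fractions), ``age``,
        ``sex`` (female/male), ``year``, ``plate``, ``label``
        (control/case) and optionally ``is_synthetic``.
    schema_mode : {"fraction", "percent"}
        How GP values were stored on disk.  Internally always fractions.
    require_unit_sum : bool
        Whether per-sample GP sums must equal 1 within tolerance.  Batch
        correction deliberately does not renormalise, so downstream stages
        construct cohorts with this check relaxed.
    """

    table: pd.DataFrame
    schema_mode: str = "fraction"
    require_unit_sum: bool = True

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self.validate()

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gp(self) -> np.ndarray:
        """(n, 24) array of GP fractions."""
        return self.table[GP_COLUMNS].to_numpy(dtype=float)

    @property
    def age(self) -> np.ndarray:
        return self.table["age"].to_numpy(dtype=int)

    @property
    def sex_male(self) -> np.ndarray:
        """One-hot male indicator used as the modelling encoding of sex."""
        return (self.table["sex"].to_numpy() == "male").astype(int)

    @property
    def labels(self) -> np.ndarray:
        """Binary class labels, case = 1."""
        return (self.table["label"].to_numpy() == "case").astype(int)

    @property
    def is_synthetic(self) -> np.ndarray:
        if "is_synthetic" in self.table.columns:
            return self.table["is_synthetic"].to_numpy(dtype=bool)
        return np.zeros(len(self.table), dtype=bool)

    def batch_key(self, cols: tuple[str, ...] = ("year", "plate")) -> np.ndarray:
        """Combined batch factor, e.g. year x plate treated as one level set."""
        key = self.table[cols[0]].astype(str)
        for c in cols[1:]:
            key = key + ":" + self.table[c].astype(str)
        return key.to_numpy()

    def feature_matrix(self, include_covariates: bool = True) -> pd.DataFrame:
        """Model features: the 24 GPs plus age and the one-hot male flag."""
        feats = self.table[GP_COLUMNS].astype(float).copy()
        if include_covariates:
            feats["age"] = self.age
            feats["sex_male"] = self.sex_male
        return feats

    def with_gp(self, gp: np.ndarray, require_unit_sum: bool | None = None) -> "GlycomicsCohort":
        """Copy of the cohort with the GP block replaced."""
        if gp.shape != (len(self.table), N_GP):
            raise ValueError(f"GP block shape {gp.shape} != {(len(self.table), N_GP)}")
        tab = self.table.copy()
        tab[GP_COLUMNS] = gp
        rus = self.require_unit_sum if require_unit_sum is None else require_unit_sum
        return GlycomicsCohort(tab, schema_mode=self.schema_mode, require_unit_sum=rus)

    def subset(self, idx) -> "GlycomicsCohort":
        return GlycomicsCohort(
            self.table.iloc[np.asarray(idx)].reset_index(drop=True),
            schema_mode=self.schema_mode,
            require_unit_sum=self.require_unit_sum,
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        tab = self.table
        missing = [c for c in META_COLUMNS + GP_COLUMNS if c not in tab.columns]
        if missing:
            raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
        if self.schema_mode not in ("fraction", "percent"):
            raise CohortSchemaError(f"unknown schema_mode {self.schema_mode!r}")

        if tab[META_COLUMNS + GP_COLUMNS].isna().any().any():
            bad = tab.loc[tab[META_COLUMNS + GP_COLUMNS].isna().any(axis=1), "sample_id"]
            raise CohortValidationError(f"missing values in sample(s): {_fmt_ids(bad)}")

        ids = tab["sample_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise CohortValidationError(f"duplicate sample_id(s): {_fmt_ids(dup)}")

        gp = tab[GP_COLUMNS].to_numpy(dtype=float)
        neg = (gp < 0).any(axis=1)
        if neg.any():
            raise CohortValidationError(
                f"negative GP value in sample(s): {_fmt_ids(tab.loc[neg, 'sample_id'])}"
            )
        if self.require_unit_sum:
            sums = gp.sum(axis=1)
            bad = np.abs(sums - 1.0) > FRACTION_SUM_TOL
            if bad.any():
                raise CohortValidationError(
                    "GP fractions do not sum to 1 in sample(s): "
                    f"{_fmt_ids(tab.loc[bad, 'sample_id'])}"
                )

        age = tab["age"].to_numpy()
        bad_age = (age < AGE_MIN) | (age > AGE_MAX)
        if bad_age.any():
            raise CohortValidationError(
                f"age outside [{AGE_MIN}, {AGE_MAX}] in sample(s): "
                f"{_fmt_ids(tab.loc[bad_age, 'sample_id'])}"
            )

        for col, levels in (("sex", SEX_LEVELS), ("label", LABEL_LEVELS)):
            vals = set(tab[col].astype(str))
            extra = vals - set(levels)
            if extra:
                raise CohortValidationError(
                    f"column {col!r} has values outside {levels}: {sorted(extra)}"
                )


@dataclass
class CohortSplit:
    """Disjoint train / calibration / test index lists over one cohort."""

    train_idx: np.ndarray
    calib_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    test_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        a = set(np.asarray(self.train_idx).tolist())
        b = set(np.asarray(self.calib_idx).tolist())
        c = set(np.asarray(self.test_idx).tolist())
        if a & b or a & c or b & c:
            raise ValueError("split index lists are not pairwise disjoint")


def _fmt_ids(ids, limit: int = 5) -> str:
    vals = [str(v) for v in list(ids)[:limit]]
    suffix = ", ..." if len(ids) > limit else ""
    return ", ".join(vals) + suffix


def read_cohort(
    path,
    schema_mode: str = "fraction",
    require_unit_sum: bool = True,
) -> GlycomicsCohort:
    """Read and validate a cohort CSV.

    ``schema_mode="percent"`` declares that GP columns hold percentages of
    total area; they are rescaled to fractions internally and the mode is
    recorded on the cohort (never guessed from the data).
    """
    tab = pd.read_csv(path)
    missing = [c for c in ["sample_id"] + GP_COLUMNS + ["age", "sex", "year", "plate", "label"]
               if c not in tab.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    tab["sample_id"] = tab["sample_id"].astype(str)
    tab["year"] = tab["year"].astype(str)
    tab["plate"] = tab["plate"].astype(str)
    if schema_mode == "percent":
        gp = tab[GP_COLUMNS].to_numpy(dtype=float)
        if require_unit_sum:
            sums = gp.sum(axis=1)
            bad = np.abs(sums - 100.0) > PERCENT_SUM_TOL
            if bad.any():
                raise CohortValidationError(
                    "GP percentages do not sum to 100 in sample(s): "
                    f"{_fmt_ids(tab.loc[bad, 'sample_id'])}"
                )
        tab[GP_COLUMNS] = gp / 100.0
        return GlycomicsCohort(tab, schema_mode="percent", require_unit_sum=require_unit_sum)
    return GlycomicsCohort(tab, schema_mode=schema_mode, require_unit_sum=require_unit_sum)


def write_cohort(cohort: GlycomicsCohort, path) -> str:
    """Write a cohort CSV with deterministic column order.

    GP fractions are printed at 12 significant digits so that
    ``read_cohort(write_cohort(c))`` reproduces the table exactly at that
    precision.  Percent-mode cohorts are written back on the percent scale.
    """
    cols = ["sample_id"] + GP_COLUMNS + ["age", "sex", "year", "plate", "label"]
    if "is_synthetic" in cohort.table.columns:
        cols.append("is_synthetic")
    out = cohort.table[cols].copy()
    gp = out[GP_COLUMNS].to_numpy(dtype=float)
    if cohort.schema_mode == "percent":
        gp = gp * 100.0
    for j, c in enumerate(GP_COLUMNS):
        out[c] = [float(f"{v:.12g}") for v in gp[:, j]]
    buf = io.StringIO()
    out.to_csv(buf, index=False, float_format="%.12g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
    return str(path)
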