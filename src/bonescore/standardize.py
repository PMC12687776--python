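"""Panel validation and within-model z-standardization.

Cross-cohort harmonization: each bone variable is standardized using the mean
and sample SD of all animals of the same mouse model, separately for each sex
and age, pooling euploid and trisomic littermates within a stratum. On the
standardized scale, background-strain and instrument offsets between models
drop out, so models can be compared directly; in a balanced design this makes
the mouse-model main effect on any downstream composite exactly null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ContractError, DegenerateStratumError, InputError
from .variables import COMPARTMENT_VARIABLES, ID_COLUMN

__all__ = [
    "ValidationReport",
    "validate_panels",
    "WithinGroupStandardizer",
    "standardize_within_model",
]


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panels`."""

    clean: pd.DataFrame
    exclusions: pd.DataFrame          # columns: animal_id, reason
    missing: pd.DataFrame             # columns: animal_id, variable
    n_input: int = 0
    issues: list = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.exclusions[ID_COLUMN].nunique() if len(self.exclusions) else 0


def validate_panels(table: pd.DataFrame, variables: list | None = None) -> ValidationReport:
    """Check panel invariants and return a cleaned table plus exclusion log.

    Rows violating hard invariants (negative values where impossible,
    Ct.Ar > Tt.Ar, duplicate animal ids, infinite values) are excluded with a
    reason. Missing (NaN) cells are *flagged*, not excluded: the animal is
    dropped later only from analyses of the affected compartment.
    """
    if table is None or len(table) == 0:
        raise InputError("empty panel table")
    if ID_COLUMN not in table.columns:
        raise InputError(f"panel table lacks an {ID_COLUMN!r} column")
    if variables is None:
        variables = [v for vs in COMPARTMENT_VARIABLES.values() for v in vs
                     if v in table.columns]
    reasons: dict[object, str] = {}

    dup = table[ID_COLUMN][table[ID_COLUMN].duplicated(keep=False)]
    for aid in dup.unique():
        reasons[aid] = "duplicate animal_id"

    missing_rows = []
    for _, row in table.iterrows():
        aid = row[ID_COLUMN]
        for v in variables:
            val = row[v]
            if pd.isna(val):
                missing_rows.append({ID_COLUMN: aid, "variable": v})
            elif not np.isfinite(val):
                reasons.setdefault(aid, f"non-finite value in {v}")
            elif val < 0:
                reasons.setdefault(aid, f"negative value in {v}")
        if ("Ct.Ar" in variables and "Tt.Ar" in variables
                and pd.notna(row.get("Ct.Ar")) and pd.notna(row.get("Tt.Ar"))
                and row["Ct.Ar"] > row["Tt.Ar"]):
            reasons.setdefault(aid, "Ct.Ar exceeds Tt.Ar")

    exclusions = pd.DataFrame(
        [{ID_COLUMN: k, "reason": v} for k, v in reasons.items()],
        columns=[ID_COLUMN, "reason"])
    clean = table[~table[ID_COLUMN].isin(reasons)].copy()
    missing = pd.DataFrame(missing_rows, columns=[ID_COLUMN, "variable"])
    return ValidationReport(clean=clean, exclusions=exclusions, missing=missing,
                            n_input=len(table))


class WithinGroupStandardizer(BaseEstimator, TransformerMixin):
    """Standardize variables within strata defined by grouping columns.

    z = (value - stratum mean) / stratum SD, with the sample (n-1) SD, where a
    stratum is one combination of ``group_cols`` (default mouse model x sex x
    age) pooling all genotypes of that model. Fitting records per-stratum
    n/mean/SD as provenance; transforming maps raw values to z-scores, so a
    fitted instance can standardize new animals against the cohort statistics.

    Parameters
    ----------
    variables : list of str, optional
        Panel columns to standardize; default: every known panel variable
        present at fit time.
    group_cols : tuple of str
        Stratification columns; must exist in the fitted table.
    ddof : int
        SD denominator delta (1 = sample SD).

    Attributes
    ----------
    stats_ : pandas.DataFrame
        Tidy provenance: one row per (stratum, variable) with n, mean, sd.
    variables_ : list of str
    group_cols_ : tuple of str
    """

    def __init__(self, variables=None, group_cols=("model", "sex", "age"), ddof=1):
        self.variables = variables
        self.group_cols = group_cols
        self.ddof = ddof

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise ContractError("WithinGroupStandardizer expects a DataFrame")
        if len(X) == 0:
            raise InputError("empty table")
        group_cols = tuple(self.group_cols)
        for c in group_cols:
            if c not in X.columns:
                raise ContractError(f"grouping column {c!r} not in table")
        if self.variables is None:
            variables = [v for vs in COMPARTMENT_VARIABLES.values() for v in vs
                         if v in X.columns]
        else:
            variables = list(self.variables)
            for v in variables:
                if v not in X.columns:
                    raise ContractError(f"variable {v!r} not in table")
        if not variables:
            raise InputError("no panel variables to standardize")

        records = []
        for key, sub in X.groupby(list(group_cols), observed=True, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            for v in variables:
                vals = sub[v].dropna().to_numpy(dtype=float)
                n = vals.size
                if n < 2:
                    raise DegenerateStratumError(
                        f"stratum {dict(zip(group_cols, key))} has n={n} for {v!r}")
                sd = float(np.std(vals, ddof=self.ddof))
                if sd == 0.0:
                    raise DegenerateStratumError(
                        f"zero SD for {v!r} in stratum {dict(zip(group_cols, key))}")
                records.append({**dict(zip(group_cols, key)), "variable": v,
                                "n": n, "mean": float(np.mean(vals)), "sd": sd})
        self.stats_ = pd.DataFrame(records)
        self.variables_ = variables
        self.group_cols_ = group_cols
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "stats_")
        if not isinstance(X, pd.DataFrame):
            raise ContractError("WithinGroupStandardizer expects a DataFrame")
        out = X.copy()
        keys = X[list(self.group_cols_)].reset_index(drop=True)
        for v in self.variables_:
            st = self.stats_.loc[self.stats_["variable"] == v,
                                 [*self.group_cols_, "mean", "sd"]]
            merged = keys.merge(st, on=list(self.group_cols_), how="left")
            if merged["sd"].isna().any():
                bad = keys[merged["sd"].isna()].drop_duplicates().iloc[0].to_dict()
                raise ContractError(f"no fitted statistics for stratum {bad!r}")
            out[v] = ((X[v].to_numpy(dtype=float) - merged["mean"].to_numpy())
                      / merged["sd"].to_numpy())
        return out

    def provenance(self) -> pd.DataFrame:
        """Per-stratum n/mean/sd table, suitable for a provenance CSV."""
        check_is_fitted(self, "stats_")
        return self.stats_.copy()


def standardize_within_model(
    table: pd.DataFrame,
    variables=None,
    stratify_by=("model", "sex", "age"),
    ddof: int = 1,
):
    """Functional wrapper: fit + transform in one call.

    Returns ``(z_table, provenance)``; ``z_table`` keeps all non-panel columns
    unchanged and replaces panel values by z-scores. Strata pool both
    genotypes of a model, which is what removes between-model offsets.
    """
    stratify_by = tuple(c for c in stratify_by if c in table.columns)
    if not stratify_by:
        raise ContractError("no stratification columns present in table")
    est = WithinGroupStandardizer(variables=variables, group_cols=stratify_by, ddof=ddof)
    z = est.fit(table).transform(table)
    return z, est.provenance()
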