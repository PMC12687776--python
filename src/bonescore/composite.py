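"""PC1 composite scores for trabecular and cortical bone.

The composite score collapses a correlated panel of standardized bone
variables into one number per animal: principal components analysis is fitted
on the pooled z-scores of the cohorts under comparison, the first component's
loadings are oriented so that the anchor variable (BV/TV for trabecular,
Ct.Ar for cortical) loads positively, and each animal's score is the inner
product of the PC1 loading vector with its standardized variable vector:

    score_i = sum_v loading_v * z_{iv}

Because every variable contributes, a diffuse sub-threshold deficit spread
over the whole panel accumulates into the score, which is what lets the
composite detect subclinical phenotypes that per-variable testing (with its
multiplicity penalty) misses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ContractError, DegenerateVariableError, InputError
from .variables import ID_COLUMN

__all__ = ["PC1CompositeScorer", "fit_pc1", "orient_loadings", "composite_scores"]


class PC1CompositeScorer(BaseEstimator, TransformerMixin):
    """Fit PC1 on pooled standardized panels and score animals with it.

    Parameters
    ----------
    variables : list of str, optional
        Panel columns to use, in order. Default: all columns of the fitted
        DataFrame (or all array columns).
    anchor : str, optional
        Variable whose PC1 loading is forced positive. If its loading is
        exactly zero, orientation fails with an error suggesting another
        anchor.
    use_correlation : bool
        Decompose the correlation matrix instead of the covariance matrix.
        After within-model standardization the two nearly coincide; the
        covariance of z-scores is the default.
    center : bool
        Subtract pooled column means before the decomposition. Pooled
        z-means are already ~0 (exactly 0 per stratum), so this only matters
        in unbalanced multi-stratum pools.

    Attributes
    ----------
    variables_ : list of str — variable order of the loading vector.
    loadings_ : ndarray — unit-norm PC1 loading vector.
    components_ : ndarray, shape (p, p) — all eigenvectors, rows ordered by
        descending eigenvalue.
    explained_variance_ : ndarray — eigenvalues, descending.
    explained_variance_ratio_ : ndarray — eigenvalues / sum, in [0, 1].
    mean_ : ndarray — pooled column means.
    n_samples_ : int
    anchor_ : str or None — orientation anchor actually applied.

    Notes
    -----
    ``transform``/``score`` apply the loading vector to the standardized
    values as given (no re-centering), exactly as the composite is defined;
    scores therefore average to zero over any pool whose per-stratum z-means
    are zero.
    """

    def __init__(self, variables=None, anchor=None, use_correlation=False, center=True):
        self.variables = variables
        self.anchor = anchor
        self.use_correlation = use_correlation
        self.center = center

    # ------------------------------------------------------------------
    def _resolve_variables(self, X):
        if self.variables is not None:
            return list(self.variables)
        if isinstance(X, pd.DataFrame):
            return [c for c in X.columns if c != ID_COLUMN
                    and pd.api.types.is_numeric_dtype(X[c])]
        return [f"x{i}" for i in range(np.asarray(X).shape[1])]

    def _matrix(self, X, variables):
        if isinstance(X, pd.DataFrame):
            missing = [v for v in variables if v not in X.columns]
            if missing:
                raise ContractError(f"variables absent from table: {missing!r}")
            m = X[variables].to_numpy(dtype=float)
        else:
            m = np.asarray(X, dtype=float)
            if m.ndim != 2 or m.shape[1] != len(variables):
                raise ContractError(
                    f"expected {len(variables)} columns, got shape {m.shape}")
        return m

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        variables = self._resolve_variables(X)
        if len(variables) < 2:
            raise InputError("PCA needs at least 2 variables")
        m = self._matrix(X, variables)
        if np.isnan(m).any():
            raise InputError("PCA input must be complete-case (no missing values)")
        n, p = m.shape
        if n < 3:
            raise InputError("PCA needs at least 3 complete animals")
        sds = m.std(axis=0, ddof=1)
        if np.any(sds == 0):
            bad = variables[int(np.argmin(sds))]
            raise DegenerateVariableError(f"constant variable {bad!r} in PCA input")
        self.mean_ = m.mean(axis=0)
        centered = m - self.mean_ if self.center else m
        cov = np.cov(centered, rowvar=False, ddof=1)
        if self.use_correlation:
            d = np.sqrt(np.diag(cov))
            cov = cov / np.outer(d, d)
        if n - 1 < p:
            warnings.warn(
                f"fewer animals ({n}) than variables ({p}): components beyond "
                f"rank {n - 1} have zero variance", stacklevel=2)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order]
        self.components_ = eigvec.T
        self.explained_variance_ = eigval
        self.explained_variance_ratio_ = eigval / eigval.sum()
        self.loadings_ = eigvec[:, 0].copy()
        self.variables_ = variables
        self.n_samples_ = n
        self.anchor_ = None
        if self.anchor is not None:
            orient_loadings(self, self.anchor)
        return self

    # ------------------------------------------------------------------
    def transform(self, X):
        """Composite scores as an (n, 1) array."""
        check_is_fitted(self, "loadings_")
        m = self._matrix(X, self.variables_)
        if np.isnan(m).any():
            raise InputError("cannot score animals with missing standardized values")
        return (m @ self.loadings_)[:, None]

    def score_table(self, X, compartment: str = "") -> pd.DataFrame:
        """Scores as a tidy DataFrame (animal_id carried through if present)."""
        scores = self.transform(X)[:, 0]
        out = pd.DataFrame({"score": scores})
        if isinstance(X, pd.DataFrame) and ID_COLUMN in X.columns:
            out.insert(0, ID_COLUMN, X[ID_COLUMN].to_numpy())
        if compartment:
            out.insert(len(out.columns) - 1, "compartment", compartment)
        return out

    def loadings_table(self) -> pd.DataFrame:
        check_is_fitted(self, "loadings_")
        return pd.DataFrame({
            "variable": self.variables_,
            "loading": self.loadings_,
            "pc1_variance_explained": self.explained_variance_ratio_[0],
        })


def orient_loadings(model: PC1CompositeScorer, anchor: str) -> PC1CompositeScorer:
    """Resolve the eigenvector sign: force the anchor variable's loading > 0.

    Mutates and returns ``model``. Idempotent; raises if the anchor loading is
    exactly zero (orientation undefined — pick a different anchor).
    """
    check_is_fitted(model, "loadings_")
    if anchor not in model.variables_:
        raise ContractError(f"anchor {anchor!r} not among {model.variables_!r}")
    idx = model.variables_.index(anchor)
    val = model.loadings_[idx]
    if val == 0.0:
        raise ContractError(
            f"anchor {anchor!r} has zero PC1 loading; choose a different anchor")
    if val < 0:
        model.loadings_ = -model.loadings_
        model.components_[0] = model.loadings_
    model.anchor_ = anchor
    return model


def fit_pc1(table, variables=None, anchor=None, use_correlation=False) -> PC1CompositeScorer:
    """Fit a :class:`PC1CompositeScorer` on a pooled standardized table."""
    return PC1CompositeScorer(
        variables=variables, anchor=anchor, use_correlation=use_correlation
    ).fit(table)


def composite_scores(model: PC1CompositeScorer, table, compartment: str = "") -> pd.DataFrame:
    """Per-animal composite scores: ``sum_v loading_v * z_v``."""
    return model.score_table(table, compartment=compartment)
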