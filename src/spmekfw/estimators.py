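"""scikit-learn style estimators for the QSPR workflow.

:class:`MolecularDescriptors` turns SMILES strings into a numeric design
matrix of structure-derived descriptors; :class:`KfwRegressor` is the
ordinary-least-squares model of log10 Kfw on those descriptors.  Both
compose with sklearn pipelines and model selection; the functional API in
:mod:`spmekfw.regress` is a thin wrapper over :class:`KfwRegressor`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .descriptors import PolarizabilityScheme, compute_descriptors
from .molgraph import parse_smiles

__all__ = ["MolecularDescriptors", "KfwRegressor", "CollinearityError"]


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""

    def __init__(self, columns):
        super().__init__(f"rank-deficient design; offending columns: {list(columns)}")
        self.columns = list(columns)


class MolecularDescriptors(TransformerMixin, BaseEstimator):
    """Transform SMILES strings into descriptor columns.

    Parameters
    ----------
    features : tuple of str
        Descriptor columns to emit, drawn from
        ``{"phi", "chi1", "indicator", "mw"}``.
    scheme : PolarizabilityScheme or None
        Polarizability conventions; None means the published defaults.
    """

    _ALLOWED = ("phi", "chi1", "indicator", "mw")

    def __init__(self, features: tuple = ("phi", "chi1", "indicator"),
                 scheme: PolarizabilityScheme | None = None):
        self.features = features
        self.scheme = scheme

    def fit(self, X, y=None):
        unknown = set(self.features) - set(self._ALLOWED)
        if unknown:
            raise ValueError(f"unknown descriptor feature(s): {sorted(unknown)}")
        self.n_features_in_ = 1  # a single SMILES column
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        smiles = self._as_smiles_list(X)
        rows = []
        for s in smiles:
            d = compute_descriptors(parse_smiles(s), scheme=self.scheme)
            vals = d.as_dict()
            rows.append([vals[f] for f in self.features])
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.features, dtype=object)

    @staticmethod
    def _as_smiles_list(X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            if "smiles" in X.columns:
                return X["smiles"].tolist()
            if X.shape[1] == 1:
                return X.iloc[:, 0].tolist()
            raise ValueError("DataFrame input needs a 'smiles' column")
        if isinstance(X, pd.Series):
            return X.tolist()
        arr = np.asarray(X, dtype=object)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        if arr.ndim != 1:
            raise ValueError("expected a 1-d sequence of SMILES strings")
        return [str(s) for s in arr]


class KfwRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares for log10 partition coefficients.

    The model is log10 Kfw = b0 + Σ bi·xi, fitted by OLS (statsmodels under
    the hood, QR-based pseudoinverse solve).  Fitted attributes follow
    sklearn conventions; the multiple correlation coefficient
    ``r_ = sqrt(1 - SSE/SST)`` is the fit statistic quoted throughout the
    partitioning literature.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
    r_ : float
        Multiple correlation coefficient of the fit.
    bse_ : ndarray
        Standard errors of (intercept, coefficients).
    pvalues_ : ndarray
        Two-sided t-test p-values of (intercept, coefficients).
    feature_names_in_ : ndarray of str, when X is a DataFrame.
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        min_n = p + (2 if self.fit_intercept else 1)
        if n < min_n:
            raise ValueError(f"need at least {min_n} observations for {p} predictors")
        design = sm.add_constant(X, has_constant="add") if self.fit_intercept else X
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            offending = self._rank_deficient_columns(design, names, self.fit_intercept)
            raise CollinearityError(offending)
        res = sm.OLS(y, design).fit()
        params = np.asarray(res.params, dtype=float)
        if self.fit_intercept:
            self.intercept_ = float(params[0])
            self.coef_ = params[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = params
        self.bse_ = np.asarray(res.bse, dtype=float)
        self.pvalues_ = np.asarray(res.pvalues, dtype=float)
        sst = float(np.sum((y - y.mean()) ** 2))
        sse = float(np.sum(res.resid**2))
        self.r_ = float(np.sqrt(max(0.0, 1.0 - sse / sst))) if sst > 0 else 0.0
        self.n_features_in_ = p
        self.n_obs_ = n
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        self._residuals = np.asarray(res.resid, dtype=float)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_

    @staticmethod
    def _rank_deficient_columns(design, names, has_const):
        """Identify columns whose removal does not reduce the rank further."""
        offending = []
        full = np.linalg.matrix_rank(design)
        for j in range(design.shape[1]):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == full:
                if has_const and j == 0:
                    label = "const"
                else:
                    k = j - 1 if has_const else j
                    label = names[k] if names is not None else f"x{k}"
                offending.append(label)
        return offending or ["<unidentified>"]
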