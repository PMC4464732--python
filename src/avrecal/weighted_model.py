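"""Weighted-parameter-sum model of the auditory aftereffect.

The per-type shift vector **SH** (32 sequence-type means) is modelled
as a weighted sum of sequence properties, ``SH = P · W`` with no
intercept, where **P** is the property design matrix.  The least-squares
weights are the pseudo-inverse solution

    W = (Pᵀ P)⁻¹ Pᵀ SH

Because the model has no intercept, an all-matching sequence is always
predicted to produce zero shift; any constant background recalibration
observed in data therefore shows up in the residuals, not the weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .sequence_features import property_matrix


class RankDeficientError(ValueError):
    """The property design matrix has collinear columns."""


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    full = np.linalg.matrix_rank(X)
    redundant = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            redundant.append(str(names[j]))
    return redundant


class PropertyWeightRegressor(RegressorMixin, BaseEstimator):
    """Linear least-squares fit of shift on sequence properties, no intercept.

    Follows the scikit-learn estimator protocol: ``fit(X, y)`` where
    ``X`` is the (n_types × K) property design matrix (array or
    DataFrame) and ``y`` the per-type mean shifts in degrees.

    Parameters
    ----------
    allow_rank_deficient : bool, default False
        By default a design matrix with collinear property columns is
        refused, naming the offending columns — e.g. ``D`` is an exact
        linear combination of ``SQ1…SQ5``.  When True, the fit falls
        back to the minimum-norm least-squares solution; the residual
        sum of squares is then still well defined even though the
        weights are not unique.

    Attributes
    ----------
    coef_ : ndarray of shape (K,)
        Fitted weights, degrees of shift per unit property.
    rank_ : int
        Numerical rank of the design matrix.
    feature_names_in_ : ndarray of str, when X is a DataFrame.
    """

    def __init__(self, allow_rank_deficient: bool = False):
        self.allow_rank_deficient = allow_rank_deficient

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
            )
        if X.shape[0] < X.shape[1]:
            raise ValueError("more properties than equations")
        self.n_features_in_ = X.shape[1]
        self.rank_ = int(np.linalg.matrix_rank(X))
        if self.rank_ < X.shape[1]:
            if not self.allow_rank_deficient:
                names = getattr(
                    self, "feature_names_in_", np.arange(X.shape[1]).astype(str)
                )
                cols = _collinear_columns(X, names)
                raise RankDeficientError(
                    "design matrix is rank deficient; collinear column(s): "
                    + ", ".join(cols)
                )
            self.coef_, *_ = np.linalg.lstsq(X, y, rcond=None)
        else:
            xtx = X.T @ X
            self.coef_ = np.linalg.solve(xtx, X.T @ y)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"X must have {self.coef_.shape[0]} columns, got shape {X.shape}"
            )
        return X @ self.coef_


@dataclass(frozen=True)
class FitResult:
    """One fitted candidate model and its goodness of fit."""

    property_names: tuple[str, ...]
    weights: np.ndarray
    predicted: np.ndarray
    rss: float
    r2_pearson: float
    r2_spearman: float

    def to_dict(self) -> dict:
        return {
            "property_names": list(self.property_names),
            "weights": [float(w) for w in self.weights],
            "predicted": [float(v) for v in self.predicted],
            "rss": self.rss,
            "r2_pearson": self.r2_pearson,
            "r2_spearman": self.r2_spearman,
        }


def fit_weights(P, shifts, allow_rank_deficient: bool = False) -> np.ndarray:
    """Pseudo-inverse least-squares weights of ``P · W = SH``."""
    model = PropertyWeightRegressor(allow_rank_deficient=allow_rank_deficient)
    return model.fit(P, shifts).coef_


def predict(P, weights) -> np.ndarray:
    """Weighted parameter sum ``P · W``."""
    P = np.asarray(P, dtype=float)
    weights = np.asarray(weights, dtype=float).ravel()
    if P.ndim != 2 or P.shape[1] != weights.shape[0]:
        raise ValueError(
            f"design matrix shape {P.shape} does not conform with "
            f"{weights.shape[0]} weights"
        )
    return P @ weights


def fit_quality(predicted, observed) -> tuple[float, float, float]:
    """(RSS, Pearson r², Spearman r²) of predicted vs observed shifts.

    A constant prediction vector leaves the correlations undefined;
    they are returned as NaN with a warning.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size < 3:
        raise ValueError("need at least 3 paired observations")
    rss = float(np.sum((observed - predicted) ** 2))
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        warnings.warn(
            "constant vector: correlation-based r² undefined", RuntimeWarning
        )
        return rss, float("nan"), float("nan")
    r_p, _ = stats.pearsonr(predicted, observed)
    r_s, _ = stats.spearmanr(predicted, observed)
    return rss, float(r_p**2), float(r_s**2)


def fit_properties(
    shifts: pd.DataFrame | pd.Series,
    names: Sequence[str],
    allow_rank_deficient: bool = False,
    sequence_length: int | None = None,
) -> FitResult:
    """Fit one candidate property set to a per-type shift vector.

    ``shifts`` is the output of
    :func:`avrecal.shift_analysis.shifts_by_sequence_type` (or a Series
    indexed by sequence id); the design matrix is built from the
    sequence types present in its index.
    """
    from .experiment_design import SequenceType

    sh = shifts["mean_shift"] if isinstance(shifts, pd.DataFrame) else shifts
    ids = [int(i) for i in sh.index]
    if not ids:
        raise ValueError("empty shift vector")
    seq_len = sequence_length or max(5, max(ids).bit_length())
    seqs = [SequenceType.from_id(i, seq_len) for i in ids]
    P = property_matrix(seqs, names)
    y = sh.to_numpy(dtype=float)
    w = fit_weights(P, y, allow_rank_deficient=allow_rank_deficient)
    pred = predict(P.to_numpy(), w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rss, r2p, r2s = fit_quality(pred, y)
    return FitResult(tuple(names), w, pred, rss, r2p, r2s)
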