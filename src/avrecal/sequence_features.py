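"""Predictor features of an AV sequence.

Each five-trial sequence is summarized by eight properties, all scaled
to [0, 1] so that larger values mean more discrepant stimulation:

``SQ1`` … ``SQ5``
    Whether trial 1 … 5 of the sequence was discrepant (binary).
``D``
    Proportion of discrepant trials in the sequence.
``MaxD``
    Longest run of consecutive discrepant trials, as a proportion of
    the sequence length.
``MaxDend``
    Length of the discrepant run that ends the sequence, as a
    proportion of the sequence length (0 if the last trial matched).

Generalized sequence lengths are supported; proportions then divide by
the actual length and the ``SQi`` names run up to that length.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .experiment_design import SequenceType

PROPERTY_NAMES = ("SQ1", "SQ2", "SQ3", "SQ4", "SQ5", "D", "MaxD", "MaxDend")


def _as_flags(sequence) -> tuple[int, ...]:
    if isinstance(sequence, SequenceType):
        return sequence.flags
    return SequenceType(tuple(sequence)).flags


def _longest_run(flags: Sequence[int]) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def _trailing_run(flags: Sequence[int]) -> int:
    run = 0
    for f in reversed(flags):
        if not f:
            break
        run += 1
    return run


def extract_properties(sequence) -> dict[str, float]:
    """All properties of one sequence, keyed by name."""
    flags = _as_flags(sequence)
    n = len(flags)
    props = {f"SQ{i + 1}": float(f) for i, f in enumerate(flags)}
    props["D"] = sum(flags) / n
    props["MaxD"] = _longest_run(flags) / n
    props["MaxDend"] = _trailing_run(flags) / n
    return props


def property_matrix(
    sequences: Iterable, names: Sequence[str] = PROPERTY_NAMES
) -> pd.DataFrame:
    """Design matrix: one row per sequence, one column per property.

    This is the matrix **P** of the weighted-sum model; rows follow the
    order of ``sequences`` and columns the order of ``names``.
    """
    names = list(names)
    if not names:
        raise ValueError("names must be non-empty")
    if len(set(names)) != len(names):
        raise ValueError("duplicate property names")
    rows = [extract_properties(s) for s in sequences]
    unknown = [n for n in names if rows and n not in rows[0]]
    if unknown:
        raise ValueError(f"unknown property name(s): {', '.join(unknown)}")
    return pd.DataFrame([[r[n] for n in names] for r in rows], columns=names)


class SequencePropertyTransformer(TransformerMixin, BaseEstimator):
    """Map binary sequences to their property features.

    A stateless transformer so that feature extraction composes with
    scikit-learn pipelines.  Input ``X`` is an array-like of shape
    ``(n_sequences, sequence_length)`` with binary entries, or an
    iterable of :class:`SequenceType`.

    Parameters
    ----------
    properties : sequence of str, default all eight
        Which properties to emit, in column order.
    """

    def __init__(self, properties: Sequence[str] = PROPERTY_NAMES):
        self.properties = properties

    def fit(self, X, y=None):
        property_matrix(self._sequences(X)[:1] or [(0,) * 5], self.properties)
        self.n_features_in_ = len(self._sequences(X)[0]) if len(X) else 5
        return self

    @staticmethod
    def _sequences(X) -> list[tuple[int, ...]]:
        return [_as_flags(row) for row in X]

    def transform(self, X) -> np.ndarray:
        return property_matrix(self._sequences(X), self.properties).to_numpy()

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.properties, dtype=object)
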