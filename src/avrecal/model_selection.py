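"""Candidate-model comparison with AIC, AICc and Akaike weights.

Each candidate is a set of sequence properties fitted by the
weighted-sum model over the 32 sequence-type equations.  Information
criteria are computed from the residual sum of squares,

    AIC  = n · ln(RSS / n) + 2K
    AICc = AIC + 2K(K + 1) / (n − K − 1)

with n = 32 (the number of per-type equations) and K the number of
properties in the candidate.  Akaike weights normalize
``exp(−Δ/2)`` over the candidates, where Δ is each AICc minus the
best (smallest) AICc; they read as the relative probability that a
candidate is the best description of the shifts.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import weighted_model

#: The seven canonical candidate property sets, in reporting order.
DEFAULT_CANDIDATES: tuple[tuple[str, ...], ...] = (
    ("SQ1", "SQ2", "SQ3", "SQ4", "SQ5"),
    ("SQ1", "SQ2", "SQ3", "SQ4", "SQ5", "D"),
    ("SQ1", "SQ2", "SQ3", "SQ4", "SQ5", "MaxD"),
    ("SQ1", "SQ2", "SQ3", "SQ4", "SQ5", "D", "MaxD"),
    ("SQ5", "D"),
    ("SQ5", "MaxD"),
    ("SQ5", "D", "MaxD"),
)

#: Published AICc values of the seven candidates for the original
#: eleven-subject experiment, reused as reference inputs when checking
#: the Akaike-weight arithmetic without raw data.
REFERENCE_AICC: dict[tuple[str, ...], float] = {
    DEFAULT_CANDIDATES[0]: -79.320,
    DEFAULT_CANDIDATES[1]: -72.27,
    DEFAULT_CANDIDATES[2]: -71.902,
    DEFAULT_CANDIDATES[3]: -49.438,
    DEFAULT_CANDIDATES[4]: -82.364,
    DEFAULT_CANDIDATES[5]: -47.673,
    DEFAULT_CANDIDATES[6]: -79.926,
}


class PerfectFitError(ValueError):
    """RSS is zero: AIC diverges and the benchmark is degenerate."""


def aic(rss: float, n: int, k: int) -> float:
    """Akaike Information Criterion from a residual sum of squares."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("K must be >= 0")
    if rss == 0:
        raise PerfectFitError("RSS is 0: AIC diverges (perfect fit)")
    if rss < 0:
        raise ValueError("RSS must be positive")
    return n * math.log(rss / n) + 2 * k


def aicc(aic_value: float, n: int, k: int) -> float:
    """Small-sample corrected AIC."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, K={k} (need n > K + 1)")
    return aic_value + 2 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Normalized evidence weights ``exp(−Δ/2) / Σ exp(−Δ/2)``.

    Invariant to adding a constant to all inputs; sums to 1.
    """
    values = np.asarray(list(aicc_values), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one AICc value")
    if not np.all(np.isfinite(values)):
        raise ValueError("AICc values must be finite")
    delta = values - values.min()
    rel = np.exp(-0.5 * delta)
    return rel / rel.sum()


def compare_models(
    shifts: pd.DataFrame | pd.Series,
    candidates: Sequence[Sequence[str]] = DEFAULT_CANDIDATES,
    n: int | None = None,
    rss_tol: float = 1e-10,
) -> pd.DataFrame:
    """Fit every candidate property set and rank them by Akaike weight.

    ``shifts`` is the per-type shift vector; ``n`` defaults to its
    length (32 for the full type system).  Candidates containing
    collinear properties (e.g. ``SQ1…SQ5`` together with ``D``) are
    fitted by minimum-norm least squares — their RSS, which is all the
    information criteria need, is unaffected by the non-uniqueness and
    K still counts the named properties.  A candidate fitting the
    shifts perfectly (RSS ≈ 0) signals a degenerate benchmark and
    raises :class:`PerfectFitError`.
    """
    candidates = [tuple(c) for c in candidates]
    if not candidates:
        raise ValueError("need at least one candidate property set")
    sh = shifts["mean_shift"] if isinstance(shifts, pd.DataFrame) else shifts
    n_eq = len(sh) if n is None else int(n)

    rows = []
    for names in candidates:
        fit = weighted_model.fit_properties(sh, names, allow_rank_deficient=True)
        if fit.rss <= rss_tol:
            raise PerfectFitError(
                f"candidate {names} fits the shift vector perfectly "
                "(RSS ≈ 0); information criteria are undefined"
            )
        k = len(names)
        aic_val = aic(fit.rss, n_eq, k)
        rows.append(
            {
                "properties": ", ".join(names),
                "K": k,
                "weights": fit.weights,
                "RSS": fit.rss,
                "r2_pearson": fit.r2_pearson,
                "r2_spearman": fit.r2_spearman,
                "AIC": aic_val,
                "AICc": aicc(aic_val, n_eq, k),
            }
        )
    table = pd.DataFrame(rows)
    table["delta"] = table["AICc"] - table["AICc"].min()
    table["AICW"] = akaike_weights(table["AICc"].to_numpy())
    table["selected"] = table["AICW"] == table["AICW"].max()
    return table
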