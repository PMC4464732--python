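"""Auditory-shift statistics.

The central quantity is the *auditory shift* of a probe trial:
``response − stimulus position``, sign-corrected per mirror group so
that positive values point toward the visual stimulus of discrepant
trials.  This module aggregates shifts by sequence type (the 32-entry
shift vector fed to the weighted-sum model), by sequence position, and
by time block, and recomputes the descriptive statistics used to
screen sequence properties.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .experiment_design import GROUP_LIGHT_LEFT, GROUPS, SequenceType
from .sequence_features import PROPERTY_NAMES, property_matrix


def compute_shift(auditory_pos, auditory_resp, group):
    """Mirror-corrected auditory shift in degrees.

    Raw shift is ``resp − pos``; for the group whose light sat to the
    left of the sound the sign is flipped, so positive always means
    "toward the light".
    """
    pos = np.asarray(auditory_pos, dtype=float)
    resp = np.asarray(auditory_resp, dtype=float)
    if np.any(np.isnan(pos)) or np.any(np.isnan(resp)):
        raise ValueError("auditory position/response missing")
    if isinstance(group, str):
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        sign = -1.0 if group == GROUP_LIGHT_LEFT else 1.0
    else:
        g = np.asarray(group)
        bad = set(np.unique(g)) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group value(s): {sorted(bad)}")
        sign = np.where(g == GROUP_LIGHT_LEFT, -1.0, 1.0)
    out = (resp - pos) * sign
    return float(out) if np.isscalar(auditory_pos) else out


def _probe_trials(table: pd.DataFrame) -> pd.DataFrame:
    probes = table[table["modality"] == "A"].copy()
    if probes.empty:
        raise ValueError("table contains no auditory probe trials")
    if probes["auditory_resp"].isna().any():
        raise ValueError("auditory probe trials are missing responses")
    probes["shift"] = compute_shift(
        probes["auditory_pos"].to_numpy(),
        probes["auditory_resp"].to_numpy(),
        probes["group"].to_numpy(),
    )
    return probes


def _sequence_length(table: pd.DataFrame) -> int:
    av = table[table["modality"] == "AV"]
    return int(av["trial_index"].max()) if len(av) else 5


def shifts_by_sequence_type(
    table: pd.DataFrame, per_subject: bool = False
) -> pd.DataFrame:
    """Mean shift of the auditory probe per preceding sequence type.

    Pools subjects and stimulus areas (the default analysis).  With
    ``per_subject=True`` returns a subject × sequence-type table of
    means instead.  Every sequence type must be observed.
    """
    probes = _probe_trials(table)
    n_types = 2 ** _sequence_length(table)
    missing = sorted(set(range(n_types)) - set(probes["sequence_id"].astype(int)))
    if missing:
        raise ValueError(f"no observations for sequence type(s): {missing}")
    if per_subject:
        return probes.pivot_table(
            index="subject_id", columns="sequence_id", values="shift", aggfunc="mean"
        )
    grouped = probes.groupby(probes["sequence_id"].astype(int))["shift"]
    out = pd.DataFrame({"mean_shift": grouped.mean(), "n": grouped.size()})
    out.index.name = "sequence_id"
    return out


def conditional_shift_by_position(table: pd.DataFrame) -> pd.DataFrame:
    """Mean probe shift conditioned on each sequence trial's type.

    Row k reports the mean shift over all probes whose preceding
    sequence had trial k discrepant, and over those where it matched.
    """
    probes = _probe_trials(table)
    seq_len = _sequence_length(table)
    seq_ids = probes["sequence_id"].to_numpy().astype(int)
    shifts = probes["shift"].to_numpy()
    rows = {}
    for k in range(1, seq_len + 1):
        bit = (seq_ids >> (seq_len - k)) & 1
        if not bit.any() or bit.all():
            raise ValueError(f"position {k} has an empty matching/discrepant cell")
        rows[k] = {
            "discrepant": shifts[bit == 1].mean(),
            "matching": shifts[bit == 0].mean(),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "position"
    return out


def single_discrepant_summary(table: pd.DataFrame) -> pd.Series:
    """Mean probe shift after sequences with exactly one discrepant trial."""
    probes = _probe_trials(table)
    seq_len = _sequence_length(table)
    seq_ids = probes["sequence_id"].to_numpy().astype(int)
    shifts = probes["shift"].to_numpy()
    means = {}
    for k in range(1, seq_len + 1):
        target = 1 << (seq_len - k)
        sel = seq_ids == target
        if not sel.any():
            raise ValueError(f"no sequences with the single discrepant trial at {k}")
        means[k] = shifts[sel].mean()
    out = pd.Series(means, name="mean_shift")
    out.index.name = "position"
    return out


class AnovaResult(NamedTuple):
    block_means: pd.Series
    F: float
    p: float


def block_time_course(table: pd.DataFrame, n_blocks: int = 4) -> AnovaResult:
    """Probe shifts grouped into contiguous time blocks, with one-way ANOVA.

    Each subject's probe trials, in presentation order, are split into
    ``n_blocks`` equal contiguous blocks (e.g. 288 probes → 4 blocks of
    72); blocks pool subjects.  Tests whether the aftereffect drifts
    over the session.
    """
    if n_blocks < 2:
        raise ValueError("ANOVA needs at least 2 blocks")
    probes = _probe_trials(table)
    block_values: dict[int, list[np.ndarray]] = {b: [] for b in range(n_blocks)}
    for _, sub in probes.groupby("subject_id"):
        shifts = sub.sort_values("sequence_index")["shift"].to_numpy()
        if len(shifts) % n_blocks:
            raise ValueError(
                f"{len(shifts)} probe trials not divisible into {n_blocks} blocks"
            )
        for b, chunk in enumerate(np.split(shifts, n_blocks)):
            block_values[b].append(chunk)
    pooled = [np.concatenate(block_values[b]) for b in range(n_blocks)]
    f, p = stats.f_oneway(*pooled)
    means = pd.Series(
        {b + 1: blk.mean() for b, blk in enumerate(pooled)}, name="mean_shift"
    )
    means.index.name = "block"
    return AnovaResult(means, float(f), float(p))


class TTestResult(NamedTuple):
    t: float
    p: float
    df: int


def one_sample_t(mean: float, sd: float, n: int) -> TTestResult:
    """Two-tailed one-sample t test against zero from summary statistics.

    ``t = mean / (sd / sqrt(n))`` with ``n − 1`` degrees of freedom;
    lets printed condition summaries (mean, SD, n) be re-tested without
    raw data.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    t = mean / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(p), df)


def property_shift_correlations(
    shifts: pd.DataFrame | pd.Series,
    names: Sequence[str] = PROPERTY_NAMES,
    sequence_length: int | None = None,
) -> pd.DataFrame:
    """Pearson screen of each sequence property against the shift vector.

    ``shifts`` is the per-type output of :func:`shifts_by_sequence_type`
    (or a Series indexed by sequence id).  Correlations are computed
    over the sequence-type means.  Properties with zero variance over
    the supplied types are flagged undefined (r, p = NaN).
    """
    sh = shifts["mean_shift"] if isinstance(shifts, pd.DataFrame) else shifts
    ids = [int(i) for i in sh.index]
    if not ids:
        raise ValueError("empty shift vector")
    # infer the sequence length from the largest type id unless given
    seq_len = sequence_length or max(5, max(ids).bit_length())
    seqs = [SequenceType.from_id(i, seq_len) for i in ids]
    props = property_matrix(seqs, names)
    y = sh.to_numpy(dtype=float)
    rows = {}
    for name in names:
        x = props[name].to_numpy()
        if np.ptp(x) == 0:
            rows[name] = {"r": np.nan, "p": np.nan, "undefined": True}
        else:
            r, p = stats.pearsonr(x, y)
            rows[name] = {"r": float(r), "p": float(p), "undefined": False}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "property"
    return out


def colocalization_rate(table: pd.DataFrame, trial_filter: str | None = None) -> float:
    """Fraction of AV trials whose two estimates landed on the same LED.

    ``trial_filter`` restricts to ``"discrepant"`` or ``"matching"``
    trials; equality is exact on the quantized response grid.
    """
    av = table[table["modality"] == "AV"]
    av = av[av["visual_resp"].notna() & av["auditory_resp"].notna()]
    if trial_filter == "discrepant":
        av = av[av["visual_pos"] != av["auditory_pos"]]
    elif trial_filter == "matching":
        av = av[av["visual_pos"] == av["auditory_pos"]]
    elif trial_filter is not None:
        raise ValueError(f"unknown trial_filter {trial_filter!r}")
    if av.empty:
        raise ValueError("no AV trials with both responses in selection")
    return float((av["visual_resp"] == av["auditory_resp"]).mean())


def condition_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Across-subject localization summary per condition.

    For each condition (unimodal, AV discrepant, AV matching) the
    per-subject mean mirror-corrected localization error is computed
    for each modality, then summarized as mean and SD over subjects —
    the quantities a summary-level one-sample t test consumes.
    """
    rows = {}
    sign = pd.Series(
        np.where(table["group"] == GROUP_LIGHT_LEFT, -1.0, 1.0), index=table.index
    )
    vis_err = (table["visual_resp"] - table["visual_pos"]) * sign
    aud_err = (table["auditory_resp"] - table["auditory_pos"]) * sign
    av = table["modality"] == "AV"
    discrepant = av & (table["visual_pos"] != table["auditory_pos"])
    matching = av & (table["visual_pos"] == table["auditory_pos"])
    unimodal_v = table["modality"] == "V"
    unimodal_a = table["modality"] == "A"

    def _across_subjects(errors: pd.Series, mask: pd.Series) -> tuple[float, float]:
        per_subj = errors[mask].groupby(table.loc[mask, "subject_id"]).mean()
        return float(per_subj.mean()), float(per_subj.std(ddof=1))

    for label, v_mask, a_mask in [
        ("unimodal", unimodal_v, unimodal_a),
        ("discrepant", discrepant, discrepant),
        ("matching", matching, matching),
    ]:
        mv, sv = _across_subjects(vis_err, v_mask)
        ma, sa = _across_subjects(aud_err, a_mask)
        rows[label] = {
            "mean_visual": mv,
            "sd_visual": sv,
            "mean_auditory": ma,
            "sd_auditory": sa,
            "n_subjects": table.loc[v_mask | a_mask, "subject_id"].nunique(),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "condition"
    return out
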