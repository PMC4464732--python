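"""A generative observer for the audiovisual localization task.

The observer reproduces the statistical structure of human responses in
this paradigm:

* visual localization is unbiased with small Gaussian noise;
* in discrepant AV trials the auditory response is pulled toward the
  light by a fixed fraction of the discrepancy (immediate ventriloquism
  / cross-modal bias);
* the auditory-only probe after each sequence is shifted toward the
  light side by a weighted sum of sequence properties — by default the
  last-trial indicator SQ5 (weight 0.88°) and the discrepant proportion
  D (weight 3.42°), the selected aftereffect model;
* responses are quantized to the 1° LED grid of the response display.

All responses are i.i.d. Gaussian around their mean; the observer has
no memory beyond the current sequence and no time trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiment_design import (
    GROUP_LIGHT_LEFT,
    GROUP_LIGHT_RIGHT,
    GROUPS,
    SequenceType,
)


@dataclass(frozen=True)
class ObserverParams:
    """Tunable parameters of the synthetic observer.

    sigma_V, sigma_A
        Response SDs in degrees for visual and auditory estimates.
    capture_fraction
        Fraction of the AV discrepancy by which the auditory response
        in an AV trial moves toward the light (0.35 × 12° ≈ 4.2°).
    baseline_shift
        Constant long-term auditory shift toward the light side, in
        degrees (default 0: the aftereffect model carries no intercept).
    w_SQ5, w_D
        Aftereffect weights (degrees) of the last-trial indicator and
        the discrepant proportion.
    quantize
        Round responses to the nearest integer degree (LED grid).
    """

    sigma_V: float = 0.73
    sigma_A: float = 2.5
    capture_fraction: float = 0.35
    baseline_shift: float = 0.0
    w_SQ5: float = 0.88
    w_D: float = 3.42
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.sigma_V < 0 or self.sigma_A < 0:
            raise ValueError("response SDs must be >= 0")
        if not 0.0 <= self.capture_fraction <= 1.0:
            raise ValueError("capture_fraction must be in [0, 1]")


def light_sign(group: str):
    """+1 if the light of discrepant trials is on the subject's right."""
    if isinstance(group, str):
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return 1.0 if group == GROUP_LIGHT_RIGHT else -1.0
    group = np.asarray(group)
    bad = set(np.unique(group)) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group value(s): {sorted(bad)}")
    return np.where(group == GROUP_LIGHT_RIGHT, 1.0, -1.0)


def _finish(x, quantize: bool):
    return np.round(x) if quantize else x


def simulate_visual_response(
    visual_pos, params: ObserverParams, rng: np.random.Generator
):
    """Unbiased visual estimate: position + N(0, sigma_V), quantized."""
    pos = np.asarray(visual_pos, dtype=float)
    resp = pos + rng.normal(0.0, params.sigma_V, size=pos.shape)
    out = _finish(resp, params.quantize)
    return float(out) if np.isscalar(visual_pos) else out


def simulate_av_responses(
    visual_pos,
    auditory_pos,
    params: ObserverParams,
    group: str,
    rng: np.random.Generator,
):
    """Visual and auditory estimates of one AV trial.

    The auditory mean is attracted toward the light by
    ``capture_fraction`` of the discrepancy, plus any constant
    baseline shift toward the light side.
    """
    vis = np.asarray(visual_pos, dtype=float)
    aud = np.asarray(auditory_pos, dtype=float)
    s = light_sign(group)
    visual_resp = vis + rng.normal(0.0, params.sigma_V, size=vis.shape)
    mean = aud + params.capture_fraction * (vis - aud) + s * params.baseline_shift
    auditory_resp = mean + rng.normal(0.0, params.sigma_A, size=aud.shape)
    visual_resp = _finish(visual_resp, params.quantize)
    auditory_resp = _finish(auditory_resp, params.quantize)
    if np.isscalar(visual_pos):
        return float(visual_resp), float(auditory_resp)
    return visual_resp, auditory_resp


def simulate_auditory_after_sequence(
    auditory_pos,
    sequence,
    params: ObserverParams,
    group: str,
    rng: np.random.Generator,
):
    """Auditory probe response after one AV sequence.

    The mean response is displaced toward the light side by the
    aftereffect predictor ``baseline + w_SQ5·SQ_last + w_D·D`` of the
    given sequence.
    """
    flags = sequence.flags if isinstance(sequence, SequenceType) else tuple(sequence)
    d = sum(flags) / len(flags)
    sq_last = flags[-1]
    s = light_sign(group)
    shift = s * (params.baseline_shift + params.w_SQ5 * sq_last + params.w_D * d)
    resp = float(auditory_pos) + shift + rng.normal(0.0, params.sigma_A)
    return float(_finish(resp, params.quantize))


def simulate_experiment(
    schedule: pd.DataFrame,
    params: ObserverParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill the response columns of a schedule, vectorized over trials.

    Raises if the schedule already carries responses; the input is not
    modified.  Deterministic for a fixed generator state.
    """
    if rng is None:
        rng = np.random.default_rng()
    if schedule["visual_resp"].notna().any() or schedule["auditory_resp"].notna().any():
        raise ValueError("schedule already contains responses")
    table = schedule.copy()
    s = light_sign(table["group"].to_numpy())

    vis_pos = table["visual_pos"].to_numpy()
    aud_pos = table["auditory_pos"].to_numpy()
    modality = table["modality"].to_numpy()

    # Visual estimates: every trial showing a light (AV and V trials).
    vis_mask = ~np.isnan(vis_pos)
    visual_resp = np.full(len(table), np.nan)
    visual_resp[vis_mask] = vis_pos[vis_mask] + rng.normal(
        0.0, params.sigma_V, size=vis_mask.sum()
    )

    auditory_resp = np.full(len(table), np.nan)

    # AV trials: auditory estimate attracted toward the light.
    av = modality == "AV"
    mean_av = (
        aud_pos[av]
        + params.capture_fraction * (vis_pos[av] - aud_pos[av])
        + s[av] * params.baseline_shift
    )
    auditory_resp[av] = mean_av + rng.normal(0.0, params.sigma_A, size=av.sum())

    # Auditory probes: aftereffect of the preceding sequence.
    a = modality == "A"
    seq_len = int(table.loc[av, "trial_index"].max())
    seq_ids = table["sequence_id"].to_numpy()[a].astype(int)
    flags = (seq_ids[:, None] >> (seq_len - 1 - np.arange(seq_len))) & 1
    d = flags.mean(axis=1)
    sq_last = flags[:, -1]
    shift = s[a] * (params.baseline_shift + params.w_SQ5 * sq_last + params.w_D * d)
    auditory_resp[a] = (
        aud_pos[a] + shift + rng.normal(0.0, params.sigma_A, size=a.sum())
    )

    if params.quantize:
        visual_resp = np.round(visual_resp)
        auditory_resp = np.round(auditory_resp)
    table["visual_resp"] = visual_resp
    table["auditory_resp"] = auditory_resp
    return table
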