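"""Trial-schedule construction for an audiovisual recalibration experiment.

The paradigm probes how recent multisensory experience recalibrates
auditory space.  Stimuli are presented in *sequences* of eight trials:
five audiovisual (AV) trials, each independently *matching* (light and
sound co-located) or *discrepant* (sound offset by a fixed azimuth),
followed by one auditory-only probe trial and two visual-only trials.
The binary pattern of matching/discrepant assignments over the five AV
trials is the *sequence type*; with five trials there are 2**5 = 32
types, and each subject sees every type an equal number of times in
randomized order.

Counterbalancing is by *mirror group*: for half the subjects the sound
in discrepant trials sits to the left of the light, for the other half
to the right.  Azimuths are in degrees, positive to the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Group whose light is to the right of the sound in discrepant trials.
GROUP_LIGHT_RIGHT = "light_right_of_sound"
#: Group whose light is to the left of the sound in discrepant trials.
GROUP_LIGHT_LEFT = "light_left_of_sound"
GROUPS = (GROUP_LIGHT_RIGHT, GROUP_LIGHT_LEFT)

#: Azimuth intervals of the three stimulus areas (degrees).
DEFAULT_AREAS: tuple[tuple[float, float], ...] = (
    (-5.0, 5.0),
    (-20.0, -10.0),
    (10.0, 20.0),
)

#: Column order of the tidy trial-table CSV dialect.
TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "sequence_index",
    "sequence_id",
    "trial_index",
    "modality",
    "area",
    "visual_pos",
    "auditory_pos",
    "visual_resp",
    "auditory_resp",
]


@dataclass(frozen=True)
class SequenceType:
    """Binary pattern of one AV sequence; 1 = discrepant, 0 = matching.

    The integer ``id`` encodes the flags with trial 1 as the most
    significant bit, so ``(1, 0, 0, 0, 0)`` has id 16 and
    ``(0, 0, 0, 0, 1)`` has id 1.
    """

    flags: tuple[int, ...]

    def __post_init__(self) -> None:
        flags = tuple(int(f) for f in self.flags)
        if len(flags) == 0:
            raise ValueError("sequence must contain at least one trial")
        if any(f not in (0, 1) for f in flags):
            raise ValueError(f"flags must be binary, got {self.flags!r}")
        object.__setattr__(self, "flags", flags)

    @property
    def id(self) -> int:
        out = 0
        for f in self.flags:
            out = (out << 1) | f
        return out

    @classmethod
    def from_id(cls, seq_id: int, length: int = 5) -> "SequenceType":
        if not 0 <= seq_id < 2**length:
            raise ValueError(f"id {seq_id} out of range for length {length}")
        return cls(tuple((seq_id >> (length - 1 - i)) & 1 for i in range(length)))

    def __len__(self) -> int:
        return len(self.flags)

    def __iter__(self):
        return iter(self.flags)


def enumerate_sequence_types(length: int = 5) -> list[SequenceType]:
    """All binary sequence types of the given length, sorted by id."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return [SequenceType.from_id(i, length) for i in range(2**length)]


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the stimulus schedule.

    discrepancy_deg
        Azimuthal offset between sound and light in discrepant AV
        trials (degrees; the apparatus uses 12).
    reps_per_type
        Repetitions of each of the 32 sequence types per subject.
    areas
        Azimuth intervals from which base positions are drawn; all
        eight trials of a sequence stay within one area.
    visual_limit_deg / auditory_limit_deg
        Hard apparatus limits on stimulus azimuth.
    seed
        Seed for schedule randomization when no generator is supplied.
    """

    discrepancy_deg: float = 12.0
    reps_per_type: int = 9
    areas: tuple[tuple[float, float], ...] = DEFAULT_AREAS
    visual_limit_deg: float = 20.0
    auditory_limit_deg: float = 32.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.discrepancy_deg <= 0:
            raise ValueError("discrepancy_deg must be > 0")
        if self.reps_per_type < 1:
            raise ValueError("reps_per_type must be >= 1")
        if len(self.areas) < 1:
            raise ValueError("at least one stimulus area is required")
        for lo, hi in self.areas:
            if hi < lo:
                raise ValueError(f"empty area interval ({lo}, {hi})")
            if max(abs(lo), abs(hi)) > self.visual_limit_deg:
                raise ValueError(
                    f"area ({lo}, {hi}) exceeds visual limit ±{self.visual_limit_deg}"
                )
            if max(abs(lo), abs(hi)) + self.discrepancy_deg > self.auditory_limit_deg:
                raise ValueError(
                    f"area ({lo}, {hi}) plus discrepancy {self.discrepancy_deg} "
                    f"exceeds auditory limit ±{self.auditory_limit_deg}"
                )


def area_label(area: tuple[float, float]) -> str:
    """Human-readable label of an azimuth interval."""
    lo, hi = area
    if lo <= 0.0 <= hi:
        return "center"
    return "left" if hi < 0 else "right"


def sample_base_position(
    area: tuple[float, float], rng: np.random.Generator
) -> float:
    """Uniform draw of a stimulus base position within an azimuth interval."""
    lo, hi = area
    if hi < lo:
        raise ValueError(f"empty area interval ({lo}, {hi})")
    if hi == lo:
        return float(lo)
    return float(rng.uniform(lo, hi))


def apply_discrepancy(
    base: float,
    flag: int,
    group: str,
    discrepancy_deg: float = 12.0,
    auditory_limit_deg: float = 32.0,
) -> tuple[float, float]:
    """Light/sound positions of one AV trial.

    Matching trials co-locate both stimuli at ``base``.  In discrepant
    trials the light stays at ``base`` and the sound is displaced by
    ``discrepancy_deg`` away from the light's side: for the
    light-left-of-sound group the sound goes to ``base + discrepancy``
    (positive azimuth = right), for the other group to
    ``base - discrepancy``.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if not flag:
        return float(base), float(base)
    offset = discrepancy_deg if group == GROUP_LIGHT_LEFT else -discrepancy_deg
    auditory = float(base) + offset
    if abs(auditory) > auditory_limit_deg + 1e-9:
        raise ValueError(
            f"auditory position {auditory}° outside ±{auditory_limit_deg}°"
        )
    return float(base), auditory


def assign_groups(n_subjects: int) -> list[str]:
    """Split subjects between mirror groups; odd counts favor light-right."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    n_right = (n_subjects + 1) // 2
    return [GROUP_LIGHT_RIGHT] * n_right + [GROUP_LIGHT_LEFT] * (n_subjects - n_right)


def build_schedule(
    config: DesignConfig,
    n_subjects: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Full randomized trial schedule, responses left empty.

    Per subject: ``32 * reps_per_type`` sequences in shuffled order,
    each assigned one stimulus area uniformly at random; eight trials
    per sequence (five AV, one A, two V) with base positions drawn
    uniformly within the sequence's area, independently per trial.

    Returns a tidy trial table (one row per trial) in the
    :data:`TRIAL_COLUMNS` dialect, with ``visual_resp`` and
    ``auditory_resp`` set to NaN.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    groups = assign_groups(n_subjects)
    seq_len = 5
    n_types = 2**seq_len
    n_seq = n_types * config.reps_per_type
    n_trials = 8

    area_lo = np.array([a[0] for a in config.areas])
    area_hi = np.array([a[1] for a in config.areas])
    labels = np.array([area_label(a) for a in config.areas])
    modality = np.array(["AV"] * 5 + ["A"] + ["V"] * 2)

    chunks: list[dict[str, np.ndarray]] = []
    for subj, group in enumerate(groups, start=1):
        seq_ids = np.repeat(np.arange(n_types), config.reps_per_type)
        rng.shuffle(seq_ids)
        area_idx = rng.integers(0, len(config.areas), size=n_seq)
        base = rng.uniform(
            area_lo[area_idx][:, None], area_hi[area_idx][:, None], (n_seq, n_trials)
        )
        flags = (seq_ids[:, None] >> (seq_len - 1 - np.arange(seq_len))) & 1
        offset = (
            config.discrepancy_deg
            if group == GROUP_LIGHT_LEFT
            else -config.discrepancy_deg
        )

        vis = np.full((n_seq, n_trials), np.nan)
        aud = np.full((n_seq, n_trials), np.nan)
        vis[:, :5] = base[:, :5]
        aud[:, :5] = base[:, :5] + flags * offset
        aud[:, 5] = base[:, 5]
        vis[:, 6:8] = base[:, 6:8]

        chunks.append(
            {
                "subject_id": np.full(n_seq * n_trials, subj),
                "group": np.full(n_seq * n_trials, group, dtype=object),
                "sequence_index": np.repeat(np.arange(1, n_seq + 1), n_trials),
                "sequence_id": np.repeat(seq_ids, n_trials),
                "trial_index": np.tile(np.arange(1, n_trials + 1), n_seq),
                "modality": np.tile(modality, n_seq),
                "area": np.repeat(labels[area_idx], n_trials),
                "visual_pos": vis.ravel(),
                "auditory_pos": aud.ravel(),
            }
        )

    table = pd.DataFrame(
        {col: np.concatenate([c[col] for c in chunks]) for col in chunks[0]}
    )
    table["visual_resp"] = np.nan
    table["auditory_resp"] = np.nan
    return table[TRIAL_COLUMNS]


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV; missing azimuths become empty fields."""
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial-table CSV, checking the dialect's columns."""
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing column(s): {', '.join(missing)}")
    bad = set(table["group"].dropna().unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group value(s): {sorted(bad)}")
    return table[TRIAL_COLUMNS]
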