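"""Core in-memory containers for the pipeline.

An :class:`EpochSet` holds epoched multi-channel EEG voltages as a single
``channels x samples x trials`` array with one shared time axis, addressed by
10/20 channel label.  Trial-level design and behavior live in a plain pandas
``DataFrame`` (the "trial table") whose schema is validated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "RETROCUE_LEVELS",
    "PROBE_LEVELS",
    "RESPONSE_LEVELS",
    "SIDE_LEVELS",
    "CONDITIONS",
    "CUE_TOKENS",
    "TRIAL_COLUMNS",
    "condition_of",
    "validate_trial_table",
]

#: Retro-cue categories.  The lateral item stays relevant in the two
#: target-lateral cues, becomes irrelevant after the distractor-lateral cue,
#: and both items stay relevant after the neutral cue.
RETROCUE_LEVELS = (
    "target_lateral_left",
    "target_lateral_right",
    "distractor_lateral",
    "neutral",
)

#: Spoken-syllable tokens of the four retro-cues ("li", "re", "mi", "bei").
CUE_TOKENS = {
    "target_lateral_left": "li",
    "target_lateral_right": "re",
    "distractor_lateral": "mi",
    "neutral": "bei",
}

PROBE_LEVELS = ("cued", "noncued", "new")
RESPONSE_LEVELS = ("yes", "no", "none")
SIDE_LEVELS = ("left", "right")

#: Analysis conditions obtained by collapsing the two target-lateral cues.
CONDITIONS = ("target_lateral", "distractor_lateral", "neutral")

TRIAL_COLUMNS = (
    "trial_id",
    "block",
    "precue_side",
    "retrocue",
    "probe",
    "response",
    "rt_ms",
    "correct",
    "rejected",
)


def condition_of(retrocue: str) -> str:
    """Collapse a retro-cue level onto its analysis condition."""
    if retrocue in ("target_lateral_left", "target_lateral_right"):
        return "target_lateral"
    if retrocue in ("distractor_lateral", "neutral"):
        return retrocue
    raise ValueError(f"unknown retro-cue level: {retrocue!r}")


class TrialTableError(ValueError):
    """Raised when a trial table violates the design schema."""


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the design schema.

    Checks column presence, categorical levels, the design constraint that
    neutral retro-cue trials cannot carry a non-cued probe (after a neutral
    cue both memorized items remain relevant, so no item is "non-cued"), and
    that a response time is present exactly when a response was given.

    Returns the table unchanged; raises :class:`TrialTableError` otherwise.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialTableError(f"trial table missing columns: {missing}")
    if len(trials) == 0:
        return trials
    for col, levels in (
        ("precue_side", SIDE_LEVELS),
        ("retrocue", RETROCUE_LEVELS),
        ("probe", PROBE_LEVELS),
        ("response", RESPONSE_LEVELS),
    ):
        bad = set(trials[col].unique()) - set(levels)
        if bad:
            raise TrialTableError(f"invalid {col} values: {sorted(bad)}")
    neutral_noncued = (trials["retrocue"] == "neutral") & (trials["probe"] == "noncued")
    if neutral_noncued.any():
        raise TrialTableError(
            "neutral retro-cue trials cannot have a non-cued probe "
            f"(rows {trials.index[neutral_noncued].tolist()})"
        )
    has_resp = trials["response"] != "none"
    rt_present = trials["rt_ms"].notna()
    if (has_resp != rt_present).any():
        raise TrialTableError("rt_ms must be present exactly when response != 'none'")
    if trials["trial_id"].duplicated().any():
        raise TrialTableError("duplicate trial_id values")
    return trials


@dataclass
class EpochSet:
    """Epoched multi-channel EEG voltages on one shared time axis.

    Parameters
    ----------
    data
        Voltages in microvolts, shaped ``(n_channels, n_samples, n_trials)``.
        Stored as little-endian float32 (the on-disk dtype).
    srate
        Sampling rate in Hz.
    t0_ms
        Epoch time of the first sample, in ms relative to pre-cue onset.
    channels
        Ordered, unique 10/20 channel labels, one per data row.
    """

    data: np.ndarray
    srate: float
    t0_ms: float
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (channels x samples x trials)")
        self.channels = list(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.srate <= 0:
            raise ValueError("srate must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to pre-cue onset."""
        return self.t0_ms + 1000.0 * np.arange(self.n_samples) / self.srate

    # -- addressing by label --------------------------------------------
    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in EpochSet") from None

    def get_channels(self, labels: list[str]) -> np.ndarray:
        """Return a ``(len(labels), n_samples, n_trials)`` view-copy."""
        idx = [self.channel_index(lb) for lb in labels]
        return self.data[idx]

    def select_trials(self, keep: np.ndarray) -> "EpochSet":
        """New EpochSet restricted to the boolean/index trial selection."""
        return replace(self, data=self.data[:, :, keep], channels=list(self.channels))

    def drop_channels(self, labels: list[str]) -> "EpochSet":
        keep = [i for i, lb in enumerate(self.channels) if lb not in set(labels)]
        return replace(
            self,
            data=self.data[keep],
            channels=[self.channels[i] for i in keep],
        )

    def sorted_channels(self) -> "EpochSet":
        """Canonical alphabetical channel order (the on-disk convention)."""
        order = np.argsort(np.asarray(self.channels, dtype=object))
        return replace(
            self,
            data=self.data[order],
            channels=[self.channels[i] for i in order],
        )
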