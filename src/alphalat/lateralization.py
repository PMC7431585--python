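"""Hemispheric assignment and the Alpha Lateralization Index (ALI).

The ALI contrasts spectral power between the hemisphere ipsilateral and the
hemisphere contralateral to the lateralized working-memory item:

    ALI = (ipsilateral power - contralateral power)
          / (ipsilateral power + contralateral power)

Positive values indicate a *contralateral decrease* of alpha power (the
signature of attentional selection of the lateral item), negative values a
contralateral increase (suppression of a lateral distractor).  The
lateralized item is the one retained after the pre-cue: the target in
target-lateral and neutral trials, the distractor in distractor-lateral
trials — in every case it sits on ``precue_side``.

Power is averaged across the posterior electrode cluster per hemisphere and
across a condition's trials *before* the ratio is formed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DEFAULT_CLUSTER_PAIRS
from .containers import condition_of
from .timefreq import TFPower

__all__ = [
    "lateral_side",
    "ipsi_contra_power",
    "compute_ali",
    "window_mean",
    "ali_map",
]


def lateral_side(trial: pd.Series) -> str:
    """Side of the lateralized item for a trial (always the pre-cued side)."""
    side = trial["precue_side"]
    if side not in ("left", "right"):
        raise ValueError(f"invalid precue_side {side!r}")
    return side


def ipsi_contra_power(
    tf: TFPower,
    trials: pd.DataFrame,
    pairs=DEFAULT_CLUSTER_PAIRS,
    condition: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged ipsi- and contralateral cluster power for a condition.

    Per trial, the left-hemisphere member of each electrode pair counts as
    ipsilateral when the lateralized item is on the left (and conversely);
    power is averaged over the cluster electrodes within hemisphere, then
    across the condition's retained trials.

    Parameters
    ----------
    tf
        Per-trial power whose trial axis aligns row-for-row with ``trials``.
    condition
        One of ``target_lateral``, ``distractor_lateral``, ``neutral``, or
        None to pool all retained trials.

    Returns
    -------
    (ipsi, contra) : two ``(n_freqs, n_times)`` arrays.
    """
    if len(trials) != tf.power.shape[-1]:
        raise ValueError(
            f"{len(trials)} trial rows for {tf.power.shape[-1]} power trials"
        )
    left_idx = [tf.channel_index(lb) for lb, _ in pairs]
    right_idx = [tf.channel_index(rb) for _, rb in pairs]

    mask = ~trials["rejected"].to_numpy(dtype=bool)
    if condition is not None:
        mask &= trials["retrocue"].map(condition_of).to_numpy() == condition
    if not mask.any():
        raise ValueError(f"no retained trials for condition {condition!r}")

    sides = trials["precue_side"].to_numpy()
    left_pow = tf.power[left_idx].mean(axis=0)    # (freq, time, trial)
    right_pow = tf.power[right_idx].mean(axis=0)
    is_left = (sides == "left") & mask
    is_right = (sides == "right") & mask
    n = int(is_left.sum() + is_right.sum())
    ipsi = (left_pow[:, :, is_left].sum(axis=2) + right_pow[:, :, is_right].sum(axis=2)) / n
    contra = (right_pow[:, :, is_left].sum(axis=2) + left_pow[:, :, is_right].sum(axis=2)) / n
    return ipsi, contra


def compute_ali(ipsi: np.ndarray, contra: np.ndarray) -> np.ndarray:
    """Elementwise ALI; defined as 0 where total power is 0."""
    ipsi = np.asarray(ipsi, dtype=float)
    contra = np.asarray(contra, dtype=float)
    if ipsi.shape != contra.shape:
        raise ValueError(f"shape mismatch {ipsi.shape} vs {contra.shape}")
    total = ipsi + contra
    with np.errstate(divide="ignore", invalid="ignore"):
        ali = np.where(total > 0, (ipsi - contra) / np.where(total > 0, total, 1.0), 0.0)
    return ali


def window_mean(
    ali: np.ndarray,
    freqs: np.ndarray,
    times_ms: np.ndarray,
    band_hz: tuple[float, float] = (8.0, 13.0),
    window_ms: tuple[float, float] = (3700.0, 4300.0),
) -> float:
    """Unweighted mean of an ALI map over a closed frequency band x time window.

    ``window_ms`` is in epoch time (700-1,300 ms post retro-cue at defaults).
    """
    fsel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    tsel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("band/window does not intersect the grid")
    return float(ali[np.ix_(fsel, tsel)].mean())


def ali_map(
    tf: TFPower,
    trials: pd.DataFrame,
    condition: str,
    pairs=DEFAULT_CLUSTER_PAIRS,
) -> np.ndarray:
    """Convenience: condition's trial-averaged ipsi/contra power -> ALI map."""
    ipsi, contra = ipsi_contra_power(tf, trials, pairs=pairs, condition=condition)
    return compute_ali(ipsi, contra)
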