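"""Implementable subset of the EEG cleaning chain.

Covers channel rejection by trimmed-normalized kurtosis, average
re-referencing, iterative SD-threshold trial rejection, and integer-factor
downsampling.  Filtering, ICA-based ocular correction and channel
interpolation are deliberately out of scope: data enter this module already
band-limited (synthetic epochs are by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from scipy.stats.mstats import trimmed_std

from .containers import EpochSet

__all__ = [
    "RejectionReport",
    "reject_channels_kurtosis",
    "rereference_average",
    "reject_trials_iterative",
    "downsample",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class RejectionReport:
    """What a rejection step removed and under which thresholds."""

    rejected_channels: list[str] = field(default_factory=list)
    rejected_trials: list[int] = field(default_factory=list)
    iterations: int = 0
    thresholds: dict = field(default_factory=dict)


def reject_channels_kurtosis(
    epochs: EpochSet,
    trim: float = 0.2,
    z_thresh: float = 5.0,
    protected: list[str] | None = None,
) -> tuple[EpochSet, RejectionReport]:
    """Reject channels whose kurtosis is an outlier among channels.

    Each channel's excess kurtosis over its concatenated signal is z-scored
    against the trimmed mean and trimmed SD of the across-channel kurtosis
    distribution (``trim`` is the total trimmed fraction, split between the
    two tails); channels exceeding ``z_thresh`` are removed.  ``protected``
    channels (e.g. anterior lateral sites kept for ocular monitoring) are
    never rejected.
    """
    if not (0 <= trim < 0.5):
        raise ValueError("trim must be in [0, 0.5)")
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    protected = set(protected or [])
    flat = epochs.data.reshape(epochs.n_channels, -1).astype(np.float64)
    k = sp_stats.kurtosis(flat, axis=1, fisher=True, bias=True)
    cut = trim / 2.0
    mu = sp_stats.trim_mean(k, cut)
    sd = float(trimmed_std(k, limits=(cut, cut)))
    z = (k - mu) / sd if sd > 0 else np.zeros_like(k)
    reject = [
        ch
        for ch, zi in zip(epochs.channels, z)
        if zi > z_thresh and ch not in protected
    ]
    if len(reject) == epochs.n_channels:
        raise PipelineError("kurtosis criterion rejected every channel")
    report = RejectionReport(
        rejected_channels=reject,
        thresholds={"trim": trim, "z_thresh": z_thresh},
    )
    return epochs.drop_channels(reject), report


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference to the average of all (retained) channels.

    After the operation the across-channel mean is zero at every sample of
    every trial.  Requires at least two channels.
    """
    if epochs.n_channels < 2:
        raise ValueError("average reference needs >= 2 channels")
    data = epochs.data - epochs.data.mean(axis=0, keepdims=True)
    return EpochSet(data=data, srate=epochs.srate, t0_ms=epochs.t0_ms,
                    channels=list(epochs.channels))


def reject_trials_iterative(
    epochs: EpochSet,
    trials=None,
    z_thresh: float = 5.0,
    abs_limit: float = 1000.0,
    max_frac_per_iter: float = 0.05,
    max_iter: int = 100,
) -> tuple[EpochSet, RejectionReport]:
    """Iteratively reject trials with extreme values.

    Per iteration, a trial is flagged if any channel-sample value lies beyond
    ``z_thresh`` SDs of the across-trial distribution at that channel-sample,
    or beyond ``abs_limit`` microvolts outright.  At most
    ``max_frac_per_iter`` of the remaining trials (the worst offenders) are
    removed per iteration; iteration stops when nothing is flagged.

    ``trials`` may be a trial table aligned with the epoch trial axis; if
    given, a copy with the ``rejected`` column updated is returned in place
    of the trial-id list semantics (ids are positional indices otherwise).
    """
    if z_thresh <= 0 or not (0 < max_frac_per_iter <= 1):
        raise ValueError("invalid thresholds")
    data = epochs.data.astype(np.float64)
    n_tr = epochs.n_trials
    keep = np.ones(n_tr, dtype=bool)
    rejected: list[int] = []
    for it in range(1, max_iter + 1):
        sub = data[:, :, keep]
        mu = sub.mean(axis=2, keepdims=True)
        sd = sub.std(axis=2, ddof=0, keepdims=True)
        sd[sd == 0] = np.inf
        z = np.abs((sub - mu) / sd)
        offense = np.maximum(
            z.max(axis=(0, 1)),
            np.where(np.abs(sub).max(axis=(0, 1)) > abs_limit, np.inf, 0.0),
        )
        flagged = offense > z_thresh
        if not flagged.any():
            return _finalize_trial_rejection(epochs, trials, keep, rejected, it, z_thresh, abs_limit, max_frac_per_iter)
        cap = max(1, int(np.floor(max_frac_per_iter * keep.sum())))
        order = np.argsort(offense)[::-1]
        worst = order[flagged[order]][:cap]
        keep_idx = np.flatnonzero(keep)
        for w in worst:
            rejected.append(int(keep_idx[w]))
            keep[keep_idx[w]] = False
        if keep.sum() == 0:
            raise PipelineError("trial rejection removed every trial")
    raise PipelineError(
        f"trial rejection did not converge in {max_iter} iterations "
        f"(rejected so far: {sorted(rejected)})"
    )


def _finalize_trial_rejection(epochs, trials, keep, rejected, iterations,
                              z_thresh, abs_limit, max_frac):
    report = RejectionReport(
        rejected_trials=sorted(rejected),
        iterations=iterations,
        thresholds={
            "z_thresh": z_thresh,
            "abs_limit": abs_limit,
            "max_frac_per_iter": max_frac,
        },
    )
    out = epochs.select_trials(keep)
    if trials is not None:
        trials = trials.copy()
        col = trials.columns.get_loc("rejected")
        trials.iloc[sorted(rejected), col] = True
        return (out, trials, report)
    return (out, report)


def downsample(epochs: EpochSet, new_srate: float) -> EpochSet:
    """Anti-alias filter and decimate to an integer divisor of the rate."""
    ratio = epochs.srate / new_srate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"{epochs.srate} Hz -> {new_srate} Hz is not an integer decimation"
        )
    q = int(round(ratio))
    if q == 1:
        return epochs
    data = sp_signal.decimate(
        epochs.data.astype(np.float64), q, axis=1, ftype="fir", zero_phase=True
    )
    return EpochSet(data=data, srate=new_srate, t0_ms=epochs.t0_ms,
                    channels=list(epochs.channels))
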