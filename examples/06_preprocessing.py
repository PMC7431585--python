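"""Cleaning steps on epochs with planted artifacts.

Two small demonstrations: a channel of sparse large spikes is caught by the
trimmed-kurtosis criterion, and a trial with a large voltage excursion on a
few channels is caught by the iterative 5-SD / 1000 uV rejection after
average re-referencing.
"""

import numpy as np

from alphalat.containers import EpochSet
from alphalat.preprocess import (
    reject_channels_kurtosis,
    reject_trials_iterative,
    rereference_average,
)

rng = np.random.default_rng(0)


def fresh_epochs():
    return EpochSet(data=rng.normal(0, 10, (32, 500, 40)), srate=500.0,
                    t0_ms=-1000.0, channels=[f"E{i:02d}" for i in range(32)])


# --- channel rejection: one channel carries sparse 500 uV spikes ----------
epochs = fresh_epochs()
epochs.data[7, ::61, :] = 500.0
cleaned, ch_report = reject_channels_kurtosis(epochs, trim=0.2, z_thresh=5.0)
print("rejected channels:", ch_report.rejected_channels,
      f"({cleaned.n_channels} of {epochs.n_channels} kept)")

# --- trial rejection: one trial has a 600 uV excursion on three channels --
epochs = fresh_epochs()
epochs.data[3:6, 200:300, 12] += 600.0
epochs = rereference_average(epochs)
print(f"after average reference, max |channel mean| = "
      f"{np.abs(epochs.data.mean(axis=0)).max():.2e} uV")
cleaned, tr_report = reject_trials_iterative(epochs, z_thresh=5.0,
                                             abs_limit=1000.0,
                                             max_frac_per_iter=0.05)
print(f"rejected trials {tr_report.rejected_trials} in "
      f"{tr_report.iterations} iteration(s); {cleaned.n_trials} trials kept")
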