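"""On-disk formats.

Epochs live in a portable two-file container: ``<name>.dat`` holding the raw
little-endian float32 voltages and a human-readable ``<name>.json`` sidecar
with the sampling rate, epoch origin, channel labels and array layout.  Trial
tables are plain UTF-8 CSV.  Time-frequency power and lateralization maps are
stored in HDF5.  An EDF import path is provided for real recordings.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, TRIAL_COLUMNS, validate_trial_table

__all__ = [
    "FormatError",
    "write_epochs",
    "read_epochs",
    "write_trial_table",
    "read_trial_table",
    "write_tfpower",
    "read_tfpower",
    "read_edf_epochs",
]

_LAYOUT = "trial-major, sample, channel-fastest"


class FormatError(ValueError):
    """Raised for malformed on-disk containers."""


def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (".dat", ".json"):
        base = base.with_suffix("")
    return base.with_suffix(".dat"), base.with_suffix(".json")


def write_epochs(epochs: EpochSet, path: str | Path, overwrite: bool = False) -> Path:
    """Write an EpochSet to ``<path>.dat`` + ``<path>.json``.

    Channels are canonicalized to alphabetical order on write; consumers
    address channels by label only, so this is lossless.  Returns the ``.dat``
    path.
    """
    dat, sidecar = _paths(path)
    if not overwrite and (dat.exists() or sidecar.exists()):
        raise FileExistsError(f"{dat} exists (pass overwrite=True to replace)")
    ep = epochs.sorted_channels()
    meta = {
        "format": "alphalat-epochs-v1",
        "srate": float(ep.srate),
        "t0_ms": float(ep.t0_ms),
        "channels": ep.channels,
        "shape": [ep.n_channels, ep.n_samples, ep.n_trials],
        "dtype": "<f4",
        "layout": _LAYOUT,
    }
    # channel-fastest: (trial, sample, channel) in C order
    arr = np.ascontiguousarray(ep.data.transpose(2, 1, 0), dtype="<f4")
    arr.tofile(dat)
    sidecar.write_text(json.dumps(meta, indent=2))
    return dat


def read_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs` (bit-exact round trip)."""
    dat, sidecar = _paths(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("srate", "t0_ms", "channels", "shape"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required field {key!r}")
    n_ch, n_samp, n_tr = meta["shape"]
    if len(meta["channels"]) != n_ch:
        raise FormatError(
            f"sidecar lists {len(meta['channels'])} channels but shape says {n_ch}"
        )
    raw = np.fromfile(dat, dtype="<f4")
    if raw.size != n_ch * n_samp * n_tr:
        raise FormatError(
            f"{dat}: {raw.size} values on disk, sidecar shape implies {n_ch * n_samp * n_tr}"
        )
    data = raw.reshape(n_tr, n_samp, n_ch).transpose(2, 1, 0)
    return EpochSet(data=data, srate=meta["srate"], t0_ms=meta["t0_ms"], channels=meta["channels"])


def write_trial_table(trials: pd.DataFrame, path: str | Path, overwrite: bool = True) -> Path:
    path = Path(path)
    if not overwrite and path.exists():
        raise FileExistsError(str(path))
    validate_trial_table(trials)
    trials.to_csv(path, index=False)
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV; an empty file yields an empty table."""
    path = Path(path)
    try:
        trials = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(TRIAL_COLUMNS))
    if "rt_ms" in trials.columns:
        trials["rt_ms"] = pd.to_numeric(trials["rt_ms"], errors="coerce")
    for col in ("correct", "rejected"):
        if col in trials.columns and trials[col].dtype != bool:
            trials[col] = trials[col].astype(bool)
    return validate_trial_table(trials)


# ---------------------------------------------------------------------------
# HDF5 containers for derived arrays (time-frequency power, ALI maps)
# ---------------------------------------------------------------------------

def write_tfpower(tf, path: str | Path) -> Path:
    """Write a TFPower to HDF5 (axes stored alongside the power array)."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("power", data=tf.power, compression="gzip", compression_opts=1)
        h5.create_dataset("freqs_hz", data=tf.freqs)
        h5.create_dataset("times_ms", data=tf.times_ms)
        h5.attrs["channels"] = np.array(tf.channels, dtype=object).astype("S")
    return path


def read_tfpower(path: str | Path):
    from .timefreq import TFPower

    with h5py.File(path, "r") as h5:
        return TFPower(
            power=h5["power"][()],
            freqs=h5["freqs_hz"][()],
            times_ms=h5["times_ms"][()],
            channels=[c.decode() for c in h5.attrs["channels"]],
        )


# ---------------------------------------------------------------------------
# Optional EDF import
# ---------------------------------------------------------------------------

def read_edf_epochs(
    path: str | Path,
    event_onsets_ms: np.ndarray,
    t0_ms: float,
    duration_ms: float,
) -> EpochSet:
    """Epoch a continuous EDF recording around the given event onsets.

    Requires :mod:`mne`.  ``event_onsets_ms`` are pre-cue onsets in recording
    time; each epoch spans ``[onset + t0_ms, onset + t0_ms + duration_ms)``.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is optional
        raise ImportError("EDF import requires the optional dependency 'mne'") from exc

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    srate = float(raw.info["sfreq"])
    sig = raw.get_data() * 1e6  # volts -> microvolts
    n_samp = int(round(duration_ms / 1000.0 * srate))
    starts = np.round((np.asarray(event_onsets_ms) + t0_ms) / 1000.0 * srate).astype(int)
    if (starts < 0).any() or (starts + n_samp > sig.shape[1]).any():
        raise FormatError("epoch window extends beyond the recording")
    data = np.stack([sig[:, s : s + n_samp] for s in starts], axis=2)
    return EpochSet(data=data, srate=srate, t0_ms=t0_ms, channels=list(raw.ch_names))
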