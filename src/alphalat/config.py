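"""Pipeline configuration.

All analysis-relevant constants in one validated dataclass, loadable from
YAML.  Defaults are the study design values: a 52-step log frequency grid
from 4 to 30 Hz with 3 -> 11.25 cycles, the posterior electrode cluster
PO7/8 P7/8 P5/6 PO3/4, the 8-13 Hz x 700-1300 ms post-retro-cue analysis
window, 1,000 permutations with a 95th-percentile cutoff at alpha = 0.05,
and a 200-point time grid.

Epoch time is always expressed in ms relative to pre-cue onset.  The
retro-cue appears 3,000 ms later (400 ms pre-cue + 1,000 ms ISI + 600 ms
sound array + 1,000 ms delay), so windows stated "post retro-cue" are
shifted by +3,000 ms internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "RETROCUE_ONSET_MS", "DEFAULT_CLUSTER_PAIRS"]

#: Derived event-timing constant: retro-cue onset in epoch time (ms).
RETROCUE_ONSET_MS = 400 + 1000 + 600 + 1000

#: Left/right homologue electrode pairs of the posterior cluster of interest.
DEFAULT_CLUSTER_PAIRS = (("PO7", "PO8"), ("P7", "P8"), ("P5", "P6"), ("PO3", "PO4"))


@dataclass
class PipelineConfig:
    # wavelet family
    f_min_hz: float = 4.0
    f_max_hz: float = 30.0
    n_freqs: int = 52
    cycles_min: float = 3.0
    cycles_max: float = 11.25
    # electrode cluster (list of [left, right] homologue pairs)
    cluster_pairs: tuple = DEFAULT_CLUSTER_PAIRS
    # analysis window, ms relative to retro-cue onset, and band in Hz
    band_hz: tuple = (8.0, 13.0)
    window_post_cue_ms: tuple = (700.0, 1300.0)
    # statistics
    alpha: float = 0.05
    n_perm: int = 1000
    percentile: float = 95.0
    seed: int = 0
    # time grid of the time-frequency decomposition
    time_grid: int = 200

    def __post_init__(self) -> None:
        self.cluster_pairs = tuple(tuple(p) for p in self.cluster_pairs)
        self.band_hz = tuple(float(v) for v in self.band_hz)
        self.window_post_cue_ms = tuple(float(v) for v in self.window_post_cue_ms)
        self.validate()

    def validate(self) -> None:
        if not (0 < self.f_min_hz < self.f_max_hz):
            raise ValueError("need 0 < f_min_hz < f_max_hz")
        if self.n_freqs < 2 or self.time_grid < 2:
            raise ValueError("n_freqs and time_grid must be >= 2")
        if not (0 < self.cycles_min <= self.cycles_max):
            raise ValueError("need 0 < cycles_min <= cycles_max")
        if not (0 < self.alpha < 1) or not (0 < self.percentile < 100):
            raise ValueError("alpha in (0,1), percentile in (0,100)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.window_post_cue_ms[0] >= self.window_post_cue_ms[1]:
            raise ValueError("analysis window must be a nonempty interval")
        for pair in self.cluster_pairs:
            if len(pair) != 2:
                raise ValueError(f"cluster pair {pair!r} is not a (left, right) pair")

    @property
    def window_epoch_ms(self) -> tuple[float, float]:
        """Analysis window in epoch time (ms relative to pre-cue onset)."""
        lo, hi = self.window_post_cue_ms
        return (lo + RETROCUE_ONSET_MS, hi + RETROCUE_ONSET_MS)

    @property
    def cluster_channels(self) -> list[str]:
        return [ch for pair in self.cluster_pairs for ch in pair]

    # -- YAML round trip -------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["cluster_pairs"] = [list(p) for p in self.cluster_pairs]
        d["band_hz"] = list(self.band_hz)
        d["window_post_cue_ms"] = list(self.window_post_cue_ms)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path
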