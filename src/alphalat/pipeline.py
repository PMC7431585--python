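"""End-to-end orchestration: subjects -> ALI maps -> group statistics.

`run_subject` chains the per-subject pipeline (simulate or load, wavelet
decomposition at the posterior cluster, per-condition ALI maps and window
means); `run_cohort` stacks subjects; `analyze_cohort` runs the cluster
permutation contrast, the ALI follow-up statistics, and the behavioral
analysis, returning one machine-readable report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterResult, cluster_test
from .config import PipelineConfig
from .containers import CONDITIONS, EpochSet
from .lateralization import ali_map, window_mean
from .simulate import SimParams, simulate_subject
from .stats import ali_followup, behavioral_analysis
from .timefreq import build_wavelet_family, morlet_power

__all__ = ["SubjectResult", "CohortResult", "run_subject", "run_cohort",
           "analyze_cohort", "report_dict"]


@dataclass
class SubjectResult:
    trials: pd.DataFrame
    ali_maps: dict            # condition -> (freq, time) array
    window_means: dict        # condition -> float
    freqs: np.ndarray
    times_ms: np.ndarray


@dataclass
class CohortResult:
    subjects: list[SubjectResult]

    @property
    def freqs(self) -> np.ndarray:
        return self.subjects[0].freqs

    @property
    def times_ms(self) -> np.ndarray:
        return self.subjects[0].times_ms

    def stacked_maps(self, condition: str) -> np.ndarray:
        return np.stack([s.ali_maps[condition] for s in self.subjects])

    @property
    def window_means(self) -> pd.DataFrame:
        return pd.DataFrame([s.window_means for s in self.subjects])

    @property
    def trial_tables(self) -> list[pd.DataFrame]:
        return [s.trials for s in self.subjects]


def subject_from_epochs(
    epochs: EpochSet, trials: pd.DataFrame, config: PipelineConfig
) -> SubjectResult:
    """Per-subject analysis of already-cleaned epochs."""
    family = build_wavelet_family(
        config.f_min_hz, config.f_max_hz, config.n_freqs,
        config.cycles_min, config.cycles_max, epochs.srate,
    )
    tf = morlet_power(epochs, family, channels=config.cluster_channels,
                      time_grid=config.time_grid)
    maps, wmeans = {}, {}
    for cond in CONDITIONS:
        m = ali_map(tf, trials, cond, pairs=config.cluster_pairs)
        maps[cond] = m
        wmeans[cond] = window_mean(
            m, tf.freqs, tf.times_ms, band_hz=config.band_hz,
            window_ms=config.window_epoch_ms,
        )
    return SubjectResult(trials=trials, ali_maps=maps, window_means=wmeans,
                         freqs=tf.freqs, times_ms=tf.times_ms)


def run_subject(params: SimParams, config: PipelineConfig, seed: int) -> SubjectResult:
    """Simulate one subject and analyze it."""
    trials, epochs = simulate_subject(params, seed=seed)
    return subject_from_epochs(epochs, trials, config)


def run_cohort(params: SimParams, config: PipelineConfig,
               seed: int | None = None) -> CohortResult:
    """Simulate and analyze ``params.n_subjects`` independent subjects."""
    seed = params.seed if seed is None else seed
    subject_seeds = np.random.SeedSequence(seed).generate_state(params.n_subjects) % 2**31
    return CohortResult(
        subjects=[run_subject(params, config, int(s)) for s in subject_seeds]
    )


def analyze_cohort(cohort: CohortResult, config: PipelineConfig) -> dict:
    """Group statistics: cluster permutation contrast + follow-up + behavior."""
    a = cohort.stacked_maps("target_lateral")
    b = cohort.stacked_maps("distractor_lateral")
    clusters = cluster_test(a, b, n_perm=config.n_perm, alpha=config.alpha,
                            percentile=config.percentile, seed=config.seed)
    followup = ali_followup(cohort.window_means)
    behavior = behavioral_analysis(cohort.trial_tables)
    return {"cluster": clusters, "ali_followup": followup, "behavior": behavior}


def report_dict(analysis: dict, cohort: CohortResult | None = None) -> dict:
    """JSON-serializable summary of an `analyze_cohort` result."""
    cl: ClusterResult = analysis["cluster"]
    out = {
        "cluster_test": {
            "cutoff": cl.cutoff,
            "n_permutations": int(cl.null_max_sizes.size),
            "clusters": [
                {"size": c.size, "sign": c.sign, "significant": sig}
                for c, sig in zip(cl.clusters, cl.significant)
            ],
            "any_significant": cl.any_significant,
        },
        "ali_followup": {k: r.as_dict() for k, r in analysis["ali_followup"].items()},
        "behavior": {k: r.as_dict() for k, r in analysis["behavior"].items()},
    }
    if cohort is not None:
        out["window_means"] = {
            cond: cohort.window_means[cond].tolist()
            for cond in cohort.window_means.columns
        }
    return out
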