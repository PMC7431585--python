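"""Synthetic data emulating the retro-cue working-memory study design.

Three generators:

* :func:`generate_design` — the trial design: four retro-cue types at 25%
  each (tokens "li", "re", "mi", "bei"), probes 50% cued / 25% non-cued /
  25% new overall (neutral trials draw only cued/new), 800 trials in blocks
  of 100, pseudo-random order.
* :func:`simulate_eeg` — epoched EEG: 1/f pink-noise background on every
  channel plus a 10 Hz alpha oscillation at the posterior electrodes whose
  ipsi/contralateral amplitudes are modulated inside a post-retro-cue window
  so that the *expected* lateralization index at the alpha frequency equals
  the injected per-condition value.  The required amplitude ratio is solved
  in closed form from ALI = (ipsi - contra)/(ipsi + contra), including the
  pink-noise floor seen through the analysis wavelet.
* :func:`simulate_behavior` — log-normal response times with a retro-cue
  benefit (selective faster than neutral) and non-cued-probe interference
  (slower and less accurate than new probes), plus occasional premature,
  late and missing responses.

Identical seeds give identical outputs end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_CLUSTER_PAIRS, RETROCUE_ONSET_MS
from .containers import EpochSet, condition_of, validate_trial_table
from .timefreq import build_wavelet_family

__all__ = ["SimParams", "generate_design", "simulate_eeg", "simulate_behavior",
           "simulate_subject", "pink_noise"]

_LEFT_CLUSTER = tuple(lb for lb, _ in DEFAULT_CLUSTER_PAIRS)
_RIGHT_CLUSTER = tuple(rb for _, rb in DEFAULT_CLUSTER_PAIRS)

#: Response deadline: 1,500 ms after probe offset (600 ms probe).
RESPONSE_LIMIT_MS = 1500 + 600
#: Premature-response bound.
MIN_RT_MS = 200


@dataclass
class SimParams:
    """Generator settings; defaults are the study's design values.

    The injected ALIs are dimensionless lateralization indices (|ALI| < 1):
    positive for target-lateral trials (contralateral alpha decrease),
    negative for distractor-lateral (contralateral increase), zero for
    neutral.  ``ali_subject_sd`` adds between-subject variability around the
    injected values.  Behavioral effect sizes are free parameters of the
    simulation (the study reports test statistics, not raw means).
    """

    n_subjects: int = 20
    n_trials: int = 800
    srate: float = 500.0
    epoch_span_ms: tuple = (-1000.0, 7500.0)
    alpha_freq: float = 10.0
    # background pink noise
    noise_exponent: float = 1.0
    noise_rms_uv: float = 10.0
    # posterior alpha oscillation
    alpha_amp_uv: float = 6.0
    effect_window_post_cue_ms: tuple = (700.0, 1300.0)
    ramp_ms: float = 100.0
    bilateral_suppression: float = 0.0   # fractional post-cue amp drop, both sides
    # injected lateralization
    ali_target_lateral: float = 0.2
    ali_distractor_lateral: float = -0.2
    ali_neutral: float = 0.0
    ali_subject_sd: float = 0.08
    # behavior
    rt_base_ms: float = 900.0
    rt_benefit_ms: float = 60.0
    interference_ms: float = 80.0
    rt_sigma: float = 0.25               # log-scale trial SD
    rt_subject_sd_ms: float = 50.0
    rt_effect_sd_ms: float = 25.0
    accuracy_base: float = 0.92
    noncued_error_factor: float = 2.0
    acc_subject_sd: float = 0.3          # SD of log error-rate multiplier
    lapse_rate: float = 0.02
    channels: tuple = _LEFT_CLUSTER + _RIGHT_CLUSTER + ("Fz", "Cz", "Pz", "Oz")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ali_target_lateral", "ali_distractor_lateral", "ali_neutral"):
            if abs(getattr(self, name)) >= 1:
                raise ValueError(f"|{name}| must be < 1")
        if self.rt_benefit_ms < 0 or self.interference_ms < 0:
            raise ValueError("rt_benefit_ms and interference_ms must be >= 0")
        if not (0 <= self.accuracy_base <= 1) or not (0 <= self.lapse_rate <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.effect_window_post_cue_ms
        e0, e1 = self.epoch_span_ms
        if not (e0 <= lo + RETROCUE_ONSET_MS < hi + RETROCUE_ONSET_MS <= e1):
            raise ValueError("effect window must lie inside the epoch span")

    @property
    def injected_ali(self) -> dict[str, float]:
        return {
            "target_lateral": self.ali_target_lateral,
            "distractor_lateral": self.ali_distractor_lateral,
            "neutral": self.ali_neutral,
        }

    @property
    def n_samples(self) -> int:
        e0, e1 = self.epoch_span_ms
        return int(round((e1 - e0) / 1000.0 * self.srate))


# ---------------------------------------------------------------------------
# trial design
# ---------------------------------------------------------------------------

def _split_even(total: int, parts: int) -> list[int]:
    """Deterministic near-even integer split, remainder to earliest parts."""
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def generate_design(n_trials: int = 800, seed: int = 0) -> pd.DataFrame:
    """Generate the full factorial trial design in pseudo-random order.

    ``n_trials`` must be divisible by 16 so that the cue and probe
    proportions are exactly realizable: each retro-cue type gets 25% of
    trials, cued probes 50% overall, non-cued and new probes 25% each, and
    neutral trials never receive a non-cued probe.
    """
    if n_trials % 16 != 0:
        raise ValueError(f"n_trials={n_trials} must be divisible by 16")
    q = n_trials // 4          # per retro-cue type
    e = n_trials // 8

    rows: list[tuple[str, str, str]] = []
    # neutral: cued/new split evenly, sides split evenly within each probe
    for probe, count in (("cued", e), ("new", e)):
        half = count // 2
        rows += [("neutral", "left", probe)] * half
        rows += [("neutral", "right", probe)] * (count - half)
    # selective types: cued = n/8 each; non-cued total n/4 and new total n/8
    # distributed near-evenly across the three selective cue types
    selective = ["target_lateral_left", "target_lateral_right", "distractor_lateral"]
    noncued_counts = _split_even(n_trials // 4, 3)
    for cue, n_noncued in zip(selective, noncued_counts):
        n_new = q - e - n_noncued
        for probe, count in (("cued", e), ("noncued", n_noncued), ("new", n_new)):
            if cue == "target_lateral_left":
                sides = ["left"] * count
            elif cue == "target_lateral_right":
                sides = ["right"] * count
            else:
                half = count // 2
                sides = ["left"] * half + ["right"] * (count - half)
            rows += [(cue, s, probe) for s in sides]
    assert len(rows) == n_trials

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_trials)
    rows = [rows[i] for i in order]
    design = pd.DataFrame(
        {
            "trial_id": np.arange(1, n_trials + 1),
            "block": np.arange(n_trials) // 100 + 1,
            "precue_side": [r[1] for r in rows],
            "retrocue": [r[0] for r in rows],
            "probe": [r[2] for r in rows],
            "response": "none",
            "rt_ms": np.nan,
            "correct": False,
            "rejected": False,
        }
    )
    return validate_trial_table(design)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def pink_noise(
    rng: np.random.Generator,
    n_samples: int,
    srate: float,
    exponent: float,
    rms: float,
    n_series: int,
) -> tuple[np.ndarray, np.ndarray]:
    """1/f^exponent noise, spectrally synthesized with exact expected RMS.

    Returns ``(signals, bin_var)``: signals shaped ``(n_samples, n_series)``
    and the per-frequency-bin variance ``E|X_k|^2`` of the synthesis (used by
    the wavelet noise-floor calibration).
    """
    nb = n_samples // 2 + 1
    f = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    amps = np.zeros(nb)
    amps[1:] = f[1:] ** (-exponent / 2.0)
    amps[-1] = 0.0 if n_samples % 2 == 0 else amps[-1]
    # Var(x) = (2 / n^2) * sum amps_k^2 * scale^2  (DC and Nyquist zeroed)
    scale = rms * n_samples / np.sqrt(2.0 * np.sum(amps**2))
    amps = amps * scale
    z = (rng.standard_normal((nb, n_series)) + 1j * rng.standard_normal((nb, n_series)))
    x = np.fft.irfft(amps[:, None] * z / np.sqrt(2.0), n=n_samples, axis=0)
    return x, amps**2


def _alpha_wavelet(params: SimParams) -> np.ndarray:
    """Analysis-convention wavelet at the simulated alpha frequency."""
    fam = build_wavelet_family(srate=params.srate)
    c = fam.cycles[0] + (fam.cycles[-1] - fam.cycles[0]) * (
        (params.alpha_freq - fam.freqs[0]) / (fam.freqs[-1] - fam.freqs[0])
    )
    from .timefreq import WaveletFamily

    one = WaveletFamily(
        freqs=np.array([params.alpha_freq]), cycles=np.array([c]), srate=params.srate
    )
    return one.wavelet(0)


def alpha_band_calibration(params: SimParams) -> tuple[float, float]:
    """(sinusoid gain k, noise floor N) of the analysis wavelet at alpha_freq.

    ``k`` maps squared sinusoid amplitude to wavelet power (steady state);
    ``N`` is the expected wavelet power of the pink-noise background.  Both
    are exact bin sums, no simulation involved.
    """
    w = _alpha_wavelet(params)
    n = params.n_samples
    m = np.arange(w.size)
    resp = np.sum(w * np.exp(-2j * np.pi * params.alpha_freq * m / params.srate))
    k = np.abs(resp) ** 2 / 4.0

    _, bin_var = pink_noise(
        np.random.default_rng(0), n, params.srate, params.noise_exponent,
        params.noise_rms_uv, 0,
    )
    wf = np.fft.fft(w, n)
    # E|y|^2 = (1/n^2) sum_k E|X_k|^2 |W(f_k)|^2 over the full spectrum
    full_var = np.zeros(n)
    full_var[: n // 2 + 1] = bin_var
    full_var[-(n // 2 - 1):] = bin_var[1 : n // 2][::-1]
    noise_floor = float(np.sum(full_var * np.abs(wf) ** 2) / n**2)
    return float(k), noise_floor


def _condition_amplitudes(params: SimParams, ali: dict[str, float]) -> dict[str, tuple[float, float]]:
    """Solve per-condition (ipsi, contra) alpha amplitudes for target ALIs.

    Total (alpha + noise) wavelet power is held at the baseline value P0 on
    average while the hemispheric split realizes the requested ALI:
    ipsi = P0 (1 + ALI), contra = P0 (1 - ALI).
    """
    k, nf = alpha_band_calibration(params)
    a0sq = params.alpha_amp_uv**2
    p0 = nf + k * a0sq
    out = {}
    for cond, L in ali.items():
        hi = a0sq + L * p0 / k
        lo = a0sq - L * p0 / k
        if lo < 0 or hi < 0:
            raise ValueError(
                f"injected ALI {L} for {cond} infeasible: would require negative "
                "alpha power; raise alpha_amp_uv or lower |ALI|"
            )
        out[cond] = (np.sqrt(hi), np.sqrt(lo))
    return out


def _effect_envelope(params: SimParams, times_ms: np.ndarray) -> np.ndarray:
    """0->1 envelope of the effect window with raised-cosine ramps."""
    lo = params.effect_window_post_cue_ms[0] + RETROCUE_ONSET_MS
    hi = params.effect_window_post_cue_ms[1] + RETROCUE_ONSET_MS
    r = params.ramp_ms
    env = np.zeros_like(times_ms, dtype=float)
    env[(times_ms >= lo + r) & (times_ms <= hi - r)] = 1.0
    up = (times_ms >= lo) & (times_ms < lo + r)
    env[up] = 0.5 * (1 - np.cos(np.pi * (times_ms[up] - lo) / r))
    down = (times_ms > hi - r) & (times_ms <= hi)
    env[down] = 0.5 * (1 - np.cos(np.pi * (hi - times_ms[down]) / r))
    return env


def simulate_eeg(
    design: pd.DataFrame,
    params: SimParams,
    rng: np.random.Generator | None = None,
    subject_ali: dict[str, float] | None = None,
) -> EpochSet:
    """Simulate epoched EEG for one subject given a trial design.

    Every channel carries pink noise; posterior cluster channels additionally
    carry a 10 Hz oscillation (random phase per trial and channel) whose
    hemispheric amplitudes, inside the effect window, realize the injected
    per-condition ALI.  ``subject_ali`` overrides the per-condition targets
    (used for between-subject variability).
    """
    validate_trial_table(design)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    missing = [ch for ch in _LEFT_CLUSTER + _RIGHT_CLUSTER if ch not in params.channels]
    if missing:
        raise ValueError(f"cluster channels missing from simulation: {missing}")

    ali = dict(params.injected_ali if subject_ali is None else subject_ali)
    amps = _condition_amplitudes(params, ali)
    n_samp = params.n_samples
    n_tr = len(design)
    t = params.epoch_span_ms[0] / 1000.0 + np.arange(n_samp) / params.srate
    times_ms = t * 1000.0
    env = _effect_envelope(params, times_ms)
    a0 = params.alpha_amp_uv

    conds = design["retrocue"].map(condition_of).to_numpy()
    sides = design["precue_side"].to_numpy()
    a_ipsi = np.array([amps[c][0] for c in conds])
    a_contra = np.array([amps[c][1] for c in conds])

    post_cue = times_ms >= RETROCUE_ONSET_MS
    bilateral = 1.0 - params.bilateral_suppression * post_cue.astype(float)

    data = np.empty((len(params.channels), n_samp, n_tr), dtype=np.float32)
    for ci, ch in enumerate(params.channels):
        noise, _ = pink_noise(
            rng, n_samp, params.srate, params.noise_exponent, params.noise_rms_uv, n_tr
        )
        sig = noise
        if ch in _LEFT_CLUSTER or ch in _RIGHT_CLUSTER:
            is_left_hemi = ch in _LEFT_CLUSTER
            ipsi_role = (sides == "left") == is_left_hemi
            a_target = np.where(ipsi_role, a_ipsi, a_contra)
            amp = a0 + (a_target[None, :] - a0) * env[:, None]   # (samp, trial)
            amp = amp * bilateral[:, None]
            phase = rng.uniform(0, 2 * np.pi, n_tr)
            sig = sig + amp * np.cos(
                2 * np.pi * params.alpha_freq * t[:, None] + phase[None, :]
            )
        data[ci] = sig.astype(np.float32)
    return EpochSet(
        data=data,
        srate=params.srate,
        t0_ms=params.epoch_span_ms[0],
        channels=list(params.channels),
    )


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(
    design: pd.DataFrame,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill one subject's responses, RTs and correctness into a design table.

    RTs are log-normal with the subject's condition means (selective cues
    faster than neutral by ``rt_benefit_ms``; non-cued probes slower than new
    by ``interference_ms``); correctness is Bernoulli with an inflated error
    rate for non-cued probes; a small fraction of trials are premature, late
    or missing and therefore count as errors.
    """
    validate_trial_table(design)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = len(design)
    trials = design.copy()

    # subject-level random effects
    intercept = rng.normal(0.0, params.rt_subject_sd_ms)
    benefit = params.rt_benefit_ms + rng.normal(0.0, params.rt_effect_sd_ms)
    interference = params.interference_ms + rng.normal(0.0, params.rt_effect_sd_ms)
    acc_mult = np.exp(rng.normal(0.0, params.acc_subject_sd))

    selective = trials["retrocue"] != "neutral"
    noncued = trials["probe"] == "noncued"
    mean_rt = np.full(n, params.rt_base_ms + intercept)
    mean_rt[selective.to_numpy()] -= benefit
    mean_rt[noncued.to_numpy()] += interference
    mean_rt = np.clip(mean_rt, 150.0, None)
    mu = np.log(mean_rt) - params.rt_sigma**2 / 2.0
    rt = np.exp(rng.normal(mu, params.rt_sigma))

    err = (1.0 - params.accuracy_base) * acc_mult * np.where(
        noncued.to_numpy(), params.noncued_error_factor, 1.0
    )
    err = np.clip(err, 0.0, 1.0)
    wrong_button = rng.random(n) < err

    truth_yes = (trials["probe"] == "cued").to_numpy()
    answered_yes = truth_yes ^ wrong_button
    response = np.where(answered_yes, "yes", "no")

    # lapses: premature / late / missing in equal shares
    lapse = rng.random(n) < params.lapse_rate
    kind = rng.integers(0, 3, n)
    premature = lapse & (kind == 0)
    late = lapse & (kind == 1)
    missing = lapse & (kind == 2)
    rt[premature] = rng.uniform(50.0, MIN_RT_MS - 10.0, int(premature.sum()))
    rt[late] = rng.uniform(RESPONSE_LIMIT_MS + 1.0, RESPONSE_LIMIT_MS + 300.0, int(late.sum()))
    response = np.where(missing, "none", response)
    rt = np.where(missing, np.nan, rt)

    timely = (~missing) & (rt >= MIN_RT_MS) & (rt <= RESPONSE_LIMIT_MS)
    trials["response"] = response
    trials["rt_ms"] = rt
    trials["correct"] = (answered_yes == truth_yes) & timely
    return validate_trial_table(trials)


def simulate_subject(
    params: SimParams, seed: int | None = None
) -> tuple[pd.DataFrame, EpochSet]:
    """Design + behavior + EEG for one subject, with subject-level ALI draw."""
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_design, s_beh, s_eeg, s_ali = ss.spawn(4)
    design = generate_design(params.n_trials, seed=int(s_design.generate_state(1)[0] % 2**31))
    trials = simulate_behavior(design, params, rng=np.random.default_rng(s_beh))
    ali_rng = np.random.default_rng(s_ali)
    subject_ali = {
        cond: float(np.clip(v + ali_rng.normal(0.0, params.ali_subject_sd), -0.9, 0.9))
        for cond, v in params.injected_ali.items()
    }
    epochs = simulate_eeg(design, params, rng=np.random.default_rng(s_eeg),
                          subject_ali=subject_ali)
    return trials, epochs
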