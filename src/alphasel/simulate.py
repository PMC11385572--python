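"""Synthetic EEG + behavior generator for the three-phase location-memory task.

Emulates the cueing phase of a long-term-memory experiment in which each
object was encoded with one lateral (left/right) and one vertical
(top/bottom) location, and a cue then made one location (selective cue,
horizontal or vertical axis) or both locations (neutral cue) relevant.

Per participant the generator produces epoched EEG (trials x 64 channels x
time, microvolts) composed of

* 1/f (pink) background noise per channel,
* ongoing posterior 10 Hz alpha with random per-trial phase,
* in selective trials with a lateral target: contralateral posterior alpha
  suppression (a dB step inside a post-cue window) and a transient negative
  ERP deflection (the PCN) at the contralateral member of PO7/PO8,
* a location-specific alpha-band scalp pattern, active post-cue, at full
  gain in selective trials and (by default) at half gain for both encoded
  locations in neutral trials,

plus a behavioral table (accuracy, RT, confidence 1-4) for the retrieval
phase, with a selective-condition RT/confidence advantage at equal accuracy.

Everything is deterministic given ``(cfg.seed, participant_id)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .containers import EpochSet
from .montage import Montage, make_montage, posterior_channels

CONDITIONS = ("selective", "neutral")
CUE_AXES = ("horizontal", "vertical")
LOCATIONS = ("left", "right", "top", "bottom")


def _default_rt_params() -> dict[str, Any]:
    # Log-normal RT model: participant means spread widely (between-SD
    # dominates, as in typical retrieval RT data), selective condition
    # shifted ~ -135 ms, incorrect responses slower.
    return {
        "selective": {"mu": 7.159, "sigma": 0.35},
        "neutral": {"mu": 7.249, "sigma": 0.35},
        "sigma_between": 0.30,
        "sigma_condition": 0.03,
        "incorrect_shift": 0.40,
    }


def _default_acc_params() -> dict[str, float]:
    return {"selective": 0.84, "neutral": 0.84}


def _default_conf_params() -> dict[str, dict[str, list[float]]]:
    # Ordinal 1-4 category probabilities; confidence is higher on correct
    # trials and slightly higher in the selective condition.
    return {
        "selective": {
            "correct": [0.03, 0.09, 0.36, 0.52],
            "incorrect": [0.15, 0.25, 0.40, 0.20],
        },
        "neutral": {
            "correct": [0.035, 0.105, 0.39, 0.47],
            "incorrect": [0.16, 0.26, 0.39, 0.19],
        },
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study's design counts (30 participants, 120
    objects x 3 repetitions x 3 cue types = 360 cueing trials, epochs
    -1000..3000 ms at 1000 Hz, cue at 500 ms).  Effect magnitudes are in
    physical units: ``alpha_suppression_db`` is the contralateral-minus-
    ipsilateral posterior alpha change in dB (negative = suppression),
    ``pcn_amplitude_uv`` the PCN peak in microvolts (negative),
    ``location_pattern_gain`` the per-channel RMS amplitude (microvolts) of
    the location-specific alpha pattern.
    """

    n_participants: int = 30
    n_objects: int = 120
    reps_per_object: int = 3
    sfreq_native: float = 1000.0
    epoch_window: tuple[float, float] = (-1000.0, 3000.0)
    cue_onset: float = 500.0
    alpha_freq: float = 10.0
    alpha_suppression_db: float = -1.0
    suppression_window: tuple[float, float] = (200.0, 900.0)  # ms post-cue
    pcn_amplitude_uv: float = -2.0
    pcn_latency_ms: float = 450.0  # ms post-cue
    pcn_width_ms: float = 60.0  # Gaussian SD
    location_pattern_gain: float = 0.6
    pattern_window: tuple[float, float] = (0.0, 2000.0)  # ms post-cue
    noise_exponent: float = 1.0
    noise_std_uv: float = 5.0
    alpha_amplitude_uv: float = 12.0
    frontal_alpha_fraction: float = 0.2
    neutral_pattern: str = "half"  # 'half' (diluted) or 'zero'
    rt_params: dict[str, Any] = field(default_factory=_default_rt_params)
    acc_params: dict[str, float] = field(default_factory=_default_acc_params)
    conf_params: dict[str, dict[str, list[float]]] = field(default_factory=_default_conf_params)
    seed: int = 0

    def __post_init__(self) -> None:
        validate_config(self)


def validate_config(cfg: SimConfig) -> None:
    """Reject an invalid configuration with a message naming the field."""
    for name in ("n_participants", "n_objects", "reps_per_object"):
        v = getattr(cfg, name)
        if not (isinstance(v, (int, np.integer)) and v > 0):
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    if cfg.n_objects % 6 != 0:
        raise ValueError(
            "n_objects must be divisible by 6 so the three cue types are "
            f"balanced over left/right and top/bottom, got {cfg.n_objects}"
        )
    if cfg.sfreq_native <= 0:
        raise ValueError(f"sfreq_native must be positive, got {cfg.sfreq_native}")
    t0, t1 = cfg.epoch_window
    if not t0 < t1:
        raise ValueError(f"epoch_window must be increasing, got {cfg.epoch_window}")
    if not (t0 < cfg.cue_onset < t1):
        raise ValueError(
            f"cue_onset {cfg.cue_onset} must lie inside epoch_window {cfg.epoch_window}"
        )
    if not (8.0 <= cfg.alpha_freq <= 13.0):
        raise ValueError(f"alpha_freq must lie in [8, 13] Hz, got {cfg.alpha_freq}")
    if cfg.alpha_suppression_db > 0:
        raise ValueError(
            f"alpha_suppression_db is a suppression and must be <= 0, got {cfg.alpha_suppression_db}"
        )
    if cfg.pcn_amplitude_uv > 0:
        raise ValueError(
            f"pcn_amplitude_uv is a negativity and must be <= 0, got {cfg.pcn_amplitude_uv}"
        )
    if cfg.suppression_window[0] >= cfg.suppression_window[1]:
        raise ValueError(f"suppression_window must be increasing, got {cfg.suppression_window}")
    if cfg.location_pattern_gain < 0:
        raise ValueError(f"location_pattern_gain must be >= 0, got {cfg.location_pattern_gain}")
    for name in ("pcn_width_ms", "noise_std_uv", "alpha_amplitude_uv"):
        if getattr(cfg, name) < 0:
            raise ValueError(f"{name} must be >= 0, got {getattr(cfg, name)}")
    if cfg.neutral_pattern not in ("half", "zero"):
        raise ValueError(f"neutral_pattern must be 'half' or 'zero', got {cfg.neutral_pattern!r}")
    for cond in CONDITIONS:
        p = cfg.acc_params.get(cond)
        if p is None or not (0.0 <= p <= 1.0):
            raise ValueError(f"acc_params[{cond!r}] must be a probability, got {p!r}")
        for outcome in ("correct", "incorrect"):
            probs = np.asarray(cfg.conf_params[cond][outcome], dtype=float)
            if probs.size != 4 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
                raise ValueError(
                    f"conf_params[{cond!r}][{outcome!r}] must be 4 nonnegative "
                    f"probabilities summing to 1, got {probs.tolist()}"
                )
        if cfg.rt_params[cond]["sigma"] <= 0:
            raise ValueError(f"rt_params[{cond!r}]['sigma'] must be positive")


# ---------------------------------------------------------------------------
# trial structure


def make_trial_table(cfg: SimConfig, participant_id: int, rng: np.random.Generator) -> pd.DataFrame:
    """One row per cueing-phase trial, balanced within each cue type.

    Objects are split in thirds over the cue types (selective-horizontal,
    selective-vertical, neutral); within each third, encoded lateral and
    vertical locations cycle over the four (lateral, vertical) combinations,
    so left/right and top/bottom each occur on half the trials.  Trial order
    is shuffled per participant.
    """
    per_cue = cfg.n_objects // 3
    rows = []
    # ordering guarantees exact left/right and top/bottom balance for any even per_cue
    combos = [("left", "top"), ("right", "bottom"), ("left", "bottom"), ("right", "top")]
    cue_specs = [("selective", "horizontal"), ("selective", "vertical"), ("neutral", None)]
    obj = 0
    for condition, axis in cue_specs:
        for j in range(per_cue):
            lat, vert = combos[j % 4]
            cue_axis = axis if condition == "selective" else ("horizontal" if j % 4 < 2 else "vertical")
            rows.append(
                {
                    "participant_id": participant_id,
                    "object_id": obj,
                    "condition": condition,
                    "cue_axis": cue_axis,
                    "lateral_location": lat,
                    "vertical_location": vert,
                }
            )
            obj += 1
    objects = pd.DataFrame(rows)
    trials = pd.concat([objects] * cfg.reps_per_object, ignore_index=True)
    order = rng.permutation(len(trials))
    return trials.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# signal components


def _pink_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_times: int, exponent: float, std: float
) -> np.ndarray:
    """Gaussian 1/f^exponent noise, unit structure ``shape + (n_times,)``, RMS ``std``."""
    freqs = np.fft.rfftfreq(n_times)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal(shape + (freqs.size,)) + 1j * rng.standard_normal(shape + (freqs.size,))
    ) * amp
    x = np.fft.irfft(spec, n=n_times, axis=-1)
    # analytic variance of irfft with this envelope -> scale to requested RMS
    w = np.full(freqs.size, 2.0)
    w[0] = 1.0
    if n_times % 2 == 0:
        w[-1] = 1.0
    expected_var = float(np.sum(w * amp**2)) / n_times**2 * 2.0
    x *= std / np.sqrt(expected_var)
    return x


def _envelope(times: np.ndarray, start: float, stop: float, ramp: float = 100.0) -> np.ndarray:
    """0..1 window with raised-cosine ramps of ``ramp`` ms at both edges."""
    env = np.zeros_like(times)
    core = (times >= start + ramp) & (times <= stop - ramp)
    env[core] = 1.0
    up = (times >= start) & (times < start + ramp)
    env[up] = 0.5 * (1 - np.cos(np.pi * (times[up] - start) / ramp))
    down = (times > stop - ramp) & (times <= stop)
    env[down] = 0.5 * (1 - np.cos(np.pi * (stop - times[down]) / ramp))
    return env


def make_location_patterns(cfg: SimConfig, montage: Montage) -> dict[str, np.ndarray]:
    """Fixed location-specific alpha topographies, shared across participants.

    Four channel vectors (left/right/top/bottom), orthogonalized in the
    left-hemisphere + midline subspace and magnitude-mirrored onto the right
    homologues so that squared pattern amplitude is hemisphere-symmetric.
    The mirror keeps the location pattern from leaking a spurious
    contralateral/ipsilateral power asymmetry into the lateralization
    analyses, while the four power topographies remain linearly separable.
    Vectors are scaled to unit RMS across channels.
    """
    rng = np.random.default_rng([cfg.seed, 987_654_321])
    left_chs = [l for l, _ in montage.lateral_pairs]
    base_chs = left_chs + montage.midline
    raw = rng.standard_normal((4, len(base_chs)))
    q, _ = np.linalg.qr(raw.T)  # orthonormal columns
    patterns = {}
    for k, loc in enumerate(LOCATIONS):
        vec = np.zeros(montage.n_channels)
        for i, ch in enumerate(base_chs):
            v = q[i, k]
            vec[montage.index(ch)] = v
            hom = montage.homologue(ch)
            if hom is not None:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                vec[montage.index(hom)] = sign * abs(v)
        vec /= np.sqrt(np.mean(vec**2))
        patterns[loc] = vec
    return patterns


# ---------------------------------------------------------------------------
# main generators


def generate_participant(
    cfg: SimConfig, participant_id: int, montage: Montage | None = None
) -> tuple[EpochSet, pd.DataFrame]:
    """Simulate one participant's cueing-phase epochs and behavioral table."""
    validate_config(cfg)
    if montage is None:
        montage = make_montage()
    rng = np.random.default_rng([cfg.seed, int(participant_id)])
    trials = make_trial_table(cfg, participant_id, rng)
    n_trials = len(trials)
    t0, t1 = cfg.epoch_window
    dt = 1000.0 / cfg.sfreq_native
    times = np.arange(t0, t1, dt)
    n_times = times.size
    t_sec = times / 1000.0

    post = posterior_channels(montage)
    alpha_amp = np.full(montage.n_channels, cfg.alpha_amplitude_uv * cfg.frontal_alpha_fraction)
    for ch in post:
        alpha_amp[montage.index(ch)] = cfg.alpha_amplitude_uv
    post_left = [c for c in post if montage.hemisphere(c) == "left"]
    post_right = [c for c in post if montage.hemisphere(c) == "right"]
    idx_left = np.array([montage.index(c) for c in post_left])
    idx_right = np.array([montage.index(c) for c in post_right])

    s_factor = 10.0 ** (cfg.alpha_suppression_db / 20.0)
    supp_env = _envelope(
        times,
        cfg.cue_onset + cfg.suppression_window[0],
        cfg.cue_onset + cfg.suppression_window[1],
    )
    pat_env = _envelope(
        times, cfg.cue_onset + cfg.pattern_window[0], cfg.cue_onset + cfg.pattern_window[1]
    )
    t_pcn = cfg.cue_onset + cfg.pcn_latency_ms
    pcn_bump = cfg.pcn_amplitude_uv * np.exp(-0.5 * ((times - t_pcn) / cfg.pcn_width_ms) ** 2)
    patterns = make_location_patterns(cfg, montage)
    omega = 2 * np.pi * cfg.alpha_freq

    data = np.empty((n_trials, montage.n_channels, n_times), dtype=np.float64)
    chunk = max(1, int(2e7 // (montage.n_channels * n_times)))
    for lo in range(0, n_trials, chunk):
        hi = min(lo + chunk, n_trials)
        data[lo:hi] = _pink_noise(
            rng, (hi - lo, montage.n_channels), n_times, cfg.noise_exponent, cfg.noise_std_uv
        )

    phases = rng.uniform(0, 2 * np.pi, size=n_trials)
    pattern_phases = rng.uniform(0, 2 * np.pi, size=(n_trials, 2))
    for i in range(n_trials):
        row = trials.iloc[i]
        osc = np.sin(omega * t_sec + phases[i])
        carrier = alpha_amp[:, None] * osc[None, :]
        lateralized = row.condition == "selective" and row.cue_axis == "horizontal"
        if lateralized and s_factor != 1.0:
            contra = idx_right if row.lateral_location == "left" else idx_left
            mod = 1.0 + (s_factor - 1.0) * supp_env
            carrier[contra] *= mod[None, :]
        data[i] += carrier
        if lateralized and cfg.pcn_amplitude_uv != 0.0:
            contra_pcn = "PO8" if row.lateral_location == "left" else "PO7"
            data[i, montage.index(contra_pcn)] += pcn_bump
        if cfg.location_pattern_gain > 0:
            if row.condition == "selective":
                loc = row.lateral_location if row.cue_axis == "horizontal" else row.vertical_location
                sig = np.sin(omega * t_sec + pattern_phases[i, 0]) * pat_env
                data[i] += cfg.location_pattern_gain * patterns[loc][:, None] * sig[None, :]
            elif cfg.neutral_pattern == "half":
                for k, loc in enumerate((row.lateral_location, row.vertical_location)):
                    sig = np.sin(omega * t_sec + pattern_phases[i, k]) * pat_env
                    data[i] += (
                        0.5 * cfg.location_pattern_gain * patterns[loc][:, None] * sig[None, :]
                    )

    epochs = EpochSet(
        data=data,
        times=times,
        sfreq=cfg.sfreq_native,
        channel_names=list(montage.channel_names),
        trial_info=trials,
    )
    behavior = _generate_behavior(cfg, participant_id, trials, rng)
    return epochs, behavior


def _generate_behavior(
    cfg: SimConfig, participant_id: int, trials: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Retrieval-phase table: one report per object (accuracy, RT, confidence)."""
    objects = trials.drop_duplicates("object_id").sort_values("object_id")
    rtp = cfg.rt_params
    b_i = rng.normal(0.0, rtp["sigma_between"])
    cond_shift = {c: rng.normal(0.0, rtp["sigma_condition"]) for c in CONDITIONS}
    # participant-level confidence bias: tilts the category probabilities so
    # participant means spread realistically (~0.35-0.45 categories SD)
    conf_bias = rng.normal(0.0, 0.6)
    categories = np.array([1, 2, 3, 4])
    rows = []
    for _, obj in objects.iterrows():
        cond = obj.condition
        correct = rng.random() < cfg.acc_params[cond]
        mu = rtp[cond]["mu"] + b_i + cond_shift[cond]
        if not correct:
            mu += rtp["incorrect_shift"]
        rt = float(np.exp(rng.normal(mu, rtp[cond]["sigma"])))
        probs = np.asarray(cfg.conf_params[cond]["correct" if correct else "incorrect"])
        probs = probs * np.exp(conf_bias * (categories - 2.5))
        probs /= probs.sum()
        confidence = int(rng.choice(categories, p=probs))
        rows.append(
            {
                "participant_id": participant_id,
                "condition": cond,
                "correct": bool(correct),
                "rt_ms": rt,
                "confidence": confidence,
            }
        )
    return pd.DataFrame(rows)


def generate_dataset(
    cfg: SimConfig, montage: Montage | None = None
) -> list[tuple[EpochSet, pd.DataFrame]]:
    """Simulate ``cfg.n_participants`` participants (ids 0..n-1)."""
    if montage is None:
        montage = make_montage()
    return [generate_participant(cfg, pid, montage) for pid in range(cfg.n_participants)]
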