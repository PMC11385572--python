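"""Time-resolved two-class decoding of target location from alpha power.

The procedure follows the block-averaged cross-validation scheme common in
EEG location decoding: per iteration, trials of each class are randomly
split into three blocks (surplus trials dropped so blocks are balanced),
trials are averaged within each (block, class) cell, a linear SVM is trained
on 2/3 of the averages and tested on the remaining 1/3 at every timepoint
(3-fold cross-validation), and the whole assignment is redrawn over 10
iterations.  Accuracy is averaged over iterations, folds and contrasts,
smoothed with a 5-point moving window, and compared against the 50% chance
level.  Features are all (channel, in-band frequency) pairs of raw wavelet
power; with 64 channels and 6 alpha-band frequencies this is 384 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .containers import DecodingResult, TFRSet
from .tfr import ALPHA_BAND

#: (contrast trial filter, label column, class pair) for the two location contrasts
DEFAULT_CONTRASTS = [("lateral_location", ("left", "right")), ("vertical_location", ("top", "bottom"))]


@dataclass
class DecodingConfig:
    """Settings of the block-averaged decoding procedure."""

    alpha_band: tuple[float, float] = ALPHA_BAND
    n_blocks: int = 3
    n_iterations: int = 10
    smoothing_points: int = 5
    time_window: tuple[float, float] = (-200.0, 2000.0)
    subsample: int = 5  # take every k-th TFR sample (250 Hz -> 50 Hz)
    contrasts: list = field(default_factory=lambda: list(DEFAULT_CONTRASTS))
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError(f"n_blocks must be >= 2, got {self.n_blocks}")
        if self.smoothing_points < 1 or self.smoothing_points % 2 == 0:
            raise ValueError(f"smoothing_points must be odd and >= 1, got {self.smoothing_points}")
        if self.time_window[0] >= self.time_window[1]:
            raise ValueError(f"time_window must be increasing, got {self.time_window}")
        if self.subsample < 1:
            raise ValueError(f"subsample must be >= 1, got {self.subsample}")


def crop_tfr_for_decoding(tfr: TFRSet, cfg: "DecodingConfig") -> TFRSet:
    """Restrict a TFRSet to the decoding time grid (window + subsampling).

    Produces the exact grid ``decode_timecourse`` would select internally, so
    the cropped set can be decoded with ``subsample=1``.  Useful to shed the
    full-rate power array before concatenating participants.
    """
    lo, hi = cfg.time_window
    idx = np.flatnonzero((tfr.times >= lo) & (tfr.times <= hi))[:: cfg.subsample]
    if idx.size == 0:
        raise ValueError(f"time_window {cfg.time_window} contains no TFR samples")
    return TFRSet(
        power=np.ascontiguousarray(tfr.power[..., idx]),
        times=tfr.times[idx],
        frequencies=tfr.frequencies.copy(),
        sfreq=tfr.sfreq / cfg.subsample,
        channel_names=list(tfr.channel_names),
        trial_info=tfr.trial_info.reset_index(drop=True),
        units=tfr.units,
    )


def select_alpha_features(tfr: TFRSet, band: tuple[float, float] = ALPHA_BAND) -> np.ndarray:
    """Flatten in-band (channel, frequency) power into trials x features x time.

    Features are ordered channel-major: all in-band frequencies of channel 0,
    then channel 1, and so on.  64 channels x 6 in-band frequencies -> 384.
    """
    if tfr.units != "raw":
        raise ValueError("decoding features are raw (non-baselined) power")
    idx = tfr.band_indices(band)
    sub = tfr.power[:, :, idx, :]  # trials x ch x band_freqs x time
    n_trials, n_ch, n_f, n_t = sub.shape
    return sub.reshape(n_trials, n_ch * n_f, n_t)


def assign_blocks(labels: np.ndarray, n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    """Random balanced block assignment per class; surplus trials get -1.

    Each class contributes exactly floor(n_class / n_blocks) trials to every
    block; the remainder is removed (uniformly at random), as required to
    keep the within-block class averages balanced.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.tolist()}")
    blocks = np.full(labels.size, -1, dtype=int)
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        per_block = idx.size // n_blocks
        if per_block < 1:
            raise ValueError(
                f"class {cls!r} has only {idx.size} trials, need at least {n_blocks}"
            )
        idx = rng.permutation(idx)
        for b in range(n_blocks):
            blocks[idx[b * per_block : (b + 1) * per_block]] = b
    return blocks


def block_average(
    features: np.ndarray, blocks: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average feature vectors within each (block, class) cell.

    Returns ``(averages, avg_blocks, avg_labels)`` where averages has shape
    (n_blocks * n_classes) x features x time.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels[blocks >= 0])
    n_blocks = int(blocks.max()) + 1
    out, out_blocks, out_labels = [], [], []
    for b in range(n_blocks):
        for cls in classes:
            sel = (blocks == b) & (labels == cls)
            if not sel.any():
                raise ValueError(f"empty cell: block {b}, class {cls!r}")
            out.append(features[sel].mean(axis=0))
            out_blocks.append(b)
            out_labels.append(cls)
    return np.stack(out), np.asarray(out_blocks), np.asarray(out_labels)


def decode_timepoint(
    train_averages: np.ndarray,
    train_labels: np.ndarray,
    test_averages: np.ndarray,
    c: float = 1.0,
) -> np.ndarray:
    """Predict test labels with a linear soft-margin SVM (C fixed, standardized).

    With two classes the error-correcting-output-codes construction reduces
    to this single binary learner.  Standardization statistics are estimated
    on the training averages only.
    """
    train_labels = np.asarray(train_labels)
    if np.unique(train_labels).size < 2:
        raise ValueError("training set must contain both classes")
    mu = train_averages.mean(axis=0)
    sd = train_averages.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="linear", C=c)
    clf.fit((train_averages - mu) / sd, train_labels)
    return clf.predict((test_averages - mu) / sd)


def smooth_moving_average(series: np.ndarray, w: int = 5) -> np.ndarray:
    """Centered moving mean along the last axis; the window shrinks at edges."""
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {w}")
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n == 0:
        raise ValueError("cannot smooth an empty series")
    half = w // 2
    csum = np.cumsum(series, axis=-1)
    zero = np.zeros(series.shape[:-1] + (1,))
    csum = np.concatenate([zero, csum], axis=-1)
    out = np.empty_like(series)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[..., i] = (csum[..., hi] - csum[..., lo]) / (hi - lo)
    return out


def _decode_one_contrast(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: DecodingConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Accuracy time course (unsmoothed) for one participant and contrast."""
    n_t = features.shape[-1]
    correct = np.zeros(n_t)
    total = 0
    for _ in range(cfg.n_iterations):
        blocks = assign_blocks(labels, cfg.n_blocks, rng)
        keep = blocks >= 0
        averages, avg_blocks, avg_labels = block_average(
            features[keep], blocks[keep], np.asarray(labels)[keep]
        )
        for fold in range(cfg.n_blocks):
            test_sel = avg_blocks == fold
            train_x, train_y = averages[~test_sel], avg_labels[~test_sel]
            test_x, test_y = averages[test_sel], avg_labels[test_sel]
            total += test_y.size
            for ti in range(n_t):
                pred = decode_timepoint(train_x[..., ti], train_y, test_x[..., ti], c=cfg.svm_c)
                correct[ti] += np.sum(pred == test_y)
    return correct / total


def decode_timecourse(
    tfr: TFRSet, trial_info: pd.DataFrame, cfg: DecodingConfig, condition: str = "selective"
) -> DecodingResult:
    """Run the full decoding chain for every participant in ``trial_info``.

    For the selective condition, the left/right contrast uses the
    horizontal-cue trials and the top/bottom contrast the vertical-cue
    trials (the target location label).  For the neutral condition the same
    two contrasts are run on all neutral trials, labelled by their encoded
    locations.  Accuracies are averaged over iterations, folds and
    contrasts, then smoothed.  Deterministic given ``cfg.seed``.
    """
    for col in ("participant_id", "condition", "cue_axis"):
        if col not in trial_info.columns:
            raise ValueError(f"trial_info is missing column {col!r}")
    features_all = select_alpha_features(tfr, cfg.alpha_band)
    lo, hi = cfg.time_window
    tmask = (tfr.times >= lo) & (tfr.times <= hi)
    tidx = np.flatnonzero(tmask)[:: cfg.subsample]
    times = tfr.times[tidx]
    features_all = features_all[..., tidx]

    participant_ids = sorted(trial_info["participant_id"].unique())
    accuracy = np.zeros((len(participant_ids), times.size))
    for p, pid in enumerate(participant_ids):
        p_mask = (trial_info["participant_id"] == pid).to_numpy()
        acc_contrasts = []
        for ci, (label_col, classes) in enumerate(cfg.contrasts):
            if label_col not in trial_info.columns:
                raise ValueError(f"trial_info is missing contrast label column {label_col!r}")
            if condition == "selective":
                axis = "horizontal" if label_col == "lateral_location" else "vertical"
                sel = p_mask & (trial_info["condition"] == "selective").to_numpy() & (
                    trial_info["cue_axis"] == axis
                ).to_numpy()
            else:
                sel = p_mask & (trial_info["condition"] == "neutral").to_numpy()
            labels = trial_info.loc[sel, label_col].to_numpy()
            if not set(np.unique(labels)) == set(classes):
                raise ValueError(
                    f"contrast {classes} needs both labels present for participant {pid}"
                )
            rng = np.random.default_rng([cfg.seed, int(pid), ci])
            acc_contrasts.append(_decode_one_contrast(features_all[sel], labels, cfg, rng))
        accuracy[p] = smooth_moving_average(np.mean(acc_contrasts, axis=0), cfg.smoothing_points)

    return DecodingResult(
        accuracy=accuracy,
        times=times,
        chance=0.5,
        participant_ids=[int(p) for p in participant_ids],
        config={**asdict(cfg), "condition": condition},
    )
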