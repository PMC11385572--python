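"""Contralateral/ipsilateral alpha-power and ERP (PCN) time courses.

Lateralized analyses are defined relative to the lateral target location:
for a left-side target the contralateral signal is the mean over the
right-hemisphere members of the chosen posterior electrode pairs and the
ipsilateral signal the mean over the left-hemisphere members (mirrored for
right-side targets).  Trials whose selective cue marked the vertical axis
have no lateral target and are excluded; neutral trials keep their encoded
lateral location as the side definition, since both encoded locations
remain relevant under a neutral cue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EpochSet, LateralizationSeries, TFRSet
from .montage import Montage, PCN_PAIR, POSTERIOR_CLUSTER_PAIRS
from .tfr import ALPHA_BAND


def select_lateral_trials(trial_info: pd.DataFrame, condition: str) -> np.ndarray:
    """Boolean mask of trials with a defined lateral target side.

    selective -> only horizontal-cue selective trials (the vertical-cue half
    is dropped); neutral -> all neutral trials, sided by their encoded
    lateral location.
    """
    if condition not in ("selective", "neutral"):
        raise ValueError(f"condition must be 'selective' or 'neutral', got {condition!r}")
    if condition == "selective":
        mask = (trial_info["condition"] == "selective") & (
            trial_info["cue_axis"] == "horizontal"
        )
    else:
        mask = trial_info["condition"] == "neutral"
    mask = mask.to_numpy()
    if not mask.any():
        raise ValueError(f"no lateral trials retained for condition {condition!r}")
    return mask


def contra_ipsi_split(
    data: np.ndarray,
    sides: np.ndarray,
    montage: Montage,
    cluster_pairs: list[tuple[str, str]] = POSTERIOR_CLUSTER_PAIRS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial contralateral and ipsilateral means over an electrode cluster.

    ``data`` is trials x channels x ... (any trailing axes); ``sides`` gives
    each trial's lateral target side ('left'/'right').  Returns per-trial
    arrays with the channel axis averaged out.
    """
    sides = np.asarray(sides)
    if sides.size != data.shape[0]:
        raise ValueError("sides must have one entry per trial")
    bad = set(np.unique(sides)) - {"left", "right"}
    if bad:
        raise ValueError(f"sides must be 'left' or 'right', got {sorted(bad)}")
    left_idx, right_idx = [], []
    for left_ch, right_ch in cluster_pairs:
        for ch in (left_ch, right_ch):
            if ch not in montage.channel_names:
                raise ValueError(f"channel {ch!r} missing from montage")
        left_idx.append(montage.index(left_ch))
        right_idx.append(montage.index(right_ch))
    left_mean = data[:, left_idx].mean(axis=1)
    right_mean = data[:, right_idx].mean(axis=1)
    is_left = sides == "left"
    # contralateral = opposite hemisphere to the target side
    contra = np.where(is_left[(...,) + (None,) * (left_mean.ndim - 1)], right_mean, left_mean)
    ipsi = np.where(is_left[(...,) + (None,) * (left_mean.ndim - 1)], left_mean, right_mean)
    return contra, ipsi


def alpha_lateralization(
    tfr_db: TFRSet,
    montage: Montage,
    condition: str = "selective",
    band: tuple[float, float] = ALPHA_BAND,
    cluster_pairs: list[tuple[str, str]] = POSTERIOR_CLUSTER_PAIRS,
) -> LateralizationSeries:
    """Contra/ipsi alpha-power (dB) series per participant over the posterior cluster.

    Power is averaged over the closed frequency band, the cluster electrode
    pairs and the retained lateral trials, per participant and condition.
    """
    if tfr_db.units != "dB":
        raise ValueError("alpha_lateralization expects dB-baselined power")
    fidx = tfr_db.band_indices(band)
    mask = select_lateral_trials(tfr_db.trial_info, condition)
    info = tfr_db.trial_info.loc[mask]
    band_power = tfr_db.power[mask][:, :, fidx, :].mean(axis=2)  # trials x ch x time
    contra_t, ipsi_t = contra_ipsi_split(
        band_power, info["lateral_location"].to_numpy(), montage, cluster_pairs
    )
    pids = sorted(info["participant_id"].unique())
    contra, ipsi, n_used = [], [], []
    for pid in pids:
        sel = (info["participant_id"] == pid).to_numpy()
        contra.append(contra_t[sel].mean(axis=0))
        ipsi.append(ipsi_t[sel].mean(axis=0))
        n_used.append(int(sel.sum()))
    return LateralizationSeries(
        contra=np.stack(contra),
        ipsi=np.stack(ipsi),
        times=tfr_db.times.copy(),
        electrode_cluster=list(cluster_pairs),
        signal_kind="alpha_power",
        band=band,
        participant_ids=[int(p) for p in pids],
        n_trials_used=n_used,
    )


def compute_erp(epochs: EpochSet, baseline: tuple[float, float] = (-200.0, 0.0)) -> np.ndarray:
    """Baseline-corrected single-trial voltages (trials x channels x time, uV)."""
    lo, hi = baseline
    mask = (epochs.times >= lo) & (epochs.times <= hi)
    if not mask.any():
        raise ValueError(f"baseline window {baseline} lies outside the epoch")
    data = np.asarray(epochs.data, dtype=float)
    return data - data[:, :, mask].mean(axis=2, keepdims=True)


def pcn_series(
    epochs: EpochSet,
    montage: Montage,
    condition: str = "selective",
    baseline: tuple[float, float] = (-200.0, 0.0),
    pairs: list[tuple[str, str]] = [PCN_PAIR],
    smooth_ms: float | None = None,
) -> LateralizationSeries:
    """Contra/ipsi ERP time courses at PO7/PO8; the difference estimates the PCN.

    ``smooth_ms`` optionally applies a moving-average low-pass of that width
    to the trial-averaged series (off by default).
    """
    erp = compute_erp(epochs, baseline)
    mask = select_lateral_trials(epochs.trial_info, condition)
    info = epochs.trial_info.loc[mask]
    contra_t, ipsi_t = contra_ipsi_split(
        erp[mask], info["lateral_location"].to_numpy(), montage, pairs
    )
    pids = sorted(info["participant_id"].unique())
    contra, ipsi, n_used = [], [], []
    for pid in pids:
        sel = (info["participant_id"] == pid).to_numpy()
        contra.append(contra_t[sel].mean(axis=0))
        ipsi.append(ipsi_t[sel].mean(axis=0))
        n_used.append(int(sel.sum()))
    contra = np.stack(contra)
    ipsi = np.stack(ipsi)
    if smooth_ms is not None:
        from .decoding import smooth_moving_average

        w = max(1, int(round(smooth_ms * epochs.sfreq / 1000.0)))
        w += 1 - w % 2  # next odd
        contra = smooth_moving_average(contra, w)
        ipsi = smooth_moving_average(ipsi, w)
    return LateralizationSeries(
        contra=contra,
        ipsi=ipsi,
        times=epochs.times.copy(),
        electrode_cluster=list(pairs),
        signal_kind="erp",
        band=None,
        participant_ids=[int(p) for p in pids],
        n_trials_used=n_used,
    )
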