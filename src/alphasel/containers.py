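"""In-memory and on-disk containers for epoched EEG, TFR power and results.

The on-disk convention is deliberately simple and language-portable: one
little-endian ``.npy`` array per container plus a JSON metadata sidecar
(sampling rate, time axis in ms, channel labels, per-trial metadata).
Behavioral tables travel as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

TRIAL_COLUMNS = [
    "participant_id",
    "object_id",
    "condition",
    "cue_axis",
    "lateral_location",
    "vertical_location",
]


@dataclass
class EpochSet:
    """Epoched multichannel EEG: trials x channels x time, in microvolts.

    ``times`` is in milliseconds relative to object onset; ``trial_info``
    carries one row per trial (condition, cue axis, encoded locations).
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channel_names: list[str]
    trial_info: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be trials x channels x time")
        n_trials, n_ch, n_times = self.data.shape
        if n_ch != len(self.channel_names):
            raise ValueError("channel_names length does not match data")
        if n_times != self.times.size:
            raise ValueError("times length does not match data")
        if len(self.trial_info) != n_trials:
            raise ValueError("trial_info rows do not match number of trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_index(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    def resample(self, sfreq_new: float) -> "EpochSet":
        """Polyphase resampling along time (e.g. 1000 Hz -> 250 Hz)."""
        from fractions import Fraction

        frac = Fraction(sfreq_new / self.sfreq).limit_denominator(1000)
        up, down = frac.numerator, frac.denominator
        data = resample_poly(self.data.astype(float), up, down, axis=-1)
        n_new = data.shape[-1]
        times = self.times[0] + np.arange(n_new) * 1000.0 / sfreq_new
        return EpochSet(
            data=data.astype(self.data.dtype),
            times=times,
            sfreq=float(sfreq_new),
            channel_names=list(self.channel_names),
            trial_info=self.trial_info.reset_index(drop=True),
        )

    def save(self, directory: str | Path, name: str = "epochs") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / f"{name}.npy", self.data)
        meta = {
            "kind": "EpochSet",
            "sfreq": self.sfreq,
            "times_ms": self.times.tolist(),
            "channel_names": list(self.channel_names),
            "trial_info": self.trial_info.to_dict(orient="list"),
        }
        (directory / f"{name}.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path, name: str = "epochs") -> "EpochSet":
        directory = Path(directory)
        data = np.load(directory / f"{name}.npy")
        meta = json.loads((directory / f"{name}.json").read_text())
        if meta.get("kind") != "EpochSet":
            raise ValueError(f"{name}.json does not describe an EpochSet")
        return cls(
            data=data,
            times=np.asarray(meta["times_ms"], dtype=float),
            sfreq=float(meta["sfreq"]),
            channel_names=meta["channel_names"],
            trial_info=pd.DataFrame(meta["trial_info"]),
        )


@dataclass
class TFRSet:
    """Oscillatory power: trials x channels x frequencies x time.

    ``units`` is ``'raw'`` (squared microvolts, arbitrary wavelet scale) or
    ``'dB'`` after decibel baseline normalization.  ``edge_samples`` records,
    per frequency, how many samples at each end of the epoch are contaminated
    by the wavelet's zero-padded edges (half the wavelet length).
    """

    power: np.ndarray
    times: np.ndarray
    frequencies: np.ndarray
    sfreq: float
    channel_names: list[str]
    trial_info: pd.DataFrame
    units: str = "raw"
    baseline_window: tuple[float, float] | None = None
    edge_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power)
        self.times = np.asarray(self.times, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.power.ndim != 4:
            raise ValueError("TFRSet.power must be trials x channels x frequencies x time")
        if self.units not in ("raw", "dB"):
            raise ValueError("units must be 'raw' or 'dB'")
        n_trials, n_ch, n_freq, n_times = self.power.shape
        if n_ch != len(self.channel_names):
            raise ValueError("channel_names length does not match power")
        if n_freq != self.frequencies.size:
            raise ValueError("frequencies length does not match power")
        if n_times != self.times.size:
            raise ValueError("times length does not match power")
        if len(self.trial_info) != n_trials:
            raise ValueError("trial_info rows do not match number of trials")

    def band_indices(self, band: tuple[float, float]) -> np.ndarray:
        """Indices of family frequencies inside the closed interval ``band``."""
        lo, hi = band
        idx = np.flatnonzero((self.frequencies >= lo) & (self.frequencies <= hi))
        if idx.size == 0:
            raise ValueError(f"no family frequency inside band {band}")
        return idx

    def save(self, directory: str | Path, name: str = "tfr") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / f"{name}.npy", self.power)
        meta = {
            "kind": "TFRSet",
            "sfreq": self.sfreq,
            "times_ms": self.times.tolist(),
            "frequencies_hz": self.frequencies.tolist(),
            "channel_names": list(self.channel_names),
            "trial_info": self.trial_info.to_dict(orient="list"),
            "units": self.units,
            "baseline_window": self.baseline_window,
            "edge_samples": None if self.edge_samples is None else np.asarray(self.edge_samples).tolist(),
        }
        (directory / f"{name}.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path, name: str = "tfr") -> "TFRSet":
        directory = Path(directory)
        power = np.load(directory / f"{name}.npy")
        meta = json.loads((directory / f"{name}.json").read_text())
        if meta.get("kind") != "TFRSet":
            raise ValueError(f"{name}.json does not describe a TFRSet")
        bw = meta.get("baseline_window")
        return cls(
            power=power,
            times=np.asarray(meta["times_ms"], dtype=float),
            frequencies=np.asarray(meta["frequencies_hz"], dtype=float),
            sfreq=float(meta["sfreq"]),
            channel_names=meta["channel_names"],
            trial_info=pd.DataFrame(meta["trial_info"]),
            units=meta["units"],
            baseline_window=None if bw is None else tuple(bw),
            edge_samples=None
            if meta.get("edge_samples") is None
            else np.asarray(meta["edge_samples"], dtype=int),
        )


@dataclass
class DecodingResult:
    """Participants x time decoding accuracy with provenance."""

    accuracy: np.ndarray
    times: np.ndarray
    chance: float
    participant_ids: list[int]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.accuracy.ndim != 2:
            raise ValueError("accuracy must be participants x time")
        if self.accuracy.shape[1] != self.times.size:
            raise ValueError("times length does not match accuracy")
        if np.any(self.accuracy < 0) or np.any(self.accuracy > 1):
            raise ValueError("accuracy must lie in [0, 1]")

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.times >= lo) & (self.times <= hi)


@dataclass
class LateralizationSeries:
    """Contralateral / ipsilateral time courses over a posterior electrode set.

    ``signal_kind`` is ``'alpha_power'`` (dB) or ``'erp'`` (microvolts);
    ``diff`` is always contra minus ipsi.
    """

    contra: np.ndarray
    ipsi: np.ndarray
    times: np.ndarray
    electrode_cluster: list[tuple[str, str]]
    signal_kind: str
    band: tuple[float, float] | None
    participant_ids: list[int]
    n_trials_used: list[int]

    def __post_init__(self) -> None:
        self.contra = np.asarray(self.contra, dtype=float)
        self.ipsi = np.asarray(self.ipsi, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.contra.shape != self.ipsi.shape:
            raise ValueError("contra and ipsi must have the same shape")
        if self.signal_kind not in ("alpha_power", "erp"):
            raise ValueError("signal_kind must be 'alpha_power' or 'erp'")

    @property
    def diff(self) -> np.ndarray:
        return self.contra - self.ipsi


def save_behavior(table: pd.DataFrame, path: str | Path) -> None:
    """Write a behavioral table as CSV (participant_id,condition,correct,rt_ms,confidence)."""
    cols = ["participant_id", "condition", "correct", "rt_ms", "confidence"]
    table[cols].to_csv(path, index=False)


def load_behavior(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    expected = {"participant_id", "condition", "correct", "rt_ms", "confidence"}
    missing = expected - set(table.columns)
    if missing:
        raise ValueError(f"behavior table is missing columns: {sorted(missing)}")
    return table
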