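"""End-to-end orchestration of the three analysis arms on (synthetic) data.

``run_all`` binds the stages together: simulate (or load) epochs per
participant, wavelet-transform them, decode target location per condition,
test accuracy against chance and between conditions with sign-flip cluster
permutation tests, compute alpha lateralization and the PCN with paired
label-exchange cluster tests (within and between conditions), and summarize
behavior with paired contrasts.  The report carries full provenance (seeds,
config hash) and is byte-stable under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import behavior_stats
from .containers import EpochSet, TFRSet
from .decoding import DecodingConfig, crop_tfr_for_decoding, decode_timecourse
from .lateralization import alpha_lateralization, pcn_series
from .montage import Montage, make_montage
from .permstats import (
    ClusterResult,
    paired_cluster_permutation_test,
    sign_permutation_cluster_test,
)
from .simulate import SimConfig, generate_participant
from .tfr import ALPHA_BAND, build_wavelet_family, db_baseline, morlet_power

CONDITIONS = ("selective", "neutral")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    analysis_sfreq: float = 250.0
    decoding_window: tuple[float, float] = (500.0, 2000.0)
    lateralization_window: tuple[float, float] = (500.0, 1500.0)
    n_perm_sign: int = 100_000
    n_perm_paired: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        t0, t1 = self.sim.epoch_window
        for name in ("decoding_window", "lateralization_window"):
            lo, hi = getattr(self, name)
            if not (t0 <= lo < hi <= t1):
                raise ValueError(f"{name} {(lo, hi)} must lie inside epoch window {(t0, t1)}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cluster_report(result: ClusterResult) -> dict:
    return result.to_dict()


def run_all(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute simulation, decoding, lateralization/PCN and behavior arms.

    Returns the report dict; if ``out_dir`` is given, writes ``report.json``
    there (and raises on any stage failure, naming the stage).
    """
    montage = make_montage()
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.hash(),
            "config": json.loads(json.dumps(asdict(cfg), default=str)),
        }
    }

    stage = "simulate"
    try:
        # stream participants: keep only the cropped decoding TFR and the tiny
        # lateralization/PCN series per participant, never the full dataset
        family = build_wavelet_family(sfreq=cfg.analysis_sfreq)
        alpha_family = family.subset(ALPHA_BAND)
        behavior_tables = []
        decoding_tfrs = []
        lat_series_parts = {c: [] for c in CONDITIONS}
        pcn_series_parts = {c: [] for c in CONDITIONS}
        for pid in range(cfg.sim.n_participants):
            stage = "simulate"
            epochs, behavior = generate_participant(cfg.sim, pid, montage)
            if not np.isclose(cfg.sim.sfreq_native, cfg.analysis_sfreq):
                epochs = epochs.resample(cfg.analysis_sfreq)
            behavior_tables.append(behavior)
            stage = "tfr"
            tfr_raw = morlet_power(epochs, alpha_family)
            tfr_db = db_baseline(tfr_raw)
            stage = "lateralization"
            for condition in CONDITIONS:
                lat_series_parts[condition].append(
                    alpha_lateralization(tfr_db, montage, condition=condition)
                )
                pcn_series_parts[condition].append(
                    pcn_series(epochs, montage, condition=condition)
                )
            del tfr_db
            stage = "decoding"
            decoding_tfrs.append(crop_tfr_for_decoding(tfr_raw, cfg.decoding))
            del tfr_raw, epochs
        behavior_table = pd.concat(behavior_tables, ignore_index=True)

        stage = "decoding"
        decoding_results = {}
        merged_raw = _concat_tfr(decoding_tfrs)
        decode_cfg = replace(cfg.decoding, subsample=1)  # grid already cropped
        for condition in CONDITIONS:
            decoding_results[condition] = decode_timecourse(
                merged_raw, merged_raw.trial_info, decode_cfg, condition=condition
            )

        stage = "decoding-stats"
        decode_report = {}
        for condition in CONDITIONS:
            res = decoding_results[condition]
            test = sign_permutation_cluster_test(
                res.accuracy,
                res.times,
                null_value=res.chance,
                n_perm=cfg.n_perm_sign,
                alpha=cfg.alpha,
                sidedness="greater",
                window=cfg.decoding_window,
                rng=np.random.default_rng([cfg.seed, 11]),
            )
            decode_report[condition] = {
                "mean_accuracy": res.accuracy.mean(axis=0).tolist(),
                "times_ms": res.times.tolist(),
                "vs_chance": _cluster_report(test),
            }
        between = sign_permutation_cluster_test(
            decoding_results["selective"].accuracy - decoding_results["neutral"].accuracy,
            decoding_results["selective"].times,
            null_value=0.0,
            n_perm=cfg.n_perm_sign,
            alpha=cfg.alpha,
            sidedness="two-sided",
            window=cfg.decoding_window,
            rng=np.random.default_rng([cfg.seed, 12]),
        )
        decode_report["selective_vs_neutral"] = _cluster_report(between)
        report["decoding"] = decode_report

        stage = "lateralization-stats"
        lat_report = {}
        lat_series = {}
        for condition in CONDITIONS:
            per_p = lat_series_parts[condition]
            contra = np.concatenate([s.contra for s in per_p])
            ipsi = np.concatenate([s.ipsi for s in per_p])
            times = per_p[0].times
            lat_series[condition] = (contra, ipsi, times)
            test = paired_cluster_permutation_test(
                contra,
                ipsi,
                times,
                n_perm=cfg.n_perm_paired,
                alpha=cfg.alpha,
                window=cfg.lateralization_window,
                rng=np.random.default_rng([cfg.seed, 21]),
            )
            lat_report[condition] = {
                "mean_diff_db": (contra - ipsi).mean(axis=0).tolist(),
                "times_ms": times.tolist(),
                "contra_vs_ipsi": _cluster_report(test),
            }
        diff_sel = lat_series["selective"][0] - lat_series["selective"][1]
        diff_neu = lat_series["neutral"][0] - lat_series["neutral"][1]
        between = paired_cluster_permutation_test(
            diff_sel,
            diff_neu,
            lat_series["selective"][2],
            n_perm=cfg.n_perm_paired,
            alpha=cfg.alpha,
            window=cfg.lateralization_window,
            rng=np.random.default_rng([cfg.seed, 22]),
        )
        lat_report["selective_vs_neutral"] = _cluster_report(between)
        report["alpha_lateralization"] = lat_report

        stage = "pcn"
        pcn_report = {}
        pcn_diffs = {}
        for condition in CONDITIONS:
            per_p = pcn_series_parts[condition]
            contra = np.concatenate([s.contra for s in per_p])
            ipsi = np.concatenate([s.ipsi for s in per_p])
            times = per_p[0].times
            pcn_diffs[condition] = (contra - ipsi, times)
            test = paired_cluster_permutation_test(
                contra,
                ipsi,
                times,
                n_perm=cfg.n_perm_paired,
                alpha=cfg.alpha,
                window=cfg.lateralization_window,
                rng=np.random.default_rng([cfg.seed, 31]),
            )
            pcn_report[condition] = {
                "mean_diff_uv": (contra - ipsi).mean(axis=0).tolist(),
                "times_ms": times.tolist(),
                "contra_vs_ipsi": _cluster_report(test),
            }
        between = paired_cluster_permutation_test(
            pcn_diffs["selective"][0],
            pcn_diffs["neutral"][0],
            pcn_diffs["selective"][1],
            n_perm=cfg.n_perm_paired,
            alpha=cfg.alpha,
            window=cfg.lateralization_window,
            rng=np.random.default_rng([cfg.seed, 32]),
        )
        pcn_report["selective_vs_neutral"] = _cluster_report(between)
        report["pcn"] = pcn_report

        stage = "behavior"
        report["behavior"] = {
            measure: contrast.to_dict()
            for measure, contrast in behavior_stats(behavior_table).items()
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _concat_tfr(tfrs: list[TFRSet]) -> TFRSet:
    """Stack per-participant TFRSets along the trial axis."""
    first = tfrs[0]
    for t in tfrs[1:]:
        if not np.allclose(t.times, first.times) or not np.allclose(
            t.frequencies, first.frequencies
        ):
            raise ValueError("TFRSets have mismatching axes and cannot be concatenated")
    return TFRSet(
        power=np.concatenate([t.power for t in tfrs], axis=0),
        times=first.times.copy(),
        frequencies=first.frequencies.copy(),
        sfreq=first.sfreq,
        channel_names=list(first.channel_names),
        trial_info=pd.concat([t.trial_info for t in tfrs], ignore_index=True),
        units=first.units,
        edge_samples=first.edge_samples,
    )
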