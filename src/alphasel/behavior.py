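"""Retrieval-phase behavioral summaries and paired inference with Cohen's d_av.

Five measures are computed per participant and condition: accuracy (% of
correct location reports), RT over all trials, RT over correct trials only,
confidence (1-4) over all trials, and confidence over correct trials only.
Condition contrasts use paired t-tests; the effect size is Cohen's d_av,
the mean paired difference divided by the average of the two conditions'
(sample) standard deviations.  Published effect sizes of this form are
conventionally printed truncated to two decimals, which ``truncate2``
reproduces; internal values keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MEASURES = ["accuracy_pct", "rt_all_ms", "rt_correct_ms", "conf_all", "conf_correct"]
CONDITIONS = ("selective", "neutral")


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant x condition means of the five behavioral measures.

    Returns a tidy frame indexed by (participant_id, condition) with columns
    ``MEASURES``.  Raises if a participant lacks trials (or correct trials)
    in either condition, naming the offending cell.
    """
    required = {"participant_id", "condition", "correct", "rt_ms", "confidence"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"behavior table is missing columns: {sorted(missing)}")
    rows = []
    for pid, sub_p in table.groupby("participant_id"):
        for cond in CONDITIONS:
            sub = sub_p[sub_p["condition"] == cond]
            if len(sub) == 0:
                raise ValueError(f"participant {pid} has no trials in condition {cond!r}")
            correct = sub[sub["correct"].astype(bool)]
            if len(correct) == 0:
                raise ValueError(
                    f"participant {pid} has no correct trials in condition {cond!r} "
                    "(correct-only measures undefined)"
                )
            rows.append(
                {
                    "participant_id": pid,
                    "condition": cond,
                    "accuracy_pct": 100.0 * sub["correct"].astype(bool).mean(),
                    "rt_all_ms": sub["rt_ms"].mean(),
                    "rt_correct_ms": correct["rt_ms"].mean(),
                    "conf_all": sub["confidence"].mean(),
                    "conf_correct": correct["confidence"].mean(),
                }
            )
    return pd.DataFrame(rows).set_index(["participant_id", "condition"])


def cohens_d_av(mean_x: float, mean_y: float, sd_x: float, sd_y: float) -> float:
    """Paired-design effect size: (mean_x - mean_y) / ((sd_x + sd_y) / 2)."""
    denom = (sd_x + sd_y) / 2.0
    if denom == 0:
        return 0.0
    return (mean_x - mean_y) / denom


def truncate2(value: float) -> float:
    """Truncate toward zero at two decimals (the printed-report convention)."""
    return math.trunc(value * 100) / 100.0


@dataclass
class PairedContrast:
    """Paired t-test summary between two condition vectors."""

    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    t: float
    df: int
    p: float
    d_av: float
    ci95: tuple[float, float]
    zero_variance: bool = False

    def to_dict(self) -> dict:
        return {
            "mean_x": self.mean_x,
            "mean_y": self.mean_y,
            "sd_x": self.sd_x,
            "sd_y": self.sd_y,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "d_av": self.d_av,
            "ci95": list(self.ci95),
            "zero_variance": self.zero_variance,
        }


def paired_contrast(x: np.ndarray, y: np.ndarray) -> PairedContrast:
    """Paired t statistic, two-sided p, d_av and the 95% CI of the mean difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D and equally long, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 paired observations, got {n}")
    diff = x - y
    df = n - 1
    sd_diff = diff.std(ddof=1)
    mean_diff = diff.mean()
    zero_variance = sd_diff == 0
    if zero_variance:
        t_stat = 0.0
        p = 1.0
        ci = (mean_diff, mean_diff)
    else:
        se = sd_diff / np.sqrt(n)
        t_stat = float(mean_diff / se)
        p = float(2 * stats.t.sf(abs(t_stat), df))
        half = float(stats.t.ppf(0.975, df) * se)
        ci = (float(mean_diff - half), float(mean_diff + half))
    return PairedContrast(
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)),
        sd_y=float(y.std(ddof=1)),
        t=t_stat,
        df=df,
        p=p,
        d_av=float(cohens_d_av(x.mean(), y.mean(), x.std(ddof=1), y.std(ddof=1))),
        ci95=ci,
        zero_variance=bool(zero_variance),
    )


def behavior_stats(table: pd.DataFrame) -> dict:
    """Selective-vs-neutral paired contrasts for all five behavioral measures."""
    summary = summarize(table)
    out = {}
    for measure in MEASURES:
        wide = summary[measure].unstack("condition")
        contrast = paired_contrast(
            wide["selective"].to_numpy(), wide["neutral"].to_numpy()
        )
        out[measure] = contrast
    return out
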