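"""Behavioral contrasts with Cohen's d_av on a simulated retrieval phase.

Generates retrieval-phase behavior for 30 simulated participants and runs
the five paired selective-vs-neutral contrasts: accuracy, RT (all / correct
trials) and confidence (all / correct trials).
"""

import numpy as np
import pandas as pd

import alphasel as a
from alphasel.simulate import _generate_behavior

cfg = a.SimConfig(n_participants=30, n_objects=120, reps_per_object=1, seed=4)
tables = []
for pid in range(cfg.n_participants):
    rng = np.random.default_rng([cfg.seed, pid])
    trials = a.make_trial_table(cfg, pid, rng)
    tables.append(_generate_behavior(cfg, pid, trials, rng))
table = pd.concat(tables, ignore_index=True)

stats = a.behavior_stats(table)
print(f"{'measure':<14} {'M_sel':>9} {'M_neu':>9} {'t':>7} {'p':>8} {'d_av':>6}")
for measure, res in stats.items():
    print(f"{measure:<14} {res.mean_x:>9.2f} {res.mean_y:>9.2f} "
          f"{res.t:>7.2f} {res.p:>8.4f} {a.truncate2(res.d_av):>6.2f}")
print("\nExpected pattern: faster RTs and higher confidence after selective "
      "cues (negative RT t, positive confidence t) with no accuracy "
      "difference — the behavioral signature of goal-directed retrieval "
      "increasing accessibility, not representation strength.")
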