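"""Time-resolved decoding of the cued target location from alpha power.

Simulates a few participants, decodes left/right and top/bottom target
location per timepoint (block-averaged 3-fold cross-validated linear SVM,
10 iterations), and tests the group accuracy against the 50% chance level
with the sign-flip cluster permutation test.
"""

import numpy as np

import alphasel as a
from alphasel.pipeline import _concat_tfr

# at least 6 participants: the one-sided sign-flip test needs 2^n sign
# patterns, so n=4 could never reach p < 0.05
sim = a.SimConfig(n_participants=6, n_objects=24, reps_per_object=3,
                  sfreq_native=250.0, seed=2)
family = a.build_wavelet_family(sfreq=250.0).subset(a.ALPHA_BAND)
cfg = a.DecodingConfig(seed=2)
tfrs = []
for pid in range(sim.n_participants):
    epochs, _ = a.generate_participant(sim, pid)
    tfrs.append(a.crop_tfr_for_decoding(a.morlet_power(epochs, family), cfg))
merged = _concat_tfr(tfrs)

from dataclasses import replace
result = a.decode_timecourse(merged, merged.trial_info,
                             replace(cfg, subsample=1), condition="selective")
window = result.window_mask((500.0, 2000.0))
print(f"group accuracy, 500-2000 ms: {result.accuracy[:, window].mean():.3f} "
      f"(chance {result.chance})")
pre = result.window_mask((-200.0, 400.0))
print(f"group accuracy before the cue: {result.accuracy[:, pre].mean():.3f}")

test = a.sign_permutation_cluster_test(
    result.accuracy, result.times, null_value=result.chance,
    n_perm=5000, sidedness="greater", window=(500.0, 2000.0), rng=0)
for c in test.clusters:
    flag = "significant" if c.significant else "n.s."
    print(f"cluster {c.start_ms:.0f}-{c.end_ms:.0f} ms, mass {c.cluster_stat:.1f}, "
          f"p={c.p_value:.4f} ({flag})")
print("Above-chance post-cue accuracy with a significant cluster shows that "
      "the alpha-power scalp topography carries the retrieved target location; "
      "pre-cue accuracy stays at chance because the location-specific pattern "
      "is injected only after the cue.")
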