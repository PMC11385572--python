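"""One-call pipeline run: simulation, decoding, lateralization, PCN, behavior.

Runs the complete analysis chain at desk scale (8 participants, reduced
permutation counts) and prints which analyses produced significant clusters
per condition.  With the default injected effects the selective condition
shows all three EEG signatures and the neutral condition none.  (At this
small group size the behavioral RT contrast is underpowered; study-scale
behavior is shown in example 05.)
"""

import alphasel as a

cfg = a.RunConfig(
    sim=a.SimConfig(n_participants=8, n_objects=48, reps_per_object=3,
                    sfreq_native=250.0, seed=42),
    decoding=a.DecodingConfig(seed=42),
    n_perm_sign=2000,
    n_perm_paired=2000,
    seed=42,
)
report = a.run_all(cfg, out_dir="scratch/pipeline_run")


def describe(cluster_report):
    sig = [c for c in cluster_report["clusters"] if c["significant"]]
    if not sig:
        return "none"
    return ", ".join(f"{c['start_ms']:.0f}-{c['end_ms']:.0f} ms (p={c['p_value']:.4f})"
                     for c in sig)


for cond in ("selective", "neutral"):
    print(f"{cond}:")
    print(f"  decoding vs chance : {describe(report['decoding'][cond]['vs_chance'])}")
    print(f"  alpha contra<ipsi  : {describe(report['alpha_lateralization'][cond]['contra_vs_ipsi'])}")
    print(f"  PCN contra<ipsi    : {describe(report['pcn'][cond]['contra_vs_ipsi'])}")
rt = report["behavior"]["rt_all_ms"]
print(f"behavior RT (all trials): t({rt['df']})={rt['t']:.2f}, p={rt['p']:.4f}, "
      f"d_av={rt['d_av']:.2f}")
print("\nSignificant clusters only in the selective condition reproduce the "
      "dissociation the pipeline is built to detect: attentional selection "
      "of one remembered location is visible in decoding accuracy, "
      "lateralized alpha power and the PCN, while the neutral cue leaves "
      "no lateralized trace.")
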