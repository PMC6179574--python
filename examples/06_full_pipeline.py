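"""Full pipeline: the headline dissociation at cohort level.

Runs generate -> preprocess -> decode (gaze, within-task MEG, localizer-
trained) -> cluster statistics for a small simulated cohort in the
confound-only world and prints the machine-readable verdict.  Writes the
complete report bundle (TSV profiles and matrices, cluster tables,
summary.json) under ./gazedecode_output.

Takes around a minute.
"""

import json

from gazedecode import GeneratorConfig, PipelineConfig, run_full

cfg = PipelineConfig(
    generator=GeneratorConfig(n_subjects=8, n_sensors=48,
                              sample_rate_hz=60.0, delay_s=3.0,
                              localizer_trials_per_orientation=60, seed=0),
    n_perm=1000, tg_decim=2, localizer_train_decim=2,
    out_dir="gazedecode_output", seed=1,
)
summary = run_full(cfg)

print("\nheadline:", json.dumps(summary["headline"], indent=2))
print("\nmean target-class posterior in the delay, within-task MEG:")
for cond, value in summary["condition_means_delay"]["meg"].items():
    print(f"  {cond:6s} {value:.3f}   (chance 0.333)")
print("\nmean rho in the delay, localizer-trained:")
for cond, value in summary["condition_means_delay"]["localizer"].items():
    print(f"  {cond:6s} {value:+.3f}  (chance 0)")

# Within-task delay decoding is significant (eye movements), while the
# localizer-trained decoder -- trained on data without systematic eye
# movements -- finds nothing in the same delay period.
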