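"""Score a synthetic segment with the rule-based mini-epoch scorer.

Renders one clean 20-min segment with the default 30.8% characteristic
suppression, scores it mini-epoch by mini-epoch with the AASM-style rules
(alpha >50% -> W, slow waves >50% -> N3, graphoelements -> N1/N2/REM,
context for the rest), and compares against the planted ground truth.
"""

from minisleep import (
    build_confusion,
    f1_report,
    sample_hypnogram,
    score_segment,
    synthesize_signals,
)
from minisleep.types import SimConfig, SubjectMeta

meta = SubjectMeta("demo", "SIB", 25.0, "F", "fam-demo")
cfg = SimConfig(record_duration=1200.0, p_no_char=0.308, p_artifact=0.0,
                noise_scale=0.0)

truth = sample_hypnogram(cfg, meta, rng_seed=0)
recording, events = synthesize_signals(truth, cfg, rng_seed=1, meta=meta)
print(f"rendered {len(truth)} mini-epochs with {len(events)} graphoelements, "
      f"{int((~truth.char_flag).sum())} suppressed ('without characteristics')")

scored = score_segment(recording)
report = f1_report(build_confusion(truth, scored))

print("\nagreement with planted truth (per-stage F1):")
for stage in ("W", "N1", "N2", "N3", "REM"):
    v = report.f1[stage]
    print(f"  {stage:3s} {'—' if v is None else f'{v:.3f}'}"
          f"  (support {report.support[stage]})")
print(f"overall weighted F1: {report.overall_weighted_f1:.3f}")

# W and N3 are recovered exactly (their >50% coverage rules are mandatory);
# errors concentrate in suppressed N1/N2/REM mini-epochs near stage
# boundaries, where context resolution has to guess between neighbours.
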