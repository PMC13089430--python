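"""Agreement and fragmentation statistics on a synthetic cohort.

Generates ground-truth hypnograms for a 30-recording NT1/sibling cohort and
walks through the evaluation stack: the mini-epoch vs 30-s epoch transition
contrast (paired Wilcoxon with r = Z/sqrt(n)), and the NT1-vs-sibling
difference in sleep-wake transition rate (linear mixed model with a family
random intercept, age/sex adjusted, sqrt-transformed outcome, Cohen's d).
"""

import numpy as np

from minisleep import (
    collapse_to_epochs,
    expand_epochs,
    group_compare_lmm,
    paired_compare,
    sample_hypnogram,
    transition_stats,
)
from minisleep.synth import sample_metadata, select_segment_windows
from minisleep.types import SimConfig

cfg = SimConfig(n_recordings=30, seed=4)
root = np.random.SeedSequence(cfg.seed)
kids = root.spawn(cfg.n_recordings + 1)
metas = sample_metadata(cfg, np.random.default_rng(kids[0]))

mini_rate, epoch_rate, sw_rate = [], [], []
for i, meta in enumerate(metas):
    hyp_ss, win_ss = kids[i + 1].spawn(2)
    hyp = sample_hypnogram(cfg, meta, hyp_ss)
    starts = select_segment_windows(
        len(hyp), cfg.period, cfg.lights_off, cfg.lights_on, cfg.n_segments,
        cfg.segment_minutes, np.random.default_rng(win_ss))
    segs = [hyp.slice(s, s + 240) for s in starts]
    ts = transition_stats(segs, meta.subject_id)
    mini_rate.append(ts.any_transitions_per_min)
    sw_rate.append(ts.sleep_wake_transitions_per_min)
    coarse = [expand_epochs(collapse_to_epochs(h)) for h in segs]
    epoch_rate.append(transition_stats(coarse).any_transitions_per_min)

print(f"mean transitions/min, 5-s mini-epochs:     {np.mean(mini_rate):.2f}")
print(f"mean transitions/min, 30-s epoch view:     {np.mean(epoch_rate):.2f}")
res = paired_compare(mini_rate, epoch_rate)
print(f"paired Wilcoxon: p = {res.p_value:.2e}, r = {res.effect_size:.2f}")

grp = group_compare_lmm(sw_rate, metas)
print(f"\nsleep-wake transitions/min, NT1 vs siblings ({grp.model}):")
print(f"  Cohen's d = {grp.effect_size:.2f}, p = {grp.p_value:.4f}")

# Majority-collapsing to 30-s epochs conceals most transitions, and the
# planted NT1 fragmentation (2.0 vs 1.5 transitions/min) surfaces as a
# positive group effect on the sleep-wake transition index.
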