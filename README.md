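# minisleep

A toolkit for **high-resolution sleep staging** at 5-second "mini-epoch"
resolution. Conventional AASM sleep scoring assigns one stage label per 30-s
epoch, which averages away brief wake intrusions and rapid stage shifts —
dynamics that matter in fragmented-sleep disorders such as narcolepsy type 1
(NT1). minisleep implements the full methodology needed to study and automate
mini-epoch scoring when clinical polysomnography (PSG) cannot be shared:

- **`synth`** — a synthetic PSG generator: semi-Markov stage sequences on the
  5-s grid with ground-truth hypnograms, stage-defining graphoelements
  (alpha runs, spindles, K-complexes, slow waves, vertex waves, slow/rapid
  eye movements) rendered on the standard 8-derivation EEG/EOG montage at
  256 Hz, "without characteristics" suppression, artifact bursts, and an
  NT1-vs-sibling cohort structure with family clustering.
- **`rules`** — a deterministic rule-based mini-epoch scorer: W when alpha
  activity covers >50% of the mini-epoch, N3 when ≥75 µV slow waves cover
  >50%, N1/N2/REM from their graphoelements, predominance by evidence
  duration when stages compete, and two-pass context resolution for
  mini-epochs without characteristics.
- **`netmodel`** — a fully-convolutional encoder–decoder segmentation network
  (NumPy, hand-written backprop) with a configurable output period: the
  segment classifier mean-pools decoded features over 30 s or 5 s, so a model
  trained at epoch resolution transfers to mini-epochs with every parameter
  intact. Inputs are EEG×EOG pairs resampled to 128 Hz, robust-scaled and
  outlier-clipped; predictions are majority-voted over all 12 channel pairs.
- **`transfer`** — recording-level stratified 80/10/10 splits (both segments
  of a PSG stay together — no leakage), fivefold cross-validation, and an
  Adam + cross-entropy fine-tuning loop with validation-F1 patience that
  returns the best-validation checkpoint.
- **`evalstats`** — the evaluation stack: per-recording confusion matrices
  (artifacts excluded), per-stage precision/recall/F1 with absent-stage
  handling, prevalence-weighted overall
  F1 = Σ<sub>s</sub> w<sub>s</sub> · 2·P<sub>s</sub>R<sub>s</sub>/(P<sub>s</sub>+R<sub>s</sub>),
  percentile-bootstrap means and 95% CIs (n = 1000), Wilcoxon signed-rank
  with effect size r = Z/√n, row/column confusion normalization, 30-s→5-s
  epoch expansion, transition and sleep–wake transition indices, and a linear
  mixed model (family random intercept, age/sex adjusted, √-transformed
  outcome) reporting Cohen's d = β<sub>group</sub>/σ̂<sub>resid</sub>.
- **`iohub`** — EDF writing/reading (16-bit, µV; read via MNE), hypnogram and
  metadata TSVs, dataset manifests, and a seeded end-to-end pipeline.

## Worked example

`examples/02_rule_scoring.py` renders one clean 20-min segment (240
mini-epochs) with the default 30.8% characteristic suppression and scores it
with the rule-based scorer:

```
rendered 240 mini-epochs with 187 graphoelements, 53 suppressed ('without characteristics')

agreement with planted truth (per-stage F1):
  W   1.000  (support 23)
  N1  0.947  (support 9)
  N2  0.961  (support 77)
  N3  1.000  (support 56)
  REM 0.953  (support 75)
overall weighted F1: 0.971
```

W and N3 are recovered exactly — their >50%-coverage rules are mandatory and
construction-matched — while the residual errors sit in suppressed N1/N2/REM
mini-epochs near stage boundaries, where context resolution must choose
between neighbours.

`examples/03_transfer_learning.py` shows the central transfer result at desk
scale: a compact segmenter pretrained only on 30-s majority labels, then
fine-tuned at 5 s:

```
held-out mini-epoch overall F1, pretrained at 30 s: 0.455
held-out mini-epoch overall F1, fine-tuned at 5 s:  0.635
```

The pretrained model over-smooths (it was never shown sub-epoch structure);
fine-tuning every component at the higher resolution recovers short stage
intrusions and raises held-out mini-epoch F1. The other examples cover
dataset simulation, the agreement/fragmentation statistics (mini-epoch
scoring surfaces roughly twice the transitions of the 30-s epoch view, and
the planted NT1 fragmentation appears as a positive Cohen's d on the
sleep–wake transition index), and the full seeded pipeline.

A thin CLI mirrors the library:
`minisleep simulate|score-rules|train|finetune|predict|evaluate|compare|run`.

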