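"""Dataset splitting, training, fine-tuning and cross-validation.

Splits are made at the recording level so both 20-min segments of a PSG stay
in one set (leakage guard), stratified on group and sex.  Training iterates
minibatches of (channel pair, window) samples over all 12 EEG x EOG pairs
with a cross-entropy loss (artifact mini-epochs masked); convergence is
monitored by prevalence-weighted F1 on the validation set with a patience
counter, and the returned weights are those of the best-validation step, not
the last one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evalstats, netmodel, nn
from .types import (
    EEG_CHANNELS,
    EOG_CHANNELS,
    STAGE_INDEX,
    MiniEpochHypnogram,
    Recording,
    SubjectMeta,
)

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class SplitPlan:
    assignment: dict  # recording_id -> split name
    counts: dict
    stratification: pd.DataFrame

    def ids(self, split: str) -> list[str]:
        return [rid for rid, s in self.assignment.items() if s == split]


def _largest_remainder(total_by_stratum: dict, sizes: tuple[int, ...]) -> dict:
    """Allocate each stratum's recordings across splits, preserving
    proportions, with split totals exactly equal to ``sizes``."""
    n = sum(total_by_stratum.values())
    alloc = {g: [0] * len(sizes) for g in total_by_stratum}
    for si, target in enumerate(sizes):
        quotas = {g: total_by_stratum[g] * target / n for g in total_by_stratum}
        base = {g: int(np.floor(q)) for g, q in quotas.items()}
        short = target - sum(base.values())
        order = sorted(total_by_stratum, key=lambda g: quotas[g] - base[g],
                       reverse=True)
        for g in order[:short]:
            base[g] += 1
        for g in total_by_stratum:
            alloc[g][si] = base[g]
    # repair any stratum over-allocation caused by independent split rounding
    for g, n_g in total_by_stratum.items():
        while sum(alloc[g]) > n_g:
            si = int(np.argmax(alloc[g]))
            alloc[g][si] -= 1
        while sum(alloc[g]) < n_g:
            deficit = [sizes[si] - sum(alloc[h][si] for h in alloc)
                       for si in range(len(sizes))]
            si = int(np.argmax(deficit))
            alloc[g][si] += 1
    return alloc


def make_split(metas: list[SubjectMeta], sizes: tuple[int, int, int] = (80, 10, 10),
               rng_seed: int = 0) -> SplitPlan:
    """Recording-level random 80/10/10 assignment stratified on group and sex."""
    if sum(sizes) > len(metas):
        raise ValueError(f"sizes {sizes} exceed the {len(metas)} recordings")
    sizes = tuple(sizes)
    extra = len(metas) - sum(sizes)
    if extra:  # surplus recordings enlarge the training set
        sizes = (sizes[0] + extra, sizes[1], sizes[2])
    rng = np.random.default_rng(rng_seed)
    strata: dict[tuple[str, str], list[SubjectMeta]] = {}
    for m in metas:
        strata.setdefault((m.group, m.sex), []).append(m)
    alloc = _largest_remainder({g: len(v) for g, v in strata.items()}, sizes)
    assignment: dict[str, str] = {}
    for g, members in strata.items():
        members = list(members)
        rng.shuffle(members)
        i = 0
        for si, cnt in enumerate(alloc[g]):
            for m in members[i:i + cnt]:
                assignment[m.subject_id] = SPLIT_NAMES[si]
            i += cnt
    counts = {s: sum(v == s for v in assignment.values()) for s in SPLIT_NAMES}
    rows = []
    by_id = {m.subject_id: m for m in metas}
    for s in SPLIT_NAMES:
        ms = [by_id[r] for r, v in assignment.items() if v == s]
        if ms:
            rows.append({
                "split": s, "n": len(ms),
                "frac_nt1": np.mean([m.group == "NT1" for m in ms]),
                "frac_f": np.mean([m.sex == "F" for m in ms]),
                "mean_age": np.mean([m.age for m in ms]),
            })
    plan = SplitPlan(assignment=assignment, counts=counts,
                     stratification=pd.DataFrame(rows))
    assert len(set(plan.ids("train")) & set(plan.ids("test"))) == 0
    return plan


def make_cv_folds(metas: list[SubjectMeta], k: int = 5, val_size: int = 10,
                  rng_seed: int = 0) -> list[SplitPlan]:
    """k-fold CV: test sets partition the recordings into k disjoint sets;
    each fold draws ``val_size`` validation recordings from the rest."""
    n = len(metas)
    if k < 2:
        raise ValueError("k must be at least 2 (test partition undefined for k=1)")
    if n % k:
        raise ValueError(f"k={k} does not divide {n} recordings")
    rng = np.random.default_rng(rng_seed)
    ids = [m.subject_id for m in metas]
    order = list(ids)
    rng.shuffle(order)
    fold_size = n // k
    plans = []
    by_id = {m.subject_id: m for m in metas}
    for f in range(k):
        test = set(order[f * fold_size:(f + 1) * fold_size])
        rest = [r for r in order if r not in test]
        val = set(rng.choice(rest, size=val_size, replace=False))
        assignment = {}
        for rid in ids:
            assignment[rid] = ("test" if rid in test
                               else "val" if rid in val else "train")
        counts = {s: sum(v == s for v in assignment.values()) for s in SPLIT_NAMES}
        ms = lambda s: [by_id[r] for r, v in assignment.items() if v == s]
        rows = [{"split": s, "n": counts[s],
                 "frac_nt1": np.mean([m.group == "NT1" for m in ms(s)])}
                for s in SPLIT_NAMES]
        plans.append(SplitPlan(assignment=assignment, counts=counts,
                               stratification=pd.DataFrame(rows)))
    return plans


@dataclass
class TrainState:
    """Optimization state; ``patience`` counts evaluation rounds without a
    validation-F1 improvement before termination."""

    step: int = 0
    best_val_f1: float = -np.inf
    steps_since_best: int = 0
    patience: int = 500
    learning_rate: float = 1e-7
    max_steps: int = 1000
    batch_size: int = 8
    eval_interval: int = 1  # evaluate validation F1 every optimizer step
    val_pairs: int | None = None  # None = all 12 pairs


def labels_to_targets(hyp: MiniEpochHypnogram, output_period: float) -> np.ndarray:
    """Stage indices at the model's output resolution; ART -> -1 (masked).

    Coarser output periods take the majority label of the covered
    mini-epochs (ties to the earlier stage in canonical order)."""
    ratio = output_period / hyp.period
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9:
        raise ValueError("output_period must be a multiple of the hypnogram period")
    idx = np.array([STAGE_INDEX.get(lab, -1) for lab in hyp.labels])
    if r == 1:
        return idx
    n_out = len(idx) // r
    out = np.empty(n_out, dtype=int)
    for i in range(n_out):
        block = idx[i * r:(i + 1) * r]
        valid = block[block >= 0]
        if valid.size == 0:
            out[i] = -1
        else:
            counts = np.bincount(valid, minlength=5)
            out[i] = int(counts.argmax())
    return out


def prepare_pairs(rec: Recording, input_fs: float = 128.0) -> np.ndarray:
    """All 12 preprocessed EEG x EOG pairs of a segment: (12, 2, L)."""
    pairs = []
    for eeg_name in EEG_CHANNELS:
        eeg, fs = rec.get(eeg_name)
        for eog_name in EOG_CHANNELS:
            eog, _ = rec.get(eog_name)
            pairs.append(netmodel.preprocess(eeg, eog, fs, target_fs=input_fs))
    return np.stack(pairs)


def _val_f1(model: netmodel.SleepSegmenter, val_data: list[dict],
            n_pairs: int | None) -> float:
    """Prevalence-weighted F1 of voted predictions pooled over val segments."""
    refs, preds = [], []
    for seg in val_data:
        pairs = seg["pairs"] if n_pairs is None else seg["pairs"][:n_pairs]
        probs = []
        for pair in pairs:
            probs.append(netmodel.predict_pair(model, pair))
        votes = np.stack(probs).argmax(axis=2)
        t = votes.shape[1]
        lab = np.empty(t, dtype=int)
        for i in range(t):
            lab[i] = np.bincount(votes[:, i], minlength=5).argmax()
        mask = seg["targets"] >= 0
        refs.append(seg["targets"][mask])
        preds.append(lab[mask])
    ref = np.concatenate(refs)
    pred = np.concatenate(preds)
    cm = evalstats.confusion_from_indices(ref, pred)
    rep = evalstats.f1_report(cm)
    return rep.overall_weighted_f1 if rep.overall_weighted_f1 is not None else 0.0


def prepare_segments(segments: list[tuple[Recording, MiniEpochHypnogram]],
                     output_period: float, input_fs: float = 128.0) -> list[dict]:
    """Preprocess segments into training-ready pair stacks and targets."""
    out = []
    for rec, hyp in segments:
        out.append({
            "pairs": prepare_pairs(rec, input_fs).astype(np.float32),
            "targets": labels_to_targets(hyp, output_period),
        })
    return out


def finetune(
    model: netmodel.SleepSegmenter,
    train_data: list[dict],
    val_data: list[dict],
    state: TrainState | None = None,
    rng_seed: int = 0,
) -> tuple[netmodel.SleepSegmenter, list[dict]]:
    """Train/fine-tune with Adam + cross-entropy and validation-F1 patience.

    ``train_data``/``val_data`` come from :func:`prepare_segments` at the
    model's output period.  Returns the model restored to its best-validation
    weights together with the training log (step, loss, val_f1 records).
    """
    if not train_data:
        raise ValueError("empty training set")
    state = state or TrainState()
    rng = np.random.default_rng(rng_seed)
    opt = nn.Adam(model.params(), lr=state.learning_rate)
    pw = model.config.pool_samples
    win = model.config.window_samples
    out_per_win = win // pw

    log: list[dict] = []
    f1 = _val_f1(model, val_data, state.val_pairs) if val_data else 0.0
    state.best_val_f1 = f1
    best_weights = model.get_weights()
    log.append({"step": 0, "loss": None, "val_f1": f1})

    while state.step < state.max_steps:
        xs, ys = [], []
        for _ in range(state.batch_size):
            seg = train_data[rng.integers(len(train_data))]
            pair = seg["pairs"][rng.integers(len(seg["pairs"]))]
            n_out = len(seg["targets"])
            start = int(rng.integers(0, n_out - out_per_win + 1))
            xs.append(pair[:, start * pw:(start + out_per_win) * pw])
            ys.append(seg["targets"][start:start + out_per_win])
        x = np.stack(xs).astype(np.float64)
        y = np.stack(ys)
        opt.zero_grad()
        logits = model.forward(x, train=True)
        loss, dlogits = nn.masked_cross_entropy(logits, y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"NaN/inf loss at step {state.step}")
        model.backward(dlogits)
        opt.step()
        state.step += 1

        if val_data and state.step % state.eval_interval == 0:
            f1 = _val_f1(model, val_data, state.val_pairs)
            if f1 > state.best_val_f1:
                state.best_val_f1 = f1
                state.steps_since_best = 0
                best_weights = model.get_weights()
            else:
                state.steps_since_best += 1
            log.append({"step": state.step, "loss": loss, "val_f1": f1})
            if state.steps_since_best >= state.patience:
                break
        else:
            log.append({"step": state.step, "loss": loss, "val_f1": None})

    model.set_weights(best_weights)
    return model, log


def transfer_experiment(seed: int = 0, n_recordings: int = 12,
                        segment_minutes: float = 5.0,
                        sizes: tuple[int, int, int] = (7, 2, 3),
                        pretrain_steps: int = 150, finetune_steps: int = 300,
                        filters_base: int = 4) -> dict:
    """Desk-scale pretrain-at-30s / fine-tune-at-5s experiment.

    Generates a small synthetic cohort, pretrains a compact segmenter on
    30-s (majority-collapsed) labels, then fine-tunes all components at 5-s
    resolution, and reports held-out mini-epoch overall weighted F1 before
    and after fine-tuning (majority-voted over all 12 channel pairs).
    """
    from . import evalstats, synth
    from .types import SimConfig

    cfg = SimConfig(n_recordings=n_recordings, record_duration=1800.0,
                    n_segments=1, segment_minutes=segment_minutes, seed=seed)
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(n_recordings + 1)
    metas = synth.sample_metadata(cfg, np.random.default_rng(kids[0]))
    seg_len = int(round(segment_minutes * 60.0 / cfg.period))
    segs = []
    for i, m in enumerate(metas):
        hyp_ss, win_ss, sig_ss = kids[i + 1].spawn(3)
        hyp = synth.sample_hypnogram(cfg, m, hyp_ss)
        starts = synth.select_segment_windows(
            len(hyp), cfg.period, cfg.lights_off, cfg.lights_on, 1,
            segment_minutes, np.random.default_rng(win_ss))
        h = hyp.slice(starts[0], starts[0] + seg_len)
        rec, _ = synth.synthesize_signals(h, cfg, sig_ss, m)
        segs.append((m, rec, h))

    plan = make_split(metas, sizes=sizes, rng_seed=seed)
    by = {s: [x for x in segs if plan.assignment[x[0].subject_id] == s]
          for s in SPLIT_NAMES}
    pairs5 = {s: prepare_segments([(r, h) for _, r, h in by[s]], 5.0)
              for s in SPLIT_NAMES}
    # 30-s targets reuse the same preprocessed pairs
    pairs30 = {s: [{"pairs": seg5["pairs"],
                    "targets": labels_to_targets(h, 30.0)}
                   for seg5, (_, r, h) in zip(pairs5[s], by[s])]
               for s in ("train", "val")}

    mcfg = netmodel.ModelConfig(depth=2, filters_base=filters_base, kernel=9,
                                output_period=30.0, input_window=30.0)
    model = netmodel.SleepSegmenter(mcfg, rng_seed=seed)
    pre_state = TrainState(learning_rate=1e-3, max_steps=pretrain_steps,
                           batch_size=8, eval_interval=20, patience=10,
                           val_pairs=4)
    model, pre_log = finetune(model, pairs30["train"], pairs30["val"],
                              pre_state, rng_seed=seed)

    model5 = model.with_output_period(5.0)

    def held_out_f1(m):
        reps = []
        for (meta, rec, h) in by["test"]:
            pred = netmodel.predict_voted(m, rec, 5.0)
            cm = evalstats.build_confusion(h, pred, meta.subject_id)
            reps.append(evalstats.f1_report(cm))
        return float(np.mean([r.overall_weighted_f1 for r in reps]))

    f1_before = held_out_f1(model5)
    ft_state = TrainState(learning_rate=3e-4, max_steps=finetune_steps,
                          batch_size=8, eval_interval=20, patience=12,
                          val_pairs=4)
    model5, ft_log = finetune(model5, pairs5["train"], pairs5["val"],
                              ft_state, rng_seed=seed + 1)
    f1_after = held_out_f1(model5)
    return {"f1_before": f1_before, "f1_after": f1_after,
            "pretrain_log": pre_log, "finetune_log": ft_log,
            "model": model5}
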