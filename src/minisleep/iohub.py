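"""On-disk formats: EDF signals, hypnogram/metadata TSVs, dataset manifests.

Signals travel as plain EDF (16-bit, physical dimension uV, 1-s data
records) so any PSG viewer can open them.  Reading goes through
``mne.io.read_raw_edf``; writing uses a minimal EDF encoder implemented here.
Hypnograms are TSV with columns onset_sec, duration_sec, stage, char.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ALL_LABELS,
    MONTAGE,
    MiniEpochHypnogram,
    Recording,
    SubjectMeta,
)

# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, rec: Recording) -> None:
    """Write a Recording as plain EDF (16-bit, uV, 1-s records).

    The duration must be a whole number of seconds and every channel's
    sampling rate an integer, which the synthetic montage guarantees.
    """
    path = Path(path)
    names = list(rec.channels)
    duration = rec.duration
    n_records = int(round(duration))
    if abs(duration - n_records) > 1e-9:
        raise ValueError(f"EDF writer requires whole-second duration, got {duration}")

    spr = []  # samples per 1-s record
    scaled = []
    phys_ranges = []
    for name in names:
        sig, fs = rec.channels[name]
        if abs(fs - round(fs)) > 1e-9:
            raise ValueError(f"channel {name}: non-integer sampling rate {fs}")
        spr.append(int(round(fs)))
        pmin, pmax = float(np.min(sig)), float(np.max(sig))
        if pmax - pmin < 1e-6:
            pmin, pmax = pmin - 1.0, pmax + 1.0
        phys_ranges.append((pmin, pmax))
        gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        dig = np.round((sig - pmin) * gain + _DIG_MIN).astype("<i2")
        scaled.append(dig)

    ns = len(names)
    header_bytes = 256 + 256 * ns
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(f"{rec.meta.subject_id} sex={rec.meta.sex}", 80))
        fh.write(_pad(f"Startdate 01-JAN-2000 {rec.meta.subject_id}", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(ns), 4))
        # field-major signal headers
        for name in names:
            fh.write(_pad(name, 16))
        for _ in names:
            fh.write(_pad("AgAgCl electrode", 80))
        for _ in names:
            fh.write(_pad("uV", 8))
        for pmin, _ in phys_ranges:
            fh.write(_pad(f"{pmin:.3f}"[:8], 8))
        for _, pmax in phys_ranges:
            fh.write(_pad(f"{pmax:.3f}"[:8], 8))
        for _ in names:
            fh.write(_pad(str(_DIG_MIN), 8))
        for _ in names:
            fh.write(_pad(str(_DIG_MAX), 8))
        for _ in names:
            fh.write(_pad("", 80))
        for k in spr:
            fh.write(_pad(str(k), 8))
        for _ in names:
            fh.write(_pad("", 32))
        for r in range(n_records):
            for c in range(ns):
                fh.write(scaled[c][r * spr[c]:(r + 1) * spr[c]].tobytes())


def read_edf(path, meta: SubjectMeta | None = None,
             lights: tuple[float, float] | None = None) -> Recording:
    """Load an EDF as a Recording (signals in microvolt).

    Montage channels missing from the file produce a warning-style log line
    but not an error; extra channels (e.g. EMG) are loaded and simply unused
    by the model path.
    """
    import logging

    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    channels: dict[str, tuple[np.ndarray, float]] = {}
    fs = float(raw.info["sfreq"])
    data = raw.get_data()  # volts for uV-dimension channels
    for i, name in enumerate(raw.ch_names):
        channels[name] = (data[i] * 1e6, fs)
    missing = [ch for ch in MONTAGE if ch not in channels]
    if missing:
        logging.getLogger(__name__).warning(
            "EDF %s lacks montage channels: %s", path, missing)
    if meta is None:
        meta = SubjectMeta(Path(path).stem, "SIB", 25.0, "F", "fam-unknown")
    dur = len(data[0]) / fs
    lo, lon = lights if lights is not None else (0.0, dur)
    return Recording(meta=meta, channels=channels, lights_off=lo, lights_on=lon)


# ---------------------------------------------------------------------------
# hypnogram TSV
# ---------------------------------------------------------------------------

def write_hypnogram(path, hyp: MiniEpochHypnogram) -> None:
    onsets = hyp.t0 + np.arange(len(hyp)) * hyp.period
    df = pd.DataFrame({
        "onset_sec": onsets,
        "duration_sec": np.full(len(hyp), hyp.period),
        "stage": hyp.labels,
        "char": hyp.char_flag.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def read_hypnogram(path, expected_period: float | None = None) -> MiniEpochHypnogram:
    """Read a hypnogram TSV; rejects gaps, overlaps and unknown stages."""
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise ValueError(f"hypnogram {path} is empty")
    required = {"onset_sec", "duration_sec", "stage"}
    if not required.issubset(df.columns):
        raise ValueError(f"hypnogram {path} lacks columns {required - set(df.columns)}")
    periods = df["duration_sec"].to_numpy(float)
    period = periods[0]
    if not np.allclose(periods, period):
        raise ValueError(f"hypnogram {path}: non-uniform durations")
    onsets = df["onset_sec"].to_numpy(float)
    expected = onsets[0] + np.arange(len(df)) * period
    bad = np.nonzero(~np.isclose(onsets, expected, atol=1e-6))[0]
    if bad.size:
        r = bad[0]
        raise ValueError(
            f"hypnogram {path}: gap/overlap at row {r} "
            f"(onset {onsets[r]}, expected {expected[r]})"
        )
    labels = df["stage"].astype(str).to_numpy()
    unknown = set(labels) - set(ALL_LABELS)
    if unknown:
        raise ValueError(f"hypnogram {path}: unknown stage tokens {sorted(unknown)}")
    if expected_period is not None and abs(period - expected_period) > 1e-9:
        raise ValueError(
            f"hypnogram {path}: period {period}s, expected {expected_period}s")
    if "char" in df.columns:
        char = df["char"].to_numpy(int).astype(bool)
    else:
        char = np.ones(len(df), bool)
    return MiniEpochHypnogram(labels=labels, char_flag=char, period=float(period),
                              t0=float(onsets[0]))


# ---------------------------------------------------------------------------
# metadata + manifest
# ---------------------------------------------------------------------------

def write_metadata(path, metas: list[SubjectMeta], seed: int) -> None:
    df = pd.DataFrame([{
        "subject_id": m.subject_id, "group": m.group, "age": m.age,
        "sex": m.sex, "family_id": m.family_id, "seed": seed,
    } for m in metas])
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list[SubjectMeta]:
    df = pd.read_csv(path, sep="\t")
    return [SubjectMeta(str(r.subject_id), str(r.group), float(r.age),
                        str(r.sex), str(r.family_id))
            for r in df.itertuples()]


def config_hash(cfg) -> str:
    """Stable short hash of a (nested) dataclass or dict configuration."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        cfg = dataclasses.asdict(cfg)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class Manifest:
    """Dataset index: per-recording segment files plus subject metadata."""

    records: list[dict]
    seed: int
    config_hash: str
    n_mini_epochs: int
    root: Path | None = None

    def __post_init__(self) -> None:
        ids = [r["recording_id"] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("recording ids must be unique")

    def metas(self) -> list[SubjectMeta]:
        return [r["meta"] for r in self.records]

    def segment_paths(self, key: str = "hypnogram") -> list[tuple[str, Path]]:
        out = []
        for r in self.records:
            for seg in r["segments"]:
                if key in seg:
                    out.append((r["recording_id"], Path(self.root) / seg[key]))
        return out


def write_manifest(path, manifest: Manifest) -> None:
    payload = {
        "seed": manifest.seed,
        "config_hash": manifest.config_hash,
        "n_mini_epochs": manifest.n_mini_epochs,
        "records": [
            {
                "recording_id": r["recording_id"],
                "meta": dataclasses.asdict(r["meta"]),
                "segments": r["segments"],
            }
            for r in manifest.records
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_manifest(path, check_files: bool = True) -> Manifest:
    path = Path(path)
    payload = json.loads(path.read_text())
    records = []
    for r in payload["records"]:
        records.append({
            "recording_id": r["recording_id"],
            "meta": SubjectMeta(**r["meta"]),
            "segments": r["segments"],
        })
    man = Manifest(records=records, seed=payload["seed"],
                   config_hash=payload["config_hash"],
                   n_mini_epochs=payload["n_mini_epochs"], root=path.parent)
    if check_files:
        for r in man.records:
            for seg in r["segments"]:
                for key in ("hypnogram", "edf"):
                    if key in seg and not (path.parent / seg[key]).exists():
                        raise FileNotFoundError(path.parent / seg[key])
    return man


# ---------------------------------------------------------------------------
# run configuration + full pipeline
# ---------------------------------------------------------------------------

DEFAULT_RUN_CONFIG: dict = {
    "synth": {
        "n_recordings": 12,
        "record_duration": 1800.0,
        "n_segments": 1,
        "segment_minutes": 5,
        "fraction_nt1": 0.38,
        "p_no_char": 0.308,
        "p_artifact": 0.0046,
        "noise_scale": 1.0,
    },
    "rules": {},  # RuleScorerConfig field overrides
    "model": {
        "depth": 2,
        "filters_base": 4,
        "kernel": 9,
        "input_window": 30.0,
    },
    "transfer": {
        "sizes": [7, 2, 3],
        "pretrain_steps": 100,
        "finetune_steps": 150,
        "pretrain_lr": 1e-3,
        "finetune_lr": 3e-4,
        "batch_size": 8,
        "eval_interval": 20,
        "patience": 10,
        "val_pairs": 2,
    },
    "eval": {
        "n_boot": 1000,
        "weights": "reference",
    },
}


def _merge_config(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    for key, val in defaults.items():
        out[key] = val.copy() if isinstance(val, dict) else val
    for key, val in override.items():
        if key not in defaults:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise TypeError(f"config section {path + key!r} must be a mapping")
            out[key] = _merge_config(defaults[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_run_config(path=None, overrides: dict | None = None) -> dict:
    """Load a nested run configuration, rejecting unknown keys (typo guard)."""
    import yaml

    cfg = {}
    if path is not None:
        cfg = yaml.safe_load(Path(path).read_text()) or {}
    merged = _merge_config(DEFAULT_RUN_CONFIG, cfg)
    if overrides:
        merged = _merge_config(merged, overrides)
    return merged


def run_pipeline(out_dir, seed: int = 0, config: dict | None = None) -> dict:
    """Full chain: simulate -> rule-score -> split -> pretrain (30 s) ->
    fine-tune (5 s) -> predict -> evaluate; writes ``summary.json``.

    Every stage draws from a named substream of the master seed, so a rerun
    with the same seed reproduces the summary except for timing fields.
    """
    import time as _time

    import numpy as np

    from . import evalstats, netmodel, rules, synth, transfer
    from .types import SimConfig

    cfg = config or load_run_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timing: dict[str, float] = {}
    master = np.random.SeedSequence(seed)
    sub = {name: s for name, s in zip(
        ("simulate", "split", "train", "bootstrap"), master.spawn(4))}

    # -- simulate -----------------------------------------------------------
    t0 = _time.time()
    sim = SimConfig(seed=int(sub["simulate"].generate_state(1)[0] % 2**31),
                    **cfg["synth"])
    manifest = synth.build_dataset(sim, out / "data", overwrite=True,
                                   include_signals=True)
    timing["simulate"] = _time.time() - t0

    # -- load segments back (exercises the EDF/TSV round trip) -------------
    segs_by_rec: dict[str, list] = {}
    for r in manifest.records:
        meta = r["meta"]
        segs = []
        for seg in r["segments"]:
            rec = read_edf(Path(manifest.root) / seg["edf"], meta=meta)
            hyp = read_hypnogram(Path(manifest.root) / seg["hypnogram"])
            segs.append((rec, hyp))
        segs_by_rec[r["recording_id"]] = segs

    # -- rule-based scoring -------------------------------------------------
    t0 = _time.time()
    rcfg = rules.RuleScorerConfig(**cfg["rules"])
    rules_by_rec = {}
    for rid, segs in segs_by_rec.items():
        scored = [rules.score_segment(rec, rcfg) for rec, _ in segs]
        for si, sc in enumerate(scored):
            write_hypnogram(out / "data" / f"{rid}_s{si}.rules.tsv", sc)
        rules_by_rec[rid] = scored
    timing["score_rules"] = _time.time() - t0

    # -- split + training ---------------------------------------------------
    t0 = _time.time()
    metas = manifest.metas()
    tcfg = cfg["transfer"]
    plan = transfer.make_split(
        metas, sizes=tuple(tcfg["sizes"]),
        rng_seed=int(sub["split"].generate_state(1)[0] % 2**31))
    train_seed = int(sub["train"].generate_state(1)[0] % 2**31)
    split_segs = {name: [] for name in transfer.SPLIT_NAMES}
    for rid, segs in segs_by_rec.items():
        split_segs[plan.assignment[rid]].extend(segs)
    prep5 = {name: transfer.prepare_segments(split_segs[name], 5.0)
             for name in transfer.SPLIT_NAMES}
    prep30 = {name: [{"pairs": p["pairs"],
                      "targets": transfer.labels_to_targets(h, 30.0)}
                     for p, (rec, h) in zip(prep5[name], split_segs[name])]
              for name in ("train", "val")}
    mcfg = netmodel.ModelConfig(output_period=30.0, **cfg["model"])
    model = netmodel.SleepSegmenter(mcfg, rng_seed=train_seed)
    pre_state = transfer.TrainState(
        learning_rate=tcfg["pretrain_lr"], max_steps=tcfg["pretrain_steps"],
        batch_size=tcfg["batch_size"], eval_interval=tcfg["eval_interval"],
        patience=tcfg["patience"], val_pairs=tcfg["val_pairs"])
    model, _ = transfer.finetune(model, prep30["train"], prep30["val"],
                                 pre_state, rng_seed=train_seed)
    model5 = model.with_output_period(5.0)

    test_ids = plan.ids("test")
    def predict_test(m, tag):
        preds = {}
        for rid in test_ids:
            preds[rid] = []
            for si, (rec, hyp) in enumerate(segs_by_rec[rid]):
                p = netmodel.predict_voted(m, rec, 5.0)
                write_hypnogram(out / "data" / f"{rid}_s{si}.{tag}.tsv", p)
                preds[rid].append(p)
        return preds

    baseline_preds = predict_test(model5, "baseline")
    ft_state = transfer.TrainState(
        learning_rate=tcfg["finetune_lr"], max_steps=tcfg["finetune_steps"],
        batch_size=tcfg["batch_size"], eval_interval=tcfg["eval_interval"],
        patience=tcfg["patience"], val_pairs=tcfg["val_pairs"])
    model5, _ = transfer.finetune(model5, prep5["train"], prep5["val"],
                                  ft_state, rng_seed=train_seed + 1)
    model5.save(out / "model_finetuned.npz")
    tuned_preds = predict_test(model5, "finetuned")
    timing["train_predict"] = _time.time() - t0

    # -- evaluation ---------------------------------------------------------
    t0 = _time.time()
    boot_seed = int(sub["bootstrap"].generate_state(1)[0] % 2**31)
    n_boot = cfg["eval"]["n_boot"]

    def f1_vs_truth(pred_by_rec, ids):
        reps = []
        for rid in ids:
            truth = [h for _, h in segs_by_rec[rid]]
            cm = evalstats.build_confusion(truth, pred_by_rec[rid], rid)
            reps.append(evalstats.f1_report(cm, weights=cfg["eval"]["weights"]))
        return reps

    rules_reps = f1_vs_truth(rules_by_rec, list(segs_by_rec))
    base_reps = f1_vs_truth(baseline_preds, test_ids)
    tuned_reps = f1_vs_truth(tuned_preds, test_ids)

    # fragmentation: mini-epoch vs epoch-derived transition rates (truth)
    mini_rates, epoch_rates, sw_rates = [], [], []
    for rid, segs in segs_by_rec.items():
        hyps = [h for _, h in segs]
        ts = evalstats.transition_stats(hyps, rid)
        mini_rates.append(ts.any_transitions_per_min)
        sw_rates.append(ts.sleep_wake_transitions_per_min)
        expanded = [evalstats.expand_epochs(evalstats.collapse_to_epochs(h))
                    for h in hyps]
        epoch_rates.append(
            evalstats.transition_stats(expanded, rid).any_transitions_per_min)
    rate_cmp = evalstats.paired_compare(mini_rates, epoch_rates)
    group_cmp = evalstats.group_compare_lmm(sw_rates, metas)

    fractions = evalstats.stage_fractions(
        [h for segs in segs_by_rec.values() for _, h in segs])

    summary = {
        "seed": seed,
        "config_hash": config_hash(cfg),
        "n_recordings": len(segs_by_rec),
        "n_mini_epochs": manifest.n_mini_epochs,
        "split_counts": plan.counts,
        "rules_scorer": evalstats.aggregate_f1(rules_reps, n_boot, boot_seed),
        "model_before_finetune": evalstats.aggregate_f1(base_reps, n_boot, boot_seed),
        "model_after_finetune": evalstats.aggregate_f1(tuned_reps, n_boot, boot_seed),
        "stage_fractions": fractions,
        "transition_rates": {
            "mini_epoch_mean_per_min": float(np.mean(mini_rates)),
            "epoch_derived_mean_per_min": float(np.mean(epoch_rates)),
            "per_recording_mini_gt_epoch": bool(
                np.all(np.array(mini_rates) > np.array(epoch_rates))),
            "wilcoxon_p": rate_cmp.p_value,
            "wilcoxon_r": rate_cmp.effect_size,
        },
        "group_comparison_sw_rate": {
            "cohens_d": group_cmp.effect_size,
            "p_value": group_cmp.p_value,
            "model": group_cmp.model,
        },
        "timing_sec": timing,
    }
    timing["evaluate"] = _time.time() - t0
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
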