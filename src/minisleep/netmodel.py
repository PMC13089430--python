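"""Fully-convolutional sleep-stage segmentation with configurable resolution.

The network follows the U-shaped encoder-decoder family: the encoder halves
the temporal resolution per block, the decoder mirrors it with skip
connections, and a segment classifier mean-pools the decoded features over
the output period (30 s for conventional epochs, 5 s for mini-epochs) before
a 1x1 convolution maps them to stage probabilities.  Because only the
pooling width depends on the output period, a model trained at 30-s
resolution transfers to 5-s scoring with every parameter intact.

Inputs are single EEG/EOG channel pairs resampled to 128 Hz and robust-scaled;
predictions from all 12 EEG x EOG pairs are combined by majority voting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from . import nn
from .types import (
    EEG_CHANNELS,
    EOG_CHANNELS,
    STAGES,
    MiniEpochHypnogram,
    Recording,
)


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 2
    filters_base: int = 8
    kernel: int = 9
    output_period: float = 5.0
    n_classes: int = 5
    input_fs: float = 128.0
    input_window: float = 30.0  # seconds processed per forward tile

    def __post_init__(self) -> None:
        win = self.input_window * self.input_fs
        if abs(win - round(win)) > 1e-9 or int(round(win)) % (2**self.depth):
            raise ValueError(
                f"input_window*input_fs ({win}) must be divisible by 2^depth")
        ratio = self.input_window / self.output_period
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("input_window must be divisible by output_period")

    @property
    def window_samples(self) -> int:
        return int(round(self.input_window * self.input_fs))

    @property
    def pool_samples(self) -> int:
        return int(round(self.output_period * self.input_fs))


def preprocess(eeg: np.ndarray, eog: np.ndarray, native_fs: float,
               target_fs: float = 128.0, clip: float = 20.0) -> np.ndarray:
    """Resample a channel pair to 128 Hz, robust-scale and clip outliers.

    Scaling subtracts the median and divides by the IQR per channel (falling
    back to the standard deviation for zero-IQR channels); samples beyond
    ``clip`` scaled units are clipped, removing extreme outliers.
    """
    if len(eeg) != len(eog):
        raise ValueError("EEG and EOG must have equal duration")
    frac = Fraction(target_fs / native_fs).limit_denominator(1000)
    out = []
    for x in (eeg, eog):
        y = resample_poly(x, frac.numerator, frac.denominator)
        med = np.median(y)
        iqr = np.subtract(*np.percentile(y, [75, 25]))
        if iqr <= 0:
            sd = y.std()
            if sd <= 0:
                raise ValueError("all-constant channel cannot be scaled")
            iqr = sd
        y = np.clip((y - med) / iqr, -clip, clip)
        out.append(y)
    return np.stack(out)


class SleepSegmenter:
    """Encoder-decoder segmentation network over one EEG/EOG pair."""

    def __init__(self, config: ModelConfig, rng_seed: int = 0):
        self.config = config
        rng = np.random.default_rng(rng_seed)
        d, f0, k = config.depth, config.filters_base, config.kernel
        filters = [min(f0 * 2**i, 64) for i in range(d + 1)]
        self.enc = []
        cin = 2
        for i in range(d):
            self.enc.append({
                "conv": nn.Conv1d(cin, filters[i], k, rng),
                "act": nn.ELU(), "bn": nn.BatchNorm1d(filters[i]),
                "pool": nn.MaxPool2(),
            })
            cin = filters[i]
        self.bottom = {
            "conv": nn.Conv1d(cin, filters[d], k, rng),
            "act": nn.ELU(), "bn": nn.BatchNorm1d(filters[d]),
        }
        self.dec = []
        cin = filters[d]
        for i in reversed(range(d)):
            self.dec.append({
                "up": nn.Upsample2(),
                "conv": nn.Conv1d(cin + filters[i], filters[i], k, rng),
                "act": nn.ELU(), "bn": nn.BatchNorm1d(filters[i]),
                "skip_channels": filters[i],
            })
            cin = filters[i]
        # segment classifier: mean-pool over the output period, then 1x1 conv
        self.classifier = nn.Conv1d(cin, config.n_classes, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = []
        for blk in self.enc + [self.bottom] + self.dec:
            for layer in blk.values():
                if hasattr(layer, "params"):
                    ps.extend(layer.params())
        ps.extend(self.classifier.params())
        return ps

    def param_shapes(self) -> list[tuple[int, ...]]:
        return [p.v.shape for p in self.params()]

    def get_weights(self) -> list[np.ndarray]:
        """Parameters plus BatchNorm running statistics (a full snapshot)."""
        ws = [p.v.copy() for p in self.params()]
        for bn in self._bn_layers():
            ws.append(bn.run_mean.copy())
            ws.append(bn.run_var.copy())
        return ws

    def set_weights(self, weights: list[np.ndarray]) -> None:
        n_params = len(self.params())
        for p, w in zip(self.params(), weights[:n_params], strict=True):
            p.v[...] = w
        rest = weights[n_params:]
        bns = self._bn_layers()
        if rest:
            if len(rest) != 2 * len(bns):
                raise ValueError("weight list does not match model structure")
            for i, bn in enumerate(bns):
                bn.run_mean = rest[2 * i].copy()
                bn.run_var = rest[2 * i + 1].copy()

    def with_output_period(self, period: float) -> "SleepSegmenter":
        """Same weights, different output resolution (pooling width only)."""
        clone = SleepSegmenter(replace(self.config, output_period=period))
        clone.set_weights(self.get_weights())
        for a, b in zip(self._bn_layers(), clone._bn_layers()):
            b.run_mean = a.run_mean.copy()
            b.run_var = a.run_var.copy()
        return clone

    def _bn_layers(self):
        out = []
        for blk in self.enc + [self.bottom] + self.dec:
            for layer in blk.values():
                if isinstance(layer, nn.BatchNorm1d):
                    out.append(layer)
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, 2, L) -> logits (N, L/pool, n_classes)."""
        n, c, length = x.shape
        if length % (2**self.config.depth) or length % self.config.pool_samples:
            raise ValueError(
                f"window of {length} samples incompatible: must be divisible "
                f"by 2^depth={2**self.config.depth} and by the pooling width "
                f"{self.config.pool_samples}")
        skips = []
        h = x
        for blk in self.enc:
            h = blk["bn"].forward(blk["act"].forward(blk["conv"].forward(h, train), train), train)
            skips.append(h)
            h = blk["pool"].forward(h, train)
        h = self.bottom["bn"].forward(
            self.bottom["act"].forward(self.bottom["conv"].forward(h, train), train), train)
        for i, blk in enumerate(self.dec):
            h = blk["up"].forward(h, train)
            skip = skips[-1 - i]
            h = np.concatenate([h, skip], axis=1)
            h = blk["bn"].forward(blk["act"].forward(blk["conv"].forward(h, train), train), train)
        if train:
            self._feat_len = h.shape[2]
        pw = self.config.pool_samples
        pooled = h.reshape(n, h.shape[1], h.shape[2] // pw, pw).mean(axis=3)
        logits = self.classifier.forward(pooled, train)  # (N, classes, T)
        return logits.transpose(0, 2, 1)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.classifier.backward(dlogits.transpose(0, 2, 1))
        pw = self.config.pool_samples
        n, c, t = d.shape
        dh = np.repeat(d / pw, pw, axis=2)
        for i, blk in enumerate(reversed(self.dec)):
            dh = blk["conv"].backward(blk["act"].backward(blk["bn"].backward(dh)))
            sk = blk["skip_channels"]
            dh, dskip = dh[:, :-sk, :], dh[:, -sk:, :]
            dh = blk["up"].backward(dh)
            self._pending_skip = getattr(self, "_pending_skip", {})
            self._pending_skip[len(self.dec) - 1 - i] = dskip
        dh = self.bottom["conv"].backward(
            self.bottom["act"].backward(self.bottom["bn"].backward(dh)))
        for j, blk in enumerate(reversed(self.enc)):
            dh = blk["pool"].backward(dh)
            # skip gradient joins here: decoder block i consumed encoder skip -1-i
            enc_index = len(self.enc) - 1 - j
            dec_index = len(self.dec) - 1 - enc_index
            dh = dh + self._pending_skip.pop(dec_index)
            dh = blk["conv"].backward(blk["act"].backward(blk["bn"].backward(dh)))
        self._pending_skip = {}

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.v for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bn_layers()):
            arrays[f"bn{i}_mean"] = bn.run_mean
            arrays[f"bn{i}_var"] = bn.run_var
        np.savez(path, **arrays)
        side = path.with_suffix(".json")
        side.write_text(json.dumps({"schema": 1, "config": asdict(self.config)}))

    @classmethod
    def load(cls, path) -> "SleepSegmenter":
        path = Path(path)
        side = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**side["config"]))
        data = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
        model.set_weights([data[f"p{i}"] for i in range(len(model.params()))])
        for i, bn in enumerate(model._bn_layers()):
            bn.run_mean = data[f"bn{i}_mean"]
            bn.run_var = data[f"bn{i}_var"]
        return model


def predict_pair(model: SleepSegmenter, pair: np.ndarray,
                 output_period: float | None = None) -> np.ndarray:
    """Stage probabilities for one preprocessed pair (2, L).

    The signal is tiled into non-overlapping input windows; L must be a
    multiple of the window length.  Returns (n_periods, n_classes) rows
    summing to 1.
    """
    if output_period is not None and output_period != model.config.output_period:
        model = model.with_output_period(output_period)
    w = model.config.window_samples
    c, length = pair.shape
    if length % w:
        raise ValueError(
            f"signal length {length} must be a multiple of the "
            f"{w}-sample input window")
    tiles = pair.reshape(c, length // w, w).transpose(1, 0, 2)
    logits = model.forward(tiles, train=False)
    probs = nn.softmax(logits, axis=-1)
    return probs.reshape(-1, model.config.n_classes)


def predict_voted(model: SleepSegmenter, rec: Recording,
                  output_period: float | None = None) -> MiniEpochHypnogram:
    """Majority vote over all available EEG x EOG channel pairs.

    Per period the label is the mode of the per-pair argmax labels; ties are
    broken by the highest mean probability across pairs, then by the fixed
    stage order W < N1 < N2 < N3 < REM.  Missing montage channels shrink the
    vote with a logged warning.
    """
    import logging

    period = output_period or model.config.output_period
    if output_period is not None and output_period != model.config.output_period:
        model = model.with_output_period(output_period)
    eegs = [ch for ch in EEG_CHANNELS if ch in rec.channels]
    eogs = [ch for ch in EOG_CHANNELS if ch in rec.channels]
    n_missing = (len(EEG_CHANNELS) - len(eegs)) + (len(EOG_CHANNELS) - len(eogs))
    if n_missing:
        logging.getLogger(__name__).warning(
            "voting over %d pairs only (%d montage channels missing)",
            len(eegs) * len(eogs), n_missing)
    if not eegs or not eogs:
        raise ValueError("need at least one EEG and one EOG channel to vote")
    all_probs = []
    for eeg_name in eegs:
        eeg, fs = rec.get(eeg_name)
        for eog_name in eogs:
            eog, _ = rec.get(eog_name)
            pair = preprocess(eeg, eog, fs, target_fs=model.config.input_fs)
            all_probs.append(predict_pair(model, pair))
    labels = vote_labels(np.stack(all_probs))
    return MiniEpochHypnogram(labels=labels,
                              char_flag=np.ones(len(labels), bool),
                              period=period, t0=0.0)


def vote_labels(probs: np.ndarray) -> np.ndarray:
    """Majority vote over per-pair probabilities (pairs, T, classes).

    Per period: mode of the per-pair argmax labels; ties broken by the
    highest mean probability across pairs, then by the fixed stage order
    W < N1 < N2 < N3 < REM.
    """
    votes = probs.argmax(axis=2)  # (pairs, T)
    n_pairs, t = votes.shape
    k = probs.shape[2]
    counts = np.zeros((t, k), dtype=int)
    for c in range(k):
        counts[:, c] = (votes == c).sum(axis=0)
    mean_p = probs.mean(axis=0)
    labels = np.empty(t, dtype="<U3")
    for i in range(t):
        top = counts[i].max()
        tied = np.nonzero(counts[i] == top)[0]
        if len(tied) > 1:
            best_p = mean_p[i, tied].max()
            tied = tied[np.isclose(mean_p[i, tied], best_p)]
        labels[i] = STAGES[tied[0]]
    return labels
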