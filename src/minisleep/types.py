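"""Core containers shared by every module.

Stages follow the five-class AASM vocabulary {W, N1, N2, N3, REM}; an extra
``ART`` token marks mini-epochs that cannot be scored (artifact).  All times
are seconds as floats, mini-epoch indices are 0-based and label ``i`` covers
the half-open interval ``[t0 + i*period, t0 + (i+1)*period)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
ART = "ART"
ALL_LABELS: tuple[str, ...] = STAGES + (ART,)
STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

#: stages where the defining graphoelement is mandatory — a "without
#: characteristics" call is never allowed for these
MANDATORY_CHAR_STAGES = frozenset({"W", "N3"})
#: stages that may be scored from context alone
CONTEXT_STAGES = ("N1", "N2", "REM")

#: the 8-derivation referential montage, in canonical order
EEG_CHANNELS = ("C3:A2", "C4:A1", "F3:A2", "F4:A1", "O1:A2", "O2:A1")
EOG_CHANNELS = ("EOG1:A2", "EOG2:A1")
MONTAGE = EEG_CHANNELS + EOG_CHANNELS

OCCIPITAL = ("O1:A2", "O2:A1")
CENTRAL = ("C3:A2", "C4:A1")
FRONTAL = ("F3:A2", "F4:A1")


@dataclass(frozen=True)
class SubjectMeta:
    """Demographics attached to one recording.

    ``family_id`` may be shared between two subjects (NT1 proband and
    non-narcoleptic sibling) and is the clustering unit of the mixed model.
    """

    subject_id: str
    group: str  # "NT1" | "SIB"
    age: float
    sex: str  # "F" | "M"
    family_id: str

    def __post_init__(self) -> None:
        if self.group not in ("NT1", "SIB"):
            raise ValueError(f"group must be NT1 or SIB, got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if not self.family_id:
            raise ValueError("family_id must be non-empty")
        if not self.age > 0:
            raise ValueError("age must be positive")


@dataclass
class Recording:
    """Multi-channel PSG signal container.

    ``channels`` maps derivation name -> (signal in microvolt, sampling rate).
    All signals must span the same duration; ``lights_off < lights_on`` frame
    the scorable window.
    """

    meta: SubjectMeta
    channels: dict[str, tuple[np.ndarray, float]]
    lights_off: float
    lights_on: float

    def __post_init__(self) -> None:
        durations = {
            name: len(sig) / fs for name, (sig, fs) in self.channels.items()
        }
        if len(set(round(d, 6) for d in durations.values())) > 1:
            raise ValueError(f"channels differ in duration: {durations}")
        if not self.lights_off < self.lights_on:
            raise ValueError("lights_off must precede lights_on")

    @property
    def duration(self) -> float:
        sig, fs = next(iter(self.channels.values()))
        return len(sig) / fs

    def get(self, name: str) -> tuple[np.ndarray, float]:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"required channel {name!r} missing from montage") from None

    def slice(self, start: float, stop: float) -> "Recording":
        """Extract [start, stop) as a new Recording (lights marks clipped)."""
        chans = {}
        for name, (sig, fs) in self.channels.items():
            i0, i1 = int(round(start * fs)), int(round(stop * fs))
            chans[name] = (sig[i0:i1].copy(), fs)
        return Recording(meta=self.meta, channels=chans, lights_off=0.0,
                         lights_on=stop - start)


@dataclass
class MiniEpochHypnogram:
    """Fixed-period stage-label sequence with characteristic/artifact flags.

    ``char_flag[i]`` is True when the stage-defining graphoelement is present
    in mini-epoch ``i``; it is forced True for W and N3 (mandatory) and is
    True-by-convention for ART.
    """

    labels: np.ndarray  # dtype <U3 over ALL_LABELS
    char_flag: np.ndarray  # bool
    period: float = 5.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U3")
        self.char_flag = np.asarray(self.char_flag, dtype=bool)
        if self.labels.shape != self.char_flag.shape:
            raise ValueError("labels and char_flag must have equal length")
        bad = set(np.unique(self.labels)) - set(ALL_LABELS)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        mandatory = np.isin(self.labels, list(MANDATORY_CHAR_STAGES) + [ART])
        if np.any(mandatory & ~self.char_flag):
            raise ValueError("char_flag must be True for W, N3 and ART labels")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return len(self.labels) * self.period

    def slice(self, i0: int, i1: int) -> "MiniEpochHypnogram":
        return MiniEpochHypnogram(
            labels=self.labels[i0:i1].copy(),
            char_flag=self.char_flag[i0:i1].copy(),
            period=self.period,
            t0=self.t0 + i0 * self.period,
        )


@dataclass(frozen=True)
class GraphoelementEvent:
    """A planted (or detected) stage-defining transient."""

    kind: str  # ALPHA_RUN | SPINDLE | KCOMPLEX | DELTA_WAVE | SEM | REM_EM | VERTEX
    onset: float
    duration: float
    channels: tuple[str, ...]
    amplitude: float

    KINDS = ("ALPHA_RUN", "SPINDLE", "KCOMPLEX", "DELTA_WAVE", "SEM", "REM_EM", "VERTEX")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown graphoelement kind {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-dataset generation settings.

    Defaults emulate the study conditions: 100 recordings, 38% NT1, 256 Hz,
    two 20-min segments each (48 000 mini-epochs total), ~0.46% artifact
    mini-epochs, ~30.8% "without characteristics" among N1/N2/REM, and a
    planted fragmentation contrast (NT1 2.0 vs siblings 1.5 transitions/min).
    """

    n_recordings: int = 100
    fraction_nt1: float = 0.38
    fs: float = 256.0
    record_duration: float = 4 * 3600.0
    period: float = 5.0
    n_segments: int = 2
    segment_minutes: int = 20
    transition_rate_target: dict = field(
        default_factory=lambda: {"NT1": 2.0, "SIB": 1.5}
    )
    stage_prior: dict = field(
        default_factory=lambda: {"W": 0.08, "N1": 0.07, "N2": 0.52, "N3": 0.16, "REM": 0.17}
    )
    p_no_char: float = 0.308
    p_artifact: float = 0.0046
    noise_scale: float = 1.0
    lights_margin: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.fraction_nt1, self.p_no_char, self.p_artifact):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        prior_sum = sum(self.stage_prior.values())
        if abs(prior_sum - 1.0) > 1e-9:
            raise ValueError(f"stage_prior must sum to 1, sums to {prior_sum}")

    @property
    def lights_off(self) -> float:
        return self.lights_margin

    @property
    def lights_on(self) -> float:
        return self.record_duration - self.lights_margin
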