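"""Deterministic rule-based mini-epoch scorer.

Operationalizes AASM-style mini-epoch scoring: a mini-epoch is scored W when
alpha activity covers more than half of it, N3 when high-amplitude slow waves
cover more than half of it, and N1/N2/REM when their defining graphoelements
(slow eye movements or vertex waves; spindles or K-complexes; rapid eye
movements) are detected.  When several stages present evidence, the
predominant stage (largest total evidence duration) wins.  Mini-epochs with
no evidence are resolved from context in a second pass and flagged
"without characteristics"; with no usable context, the background spectrum is
matched against stage templates.  EMG is deliberately ignored: low muscle
tone is not used as a REM criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .types import (
    ART,
    CENTRAL,
    CONTEXT_STAGES,
    EOG_CHANNELS,
    FRONTAL,
    OCCIPITAL,
    GraphoelementEvent,
    MiniEpochHypnogram,
    Recording,
)

BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
}


@dataclass(frozen=True)
class RuleScorerConfig:
    """Detector thresholds.  The scoring rules themselves are visual criteria;
    these parameters turn them into operational signal tests."""

    alpha_band: tuple[float, float] = (8.0, 12.0)
    alpha_envelope_uv: float = 20.0
    sws_band: tuple[float, float] = (0.5, 2.0)
    sws_envelope_uv: float = 37.5  # half of the 75 uV peak-to-peak convention
    sigma_band: tuple[float, float] = (11.0, 16.0)
    spindle_envelope_uv: float = 15.0
    spindle_dur: tuple[float, float] = (0.4, 2.0)
    kcomplex_band: tuple[float, float] = (0.5, 3.0)
    kcomplex_envelope_uv: float = 45.0  # ~100 uV peak-to-peak frontal
    kcomplex_dur: tuple[float, float] = (0.4, 1.2)
    vertex_band: tuple[float, float] = (2.0, 8.0)
    vertex_envelope_uv: float = 40.0
    vertex_max_dur: float = 0.5
    eog_lowpass: float = 20.0
    eog_amp_uv: float = 40.0
    eog_slope_uv_per_s: float = 400.0  # separates rapid from slow eye movements
    antiphase_corr: float = -0.3
    artifact_rms_uv: float = 150.0
    detect_artifacts: bool = True
    alpha_all_channels: bool = False  # default: occipital-only alpha rule
    context_window: int | None = None  # mini-epochs; None = whole segment

    def __post_init__(self) -> None:
        for lo, hi in (self.alpha_band, self.sws_band, self.sigma_band,
                       self.kcomplex_band, self.vertex_band):
            if not 0 < lo < hi:
                raise ValueError("bands must be non-degenerate")
        for thr in (self.alpha_envelope_uv, self.sws_envelope_uv,
                    self.spindle_envelope_uv, self.kcomplex_envelope_uv,
                    self.vertex_envelope_uv, self.eog_amp_uv,
                    self.eog_slope_uv_per_s):
            if not thr > 0:
                raise ValueError("thresholds must be positive")


@dataclass
class CharacteristicProfile:
    """Per-mini-epoch detector summary feeding the scoring decision."""

    alpha_fraction: float
    sws_fraction: float
    spindle_present: bool
    kcomplex_present: bool
    sem_present: bool
    vertex_present: bool
    rem_present: bool
    evidence: dict  # stage -> evidence duration (s), for W..REM
    band_powers: np.ndarray  # log10 band power per BANDS entry
    artifact: bool = False
    events: list = field(default_factory=list)


def _bandpass_env(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    from scipy.fft import next_fast_len

    return np.abs(sps.hilbert(y, N=next_fast_len(len(y)))[: len(y)])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, stop) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _mean(rec: Recording, names) -> tuple[np.ndarray, float]:
    sigs = []
    fs = None
    for n in names:
        s, fs = rec.get(n)
        sigs.append(s)
    return np.mean(sigs, axis=0), fs


def detect_characteristics(
    rec: Recording, period: float, cfg: RuleScorerConfig | None = None
) -> list[CharacteristicProfile]:
    """Run all graphoelement detectors over a segment.

    Returns one profile per mini-epoch.  Detected events (with onsets
    relative to the segment start) are attached to the profile covering them,
    so detector recall/precision can be scored against a planted ground
    truth.
    """
    cfg = cfg or RuleScorerConfig()
    n = int(round(rec.duration / period))
    if abs(n * period - rec.duration) > 1e-6:
        raise ValueError("segment duration must be a multiple of the period")

    occ, fs = _mean(rec, rec.channels.keys() if cfg.alpha_all_channels else OCCIPITAL)
    frontal, _ = _mean(rec, FRONTAL)
    central, _ = _mean(rec, CENTRAL)
    eog1, _ = rec.get(EOG_CHANNELS[0])
    eog2, _ = rec.get(EOG_CHANNELS[1])
    spe = int(round(period * fs))  # samples per mini-epoch

    alpha_env = _bandpass_env(occ, fs, cfg.alpha_band)
    sws_env = _bandpass_env(frontal, fs, cfg.sws_band)
    sigma_env = _bandpass_env(central, fs, cfg.sigma_band)
    kc_env = _bandpass_env(frontal, fs, cfg.kcomplex_band)
    vx_env = _bandpass_env(central, fs, cfg.vertex_band)
    sos_lp = sps.butter(4, cfg.eog_lowpass, btype="lowpass", fs=fs, output="sos")
    d_eog = sps.sosfiltfilt(sos_lp, eog1 - eog2)
    eog1_lp = sps.sosfiltfilt(sos_lp, eog1)
    eog2_lp = sps.sosfiltfilt(sos_lp, eog2)
    slope = np.gradient(d_eog) * fs

    # spectral profile per epoch for the background-similarity fallback
    all_eeg, _ = _mean(rec, CENTRAL + FRONTAL + OCCIPITAL)

    sws_frac_by_epoch = np.array([
        float(np.mean(sws_env[i * spe:(i + 1) * spe] > cfg.sws_envelope_uv))
        for i in range(n)
    ])

    profiles: list[CharacteristicProfile] = []
    for i in range(n):
        a, b = i * spe, (i + 1) * spe
        alpha_fraction = float(np.mean(alpha_env[a:b] > cfg.alpha_envelope_uv))
        sws_fraction = float(sws_frac_by_epoch[i])
        events: list[GraphoelementEvent] = []

        if alpha_fraction > 0.5:
            runs = _runs(alpha_env[a:b] > cfg.alpha_envelope_uv)
            r0, r1 = max(runs, key=lambda r: r[1] - r[0])
            events.append(GraphoelementEvent(
                "ALPHA_RUN", (a + r0) / fs, (r1 - r0) / fs, OCCIPITAL,
                float(alpha_env[a + r0:a + r1].max())))

        if sws_fraction > 0.5:
            runs = _runs(sws_env[a:b] > cfg.sws_envelope_uv)
            r0, r1 = max(runs, key=lambda r: r[1] - r[0])
            events.append(GraphoelementEvent(
                "DELTA_WAVE", (a + r0) / fs, (r1 - r0) / fs, FRONTAL,
                float(sws_env[a + r0:a + r1].max())))

        spindle_dur = kcomplex_dur = vertex_dur = sem_dur = rem_dur = 0.0
        for r0, r1 in _runs(sigma_env[a:b] > cfg.spindle_envelope_uv):
            dur = (r1 - r0) / fs
            if cfg.spindle_dur[0] <= dur <= cfg.spindle_dur[1]:
                spindle_dur += dur
                events.append(GraphoelementEvent(
                    "SPINDLE", (a + r0) / fs, dur, CENTRAL,
                    float(sigma_env[a + r0:a + r1].max())))
        # K-complex: an isolated frontal slow transient; suppressed when slow
        # waves dominate the epoch (that is delta activity, not a K-complex)
        if sws_fraction <= 0.5:
            for r0, r1 in _runs(kc_env[a:b] > cfg.kcomplex_envelope_uv):
                dur = (r1 - r0) / fs
                if cfg.kcomplex_dur[0] <= dur <= cfg.kcomplex_dur[1]:
                    kcomplex_dur += dur
                    events.append(GraphoelementEvent(
                        "KCOMPLEX", (a + r0) / fs, dur, FRONTAL,
                        float(kc_env[a + r0:a + r1].max())))
        for r0, r1 in _runs(vx_env[a:b] > cfg.vertex_envelope_uv):
            dur = (r1 - r0) / fs
            if 0.05 <= dur <= cfg.vertex_max_dur:
                vertex_dur += dur
                events.append(GraphoelementEvent(
                    "VERTEX", (a + r0) / fs, dur, CENTRAL,
                    float(vx_env[a + r0:a + r1].max())))
        for r0, r1 in _runs(np.abs(d_eog[a:b]) > cfg.eog_amp_uv):
            dur = (r1 - r0) / fs
            if dur < 0.05:
                continue
            seg1, seg2 = eog1_lp[a + r0:a + r1], eog2_lp[a + r0:a + r1]
            if seg1.std() > 0 and seg2.std() > 0:
                corr = float(np.corrcoef(seg1, seg2)[0, 1])
            else:
                corr = 0.0
            if corr > cfg.antiphase_corr:
                continue  # eye movements must be anti-phase across EOGs
            peak_slope = float(np.abs(slope[a + r0:a + r1]).max())
            if peak_slope > cfg.eog_slope_uv_per_s:
                rem_dur += dur
                events.append(GraphoelementEvent(
                    "REM_EM", (a + r0) / fs, dur, EOG_CHANNELS, peak_slope))
            else:
                sem_dur += dur
                events.append(GraphoelementEvent(
                    "SEM", (a + r0) / fs, dur, EOG_CHANNELS, peak_slope))

        x = all_eeg[a:b]
        f, pxx = sps.welch(x, fs=fs, nperseg=min(len(x), int(2 * fs)))
        bp = []
        for lo, hi in BANDS.values():
            m = (f >= lo) & (f < hi)
            bp.append(np.log10(pxx[m].mean() + 1e-12))
        artifact = False
        if cfg.detect_artifacts:
            rms = np.sqrt(np.mean(np.square(
                [rec.get(ch)[0][a:b] for ch in rec.channels])))
            artifact = bool(rms > cfg.artifact_rms_uv)

        evidence = {
            "W": alpha_fraction * period,
            "N1": min(sem_dur + vertex_dur, period),
            "N2": min(spindle_dur + kcomplex_dur, period),
            "N3": sws_fraction * period,
            "REM": min(rem_dur, period),
        }
        profiles.append(CharacteristicProfile(
            alpha_fraction=alpha_fraction, sws_fraction=sws_fraction,
            spindle_present=spindle_dur > 0, kcomplex_present=kcomplex_dur > 0,
            sem_present=sem_dur > 0, vertex_present=vertex_dur > 0,
            rem_present=rem_dur > 0, evidence=evidence,
            band_powers=np.array(bp), artifact=artifact, events=events,
        ))
    return profiles


# canonical background log-band-power templates for the no-context fallback,
# derived from the 1/f^beta stage colours the simulator uses
import functools


@functools.lru_cache(maxsize=1)
def _canonical_templates() -> dict[str, np.ndarray]:
    from .synth import BACKGROUND

    f = np.linspace(0.5, 30.0, 600)
    out = {}
    for stage in CONTEXT_STAGES:
        beta, rms = BACKGROUND[stage]
        pxx = f ** (-beta)
        pxx *= rms**2 / np.trapezoid(pxx, f)
        bp = []
        for lo, hi in BANDS.values():
            m = (f >= lo) & (f < hi)
            bp.append(np.log10(pxx[m].mean() + 1e-12))
        out[stage] = np.array(bp)
    return out


def score_mini_epoch(
    profile: CharacteristicProfile,
    context: list[tuple[int, str]] | None = None,
    cfg: RuleScorerConfig | None = None,
    templates: dict[str, np.ndarray] | None = None,
) -> tuple[str, bool]:
    """Score one mini-epoch from its profile and optional scored context.

    ``context`` is a list of (signed offset, label) pairs of already-scored
    neighbours.  Decision order: artifact; the >50% alpha rule (W); the >50%
    slow-wave rule (N3); graphoelement evidence with predominance by total
    evidence duration (ties N2 > REM > N1); nearest context label among
    N1/N2/REM (preceding wins at equal distance); background spectral
    similarity as last resort.
    """
    cfg = cfg or RuleScorerConfig()
    if cfg.detect_artifacts and profile.artifact:
        return ART, True
    if profile.alpha_fraction > 0.5:
        return "W", True
    if profile.sws_fraction > 0.5:
        return "N3", True
    candidates = []
    if profile.sem_present or profile.vertex_present:
        candidates.append("N1")
    if profile.spindle_present or profile.kcomplex_present:
        candidates.append("N2")
    if profile.rem_present:
        candidates.append("REM")
    if len(candidates) == 1:
        return candidates[0], True
    if len(candidates) > 1:
        tie_rank = {"N2": 0, "REM": 1, "N1": 2}
        best = max(candidates,
                   key=lambda s: (profile.evidence[s], -tie_rank[s]))
        return best, True
    # no evidence: context fallback
    if context:
        eligible = [(off, lab) for off, lab in context if lab in CONTEXT_STAGES]
        if cfg.context_window is not None:
            eligible = [(o, l) for o, l in eligible if abs(o) <= cfg.context_window]
        if eligible:
            # nearest wins; preceding (negative offset) preferred at ties
            off, lab = min(eligible, key=lambda ol: (abs(ol[0]), ol[0] > 0))
            return lab, False
    templates = templates or _canonical_templates()
    dists = {s: float(np.linalg.norm(profile.band_powers - t))
             for s, t in templates.items()}
    return min(dists, key=dists.get), False


def score_segment(
    rec: Recording,
    cfg: RuleScorerConfig | None = None,
    period: float = 5.0,
) -> MiniEpochHypnogram:
    """Score a whole segment with the two-pass procedure.

    Pass 1 scores every mini-epoch with characteristics (or artifact); pass 2
    resolves the remainder against pass-1 labels, which replaces the human
    scorer's free scrolling with a deterministic, order-independent rule.
    In-segment spectral templates (means over pass-1 N1/N2/REM mini-epochs)
    back the last-resort fallback where available.
    """
    cfg = cfg or RuleScorerConfig()
    profiles = detect_characteristics(rec, period, cfg)
    n = len(profiles)
    labels = np.array([""] * n, dtype="<U3")
    char = np.ones(n, dtype=bool)

    pending = []
    for i, prof in enumerate(profiles):
        has_evidence = (
            (cfg.detect_artifacts and prof.artifact)
            or prof.alpha_fraction > 0.5 or prof.sws_fraction > 0.5
            or prof.spindle_present or prof.kcomplex_present
            or prof.sem_present or prof.vertex_present or prof.rem_present
        )
        if has_evidence:
            labels[i], _ = score_mini_epoch(prof, context=None, cfg=cfg,
                                            templates={"N2": prof.band_powers})
        else:
            pending.append(i)

    templates = dict(_canonical_templates())
    for stage in CONTEXT_STAGES:
        idx = [i for i in range(n) if labels[i] == stage]
        if idx:
            templates[stage] = np.mean(
                [profiles[i].band_powers for i in idx], axis=0)

    scored = [(i, labels[i]) for i in range(n) if labels[i]]
    for i in pending:
        context = [(j - i, lab) for j, lab in scored]
        stage, has_char = score_mini_epoch(profiles[i], context=context,
                                           cfg=cfg, templates=templates)
        labels[i] = stage
        char[i] = has_char

    return MiniEpochHypnogram(labels=labels, char_flag=char, period=period, t0=0.0)
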