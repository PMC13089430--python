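"""Synthetic polysomnography with ground-truth 5-s mini-epoch hypnograms.

The generator emulates the structure of a mini-epoch scoring study: each
recording gets a semi-Markov stage sequence on the 5-s grid, two 20-min
segments are cut from the lights-off/lights-on window, and the rendered
signals carry the stage-defining graphoelements (alpha runs, spindles,
K-complexes, delta waves, vertex waves, slow/rapid eye movements) on the
channels where a human scorer would look for them.  Mini-epochs drawn as
"without characteristics" (N1/N2/REM only) are rendered as background alone;
artifact mini-epochs are high-amplitude broadband bursts labelled ART.

The planted event list is returned as ground truth so detector modules can be
scored against it.
"""

from __future__ import annotations

import numpy as np

from .types import (
    ART,
    CENTRAL,
    CONTEXT_STAGES,
    EOG_CHANNELS,
    FRONTAL,
    MONTAGE,
    OCCIPITAL,
    STAGES,
    GraphoelementEvent,
    MiniEpochHypnogram,
    Recording,
    SimConfig,
    SubjectMeta,
)

# background 1/f^beta colour and RMS (microvolt) per stage; ART is a broadband
# high-amplitude burst.  Values chosen so graphoelement amplitudes (>= 35 uV)
# stand clear of background envelopes at the default noise scale.
BACKGROUND = {
    "W": (1.0, 10.0),
    "N1": (1.6, 12.0),
    "N2": (1.8, 14.0),
    "N3": (2.2, 20.0),
    "REM": (1.4, 11.0),
    ART: (0.2, 300.0),
}
EOG_BACKGROUND_RMS = 8.0

# graphoelement morphology defaults (AASM-style): (duration s, amplitude uV)
ALPHA_FREQ = 10.0
ALPHA_COVER = 0.6  # fraction of the mini-epoch covered (> 0.5 rule)
ALPHA_AMP = 40.0
DELTA_FREQ = 1.0
DELTA_COVER = 0.7
DELTA_AMP = 75.0  # sinusoid amplitude -> 150 uV peak-to-peak
SPINDLE_FREQ = 13.0
SPINDLE_DUR = 1.0
SPINDLE_AMP = 35.0
KCOMPLEX_DUR = 0.8
KCOMPLEX_AMP = 90.0
VERTEX_DUR = 0.3
VERTEX_AMP = 70.0
SEM_DUR = 1.2
SEM_AMP = 60.0
REM_EM_DUR = 0.25
REM_EM_AMP = 80.0

MAX_RATE_PER_MIN = 12.0  # one switch opportunity per 5-s boundary


def colored_noise(n: int, fs: float, beta: float, rms: float,
                  rng: np.random.Generator) -> np.ndarray:
    """1/f^beta Gaussian noise of length ``n`` scaled to the requested RMS."""
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-beta / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    if sd > 0:
        x *= rms / sd
    return x


def sample_hypnogram(cfg: SimConfig, meta: SubjectMeta,
                     rng_seed: int | np.random.SeedSequence) -> MiniEpochHypnogram:
    """Draw a semi-Markov stage sequence on the mini-epoch grid.

    At each 5-s boundary the stage switches with probability
    ``rate / 12 per min`` (geometric dwell times); the new stage is drawn from
    the stage-occupancy prior restricted to the other stages.  The expected
    transition rate therefore equals the group's target exactly.  Artifact
    labels are injected i.i.d. afterwards, and char_flag is drawn False with
    probability ``p_no_char`` for N1/N2/REM labels only.
    """
    period = cfg.period
    n_float = cfg.record_duration / period
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9:
        raise ValueError(
            f"record_duration {cfg.record_duration} is not a multiple of period {period}"
        )
    rate = cfg.transition_rate_target[meta.group]
    if rate < 0 or rate > MAX_RATE_PER_MIN:
        raise ValueError(
            f"transition rate target {rate}/min unreachable on a {period}-s grid "
            f"(max {MAX_RATE_PER_MIN}/min)"
        )
    p_switch = rate * period / 60.0

    rng = np.random.default_rng(rng_seed)
    prior_stages = list(cfg.stage_prior)
    prior = np.array([cfg.stage_prior[s] for s in prior_stages])

    labels = np.empty(n, dtype="<U3")
    state = rng.choice(len(prior_stages), p=prior)
    labels[0] = prior_stages[state]
    switches = rng.random(n - 1) < p_switch if n > 1 else np.zeros(0, bool)
    for i in range(1, n):
        if switches[i - 1]:
            w = prior.copy()
            w[state] = 0.0
            w /= w.sum()
            state = rng.choice(len(prior_stages), p=w)
        labels[i] = prior_stages[state]

    art = rng.random(n) < cfg.p_artifact
    labels[art] = ART

    char = np.ones(n, dtype=bool)
    sleepy = np.isin(labels, CONTEXT_STAGES)
    char[sleepy] = rng.random(sleepy.sum()) >= cfg.p_no_char
    return MiniEpochHypnogram(labels=labels, char_flag=char, period=period, t0=0.0)


def _place(rng: np.random.Generator, period: float, dur: float) -> float:
    """Random onset of an event of length ``dur`` inside a mini-epoch."""
    slack = period - dur
    return float(rng.uniform(0, slack)) if slack > 0 else 0.0


def _add(sig: dict[str, np.ndarray], chans, fs: float, t_on: float,
         wave: np.ndarray, signs=None) -> None:
    i0 = int(round(t_on * fs))
    for j, ch in enumerate(chans):
        s = 1.0 if signs is None else signs[j]
        sig[ch][i0:i0 + len(wave)] += s * wave


def synthesize_signals(
    hyp: MiniEpochHypnogram,
    cfg: SimConfig,
    rng_seed: int | np.random.SeedSequence,
    meta: SubjectMeta | None = None,
) -> tuple[Recording, list[GraphoelementEvent]]:
    """Render the montage signals for a hypnogram and return planted events.

    Background is stage-coloured 1/f noise (scaled by ``cfg.noise_scale``;
    0 gives a clean render for detector validation).  Each mini-epoch whose
    char_flag is set receives its stage-defining graphoelement; suppressed
    mini-epochs receive background only.
    """
    rng = np.random.default_rng(rng_seed)
    fs = cfg.fs
    n = len(hyp)
    period = hyp.period
    unknown = set(np.unique(hyp.labels)) - set(BACKGROUND)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    nsamp = int(round(n * period * fs))
    sig = {ch: np.zeros(nsamp) for ch in MONTAGE}

    # --- background, generated per maximal run of equal labels -------------
    if cfg.noise_scale > 0:
        i = 0
        while i < n:
            j = i
            while j < n and hyp.labels[j] == hyp.labels[i]:
                j += 1
            beta, rms = BACKGROUND[hyp.labels[i]]
            a, b = int(round(i * period * fs)), int(round(j * period * fs))
            for ch in MONTAGE:
                ch_rms = rms if ch not in EOG_CHANNELS else (
                    rms if hyp.labels[i] == ART else EOG_BACKGROUND_RMS)
                sig[ch][a:b] += cfg.noise_scale * colored_noise(
                    b - a, fs, beta, ch_rms, rng)
            i = j

    # --- graphoelements ----------------------------------------------------
    events: list[GraphoelementEvent] = []
    t = np.arange(nsamp) / fs
    for i in range(n):
        lab = hyp.labels[i]
        if lab == ART or not hyp.char_flag[i]:
            continue
        e0 = i * period
        if lab == "W":
            dur = ALPHA_COVER * period
            on = e0 + _place(rng, period, dur)
            k0, k1 = int(round(on * fs)), int(round((on + dur) * fs))
            wave = ALPHA_AMP * np.sin(2 * np.pi * ALPHA_FREQ * t[k0:k1])
            for ch in OCCIPITAL:
                sig[ch][k0:k1] += wave
            events.append(GraphoelementEvent("ALPHA_RUN", on, dur, OCCIPITAL, ALPHA_AMP))
        elif lab == "N3":
            dur = DELTA_COVER * period
            on = e0 + _place(rng, period, dur)
            k0, k1 = int(round(on * fs)), int(round((on + dur) * fs))
            tau = np.arange(k1 - k0) / fs
            wave = DELTA_AMP * np.sin(2 * np.pi * DELTA_FREQ * tau)
            for ch in FRONTAL:
                sig[ch][k0:k1] += wave
            events.append(GraphoelementEvent("DELTA_WAVE", on, dur, FRONTAL, DELTA_AMP))
        elif lab == "N1":
            if rng.random() < 0.5:
                on = e0 + _place(rng, period, SEM_DUR)
                k = int(round(SEM_DUR * fs))
                tau = np.arange(k) / fs
                wave = SEM_AMP * np.sin(np.pi * tau / SEM_DUR)
                _add(sig, EOG_CHANNELS, fs, on, wave, signs=(1.0, -1.0))
                events.append(GraphoelementEvent("SEM", on, SEM_DUR, EOG_CHANNELS, SEM_AMP))
            else:
                on = e0 + _place(rng, period, VERTEX_DUR)
                k = int(round(VERTEX_DUR * fs))
                tau = np.arange(k) / fs
                wave = VERTEX_AMP * np.sin(2 * np.pi * tau / VERTEX_DUR)
                _add(sig, CENTRAL, fs, on, wave)
                events.append(GraphoelementEvent("VERTEX", on, VERTEX_DUR, CENTRAL, VERTEX_AMP))
        elif lab == "N2":
            if rng.random() < 0.5:
                on = e0 + _place(rng, period, SPINDLE_DUR)
                k = int(round(SPINDLE_DUR * fs))
                tau = np.arange(k) / fs
                env = np.sin(np.pi * tau / SPINDLE_DUR) ** 2
                wave = SPINDLE_AMP * env * np.sin(2 * np.pi * SPINDLE_FREQ * tau)
                _add(sig, CENTRAL, fs, on, wave)
                events.append(GraphoelementEvent("SPINDLE", on, SPINDLE_DUR, CENTRAL, SPINDLE_AMP))
            else:
                on = e0 + _place(rng, period, KCOMPLEX_DUR)
                k = int(round(KCOMPLEX_DUR * fs))
                tau = np.arange(k) / fs
                wave = KCOMPLEX_AMP * np.sin(2 * np.pi * tau / KCOMPLEX_DUR)
                _add(sig, FRONTAL, fs, on, wave)
                events.append(GraphoelementEvent("KCOMPLEX", on, KCOMPLEX_DUR, FRONTAL, KCOMPLEX_AMP))
        elif lab == "REM":
            on = e0 + _place(rng, period, REM_EM_DUR)
            k = int(round(REM_EM_DUR * fs))
            tau = np.arange(k) / fs
            wave = REM_EM_AMP * np.sin(np.pi * tau / REM_EM_DUR)
            _add(sig, EOG_CHANNELS, fs, on, wave, signs=(1.0, -1.0))
            events.append(GraphoelementEvent("REM_EM", on, REM_EM_DUR, EOG_CHANNELS, REM_EM_AMP))
        else:  # pragma: no cover - labels validated by MiniEpochHypnogram
            raise ValueError(f"unknown stage label {lab!r}")

    if meta is None:
        meta = SubjectMeta("synthetic", "SIB", 25.0, "F", "fam-synthetic")
    rec = Recording(
        meta=meta,
        channels={ch: (sig[ch], fs) for ch in MONTAGE},
        lights_off=0.0,
        lights_on=n * period,
    )
    return rec, events


def select_segment_windows(
    n_epochs_total: int,
    period: float,
    lights_off: float,
    lights_on: float,
    n_segments: int,
    segment_minutes: float,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> list[int]:
    """Pick ``n_segments`` non-overlapping start indices on the mini-epoch grid.

    Starts are uniform over grid positions inside [lights_off, lights_on);
    overlapping draws are rejected and redrawn.  Returns sorted start indices.
    """
    seg_len = int(round(segment_minutes * 60.0 / period))
    i_lo = int(np.ceil(lights_off / period - 1e-9))
    i_hi = int(np.floor(lights_on / period + 1e-9)) - seg_len
    i_hi = min(i_hi, n_epochs_total - seg_len)
    n_positions = i_hi - i_lo + 1
    if n_positions < 1 or (lights_on - lights_off) < n_segments * segment_minutes * 60.0:
        avail = max(0.0, (lights_on - lights_off)) / 60.0
        raise ValueError(
            f"lights window too small: {avail:.1f} min available, "
            f"{n_segments * segment_minutes:.1f} min required"
        )
    for _ in range(max_tries):
        starts = sorted(int(s) for s in rng.integers(i_lo, i_hi + 1, size=n_segments))
        if all(starts[k + 1] - starts[k] >= seg_len for k in range(n_segments - 1)):
            return starts
    raise RuntimeError("could not place non-overlapping segments")  # pragma: no cover


def extract_segments(
    rec: Recording,
    hyp: MiniEpochHypnogram,
    n_segments: int,
    segment_minutes: float,
    rng_seed: int | np.random.SeedSequence,
) -> list[tuple[Recording, MiniEpochHypnogram]]:
    """Cut non-overlapping scoring segments from the lights-off/on window."""
    rng = np.random.default_rng(rng_seed)
    seg_len = int(round(segment_minutes * 60.0 / hyp.period))
    starts = select_segment_windows(
        len(hyp), hyp.period, rec.lights_off, rec.lights_on,
        n_segments, segment_minutes, rng,
    )
    out = []
    for s in starts:
        t_start = s * hyp.period
        t_stop = (s + seg_len) * hyp.period
        out.append((rec.slice(t_start, t_stop), hyp.slice(s, s + seg_len)))
    return out


def sample_metadata(cfg: SimConfig, rng: np.random.Generator) -> list[SubjectMeta]:
    """Draw the cohort: NT1 probands and non-narcoleptic siblings.

    A share of NT1 subjects is paired with a sibling under one family id,
    mirroring a family-clustered cohort; the rest are singleton families.
    """
    n = cfg.n_recordings
    n_nt1 = int(round(n * cfg.fraction_nt1))
    groups = ["NT1"] * n_nt1 + ["SIB"] * (n - n_nt1)
    n_pairs = int(0.6 * min(n_nt1, n - n_nt1))
    metas = []
    fam = 0
    nt1_ids = list(range(n_nt1))
    sib_ids = list(range(n_nt1, n))
    family_of: dict[int, str] = {}
    for k in range(n_pairs):
        fid = f"fam{fam:03d}"
        family_of[nt1_ids[k]] = fid
        family_of[sib_ids[k]] = fid
        fam += 1
    for idx in range(n):
        fid = family_of.get(idx)
        if fid is None:
            fid = f"fam{fam:03d}"
            fam += 1
        age = float(np.clip(rng.normal(23.0, 10.0), 6.0, 70.0))
        sex = "F" if rng.random() < 0.59 else "M"
        metas.append(SubjectMeta(
            subject_id=f"rec{idx:03d}", group=groups[idx], age=age,
            sex=sex, family_id=fid,
        ))
    return metas


def build_dataset(
    cfg: SimConfig,
    out_dir,
    overwrite: bool = False,
    include_signals: bool = True,
):
    """Generate the full synthetic dataset on disk and return its manifest.

    Writes, per recording and segment, an EDF (montage signals, 16-bit,
    microvolt) and a hypnogram TSV, plus one metadata table and a manifest
    JSON.  Label sequences are bit-identical under a fixed seed.  With
    ``include_signals=False`` only hypnograms and metadata are written (the
    label-level statistics are unchanged).
    """
    from pathlib import Path

    from . import iohub

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"output directory {out} is not empty; pass overwrite=True"
            )
    out.mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(cfg.seed)
    children = root_ss.spawn(cfg.n_recordings + 1)
    meta_rng = np.random.default_rng(children[0])
    metas = sample_metadata(cfg, meta_rng)

    records = []
    n_mini_epochs = 0
    for rec_idx, meta in enumerate(metas):
        hyp_ss, seg_ss, sig_ss = children[rec_idx + 1].spawn(3)
        hyp = sample_hypnogram(cfg, meta, hyp_ss)
        seg_rng = np.random.default_rng(seg_ss)
        starts = select_segment_windows(
            len(hyp), cfg.period, cfg.lights_off, cfg.lights_on,
            cfg.n_segments, cfg.segment_minutes, seg_rng,
        )
        seg_len = int(round(cfg.segment_minutes * 60.0 / cfg.period))
        seg_entries = []
        for si, s in enumerate(starts):
            hslice = hyp.slice(s, s + seg_len)
            tsv = out / f"{meta.subject_id}_s{si}.tsv"
            iohub.write_hypnogram(tsv, hslice)
            entry = {"hypnogram": tsv.name, "t0": hslice.t0,
                     "n_mini_epochs": len(hslice)}
            if include_signals:
                rec_slice, _events = synthesize_signals(
                    hslice, cfg, sig_ss.spawn(1)[0], meta=meta)
                edf = out / f"{meta.subject_id}_s{si}.edf"
                iohub.write_edf(edf, rec_slice)
                entry["edf"] = edf.name
            seg_entries.append(entry)
            n_mini_epochs += len(hslice)
        records.append({"recording_id": meta.subject_id, "meta": meta,
                        "segments": seg_entries})

    manifest = iohub.Manifest(records=records, seed=cfg.seed,
                              config_hash=iohub.config_hash(cfg),
                              n_mini_epochs=n_mini_epochs, root=out)
    iohub.write_manifest(out / "manifest.json", manifest)
    iohub.write_metadata(out / "metadata.tsv", metas, cfg.seed)
    return manifest
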