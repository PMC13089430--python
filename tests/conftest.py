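"""Shared fixtures: small synthetic cohorts and clean rendered segments.

Everything is generated programmatically at test time; the expensive clean
20-min render is session-scoped because several modules score against it.
"""

from __future__ import annotations

import numpy as np
import pytest

from minisleep import synth
from minisleep.types import MiniEpochHypnogram, SimConfig, SubjectMeta


@pytest.fixture(scope="session")
def subject() -> SubjectMeta:
    return SubjectMeta("rec000", "SIB", 27.0, "F", "fam000")


@pytest.fixture(scope="session")
def clean_segment(subject):
    """A 20-min noise-free render with every characteristic planted."""
    cfg = SimConfig(record_duration=1200.0, p_no_char=0.0, p_artifact=0.0,
                    noise_scale=0.0)
    hyp = synth.sample_hypnogram(cfg, subject, 11)
    rec, events = synth.synthesize_signals(hyp, cfg, 12, subject)
    return rec, hyp, events


@pytest.fixture(scope="session")
def cohort_metas():
    """100-subject cohort metadata mirroring the study's group mix."""
    cfg = SimConfig()
    return synth.sample_metadata(cfg, np.random.default_rng(5))


def random_hypnogram(rng: np.random.Generator, n: int, period: float = 5.0,
                     p_art: float = 0.0) -> MiniEpochHypnogram:
    stages = np.array(["W", "N1", "N2", "N3", "REM"])
    labels = rng.choice(stages, size=n)
    if p_art > 0:
        labels[rng.random(n) < p_art] = "ART"
    char = np.ones(n, bool)
    sleepy = np.isin(labels, ["N1", "N2", "REM"])
    char[sleepy] = rng.random(int(sleepy.sum())) > 0.3
    return MiniEpochHypnogram(labels=labels, char_flag=char, period=period)
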