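"""Generate a synthetic mini-epoch dataset and inspect its composition.

Builds a small cohort of synthetic PSG recordings (labels only, for speed),
then reports the dataset geometry, stage mix, artifact rate and the share of
"without characteristics" mini-epochs among N1/N2/REM.
"""

import tempfile
from pathlib import Path

import numpy as np

from minisleep import build_dataset, read_hypnogram, stage_fractions
from minisleep.types import ART, SimConfig

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimConfig(n_recordings=20, seed=1)
    manifest = build_dataset(cfg, Path(tmp) / "data", include_signals=False)

    hyps = [read_hypnogram(p) for _, p in manifest.segment_paths("hypnogram")]
    labels = np.concatenate([h.labels for h in hyps])
    char = np.concatenate([h.char_flag for h in hyps])

    print(f"recordings:        {len(manifest.records)}")
    print(f"segments:          {len(hyps)}  (two 20-min segments per recording)")
    print(f"mini-epochs total: {manifest.n_mini_epochs}  (240 per segment)")

    fr = stage_fractions(hyps)
    print("stage fractions (of non-artifact mini-epochs):")
    for s, v in fr.items():
        print(f"  {s:3s} {100 * v:5.1f} %")

    art_pct = 100 * (labels == ART).mean()
    sleepy = np.isin(labels, ["N1", "N2", "REM"])
    nochar_pct = 100 * (~char[sleepy]).mean()
    print(f"artifact mini-epochs:          {art_pct:.2f} %  (target ~0.46 %)")
    print(f"'without characteristics' among N1/N2/REM: {nochar_pct:.1f} %  "
          f"(target ~30.8 %)")

# The stage mix is N2-dominant with smaller W/N1 shares, the artifact rate
# reflects unscorable mini-epochs, and the without-characteristics share
# drives how often a scorer must fall back on surrounding context.
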