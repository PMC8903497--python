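"""Shared configuration of the analysis drivers.

The drivers run the demonstration-scale study: a matched-size cohort
(14 positive vs 40 negative) on a reduced montage with strong injected
group effects, and a later-age analog cohort whose effects sit in higher
frequency bands.  Tables land under results/.
"""

from pathlib import Path

from nldeeg.cohort import GroupEffect
from nldeeg.presets import demo_effect, demo_strong_spec

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

SEED_EARLY = 11
SEED_LATE = 12

SPEC_EARLY = demo_strong_spec(seed=SEED_EARLY)
EFFECT_EARLY = demo_effect()

# later-age analog: differences concentrated in beta/gamma bands
SPEC_LATE = demo_strong_spec(seed=SEED_LATE)
EFFECT_LATE = GroupEffect(
    band_power_shifts={
        ("F7", "15.6-31.2Hz"): 2.0,
        ("F7", "31.2-62.2Hz"): 1.8,
        ("C3", "15.6-31.2Hz"): 1.8,
        ("C3", "62.5-100Hz"): 1.8,
    },
    spectral_slope_shift=-0.2,
    chaos_mix_positive=0.5,
)

FEATURES_EARLY = RESULTS / "features_early.csv"
LABELS_EARLY = RESULTS / "labels_early.json"
FEATURES_LATE = RESULTS / "features_late.csv"
LABELS_LATE = RESULTS / "labels_late.json"


def ensure_results() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
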