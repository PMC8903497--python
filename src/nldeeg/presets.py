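"""Canonical study conditions and the reduced demonstration conditions.

The full design — 14 vs 40 subjects (matched cohort) or 27 vs 40 (full
12-month sample), 18 channels at 250 Hz, ~700-s recordings — is expressed
by :class:`~nldeeg.cohort.CohortSpec` defaults.  Running the complete
measure battery over it costs hours of CPU, so the demonstration
configurations below keep the study's subject counts and class imbalance
while trimming the montage and recording length; they are what the
analysis drivers, the test suite and the acceptance script execute.

``demo_effect`` injects strong, localized group differences (doubled band
amplitudes in two channels, a steeper 1/f slope and an added chaotic
component for the positive group) so that the classification stage has a
recoverable signal; ``null_effect`` is all-zero, making the groups
exchangeable.
"""

from __future__ import annotations

from .cohort import CohortSpec, GroupEffect

__all__ = [
    "DEMO_CHANNELS", "CHEAP_MEASURES",
    "matched_spec", "full_sample_spec", "demo_strong_spec", "demo_effect",
    "null_effect", "demo_null_spec",
]

#: montage subset used by the demonstration pipeline
DEMO_CHANNELS: tuple[str, ...] = ("F7", "C3")

#: inexpensive measure subset for repeated-simulation calibration loops
CHEAP_MEASURES: tuple[str, ...] = (
    "Power", "PermE", "SpecE", "SVDE", "HFD", "KFD", "DFA", "HurstE")


def matched_spec(seed: int = 0) -> CohortSpec:
    """The matched-sample design: 14 positive vs 40 negative subjects."""
    return CohortSpec(n_positive=14, n_negative=40, seed=seed)


def full_sample_spec(seed: int = 0) -> CohortSpec:
    """The full 12-month design: 27 positive vs 40 negative subjects."""
    return CohortSpec(n_positive=27, n_negative=40, seed=seed)


def demo_strong_spec(seed: int = 11) -> CohortSpec:
    """Matched-size cohort at demonstration scale (2 channels, 90 s)."""
    return CohortSpec(n_positive=14, n_negative=40, channels=DEMO_CHANNELS,
                      duration=90.0, seed=seed)


def demo_effect() -> GroupEffect:
    return GroupEffect(
        band_power_shifts={
            ("F7", "7.8-15.6Hz"): 2.0,
            ("F7", "3.9-7.8Hz"): 2.0,
            ("C3", "1-3.9Hz"): 1.8,
            ("C3", "15.6-31.2Hz"): 1.8,
        },
        spectral_slope_shift=0.3,
        chaos_mix_positive=0.5,
    )


def null_effect() -> GroupEffect:
    return GroupEffect()


def demo_null_spec(seed: int) -> CohortSpec:
    """Small imbalanced cohort (5 vs 15) for repeated null-calibration runs."""
    return CohortSpec(n_positive=5, n_negative=15, channels=("F3", "Pz"),
                      duration=60.0, seed=seed)
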