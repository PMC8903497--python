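"""End-to-end convenience: recordings -> analysis segments -> sub-bands ->
feature table, with an exclusion log for subjects lacking a long-enough
standard run."""

from __future__ import annotations

from typing import Sequence

from .decomposition import DEFAULT_SCALES, WaveletConfig, decompose_segment
from .features import (ALL_MEASURE_NAMES, FeatureTable, build_feature_table,
                       impute_missing)
from .measures import MeasureConfig
from .segmentation import (EegRecording, InsufficientRunError,
                           extract_middle_window, find_longest_standard_run)

__all__ = ["extract_cohort_features"]


def extract_cohort_features(recordings: Sequence[EegRecording],
                            window_s: float = 20.0,
                            wavelet: WaveletConfig = WaveletConfig(),
                            scales: Sequence[int] = DEFAULT_SCALES,
                            cfg: MeasureConfig = MeasureConfig(),
                            measures: Sequence[str] = ALL_MEASURE_NAMES,
                            missing_policy: str = "drop",
                            ) -> tuple[FeatureTable, list[tuple[str, str]]]:
    """Run segmentation, decomposition and the measure battery per subject.

    Returns the feature table and an exclusion log of (subject_id, reason)
    for recordings whose longest standard run is shorter than the window.
    """
    subbands = {}
    excluded: list[tuple[str, str]] = []
    for rec in recordings:
        try:
            run = find_longest_standard_run(rec.events)
            seg = extract_middle_window(rec, run, window_s=window_s)
        except (InsufficientRunError, ValueError) as exc:
            excluded.append((rec.subject_id, str(exc)))
            continue
        subbands[rec.subject_id] = decompose_segment(seg, wavelet, scales)
    if not subbands:
        raise InsufficientRunError("no subject had a usable standard run")
    table = build_feature_table(subbands, cfg, scales, measures)
    return impute_missing(table, missing_policy), excluded
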