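"""Per-subject feature vectors with traceable feature identities.

A feature is identified by (channel, band-or-scale, measure) and rendered
as the string ``"CHANNEL|BAND|MEASURE"`` (e.g. ``"F3|1-3.9Hz|AppE"``),
which round-trips losslessly and maps one-to-one onto report rows.  The
default grid over 18 channels is 12 measures x 6 sub-bands plus sample
entropy at 5 coarse-graining scales (MSE): 18 x 77 = 1386 features.
Column order is deterministic: channel-major, band in decomposition order,
measure in registry order, then MSE scales.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CHANNELS_1020
from .decomposition import DEFAULT_SCALES, SubbandSet, scale_label
from .measures import MEASURE_NAMES, MEASURES, MeasureConfig, power_rel, sample_entropy

__all__ = [
    "ALL_MEASURE_NAMES",
    "FeatureId",
    "FeatureTable",
    "CohortLabels",
    "feature_grid",
    "build_feature_table",
    "impute_missing",
    "write_feature_table",
    "read_feature_table",
    "write_labels",
    "read_labels",
]

log = logging.getLogger(__name__)

#: the 13 registered measure names (12 per-band + MSE on coarse scales)
ALL_MEASURE_NAMES: tuple[str, ...] = MEASURE_NAMES + ("MSE",)


@dataclass(frozen=True, order=True)
class FeatureId:
    channel: str
    band_or_scale: str
    measure: str

    def __post_init__(self) -> None:
        if self.measure not in ALL_MEASURE_NAMES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.channel not in CHANNELS_1020:
            raise ValueError(f"unknown 10-20 channel {self.channel!r}")
        if "|" in self.band_or_scale:
            raise ValueError("band label must not contain '|'")

    def __str__(self) -> str:
        return f"{self.channel}|{self.band_or_scale}|{self.measure}"

    @classmethod
    def parse(cls, s: str) -> "FeatureId":
        parts = s.split("|")
        if len(parts) != 3:
            raise ValueError(f"malformed feature id {s!r}")
        return cls(*parts)


@dataclass
class FeatureTable:
    """subjects x features value matrix with ordered identities."""

    values: np.ndarray
    feature_ids: list[FeatureId]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_ids)):
            raise ValueError("values shape must be subjects x features")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicated feature ids")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicated subject ids")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=[str(f) for f in self.feature_ids])


@dataclass
class CohortLabels:
    """subject_id -> 'positive' (outcome) / 'negative' mapping."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - {"positive", "negative"}
        if bad:
            raise ValueError(f"unknown labels {bad}")

    def y(self, subject_ids: Sequence[str]) -> np.ndarray:
        """Binary vector aligned to the given subject order (positive=1)."""
        missing = set(subject_ids) - set(self.mapping)
        if missing:
            raise ValueError(f"labels missing for subjects {sorted(missing)}")
        return np.array([1 if self.mapping[s] == "positive" else 0
                         for s in subject_ids], dtype=int)

    def __len__(self) -> int:
        return len(self.mapping)


def feature_grid(channels: Sequence[str] = CHANNELS_1020,
                 band_labels: Sequence[str] | None = None,
                 measures: Sequence[str] = ALL_MEASURE_NAMES,
                 scales: Sequence[int] = DEFAULT_SCALES,
                 fs: float = 250.0) -> list[FeatureId]:
    """Deterministic feature-id grid: channel-major, band, measure."""
    from .decomposition import BAND_LABELS
    band_labels = list(BAND_LABELS if band_labels is None else band_labels)
    ids: list[FeatureId] = []
    for ch in channels:
        for band in band_labels:
            for m in measures:
                if m != "MSE":
                    ids.append(FeatureId(ch, band, m))
        if "MSE" in measures:
            for s in scales:
                ids.append(FeatureId(ch, scale_label(s, fs), "MSE"))
    return ids


def _compute_one(fid: FeatureId, sb: SubbandSet, cfg: MeasureConfig,
                 scales: Sequence[int]) -> float:
    ch = fid.channel
    if fid.measure == "MSE":
        scale = next(s for s in scales if scale_label(s, sb.fs) == fid.band_or_scale)
        return sample_entropy(sb.coarse[ch][scale], cfg)
    band = sb.bands[ch][fid.band_or_scale]
    if fid.measure == "Power":
        return power_rel(band, sb.broadband[ch], cfg)
    return MEASURES[fid.measure](band, cfg)


def build_feature_table(subband_sets: Mapping[str, SubbandSet],
                        cfg: MeasureConfig = MeasureConfig(),
                        scales: Sequence[int] = DEFAULT_SCALES,
                        measures: Sequence[str] = ALL_MEASURE_NAMES,
                        ) -> FeatureTable:
    """Compute the measure battery for every subject's decomposition.

    All subjects must share channel set, band labels and scales.  A failed
    per-feature computation is logged and flagged missing (NaN) instead of
    aborting the cohort run.
    """
    subject_ids = list(subband_sets)
    if not subject_ids:
        raise ValueError("no subjects")
    first = subband_sets[subject_ids[0]]
    for sid in subject_ids[1:]:
        sb = subband_sets[sid]
        if (sb.channels != first.channels
                or sb.band_labels != first.band_labels
                or tuple(sb.scales) != tuple(first.scales)):
            raise ValueError(f"inconsistent decomposition config for {sid}")
    ids = feature_grid(first.channels, first.band_labels, measures,
                       scales, fs=first.fs)
    values = np.empty((len(subject_ids), len(ids)))
    for si, sid in enumerate(subject_ids):
        sb = subband_sets[sid]
        for fi, fid in enumerate(ids):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    values[si, fi] = _compute_one(fid, sb, cfg, scales)
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("feature %s failed for %s: %s", fid, sid, exc)
                values[si, fi] = np.nan
    return FeatureTable(values=values, feature_ids=ids, subject_ids=subject_ids)


def impute_missing(table: FeatureTable, policy: str = "drop") -> FeatureTable:
    """Handle missing feature values.

    ``drop`` removes any feature missing for at least one subject;
    ``median`` replaces missing entries with the feature's median over the
    subjects that have it.  Counts are logged.
    """
    missing = np.isnan(table.values)
    if not missing.any():
        return table
    if policy == "drop":
        keep = ~missing.any(axis=0)
        log.info("dropping %d features with missing values",
                 int((~keep).sum()))
        return FeatureTable(values=table.values[:, keep],
                            feature_ids=[f for f, k in
                                         zip(table.feature_ids, keep) if k],
                            subject_ids=list(table.subject_ids))
    if policy == "median":
        values = table.values.copy()
        for j in np.flatnonzero(missing.any(axis=0)):
            col = values[:, j]
            med = np.nanmedian(col)
            col[np.isnan(col)] = med
        log.info("median-imputed %d missing entries", int(missing.sum()))
        return FeatureTable(values=values,
                            feature_ids=list(table.feature_ids),
                            subject_ids=list(table.subject_ids))
    raise ValueError(f"unknown policy {policy!r}")


# --------------------------------------------------------------------------
# serialization


def write_feature_table(table: FeatureTable, path) -> Path:
    """CSV with subject_id first column and feature-id strings as header;
    values round-trip at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.to_frame()
    df.index.name = "subject_id"
    df.to_csv(path, float_format="%.17g")
    return path


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.index.name != "subject_id":
        raise ValueError("malformed header: first column must be subject_id")
    ids = [FeatureId.parse(c) for c in df.columns]
    return FeatureTable(values=df.to_numpy(dtype=float),
                        feature_ids=ids,
                        subject_ids=[str(s) for s in df.index])


def write_labels(labels: CohortLabels, path) -> Path:
    import json
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(labels.mapping, indent=1, sort_keys=True))
    return path


def read_labels(path) -> CohortLabels:
    import json
    return CohortLabels(mapping=json.loads(Path(path).read_text()))
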