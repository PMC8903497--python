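"""Discrete-wavelet sub-band decomposition and coarse-graining.

Each 20-s channel segment (250 Hz) is decomposed with a 6-level orthogonal
DWT (Daubechies-4, symmetric extension).  The six detail levels are
reconstructed individually to full-length band signals with nominal dyadic
edges 125-62.5, 62.5-31.2, 31.2-15.6, 15.6-7.8, 7.8-3.9 and 3.9-1.95 Hz;
the <2 Hz approximation residual is discarded.  Printed band labels follow
the convention of the acquisition filters (1 Hz high-pass, 100 Hz
low-pass), so the outermost bands read 62.5-100 and 1-3.9 Hz.

Coarse-graining replaces a series by non-overlapping block means; scale s
uses factor 2**(s-1), halving the effective bandwidth per scale (scale 3 ->
1-31.2 Hz, scale 4 -> 1-15.6 Hz at 250 Hz).  It is applied to the broadband
segment, not to sub-bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .segmentation import AnalysisSegment

__all__ = [
    "BAND_LABELS",
    "DEFAULT_SCALES",
    "WaveletConfig",
    "SubbandSet",
    "scale_factor",
    "scale_label",
    "dwt_decompose",
    "coarse_grain",
    "decompose_segment",
]

#: printed labels for detail levels D1..D6 at fs = 250 Hz (high to low band)
BAND_LABELS: tuple[str, ...] = (
    "62.5-100Hz",
    "31.2-62.2Hz",
    "15.6-31.2Hz",
    "7.8-15.6Hz",
    "3.9-7.8Hz",
    "1-3.9Hz",
)

DEFAULT_SCALES: tuple[int, ...] = (2, 3, 4, 5, 6)


def scale_factor(scale: int) -> int:
    """Coarse-graining factor 2**(scale-1) for a multiscale-entropy scale."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    return 2 ** (scale - 1)


def scale_label(scale: int, fs: float = 250.0) -> str:
    """Band label of a coarse-grained broadband series, e.g. scale 3 at
    250 Hz -> '1-31.2Hz(scale3)' (upper edge fs/2/factor, printed truncated
    to one decimal as in report tables)."""
    upper = np.floor(fs / 2.0 / scale_factor(scale) * 10.0) / 10.0
    return f"1-{upper:g}Hz(scale{scale})"


@dataclass(frozen=True)
class WaveletConfig:
    family: str = "db4"
    levels: int = 6
    boundary: str = "symmetric"
    band_labels: tuple[str, ...] = BAND_LABELS

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.band_labels) != self.levels:
            raise ValueError("need one band label per detail level")


@dataclass
class SubbandSet:
    """Per-channel decomposition products of one analysis segment.

    bands
        channel label -> {band label -> full-length detail reconstruction}.
    coarse
        channel label -> {scale -> block-averaged broadband series}.
    broadband
        channel label -> the original segment channel (parent for relative
        power and the source of the coarse-grained series).
    """

    bands: dict[str, dict[str, np.ndarray]]
    coarse: dict[str, dict[int, np.ndarray]]
    broadband: dict[str, np.ndarray]
    fs: float
    band_labels: tuple[str, ...] = BAND_LABELS
    scales: tuple[int, ...] = DEFAULT_SCALES

    @property
    def channels(self) -> list[str]:
        return list(self.bands)


def dwt_decompose(signal, fs: float, cfg: WaveletConfig = WaveletConfig()):
    """Reconstruct the detail levels D1..D`levels` of an orthogonal DWT.

    Returns ``(bands, approx)``: a dict {band label -> full-length band
    signal} ordered high to low frequency, plus the discarded approximation
    reconstruction (useful for energy checks; the six reconstructions and
    the approximation sum to the input to machine precision).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("dwt_decompose expects a 1-D series")
    min_len = 2 ** cfg.levels
    if x.size < min_len:
        raise ValueError(f"series of length {x.size} too short for "
                         f"{cfg.levels} decomposition levels")
    coeffs = pywt.wavedec(x, cfg.family, mode=cfg.boundary, level=cfg.levels)
    # coeffs = [cA_L, cD_L, ..., cD_1]
    bands: dict[str, np.ndarray] = {}
    for det_level in range(1, cfg.levels + 1):  # D1 (highest band) first
        sel = [np.zeros_like(c) for c in coeffs]
        pos = len(coeffs) - det_level
        sel[pos] = coeffs[pos]
        rec = pywt.waverec(sel, cfg.family, mode=cfg.boundary)[: x.size]
        bands[cfg.band_labels[det_level - 1]] = rec
    sel = [np.zeros_like(c) for c in coeffs]
    sel[0] = coeffs[0]
    approx = pywt.waverec(sel, cfg.family, mode=cfg.boundary)[: x.size]
    return bands, approx


def coarse_grain(signal, factor: int) -> np.ndarray:
    """Non-overlapping block means of length ``factor``.

    Output length floor(N/factor); a trailing remainder shorter than one
    block is dropped.  factor 1 is the identity (copy).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("coarse_grain expects a 1-D series")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > x.size:
        raise ValueError(f"factor {factor} exceeds series length {x.size}")
    nb = x.size // factor
    return x[: nb * factor].reshape(nb, factor).mean(axis=1)


def decompose_segment(segment: AnalysisSegment,
                      cfg: WaveletConfig = WaveletConfig(),
                      scales: Sequence[int] = DEFAULT_SCALES) -> SubbandSet:
    """Decompose every channel of a segment into sub-bands and
    coarse-grained series; channel order is preserved."""
    scales = tuple(scales)
    bands: dict[str, dict[str, np.ndarray]] = {}
    coarse: dict[str, dict[int, np.ndarray]] = {}
    broadband: dict[str, np.ndarray] = {}
    for ch, row in zip(segment.channel_labels, segment.data):
        ch_bands, _ = dwt_decompose(row, segment.fs, cfg)
        bands[ch] = ch_bands
        coarse[ch] = {s: coarse_grain(row, scale_factor(s)) for s in scales}
        broadband[ch] = np.asarray(row, dtype=float)
    return SubbandSet(bands=bands, coarse=coarse, broadband=broadband,
                      fs=segment.fs, band_labels=cfg.band_labels,
                      scales=scales)
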