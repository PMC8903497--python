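"""Synthetic labeled EEG cohorts with controllable group differences.

Emulates the structure of a high-risk infant phoneme-oddball study: two
outcome groups (positive = later-diagnosed), 18 channels of the 10-20
montage sampled at 250 Hz, an event stream of frequent standard and rare
deviant trials, and recordings long enough to contain a >= 20 s run of
consecutive standards.

Each channel is a sum of independent components:

* six band-limited Gaussian noises (order-4 zero-phase Butterworth on
  white noise, standardized, scaled by per-band amplitudes) — per-subject
  log-normal amplitude jitter provides between-subject variability;
* a 1/f**beta "pink" background (spectrally shaped white noise);
* optionally a standardized, low-pass-filtered logistic-map series
  (x -> 4x(1-x), a deterministic chaotic component with Lyapunov exponent
  ln 2) whose mixing weight may differ by group;
* white observation noise.

Group differences are injected through :class:`GroupEffect`: multiplicative
band-amplitude shifts per (channel, band), an additive change to the pink
spectral exponent, and a chaos-mix difference.  All-zero effects make the
groups statistically exchangeable.  Everything is deterministic given the
cohort seed; per-subject seeds fan out via ``SeedSequence([seed, index])``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .segmentation import (DEVIANT, STANDARD, STIMULUS_DURATION_S,
                           EegRecording, EventSequence, Trial)

__all__ = [
    "CHANNELS_1020",
    "BAND_EDGES",
    "CohortSpec",
    "GroupEffect",
    "SignalModel",
    "POSITIVE",
    "NEGATIVE",
    "simulate_events",
    "simulate_recording",
    "simulate_cohort",
    "subject_seed",
    "target_relative_power",
    "target_effect_size",
    "write_recording",
    "read_recording",
]

#: the 18 10-20 channels analyzed (Cz excluded: it is the online reference)
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: synthesis band edges in Hz, keyed by the printed band labels
BAND_EDGES: dict[str, tuple[float, float]] = {
    "62.5-100Hz": (62.5, 100.0),
    "31.2-62.2Hz": (31.2, 62.2),
    "15.6-31.2Hz": (15.6, 31.2),
    "7.8-15.6Hz": (7.8, 15.6),
    "3.9-7.8Hz": (3.9, 7.8),
    "1-3.9Hz": (1.0, 3.9),
}

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a simulated cohort."""

    n_positive: int = 14
    n_negative: int = 40
    channels: tuple[str, ...] = CHANNELS_1020
    fs: float = 250.0
    duration: float = 700.0
    seed: int = 0
    deviant_prob: float = 0.2
    isi_range: tuple[float, float] = (1.0, 1.2)
    min_standard_run_s: float = 25.0

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("both groups need at least one subject")
        top = max(hi for _, hi in BAND_EDGES.values())
        if self.fs <= 2 * top:
            raise ValueError(f"fs={self.fs} below Nyquist for {top} Hz band")
        if self.duration < self.min_standard_run_s:
            raise ValueError("duration too short for the required standard run")

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative


@dataclass(frozen=True)
class GroupEffect:
    """Injected group differences; zeros give exchangeable groups."""

    band_power_shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    spectral_slope_shift: float = 0.0
    chaos_mix_negative: float = 0.0
    chaos_mix_positive: float = 0.0
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.band_power_shifts.values()):
            raise ValueError("band power shift factors must be > 0")

    def shift(self, channel: str, band: str, group: str) -> float:
        if group == POSITIVE:
            return self.band_power_shifts.get((channel, band), 1.0)
        return 1.0

    def chaos_mix(self, group: str) -> float:
        return (self.chaos_mix_positive if group == POSITIVE
                else self.chaos_mix_negative)


@dataclass(frozen=True)
class SignalModel:
    """Generator conventions: base spectra shared by both groups.

    Band amplitudes fall off with frequency (roughly 1/f power) on top of a
    pink background with exponent ``pink_beta``.  ``amp_jitter_sd`` is the
    SD of the per-subject log-amplitude jitter per (channel, band), the
    dominant between-subject variance.  ``sinusoids`` are injected test
    tones added to every channel.
    """

    band_amplitudes: dict[str, float] = field(default_factory=lambda: {
        "62.5-100Hz": 0.25,
        "31.2-62.2Hz": 0.35,
        "15.6-31.2Hz": 0.5,
        "7.8-15.6Hz": 0.7,
        "3.9-7.8Hz": 0.85,
        "1-3.9Hz": 1.0,
    })
    pink_amplitude: float = 0.5
    pink_beta: float = 1.0
    chaos_lowpass_hz: float = 30.0
    amp_jitter_sd: float = 0.2
    sinusoids: tuple[tuple[float, float], ...] = ()


DEFAULT_MODEL = SignalModel()


# --------------------------------------------------------------------------
# events


def simulate_events(duration: float, deviant_prob: float = 0.2,
                    isi_range: Sequence[float] = (1.0, 1.2),
                    seed: int = 0,
                    force_min_run: Optional[float] = None) -> EventSequence:
    """Draw an oddball trial stream.

    Trials are 0.3 s stimuli separated by ISIs uniform on ``isi_range``;
    each is independently a deviant with probability ``deviant_prob``.
    ``force_min_run`` guarantees at least one run of consecutive standards
    spanning at least that many seconds (a contiguous block is relabeled at
    a random admissible position if needed).
    """
    if not (0.0 <= deviant_prob < 1.0):
        raise ValueError("deviant_prob must be in [0, 1)")
    lo, hi = float(isi_range[0]), float(isi_range[1])
    if lo > hi or lo < 0:
        raise ValueError("invalid isi_range")
    if duration < STIMULUS_DURATION_S:
        raise ValueError("duration too short to fit one trial")
    rng = np.random.default_rng(seed)
    onsets, isis = [], []
    t = 0.0
    while t + STIMULUS_DURATION_S <= duration:
        onsets.append(t)
        isi = float(rng.uniform(lo, hi))
        isis.append(isi)
        t += STIMULUS_DURATION_S + isi
    labels = [DEVIANT if rng.random() < deviant_prob else STANDARD
              for _ in onsets]

    if force_min_run is not None:
        ends = [o + STIMULUS_DURATION_S + i for o, i in zip(onsets, isis)]
        n = len(onsets)

        def run_ok(i: int, j: int) -> bool:
            return ends[j] - onsets[i] >= force_min_run

        # smallest block [i, j] at each start that spans the target
        choices = []
        for i in range(n):
            j = i
            while j < n and not run_ok(i, j):
                j += 1
            if j < n:
                choices.append((i, j))
        if not choices:
            raise ValueError(
                f"duration {duration} s cannot contain a {force_min_run} s run")
        has_run = any(
            all(lab == STANDARD for lab in labels[i:j + 1])
            for i, j in choices)
        if not has_run:
            i, j = choices[int(rng.integers(len(choices)))]
            for k in range(i, j + 1):
                labels[k] = STANDARD

    trials = [Trial(onset=o, label=lab, isi=isi)
              for o, lab, isi in zip(onsets, labels, isis)]
    return EventSequence(trials=trials, max_isi=hi)


# --------------------------------------------------------------------------
# signal synthesis


def _unit_variance(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                edges: tuple[float, float]) -> np.ndarray:
    sos = sps.butter(4, edges, btype="bandpass", fs=fs, output="sos")
    return _unit_variance(sps.sosfiltfilt(sos, rng.standard_normal(n)))


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                beta: float) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f[0] = f[1]
    shaped = np.fft.irfft(spec * f ** (-beta / 2.0), n)
    return _unit_variance(shaped)


def _chaos_series(rng: np.random.Generator, n: int, fs: float,
                  lowpass_hz: float) -> np.ndarray:
    x = np.empty(n + 100)
    x[0] = rng.uniform(0.1, 0.9)
    for t in range(1, n + 100):
        x[t] = 4.0 * x[t - 1] * (1.0 - x[t - 1])
    series = x[100:]
    if 0 < lowpass_hz < fs / 2:
        sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=fs, output="sos")
        series = sps.sosfiltfilt(sos, series)
    return _unit_variance(series - series.mean())


def simulate_recording(spec: CohortSpec, effect: GroupEffect, group: str,
                       subject_seed: int, subject_id: str = "",
                       model: SignalModel = DEFAULT_MODEL) -> EegRecording:
    """Synthesize one subject's recording (deterministic given seeds)."""
    if group not in (POSITIVE, NEGATIVE):
        raise ValueError(f"group must be {POSITIVE!r} or {NEGATIVE!r}")
    n = int(round(spec.duration * spec.fs))
    rng = np.random.default_rng(subject_seed)
    beta = model.pink_beta + (effect.spectral_slope_shift
                              if group == POSITIVE else 0.0)
    chaos_w = effect.chaos_mix(group)
    t = np.arange(n) / spec.fs
    tones = sum((amp * np.sin(2 * np.pi * freq * t)
                 for freq, amp in model.sinusoids), np.zeros(n))

    data = np.empty((len(spec.channels), n))
    for ci, ch in enumerate(spec.channels):
        sig = np.zeros(n)
        for band, edges in BAND_EDGES.items():
            amp = model.band_amplitudes.get(band, 0.0)
            jitter = math.exp(rng.normal(0.0, model.amp_jitter_sd))
            amp_eff = amp * effect.shift(ch, band, group) * jitter
            if amp_eff > 0:
                sig += amp_eff * _band_noise(rng, n, spec.fs, edges)
            else:  # keep the RNG stream aligned across configurations
                rng.standard_normal(n)
        if model.pink_amplitude > 0:
            sig += model.pink_amplitude * _pink_noise(rng, n, spec.fs, beta)
        else:
            rng.standard_normal(n)
        if chaos_w > 0:
            sig += chaos_w * _chaos_series(rng, n, spec.fs,
                                           model.chaos_lowpass_hz)
        if effect.noise_sd > 0:
            sig += effect.noise_sd * rng.standard_normal(n)
        data[ci] = sig + tones

    events = simulate_events(spec.duration, spec.deviant_prob,
                             spec.isi_range, seed=subject_seed,
                             force_min_run=spec.min_standard_run_s)
    return EegRecording(data=data, fs=spec.fs,
                        channel_labels=list(spec.channels), events=events,
                        subject_id=subject_id, group=group,
                        seed=subject_seed)


def subject_seed(cohort_seed: int, index: int) -> int:
    """Stable per-subject seed fan-out: SeedSequence([cohort_seed, index])."""
    return int(np.random.SeedSequence([cohort_seed, index])
               .generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(spec: CohortSpec, effect: GroupEffect,
                    model: SignalModel = DEFAULT_MODEL):
    """Simulate the full labeled cohort (positives first).

    Returns ``(recordings, labels)`` with ``labels`` mapping subject_id to
    'positive' / 'negative'.
    """
    recordings, labels = [], {}
    groups = [POSITIVE] * spec.n_positive + [NEGATIVE] * spec.n_negative
    for idx, group in enumerate(groups):
        sid = f"S{idx:03d}"
        rec = simulate_recording(spec, effect, group,
                                 subject_seed(spec.seed, idx),
                                 subject_id=sid, model=model)
        recordings.append(rec)
        labels[sid] = group
    return recordings, labels


# --------------------------------------------------------------------------
# analytic effect-size targeting


def _pink_band_fraction(edges: tuple[float, float], beta: float,
                        f_lo: float, f_hi: float) -> float:
    """Fraction of unit-variance 1/f**beta noise inside a band."""

    def integral(a: float, b: float) -> float:
        if abs(beta - 1.0) < 1e-12:
            return math.log(b / a)
        p = 1.0 - beta
        return (b ** p - a ** p) / p

    lo = max(edges[0], f_lo)
    hi = min(edges[1], f_hi)
    if hi <= lo:
        return 0.0
    return integral(lo, hi) / integral(f_lo, f_hi)


def target_relative_power(spec: CohortSpec, effect: GroupEffect,
                          channel: str, band: str, group: str,
                          model: SignalModel = DEFAULT_MODEL) -> float:
    """Expected relative power (band variance / total variance)."""
    f_lo, f_hi = 1.0 / spec.duration, spec.fs / 2.0
    beta = model.pink_beta + (effect.spectral_slope_shift
                              if group == POSITIVE else 0.0)
    v = {b: (model.band_amplitudes.get(b, 0.0)
             * effect.shift(channel, b, group)) ** 2
         for b in BAND_EDGES}
    pink = model.pink_amplitude ** 2
    noise = effect.noise_sd ** 2
    total = sum(v.values()) + pink + noise + effect.chaos_mix(group) ** 2
    in_band = (v[band]
               + pink * _pink_band_fraction(BAND_EDGES[band], beta, f_lo, f_hi)
               + noise * (BAND_EDGES[band][1] - BAND_EDGES[band][0]) / f_hi)
    return in_band / total


def target_effect_size(spec: CohortSpec, effect: GroupEffect,
                       channel: str, band: str,
                       model: SignalModel = DEFAULT_MODEL) -> float:
    """First-order analytic Cohen's d of the relative-power feature.

    Propagates the per-band log-amplitude jitter and the finite-window
    variance-estimation noise (2*bandwidth*duration degrees of freedom)
    through the relative-power ratio by the delta method.
    """

    def moments(group: str) -> tuple[float, float]:
        rp = target_relative_power(spec, effect, channel, band, group, model)
        v = {b: (model.band_amplitudes.get(b, 0.0)
                 * effect.shift(channel, b, group)) ** 2
             for b in BAND_EDGES}
        total = (sum(v.values()) + model.pink_amplitude ** 2
                 + effect.noise_sd ** 2 + effect.chaos_mix(group) ** 2)
        q = {b: vb / total for b, vb in v.items()}
        var_jitter = 4.0 * model.amp_jitter_sd ** 2 * (
            q[band] ** 2 * (1.0 - rp) ** 2
            + rp ** 2 * sum(qk ** 2 for b, qk in q.items() if b != band))
        bw = BAND_EDGES[band][1] - BAND_EDGES[band][0]
        n_eff = 2.0 * bw * spec.duration
        var_est = (rp * (1.0 - rp)) ** 2 * 2.0 / n_eff
        return rp, var_jitter + var_est

    rp_pos, var_pos = moments(POSITIVE)
    rp_neg, var_neg = moments(NEGATIVE)
    pooled = math.sqrt((var_pos + var_neg) / 2.0)
    return (rp_pos - rp_neg) / pooled


# --------------------------------------------------------------------------
# serialization (CSV matrix + JSON sidecar)


def write_recording(rec: EegRecording, out_dir, basename: Optional[str] = None):
    """Write samples-x-channels CSV plus a JSON sidecar; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = basename or rec.subject_id or "recording"
    csv_path = out_dir / f"{base}.csv"
    json_path = out_dir / f"{base}.json"
    header = ",".join(rec.channel_labels)
    np.savetxt(csv_path, rec.data.T, delimiter=",", header=header,
               comments="", fmt="%.17g")
    meta = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "seed": rec.seed,
        "max_isi": rec.events.max_isi,
        "events": [{"onset_s": t.onset, "label": t.label, "isi": t.isi}
                   for t in rec.events.trials],
    }
    json_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path, json_path


def read_recording(csv_path) -> EegRecording:
    """Inverse of :func:`write_recording` (expects the sidecar next to it)."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    with open(csv_path) as fh:
        labels = fh.readline().strip().split(",")
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2).T
    events = EventSequence(
        trials=[Trial(onset=e["onset_s"], label=e["label"], isi=e.get("isi"))
                for e in meta["events"]],
        max_isi=meta.get("max_isi", 1.2))
    return EegRecording(data=data, fs=meta["fs"], channel_labels=labels,
                        events=events, subject_id=meta["subject_id"],
                        group=meta.get("group"), seed=meta.get("seed"))
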