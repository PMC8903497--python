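"""Event handling and extraction of the 20-s standard-run analysis window.

The oddball stream mixes frequent "standard" and rare "deviant" phoneme
trials.  Only continuous EEG during the longest run of consecutive
standards is analyzed: the run is located from the event annotations and
the centered 20-s window is sliced out of every channel identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "STIMULUS_DURATION_S",
    "Trial",
    "EventSequence",
    "EegRecording",
    "AnalysisSegment",
    "StandardRun",
    "InsufficientRunError",
    "find_longest_standard_run",
    "extract_middle_window",
]

#: auditory stimulus length in seconds (fixed by the paradigm)
STIMULUS_DURATION_S = 0.3

STANDARD = "standard"
DEVIANT = "deviant"


class InsufficientRunError(ValueError):
    """No standard run long enough for the requested analysis window."""


@dataclass(frozen=True)
class Trial:
    onset: float
    label: str
    isi: Optional[float] = None  # realized post-stimulus interval, if known

    def __post_init__(self) -> None:
        if self.label not in (STANDARD, DEVIANT):
            raise ValueError(f"unknown trial label {self.label!r}")


@dataclass
class EventSequence:
    """Ordered trial onsets with labels; onsets strictly increasing."""

    trials: list[Trial]
    max_isi: float = 1.2  # fallback trailing interval when per-trial ISI unknown

    def __post_init__(self) -> None:
        onsets = [t.onset for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)

    def labels(self) -> list[str]:
        return [t.label for t in self.trials]

    def trial_end(self, index: int) -> float:
        """End of a trial's span: onset + stimulus + realized (or max) ISI."""
        t = self.trials[index]
        isi = t.isi if t.isi is not None else self.max_isi
        return t.onset + STIMULUS_DURATION_S + isi


@dataclass
class EegRecording:
    """channels x samples signal matrix with events and metadata."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    events: EventSequence
    subject_id: str = ""
    group: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        dur = self.duration
        if any(not (0.0 <= t.onset < dur) for t in self.events.trials):
            raise ValueError("event onsets must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class StandardRun:
    first: int
    last: int  # inclusive trial indices
    t0: float
    t1: float  # half-open span [t0, t1) in seconds

    @property
    def n_trials(self) -> int:
        return self.last - self.first + 1

    @property
    def span(self) -> float:
        return self.t1 - self.t0


@dataclass
class AnalysisSegment:
    """Fixed-length window sliced identically from all channels."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    window: tuple[float, float]  # [start_s, end_s)
    source_run: tuple[int, int]
    subject_id: str = ""

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def find_longest_standard_run(events: EventSequence) -> StandardRun:
    """Locate the maximal run of consecutive standard trials.

    Runs are ranked by trial count, ties broken by earliest start.  The
    run's time span extends from its first onset to the last trial's onset
    + 0.3 s stimulus + its realized ISI (the sequence's max ISI when the
    per-trial value is unknown).
    """
    if len(events) == 0:
        raise ValueError("empty event sequence")
    labels = events.labels()
    best: Optional[tuple[int, int]] = None
    start: Optional[int] = None
    for i, lab in enumerate(labels + [DEVIANT]):  # sentinel flushes last run
        if lab == STANDARD:
            if start is None:
                start = i
        elif start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (start, i - 1)
            start = None
    if best is None:
        raise InsufficientRunError("no standard run")
    first, last = best
    return StandardRun(first=first, last=last,
                       t0=events.trials[first].onset,
                       t1=events.trial_end(last))


def extract_middle_window(recording: EegRecording, run: StandardRun,
                          window_s: float = 20.0) -> AnalysisSegment:
    """Slice the centered ``window_s`` seconds of the run from all channels.

    The window start t0 + (span - window_s)/2 is rounded to the nearest
    sample; the slice is the half-open sample interval of exactly
    round(window_s * fs) samples.
    """
    if run.span < window_s:
        raise InsufficientRunError(
            f"standard run spans {run.span:.2f} s < window {window_s:.2f} s")
    fs = recording.fs
    n_win = int(round(window_s * fs))
    start_s = run.t0 + (run.span - window_s) / 2.0
    i0 = int(round(start_s * fs))
    i1 = i0 + n_win
    if i1 > recording.data.shape[1]:
        raise InsufficientRunError("run window extends past end of recording")
    return AnalysisSegment(
        data=recording.data[:, i0:i1].copy(),
        fs=fs,
        channel_labels=list(recording.channel_labels),
        window=(i0 / fs, i1 / fs),
        source_run=(run.first, run.last),
        subject_id=recording.subject_id,
    )
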