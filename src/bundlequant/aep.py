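"""Auditory-evoked-potential analysis.

Tone pips are Blackman-windowed sinusoids (default 10 ms).  Epochs
sharing a (frequency, level) condition are averaged stimulus-locked, and
a response is called *detected* when the peak-to-peak amplitude of the
post-stimulus window of the averaged trace reaches ``k`` times the
baseline RMS.  The baseline RMS is measured on the *raw* trace in the
pre-stimulus windows (single-sweep noise floor): averaging N epochs
suppresses the noise in the average by √N, so a detected response is one
whose averaged amplitude still rivals the single-sweep noise.  The
threshold at one frequency is the lowest tested level that is detected
together with every tested level above it; if even the highest level is
undetected the threshold is *not reached*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .phantoms import AepRecording

__all__ = [
    "Waveform",
    "make_tone_pip",
    "EpochAverage",
    "average_epochs",
    "detect_response",
    "estimate_threshold",
    "AepThresholdEstimator",
    "NOT_REACHED",
]

NOT_REACHED = "not reached"


@dataclass
class Waveform:
    samples: np.ndarray
    sample_rate: float
    label: tuple[float, float] | None = None  # (frequency Hz, level dB)


def make_tone_pip(
    frequency: float,
    duration_s: float = 0.010,
    sample_rate: float = 44100.0,
    amplitude: float = 1.0,
) -> Waveform:
    """Blackman-windowed tone pip spanning the full duration."""
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    if frequency >= sample_rate / 2.0:
        raise ValueError(
            f"frequency {frequency} Hz aliases at sample rate {sample_rate} Hz"
        )
    n = int(round(duration_s * sample_rate))
    if n < 2:
        raise ValueError("duration too short for the sample rate")
    t = np.arange(n) / sample_rate
    samples = amplitude * np.sin(2.0 * np.pi * frequency * t) * np.blackman(n)
    return Waveform(samples, sample_rate)


@dataclass
class EpochAverage:
    """Stimulus-locked average for one (frequency, level) condition.

    ``trace`` spans [-pre_ms, +post_ms] around stimulus onset; the onset
    sample index is ``onset_index``.
    """

    frequency: float
    level_db: float
    trace: np.ndarray
    sample_rate: float
    onset_index: int
    n_epochs: int


def average_epochs(
    rec: AepRecording,
    pre_ms: float = 10.0,
    post_ms: float = 30.0,
    reject_above: float | None = None,
) -> dict[tuple[float, float], EpochAverage]:
    """Arithmetic mean over epochs per (frequency, level) condition.

    ``reject_above`` enables artifact rejection: epochs whose absolute
    amplitude exceeds the limit anywhere are dropped before averaging
    (off by default).
    """
    fs = rec.sample_rate
    pre = int(round(pre_ms / 1000.0 * fs))
    post = int(round(post_ms / 1000.0 * fs))
    groups: dict[tuple[float, float], list[np.ndarray]] = {}
    for idx, (onset_s, freq, level) in enumerate(rec.events):
        onset = int(round(onset_s * fs))
        lo, hi = onset - pre, onset + post
        if lo < 0 or hi > rec.trace.size:
            raise ValueError(
                f"epoch for event {idx} (onset {onset_s:.4f} s, {freq} Hz, "
                f"{level} dB) extends outside the trace"
            )
        epoch = rec.trace[lo:hi]
        if reject_above is not None and np.abs(epoch).max() > reject_above:
            continue
        groups.setdefault((freq, level), []).append(epoch)
    return {
        key: EpochAverage(
            frequency=key[0],
            level_db=key[1],
            trace=np.mean(np.stack(epochs), axis=0),
            sample_rate=fs,
            onset_index=pre,
            n_epochs=len(epochs),
        )
        for key, epochs in groups.items()
    }


def detect_response(
    avg: EpochAverage | np.ndarray,
    baseline_rms: float,
    k: float = 2.0,
    onset_index: int | None = None,
) -> tuple[bool, float]:
    """Peak-to-peak detection of an averaged response.

    ``amplitude`` is the peak-to-peak of the post-stimulus part of the
    averaged trace; the response is detected iff
    ``amplitude >= k * baseline_rms`` (ties count as detected).  With a
    noiseless recording (``baseline_rms == 0``) any strictly positive
    amplitude is detected, so a flat trace is still not.
    """
    if baseline_rms < 0:
        raise ValueError("baseline_rms must be >= 0")
    if isinstance(avg, EpochAverage):
        window = avg.trace[avg.onset_index :]
    else:
        window = np.asarray(avg, dtype=float)
        if onset_index is not None:
            window = window[onset_index:]
    if window.size == 0:
        raise ValueError("empty post-stimulus window")
    amplitude = float(window.max() - window.min())
    if baseline_rms == 0:
        return amplitude > 0.0, amplitude
    return amplitude >= k * baseline_rms, amplitude


def estimate_threshold(
    detections: Mapping[float, bool] | Sequence[tuple[float, bool]],
) -> float | str:
    """Lowest level detected contiguously from the top of a descending run.

    ``detections`` maps tested level (dB) to the detection flag.  Levels
    are processed in descending order; the threshold is the lowest level
    L such that L and every tested level above L are detected.  Detections
    below an undetected level (a non-monotone inversion) are ignored with
    a warning.  Returns ``NOT_REACHED`` when the top level is undetected.
    """
    items = sorted(
        detections.items() if isinstance(detections, Mapping) else detections,
        key=lambda lv: -lv[0],
    )
    if not items:
        raise ValueError("no detection flags given")
    levels = [lv for lv, _ in items]
    if len(set(levels)) != len(levels):
        raise ValueError("duplicate levels in detection flags")
    threshold: float | str = NOT_REACHED
    broken = False
    inversion = False
    for level, det in items:
        if not broken:
            if det:
                threshold = level
            else:
                broken = True
        elif det:
            inversion = True
    if inversion:
        warnings.warn(
            "non-monotone detection sequence: detections below an undetected "
            "level were ignored (contiguous-from-top rule)",
            stacklevel=2,
        )
    return threshold


class AepThresholdEstimator(BaseEstimator):
    """Per-frequency evoked-potential threshold from a recording.

    Parameters
    ----------
    k : float
        Detection criterion: averaged peak-to-peak must reach
        ``k`` × single-sweep baseline RMS.
    pre_ms, post_ms : float
        Epoch window around stimulus onset; the pre-stimulus part of the
        raw trace provides the baseline RMS estimate.

    Attributes
    ----------
    thresholds_ : dict[float, float | str]
        Estimated threshold (dB) or ``NOT_REACHED`` per frequency.
    results_ : pandas.DataFrame
        One row per (frequency, level): amplitude, detected flag, epochs.
    baseline_rms_ : float
        Pooled RMS of the raw pre-stimulus segments.
    """

    def __init__(
        self,
        k: float = 2.0,
        pre_ms: float = 10.0,
        post_ms: float = 30.0,
        reject_above: float | None = None,
    ):
        self.k = k
        self.pre_ms = pre_ms
        self.post_ms = post_ms
        self.reject_above = reject_above

    def fit(self, rec: AepRecording, y=None):
        fs = rec.sample_rate
        pre = int(round(self.pre_ms / 1000.0 * fs))
        baseline_segments = []
        for onset_s, _freq, _level in rec.events:
            onset = int(round(onset_s * fs))
            if onset - pre >= 0:
                baseline_segments.append(rec.trace[onset - pre : onset])
        if not baseline_segments:
            raise ValueError("no pre-stimulus baseline segments available")
        baseline = np.concatenate(baseline_segments)
        self.baseline_rms_ = float(np.sqrt(np.mean(baseline**2)))

        averages = average_epochs(rec, self.pre_ms, self.post_ms, self.reject_above)
        rows = []
        by_freq: dict[float, dict[float, bool]] = {}
        for (freq, level), avg in sorted(averages.items(), key=lambda kv: (kv[0][0], -kv[0][1])):
            detected, amplitude = detect_response(avg, self.baseline_rms_, self.k)
            by_freq.setdefault(freq, {})[level] = detected
            rows.append(
                {
                    "frequency_hz": freq,
                    "level_db": level,
                    "n_epochs": avg.n_epochs,
                    "amplitude": amplitude,
                    "detected": detected,
                }
            )
        self.results_ = pd.DataFrame(
            rows, columns=["frequency_hz", "level_db", "n_epochs", "amplitude", "detected"]
        )
        self.thresholds_ = {
            freq: estimate_threshold(dets) for freq, dets in by_freq.items()
        }
        return self

    def threshold_table(self) -> pd.DataFrame:
        rows = [
            {"frequency_hz": f, "threshold_db": t if t != NOT_REACHED else np.nan,
             "reached": t != NOT_REACHED}
            for f, t in sorted(self.thresholds_.items())
        ]
        return pd.DataFrame(rows, columns=["frequency_hz", "threshold_db", "reached"])
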