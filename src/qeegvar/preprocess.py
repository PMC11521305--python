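"""Centralised pre-processing chain.

The chain applied to every recording before spectral analysis is:

1. remove the DC shift (whole-recording mean subtraction),
2. interpolate to the common 100 Hz grid,
3. zero-phase FIR low-pass at 49 Hz (rejects both 50 Hz and 60 Hz mains),
4. RMS-threshold artifact rejection,
5. extraction of artifact-free spans inside the analysis window.

The artifact threshold is fully deterministic: the RMS of consecutive
windows is summarised by its median and median absolute deviation (MAD),
and windows with RMS above ``median + k * MAD`` are flagged, padded and
merged.  Because the threshold is data-relative, rescaling the whole
recording by a constant gain leaves the mask unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .edf_io import Recording
from .errors import MissingEventError, TooShortError, UnsupportedRateError

__all__ = [
    "ArtifactMask",
    "CleanSegmentSet",
    "remove_dc",
    "resample_100hz",
    "lowpass_49",
    "design_lowpass",
    "detect_artifacts",
    "clean_segments",
    "resolve_window",
    "mask_to_bed",
]

TARGET_RATE = 100.0
#: Minimum clean-span length: one full Welch segment (1024 samples at 100 Hz).
MIN_SEGMENT_S = 10.24

# Pre/post analysis windows relative to the dose event (seconds): the
# baseline is the 30-60 minutes before treatment, the post window the
# 30-60 minutes after.
PRE_WINDOW = (-3600.0, -1800.0)
POST_WINDOW = (1800.0, 3600.0)


@dataclass
class ArtifactMask:
    """Sorted, disjoint (start_s, end_s) intervals flagged as artifact."""

    intervals: list[tuple[float, float]]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for a, b in self.intervals:
            if a >= b or a < prev_end:
                raise ValueError("mask intervals must be sorted and disjoint")
            prev_end = b

    @property
    def total_masked_s(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    def masked_fraction(self, window: tuple[float, float]) -> float:
        """Fraction of ``window`` covered by the mask."""
        lo, hi = window
        covered = sum(
            max(0.0, min(b, hi) - max(a, lo)) for a, b in self.intervals
        )
        return covered / (hi - lo) if hi > lo else 0.0

    def overlaps(self, start: float, end: float) -> bool:
        return any(a < end and b > start for a, b in self.intervals)


@dataclass
class CleanSegmentSet:
    """Disjoint artifact-free spans of a recording within a window."""

    spans: list[tuple[float, float]]
    window: tuple[float, float]

    @property
    def total_clean_s(self) -> float:
        return float(sum(b - a for a, b in self.spans))

    def extract(self, recording: Recording) -> list[np.ndarray]:
        """Sample arrays for each clean span."""
        rate = recording.sampling_rate
        out = []
        for a, b in self.spans:
            i = int(round(a * rate))
            j = int(round(b * rate))
            out.append(recording.samples[i:j])
        return out


def remove_dc(recording: Recording) -> Recording:
    """Subtract the whole-recording mean (spectra are only used above 1 Hz)."""
    if recording.n_samples < 1:
        raise TooShortError("cannot remove DC from an empty recording")
    return recording.with_samples(recording.samples - recording.samples.mean())


def resample_100hz(recording: Recording, interp: str = "linear") -> Recording:
    """Interpolate the signal onto the common 100 Hz grid.

    ``interp`` selects the dialect: "linear" (default; plain interpolation
    onto the 100 Hz time grid) or "polyphase" (band-limited resampling via
    ``scipy.signal.resample_poly``, offered for sensitivity analyses).
    Recordings already at 100 Hz pass through unchanged.
    """
    rate = recording.sampling_rate
    if rate < TARGET_RATE:
        raise UnsupportedRateError(
            f"native rate {rate} Hz is below the {TARGET_RATE:g} Hz target"
        )
    if rate == TARGET_RATE:
        return recording
    n_out = int(round(recording.duration * TARGET_RATE))
    if interp == "linear":
        t_in = np.arange(recording.n_samples) / rate
        t_out = np.arange(n_out) / TARGET_RATE
        y = np.interp(t_out, t_in, recording.samples)
    elif interp == "polyphase":
        from fractions import Fraction

        frac = Fraction(int(TARGET_RATE), int(rate)) if rate == int(rate) else None
        if frac is None:
            raise UnsupportedRateError("polyphase resampling needs an integer rate")
        y = signal.resample_poly(recording.samples, frac.numerator, frac.denominator)
        y = y[:n_out]
    else:
        raise ValueError(f"unknown interpolation dialect {interp!r}")
    return recording.with_samples(y, sampling_rate=TARGET_RATE)


def design_lowpass(
    cutoff_hz: float = 49.0, numtaps: int = 201, rate: float = TARGET_RATE
) -> np.ndarray:
    """Hamming-windowed sinc FIR taps (half-amplitude, -6 dB, at the cutoff)."""
    return signal.firwin(numtaps, cutoff_hz, fs=rate, window="hamming")


def lowpass_49(recording: Recording, cutoff_hz: float = 49.0, numtaps: int = 201) -> Recording:
    """Zero-phase 49 Hz low-pass (forward-backward FIR filtering)."""
    taps = design_lowpass(cutoff_hz, numtaps, recording.sampling_rate)
    pad = min(3 * len(taps), recording.n_samples - 1)
    y = signal.filtfilt(taps, [1.0], recording.samples, padlen=pad)
    return recording.with_samples(y)


def detect_artifacts(
    recording: Recording,
    rms_window_s: float = 1.0,
    threshold_multiplier: float = 6.0,
    pad_s: float = 0.5,
) -> ArtifactMask:
    """Deterministic RMS amplitude-threshold artifact rejection.

    The signal is split into consecutive windows of ``rms_window_s``; a
    window is flagged when its RMS exceeds ``median(RMS) + k * MAD(RMS)``
    (k = ``threshold_multiplier``; the MAD carries the usual 1.4826
    normal-consistency factor, so k is in robust-sigma units).  Flagged
    windows are padded by ``pad_s`` on both sides and merged.  When the
    MAD is zero (perfectly homogeneous RMS) only windows above
    ``10 * median`` are flagged, so a clean stationary signal yields an
    empty mask.
    """
    if rms_window_s <= 0:
        raise ValueError("rms_window_s must be positive")
    rate = recording.sampling_rate
    wlen = int(round(rms_window_s * rate))
    n_win = recording.n_samples // wlen
    if n_win < 1:
        raise TooShortError("recording shorter than one RMS window")

    x = recording.samples[: n_win * wlen].reshape(n_win, wlen)
    rms = np.sqrt(np.mean(x**2, axis=1))
    med = float(np.median(rms))
    mad = 1.4826 * float(np.median(np.abs(rms - med)))
    if mad > 1e-9 * max(med, 1e-300):
        threshold = med + threshold_multiplier * mad
    else:
        threshold = 10.0 * med  # degenerate fallback: flat RMS profile
    flagged = np.flatnonzero(rms > threshold)

    intervals: list[tuple[float, float]] = []
    for k in flagged:
        a = max(0.0, k * rms_window_s - pad_s)
        b = min(recording.duration, (k + 1) * rms_window_s + pad_s)
        if intervals and a <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], b))
        else:
            intervals.append((a, b))
    return ArtifactMask(
        intervals=intervals,
        params={
            "rms_window_s": rms_window_s,
            "threshold_multiplier": threshold_multiplier,
            "pad_s": pad_s,
            "threshold_uV": threshold,
        },
    )


def resolve_window(
    recording: Recording, window: str | tuple[float, float]
) -> tuple[float, float]:
    """Resolve a symbolic window ("pre"/"post") against the dose event.

    "pre" is the 30-60 minutes before the (first) dose, "post" the 30-60
    minutes after.  Explicit (start_s, end_s) tuples pass through.
    """
    if isinstance(window, str):
        if not recording.dose_events:
            raise MissingEventError(
                f"symbolic window {window!r} requested but "
                f"{recording.lab_id}/{recording.subject_id} has no dose event"
            )
        t0 = recording.dose_events[0][0]
        if window == "pre":
            lo, hi = PRE_WINDOW
        elif window == "post":
            lo, hi = POST_WINDOW
        else:
            raise ValueError(f"unknown symbolic window {window!r}")
        window = (t0 + lo, t0 + hi)
    lo, hi = float(window[0]), float(window[1])
    if lo < 0 or hi > recording.duration + 1e-9 or lo >= hi:
        raise TooShortError(
            f"window ({lo}, {hi}) s outside recording of {recording.duration} s"
        )
    return (lo, hi)


def clean_segments(
    recording: Recording,
    mask: ArtifactMask,
    window: str | tuple[float, float],
    min_seg_s: float = MIN_SEGMENT_S,
) -> CleanSegmentSet:
    """Artifact-free spans inside the analysis window.

    The complement of the mask within the window, dropping spans shorter
    than ``min_seg_s`` (default: one full Welch segment).  An empty result
    is allowed; the pipeline treats it as an excluded recording.
    """
    lo, hi = resolve_window(recording, window)
    spans: list[tuple[float, float]] = []
    cursor = lo
    for a, b in mask.intervals:
        a, b = max(a, lo), min(b, hi)
        if a >= b:
            continue
        if a > cursor:
            spans.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < hi:
        spans.append((cursor, hi))
    spans = [(a, b) for a, b in spans if b - a >= min_seg_s]
    return CleanSegmentSet(spans=spans, window=(lo, hi))


def mask_to_bed(recording: Recording, mask: ArtifactMask) -> str:
    """BED-like export of the mask (name, start_s, end_s), for audit."""
    name = f"{recording.lab_id}_{recording.subject_id}"
    lines = [f"{name}\t{a:.3f}\t{b:.3f}" for a, b in mask.intervals]
    return "\n".join(lines) + ("\n" if lines else "")
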