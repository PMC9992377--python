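"""Baseline trimming, fixed-length segmentation and rhythm-band filtering.

A raw trial is 63 s of 32-channel EEG at 128 Hz.  The first 3 s precede
stimulus onset and are discarded; the remaining 60 s are cut into twenty
non-overlapping 3-s windows, and each window is band-pass filtered into
the four classical EEG rhythms before phase analysis:

=======  ==========
rhythm   band (Hz)
=======  ==========
theta    4 - 8
alpha    8 - 13
beta     13 - 30
gamma    30 - 45
=======  ==========

Filtering is a 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), i.e. zero-phase: instantaneous phase extracted
downstream is not distorted by filter group delay.  By default each 3-s
segment is filtered independently; ``bandpass_recording`` supports
filtering the full trial before segmentation instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io import Recording

__all__ = [
    "BandSpec",
    "BANDS",
    "Segment",
    "trim_baseline",
    "segment_recording",
    "bandpass",
    "bandpass_recording",
    "segments_from_recording",
]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with inclusive edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: The four canonical rhythm bands, in ascending frequency order.
BANDS: tuple[BandSpec, ...] = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 45.0),
)

BAND_BY_NAME: dict[str, BandSpec] = {b.name: b for b in BANDS}


@dataclass(frozen=True)
class Segment:
    """One fixed-length window of a trial, optionally band-filtered.

    ``band`` is None for a broadband (unfiltered) segment.
    """

    participant: int
    video: int
    index: int
    signals: np.ndarray  # channels x samples
    fs: float
    band: BandSpec | None = None

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


def trim_baseline(recording: Recording, baseline_seconds: float = 3.0) -> Recording:
    """Drop the pre-stimulus baseline from the start of every channel.

    Parameters
    ----------
    recording
        Full-length trial.
    baseline_seconds
        Length of the leading baseline to remove (default 3 s).

    Raises
    ------
    ValueError
        If the baseline is as long as (or longer than) the recording.
    """
    n_drop = int(round(baseline_seconds * recording.fs))
    if not np.isclose(n_drop, baseline_seconds * recording.fs):
        raise ValueError("baseline_seconds * fs must be an integer sample count")
    if n_drop >= recording.signals.shape[1]:
        raise ValueError("baseline covers the entire recording")
    if n_drop == 0:
        return recording
    return replace(recording, signals=recording.signals[:, n_drop:])


def segment_recording(recording: Recording, seg_seconds: float = 3.0) -> list[Segment]:
    """Cut a (trimmed) trial into consecutive non-overlapping windows.

    A trailing remainder shorter than one window is discarded, so the
    number of segments is ``floor(duration / seg_seconds)``.
    """
    if seg_seconds <= 0:
        raise ValueError("seg_seconds must be positive")
    win = int(round(seg_seconds * recording.fs))
    if not np.isclose(win, seg_seconds * recording.fs):
        raise ValueError("seg_seconds * fs must be an integer sample count")
    n_total = recording.signals.shape[1]
    n_seg = n_total // win
    return [
        Segment(
            participant=recording.participant,
            video=recording.video,
            index=k,
            signals=recording.signals[:, k * win : (k + 1) * win],
            fs=recording.fs,
        )
        for k in range(n_seg)
    ]


def _band_sos(band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if band.high >= nyq:
        raise ValueError(f"band edge {band.high} Hz >= Nyquist ({nyq} Hz)")
    return sps.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")


def bandpass(segment: Segment, band: BandSpec, order: int = 4) -> Segment:
    """Zero-phase Butterworth band-pass of one segment.

    Returns a new segment of identical shape with ``band`` recorded.
    """
    sos = _band_sos(band, segment.fs, order)
    filtered = sps.sosfiltfilt(sos, segment.signals, axis=-1)
    return replace(segment, signals=filtered, band=band)


def bandpass_recording(recording: Recording, band: BandSpec, order: int = 4) -> Recording:
    """Zero-phase band-pass of a whole trial (filter-then-segment variant)."""
    sos = _band_sos(band, recording.fs, order)
    return replace(recording, signals=sps.sosfiltfilt(sos, recording.signals, axis=-1))


def segments_from_recording(
    recording: Recording,
    band: BandSpec,
    *,
    baseline_seconds: float = 3.0,
    seg_seconds: float = 3.0,
    filter_whole: bool = False,
) -> list[Segment]:
    """Full per-trial preprocessing: trim, segment, band-filter.

    ``filter_whole=True`` filters the trimmed 60-s trial before cutting it
    into windows; the default filters each window independently.
    """
    trimmed = trim_baseline(recording, baseline_seconds)
    if filter_whole:
        trimmed = bandpass_recording(trimmed, band, order=4)
        segs = segment_recording(trimmed, seg_seconds)
        return [replace(s, band=band) for s in segs]
    return [bandpass(s, band) for s in segment_recording(trimmed, seg_seconds)]
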