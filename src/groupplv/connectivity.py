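r"""Phase-locking value (PLV) connectivity from band-limited EEG.

For a real signal :math:`s(t)` the analytic signal is

.. math:: z(t) = s(t) + i\,H\{s(t)\} = A(t)\,e^{i\phi(t)}

with :math:`H` the Hilbert transform, :math:`A(t) = |z(t)|` the
instantaneous amplitude and :math:`\phi(t) = \arg z(t) \in [-\pi, \pi]`
the instantaneous phase (four-quadrant angle).  For two channels with
relative phase :math:`\phi_{12}(t) = \phi_1(t) - \phi_2(t)` sampled at
:math:`N` points, the phase-locking value is the length of the circular
mean of the phase differences,

.. math::

   \mathrm{PLV} = \sqrt{\Big[\tfrac1N\sum_j \sin\phi_{12}(j)\Big]^2
                       + \Big[\tfrac1N\sum_j \cos\phi_{12}(j)\Big]^2}
                = \Big|\tfrac1N\sum_j e^{i\phi_{12}(j)}\Big| \in [0, 1].

1 means a constant phase difference (perfect locking), 0 no phase
relationship.  Pairwise PLVs over all channels form a symmetric
adjacency matrix with unit diagonal, one per (segment, band).  Matrices
of all participants for the same stimulus window are element-wise
averaged into a single group matrix representing the collective
synchrony of the cohort.

The Hilbert transform is computed per 3-s segment without tapering or
padding; the resulting edge bias is bounded in tests with integer-cycle
tones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import hilbert

from .io import LabeledDataset
from .preprocess import BandSpec, Segment

__all__ = [
    "AnalyticSignal",
    "PLVMatrix",
    "analytic_phase",
    "relative_phase",
    "plv_pair",
    "plv_matrix",
    "group_average",
    "condition_average",
]


@dataclass(frozen=True)
class AnalyticSignal:
    """Instantaneous amplitude and phase of one channel."""

    amplitude: np.ndarray  # A(t) >= 0
    phase: np.ndarray  # phi(t) in [-pi, pi]
    fs: float


@dataclass(frozen=True)
class PLVMatrix:
    """Channels x channels PLV adjacency matrix for one band.

    ``level`` is "individual" (one participant, one segment), "group"
    (averaged over participants for one stimulus window) or
    "condition-mean" (averaged over all items of one label).
    """

    values: np.ndarray
    band: BandSpec
    level: str = "individual"
    participant: int | None = None
    video: int | None = None
    segment: int | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("PLV entries must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def analytic_phase(signal: np.ndarray, fs: float) -> AnalyticSignal:
    """Instantaneous amplitude and phase via the Hilbert analytic signal.

    Raises on an all-zero input, whose phase is undefined.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be 1-D with length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if not np.any(x):
        raise ValueError("phase of an all-zero signal is undefined")
    z = hilbert(x)
    return AnalyticSignal(amplitude=np.abs(z), phase=np.angle(z), fs=fs)


def relative_phase(phase1: np.ndarray, phase2: np.ndarray) -> np.ndarray:
    """Phase difference series phi1 - phi2 (unwrapped differences are
    unnecessary: the PLV takes sin/cos of it)."""
    p1, p2 = np.asarray(phase1), np.asarray(phase2)
    if p1.shape != p2.shape:
        raise ValueError("phase series length mismatch")
    return p1 - p2


def plv_pair(phase_difference: np.ndarray) -> float:
    """PLV of one phase-difference series: length of its circular mean."""
    d = np.asarray(phase_difference, dtype=float)
    if d.size == 0:
        raise ValueError("empty phase-difference series")
    return float(min(1.0, np.hypot(np.mean(np.sin(d)), np.mean(np.cos(d)))))


def plv_matrix(segment: Segment) -> PLVMatrix:
    """All-pairs PLV adjacency matrix of one band-filtered segment.

    Equivalent to ``plv_pair`` over every channel pair; implemented as a
    single complex Gram product ``|Z Z^H| / N`` with ``Z = exp(i phi)``.
    The diagonal is 1 by definition (self-synchrony).
    """
    if segment.band is None:
        raise ValueError("segment must be band-filtered before PLV")
    x = segment.signals
    z = hilbert(x, axis=-1)
    unit = z / np.abs(z)
    n = x.shape[1]
    plv = np.abs(unit @ unit.conj().T) / n
    plv = np.minimum((plv + plv.T) / 2.0, 1.0)
    np.fill_diagonal(plv, 1.0)
    return PLVMatrix(
        values=plv,
        band=segment.band,
        level="individual",
        participant=segment.participant,
        video=segment.video,
        segment=segment.index,
    )


def _check_same(matrices: Sequence[PLVMatrix], attrs: Iterable[str]) -> None:
    for a in attrs:
        vals = {getattr(m, a) for m in matrices}
        if len(vals) > 1:
            raise ValueError(f"matrices disagree on {a}: {vals}")


def group_average(matrices: Sequence[PLVMatrix]) -> PLVMatrix:
    """Element-wise mean over participants for one (video, segment, band).

    The result represents the whole cohort's synchrony for that stimulus
    window; PLV bounds, symmetry and the unit diagonal are preserved by
    convexity.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to average")
    _check_same(matrices, ("video", "segment"))
    _check_same(matrices, ("band",))
    mean = np.mean([m.values for m in matrices], axis=0)
    first = matrices[0]
    return PLVMatrix(
        values=mean,
        band=first.band,
        level="group",
        video=first.video,
        segment=first.segment,
        description=f"mean over {len(matrices)} participants",
    )


def condition_average(dataset: LabeledDataset, condition: str) -> PLVMatrix:
    """Mean matrix over all dataset items carrying one label.

    Produces the per-band high/low comparison maps (e.g. average PLV of
    the high-arousal condition).
    """
    picked = [m for m, lab in zip(dataset.matrices, dataset.labels) if lab == condition]
    if not picked:
        raise ValueError(f"no items with label {condition!r}")
    mean = np.mean([m.values for m in picked], axis=0)
    return PLVMatrix(
        values=mean,
        band=dataset.band,
        level="condition-mean",
        description=f"{dataset.dimension}={condition}, n={len(picked)}, level={dataset.level}",
    )
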